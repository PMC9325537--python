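import numpy as np
import pandas as pd
import pytest

from gnorms.io_norm import CountMatrix, NormalizedMatrix, SampleDesign


def make_design(genotypes=("g1", "g2"), envs=(0.0, 1.0, 2.0), reps=2,
                batches=1, **extra_cols):
    """Full-factorial design table: genotypes x envs x reps, batches cycled."""
    rows = []
    for g in genotypes:
        for ei, e in enumerate(envs):
            for r in range(reps):
                rows.append({
                    "sample_id": f"{g}_e{ei}_r{r}",
                    "genotype": g,
                    "environment": e,
                    "batch": f"b{(r % batches) + 1}",
                })
    df = pd.DataFrame(rows)
    for name, mapper in extra_cols.items():
        df[name] = df["genotype"].map(mapper)
    return SampleDesign(df)


def norm_from_values(values: np.ndarray, design: SampleDesign) -> NormalizedMatrix:
    """Wrap a genes x samples value array as a NormalizedMatrix (factors 1)."""
    values = np.atleast_2d(values)
    genes = [f"gene{i}" for i in range(values.shape[0])]
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=genes, columns=design.sample_ids),
        size_factors=pd.Series(1.0, index=design.sample_ids),
    )


def expression_from_norms(design: SampleDesign, intercepts: dict, slopes: dict,
                          batch_offsets: dict | None = None) -> np.ndarray:
    """Noise-free expression from per-genotype (intercept, slope) over env."""
    df = design.table
    y = np.array([
        intercepts[row.genotype] + slopes[row.genotype] * row.environment
        + (batch_offsets or {}).get(row.batch, 0.0)
        for row in df.itertuples()
    ])
    return y


@pytest.fixture
def toy_design():
    """2 genotypes x 3 environments x 2 replicates, one batch (12 samples)."""
    return make_design()


@pytest.fixture
def toy_counts():
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.poisson(50, size=(30, 6)) + 1,
        index=[f"gene{i}" for i in range(30)],
        columns=[f"s{j}" for j in range(6)],
    )
    return CountMatrix(data)
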