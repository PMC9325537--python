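"""Input, validation and normalization of count matrices and sample designs.

Counts are tab-separated tables (first column: gene id, remaining columns:
samples); sample designs are tab-separated tables with the required columns
``sample_id``, ``genotype``, ``environment``, ``batch`` and a small set of
recognized optional columns. Normalization uses median-of-ratios size factors
(computed over genes with no zero counts) followed by a log2 counts-per-million
transform with a pseudocount.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

#: design columns understood by the modelling layer
REQUIRED_DESIGN_COLUMNS = ("sample_id", "genotype", "environment", "batch")
OPTIONAL_DESIGN_COLUMNS = ("upper_genotype", "replicate_unit", "snp_group", "sv_group")
FITNESS_PREFIX = "fitness"


@dataclass
class CountMatrix:
    """Integer expression counts, genes x samples.

    ``data`` is indexed by gene id with one column per sample id. Construction
    validates uniqueness of identifiers, integrality and non-negativity.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups[:5]}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups[:5]}")
        if df.isna().any().any():
            gene, sample = _first_offender(df.isna())
            raise ValidationError(f"missing count for gene {gene!r}, sample {sample!r}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            frac = df != np.floor(df)
            if frac.any().any():
                gene, sample = _first_offender(frac)
                raise ValidationError(
                    f"non-integer count for gene {gene!r}, sample {sample!r}"
                )
            df = df.astype(np.int64)
        if (df.to_numpy() < 0).any():
            gene, sample = _first_offender(df < 0)
            raise ValidationError(f"negative count for gene {gene!r}, sample {sample!r}")
        df.index.name = "gene_id"
        df.columns.name = None
        self.data = df

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def write(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id")


def _first_offender(mask: pd.DataFrame) -> tuple[str, str]:
    stacked = mask.stack()
    gene, sample = stacked[stacked].index[0]
    return str(gene), str(sample)


@dataclass
class SampleDesign:
    """Per-sample factor assignments for a common-garden-gradient experiment.

    Houses the genotype (G), optional upper-scale genotype (nested designs),
    numeric environment (E), batch (B), optional replicate unit, optional
    SNP-cluster / SV-genotype architecture groupings and optional fitness
    phenotype columns (any column whose name starts with ``fitness``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in REQUIRED_DESIGN_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"design is missing required columns: {missing}")
        known = set(REQUIRED_DESIGN_COLUMNS) | set(OPTIONAL_DESIGN_COLUMNS)
        unknown = [
            c for c in df.columns
            if c not in known and not str(c).startswith(FITNESS_PREFIX)
        ]
        if unknown:
            raise ValidationError(f"unknown design columns: {unknown}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample_id in design: {dups[:5]}")
        try:
            df["environment"] = pd.to_numeric(df["environment"])
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"environment column is not numeric: {exc}") from exc
        for col in ("genotype", "batch"):
            df[col] = df[col].astype(str)
        if df["environment"].nunique() < 2:
            raise ValidationError("design needs at least 2 distinct environment values")
        env_per_geno = df.groupby("genotype")["environment"].nunique()
        thin = env_per_geno[env_per_geno < 2]
        if not thin.empty:
            raise ValidationError(
                "each genotype must be observed at >=2 environment values; "
                f"offending genotypes: {list(thin.index)}"
            )
        self.table = df.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.table["genotype"].unique())

    @property
    def env_levels(self) -> np.ndarray:
        return np.sort(self.table["environment"].unique())

    @property
    def fitness_columns(self) -> list[str]:
        return [c for c in self.table.columns if str(c).startswith(FITNESS_PREFIX)]

    def has(self, column: str) -> bool:
        return column in self.table.columns and self.table[column].notna().all()

    def aligned_to(self, counts: CountMatrix) -> "SampleDesign":
        """Reorder design rows to match the count matrix columns.

        Matching is by identifier, never by position.
        """
        missing = [s for s in counts.sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"samples in counts but not in design: {missing}")
        extra = [s for s in self.table.index if s not in counts.sample_ids]
        if extra:
            raise ValidationError(f"samples in design but not in counts: {extra}")
        return SampleDesign(self.table.loc[counts.sample_ids].reset_index(drop=True))

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class NormalizedMatrix:
    """log2-scale normalized expression with per-sample size factors."""

    values: pd.DataFrame
    size_factors: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        sf = self.size_factors
        if (sf <= 0).any():
            raise ValidationError("size factors must be strictly positive")
        gm = np.exp(np.mean(np.log(sf.to_numpy())))
        if abs(gm - 1.0) > 1e-9:
            raise ValidationError("size factors must have geometric mean 1")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("normalized values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def write(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> CountMatrix:
    """Read a tab-separated count table (first column gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix(df)


def read_counts_mtx(mtx_path, genes_path, samples_path) -> CountMatrix:
    """Read counts from a MatrixMarket triplet file plus id lists.

    ``genes_path`` and ``samples_path`` are one-id-per-line text files giving
    row and column identifiers respectively.
    """
    from pathlib import Path

    from scipy.io import mmread

    mat = mmread(mtx_path).toarray()
    genes = Path(genes_path).read_text().split()
    samples = Path(samples_path).read_text().split()
    if mat.shape != (len(genes), len(samples)):
        raise ValidationError(
            f"MTX shape {mat.shape} does not match {len(genes)} genes x "
            f"{len(samples)} samples"
        )
    return CountMatrix(pd.DataFrame(mat, index=genes, columns=samples))


def read_design(path) -> SampleDesign:
    """Read a tab-separated sample design table."""
    df = pd.read_csv(path, sep="\t")
    return SampleDesign(df)


def compute_size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors over zero-free reference genes.

    For each sample, the factor is the median across reference genes (genes
    with no zero count in any sample) of count / per-gene geometric mean;
    factors are rescaled to geometric mean 1. If no zero-free gene exists,
    falls back to total-count factors with a logged warning.
    """
    arr = counts.data.to_numpy(dtype=float)
    zero_free = (arr > 0).all(axis=1)
    if zero_free.any():
        logs = np.log(arr[zero_free])
        log_geo = logs.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logs - log_geo, axis=0))
    else:
        logger.warning(
            "no zero-free reference genes; falling back to total-count size factors"
        )
        libs = arr.sum(axis=0)
        if (libs <= 0).any():
            raise ValidationError("samples with zero total counts cannot be normalized")
        sf = libs
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.sample_ids, name="size_factor")


def normalize(counts: CountMatrix, pseudocount: float = 0.5) -> NormalizedMatrix:
    """log2 counts-per-million after size-factor correction.

    value = log2( (count / size_factor) / mean_adjusted_library * 1e6
                  + pseudocount )

    where ``mean_adjusted_library`` is the mean across samples of the
    size-factor-adjusted library size. The pseudocount (default 0.5) is
    applied on the CPM scale, which keeps normalized values exactly invariant
    to rescaling any single sample's counts.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    sf = compute_size_factors(counts)
    adj = counts.data.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    mean_lib = adj.sum(axis=0).mean()
    if mean_lib <= 0:
        raise ValidationError("count matrix has zero total counts")
    values = np.log2(adj / mean_lib * 1e6 + pseudocount)
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=counts.gene_ids, columns=counts.sample_ids),
        size_factors=sf,
    )


def pca_overview(norm: NormalizedMatrix, n_components: int = 2) -> pd.DataFrame:
    """Sample scores on the leading principal components (sanity check).

    Genes are centered across samples; scores are returned per sample for
    quick inspection of batch/condition structure.
    """
    x = norm.values.to_numpy()
    x = x - x.mean(axis=1, keepdims=True)
    # samples are observations: SVD of the samples x genes matrix
    u, s, _ = np.linalg.svd(x.T, full_matrices=False)
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    return pd.DataFrame(
        scores, index=norm.sample_ids, columns=[f"PC{i + 1}" for i in range(k)]
    )
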