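"""Co-expression module summaries and expression-fitness correlation.

Genes are clustered into co-expression modules by average-linkage
hierarchical clustering on the correlation distance (1 - Pearson), and each
module is summarized by the first principal-component score of its genes'
standardized expression — the module "eigengene" — oriented so the mean gene
loading is nonnegative. Module summaries re-enter the reaction-norm model
through the same matrix interface as genes.

Fitness phenotypes are analyzed at the genotype-unit level: a per-genotype
feature (mean expression, reaction-norm slope, or DP magnitude) is
correlated with a per-genotype fitness value, with significance from a
permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .exceptions import ValidationError
from .io_norm import NormalizedMatrix

UNASSIGNED = "unassigned"


@dataclass
class ModuleAssignment:
    """Gene -> module map plus per-module summary profiles.

    ``summaries`` is modules x samples; each row has zero mean across
    samples. Zero-variance genes live in the explicit ``unassigned`` bucket.
    """

    assignments: pd.Series
    summaries: pd.DataFrame

    @property
    def module_ids(self) -> list[str]:
        return list(self.summaries.index)

    def as_matrix(self) -> NormalizedMatrix:
        """Module summaries shaped like a normalized matrix for refitting."""
        return NormalizedMatrix(
            values=self.summaries.copy(),
            size_factors=pd.Series(1.0, index=self.summaries.columns),
        )

    def write(self, path) -> None:
        self.assignments.rename("module").to_csv(path, sep="\t", index_label="gene_id")


def summarize_modules(norm: NormalizedMatrix, k: int, seed: int = 0) -> ModuleAssignment:
    """Cluster genes into k co-expression modules and summarize each.

    ``seed`` is accepted for interface stability; the procedure (average
    linkage + SVD) is deterministic.
    """
    if k <= 1:
        raise ValidationError("k must be at least 2")
    x = norm.values.to_numpy(dtype=float)
    sd = x.std(axis=1)
    variable = sd > 1e-12
    if int(variable.sum()) <= k:
        raise ValidationError(
            f"k={k} must be smaller than the number of variable genes "
            f"({int(variable.sum())})")
    genes = np.asarray(norm.gene_ids)

    z = x[variable]
    z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
    corr = np.clip(np.corrcoef(z), -1.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    tree = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(tree, t=k, criterion="maxclust")

    assignments = pd.Series(UNASSIGNED, index=norm.gene_ids, name="module", dtype=object)
    assignments.loc[genes[variable]] = [f"M{int(lbl)}" for lbl in labels]

    summaries = {}
    for mod in sorted(set(labels)):
        zi = z[labels == mod]
        u, s, vt = np.linalg.svd(zi, full_matrices=False)
        score = vt[0] * s[0]
        if u[:, 0].mean() < 0:  # orient: mean gene loading >= 0
            score = -score
        summaries[f"M{mod}"] = score - score.mean()
    summary_df = pd.DataFrame(summaries, index=norm.sample_ids).T
    return ModuleAssignment(assignments=assignments, summaries=summary_df)


@dataclass
class FitnessCorrelation:
    """Pearson correlation of one feature with fitness across genotype units."""

    feature_id: str
    statistic: str
    r: float
    p_value: float
    n_perm: int
    n_units: int

    def defined(self) -> bool:
        return np.isfinite(self.r)


def correlate_fitness(feature: pd.Series, fitness: pd.Series,
                      statistic: str = "feature", n_perm: int = 1000,
                      seed: int = 0, feature_id: str = "feature") -> FitnessCorrelation:
    """Permutation-tested Pearson correlation across genotype units.

    The null is built by permuting fitness labels ``n_perm`` times;
    p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm), so the smallest
    attainable p is 1/(n_perm + 1). Constant feature or fitness vectors give
    an undefined (NaN) correlation.
    """
    units = feature.index.intersection(fitness.index)
    if len(units) < 3:
        raise ValidationError(
            "need >=3 genotype units with both feature and fitness values")
    x = feature.loc[units].to_numpy(dtype=float)
    y = fitness.loc[units].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        return FitnessCorrelation(feature_id, statistic, float("nan"),
                                  float("nan"), n_perm, len(units))
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    perms = np.stack([rng.permutation(yc) for _ in range(n_perm)])
    r_perm = perms @ xc / len(x)
    n_extreme = int((np.abs(r_perm) >= abs(r_obs) - 1e-12).sum())
    p = (1 + n_extreme) / (1 + n_perm)
    return FitnessCorrelation(feature_id, statistic, r_obs, p, n_perm, len(units))


def correlate_fitness_table(features: pd.DataFrame, fitness: pd.Series,
                            statistic: str = "feature", n_perm: int = 1000,
                            seed: int = 0) -> pd.DataFrame:
    """Correlate every column of a genotype-unit x feature table with fitness."""
    child_seeds = np.random.SeedSequence(seed).generate_state(features.shape[1])
    records = []
    for (name, col), s in zip(features.items(), child_seeds):
        res = correlate_fitness(col, fitness, statistic=statistic,
                                n_perm=n_perm, seed=int(s % (2**31)),
                                feature_id=str(name))
        records.append({
            "feature_id": res.feature_id, "statistic": res.statistic,
            "r": res.r, "p_value": res.p_value, "n_perm": res.n_perm,
            "n_units": res.n_units,
        })
    return pd.DataFrame(records)
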