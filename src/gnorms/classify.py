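"""Reaction norms, DE/DP directions and magnitudes, and pattern categories.

A gene's reaction norm is, per genotype, the (intercept, slope[, curvature])
of its fitted log2 expression over the environmental gradient, with the
intercept taken at the reference environment. From the norms we derive:

* DE — differential expression: genotypes differ in mean expression across
  the observed environment range (significant G term);
* plastic — expression changes along the gradient (significant E term);
* DP — differential plasticity: genotypes differ in slope (significant G:E).

Every gene is placed in one of 12 canonical categories, the cells of the grid
{DE yes/no} x {DP yes/no} x {mean environmental direction up/down/none}. The
grid axes are this package's operationalization of the field's DE / plastic /
DP vocabulary; panel-letter orderings used elsewhere are not reproduced.

Differentially plastic genes can additionally be labelled with an
evolutionary pattern relative to a user-designated ancestral-proxy genotype:

* reversal      — the genotypes' slopes have opposite signs;
* assimilation  — the derived genotype constitutively expresses the level the
  ancestral genotype only reaches plastically at the derived end of the
  gradient;
* compensation  — the derived genotype constitutively expresses the ancestral
  (pre-plastic) level, its intercept offset opposing the plastic direction.

The quantitative tau-based rules for these patterns are heuristics of this
package; they are controlled by a tolerance with log2-expression units.
"""

from __future__ import annotations

import logging
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DesignError, ValidationError
from .fit import BASIC, GeneFitTable

logger = logging.getLogger(__name__)

UP, DOWN, NONE = "up", "down", "none"
DIRECTIONS = (UP, DOWN, NONE)

#: canonical names for the 12 cells of {DE} x {DP} x {mean direction}
_CATEGORY_NAMES = {
    (False, False, NONE): "conserved",
    (False, False, UP): "plastic-up",
    (False, False, DOWN): "plastic-down",
    (True, False, NONE): "DE",
    (True, False, UP): "DE+plastic-up",
    (True, False, DOWN): "DE+plastic-down",
    (False, True, NONE): "DP-mean-none",
    (False, True, UP): "DP-mean-up",
    (False, True, DOWN): "DP-mean-down",
    (True, True, NONE): "DE+DP-mean-none",
    (True, True, UP): "DE+DP-mean-up",
    (True, True, DOWN): "DE+DP-mean-down",
}
CATEGORIES = tuple(_CATEGORY_NAMES.values())
NULL_CATEGORY = _CATEGORY_NAMES[(False, False, NONE)]

EVO_PATTERNS = ("compensation", "assimilation", "reversal", "none")

DeDp = namedtuple("DeDp", "de_magnitude de_direction dp_magnitude dp_direction")


def classify_gene(de_flag: bool, dp_flag: bool, mean_env_direction: str) -> str:
    """Map (DE flag, DP flag, mean environmental direction) to its category."""
    if mean_env_direction not in DIRECTIONS:
        raise ValidationError(f"direction must be one of {DIRECTIONS}")
    return _CATEGORY_NAMES[(bool(de_flag), bool(dp_flag), mean_env_direction)]


def category_of(de_flag: bool, dp_flag: bool, mean_slope: float, tol: float = 1e-9) -> str:
    """Noise-free categorization given exact flags and the across-genotype mean slope."""
    direction = NONE
    if abs(mean_slope) > tol:
        direction = UP if mean_slope > 0 else DOWN
    return classify_gene(de_flag, dp_flag, direction)


def true_category(intercepts, slopes, env_values, tol: float = 1e-9) -> str:
    """Category implied by exact per-genotype coefficients (the noise-free rule).

    DE iff genotype means over the observed environment values differ beyond
    ``tol``; DP iff slopes differ beyond ``tol``; direction from the mean
    slope across genotypes.
    """
    intercepts = np.asarray(intercepts, dtype=float)
    slopes = np.asarray(slopes, dtype=float)
    env = np.asarray(env_values, dtype=float)
    means = intercepts + slopes * env.mean()
    de = np.ptp(means) > tol
    dp = np.ptp(slopes) > tol
    return category_of(de, dp, float(slopes.mean()), tol=tol)


@dataclass
class ReactionNormSet:
    """Per-gene, per-genotype linear (or quadratic) reaction norms.

    ``norms`` is a long frame indexed by (gene_id, genotype) with columns
    intercept, slope, curvature; intercepts are log2 expression at the
    reference environment (centered coordinate 0). ``env_values`` are the
    observed environment levels in centered coordinates.
    """

    norms: pd.DataFrame
    env_values: np.ndarray
    reference_genotype: str
    reference_env: float

    @property
    def genotypes(self) -> list[str]:
        return list(self.norms.index.get_level_values("genotype").unique())

    def gene(self, gene_id: str) -> pd.DataFrame:
        return self.norms.loc[gene_id]

    def evaluate(self, env) -> pd.DataFrame:
        """Predicted log2 expression at centered environment values ``env``."""
        env = np.atleast_1d(np.asarray(env, dtype=float))
        vals = (
            self.norms["intercept"].to_numpy()[:, None]
            + self.norms["slope"].to_numpy()[:, None] * env[None, :]
            + self.norms["curvature"].to_numpy()[:, None] * env[None, :] ** 2
        )
        return pd.DataFrame(vals, index=self.norms.index, columns=env)

    def write(self, path) -> None:
        self.norms.to_csv(path, sep="\t")


def build_reaction_norms(fit: GeneFitTable) -> ReactionNormSet:
    """Assemble per-genotype norms from treatment-coded fit coefficients.

    The reference genotype's (intercept, slope) are the model intercept and E
    coefficient; other genotypes add their offset and interaction terms.
    Requires the basic model with numeric (linear or quadratic) environment
    coding — with categorical coding no slope is defined.
    """
    mm = fit.model
    if mm.formula_kind != BASIC:
        raise DesignError(
            "reaction norms are drawn per genotype from the basic model; "
            "refit with formula_kind='basic' at the genotype scale of interest"
        )
    if mm.env_coding not in ("linear", "quadratic"):
        raise DesignError("reaction norms require linear or quadratic environment coding")

    coef = fit.coef
    genes = fit.gene_ids
    quad = mm.env_coding == "quadratic"
    rows = []
    for g in mm.genotypes:
        intercept = coef["Intercept"].to_numpy().copy()
        slope = coef["E"].to_numpy().copy()
        curv = coef["E^2"].to_numpy().copy() if quad else np.zeros(len(genes))
        if g != mm.reference_genotype:
            intercept += coef[f"G[{g}]"].to_numpy()
            slope += coef[f"G[{g}]:E"].to_numpy()
            if quad:
                curv += coef[f"G[{g}]:E^2"].to_numpy()
        rows.append(pd.DataFrame(
            {"intercept": intercept, "slope": slope, "curvature": curv},
            index=pd.MultiIndex.from_product([genes, [g]], names=["gene_id", "genotype"]),
        ))
    norms = pd.concat(rows).sort_index()
    return ReactionNormSet(
        norms=norms,
        env_values=mm.env_values - mm.reference_env,
        reference_genotype=mm.reference_genotype,
        reference_env=mm.reference_env,
    )


def _mean_level(intercept, slope, curvature, env: np.ndarray):
    """Mean predicted expression over the observed environment values."""
    return intercept + slope * env.mean() + curvature * (env**2).mean()


def _mean_derivative(slope, curvature, env: np.ndarray):
    return slope + 2.0 * curvature * env.mean()


def _sign_dir(x: float, tol: float) -> str:
    if x > tol:
        return "+"
    if x < -tol:
        return "-"
    return NONE


def compute_de_dp(gene_norms: pd.DataFrame, reference: str,
                  comparison: str | None = None,
                  env_values=None, tol: float = 1e-12) -> DeDp:
    """DE and DP of one comparison genotype against the reference.

    de = comparison's mean expression over the observed environment range
    minus the reference's; dp = comparison slope minus reference slope
    (mean derivative if curvature is present). Directions are signs,
    magnitudes absolute values. With opposite-sign equal slopes +s/-s the DP
    magnitude is 2s; with same-sign slopes it is the difference of the slope
    magnitudes.
    """
    if reference not in gene_norms.index:
        raise ValidationError(f"reference genotype {reference!r} not in norms")
    others = [g for g in gene_norms.index if g != reference]
    if comparison is None:
        if len(others) != 1:
            raise ValidationError(
                "comparison genotype must be named when more than two genotypes "
                "are present; iterate pairs for post hoc contrasts"
            )
        comparison = others[0]
    if comparison not in gene_norms.index:
        raise ValidationError(f"comparison genotype {comparison!r} not in norms")
    env = np.asarray(env_values if env_values is not None else [0.0, 1.0], dtype=float)

    def row(g):
        r = gene_norms.loc[g]
        return float(r["intercept"]), float(r["slope"]), float(r.get("curvature", 0.0))

    a_ref, b_ref, c_ref = row(reference)
    a_cmp, b_cmp, c_cmp = row(comparison)
    de = _mean_level(a_cmp, b_cmp, c_cmp, env) - _mean_level(a_ref, b_ref, c_ref, env)
    dp = _mean_derivative(b_cmp, c_cmp, env) - _mean_derivative(b_ref, c_ref, env)
    return DeDp(abs(de), _sign_dir(de, tol), abs(dp), _sign_dir(dp, tol))


def classify_evo_pattern(ancestral_norm, derived_norm, env_values,
                         tau: float | None = None) -> str:
    """Evolutionary pattern of a differentially plastic gene pair.

    ``ancestral_norm`` / ``derived_norm`` are (intercept, slope[, curvature])
    sequences in centered environment coordinates; the ancestral genotype is
    assumed native to the low end of the observed gradient and the derived
    genotype to the high end. Slopes are assessed as total log2 change across
    the observed range so that slope and expression criteria share units.
    ``tau`` defaults to 25% of the ancestral total change.
    """
    env = np.asarray(env_values, dtype=float)
    lo, hi = float(env.min()), float(env.max())
    width = hi - lo
    if width <= 0:
        raise ValidationError("environment range must span more than one value")

    def unpack(norm):
        norm = tuple(np.atleast_1d(np.asarray(norm, dtype=float)))
        a, b = float(norm[0]), float(norm[1])
        c = float(norm[2]) if len(norm) > 2 else 0.0
        return a, b, c

    a_a, b_a, c_a = unpack(ancestral_norm)
    a_d, b_d, c_d = unpack(derived_norm)
    anc_change = _mean_derivative(b_a, c_a, env) * width
    der_change = _mean_derivative(b_d, c_d, env) * width
    if tau is None:
        tau = 0.25 * abs(anc_change)
    if tau <= 0:
        return "none"

    if abs(anc_change) > tau and abs(der_change) > tau and anc_change * der_change < 0:
        return "reversal"
    if abs(der_change) < tau:
        derived_mean = _mean_level(a_d, b_d, c_d, env)
        anc_at = lambda e: a_a + b_a * e + c_a * e**2
        if abs(derived_mean - anc_at(hi)) <= tau:
            return "assimilation"
        if abs(derived_mean - anc_at(lo)) <= tau:
            return "compensation"
    return "none"


@dataclass
class CategoryTable:
    """Per-gene flags, directions, magnitudes, category and evolutionary pattern."""

    table: pd.DataFrame
    alpha: float

    def summary(self) -> pd.DataFrame:
        counts = self.table["category"].value_counts()
        out = pd.DataFrame({
            "category": CATEGORIES,
            "n_genes": [int(counts.get(c, 0)) for c in CATEGORIES],
        })
        return out

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def categorize(fit: GeneFitTable, alpha: float | None = None,
               ancestral: str | None = None, tau: float | None = None,
               flags_override: pd.DataFrame | None = None) -> CategoryTable:
    """Assign every gene with a defined fit one of the 12 categories.

    Flags come from per-term BH q-values at ``alpha`` (default: the fit
    spec's alpha). The mean environmental direction is the sign of the
    across-genotype mean slope, reported only when the E term is significant
    or the gene is differentially plastic, and only when the mean slope
    itself is distinguishable from zero (t-test on the corresponding
    coefficient contrast at the same alpha).

    ``flags_override`` (columns de, dp, e; boolean, indexed by gene) replaces
    the q-value flags — used to propagate known truth in validation studies.
    ``ancestral`` names the ancestral-proxy genotype; when given,
    differentially plastic genes also get an evolutionary-pattern label
    (with >2 genotypes the derived norm is the mean across non-ancestral
    genotypes).
    """
    alpha = alpha if alpha is not None else fit.spec.alpha
    norms = build_reaction_norms(fit)
    mm = fit.model
    genes = fit.gene_ids
    genotypes = mm.genotypes
    n_g = len(genotypes)
    env = norms.env_values

    wide = norms.norms.unstack("genotype")  # columns (field, genotype)
    I = wide["intercept"][genotypes].to_numpy()
    S = wide["slope"][genotypes].to_numpy()
    C = wide["curvature"][genotypes].to_numpy()

    defined = fit.flags.str.len() == 0
    if flags_override is not None:
        de_flag = flags_override["de"].reindex(genes).to_numpy(dtype=bool)
        dp_flag = flags_override["dp"].reindex(genes).to_numpy(dtype=bool)
        e_flag = flags_override["e"].reindex(genes).to_numpy(dtype=bool)
    else:
        de_flag = (fit.term_q("G") < alpha).to_numpy()
        dp_flag = (fit.term_q("G:E") < alpha).to_numpy()
        e_flag = (fit.term_q("E") < alpha).to_numpy()
    mean_slope_sig = _mean_slope_significant(fit, alpha)

    mean_levels = I + S * env.mean() + C * (env**2).mean()
    mean_deriv = S + 2.0 * C * env.mean()
    ref_idx = genotypes.index(mm.reference_genotype)
    other = [i for i in range(n_g) if i != ref_idx]

    de_val = mean_levels[:, other].mean(axis=1) - mean_levels[:, ref_idx]
    dp_val = mean_deriv[:, other].mean(axis=1) - mean_deriv[:, ref_idx]
    mean_slope = mean_deriv.mean(axis=1)

    # a direction call needs the mean slope to be statistically nonzero AND
    # non-negligible against the slope heterogeneity across genotypes (25%,
    # matching the evolutionary-pattern tau default) — otherwise genotypes
    # with cancelling slopes would receive arbitrary directions
    tol = 1e-9
    slope_scale = np.ptp(mean_deriv, axis=1)
    slope_nonzero = (mean_slope_sig & (np.abs(mean_slope) > tol)
                     & (np.abs(mean_slope) >= 0.25 * slope_scale))
    gated = (e_flag | dp_flag) & slope_nonzero
    direction = np.where(gated, np.where(mean_slope > 0, UP, DOWN), NONE)

    categories = np.array([
        _CATEGORY_NAMES[(bool(d), bool(p), dirn)]
        for d, p, dirn in zip(de_flag, dp_flag, direction)
    ])

    de_dir = np.where(de_flag, np.where(de_val > tol, "+",
                      np.where(de_val < -tol, "-", NONE)), NONE)
    dp_dir = np.where(dp_flag, np.where(dp_val > tol, "+",
                      np.where(dp_val < -tol, "-", NONE)), NONE)

    evo = np.full(len(genes), "none", dtype=object)
    if ancestral is not None:
        if ancestral not in genotypes:
            raise ValidationError(f"ancestral genotype {ancestral!r} not in design")
        a_idx = genotypes.index(ancestral)
        d_idx = [i for i in range(n_g) if i != a_idx]
        for k in np.flatnonzero(dp_flag & defined.to_numpy()):
            anc = (I[k, a_idx], S[k, a_idx], C[k, a_idx])
            der = (I[k, d_idx].mean(), S[k, d_idx].mean(), C[k, d_idx].mean())
            evo[k] = classify_evo_pattern(anc, der, env, tau=tau)
    elif tau is not None:
        logger.warning("tau given without an ancestral genotype; pattern column omitted")

    table = pd.DataFrame({
        "de_flag": de_flag,
        "plastic_flag": e_flag,
        "dp_flag": dp_flag,
        "de_direction": de_dir,
        "mean_env_direction": direction,
        "dp_direction": dp_dir,
        "de_magnitude": np.abs(de_val),
        "dp_magnitude": np.abs(dp_val),
        "category": categories,
        "evo_pattern": evo,
    }, index=pd.Index(genes, name="gene_id"))
    table.loc[~defined, ["category", "evo_pattern"]] = np.nan
    n_dropped = int((~defined).sum())
    if n_dropped:
        logger.info("%d genes with undefined fits were not categorized", n_dropped)
    return CategoryTable(table=table, alpha=alpha)


def _mean_slope_significant(fit: GeneFitTable, alpha: float) -> np.ndarray:
    """t-test of the across-genotype mean slope contrast per gene."""
    mm = fit.model
    c = np.zeros(len(mm.columns))
    n_g = len(mm.genotypes)
    env = mm.env_values - mm.reference_env
    cols = {name: i for i, name in enumerate(mm.columns)}
    c[cols["E"]] = 1.0
    if "E^2" in cols:
        c[cols["E^2"]] = 2.0 * env.mean()
    for g in mm.genotypes:
        if g == mm.reference_genotype:
            continue
        c[cols[f"G[{g}]:E"]] = 1.0 / n_g
        if f"G[{g}]:E^2" in cols:
            c[cols[f"G[{g}]:E^2"]] = 2.0 * env.mean() / n_g
    _, _, _, p = fit.contrast(c)
    return p < alpha


def plot_reaction_norms(norms: ReactionNormSet, gene_ids, path=None, ncols: int = 4):
    """One panel per gene: genotype-colored fitted norms over the gradient."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gene_ids = list(gene_ids)
    ncols = min(ncols, max(1, len(gene_ids)))
    nrows = int(np.ceil(len(gene_ids) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.5 * nrows),
                             squeeze=False)
    grid = np.linspace(norms.env_values.min(), norms.env_values.max(), 50)
    for ax, gid in zip(axes.flat, gene_ids):
        sub = norms.gene(gid)
        for g, row in sub.iterrows():
            y = row["intercept"] + row["slope"] * grid + row["curvature"] * grid**2
            ax.plot(grid, y, label=str(g))
        ax.set_title(str(gid), fontsize=8)
    for ax in axes.flat[len(gene_ids):]:
        ax.axis("off")
    axes.flat[0].legend(fontsize=6)
    fig.supxlabel("environment (centered)")
    fig.supylabel("log2 expression")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
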