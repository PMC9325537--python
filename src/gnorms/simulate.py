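"""Synthetic common-garden-gradient RNA-seq experiments with known truth.

Generates a factorial design — G genotype units x E environment levels x R
replicates, spread over B batches — and negative-binomial counts whose log2
means follow per-gene, per-genotype linear reaction norms:

    log2 mean = baseline + genotype mean offset + slope * environment
                + batch offset + log2(library-size factor)

Each gene is first assigned one of the 12 pattern categories; category
membership then dictates which effects (genotype mean offsets, common slope,
slope deviations) are nonzero, so the generating truth and the downstream
classifier agree by construction. Gene-wise dispersions are log-normal, the
de facto description of bulk RNA-seq overdispersion; library sizes are
log-normal multiplicative offsets; batch offsets are gene-shared Gaussian
shifts on the log2 scale. A single integer seed drives all randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import classify
from .exceptions import DesignError, ValidationError
from .io_norm import CountMatrix, SampleDesign

#: default category mixture: null-heavy, with modest mass on every pattern
DEFAULT_CATEGORY_PROPORTIONS = {
    "conserved": 0.55,
    "plastic-up": 0.08,
    "plastic-down": 0.08,
    "DE": 0.08,
    "DE+plastic-up": 0.03,
    "DE+plastic-down": 0.03,
    "DP-mean-none": 0.03,
    "DP-mean-up": 0.03,
    "DP-mean-down": 0.03,
    "DE+DP-mean-none": 0.02,
    "DE+DP-mean-up": 0.02,
    "DE+DP-mean-down": 0.02,
}

_GRID_INV = {name: key for key, name in classify._CATEGORY_NAMES.items()}


@dataclass
class SimConfig:
    """Parameters of a simulated common-garden-gradient experiment.

    Effect sizes are on the log2 scale: ``effect_size_de`` is the difference
    in genotype mean expression, ``effect_size_slope`` the common change per
    environment unit of plastic genes, ``effect_size_dp`` the slope
    difference between genotypes of differentially plastic genes.
    """

    n_genes: int = 1000
    genotypes: tuple = ("g1", "g2", "g3")
    upper_groups: dict | None = None
    env_levels: tuple = (0.0, 1.0, 2.0)
    n_replicates_per_cell: int = 4
    n_batches: int = 2
    category_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROPORTIONS))
    effect_size_de: float = 1.0
    effect_size_slope: float = 0.5
    effect_size_dp: float = 0.5
    baseline_log2_mean_range: tuple = (2.0, 12.0)
    dispersion_meanlog: float = math.log(0.1)
    dispersion_sdlog: float = 0.5
    libsize_meanlog: float = 0.0
    libsize_sdlog: float = 0.2
    batch_effect_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be positive")
        if len(self.genotypes) < 2:
            raise ValidationError("at least 2 genotypes are required")
        if len(set(self.genotypes)) != len(self.genotypes):
            raise ValidationError("genotype labels must be unique")
        env = np.asarray(self.env_levels, dtype=float)
        if len(env) < 2 or not np.all(np.diff(env) > 0):
            raise ValidationError(
                "env_levels must be >=2 strictly increasing distinct values")
        if self.n_replicates_per_cell < 1 or self.n_batches < 1:
            raise ValidationError("replicate and batch counts must be >=1")
        unknown = set(self.category_proportions) - set(classify.CATEGORIES)
        if unknown:
            raise ValidationError(f"unknown category labels: {sorted(unknown)}")
        props = np.array(list(self.category_proportions.values()), dtype=float)
        if (props < 0).any():
            raise ValidationError("category proportions must be nonnegative")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"category proportions must sum to 1, got {props.sum():.12f}")
        for name in ("effect_size_de", "effect_size_slope", "effect_size_dp",
                     "dispersion_sdlog", "libsize_sdlog", "batch_effect_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.upper_groups is not None:
            missing = [g for g in self.genotypes if g not in self.upper_groups]
            if missing:
                raise ValidationError(f"upper_groups missing genotypes: {missing}")
        # categories with mass need the effect sizes that realize them
        for cat, prop in self.category_proportions.items():
            if prop <= 0:
                continue
            de, dp, direction = _GRID_INV[cat]
            if de and self.effect_size_de <= 0:
                raise ValidationError(f"category {cat!r} needs effect_size_de > 0")
            if direction != "none" and self.effect_size_slope <= 0:
                raise ValidationError(f"category {cat!r} needs effect_size_slope > 0")
            if dp and direction != "none" and self.effect_size_dp <= 0:
                raise ValidationError(f"category {cat!r} needs effect_size_dp > 0")
            if dp and direction == "none" and (
                    self.effect_size_slope <= 0 and self.effect_size_dp <= 0):
                raise ValidationError(
                    f"category {cat!r} needs effect_size_slope or effect_size_dp > 0")

    def n_samples(self) -> int:
        return len(self.genotypes) * len(self.env_levels) * self.n_replicates_per_cell

    def n_model_params(self) -> int:
        g, e = len(self.genotypes), 2  # intercept-like + slope-like per genotype
        return 1 + (g - 1) + 1 + (g - 1) + (self.n_batches - 1)


@dataclass
class SimTruth:
    """Ground truth for a simulated experiment.

    ``table`` has one row per gene: category, per-genotype true intercepts
    (log2 expression at environment 0 on the raw scale) and slopes, DE /
    plastic / DP flags and directions, and NB dispersion. ``batch_offsets``
    are the gene-shared log2 batch shifts.
    """

    table: pd.DataFrame
    batch_offsets: pd.Series
    config: SimConfig

    @property
    def categories(self) -> pd.Series:
        return self.table["category"]

    def genotype_coefficients(self, gene_id: str):
        row = self.table.loc[gene_id]
        genos = list(self.config.genotypes)
        intercepts = np.array([row[f"intercept_{g}"] for g in genos])
        slopes = np.array([row[f"slope_{g}"] for g in genos])
        return intercepts, slopes

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def truth_to_category(intercepts, slopes, env_levels, tol: float = 1e-9) -> str:
    """Category implied by exact coefficients — the classifier's noise-free rule."""
    return classify.true_category(intercepts, slopes, env_levels, tol=tol)


def _opposite_slope_pattern(n: int, s: float, rng: np.random.Generator) -> np.ndarray:
    """Slopes +s and -s (zeros pad n > 2), shuffled; mean exactly 0."""
    pat = np.concatenate([[s, -s], np.zeros(n - 2)])
    return rng.permutation(pat)


def _gene_effects(category: str, cfg: SimConfig, rng: np.random.Generator):
    """Per-genotype mean offsets and slopes realizing a category exactly.

    Effects follow the reference-intercept convention: the first genotype is
    the reference; each non-reference genotype of a DE gene is offset by
    +-effect_size_de in mean expression, and of a directional DP gene by
    +-effect_size_dp in slope. Mean-direction-none DP genes get
    opposite-sign slopes +-effect_size_slope (DP magnitude = 2 x slope).
    """
    de, dp, direction = _GRID_INV[category]
    n_g = len(cfg.genotypes)
    m = {"up": cfg.effect_size_slope, "down": -cfg.effect_size_slope, "none": 0.0}[direction]
    slopes = np.full(n_g, m)
    if dp:
        if direction == "none":
            s = cfg.effect_size_slope if cfg.effect_size_slope > 0 else cfg.effect_size_dp / 2
            slopes = _opposite_slope_pattern(n_g, s, rng)
        else:
            signs = rng.choice([-1.0, 1.0], size=n_g - 1)
            slopes = np.concatenate([[m], m + signs * cfg.effect_size_dp])
            # the across-genotype mean slope must keep the category's sign;
            # flip opposing genotypes until it does (all-aligned always works)
            while np.sign(slopes.mean()) != np.sign(m):
                opposing = np.flatnonzero(signs != np.sign(m))
                signs[opposing[0]] *= -1
                slopes = np.concatenate([[m], m + signs * cfg.effect_size_dp])
    mean_offsets = np.zeros(n_g)
    if de:
        mean_offsets = np.concatenate(
            [[0.0], rng.choice([-1.0, 1.0], size=n_g - 1) * cfg.effect_size_de])
    return mean_offsets, slopes, m


def simulate_experiment(config: SimConfig) -> tuple[CountMatrix, SampleDesign, SimTruth]:
    """Generate counts, design and ground truth for one experiment.

    Raises a design error when the factorial is too small to identify the
    basic per-gene model (total samples must exceed the parameter count).
    """
    cfg = config
    if cfg.n_samples() < cfg.n_model_params() + 1:
        raise DesignError(
            "design too small for model rank: "
            f"{cfg.n_samples()} samples for {cfg.n_model_params()} parameters; "
            "increase n_replicates_per_cell (or env levels)"
        )
    rng = np.random.default_rng(cfg.seed)
    env_levels = np.asarray(cfg.env_levels, dtype=float)
    e_bar = env_levels.mean()
    genos = list(cfg.genotypes)
    n_g = len(genos)

    # --- samples -----------------------------------------------------------
    rows = []
    for g in genos:
        for ei, e in enumerate(env_levels):
            for r in range(cfg.n_replicates_per_cell):
                batch = f"b{(r % cfg.n_batches) + 1}"
                sid = f"{g}_e{ei + 1}_r{r + 1}"
                row = {"sample_id": sid, "genotype": g, "environment": e,
                       "batch": batch, "replicate_unit": sid}
                if cfg.upper_groups is not None:
                    row["upper_genotype"] = cfg.upper_groups[g]
                rows.append(row)
    design_df = pd.DataFrame(rows)
    n_samples = len(design_df)

    # --- per-gene truth ----------------------------------------------------
    labels = list(cfg.category_proportions.keys())
    probs = np.array(list(cfg.category_proportions.values()), dtype=float)
    categories = rng.choice(labels, size=cfg.n_genes, p=probs)
    baselines = rng.uniform(*cfg.baseline_log2_mean_range, size=cfg.n_genes)
    dispersions = rng.lognormal(cfg.dispersion_meanlog, cfg.dispersion_sdlog,
                                size=cfg.n_genes)
    gene_ids = [f"gene{i + 1:05d}" for i in range(cfg.n_genes)]

    intercepts = np.empty((cfg.n_genes, n_g))
    slopes = np.empty((cfg.n_genes, n_g))
    for i, cat in enumerate(categories):
        mu_off, sl, m = _gene_effects(cat, cfg, rng)
        slopes[i] = sl
        # genotype mean over the env grid = baseline + mu_off + m * e_bar
        intercepts[i] = baselines[i] + mu_off + (m - sl) * e_bar

    # --- nuisance terms ----------------------------------------------------
    batch_names = [f"b{b + 1}" for b in range(cfg.n_batches)]
    batch_offsets = rng.normal(0.0, cfg.batch_effect_sd, size=cfg.n_batches)
    if cfg.n_batches == 1:
        batch_offsets[:] = 0.0
    lib_factors = rng.lognormal(cfg.libsize_meanlog, cfg.libsize_sdlog,
                                size=n_samples)

    # --- counts ------------------------------------------------------------
    geno_idx = design_df["genotype"].map({g: i for i, g in enumerate(genos)}).to_numpy()
    env = design_df["environment"].to_numpy()
    batch_idx = design_df["batch"].map(
        {b: i for i, b in enumerate(batch_names)}).to_numpy()

    log2_mu = (intercepts[:, geno_idx] + slopes[:, geno_idx] * env[None, :]
               + batch_offsets[batch_idx][None, :])
    mu = np.exp2(log2_mu) * lib_factors[None, :]
    size = 1.0 / dispersions  # NB shape: var = mu + dispersion * mu^2
    p = size[:, None] / (size[:, None] + mu)
    counts = rng.negative_binomial(size[:, None], p)

    count_matrix = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=design_df["sample_id"]))
    design = SampleDesign(design_df)

    # --- truth table -------------------------------------------------------
    tol = 1e-9
    means = intercepts + slopes * e_bar
    de_flag = np.ptp(means, axis=1) > tol
    dp_flag = np.ptp(slopes, axis=1) > tol
    plastic_flag = np.abs(slopes).max(axis=1) > tol
    mean_slope = slopes.mean(axis=1)

    def dir_of(vals):
        return np.where(vals > tol, "up", np.where(vals < -tol, "down", "none"))

    truth_df = pd.DataFrame({"category": categories}, index=gene_ids)
    for j, g in enumerate(genos):
        truth_df[f"intercept_{g}"] = intercepts[:, j]
        truth_df[f"slope_{g}"] = slopes[:, j]
    truth_df["de_flag"] = de_flag
    truth_df["de_direction"] = np.where(
        de_flag, dir_of(means[:, 1:].mean(axis=1) - means[:, 0]), "none")
    truth_df["plastic_flag"] = plastic_flag
    truth_df["plastic_direction"] = dir_of(np.where(plastic_flag, mean_slope, 0.0))
    truth_df["dp_flag"] = dp_flag
    truth_df["dp_direction"] = np.where(
        dp_flag, dir_of(slopes[:, 1:].mean(axis=1) - slopes[:, 0]), "none")
    truth_df["dispersion"] = dispersions

    truth = SimTruth(
        table=truth_df,
        batch_offsets=pd.Series(batch_offsets, index=batch_names, name="batch_offset"),
        config=cfg,
    )
    return count_matrix, design, truth


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a plain mapping (e.g. parsed YAML)."""
    d = dict(d)
    for key in ("genotypes", "env_levels", "baseline_log2_mean_range"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    unknown = set(d) - set(SimConfig.__dataclass_fields__)
    if unknown:
        raise ValidationError(f"unknown simulate config keys: {sorted(unknown)}")
    return SimConfig(**d)


def config_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    for key in ("genotypes", "env_levels", "baseline_log2_mean_range"):
        d[key] = list(d[key])
    return d
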