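"""Per-gene fixed-effect models for expression variation.

Each gene's log2-normalized expression is decomposed with ordinary least
squares into genotype (G), environment (E), genotype-by-environment (GxE) and
batch (B) components — the gene-expression analogue of a quantitative-trait
variance-component model:

    V_Px = V_G + V_E + V_GxE + B + error

Three formula kinds are supported:

* ``basic``        — G + E + G:E + B
* ``nested``       — upper-scale genotype G_j, genotype-within-upper G_i(G_j),
                     E, both interaction tiers, B
* ``architecture`` — SNP-cluster group + SV group + E + both groups' E
                     interactions + B

All factors are treatment-coded against an explicit reference level; the
environment is numeric and shifted so the reference level (by default the
minimum observed) maps to zero. This fixes the model intercept — the genotype
and environment all coefficient signs are expressed against — which is what
makes the downstream reaction-norm directions interpretable.

Per-term significance uses type-III partial F-tests computed on an equivalent
sum-to-zero (deviation) coded matrix spanning the same column space, with the
environment centered at the sample mean. This makes the tests invariant to
the choice of reference genotype and environment and aligns each test with
its concept: E tests the across-genotype average slope (plasticity), G the
genotype differences in mean expression at the average environment (DE), and
G:E the heterogeneity of slopes (DP). p-values are converted to
Benjamini-Hochberg q-values within each term across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DesignError, ValidationError
from .io_norm import NormalizedMatrix, SampleDesign

logger = logging.getLogger(__name__)

BASIC = "basic"
NESTED = "nested"
ARCHITECTURE = "architecture"
FORMULA_KINDS = (BASIC, NESTED, ARCHITECTURE)
ENV_CODINGS = ("linear", "quadratic", "categorical")

#: sequential term order used by variance_partition, per formula kind
TERM_ORDER = {
    BASIC: ("G", "E", "G:E", "B"),
    NESTED: ("G_upper", "G_within", "E", "G_upper:E", "G_within:E", "B"),
    ARCHITECTURE: ("G_snp", "G_sv", "E", "G_snp:E", "G_sv:E", "B"),
}

_RSS_TOL = 1e-10  # sum-of-squares below this (relative) is treated as exactly zero


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of the per-gene model.

    reference_genotype / reference_env define the model intercept; defaults
    are the first genotype in sorted order and the minimum observed
    environment. ``alpha`` is the per-term FDR threshold used downstream.
    """

    formula_kind: str = BASIC
    env_coding: str = "linear"
    reference_genotype: str | None = None
    reference_env: float | None = None
    batch_as: str = "fixed"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.formula_kind not in FORMULA_KINDS:
            raise ValidationError(f"formula_kind must be one of {FORMULA_KINDS}")
        if self.env_coding not in ENV_CODINGS:
            raise ValidationError(f"env_coding must be one of {ENV_CODINGS}")
        if self.batch_as != "fixed":
            raise ValidationError("only fixed-effect batch modelling is supported")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")


@dataclass
class Finding:
    level: str  # "error" | "warning"
    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.level}] {self.code}: {self.message}"


@dataclass
class ModelMatrix:
    """A fixed-effects design matrix with term bookkeeping.

    ``X`` is treatment-coded (interpretable coefficients); ``T`` is a
    deviation-coded matrix spanning the same column space, used for
    reference-invariant type-III term tests. ``terms`` / ``test_terms`` map
    term names to column indices of ``X`` / ``T`` respectively.
    """

    X: np.ndarray
    columns: list[str]
    terms: dict[str, list[int]]
    sample_ids: list[str]
    genotypes: list[str]
    reference_genotype: str
    reference_env: float
    env_values: np.ndarray  # distinct observed environment levels, raw scale
    env_coding: str
    formula_kind: str
    aliased_terms: list[str] = field(default_factory=list)
    T: np.ndarray = field(default=None, repr=False)
    test_terms: dict[str, list[int]] = field(default_factory=dict)

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.X))


def _dummy_columns(values: pd.Series, reference: str, name: str):
    """Treatment coding: one indicator per non-reference level."""
    levels = sorted(values.unique())
    if reference not in levels:
        raise ValidationError(f"reference level {reference!r} not found in {name}")
    cols, names = [], []
    for lv in levels:
        if lv == reference:
            continue
        cols.append((values == lv).to_numpy(dtype=float))
        names.append(f"{name}[{lv}]")
    return cols, names


def _deviation_columns(values: pd.Series, name: str):
    """Sum-to-zero coding; spans the same space independent of any reference."""
    levels = sorted(values.unique())
    last = levels[-1]
    cols, names = [], []
    for lv in levels[:-1]:
        col = (values == lv).to_numpy(dtype=float) - (values == last).to_numpy(dtype=float)
        cols.append(col)
        names.append(f"{name}.dev[{lv}]")
    return cols, names


def _env_columns(env: np.ndarray, center: float, coding: str,
                 reference_env: float | None = None, deviation: bool = False):
    e = env - center
    if coding == "linear":
        return [e], ["E"]
    if coding == "quadratic":
        return [e, e**2], ["E", "E^2"]
    # categorical environment: indicator coding against the reference level,
    # or sum-to-zero for the test matrix
    series = pd.Series(env)
    if deviation:
        cols, names = _deviation_columns(series.map(lambda v: f"{v:g}"), "E")
        return cols, names
    levels = np.sort(np.unique(env))
    if reference_env not in levels:
        raise ValidationError("reference_env must be an observed level for categorical coding")
    cols, names = [], []
    for lv in levels:
        if lv == reference_env:
            continue
        cols.append((env == lv).astype(float))
        names.append(f"E[{lv:g}]")
    return cols, names


def _interact(fac_cols, fac_names, env_cols, env_names):
    cols, names = [], []
    for fc, fn in zip(fac_cols, fac_names):
        for ec, en in zip(env_cols, env_names):
            cols.append(fc * ec)
            names.append(f"{fn}:{en}")
    return cols, names


def _assemble(design: SampleDesign, spec: ModelSpec, deviation: bool,
              ref_geno: str, ref_env: float):
    """Build one coding of the model matrix (treatment or sum-to-zero)."""
    df = design.table
    env = df["environment"].to_numpy(dtype=float)
    center = float(env.mean()) if deviation else ref_env

    cols = [np.ones(len(df))]
    names = ["Intercept"]
    terms: dict[str, list[int]] = {}

    def add_term(term: str, tcols, tnames) -> None:
        if not tcols:
            return
        start = len(cols)
        cols.extend(tcols)
        names.extend(tnames)
        terms[term] = list(range(start, start + len(tcols)))

    def factor(series, reference, name):
        if deviation:
            return _deviation_columns(series, name)
        return _dummy_columns(series, reference, name)

    env_cols, env_names = _env_columns(env, center, spec.env_coding,
                                       reference_env=ref_env, deviation=deviation)

    if spec.formula_kind == BASIC:
        g_cols, g_names = factor(df["genotype"], ref_geno, "G")
        add_term("G", g_cols, g_names)
        add_term("E", env_cols, env_names)
        add_term("G:E", *_interact(g_cols, g_names, env_cols, env_names))
    elif spec.formula_kind == NESTED:
        if not design.has("upper_genotype"):
            raise DesignError("nested model requires an upper_genotype column")
        upper = df["upper_genotype"].astype(str)
        mapping = df.groupby("genotype")["upper_genotype"].nunique()
        bad = mapping[mapping > 1]
        if not bad.empty:
            raise DesignError(
                f"genotypes assigned to multiple upper groups: {list(bad.index)}"
            )
        ref_upper = str(df.loc[df["genotype"] == ref_geno, "upper_genotype"].iloc[0])
        u_cols, u_names = factor(upper, ref_upper, "Gj")
        add_term("G_upper", u_cols, u_names)
        # genotype-within-upper: contrasts among each group's members
        w_cols, w_names = [], []
        for grp in sorted(upper.unique()):
            members = sorted(df.loc[upper == grp, "genotype"].unique())
            if deviation:
                last = members[-1]
                for m in members[:-1]:
                    w_cols.append((df["genotype"] == m).to_numpy(dtype=float)
                                  - (df["genotype"] == last).to_numpy(dtype=float))
                    w_names.append(f"Gi.dev[{m}]")
            else:
                ref_member = ref_geno if ref_geno in members else members[0]
                for m in members:
                    if m == ref_member:
                        continue
                    w_cols.append((df["genotype"] == m).to_numpy(dtype=float))
                    w_names.append(f"Gi[{m}]")
        add_term("G_within", w_cols, w_names)
        add_term("E", env_cols, env_names)
        add_term("G_upper:E", *_interact(u_cols, u_names, env_cols, env_names))
        add_term("G_within:E", *_interact(w_cols, w_names, env_cols, env_names))
    else:  # ARCHITECTURE
        for col in ("snp_group", "sv_group"):
            if not design.has(col):
                raise DesignError(f"architecture model requires a {col} column")
        snp = df["snp_group"].astype(str)
        sv = df["sv_group"].astype(str)
        s_cols, s_names = factor(snp, sorted(snp.unique())[0], "Gsnp")
        v_cols, v_names = factor(sv, sorted(sv.unique())[0], "Gsv")
        add_term("G_snp", s_cols, s_names)
        add_term("G_sv", v_cols, v_names)
        add_term("E", env_cols, env_names)
        add_term("G_snp:E", *_interact(s_cols, s_names, env_cols, env_names))
        add_term("G_sv:E", *_interact(v_cols, v_names, env_cols, env_names))

    b_cols, b_names = factor(df["batch"], sorted(df["batch"].unique())[0], "B")
    add_term("B", b_cols, b_names)
    return np.column_stack(cols), names, terms


def build_model_matrix(design: SampleDesign, spec: ModelSpec) -> ModelMatrix:
    """Construct the treatment-coded matrix plus its sum-to-zero test twin."""
    df = design.table
    env = df["environment"].to_numpy(dtype=float)
    ref_env = float(spec.reference_env) if spec.reference_env is not None else float(env.min())
    genotypes = sorted(df["genotype"].unique())
    ref_geno = spec.reference_genotype or genotypes[0]
    if ref_geno not in genotypes:
        raise ValidationError(f"reference genotype {ref_geno!r} not in design")

    X, names, terms = _assemble(design, spec, False, ref_geno, ref_env)
    T, _, test_terms = _assemble(design, spec, True, ref_geno, ref_env)

    mm = ModelMatrix(
        X=X,
        columns=names,
        terms=terms,
        sample_ids=list(df["sample_id"]),
        genotypes=genotypes,
        reference_genotype=ref_geno,
        reference_env=ref_env,
        env_values=np.sort(np.unique(env)),
        env_coding=spec.env_coding,
        formula_kind=spec.formula_kind,
        T=T,
        test_terms=test_terms,
    )
    # aliasing: a term whose columns add less rank than their count is confounded
    rank_full = mm.rank
    for term, idx in test_terms.items():
        keep = [i for i in range(T.shape[1]) if i not in idx]
        if rank_full - np.linalg.matrix_rank(T[:, keep]) < len(idx):
            mm.aliased_terms.append(term)
    return mm


def validate_design(design: SampleDesign, spec: ModelSpec) -> list[Finding]:
    """Check identifiability of the requested model on this design.

    Returns findings rather than raising; callers decide whether errors are
    fatal. Notable checks: quadratic (nonlinear) environment coding requires
    at least 3 distinct environment levels — with only 2 treatments a
    nonlinear reaction norm is unidentifiable — and G / G:E terms require at
    least 2 genotype levels.
    """
    findings: list[Finding] = []
    df = design.table
    n_env = df["environment"].nunique()
    n_geno = df["genotype"].nunique()

    if n_env < 2:
        findings.append(Finding("error", "env-levels",
                                "at least 2 distinct environment levels are required"))
    if spec.env_coding == "quadratic" and n_env < 3:
        findings.append(Finding(
            "error", "nonlinear-unidentifiable",
            "nonlinear reaction norm unidentifiable: quadratic environment "
            f"coding requires >=3 distinct environment levels, found {n_env}",
        ))
    if spec.env_coding == "categorical" and n_env < 2:
        findings.append(Finding("error", "env-levels",
                                "categorical environment coding requires >=2 levels"))
    if spec.formula_kind == BASIC and n_geno < 2:
        findings.append(Finding(
            "error", "single-genotype",
            "G and G:E terms are undefined with a single genotype level",
        ))
    if spec.formula_kind == NESTED:
        if not design.has("upper_genotype"):
            findings.append(Finding("error", "missing-upper",
                                    "nested model requires upper_genotype"))
        else:
            multi = df.groupby("genotype")["upper_genotype"].nunique()
            bad = multi[multi > 1]
            if not bad.empty:
                findings.append(Finding(
                    "error", "ambiguous-nesting",
                    f"genotypes in multiple upper groups: {list(bad.index)}"))
    if spec.formula_kind == ARCHITECTURE:
        for col in ("snp_group", "sv_group"):
            if not design.has(col):
                findings.append(Finding("error", "missing-architecture",
                                        f"architecture model requires {col}"))

    # empty genotype x environment cells leave the interaction poorly supported
    if n_geno >= 2 and n_env >= 2:
        cells = df.groupby(["genotype", "environment"]).size()
        full = pd.MultiIndex.from_product(
            [sorted(df["genotype"].unique()), np.sort(df["environment"].unique())]
        )
        empty = full.difference(cells.index)
        if len(empty):
            findings.append(Finding(
                "warning", "empty-cell",
                f"genotype x environment cells with no replicate: {list(empty)[:5]}"))

    if not any(f.level == "error" for f in findings):
        try:
            mm = build_model_matrix(design, spec)
        except (DesignError, ValidationError) as exc:
            findings.append(Finding("error", "matrix", str(exc)))
        else:
            if mm.aliased_terms and spec.formula_kind != ARCHITECTURE:
                findings.append(Finding(
                    "error", "rank-deficient",
                    f"model matrix is rank deficient; aliased terms: {mm.aliased_terms}"))
            elif mm.aliased_terms:
                findings.append(Finding(
                    "warning", "aliased",
                    f"aliased architecture terms (tests undefined): {mm.aliased_terms}"))
            if mm.X.shape[0] - mm.rank <= 0:
                findings.append(Finding(
                    "warning", "saturated",
                    "no residual degrees of freedom; term tests will be undefined"))
    return findings


@dataclass
class GeneFitTable:
    """Per-gene coefficient estimates and per-term tests.

    ``coef``/``se`` are genes x coefficient frames; ``tests`` holds, for every
    model term, columns ``<term>_F``, ``<term>_p``, ``<term>_q``. ``flags``
    marks genes whose tests are undefined (e.g. constant expression).
    """

    coef: pd.DataFrame
    se: pd.DataFrame
    tests: pd.DataFrame
    residual_var: pd.Series
    df_resid: int
    flags: pd.Series
    model: ModelMatrix
    spec: ModelSpec
    cov_unit: np.ndarray = field(repr=False, default=None)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.coef.index)

    def contrast(self, c: np.ndarray):
        """Estimate, SE, t and two-sided p for the linear combination c'beta."""
        c = np.asarray(c, dtype=float)
        est = self.coef.to_numpy() @ c
        var_unit = float(c @ self.cov_unit @ c)
        se = np.sqrt(np.maximum(var_unit * self.residual_var.to_numpy(), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = est / se
        if self.df_resid > 0:
            p = 2.0 * stats.t.sf(np.abs(t), self.df_resid)
        else:
            p = np.full_like(est, np.nan)
        # zero-residual fits: call the contrast exactly
        exact = se == 0
        p = np.where(exact & (np.abs(est) > 1e-9), 0.0, p)
        p = np.where(exact & (np.abs(est) <= 1e-9), 1.0, p)
        return est, se, t, p

    def term_q(self, term: str) -> pd.Series:
        return self.tests[f"{term}_q"]

    def to_frame(self) -> pd.DataFrame:
        out = pd.concat(
            [
                self.coef.add_suffix("__est"),
                self.se.add_suffix("__se"),
                self.tests,
            ],
            axis=1,
        )
        out["residual_var"] = self.residual_var
        out["flags"] = self.flags
        out.index.name = "gene_id"
        return out

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _bh(p: np.ndarray) -> np.ndarray:
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = stats.false_discovery_control(p[ok], method="bh")
    return q


def _fit_matrix(Y: np.ndarray, mm: ModelMatrix):
    """OLS of every gene on the shared design matrix; returns coefs and RSS."""
    pinv = np.linalg.pinv(mm.X)
    B = Y @ pinv.T
    resid = Y - B @ mm.X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    return B, rss, pinv


def fit_models(norm: NormalizedMatrix, design: SampleDesign, spec: ModelSpec) -> GeneFitTable:
    """Fit the per-gene model of the requested kind and test every term."""
    findings = validate_design(design, spec)
    errors = [f for f in findings if f.level == "error"]
    if errors:
        raise DesignError("; ".join(f.message for f in errors))
    for f in findings:
        logger.warning("%s", f)

    if list(norm.sample_ids) != list(design.table["sample_id"]):
        design = SampleDesign(
            design.table.loc[list(norm.sample_ids)].reset_index(drop=True)
        )
    mm = build_model_matrix(design, spec)
    Y = norm.values.to_numpy(dtype=float)
    genes = norm.gene_ids
    n, _ = mm.X.shape
    rank_full = mm.rank
    df_resid = n - rank_full

    B, rss, pinv = _fit_matrix(Y, mm)
    cov_unit = pinv @ pinv.T
    total_ss = np.einsum("ij,ij->i", Y - Y.mean(1, keepdims=True), Y - Y.mean(1, keepdims=True))
    constant = total_ss < 1e-12

    resid_var = rss / df_resid if df_resid > 0 else np.full(len(genes), np.nan)
    se = np.sqrt(np.outer(np.maximum(resid_var, 0.0), np.clip(np.diag(cov_unit), 0, None)))

    tests: dict[str, np.ndarray] = {}
    for term, idx in mm.test_terms.items():
        if term in mm.aliased_terms or df_resid <= 0:
            F = np.full(len(genes), np.nan)
            p = np.full(len(genes), np.nan)
        else:
            keep = [i for i in range(mm.T.shape[1]) if i not in idx]
            Xr = mm.T[:, keep]
            rank_r = int(np.linalg.matrix_rank(Xr))
            df_t = rank_full - rank_r
            if df_t == 0:
                F = np.full(len(genes), np.nan)
                p = np.full(len(genes), np.nan)
            else:
                Br = Y @ np.linalg.pinv(Xr).T
                rss_r = np.einsum("ij,ij->i", Y - Br @ Xr.T, Y - Br @ Xr.T)
                ss = np.clip(rss_r - rss, 0.0, None)
                denom = rss / df_resid
                with np.errstate(divide="ignore", invalid="ignore"):
                    F = (ss / df_t) / denom
                # zero-residual (noise-free) genes: decide the term exactly
                zero_resid = denom <= _RSS_TOL * np.maximum(total_ss, 1.0) / max(df_resid, 1)
                big = ss > _RSS_TOL * np.maximum(total_ss, 1.0)
                F = np.where(zero_resid, np.where(big, np.inf, 0.0), F)
                p = stats.f.sf(F, df_t, df_resid)
        p = np.where(constant, np.nan, p)
        F = np.where(constant, np.nan, F)
        tests[f"{term}_F"] = F
        tests[f"{term}_p"] = p
        tests[f"{term}_q"] = _bh(p)

    alias_note = "".join(f"|aliased:{t}" for t in mm.aliased_terms)
    flags = ["constant" + alias_note if c else alias_note.lstrip("|") for c in constant]

    return GeneFitTable(
        coef=pd.DataFrame(B, index=genes, columns=mm.columns),
        se=pd.DataFrame(se, index=genes, columns=mm.columns),
        tests=pd.DataFrame(tests, index=genes),
        residual_var=pd.Series(resid_var, index=genes, name="residual_var"),
        df_resid=df_resid,
        flags=pd.Series(flags, index=genes, name="flags"),
        model=mm,
        spec=spec,
        cov_unit=cov_unit,
    )


def fit_gene_models(norm, design, spec: ModelSpec | None = None) -> GeneFitTable:
    """Basic model: G + E + G:E + B."""
    spec = spec or ModelSpec()
    if spec.formula_kind != BASIC:
        spec = replace(spec, formula_kind=BASIC)
    return fit_models(norm, design, spec)


def fit_nested(norm, design, spec: ModelSpec | None = None) -> GeneFitTable:
    """Nested model: upper-scale genotype, genotype-within-upper, and their E tiers."""
    spec = spec or ModelSpec(formula_kind=NESTED)
    if spec.formula_kind != NESTED:
        spec = replace(spec, formula_kind=NESTED)
    return fit_models(norm, design, spec)


def fit_architecture(norm, design, spec: ModelSpec | None = None) -> GeneFitTable:
    """Architecture model: SNP-cluster and SV groupings with E interactions."""
    spec = spec or ModelSpec(formula_kind=ARCHITECTURE)
    if spec.formula_kind != ARCHITECTURE:
        spec = replace(spec, formula_kind=ARCHITECTURE)
    return fit_models(norm, design, spec)


def variance_partition(norm: NormalizedMatrix, design: SampleDesign,
                       spec: ModelSpec | None = None) -> pd.DataFrame:
    """Fraction of each gene's total sum of squares per model term.

    Sequential (type-I) sums of squares in the fixed order given by
    TERM_ORDER for the formula kind, plus a residual column; fractions sum
    to 1 for every gene with nonzero variance. Genes with zero total variance
    get NaN fractions.
    """
    spec = spec or ModelSpec()
    mm = build_model_matrix(design, spec)
    Y = norm.values.to_numpy(dtype=float)
    order = [t for t in TERM_ORDER[spec.formula_kind] if t in mm.terms]

    Yc = Y - Y.mean(axis=1, keepdims=True)
    total = np.einsum("ij,ij->i", Yc, Yc)

    cols = [0]  # intercept
    prev_rss = total.copy()
    ss = {}
    for term in order:
        cols = cols + mm.terms[term]
        Xk = mm.X[:, cols]
        Bk = Y @ np.linalg.pinv(Xk).T
        rss_k = np.einsum("ij,ij->i", Y - Bk @ Xk.T, Y - Bk @ Xk.T)
        ss[term] = np.clip(prev_rss - rss_k, 0.0, None)
        prev_rss = rss_k
    ss["residual"] = prev_rss

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = {k: np.where(total > 1e-12, v / total, np.nan) for k, v in ss.items()}
    return pd.DataFrame(frac, index=norm.gene_ids)
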