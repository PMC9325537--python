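"""Per-gene model fitting: exact recovery, term tests, design validation."""

import numpy as np
import pandas as pd
import pytest

from gnorms.exceptions import DesignError
from gnorms.fit import (
    ModelSpec,
    build_model_matrix,
    fit_architecture,
    fit_gene_models,
    fit_models,
    fit_nested,
    validate_design,
    variance_partition,
)

from conftest import expression_from_norms, make_design, norm_from_values


def errors(findings):
    return [f for f in findings if f.level == "error"]


class TestValidateDesign:
    def test_quadratic_rejected_at_two_env_levels(self):
        design = make_design(envs=(0.0, 1.0))
        found = validate_design(design, ModelSpec(env_coding="quadratic"))
        assert any("nonlinear reaction norm unidentifiable" in f.message
                   for f in errors(found))

    def test_quadratic_accepted_at_three_env_levels(self):
        design = make_design(envs=(0.0, 1.0, 2.0))
        found = validate_design(design, ModelSpec(env_coding="quadratic"))
        assert not errors(found)

    def test_single_genotype_rejected_for_basic_model(self):
        design = make_design(genotypes=("g1",))
        found = validate_design(design, ModelSpec())
        assert any("single genotype" in f.message.lower() or
                   "undefined" in f.message for f in errors(found))

    def test_empty_cell_warns(self):
        df = make_design(reps=1).table.reset_index(drop=True)
        df = df[~((df["genotype"] == "g2") & (df["environment"] == 2.0))]
        from gnorms.io_norm import SampleDesign
        found = validate_design(SampleDesign(df), ModelSpec())
        assert any(f.code == "empty-cell" and f.level == "warning" for f in found)


class TestBasicFit:
    def test_noise_free_coefficients_recovered_exactly(self, toy_design):
        # intercepts (5, 6), slopes (1, -1) over env 0..2
        y = expression_from_norms(toy_design, {"g1": 5, "g2": 6}, {"g1": 1, "g2": -1})
        fit = fit_gene_models(norm_from_values(y, toy_design), toy_design)
        coef = fit.coef.iloc[0]
        assert coef["Intercept"] == pytest.approx(5.0, abs=1e-10)
        assert coef["G[g2]"] == pytest.approx(1.0, abs=1e-10)
        assert coef["E"] == pytest.approx(1.0, abs=1e-10)
        assert coef["G[g2]:E"] == pytest.approx(-2.0, abs=1e-10)

    def test_balanced_batch_offset_recovered(self):
        design = make_design(batches=2)  # batches balanced within each cell
        y = expression_from_norms(design, {"g1": 5, "g2": 6}, {"g1": 1, "g2": -1},
                                  batch_offsets={"b1": 0.0, "b2": 0.3})
        fit = fit_gene_models(norm_from_values(y, design), design)
        coef = fit.coef.iloc[0]
        assert coef["B[b2]"] == pytest.approx(0.3, abs=1e-10)
        assert coef["G[g2]"] == pytest.approx(1.0, abs=1e-10)
        assert coef["E"] == pytest.approx(1.0, abs=1e-10)

    def test_noise_free_term_calls_are_exact(self, toy_design):
        y = expression_from_norms(toy_design, {"g1": 5, "g2": 6}, {"g1": 1, "g2": -1})
        fit = fit_gene_models(norm_from_values(y, toy_design), toy_design)
        t = fit.tests.iloc[0]
        # genotype means differ and slopes differ; the across-genotype mean
        # slope is exactly zero for slopes +1/-1, so E is (correctly) null
        assert t["G_p"] == 0.0 and t["G:E_p"] == 0.0 and t["E_p"] == 1.0

    def test_common_slope_hits_e_term_exactly(self, toy_design):
        y = expression_from_norms(toy_design, {"g1": 5, "g2": 5}, {"g1": 1, "g2": 1})
        fit = fit_gene_models(norm_from_values(y, toy_design), toy_design)
        t = fit.tests.iloc[0]
        assert t["E_p"] == 0.0 and t["G_p"] == 1.0 and t["G:E_p"] == 1.0

    def test_null_term_of_noise_free_gene_not_called(self, toy_design):
        y = expression_from_norms(toy_design, {"g1": 5, "g2": 5}, {"g1": 1, "g2": 1})
        fit = fit_gene_models(norm_from_values(y, toy_design), toy_design)
        t = fit.tests.iloc[0]
        assert t["G_p"] == 1.0 and t["G:E_p"] == 1.0 and t["E_p"] == 0.0

    def test_constant_gene_flagged_not_dropped(self, toy_design):
        y = np.vstack([
            np.full(len(toy_design.sample_ids), 3.0),
            expression_from_norms(toy_design, {"g1": 5, "g2": 6}, {"g1": 1, "g2": -1}),
        ])
        fit = fit_gene_models(norm_from_values(y, toy_design), toy_design)
        assert fit.flags.iloc[0] == "constant"
        assert np.isnan(fit.tests.iloc[0]["G_p"])
        assert fit.flags.iloc[1] == ""

    def test_reference_change_preserves_tests(self, toy_design):
        rng = np.random.default_rng(11)
        y = rng.normal(size=(20, len(toy_design.sample_ids)))
        f1 = fit_models(norm_from_values(y, toy_design), toy_design, ModelSpec())
        f2 = fit_models(norm_from_values(y, toy_design), toy_design,
                        ModelSpec(reference_genotype="g2", reference_env=2.0))
        for term in ("G", "E", "G:E"):
            np.testing.assert_allclose(f1.tests[f"{term}_F"], f2.tests[f"{term}_F"],
                                       rtol=1e-9, atol=1e-9)
        # coefficients differ but fitted values agree
        fitted1 = f1.coef.to_numpy() @ f1.model.X.T
        fitted2 = f2.coef.to_numpy() @ f2.model.X.T
        np.testing.assert_allclose(fitted1, fitted2, atol=1e-9)

    def test_ols_matches_normal_equations_oracle(self):
        # brute-force normal equations on an independently built matrix
        rng = np.random.default_rng(5)
        for trial in range(20):
            design = make_design(
                genotypes=("g1", "g2"), envs=(0.0, 1.0, 2.0),
                reps=int(rng.integers(2, 4)), batches=int(rng.integers(1, 3)))
            df = design.table
            n = len(df)
            X = np.column_stack([
                np.ones(n),
                (df["genotype"] == "g2").to_numpy(float),
                df["environment"].to_numpy(float),
                (df["genotype"] == "g2").to_numpy(float) * df["environment"].to_numpy(float),
            ] + ([(df["batch"] == "b2").to_numpy(float)] if df["batch"].nunique() > 1 else []))
            y = rng.normal(size=(3, n))
            beta = np.linalg.solve(X.T @ X, X.T @ y.T).T
            fit = fit_gene_models(norm_from_values(y, design), design)
            cols = ["Intercept", "G[g2]", "E", "G[g2]:E"] + (
                ["B[b2]"] if df["batch"].nunique() > 1 else [])
            np.testing.assert_allclose(fit.coef[cols].to_numpy(), beta, atol=1e-8)


class TestQuadraticCoding:
    def test_curvature_recovered_exactly(self):
        design = make_design(reps=2)
        df = design.table
        e = df["environment"].to_numpy()
        g2 = (df["genotype"] == "g2").to_numpy(float)
        y = 5.0 + 0.5 * e + 0.25 * e**2 + g2 * (1.0 - 0.3 * e**2)
        fit = fit_gene_models(norm_from_values(y, design), design,
                              ModelSpec(env_coding="quadratic"))
        coef = fit.coef.iloc[0]
        assert coef["E^2"] == pytest.approx(0.25, abs=1e-9)
        assert coef["G[g2]:E^2"] == pytest.approx(-0.3, abs=1e-9)

    def test_quadratic_reference_invariance(self):
        design = make_design(reps=2)
        rng = np.random.default_rng(14)
        y = rng.normal(size=(10, len(design.sample_ids)))
        f1 = fit_models(norm_from_values(y, design), design,
                        ModelSpec(env_coding="quadratic"))
        f2 = fit_models(norm_from_values(y, design), design,
                        ModelSpec(env_coding="quadratic",
                                  reference_genotype="g2", reference_env=1.0))
        for term in ("G", "E", "G:E"):
            np.testing.assert_allclose(f1.tests[f"{term}_F"],
                                       f2.tests[f"{term}_F"], rtol=1e-9)


class TestNestedFit:
    def _nested_design(self, reps=2):
        return make_design(
            genotypes=("a1", "a2", "b1", "b2"), reps=reps,
            upper_genotype={"a1": "A", "a2": "A", "b1": "B", "b2": "B"})

    def test_upper_intercept_shift_hits_upper_term_only(self):
        design = self._nested_design()
        inter = {"a1": 5, "a2": 5, "b1": 5.8, "b2": 5.8}
        slope = {g: 0.5 for g in inter}
        y = expression_from_norms(design, inter, slope)
        fit = fit_nested(norm_from_values(y, design), design)
        t = fit.tests.iloc[0]
        assert t["G_upper_p"] == 0.0
        assert t["G_within_p"] == 1.0
        assert fit.coef.iloc[0]["Gj[B]"] == pytest.approx(0.8, abs=1e-10)

    def test_upper_slope_difference_recovered_exactly(self):
        design = self._nested_design(reps=3)  # 2 upper x 2 lower x 3 env
        inter = {g: 5.0 for g in ("a1", "a2", "b1", "b2")}
        slope = {"a1": 0.2, "a2": 0.2, "b1": 1.1, "b2": 1.1}
        y = expression_from_norms(design, inter, slope)
        fit = fit_nested(norm_from_values(y, design), design)
        assert fit.coef.iloc[0]["Gj[B]:E"] == pytest.approx(0.9, abs=1e-10)
        assert fit.tests.iloc[0]["G_upper:E_p"] == 0.0
        assert fit.tests.iloc[0]["G_within:E_p"] == 1.0

    def test_single_upper_group_matches_basic_fit(self):
        design = make_design(genotypes=("g1", "g2"),
                             upper_genotype={"g1": "U", "g2": "U"})
        rng = np.random.default_rng(2)
        y = rng.normal(size=(5, len(design.sample_ids)))
        nested = fit_nested(norm_from_values(y, design), design)
        basic = fit_gene_models(norm_from_values(y, design), design)
        fitted_n = nested.coef.to_numpy() @ nested.model.X.T
        fitted_b = basic.coef.to_numpy() @ basic.model.X.T
        np.testing.assert_allclose(fitted_n, fitted_b, atol=1e-9)
        np.testing.assert_allclose(nested.tests["G_within_F"], basic.tests["G_F"],
                                   atol=1e-9)

    def test_genotype_in_two_upper_groups_rejected(self):
        df = self._nested_design().table.reset_index(drop=True)
        df.loc[df.index[0], "upper_genotype"] = "B"
        from gnorms.io_norm import SampleDesign
        with pytest.raises(DesignError, match="multiple upper"):
            fit_nested(norm_from_values(np.zeros((1, len(df))), SampleDesign(df)),
                       SampleDesign(df))


class TestArchitectureFit:
    def _arch_design(self, sv_map=None):
        sv_map = sv_map or {"g1": "sv1", "g2": "sv1", "g3": "sv2", "g4": "sv2"}
        return make_design(
            genotypes=("g1", "g2", "g3", "g4"),
            snp_group={"g1": "s1", "g2": "s2", "g3": "s1", "g4": "s2"},
            sv_group=sv_map)

    def test_orthogonal_groupings_recovered_exactly(self):
        design = self._arch_design()
        df = design.table
        y = (5.0 + 0.7 * (df["snp_group"] == "s2").to_numpy(float)
             + 0.4 * (df["sv_group"] == "sv2").to_numpy(float))
        fit = fit_architecture(norm_from_values(y, design), design)
        assert fit.coef.iloc[0]["Gsnp[s2]"] == pytest.approx(0.7, abs=1e-10)
        assert fit.coef.iloc[0]["Gsv[sv2]"] == pytest.approx(0.4, abs=1e-10)

    def test_identical_groupings_reported_aliased(self):
        design = self._arch_design(
            sv_map={"g1": "x1", "g2": "x2", "g3": "x1", "g4": "x2"})
        # sv_group now mirrors snp_group exactly -> aliased, not a crash
        rng = np.random.default_rng(0)
        y = rng.normal(size=(3, len(design.sample_ids)))
        fit = fit_architecture(norm_from_values(y, design), design)
        assert fit.model.aliased_terms
        aliased = fit.model.aliased_terms[0]
        assert np.isnan(fit.tests[f"{aliased}_p"]).all()
        assert fit.flags.str.contains("aliased").all()


class TestVariancePartition:
    def test_fractions_sum_to_one(self, toy_design):
        rng = np.random.default_rng(8)
        y = rng.normal(size=(50, len(toy_design.sample_ids)))
        vp = variance_partition(norm_from_values(y, toy_design), toy_design)
        np.testing.assert_allclose(vp.sum(axis=1), 1.0, atol=1e-9)

    def test_pure_genotype_gene_is_all_G(self, toy_design):
        y = expression_from_norms(toy_design, {"g1": 5, "g2": 7}, {"g1": 0, "g2": 0})
        vp = variance_partition(norm_from_values(y, toy_design), toy_design)
        assert vp.iloc[0]["G"] == pytest.approx(1.0, abs=1e-9)
        assert vp.iloc[0][["E", "G:E", "residual"]].abs().max() < 1e-9

    def test_pure_slope_gene_is_all_E(self, toy_design):
        y = expression_from_norms(toy_design, {"g1": 5, "g2": 5}, {"g1": 1, "g2": 1})
        vp = variance_partition(norm_from_values(y, toy_design), toy_design)
        assert vp.iloc[0]["E"] == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_gene_undefined(self, toy_design):
        y = np.full((1, len(toy_design.sample_ids)), 2.0)
        vp = variance_partition(norm_from_values(y, toy_design), toy_design)
        assert vp.iloc[0].isna().all()
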