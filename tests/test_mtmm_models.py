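"""Model builders: df arithmetic, structure, R-squared, invariance ladder."""

import numpy as np
import pandas as pd
import pytest

from gmintegrity.fit import fit
from gmintegrity.modelspec import ModelSpec
from gmintegrity.mtmm import (ROI_INDICATORS, add_age, correlational_spec,
                              covariate_adjusted_spec, invariance_ladder,
                              median_split, mtmm_measurement_spec, r_squared,
                              regression_spec, roi_cfa_spec)
from gmintegrity.ram import compile_ram, model_df
from gmintegrity.dataset import Dataset

from conftest import sample_from_spec


class TestDegreesOfFreedom:
    """Hand-counted moment arithmetic for every builder (t1-t4 skeleton)."""

    @pytest.mark.parametrize("spec,expected", [
        (mtmm_measurement_spec(), 64),
        (mtmm_measurement_spec(fix_md_mofc_residual=True), 65),
        (add_age(mtmm_measurement_spec(fix_md_mofc_residual=True)), 73),
        (correlational_spec(False), 120),
        (correlational_spec(True), 123),
        (regression_spec(), 123),
        # 20 observed -> 210 moments; 76 free covariance-structure params
        (covariate_adjusted_spec(("age",)), 134),
        (roi_cfa_spec("HC"), 0),
        # 21 moments - (5 loadings + 1 variance + 6 residuals)
        (roi_cfa_spec("PFC"), 9),
    ], ids=["mtmm", "mtmm-fixed", "age", "corr-free", "corr-zero",
            "regression", "covariate-age", "cfa-hc", "cfa-pfc"])
    def test_model_df(self, spec, expected):
        assert model_df(spec) == expected

    def test_mtmm_free_covariance_parameter_count(self):
        assert len(mtmm_measurement_spec().free_structure_labels()) == 56


class TestStructure:
    def test_pfc_has_six_indicators_others_three(self):
        assert len(ROI_INDICATORS["PFC"]) == 6
        for roi in ("HC", "PHG", "PRE"):
            assert len(ROI_INDICATORS[roi]) == 3

    def test_method_factors_orthogonal_to_traits(self):
        spec = mtmm_measurement_spec()
        trait = {"PFC", "HC", "PHG", "PRE"}
        method = {"VBM", "MT", "MD"}
        for c in spec.covs:
            assert not ({c.a, c.b} & trait and {c.a, c.b} & method)

    def test_reference_indicators(self):
        spec = mtmm_measurement_spec()
        fixed = {(p.src, p.dst) for p in spec.paths if p.value == 1.0}
        assert ("HC", "vbm_hc") in fixed
        assert ("VBM", "vbm_pre") in fixed
        assert ("MT", "mt_pre") in fixed
        assert ("MD", "md_pre") in fixed

    def test_roi_cfa_unknown_roi(self):
        with pytest.raises(ValueError, match="unknown ROI"):
            roi_cfa_spec("AMY")

    def test_add_age_rejects_double_add(self):
        spec = add_age(mtmm_measurement_spec(fix_md_mofc_residual=True))
        with pytest.raises(ValueError, match="already"):
            add_age(spec)


class TestRSquared:
    def _toy_regression(self, beta, n, seed):
        spec = ModelSpec(observed=["x1", "x2", "x3", "y1", "y2", "y3"],
                         latents=["F", "EM"])
        for ind, fixed in [("x1", 1.0), ("x2", None), ("x3", None)]:
            spec.add_loading("F", ind, fixed=fixed)
        for ind, fixed in [("y1", 1.0), ("y2", None), ("y3", None)]:
            spec.add_loading("EM", ind, fixed=fixed)
        spec.add_regression("EM", "F")
        spec.add_cov("F", "F", start=1.0)
        spec.add_cov("EM", "EM", start=1.0)
        for v in spec.observed:
            spec.add_cov(v, v)
        gen = ModelSpec.from_dict(spec.to_dict())
        # generating values: unit factor variance, residual closes EM var to 1
        ram = compile_ram(gen)
        th = np.zeros(ram.n_params)
        vals = {"v_F": 1.0, "v_EM": 1.0 - beta ** 2, "b_EM_F": beta,
                "l_F_x2": 0.9, "l_F_x3": 0.8, "l_EM_y2": 0.9, "l_EM_y3": 0.8}
        for k, lab in enumerate(ram.param_names):
            th[k] = vals.get(lab, 0.5 if lab.startswith("v_") else 0.0)
        frame = sample_from_spec(gen, th, n, seed)
        return fit(spec, frame, compute_se=False)

    def test_single_predictor_closed_form(self):
        fr = self._toy_regression(beta=0.5, n=5000, seed=30)
        assert r_squared(fr) == pytest.approx(0.25, abs=0.03)

    def test_zero_weights_give_zero(self):
        fr = self._toy_regression(beta=0.0, n=5000, seed=31)
        assert r_squared(fr) == pytest.approx(0.0, abs=0.01)

    def test_unknown_outcome(self):
        fr = self._toy_regression(beta=0.3, n=500, seed=32)
        with pytest.raises(ValueError):
            r_squared(fr, outcome="nope")


@pytest.fixture(scope="module")
def grouped_data(two_factor_spec):
    from conftest import two_factor_theta
    ram = compile_ram(two_factor_spec)
    th = two_factor_theta(ram)
    a = sample_from_spec(two_factor_spec, th, 600, seed=33)
    b = sample_from_spec(two_factor_spec, th, 600, seed=34)
    frame = pd.concat([a, b], ignore_index=True)
    frame["grp"] = [0] * 600 + [1] * 600
    return Dataset(frame, {"grp": "group"})


class TestInvariance:

    def test_metric_step_delta_df_equals_equated_loadings(self, two_factor_spec,
                                                          grouped_data):
        fits, tests = invariance_ladder(two_factor_spec, grouped_data, "grp",
                                        levels=("configural", "metric"))
        # 4 free loadings equated across 2 groups
        assert tests["metric"].delta_df == 4
        assert fits["configural"].df + 4 == fits["metric"].df

    def test_null_population_not_rejected(self, two_factor_spec, grouped_data):
        _, tests = invariance_ladder(two_factor_spec, grouped_data, "grp",
                                     levels=("configural", "metric", "scalar"))
        assert tests["metric"].p_value > 0.001
        assert tests["scalar"].p_value > 0.001

    def test_scalar_step_frees_latent_means(self, two_factor_spec, grouped_data):
        fits, _ = invariance_ladder(two_factor_spec, grouped_data, "grp",
                                    levels=("configural", "metric", "scalar"))
        names = fits["scalar"].params.index
        assert "alpha_F.g1" in names and "alpha_F.g0" not in names
        # scalar adds (p - m)(G - 1) = (6 - 2) * 1 df over metric
        assert fits["scalar"].df - fits["metric"].df == 4

    def test_unequal_loadings_detected(self, two_factor_spec):
        from conftest import two_factor_theta
        ram = compile_ram(two_factor_spec)
        th = two_factor_theta(ram)
        th2 = th.copy()
        th2[ram.index_of("l_F_x2")] += 0.4
        a = sample_from_spec(two_factor_spec, th, 1000, seed=35)
        b = sample_from_spec(two_factor_spec, th2, 1000, seed=36)
        frame = pd.concat([a, b], ignore_index=True)
        frame["grp"] = [0] * 1000 + [1] * 1000
        ds = Dataset(frame, {"grp": "group"})
        _, tests = invariance_ladder(two_factor_spec, ds, "grp",
                                     levels=("configural", "metric"))
        assert tests["metric"].p_value < 0.05

    def test_median_split_ties_to_lower_group(self):
        s = pd.Series([1.0, 2.0, 2.0, 3.0, 4.0])
        out = median_split(s)
        assert out.tolist() == [0, 0, 0, 1, 1]

    def test_small_group_rejected(self, two_factor_spec, grouped_data):
        ds = Dataset(grouped_data.frame.iloc[:610].copy(), dict(grouped_data.roles))
        with pytest.raises(ValueError, match="fewer than"):
            invariance_ladder(two_factor_spec, ds, "grp")
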