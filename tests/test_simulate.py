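"""Generator: defaults, closed-form moments vs sampling, missingness design."""

import numpy as np
import pandas as pd
import pytest

from gmintegrity.simulate import (MEMORY_INDICATORS, MR_INDICATORS,
                                  SimulationConfig, apply_missingness,
                                  default_base2_config, emit_raw_scale,
                                  generate_complete, population_moments)


class TestDefaultConfig:
    def test_sample_sizes_and_missing_fraction(self, base_config):
        assert base_config.n_total == 1522
        assert base_config.n_mr == 333
        frac = (base_config.n_total - base_config.n_mr) / base_config.n_total
        assert frac == pytest.approx(0.7812, abs=5e-5)

    def test_published_factor_correlations(self, base_config):
        phi = base_config.roi_factor_cov
        # order PFC, HC, PHG, PRE
        assert phi[1, 2] == pytest.approx(0.84)
        assert phi[0, 2] == pytest.approx(0.68)
        assert phi[0, 1] == pytest.approx(0.59)
        assert phi[2, 3] == pytest.approx(0.37)
        m = base_config.method_factor_cov  # order VBM, MT, MD
        assert m[0, 2] == pytest.approx(-0.53)
        assert m[1, 2] == pytest.approx(-0.77)
        assert m[0, 1] == pytest.approx(0.25)

    def test_covariate_effects_from_published_table(self, base_config):
        eff = base_config.covariate_effects
        assert eff["age"]["HC"] == pytest.approx(-0.28)
        assert eff["education"]["EM"] == pytest.approx(0.29)

    def test_loading_ranges(self, base_config):
        roi = [v for _, v in base_config.roi_loadings.values()]
        assert all(0.27 <= abs(v) <= 0.86 for v in roi)
        assert all(v < 0 for ind, (_, v) in base_config.roi_loadings.items()
                   if ind.startswith("md_"))
        meth = [v for _, v in base_config.method_loadings.values()]
        assert all(abs(v) > 0.18 for v in meth)

    def test_validation_rejects_bad_configs(self, base_config):
        import dataclasses
        bad = dataclasses.replace(base_config, n_mr=2000)
        with pytest.raises(ValueError, match="n_mr"):
            bad.validate()
        bad = dataclasses.replace(base_config, missingness={"vbm": 1.2})
        with pytest.raises(ValueError, match="probability"):
            bad.validate()
        phi = base_config.roi_factor_cov.copy()
        phi[0, 1] = phi[1, 0] = 1.5  # impossible correlation
        bad = dataclasses.replace(base_config, roi_factor_cov=phi)
        with pytest.raises(ValueError, match="positive definite"):
            bad.validate()


class TestPopulationMoments:
    def test_single_factor_closed_form(self):
        # one indicator, loading 1, factor var 1, residual var 1 -> var 2
        cfg = default_base2_config()
        lam = cfg.loading_matrix()
        phi = cfg.factor_corr()
        theta = cfg.residual_cov()
        var_vbm_hc = lam[0] @ phi @ lam[0] + theta[0, 0]
        # by construction every indicator variance is indicator_sd^2
        assert var_vbm_hc == pytest.approx(cfg.indicator_sd ** 2, abs=1e-10)

    def test_moments_match_sampling_oracle(self, base_config):
        mu, cov = population_moments(base_config)
        n = 200_000
        ds = generate_complete(base_config, n, seed=101)
        emp_mean = ds.frame[mu.index].mean()
        emp_cov = ds.frame[mu.index].cov()
        sds = np.sqrt(np.diag(cov.values))
        # elementwise Monte-Carlo SE of a covariance ~ sqrt((s_ii s_jj + s_ij^2)/n)
        se_cov = np.sqrt((np.outer(np.diag(cov), np.diag(cov))
                          + cov.values ** 2) / n)
        assert (np.abs(emp_cov.values - cov.values) < 3.5 * se_cov).all()
        se_mean = sds / np.sqrt(n)
        assert (np.abs(emp_mean.values - mu.values) < 4 * se_mean).all()

    def test_zero_covariate_effects_decouple_age(self, base_config):
        import dataclasses
        cfg = dataclasses.replace(base_config, covariate_effects={})
        mu, cov = population_moments(cfg)
        np.testing.assert_allclose(cov.loc["age", list(MR_INDICATORS)], 0.0,
                                   atol=1e-12)
        ds = generate_complete(cfg, 50_000, seed=7)
        r = ds.frame.corr().loc["age", list(MR_INDICATORS)]
        assert (np.abs(r) < 4 / np.sqrt(50_000)).all()


class TestGenerateComplete:
    def test_deterministic_given_seed(self, base_config):
        a = generate_complete(base_config, 200, seed=42)
        b = generate_complete(base_config, 200, seed=42)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_columns_and_roles(self, base_config):
        ds = generate_complete(base_config, 10, seed=0)
        assert set(MR_INDICATORS) <= set(ds.columns)
        assert set(MEMORY_INDICATORS) <= set(ds.columns)
        assert ds.role_of("age") == "covariate"
        assert ds.role_of("pid") == "id"
        assert ds.n == 10
        ds.validate()

    def test_csv_roundtrip_byte_identical(self, base_config, tmp_path):
        from gmintegrity.dataset import Dataset
        ds = apply_missingness(generate_complete(base_config, 100, seed=9),
                               base_config, seed=10)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        ds.to_csv(p1)
        ds.to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = Dataset.read_csv(p1, roles=dict(ds.roles))
        pd.testing.assert_frame_equal(back.frame, ds.frame)


class TestApplyMissingness:
    def test_no_masking_when_probabilities_one(self, base_config):
        import dataclasses
        cfg = dataclasses.replace(
            base_config, n_mr=base_config.n_total,
            missingness={k: 1.0 for k in base_config.missingness})
        ds = generate_complete(cfg, cfg.n_total, seed=3)
        out = apply_missingness(ds, cfg, seed=4)
        pd.testing.assert_frame_equal(out.frame, ds.frame)

    def test_observed_counts_near_design(self, base_config):
        ds = apply_missingness(generate_complete(base_config, seed=21),
                               base_config, seed=22)
        counts = ds.frame[["vbm_hc", "mt_hc", "md_hc"]].notna().sum()
        # binomial 99% interval around the design counts within n_mr = 333
        for col, target, p in [("vbm_hc", 330, 330 / 333),
                               ("mt_hc", 197, 197 / 333),
                               ("md_hc", 274, 274 / 333)]:
            half = 2.58 * np.sqrt(333 * p * (1 - p))
            assert abs(counts[col] - target) <= half + 1
        mem = ds.frame[list(MEMORY_INDICATORS)].notna().sum()
        assert ((mem - 1500).abs() <= 2.58 * np.sqrt(1522 * (22 / 1522) * (1500 / 1522)) + 1).all()

    def test_block_structure_within_modality(self, base_config):
        ds = apply_missingness(generate_complete(base_config, seed=31),
                               base_config, seed=32)
        for m in ("vbm", "mt", "md"):
            cols = [c for c in MR_INDICATORS if c.startswith(m + "_")]
            mask = ds.frame[cols].isna()
            # a row is either fully observed or fully missing on the block
            assert ((mask.sum(axis=1) == 0) | (mask.sum(axis=1) == len(cols))).all()

    def test_sex_selectivity_is_mar(self, base_config):
        # selection depends on observed sex only: the female share in the MR
        # subsample tracks the configured value, and conditional on sex the
        # latent generating draws of masked vs unmasked rows agree
        ds0 = generate_complete(base_config, 20_000, seed=41)
        import dataclasses
        cfg = dataclasses.replace(base_config, n_total=20_000,
                                  n_mr=int(20_000 * 333 / 1522))
        ds = apply_missingness(ds0, cfg, seed=42)
        mr = ds.frame["vbm_hc"].notna() | ds.frame["mt_hc"].notna() | ds.frame["md_hc"].notna()
        share = ds.frame.loc[mr, "sex"].mean()
        assert share == pytest.approx(cfg.sex_p_mr, abs=0.03)
        for sex in (0.0, 1.0):
            sel = ds0.frame["sex"] == sex
            a = ds0.frame.loc[sel & mr, "vlmt"]
            b = ds0.frame.loc[sel & ~mr, "vlmt"]
            pooled = np.sqrt(a.var() / len(a) + b.var() / len(b))
            assert abs(a.mean() - b.mean()) < 4 * pooled

    def test_bad_probability_rejected(self, base_config):
        import dataclasses
        cfg = dataclasses.replace(base_config, missingness={"vbm": -0.1})
        ds = generate_complete(base_config, 50, seed=1)
        with pytest.raises(ValueError, match="probability"):
            apply_missingness(ds, cfg, seed=2)


class TestRawScale:
    def test_affine_map_to_published_scales(self, base_config):
        ds = generate_complete(base_config, 20_000, seed=55)
        raw = emit_raw_scale(ds, base_config)
        assert raw.frame["vbm_hc"].mean() == pytest.approx(0.5218, abs=0.002)
        assert raw.frame["vbm_hc"].std() == pytest.approx(0.0458, rel=0.05)
        assert raw.frame["md_hc"].mean() == pytest.approx(0.0014, abs=1e-5)

    def test_icv_component_is_removable(self, base_config):
        from gmintegrity.prep import adjust_for_icv
        ds = generate_complete(base_config, 5000, seed=56)
        raw = emit_raw_scale(ds, base_config, include_icv=True, seed=57)
        vol = raw.frame["vbm_hc"].to_numpy()
        icv = raw.frame["icv"].to_numpy()
        assert abs(np.corrcoef(vol, icv)[0, 1]) > 0.2
        adj = adjust_for_icv(vol, icv, vol, icv)
        assert abs(np.corrcoef(adj, icv)[0, 1]) < 1e-10
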