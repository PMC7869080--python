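"""Preparation operators: MTR, ICV adjustment, outliers, rescaling,
selectivity and exclusion accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmintegrity.dataset import Dataset
from gmintegrity.prep import (adjust_for_icv, compute_mtr,
                              detect_multivariate_outliers,
                              exclusion_accounting, rescale, selectivity,
                              selectivity_table)


class TestMtr:
    @pytest.mark.parametrize("no_mt,mt,expected", [
        (2.0, 1.0, 0.5),
        (3.7, 3.7, 0.0),                 # identical signals -> no transfer
        (1.0, 0.64419, 0.35581),         # cortical-scale ratio, direct arithmetic
    ])
    def test_scalar_values(self, no_mt, mt, expected):
        assert compute_mtr(no_mt, mt) == pytest.approx(expected, abs=1e-12)

    def test_elementwise_and_zero_denominator(self):
        out = compute_mtr([2.0, 4.0], [1.0, 3.0])
        np.testing.assert_allclose(out, [0.5, 0.25])
        with pytest.raises(ValueError, match="zero"):
            compute_mtr([1.0, 0.0], [0.5, 0.1])


class TestIcvAdjustment:
    def test_hand_ols(self):
        # slope 1, mean ICV 2: adjusted = 2 - 1*(3-2) = 1
        ref_v, ref_i = [1.0, 2.0, 3.0], [1.0, 2.0, 3.0]
        assert adjust_for_icv(2.0, 3.0, ref_v, ref_i) == pytest.approx(1.0)

    def test_zero_slope_leaves_raw(self):
        rng = np.random.default_rng(0)
        icv = rng.normal(size=200)
        vol = np.full(200, 3.0)  # no association
        out = adjust_for_icv(vol, icv, vol, icv)
        np.testing.assert_allclose(out, vol)

    def test_orthogonality_on_reference_sample(self):
        rng = np.random.default_rng(1)
        icv = rng.normal(1450, 150, 400)
        vol = 0.5 + 1e-4 * icv + rng.normal(0, 0.03, 400)
        adj = adjust_for_icv(vol, icv, vol, icv)
        assert abs(np.corrcoef(adj, icv)[0, 1]) < 1e-10

    def test_degenerate_reference(self):
        with pytest.raises(ValueError, match="slope undefined"):
            adjust_for_icv(1.0, 1.0, [1, 2, 3], [2, 2, 2])
        with pytest.raises(ValueError, match="3 finite"):
            adjust_for_icv(1.0, 1.0, [1, 2], [1, 2])


class TestOutliers:
    def test_null_data_flags_almost_nothing(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((500, 4))
        rep = detect_multivariate_outliers(pd.DataFrame(x), p_cutoff=1e-4)
        assert len(rep.flagged) <= 1          # expected 500 * 1e-4 = 0.05
        assert rep.n_complete == 500

    def test_gross_outlier_is_flagged_and_report_consistent(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((500, 4))
        x[123] = 10.0
        rep = detect_multivariate_outliers(pd.DataFrame(x))
        assert 123 in rep.flagged
        # all flagged distances exceed the cutoff; flags are complete cases
        assert (rep.distances.loc[rep.flagged] > rep.cutoff).all()

    def test_complete_cases_only_and_column_list(self):
        rng = np.random.default_rng(4)
        frame = pd.DataFrame(rng.standard_normal((300, 6)),
                             columns=list("abcdef"))
        frame.loc[:49, "a"] = np.nan
        rep = detect_multivariate_outliers(frame, columns=["a", "b", "c"])
        assert rep.n_complete == 250
        assert set(rep.columns) == {"a", "b", "c"}
        assert all(i >= 50 for i in rep.flagged)

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="complete rows"):
            detect_multivariate_outliers(pd.DataFrame(np.eye(3)))


class TestRescale:
    def _ds(self, values):
        return Dataset(pd.DataFrame({"x": values}))

    def test_exact_targets_and_idempotence(self):
        ds = rescale(self._ds([1.0, 2.0, 3.0]), ["x"])
        x = ds.frame["x"]
        assert x.mean() == pytest.approx(5.0, abs=1e-10)
        assert x.std(ddof=1) == pytest.approx(2.0, abs=1e-10)
        again = rescale(ds, ["x"])
        np.testing.assert_allclose(again.frame["x"], x, atol=1e-12)

    def test_missing_cells_stay_missing_and_correlations_invariant(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(rng.standard_normal((100, 3)), columns=list("abc"))
        frame.iloc[::7, 1] = np.nan
        before = frame.corr().to_numpy()
        ds = rescale(Dataset(frame.copy()), ["a", "b", "c"])
        assert ds.frame["b"].isna().equals(frame["b"].isna())
        np.testing.assert_allclose(ds.frame.corr().to_numpy(), before, atol=1e-12)

    def test_zero_variance_names_column(self):
        with pytest.raises(ValueError, match="'x'"):
            rescale(self._ds([2.0, 2.0, 2.0]), ["x"])


class TestSelectivity:
    @pytest.mark.parametrize("mt,ms,sd,expected", [
        (70.60, 70.08, 3.84, 0.1354),   # age row of the descriptive table
        (14.16, 14.08, 2.89, 0.0277),   # education row
    ])
    def test_formula_on_printed_summaries(self, mt, ms, sd, expected):
        assert selectivity(mt, ms, sd) == pytest.approx(expected, abs=5e-5)

    def test_table_and_identical_subsample(self):
        rng = np.random.default_rng(6)
        frame = pd.DataFrame({"pid": np.arange(50),
                              "v": rng.normal(10, 2, 50)})
        ds = Dataset(frame, {"pid": "id"})
        rows = selectivity_table(ds, frame["pid"].tolist())
        assert rows[0].selectivity == pytest.approx(0.0, abs=1e-12)
        # kurtosis convention: plain, normal ~ 3
        big = Dataset(pd.DataFrame({"pid": np.arange(5000),
                                    "v": rng.standard_normal(5000)}),
                      {"pid": "id"})
        row = selectivity_table(big, list(range(1000)))[0]
        assert row.kurtosis_total == pytest.approx(3.0, abs=0.3)

    def test_errors(self):
        ds = Dataset(pd.DataFrame({"pid": [1, 2], "v": [1.0, 2.0]}), {"pid": "id"})
        with pytest.raises(ValueError, match="empty"):
            selectivity_table(ds, [])
        with pytest.raises(ValueError, match="not in total"):
            selectivity_table(ds, [99])


class TestExclusionAccounting:
    @pytest.mark.parametrize("initial,err,out,expected", [
        (1532, 9, 1, 1522),   # cognition sample accounting
        (342, 2, 7, 333),     # MR sample accounting
        (100, 0, 0, 100),
    ])
    def test_values(self, initial, err, out, expected):
        assert exclusion_accounting(initial, err, out) == expected

    def test_errors(self):
        with pytest.raises(ValueError):
            exclusion_accounting(5, 4, 2)
        with pytest.raises(ValueError):
            exclusion_accounting(5, -1, 0)


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(min_value=-1e3, max_value=1e3), min_size=3, max_size=40)
       .filter(lambda v: np.std(v) > 1e-6),
       st.floats(min_value=-10, max_value=10),
       st.floats(min_value=0.1, max_value=10))
def test_rescale_hits_any_target(values, target_mean, target_sd):
    ds = Dataset(pd.DataFrame({"x": values}))
    out = rescale(ds, ["x"], target_mean=target_mean, target_sd=target_sd)
    assert out.frame["x"].mean() == pytest.approx(target_mean, abs=1e-8)
    assert out.frame["x"].std(ddof=1) == pytest.approx(target_sd, abs=1e-8)
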