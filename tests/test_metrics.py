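import numpy as np
import pytest

from lulctraj import (
    MF, NF, NODATA, SF,
    ASF_BINS, FC_BINS, PALU_BINS, BinSpec,
    compute_metrics, crosstab_palu_fc, landcover_proportion_table,
    ols_trend, sf_class_proportion_curves,
)
from lulctraj.metrics import effective_fc

from conftest import stack_from_sequences


def _metrics(*sequences):
    stack = stack_from_sequences(list(sequences))
    return stack, compute_metrics(stack)


class TestASF:
    def test_age_counts_from_run_onset(self):
        stack, mm = _metrics([MF, NF, SF, SF])  # annual 2000-2003
        t = stack.times
        assert mm.asf[3, 0, 0] == pytest.approx(t[3] - t[2])  # ~1 year
        assert mm.asf[3, 0, 0] == pytest.approx(1.0, abs=0.01)
        assert not mm.asf_censored[3, 0, 0]

    def test_first_date_sf_is_minimum_age(self):
        stack, mm = _metrics([SF, SF, SF])
        t = stack.times
        assert mm.asf[2, 0, 0] == pytest.approx(t[2] - t[0])
        assert mm.asf_censored[2, 0, 0]

    def test_run_restarts_after_clearance(self):
        stack, mm = _metrics([SF, NF, SF])
        assert mm.asf[2, 0, 0] == 0.0
        assert not mm.asf_censored[2, 0, 0]

    def test_undefined_off_sf(self):
        _, mm = _metrics([MF, NF, SF, NF])
        assert np.isnan(mm.asf[0, 0, 0]) and np.isnan(mm.asf[3, 0, 0])

    def test_run_continues_across_nodata(self):
        stack, mm = _metrics([MF, NF, SF, NODATA, SF])
        t = stack.times
        assert mm.asf[4, 0, 0] == pytest.approx(t[4] - t[2])
        assert np.isnan(mm.asf[3, 0, 0])  # unobserved date


class TestPALU:
    def test_duration_of_preceding_nf_run(self):
        stack, mm = _metrics([MF, NF, NF, SF])
        assert mm.palu[3, 0, 0] == pytest.approx(2.0, abs=0.01)

    def test_sf_from_first_date_flagged_zero(self):
        _, mm = _metrics([SF, SF])
        assert mm.palu[1, 0, 0] == 0.0
        assert mm.palu_zero[1, 0, 0]

    def test_only_most_recent_nf_run_counts(self):
        stack, mm = _metrics([MF, NF, SF, NF, NF, SF])
        assert mm.palu[5, 0, 0] == pytest.approx(2.0, abs=0.01)
        assert not mm.palu_zero[5, 0, 0]


class TestFC:
    def test_counts_clearance_transitions(self):
        _, mm = _metrics([MF, NF, SF, NF, SF])
        assert mm.fc[4, 0, 0] == 2
        assert list(mm.fc[:, 0, 0]) == [0, 1, 1, 2, 2]

    def test_stable_mf_zero(self):
        _, mm = _metrics([MF, MF, MF])
        assert mm.fc[2, 0, 0] == 0

    def test_nf_start_flagged_and_binned_low(self):
        _, mm = _metrics([NF, SF, SF])
        assert mm.fc[2, 0, 0] == 0
        assert mm.fc_nf_start[2, 0, 0]
        eff = effective_fc(mm, 2)
        assert FC_BINS.assign(eff)[0, 0] == 0  # low class

    def test_monotone_nondecreasing(self, sim_default):
        _, stack, _ = sim_default
        mm = compute_metrics(stack)
        fc = mm.fc.astype(float)
        fc[fc < 0] = 0
        assert (np.diff(fc, axis=0) >= 0).all()


class TestBins:
    def test_asf_class_edges(self):
        vals = np.array([[5.0, 6.0, 16.0]])
        assert list(ASF_BINS.assign(vals)[0]) == [0, 1, 2]

    def test_palu_class_edges(self):
        vals = np.array([[2.0, 3.0, 5.0]])
        assert list(PALU_BINS.assign(vals)[0]) == [0, 1, 2]

    def test_fractional_years_floor(self):
        # 5.9 decimal years is still "5 whole years" -> initial
        assert ASF_BINS.assign(np.array([[5.9]]))[0, 0] == 0

    def test_nan_maps_to_undefined(self):
        assert ASF_BINS.assign(np.array([[np.nan]]))[0, 0] == -1

    def test_empty_grid(self):
        assert ASF_BINS.assign(np.empty((0, 0))).shape == (0, 0)

    def test_bad_spec_rejected(self):
        with pytest.raises(ValueError):
            BinSpec("x", ("a", "b"), (5,))


class TestCrosstab:
    def test_all_short_low_is_100(self):
        stack, mm = _metrics([MF, NF, SF], [MF, NF, SF])
        table = crosstab_palu_fc(mm, -1)
        assert table.loc["short", "low"] == 100.0
        assert table.to_numpy().sum() == pytest.approx(100.0)

    def test_margins_match_class_proportions(self, sim_default):
        _, stack, _ = sim_default
        mm = compute_metrics(stack)
        table = crosstab_palu_fc(mm, -1)
        assert table.to_numpy().sum() == pytest.approx(100.0, abs=0.05)
        k = stack.n_dates - 1
        is_sf = ~np.isnan(mm.asf[k])
        p_cls = PALU_BINS.assign(mm.palu[k])
        for i, lab in enumerate(PALU_BINS.labels):
            share = 100.0 * ((p_cls == i) & is_sf).sum() / is_sf.sum()
            assert table.loc[lab].sum() == pytest.approx(share, abs=1e-9)

    def test_error_when_no_sf(self):
        stack, mm = _metrics([MF, MF], [NF, NF])
        with pytest.raises(ValueError, match="no SF"):
            crosstab_palu_fc(mm, -1)

    def test_matches_truth_tally(self, sim_default):
        _, stack, truth = sim_default
        mm = compute_metrics(stack)
        table = crosstab_palu_fc(mm, -1)
        k = stack.n_dates - 1
        is_sf = ~np.isnan(truth.asf[k])
        p_cls = PALU_BINS.assign(truth.palu[k])
        fc = truth.fc[k].astype(float)
        fc[is_sf & (truth.fc[k] == 0)] = 1
        fc[~is_sf] = np.nan
        f_cls = FC_BINS.assign(fc)
        expected = np.zeros((3, 3))
        sel = is_sf
        np.add.at(expected, (p_cls[sel], f_cls[sel]), 1)
        expected = 100 * expected / is_sf.sum()
        assert np.allclose(table.to_numpy(), expected)


class TestProportionsAndTrends:
    def test_proportions_match_known_map(self):
        # 100 pixels: 91 MF, 4 NF, 5 SF
        seqs = [[MF, MF]] * 91 + [[NF, NF]] * 4 + [[SF, SF]] * 5
        stack = stack_from_sequences(seqs)
        table = landcover_proportion_table(stack)
        assert list(table.loc[0, ["MF", "NF", "SF"]]) == [91.0, 4.0, 5.0]
        assert table[["MF", "NF", "SF"]].sum(axis=1).tolist() == [100.0, 100.0]

    def test_water_and_nodata_excluded_from_denominator(self):
        seqs = [[MF, MF]] * 8 + [[NF, NF]] * 2 + [[0, 0]] * 5 + [[NODATA, NODATA]] * 5
        stack = stack_from_sequences(seqs)
        table = landcover_proportion_table(stack)
        assert table.loc[0, "MF"] == 80.0

    def test_ols_exact_line(self):
        years = np.arange(2000, 2010)
        slope, intercept, r2 = ols_trend(years, 2 * years + 1)
        assert (slope, r2) == (pytest.approx(2.0), pytest.approx(1.0))

    def test_ols_matches_closed_form(self):
        rng = np.random.default_rng(12)
        x = np.arange(1984, 2012, dtype=float)
        y = rng.normal(size=x.size)
        slope, _, _ = ols_trend(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        assert slope == pytest.approx((xc * yc).sum() / (xc**2).sum(), rel=1e-12)

    def test_ols_needs_varying_years(self):
        with pytest.raises(ValueError):
            ols_trend([2000, 2000, 2000], [1, 2, 3])


class TestCurves:
    def test_initial_share_100_at_onset(self):
        stack, mm = _metrics([MF, NF, SF, SF], [MF, MF, MF, MF])
        curves = sf_class_proportion_curves(stack, mm, ASF_BINS)
        assert curves.iloc[0]["initial"] == 100.0
        assert curves.iloc[0]["years_since_onset"] == 0.0

    def test_shares_sum_to_100(self, sim_default):
        _, stack, _ = sim_default
        mm = compute_metrics(stack)
        for spec in (ASF_BINS, PALU_BINS, FC_BINS):
            curves = sf_class_proportion_curves(stack, mm, spec)
            sums = curves[list(spec.labels)].sum(axis=1)
            assert np.allclose(sums, 100.0, atol=0.05)

    def test_shift_toward_advanced_without_reclearance(self):
        # three pixels abandoned at the second date, never recleared,
        # observed annually for 18 years: initial -> intermediate -> advanced
        n = 19
        seq = [[MF] + [SF] * (n - 1)] * 3
        stack = stack_from_sequences(seq, start_year=1990)
        mm = compute_metrics(stack)
        curves = sf_class_proportion_curves(stack, mm, ASF_BINS)
        assert curves.iloc[0]["initial"] == 100.0
        mid = curves.iloc[8]
        assert mid["intermediate"] == 100.0
        assert curves.iloc[-1]["advanced"] == 100.0

    def test_empty_when_no_sf(self):
        stack, mm = _metrics([MF, MF], [NF, NF])
        curves = sf_class_proportion_curves(stack, mm, ASF_BINS)
        assert curves.empty
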