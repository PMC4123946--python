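import numpy as np
import pytest
from scipy import stats

from lulctraj import (
    MF, NF, SF, WATER,
    ConfusionSpec, LandCoverMap, SimulationConfig, build_stack,
    compute_metrics, corrupt_with_confusion, make_reference_sample, simulate_stack,
)


def annual_dates(y0, y1):
    return tuple(int(f"{y}0701") for y in range(y0, y1 + 1))


def metric_maps_equal(mm, truth):
    def nan_eq(a, b):
        return np.array_equal(np.isnan(a), np.isnan(b)) and np.allclose(
            np.nan_to_num(a), np.nan_to_num(b), rtol=0, atol=0
        )

    return (
        nan_eq(mm.asf, truth.asf)
        and nan_eq(mm.palu, truth.palu)
        and np.array_equal(mm.fc, truth.fc)
        and np.array_equal(mm.asf_censored, truth.asf_censored)
        and np.array_equal(mm.palu_zero, truth.palu_zero)
        and np.array_equal(mm.fc_nf_start, truth.fc_nf_start)
    )


class TestSimulateStack:
    def test_no_event_limit_all_mf(self):
        config = SimulationConfig(
            shape=(10, 10), dates=annual_dates(2000, 2005),
            p_clear_mf=0.0, p_initial_sf=0.0, p_initial_nf=0.0, seed=1,
        )
        stack, truth = simulate_stack(config)
        grids = stack.grids()
        thematic = ~stack.water_mask
        assert (grids[:, thematic] == MF).all()
        assert (truth.fc[:, thematic] == 0).all()

    def test_deterministic_limit_clear_then_regrow(self):
        config = SimulationConfig(
            shape=(8, 8), dates=annual_dates(2000, 2006), water_border=0,
            p_clear_mf=1.0, palu_distribution=("constant", 1.0),
            p_reclear_sf=0.0, p_initial_sf=0.0, p_initial_nf=0.0, seed=2,
        )
        stack, _ = simulate_stack(config)
        grids = stack.grids()
        assert (grids[0] == MF).all()
        assert (grids[1] == NF).all()  # cleared within the first year
        assert (grids[2:] == SF).all()  # one year of use, then regrowth

    def test_mf_survival_matches_closed_form(self):
        p = 0.05
        config = SimulationConfig(
            shape=(200, 200), dates=annual_dates(1984, 2011), water_border=0,
            p_clear_mf=p, p_initial_sf=0.0, p_initial_nf=0.0, seed=3,
        )
        stack, _ = simulate_stack(config)
        last = stack.grids()[-1]
        frac_mf = np.mean(last == MF)
        years = stack.times[-1]
        expected = (1 - p) ** years
        se = np.sqrt(expected * (1 - expected) / last.size)
        assert abs(frac_mf - expected) < 3 * se

    def test_seed_determinism(self):
        config = SimulationConfig(shape=(20, 20), seed=9)
        s1, t1 = simulate_stack(config)
        s2, t2 = simulate_stack(config)
        assert np.array_equal(s1.grids(), s2.grids())
        assert metric_maps_equal(t1, t2)

    def test_water_border_applied(self):
        config = SimulationConfig(shape=(10, 10), water_border=2, seed=0)
        stack, _ = simulate_stack(config)
        assert (stack.grids()[:, :2, :] == WATER).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(p_clear_mf=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(p_initial_sf=0.7, p_initial_nf=0.6)
        with pytest.raises(ValueError):
            SimulationConfig(dates=(20000101,))

    def test_ground_truth_recovery(self, sim_default):
        _, stack, truth = sim_default
        mm = compute_metrics(stack)
        assert metric_maps_equal(mm, truth)


class TestCorruption:
    def _all_sf_stack(self, n_cells=100_000):
        side = int(np.ceil(np.sqrt(n_cells)))
        g = np.full((side, side), SF, dtype=np.uint8)
        maps = [
            LandCoverMap(grid=g, date=20000101, pixel_area_ha=1.0),
            LandCoverMap(grid=g, date=20010101, pixel_area_ha=1.0),
        ]
        return build_stack(maps)

    def test_identity_spec_is_noop(self, sim_default):
        _, stack, _ = sim_default
        out = corrupt_with_confusion(stack, ConfusionSpec(np.eye(3)), seed=1)
        assert np.array_equal(out.grids(), stack.grids())

    def test_sf_row_marginals_within_3se(self):
        # row from a published SF validation row: 19/200 MF, 37/200 NF, 144/200 SF
        row = np.array([19, 37, 144]) / 200.0
        spec = ConfusionSpec(np.array([[1, 0, 0], [0, 1, 0], row]))
        stack = self._all_sf_stack()
        out = corrupt_with_confusion(stack, spec, seed=4).grids()[0]
        n = out.size
        for code, p in zip((MF, NF, SF), row):
            frac = np.mean(out == code)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(frac - p) < 3 * se

    def test_mf_flip_fraction(self):
        spec = ConfusionSpec(np.array([[0.93, 0.035, 0.035], [0, 1, 0], [0, 0, 1]]))
        g = np.full((300, 300), MF, dtype=np.uint8)
        stack = build_stack([
            LandCoverMap(grid=g, date=20000101, pixel_area_ha=1.0),
            LandCoverMap(grid=g, date=20010101, pixel_area_ha=1.0),
        ])
        out = corrupt_with_confusion(stack, spec, seed=5).grids()[0]
        flipped = np.mean(out != MF)
        se = np.sqrt(0.07 * 0.93 / out.size)
        assert abs(flipped - 0.07) < 3 * se

    def test_chi_square_goodness_of_fit(self):
        spec = ConfusionSpec(np.array([[1, 0, 0], [0, 1, 0], [0.095, 0.185, 0.72]]))
        stack = self._all_sf_stack()
        out = corrupt_with_confusion(stack, spec, seed=6).grids()[0]
        observed = [int((out == c).sum()) for c in (MF, NF, SF)]
        expected = np.array([0.095, 0.185, 0.72]) * out.size
        chi2 = ((np.array(observed) - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=2)

    def test_non_stochastic_rows_rejected(self):
        with pytest.raises(ValueError):
            ConfusionSpec(np.array([[0.5, 0.5, 0.1], [0, 1, 0], [0, 0, 1]]))


class TestReferenceSample:
    def _patchy_map(self, n_patches=12, patch=4, n_sf_patches=None):
        # disconnected square patches of each class on a WATER background
        per_class = {MF: n_patches, NF: n_patches, SF: n_sf_patches if n_sf_patches is not None else n_patches}
        side = n_patches * (patch + 2) + 2
        width = 2 + 3 * (patch + 2)
        g = np.zeros((side, width), dtype=np.uint8)
        for ci, (code, count) in enumerate(per_class.items()):
            for k in range(count):
                r = 2 + k * (patch + 2)
                c = 2 + ci * (patch + 2)
                g[r : r + patch, c : c + patch] = code
        return LandCoverMap(grid=g, date=20100101, pixel_area_ha=1.0)

    def test_samples_n_per_class_from_distinct_patches(self):
        m = self._patchy_map()
        pts = make_reference_sample(m, n_per_class=10, min_patch_ha=6, seed=1)
        assert len(pts) == 30
        counts = pts["label"].value_counts()
        assert all(counts[c] == 10 for c in (MF, NF, SF))
        # each point carries the label of the cell it sits on
        for _, p in pts.iterrows():
            assert m.grid[p["row"], p["col"]] == p["label"]
        # distinct patches: no duplicate points
        assert not pts.duplicated(["row", "col"]).any()

    def test_insufficient_patches_names_class(self):
        m = self._patchy_map(n_patches=8, n_sf_patches=3)
        with pytest.raises(ValueError, match="SF"):
            make_reference_sample(m, n_per_class=5, min_patch_ha=6, seed=1)

    def test_tiny_patch_excluded(self):
        # MF and NF have large patches; the only SF patch is a single
        # 1-ha pixel, below the 6-ha floor
        g = np.zeros((20, 20), dtype=np.uint8)
        g[2:6, 2:8] = MF
        g[10:14, 2:8] = NF
        g[17, 17] = SF
        m = LandCoverMap(grid=g, date=20100101, pixel_area_ha=1.0)
        with pytest.raises(ValueError, match="SF"):
            make_reference_sample(m, n_per_class=1, min_patch_ha=6, seed=1)

    def test_concave_patch_centroid_snaps_into_patch(self):
        # U-shaped SF patch whose centroid falls in the notch
        g = np.zeros((20, 20), dtype=np.uint8)
        g[2:10, 2:4] = SF
        g[2:10, 8:10] = SF
        g[8:10, 4:8] = SF
        g[13:17, 2:8] = MF
        g[13:17, 10:16] = NF
        m = LandCoverMap(grid=g, date=20100101, pixel_area_ha=1.0)
        pts = make_reference_sample(m, n_per_class=1, min_patch_ha=6, seed=1)
        sf_pt = pts[pts["label"] == SF].iloc[0]
        assert g[sf_pt["row"], sf_pt["col"]] == SF
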