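"""QC filtering, log transform, spatial correction and background subtraction."""

import numpy as np
import pytest

from tftscreen.errors import QCError
from tftscreen.normalization import (
    NormalizationConfig,
    background_and_median_normalize,
    log_transform,
    loess_2d,
    qc_filter,
    spatial_normalize,
)
from tftscreen.screen_data import QC_FAILED_CROSS, QC_PASS
from tftscreen.synthetic_data import (
    SpatialFieldConfig,
    default_screen_config,
    generate_screen,
)

from conftest import make_layout, make_plateset

CFG = NormalizationConfig()


def grid_layout(rows=8, cols=12, role="mutant"):
    cells = [
        ("p1", r, c, f"g{r * cols + c:03d}", role)
        for r in range(rows)
        for c in range(cols)
    ]
    return make_layout(rows, cols, cells)


class TestQCFilter:
    def test_small_colony_flagged(self):
        layout = grid_layout(2, 2)
        plates = make_plateset(layout, sfgfp=100.0, size=[100.0, 100.0, 100.0, 30.0])
        out = qc_filter(plates, CFG)
        assert list(out.data["qc_flag"]) == [QC_PASS] * 3 + [QC_FAILED_CROSS]

    def test_uniform_sizes_pass(self):
        plates = make_plateset(grid_layout(2, 2), sfgfp=100.0, size=100.0)
        out = qc_filter(plates, CFG)
        assert (out.data["qc_flag"] == QC_PASS).all()

    def test_matches_bruteforce_fixpoint_and_is_idempotent(self, rng):
        layout = grid_layout(8, 12)
        sizes = rng.uniform(10, 200, layout.n_positions)
        plates = make_plateset(layout, sfgfp=100.0, size=sizes)
        out = qc_filter(plates, CFG)

        # Brute-force oracle: iterate the definition over all colonies.
        passing = np.ones(sizes.size, bool)
        while True:
            med = np.median(sizes[passing])
            fail = passing & (sizes < CFG.min_size_fraction * med)
            if not fail.any():
                break
            passing &= ~fail
        expected = np.where(passing, QC_PASS, QC_FAILED_CROSS)
        np.testing.assert_array_equal(out.data["qc_flag"].to_numpy(), expected)

        again = qc_filter(out, CFG)
        np.testing.assert_array_equal(
            again.data["qc_flag"].to_numpy(), out.data["qc_flag"].to_numpy()
        )

    def test_all_zero_sizes_rejected(self):
        plates = make_plateset(grid_layout(2, 2), sfgfp=100.0, size=0.0)
        with pytest.raises(QCError):
            qc_filter(plates, CFG)


class TestLogTransform:
    def test_ratio_channel_is_log_difference(self):
        plates = make_plateset(grid_layout(2, 2), sfgfp=100.0, mcherry=50.0)
        out = log_transform(plates, CFG)
        np.testing.assert_allclose(out.data["log_ratio"], -np.log(2), rtol=1e-12)

    def test_equal_channels_give_zero_ratio(self):
        plates = make_plateset(grid_layout(2, 2), sfgfp=77.0, mcherry=77.0)
        out = log_transform(plates, CFG)
        np.testing.assert_array_equal(out.data["log_ratio"], 0.0)

    def test_exponentiating_recovers_raw(self, rng):
        g = rng.lognormal(7, 1, 96)
        m = rng.lognormal(6, 1, 96)
        out = log_transform(make_plateset(grid_layout(8, 12), sfgfp=g, mcherry=m), CFG)
        np.testing.assert_allclose(np.exp(out.data["log_sfGFP"]), g, rtol=1e-12)
        np.testing.assert_allclose(np.exp(out.data["log_mCherry"]), m, rtol=1e-12)

    def test_zero_intensity_flagged_not_dropped(self):
        g = np.full(96, 50.0)
        g[5] = 0.0
        out = log_transform(make_plateset(grid_layout(8, 12), sfgfp=g), CFG)
        assert out.data.loc[5, "qc_flag"] == "excluded"
        assert np.isnan(out.data.loc[5, "log_sfGFP"])
        assert len(out.data) == 96


class TestSpatialNormalize:
    def grid(self, rows=32, cols=48):
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        return rr.ravel().astype(float), cc.ravel().astype(float)

    def plates_with_values(self, values):
        layout = grid_layout(32, 48)
        plates = make_plateset(layout, sfgfp=np.exp(values))
        return log_transform(plates, CFG)

    def test_constant_plate_unchanged(self):
        out = spatial_normalize(self.plates_with_values(np.full(1536, 10.0)), CFG)
        np.testing.assert_allclose(out.data["log_sfGFP"], 10.0, atol=1e-9)

    def test_linear_gradient_removed(self):
        _, cols = self.grid()
        vals = 10.0 + 0.5 * cols / 47.0
        out = spatial_normalize(self.plates_with_values(vals), CFG)
        corrected = out.data["log_sfGFP"].to_numpy()
        assert corrected.max() - corrected.min() < 0.02

    def test_plate_median_preserved(self, rng):
        vals = 10.0 + rng.normal(0, 0.2, 1536)
        plates = self.plates_with_values(vals)
        out = spatial_normalize(plates, CFG)
        assert np.median(out.data["log_sfGFP"]) == pytest.approx(
            np.median(vals), abs=1e-9
        )

    def test_shift_equivariance(self, rng):
        vals = rng.normal(5, 0.3, 1536)
        a = spatial_normalize(self.plates_with_values(vals), CFG)
        b = spatial_normalize(self.plates_with_values(vals + 2.5), CFG)
        np.testing.assert_allclose(
            b.data["log_sfGFP"], a.data["log_sfGFP"] + 2.5, atol=1e-9
        )

    def test_radial_bowl_from_simulator_decorrelated(self):
        cfg = default_screen_config(
            seed=7,
            n_genes=384,
            n_hits=0,
            n_confounders=0,
            spatial_field=SpatialFieldConfig(shape="radial", amplitude=np.log(2)),
        )
        query, _, _ = generate_screen(cfg)
        out = spatial_normalize(log_transform(qc_filter(query, CFG), CFG), CFG)
        pm = out.passing_mutants()
        corr = np.corrcoef(pm["log_sfGFP"], pm["_field_sfGFP"])[0, 1]
        assert abs(corr) < 0.05

    def test_qc_flags_untouched(self, rng):
        layout = grid_layout(8, 12)
        sizes = rng.uniform(20, 150, 96)
        plates = make_plateset(layout, sfgfp=rng.lognormal(5, 0.3, 96), size=sizes)
        q = qc_filter(plates, CFG)
        flags = q.data["qc_flag"].copy()
        out = spatial_normalize(log_transform(q, CFG), CFG)
        np.testing.assert_array_equal(out.data["qc_flag"], flags)

    def test_loess_median_filter_mode_runs(self, rng):
        cfg = NormalizationConfig(spatial_method="median_filter")
        vals = 8.0 + rng.normal(0, 0.1, 1536)
        out = spatial_normalize(self.plates_with_values(vals), cfg)
        assert np.isfinite(out.data["log_sfGFP"]).all()

    def test_loess_2d_tracks_low_frequency_surface(self, rng):
        rows, cols = self.grid()
        truth = 0.4 * np.sin(rows / 12.0) + 0.3 * np.cos(cols / 15.0)
        vals = truth + rng.normal(0, 0.05, rows.size)
        fit = loess_2d(rows, cols, vals, span=0.3, degree=2, robustness_iters=1)
        assert np.sqrt(np.mean((fit - truth) ** 2)) < 0.03


class TestBackgroundAndMedian:
    def controls_layout(self):
        cells = []
        for r in range(8):
            for c in range(12):
                role = "non_fluorescent_control" if c in (0, 6) else "mutant"
                cells.append(("p1", r, c, f"g{r * 12 + c:03d}", role))
        return make_layout(8, 12, cells)

    def test_nearest_control_subtraction(self):
        layout = self.controls_layout()
        g = np.where(layout.table["role"] == "mutant", 1200.0, 200.0)
        plates = make_plateset(layout, sfgfp=g, mcherry=g)
        cfg = NormalizationConfig(background_mode="local_control_colonies")
        out = background_and_median_normalize(plates, cfg)
        mut = out.data[out.data["role"] == "mutant"]
        np.testing.assert_allclose(mut["sfGFP"], 1000.0, rtol=1e-12)

    def test_median_scaling_sets_screen_median_to_one(self, rng):
        layout = self.controls_layout()
        g = rng.lognormal(7, 0.5, 96)
        plates = make_plateset(layout, sfgfp=g, mcherry=g)
        cfg = NormalizationConfig(median_scale=True)
        out = background_and_median_normalize(plates, cfg)
        assert np.median(out.passing_mutants()["sfGFP"]) == pytest.approx(1.0)

    def test_matches_bruteforce_oracle(self, rng):
        # Corner controls on an 8x12 grid: grid midlines fall between
        # integer coordinates, so the nearest control is always unique and
        # the oracle's selection cannot diverge on distance ties.
        cells = []
        corners = {(0, 0), (0, 11), (7, 0), (7, 11)}
        for r in range(8):
            for c in range(12):
                role = "non_fluorescent_control" if (r, c) in corners else "mutant"
                cells.append(("p1", r, c, f"g{r * 12 + c:03d}", role))
        layout = make_layout(8, 12, cells)
        is_ctrl = (layout.table["role"] == "non_fluorescent_control").to_numpy()
        g = np.where(is_ctrl, rng.uniform(100, 300, 96), rng.uniform(2000, 4000, 96))
        m = np.where(is_ctrl, rng.uniform(80, 250, 96), rng.uniform(1500, 3000, 96))
        plates = make_plateset(layout, sfgfp=g, mcherry=m)
        cfg = NormalizationConfig(
            background_mode="local_control_colonies", median_scale=True, k_controls=1
        )
        out = background_and_median_normalize(plates, cfg)

        # Brute force from the definition.
        t = layout.table
        ctrl = t[t["role"] == "non_fluorescent_control"].index.to_numpy()
        mut_mask = (t["role"] == "mutant").to_numpy()
        for ch, raw in (("sfGFP", g), ("mCherry", m)):
            corr = np.empty(96)
            for i in range(96):
                d2 = (t.loc[i, "row"] - t.loc[ctrl, "row"]) ** 2 + (
                    t.loc[i, "col"] - t.loc[ctrl, "col"]
                ) ** 2
                corr[i] = raw[i] - raw[ctrl[int(np.argmin(d2.to_numpy()))]]
            expected = corr / np.median(corr[mut_mask])
            np.testing.assert_allclose(
                out.data.loc[mut_mask, ch], expected[mut_mask], rtol=1e-10
            )
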