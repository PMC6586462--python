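"""Generator determinism, ground-truth consistency and planted-effect wiring."""

import numpy as np
import pandas as pd
import pytest

from tftscreen.errors import ConfigError
from tftscreen.normalization import NormalizationConfig, normalize_screen
from tftscreen.scoring import score_screen
from tftscreen.synthetic_data import (
    SpatialFieldConfig,
    SynthScreenConfig,
    build_layout,
    default_screen_config,
    generate_chase,
    generate_flow,
    generate_screen,
)
from tftscreen.timer_model import TimerParams, steady_state_prediction


def small_cfg(**kw):
    base = dict(n_genes=96, plate_format=384, seed=5)
    base.update(kw)
    return default_screen_config(**base) if "n_hits" in kw else SynthScreenConfig(**base)


class TestGenerateScreen:
    def test_seeded_determinism_byte_identical(self):
        cfg = small_cfg()
        q1, c1, t1 = generate_screen(cfg)
        q2, c2, t2 = generate_screen(cfg)
        pd.testing.assert_frame_equal(q1.data, q2.data)
        pd.testing.assert_frame_equal(c1.data, c2.data)
        pd.testing.assert_frame_equal(t1, t2)
        assert q1.data.to_csv() == q2.data.to_csv()

    def test_truth_reproduces_timer_closed_forms_exactly(self):
        cfg = small_cfg(n_hits=3, n_confounders=1)
        _, _, truth = generate_screen(cfg)
        for _, row in truth.iterrows():
            pred = steady_state_prediction(cfg.timer.with_alpha(row["alpha_query"]))
            assert row["expected_sfGFP"] == pred.iG
            assert row["expected_ratio"] == pred.ratio

    def test_layout_blocks_and_capacity(self):
        cfg = small_cfg()
        layout = build_layout(cfg)
        assert (layout.n_rows, layout.n_cols) == (16, 24)
        groups = layout.replicate_groups()
        assert len(groups) == 96
        assert all(len(v) == 4 for v in groups.values())

    def test_effects_shift_query_only_confounders_both(self):
        cfg = small_cfg(n_hits=4, n_confounders=2)
        _, _, truth = generate_screen(cfg)
        hits = truth[truth["is_planted_hit"]]
        conf = truth[truth["is_confounder"]]
        null = truth[~(truth["is_planted_hit"] | truth["is_confounder"])]
        assert (hits["alpha_query"] < hits["alpha_control"]).all()
        assert (hits["alpha_control"] == cfg.baseline_alpha).all()
        assert (conf["alpha_query"] == conf["alpha_control"]).all()
        assert (conf["alpha_query"] < cfg.baseline_alpha).all()
        assert (null["alpha_query"] == cfg.baseline_alpha).all()

    def test_dropouts_are_small_and_rate_consistent(self):
        cfg = small_cfg(n_genes=384, plate_format=1536, dropout_rate=0.1)
        q, _, _ = generate_screen(cfg)
        small = q.data["size"] < 50
        assert 0.06 < small.mean() < 0.14
        from tftscreen.normalization import qc_filter

        flagged = qc_filter(q, NormalizationConfig()).data["qc_flag"] == "failed_cross"
        assert (flagged == small).mean() > 0.99

    def test_planted_stabilizers_separate_from_null_in_ratio_z(self):
        """A 3-fold degradation-rate reduction lifts the mean ratio z of
        planted genes far above the null gene population."""
        cfg = default_screen_config(
            seed=11, n_genes=384, n_hits=8, n_confounders=0, plate_format=1536
        )
        query, _, truth = generate_screen(cfg)
        scores = score_screen(normalize_screen(query, NormalizationConfig()))
        ratio = scores[scores["readout"] == "ratio"].merge(truth, on="gene")
        planted = ratio.loc[ratio["is_planted_hit"], "z_mean"]
        null = ratio.loc[~ratio["is_planted_hit"], "z_mean"]
        null_mad = np.median(np.abs(null - null.median()))
        assert planted.mean() > null.mean() + 3 * null_mad

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            SynthScreenConfig(n_genes=10, plate_format=1000)
        with pytest.raises(ConfigError):
            SynthScreenConfig(n_genes=10, dropout_rate=0.7)
        with pytest.raises(ConfigError):
            SynthScreenConfig(n_genes=10, replicates=3)
        with pytest.raises(ConfigError):
            SynthScreenConfig(n_genes=4, effects=(("g00001", -1.0),))
        with pytest.raises(ConfigError):
            generate_screen(SynthScreenConfig(n_genes=4, effects=(("nope", 0.5),)))

    def test_spatial_field_peak_amplitude_and_zero_mean(self):
        cfg = small_cfg(
            n_genes=384,
            plate_format=1536,
            spatial_field=SpatialFieldConfig(shape="radial", amplitude=0.5),
        )
        q, _, _ = generate_screen(cfg)
        f = q.data["_field_sfGFP"].to_numpy()
        assert np.max(np.abs(f)) == pytest.approx(0.5, rel=1e-9)
        assert abs(f.mean()) < 0.02


class TestGenerateChaseAndFlow:
    def test_noise_free_chase_is_exact_exponential(self):
        s = generate_chase(12.0, noise_sd=0.0, n_points=5, n_replicates=2)
        expected = np.power(2.0, -s.times / 12.0)
        np.testing.assert_allclose(
            s.values, np.broadcast_to(expected, s.values.shape), rtol=1e-12
        )

    def test_chase_seeded_reproducibility(self):
        a = generate_chase(20.0, seed=9)
        b = generate_chase(20.0, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_chase_parameter_validation(self):
        with pytest.raises(ConfigError):
            generate_chase(-1.0)
        with pytest.raises(ConfigError):
            generate_chase(10.0, n_points=2)

    def test_flow_cv_zero_means_exact(self):
        truth = {"wt": {"sfGFP": 4000.0, "mCherry": 1000.0}}
        events = generate_flow(truth, blank_mean=100.0, event_noise_cv=0.0,
                               n_events=500, seed=0)
        wt = events[events["sample"] == "wt"]
        assert wt["sfGFP"].mean() == pytest.approx(4100.0, rel=1e-12)
        blank = events[events["sample"] == "blank"]
        assert blank["sfGFP"].mean() == pytest.approx(100.0, rel=1e-12)

    def test_flow_validation(self):
        with pytest.raises(ConfigError):
            generate_flow({}, n_events=10)


class TestNoiseMonotonicity:
    def test_more_noise_weakens_separation_of_planted_hits(self):
        """Increasing measurement noise strictly degrades how far planted
        stabilizers stand out from the null distribution."""
        seps = []
        for noise in (0.05, 0.15, 0.45):
            cfg = default_screen_config(
                seed=21, n_genes=384, n_hits=8, n_confounders=0,
                plate_format=1536, noise_sd=noise,
            )
            query, _, truth = generate_screen(cfg)
            scores = score_screen(normalize_screen(query, NormalizationConfig()))
            ratio = scores[scores["readout"] == "ratio"].merge(truth, on="gene")
            seps.append(float(ratio.loc[ratio["is_planted_hit"], "z_mean"].mean()))
        assert seps[0] > seps[1] > seps[2]
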