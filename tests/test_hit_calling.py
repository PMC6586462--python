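"""Dual-reporter verdicts, fold-change screens and targeted rescreens."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from tftscreen.errors import ConfigError
from tftscreen.hit_calling import call_hits, fold_change_screen, rescreen_compare
from tftscreen.normalization import NormalizationConfig, background_and_median_normalize

from conftest import make_layout, make_plateset


def scores_frame(entries):
    """entries: gene -> ((z_sfGFP, q_sfGFP), (z_ratio, q_ratio))"""
    rows = []
    for gene, ((zg, qg), (zr, qr)) in entries.items():
        rows.append({"gene": gene, "readout": "sfGFP", "z_mean": zg, "q": qg,
                     "n": 4, "z_sd": 1.0, "p": qg})
        rows.append({"gene": gene, "readout": "ratio", "z_mean": zr, "q": qr,
                     "n": 4, "z_sd": 1.0, "p": qr})
    return pd.DataFrame(rows)


NULL_CONTROL = {"g1": ((0.2, 0.9), (-0.1, 0.9))}


class TestCallHits:
    def test_specific_stabilizer_is_hit(self):
        query = scores_frame({"g1": ((4.2, 0.01), (3.5, 0.02))})
        control = scores_frame(NULL_CONTROL)
        out = call_hits(query, control)
        assert out.loc[0, "verdict"] == "hit"

    def test_ratio_below_threshold_not_hit(self):
        query = scores_frame({"g1": ((4.2, 0.01), (2.0, 0.02))})
        out = call_hits(query, scores_frame(NULL_CONTROL))
        assert out.loc[0, "verdict"] == "not_hit"

    def test_control_affected_gene_excluded(self):
        query = scores_frame({"g1": ((5.0, 0.01), (5.0, 0.01))})
        control = scores_frame({"g1": ((4.5, 0.1), (0.3, 0.9))})
        out = call_hits(query, control)
        assert out.loc[0, "verdict"] == "excluded_control_affected"

    def test_gene_missing_from_control_insufficient(self):
        query = scores_frame({"g1": ((5.0, 0.01), (5.0, 0.01))})
        control = scores_frame({"g2": ((0.0, 0.9), (0.0, 0.9))})
        out = call_hits(query, control)
        assert out.loc[0, "verdict"] == "insufficient_data"

    def test_fdr_leg_required_for_hit(self):
        query = scores_frame({"g1": ((5.0, 0.01), (5.0, 0.2))})
        out = call_hits(query, scores_frame(NULL_CONTROL))
        assert out.loc[0, "verdict"] == "not_hit"

    def test_raising_threshold_never_adds_hits(self, rng):
        genes = {}
        for i in range(200):
            genes[f"g{i}"] = (
                (rng.normal(2, 2), rng.uniform(0, 0.1)),
                (rng.normal(2, 2), rng.uniform(0, 0.1)),
            )
        query = scores_frame(genes)
        control = scores_frame(
            {g: ((rng.normal(0, 1), 0.9), (rng.normal(0, 1), 0.9)) for g in genes}
        )
        hits = None
        for thr in (2.0, 3.0, 4.0, 5.0):
            out = call_hits(query, control, z_threshold=thr)
            now = set(out.loc[out["verdict"] == "hit", "gene"])
            if hits is not None:
                assert now <= hits
            hits = now

    def test_verdicts_reproducible_from_stored_thresholds(self, rng):
        genes = {
            f"g{i}": (
                (rng.normal(2, 2), rng.uniform(0, 0.1)),
                (rng.normal(2, 2), rng.uniform(0, 0.1)),
            )
            for i in range(100)
        }
        query = scores_frame(genes)
        control = scores_frame(
            {g: ((rng.normal(0, 2), 0.9), (rng.normal(0, 2), 0.9)) for g in genes}
        )
        out = call_hits(query, control)
        z_ok = (out["z_sfGFP"] > out["z_threshold"]) & (
            out["z_ratio"] > out["z_threshold"]
        )
        q_ok = (out["q_sfGFP"] <= out["fdr_level"]) & (
            out["q_ratio"] <= out["fdr_level"]
        )
        c_ok = (out["control_z_sfGFP"].abs() < out["control_z_max"]) & (
            out["control_z_ratio"].abs() < out["control_z_max"]
        )
        expected = np.where(
            z_ok & ~c_ok,
            "excluded_control_affected",
            np.where(z_ok & q_ok & c_ok, "hit", "not_hit"),
        )
        np.testing.assert_array_equal(out["verdict"].to_numpy(), expected)


def ta_pair(quad_layout, mutant_vals, wt_vals):
    mut = make_plateset(quad_layout, sfgfp=mutant_vals, screen_id="mutant")
    wt = make_plateset(quad_layout, sfgfp=wt_vals, screen_id="wt")
    return mut, wt


class TestFoldChangeScreen:
    def test_clear_enrichment_flagged(self, quad_layout):
        mut, wt = ta_pair(
            quad_layout,
            [208.0, 212.0, 205.0, 215.0, 100.0, 101.0, 99.0, 100.0],
            [99.0, 101.0, 100.0, 100.0, 100.0, 101.0, 99.0, 100.0],
        )
        out = fold_change_screen(mut, wt).set_index("gene")
        assert out.loc["geneA", "fold_change"] == pytest.approx(2.1, rel=1e-3)
        assert out.loc["geneA", "flagged"] and out.loc["geneA", "fold_change"] > 2
        assert not out.loc["geneB", "flagged"]

    def test_identical_screens_fold_one(self, quad_layout):
        vals = [100.0, 105.0, 95.0, 100.0] * 2
        mut, wt = ta_pair(quad_layout, vals, vals)
        out = fold_change_screen(mut, wt)
        np.testing.assert_allclose(out["fold_change"], 1.0)
        assert not out["flagged"].any()

    def test_matches_bruteforce_recomputation(self, quad_layout, rng):
        mv = rng.lognormal(5, 0.3, 8)
        wv = rng.lognormal(5, 0.3, 8)
        mut, wt = ta_pair(quad_layout, mv, wv)
        out = fold_change_screen(mut, wt).set_index("gene")
        for gene, sl in (("geneA", slice(0, 4)), ("geneB", slice(4, 8))):
            f = mv[sl].mean() / wv[sl].mean()
            p = ss.ttest_ind(mv[sl], wv[sl], equal_var=True).pvalue
            assert out.loc[gene, "fold_change"] == pytest.approx(f, rel=1e-12)
            assert out.loc[gene, "p"] == pytest.approx(p, rel=1e-12)


class TestRescreenCompare:
    def layout_with_reference(self):
        cells = []
        genes = ["ref", "mutA", "mutB"]
        for j, gene in enumerate(genes):
            for dr in (0, 1):
                for dc in (0, 1):
                    cells.append(("p1", dr, 2 * j + dc, gene, "mutant"))
            # fill remaining grid with empties
        return make_layout(2, 6, cells)

    def test_median_strain_ranks_mid_and_top_rank_for_bright(self):
        layout = self.layout_with_reference()
        vals = np.array([1.0, 1.0, 1.0, 1.0, 1.1, 1.1, 1.1, 1.1, 3.0, 3.0, 3.0, 3.0])
        plates = make_plateset(layout, sfgfp=vals)
        cfg = NormalizationConfig(median_scale=True)
        norm = background_and_median_normalize(plates, cfg)
        out = rescreen_compare(norm, "ref")
        top = out.iloc[0]
        assert top["gene"] == "mutB" and top["rank"] == 1
        assert top["norm_sfGFP"] == pytest.approx(3.0 / 1.1, rel=1e-9)
        # the strain sitting at the screen median is normalized to exactly 1
        byg = out.set_index("gene")
        assert byg.loc["mutA", "norm_sfGFP"] == pytest.approx(1.0, rel=1e-12)
        assert byg.loc["mutA", "rank"] == 2

    def test_ranking_matches_bruteforce_sort(self, rng):
        layout = self.layout_with_reference()
        vals = rng.lognormal(0, 0.4, 12)
        plates = make_plateset(layout, sfgfp=vals)
        norm = background_and_median_normalize(
            plates, NormalizationConfig(median_scale=True)
        )
        out = rescreen_compare(norm, "ref")
        med = np.median(vals)
        means = {
            g: vals[sl].mean() / med
            for g, sl in (("ref", slice(0, 4)), ("mutA", slice(4, 8)),
                          ("mutB", slice(8, 12)))
        }
        expected = sorted(means, key=means.get, reverse=True)
        assert out["gene"].tolist() == expected
        for g in means:
            assert out.set_index("gene").loc[g, "norm_sfGFP"] == pytest.approx(
                means[g], rel=1e-12
            )

    def test_missing_reference_rejected(self, quad_layout):
        plates = make_plateset(quad_layout, sfgfp=1.0)
        with pytest.raises(ConfigError):
            rescreen_compare(plates, "nosuchstrain")
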