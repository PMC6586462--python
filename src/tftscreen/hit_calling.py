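"""Hit calling for dual-reporter, targeted and TA-array screens.

The genome-wide screen pairs a query reporter (a short-lived, mislocalized
tail-anchored protein fusion) with a control reporter (a stable TA protein)
measured in an independent cross of the same deletion collection.  A gene
is a *hit* when it raises both the abundance (sfGFP) and stability
(mCherry/sfGFP ratio) z-scores of the query reporter above threshold at
controlled FDR, while leaving the control reporter unaffected - the control
leg removes perturbations (e.g. of organelle physiology or fluorophore
maturation) that move the timer readout without changing the query
protein's turnover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DomainError
from .scoring import bh_adjust
from .screen_data import PlateSet

__all__ = [
    "HitThresholds",
    "call_hits",
    "fold_change_screen",
    "rescreen_compare",
]

VERDICT_HIT = "hit"
VERDICT_NOT_HIT = "not_hit"
VERDICT_CONTROL = "excluded_control_affected"
VERDICT_INSUFFICIENT = "insufficient_data"


@dataclass(frozen=True)
class HitThresholds:
    """Thresholds applied by :func:`call_hits` (echoed into its output)."""

    z_threshold: float = 3.0
    fdr_level: float = 0.05
    control_z_max: float = 3.0
    direction: str = "stabilized"  # or "two_sided"

    def __post_init__(self) -> None:
        if self.z_threshold <= 0 or self.fdr_level <= 0 or self.control_z_max <= 0:
            raise ConfigError("all thresholds must be positive")
        if self.direction not in ("stabilized", "two_sided"):
            raise ConfigError(f"unknown direction {self.direction!r}")


def _pivot_scores(scores: pd.DataFrame, what: str) -> pd.DataFrame:
    need = {"gene", "readout", "z_mean", "q", "n"}
    missing = need - set(scores.columns)
    if missing:
        raise DomainError(f"{what} scores lack columns {sorted(missing)}")
    wide = scores.pivot(index="gene", columns="readout", values=["z_mean", "q", "n"])
    for r in ("sfGFP", "ratio"):
        if ("z_mean", r) not in wide.columns:
            raise DomainError(f"{what} scores lack readout {r!r}")
    return wide


def call_hits(
    query_scores: pd.DataFrame,
    control_scores: pd.DataFrame,
    z_threshold: float = 3.0,
    fdr_level: float = 0.05,
    control_z_max: float = 3.0,
    direction: str = "stabilized",
) -> pd.DataFrame:
    """Dual-reporter hit calling.

    Verdicts per gene, in order of precedence:

    ``insufficient_data``
        gene missing from the control screen, or either screen has no
        usable replicate z-scores for a readout;
    ``excluded_control_affected``
        query z-scores clear ``z_threshold`` on both readouts but the
        control reporter is affected (``|control z_mean| >= control_z_max``
        on either readout) - the effect is not specific to the query
        protein, whatever its significance status;
    ``hit``
        query ``z_mean > z_threshold`` and ``q <= fdr_level`` on *both*
        readouts, control unaffected;
    ``not_hit``
        everything else.

    With ``direction="stabilized"`` (default) only positive query
    z-scores count; ``"two_sided"`` thresholds ``|z_mean|`` instead.
    """
    thr = HitThresholds(z_threshold, fdr_level, control_z_max, direction)
    q_wide = _pivot_scores(query_scores, "query")
    c_wide = _pivot_scores(control_scores, "control")

    genes = q_wide.index
    out = pd.DataFrame(index=genes)
    for r in ("sfGFP", "ratio"):
        out[f"z_{r}"] = q_wide[("z_mean", r)]
        out[f"q_{r}"] = q_wide[("q", r)]
        out[f"n_{r}"] = q_wide[("n", r)].fillna(0).astype(int)
    joined = c_wide.reindex(genes)
    for r in ("sfGFP", "ratio"):
        out[f"control_z_{r}"] = joined[("z_mean", r)]

    zq = out[["z_sfGFP", "z_ratio"]].to_numpy(float)
    if thr.direction == "two_sided":
        zq = np.abs(zq)
    qq = out[["q_sfGFP", "q_ratio"]].to_numpy(float)
    zc = out[["control_z_sfGFP", "control_z_ratio"]].to_numpy(float)

    has_query = np.isfinite(out[["z_sfGFP", "z_ratio"]].to_numpy(float)).all(axis=1)
    has_control = np.isfinite(zc).all(axis=1)
    z_pass = has_query & (zq > thr.z_threshold).all(axis=1)
    q_pass = np.isfinite(qq).all(axis=1) & (qq <= thr.fdr_level).all(axis=1)
    control_ok = has_control & (np.abs(zc) < thr.control_z_max).all(axis=1)

    verdict = np.full(len(genes), VERDICT_NOT_HIT, dtype=object)
    verdict[z_pass & q_pass & control_ok] = VERDICT_HIT
    verdict[z_pass & has_control & ~control_ok] = VERDICT_CONTROL
    verdict[~(has_query & has_control)] = VERDICT_INSUFFICIENT
    out["verdict"] = verdict
    out = out.reset_index().rename(columns={"index": "gene"})
    out["z_threshold"] = thr.z_threshold
    out["fdr_level"] = thr.fdr_level
    out["control_z_max"] = thr.control_z_max
    out.attrs["thresholds"] = thr
    return out


def fold_change_screen(
    mutant: PlateSet,
    wt: PlateSet,
    alpha_level: float = 0.05,
    fold_threshold: float = 2.0,
    channel: str = "sfGFP",
) -> pd.DataFrame:
    """Per-strain fold change of background-corrected GFP versus wild type.

    Both plate sets must hold the same strain layout measured in the
    mutant and wild-type backgrounds, background-corrected against local
    non-fluorescent controls, with at least two passing replicates per
    strain.  Reports the fold change ``F = mutant_mean / wt_mean``, a
    two-sample Student's t-test p-value over replicate intensities, its BH
    q-value across strains, and ``flagged = (p < alpha_level)``; callers
    apply the fold filter of their screen design via ``fold_threshold``
    (carried in the output for provenance).
    """
    rows = []
    mut_pm = mutant.passing_mutants()
    wt_pm = wt.passing_mutants()
    genes = sorted(set(mut_pm["gene"]) | set(wt_pm["gene"]))
    for gene in genes:
        mv = mut_pm.loc[mut_pm["gene"] == gene, channel].to_numpy(float)
        wv = wt_pm.loc[wt_pm["gene"] == gene, channel].to_numpy(float)
        rec = {
            "gene": gene,
            "mutant_mean": mv.mean() if mv.size else np.nan,
            "wt_mean": wv.mean() if wv.size else np.nan,
            "n_mutant": mv.size,
            "n_wt": wv.size,
        }
        valid = mv.size >= 2 and wv.size >= 2 and rec["wt_mean"] > 0
        rec["valid"] = valid
        if valid:
            rec["fold_change"] = rec["mutant_mean"] / rec["wt_mean"]
            rec["p"] = float(stats.ttest_ind(mv, wv, equal_var=True).pvalue)
        else:
            rec["fold_change"] = np.nan
            rec["p"] = np.nan
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["flagged"] = out["p"] < alpha_level
    out["fold_threshold"] = fold_threshold
    out["alpha_level"] = alpha_level
    return out


def rescreen_compare(plates: PlateSet, reference_gene: str) -> pd.DataFrame:
    """Ranked table for a targeted (median-normalized) rescreen.

    ``plates`` must be normalized with ``median_scale`` on, so raw-scale
    values are expressed relative to the screen median (median strain =
    1.0).  Each mutant's mean normalized sfGFP and mCherry/sfGFP ratio is
    reported with its rank (1 = highest sfGFP) and a two-sample Student's
    t-test against the replicates of ``reference_gene``.
    """
    pm = plates.passing_mutants()
    if reference_gene not in set(pm["gene"]):
        raise ConfigError(f"reference strain {reference_gene!r} not in screen")
    ref = pm[pm["gene"] == reference_gene]
    rows = []
    for gene, grp in pm.groupby("gene"):
        g = grp["sfGFP"].to_numpy(float)
        rec = {
            "gene": gene,
            "norm_sfGFP": g.mean(),
            "norm_ratio": (grp["mCherry"] / grp["sfGFP"]).mean(),
            "n": len(grp),
        }
        rg = ref["sfGFP"].to_numpy(float)
        if len(g) >= 2 and len(rg) >= 2 and gene != reference_gene:
            rec["p_vs_reference"] = float(stats.ttest_ind(g, rg, equal_var=True).pvalue)
        else:
            rec["p_vs_reference"] = np.nan
        rows.append(rec)
    out = pd.DataFrame(rows).sort_values(
        "norm_sfGFP", ascending=False, kind="mergesort"
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
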