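"""Robust z-scores, replicate summarization, per-gene tests and FDR control.

Each colony's corrected log readout is converted to a robust z-score
against the screen's central tendency:

    z = (value - median) / MAD

where median and MAD (raw, unscaled median absolute deviation) are taken
over all qc-passing mutant colonies pooled across plates (a per-plate
reference is available via ``reference="per_plate"``).  Technical
replicates of a gene are summarized by the mean and sample standard
deviation of their z-scores; a one-sample two-sided t-test of the
replicate z-scores against 0 yields a per-gene p-value, and
Benjamini-Hochberg step-up adjustment across genes yields q-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDistributionError, DomainError
from .screen_data import ChannelStats, PlateSet

__all__ = [
    "ScoringConfig",
    "robust_z",
    "summarize_replicates",
    "gene_test",
    "bh_adjust",
    "score_screen",
]

#: Normal-consistency constant for the MAD (sigma estimate = 1.4826 * MAD).
MAD_NORMAL_CONSTANT = 1.4826

#: Readout name -> corrected log column holding its per-colony values.
READOUT_COLUMNS = {"sfGFP": "log_sfGFP", "ratio": "log_ratio"}


@dataclass(frozen=True)
class ScoringConfig:
    """Options for z-score computation.

    ``scale_mad`` multiplies the MAD by the 1.4826 normal-consistency
    constant (off by default: the raw MAD is used as the robust scale).
    ``reference`` selects the median/MAD population: ``"pooled"`` across
    all plates (default) or ``"per_plate"``.
    """

    scale_mad: bool = False
    reference: str = "pooled"

    def __post_init__(self) -> None:
        if self.reference not in ("pooled", "per_plate"):
            raise DomainError(f"unknown reference mode {self.reference!r}")


def robust_z(
    values,
    reference_stats: ChannelStats | None = None,
    channel: str = "value",
    scale_mad: bool = False,
) -> tuple[np.ndarray, ChannelStats]:
    """Robust z-scores of ``values`` against median/MAD reference stats.

    When ``reference_stats`` is None the median and raw MAD are computed
    from ``values`` itself (NaNs excluded from the reference, propagated
    in the output).  A zero MAD raises
    :class:`~tftscreen.errors.DegenerateDistributionError` - infinities
    are never emitted.
    """
    v = np.asarray(values, dtype=float)
    if reference_stats is None:
        finite = v[np.isfinite(v)]
        if finite.size < 10:
            raise DomainError(
                f"need >= 10 finite values to estimate reference stats, "
                f"got {finite.size}"
            )
        med = float(np.median(finite))
        mad = float(np.median(np.abs(finite - med)))
        if scale_mad:
            mad *= MAD_NORMAL_CONSTANT
        reference_stats = ChannelStats(channel=channel, median=med, mad=mad)
    if reference_stats.mad == 0:
        raise DegenerateDistributionError(
            f"MAD of {reference_stats.channel!r} reference distribution is zero"
        )
    z = (v - reference_stats.median) / reference_stats.mad
    return z, reference_stats


def summarize_replicates(
    z_by_colony: pd.DataFrame, replicate_groups=None
) -> pd.DataFrame:
    """Per-gene mean/sd/n of replicate z-scores.

    ``z_by_colony`` needs columns ``gene`` and ``z`` (qc-passing colonies
    only).  ``replicate_groups`` may be the layout's replicate-group
    mapping or any collection of gene names: genes listed there but absent
    from the input are reported with ``n = 0`` and missing scores, never
    silently dropped.  The standard deviation uses the n-1 denominator.
    """
    grouped = z_by_colony.groupby("gene")["z"]
    out = grouped.agg(z_mean="mean", z_sd="std", n="size").reset_index()
    out["n"] = out["n"].astype(int)
    if replicate_groups is not None:
        missing = sorted(set(replicate_groups) - set(out["gene"]))
        if missing:
            pad = pd.DataFrame(
                {"gene": missing, "z_mean": np.nan, "z_sd": np.nan, "n": 0}
            )
            out = pd.concat([out, pad], ignore_index=True)
            out = out.sort_values("gene", kind="mergesort").reset_index(drop=True)
    return out


def gene_test(z_replicates) -> tuple[float, str]:
    """One-sample two-sided t-test of replicate z-scores against 0.

    Returns ``(p, reason)``; ``p`` is NaN with an explanatory reason when
    the test is undefined (fewer than 2 replicates, or zero variance).
    """
    z = np.asarray(z_replicates, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < 2:
        return float("nan"), "fewer than 2 replicates"
    if np.std(z, ddof=1) == 0:
        return float("nan"), "zero variance"
    t = stats.ttest_1samp(z, popmean=0.0)
    return float(t.pvalue), ""


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} min(1, p_(j) * m / j)`` over the sorted
    p-values.  Missing entries (NaN) are passed through and do not count
    towards ``m``.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if not ok.any():
        return q
    if (p[ok] < 0).any() or (p[ok] > 1).any():
        raise DomainError("p-values must lie in [0, 1]")
    q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def score_screen(
    plates: PlateSet,
    cfg: ScoringConfig | None = None,
    readouts: tuple[str, ...] = ("sfGFP", "ratio"),
) -> pd.DataFrame:
    """Full scoring of a normalized screen.

    For each readout: per-colony robust z-scores over qc-passing mutant
    colonies, replicate summarization per gene, a one-sample t-test of the
    replicate z-scores, and BH adjustment across genes.  Returns the
    GeneScore table with columns
    ``gene, readout, n, z_mean, z_sd, p, q, p_reason``.
    """
    cfg = cfg or ScoringConfig()
    pm = plates.passing_mutants()
    lt = plates.layout.table
    all_genes = lt.loc[lt["role"] == "mutant", "gene"].unique()
    tables = []
    for readout in readouts:
        col = READOUT_COLUMNS.get(readout, readout)
        if col not in pm.columns:
            raise DomainError(f"readout column {col!r} missing; normalize first")
        sub = pm[np.isfinite(pm[col])]
        if cfg.reference == "pooled":
            z, _ = robust_z(sub[col], channel=readout, scale_mad=cfg.scale_mad)
            zdf = pd.DataFrame({"gene": sub["gene"].to_numpy(), "z": z})
        else:
            parts = []
            for _, psub in sub.groupby("plate"):
                z, _ = robust_z(psub[col], channel=readout, scale_mad=cfg.scale_mad)
                parts.append(pd.DataFrame({"gene": psub["gene"].to_numpy(), "z": z}))
            zdf = pd.concat(parts, ignore_index=True)
        summary = summarize_replicates(zdf, all_genes)
        # Vectorized equivalent of gene_test over all genes.
        n = summary["n"].to_numpy(float)
        zm = summary["z_mean"].to_numpy(float)
        zsd = summary["z_sd"].to_numpy(float)
        testable = (n >= 2) & np.isfinite(zsd) & (zsd > 0)
        p = np.full(len(summary), np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.abs(zm[testable]) * np.sqrt(n[testable]) / zsd[testable]
        p[testable] = 2.0 * stats.t.sf(tstat, df=n[testable] - 1)
        reason = np.where(
            testable,
            "",
            np.where(
                n == 0,
                "no passing replicates",
                np.where(n < 2, "fewer than 2 replicates", "zero variance"),
            ),
        )
        summary["p"] = p
        summary["p_reason"] = reason
        summary["q"] = bh_adjust(p)
        summary.insert(1, "readout", readout)
        tables.append(summary)
    out = pd.concat(tables, ignore_index=True)
    return out[["gene", "readout", "n", "z_mean", "z_sd", "p", "q", "p_reason"]]
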