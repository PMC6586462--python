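"""Follow-up quantifications: cycloheximide-chase decay fits and flow cytometry.

A cycloheximide chase blocks translation at t = 0; the remaining tagged
protein then decays (to first order) as ``exp(-alpha * t)``.  Band or
reporter intensities are normalized per replicate to t = 0 (optionally
after division by a loading control) and ``log(value)`` is regressed on
time by ordinary least squares pooled across replicates:
``alpha = -slope`` and ``t_half = ln2 / alpha``, with a confidence
interval from the slope's standard error (t quantile, df = points - 2).

Flow-cytometry summaries follow the screen conventions: per-channel means
are blank-corrected against a non-fluorescent control, normalized to the
wild-type sample, and compared to wild type by a two-sample Student's
t-test across replicates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

__all__ = ["ChaseSeries", "ChaseFit", "fit_chase", "flow_summarize"]

log = logging.getLogger(__name__)
LN2 = math.log(2.0)


@dataclass
class ChaseSeries:
    """One chase time course: shared times, per-replicate intensities.

    ``values`` has shape (n_replicates, n_times); ``loading_control``,
    when given, has the same shape and divides the values lane by lane
    before t = 0 normalization.
    """

    times: np.ndarray
    values: np.ndarray
    loading_control: np.ndarray | None = None
    label: str = "chase"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.times.ndim != 1 or self.times.size < 2:
            raise DomainError("times must be a 1-D array with >= 2 points")
        if self.times[0] != 0:
            raise DomainError("times must start at 0 (chase start)")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")
        if self.values.shape[1] != self.times.size:
            raise DomainError("values must have one column per time point")
        if np.any(self.values < 0):
            raise DomainError("intensities must be >= 0")
        if self.loading_control is not None:
            self.loading_control = np.atleast_2d(
                np.asarray(self.loading_control, dtype=float)
            )
            if self.loading_control.shape != self.values.shape:
                raise DomainError("loading_control must match values' shape")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ChaseFit:
    """Result of a first-order decay fit.

    ``half_life`` is ``math.inf`` (with ``no_decay=True``) when the fitted
    slope is non-negative, i.e. no detectable decay.
    """

    alpha: float
    half_life: float
    ci_half_life: tuple[float, float]
    r2: float
    n_replicates: int
    n_points: int
    no_decay: bool = False
    label: str = "chase"


def _halflife_from_alpha(a: float) -> float:
    return math.inf if a <= 0 else LN2 / a


def fit_chase(series: ChaseSeries, ci_level: float = 0.95) -> ChaseFit:
    """Fit a first-order decay rate to a chase series.

    Per replicate the trace is divided by its loading control (if any) and
    normalized to its t = 0 value; non-positive points are dropped with a
    warning.  ``log(value)`` is then regressed on time, pooled across
    replicates, with a free intercept.
    """
    if series.times.size < 3:
        raise DomainError("need >= 3 time points for a decay fit")
    ts, ys = [], []
    for rep in range(series.n_replicates):
        v = series.values[rep].copy()
        if series.loading_control is not None:
            lc = series.loading_control[rep]
            ok = lc > 0
            v = np.where(ok, v / np.where(ok, lc, 1.0), np.nan)
        if not v[0] > 0:
            log.warning("%s rep %d: non-positive t=0 value, replicate dropped",
                        series.label, rep)
            continue
        v = v / v[0]
        good = np.isfinite(v) & (v > 0)
        if (~good).any():
            log.warning("%s rep %d: dropped %d non-positive point(s)",
                        series.label, rep, int((~good).sum()))
        ts.append(series.times[good])
        ys.append(np.log(v[good]))
    if not ts:
        raise DomainError("no usable replicate traces")
    t = np.concatenate(ts)
    y = np.concatenate(ys)
    if np.unique(t).size < 3:
        raise DomainError("fewer than 3 distinct usable time points")
    res = stats.linregress(t, y)
    alpha = -res.slope
    df = t.size - 2
    tq = stats.t.ppf(0.5 + ci_level / 2.0, df)
    slope_lo = res.slope - tq * res.stderr
    slope_hi = res.slope + tq * res.stderr
    # alpha = -slope: the CI flips.
    a_lo, a_hi = -slope_hi, -slope_lo
    ci = (_halflife_from_alpha(a_hi), _halflife_from_alpha(a_lo))
    r2 = float(res.rvalue**2)
    if alpha <= 0:
        return ChaseFit(
            alpha=alpha,
            half_life=math.inf,
            ci_half_life=ci,
            r2=r2,
            n_replicates=len(ts),
            n_points=t.size,
            no_decay=True,
            label=series.label,
        )
    return ChaseFit(
        alpha=alpha,
        half_life=LN2 / alpha,
        ci_half_life=ci,
        r2=r2,
        n_replicates=len(ts),
        n_points=t.size,
        label=series.label,
    )


def flow_summarize(
    events: pd.DataFrame,
    blank: str = "blank",
    wt: str = "wt",
    channels: tuple[str, ...] = ("sfGFP", "mCherry"),
    epsilon: float = 1e-12,
) -> pd.DataFrame:
    """Summarize flow-cytometry samples with blank correction and wt scaling.

    ``events`` is tidy with columns ``sample, replicate`` and one column
    per channel, holding either per-event intensities (many rows per
    replicate) or precomputed per-replicate means (one row each).  Per
    channel: replicate means are blank-corrected by subtracting the mean
    over the blank sample's replicates (floored at ``epsilon`` and flagged
    ``low_signal`` if the signal does not exceed the blank); sample means
    are then normalized to the wild-type sample (wt = 1 exactly).  The
    ratio readout is the per-replicate corrected mCherry/sfGFP ratio, also
    normalized to wt.  p-values are two-sample Student's t-tests against
    the wt replicates.
    """
    need = {"sample", "replicate", *channels}
    missing = need - set(events.columns)
    if missing:
        raise DomainError(f"event table lacks columns {sorted(missing)}")
    for name in (blank, wt):
        if name not in set(events["sample"]):
            raise DomainError(f"sample {name!r} missing from event table")

    rep_means = (
        events.groupby(["sample", "replicate"], sort=True)
        .agg(n_events=("replicate", "size"), **{ch: (ch, "mean") for ch in channels})
        .reset_index()
    )
    blank_means = {
        ch: float(rep_means.loc[rep_means["sample"] == blank, ch].mean())
        for ch in channels
    }
    for ch in channels:
        rep_means[f"{ch}_corr"] = np.maximum(rep_means[ch] - blank_means[ch], epsilon)
    if len(channels) == 2:
        c0, c1 = channels
        rep_means["ratio"] = rep_means[f"{c1}_corr"] / rep_means[f"{c0}_corr"]

    def sample_frame(name: str) -> pd.DataFrame:
        return rep_means[rep_means["sample"] == name]

    wt_f = sample_frame(wt)
    rows = []
    for name, grp in rep_means.groupby("sample", sort=True):
        rec: dict = {
            "sample": name,
            "n_replicates": len(grp),
            "n_events": int(grp["n_events"].sum()),
        }
        low = False
        for ch in channels:
            raw_mean = float(grp[ch].mean())
            corr = float(np.maximum(raw_mean - blank_means[ch], epsilon))
            if raw_mean - blank_means[ch] <= 0 and name != blank:
                low = True
            wt_corr = float(
                np.maximum(wt_f[ch].mean() - blank_means[ch], epsilon)
            )
            rec[f"{ch}_mean"] = raw_mean
            rec[f"{ch}_corrected"] = corr
            rec[f"{ch}_norm"] = corr / wt_corr
            a = grp[f"{ch}_corr"].to_numpy(float)
            b = wt_f[f"{ch}_corr"].to_numpy(float)
            rec[f"p_{ch}"] = (
                float(stats.ttest_ind(a, b, equal_var=True).pvalue)
                if name != wt and len(a) >= 2 and len(b) >= 2
                else np.nan
            )
        if "ratio" in rep_means.columns:
            rec["ratio"] = float(grp["ratio"].mean())
            rec["ratio_norm"] = rec["ratio"] / float(wt_f["ratio"].mean())
            a = grp["ratio"].to_numpy(float)
            b = wt_f["ratio"].to_numpy(float)
            rec["p_ratio"] = (
                float(stats.ttest_ind(a, b, equal_var=True).pvalue)
                if name != wt and len(a) >= 2 and len(b) >= 2
                else np.nan
            )
        rec["low_signal"] = low
        rows.append(rec)
    return pd.DataFrame(rows)
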