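"""Colony QC and intensity normalization.

The normalization chain for a colony-array fluorescence screen is:

1. :func:`qc_filter` - flag potentially failed crosses by colony size
   (small colonies indicate an unsuccessful mating/selection, not biology).
2. :func:`background_and_median_normalize` - optional local background
   subtraction against neighbouring non-fluorescent control colonies and
   scaling to the screen median (used for targeted and TA-array screens).
3. :func:`log_transform` - per-channel log transform; the timer readout
   becomes the additive ``log_ratio = log mCherry - log sfGFP``.
4. :func:`spatial_normalize` - per-plate correction of smooth spatial
   intensity trends (edge effects, uneven illumination, agar thickness) by
   2-D locally weighted polynomial regression on the grid coordinates.

Flagged colonies are excluded from every fitted statistic but are carried
through (with flags) so nothing is dropped silently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, QCError
from .screen_data import (
    CHANNELS,
    QC_EXCLUDED,
    QC_FAILED_CROSS,
    QC_PASS,
    PlateSet,
)

__all__ = [
    "NormalizationConfig",
    "qc_filter",
    "log_transform",
    "loess_2d",
    "spatial_normalize",
    "background_and_median_normalize",
    "normalize_screen",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizationConfig:
    """Tunable knobs of the normalization chain.

    Parameters
    ----------
    min_size_fraction
        Colonies smaller than this fraction of the plate median size are
        flagged ``failed_cross``.
    log_base
        Base of the log transform (natural log by default; the choice only
        rescales z-scores, it never changes their ranking).
    spatial_method
        ``"local_regression"`` (2-D loess), ``"median_filter"`` or
        ``"none"``.
    span
        Fraction of plate colonies in each local regression neighbourhood.
    degree
        Local polynomial degree (1 or 2).  Degree 2 also removes
        curvature bias of bowl-shaped fields at plate edges.
    robustness_iters
        Number of bisquare reweighting passes after the initial fit.
    background_mode
        ``"none"`` or ``"local_control_colonies"`` (subtract the mean raw
        intensity of the ``k_controls`` nearest non-fluorescent controls).
    median_scale
        Divide each channel by the screen-wide median of qc-passing mutant
        colonies so the screen median becomes 1 (0 in log space).
    """

    min_size_fraction: float = 0.5
    log_base: float = math.e
    spatial_method: str = "local_regression"
    span: float = 0.3
    degree: int = 2
    robustness_iters: int = 1
    background_mode: str = "none"
    k_controls: int = 4
    median_scale: bool = False
    min_colonies_spatial: int = 30
    include_reference_in_fit: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.min_size_fraction < 1.0:
            raise ConfigError("min_size_fraction must be in (0, 1)")
        if not 0.0 < self.span <= 1.0:
            raise ConfigError("span must be in (0, 1]")
        if self.degree not in (1, 2):
            raise ConfigError("degree must be 1 or 2")
        if self.spatial_method not in ("local_regression", "median_filter", "none"):
            raise ConfigError(f"unknown spatial_method {self.spatial_method!r}")
        if self.background_mode not in ("none", "local_control_colonies"):
            raise ConfigError(f"unknown background_mode {self.background_mode!r}")


def qc_filter(plates: PlateSet, cfg: NormalizationConfig) -> PlateSet:
    """Flag potentially failed crosses based on colony size.

    A colony is flagged ``failed_cross`` when its size falls below
    ``min_size_fraction`` times the median size of qc-passing colonies on
    the same plate.  Because flagging shrinks the passing population (and
    can only raise the median), the criterion is iterated to a fixed point,
    which makes the operation idempotent.  Empty layout positions are
    flagged ``excluded`` outright.
    """
    out = plates.copy()
    d = out.data
    d.loc[d["role"] == "empty", "qc_flag"] = QC_EXCLUDED
    for plate_id, idx in d.groupby("plate").groups.items():
        sizes = d.loc[idx, "size"].to_numpy(float)
        if np.all(sizes == 0):
            raise QCError(f"plate {plate_id!r}: all colony sizes are zero")
        flags = d.loc[idx, "qc_flag"].to_numpy(object)
        passing = flags == QC_PASS
        while True:
            med = np.median(sizes[passing])
            new_fail = passing & (sizes < cfg.min_size_fraction * med)
            if not new_fail.any():
                break
            passing &= ~new_fail
            flags[new_fail] = QC_FAILED_CROSS
            if not passing.any():
                raise QCError(f"plate {plate_id!r}: every colony flagged failed_cross")
        d.loc[idx, "qc_flag"] = flags
    _warn_low_replicate_groups(out)
    return out


def _warn_low_replicate_groups(plates: PlateSet) -> None:
    pm = plates.passing_mutants()
    n_pass = pm["gene"].value_counts()
    lt = plates.layout.table
    n_total = lt.loc[lt["role"] != "empty", "gene"].value_counts()
    low = [
        g
        for g in n_total.index[n_total >= 2]
        if n_pass.get(g, 0) < 2
    ]
    if low:
        log.warning(
            "REDUCED_CONFIDENCE %s: %d gene(s) with <2 passing replicates: %s",
            plates.screen_id,
            len(low),
            ",".join(low[:10]) + ("..." if len(low) > 10 else ""),
        )


def log_transform(plates: PlateSet, cfg: NormalizationConfig | None = None) -> PlateSet:
    """Attach per-channel log intensities and the additive ratio channel.

    Colonies with a non-positive intensity in either channel are flagged
    ``excluded`` (their logs are undefined) rather than dropped.
    Exponentiating the stored logs recovers the raw values.
    """
    cfg = cfg or NormalizationConfig()
    out = plates.copy()
    d = out.data
    scale = math.log(cfg.log_base)
    nonpos = (d["sfGFP"] <= 0) | (d["mCherry"] <= 0)
    newly = nonpos & (d["qc_flag"] == QC_PASS)
    if newly.any():
        log.warning(
            "%s: %d colony(ies) with non-positive intensity excluded from logs",
            out.screen_id,
            int(newly.sum()),
        )
        d.loc[newly, "qc_flag"] = QC_EXCLUDED
    for ch in CHANNELS:
        vals = d[ch].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            logged = np.log(vals) / scale
        logged[nonpos.to_numpy()] = np.nan
        d[f"log_{ch}"] = logged
    d["log_ratio"] = d["log_mCherry"] - d["log_sfGFP"]
    return out


def _poly_basis(r: np.ndarray, c: np.ndarray, degree: int) -> np.ndarray:
    cols = [np.ones_like(r), r, c]
    if degree == 2:
        cols += [r * r, r * c, c * c]
    return np.column_stack(cols)


def loess_2d(
    rows,
    cols,
    values,
    span: float = 0.3,
    degree: int = 2,
    robustness_iters: int = 1,
    eval_rows=None,
    eval_cols=None,
) -> np.ndarray:
    """Locally weighted polynomial surface fit on grid coordinates.

    For each evaluation point, a polynomial of the given degree in
    ``(row, col)`` is fitted by weighted least squares over the ``span``
    fraction of nearest training colonies with tricube distance weights;
    ``robustness_iters`` bisquare reweighting passes downweight outliers.
    All point-wise fits are solved in one batched pass.

    Returns the fitted surface at the evaluation points (the training
    points by default).
    """
    r = np.asarray(rows, float)
    c = np.asarray(cols, float)
    v = np.asarray(values, float)
    n = v.size

    # Scale coordinates for conditioning of the normal equations.
    s = max(r.max() - r.min(), c.max() - c.min(), 1.0)
    r0, c0 = r.mean(), c.mean()
    rs, cs = (r - r0) / s, (c - c0) / s

    # Evaluation points: the training points first, then any extra points,
    # so robust residuals can be read off the same batched fit.
    external = eval_rows is not None
    if external:
        ers = np.concatenate([rs, (np.asarray(eval_rows, float) - r0) / s])
        ecs = np.concatenate([cs, (np.asarray(eval_cols, float) - c0) / s])
    else:
        ers, ecs = rs, cs

    X = _poly_basis(rs, cs, degree)
    E = _poly_basis(ers, ecs, degree)
    W = _tricube_weights(rs, cs, ers, ecs, span, X.shape[1])
    fit = _weighted_fit(W, X, E, v, robustness_iters, train_rows=np.arange(n))
    return fit[n:] if external else fit


def _tricube_weights(rs, cs, ers, ecs, span: float, p: int) -> np.ndarray:
    """Tricube kernel weights between evaluation and training points."""
    n = rs.size
    k = int(np.clip(math.ceil(span * n), p + 2, n))
    d2 = (ers[:, None] - rs[None, :]) ** 2 + (ecs[:, None] - cs[None, :]) ** 2
    dmax = np.sqrt(np.partition(d2, k - 1, axis=1)[:, k - 1])
    dmax = np.maximum(dmax, 1e-12)
    u = np.sqrt(d2, out=d2)
    u /= dmax[:, None]
    w = u * u * u  # tricube without float powers (hot path)
    np.subtract(1.0, w, out=w)
    np.maximum(w, 0.0, out=w)
    W = w * w * w
    dead = W.sum(axis=1) <= 0.0
    if dead.any():  # isolated evaluation point: fall back to uniform k-NN
        W[dead] = (u[dead] <= 1.0).astype(float)
    return W


def _weighted_fit(
    W: np.ndarray,
    X: np.ndarray,
    E: np.ndarray,
    v: np.ndarray,
    robustness_iters: int,
    train_rows: np.ndarray,
) -> np.ndarray:
    """Batched weighted polynomial solves, with bisquare robustness passes.

    ``train_rows`` indexes the evaluation rows of ``E`` that correspond to
    the training points (robust residuals are computed there).
    """
    n, p = X.shape
    XX = (X[:, :, None] * X[:, None, :]).reshape(n, p * p)
    Xv = X * v[:, None]
    ridge = 1e-10 * np.eye(p)[None, :, :]
    robust = np.ones(n)
    fit = np.zeros(E.shape[0])
    for it in range(robustness_iters + 1):
        Wr = W if it == 0 else W * robust[None, :]
        A = (Wr @ XX).reshape(-1, p, p) + ridge
        b = Wr @ Xv
        beta = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        fit = np.einsum("ij,ij->i", E, beta)
        if it == robustness_iters:
            break
        resid = v - fit[train_rows]
        sres = np.median(np.abs(resid))
        if sres <= 0:
            break
        r = resid / (6.0 * sres)
        robust = np.maximum(1.0 - r * r, 0.0)
        robust *= robust
    return fit


def _median_filter_surface(
    rows, cols, values, n_rows: int, n_cols: int, span: float
) -> np.ndarray:
    from scipy.ndimage import median_filter

    grid = np.full((n_rows, n_cols), np.nan)
    grid[np.asarray(rows, int), np.asarray(cols, int)] = values
    fill = np.nanmedian(grid)
    grid = np.where(np.isnan(grid), fill, grid)
    w = max(3, int(round(math.sqrt(span * n_rows * n_cols))) | 1)
    smooth = median_filter(grid, size=w, mode="nearest")
    return smooth[np.asarray(rows, int), np.asarray(cols, int)]


def spatial_normalize(
    plates: PlateSet,
    cfg: NormalizationConfig,
    channels: tuple[str, ...] = ("log_sfGFP", "log_mCherry"),
) -> PlateSet:
    """Remove smooth spatial trends from each plate and channel.

    A surface ``f(row, col)`` is fitted to the qc-passing log values and
    subtracted; corrected values are recentred so the plate median is
    exactly preserved.  The correction (the fitted surface) is evaluated at
    and applied to *every* colony of the plate, flagged ones included.
    Plates with fewer than ``min_colonies_spatial`` passing colonies fall
    back to plate-median centring with a logged warning.

    The ratio channel is recomputed from the corrected per-channel logs.
    """
    if cfg.spatial_method == "none":
        return plates
    out = plates.copy()
    d = out.data
    for plate_id, idx in d.groupby("plate").groups.items():
        sub = d.loc[idx]
        fit_mask = (sub["qc_flag"] == QC_PASS).to_numpy()
        if not cfg.include_reference_in_fit:
            fit_mask &= (sub["role"] != "reference").to_numpy()
        rows = sub["row"].to_numpy(float)
        cols = sub["col"].to_numpy(float)
        # The tricube weight geometry depends only on the usable-colony
        # mask; it is shared between channels with identical masks (the
        # common case, since log-transform flags both channels together).
        geom_cache: dict[bytes, tuple] = {}
        for ch in channels:
            vals = sub[ch].to_numpy(float)
            ok = fit_mask & np.isfinite(vals)
            if ok.sum() < cfg.min_colonies_spatial:
                log.warning(
                    "%s plate %s channel %s: only %d usable colonies; "
                    "falling back to median centring",
                    out.screen_id,
                    plate_id,
                    ch,
                    int(ok.sum()),
                )
                continue
            if cfg.spatial_method == "local_regression":
                key = ok.tobytes()
                if key not in geom_cache:
                    s = max(rows.max() - rows.min(), cols.max() - cols.min(), 1.0)
                    r0, c0 = rows[ok].mean(), cols[ok].mean()
                    rs, cs = (rows - r0) / s, (cols - c0) / s
                    X = _poly_basis(rs[ok], cs[ok], cfg.degree)
                    E = _poly_basis(rs, cs, cfg.degree)
                    W = _tricube_weights(
                        rs[ok], cs[ok], rs, cs, cfg.span, X.shape[1]
                    )
                    geom_cache[key] = (W, X, E, np.flatnonzero(ok))
                W, X, E, train_rows = geom_cache[key]
                surface = _weighted_fit(
                    W, X, E, vals[ok], cfg.robustness_iters, train_rows
                )
            else:
                surface = _median_filter_surface(
                    rows, cols, vals, out.layout.n_rows, out.layout.n_cols, cfg.span
                )
            med_in = np.median(vals[ok])
            corrected = vals - surface
            corrected += med_in - np.median(corrected[ok])
            d.loc[idx, ch] = corrected
    if "log_sfGFP" in channels and "log_mCherry" in channels:
        d["log_ratio"] = d["log_mCherry"] - d["log_sfGFP"]
    return out


def background_and_median_normalize(
    plates: PlateSet, cfg: NormalizationConfig
) -> PlateSet:
    """Local background correction and screen-median scaling (raw scale).

    With ``background_mode="local_control_colonies"``, each colony's raw
    intensity is reduced by the mean intensity of its ``k_controls``
    nearest non-fluorescent control colonies on the same plate.  Values
    driven to or below zero are floored at ``1e-6 x`` the screen median and
    the colony is flagged ``excluded``.  With ``median_scale`` on, each
    channel is then divided by the screen-wide median over qc-passing
    mutant colonies, so the screen median becomes exactly 1.
    """
    out = plates.copy()
    d = out.data
    if cfg.background_mode == "local_control_colonies":
        pre_medians = {
            ch: float(np.median(out.passing_mutants()[ch])) for ch in CHANNELS
        }
        for plate_id, idx in d.groupby("plate").groups.items():
            sub = d.loc[idx]
            ctrl = sub[
                (sub["role"] == "non_fluorescent_control")
                & (sub["qc_flag"] == QC_PASS)
            ]
            if ctrl.empty:
                raise ConfigError(
                    f"plate {plate_id!r}: background_mode=local_control_colonies "
                    "but no passing non-fluorescent control colonies in layout"
                )
            k = min(cfg.k_controls, len(ctrl))
            dr = sub["row"].to_numpy(float)[:, None] - ctrl["row"].to_numpy(float)
            dc = sub["col"].to_numpy(float)[:, None] - ctrl["col"].to_numpy(float)
            d2 = dr * dr + dc * dc
            nearest = np.argpartition(d2, k - 1, axis=1)[:, :k]
            for ch in CHANNELS:
                bg = ctrl[ch].to_numpy(float)[nearest].mean(axis=1)
                vals = sub[ch].to_numpy(float) - bg
                eps = 1e-6 * max(pre_medians[ch], 1e-300)
                low = vals < eps
                newly = low & (sub["qc_flag"] == QC_PASS).to_numpy()
                if newly.any():
                    d.loc[idx[newly], "qc_flag"] = QC_EXCLUDED
                d.loc[idx, ch] = np.where(low, eps, vals)
    if cfg.median_scale:
        pm = out.passing_mutants()
        for ch in CHANNELS:
            med = float(np.median(pm[ch]))
            if med <= 0:
                raise QCError(f"screen median of {ch} is not positive")
            d[ch] = d[ch] / med
    return out


def normalize_screen(plates: PlateSet, cfg: NormalizationConfig) -> PlateSet:
    """Full normalization chain in canonical order.

    qc_filter -> background/median (raw scale) -> log transform -> spatial
    correction per plate per channel -> ratio channel from corrected logs.
    """
    out = qc_filter(plates, cfg)
    if cfg.background_mode != "none" or cfg.median_scale:
        out = background_and_median_normalize(out, cfg)
    out = log_transform(out, cfg)
    out = spatial_normalize(out, cfg)
    return out
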