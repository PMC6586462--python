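"""Kinetic model of the tandem fluorescent timer (tFT).

A tFT is a fusion of a fast-maturing green fluorophore (sfGFP) and a
slow-maturing red one (mCherry).  Newly made fusion protein is dark, turns
green quickly, and acquires red fluorescence only if it survives long
enough for mCherry to mature.  The mCherry/sfGFP intensity ratio therefore
increases with the half-life of the tagged protein and can be used as an
in-vivo turnover readout.

The model is a linear ODE system.  For each fluorophore, synthesis (rate
``beta``) produces an immature species that matures with first-order rate
``mG`` (sfGFP) or ``mC1`` (mCherry; optionally two sequential steps ``mC1``
then ``mC2``).  Every species - immature or mature - is degraded with the
first-order rate ``alpha`` of the tagged protein.  At steady state the
mature pools are

    I_G = beta * mG / (alpha * (mG + alpha))
    I_C = beta * mC1 / (alpha * (mC1 + alpha))            (one-step mCherry)

so the intensity ratio

    R(alpha) = I_C / I_G = mC1 * (mG + alpha) / (mG * (mC1 + alpha))

is dimensionless, tends to 1 for a stable protein (alpha -> 0), decreases
strictly monotonically in ``alpha`` and approaches ``mC1/mG`` as
``alpha -> inf``.  Protein half-life is ``t_half = ln2 / alpha``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import brentq

from .errors import DomainError, InvalidParameterError

__all__ = [
    "TimerParams",
    "TimerPrediction",
    "steady_state_prediction",
    "steady_state_arrays",
    "ratio_to_halflife",
    "alpha_from_ratio",
    "timer_timecourse",
    "DEFAULT_MG",
    "DEFAULT_MC1",
]

LN2 = math.log(2.0)

#: Default maturation rate constants (1/min).  These are configurable
#: placeholders in the range reported for sfGFP (~6 min maturation
#: half-time) and mCherry (~40 min); calibrate them per instrument and
#: strain background before quantitative half-life inversion.
DEFAULT_MG = LN2 / 6.0
DEFAULT_MC1 = LN2 / 40.0


@dataclass(frozen=True)
class TimerParams:
    """Rate constants of the timer reporter.

    Parameters
    ----------
    beta
        Protein production rate (AU/min); must be > 0 for steady-state
        operations.
    alpha
        First-order degradation rate of the tagged protein (1/min);
        half-life is ``ln2 / alpha``.  May be 0 (stable protein).
    mG
        sfGFP maturation rate (1/min).
    mC1, mC2
        mCherry maturation rate(s) (1/min); ``mC2`` is used only in
        ``two_step`` mode.
    mode
        ``"one_step"`` (single effective mCherry maturation rate, admits
        closed forms) or ``"two_step"``.
    """

    beta: float = 1.0
    alpha: float = 0.0
    mG: float = DEFAULT_MG
    mC1: float = DEFAULT_MC1
    mC2: float | None = None
    mode: str = "one_step"

    def __post_init__(self) -> None:
        if self.mode not in ("one_step", "two_step"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        rates = [self.beta, self.alpha, self.mG, self.mC1]
        if self.mode == "two_step":
            if self.mC2 is None:
                raise InvalidParameterError("two_step mode requires mC2")
            rates.append(self.mC2)
        if any(r < 0 for r in rates):
            raise InvalidParameterError("all rates must be >= 0")
        if self.mG <= 0 or self.mC1 <= 0 or (self.mode == "two_step" and self.mC2 <= 0):
            raise InvalidParameterError("maturation rates must be > 0")

    @property
    def half_life(self) -> float:
        return math.inf if self.alpha == 0 else LN2 / self.alpha

    def with_alpha(self, alpha: float) -> "TimerParams":
        return replace(self, alpha=alpha)


@dataclass(frozen=True)
class TimerPrediction:
    """Steady-state mature intensities and their normalized ratio.

    ``bounded`` is False when ``alpha == 0``: the ratio limit (exactly 1)
    is still reported but the absolute pools grow without bound.
    """

    iG: float
    iC: float
    ratio: float
    bounded: bool = True


def _ratio_one_step(alpha, mG, mC1):
    return mC1 * (mG + alpha) / (mG * (mC1 + alpha))


def _ratio_two_step(alpha, mG, mC1, mC2):
    return (mC1 * mC2 * (mG + alpha)) / (mG * (mC1 + alpha) * (mC2 + alpha))


def steady_state_prediction(params: TimerParams) -> TimerPrediction:
    """Closed-form steady state of the timer ODE system.

    Requires ``beta > 0``.  For ``alpha == 0`` the analytic limit
    ``ratio = 1`` is returned with infinite pools and ``bounded=False``.
    """
    p = params
    if p.beta <= 0:
        raise InvalidParameterError("steady state requires beta > 0")
    if p.alpha == 0:
        return TimerPrediction(iG=math.inf, iC=math.inf, ratio=1.0, bounded=False)
    a = p.alpha
    iG = p.beta * p.mG / (a * (p.mG + a))
    if p.mode == "one_step":
        iC = p.beta * p.mC1 / (a * (p.mC1 + a))
        ratio = _ratio_one_step(a, p.mG, p.mC1)
    else:
        iC = p.beta * p.mC1 * p.mC2 / (a * (p.mC1 + a) * (p.mC2 + a))
        ratio = _ratio_two_step(a, p.mG, p.mC1, p.mC2)
    return TimerPrediction(iG=iG, iC=iC, ratio=ratio, bounded=True)


def steady_state_arrays(params: TimerParams, alphas: np.ndarray):
    """Vectorized steady-state (iG, iC, ratio) over an array of alphas.

    All alphas must be > 0 (use :func:`steady_state_prediction` for the
    alpha = 0 limit).
    """
    a = np.asarray(alphas, dtype=float)
    if np.any(a <= 0):
        raise DomainError("steady_state_arrays requires alpha > 0")
    p = params
    iG = p.beta * p.mG / (a * (p.mG + a))
    if p.mode == "one_step":
        iC = p.beta * p.mC1 / (a * (p.mC1 + a))
        ratio = _ratio_one_step(a, p.mG, p.mC1)
    else:
        iC = p.beta * p.mC1 * p.mC2 / (a * (p.mC1 + a) * (p.mC2 + a))
        ratio = _ratio_two_step(a, p.mG, p.mC1, p.mC2)
    return iG, iC, ratio


def alpha_from_ratio(ratio: float, params: TimerParams) -> float:
    """Invert the monotone map alpha -> R(alpha) for the degradation rate.

    ``ratio = 1`` maps to ``alpha = 0`` (stable protein).  Outside the
    attainable interval a :class:`DomainError` names the interval.
    """
    p = params
    if ratio == 1.0:
        return 0.0
    if p.mode == "one_step":
        lo = p.mC1 / p.mG
        if not lo < ratio < 1.0:
            raise DomainError(
                f"ratio {ratio} outside attainable interval ({lo:.6g}, 1] "
                f"for one_step timer (mC1/mG = {lo:.6g})"
            )
        return p.mC1 * p.mG * (1.0 - ratio) / (ratio * p.mG - p.mC1)
    if not 0.0 < ratio < 1.0:
        raise DomainError(f"ratio {ratio} outside attainable interval (0, 1]")

    def f(a):
        return _ratio_two_step(a, p.mG, p.mC1, p.mC2) - ratio

    hi = 1.0
    while f(hi) > 0:
        hi *= 10.0
        if hi > 1e12:  # pragma: no cover - unreachable for valid params
            raise DomainError("failed to bracket ratio inversion")
    return brentq(f, 0.0, hi, xtol=1e-15, rtol=1e-14)


def ratio_to_halflife(ratio: float, params: TimerParams) -> float:
    """Protein half-life (min) implied by a normalized timer ratio.

    Returns ``math.inf`` for ``ratio = 1`` (no detectable turnover).
    """
    alpha = alpha_from_ratio(ratio, params)
    return math.inf if alpha == 0 else LN2 / alpha


def _species(params: TimerParams) -> list[str]:
    if params.mode == "one_step":
        return ["sfGFP_dark", "sfGFP", "mCherry_dark", "mCherry"]
    return ["sfGFP_dark", "sfGFP", "mCherry_dark", "mCherry_int", "mCherry"]


def _system_matrix(params: TimerParams, production_on: bool) -> tuple[np.ndarray, np.ndarray]:
    p = params
    a = p.alpha
    if p.mode == "one_step":
        A = np.array(
            [
                [-(p.mG + a), 0.0, 0.0, 0.0],
                [p.mG, -a, 0.0, 0.0],
                [0.0, 0.0, -(p.mC1 + a), 0.0],
                [0.0, 0.0, p.mC1, -a],
            ]
        )
        b = np.array([1.0, 0.0, 1.0, 0.0])
    else:
        A = np.array(
            [
                [-(p.mG + a), 0.0, 0.0, 0.0, 0.0],
                [p.mG, -a, 0.0, 0.0, 0.0],
                [0.0, 0.0, -(p.mC1 + a), 0.0, 0.0],
                [0.0, 0.0, p.mC1, -(p.mC2 + a), 0.0],
                [0.0, 0.0, 0.0, p.mC2, -a],
            ]
        )
        b = np.array([1.0, 0.0, 1.0, 0.0, 0.0])
    b = b * (p.beta if production_on else 0.0)
    return A, b


def _default_y0(params: TimerParams, production_on: bool) -> np.ndarray:
    n = len(_species(params))
    if production_on:
        return np.zeros(n)
    # Translation shutoff (cycloheximide chase): start from the pre-shutoff
    # steady state when it exists, otherwise from unit immature pools.
    if params.alpha > 0 and params.beta > 0:
        p = params
        a = p.alpha
        gf = p.beta / (p.mG + a)
        G = p.mG * gf / a
        c1 = p.beta / (p.mC1 + a)
        if p.mode == "one_step":
            C = p.mC1 * c1 / a
            return np.array([gf, G, c1, C])
        c2 = p.mC1 * c1 / (p.mC2 + a)
        C = p.mC2 * c2 / a
        return np.array([gf, G, c1, c2, C])
    y0 = np.zeros(n)
    y0[0] = 1.0
    y0[2] = 1.0
    return y0


def timer_timecourse(
    params: TimerParams,
    times,
    production_on: bool = True,
    y0: np.ndarray | None = None,
) -> pd.DataFrame:
    """Solve the timer ODE system at the requested times.

    The system is linear with constant coefficients, so each time point is
    propagated exactly with a matrix exponential of the augmented system
    (state extended by the constant production input).

    With ``production_on=False`` (translation shutoff) the total tagged
    protein of each fluorophore, immature + mature, decays as
    ``exp(-alpha * t)``: maturation only interconverts species within a
    fluorophore while degradation removes every species at rate ``alpha``.

    Returns a DataFrame indexed by time with one column per species plus
    ``total_sfGFP`` and ``total_mCherry``.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise DomainError("times must be a non-empty 1-D array")
    if np.any(t < 0):
        raise DomainError("times must be >= 0")
    if np.any(np.diff(t) < 0):
        raise DomainError("times must be sorted ascending")

    species = _species(params)
    A, b = _system_matrix(params, production_on)
    x0 = _default_y0(params, production_on) if y0 is None else np.asarray(y0, float)
    if x0.shape != (len(species),):
        raise DomainError(f"y0 must have shape ({len(species)},)")

    n = len(species)
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = A
    M[:n, n] = b
    aug0 = np.append(x0, 1.0)

    out = np.empty((t.size, n))
    for i, ti in enumerate(t):
        out[i] = (expm(M * ti) @ aug0)[:n]

    df = pd.DataFrame(out, index=pd.Index(t, name="time_min"), columns=species)
    df["total_sfGFP"] = df["sfGFP_dark"] + df["sfGFP"]
    red = [s for s in species if s.startswith("mCherry")]
    df["total_mCherry"] = df[red].sum(axis=1)
    return df
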