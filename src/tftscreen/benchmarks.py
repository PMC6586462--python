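"""Simulation benchmarks closing the loop between generator and analysis.

Each benchmark plants known truth with the synthetic generator, runs the
actual analysis chain, and measures recovery.  They are used both by the
test suite and by ``scripts/acceptance.py``; all are pure functions of
their seeds.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import solve_ivp

from .assays import fit_chase
from .hit_calling import VERDICT_CONTROL, VERDICT_HIT
from .normalization import NormalizationConfig, normalize_screen
from .pipeline import analyze_screen
from .scoring import ScoringConfig, score_screen
from .synthetic_data import (
    SpatialFieldConfig,
    default_screen_config,
    generate_chase,
    generate_screen,
)
from .timer_model import TimerParams, steady_state_prediction

__all__ = [
    "hit_recovery",
    "null_fdr",
    "spatial_residual",
    "chase_recovery",
    "timer_consistency",
]

LN2 = math.log(2.0)


def hit_recovery(
    n_seeds: int = 20,
    base_seed: int = 0,
    n_genes: int = 4608,
    n_hits: int = 20,
    n_confounders: int = 5,
    **config_overrides,
) -> dict:
    """Planted-hit recovery of the full dual-reporter pipeline.

    Aggregated over ``n_seeds`` simulated screens (default: the desk-scale
    default screen with 20 planted 3-fold stabilizers and 5 dual-reporter
    confounders): sensitivity of the final hit verdict for planted genes,
    empirical false discovery proportion among called hits, and the
    fraction of confounders routed to ``excluded_control_affected``.
    ``z_sensitivity`` tracks the z-threshold-and-control criterion alone
    (without the FDR leg) for diagnosis.
    """
    tp = fp = called = 0
    z_tp = 0
    conf_routed = conf_total = 0
    planted_total = 0
    for i in range(n_seeds):
        cfg = default_screen_config(
            seed=base_seed + i,
            n_genes=n_genes,
            n_hits=n_hits,
            n_confounders=n_confounders,
            **config_overrides,
        )
        query, control, truth = generate_screen(cfg)
        _, _, qs, cs, hits = analyze_screen(query, control)
        merged = hits.merge(truth, on="gene")
        is_hit = merged["verdict"] == VERDICT_HIT
        planted = merged["is_planted_hit"]
        conf = merged["is_confounder"]
        tp += int((is_hit & planted).sum())
        fp += int((is_hit & ~planted).sum())
        called += int(is_hit.sum())
        planted_total += int(planted.sum())
        z_pass = (
            (merged["z_sfGFP"] > merged["z_threshold"])
            & (merged["z_ratio"] > merged["z_threshold"])
            & (merged["control_z_sfGFP"].abs() < merged["control_z_max"])
            & (merged["control_z_ratio"].abs() < merged["control_z_max"])
        )
        z_tp += int((z_pass & planted).sum())
        conf_routed += int((conf & (merged["verdict"] == VERDICT_CONTROL)).sum())
        conf_total += int(conf.sum())
    return {
        "n_seeds": n_seeds,
        "sensitivity": tp / planted_total if planted_total else float("nan"),
        "fdp": fp / called if called else 0.0,
        "confounder_routing": conf_routed / conf_total if conf_total else float("nan"),
        "z_sensitivity": z_tp / planted_total if planted_total else float("nan"),
        "n_called": called,
    }


def null_fdr(
    n_seeds: int = 100,
    base_seed: int = 0,
    n_genes: int = 1152,
    q_level: float = 0.05,
    z_threshold: float = 3.0,
) -> dict:
    """False-positive control on pure-null screens (no planted effects).

    Per seed, a query screen without effects is generated, normalized and
    scored; reported are the mean fraction of genes with ``q <= q_level``
    on either readout and the mean fraction with both ``z_mean >
    z_threshold`` and both ``q <= q_level`` (the hit criterion without the
    control leg).
    """
    q_fracs, joint_fracs = [], []
    for i in range(n_seeds):
        cfg = default_screen_config(
            seed=base_seed + i, n_genes=n_genes, n_hits=0, n_confounders=0
        )
        query, _, _ = generate_screen(cfg)
        scores = score_screen(normalize_screen(query, NormalizationConfig()))
        wide = scores.pivot(index="gene", columns="readout",
                            values=["z_mean", "q"])
        q = wide["q"].to_numpy(float)
        z = wide["z_mean"].to_numpy(float)
        with np.errstate(invalid="ignore"):
            q_hit = (q <= q_level).any(axis=1)
            joint = ((z > z_threshold) & (q <= q_level)).all(axis=1)
        q_fracs.append(q_hit.mean())
        joint_fracs.append(joint.mean())
    return {
        "n_seeds": n_seeds,
        "n_genes": n_genes,
        "mean_q_fraction": float(np.mean(q_fracs)),
        "mean_joint_fraction": float(np.mean(joint_fracs)),
    }


def spatial_residual(
    n_seeds: int = 20,
    base_seed: int = 0,
    n_genes: int = 1152,
    amplitude: float = LN2,
    noise_sd: float = 0.1,
) -> dict:
    """Residual correlation with the injected spatial field after correction.

    Per seed, a null screen is generated with a known multiplicative field
    of the given log amplitude (``ln 2`` = 2-fold edge-to-center), cycling
    through linear, radial and smooth-random shapes; the corrected log
    values of qc-passing mutant colonies, pooled across the run's plates,
    are correlated with the injected field.  Reports per-seed absolute
    correlations and their maximum over seeds and channels.
    """
    shapes = ("linear", "radial", "smooth_random")
    corrs = []
    for i in range(n_seeds):
        cfg = default_screen_config(
            seed=base_seed + i,
            n_genes=n_genes,
            n_hits=0,
            n_confounders=0,
            spatial_field=SpatialFieldConfig(shape=shapes[i % 3], amplitude=amplitude),
            noise_sd=noise_sd,
        )
        query, _, _ = generate_screen(cfg)
        norm = normalize_screen(query, NormalizationConfig())
        pm = norm.passing_mutants()
        seed_corrs = {}
        for ch in ("sfGFP", "mCherry"):
            # Plate-centred pooled correlation: the correction is per
            # plate, so the residual-field statistic is a within-plate
            # quantity pooled over the run's plates.
            parts_v, parts_f = [], []
            for _, grp in pm.groupby("plate"):
                v = grp[f"log_{ch}"].to_numpy(float)
                f = grp[f"_field_{ch}"].to_numpy(float)
                ok = np.isfinite(v) & np.isfinite(f)
                parts_v.append(v[ok] - v[ok].mean())
                parts_f.append(f[ok] - f[ok].mean())
            v = np.concatenate(parts_v)
            f = np.concatenate(parts_f)
            seed_corrs[ch] = float(abs(np.corrcoef(v, f)[0, 1]))
        corrs.append(seed_corrs)
    max_corr = max(max(c.values()) for c in corrs)
    return {"n_seeds": n_seeds, "per_seed": corrs, "max_abs_corr": max_corr}


def chase_recovery(
    n_series: int = 1000,
    base_seed: int = 0,
    true_half_life: float = 12.0,
    noise_sd: float = 0.1,
    n_points: int = 5,
    n_replicates: int = 3,
    tolerance: float = 0.2,
) -> dict:
    """Half-life recovery on simulated chase series with known truth."""
    estimates = np.empty(n_series)
    for i in range(n_series):
        series = generate_chase(
            true_half_life,
            noise_sd=noise_sd,
            n_points=n_points,
            n_replicates=n_replicates,
            seed=base_seed + i,
        )
        estimates[i] = fit_chase(series).half_life
    rel_err = np.abs(estimates - true_half_life) / true_half_life
    return {
        "n_series": n_series,
        "true_half_life": true_half_life,
        "fraction_within_tolerance": float((rel_err <= tolerance).mean()),
        "mean_estimate": float(estimates.mean()),
        "mean_rel_err": float(rel_err.mean()),
    }


def _ode_steady_state(params: TimerParams) -> tuple[float, float]:
    """Independent numerical steady state by long-horizon ODE integration."""
    p = params
    a = p.alpha

    def rhs(_, y):
        gf, G, c1, C = y
        return [
            p.beta - (p.mG + a) * gf,
            p.mG * gf - a * G,
            p.beta - (p.mC1 + a) * c1,
            p.mC1 * c1 - a * C,
        ]

    horizon = 40.0 / min(a, p.mG, p.mC1)
    sol = solve_ivp(rhs, (0.0, horizon), [0.0, 0.0, 0.0, 0.0],
                    method="LSODA", rtol=1e-11, atol=1e-12)
    return float(sol.y[1, -1]), float(sol.y[3, -1])


def timer_consistency(n_draws: int = 100, seed: int = 0) -> dict:
    """Closed-form steady state versus numerical ODE integration.

    Draws random one-step timer parameter sets (maturation half-times
    2-120 min, protein half-lives 3-300 min) and reports the maximum
    relative deviation of the closed-form mature-pool intensities and
    ratio from the integrated steady state.
    """
    rng = np.random.default_rng(seed)
    max_rel = 0.0
    for _ in range(n_draws):
        mG = LN2 / rng.uniform(2.0, 20.0)
        mC1 = LN2 / rng.uniform(25.0, 120.0)
        alpha = LN2 / rng.uniform(3.0, 300.0)
        beta = 10.0 ** rng.uniform(0.0, 3.0)
        params = TimerParams(beta=beta, alpha=alpha, mG=mG, mC1=mC1)
        pred = steady_state_prediction(params)
        iG, iC = _ode_steady_state(params)
        rel = max(
            abs(pred.iG - iG) / iG,
            abs(pred.iC - iC) / iC,
            abs(pred.ratio - iC / iG) / (iC / iG),
        )
        max_rel = max(max_rel, rel)
    return {"n_draws": n_draws, "max_rel_deviation": max_rel}
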