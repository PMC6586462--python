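"""Synthetic screens, chase series and flow samples with known ground truth.

The generator emulates the statistical structure the analysis assumes for
a dual-reporter timer screen crossed into an arrayed deletion collection:

* colonies on 1536- (32x48) or 384-format (16x24) plates, four technical
  replicates of each cross pinned as an adjacent 2x2 block;
* per-gene expected sfGFP and mCherry intensities from the timer kinetic
  model at that gene's degradation rate (baseline rate times a planted
  multiplier for stabilizer/destabilizer genes);
* *confounder* genes whose multiplier applies to the reporter in **both**
  the query and the control screen, mimicking perturbations (organelle
  physiology, fluorophore maturation) that move the timer readout without
  being specific to the query protein;
* smooth multiplicative spatial intensity fields per plate and channel
  (linear gradient, radial bowl, or smooth random surface), additive on
  the log scale with a configured maximum log-deviation amplitude;
* i.i.d. Gaussian measurement noise on each channel's log intensity;
* failed-cross dropouts: a configurable fraction of colonies grows small,
  with correspondingly reduced fluorescence.

All generators are pure functions of (config, seed): the same seed yields
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assays import ChaseSeries
from .errors import ConfigError
from .screen_data import PlateSet, ScreenLayout
from .timer_model import TimerParams, steady_state_arrays

__all__ = [
    "SpatialFieldConfig",
    "SynthScreenConfig",
    "default_screen_config",
    "generate_screen",
    "generate_chase",
    "generate_flow",
]

LN2 = math.log(2.0)

PLATE_SHAPES = {1536: (32, 48), 384: (16, 24)}


@dataclass(frozen=True)
class SpatialFieldConfig:
    """Shape and amplitude of per-plate spatial intensity fields.

    ``amplitude`` is the maximum absolute log-deviation (natural log), so
    ``amplitude = ln 2`` means up to 2-fold multiplicative distortion
    between plate regions.  ``shape`` is one of ``none``, ``linear``,
    ``radial``, ``smooth_random``.
    """

    shape: str = "smooth_random"
    amplitude: float = 0.2

    def __post_init__(self) -> None:
        if self.shape not in ("none", "linear", "radial", "smooth_random"):
            raise ConfigError(f"unknown spatial field shape {self.shape!r}")
        if self.amplitude < 0:
            raise ConfigError("amplitude must be >= 0")


@dataclass(frozen=True)
class SynthScreenConfig:
    """Conditions of a simulated dual-reporter screen.

    ``effects`` are planted (gene, alpha_multiplier) pairs applied in the
    query screen only; a multiplier of 1/3 is a 3-fold stabilizer.
    ``confounders`` are (gene, alpha_multiplier) pairs applied in *both*
    screens.  ``baseline_alpha`` is the degradation rate of the query
    reporter in the unperturbed background (default ln2/12 per minute, a
    12-minute half-life, the regime of a short-lived mislocalized
    tail-anchored reporter); the control reporter is simulated at the same
    baseline so both screens share their dynamic range.
    """

    n_genes: int = 4608
    plate_format: int = 1536
    replicates: int = 4
    timer: TimerParams = field(default_factory=lambda: TimerParams(beta=100.0))
    baseline_alpha: float = LN2 / 12.0
    effects: tuple[tuple[str, float], ...] = ()
    confounders: tuple[tuple[str, float], ...] = ()
    spatial_field: SpatialFieldConfig = field(default_factory=SpatialFieldConfig)
    noise_sd: float = 0.1
    dropout_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plate_format not in PLATE_SHAPES:
            raise ConfigError(f"plate_format must be one of {sorted(PLATE_SHAPES)}")
        if self.replicates not in (1, 2, 4):
            raise ConfigError("replicates must be 1, 2 or 4 (2x2 block)")
        if not 0 <= self.dropout_rate < 0.5:
            raise ConfigError("dropout_rate must be in [0, 0.5)")
        if self.baseline_alpha <= 0:
            raise ConfigError("baseline_alpha must be > 0")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        for g, m in (*self.effects, *self.confounders):
            if m <= 0:
                raise ConfigError(f"alpha_multiplier for {g!r} must be > 0")

    @property
    def grid(self) -> tuple[int, int]:
        return PLATE_SHAPES[self.plate_format]

    @property
    def genes_per_plate(self) -> int:
        r, c = self.grid
        return (r * c) // self.replicates

    @property
    def n_plates(self) -> int:
        return math.ceil(self.n_genes / self.genes_per_plate)


def default_screen_config(
    seed: int = 0,
    n_genes: int = 4608,
    n_hits: int = 20,
    n_confounders: int = 5,
    hit_multiplier: float = 1.0 / 3.0,
    confounder_multiplier: float = 1.0 / 3.0,
    **overrides,
) -> SynthScreenConfig:
    """Desk-scale default screen: 12 full 1536-format plates, 4608 genes,
    20 planted 3-fold stabilizers and 5 dual-reporter confounders.

    Planted genes are spread deterministically across the gene list (hence
    across plates); the seed only drives measurement-level randomness.
    """
    m = n_hits + n_confounders
    pts = np.unique(np.linspace(0, n_genes - 1, m + 2).round().astype(int)[1:-1])
    if len(pts) < m:
        raise ConfigError("n_genes too small for the requested planted genes")
    conf_pos = (
        set(np.linspace(0, len(pts) - 1, n_confounders).round().astype(int))
        if n_confounders
        else set()
    )
    conf_idx = [int(pts[i]) for i in sorted(conf_pos)][:n_confounders]
    hit_idx = [int(p) for i, p in enumerate(pts) if i not in conf_pos][:n_hits]
    effects = tuple((_gene_name(i), hit_multiplier) for i in hit_idx)
    confounders = tuple((_gene_name(i), confounder_multiplier) for i in conf_idx)
    return SynthScreenConfig(
        n_genes=n_genes,
        effects=effects,
        confounders=confounders,
        seed=seed,
        **overrides,
    )


def _gene_name(i: int) -> str:
    return f"g{i + 1:05d}"


def build_layout(cfg: SynthScreenConfig) -> ScreenLayout:
    """Arrayed layout with each gene's replicates in an adjacent block."""
    n_rows, n_cols = cfg.grid
    gpp = cfg.genes_per_plate
    if cfg.replicates == 4:
        block_r, block_c = 2, 2
    elif cfg.replicates == 2:
        block_r, block_c = 1, 2
    else:
        block_r, block_c = 1, 1
    bcols = n_cols // block_c

    total_slots = cfg.n_plates * gpp
    gene_idx = np.arange(total_slots)
    is_real = gene_idx < cfg.n_genes
    genes = np.where(is_real, [_gene_name(i) for i in gene_idx], "EMPTY")
    roles = np.where(is_real, "mutant", "empty")

    plate = gene_idx // gpp
    j = gene_idx % gpp
    br, bc = j // bcols, j % bcols

    reps = cfg.replicates
    plate_v = np.repeat(plate, reps)
    gene_v = np.repeat(genes, reps)
    role_v = np.repeat(roles, reps)
    dr = np.tile(np.arange(block_r).repeat(block_c), total_slots)
    dc = np.tile(np.tile(np.arange(block_c), block_r), total_slots)
    row_v = np.repeat(br * block_r, reps) + dr
    col_v = np.repeat(bc * block_c, reps) + dc

    table = pd.DataFrame(
        {
            "plate": [f"p{p + 1:02d}" for p in plate_v],
            "row": row_v.astype(int),
            "col": col_v.astype(int),
            "gene": gene_v,
            "role": role_v,
        }
    )
    return ScreenLayout(n_rows=n_rows, n_cols=n_cols, table=table)


def _spatial_field(
    cfg: SpatialFieldConfig, n_rows: int, n_cols: int, rng: np.random.Generator
) -> np.ndarray:
    """One plate's field on the full grid, max |f| = amplitude."""
    a = cfg.amplitude
    if cfg.shape == "none" or a == 0:
        return np.zeros((n_rows, n_cols))
    r = (np.arange(n_rows)[:, None] - (n_rows - 1) / 2) / ((n_rows - 1) / 2)
    c = (np.arange(n_cols)[None, :] - (n_cols - 1) / 2) / ((n_cols - 1) / 2)
    if cfg.shape == "linear":
        theta = rng.uniform(0, 2 * np.pi)
        f = r * np.cos(theta) + c * np.sin(theta)
    elif cfg.shape == "radial":
        sign = rng.choice([-1.0, 1.0])
        d2 = (r**2 + c**2) / 2.0
        f = sign * (2.0 * d2 - 1.0)
    else:  # smooth_random: a few low-frequency cosine modes
        # Sum of three random plate-scale cosine modes.  Mode frequency is
        # capped at 3/4 of a period across the plate: colony-plate
        # artifacts (edge effects, agar thickness, incubator gradients)
        # vary at the scale of the plate, which is also the smoothness
        # regime the local-regression correction assumes.
        f = np.zeros((n_rows, n_cols))
        for _ in range(3):
            theta = rng.uniform(0, 2 * np.pi)
            freq = rng.uniform(0.25, 0.75)
            phase = rng.uniform(0, 2 * np.pi)
            amp = rng.uniform(0.3, 1.0)
            g = freq * (np.cos(theta) * r + np.sin(theta) * c)
            f = f + amp * np.cos(np.pi * g + phase)
    # Fields model *within-plate* structure: zero mean over the grid, with
    # `amplitude` the peak log deviation.  Plate-level brightness offsets
    # are a distinct effect and are not simulated.
    f = f - f.mean()
    peak = np.max(np.abs(f))
    return a * f / peak if peak > 0 else f


def _alpha_vector(cfg: SynthScreenConfig, screen: str) -> np.ndarray:
    mult = np.ones(cfg.n_genes)
    name_to_idx = {_gene_name(i): i for i in range(cfg.n_genes)}
    pairs = cfg.confounders if screen == "control" else (*cfg.effects, *cfg.confounders)
    for g, m in pairs:
        if g not in name_to_idx:
            raise ConfigError(f"planted gene {g!r} not in gene list")
        mult[name_to_idx[g]] *= m
    return cfg.baseline_alpha * mult


def _simulate_screen(
    cfg: SynthScreenConfig,
    layout: ScreenLayout,
    alphas: np.ndarray,
    screen_id: str,
    rng: np.random.Generator,
) -> PlateSet:
    n_rows, n_cols = cfg.grid
    t = layout.table
    d = t.copy()
    is_mutant = (t["role"] == "mutant").to_numpy()
    gidx = np.zeros(len(t), dtype=int)
    gidx[is_mutant] = (
        t.loc[is_mutant, "gene"].str.slice(1).astype(int).to_numpy() - 1
    )

    iG, iC, _ = steady_state_arrays(cfg.timer, alphas)
    log_g = np.where(is_mutant, np.log(iG[gidx]), np.log(1e-3))
    log_c = np.where(is_mutant, np.log(iC[gidx]), np.log(1e-3))

    plates = t["plate"].to_numpy()
    rows = t["row"].to_numpy()
    cols = t["col"].to_numpy()
    field_g = np.zeros(len(t))
    field_c = np.zeros(len(t))
    for p in pd.unique(plates):
        m = plates == p
        fg = _spatial_field(cfg.spatial_field, n_rows, n_cols, rng)
        fc = _spatial_field(cfg.spatial_field, n_rows, n_cols, rng)
        field_g[m] = fg[rows[m], cols[m]]
        field_c[m] = fc[rows[m], cols[m]]

    n = len(t)
    noise_g = rng.normal(0.0, cfg.noise_sd, size=n)
    noise_c = rng.normal(0.0, cfg.noise_sd, size=n)

    size = rng.normal(100.0, 10.0, size=n).clip(min=60.0)
    dropout = rng.random(n) < cfg.dropout_rate
    size[dropout] = rng.uniform(10.0, 40.0, size=int(dropout.sum()))
    growth = np.where(dropout, size / 100.0, 1.0)

    d["size"] = size
    d["sfGFP"] = np.exp(log_g + field_g + noise_g) * growth
    d["mCherry"] = np.exp(log_c + field_c + noise_c) * growth
    d["qc_flag"] = "pass"
    d["_field_sfGFP"] = field_g
    d["_field_mCherry"] = field_c
    d["_true_alpha"] = np.where(is_mutant, alphas[gidx], np.nan)
    return PlateSet(layout=layout, data=d, screen_id=screen_id)


def generate_screen(
    cfg: SynthScreenConfig,
) -> tuple[PlateSet, PlateSet, pd.DataFrame]:
    """Simulate the dual-reporter screen.

    Returns (query PlateSet, control PlateSet, truth table).  The truth
    table holds, per gene, the true degradation rates in each screen, the
    expected steady-state sfGFP level and timer ratio of the query
    reporter (exactly the timer-model closed forms), and the planted-hit /
    confounder labels.
    """
    layout = build_layout(cfg)
    alpha_q = _alpha_vector(cfg, "query")
    alpha_c = _alpha_vector(cfg, "control")

    ss = np.random.SeedSequence(cfg.seed)
    q_ss, c_ss = ss.spawn(2)
    query = _simulate_screen(
        cfg, layout, alpha_q, "query", np.random.default_rng(q_ss)
    )
    control = _simulate_screen(
        cfg, layout, alpha_c, "control", np.random.default_rng(c_ss)
    )

    iG, _, ratio = steady_state_arrays(cfg.timer, alpha_q)
    eff = {g for g, _ in cfg.effects}
    conf = {g for g, _ in cfg.confounders}
    genes = [_gene_name(i) for i in range(cfg.n_genes)]
    truth = pd.DataFrame(
        {
            "gene": genes,
            "alpha_query": alpha_q,
            "alpha_control": alpha_c,
            "expected_sfGFP": iG,
            "expected_ratio": ratio,
            "is_planted_hit": [g in eff for g in genes],
            "is_confounder": [g in conf for g in genes],
        }
    )
    return query, control, truth


def generate_chase(
    true_half_life: float,
    noise_sd: float = 0.1,
    n_points: int = 5,
    n_replicates: int = 3,
    t_max: float | None = None,
    seed: int = 0,
) -> ChaseSeries:
    """Simulated chase: ``2^(-t / t_half)`` with multiplicative log-normal
    noise (sd ``noise_sd`` on the natural-log scale) per point, including
    t = 0."""
    if true_half_life <= 0:
        raise ConfigError("true_half_life must be > 0")
    if n_points < 3 or n_replicates < 1:
        raise ConfigError("need n_points >= 3 and n_replicates >= 1")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if t_max is None:
        t_max = 4.0 * true_half_life
    times = np.linspace(0.0, t_max, n_points)
    clean = np.power(2.0, -times / true_half_life)
    noise = rng.normal(0.0, noise_sd, size=(n_replicates, n_points))
    values = clean[None, :] * np.exp(noise)
    return ChaseSeries(times=times, values=values,
                       label=f"sim_thalf_{true_half_life:g}")


def generate_flow(
    true_means: dict[str, dict[str, float]],
    blank_mean: dict[str, float] | float = 150.0,
    event_noise_cv: float = 0.25,
    n_events: int = 10_000,
    n_replicates: int = 3,
    channels: tuple[str, ...] = ("sfGFP", "mCherry"),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated per-event flow table for :func:`tftscreen.assays.flow_summarize`.

    Each event intensity is ``strain_mean x LN + blank_mean x LN'`` where
    LN are independent log-normal multipliers with mean exactly 1 and
    coefficient of variation ``event_noise_cv`` (so at cv = 0 the sample
    mean equals strain mean + blank exactly).  A ``blank`` sample (strain
    mean 0) is always included.
    """
    if n_events < 100:
        raise ConfigError("n_events must be >= 100")
    if event_noise_cv < 0:
        raise ConfigError("event_noise_cv must be >= 0")
    if isinstance(blank_mean, (int, float)):
        blank_mean = {ch: float(blank_mean) for ch in channels}
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + event_noise_cv**2))
    mu = -(sigma**2) / 2.0  # log-normal multiplier with mean exactly 1

    def ln(size):
        if sigma == 0:
            return np.ones(size)
        return rng.lognormal(mean=mu, sigma=sigma, size=size)

    frames = []
    strains = {"blank": {ch: 0.0 for ch in channels}, **true_means}
    for strain, means in strains.items():
        for rep in range(1, n_replicates + 1):
            cols = {"sample": strain, "replicate": rep}
            for ch in channels:
                cols[ch] = means.get(ch, 0.0) * ln(n_events) + blank_mean[ch] * ln(
                    n_events
                )
            frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)
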