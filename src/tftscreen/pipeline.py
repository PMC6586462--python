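"""End-to-end screen runs: normalize -> score -> call hits, plus assays.

A run is described by a :class:`RunConfig` (usually loaded from YAML) and
produces a results directory containing normalized plate tables, gene
score tables, the hit table, a JSON run manifest (software version, seed,
config hash and thresholds - enough to reproduce the run bit for bit) and
a log file.  All tabular outputs use the screen_data TSV dialect.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assays import ChaseSeries, fit_chase, flow_summarize
from .errors import ConfigError, TFTScreenError
from .hit_calling import HitThresholds, call_hits
from .normalization import NormalizationConfig, normalize_screen
from .scoring import ScoringConfig, score_screen
from .screen_data import (
    PlateSet,
    read_layout,
    read_plate_measurements,
    write_plateset,
    write_results,
)
from .synthetic_data import (
    SynthScreenConfig,
    default_screen_config,
    generate_screen,
)

__all__ = ["RunConfig", "analyze_screen", "run_screen", "run_assay"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one screen run.

    Exactly one of ``inputs`` (paths to layout/query/control measurement
    TSVs) or ``synthetic`` (keyword arguments for
    :func:`tftscreen.synthetic_data.default_screen_config`) must be given.
    """

    seed: int = 0
    inputs: dict[str, str] | None = None
    synthetic: dict[str, Any] | None = None
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    thresholds: HitThresholds = field(default_factory=HitThresholds)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ConfigError("exactly one of inputs/synthetic must be configured")

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        known = {"seed", "inputs", "synthetic", "normalization", "scoring",
                 "thresholds", "log_level"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kw: dict[str, Any] = {k: raw[k] for k in ("seed", "inputs", "synthetic",
                                                  "log_level") if k in raw}
        if "normalization" in raw:
            kw["normalization"] = NormalizationConfig(**raw["normalization"])
        if "scoring" in raw:
            kw["scoring"] = ScoringConfig(**raw["scoring"])
        if "thresholds" in raw:
            kw["thresholds"] = HitThresholds(**raw["thresholds"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def canonical(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "seed": self.seed,
            "inputs": self.inputs,
            "synthetic": self.synthetic,
            "normalization": asdict(self.normalization),
            "scoring": asdict(self.scoring),
            "thresholds": asdict(self.thresholds),
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def analyze_screen(
    query: PlateSet,
    control: PlateSet,
    norm_cfg: NormalizationConfig | None = None,
    scoring_cfg: ScoringConfig | None = None,
    thresholds: HitThresholds | None = None,
) -> tuple[PlateSet, PlateSet, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Normalize both screens, score them, and call dual-reporter hits.

    Returns (normalized query, normalized control, query scores, control
    scores, hit table).
    """
    norm_cfg = norm_cfg or NormalizationConfig()
    scoring_cfg = scoring_cfg or ScoringConfig()
    thresholds = thresholds or HitThresholds()
    nq = normalize_screen(query, norm_cfg)
    nc = normalize_screen(control, norm_cfg)
    qs = score_screen(nq, scoring_cfg)
    cs = score_screen(nc, scoring_cfg)
    hits = call_hits(
        qs,
        cs,
        z_threshold=thresholds.z_threshold,
        fdr_level=thresholds.fdr_level,
        control_z_max=thresholds.control_z_max,
        direction=thresholds.direction,
    )
    return nq, nc, qs, cs, hits


def _load_input_screens(cfg: RunConfig) -> tuple[PlateSet, PlateSet]:
    inputs = cfg.inputs or {}
    for key in ("layout", "query", "control"):
        if key not in inputs:
            raise ConfigError(f"inputs.{key} missing from config")
        if not Path(inputs[key]).exists():
            raise ConfigError(f"inputs.{key}: no such file: {inputs[key]}")
    layout = read_layout(inputs["layout"])
    query = read_plate_measurements(inputs["query"], layout, screen_id="query")
    control = read_plate_measurements(inputs["control"], layout, screen_id="control")
    return query, control


def _manifest(cfg: RunConfig, extra: dict[str, Any]) -> dict[str, Any]:
    return {
        "tftscreen_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": cfg.canonical(),
        **extra,
    }


def _write_manifest(outdir: Path, manifest: dict[str, Any]) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def run_screen(cfg: RunConfig, outdir: str | Path) -> Path:
    """Execute a full screen analysis into ``outdir``.

    Writes normalized plate TSVs, gene score TSVs for both reporters, the
    hit table, the run manifest and a log file.  Output tables are a pure
    function of (config, seed): re-running the same configuration yields
    byte-identical score and hit files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("tftscreen")
    root.addHandler(handler)
    root.setLevel(cfg.log_level)
    try:
        if cfg.synthetic is not None:
            scfg = default_screen_config(seed=cfg.seed, **cfg.synthetic)
            query, control, truth = generate_screen(scfg)
            write_results(truth, outdir / "truth.tsv")
        else:
            query, control = _load_input_screens(cfg)
        nq, nc, qs, cs, hits = analyze_screen(
            query, control, cfg.normalization, cfg.scoring, cfg.thresholds
        )
        write_plateset(nq, outdir / "query_normalized.tsv")
        write_plateset(nc, outdir / "control_normalized.tsv")
        write_results(qs, outdir / "gene_scores_query.tsv")
        write_results(cs, outdir / "gene_scores_control.tsv")
        write_results(hits, outdir / "hits.tsv")
        n_hits = int((hits["verdict"] == "hit").sum())
        _write_manifest(outdir, _manifest(cfg, {"n_genes": len(hits),
                                                "n_hits_called": n_hits}))
        log.info("run complete: %d genes, %d hits", len(hits), n_hits)
        return outdir
    finally:
        root.removeHandler(handler)
        handler.close()


def _chase_series_from_table(df: pd.DataFrame, label: str) -> ChaseSeries:
    need = {"replicate", "time_min", "value"}
    if not need <= set(df.columns):
        raise TFTScreenError(f"{label}: chase table needs columns {sorted(need)}")
    wide = df.pivot(index="replicate", columns="time_min", values="value")
    times = wide.columns.to_numpy(float)
    lc = None
    if "loading_control" in df.columns and df["loading_control"].notna().all():
        lc = df.pivot(index="replicate", columns="time_min",
                      values="loading_control").to_numpy(float)
    return ChaseSeries(times=times, values=wide.to_numpy(float),
                       loading_control=lc, label=label)


def run_assay(
    kind: str,
    input_path: str | Path,
    outdir: str | Path,
    cfg: RunConfig | None = None,
    blank: str = "blank",
    wt: str = "wt",
) -> Path:
    """Run a follow-up assay (``kind`` = ``chase`` or ``flow``) on a table.

    Chase input: TSV with columns ``series, replicate, time_min, value``
    (optional ``loading_control``); one decay fit per series.  A malformed
    series produces an error record while the run continues.  Flow input:
    CSV/TSV with ``sample, replicate`` and channel columns.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    input_path = Path(input_path)
    if not input_path.exists():
        raise ConfigError(f"no such input file: {input_path}")
    sep = "," if input_path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(input_path, sep=sep)
    cfg = cfg or RunConfig(synthetic={})
    if kind == "chase":
        if "series" not in df.columns:
            df["series"] = "series1"
        rows = []
        for label, grp in df.groupby("series", sort=True):
            try:
                fit = fit_chase(_chase_series_from_table(grp, str(label)))
                rows.append(
                    {
                        "series": label,
                        "alpha_per_min": fit.alpha,
                        "half_life_min": fit.half_life,
                        "ci_low_min": fit.ci_half_life[0],
                        "ci_high_min": fit.ci_half_life[1],
                        "r2": fit.r2,
                        "n_replicates": fit.n_replicates,
                        "n_points": fit.n_points,
                        "no_decay": fit.no_decay,
                        "error": "",
                    }
                )
            except TFTScreenError as exc:
                log.warning("series %s failed: %s", label, exc)
                rows.append({"series": label, "error": str(exc)})
        out = pd.DataFrame(rows)
        write_results(out, outdir / "chase_fits.tsv")
    elif kind == "flow":
        out = flow_summarize(df, blank=blank, wt=wt)
        write_results(out, outdir / "flow_summary.tsv")
    else:
        raise ConfigError(f"unknown assay kind {kind!r}")
    _write_manifest(outdir, _manifest(cfg, {"assay": kind, "n_records": len(out)}))
    return outdir
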