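"""Domain types and readers/writers for colony-array screens.

A screen is a grid of yeast colonies pinned on agar plates (1536-colony
plates on a 32x48 grid, or 384-colony plates on a 16x24 grid).  Each grid
position carries a strain identity (the *gene* whose deletion or mutant
allele the strain carries) and a *role*: an ordinary ``mutant`` colony, a
``reference`` strain, a ``non_fluorescent_control`` used for local
background correction, or an ``empty`` position.  Technical replicates of a
cross are pinned next to each other, typically as a 2x2 block of four.

Files are tab-separated UTF-8 with one header row; comma-separated input is
accepted via ``sep=","``.  Grid coordinates are 0-based ``(row, col)`` with
row 0 at the top-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, IncompleteDataError

__all__ = [
    "ROLES",
    "QC_PASS",
    "QC_FAILED_CROSS",
    "QC_EXCLUDED",
    "ScreenLayout",
    "PlateSet",
    "ChannelStats",
    "read_layout",
    "read_plate_measurements",
    "write_plate_measurements",
    "write_plateset",
    "write_results",
    "read_results",
]

ROLES = frozenset({"mutant", "reference", "non_fluorescent_control", "empty"})

QC_PASS = "pass"
QC_FAILED_CROSS = "failed_cross"
QC_EXCLUDED = "excluded"

LAYOUT_COLUMNS = ["plate", "row", "col", "gene", "role"]
MEASUREMENT_COLUMNS = ["plate", "row", "col", "size", "sfGFP", "mCherry"]

#: Channels measured for every colony.
CHANNELS = ("sfGFP", "mCherry")


@dataclass(frozen=True)
class ChannelStats:
    """Location and scale of a reference distribution for one readout.

    ``mad`` is the raw (unscaled) median absolute deviation, in the same
    units as the values; robust z-scores are ``(value - median) / mad``.
    """

    channel: str
    median: float
    mad: float

    def __post_init__(self) -> None:
        if self.mad < 0:
            raise ValueError("mad must be >= 0")


@dataclass(frozen=True)
class ScreenLayout:
    """Mapping from grid positions to strain identities and roles.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape of a single plate (32x48 for 1536-format, 16x24 for
        384-format).
    table
        One row per position with columns ``plate, row, col, gene, role``.
    """

    n_rows: int
    n_cols: int
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in LAYOUT_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"layout table lacks columns: {missing}")
        bad_roles = set(t["role"].unique()) - ROLES
        if bad_roles:
            raise FormatError(f"unknown role token(s): {sorted(bad_roles)}")
        dup = t.duplicated(subset=["plate", "row", "col"])
        if dup.any():
            first = t.loc[dup.idxmax(), ["plate", "row", "col"]].tolist()
            raise FormatError(f"duplicate position {tuple(first)} in layout")
        if (t["row"] < 0).any() or (t["row"] >= self.n_rows).any():
            raise FormatError(f"row index outside 0..{self.n_rows - 1}")
        if (t["col"] < 0).any() or (t["col"] >= self.n_cols).any():
            raise FormatError(f"col index outside 0..{self.n_cols - 1}")

    @property
    def positions(self) -> pd.DataFrame:
        return self.table[["plate", "row", "col"]]

    def replicate_groups(self) -> dict[str, list[tuple]]:
        """Positions holding technical replicates, keyed by gene.

        Grouping is taken from repeated gene identifiers in the layout
        (not inferred geometrically), so non-adjacent replicate designs
        remain usable.  ``empty`` positions are not grouped.
        """
        out: dict[str, list[tuple]] = {}
        sub = self.table[self.table["role"] != "empty"]
        for gene, grp in sub.groupby("gene", sort=True):
            out[str(gene)] = list(
                zip(grp["plate"], grp["row"].astype(int), grp["col"].astype(int))
            )
        return out

    @property
    def n_positions(self) -> int:
        return len(self.table)


@dataclass
class PlateSet:
    """All colony measurements of one screen, joined with its layout.

    ``data`` holds one row per layout position with at least the columns
    ``plate, row, col, gene, role, size, sfGFP, mCherry, qc_flag``.
    Normalization steps append ``log_sfGFP``, ``log_mCherry`` and
    ``log_ratio`` (= log mCherry - log sfGFP) columns.  Columns whose name
    starts with an underscore are internal (e.g. simulated ground-truth
    fields) and are never serialized.
    """

    layout: ScreenLayout
    data: pd.DataFrame = field(repr=False)
    screen_id: str = "screen"

    def __post_init__(self) -> None:
        d = self.data
        needed = ["plate", "row", "col", "gene", "role", "size", "sfGFP", "mCherry"]
        missing = [c for c in needed if c not in d.columns]
        if missing:
            raise FormatError(f"plate data lacks columns: {missing}")
        if "qc_flag" not in d.columns:
            d["qc_flag"] = QC_PASS
        if len(d) != self.layout.n_positions:
            raise IncompleteDataError(
                f"{self.screen_id}: {len(d)} records for "
                f"{self.layout.n_positions} layout positions"
            )

    def copy(self) -> "PlateSet":
        return replace(self, data=self.data.copy())

    @property
    def passing(self) -> pd.DataFrame:
        """Records that currently pass QC."""
        return self.data[self.data["qc_flag"] == QC_PASS]

    def passing_mutants(self) -> pd.DataFrame:
        """QC-passing colonies with role ``mutant`` (the statistics population)."""
        d = self.data
        return d[(d["qc_flag"] == QC_PASS) & (d["role"] == "mutant")]


def _read_table(path: str | Path, sep: str, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    return df


def read_layout(path: str | Path, sep: str = "\t") -> ScreenLayout:
    """Read a screen layout table (columns ``plate,row,col,gene,role``).

    Grid shape is inferred from the maximal indices, rounded up to the
    nearest standard colony format (384 or 1536) when one fits.
    """
    df = _read_table(path, sep, LAYOUT_COLUMNS)
    df = df[LAYOUT_COLUMNS].copy()
    for c in ("row", "col"):
        df[c] = pd.to_numeric(df[c], errors="raise").astype(int)
    n_rows, n_cols = _infer_grid(df["row"].max() + 1, df["col"].max() + 1)
    return ScreenLayout(n_rows=n_rows, n_cols=n_cols, table=df.reset_index(drop=True))


def _infer_grid(min_rows: int, min_cols: int) -> tuple[int, int]:
    for r, c in ((16, 24), (32, 48)):  # 384- then 1536-format
        if min_rows <= r and min_cols <= c:
            return r, c
    return min_rows, min_cols


def read_plate_measurements(
    path: str | Path,
    layout: ScreenLayout,
    screen_id: str = "screen",
    sep: str = "\t",
) -> PlateSet:
    """Read colony measurements and join them onto ``layout``.

    Every layout position must be present exactly once; intensities and
    sizes must be non-negative reals.
    """
    df = _read_table(path, sep, MEASUREMENT_COLUMNS)
    df = df[MEASUREMENT_COLUMNS].copy()
    for c in ("row", "col"):
        df[c] = pd.to_numeric(df[c], errors="raise").astype(int)
    for c in ("size", "sfGFP", "mCherry"):
        df[c] = pd.to_numeric(df[c], errors="raise").astype(float)
        if (df[c] < 0).any():
            bad = df.loc[df[c] < 0].iloc[0]
            raise FormatError(
                f"{path}: negative {c} at plate={bad['plate']} "
                f"row={int(bad['row'])} col={int(bad['col'])}"
            )
    dup = df.duplicated(subset=["plate", "row", "col"])
    if dup.any():
        bad = df.loc[dup.idxmax()]
        raise FormatError(
            f"{path}: duplicate position plate={bad['plate']} "
            f"row={int(bad['row'])} col={int(bad['col'])}"
        )
    merged = layout.table.merge(df, on=["plate", "row", "col"], how="left")
    absent = merged["size"].isna()
    if absent.any():
        bad = merged.loc[absent.idxmax()]
        raise IncompleteDataError(
            f"{path}: missing measurement for plate={bad['plate']} "
            f"row={int(bad['row'])} col={int(bad['col'])}"
        )
    merged["qc_flag"] = QC_PASS
    return PlateSet(layout=layout, data=merged, screen_id=screen_id)


def _public_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if not str(c).startswith("_")]


def write_plate_measurements(plates: PlateSet, path: str | Path, sep: str = "\t") -> None:
    """Write raw measurement columns in the canonical TSV dialect."""
    plates.data[MEASUREMENT_COLUMNS].to_csv(path, sep=sep, index=False)


def write_plateset(plates: PlateSet, path: str | Path, sep: str = "\t") -> None:
    """Write all public columns of a (possibly normalized) plate set."""
    plates.data[_public_columns(plates.data)].to_csv(path, sep=sep, index=False)


def write_results(table: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a result table (gene scores, hits, fold changes) as delimited text.

    Column order is preserved as given; an empty table produces a
    header-only file.  The written file round-trips through
    :func:`read_results`.
    """
    table[_public_columns(table)].to_csv(path, sep=sep, index=False)


def read_results(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def layout_from_frame(table: pd.DataFrame, n_rows: int, n_cols: int) -> ScreenLayout:
    """Build a validated layout from an in-memory table."""
    return ScreenLayout(n_rows=n_rows, n_cols=n_cols, table=table.reset_index(drop=True))
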