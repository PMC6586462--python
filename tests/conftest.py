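"""Shared fixtures: hand-built miniature screens and generated plate sets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tftscreen.screen_data import PlateSet, ScreenLayout


def make_layout(rows: int, cols: int, assignments: list[tuple]) -> ScreenLayout:
    """Build a layout from (plate, row, col, gene, role) tuples."""
    table = pd.DataFrame(assignments, columns=["plate", "row", "col", "gene", "role"])
    return ScreenLayout(n_rows=rows, n_cols=cols, table=table)


def make_plateset(
    layout: ScreenLayout,
    sfgfp,
    mcherry=None,
    size=100.0,
    screen_id: str = "test",
) -> PlateSet:
    """Attach measurement vectors (in layout row order) to a layout."""
    n = layout.n_positions
    d = layout.table.copy()
    d["size"] = np.broadcast_to(np.asarray(size, float), n).copy()
    d["sfGFP"] = np.broadcast_to(np.asarray(sfgfp, float), n).copy()
    mc = sfgfp if mcherry is None else mcherry
    d["mCherry"] = np.broadcast_to(np.asarray(mc, float), n).copy()
    d["qc_flag"] = "pass"
    return PlateSet(layout=layout, data=d, screen_id=screen_id)


@pytest.fixture
def quad_layout() -> ScreenLayout:
    """2 genes x 4 adjacent replicates on a 2x4 grid."""
    rows = []
    for j, gene in enumerate(["geneA", "geneB"]):
        for dr in (0, 1):
            for dc in (0, 1):
                rows.append(("p1", dr, 2 * j + dc, gene, "mutant"))
    return make_layout(2, 4, rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
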