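"""Editing-level and splice-isoform quantification ratios.

RNA-editing level from a Sanger electropherogram: at an edited adenosine
the trace shows overlapping A (unedited) and G (edited, read from inosine)
peaks, and the editing level is

    level% = 100 · area_G / (area_A + area_G).

Splice-cassette inclusion from capillary-electrophoresis band molarities:

    inclusion% = 100 · molarity_long / (molarity_long + molarity_short),

with the long band the cassette-containing isoform. Inputs are
pre-integrated peak areas / band molarities; chromatogram parsing and peak
integration are out of scope. Replicate summaries report mean ± SEM with
the sample (n−1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import QuantificationError, SchemaError

__all__ = [
    "PeakAreas",
    "BandMolarities",
    "QuantReport",
    "editing_level",
    "cassette_inclusion",
    "batch_quantify",
]

EDITING_COLUMNS = ("area_A", "area_G")
SPLICING_COLUMNS = ("molarity_long", "molarity_short")


@dataclass(frozen=True)
class PeakAreas:
    """A- and G-peak areas at one editing site (arbitrary units, ≥ 0)."""

    area_A: float
    area_G: float
    site: str = ""

    def __post_init__(self):
        if self.area_A < 0 or self.area_G < 0:
            raise QuantificationError("peak areas must be non-negative")


@dataclass(frozen=True)
class BandMolarities:
    """Band molarities of the cassette-containing (long) and cassette-free
    (short) splice isoforms, in the same (arbitrary) molar units."""

    molarity_long: float
    molarity_short: float

    def __post_init__(self):
        if self.molarity_long < 0 or self.molarity_short < 0:
            raise QuantificationError("molarities must be non-negative")


def editing_level(p: PeakAreas) -> float:
    """Percent edited: 100 · G / (A + G)."""
    total = p.area_A + p.area_G
    if total <= 0:
        raise QuantificationError(
            f"site {p.site!r}: A + G peak area is zero; level undefined")
    return 100.0 * (p.area_G / total)  # ratio first: result stays ≤ 100


def cassette_inclusion(b: BandMolarities) -> float:
    """Percent cassette inclusion: 100 · long / (long + short)."""
    total = b.molarity_long + b.molarity_short
    if total <= 0:
        raise QuantificationError("total band molarity is zero; ratio undefined")
    return 100.0 * (b.molarity_long / total)


@dataclass
class QuantReport:
    """Per-row percentages plus a per-group mean ± SEM summary."""

    rows: pd.DataFrame     # input columns + 'percent'
    summary: pd.DataFrame  # group, n, mean, sem
    mode: str              # 'editing' | 'splicing' | 'empty'


def _sem(x: pd.Series) -> float:
    # sample (n−1) standard deviation over sqrt(n); NaN for n = 1
    return float(x.std(ddof=1) / np.sqrt(len(x)))


def batch_quantify(table: pd.DataFrame) -> QuantReport:
    """Quantify a table of sites (editing) or bands (splicing).

    The mode is detected from the columns: ``area_A``/``area_G`` for
    editing, ``molarity_long``/``molarity_short`` for splicing. A ``group``
    column (defaulting to a single group) drives the mean ± SEM summary.
    An empty table yields an empty report; a missing required column raises
    :class:`SchemaError` naming it.
    """
    if table is None or len(table) == 0:
        empty = pd.DataFrame()
        return QuantReport(empty, empty, mode="empty")

    cols = set(table.columns)
    if cols & set(EDITING_COLUMNS):
        required, mode = EDITING_COLUMNS, "editing"
    elif cols & set(SPLICING_COLUMNS):
        required, mode = SPLICING_COLUMNS, "splicing"
    else:
        raise SchemaError(
            "table has neither editing columns "
            f"{EDITING_COLUMNS} nor splicing columns {SPLICING_COLUMNS}")
    missing = [c for c in required if c not in cols]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    rows = table.copy()
    if mode == "editing":
        rows["percent"] = [
            editing_level(PeakAreas(r.area_A, r.area_G,
                                    site=str(getattr(r, "site", ""))))
            for r in rows.itertuples()
        ]
    else:
        rows["percent"] = [
            cassette_inclusion(BandMolarities(r.molarity_long, r.molarity_short))
            for r in rows.itertuples()
        ]
    if "group" not in rows.columns:
        rows["group"] = "all"
    summary = (
        rows.groupby("group", sort=True)["percent"]
        .agg(n="size", mean="mean", sem=_sem)
        .reset_index()
    )
    return QuantReport(rows, summary, mode=mode)
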