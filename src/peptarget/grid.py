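"""Targeting-outcome grid: data model and tally logic.

The construct grid records, for every chimeric construct (row A-L = element
combination, column a-s = core peptide), the microscopy targeting call per
organelle: NONE, PARTIAL or FULL localization of the fluorescent cargo to the
mitochondria and to the chloroplast. Rows come in K/R pairs — (A,B), (C,D),
(E,F), (G,H), (I,J), (K,L) — differing only in the basic-residue variant of
the core, so comparing the members of a pair isolates the effect of the
lysine-to-arginine switch. Dual targeting (both organelles at least partial)
is always derived, never stored.

Columns a-m are the 13 antimicrobial core peptides and are the universe for
all tallies; columns n-s (random peptides and TP-element controls) are kept
in the grid but excluded from them. The mt set {B2I, R2G, MII} (columns
a, b, c) and cp set {E1S, LCA, SIM, B15, EHF} (columns i-m) group the cores
by their preferred target organelle.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional

import pandas as pd

from .peptides import COLUMN_CORES, ROW_SIGNATURES


class TargetLevel(enum.IntEnum):
    """Ordered targeting call for one organelle."""

    NONE = 0
    PARTIAL = 1
    FULL = 2


class Organelle(str, enum.Enum):
    MITO = "mito"
    CHLORO = "chloro"


@dataclass(frozen=True)
class TargetingCall:
    mito: TargetLevel
    chloro: TargetLevel

    @property
    def dual(self) -> bool:
        return self.mito >= TargetLevel.PARTIAL and self.chloro >= TargetLevel.PARTIAL

    def level(self, organelle: Organelle) -> TargetLevel:
        return self.mito if organelle is Organelle.MITO else self.chloro


KR_PAIRS = (("A", "B"), ("C", "D"), ("E", "F"), ("G", "H"), ("I", "J"), ("K", "L"))
HA_RAMP_COLUMNS = tuple("abcdefghijklm")
CONTROL_COLUMNS = tuple("nopqrs")
MT_SET_COLUMNS = tuple("abc")    # B2I, MII, R2G
CP_SET_COLUMNS = tuple("ijklm")  # E1S, LCA, SIM, B15, EHF


class GridError(ValueError):
    pass


class TargetingGrid:
    """Mapping (row, column) -> TargetingCall with per-cell provenance notes."""

    def __init__(self) -> None:
        self._cells: dict[tuple[str, str], TargetingCall] = {}
        self._notes: dict[tuple[str, str], str] = {}

    def add(self, row: str, column: str, call: TargetingCall, note: str = "") -> None:
        if row not in ROW_SIGNATURES:
            raise GridError(f"unknown grid row {row!r}")
        if column not in COLUMN_CORES:
            raise GridError(f"unknown grid column {column!r}")
        key = (row, column)
        if key in self._cells:
            raise GridError(f"duplicate grid cell {row}{column}")
        self._cells[key] = call
        self._notes[key] = note

    def get(self, row: str, column: str) -> Optional[TargetingCall]:
        return self._cells.get((row, column))

    def note(self, row: str, column: str) -> str:
        return self._notes.get((row, column), "")

    def cells(self) -> Iterable[tuple[str, str, TargetingCall]]:
        for (row, col), call in sorted(self._cells.items()):
            yield row, col, call

    def __len__(self) -> int:
        return len(self._cells)


def load_grid(path: str | Path) -> TargetingGrid:
    """Read a grid TSV (columns row, column, mito, chloro[, note])."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"row", "column", "mito", "chloro"}
    if not required <= set(df.columns):
        raise GridError(f"grid file must have columns {sorted(required)}")
    grid = TargetingGrid()
    for rec in df.itertuples(index=False):
        try:
            call = TargetingCall(mito=TargetLevel[rec.mito.strip()],
                                 chloro=TargetLevel[rec.chloro.strip()])
        except KeyError as exc:
            raise GridError(
                f"cell {rec.row}{rec.column}: invalid call {exc.args[0]!r}"
            ) from None
        grid.add(rec.row.strip(), rec.column.strip(), call,
                 note=str(getattr(rec, "note", "") or ""))
    return grid


def packaged_grid() -> TargetingGrid:
    """The transcribed targeting-outcome grid shipped with the package."""
    path = resources.files("peptarget.data").joinpath("targeting_grid.tsv")
    with resources.as_file(path) as p:
        return load_grid(p)


class Change(str, enum.Enum):
    GAIN = "GAIN"          # NONE -> PARTIAL or FULL
    IMPROVE = "IMPROVE"    # PARTIAL -> FULL
    LOSS = "LOSS"          # PARTIAL or FULL -> NONE
    DECREASE = "DECREASE"  # FULL -> PARTIAL
    UNCHANGED = "UNCHANGED"


def _classify_change(before: TargetLevel, after: TargetLevel) -> Change:
    if before == after:
        return Change.UNCHANGED
    if before == TargetLevel.NONE:
        return Change.GAIN
    if after == TargetLevel.NONE:
        return Change.LOSS
    return Change.IMPROVE if after > before else Change.DECREASE


def compare_kr_pairs(
    grid: TargetingGrid,
    organelle: Organelle | str,
    columns: Iterable[str] = HA_RAMP_COLUMNS,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Effect of the K-to-R switch per row pair and column.

    Returns the per-(pair, column) change table and aggregate counts,
    including ``gain_improve`` (enabled or improved targeting) and
    ``dual_gain`` (the R variant targets both organelles at least partially
    where the K variant did not).
    """
    organelle = Organelle(organelle)
    rows = []
    for k_row, r_row in KR_PAIRS:
        for col in columns:
            k_call, r_call = grid.get(k_row, col), grid.get(r_row, col)
            if k_call is None or r_call is None:
                continue
            change = _classify_change(k_call.level(organelle), r_call.level(organelle))
            rows.append(dict(
                pair=f"{k_row}{r_row}", column=col,
                before=k_call.level(organelle).name,
                after=r_call.level(organelle).name,
                change=change.value,
                dual_gain=r_call.dual and not k_call.dual,
            ))
    table = pd.DataFrame(rows)
    counts = {c.value.lower(): int((table["change"] == c.value).sum())
              for c in Change}
    counts["gain_improve"] = counts["gain"] + counts["improve"]
    counts["dual_gain"] = int(
        (table["dual_gain"] & table["change"].isin(["GAIN", "IMPROVE"])).sum())
    return table, counts


def tally_grid(
    grid: TargetingGrid,
    rows: Iterable[str],
    predicate: Callable[[TargetingCall], bool],
    columns: Iterable[str] = HA_RAMP_COLUMNS,
) -> tuple[int, int]:
    """(count, denominator) of cells satisfying a predicate on the call."""
    count = denom = 0
    for row in rows:
        for col in columns:
            call = grid.get(row, col)
            if call is None:
                continue
            denom += 1
            if predicate(call):
                count += 1
    return count, denom


def specificity_summary(grid: TargetingGrid) -> dict:
    """Per-core attribution of targeting constructs, per organelle.

    For each organelle the summary gives the per-column count of constructs
    with at least partial targeting, each column's share of the total, the
    cumulative share of the mt-set and cp-set cores, and the cp-set share
    when the rows combining both cTP elements (K/L) are excluded.
    """
    result: dict = {}
    for organelle in Organelle:
        per_col = {}
        for col in HA_RAMP_COLUMNS:
            n = sum(
                1 for row in ROW_SIGNATURES
                if (call := grid.get(row, col)) is not None
                and call.level(organelle) >= TargetLevel.PARTIAL
            )
            per_col[col] = n
        total = sum(per_col.values())
        shares = {c: (n / total if total else 0.0) for c, n in per_col.items()}
        entry = dict(
            counts=per_col,
            shares=shares,
            total=total,
            mt_set_share=sum(shares[c] for c in MT_SET_COLUMNS),
            cp_set_share=sum(shares[c] for c in CP_SET_COLUMNS),
        )
        # cp-set share excluding the cTP-N/cTP-C combination rows
        n_excl = {
            col: sum(
                1 for row in ROW_SIGNATURES
                if row not in ("K", "L")
                and (call := grid.get(row, col)) is not None
                and call.level(organelle) >= TargetLevel.PARTIAL
            )
            for col in HA_RAMP_COLUMNS
        }
        total_excl = sum(n_excl.values())
        entry["cp_set_share_excl_kl"] = (
            sum(n_excl[c] for c in CP_SET_COLUMNS) / total_excl if total_excl else 0.0
        )
        result[organelle.value] = entry
    return result
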