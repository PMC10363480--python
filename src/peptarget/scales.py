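"""Packaged amino-acid scale tables.

All per-residue tables ship as TSV files under ``peptarget/data`` and are
loaded lazily. Every table covers the 20 standard residues; loading a table
that does not is an error, so downstream code can index without guards.
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources
from typing import Mapping

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def _read_table(filename: str, n_values: int) -> dict[str, tuple[float, ...]]:
    path = resources.files("peptarget.data").joinpath(filename)
    table: dict[str, tuple[float, ...]] = {}
    with path.open("r", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    header, *body = rows
    for row in body:
        res = row[0].strip()
        if res in table:
            raise ValueError(f"duplicate residue {res!r} in {filename}")
        table[res] = tuple(float(v) for v in row[1 : 1 + n_values])
    missing = set(ALPHABET) - set(table)
    if missing:
        raise ValueError(f"{filename} is missing residues: {sorted(missing)}")
    return table


@lru_cache(maxsize=None)
def zscales() -> Mapping[str, tuple[float, float, float]]:
    """Three-component Z-scale descriptors (hydrophobic, steric, electronic)."""
    return _read_table("zscales.tsv", 3)


@lru_cache(maxsize=None)
def helix_hydrophobicity() -> Mapping[str, float]:
    """Fauchere-Pliska hydrophobicity used for helical-wheel moments."""
    return {k: v[0] for k, v in _read_table("helix_hydrophobicity.tsv", 1).items()}


@lru_cache(maxsize=None)
def boman_scale() -> Mapping[str, float]:
    """Per-residue protein-interaction propensities (Boman index terms)."""
    return {k: v[0] for k, v in _read_table("boman.tsv", 1).items()}


@lru_cache(maxsize=None)
def hsp70_affinity() -> Mapping[str, float]:
    """Synthetic stand-in Hsp70 substrate-affinity scale (see data file header)."""
    return {k: v[0] for k, v in _read_table("hsp70_affinity_synthetic.tsv", 1).items()}
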