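"""Amphipathic alpha-helix detection on an ideal helical wheel.

The detector follows the helical-wheel principle: residues are placed at 100
degrees per residue (3.6 residues per turn) and a sequence stretch qualifies
as an amphipathic helix when its per-residue hydrophobic moment is high
enough AND the two wheel faces are identifiable — the face around the moment
direction is predominantly hydrophobic while the opposite face carries polar
or charged residues. The longest qualifying stretch is recorded, masked, and
the search recurses on both flanks, so multiple non-overlapping helices can
be annotated per peptide.

The hydrophobic moment of a window of N residues with hydrophobicities H_n is

    mu_H = (1/N) * | sum_n H_n * (cos(n*delta), sin(n*delta)) |

i.e. the vector-sum magnitude normalized per residue. Because a constant
angular offset only rotates the sum, mu_H can be computed for any window from
prefix sums over absolute residue positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .peptides import Peptide, PeptideSet
from .scales import helix_hydrophobicity

#: residues accepted on the hydrophobic face
HYDROPHOBIC_FACE_RESIDUES = frozenset("LIVFMWYA")
#: residues counted as polar/charged on the hydrophilic face
POLAR_FACE_RESIDUES = frozenset("RKDESTNQHGP")


@dataclass(frozen=True)
class HelixConfig:
    """Tunable parameters of the amphipathic-helix search.

    ``min_length`` is the shortest stretch considered (9 residues, two and a
    half turns); ``mu_h_threshold`` the per-residue hydrophobic-moment cutoff
    under the packaged Fauchere-Pliska scale; the face rule requires at least
    ``hydrophobic_face_fraction`` of the residues within +-90 degrees of the
    moment direction to be hydrophobic and at least ``min_polar_opposite``
    polar residues on the opposite face. Amphipathicity must also hold
    locally: every ``min_length`` sub-window of a qualifying stretch must
    keep at least ``local_mu_fraction`` of the moment threshold, so a long
    stretch cannot qualify by bridging a non-amphipathic spacer between two
    strong helices.
    """

    min_length: int = 9
    mu_h_threshold: float = 0.35
    hydrophobic_face_fraction: float = 0.6
    min_polar_opposite: int = 2
    local_mu_fraction: float = 0.85
    wheel_step_deg: float = 100.0


@dataclass(frozen=True)
class HelixAnnotation:
    """One amphipathic-helix annotation (1-based inclusive indices)."""

    start: int
    end: int
    mu_h: float
    direction_deg: float = 0.0
    face_hydrophobic: tuple[int, ...] = ()
    face_hydrophilic: tuple[int, ...] = ()
    source: str = "PREDICTED"

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise ValueError(f"invalid helix span ({self.start}, {self.end})")
        if self.mu_h < 0:
            raise ValueError("mu_h must be non-negative")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class HelixProfile:
    """Non-overlapping helix annotations plus derived whole-peptide metrics.

    ``helix_fraction`` counts annotated residues within the evaluation limit
    (the cleavage site for TPs, the full length otherwise). For peptides with
    at least one helix, ``upstream_length`` is the number of residues before
    the longest helix (ties broken by the earliest start); helix-free peptides
    report the full evaluated length and are flagged via ``helix_free``.
    """

    peptide_id: str
    annotations: tuple[HelixAnnotation, ...]
    evaluation_limit: int
    helix_fraction: float
    upstream_length: int
    helix_free: bool


def hydrophobic_moment(
    window: str,
    scale: Optional[Mapping[str, float]] = None,
    delta: float = 100.0,
) -> tuple[float, float]:
    """Per-residue hydrophobic moment and moment direction of a window.

    Returns ``(mu_h, direction_deg)`` with the direction in degrees on the
    wheel of the window's own frame (first residue at angle 0).
    """
    if len(window) < 2:
        raise ValueError("hydrophobic moment needs a window of length >= 2")
    scale = scale if scale is not None else helix_hydrophobicity()
    x = y = 0.0
    for n, res in enumerate(window):
        try:
            h = scale[res]
        except KeyError:
            raise KeyError(f"residue {res!r} not covered by hydrophobicity scale")
        ang = math.radians(n * delta)
        x += h * math.cos(ang)
        y += h * math.sin(ang)
    mu = math.hypot(x, y) / len(window)
    return mu, math.degrees(math.atan2(y, x)) % 360.0


def _faces(window: str, direction_deg: float, start0: int,
           delta: float) -> tuple[list[int], list[int]]:
    """Split window positions (0-based absolute) into moment-side / opposite."""
    hydro, phil = [], []
    for k in range(len(window)):
        ang = (k * delta) % 360.0
        diff = abs((ang - direction_deg + 180.0) % 360.0 - 180.0)
        (hydro if diff <= 90.0 else phil).append(start0 + k)
    return hydro, phil


class _MomentScanner:
    """O(1) hydrophobic moments of arbitrary windows via prefix sums."""

    def __init__(self, sequence: str, scale: Mapping[str, float], delta: float):
        n = len(sequence)
        h = np.array([scale[c] for c in sequence])
        ang = np.radians(np.arange(n) * delta)
        self._cx = np.concatenate([[0.0], np.cumsum(h * np.cos(ang))])
        self._cy = np.concatenate([[0.0], np.cumsum(h * np.sin(ang))])
        self._delta = delta

    def moment(self, i: int, j: int) -> tuple[float, float]:
        """mu_H and window-frame direction for the half-open window [i, j)."""
        x = self._cx[j] - self._cx[i]
        y = self._cy[j] - self._cy[i]
        mu = math.hypot(x, y) / (j - i)
        # rotate back into the window frame (first residue at angle 0)
        direction = (math.degrees(math.atan2(y, x)) - i * self._delta) % 360.0
        return mu, direction


def _qualify(sequence: str, i: int, j: int, scanner: _MomentScanner,
             cfg: HelixConfig) -> Optional[HelixAnnotation]:
    mu, direction = scanner.moment(i, j)
    if mu < cfg.mu_h_threshold:
        return None
    local_floor = cfg.local_mu_fraction * cfg.mu_h_threshold
    for i2 in range(i, j - cfg.min_length + 1):
        if scanner.moment(i2, i2 + cfg.min_length)[0] < local_floor:
            return None
    window = sequence[i:j]
    hydro_idx, phil_idx = _faces(window, direction, i, cfg.wheel_step_deg)
    if not hydro_idx or not phil_idx:
        return None
    n_hydro = sum(1 for k in hydro_idx if sequence[k] in HYDROPHOBIC_FACE_RESIDUES)
    if n_hydro / len(hydro_idx) < cfg.hydrophobic_face_fraction:
        return None
    n_polar = sum(1 for k in phil_idx if sequence[k] in POLAR_FACE_RESIDUES)
    if n_polar < cfg.min_polar_opposite:
        return None
    return HelixAnnotation(
        start=i + 1, end=j, mu_h=mu, direction_deg=direction,
        face_hydrophobic=tuple(k + 1 for k in hydro_idx),
        face_hydrophilic=tuple(k + 1 for k in phil_idx),
    )


def _longest_qualifying(sequence: str, lo: int, hi: int,
                        scanner: _MomentScanner,
                        cfg: HelixConfig) -> Optional[HelixAnnotation]:
    """Longest qualifying stretch in [lo, hi); ties by higher mu_H, then left."""
    span = hi - lo
    for length in range(span, cfg.min_length - 1, -1):
        candidates = []
        for i in range(lo, hi - length + 1):
            mu, _ = scanner.moment(i, i + length)
            if mu >= cfg.mu_h_threshold:
                candidates.append((-mu, i))
        for _, i in sorted(candidates):
            ann = _qualify(sequence, i, i + length, scanner, cfg)
            if ann is not None:
                return ann
    return None


def find_amphipathic_helices(
    p: Peptide,
    config: Optional[HelixConfig] = None,
    scale: Optional[Mapping[str, float]] = None,
    limit_cleavage: bool = False,
    external: Optional[Sequence[HelixAnnotation]] = None,
) -> HelixProfile:
    """Annotate non-overlapping amphipathic helices in a peptide.

    When ``limit_cleavage`` is set and the peptide has a cleavage index, helix
    metrics are evaluated up to the cleavage site (the search itself runs on
    the full sequence). ``external`` annotations (e.g. from an NMR structure)
    take precedence over prediction when provided.
    """
    cfg = config or HelixConfig()
    scale = scale if scale is not None else helix_hydrophobicity()

    if external is not None:
        annotations = tuple(sorted(external, key=lambda a: a.start))
    else:
        scanner = _MomentScanner(p.sequence, scale, cfg.wheel_step_deg)
        found: list[HelixAnnotation] = []
        stack = [(0, len(p.sequence))]
        while stack:
            lo, hi = stack.pop()
            if hi - lo < cfg.min_length:
                continue
            ann = _longest_qualifying(p.sequence, lo, hi, scanner, cfg)
            if ann is None:
                continue
            found.append(ann)
            stack.append((lo, ann.start - 1))
            stack.append((ann.end, hi))
        annotations = tuple(sorted(found, key=lambda a: a.start))

    limit = len(p.sequence)
    if limit_cleavage and p.cleavage_index is not None:
        limit = p.cleavage_index

    covered = sum(max(0, min(a.end, limit) - a.start + 1) for a in annotations
                  if a.start <= limit)
    if annotations:
        longest = max(annotations, key=lambda a: (len(a), -a.start))
        upstream = longest.start - 1
        helix_free = False
    else:
        upstream = limit
        helix_free = True
    return HelixProfile(
        peptide_id=p.id,
        annotations=annotations,
        evaluation_limit=limit,
        helix_fraction=covered / limit,
        upstream_length=upstream,
        helix_free=helix_free,
    )


def helix_metrics(
    profiles: Iterable[HelixProfile],
    peptides: Optional[PeptideSet] = None,
) -> pd.DataFrame:
    """Per-peptide helix metrics table (lengths, fractions, upstream stretch)."""
    rows = []
    for prof in profiles:
        longest = max((len(a) for a in prof.annotations), default=0)
        rows.append(dict(
            peptide_id=prof.peptide_id,
            length=prof.evaluation_limit,
            helix_fraction=prof.helix_fraction,
            upstream_length=prof.upstream_length,
            n_helices=len(prof.annotations),
            longest_helix_length=longest,
            helix_free=prof.helix_free,
        ))
    return pd.DataFrame(rows)


def annotations_to_tsv(profiles: Iterable[HelixProfile], path: str | Path) -> None:
    rows = [
        dict(peptide_id=prof.peptide_id, start=a.start, end=a.end,
             mu_h=a.mu_h, source=a.source)
        for prof in profiles for a in prof.annotations
    ]
    pd.DataFrame(rows, columns=["peptide_id", "start", "end", "mu_h", "source"]
                 ).to_csv(path, sep="\t", index=False)


def load_external_annotations(path: str | Path) -> dict[str, list[HelixAnnotation]]:
    """Read a sidecar annotation TSV (peptide_id, start, end[, mu_h, source])."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[HelixAnnotation]] = {}
    for row in df.itertuples(index=False):
        ann = HelixAnnotation(
            start=int(row.start), end=int(row.end),
            mu_h=float(getattr(row, "mu_h", 0.0) or 0.0),
            source=str(getattr(row, "source", "EXTERNAL")),
        )
        out.setdefault(str(row.peptide_id), []).append(ann)
    return out
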