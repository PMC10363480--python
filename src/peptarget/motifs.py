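"""Window-rule motif scanning for translocon- and chaperone-interaction sites.

Three rules are implemented:

* FGLK — putative TOC (chloroplast outer-envelope translocon) interaction
  sites: an 8-residue window qualifies when it contains F, [P or G],
  [K or R] and [A or L or V] and neither D nor E. FGLK-1 relaxes the rule to
  any three of the four positive determinant classes (still no D/E).
* Hsp70 — sliding-window sum of per-residue substrate-affinity values; a
  window is a hit when its score reaches the threshold.
* multi-R — maximal runs of consecutive arginines within the N-terminus,
  a motif reported to interfere with chloroplast import in vascular plants.

Each determinant is a presence test (at least one occurrence per window).
Overlapping qualifying windows are merged into maximal "sites" for counting;
per-window detail is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional

import pandas as pd

from .peptides import Peptide
from .scales import hsp70_affinity

logger = logging.getLogger(__name__)


class MotifRule(str, Enum):
    FGLK = "FGLK"
    FGLK_1 = "FGLK_1"
    HSP70 = "HSP70"
    MULTI_R = "MULTI_R"


@dataclass(frozen=True)
class MotifHit:
    """One qualifying window, plus the merged site it belongs to."""

    rule: MotifRule
    window_start: int  # 1-based
    window_length: int
    merged_span: tuple[int, int]
    score: Optional[float] = None

    @property
    def window_end(self) -> int:
        return self.window_start + self.window_length - 1


def _merge_windows(starts: list[int], length: int) -> dict[int, tuple[int, int]]:
    """Map each window start to its maximal run of overlapping windows."""
    spans: dict[int, tuple[int, int]] = {}
    if not starts:
        return spans
    run: list[int] = [starts[0]]
    for s in starts[1:]:
        if s <= run[-1] + length - 1:
            run.append(s)
        else:
            span = (run[0], run[-1] + length - 1)
            spans.update({r: span for r in run})
            run = [s]
    span = (run[0], run[-1] + length - 1)
    spans.update({r: span for r in run})
    return spans


_FGLK_CLASSES = (frozenset("F"), frozenset("PG"), frozenset("KR"), frozenset("ALV"))
_ACIDIC = frozenset("DE")
FGLK_WINDOW = 8


def scan_fglk(p: Peptide, relaxed: bool = False) -> list[MotifHit]:
    """FGLK (strict) or FGLK-1 (relaxed, >= 3 of 4 determinants) window scan."""
    seq = p.sequence
    if len(seq) < FGLK_WINDOW:
        logger.info("%s: shorter than %d residues, no FGLK windows evaluated",
                    p.id, FGLK_WINDOW)
        return []
    required = 3 if relaxed else 4
    rule = MotifRule.FGLK_1 if relaxed else MotifRule.FGLK
    starts = []
    for i in range(len(seq) - FGLK_WINDOW + 1):
        window = set(seq[i : i + FGLK_WINDOW])
        if window & _ACIDIC:
            continue
        n_classes = sum(1 for cls in _FGLK_CLASSES if window & cls)
        if n_classes >= required:
            starts.append(i + 1)
    spans = _merge_windows(starts, FGLK_WINDOW)
    return [
        MotifHit(rule=rule, window_start=s, window_length=FGLK_WINDOW,
                 merged_span=spans[s])
        for s in starts
    ]


def scan_hsp70(
    p: Peptide,
    affinity: Optional[Mapping[str, float]] = None,
    window: int = 7,
    threshold: float = 5.0,
) -> list[MotifHit]:
    """Hsp70 binding-site scan: window affinity sums compared to a threshold.

    With the shipped (synthetic, see data file) scale, higher scores mean a
    more chaperone-engaging window; a window is a hit when
    ``score >= threshold``. The default window of 7 matches the length of the
    Hsp70 substrate-binding core.
    """
    affinity = affinity if affinity is not None else hsp70_affinity()
    seq = p.sequence
    if len(seq) < window:
        return []
    try:
        values = [affinity[res] for res in seq]
    except KeyError as exc:
        raise KeyError(f"{p.id}: residue {exc.args[0]!r} missing from affinity table")
    scores = []
    acc = sum(values[:window])
    scores.append(acc)
    for i in range(1, len(seq) - window + 1):
        acc += values[i + window - 1] - values[i - 1]
        scores.append(acc)
    starts = [i + 1 for i, s in enumerate(scores) if s >= threshold]
    spans = _merge_windows(starts, window)
    return [
        MotifHit(rule=MotifRule.HSP70, window_start=s, window_length=window,
                 merged_span=spans[s], score=scores[s - 1])
        for s in starts
    ]


def scan_multi_r(p: Peptide, n_term: int = 15, min_run: int = 2) -> list[MotifHit]:
    """Maximal runs of >= min_run consecutive R within the first n_term residues."""
    region = p.sequence[:n_term]
    hits = []
    i = 0
    while i < len(region):
        if region[i] != "R":
            i += 1
            continue
        j = i
        while j < len(region) and region[j] == "R":
            j += 1
        if j - i >= min_run:
            hits.append(MotifHit(
                rule=MotifRule.MULTI_R, window_start=i + 1,
                window_length=j - i, merged_span=(i + 1, j),
            ))
        i = j
    return hits


def hits_table(peptide_hits: Mapping[str, Iterable[MotifHit]]) -> pd.DataFrame:
    """Flatten per-peptide hit lists into the hits TSV layout."""
    rows = [
        dict(peptide_id=pid, rule=h.rule.value, window_start=h.window_start,
             merged_start=h.merged_span[0], merged_end=h.merged_span[1],
             score=h.score)
        for pid, hits in peptide_hits.items() for h in hits
    ]
    return pd.DataFrame(
        rows, columns=["peptide_id", "rule", "window_start",
                       "merged_start", "merged_end", "score"])


def count_sites(hits: Iterable[MotifHit]) -> int:
    """Number of merged sites (maximal runs of overlapping windows)."""
    return len({h.merged_span for h in hits})
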