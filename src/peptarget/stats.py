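"""Group-comparison statistics and property reports for peptide sets.

Two-group comparisons of continuous peptide properties use Welch's unequal-
variance t-test (two-sided by default; one-sided when a direction is
specified a priori, e.g. the trend established by the reference TP classes).
Multi-group comparisons of amino-acid frequencies use the Kruskal-Wallis
omnibus test followed by Dunn's pairwise z-tests on rank sums (with tie
correction), under a configurable multiplicity correction (Holm by default).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .features import boman_index, feature_table
from .helices import HelixProfile, helix_metrics
from .peptides import PeptideSet


class TestKind(str, enum.Enum):
    T_TWO_SIDED = "T_TWO_SIDED"
    T_ONE_SIDED = "T_ONE_SIDED"
    KRUSKAL = "KRUSKAL"
    DUNN = "DUNN"


class Correction(str, enum.Enum):
    NONE = "none"
    BONFERRONI = "bonferroni"
    HOLM = "holm"


@dataclass(frozen=True)
class ComparisonResult:
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    test: TestKind
    alternative: str = "two-sided"
    correction: Correction = Correction.NONE

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def group_ttest(
    a: Sequence[float],
    b: Sequence[float],
    sided: TestKind | str = TestKind.T_TWO_SIDED,
    direction: str = "greater",
    groups: tuple[str, str] = ("a", "b"),
    equal_var: bool = False,
) -> ComparisonResult:
    """Welch t-test between two samples (pooled variance behind a flag).

    For a one-sided test, ``direction`` states the alternative for the first
    sample: ``"greater"`` tests mean(a) > mean(b), ``"less"`` the reverse.
    """
    sided = TestKind(sided)
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        raise ValueError("zero variance in both samples; t-test undefined")
    alternative = "two-sided" if sided is TestKind.T_TWO_SIDED else direction
    stat, p = sps.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
    return ComparisonResult(groups=groups, statistic=float(stat),
                            p_value=float(p), test=sided,
                            alternative=alternative)


def _dunn_pvalues(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Uncorrected Dunn pairwise z-tests on rank sums with tie correction."""
    names = list(groups)
    data = [np.asarray(groups[g], float) for g in names]
    all_values = np.concatenate(data)
    n = len(all_values)
    ranks = sps.rankdata(all_values)
    # mean rank per group
    mean_ranks, sizes = {}, {}
    pos = 0
    for name, values in zip(names, data):
        k = len(values)
        mean_ranks[name] = ranks[pos : pos + k].mean()
        sizes[name] = k
        pos += k
    # tie correction: sum over tied groups of (t^3 - t)
    _, counts = np.unique(all_values, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        se = np.sqrt(
            (n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1)))
            * (1.0 / sizes[g1] + 1.0 / sizes[g2])
        )
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append(dict(group1=g1, group2=g2, z=float(z), p_value=float(p)))
    return pd.DataFrame(rows)


def kruskal_dunn(
    groups: Mapping[str, Sequence[float]],
    correction: Correction | str = Correction.HOLM,
) -> list[ComparisonResult]:
    """Kruskal-Wallis omnibus plus Dunn post-hoc pairwise comparisons.

    Returns the omnibus result first, followed by one result per group pair
    with the corrected p-value. If all values are tied across all groups the
    omnibus is undefined and reported with a NaN statistic and p = 1.
    """
    correction = Correction(correction)
    if len(groups) < 3:
        raise ValueError("omnibus test needs >= 3 groups")
    names = tuple(groups)
    data = [np.asarray(groups[g], float) for g in names]
    if any(len(d) < 1 for d in data):
        raise ValueError("every group needs n >= 1")
    if np.unique(np.concatenate(data)).size == 1:
        results = [ComparisonResult(groups=names, statistic=float("nan"),
                                    p_value=1.0, test=TestKind.KRUSKAL)]
        return results
    stat, p = sps.kruskal(*data)
    results = [ComparisonResult(groups=names, statistic=float(stat),
                                p_value=float(p), test=TestKind.KRUSKAL)]
    dunn = _dunn_pvalues(groups)
    pvals = dunn["p_value"].to_numpy()
    if correction is not Correction.NONE:
        pvals = multipletests(pvals, method=correction.value)[1]
    for row, p_corr in zip(dunn.itertuples(index=False), pvals):
        results.append(ComparisonResult(
            groups=(row.group1, row.group2), statistic=row.z,
            p_value=float(p_corr), test=TestKind.DUNN, correction=correction,
        ))
    return results


#: properties compared in the TP property report and the direction the
#: chloroplast-like class is expected to exceed the mitochondrion-like class
REPORT_PROPERTIES = ("length", "helix_fraction", "upstream_length",
                     "freq_K", "freq_R", "boman")


def tp_property_table(
    profiles: Mapping[str, Iterable[HelixProfile]],
    sets: Mapping[str, PeptideSet],
    pairs: Optional[Sequence[tuple[str, str]]] = None,
    sided: TestKind = TestKind.T_TWO_SIDED,
    directions: Optional[Mapping[str, str]] = None,
) -> tuple[pd.DataFrame, list[ComparisonResult]]:
    """Per-set property distributions plus pairwise group tests.

    ``profiles`` maps each set name to its helix profiles. The returned table
    has one row per peptide (set name, length, helix fraction, upstream
    stretch, K/R frequency, Boman index). For each requested pair of sets,
    every property is compared with a t-test; one-sided tests use the
    direction given per property (alternative for the FIRST set of the pair).
    With fewer than two sets, only the table is returned (no tests).
    """
    rows = []
    for set_name, pset in sets.items():
        metrics = helix_metrics(profiles[set_name]).set_index("peptide_id")
        for p in pset:
            m = metrics.loc[p.id]
            rows.append(dict(
                set_name=set_name,
                peptide_id=p.id,
                length=int(m["length"]),
                helix_fraction=float(m["helix_fraction"]),
                upstream_length=int(m["upstream_length"]),
                helix_free=bool(m["helix_free"]),
                freq_K=p.sequence.count("K") / len(p),
                freq_R=p.sequence.count("R") / len(p),
                boman=boman_index(p),
            ))
    table = pd.DataFrame(rows)

    tests: list[ComparisonResult] = []
    if pairs is None:
        names = list(sets)
        pairs = [(names[i], names[j])
                 for i in range(len(names)) for j in range(i + 1, len(names))]
    if len(sets) < 2:
        pairs = []
    for g1, g2 in pairs:
        for prop in REPORT_PROPERTIES:
            a = table.loc[table["set_name"] == g1, prop].to_numpy(float)
            b = table.loc[table["set_name"] == g2, prop].to_numpy(float)
            direction = (directions or {}).get(prop, "greater")
            try:
                res = group_ttest(a, b, sided=sided, direction=direction,
                                  groups=(f"{g1}:{prop}", f"{g2}:{prop}"))
            except ValueError:
                continue  # degenerate (constant) property, no test
            tests.append(res)
    return table, tests
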