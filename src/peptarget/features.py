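"""Z-scale auto-cross-covariance featurization and related descriptors.

Each residue is described by three Z-scale values (hydrophobic, steric,
electronic principal properties). A peptide of length N is summarized by
auto-cross covariances between scales j and k at residue lags d = 1..4:

    acc(j, k, d) = (1/(N-d)) * sum_{i=1}^{N-d} z_j(res_i) * z_k(res_{i+d})

giving 36 terms per peptide (3 x 3 scale pairs x 4 lags, (j, k, d)
lexicographic). Terms are uncentered products by default; a centered variant
(subtracting each scale's sequence mean first) is available behind a flag.
Euclidean distance between a peptide's ACC vector and the barycenter of a
reference set is used as a similarity measure to that set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .peptides import Peptide, PeptideSet
from .scales import ALPHABET, boman_scale, zscales

N_ZSCALES = 3
DEFAULT_MAX_LAG = 4

#: column labels of the 36 ACC terms, (j, k, d) lexicographic
ACC_COLUMNS = tuple(
    f"acc_{j}_{k}_{d}"
    for j in range(1, N_ZSCALES + 1)
    for k in range(1, N_ZSCALES + 1)
    for d in range(1, DEFAULT_MAX_LAG + 1)
)


def _zmatrix(sequence: str, z: Mapping[str, tuple[float, ...]]) -> np.ndarray:
    try:
        return np.array([z[res] for res in sequence])  # (N, 3)
    except KeyError as exc:
        raise KeyError(f"residue {exc.args[0]!r} not covered by Z-scale table")


def acc_vector(
    p: Peptide | str,
    z: Optional[Mapping[str, tuple[float, ...]]] = None,
    max_lag: int = DEFAULT_MAX_LAG,
    centered: bool = False,
) -> np.ndarray:
    """The ordered ACC descriptor of a peptide (9 * max_lag values)."""
    sequence = p if isinstance(p, str) else p.sequence
    n = len(sequence)
    if n < max_lag + 1:
        raise ValueError(
            f"ACC with max_lag={max_lag} needs length >= {max_lag + 1}, "
            f"got {n}"
        )
    zm = _zmatrix(sequence, z if z is not None else zscales())
    if centered:
        zm = zm - zm.mean(axis=0)
    out = np.empty(N_ZSCALES * N_ZSCALES * max_lag)
    pos = 0
    for j in range(N_ZSCALES):
        for k in range(N_ZSCALES):
            for d in range(1, max_lag + 1):
                out[pos] = float(zm[:-d, j] @ zm[d:, k]) / (n - d)
                pos += 1
    return out


def acc_matrix(peptides: Iterable[Peptide], **kwargs) -> pd.DataFrame:
    """ACC vectors for a collection of peptides, one row per peptide."""
    ids, rows = [], []
    for p in peptides:
        ids.append(p.id)
        rows.append(acc_vector(p, **kwargs))
    max_lag = kwargs.get("max_lag", DEFAULT_MAX_LAG)
    cols = [f"acc_{j}_{k}_{d}"
            for j in range(1, N_ZSCALES + 1)
            for k in range(1, N_ZSCALES + 1)
            for d in range(1, max_lag + 1)]
    return pd.DataFrame(rows, index=pd.Index(ids, name="peptide_id"), columns=cols)


def tp_barycenter_distance(
    queries: PeptideSet | Iterable[Peptide],
    reference: PeptideSet | Iterable[Peptide],
    **kwargs,
) -> pd.DataFrame:
    """Euclidean distance of each query's ACC vector to the reference barycenter.

    The barycenter is the coordinate-wise mean of the reference set's ACC
    vectors; smaller distances mean greater similarity to the reference class.
    """
    ref = acc_matrix(reference, **kwargs)
    if ref.empty:
        raise ValueError("reference set must be non-empty")
    barycenter = ref.to_numpy().mean(axis=0)
    qry = acc_matrix(queries, **kwargs)
    dist = np.linalg.norm(qry.to_numpy() - barycenter, axis=1)
    return pd.DataFrame({"peptide_id": qry.index, "tp_distance": dist}
                        ).set_index("peptide_id")


def boman_index(p: Peptide | str,
                scale: Optional[Mapping[str, float]] = None) -> float:
    """Mean per-residue protein-interaction propensity (Boman index).

    High values indicate a peptide more likely to engage proteins than lipid
    bilayers. Per-residue normalization makes the index length-invariant.
    """
    sequence = p if isinstance(p, str) else p.sequence
    scale = scale if scale is not None else boman_scale()
    return sum(scale[res] for res in sequence) / len(sequence)


#: residue charges at neutral pH; histidine configurable via charge_profile
RESIDUE_CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}


def charge_profile(
    p: Peptide | str,
    window: int = 10,
    histidine_charge: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Sliding-window charge sums along the sequence plus the net charge.

    Charges are K = R = +1, D = E = -1, others 0 (histidine configurable).
    Profile value at position i (1-based) sums the window starting there;
    windows truncated at the C-terminus are dropped.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    sequence = p if isinstance(p, str) else p.sequence
    charges = np.array([
        histidine_charge if res == "H" else RESIDUE_CHARGE.get(res, 0)
        for res in sequence
    ])
    net = int(charges.sum())
    n = len(sequence)
    if n < window:
        profile = pd.DataFrame(columns=["position", "charge"]).astype(int)
    else:
        sums = np.convolve(charges, np.ones(window, dtype=int), mode="valid")
        profile = pd.DataFrame({
            "position": np.arange(1, n - window + 2),
            "charge": sums.astype(int),
        })
    return profile, net


def aa_frequency_table(
    sets: Mapping[str, PeptideSet] | PeptideSet,
    baseline: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Per-peptide frequencies of all 20 residues, per named set.

    Returns a tidy table with one row per peptide: set name, peptide id and a
    ``freq_X`` column per residue (count / length, summing to 1). An optional
    external baseline (e.g. database-wide averages) is attached as an extra
    row with set name ``baseline`` when provided — it is configuration data,
    never recomputed.
    """
    if isinstance(sets, PeptideSet):
        sets = {sets.name: sets}
    rows = []
    for set_name, pset in sets.items():
        if len(pset) == 0:
            raise ValueError(f"set {set_name!r} is empty")
        for p in pset:
            counts = {res: 0 for res in ALPHABET}
            for res in p.sequence:
                counts[res] += 1
            row = {"set_name": set_name, "peptide_id": p.id}
            row.update({f"freq_{res}": counts[res] / len(p) for res in ALPHABET})
            rows.append(row)
    if baseline is not None:
        row = {"set_name": "baseline", "peptide_id": "baseline"}
        row.update({f"freq_{res}": baseline.get(res, 0.0) for res in ALPHABET})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FeatureRecord:
    """Bundled per-peptide descriptors."""

    peptide_id: str
    acc: np.ndarray
    boman: float
    net_charge: int
    freq_k: float
    freq_r: float
    tp_distance: Optional[float] = None


def feature_table(
    peptides: PeptideSet | Iterable[Peptide],
    reference: Optional[PeptideSet] = None,
    **acc_kwargs,
) -> pd.DataFrame:
    """Feature matrix: 36 ACC columns plus boman, net_charge and K/R freqs."""
    peptides = list(peptides)
    table = acc_matrix(peptides, **acc_kwargs)
    table["boman"] = [boman_index(p) for p in peptides]
    table["net_charge"] = [charge_profile(p)[1] for p in peptides]
    table["freq_K"] = [p.sequence.count("K") / len(p) for p in peptides]
    table["freq_R"] = [p.sequence.count("R") / len(p) for p in peptides]
    if reference is not None:
        table["tp_distance"] = tp_barycenter_distance(
            peptides, reference, **acc_kwargs)["tp_distance"]
    return table
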