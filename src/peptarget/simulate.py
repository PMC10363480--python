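"""Seeded generators for synthetic peptide sets.

The generator emulates the statistical structure of the four peptide classes
the analysis is built around, without using any real sequences:

* ``MTP_LIKE`` — mitochondrial-presequence-like: short (mean 37 residues), an
  amphipathic helix starting at residue 1 and covering ~80% of the length,
  arginine-rich.
* ``CTP_LIKE`` — chloroplast-transit-peptide-like: longer (mean 49 residues),
  an unstructured N-terminal stretch (mean 15 residues) before a central
  amphipathic helix, a short unstructured tail, arginine-rich.
* ``HARAMP_LIKE`` — antimicrobial-peptide-like: fully helical, lysine-rich.
* ``RANDOM`` — i.i.d. draws from background amino-acid frequencies.

All classes are depleted in acidic residues (D/E), which only appear in
unstructured segments at a configurable rate. Amphipathic helices are built
on an ideal helical wheel (100 degrees per residue): positions whose wheel
angle falls inside the hydrophobic arc draw from a hydrophobic pool, the
remaining positions from a polar pool in which the class's basic residue has
weight 0.5. Every generated set is a pure function of its spec (seed
included) and comes with a ground-truth table of designed helix spans.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .peptides import Peptide, PeptideSet, Role

WHEEL_STEP_DEG = 100.0

HYDROPHOBIC_POOL = "LIVFA"
POLAR_POOL = "STNQG"
#: pool for unstructured stretches (cTP-like N-termini are S/T/P/G/A/R-rich)
UNSTRUCTURED_POOL = "STPGAR"
ACIDIC = "DE"

#: Approximate database-wide background frequencies (rounded, renormalized).
BACKGROUND_FREQS = {
    "A": 0.083, "R": 0.055, "N": 0.040, "D": 0.055, "C": 0.014,
    "Q": 0.039, "E": 0.067, "G": 0.071, "H": 0.023, "I": 0.059,
    "L": 0.097, "K": 0.058, "M": 0.024, "F": 0.039, "P": 0.047,
    "S": 0.066, "T": 0.053, "W": 0.011, "Y": 0.029, "V": 0.069,
}


class GeneratorClass(str, Enum):
    MTP_LIKE = "MTP_LIKE"
    CTP_LIKE = "CTP_LIKE"
    HARAMP_LIKE = "HARAMP_LIKE"
    RANDOM = "RANDOM"


_CLASS_ROLES = {
    GeneratorClass.MTP_LIKE: Role.MTP,
    GeneratorClass.CTP_LIKE: Role.CTP,
    GeneratorClass.HARAMP_LIKE: Role.HA_RAMP,
    GeneratorClass.RANDOM: Role.RANDOM,
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic peptide class draw."""

    class_name: GeneratorClass
    n: int
    length_mean: float
    length_sd: float
    upstream_mean: float = 0.0
    upstream_sd: float = 0.0
    helix_arc: float = 180.0
    basic_residue: str = "R"
    acidic_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 60.0 < self.helix_arc < 300.0:
            raise ValueError("helix_arc must lie in (60, 300) degrees")
        if self.basic_residue not in ("K", "R"):
            raise ValueError("basic_residue must be K or R")
        if not 0.0 <= self.acidic_rate < 0.5:
            raise ValueError("acidic_rate must be in [0, 0.5)")


#: Class defaults mirroring the study conditions being emulated.
_CLASS_DEFAULTS: dict[GeneratorClass, dict] = {
    GeneratorClass.MTP_LIKE: dict(length_mean=37.0, length_sd=8.0,
                                  upstream_mean=0.0, upstream_sd=0.0,
                                  basic_residue="R"),
    GeneratorClass.CTP_LIKE: dict(length_mean=49.0, length_sd=8.0,
                                  upstream_mean=15.0, upstream_sd=5.0,
                                  basic_residue="R"),
    GeneratorClass.HARAMP_LIKE: dict(length_mean=28.0, length_sd=8.0,
                                     upstream_mean=0.0, upstream_sd=0.0,
                                     basic_residue="K"),
    GeneratorClass.RANDOM: dict(length_mean=30.0, length_sd=8.0,
                                upstream_mean=0.0, upstream_sd=0.0,
                                basic_residue="K"),
}


def default_spec(class_name: GeneratorClass | str, n: int, seed: int = 0,
                 **overrides) -> GeneratorSpec:
    """A :class:`GeneratorSpec` at the default study-condition parameters."""
    class_name = GeneratorClass(class_name)
    params = dict(_CLASS_DEFAULTS[class_name])
    params.update(overrides)
    return GeneratorSpec(class_name=class_name, n=n, seed=seed, **params)


def _wheel_angles(length: int, start: int = 0) -> np.ndarray:
    """Wheel angle of each residue, mapped to (-180, 180]."""
    ang = (np.arange(start, start + length) * WHEEL_STEP_DEG) % 360.0
    ang[ang > 180.0] -= 360.0
    return ang


def _helix_residues(length: int, arc: float, basic_residue: str,
                    rng: np.random.Generator) -> str:
    angles = _wheel_angles(length)
    out = []
    polar = [basic_residue] + list(POLAR_POOL)
    polar_w = np.array([0.5] + [0.5 / len(POLAR_POOL)] * len(POLAR_POOL))
    for a in angles:
        if abs(a) <= arc / 2.0:
            out.append(HYDROPHOBIC_POOL[rng.integers(len(HYDROPHOBIC_POOL))])
        else:
            out.append(polar[rng.choice(len(polar), p=polar_w)])
    return "".join(out)


def _unstructured(length: int, rng: np.random.Generator,
                  acidic_rate: float, pool: str = UNSTRUCTURED_POOL) -> str:
    if length <= 0:
        return ""
    idx = rng.integers(len(pool), size=length)
    seq = [pool[i] for i in idx]
    acid = rng.random(length) < acidic_rate
    for i in np.nonzero(acid)[0]:
        seq[i] = ACIDIC[rng.integers(2)]
    return "".join(seq)


def make_amphipathic_peptide(
    length: int,
    arc: float = 180.0,
    basic_residue: str = "K",
    seed: int | np.random.Generator = 0,
    peptide_id: str = "amphi",
    role: Role = Role.OTHER,
) -> tuple[Peptide, tuple[int, int]]:
    """Design an idealized amphipathic helical peptide.

    Returns the peptide and the designed helix span (1-based, inclusive),
    which is the whole sequence. Acidic residues never occur.
    """
    if length < 9:
        raise ValueError("amphipathic peptide needs length >= 9")
    if not 60.0 < arc < 300.0:
        raise ValueError("arc must lie in (60, 300) degrees")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = _helix_residues(length, arc, basic_residue, rng)
    return Peptide(id=peptide_id, sequence=seq, role=role), (1, length)


def _draw_length(rng: np.random.Generator, mean: float, sd: float,
                 minimum: int = 15) -> int:
    return max(minimum, int(round(rng.normal(mean, sd))))


def _generate_one(spec: GeneratorSpec, rng: np.random.Generator,
                  index: int) -> tuple[Peptide, dict]:
    pid = f"{spec.class_name.value}_{spec.seed}_{index:03d}"
    role = _CLASS_ROLES[spec.class_name]
    length = _draw_length(rng, spec.length_mean, spec.length_sd)

    if spec.class_name is GeneratorClass.RANDOM:
        residues = list(BACKGROUND_FREQS)
        freqs = np.array(list(BACKGROUND_FREQS.values()))
        freqs = freqs / freqs.sum()
        seq = "".join(rng.choice(residues, size=length, p=freqs))
        truth = dict(helix_start=pd.NA, helix_end=pd.NA, upstream_len=pd.NA)
    elif spec.class_name is GeneratorClass.CTP_LIKE:
        upstream = max(3, int(round(rng.normal(spec.upstream_mean, spec.upstream_sd))))
        tail = max(0, int(round(rng.normal(4.0, 2.0))))
        helix_len = length - upstream - tail
        if helix_len < 9:  # keep the central helix viable for short draws
            helix_len = 9
            length = upstream + helix_len + tail
        seq = (
            _unstructured(upstream, rng, spec.acidic_rate)
            + _helix_residues(helix_len, spec.helix_arc, spec.basic_residue, rng)
            + _unstructured(tail, rng, spec.acidic_rate)
        )
        truth = dict(helix_start=upstream + 1, helix_end=upstream + helix_len,
                     upstream_len=upstream)
    else:
        # MTP_LIKE: helix from residue 1 covering ~80%; HARAMP_LIKE: fully helical
        frac = 0.8 if spec.class_name is GeneratorClass.MTP_LIKE else 1.0
        helix_len = max(9, int(round(frac * length)))
        tail = length - helix_len
        seq = (
            _helix_residues(helix_len, spec.helix_arc, spec.basic_residue, rng)
            + _unstructured(tail, rng, spec.acidic_rate)
        )
        truth = dict(helix_start=1, helix_end=helix_len, upstream_len=0)

    peptide = Peptide(id=pid, sequence=seq, role=role)
    record = dict(id=pid, class_name=spec.class_name.value, length=len(seq),
                  seed=spec.seed, **truth)
    return peptide, record


def generate_labeled_dataset(
    specs: Sequence[GeneratorSpec] | GeneratorSpec,
) -> tuple[dict[str, PeptideSet], pd.DataFrame]:
    """Generate peptide sets for each spec plus a ground-truth table.

    Returns a mapping ``class_name -> PeptideSet`` (suffixed with the spec
    index when a class appears more than once) and a truth DataFrame with the
    designed helix span and upstream length of every peptide.
    """
    if isinstance(specs, GeneratorSpec):
        specs = [specs]
    sets: dict[str, PeptideSet] = {}
    records: list[dict] = []
    seen: dict[str, int] = {}
    for spec in specs:
        base = spec.class_name.value
        seen[base] = seen.get(base, 0) + 1
        name = base if seen[base] == 1 else f"{base}_{seen[base]}"
        rng = np.random.default_rng(spec.seed)
        pset = PeptideSet(name, provenance=f"synthetic, spec={spec}")
        for i in range(spec.n):
            peptide, record = _generate_one(spec, rng, i)
            pset.add(peptide)
            record["set_name"] = name
            records.append(record)
        sets[name] = pset
    truth = pd.DataFrame.from_records(records)
    return sets, truth
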