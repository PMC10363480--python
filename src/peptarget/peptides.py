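"""Peptide data model, FASTA I/O and chimeric construct assembly.

Peptides are short amino-acid sequences over the 20-letter alphabet. Organelle
targeting peptides (TPs) additionally carry a cleavage index: the 1-based
position of the last presequence residue, with processing occurring between
that residue and the next. Chimeric constructs combine an antimicrobial or
control core peptide with TP-derived elements:

* ``cTP-N`` — the 15 N-terminal residues of the chloroplast transit peptide,
  which lie upstream of its amphipathic helix;
* ``cTP-C`` / ``mTP-C`` — C-terminal elements spanning 10 residues upstream to
  23 residues downstream of the cTP / mTP cleavage site, carrying the
  processing-peptidase recognition region into the construct.

Constructs are named by a compact code grammar ``[^c] CORE [_K|_R] [^c|^m]``:
a leading ``^c`` marks the cTP-N element, the subscript the basic-residue
variant (all lysines vs. all arginines), and the trailing superscript the
C-terminal element. Rows A-L of the construct grid fix the twelve
(variant, N-element, C-element) combinations; columns identify the core.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scales import ALPHABET

logger = logging.getLogger(__name__)

_ALPHABET_SET = frozenset(ALPHABET)


class PeptideError(ValueError):
    """Raised for invalid peptides, parse failures and malformed codes."""


class Role(str, Enum):
    HA_RAMP = "HA_RAMP"
    MTP = "mTP"
    CTP = "cTP"
    RANDOM = "RANDOM"
    CONSTRUCT = "CONSTRUCT"
    OTHER = "OTHER"


class BasicSubstitution(str, Enum):
    K_TO_R = "K_TO_R"
    R_TO_K = "R_TO_K"


@dataclass(frozen=True)
class Peptide:
    """A named amino-acid sequence with optional cleavage-site annotation.

    ``cleavage_index`` is 1-based and points at the last presequence residue;
    for full preproteins it must be strictly inside the sequence, for isolated
    TPs it may equal the length.
    """

    id: str
    sequence: str
    role: Role = Role.OTHER
    cleavage_index: Optional[int] = None
    family: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise PeptideError("peptide id must be non-empty")
        if not self.sequence:
            raise PeptideError(f"{self.id}: sequence must be non-empty")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in _ALPHABET_SET:
                raise PeptideError(
                    f"{self.id}: invalid residue {ch!r} at position {pos}"
                )
        if self.cleavage_index is not None:
            if not 1 <= self.cleavage_index <= len(self.sequence):
                raise PeptideError(
                    f"{self.id}: cleavage_index {self.cleavage_index} outside "
                    f"sequence of length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


class PeptideSet:
    """An ordered collection of peptides with unique ids."""

    def __init__(self, name: str, peptides: Optional[list[Peptide]] = None,
                 provenance: str = ""):
        self.name = name
        self.provenance = provenance
        self._peptides: list[Peptide] = []
        self._index: dict[str, Peptide] = {}
        for p in peptides or []:
            self.add(p)

    def add(self, p: Peptide) -> None:
        if p.id in self._index:
            raise PeptideError(f"duplicate peptide id {p.id!r} in set {self.name!r}")
        self._peptides.append(p)
        self._index[p.id] = p

    def __getitem__(self, pid: str) -> Peptide:
        try:
            return self._index[pid]
        except KeyError:
            raise KeyError(f"no peptide {pid!r} in set {self.name!r}") from None

    def __contains__(self, pid: str) -> bool:
        return pid in self._index

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self._peptides)

    def __len__(self) -> int:
        return len(self._peptides)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self._peptides]


_HEADER_KEYS = ("role", "cleavage", "family")


def load_peptides(path: str | Path, name: Optional[str] = None) -> PeptideSet:
    """Read a FASTA file into a :class:`PeptideSet`.

    Headers may carry space-separated ``key=value`` tokens (``role=``,
    ``cleavage=``, ``family=``); unknown keys are ignored with a warning.
    Sequences are uppercased; any character outside the 20-letter alphabet is
    a parse error naming the record and position.
    """
    path = Path(path)
    pset = PeptideSet(name or path.stem, provenance=str(path))
    # 'fasta-pearson' additionally tolerates ';' comment lines
    for record in SeqIO.parse(str(path), "fasta-pearson"):
        tokens = record.description.split()[1:]
        meta: dict[str, str] = {}
        for tok in tokens:
            if "=" not in tok:
                continue
            key, _, value = tok.partition("=")
            if key not in _HEADER_KEYS:
                logger.warning("%s: ignoring unknown header key %r", record.id, key)
                continue
            meta[key] = value
        role = Role(meta["role"]) if "role" in meta else Role.OTHER
        cleavage = int(meta["cleavage"]) if "cleavage" in meta else None
        pset.add(
            Peptide(
                id=record.id,
                sequence=str(record.seq).upper(),
                role=role,
                cleavage_index=cleavage,
                family=meta.get("family"),
            )
        )
    return pset


def packaged_study_peptides() -> PeptideSet:
    """The packaged SYNTHETIC stand-in for the study's peptide panel.

    13 antimicrobial cores, two TP preproteins with declared cleavage sites
    and two random controls. Sequences are generated, not real; see the data
    file header.
    """
    from importlib import resources

    res = resources.files("peptarget.data").joinpath("study_peptides_synthetic.fasta")
    with resources.as_file(res) as fp:
        return load_peptides(fp, name="study_peptides_synthetic")


def write_peptides(pset: PeptideSet, path: str | Path) -> None:
    """Write a FASTA file; inverse of :func:`load_peptides` up to line wrapping."""
    records = []
    for p in pset:
        parts = [p.id, f"role={p.role.value}"]
        if p.cleavage_index is not None:
            parts.append(f"cleavage={p.cleavage_index}")
        if p.family:
            parts.append(f"family={p.family}")
        records.append(
            SeqRecord(Seq(p.sequence), id=p.id, description=" ".join(parts[1:]))
        )
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(records)


def substitute_basic(p: Peptide, direction: BasicSubstitution) -> Peptide:
    """Replace every K with R (or every R with K); length is preserved.

    A sequence lacking the source residue returns an identical-sequence copy.
    The new id is suffixed with the target residue (``_R`` or ``_K``).
    """
    direction = BasicSubstitution(direction)
    src, dst = ("K", "R") if direction is BasicSubstitution.K_TO_R else ("R", "K")
    return replace(p, id=f"{p.id}_{dst}", sequence=p.sequence.replace(src, dst))


def extract_n_element(p: Peptide, n: int = 15) -> Peptide:
    """Return the first ``n`` residues as a new element peptide (no padding)."""
    if n < 1:
        raise PeptideError(f"n must be positive, got {n}")
    if len(p) < n:
        raise PeptideError(
            f"{p.id}: cannot extract {n} N-terminal residues from "
            f"{len(p)}-residue sequence"
        )
    return Peptide(id=f"{p.id}_N{n}", sequence=p.sequence[:n], role=Role.OTHER,
                   family=p.family)


def extract_c_element(p: Peptide, upstream: int = 10, downstream: int = 23) -> Peptide:
    """Extract the cleavage-site-spanning C-terminal element.

    The element runs from ``upstream`` residues before the cleavage site to
    ``downstream`` residues after it (``upstream + downstream`` residues in
    total) and carries its own cleavage index at position ``upstream``.
    """
    if p.cleavage_index is None:
        raise PeptideError(f"{p.id}: cleavage_index required to extract C-element")
    if p.cleavage_index < upstream:
        raise PeptideError(
            f"{p.id}: only {p.cleavage_index} residues upstream of cleavage "
            f"site, need {upstream}"
        )
    end = p.cleavage_index + downstream
    if len(p) < end:
        raise PeptideError(
            f"{p.id}: only {len(p) - p.cleavage_index} residues downstream of "
            f"cleavage site, need {downstream}"
        )
    seq = p.sequence[p.cleavage_index - upstream : end]
    return Peptide(
        id=f"{p.id}_C{upstream}+{downstream}",
        sequence=seq,
        role=Role.OTHER,
        cleavage_index=upstream if upstream > 0 else None,
        family=p.family,
    )


class BasicVariant(str, Enum):
    NATIVE = "NATIVE"
    K = "K"
    R = "R"


class NElement(str, Enum):
    NONE = "NONE"
    CTP_N = "CTP_N"


class CElement(str, Enum):
    NONE = "NONE"
    CTP_C = "CTP_C"
    MTP_C = "MTP_C"


#: Core peptide codes of the 13 antimicrobial peptides, column order a-m.
HA_RAMP_CODES = (
    "B2I", "MII", "R2G", "DS4", "DDM", "B1E", "CP3",
    "S1D", "E1S", "LCA", "SIM", "B15", "EHF",
)

#: Special core tokens: cTP helix, mTP helix, poly-alanine, no core.
SPECIAL_CORES = ("CH", "MH", "AA", "-")

RANDOM_CORES = ("RP1", "RP2")

#: Grid column letter -> core code.
COLUMN_CORES = dict(zip("abcdefghijklm", HA_RAMP_CODES)) | {
    "n": "RP1", "o": "RP2", "p": "CH", "q": "MH", "r": "-", "s": "AA",
}
CORE_COLUMNS = {v: k for k, v in COLUMN_CORES.items()}

#: Grid row letter -> (basic variant, N-element, C-element).
ROW_SIGNATURES: dict[str, tuple[BasicVariant, NElement, CElement]] = {
    "A": (BasicVariant.K, NElement.NONE, CElement.NONE),
    "B": (BasicVariant.R, NElement.NONE, CElement.NONE),
    "C": (BasicVariant.K, NElement.NONE, CElement.MTP_C),
    "D": (BasicVariant.R, NElement.NONE, CElement.MTP_C),
    "E": (BasicVariant.K, NElement.NONE, CElement.CTP_C),
    "F": (BasicVariant.R, NElement.NONE, CElement.CTP_C),
    "G": (BasicVariant.K, NElement.CTP_N, CElement.NONE),
    "H": (BasicVariant.R, NElement.CTP_N, CElement.NONE),
    "I": (BasicVariant.K, NElement.CTP_N, CElement.MTP_C),
    "J": (BasicVariant.R, NElement.CTP_N, CElement.MTP_C),
    "K": (BasicVariant.K, NElement.CTP_N, CElement.CTP_C),
    "L": (BasicVariant.R, NElement.CTP_N, CElement.CTP_C),
}
SIGNATURE_ROWS = {v: k for k, v in ROW_SIGNATURES.items()}


@dataclass(frozen=True)
class ConstructSpec:
    """Composition of one chimeric construct (a cell of the construct grid)."""

    core_id: str
    basic_variant: BasicVariant = BasicVariant.NATIVE
    n_element: NElement = NElement.NONE
    c_element: CElement = CElement.NONE

    def __post_init__(self) -> None:
        known = HA_RAMP_CODES + SPECIAL_CORES + RANDOM_CORES
        if self.core_id not in known:
            raise PeptideError(f"unknown construct core {self.core_id!r}")

    @property
    def row(self) -> Optional[str]:
        """Grid row letter; only defined for K/R variants."""
        key = (self.basic_variant, self.n_element, self.c_element)
        return SIGNATURE_ROWS.get(key)

    @property
    def column(self) -> str:
        return CORE_COLUMNS[self.core_id]


_CODE_RE = re.compile(
    r"^(?P<n>\^c)?"
    r"(?P<core>" + "|".join(re.escape(c) for c in
                            HA_RAMP_CODES + RANDOM_CORES + SPECIAL_CORES) + r")"
    r"(?P<variant>_K|_R)?"
    r"(?P<c>\^c|\^m)?$"
)


def parse_construct_code(code: str) -> ConstructSpec:
    """Parse a canonical construct code like ``^cB2I_R^m``.

    Exact inverse of :func:`format_construct_code` on canonical codes.
    """
    m = _CODE_RE.match(code)
    if m is None:
        raise PeptideError(f"malformed construct code {code!r}")
    variant = {None: BasicVariant.NATIVE, "_K": BasicVariant.K,
               "_R": BasicVariant.R}[m.group("variant")]
    c_elem = {None: CElement.NONE, "^c": CElement.CTP_C,
              "^m": CElement.MTP_C}[m.group("c")]
    n_elem = NElement.CTP_N if m.group("n") else NElement.NONE
    return ConstructSpec(core_id=m.group("core"), basic_variant=variant,
                         n_element=n_elem, c_element=c_elem)


def format_construct_code(spec: ConstructSpec) -> str:
    """Render the canonical ASCII code for a construct spec."""
    parts = []
    if spec.n_element is NElement.CTP_N:
        parts.append("^c")
    parts.append(spec.core_id)
    if spec.basic_variant is not BasicVariant.NATIVE:
        parts.append(f"_{spec.basic_variant.value}")
    if spec.c_element is CElement.CTP_C:
        parts.append("^c")
    elif spec.c_element is CElement.MTP_C:
        parts.append("^m")
    return "".join(parts)


def spec_for_cell(row: str, column: str) -> ConstructSpec:
    """Construct spec for a (row, column) cell of the construct grid."""
    if row not in ROW_SIGNATURES:
        raise PeptideError(f"unknown grid row {row!r}")
    if column not in COLUMN_CORES:
        raise PeptideError(f"unknown grid column {column!r}")
    variant, n_elem, c_elem = ROW_SIGNATURES[row]
    return ConstructSpec(core_id=COLUMN_CORES[column], basic_variant=variant,
                         n_element=n_elem, c_element=c_elem)


def _helix_core(tp: Peptide, skip_n: int, upstream: int = 10) -> str:
    """TP helical fragment: after the N-terminal stretch, up to the C-element."""
    if tp.cleavage_index is None:
        raise PeptideError(f"{tp.id}: cleavage_index required for helix fragment")
    return tp.sequence[skip_n : tp.cleavage_index - upstream]


def assemble_construct(
    spec: ConstructSpec,
    library: PeptideSet,
    ctp_id: str = "RCA1-cTP",
    mtp_id: str = "CAG2-mTP",
    n_length: int = 15,
    upstream: int = 10,
    downstream: int = 23,
) -> Peptide:
    """Assemble the chimeric construct peptide described by ``spec``.

    Elements are concatenated directly (no linkers):
    ``[cTP-N] + core(after K/R substitution) + [C-element]``. Special cores:
    ``CH``/``MH`` are the TP helical fragments (between N-terminal stretch and
    C-element), ``AA`` a poly-alanine of the same length as ``CH``, ``-`` no
    core at all. When a C-element is present, the construct carries its
    cleavage index ``downstream`` residues before its end.
    """
    ctp = library[ctp_id]
    mtp = library[mtp_id]

    if spec.core_id == "CH":
        core = _helix_core(ctp, n_length, upstream)
    elif spec.core_id == "MH":
        core = _helix_core(mtp, 0, upstream)
    elif spec.core_id == "AA":
        core = "A" * len(_helix_core(ctp, n_length, upstream))
    elif spec.core_id == "-":
        core = ""
    else:
        core = library[spec.core_id].sequence

    if spec.basic_variant is BasicVariant.K:
        core = core.replace("R", "K")
    elif spec.basic_variant is BasicVariant.R:
        core = core.replace("K", "R")

    parts = []
    if spec.n_element is NElement.CTP_N:
        parts.append(extract_n_element(ctp, n_length).sequence)
    parts.append(core)
    if spec.c_element is CElement.CTP_C:
        parts.append(extract_c_element(ctp, upstream, downstream).sequence)
    elif spec.c_element is CElement.MTP_C:
        parts.append(extract_c_element(mtp, upstream, downstream).sequence)

    sequence = "".join(parts)
    cleavage = len(sequence) - downstream if spec.c_element is not CElement.NONE else None
    return Peptide(
        id=format_construct_code(spec),
        sequence=sequence,
        role=Role.CONSTRUCT,
        cleavage_index=cleavage,
    )
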