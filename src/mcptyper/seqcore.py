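"""IUPAC-degenerate DNA algebra and FASTA I/O.

Degenerate oligonucleotides are written over the 15-letter IUPAC DNA
alphabet (A, C, G, T plus the ambiguity codes R, Y, S, W, K, M, B, D, H, V,
N).  Each symbol denotes a non-empty subset of {A, C, G, T}; a degenerate
sequence therefore denotes the *set* of concrete sequences obtained by
choosing one base per position, and its degeneracy is the size of that set
(the product of per-position subset sizes).

This module provides the symbol algebra (base sets, complementation,
matching), the :class:`DegenerateSequence` container used for primers
throughout the package, and FASTA input/output for concrete DNA templates.

Conventions
-----------
* All sequences are read and stored 5'->3'; whitespace is stripped and
  letters are uppercased on input, so primer tables with grouped triplets
  ("CCC TGC TGT ...") can be pasted verbatim.
* Coordinates are 0-based, half-open, reported on the plus strand.
* A template ``N`` (masked or unknown base) matches no primer symbol by
  default; this is conservative and avoids spurious amplicons from masked
  regions.  Matching functions accept ``n_as_wildcard=True`` to flip this.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlphabetError",
    "ExpansionLimitError",
    "FastaError",
    "IUPAC_SETS",
    "SET_TO_CODE",
    "COMPLEMENT",
    "base_set",
    "matches",
    "clean",
    "degeneracy",
    "revcomp",
    "expand",
    "DegenerateSequence",
    "ConcreteTemplate",
    "read_fasta",
    "write_fasta",
]

_BASES = "ACGT"

#: IUPAC DNA codes mapped to the subset of standard bases each represents.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Inverse map: base subset -> the (unique) IUPAC code encoding it.
SET_TO_CODE: dict[frozenset[str], str] = {s: c for c, s in IUPAC_SETS.items()}

_BASE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Symbol-level complement: the code whose base set is the complement-image
#: of the original's base set (e.g. R <-> Y, N <-> N).
COMPLEMENT: dict[str, str] = {
    code: SET_TO_CODE[frozenset(_BASE_COMPLEMENT[b] for b in s)]
    for code, s in IUPAC_SETS.items()
}


class AlphabetError(ValueError):
    """A character falls outside the 15-letter IUPAC DNA alphabet."""


class ExpansionLimitError(ValueError):
    """A requested expansion would exceed the caller's size limit."""


class FastaError(ValueError):
    """Malformed FASTA input (empty file, duplicate record ids, ...)."""


def clean(text: str) -> str:
    """Strip all whitespace and uppercase (primer-table canonical form)."""
    return "".join(text.split()).upper()


def base_set(symbol: str) -> frozenset[str]:
    """Return the set of concrete bases an IUPAC symbol stands for."""
    try:
        return IUPAC_SETS[symbol]
    except KeyError:
        raise AlphabetError(f"unknown IUPAC DNA symbol {symbol!r}") from None


def matches(symbol: str, base: str, n_as_wildcard: bool = False) -> bool:
    """Does a concrete template base satisfy a (possibly degenerate) symbol?

    The template alphabet is {A, C, G, T, N}.  A template ``N`` matches
    nothing unless ``n_as_wildcard`` is set.
    """
    if base == "N":
        return n_as_wildcard
    if base not in _BASES:
        raise AlphabetError(f"template base {base!r} is not one of A/C/G/T/N")
    return base in base_set(symbol)


def _as_string(seq: "Union[str, DegenerateSequence]") -> str:
    if isinstance(seq, DegenerateSequence):
        return str(seq)
    return clean(seq)


def degeneracy(seq: "Union[str, DegenerateSequence]") -> int:
    """Product over positions of per-symbol base-set sizes."""
    s = _as_string(seq)
    score = 1
    for sym in s:
        score *= len(base_set(sym))
    return score


def revcomp(seq: "Union[str, DegenerateSequence]"):
    """Reverse complement under the symbol-level complement table.

    Returns the same type it was given (``str`` in, ``str`` out).
    """
    s = _as_string(seq)
    for sym in s:
        base_set(sym)  # validate
    rc = "".join(COMPLEMENT[sym] for sym in reversed(s))
    if isinstance(seq, DegenerateSequence):
        return DegenerateSequence(rc)
    return rc


def expand(seq: "Union[str, DegenerateSequence]", limit: int = 65536) -> set[str]:
    """All concrete sequences matching the degenerate pattern.

    Refuses (with the offending product size in the message) when the
    degeneracy exceeds ``limit``.
    """
    s = _as_string(seq)
    score = degeneracy(s)
    if score > limit:
        raise ExpansionLimitError(
            f"expansion of {s!r} has {score} members, exceeding limit {limit}"
        )
    pools = [sorted(base_set(sym)) for sym in s]
    return {"".join(choice) for choice in itertools.product(*pools)}


class DegenerateSequence:
    """An immutable 5'->3' string over the 15-letter IUPAC DNA alphabet.

    Construction canonicalises input (whitespace stripped, uppercased) and
    validates every symbol; empty sequences and gap characters are rejected.
    """

    __slots__ = ("_seq",)

    def __init__(self, seq: "Union[str, DegenerateSequence]"):
        s = _as_string(seq)
        if not s:
            raise AlphabetError("degenerate sequence must be non-empty")
        for sym in s:
            if sym not in IUPAC_SETS:
                raise AlphabetError(f"unknown IUPAC DNA symbol {sym!r} in {s!r}")
        object.__setattr__(self, "_seq", s)

    def __setattr__(self, *_):  # pragma: no cover - immutability guard
        raise AttributeError("DegenerateSequence is immutable")

    def __str__(self) -> str:
        return self._seq

    def __repr__(self) -> str:
        return f"DegenerateSequence({self._seq!r})"

    def __len__(self) -> int:
        return len(self._seq)

    def __iter__(self) -> Iterator[str]:
        return iter(self._seq)

    def __getitem__(self, item) -> str:
        return self._seq[item]

    def __eq__(self, other) -> bool:
        if isinstance(other, DegenerateSequence):
            return self._seq == other._seq
        if isinstance(other, str):
            return self._seq == clean(other)
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self._seq)

    @property
    def degeneracy(self) -> int:
        return degeneracy(self._seq)

    def base_sets(self) -> list[frozenset[str]]:
        return [base_set(sym) for sym in self._seq]

    def revcomp(self) -> "DegenerateSequence":
        return revcomp(self)

    def expand(self, limit: int = 65536) -> set[str]:
        return expand(self._seq, limit=limit)


_TEMPLATE_ALPHABET = frozenset("ACGTN")


@dataclass
class ConcreteTemplate:
    """A concrete DNA template (stands in for plaque-lysate DNA).

    ``seq`` is uppercase over {A, C, G, T, N}; ``N`` marks masked or
    unknown positions.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("template id must be non-empty")
        self.seq = clean(self.seq)
        if not self.seq:
            raise ValueError(f"template {self.id!r} has an empty sequence")
        bad = set(self.seq) - _TEMPLATE_ALPHABET
        if bad:
            raise AlphabetError(
                f"template {self.id!r} contains non-DNA characters: "
                + ", ".join(sorted(bad))
            )

    def __len__(self) -> int:
        return len(self.seq)

    def revcomp(self) -> "ConcreteTemplate":
        rc = "".join(
            {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}[b]
            for b in reversed(self.seq)
        )
        return ConcreteTemplate(self.id, rc, self.description)


def read_fasta(path) -> list[ConcreteTemplate]:
    """Read a multi-record FASTA file into templates.

    Raises :class:`FastaError` on empty files and on duplicate ids.
    Lowercase input is canonicalised to uppercase.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    seen: set[str] = set()
    templates: list[ConcreteTemplate] = []
    for rec in records:
        if rec.id in seen:
            raise FastaError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        templates.append(ConcreteTemplate(rec.id, str(rec.seq), rec.description))
    return templates


def write_fasta(records: Iterable[ConcreteTemplate], path) -> None:
    """Write templates as uppercase multi-record FASTA."""
    seqrecords = [
        SeqRecord(Seq(t.seq), id=t.id, description=t.description or "")
        for t in records
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(seqrecords, str(path), "fasta")
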