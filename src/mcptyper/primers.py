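"""Primer model, degeneracy scoring, melting temperatures, built-in panel.

The built-in panel is the seven-group major-capsid-protein (MCP) typing
panel for virulent enterobacteria phages: one forward/reverse degenerate
primer pair per target group (T4-, T7-, N4-, GJ1-, SP6-, FO1- and Vi1-like
phages), each with its singleplex annealing temperature (50 degC for T4,
FO1, GJ1 and Vi1; 55 degC for N4, SP6 and T7).

All primers follow the CODEHOP architecture: a non-degenerate 5' consensus
clamp followed by a short degenerate 3' core, so the degeneracy score (the
number of concrete oligos in the mix) stays small while the 3' end covers
every codon variant of the conserved protein motif.

Melting temperatures of a degenerate primer are summarised as a
(min, max) envelope over its concrete expansions rather than a single
number; the envelope is what multiplex grouping needs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio.SeqUtils import MeltingTemp as _mt

from .seqcore import (
    DegenerateSequence,
    base_set,
    degeneracy,
    expand,
)

__all__ = [
    "Primer",
    "PrimerPair",
    "TmConditions",
    "degeneracy_score",
    "tm_range",
    "builtin_primers",
    "builtin_panel",
    "GROUPS",
    "ANNEALING_C",
    "load_primer_table",
    "save_primer_table",
    "pairs_from_primers",
]

ORIENTATIONS = ("forward", "reverse")


@dataclass(frozen=True)
class Primer:
    """A named degenerate primer with group label and orientation."""

    name: str
    group: str
    orientation: str
    seq: DegenerateSequence

    def __post_init__(self):
        if not self.name:
            raise ValueError("primer name must be non-empty")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(
                f"primer {self.name!r}: orientation must be 'forward' or "
                f"'reverse', got {self.orientation!r}"
            )
        if not isinstance(self.seq, DegenerateSequence):
            object.__setattr__(self, "seq", DegenerateSequence(self.seq))

    @property
    def degeneracy(self) -> int:
        return self.seq.degeneracy

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PrimerPair:
    """A forward + reverse primer targeting one phage group."""

    fw: Primer
    rev: Primer
    group: str
    annealing_temp: float

    def __post_init__(self):
        if self.fw.orientation != "forward":
            raise ValueError(f"{self.fw.name!r} is not a forward primer")
        if self.rev.orientation != "reverse":
            raise ValueError(f"{self.rev.name!r} is not a reverse primer")
        if not (self.fw.group == self.rev.group == self.group):
            raise ValueError(
                f"pair {self.group!r}: primer groups disagree "
                f"({self.fw.group!r}, {self.rev.group!r})"
            )

    @property
    def primers(self) -> tuple[Primer, Primer]:
        return (self.fw, self.rev)


def degeneracy_score(seq: Union[str, DegenerateSequence, Primer]) -> int:
    """Product over positions of per-symbol base-set sizes.

    Equals the cardinality of the primer's concrete expansion.
    """
    if isinstance(seq, Primer):
        seq = seq.seq
    return degeneracy(seq)


@dataclass(frozen=True)
class TmConditions:
    """Salt and primer concentration for nearest-neighbor Tm estimates."""

    na_mM: float = 50.0
    primer_nM: float = 400.0


def tm_range(
    primer: Union[str, DegenerateSequence, Primer],
    method: str = "nearest_neighbor",
    conditions: TmConditions | None = None,
    limit: int = 4096,
) -> tuple[float, float]:
    """(min, max) melting temperature over all concrete expansions.

    ``method`` is ``"nearest_neighbor"`` (unified NN parameters at the
    given salt/primer concentration, evaluated by enumerating the
    expansion, hence the degeneracy must not exceed ``limit``) or
    ``"wallace"`` (2(A+T) + 4(G+C); the envelope has a closed form and is
    evaluated without enumeration).
    """
    seq = primer.seq if isinstance(primer, Primer) else DegenerateSequence(primer)
    if method == "wallace":
        tmin = tmax = 0.0
        for s in seq.base_sets():
            tmin += 2.0 if (s & {"A", "T"}) else 4.0
            tmax += 4.0 if (s & {"G", "C"}) else 2.0
        return (tmin, tmax)
    if method == "nearest_neighbor":
        cond = conditions or TmConditions()
        tms = [
            _mt.Tm_NN(
                s,
                Na=cond.na_mM,
                dnac1=cond.primer_nM / 2.0,
                dnac2=cond.primer_nM / 2.0,
            )
            for s in sorted(expand(seq, limit=limit))
        ]
        return (min(tms), max(tms))
    raise ValueError(f"unknown Tm method {method!r}")


# The built-in seven-group panel; whitespace inside the sequences is
# stripped on parse, so the triplet-grouped notation can stay readable.
_PANEL_ROWS: tuple[tuple[str, str, str, str], ...] = (
    ("T4-fw", "T4", "forward", "CCC TGC TGT TCC AGA TCG ANA ARG ARG C"),
    ("T4-rev", "T4", "reverse", "CTG CCT GGC GTA CTG GTC DAT RWA NAC"),
    ("T7-fw", "T7", "forward", "GAC AAG CGG AAG GAC ATC AAN CAY ACN GAR A"),
    ("T7-rev", "T7", "reverse", "CGC GTA GTT GGC GGC RTT NGG CAT NA"),
    ("N4-fw", "N4", "forward", "GGA TGA TCG TAA TAT TAA TGA TCA GGG NAT HRA YGC"),
    ("N4-rev", "N4", "reverse", "GAC ATA AAG CCC ATT TCG CCR WAN GGR TC"),
    ("GJ1-fw", "GJ1", "forward", "GGC TGC GCG TAT GAT TAG GAY ATH GAY GA"),
    ("GJ1-rev", "GJ1", "reverse", "CCA ATG CAT CAC CGG CAD CCA DAT YTC"),
    ("SP6-fw", "SP6", "forward", "CAC CGT GAT TGC GCG TAA YAC NGT NGC"),
    ("SP6-rev", "SP6", "reverse", "TTC CCA ACG ATC CGG AAT NGC NCC YTC"),
    ("FO1-fw", "FO1", "forward", "CGC CAT TGA AGA ACT GCG TRW RCA YAT GGA"),
    ("FO1-rev", "FO1", "reverse", "GGC ATC ATA TAG GAA TGC GCY TCR AAR TC"),
    ("Vi1-fw", "Vi1", "forward", "GCC GAT TAA TAT TGC GAT GGA YTT YTT"),
    ("Vi1-rev", "Vi1", "reverse", "CCA GCA TAA AGG TCA TAA ATT TCC AYT TYT C"),
)

#: Target groups in panel order.
GROUPS: tuple[str, ...] = ("T4", "T7", "N4", "GJ1", "SP6", "FO1", "Vi1")

#: Singleplex annealing temperatures (degC) per group.
ANNEALING_C: dict[str, float] = {
    "T4": 50.0,
    "FO1": 50.0,
    "GJ1": 50.0,
    "Vi1": 50.0,
    "N4": 55.0,
    "SP6": 55.0,
    "T7": 55.0,
}


def builtin_primers() -> list[Primer]:
    """The 14 panel primers, in panel row order."""
    return [
        Primer(name, group, orientation, DegenerateSequence(seq))
        for name, group, orientation, seq in _PANEL_ROWS
    ]


def builtin_panel() -> list[PrimerPair]:
    """The seven built-in primer pairs with singleplex annealing temps."""
    by_name = {p.name: p for p in builtin_primers()}
    return [
        PrimerPair(
            fw=by_name[f"{g}-fw"],
            rev=by_name[f"{g}-rev"],
            group=g,
            annealing_temp=ANNEALING_C[g],
        )
        for g in GROUPS
    ]


_TABLE_COLUMNS = ("name", "group", "orientation", "sequence")


def load_primer_table(path) -> list[Primer]:
    """Load primers from a TSV with columns name/group/orientation/sequence.

    Whitespace inside sequences is stripped; duplicate names, missing
    columns, invalid orientations and alphabet errors raise distinct
    ``ValueError`` messages.
    """
    path = Path(path)
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"primer table {path} is empty")
        missing = [c for c in _TABLE_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ValueError(
                f"primer table {path} is missing column(s): {', '.join(missing)}"
            )
        rows = list(reader)
    if not rows:
        raise ValueError(f"primer table {path} contains no primers")
    primers: list[Primer] = []
    seen: set[str] = set()
    for row in rows:
        name = (row["name"] or "").strip()
        if name in seen:
            raise ValueError(f"duplicate primer name {name!r} in {path}")
        seen.add(name)
        primers.append(
            Primer(
                name=name,
                group=(row["group"] or "").strip(),
                orientation=(row["orientation"] or "").strip().lower(),
                seq=DegenerateSequence(row["sequence"]),
            )
        )
    return primers


def save_primer_table(primers: Iterable[Primer], path) -> None:
    """Serialise primers to the TSV format read by :func:`load_primer_table`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(_TABLE_COLUMNS)
        for p in primers:
            writer.writerow([p.name, p.group, p.orientation, str(p.seq)])


def pairs_from_primers(
    primers: Sequence[Primer],
    annealing: dict[str, float] | None = None,
    default_annealing: float = 50.0,
) -> dict[str, PrimerPair]:
    """Group loose primers into pairs keyed by group label.

    Each group must contribute exactly one forward and one reverse primer.
    """
    by_group: dict[str, dict[str, Primer]] = {}
    for p in primers:
        slot = by_group.setdefault(p.group, {})
        if p.orientation in slot:
            raise ValueError(
                f"group {p.group!r} has more than one {p.orientation} primer"
            )
        slot[p.orientation] = p
    pairs: dict[str, PrimerPair] = {}
    for group, slot in by_group.items():
        if set(slot) != {"forward", "reverse"}:
            raise ValueError(
                f"group {group!r} needs one forward and one reverse primer"
            )
        temp = (annealing or {}).get(group, default_annealing)
        pairs[group] = PrimerPair(
            fw=slot["forward"], rev=slot["reverse"], group=group, annealing_temp=temp
        )
    return pairs
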