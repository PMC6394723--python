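"""CODEHOP-style degenerate primer design from protein alignments.

A COnsensus-DEgenerate Hybrid Oligonucleotide Primer (CODEHOP) targets a
conserved block of a protein multiple alignment.  It has two parts:

* a short degenerate 3' *core* (here 4 residues, ~11-12 nt) back-translated
  from the block's consensus residues so that every codon variant is
  covered — this is where annealing specificity is decided; and
* a longer non-degenerate 5' consensus *clamp* built from each consensus
  residue's most frequent codon under a host codon-usage table — it
  stabilises the duplex without inflating the degeneracy.

Primer pairs are ranked so combinations with the lowest degeneracy scores
come first.

Codon handling: each residue's codon set is encoded column-wise by the
smallest IUPAC superset per codon position.  For serine, leucine and
arginine (split codon boxes) this is a strict superset of the true codon
set; the encoding still anneals to every true codon, at the cost of a few
phantom expansions.  The degeneracy reported for a core is the degeneracy
of this encoding, which is what ends up in the oligo tube.

Alignment columns are assumed codon-aligned to the coding sequence
(column c <-> nucleotides 3c..3c+2); blocks reject gapped columns by
default, which keeps this exact for the alignments the package designs on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .codon_tables import AMINO_ACIDS, CODON_SETS, CodonUsage, ecoli_k12
from .primers import Primer, PrimerPair, tm_range
from .seqcore import SET_TO_CODE, DegenerateSequence, degeneracy, revcomp

__all__ = [
    "ProteinAlignment",
    "ConservedBlock",
    "CandidatePrimer",
    "DesignedPair",
    "find_blocks",
    "degenerate_backtranslate",
    "build_clamp",
    "design_candidates",
    "pair_candidates",
]

_GAP = "-"
_ALLOWED = set(AMINO_ACIDS) | {_GAP}


@dataclass
class ProteinAlignment:
    """Equal-length aligned amino-acid rows with '-' gaps."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        self.rows = [r.upper() for r in self.rows]
        width = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise ValueError(
                    f"ragged alignment: row {rid!r} has length {len(row)}, "
                    f"expected {width}"
                )
            bad = set(row) - _ALLOWED
            if bad:
                raise ValueError(
                    f"row {rid!r} contains non-standard residues: "
                    + ", ".join(sorted(bad))
                )

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def ncol(self) -> int:
        return len(self.rows[0])

    def column(self, c: int) -> str:
        return "".join(row[c] for row in self.rows)

    def subset(self, ids: Sequence[str]) -> "ProteinAlignment":
        index = {rid: i for i, rid in enumerate(self.ids)}
        return ProteinAlignment(
            ids=list(ids), rows=[self.rows[index[r]] for r in ids]
        )

    @classmethod
    def from_fasta(cls, path) -> "ProteinAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no records in alignment file {path}")
        return cls(
            ids=[r.id for r in records], rows=[str(r.seq) for r in records]
        )


@dataclass
class ConservedBlock:
    """A maximal run of conserved, essentially gap-free columns."""

    start_col: int
    end_col: int  # half-open
    frequencies: list[dict[str, float]]  # per column, over non-gap residues
    consensus: str

    @property
    def length(self) -> int:
        return self.end_col - self.start_col


def _column_stats(column: str) -> tuple[float, float, str]:
    """(gap fraction, majority frequency, majority residue) for a column."""
    gaps = column.count(_GAP)
    gap_fraction = gaps / len(column)
    residues = [r for r in column if r != _GAP]
    if not residues:
        return 1.0, 0.0, ""
    counts: dict[str, int] = {}
    for r in residues:
        counts[r] = counts.get(r, 0) + 1
    best = max(sorted(counts), key=lambda r: counts[r])
    return gap_fraction, counts[best] / len(residues), best


def find_blocks(
    msa: ProteinAlignment,
    min_residues: int = 4,
    min_column_conservation: float = 0.9,
    max_gap_fraction: float = 0.0,
) -> list[ConservedBlock]:
    """Maximal runs of conserved columns, at least ``min_residues`` long.

    A column qualifies when its gap fraction is at most
    ``max_gap_fraction`` and its majority residue reaches frequency
    ``min_column_conservation`` among non-gap residues.
    """
    good: list[bool] = []
    stats = []
    for c in range(msa.ncol):
        gap_fraction, maj_freq, maj_res = _column_stats(msa.column(c))
        stats.append((maj_freq, maj_res))
        good.append(
            gap_fraction <= max_gap_fraction
            and maj_freq >= min_column_conservation
        )
    blocks: list[ConservedBlock] = []
    c = 0
    while c < msa.ncol:
        if not good[c]:
            c += 1
            continue
        start = c
        while c < msa.ncol and good[c]:
            c += 1
        if c - start >= min_residues:
            freqs = []
            consensus = []
            for col in range(start, c):
                column = msa.column(col)
                residues = [r for r in column if r != _GAP]
                counts: dict[str, float] = {}
                for r in residues:
                    counts[r] = counts.get(r, 0.0) + 1.0
                freqs.append({r: n / len(residues) for r, n in sorted(counts.items())})
                consensus.append(stats[col][1])
            blocks.append(ConservedBlock(start, c, freqs, "".join(consensus)))
    return blocks


def _codon_columns(aa: str) -> list[frozenset[str]]:
    codons = CODON_SETS.get(aa)
    if codons is None:
        raise ValueError(f"non-standard amino acid {aa!r}")
    return [frozenset(codon[i] for codon in codons) for i in range(3)]


def degenerate_backtranslate(
    peptide: str | Sequence[str], trailing_nt: int = 0
) -> DegenerateSequence:
    """Fully degenerate back-translation of a peptide.

    Each residue becomes one degenerate codon — the minimal column-wise
    IUPAC encoding of its codon set.  With ``trailing_nt`` of 1 or 2, the
    final codon is truncated to that many bases (a primer ending inside a
    codon's invariant prefix); 0 keeps all three.
    """
    residues = list(peptide)
    if not residues:
        raise ValueError("peptide must be non-empty")
    if trailing_nt not in (0, 1, 2):
        raise ValueError("trailing_nt must be 0, 1 or 2")
    symbols: list[str] = []
    for aa in residues:
        for column in _codon_columns(aa):
            symbols.append(SET_TO_CODE[column])
    if trailing_nt:
        symbols = symbols[: -(3 - trailing_nt)]
    return DegenerateSequence("".join(symbols))


def _modal_cds(residues: str, usage: CodonUsage) -> str:
    return "".join(usage.modal_codon(aa) for aa in residues)


def build_clamp(
    block: ConservedBlock,
    codon_usage: CodonUsage,
    clamp_len_nt: int,
    upto_col: int | None = None,
) -> str:
    """Non-degenerate consensus clamp ending just before ``upto_col``.

    The block's consensus residues in columns ``[start_col, upto_col)``
    are back-translated with each residue's most frequent codon
    (lexicographic tie-break), and the 3'-terminal ``clamp_len_nt`` bases
    are returned.  Raises when the block cannot cover the requested
    length.
    """
    if upto_col is None:
        upto_col = block.end_col
    if not block.start_col <= upto_col <= block.end_col:
        raise ValueError("upto_col outside block")
    residues = block.consensus[: upto_col - block.start_col]
    cds = _modal_cds(residues, codon_usage)
    if len(cds) < clamp_len_nt:
        raise ValueError(
            f"block provides {len(cds)} nt upstream of column {upto_col}, "
            f"clamp needs {clamp_len_nt}"
        )
    return cds[-clamp_len_nt:]


@dataclass(frozen=True)
class CandidatePrimer:
    """A clamp+core primer candidate anchored on a conserved block.

    ``nt_start``/``nt_end`` are the candidate's footprint on the coding
    strand in nucleotides (column c <-> nt 3c); the primer sequence is
    always ``clamp + core`` read 5'->3'.
    """

    name: str
    strand: str  # 'forward' | 'reverse'
    clamp: str
    core: DegenerateSequence
    block: ConservedBlock
    core_start_col: int
    nt_start: int
    nt_end: int

    @property
    def degeneracy(self) -> int:
        return self.core.degeneracy

    @property
    def seq(self) -> DegenerateSequence:
        return DegenerateSequence(self.clamp + str(self.core))

    def __len__(self) -> int:
        return len(self.clamp) + len(self.core)


def design_candidates(
    msa: ProteinAlignment,
    codon_usage: CodonUsage | None = None,
    core_residues: int = 4,
    trailing_nt: int = 2,
    clamp_len: int = 15,
    strands: Sequence[str] = ("forward", "reverse"),
    blocks: list[ConservedBlock] | None = None,
    min_column_conservation: float = 0.9,
    max_gap_fraction: float = 0.0,
) -> list[CandidatePrimer]:
    """All clamp+core candidates anchored at every eligible core position.

    Forward candidates place the degenerate core at alignment columns
    ``[p, p+core_residues)`` with the clamp immediately upstream; reverse
    candidates are built on the reverse complement of the back-translated
    region, core at the 5'-coding side and clamp downstream.  A position
    is eligible when both parts fit inside the block.
    """
    usage = codon_usage or ecoli_k12()
    if blocks is None:
        blocks = find_blocks(
            msa,
            min_residues=core_residues,
            min_column_conservation=min_column_conservation,
            max_gap_fraction=max_gap_fraction,
        )
    candidates: list[CandidatePrimer] = []
    k = core_residues
    for block in blocks:
        for p in range(block.start_col, block.end_col - k + 1):
            core_aa = block.consensus[p - block.start_col : p - block.start_col + k]
            core_full = str(degenerate_backtranslate(core_aa, trailing_nt=0))
            if "forward" in strands and 3 * (p - block.start_col) >= clamp_len:
                core = (
                    core_full[: 3 * (k - 1) + trailing_nt]
                    if trailing_nt
                    else core_full
                )
                clamp = build_clamp(block, usage, clamp_len, upto_col=p)
                candidates.append(
                    CandidatePrimer(
                        name=f"b{block.start_col}-f{p}",
                        strand="forward",
                        clamp=clamp,
                        core=DegenerateSequence(core),
                        block=block,
                        core_start_col=p,
                        nt_start=3 * p - clamp_len,
                        nt_end=3 * p + len(core),
                    )
                )
            if "reverse" in strands and 3 * (block.end_col - (p + k)) >= clamp_len:
                offset = (3 - trailing_nt) if trailing_nt else 0
                core_dna = core_full[offset:]
                clamp_res = block.consensus[p + k - block.start_col :]
                clamp_dna = _modal_cds(clamp_res, usage)[:clamp_len]
                candidates.append(
                    CandidatePrimer(
                        name=f"b{block.start_col}-r{p}",
                        strand="reverse",
                        clamp=revcomp(clamp_dna),
                        core=DegenerateSequence(revcomp(core_dna)),
                        block=block,
                        core_start_col=p,
                        nt_start=3 * p + offset,
                        nt_end=3 * (p + k) + clamp_len,
                    )
                )
    return candidates


@dataclass(frozen=True)
class DesignedPair:
    """A ranked fw/rev combination with its expected product length."""

    pair: PrimerPair
    fw_candidate: CandidatePrimer
    rev_candidate: CandidatePrimer
    product_len: int

    @property
    def max_degeneracy(self) -> int:
        return max(self.fw_candidate.degeneracy, self.rev_candidate.degeneracy)

    @property
    def degeneracy_product(self) -> int:
        return self.fw_candidate.degeneracy * self.rev_candidate.degeneracy


def _interval_distance(a: tuple[float, float], b: tuple[float, float]) -> float:
    return max(0.0, a[0] - b[1], b[0] - a[1])


def pair_candidates(
    candidates: Sequence[CandidatePrimer],
    product_range_bp: tuple[int, int] = (100, 1000),
    max_temp_spread: float = 20.0,
    tm_method: str = "wallace",
    group: str = "designed",
) -> list[DesignedPair]:
    """Rank all fw/rev combinations by degeneracy.

    A combination qualifies when its expected product length (from coding
    footprints, i.e. alignment coordinates x 3) lies inside
    ``product_range_bp``, the primers do not overlap, and the two Tm
    envelopes lie within ``max_temp_spread`` of each other.  The default
    spread is generous because the Wallace envelope of a degenerate mix
    is itself 10-15 degC wide; tighten it when screening concrete
    primers.  Ranking is ascending by (max of the two degeneracies,
    their product), ties by candidate names.
    """
    forwards = [c for c in candidates if c.strand == "forward"]
    reverses = [c for c in candidates if c.strand == "reverse"]
    lo, hi = product_range_bp
    envelopes = {c.name: tm_range(c.seq, method=tm_method) for c in candidates}
    designed: list[DesignedPair] = []
    for fw in forwards:
        for rev in reverses:
            if rev.nt_start < fw.nt_end:
                continue
            product = rev.nt_end - fw.nt_start
            if not lo <= product <= hi:
                continue
            if _interval_distance(envelopes[fw.name], envelopes[rev.name]) > max_temp_spread:
                continue
            anneal = round(
                min(envelopes[fw.name][0], envelopes[rev.name][0]) - 5.0, 1
            )
            pair = PrimerPair(
                fw=Primer(f"{group}-{fw.name}", group, "forward", fw.seq),
                rev=Primer(f"{group}-{rev.name}", group, "reverse", rev.seq),
                group=group,
                annealing_temp=anneal,
            )
            designed.append(DesignedPair(pair, fw, rev, product))
    designed.sort(
        key=lambda d: (
            d.max_degeneracy,
            d.degeneracy_product,
            d.fw_candidate.name,
            d.rev_candidate.name,
        )
    )
    return designed
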