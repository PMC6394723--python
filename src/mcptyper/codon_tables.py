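"""Genetic-code codon sets and codon-usage tables for clamp construction.

The CODEHOP clamp is built from the *most frequent* codon of each consensus
residue under a host codon-usage table; the degenerate core is built from
the *full* codon set of each residue under the standard genetic code.  Both
resources live here.

The bundled usage table is for *Escherichia coli* K-12 (the assay's hosts
are enterobacteria).  Values are relative synonymous-codon frequencies,
normalised to sum to 1 per amino acid at load time, so small rounding in
the literal table is harmless.  Users can supply their own table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = ["CODON_SETS", "AMINO_ACIDS", "CodonUsage", "ECOLI_K12", "ecoli_k12"]

_STANDARD = unambiguous_dna_by_id[1]

#: amino acid -> tuple of DNA codons, from the standard genetic code
CODON_SETS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_STANDARD.forward_table.items()):
    CODON_SETS.setdefault(_aa, ())
    CODON_SETS[_aa] = CODON_SETS[_aa] + (_codon,)

AMINO_ACIDS = "".join(sorted(CODON_SETS))  # the 20 standard residues


# Relative synonymous codon usage, E. coli K-12 (approximate literature
# values; normalised per amino acid on load).
_ECOLI_K12_RAW: dict[str, dict[str, float]] = {
    "A": {"GCG": 0.36, "GCC": 0.27, "GCA": 0.21, "GCT": 0.16},
    "R": {"CGC": 0.40, "CGT": 0.38, "CGG": 0.10, "CGA": 0.06, "AGA": 0.04, "AGG": 0.02},
    "N": {"AAC": 0.55, "AAT": 0.45},
    "D": {"GAT": 0.63, "GAC": 0.37},
    "C": {"TGC": 0.55, "TGT": 0.45},
    "Q": {"CAG": 0.65, "CAA": 0.35},
    "E": {"GAA": 0.68, "GAG": 0.32},
    "G": {"GGC": 0.40, "GGT": 0.34, "GGG": 0.15, "GGA": 0.11},
    "H": {"CAT": 0.57, "CAC": 0.43},
    "I": {"ATT": 0.51, "ATC": 0.42, "ATA": 0.07},
    "L": {"CTG": 0.50, "TTA": 0.13, "TTG": 0.13, "CTT": 0.10, "CTC": 0.10, "CTA": 0.04},
    "K": {"AAA": 0.76, "AAG": 0.24},
    "M": {"ATG": 1.0},
    "F": {"TTT": 0.57, "TTC": 0.43},
    "P": {"CCG": 0.52, "CCA": 0.19, "CCT": 0.16, "CCC": 0.13},
    "S": {"AGC": 0.28, "TCT": 0.15, "TCC": 0.15, "TCG": 0.15, "AGT": 0.15, "TCA": 0.12},
    "T": {"ACC": 0.44, "ACG": 0.27, "ACT": 0.17, "ACA": 0.13},
    "W": {"TGG": 1.0},
    "Y": {"TAT": 0.57, "TAC": 0.43},
    "V": {"GTG": 0.37, "GTT": 0.26, "GTC": 0.22, "GTA": 0.15},
}


@dataclass(frozen=True)
class CodonUsage:
    """Per-amino-acid relative codon frequencies.

    Every standard amino acid must be covered, frequencies must be
    non-negative, and each residue's codons must belong to that residue
    under the standard genetic code.  Frequencies are normalised per
    residue.  Ties in :meth:`modal_codon` resolve to the lexicographically
    first codon so clamp construction is deterministic.
    """

    name: str
    frequencies: Mapping[str, Mapping[str, float]] = field(repr=False)

    def __post_init__(self):
        normed: dict[str, dict[str, float]] = {}
        for aa in AMINO_ACIDS:
            if aa not in self.frequencies:
                raise ValueError(f"codon usage {self.name!r} lacks amino acid {aa!r}")
            table = dict(self.frequencies[aa])
            for codon, freq in table.items():
                if codon not in CODON_SETS[aa]:
                    raise ValueError(
                        f"{codon!r} is not a codon for {aa!r} in the standard code"
                    )
                if freq < 0:
                    raise ValueError(f"negative frequency for {codon!r}")
            total = sum(table.values())
            if total <= 0:
                raise ValueError(f"all-zero frequencies for amino acid {aa!r}")
            normed[aa] = {c: f / total for c, f in sorted(table.items())}
        object.__setattr__(self, "frequencies", normed)

    def modal_codon(self, aa: str) -> str:
        """Most frequent codon for a residue (lexicographic tie-break)."""
        table = self.frequencies[aa]
        return max(sorted(table), key=lambda c: table[c])

    def sample_codon(self, aa: str, rng) -> str:
        """Draw a codon for ``aa`` proportionally to its usage."""
        codons = sorted(self.frequencies[aa])
        probs = [self.frequencies[aa][c] for c in codons]
        return codons[rng.choice(len(codons), p=probs)]


ECOLI_K12 = CodonUsage("E. coli K-12", _ECOLI_K12_RAW)


def ecoli_k12() -> CodonUsage:
    """The bundled default host usage table."""
    return ECOLI_K12
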