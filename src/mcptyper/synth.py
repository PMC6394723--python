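"""Synthetic templates, screening panels, and group-structured MCP MSAs.

The generators emulate the study conditions the assay faces: DNA templates
that carry (or pointedly fail to carry) primer-binding sites, labelled
screening panels mixing group positives with hard negatives, and
group-structured capsid-protein alignments whose conserved blocks support
primer design and whose group structure supports phylogenetic separation.

Everything is a pure function of its seed and configuration: the same seed
reproduces byte-identical output, and every planted feature is returned in
a truth record so downstream sensitivity/specificity can be computed
without re-deriving coordinates.

What is and is not emulated:

* backgrounds are uniform-composition random DNA (25% each base), which
  maximises the detectability of planted signal; real phage genomes have
  skewed composition and repeated elements;
* negatives enumerate the failure modes the virtual PCR must reject
  (no sites, a lone half-site, divergent orientation, wrong spacing)
  rather than modelling biological negatives;
* within conserved blocks the coding DNA uses each residue's most frequent
  codon, emulating the strong codon conservation of conserved regions (and
  making consensus-clamp primers anneal exactly); outside blocks codons
  are sampled from the usage table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .codehop import ProteinAlignment
from .codon_tables import AMINO_ACIDS, CodonUsage, ecoli_k12
from .primers import PrimerPair, builtin_panel
from .seqcore import ConcreteTemplate, base_set, revcomp

__all__ = [
    "PlantSpec",
    "PlantTruth",
    "plant_template",
    "PanelConfig",
    "PanelResult",
    "make_panel",
    "GroupMSA",
    "make_group_msa",
    "DEFAULT_PRODUCT_CENTERS",
    "NEGATIVE_STYLES",
]

_BASES = np.array(list("ACGT"))

NEGATIVE_STYLES = ("no_site", "single_site", "divergent", "wrong_spacing")

#: Default product-size centres (bp) per built-in group; spaced >= 100 bp
#: apart within each triplex so gel bands are visually separable.
DEFAULT_PRODUCT_CENTERS: dict[str, int] = {
    "T4": 250,
    "T7": 400,
    "SP6": 550,
    "N4": 300,
    "FO1": 450,
    "GJ1": 600,
    "Vi1": 700,
}


@dataclass
class PlantSpec:
    """Recipe for one template with a planted primer-pair product."""

    pair: PrimerPair
    product_len: int
    fw_mismatches: int = 0
    rev_mismatches: int = 0
    mismatch_in_clamp: bool = False
    clamp_len: int = 3
    background_len: int = 1200
    seed: int = 0
    template_id: str | None = None

    def __post_init__(self):
        if self.product_len < len(self.pair.fw) + len(self.pair.rev):
            raise ValueError("product_len below combined primer footprint")
        if self.product_len > self.background_len:
            raise ValueError(
                f"product_len {self.product_len} exceeds background "
                f"{self.background_len}"
            )
        for n, primer in ((self.fw_mismatches, self.pair.fw), (self.rev_mismatches, self.pair.rev)):
            if n > len(primer):
                raise ValueError("mismatch count exceeds primer length")


@dataclass
class PlantTruth:
    """Where and what was planted."""

    template_id: str
    group: str
    fw_start: int
    fw_end: int
    rev_start: int
    rev_end: int
    product_len: int
    fw_mismatches: int
    rev_mismatches: int


def _random_background(rng, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _realise(primer_seq: str, rng) -> list[str]:
    """One uniform-random concrete expansion, base by base."""
    return [sorted(base_set(sym))[rng.integers(0, len(base_set(sym)))] for sym in primer_seq]


def _inject_mismatches(
    bases: list[str],
    pattern: str,
    n_mismatches: int,
    in_clamp: bool,
    clamp_len: int,
    rng,
) -> list[str]:
    """Replace bases with guaranteed-mismatching ones.

    The 3' clamp is the last ``clamp_len`` positions of the pattern as
    written 5'->3'.  Only positions whose symbol covers < 4 bases can
    mismatch at all.
    """
    if n_mismatches == 0:
        return bases
    positions = range(len(pattern))
    if in_clamp:
        eligible = [p for p in positions if p >= len(pattern) - clamp_len]
    else:
        eligible = [p for p in positions if p < len(pattern) - clamp_len]
    eligible = [p for p in eligible if len(base_set(pattern[p])) < 4]
    if len(eligible) < n_mismatches:
        raise ValueError(
            f"cannot place {n_mismatches} mismatches in the "
            f"{'clamp' if in_clamp else 'body'} of {pattern!r}"
        )
    chosen = rng.choice(len(eligible), size=n_mismatches, replace=False)
    out = list(bases)
    for c in sorted(chosen):
        p = eligible[c]
        bad = sorted(set("ACGT") - base_set(pattern[p]))
        out[p] = bad[rng.integers(0, len(bad))]
    return out


def plant_template(spec: PlantSpec) -> tuple[ConcreteTemplate, PlantTruth]:
    """A random-background template carrying exactly one planted product.

    The forward primer is planted as a concrete expansion on the plus
    strand; the reverse primer's reverse complement is planted downstream
    so the convergent product has exactly ``product_len`` bp.  Requested
    mismatches are injected at random eligible positions (inside or
    outside the 3' clamp per the flag).  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(spec.seed)
    arr = _random_background(rng, spec.background_len)
    pair = spec.pair
    lf, lr = len(pair.fw), len(pair.rev)
    start = int(rng.integers(0, spec.background_len - spec.product_len + 1))
    fw_pattern = str(pair.fw.seq)
    fw_bases = _realise(fw_pattern, rng)
    fw_bases = _inject_mismatches(
        fw_bases, fw_pattern, spec.fw_mismatches, spec.mismatch_in_clamp,
        spec.clamp_len, rng,
    )
    rev_pattern = str(pair.rev.seq)
    rev_bases = _realise(rev_pattern, rng)
    rev_bases = _inject_mismatches(
        rev_bases, rev_pattern, spec.rev_mismatches, spec.mismatch_in_clamp,
        spec.clamp_len, rng,
    )
    arr[start : start + lf] = fw_bases
    rev_site = revcomp("".join(rev_bases))
    rev_start = start + spec.product_len - lr
    arr[rev_start : rev_start + lr] = list(rev_site)
    template_id = spec.template_id or f"{pair.group}_seed{spec.seed}"
    template = ConcreteTemplate(template_id, "".join(arr))
    truth = PlantTruth(
        template_id=template_id,
        group=pair.group,
        fw_start=start,
        fw_end=start + lf,
        rev_start=rev_start,
        rev_end=rev_start + lr,
        product_len=spec.product_len,
        fw_mismatches=spec.fw_mismatches,
        rev_mismatches=spec.rev_mismatches,
    )
    return template, truth


@dataclass
class PanelConfig:
    """Shape of a labelled screening panel.

    Defaults mirror a field survey's frequency shape: a handful of group
    positives against a large negative background.
    """

    pairs: Sequence[PrimerPair] | None = None  # default: the built-in panel
    positives_per_group: int = 2
    negatives: int = 140
    negative_styles: Sequence[str] = NEGATIVE_STYLES
    product_centers: dict[str, int] | None = None
    product_jitter: int = 15
    background_len: int = 1200
    seed: int = 0

    def __post_init__(self):
        if self.positives_per_group < 0 or self.negatives < 0:
            raise ValueError("counts must be non-negative")
        if self.positives_per_group + self.negatives < 1:
            raise ValueError("panel must contain at least one template")
        bad = set(self.negative_styles) - set(NEGATIVE_STYLES)
        if bad:
            raise ValueError(f"unknown negative styles: {sorted(bad)}")


@dataclass
class PanelResult:
    templates: list[ConcreteTemplate]
    truth: pd.DataFrame
    labels: dict[str, str]  # template_id -> group label or 'negative'


def _negative_template(
    style: str,
    pairs: Sequence[PrimerPair],
    background_len: int,
    seed: int,
    template_id: str,
) -> ConcreteTemplate:
    rng = np.random.default_rng(seed)
    arr = _random_background(rng, background_len)
    if style != "no_site":
        pair = pairs[rng.integers(0, len(pairs))]
        lf, lr = len(pair.fw), len(pair.rev)
        fw_bases = _realise(str(pair.fw.seq), rng)
        rev_site = list(revcomp("".join(_realise(str(pair.rev.seq), rng))))
        if style == "single_site":
            pos = int(rng.integers(0, background_len - lf + 1))
            arr[pos : pos + lf] = fw_bases
        elif style == "divergent":
            # reverse-primer site upstream of the forward site: primers
            # point away from each other, no product.
            a = int(rng.integers(0, background_len - (lf + lr + 200)))
            arr[a : a + lr] = rev_site
            b = a + lr + 100
            arr[b : b + lf] = fw_bases
        elif style == "wrong_spacing":
            # convergent but closer than any plausible product length
            a = int(rng.integers(0, background_len - (lf + lr + 2)))
            arr[a : a + lf] = fw_bases
            arr[a + lf + 2 : a + lf + 2 + lr] = rev_site
    return ConcreteTemplate(template_id, "".join(arr))


def make_panel(config: PanelConfig) -> PanelResult:
    """A labelled panel of group positives and styled negatives.

    Positives get per-group product lengths drawn around
    ``product_centers`` (defaults spaced so triplex bands are separable);
    negatives cycle through the configured styles.  The truth table
    carries template id, label, style and planted coordinates.
    """
    pairs = list(config.pairs) if config.pairs is not None else builtin_panel()
    centers = dict(DEFAULT_PRODUCT_CENTERS)
    if config.product_centers:
        centers.update(config.product_centers)
    for i, pair in enumerate(pairs):
        centers.setdefault(pair.group, 250 + 120 * i)
    master = np.random.default_rng(config.seed)
    templates: list[ConcreteTemplate] = []
    labels: dict[str, str] = {}
    rows: list[dict] = []
    for pair in pairs:
        for i in range(config.positives_per_group):
            sub_seed = int(master.integers(0, 2**31 - 1))
            jitter = int(master.integers(-config.product_jitter, config.product_jitter + 1))
            spec = PlantSpec(
                pair=pair,
                product_len=centers[pair.group] + jitter,
                background_len=config.background_len,
                seed=sub_seed,
                template_id=f"{pair.group}_p{i:03d}",
            )
            template, truth = plant_template(spec)
            templates.append(template)
            labels[template.id] = pair.group
            rows.append(
                {
                    "template_id": truth.template_id,
                    "label": pair.group,
                    "style": "positive",
                    "fw_start": truth.fw_start,
                    "fw_end": truth.fw_end,
                    "rev_start": truth.rev_start,
                    "rev_end": truth.rev_end,
                    "product_len": truth.product_len,
                }
            )
    styles = list(config.negative_styles)
    for i in range(config.negatives):
        style = styles[i % len(styles)]
        sub_seed = int(master.integers(0, 2**31 - 1))
        tid = f"neg_{style}_{i:03d}"
        templates.append(
            _negative_template(style, pairs, config.background_len, sub_seed, tid)
        )
        labels[tid] = "negative"
        rows.append(
            {
                "template_id": tid,
                "label": "negative",
                "style": style,
                "fw_start": -1,
                "fw_end": -1,
                "rev_start": -1,
                "rev_end": -1,
                "product_len": -1,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "template_id", "label", "style",
            "fw_start", "fw_end", "rev_start", "rev_end", "product_len",
        ],
    )
    return PanelResult(templates, truth, labels)


@dataclass
class GroupMSA:
    """Group-structured protein alignment with matching coding DNA."""

    msa: ProteinAlignment  # all groups combined
    group_of: dict[str, str]  # sequence id -> group label
    groups: dict[str, ProteinAlignment]  # per-group sub-alignments
    dna: dict[str, ConcreteTemplate]  # sequence id -> coding DNA
    blocks: tuple[tuple[int, int], ...]  # designated (start, length) in residues


def make_group_msa(
    n_groups: int = 7,
    seqs_per_group: int = 6,
    seq_len: int = 120,
    blocks: Sequence[tuple[int, int]] = ((20, 10), (70, 10)),
    within_divergence: float = 0.5,
    between_divergence: float = 0.9,
    codon_usage: CodonUsage | None = None,
    seed: int = 0,
    group_labels: Sequence[str] | None = None,
) -> GroupMSA:
    """Group-structured MSAs with designated conserved blocks.

    Each group descends from a group ancestor (the global root mutated per
    column with probability ``between_divergence``).  Designated block
    columns are held fixed within a group; every other column gives each
    sequence its ancestral residue with probability
    ``1 - within_divergence`` and otherwise a draw from a group-specific
    4-residue pool.  Coding DNA uses the modal codon inside blocks and
    usage-sampled codons elsewhere.
    """
    if not 0.0 <= within_divergence <= 1.0:
        raise ValueError("within_divergence must lie in [0, 1]")
    if not 0.0 <= between_divergence <= 1.0:
        raise ValueError("between_divergence must lie in [0, 1]")
    for start, length in blocks:
        if start < 0 or start + length > seq_len:
            raise ValueError(f"block ({start}, {length}) outside sequence")
    usage = codon_usage or ecoli_k12()
    labels = list(group_labels) if group_labels else [f"grp{g + 1}" for g in range(n_groups)]
    if len(labels) != n_groups:
        raise ValueError("group_labels length must equal n_groups")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    block_cols = {
        c for start, length in blocks for c in range(start, start + length)
    }
    root = aa[rng.integers(0, len(aa), size=seq_len)]
    ids: list[str] = []
    rows: list[str] = []
    group_of: dict[str, str] = {}
    dna: dict[str, ConcreteTemplate] = {}
    per_group_rows: dict[str, list[tuple[str, str]]] = {g: [] for g in labels}
    for g, label in enumerate(labels):
        ancestor = root.copy()
        mutate = rng.random(seq_len) < between_divergence
        ancestor[mutate] = aa[rng.integers(0, len(aa), size=int(mutate.sum()))]
        pools: dict[int, np.ndarray] = {}
        for c in range(seq_len):
            if c in block_cols:
                continue
            pool = aa[rng.choice(len(aa), size=4, replace=False)]
            if ancestor[c] not in pool:
                pool[0] = ancestor[c]
            pools[c] = pool
        for s in range(seqs_per_group):
            residues = ancestor.copy()
            for c in range(seq_len):
                if c in block_cols:
                    continue
                if rng.random() < within_divergence:
                    residues[c] = pools[c][rng.integers(0, 4)]
            protein = "".join(residues)
            sid = f"{label}_s{s}"
            ids.append(sid)
            rows.append(protein)
            group_of[sid] = label
            per_group_rows[label].append((sid, protein))
            codons = []
            for c, residue in enumerate(protein):
                if c in block_cols:
                    codons.append(usage.modal_codon(residue))
                else:
                    codons.append(usage.sample_codon(residue, rng))
            dna[sid] = ConcreteTemplate(sid, "".join(codons))
    msa = ProteinAlignment(ids, rows)
    groups = {
        label: ProteinAlignment(
            [sid for sid, _ in group_rows], [row for _, row in group_rows]
        )
        for label, group_rows in per_group_rows.items()
    }
    return GroupMSA(
        msa=msa,
        group_of=group_of,
        groups=groups,
        dna=dna,
        blocks=tuple((start, length) for start, length in blocks),
    )
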