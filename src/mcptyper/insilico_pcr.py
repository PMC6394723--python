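"""Virtual PCR: binding sites, amplicons, (multi)plex assays, group calls.

The annealing model is set membership, not thermodynamics: a primer symbol
matches a template base when the base belongs to the symbol's IUPAC base
set.  Annealing temperature plays no role in site matching (the assay is
robust over a wide annealing range); it is only used when checking
multiplex compatibility.

Group calling uses a two-tier matching scheme that mirrors how gel bands
are read.  *Stringent* thresholds (default: no mismatches anywhere, and in
particular none in the 3'-terminal clamp, where a mismatch abolishes
polymerase extension) produce calls.  A *relaxed* scan (default: up to
three mismatches outside an intact 3' clamp) additionally detects
weakly-matching products; these are recorded with a ``nonspecific_band``
flag and never produce a call — the software analogue of rating faint
size-deviant bands negative.

Coordinates are 0-based half-open on the plus strand.  Amplicon prediction
considers both physical orientations of a convergent primer pair (forward
primer annealing to either strand), so typing a template and typing its
reverse complement give identical calls and product lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from numpy.lib.stride_tricks import sliding_window_view

from .primers import Primer, PrimerPair
from .seqcore import (
    COMPLEMENT,
    ConcreteTemplate,
    DegenerateSequence,
    base_set,
    revcomp,
)

__all__ = [
    "MatchThresholds",
    "STRINGENT",
    "RELAXED",
    "BindingSite",
    "Amplicon",
    "AssayDefinition",
    "TypingResult",
    "find_binding_sites",
    "predict_amplicons",
    "run_assay",
    "evaluate_panel",
    "PanelEvaluation",
    "check_multiplex_compatibility",
    "CompatibilityReport",
    "cross_dimer_3prime",
    "load_assay_config",
    "typing_results_to_frame",
    "default_min_len",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class MatchThresholds:
    """Mismatch allowances for a binding-site scan.

    ``clamp_len`` is the number of 3'-terminal primer bases treated as the
    extension-critical clamp; ``clamp_max_mismatch`` bounds mismatches
    inside it and ``max_mismatch`` bounds mismatches over the whole primer.
    """

    max_mismatch: int = 0
    clamp_len: int = 3
    clamp_max_mismatch: int = 0


#: Call-producing thresholds: perfect match.
STRINGENT = MatchThresholds(max_mismatch=0, clamp_len=3, clamp_max_mismatch=0)
#: Nonspecific-band scan: imperfect body, intact 3' clamp.
RELAXED = MatchThresholds(max_mismatch=3, clamp_len=3, clamp_max_mismatch=0)


@dataclass(frozen=True)
class BindingSite:
    """A located primer match on a template."""

    template_id: str
    strand: str  # '+' or '-'
    start: int
    end: int
    primer_name: str
    mismatches: int
    clamp_mismatches: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (self.mismatches >= self.clamp_mismatches >= 0):
            raise ValueError("mismatches >= clamp_mismatches >= 0 violated")


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product bounded by a convergent site pair."""

    template_id: str
    start: int
    end: int
    pair: str  # group label of the producing pair
    fw_site: BindingSite
    rev_site: BindingSite
    nonspecific: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AssayDefinition:
    """One reaction: 1-3 primer pairs at a shared annealing temperature."""

    name: str
    pairs: tuple[PrimerPair, ...]
    annealing_temp: float
    min_band_separation: int = 100

    def __post_init__(self):
        pairs = tuple(self.pairs)
        object.__setattr__(self, "pairs", pairs)
        if not 1 <= len(pairs) <= 3:
            raise ValueError(f"assay {self.name!r}: need 1-3 pairs, got {len(pairs)}")
        groups = [p.group for p in pairs]
        if len(set(groups)) != len(groups):
            raise ValueError(f"assay {self.name!r}: pair groups must be distinct")


@dataclass
class TypingResult:
    """Per-template calls with supporting amplicons and flags."""

    template_id: str
    calls: set[str]
    amplicons: list[Amplicon]
    flags: set[str] = field(default_factory=set)


def default_min_len(pair: PrimerPair, margin: int = 10) -> int:
    """Smallest plausible product: both primer footprints plus a margin."""
    return len(pair.fw) + len(pair.rev) + margin


def _encode_template(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.encode("ascii").translate(
            bytes.maketrans(b"ACGTN", bytes(range(5)))
        ),
        dtype=np.uint8,
    )


def _pattern_mask(pattern: str, n_as_wildcard: bool) -> np.ndarray:
    mask = np.zeros((len(pattern), 5), dtype=bool)
    for i, sym in enumerate(pattern):
        for b in base_set(sym):
            mask[i, _BASE_INDEX[b]] = True
        mask[i, 4] = n_as_wildcard
    return mask


def _scan(
    pattern: str,
    tcode: np.ndarray,
    clamp_slice: slice,
    n_as_wildcard: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Offsets plus total/clamp mismatch counts for one strand pattern."""
    length = len(pattern)
    if len(tcode) < length:
        return (np.empty(0, int), np.empty(0, int), np.empty(0, int))
    windows = sliding_window_view(tcode, length)  # (n_offsets, length)
    mask = _pattern_mask(pattern, n_as_wildcard)
    hits = mask[np.arange(length)[None, :], windows]  # (n_offsets, length)
    mismatches = length - hits.sum(axis=1)
    clamp_cols = hits[:, clamp_slice]
    clamp_mismatches = clamp_cols.shape[1] - clamp_cols.sum(axis=1)
    offsets = np.arange(hits.shape[0])
    return offsets, mismatches, clamp_mismatches


def find_binding_sites(
    primer: Union[Primer, DegenerateSequence, str],
    template: ConcreteTemplate,
    max_mismatch: int = 0,
    clamp_len: int = 3,
    clamp_max_mismatch: int = 0,
    n_as_wildcard: bool = False,
) -> list[BindingSite]:
    """All plus- and minus-strand sites within the mismatch thresholds.

    On the plus strand the primer is matched as written (3' clamp at the
    right end of the site); on the minus strand its reverse complement is
    matched against the plus strand (3' clamp at the left end).  A
    template shorter than the primer yields an empty list.
    """
    if isinstance(primer, Primer):
        name, seq = primer.name, str(primer.seq)
    else:
        seq = str(DegenerateSequence(primer))
        name = seq
    if clamp_len > len(seq):
        raise ValueError(
            f"clamp_len {clamp_len} exceeds primer length {len(seq)}"
        )
    tcode = _encode_template(template.seq)
    sites: list[BindingSite] = []
    scans = (
        ("+", seq, slice(len(seq) - clamp_len, len(seq))),
        ("-", revcomp(seq), slice(0, clamp_len)),
    )
    for strand, pattern, clamp_slice in scans:
        offsets, mm, cmm = _scan(pattern, tcode, clamp_slice, n_as_wildcard)
        keep = (mm <= max_mismatch) & (cmm <= clamp_max_mismatch)
        for off, m, c in zip(offsets[keep], mm[keep], cmm[keep]):
            sites.append(
                BindingSite(
                    template_id=template.id,
                    strand=strand,
                    start=int(off),
                    end=int(off) + len(seq),
                    primer_name=name,
                    mismatches=int(m),
                    clamp_mismatches=int(c),
                )
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def _combine_sites(
    pair: PrimerPair,
    fw_sites: Sequence[BindingSite],
    rev_sites: Sequence[BindingSite],
    template_id: str,
    min_len: int,
    max_len: int,
) -> list[Amplicon]:
    amps: list[Amplicon] = []
    # Orientation A: forward primer on +, reverse primer on -, fw upstream.
    for f in fw_sites:
        if f.strand != "+":
            continue
        for r in rev_sites:
            if r.strand != "-" or r.start <= f.start:
                continue
            length = r.end - f.start
            if min_len <= length <= max_len:
                amps.append(
                    Amplicon(template_id, f.start, r.end, pair.group, f, r)
                )
    # Orientation B: the same product read on the other strand.
    for r in rev_sites:
        if r.strand != "+":
            continue
        for f in fw_sites:
            if f.strand != "-" or f.start <= r.start:
                continue
            length = f.end - r.start
            if min_len <= length <= max_len:
                amps.append(
                    Amplicon(template_id, r.start, f.end, pair.group, f, r)
                )
    amps.sort(key=lambda a: (a.start, a.length))
    return amps


def predict_amplicons(
    pair: PrimerPair,
    template: ConcreteTemplate,
    min_len: int | None = None,
    max_len: int = 5000,
    thresholds: MatchThresholds = STRINGENT,
    n_as_wildcard: bool = False,
) -> list[Amplicon]:
    """Products from all convergent site pairs within the length window.

    ``min_len`` defaults to the primer-length sum plus 10 bp; ``max_len``
    defaults to 5 kb (standard Taq extension reach).  Results are sorted
    by start, then length.
    """
    if min_len is None:
        min_len = default_min_len(pair)
    kwargs = dict(
        max_mismatch=thresholds.max_mismatch,
        clamp_len=thresholds.clamp_len,
        clamp_max_mismatch=thresholds.clamp_max_mismatch,
        n_as_wildcard=n_as_wildcard,
    )
    fw_sites = find_binding_sites(pair.fw, template, **kwargs)
    rev_sites = find_binding_sites(pair.rev, template, **kwargs)
    return _combine_sites(pair, fw_sites, rev_sites, template.id, min_len, max_len)


def _meets(site: BindingSite, t: MatchThresholds) -> bool:
    return (
        site.mismatches <= t.max_mismatch
        and site.clamp_mismatches <= t.clamp_max_mismatch
    )


def run_assay(
    assay: AssayDefinition,
    template: ConcreteTemplate,
    stringent: MatchThresholds = STRINGENT,
    relaxed: MatchThresholds = RELAXED,
    min_len: int | None = None,
    max_len: int = 5000,
    n_as_wildcard: bool = False,
) -> TypingResult:
    """Type one template with one (multi)plex reaction.

    Calls come from amplicons whose sites meet the stringent thresholds.
    Amplicons passing only the relaxed scan are kept, marked nonspecific,
    and flagged ``nonspecific_band``.  If two called groups yield bands
    closer than the assay's ``min_band_separation``, both contribute a
    ``band_collision`` flag (the calls stand; the gel would be ambiguous).
    """
    calls: set[str] = set()
    flags: set[str] = set()
    all_amps: list[Amplicon] = []
    called_lengths: dict[str, list[int]] = {}
    for pair in assay.pairs:
        amps = predict_amplicons(
            pair,
            template,
            min_len=min_len,
            max_len=max_len,
            thresholds=relaxed,
            n_as_wildcard=n_as_wildcard,
        )
        for amp in amps:
            specific = _meets(amp.fw_site, stringent) and _meets(
                amp.rev_site, stringent
            )
            if specific:
                calls.add(pair.group)
                called_lengths.setdefault(pair.group, []).append(amp.length)
                all_amps.append(amp)
            else:
                flags.add("nonspecific_band")
                all_amps.append(replace(amp, nonspecific=True))
    groups = sorted(called_lengths)
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            gap = min(
                abs(a - b)
                for a in called_lengths[g1]
                for b in called_lengths[g2]
            )
            if gap < assay.min_band_separation:
                flags.add("band_collision")
    return TypingResult(template.id, calls, all_amps, flags)


@dataclass
class PanelEvaluation:
    """Confusion table plus per-group sensitivity and specificity."""

    confusion: pd.DataFrame
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    results: dict[str, TypingResult]


def evaluate_panel(
    assays: Sequence[AssayDefinition],
    labeled_templates: Sequence[tuple[ConcreteTemplate, str]],
    negative_label: str = "negative",
    **run_kwargs,
) -> PanelEvaluation:
    """Screen labelled templates with a set of assays and score the panel.

    A template's calls are the union over all assays.  Per group,
    sensitivity = called true positives / labelled positives and
    specificity = 1 - false positives / templates not of that group;
    sensitivity is NaN when a group has no labelled positives.
    """
    groups = sorted({p.group for a in assays for p in a.pairs})
    valid_labels = set(groups) | {negative_label}
    results: dict[str, TypingResult] = {}
    labels: dict[str, str] = {}
    for template, label in labeled_templates:
        if not label:
            raise ValueError(f"template {template.id!r} has no label")
        if label not in valid_labels:
            raise ValueError(
                f"template {template.id!r}: label {label!r} is not a panel "
                f"group or {negative_label!r}"
            )
        merged = TypingResult(template.id, set(), [], set())
        for assay in assays:
            r = run_assay(assay, template, **run_kwargs)
            merged.calls |= r.calls
            merged.amplicons.extend(r.amplicons)
            merged.flags |= r.flags
        results[template.id] = merged
        labels[template.id] = label
    row_order = groups + [negative_label]
    confusion = pd.DataFrame(
        0, index=pd.Index(row_order, name="true"), columns=groups + ["no_call"]
    )
    for tid, label in labels.items():
        called = results[tid].calls
        if not called:
            confusion.loc[label, "no_call"] += 1
        for g in called:
            confusion.loc[label, g] += 1
    sensitivity: dict[str, float] = {}
    specificity: dict[str, float] = {}
    for g in groups:
        positives = [t for t in labels if labels[t] == g]
        others = [t for t in labels if labels[t] != g]
        if positives:
            tp = sum(g in results[t].calls for t in positives)
            sensitivity[g] = tp / len(positives)
        else:
            sensitivity[g] = float("nan")
        if others:
            fp = sum(g in results[t].calls for t in others)
            specificity[g] = 1.0 - fp / len(others)
        else:
            specificity[g] = float("nan")
    return PanelEvaluation(confusion, sensitivity, specificity, results)


def cross_dimer_3prime(
    a: Union[str, DegenerateSequence, Primer],
    b: Union[str, DegenerateSequence, Primer],
) -> int:
    """Longest 3'-anchored complementary run between two primers.

    The run aligns both 3' termini antiparallel: a run of length ``k``
    means positions ``a[-j]`` and ``b[-(k+1-j)]`` can pair for all
    ``j = 1..k``.  For degenerate symbols, "can pair" means some concrete
    realisation pairs (the base sets intersect under complementation).
    """
    sa = str(a.seq if isinstance(a, Primer) else DegenerateSequence(a))
    sb = str(b.seq if isinstance(b, Primer) else DegenerateSequence(b))
    best = 0
    for k in range(1, min(len(sa), len(sb)) + 1):
        ok = all(
            base_set(COMPLEMENT[sa[-j]]) & base_set(sb[-(k + 1 - j)])
            for j in range(1, k + 1)
        )
        if ok:
            best = k
    return best


@dataclass
class CompatibilityReport:
    """Why a multiplex combination is, or is not, workable."""

    groups: tuple[str, ...]
    temp_spread: float
    max_temp_spread: float
    product_sizes: dict[str, list[int]]
    band_separations: dict[tuple[str, str], int | None]
    cross_dimers: dict[tuple[str, str], int]
    compatible: bool
    reasons: list[str]


def check_multiplex_compatibility(
    pairs: Sequence[PrimerPair],
    reference_templates: Sequence[ConcreteTemplate],
    max_temp_spread: float = 4.0,
    min_band_separation: int = 100,
    max_len: int = 5000,
    **predict_kwargs,
) -> CompatibilityReport:
    """Can 2-3 primer pairs share one reaction?

    Checks (a) the annealing-temperature spread against
    ``max_temp_spread``, (b) pairwise predicted-product separations on the
    reference templates against ``min_band_separation``, and (c) an
    advisory 3' cross-dimer screen (longest 3'-anchored complementary run
    between any two primers; reported, never decisive).
    """
    if len(pairs) < 2:
        raise ValueError("multiplex compatibility needs at least 2 pairs")
    reasons: list[str] = []
    temps = [p.annealing_temp for p in pairs]
    spread = max(temps) - min(temps)
    if spread > max_temp_spread:
        reasons.append(
            f"annealing spread {spread:.1f} degC exceeds {max_temp_spread:.1f} degC"
        )
    sizes: dict[str, list[int]] = {}
    for pair in pairs:
        lengths: list[int] = []
        for template in reference_templates:
            lengths.extend(
                a.length
                for a in predict_amplicons(
                    pair, template, max_len=max_len, **predict_kwargs
                )
            )
        sizes[pair.group] = sorted(lengths)
    separations: dict[tuple[str, str], int | None] = {}
    for i, p1 in enumerate(pairs):
        for p2 in pairs[i + 1 :]:
            key = (p1.group, p2.group)
            if not sizes[p1.group] or not sizes[p2.group]:
                separations[key] = None
                empty = [g for g in key if not sizes[g]]
                reasons.append(
                    "no reference product for " + ", ".join(empty) + " (size check skipped)"
                )
                continue
            gap = min(
                abs(a - b) for a in sizes[p1.group] for b in sizes[p2.group]
            )
            separations[key] = gap
            if gap < min_band_separation:
                reasons.append(
                    f"bands of {p1.group} and {p2.group} differ by {gap} bp "
                    f"(< {min_band_separation} bp)"
                )
    dimers: dict[tuple[str, str], int] = {}
    all_primers = [pr for pair in pairs for pr in pair.primers]
    for i, a in enumerate(all_primers):
        for b in all_primers[i:]:
            dimers[(a.name, b.name)] = cross_dimer_3prime(a, b)
    blocking = [
        r for r in reasons if "skipped" not in r
    ]
    return CompatibilityReport(
        groups=tuple(p.group for p in pairs),
        temp_spread=spread,
        max_temp_spread=max_temp_spread,
        product_sizes=sizes,
        band_separations=separations,
        cross_dimers=dimers,
        compatible=not blocking,
        reasons=reasons,
    )


def load_assay_config(
    path, pairs_by_group: Mapping[str, PrimerPair]
) -> list[AssayDefinition]:
    """Read assay definitions from a YAML file.

    Expected structure::

        assays:
          - name: tri1
            pairs: [T4, T7, SP6]
            annealing_temp: 52
            min_band_separation: 100   # optional

    Pairs are referenced by group label; each pair is re-labelled with the
    assay's annealing temperature.
    """
    with open(path) as handle:
        config = yaml.safe_load(handle)
    if not isinstance(config, dict) or "assays" not in config:
        raise ValueError(f"assay config {path} lacks an 'assays' section")
    assays: list[AssayDefinition] = []
    for entry in config["assays"]:
        temp = float(entry["annealing_temp"])
        pairs = []
        for group in entry["pairs"]:
            if group not in pairs_by_group:
                raise ValueError(f"assay config names unknown group {group!r}")
            base = pairs_by_group[group]
            pairs.append(replace(base, annealing_temp=temp))
        assays.append(
            AssayDefinition(
                name=str(entry["name"]),
                pairs=tuple(pairs),
                annealing_temp=temp,
                min_band_separation=int(entry.get("min_band_separation", 100)),
            )
        )
    return assays


def typing_results_to_frame(results: Iterable[TypingResult]) -> pd.DataFrame:
    """Flatten typing results into the TSV report layout."""
    rows = []
    for r in results:
        lengths = sorted(a.length for a in r.amplicons if not a.nonspecific)
        rows.append(
            {
                "template_id": r.template_id,
                "calls": ",".join(sorted(r.calls)) or "-",
                "amplicon_lengths": ",".join(map(str, lengths)) or "-",
                "flags": ",".join(sorted(r.flags)) or "-",
            }
        )
    return pd.DataFrame(rows, columns=["template_id", "calls", "amplicon_lengths", "flags"])
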