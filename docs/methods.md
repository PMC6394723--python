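# Methods

This note records the models behind `mcptyper`, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical conventions that make results reproducible.

## Degenerate-sequence algebra (`seqcore`)

Primers are strings over the 15-letter IUPAC DNA alphabet; each symbol
denotes a non-empty subset of {A, C, G, T} (sizes 1, 2, 3 or 4). The
degeneracy of a sequence is the product of per-position subset sizes and
equals the cardinality of its concrete expansion; `expand` refuses
(naming the product) beyond a caller-set limit so accidental
combinatorial blow-ups fail loudly. Reverse complementation acts
symbol-wise through the complement-image of each base set (R↔Y, K↔M,
B↔V, D↔H; S, W, N self-complementary) and is an involution.

Parsing strips whitespace and uppercases, so triplet-grouped primer
notation can be pasted verbatim. Coordinates are 0-based, half-open, on
the plus strand. Template `N` (masked/unknown) matches *no* primer
symbol by default — conservative, so masked regions cannot fabricate
amplicons — with an `n_as_wildcard` escape hatch.

## Primer model and melting temperatures (`primers`)

The built-in panel is seven forward/reverse degenerate pairs, one per
target group, with singleplex annealing temperatures of 50 °C (T4, FO1,
GJ1, Vi1) or 55 °C (N4, SP6, T7). Degeneracy scores are 16/48 (T4),
64/32 (T7), 48/32 (N4), 12/18 (GJ1), 32/32 (SP6), 16/8 (FO1) and 4/4
(Vi1); the suite recomputes all of them from the sequences.

A degenerate primer has no single Tm, so `tm_range` reports a
(min, max) envelope over the concrete expansions. Two estimators:

* *nearest-neighbor* (default for concrete oligos): unified NN
  parameters via Biopython, at 50 mM monovalent salt and 0.4 µM total
  primer — evaluated by enumeration, hence bounded by the expansion
  limit;
* *Wallace* 2(A+T)+4(G+C): the envelope has a closed form (choose the
  cheapest/dearest base per position), needs no enumeration, and is used
  wherever high-degeneracy candidates must be screened quickly.

The envelope is advisory: annealing temperature plays no role in site
matching (the assay tolerates a wide annealing range), only in multiplex
compatibility reports and design-time screening.

## Virtual PCR and group calling (`insilico_pcr`)

A primer binds where every template base lies in the corresponding
symbol's base set; both strands are scanned (the reverse complement of
the primer against the plus strand for minus-strand sites). Each site
records total mismatches and mismatches inside the 3′-terminal clamp
window (default 3 nt), where a mismatch abolishes polymerase extension.

Two threshold tiers reproduce how gels are read:

* stringent (calls): 0 mismatches, clamp intact;
* relaxed (nonspecific bands): ≤3 body mismatches, clamp intact.
  Products passing only this tier are flagged `nonspecific_band` and
  never produce calls — the software analogue of rating faint,
  size-deviant bands negative.

Amplicons are convergent site pairs within a length window (default:
primer-length sum + 10 bp up to 5 kb, standard Taq reach). Both physical
orientations are considered — the forward primer may anneal to either
strand with the reverse primer converging on the other — which is what
makes typing invariant under reverse-complementing the template. (A
one-orientation model would break that symmetry, so the per-amplicon
bookkeeping stores which site played which role rather than fixing the
forward site to the plus strand.)

Within a multiplex, called groups whose band sizes differ by less than
`min_band_separation` (default 100 bp — a conservative gap a standard
agarose gel resolves; configurable) are flagged `band_collision`; the
calls stand, the flag marks gel ambiguity. Multiplex compatibility
reports check annealing-temperature spread (default limit 4 °C) and
pairwise band separations on user-supplied reference templates — product
sizes are template properties, not assay constants — plus an advisory 3′
cross-dimer screen (longest 3′-anchored complementary run between any
two primers, degenerate symbols pairing if any realisation pairs).

Panel evaluation: per group, sensitivity = called true positives /
labelled positives; specificity = 1 − false positives / templates not of
that group; sensitivity is NaN when no positives are labelled.

## CODEHOP-style design (`codehop`)

Conserved blocks are maximal runs of alignment columns whose majority
residue reaches `min_column_conservation` (default 0.9) with gap
fraction ≤ `max_gap_fraction` (default 0), at least 4 residues long.
Because the thresholds that decide whether a reference sequence is
"similar enough" to keep are not canonical, they are free parameters.

Candidates have a degenerate 3′ core of `core_residues` (default 4)
consensus residues, back-translated codon-wise: each residue's codon set
is encoded column-wise by the smallest IUPAC superset. For the split
codon boxes (Ser, Leu, Arg) this is a strict superset of the true codon
set — every true codon still anneals; a few phantom oligos join the mix.
The final codon may be truncated to 1 or 2 bases (`trailing_nt`,
default 2), ending the primer inside a codon's invariant prefix. The 5′
clamp (default 15 nt) takes each upstream consensus residue's most
frequent codon under the codon-usage table (bundled: *E. coli* K-12, the
natural host context for an enterobacteria panel; user-swappable);
equal-frequency codons resolve lexicographically so designs are
deterministic. Reverse candidates are the reverse complement of the
back-translated region with the core at the 5′-coding side.

Pairing accepts fw/rev combinations whose expected product (coding
footprint distance, alignment columns × 3) lies in `product_range_bp`
and whose Tm envelopes lie within `max_temp_spread` of each other
(default 20 °C — generous because a degenerate mix's Wallace envelope is
itself 10–15 °C wide), ranked ascending by (max degeneracy, degeneracy
product), ties by candidate names. Alignment columns are treated as
codon-aligned to the coding sequence, exact for the gap-free alignments
the package designs on.

## Phylogenetics (`phylo`)

* Distance: p-distance with pairwise deletion of gap columns (a pair
  sharing no columns is an error); Poisson correction −ln(1−p) behind a
  flag. The distance model used by typical workbench tools is rarely
  stated, so the transparent default was preferred.
* Neighbor joining: textbook Q-criterion agglomeration,
  `Q_ij = (m−2)d_ij − r_i − r_j`, ties broken to the first (row, col)
  pair in current order so runs are deterministic; standard branch-length
  formulas with negatives clamped to 0 (deficit logged at debug level).
  On additive matrices the true topology and all path lengths are
  recovered exactly (verified to 1e-9 in the suite).
* Bootstrap: replicate *r* resamples columns with a fresh RNG seeded
  `seed + r` — reproducible and trivially parallelisable; support is the
  percentage of usable replicates containing each internal bipartition
  of the full-data tree. Replicates that leave some pair without
  comparable columns are skipped.
* Collapse: internal edges below the threshold (conventionally 50%) are
  contracted into polytomies; the contracted edge's length is discarded,
  the usual convention, so paths crossing it shorten by that amount.
  Only merges, never removes leaves; idempotent.
* Dotplot: all window pairs of `word_len` (default 10) with identity ≥
  `min_identity` (default 1.0) — deliberately simple and fully
  documented, since "standard parameters" of desktop dotplot tools vary
  by version.
* Nearest-reference assignment: global-alignment identity (identical
  aligned residues over the longer sequence length, Biopython pairwise
  aligner) against a labelled reference set, or a k-mer Jaccard score;
  ties go to the alphabetically first group with a flag.

## Synthetic data (`synth`)

`plant_template` embeds one concrete expansion of the forward primer and
the reverse complement of one expansion of the reverse primer into
uniform random DNA so the convergent product has an exact requested
length; requested mismatches are injected only at positions that *can*
mismatch (symbol covering < 4 bases), inside or outside the clamp on
demand. `make_panel` builds labelled panels: per-group positives with
product sizes around fixed per-group centres (T4 250, N4 300, T7 400,
FO1 450, SP6 550, GJ1 600, Vi1 700 bp, ±15 jitter — spaced ≥ 100 bp
within every multiplex layout), and negatives cycling through four
failure modes the virtual PCR must reject: no sites, a lone forward
site, a divergent (outward-pointing) site pair, and correct orientation
at sub-minimal spacing.

`make_group_msa` emits group-structured protein alignments: each group
descends from a group ancestor (global root mutated per column with
probability `between_divergence`, default 0.9); designated conserved
blocks (default two 10-residue blocks at positions 20 and 70 of a
120-residue protein) are invariant within a group; other columns keep
the ancestral residue with probability `1 − within_divergence` (default
0.5) or draw from a group-specific 4-residue pool. Matching coding DNA
uses each residue's *modal* codon inside blocks — emulating the strong
codon conservation of functionally constrained regions, and the reason
consensus-clamp primers can anneal with zero mismatches — and
usage-sampled codons elsewhere.

All generators are pure functions of seed and configuration
(byte-identical reruns), and every planted feature is returned in a
truth record.

What passing tests on this material do and do not show: backgrounds are
uniform random DNA without repeats, composition skew or sequencing
error, and group structure is cleanly block-shaped; perfect
sensitivity/specificity on these panels demonstrates the *logic* of the
two-tier caller and the design round trip, not performance on real
plaque lysates, where detection limits, template quality and
between-group sequence gradients matter.

## Problem sizes used by the suite

The test suite's end-to-end panel uses 7 groups × 20 positives plus 100
styled negatives (240 templates of 1.2 kb) across three assay layouts;
the neighbor-joining suite uses 100 random additive trees of 5–10 taxa
with per-step oracle checks up to 8 taxa; oracle-equivalence checks use
50 random instances per operation. These sizes give each property
abundant independent instances while keeping the default test run fast.

## Known limitations

* No thermodynamic annealing efficiency, polymerase kinetics, band
  intensity or detection-limit (PFU) modelling — matching is set
  membership plus mismatch counts.
* Minimal-IUPAC codon encoding inflates Ser/Leu/Arg cores (supersets).
* Codon-aligned design coordinates are exact only for gap-free blocks.
* The bundled codon-usage table is a literature-typical *E. coli* K-12
  approximation; swap in an organism-specific table for other hosts.
* Expected product sizes of the built-in panel on real genomes are
  template properties; the package never hard-codes them.
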