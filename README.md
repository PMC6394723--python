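# mcptyper

Degenerate-primer design, virtual multiplex PCR, and major-capsid-protein
(MCP) phylogenetics for rapid bacteriophage typing.

## The problem

Phage biocontrol needs strictly lytic (virulent) isolates, but environmental
screens return hundreds of plaques whose characterisation by genome
sequencing is slow and expensive. Seven well-studied groups of virulent
phages infecting enterobacteria — T4-, T7-, N4-, GJ1-, SP6-, FO1- and
Vi1-like phages — can instead be recognised early by their *major capsid
protein* gene, a conserved signature whose phylogeny tracks whole-genome
clusters. A panel of seven degenerate primer pairs targeting conserved MCP
motifs, run as two triplex PCRs plus a singleplex, assigns a plaque to a
group from the band pattern on a gel.

`mcptyper` implements the computational side of this assay for people
building or adapting such panels: the IUPAC-degenerate sequence algebra,
the built-in seven-group primer panel, a virtual PCR that predicts binding
sites, amplicons and group calls (including the "faint band of the wrong
size, rated negative" rule), CODEHOP-style design of new
consensus-clamp/degenerate-core primers from protein alignments,
neighbor-joining trees with bootstrap support for confirming assignments,
and a synthetic-panel generator for benchmarking all of it without any
downloads.

## Core concepts

* **Degeneracy score.** A degenerate primer over the 15-letter IUPAC
  alphabet denotes a mixture of concrete oligos; its score is
  `prod_i |base_set(s_i)|`, the mixture size. Panel scores range from 4
  (Vi1) to 64 (T7-fw); low scores are what the design optimises.
* **CODEHOP architecture.** Each primer is a non-degenerate 5′ consensus
  clamp (most frequent codon per consensus residue under a host codon-usage
  table, *E. coli* K-12 bundled) followed by a short degenerate 3′ core
  (minimal IUPAC back-translation of ~4 conserved residues). All the
  degeneracy lives in the core; in all 14 built-in primers the first 15 nt
  are non-degenerate.
* **Two-tier annealing model.** A site is a *call* only at stringent
  thresholds (0 mismatches, intact 3′ clamp). A relaxed scan (≤3 body
  mismatches, clamp intact) records nonspecific products as flags, never
  calls — mirroring how size-deviant faint gel bands are rated negative.
* **Multiplexing.** Pairs share a reaction when annealing temperatures are
  close and predicted products differ by at least a configurable band
  separation (default 100 bp); a 3′ cross-dimer screen is advisory.
* **Phylogenetics.** p-distance (pairwise gap deletion), textbook
  neighbor joining with deterministic tie-breaking, bootstrap supports as
  percentages, collapse of edges below 50%, and nearest-reference group
  assignment by global-alignment identity.

## Worked example

```python
from mcptyper import builtin_panel
from mcptyper.synth import PanelConfig, make_panel
from mcptyper.insilico_pcr import AssayDefinition, run_assay, typing_results_to_frame

panel = {p.group: p for p in builtin_panel()}
print(panel["GJ1"].fw.seq, panel["GJ1"].fw.degeneracy)
# GGCTGCGCGTATGATTAGGAYATHGAYGA 12

result = make_panel(PanelConfig(positives_per_group=1, negatives=3, seed=7))
triplex = AssayDefinition("T4/T7/SP6", (panel["T4"], panel["T7"], panel["SP6"]), 52.0)
rows = [run_assay(triplex, t) for t in result.templates]
print(typing_results_to_frame(rows).to_string(index=False))
```

```
        template_id calls amplicon_lengths flags
            T4_p000    T4              254     -
            T7_p000    T7              412     -
            N4_p000     -                -     -
           GJ1_p000     -                -     -
           SP6_p000   SP6              544     -
           FO1_p000     -                -     -
           Vi1_p000     -                -     -
    neg_no_site_000     -                -     -
neg_single_site_001     -                -     -
  neg_divergent_002     -                -     -
```

The GJ1-fw primer's 3′ core is the back-translation of the conserved
D-I-D-E motif (`GAY ATH GAY GA`, degeneracy 2·1·1·1·1·3·2·1·1·2·1 = 12).
In the typing table, the triplex calls exactly the three templates that
carry a planted T4, T7 or SP6 product (with its planted band size in bp)
and stays silent on the other groups' positives and on all negatives —
including the ones that carry a lone forward site or a divergent site
pair.

The same operations are available from the shell:

```bash
mcptyper simulate --positives-per-group 1 --negatives 3 --seed 7 \
    --fasta-out panel.fasta --truth-out truth.tsv
mcptyper assay panel.fasta
mcptyper panel-eval panel.fasta truth.tsv
mcptyper design alignment.fasta --product-range 100 400
mcptyper tree alignment.fasta --bootstrap 1000 --collapse-below 50
```

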