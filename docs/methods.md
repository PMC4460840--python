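# Methods

This note documents the models, counting rules and numerical choices behind
`mitofrag`, and what its synthetic-data validation does and does not show.

## Genome representation

A genome is a set of chromosomes; each chromosome is a DNA sequence with an
explicit topology flag plus ordered features drawn from the canonical
37-gene metazoan mitochondrial vocabulary (13 PCGs, 2 rRNAs, 22 tRNAs with
S1/S2/L1/L2 disambiguated by anticodon), the control region, and free-form
noncoding regions. Coordinates are 0-based half-open internally; GenBank
I/O converts to 1-based inclusive. A feature wrapping the origin of a
circular chromosome is stored as a single interval with `end < start`
(legal only with circular topology) and serialized as a GenBank `join`
location. Strands use the organellar J/N convention (majority- vs
minority-coding), mapped to `+`/`−` on disk. Incoming feature labels are
normalized through a shipped, user-extensible alias table; labels that
cannot be mapped are kept as noncoding with a logged warning rather than
dropped. A+T content is computed over unambiguous bases only, so ambiguity
codes affect neither numerator nor denominator.

## Divergence statistic

Homologs are aligned globally with affine gap costs (defaults: match +1,
mismatch −1, gap open −2, gap extension −0.5; end gaps are penalized
normally). Biopython's `PairwiseAligner` provides the optimum; among
co-optimal alignments the aligner's first traceback is used, which is
deterministic for fixed inputs. Because co-optimal alignments can trade a
substitution for an indel, the two sequences are passed to the aligner in a
canonical order, making the statistic exactly symmetric in its arguments.

Counting rules: each mismatch column is one difference; each maximal gap
run is one difference regardless of length; for tRNAs, leading and trailing
columns that belong to terminal gap runs (annotation-boundary overhangs)
are removed before counting. The denominator is the number of *effective
columns*, `C − G + I` (columns minus gap columns plus one per gap run), so
that replacing a k-column gap by a k′-column gap changes the percentage
only through the denominator, never through the difference count. The
percent difference is `100·(S+I)/(C−G+I)`.

Aggregates over homolog sets are computed in two modes: *pooled*
(length-weighted, `100·Σdiff/Σeffective`) and *mean* (unweighted average of
percentages); pooled is the default. On a synthetic pair evolved at the
published per-homolog divergences of the two *Scirtothrips dorsalis*
cryptic species, the pooled aggregate over all 38 homologs reproduces the
published whole-genome value to within ~0.1 point while the unweighted
mean sits three points lower — evidence that published whole-genome
aggregates of this kind are length-weighted.

No model-based distance correction (Jukes–Cantor etc.) is applied anywhere:
the statistic is a raw observable, which is what published comparisons of
this kind report.

## Gene-order and event model

Each circular chromosome is linearized into a signed gene order anchored at
`cox1` (rotated so the anchor is first and flipped so it reads `+`;
anchor-less chromosomes start at their lexicographically smallest gene).
Noncoding regions are not part of the gene order. Gene boundaries
(adjacencies) are compared *strand-blind*: a tRNA inverted in place keeps
both its boundaries. This is required for shared-block analysis across
genomes that differ by in-place inversions; orientation is consulted only
when calling inversions.

The event taxonomy is deliberately small: single-gene in-place inversions,
translocations of single genes or contiguous runs, chromosome fission
(fragmentation), and feature duplication. Classification proceeds by
preference: (1) fission is read off a difference in chromosome number, with
genes occurring more often in one genome reported as a duplication
sub-event; duplicated features are reduced to their "home" copy — the copy
on the chromosome with the most genes — before any adjacency comparison, so
a mini-circle's control-region copy cannot manufacture breakpoints; (2)
inversions are genes with both strand-blind neighbors conserved but sign
flipped; (3) remaining boundary differences are explained by the smallest
set of candidate runs whose removal from both orders equalizes the
adjacency sets, where a candidate run must be contiguous in *both* orders
(a translocated run is contiguous at source and destination); ties are
broken by fewest moved genes, then alphabetically. On toy orders this
minimal count matches exhaustive breadth-first search over single-gene
moves (tested); inputs outside the taxonomy yield a single unresolved
translocation event carrying the conflicting boundaries as evidence rather
than an error. Heavier rearrangement machinery (DCJ/HP distances,
tree-aware event polarity) is intentionally out of scope.

Shared blocks across ≥ 2 genomes are maximal runs, along the first order,
of boundaries present in every order's strand-blind adjacency set; adding
an order can only split blocks, never grow them.

## In-silico PCR

Annealing is sequence-only: a primer site is a position where the primer
matches one strand with at most `max_mismatch` mismatches and an exactly
matching 3′-terminal base. No melting-temperature, dimer or efficiency
model is included — the architecture test rests purely on presence/absence
topology, not kinetics. Circular templates are searched across the origin,
and products may traverse it; a pair of outward-facing primers inside a
mini-circle gene therefore yields the complementary arc, up to a
full-circle product. All convergent site pairings within the extension
limit (default 5 kb) are reported, since duplicated regions legitimately
multiply sites. The architecture hypothesis test predicts the band pattern
of a primer panel under a unipartite and a bipartite genome model and
returns the uniquely concordant model; band sizes are matched within ±10%
(gel precision). When both or neither model fits the verdict is
"ambiguous", the all-bands case being flagged as possible coexistence of
architectures within the template DNA.

The package does not design primers. For synthetic work, a four-pair
diagnostic panel (two junction-spanning pairs, one inward internal pair,
and its outward-facing reverse complement) is extracted directly from the
unipartite model's sequence at fixed offsets (primer length 22, junction
flank 200 bp); with 20+ nt primers on near-random sequence, off-target
sites are not a practical concern.

## NGS error audit

A contig is aligned to its reference with edlib (unit-cost global
alignment; a circular reference is first rotated to the contig's best
start, found by infix search against the doubled sequence). Each mismatch
column is one substitution record; each maximal gap run is one
insertion/deletion record. Indels are left-aligned against the reference
(the usual variant-normalization convention) because their placement inside
a homopolymer run is alignment-ambiguous; after normalization, records
from independent alignments of the same contig are directly comparable.
An alignment matching under 50% of reference positions raises an error
rather than producing a meaningless change list.

Classification rules: *terminal* — contig position within 80 nt of either
contig end (measured on the contig, since the artifact is contig-end
assembly quality); *homopolymer* — the change overlaps, or lies within one
base of, a reference run of ≥ 8 identical A or T residues (runs may wrap a
circular origin; the one-base margin exists because alignments may park an
indel at a run edge, and is configurable to 0). The flags are independent;
category counts report total/terminal/homopolymer/both/neither. The raw
error rate is all changes over the reference length; the filtered rate
keeps only changes matching neither rule. Filtered ≤ raw always, with
equality exactly when no change is flagged.

## Synthetic data generator

The generator emulates the study system: an AT-rich (~75–82%) circular
thrips mitogenome whose gene order follows the published *S. dorsalis*
order with the mini-circle genes at their inferred ancestral location, and
an NGS pipeline whose errors concentrate at contig ends and in A/T runs.

* **Base model.** Sequence is drawn from a first-order Markov chain: with
  probability 0.45 a base repeats its predecessor, otherwise it is drawn
  i.i.d. from the target composition (A=T, G=C). The chain's stationary
  distribution equals the i.i.d. composition, so the A+T target is
  preserved, while run lengths approach what real AT-rich organellar
  sequence shows; an i.i.d. draw would drastically under-produce the ≥8 nt
  homopolymers on which the audit's error model depends. Gene lengths
  default to thrips-typical values (e.g. `nad6` 500 bp, tRNAs 65 bp,
  control region 350 bp), so the canonical fission products form a
  mini-circle just under 1 kb — the scale of the sequenced 921 bp
  chromosome. The control region carries its diagnostic motifs (a
  T-stretch and an A+T-rich segment).
* **Divergence planting.** Per-homolog divergence is planted as an exact
  number of substituted sites, `round(d·L/100)`, at distinct positions;
  replacement bases are drawn from the sequence's own composition, so the
  process is stationary and a diverged genome keeps its A+T content. The
  realized value of the package's own divergence statistic is verified and
  sites are re-drawn (up to 100 times) if alignment effects push it outside
  tolerance (±1 point; ±0.5 for duplicated-feature paralogs). Indels are
  not planted by default; the indel-collapse rule is exercised by dedicated
  alignment fixtures instead.
* **Event planting.** Inversions reverse-complement a gene in place;
  translocations move a gene or run to a random legal position; fission
  moves genes onto a new circle and copies duplicated features onto it at a
  target paralog divergence (defaults follow the sequenced mini-circle:
  control region 1.65%, trnS1 0%). Planted events are required to be
  mutually non-interfering — no event gene adjacent to another's, and
  translocation insertion points away from both other events' genes and
  the moved run's original neighbors. The last constraint exists because
  an adjacent-pair swap is explainable by moving either gene, so exact
  recovery would be undefined; the recoverability guarantee is therefore
  *for identifiable event sets*, which is also the regime the real genomes
  occupy.
* **Contig simulation.** Per-position error probability is a base rate
  (default 0.0045) times a terminal multiplier (default 4) inside 80-nt
  end windows and a homopolymer multiplier (default 6) inside masked runs,
  stacking multiplicatively. Errors in homopolymer context are 70% indels
  (run-length miscounts, the flow-sequencer signature), 60% substitutions
  elsewhere. Under these defaults a ~1 kb mini-circle contig accrues ~15
  changes (a ~1.6% raw rate) distributed roughly half terminal, two-thirds
  homopolymer and one-fifth neither — the regime reported for real
  mini-circle data.

**What passing tests show, and what they do not.** Planted-truth recovery
demonstrates internal consistency: the event classifier, divergence
statistic and audit recover exactly what the generator planted, under the
generator's assumptions (i.i.d. substitutions, non-interfering events,
annotation-perfect gene boundaries). Real data violate these assumptions
in known ways — rate heterogeneity along genes, overlapping or ambiguous
annotations, assembly chimeras — so recovery rates here are an upper
bound, not a field-accuracy estimate. Likewise the 50% identity floor that
separates "homologous" from "non-homologous" noncoding regions is
meaningful for mixed-composition sequence but sits *below* the chance
alignment identity of two unrelated AT-rich sequences (~70% under this
scoring, the two-letter-alphabet baseline); for AT-rich genomes the floor
should be raised (the comparison report accepts it as configuration).

## Problem sizes and reproducibility

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; generation, comparison and reporting are
byte-deterministic given seeds. The validation suite runs genome-scale
fixtures (~15 kb, 38 homologs) for end-to-end checks, 100 random genome
pairs with up to 4 planted events for event-recovery statistics, 1000
seeded contig audits for the rate inequality, and exhaustive alignment
enumeration on sequences up to 8 nt, where brute force is feasible.
`scripts/acceptance.py` re-runs the full stack at these sizes from a
single seed in a few seconds.
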