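# Methods

## The neutral indel model

The estimator assumes that in neutral sequence, indel events hit a pairwise
alignment as a Poisson process with per-base rate *p*, so inter-gap segment
(IGS) lengths are geometric with mean *K* = 1/*p*. Consecutive gap columns
are collapsed into a single delimiter regardless of which row carries the
gap — a delimiter stands for one indel event, and adjacent or overlapping
events are not distinguishable in a pairwise alignment. Segments abutting a
block edge are length-censored and are excluded from fitting by default
(configurable in `build_histogram`).

**GC stratification.** Indel rates covary with base composition, so the
reference genome is cut into fixed windows (default 10 kb; N bases excluded
from the GC numerator and denominator, all-N windows get a sentinel bin and
are dropped). Windows are ranked by GC and partitioned so that each bin
receives an equal share of aligned bases; assignment is per whole window
(ties in the quantized window GC are broken by sequence name and window
index, deterministically), and each segment takes the bin of the window
containing its reference midpoint. Sequences matching
`chrZ|chrW|chrUn|random` are excluded by default: sex chromosomes and
unplaced scaffolds violate the autosomal-rate assumption.

**Fitting.** ln *O(l)* is regressed on *l* with weights equal to the counts
(the variance of a Poisson log-count is ≈ 1/count), over a window of
short lengths assumed free from constraint. The default window is
**[2, 120] bp**: length-1 segments are disproportionately alignment
artifacts and are excluded; the upper end stays an order of magnitude below
the scale of typical functional elements while giving the regression enough
leverage that the extrapolated tail (factors of (1−p)^l over hundreds of
bases) is numerically stable — with a much shorter window the slope error is
amplified exponentially at the tail lengths where the excess is measured.
Zero-count lengths inside the window are dropped from the regression but the
fitted line is still evaluated everywhere. A non-negative slope raises a
`FitError` and marks the bin unusable.

**Excess and bounds.** The threshold *l\** defaults to the smallest length
beyond the fit window with *O(l) > E(l)* whose geometric tail probability
under the fit is below 0.01. Beyond *l\**, the departure *O − E* is summed
**signed** (the expectation tail in closed form), so Poisson noise in the
neutral tail cancels instead of accumulating; the totals *S* and *B* are
clipped at zero afterwards. Summing per-length positive parts instead would
bias every bin upward by the half-normal mean of the tail noise and, at
moderate alignment sizes, could report spurious constraint on purely neutral
input. Bounds are `lower = B − 2K·S`, `upper = B − K·S`, clipped to
[0, B]; the 2K correction corresponds to independent neutral flanks of mean
K on both sides of a functional element, K to the fully clustered case.
Bins with fewer than 1,000 segments in the fit window are flagged low
confidence and excluded from the aggregate, which is the sum of per-bin
bounds over usable bins.

**Problem sizes.** The simulation studies in the tests and in
`scripts/acceptance.py` use 10 Mb alignments at θ = 0.005 indels per neutral
base per branch with 5 GC bins, which keeps roughly 20,000 segments in each
bin's fit window — about the smallest stratification at which the per-bin
tail extrapolation is stable. Genome-scale data support the conventional 20
bins (the `run_nim` default).

## The simulator

`simulate_alignment` evolves two descendants from a common ancestor drawn
with per-window target GC (default uniform 0.41, a typical avian value).
Constrained elements of fixed length are placed without overlap, uniformly
or biased toward GC-rich windows (`element_gc_weight`). Per branch, the
number of indel events is Poisson(θ · neutral bases); each event is an
insertion or deletion with equal probability, with geometric lengths of
mean 3 by default (the length law is a parameter — it is not asserted by the
model, and the estimator never uses it). Events whose footprint touches an
element are rejected and redrawn, making element bases exactly indel-free —
the estimator's idealization — rather than merely rate-suppressed.
Substitutions (default 0.02/base/branch) apply everywhere, including
elements; they are invisible to the indel analysis. Because both branches'
edits are bookkept against ancestral coordinates, the emitted alignment is
the true one; columns deleted on both branches are dropped (they carry no
alignment information), and a truth ledger records element intervals in
ancestral and reference coordinates, the planted constrained-base total and
realized event counts. Identical parameters give bit-identical output.

What the simulator does **not** emulate: realistic substitution processes
(no transition/transversion bias, no rate heterogeneity), alignment error
(the truth alignment is emitted, so there are no spurious gaps), indel rate
variation along the genome beyond GC binning, element length variation, and
selection acting on substitutions. Passing tests therefore demonstrate that
the estimator recovers planted constraint **when its model holds and the
alignment is correct**; on real alignments, aligner behaviour near indels
and rate heterogeneity are additional error sources the tests do not probe.

## Assembly QC

- Genome size = total sequenced bases / modal coverage, with "peak" read as
  the mode of the integer per-base coverage histogram over contigs.
- Euchromatic completeness = span / (span + outgroup-shared absent): under
  the assumption that sequence aligned between two relatives was present in
  the target's ancestor, its absence from the target assembly measures
  incompleteness (rare lineage-specific deletions inflate the estimate
  slightly).
- The splice audit checks the four GT-AG dinucleotide bases of each
  annotated reference intron in the aligned target; unaligned bases leave
  the denominator, non-canonical reference introns are skipped and counted.
  The resulting rate overestimates base-call error because true point
  mutations and mis-alignments also hit these positions.
- The three-way indel bound counts gap-run events private to the target row
  (target's gap state differing from outgroup and sister, constant pattern
  within the run) per kb of columns where the outgroup is ungapped; assuming
  no true target-lineage indels makes it an upper bound on indel error.
- Percentages are reported to the integer, rates to two significant figures.

## Filter cascade

Rules run in the order: external masks (SEG/GBLOCKS/GUIDANCE outputs are
consumed from files, never recomputed), gap removal, quality masking
(phred ≤ 30, inclusive), window substitution filter, flank removal, discard
decision. Choices where the rules' prose underdetermines behaviour:

- The 15-bp window slides one nucleotide at a time (the stricter reading;
  `window_mode="tiled"` is available). A window with **more than 5**
  substitutions removes all its positions; exactly 5 is kept. A codon is
  removed if any of its three nucleotides is removed.
- Substitutions are counted after gap/quality masking (positions of
  already-removed codons, gaps, and Ns never count), matching the cascade
  order; the standalone rule can be run on the raw alignment too.
- Flank removal is a single pass: codons within 7 of previously removed
  columns go, but flank-removals do not seed further flanks.
- Discard when surviving codons < 100 **or** < 10% of the gene's predicted
  codon count.

The mask keeps an ordered ledger of (rule, columns); replaying the ledger on
the raw alignment reproduces the filtered alignment byte for byte, and a
removed column is never resurrected.

## Site enrichment

The sampling unit is the filtered codon site, not the gene: the universe N
is all filtered sites of all tested genes, K the positively selected ones,
and for each GO term n/k are the same counts restricted to genes carrying
the term after propagation. The hypergeometric upper tail then asks whether
selected sites concentrate in the term's genes under site-uniform chance;
this weights pervasively selected genes more than a gene-level test, and is
exact only under site-level exchangeability (selected sites clustering
within genes make it anti-conservative — the permutation test in the suite
shuffles at site level accordingly). Only `is_a` links are traversed by
default (`part_of` optional). Bonferroni multiplies by the number of terms
actually tested (those with ≥ 1 annotated site) by default, since terms with
no annotated sites cannot reject and would inflate the correction; a flag
switches to counting all DAG terms.

## Numerical notes and limitations

- `np.polyfit` with weights √count implements the count-weighted regression;
  slopes ≥ −1e-12 are treated as non-decaying.
- Geometric tail sums use closed forms, so *l\** beyond the observed maximum
  length is handled exactly.
- The K/2K correction assumes one functional element per excess segment;
  clustered elements inside one segment push the truth toward the lower
  bound, fragmented ones toward the upper.
- Estimates at genome scale require the real alignments; nothing here
  substitutes for them. Fixture-scale numbers in the tests are properties of
  the synthetic study conditions stated above.
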