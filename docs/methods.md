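# Methods

## Truncation geometry

All coordinates are 0-based half-open internally; consensus coordinates are
reported 1-based so that the T-loop motif reads G53…A59. A unique cDNA with
transcript-orientation 5′ end at genomic position *g* annotates the
crosslink at *g* − 1 on the plus strand and *g* + 1 on the minus strand
(the minus-strand 5′ end is the rightmost aligned base). The rule is applied
purely genomically: a truncation immediately downstream of an intron
annotates the last intronic base, exactly as a coordinate-based pipeline on
real data would.

Three stall modes are simulated and inverted:

| mode | read 5′ end (transcript) | annotated site | methylated base |
|---|---|---|---|
| catalytic read-through | the methylated base | base − 1 | annotated + 1 |
| m1A stall | m1A + 1 | the m1A itself | annotated |
| UV stall | crosslink + 1 | the crosslink itself | annotated |

The catalytic +1 inference is therefore exact by construction, and the
distance between the inferred methylation (U54) and the annotated m1A
sub-peak (A58) is 4 consensus nt, while the two *annotated* peaks are 5 nt
apart (53 vs 58). Both distances are reported, because "N nucleotides
downstream of the major site" is ambiguous between the annotated and the
inferred reading; the geometry table makes the two readings explicit.

## Synthetic data generator

The simulator is first-class, tested code; it defines the study conditions
for every downstream check.

* **Genome**: one chromosome; genes separated by 100-nt random spacers.
  tRNA genes are random 71-mers with the T-loop region forced to GTTCGAA
  (second base at mature 54); strands are drawn at random; transcripts are
  guaranteed pairwise distinct. Non-tRNA control genes are 300-nt random
  sequences, the last one forced to the minus strand (the binding-only
  minus-strand control case).
* **Region table**: acceptor-stem-5′ (7), D-stem-5′ (4), D-loop (8),
  D-stem-3′ (4), linker (2), anticodon-stem-5′ (5), anticodon-loop (7),
  anticodon-stem-3′ (5), variable-loop (5), T-stem-5′ (5), T-loop (7),
  T-stem-3′ (5), acceptor-stem-3′ (7) — 71 nt of structured mature body
  with the T-loop at mature 53–59, which is what places U54 and A58 at
  their textbook coordinates. The discriminator base and CCA tail carry no
  structural signal here and are not modelled, so the default mature
  length is the table total (71 nt).
* **Introns**: optionally inserted after mature position 37 (the canonical
  anticodon-loop insertion point); mature→genomic mapping excises them, so
  positions 3′ of the intron shift by its length. Spliced reads get `N`
  CIGAR operations.
* **Modes**: per tRNA read, catalytic read-through / m1A stall / uniform
  background at 80/15/5 by default. The read-through fraction is exposed
  rather than fixed because the underlying biochemistry ("more often
  read-through") is qualitative; 80/15 makes the major/sub-peak count
  ratio ≈ 0.19, comfortably separated from background.
* **Libraries**: each unique cDNA gets a random 8-nt UMI and is emitted
  1 + Poisson(mean 1) times (PCR duplicates share UMI and position;
  sequencing errors are not simulated because deduplication keys on exact
  identity). An in-line barcode (default two samples, `ACGT`/`TGCA`,
  Hamming distance 4) plus the UMI are prepended per the layout string
  `N…NB…B`. Reads are 30 nt, clipped at the gene 3′ end.
* **Alignment**: synthetic reads are placed at their true loci; a read
  whose insert occurs at more than one annotated locus (either
  orientation) is emitted with `NH > 1` and MAPQ 0 so the unique-only
  filter downstream is exercised. This emulates an aligner's
  unique-mapping criterion on the toy genome; it does not model mismatch
  tolerance or soft-clipping.

What the simulator does **not** emulate: base-call errors and quality
profiles, ligation and RT sequence biases, fragment-length distributions,
expression heterogeneity across genes, multi-copy tRNA families with
near-identical (rather than identical or distinct) sequences, and
non-canonical (e.g. mitochondrial) tRNA structures. Passing tests
therefore demonstrate correctness of the coordinate logic, the statistics
and the bookkeeping — not robustness to alignment artefacts on real
genomes.

## Permutation FDR caller

Per (sample, gene region): the region's total unique-cDNA count *C* is
redistributed uniformly over the region's *L* positions as one multinomial
draw per permutation (the per-event null; 100 permutations by default).
For each observed count value *k*:
raw(*k*) = mean permuted #positions ≥ *k* / observed #positions ≥ *k*,
clipped to [0, 1]. Monotonization takes FDR(*k*) = max over *k′* ≥ *k* of
raw(*k′*) — conservative, never lowering a raw estimate — and sites with
FDR < α (default 0.05) are significant. The estimator is pinned against a
100 000-permutation brute-force oracle (agreement within ±0.02 at
n_perm = 100 averaged over 50 seeds) and calibrated on pure-null
simulations. Note that a perfectly uniform observed profile yields
FDR ≈ 1 − (1 − 1/L)^C ratios around 0.6, not exactly 1: the per-event null
is less uniform than the degenerate observation. Sites in overlapping
regions are assigned to the shorter region (ties: lexicographically first
id); the null is never pooled across regions.

## Peaks, counting, normalization

Significant sites within 15 nt (same strand) form clusters; maxima are
plateau-aware local maxima of the count vector, eligible at ≥ 0.15 × the
cluster maximum, greedily selected by decreasing count (ties leftmost)
with ≥ 2 nt separation; the global maximum is always reported. The 0.15
eligibility floor is set below the ≈ 0.19 sub/major ratio implied by the
default mode mix so the m1A sub-peak survives refinement. Replicate peaks
within 3 nt merge; the representative position carries the largest summed
count (ties leftmost). Cluster counts are unique cDNAs overlapping the
cluster interval on the same strand, per replicate. Size factors are
median-of-ratios to the per-cluster geometric-mean pseudo-reference over
all-positive clusters (linear-space median); total-count ratios are
selectable, and are the automatic fallback when no cluster has all-positive
counts. Because the geometric-mean reference itself absorbs a c^(1/m)
shift, scaling one sample by *c* moves its factor by *c* only *relative to
the other samples* — the identifiable, and tested, form of scale
equivariance. Pearson correlations are computed on log2(count + 1)
columns; zero-variance columns give missing values rather than a number.

## Consensus metagene

Per structural region, consensus length = round(mean over genes); a mature
offset *o* in a region of length *l* maps to consensus offset
floor(*o* · *l*<sub>cons</sub> / *l*) — deterministic and
order-preserving, an identity for genes sharing the canonical layout. The
consensus base is the max-frequency base, ties collapsing to IUPAC codes.
Projection adds each site's count at its consensus coordinate; intronic
sites and +1-shifted positions leaving the gene are dropped and counted,
so projection conserves mass over non-dropped sites.

## Motif recovery

Flanks of ±50 nt around peak positions are extracted strand-aware
(minus-strand windows reverse-complemented; chromosome-boundary windows
N-padded and flagged). The top k-mer (k = 7, matching the T-loop motif
width) maximizes observed occurrences over its mean count in 100
per-sequence dinucleotide-preserving shuffles (Altschul–Erickson Eulerian
construction; same-strand scanning only). The reported p-value is
calibrated for selection: each shuffle round is scored by its own maximal
enrichment ratio across all k-mers, and p = (1 + #rounds ≥ observed
maximum)/(1 + #rounds), which is approximately uniform on random input
and at the 1/(n+1) floor for planted motifs. Matches are then filtered to
the modal motif-start offset ±1 relative to the crosslink, kept only when
the motif span contains the crosslink, and summarized as a column-
normalized PWM.

## Problem sizes

Default test and example runs use 6–12 tRNA genes at 400–1000 reads per
gene per replicate; the acceptance computation uses 20 genes × 5000 reads
× 2 replicates — enough that the modal geometry (4-nt offset, consensus 54
and 58) is deterministic in practice while a full run completes in well
under a minute. The brute-force FDR oracle uses 10^5 permutations on a
50-nt toy region.

## Known limitations

* The unique-mapping emulation searches annotated transcripts only;
  intergenic placements are ignored (random spacers make collisions
  vanishingly unlikely at these sizes but this is not checked genome-wide).
* UMI collapsing is exact-match by design; at very high per-position depth
  (≫ 4^8 / reads) UMI collisions will merge distinct cDNAs.
* The negative-binomial differential test applied to the exported count
  matrix is intentionally out of scope; the matrix and size factors are
  the interface to external statistical tooling.
* Mitochondrial and other non-canonical tRNA structures (e.g. lacking a
  T-loop) are not representable in the fixed region table.
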