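# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, what the synthetic data
do and do not emulate, and the known limitations.

## Linkage maps and salmonization

Phase vectors code grandparental origin (0/1, −1 missing) for the
informative meioses of one parent. The recombination fraction between two
markers is phase-agnostic, `r = min(m, n−m)/n` over the n doubly
informative meioses, and map length is plainly additive
(`Σ adjacent 100·r`, no mapping function): the refinement only ever
*compares* lengths of candidate orders, for which any monotone map function
is equivalent. The female map is the objective; the male map is computed
for reporting only.

The refinement of one linkage group proceeds in stages:

1. **Reference ordering.** Markers are stable-sorted by their coordinate on
   the assigned reference chromosome; markers without a reference position
   are excluded and reported.
2. **Break detection.** Cumulative cM positions are recomputed along the
   reference order; a break is declared between adjacent markers when the
   absolute difference exceeds 10 cM *or* is at least 8 population SDs of
   all adjacent differences in the group. The candidate gap is included in
   the SD (the text behind this rule is ambiguous; including it is the
   conservative choice and is configurable). Breaks compare adjacent
   markers only (also configurable reading).
3. **Block search.** The k! block permutations are enumerated exhaustively
   (k ≤ 8; greedy best-insertion beyond), then each block is flipped and
   the flip kept on strict improvement, in passes to convergence.
   *Joint completion:* permuting with orientations fixed and flipping with
   order fixed can each stall when the two interact — an inverted block may
   prefer a different slot once flipped. Constructed instances show the
   purely sequential scheme ending above the global optimum, so for k ≤ 6
   the search is completed jointly over all k!·2^k (order × orientation)
   configurations; junction costs are precomputed from block endpoints, so
   each configuration costs k additions. Beyond k = 6 the two passes
   alternate to convergence. Ties go to the lexicographically smallest
   configuration.
4. **Validation.** The refined order must be no longer than the original,
   reference-ordered and permuted candidates; a violation returns the best
   candidate with a diagnostic rather than silently accepting the refined
   order.

Groups whose markers map to two reference chromosomes that interleave in
the final order with no separating break are flagged *fused* and left
unsplit. A group matching two reference homeologs equally well is refined
against both and assigned to the homeolog giving the shorter map; ties are
reported.

**Resolution limit.** A planted inversion of a very short block (two or
three markers spanning less than the 10 cM break threshold) produces no
detectable break and cannot be recovered; this accounts for the residual
2–4% failures in the recovery study below.

## RAD marker filters

All thresholds are read literally and bounds are inclusive where stated as
ranges: fragment length 182–186 bp, parental per-base coverage 9–300 in
both parents; offspring qualify at coverage strictly greater than 8 and are
retained with at least 1,000 qualifying markers. The segregation test is a
Pearson chi-square without continuity correction against 1:1 (test cross)
or 1:2:1 (intercross); FDR control is Benjamini–Hochberg over the full
marker set (global control is the conservative reading; per-group control
would reject fewer). Markers with more than 10% missing offspring calls
are flagged but kept. Marker-level rules commute: the retained set is the
intersection of per-rule keeps, so rule order is immaterial (checked by a
test that reorders the pipeline).

## Synteny building

Scaffold placement scores each candidate reference chromosome by
(total aligned bp, hit count), in that tie order. The anchor is the
match-length-weighted median of reference hit midpoints — robust to a
single stray hit, where the mean is not. Orientation is the sign of the
match-length-weighted strand vote. Linkage evidence overrides synteny when
the two disagree on chromosome, or when a scaffold's cM position deviates
from the per-chromosome cm→anchor linear fit by more than 10 cM (the same
constant as the salmonization break rule, for internal consistency).
Chromosomes are concatenated with exactly 100 N between adjacent scaffolds;
AGP 2.1 gap rows use type `scaffold`, linkage `yes`, evidence `align_genus`
(the closest vocabulary for synteny-inferred joins), and the AGP↔FASTA
round trip is bit-exact by construction and by test. Chimera detection
(an automated stand-in for what is normally manual curation) requires two
query-coordinate segments of ≥10 kb aligned to different reference
chromosomes, separated by a query gap; the split point is the gap midpoint.

Synteny blocks chain query-sorted hits that share strand and progress
collinearly on the reference (gaps ≤ 1 Mb); chaining runs twice, setting
aside sub-100 kb chains as putative noise before re-chaining, so one
spurious hit cannot split a block. An inversion candidate is a block whose
orientation opposes the bp-weighted majority of its chromosome; it is
pericentric iff its query interval contains the predicted centromere.

Homeolog naming assigns each duplicated-genome chromosome to its
best-scoring outgroup chromosome; the copies of outgroup chromosome N are
lettered by descending aligned bp. Two chromosomes whose outgroup
footprints barely overlap (<20%) are treated as fission products of one
ancestral copy: the pair occupies one rank and its second piece takes the
next letter after all intact copies — a split top-ranked copy therefore
yields NA and NC around an intact NB, reproducing the naming convention for
a post-duplication fission.

## Repeat landscapes

Classification accepts a nucleotide hit under the 80-80-80 rule (alignment
≥80 bp, identity ≥80%, covering ≥80% of the unknown-base-free query length,
all inclusive) and falls back to a protein hit at e-value strictly below
1e-10. Host-gene removal compares bit scores across the nucleotide and
protein searches — the only cross-comparable score in tabular output.
Abundance merges overlapping intervals per superfamily before summing, so
no base is double-counted.

Centromere prediction bins element starts in 100 kb windows, smooths with
lowess (span f = 0.2, tricube weights, 3 robustifying iterations — verified
numerically identical to the R reference implementation) and takes the
midpoint of the argmax bin. An empty or flat profile is undetermined;
tied maxima return the earliest bin with an ambiguity flag. Karyotype
classes follow the standard centromeric-index thresholds: M ≤ 1.7 <
SM ≤ 3.0 < T (configurable).

**Limitation of the smoother.** The robustifying iterations treat a
high-amplitude narrow peak as outliers: the apex is downweighted, carving a
saddle whose flanking maxima sit roughly half a peak-SD off centre (the
identical behaviour is reproduced by R's `lowess`). Accurate peak
localisation therefore requires enrichment that is broad relative to the
smoothing window and strong relative to Poisson counting noise — which is
also what real pericentromeric repeat domains look like. The recovery
study below uses conditions in that regime; on a long chromosome with a
narrow spike the predictor is systematically off by several bins, and this
is a property of the prescribed smoother, not of the implementation.

Abundance outliers fit OLS of log2(B+1) on log2(A+1) and flag
|residual| > 1.96 sample SDs (raw residuals, matching the stated rule;
studentized residuals would differ only at high leverage). Because the +1
offset bends an exactly proportional pair off the fitted line, a minimum
meaningful residual scale is applied: when the residual SD is below 0.01
log2 units the genomes are proportional to numerical precision and nothing
is flagged.

The map-length model is OLS of map length on chromosome size (Mb) and arm
ratio; the arm-ratio term is tested by a likelihood-ratio chi-square on
1 df against the size-only model. At n ≈ 48 the LRT statistic is exactly
n·log(1 + F/(n−3)) with F ~ F(1, n−3), so the exact null distribution of
its p-value is known and is used as the calibration oracle in tests (the
chi-square p deviates from uniform by up to ~0.018 at this n).

K-mer repetitiveness counts canonical (strand-folded) 31-mers — the
counting tool convention; non-canonical counting is available via a flag —
and reports the fraction of k-mer instances whose k-mer occurs at least
twice. K-mers containing unknown bases are skipped.

## Synthetic data

The simulators define the conditions everything is tested under. A
duplicated ancestral genome (copies A/B of each ancestral chromosome,
centromeres at 10% of length by default — an acrocentric-like ancestor) is
rearranged per lineage: inversions and fissions in the grayling-like
lineage, fusions in the salmon-like lineage. Genomes are segment lists
over ancestral coordinates (FASTA rendering available), which keeps runs at
desk scale; total sequence length is conserved through every event. All
randomness flows from one seed through named substreams.

The RAD family emulates the two-parent, 69 + 44 = 113-offspring design.
Crossovers are Poisson without interference (an interval of d Morgans flips
phase with probability (1 − e^(−2d))/2); the default female recombination
rate is 2.0 cM/Mb with a 1.75:1 female:male ratio, and per-call coverage is
negative binomial with mean 30 and dispersion 5 (documented defaults).
Planted violations (3% of markers per rule by default, plus four
low-coverage offspring where the study calls for them) carry truth labels.
Markers are labelled test-cross or intercross individually, since the true
per-marker design mix is not knowable.

Alignment-hit tables contain one run of hits per conserved ancestral
segment (200 kb pieces, 1 kb gaps, identity ~N(94, 2) clipped to [80, 100]),
with strand reflecting inversion state; spurious hits are drawn in three
kinds (too short, too diverged, passing-but-tiny) so both the identity/
match filters and the chaining stage are exercised.

Repeat landscapes plant a Gaussian pericentromeric Tc1-Mariner domain and
exponential subtelomeric RTE-X enrichment over a uniform background of
mixed superfamilies.

What the simulations do **not** emulate: sequence-level mutation and
sequencing error, read-level data, genotyping error beyond missingness,
crossover interference, segmental duplications, and tandem-repeat
structure inside annotations. Passing the recovery studies shows the
algorithms invert their own generative assumptions at realistic sizes; it
does not certify performance on real data whose noise violates them.

## Validation studies (problem sizes)

Chosen once as desk-scale versions of the study design and frozen:

* **Salmonization recovery** — 100 instances of 40 markers in 5 blocks
  with 1 inverted block, 100 offspring, no genotyping noise; the true order
  (up to whole-group reversal) is recovered in ≥95 runs, and every ≤6-block
  instance must match the exhaustive k!·2^k oracle.
* **Centromere recovery** — 100 chromosomes of 5 Mb (the compact end of
  real salmonid chromosomes) with a Gaussian pericentromeric domain of
  sd 875 kb, 12,000 pericentromeric + 800 background records (~2.6
  annotation records/kb, consistent with fragmented annotation of a
  superfamily covering ~10% of the genome) and centromeres uniform in
  [0.2, 0.8] of length; prediction within ±1 bin in ≥95 chromosomes.
  Karyotype classes are compared where both true and predicted arm ratios
  are ≥0.2 from a class threshold (on a 5 Mb chromosome an allowed ±1-bin
  centromere error moves the ratio by up to ~0.4 near high ratios, so a
  margin on one side alone cannot pin the class of the other).
* **Inversion recovery** — 50 two-lineage simulations (two 20 Mb ancestral
  chromosomes, two planted inversions of mixed pericentric/paracentric
  type): calls must match the rearrangement log in 100% of noise-free runs
  and ≥90% with 10% spurious hits.
* **Calibration** — intercross segregation test: 200 × 2,000 null markers
  at n = 113, rate compared both to the enumerated exact level (0.0489)
  at Monte-Carlo precision and to the nominal 5% at replicate resolution;
  LRT: 500 null fits at n = 48 against the exact F-derived p distribution;
  outlier rule: zero flags under exact proportionality and 100/100 planted
  detections.

All studies complete in well under a minute each on one CPU; the whole
suite runs in about half a minute.
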