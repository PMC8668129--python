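# Methods

## Coordinate model

All internal intervals are 0-based half-open (BED convention); VCF
positions (1-based) are converted at the I/O boundary.  The IGH locus is
modelled as chr14:105,862,198–107,043,718 (GRCh38), ordered
J-cluster < D-cluster < V-cluster in reference coordinates; the locus is
minus-strand, so a segment's "3' end" is its lowest reference coordinate.
The V region starts at the 3' end of IGHV6-1 (chr14:105,939,756), the
conventional breakpoint for the heterozygosity partition.

The somatic deletion implied by a J/V join is the interval
`[J.end, V.start)` — the excised DNA between the selected segments.  With
the published region boundaries this makes the minimal join
(IGHJ1/IGHV6-1) 74,298 bp ≈ 74.3 kb.  Anchor points (segment end to
segment start) are a package choice; they reproduce the minimal printed
deletion size exactly and correspond to the biology (the intervening DNA
is lost).

### Bundled annotation

The default gene-segment annotation (6 J, 27 D, 41 V segments) is
**synthetic**: three anchors are pinned to published coordinates (IGHJ1
ends at the D-region start; IGHV6-1 starts at the V-region start;
IGHV7-81 starts 945 kb telomeric of IGHJ1's end, making the maximal J–V
deletion 945.0 kb), and all other per-gene coordinates are plausible
inventions.  Two deliberate departures from the real locus:

* J segments are spaced 605 bp end-to-end (real spacing is ~230–600 bp)
  with 50 bp bodies.  At Normal(450, 50) fragment lengths this makes the
  probability that a junction-spanning fragment's outer mate touches a
  *neighbouring* retained J segment negligible (< 1e-4), so monoclonal
  simulations profile as exactly one (J, V) clone.  With realistic dense
  spacing, assignments would scatter across adjacent retained J segments
  — a contamination the real data does suffer, and one reason strictly
  monoclonal profiles are rare in real cohorts.
* IGHJ6 keeps a >200 bp margin above the locus start so junction-anchored
  read pairs exist for every J within the simulated span (the simulator
  emits no reads outside the locus).

Real analyses should pass their own BED6 annotation.

## Simulator

One sample is a pool of `n_clones` B-cell clones with fractions summing
to 1 (a pinned dominant fraction with the remainder uniform, or symmetric
Dirichlet(α)).  Each clone selects one J and one V segment uniformly; the
recombined haplotype (chosen at random) carries the deletion
`[J.end, V.start)`.  The other haplotype follows `second_allele_mode`:
`dj_only` (default) carries an independent D–J join confined to the D
region — both chromosomes of a B cell are D–J joined even when only one
completes V–DJ — while `full_vdj` carries an independent V–DJ join.
`n_clones = 0` yields a germline-only control sample with no deletions.

**Germline variation.**  SNP count ~ Poisson(density × locus length) with
density 1/1000 bp, positions uniform; population allele frequencies
~ Beta(0.8, 0.8) (u-shaped, most sites common enough to matter for AF/LD
comparisons; a float value fixes all frequencies for degenerate tests);
per-haplotype alleles are independent Bernoulli draws (Hardy–Weinberg).

**SHM.**  Somatic hypermutation is modelled as allele flips at rate
5e-3/bp within the recombined V segment body of each clone's expressed
haplotype.  SHM positions that are not germline SNP sites are added to
the cohort site list with population frequency 0 — mirroring that a real
cohort callset is itself called from the LCL reads, so somatic variants
surface in it.  Junction microdiversity (N/P nucleotides) and SHM outside
the V body are not modelled.

**Reads.**  Fragments are interval-level only (no bases, qualities or
errors).  Per clone × haplotype, the fragment count is Poisson with mean
`coverage × fraction × template_length / (4 × read_length)` — counts
scale with the post-deletion template, so retained sequence is covered at
the configured depth regardless of how much DNA a clone has excised.
Fragment lengths are Normal(450, 50) resampled into
[2 × read length, template length]; placement is uniform in template
coordinates and mapped back to the reference.  A mate straddling a
deletion junction is soft-clipped to the side carrying the majority of
its bases, as an aligner would place it; clipped mates span less than a
full read length, no emitted mate ever overlaps its template's deletion,
and a fragment whose mates flank the junction maps with
insert = fragment length + deletion size — the large-insert signature.

**Genotype-call emulation.**  Per site, covering mates contribute the
germline allele of their originating haplotype (flipped at SHM
positions).  Depth 0 → missing; minor-allele fraction ≥ 0.2 with depth
≥ 4 → heterozygous; otherwise homozygous for the majority allele (ties
below the depth floor fall to hom-ref).  Called genotypes are phased into
a release-like callset using the germline orientation where the germline
is het; novel somatic hets get the alternate allele on haplotype 0 — a
statistical phaser has no information at a somatic singleton either.

**Reproducibility.**  One root seed; the germline, each sample and the
SHM site bookkeeping use independent child streams
(`numpy.random.SeedSequence.spawn`), so runs are deterministic and
insensitive to per-sample evaluation order.  Identical configurations
produce byte-identical SAM/VCF/TSV outputs.

## Detection and profiling

A pair is V(D)J-supporting iff exactly one mate overlaps (≥1 bp) a J
segment body and the other a V segment body, both mates at or above
`min_mapq` (default 0), excluding duplicate and secondary records.
Multi-segment contacts resolve to the larger overlap, then the
alphabetically first name.  Clones are unique (J, V) pairs; the dominant
event is the max-support event, ties broken by larger implied deletion
(the more conservative masked region), then lexicographically.  Zero
assignments produce a distinct *undetermined* state, not a monoclonal
call.

### Expected support and its consequences

At 30× with 2×150 bp reads, the fragment-start density per haplotype is
`coverage/(4 × read length)` = 0.05/bp, and the geometry of a 50 bp J
body plus a 150 bp mate with majority-side clipping leaves a ~130 bp
window in which a junction-spanning fragment's proximal mate can overlap
the selected J.  The expected J/V support is therefore ~6–7 pairs per
sample under these conditions.  Two consequences, measured and accepted
rather than hidden:

* The dominant-fraction estimator (max support / total support) is noisy
  and upward-biased at this support level: recovered fractions for a
  pinned 0.7 dominant clone average ~0.8, and the Pearson correlation
  between true and recovered fractions over a 0.1–1.0 grid of 20
  single-sample simulations is typically 0.5–0.9, not higher.  Recovery
  is exact for monoclonal pools (a single (J, V) pair with probability
  ≈ 1 − e^(−6.5)).
* Quantities that count unique clones (mean clone number, dominant
  fraction means) are support-limited: a 10-clone pool rarely shows more
  than ~5 distinct (J, V) pairs at this depth.

## Statistical analyses

* **Het partition** — per sample, het fraction among non-missing biallelic
  SNP genotypes centromeric vs telomeric (inclusive) of the 3' end of the
  dominant recombined V segment, over the full locus span.  Group
  comparison: two-sided paired Wilcoxon signed-rank (zeros dropped; exact
  null for ≤25 tie-free non-zero differences, else normal approximation
  with continuity correction; all-zero differences return p = 1 with a
  warning).  Fold-differences are reported both as ratio-of-means
  (primary) and mean-of-ratios.  In fully monoclonal simulations the
  centromeric het fraction approaches zero (the only diploid centromeric
  DNA is the short region below the selected J), so fold values are far
  larger than in real cohorts, where partial clonality and caller
  behaviour soften the contrast; the direction, not the magnitude, is the
  reproducible claim.
* **SHM heterozygosity** — het counts with ≥1 bp overlap of segment
  bodies; Pearson correlation of dominant fraction against het count in
  the dominant recombined V across samples (undefined on constant
  vectors), and recombined-vs-other V segment means.
* **Allele frequency** — alt alleles / (2 × non-missing samples); strata
  compared after filtering to MAF > 0.05 computed on the union of both
  strata (symmetric ascertainment); sites where either stratum is all
  missing are dropped.
* **Haplotype LD** — r² over the 2n phased haplotypes with pairwise-
  complete missing handling; undefined (NaN) where a site is monomorphic
  among retained haplotypes.  The stratum scan computes all pairs within
  the window, retains a pair if r² ≥ min_r2 in *either* stratum (each
  stratum's own retention filter, unioned; the other stratum's value is
  used as computed), and excludes undefined pairs from the difference
  count, tallying them separately.
* **Null calibration** — AF discordance between clonality strata is
  compared against an envelope of random 38/38 splits of a germline-only
  cohort of the same size: with 38 samples per stratum, pure binomial
  sampling already puts ~50% of common sites over the 0.05 threshold, so
  only the *excess* over the null split is evidence of clonality-driven
  distortion.

## Problem sizes

Tests and the acceptance script run entirely on simulated data at the
default study conditions (full 1.18 Mb locus, 30×, 2×150 bp): 20
monoclonal single-sample simulations, a 20-sample 0.1–1.0 dominance grid,
a 60-sample mixed-clonality cohort, and 76-sample (38+38) strata cohorts
with a 76-sample germline null.  These sizes give stable directions and
means while keeping a full run around a minute on one CPU.

## Known limitations

* No base-level reads: no sequencing error, mapping ambiguity, GC bias or
  soft-clip junction sequence; insert-size background away from junctions
  is exactly zero, so large-insert *fractions* are ~10–20× smaller than
  in real data even though the enrichment direction is preserved.
* The large-insert fraction and D-region depth are *presence* signatures,
  not clonality-graded ones: under the pool model every B-cell chromosome
  carries a V(D)J or D–J junction, so the junction count per sample is
  nearly invariant to how reads distribute over clones.  Clonality grades
  the depth over the dominant clone's own deletion interval, and that is
  the quantity the monotonicity checks use.
* Clone fractions within real LCLs are unknown; the Dirichlet default is
  a modelling choice.  EBV integration, IGK/IGL loci, and non-B-cell
  contamination are out of scope.
* The annotation is synthetic; per-gene coordinates other than the three
  pinned anchors are not real hg38 coordinates.
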