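# igclone

Detection and quantification of V(D)J-recombination artifacts in
lymphoblastoid-cell-line (LCL) derived short-read WGS of the human
immunoglobulin heavy-chain locus (IGH, chr14:105,862,198–107,043,718 in
GRCh38).

## The problem

LCLs are EBV-immortalised B cells, and every B cell has somatically
rewritten its IGH locus: V(D)J recombination joins one IGHJ, one IGHD and
one IGHV gene segment and excises the DNA in between — up to hundreds of
kilobases per chromosome.  DNA sequenced from an LCL therefore carries
somatic deletions whose extent depends on the *clonality* of the line: a
polyclonal pool averages over many different deletions, while a
monoclonal line simply lacks one haplotype (or both) over large parts of
the locus.  Genotypes, allele frequencies and linkage disequilibrium (LD)
estimated from such data inside IGH are systematically distorted.

`igclone` provides, for cohorts of paired-end alignments restricted to
IGH:

* **Signature detection** — the fraction of read pairs with outer insert
  size > 900 bp (a fragment spanning a deletion maps with its insert
  inflated by the deletion length), interval read depth, and direct
  detection of *J/V discordant pairs*: one mate overlapping an IGHJ
  segment, the other an IGHV segment.
* **Clone profiling** — read pairs sharing a unique (J, V) assignment are
  grouped as one "clone"; a clone's support over the total V(D)J-
  supporting reads estimates its share of the cell pool.  Per sample this
  yields the clone count, the dominant clone, its pool fraction
  `f = max support / total support`, and the implied somatic deletion
  `[J.end, V.start)`.
* **Genotype impact** — per-sample heterozygosity partitioned at the 3'
  end of the dominant recombined V segment (centromeric het calls are
  lost with the deleted haplotype; two-sided paired Wilcoxon across
  samples), and somatic-hypermutation-driven false heterozygous calls
  inside recombined V segments.
* **Population impact** — samples binned into clonality strata
  ((0,25], (25,50], (50,75], (75,100] percent dominant-clone fraction);
  alternate-allele frequencies of common SNPs (MAF > 0.05) and haplotype
  LD `r² = D²/(p_A(1−p_A)p_B(1−p_B))` (1 Mb window, min r² 0.01) compared
  between the extreme strata, flagging sites with |ΔAF| > 0.05 and pairs
  with |Δr²| > 0.1.
* **A synthetic cohort simulator** — germline phased SNPs, B-cell clone
  pools with per-haplotype V–DJ / D–J deletions, SHM, paired-end
  fragments (2×150 bp, ~450 bp inserts, 30×) emitted as alignment
  records, and emulated genotype calls — with full ground truth, so every
  stage is testable without downloading any real data.

Inputs are standard formats (SAM/BAM, BED6 gene-segment annotation,
phased VCF 4.2); outputs are TSV/BED/VCF.  A bundled hg38-like gene
segment annotation (synthetic coordinates anchored to the published
region boundaries) supports simulation and testing; real analyses should
supply their own annotation BED.

## Worked example

```sh
igclone demo --seed 7 --n-samples 20 --out-dir igdemo
```

simulates a 20-sample LCL cohort (1–12 clones per sample, skewed
Dirichlet pool fractions, 30×), profiles every sample, and runs the
het-partition and AF/LD comparisons.  The report it prints includes:

```
== COHORT CLONALITY ==
mean_support     7.25
mean_n_clones    2.5
n_monoclonal     4.0
n_dominant_gt50  12.0
n_dominant_gt75  7.0
mean_deletion_kb 517.89...
min_deletion_kb  76.718
max_deletion_kb  946.815

== HET PARTITION STATS ==
wilcoxon_p              1.9073486328125e-06
fold_ratio_of_means     1.9105695908095854
clonality_het_pearson_r 0.3485150256642141
```

Reading this: each sample showed on average 7.25 J/V discordant read
pairs grouping into 2.5 clones; 4 samples were monoclonal (all V(D)J
reads on a single (J,V) pair), and in 12 of 20 the dominant clone carried
more than half of the V(D)J reads.  Dominant-clone deletions span 77–947
kb.  Telomeric het fractions exceed centromeric ones (paired Wilcoxon
p ≈ 2e-6, ratio of means ≈ 1.9), and the SHM-driven het count in the
recombined V segment correlates positively (r ≈ 0.35) with clonal
dominance.  Rerunning with the same seed reproduces the report byte for
byte.

The same stages are available separately (`igclone simulate`, `detect`,
`impact`, `popgen`, `report`) for real alignment/VCF inputs, and as
library functions (`igclone.vdj_detection.profile_sample`,
`igclone.genotype_impact.partition_het`, ...).

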