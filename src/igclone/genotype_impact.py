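"""Genotype-level distortions caused by V(D)J recombination.

In a sample whose sequencing library derives largely from a single B-cell
clone, the somatic deletion between the selected J and V segments removes
one (or both) haplotypes over much of the locus, so truly heterozygous
SNPs centromeric of the selected V segment tend to be called homozygous,
while somatic hypermutation (SHM) inside the recombined V segment creates
false heterozygous calls.  This module quantifies both effects:

* :func:`partition_het` — per-sample heterozygosity split at the 3' end
  (reference start, minus strand) of the dominant recombined V segment,
  telomeric side inclusive of the segment;
* :func:`paired_wilcoxon` — the paired two-sided Wilcoxon signed-rank test
  comparing the centromeric and telomeric fractions across samples;
* :func:`het_count_in_segment`, :func:`clonality_het_correlation`,
  :func:`recombined_vs_other_het` — SHM-driven heterozygosity inside
  recombined V segments and its association with clonal dominance.

It also houses :class:`PhasedCallset`, the multi-sample SNP genotype
container consumed by every downstream stage, with VCF 4.2 I/O via pysam.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .locus_model import GeneSegment, GenomicInterval

if TYPE_CHECKING:  # pragma: no cover
    from .vdj_detection import ClonalityProfile

MISSING = -1  # haplotype allele / genotype-code sentinel


@dataclass
class PhasedCallset:
    """Biallelic SNP genotypes for a cohort, as per-haplotype allele codes.

    ``haplotypes`` has shape (n_sites, n_samples, 2) with entries 0 (ref),
    1 (alt) or -1 (missing).  Positions are 1-based (VCF convention) and
    strictly increasing.  ``phased`` records whether haplotype order is
    meaningful; zygosity-only analyses work either way, haplotype-LD
    requires phased=True.
    """

    chrom: str
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    samples: list[str]
    haplotypes: np.ndarray
    phased: bool = True

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape != (len(self.positions), len(self.samples), 2):
            raise ValueError("haplotypes shape inconsistent with sites/samples")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in callset") from None

    def genotype_codes(self) -> np.ndarray:
        """(n_sites, n_samples) codes: 0 hom-ref, 1 het, 2 hom-alt, -1 missing."""
        h = self.haplotypes
        codes = h.sum(axis=2).astype(np.int8)
        codes[(h < 0).any(axis=2)] = MISSING
        return codes

    def site_mask(self, span: GenomicInterval) -> np.ndarray:
        """Boolean mask of sites inside a 0-based half-open interval."""
        if span.chrom != self.chrom:
            return np.zeros(self.n_sites, dtype=bool)
        pos0 = self.positions - 1
        return (pos0 >= span.start) & (pos0 < span.end)

    def subset_samples(self, samples: Sequence[str]) -> "PhasedCallset":
        idx = [self.sample_index(s) for s in samples]
        return PhasedCallset(
            self.chrom, self.positions, self.ref, self.alt,
            list(samples), self.haplotypes[:, idx, :], self.phased,
        )


# ---------------------------------------------------------------------------
# VCF I/O (pysam)

def write_vcf(callset: PhasedCallset, path: str | Path, contig_length: int | None = None) -> None:
    """Write the callset as an uncompressed VCF 4.2 with GT fields."""
    header = pysam.VariantHeader()
    if contig_length is None:
        contig_length = int(callset.positions.max()) + 1000 if callset.n_sites else 1000
    length = int(contig_length)
    header.contigs.add(callset.chrom, length=length)
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in callset.samples:
        header.add_sample(s)
    sep = "|" if callset.phased else "/"
    with open(path, "w") as fh:
        fh.write(str(header))
        for i in range(callset.n_sites):
            gts = []
            for j in range(callset.n_samples):
                a, b = callset.haplotypes[i, j]
                gts.append(
                    "./." if a < 0 or b < 0 else f"{a}{sep}{b}"
                )
            fh.write(
                f"{callset.chrom}\t{callset.positions[i]}\t.\t{callset.ref[i]}"
                f"\t{callset.alt[i]}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path: str | Path, region: GenomicInterval | None = None) -> PhasedCallset:
    """Read biallelic SNPs from a VCF into a :class:`PhasedCallset`.

    Multiallelic or non-SNP records are skipped (the analyses are defined
    over biallelic SNPs only).
    """
    positions, refs, alts, haps = [], [], [], []
    phased = True
    chrom = None
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                continue
            if region is not None and not (
                rec.chrom == region.chrom and region.contains(rec.pos - 1)
            ):
                continue
            if chrom is None:
                chrom = rec.chrom
            elif rec.chrom != chrom:
                raise ValueError("multi-chromosome VCFs are not supported")
            row = np.full((len(samples), 2), MISSING, dtype=np.int8)
            for j, s in enumerate(samples):
                sample = rec.samples[s]
                gt = sample["GT"]
                if gt is None or len(gt) != 2 or gt[0] is None or gt[1] is None:
                    continue
                row[j] = gt
                if not sample.phased:
                    phased = False
            positions.append(rec.pos)
            refs.append(rec.ref)
            alts.append(rec.alts[0])
            haps.append(row)
    hap_arr = (
        np.array(haps, dtype=np.int8)
        if haps
        else np.empty((0, len(samples), 2), dtype=np.int8)
    )
    return PhasedCallset(
        chrom or (region.chrom if region else "chr14"),
        np.array(positions, dtype=np.int64),
        np.array(refs, dtype=object),
        np.array(alts, dtype=object),
        samples,
        hap_arr,
        phased=phased,
    )


# ---------------------------------------------------------------------------
# Heterozygosity partition

@dataclass(frozen=True)
class SideCounts:
    n_het: int
    n_total: int

    @property
    def fraction(self) -> float:
        """Het fraction; NaN when the side has no genotyped sites."""
        return self.n_het / self.n_total if self.n_total else float("nan")


@dataclass(frozen=True)
class HetPartition:
    """Per-sample het fractions centromeric / telomeric of a breakpoint.

    The breakpoint (1-based) is the 3' end of the dominant recombined V
    segment; the telomeric side is inclusive of the breakpoint position.
    """

    sample_id: str
    breakpoint: int
    cen: SideCounts
    tel: SideCounts


def partition_het(
    callset: PhasedCallset,
    sample: str,
    breakpoint: int,
    span: GenomicInterval,
) -> HetPartition:
    """Split het fractions at a breakpoint over the analysed span.

    Sites with missing genotypes are excluded from both numerator and
    denominator; every non-missing site in the span is counted on exactly
    one side.
    """
    if not span.contains(breakpoint - 1):
        raise ValueError(f"breakpoint {breakpoint} outside span {span}")
    j = callset.sample_index(sample)
    mask = callset.site_mask(span)
    codes = callset.genotype_codes()[mask, j]
    pos = callset.positions[mask]
    called = codes != MISSING
    cen_side = pos < breakpoint
    sides = {}
    for label, side in (("cen", cen_side), ("tel", ~cen_side)):
        sel = called & side
        sides[label] = SideCounts(int((codes[sel] == 1).sum()), int(sel.sum()))
    return HetPartition(sample, breakpoint, sides["cen"], sides["tel"])


def paired_wilcoxon(cen_fracs: Sequence[float], tel_fracs: Sequence[float]) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value for cen vs tel fractions.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 non-zero differences without ties, otherwise the normal
    approximation with continuity correction.  All-zero differences give
    p = 1.0 with a warning.
    """
    cen = np.asarray(cen_fracs, dtype=float)
    tel = np.asarray(tel_fracs, dtype=float)
    if cen.shape != tel.shape or cen.size < 2:
        raise ValueError("need paired vectors of equal length >= 2")
    diffs = tel - cen
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; p = 1.0", stacklevel=2)
        return 1.0
    ranks_tied = len(np.unique(np.abs(nonzero))) < nonzero.size
    method = "exact" if (nonzero.size <= 25 and not ranks_tied) else "approx"
    res = stats.wilcoxon(
        tel, cen, zero_method="wilcox", alternative="two-sided",
        correction=(method == "approx"), method=method,
    )
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# SHM-driven heterozygosity in recombined V segments

def het_count_in_segment(
    callset: PhasedCallset, sample: str, segment: GeneSegment
) -> int:
    """Number of het-called SNPs overlapping a gene segment's interval."""
    j = callset.sample_index(sample)
    mask = callset.site_mask(segment.interval)
    codes = callset.genotype_codes()[mask, j]
    return int((codes == 1).sum())


def clonality_het_correlation(
    profiles: Sequence["ClonalityProfile"],
    callset: PhasedCallset,
) -> tuple[float, float]:
    """Pearson correlation of dominant-clone fraction vs het SNPs in the
    dominant recombined V segment across samples.

    Returns (nan, nan) when fewer than 3 usable samples remain or a vector
    is constant (correlation undefined).
    """
    from .vdj_detection import ClonalityProfile  # noqa: F401  (type only)

    fracs, counts = [], []
    for prof in profiles:
        if prof.dominant_event is None or prof.dominant_v_segment is None:
            continue
        if prof.sample_id not in callset.samples:
            continue
        fracs.append(prof.dominant_fraction)
        counts.append(het_count_in_segment(callset, prof.sample_id, prof.dominant_v_segment))
    if len(fracs) < 3 or len(set(fracs)) == 1 or len(set(counts)) == 1:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(fracs, counts)
    return float(r), float(p)


def recombined_vs_other_het(
    profiles: Sequence["ClonalityProfile"],
    callset: PhasedCallset,
    segments: Sequence[GeneSegment],
) -> pd.DataFrame:
    """Het counts inside each sample's dominant recombined V segment versus
    the mean het count over all other V segments.

    Returns a per-sample DataFrame (sample_id, recombined_het,
    other_mean_het); cohort means are its column means.
    """
    v_segments = [s for s in segments if s.family == "V"]
    rows = []
    for prof in profiles:
        if prof.dominant_event is None or prof.dominant_v_segment is None:
            continue
        if prof.sample_id not in callset.samples:
            continue
        dom = prof.dominant_v_segment
        rec_het = het_count_in_segment(callset, prof.sample_id, dom)
        others = [
            het_count_in_segment(callset, prof.sample_id, seg)
            for seg in v_segments
            if seg.name != dom.name
        ]
        rows.append(
            (prof.sample_id, rec_het, float(np.mean(others)) if others else float("nan"))
        )
    return pd.DataFrame(rows, columns=["sample_id", "recombined_het", "other_mean_het"])
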