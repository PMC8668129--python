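"""Clonality-stratified allele frequencies and haplotype LD.

Samples are binned by the percentage of V(D)J-supporting reads carried by
their dominant clone — (0,25], (25,50], (50,75], (75,100] — and
population-level statistics are contrasted between the low- and
high-clonality extremes:

* allele frequencies of common SNPs (MAF > 0.05), flagging sites whose
  between-stratum difference exceeds 0.05;
* haplotype LD, r² = D² / (p_A(1-p_A) p_B(1-p_B)) with D = p_AB − p_A p_B
  over the 2n phased haplotypes, for all site pairs within a 1 Mb window
  retaining pairs with r² ≥ 0.01, flagging pairs whose between-stratum
  |Δr²| exceeds 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_impact import MISSING, PhasedCallset
from .vdj_detection import ClonalityProfile

STRATUM_LABELS = ("(0,25]", "(25,50]", "(50,75]", "(75,100]")
_EDGES = np.array([25.0, 50.0, 75.0])


def assign_strata(
    profiles: Sequence[ClonalityProfile],
) -> tuple[dict[str, list[str]], int]:
    """Bin samples by dominant-clone percentage into the four strata.

    Binning is left-open right-closed (25% falls in (0,25]); monoclonal
    samples (100%) land in (75,100].  Undetermined profiles are excluded;
    their count is returned alongside.
    """
    strata: dict[str, list[str]] = {label: [] for label in STRATUM_LABELS}
    n_excluded = 0
    for prof in profiles:
        if prof.undetermined:
            n_excluded += 1
            continue
        pct = prof.dominant_fraction * 100.0
        idx = int(np.digitize(pct, _EDGES, right=True))
        strata[STRATUM_LABELS[idx]].append(prof.sample_id)
    return strata, n_excluded


def strata_frame(strata: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    rows = [(s, label) for label, samples in strata.items() for s in samples]
    return pd.DataFrame(rows, columns=["sample_id", "stratum"])


# ---------------------------------------------------------------------------
# Allele frequency

def allele_frequencies(callset: PhasedCallset, samples: Sequence[str]) -> np.ndarray:
    """Per-site alternate-allele frequency over the given samples.

    Frequency = alt alleles / (2 x non-missing samples); NaN where every
    genotype is missing.
    """
    idx = [callset.sample_index(s) for s in samples]
    codes = callset.genotype_codes()[:, idx].astype(float)
    valid = codes != MISSING
    n_valid = valid.sum(axis=1)
    alt = np.where(valid, codes, 0.0).sum(axis=1)
    return np.divide(alt, 2 * n_valid, out=np.full(callset.n_sites, np.nan), where=n_valid > 0)


def allele_frequency(callset: PhasedCallset, samples: Sequence[str], site_index: int) -> float:
    """Alternate-allele frequency at one site; NaN when all missing."""
    return float(allele_frequencies(callset, samples)[site_index])


@dataclass
class AFCompareResult:
    records: pd.DataFrame  # pos, af_low, af_high, abs_diff
    n_exceeding: int
    exceeding_positions: np.ndarray


def af_compare(
    callset: PhasedCallset,
    stratum_low: Sequence[str],
    stratum_high: Sequence[str],
    maf_min: float = 0.05,
    diff_threshold: float = 0.05,
) -> AFCompareResult:
    """Compare common-SNP allele frequencies between two strata.

    The MAF filter (> ``maf_min``) is computed on the union of both
    strata's samples, keeping site ascertainment symmetric.  Sites where
    either stratum has no data are dropped.
    """
    if not stratum_low or not stratum_high:
        raise ValueError("both strata must be non-empty")
    union = list(dict.fromkeys([*stratum_low, *stratum_high]))
    af_union = allele_frequencies(callset, union)
    maf = np.minimum(af_union, 1 - af_union)
    keep = maf > maf_min
    af_low = allele_frequencies(callset, stratum_low)
    af_high = allele_frequencies(callset, stratum_high)
    keep &= ~np.isnan(af_low) & ~np.isnan(af_high)
    records = pd.DataFrame(
        {
            "pos": callset.positions[keep],
            "af_low": af_low[keep],
            "af_high": af_high[keep],
        }
    )
    records["abs_diff"] = (records["af_low"] - records["af_high"]).abs()
    exceeding = records.loc[records["abs_diff"] > diff_threshold, "pos"].to_numpy()
    return AFCompareResult(records, int(len(exceeding)), exceeding)


# ---------------------------------------------------------------------------
# Haplotype LD

def _haplotype_matrix(callset: PhasedCallset, samples: Sequence[str]) -> np.ndarray:
    if not callset.phased:
        raise ValueError("haplotype LD requires phased genotypes")
    idx = [callset.sample_index(s) for s in samples]
    h = callset.haplotypes[:, idx, :]
    return h.reshape(callset.n_sites, 2 * len(idx))


def hap_r2(
    callset: PhasedCallset,
    samples: Sequence[str],
    site_a: int,
    site_b: int,
) -> float:
    """Haplotype LD r² between two sites over the samples' 2n haplotypes.

    Haplotypes missing at either site are dropped pairwise.  NaN when a
    site is monomorphic among the retained haplotypes (r² undefined).
    """
    h = _haplotype_matrix(callset, samples)
    a, b = h[site_a].astype(float), h[site_b].astype(float)
    valid = (a != MISSING) & (b != MISSING)
    a, b = a[valid], b[valid]
    if a.size == 0:
        return float("nan")
    p_a, p_b = a.mean(), b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return float("nan")
    p_ab = (a * b).mean()
    d = p_ab - p_a * p_b
    return float(d * d / (p_a * (1 - p_a) * p_b * (1 - p_b)))


def _r2_matrix(h: np.ndarray) -> np.ndarray:
    """All-pairs r² for a (sites x haplotypes) 0/1 matrix with -1 missing.

    Pairwise-complete: per pair, haplotypes missing at either site are
    excluded.  Entries are NaN where a site is monomorphic among the
    retained haplotypes.
    """
    valid = (h != MISSING).astype(float)
    x = np.where(h == 1, 1.0, 0.0) * valid
    n = valid @ valid.T
    s_ab = x @ x.T
    s_a = x @ valid.T  # alt count at row site over pair-valid haplotypes
    with np.errstate(divide="ignore", invalid="ignore"):
        p_a = s_a / n
        p_b = p_a.T
        p_ab = s_ab / n
        d = p_ab - p_a * p_b
        denom = p_a * (1 - p_a) * p_b * (1 - p_b)
        r2 = d * d / denom
    r2[~np.isfinite(r2)] = np.nan
    return r2


@dataclass
class LDCompareResult:
    pairs: pd.DataFrame  # pos_a, pos_b, r2_low, r2_high, abs_diff
    n_exceeding: int
    n_undefined: int
    histogram: pd.DataFrame  # bin_low, bin_high, count


def ld_scan_and_compare(
    callset: PhasedCallset,
    stratum_low: Sequence[str],
    stratum_high: Sequence[str],
    window: int = 1_000_000,
    min_r2: float = 0.01,
    diff_threshold: float = 0.1,
) -> LDCompareResult:
    """Compute r² for all site pairs within ``window`` bp in each stratum
    and compare.

    A pair enters the comparison if its r² reaches ``min_r2`` in either
    stratum (the per-stratum retention filter, unioned); its value in the
    other stratum is used as computed, however small.  Pairs with r²
    undefined (monomorphic) in either stratum are excluded from the
    difference count and tallied in ``n_undefined``.  ``histogram`` bins
    |Δr²| at width 0.1 for the discordance profile.
    """
    h_low = _haplotype_matrix(callset, stratum_low)
    h_high = _haplotype_matrix(callset, stratum_high)
    pos = callset.positions
    n = callset.n_sites
    r2_low = _r2_matrix(h_low)
    r2_high = _r2_matrix(h_high)
    ia, ib = np.triu_indices(n, k=1)
    in_window = (pos[ib] - pos[ia]) <= window
    ia, ib = ia[in_window], ib[in_window]
    lo, hi = r2_low[ia, ib], r2_high[ia, ib]
    defined = ~np.isnan(lo) & ~np.isnan(hi)
    retained_low = ~np.isnan(lo) & (lo >= min_r2)
    retained_high = ~np.isnan(hi) & (hi >= min_r2)
    keep = (retained_low | retained_high) & defined
    n_undefined = int(((retained_low | retained_high) & ~defined).sum())
    pairs = pd.DataFrame(
        {
            "pos_a": pos[ia[keep]],
            "pos_b": pos[ib[keep]],
            "r2_low": lo[keep],
            "r2_high": hi[keep],
        }
    )
    pairs["abs_diff"] = (pairs["r2_low"] - pairs["r2_high"]).abs()
    n_exceeding = int((pairs["abs_diff"] > diff_threshold).sum())
    edges = np.arange(0.0, 1.1, 0.1)
    counts, _ = np.histogram(pairs["abs_diff"], bins=edges)
    histogram = pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )
    return LDCompareResult(pairs, n_exceeding, n_undefined, histogram)


def match_n(
    strata: Mapping[str, Sequence[str]], label_a: str, label_b: str, seed: int
) -> tuple[list[str], list[str]]:
    """Subsample the larger of two strata to the smaller's size (seeded)."""
    rng = np.random.default_rng(seed)
    a, b = list(strata[label_a]), list(strata[label_b])
    k = min(len(a), len(b))
    if len(a) > k:
        a = sorted(rng.choice(a, size=k, replace=False).tolist())
    if len(b) > k:
        b = sorted(rng.choice(b, size=k, replace=False).tolist())
    return a, b
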