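"""V(D)J-recombination signature detectors and clone profiling.

Three independent read-level signatures betray V(D)J recombination in
paired-end WGS of the IGH locus:

1. insert-size enrichment — a fragment spanning the somatic deletion maps
   with an outer insert inflated by the deletion size, so the fraction of
   pairs with insert > 900 bp (twice a typical Illumina library insert)
   rises (:func:`fraction_large_inserts`);
2. depth deficit — the D region is excised on both chromosomes of every
   recombined B cell, so coverage there collapses (:func:`mean_depth`);
3. direct J/V discordant pairs — a pair with one mate overlapping an IGHJ
   segment and the other an IGHV segment pins down the exact join
   (:func:`detect_vdj_pairs`).

Reads sharing a (J, V) assignment are grouped as one "clone"; the clone's
read support over the total V(D)J-supporting reads estimates its share of
the cell pool (:func:`profile_clonality`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .locus_model import (
    DeletionRecord,
    GeneSegment,
    GenomicInterval,
    LocusDefinition,
    deletion_interval,
)
from .reads import PairsLike, pairs_to_frame, primary_pairs

#: Insert-size threshold marking a pair as deletion-spanning: twice the
#: typical library DNA insert size.
LARGE_INSERT_BP = 900


@dataclass(frozen=True)
class VDJEvent:
    """One inferred clone: a unique (J, V) segment pair and its read support."""

    j_name: str
    v_name: str
    support: int

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("event support must be >= 1")


@dataclass(frozen=True)
class DepthSummary:
    interval: GenomicInterval
    mean_depth: float


@dataclass(frozen=True)
class ClonalityProfile:
    """Per-sample clone inventory derived from J/V discordant pairs.

    ``undetermined`` (no V(D)J-supporting pairs at all) is distinct from
    monoclonal; every real high-coverage sample yields at least some
    events, but low-coverage simulations can yield none.
    """

    sample_id: str
    events: tuple[VDJEvent, ...]
    dominant_event: VDJEvent | None
    deletion: GenomicInterval | None
    deletion_size: int | None
    dominant_v_segment: GeneSegment | None = None

    @property
    def undetermined(self) -> bool:
        return not self.events

    @property
    def n_clones(self) -> int:
        return len(self.events)

    @property
    def total_support(self) -> int:
        return sum(e.support for e in self.events)

    @property
    def dominant_fraction(self) -> float:
        if self.dominant_event is None:
            return float("nan")
        return self.dominant_event.support / self.total_support

    @property
    def monoclonal(self) -> bool:
        return self.n_clones == 1


class NoData:
    """Sentinel distinguishing 'no eligible reads' from a zero fraction."""

    def __repr__(self) -> str:  # pragma: no cover
        return "NoData"


NO_DATA = NoData()


def fraction_large_inserts(
    pairs: PairsLike,
    region: GenomicInterval,
    threshold: int = LARGE_INSERT_BP,
) -> float | NoData:
    """Fraction of eligible pairs with outer insert size > threshold.

    Eligible pairs are primary, non-duplicate records whose leftmost mate
    starts within ``region``.  Returns :data:`NO_DATA` (never 0.0) when no
    pair is eligible.
    """
    frame = primary_pairs(pairs_to_frame(pairs))
    sel = frame[
        (frame["chrom"] == region.chrom)
        & (frame["start1"] >= region.start)
        & (frame["start1"] < region.end)
    ]
    if len(sel) == 0:
        return NO_DATA
    return float((sel["insert_size"] > threshold).mean())


def mean_depth(pairs: PairsLike, interval: GenomicInterval) -> DepthSummary:
    """Mean per-base read depth over an interval, each mate counted."""
    if len(interval) == 0:
        raise ValueError("mean_depth over an empty interval is undefined")
    frame = primary_pairs(pairs_to_frame(pairs))
    frame = frame[frame["chrom"] == interval.chrom]
    total = 0
    for s_col, e_col in (("start1", "end1"), ("start2", "end2")):
        starts = np.maximum(frame[s_col].to_numpy(), interval.start)
        ends = np.minimum(frame[e_col].to_numpy(), interval.end)
        total += int(np.clip(ends - starts, 0, None).sum())
    return DepthSummary(interval, total / len(interval))


def _best_overlap(
    starts: np.ndarray,
    ends: np.ndarray,
    seg_starts: np.ndarray,
    seg_ends: np.ndarray,
    order: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Best-overlap segment per interval within one family.

    Segments are disjoint and sorted by start; a read (shorter than the
    inter-segment spacing) can touch at most the two segments flanking its
    start, so only those candidates are scored.  Ties in overlap go to the
    alphabetically first name (via ``order``, the rank of each segment name).

    Returns (overlap_bp, segment_index) with index -1 where no overlap.
    """
    n = len(starts)
    best_ov = np.zeros(n, dtype=np.int64)
    best_idx = np.full(n, -1, dtype=np.int64)
    cand0 = np.searchsorted(seg_starts, starts, side="right") - 1
    for cand in (cand0, cand0 + 1):
        valid = (cand >= 0) & (cand < len(seg_starts))
        ov = np.zeros(n, dtype=np.int64)
        idx = np.where(valid, cand, 0)
        ov[valid] = np.clip(
            np.minimum(ends[valid], seg_ends[idx[valid]])
            - np.maximum(starts[valid], seg_starts[idx[valid]]),
            0,
            None,
        )
        better = (ov > best_ov) | (
            (ov > 0)
            & (ov == best_ov)
            & valid
            & (order[idx] < np.where(best_idx >= 0, order[best_idx], np.iinfo(np.int64).max))
        )
        best_ov = np.where(better, ov, best_ov)
        best_idx = np.where(better, idx, best_idx)
    return best_ov, best_idx


def detect_vdj_pairs(
    pairs: PairsLike,
    locus: LocusDefinition,
    min_mapq: int = 0,
) -> list[tuple[str, str]]:
    """Assign read pairs to (J, V) gene-segment joins.

    A pair is assigned iff exactly one mate overlaps (>= 1 bp) a J segment
    and the other overlaps a V segment, with both mates at or above
    ``min_mapq``; secondary and duplicate records are excluded.  A mate
    touching two segments of a family is resolved to the larger overlap
    (alphabetical name on ties).
    """
    frame = primary_pairs(pairs_to_frame(pairs))
    frame = frame[
        (frame["chrom"] == locus.chrom)
        & (frame["mapq1"] >= min_mapq)
        & (frame["mapq2"] >= min_mapq)
    ]
    if len(frame) == 0:
        return []
    out: list[tuple[str, str]] = []
    fams = {}
    for family in ("J", "V"):
        segs = locus.family(family)
        if not segs:
            return []
        names = np.array([s.name for s in segs], dtype=object)
        fams[family] = (
            np.array([s.interval.start for s in segs]),
            np.array([s.interval.end for s in segs]),
            names,
            np.argsort(np.argsort(names)),
        )
    mates = {}
    for m, (s_col, e_col) in (("m1", ("start1", "end1")), ("m2", ("start2", "end2"))):
        starts = frame[s_col].to_numpy()
        ends = frame[e_col].to_numpy()
        for family in ("J", "V"):
            seg_starts, seg_ends, names, order = fams[family]
            ov, idx = _best_overlap(starts, ends, seg_starts, seg_ends, order)
            mates[(m, family)] = (ov > 0, idx)
    j1, jidx1 = mates[("m1", "J")]
    v1, vidx1 = mates[("m1", "V")]
    j2, jidx2 = mates[("m2", "J")]
    v2, vidx2 = mates[("m2", "V")]
    case_a = j1 & v2 & ~(v1 | j2)  # mate1 in J, mate2 in V
    case_b = v1 & j2 & ~(j1 | v2)  # mate1 in V, mate2 in J
    j_names = fams["J"][2]
    v_names = fams["V"][2]
    for sel, jidx, vidx in ((case_a, jidx1, vidx2), (case_b, jidx2, vidx1)):
        for ji, vi in zip(jidx[sel], vidx[sel]):
            out.append((str(j_names[ji]), str(v_names[vi])))
    return out


def profile_clonality(
    assignments: Iterable[tuple[str, str]],
    locus: LocusDefinition,
    sample_id: str = "sample",
) -> ClonalityProfile:
    """Group (J, V) assignments into clones and profile the sample.

    The dominant event is the one with maximal support; ties are broken by
    larger implied deletion, then lexicographic (J, V) — deterministic and
    conservative (the larger masked region wins).  Zero assignments yield
    an undetermined profile.
    """
    counts: dict[tuple[str, str], int] = {}
    for key in assignments:
        counts[key] = counts.get(key, 0) + 1
    if not counts:
        return ClonalityProfile(sample_id, (), None, None, None, None)

    def del_size(key: tuple[str, str]) -> int:
        _, size = deletion_interval(locus.segment(key[0]), locus.segment(key[1]))
        return size

    events = tuple(
        VDJEvent(j, v, n)
        for (j, v), n in sorted(
            counts.items(), key=lambda kv: (-kv[1], -del_size(kv[0]), kv[0])
        )
    )
    dominant = events[0]
    iv, size = deletion_interval(
        locus.segment(dominant.j_name), locus.segment(dominant.v_name)
    )
    return ClonalityProfile(
        sample_id, events, dominant, iv, size, locus.segment(dominant.v_name)
    )


def profile_sample(
    pairs: PairsLike,
    locus: LocusDefinition,
    sample_id: str = "sample",
    min_mapq: int = 0,
) -> ClonalityProfile:
    """Convenience: detect J/V pairs and profile in one step."""
    return profile_clonality(detect_vdj_pairs(pairs, locus, min_mapq), locus, sample_id)


# ---------------------------------------------------------------------------
# Cohort-level reporting

def cohort_summary(
    profiles: Sequence[ClonalityProfile],
) -> tuple[pd.Series, pd.DataFrame]:
    """Cohort clonality statistics and the J x V dominant-clone matrix.

    Counts with dominant fraction > 0.5 / > 0.75 include monoclonal
    samples (dominant fraction 1).  Undetermined profiles are excluded
    from all statistics but counted.
    """
    if not profiles:
        raise ValueError("cohort_summary needs >= 1 profile")
    usable = [p for p in profiles if not p.undetermined]
    n_clones = np.array([p.n_clones for p in usable])
    fracs = np.array([p.dominant_fraction for p in usable])
    sizes = np.array([p.deletion_size for p in usable], dtype=float)
    supports = np.array([p.total_support for p in usable])
    summary = pd.Series(
        {
            "n_samples": len(profiles),
            "n_undetermined": len(profiles) - len(usable),
            "mean_support": supports.mean() if len(usable) else float("nan"),
            "mean_n_clones": n_clones.mean() if len(usable) else float("nan"),
            "min_n_clones": n_clones.min() if len(usable) else float("nan"),
            "max_n_clones": n_clones.max() if len(usable) else float("nan"),
            "n_monoclonal": int((n_clones == 1).sum()),
            "n_dominant_gt50": int((fracs > 0.5).sum()),
            "n_dominant_gt75": int((fracs > 0.75).sum()),
            "mean_dominant_fraction": fracs.mean() if len(usable) else float("nan"),
            "min_dominant_fraction": fracs.min() if len(usable) else float("nan"),
            "max_dominant_fraction": fracs.max() if len(usable) else float("nan"),
            "mean_deletion_kb": sizes.mean() / 1e3 if len(usable) else float("nan"),
            "min_deletion_kb": sizes.min() / 1e3 if len(usable) else float("nan"),
            "max_deletion_kb": sizes.max() / 1e3 if len(usable) else float("nan"),
        }
    )
    dom = pd.DataFrame(
        [(p.dominant_event.j_name, p.dominant_event.v_name) for p in usable],
        columns=["j_name", "v_name"],
    )
    matrix = (
        pd.crosstab(dom["j_name"], dom["v_name"])
        if len(dom)
        else pd.DataFrame()
    )
    return summary, matrix


def profiles_to_frame(profiles: Sequence[ClonalityProfile]) -> pd.DataFrame:
    """Tabulate profiles (one row per sample) for TSV output."""
    rows = []
    for p in profiles:
        if p.undetermined:
            rows.append((p.sample_id, 0, 0, "", "", float("nan"), -1, -1, float("nan")))
        else:
            rows.append(
                (
                    p.sample_id, p.n_clones, p.total_support,
                    p.dominant_event.j_name, p.dominant_event.v_name,
                    p.dominant_fraction,
                    p.deletion.start, p.deletion.end, p.deletion_size / 1e3,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "n_clones", "total_support",
            "dominant_j", "dominant_v", "dominant_fraction",
            "deletion_start", "deletion_end", "deletion_kb",
        ],
    )


def frame_to_profiles(
    frame: pd.DataFrame, locus: LocusDefinition
) -> list[ClonalityProfile]:
    """Rebuild minimal profiles (dominant event only) from a profile table.

    Per-event detail below the dominant clone is not stored in the TSV;
    reconstructed profiles spread the non-dominant support over
    ``n_clones - 1`` placeholder events so that n_clones, total_support and
    dominant_fraction are preserved.
    """
    profiles = []
    for row in frame.itertuples(index=False):
        if int(row.n_clones) == 0:
            profiles.append(ClonalityProfile(row.sample_id, (), None, None, None, None))
            continue
        total = int(row.total_support)
        dom_support = int(round(row.dominant_fraction * total))
        events = [VDJEvent(row.dominant_j, row.dominant_v, dom_support)]
        n_rest = int(row.n_clones) - 1
        rest = total - dom_support
        for k in range(n_rest):
            share = rest // n_rest + (1 if k < rest % n_rest else 0)
            events.append(VDJEvent(f"IGHJ_other{k}", f"IGHV_other{k}", max(share, 1)))
        iv = GenomicInterval(locus.chrom, int(row.deletion_start), int(row.deletion_end))
        profiles.append(
            ClonalityProfile(
                row.sample_id,
                tuple(events),
                events[0],
                iv,
                len(iv),
                locus.segment(row.dominant_v),
            )
        )
    return profiles


def deletion_records(profiles: Sequence[ClonalityProfile]) -> list[DeletionRecord]:
    """Dominant-clone deletion BED records (one per determined sample)."""
    return [
        DeletionRecord(p.sample_id, p.deletion, p.dominant_event.j_name, p.dominant_event.v_name)
        for p in profiles
        if not p.undetermined
    ]
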