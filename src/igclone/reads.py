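"""Paired-end alignment records and SAM I/O.

A paired-end fragment is represented by the reference intervals of its two
mates plus the outer insert size.  Collections of pairs are carried as a
pandas DataFrame (one row per fragment, columns in :data:`PAIR_COLUMNS`)
for vectorised scanning; :class:`AlignedReadPair` is the single-record
view used at API boundaries and in tests.  SAM reading/writing goes
through pysam.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd
import pysam

from .locus_model import GenomicInterval

#: Column order of the pair DataFrame. clone/hap are simulation provenance
#: (-1 for real data); mate1 is always the leftmost mate.
PAIR_COLUMNS = [
    "sample_id", "chrom",
    "start1", "end1", "mapq1",
    "start2", "end2", "mapq2",
    "insert_size", "proper", "duplicate", "secondary",
    "clone", "hap",
]


@dataclass(frozen=True)
class Mate:
    interval: GenomicInterval
    mapq: int = 60


@dataclass(frozen=True)
class AlignedReadPair:
    """One paired-end fragment as two reference intervals + insert size."""

    sample_id: str
    chrom: str
    mate1: Mate
    mate2: Mate
    insert_size: int
    proper: bool = True
    duplicate: bool = False
    secondary: bool = False
    clone: int = -1
    hap: int = -1

    def __post_init__(self) -> None:
        span = max(self.mate1.interval.end, self.mate2.interval.end) - min(
            self.mate1.interval.start, self.mate2.interval.start
        )
        if self.insert_size != span:
            raise ValueError(
                f"insert_size {self.insert_size} != outer mate span {span}"
            )


PairsLike = Union[pd.DataFrame, Iterable[AlignedReadPair]]


def pairs_to_frame(pairs: PairsLike) -> pd.DataFrame:
    """Normalise a pair collection to the canonical DataFrame."""
    if isinstance(pairs, pd.DataFrame):
        return pairs
    rows = [
        (
            p.sample_id, p.chrom,
            p.mate1.interval.start, p.mate1.interval.end, p.mate1.mapq,
            p.mate2.interval.start, p.mate2.interval.end, p.mate2.mapq,
            p.insert_size, p.proper, p.duplicate, p.secondary,
            p.clone, p.hap,
        )
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def frame_to_pairs(frame: pd.DataFrame) -> list[AlignedReadPair]:
    return [
        AlignedReadPair(
            row.sample_id,
            row.chrom,
            Mate(GenomicInterval(row.chrom, int(row.start1), int(row.end1)), int(row.mapq1)),
            Mate(GenomicInterval(row.chrom, int(row.start2), int(row.end2)), int(row.mapq2)),
            int(row.insert_size),
            bool(row.proper),
            bool(row.duplicate),
            bool(row.secondary),
            int(row.clone),
            int(row.hap),
        )
        for row in frame.itertuples(index=False)
    ]


def primary_pairs(frame: pd.DataFrame) -> pd.DataFrame:
    """Non-duplicate primary alignments — the records all detectors scan."""
    return frame[~frame["duplicate"] & ~frame["secondary"]]


# ---------------------------------------------------------------------------
# SAM I/O

def write_sam(
    pairs: PairsLike, path: str | Path, chrom_lengths: dict[str, int]
) -> None:
    """Write pairs as a coordinate-unsorted text SAM (two records per pair).

    The query name encodes sample, clone and haplotype provenance
    (``sample:clone:hap:index``) so simulations round-trip losslessly.
    TLEN carries the signed outer insert size; SEQ/QUAL are omitted ('*')
    because the model is interval-level, not base-level.
    """
    frame = pairs_to_frame(pairs)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": int(n)} for c, n in chrom_lengths.items()],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, row in enumerate(frame.itertuples(index=False)):
            qname = f"{row.sample_id}:{int(row.clone)}:{int(row.hap)}:{i}"
            tid = out.get_tid(row.chrom)
            for mate_no in (1, 2):
                a = pysam.AlignedSegment(header)
                a.query_name = qname
                start = int(row.start1 if mate_no == 1 else row.start2)
                end = int(row.end1 if mate_no == 1 else row.end2)
                mstart = int(row.start2 if mate_no == 1 else row.start1)
                a.reference_id = tid
                a.reference_start = start
                a.next_reference_id = tid
                a.next_reference_start = mstart
                a.mapping_quality = int(row.mapq1 if mate_no == 1 else row.mapq2)
                a.cigarstring = f"{end - start}M"
                flag = 0x1  # paired
                flag |= 0x40 if mate_no == 1 else 0x80
                # Innie orientation: leftmost mate forward, rightmost reverse.
                flag |= 0x10 if mate_no == 2 else 0x20
                if row.proper:
                    flag |= 0x2
                if row.duplicate:
                    flag |= 0x400
                if row.secondary:
                    flag |= 0x100
                a.flag = flag
                a.template_length = int(row.insert_size) * (1 if mate_no == 1 else -1)
                out.write(a)


def read_sam(path: str | Path) -> pd.DataFrame:
    """Read a SAM/BAM file back into the canonical pair DataFrame.

    Mates are joined on query name; provenance fields are recovered from
    the query-name convention of :func:`write_sam` when present, else -1.
    """
    first: dict[str, pysam.AlignedSegment] = {}
    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.query_name is None:
                continue
            other = first.pop(rec.query_name, None)
            if other is None:
                first[rec.query_name] = rec
                continue
            r1, r2 = (other, rec) if other.is_read1 else (rec, other)
            if r1.reference_start > r2.reference_start:
                r1, r2 = r2, r1
            parts = rec.query_name.rsplit(":", 3)
            if len(parts) == 4 and parts[1].lstrip("-").isdigit() and parts[2].lstrip("-").isdigit():
                sample_id, clone, hap = parts[0], int(parts[1]), int(parts[2])
            else:
                sample_id, clone, hap = rec.query_name, -1, -1
            insert = max(r1.reference_end, r2.reference_end) - min(
                r1.reference_start, r2.reference_start
            )
            rows.append(
                (
                    sample_id, rec.reference_name,
                    r1.reference_start, r1.reference_end, r1.mapping_quality,
                    r2.reference_start, r2.reference_end, r2.mapping_quality,
                    insert,
                    bool(rec.is_proper_pair),
                    bool(rec.is_duplicate),
                    bool(rec.is_secondary),
                    clone, hap,
                )
            )
    if first:
        raise ValueError(f"{len(first)} unpaired records in {path}")
    frame = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return frame.astype({c: np.int64 for c in
                         ("start1", "end1", "mapq1", "start2", "end2", "mapq2",
                          "insert_size", "clone", "hap")})
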