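"""Coordinate model of the immunoglobulin heavy-chain (IGH) locus.

The IGH locus sits at the telomeric end of chromosome 14q (GRCh38) and is
organised, in reference-coordinate order, as the IGHJ cluster, the IGHD
cluster and the IGHV cluster (the locus is transcribed from the minus
strand, so "3' end" of a gene segment means its lowest reference
coordinate).  V(D)J recombination in a developing B cell joins one J, one D
and one V segment and excises the intervening DNA, so the somatic deletion
left on a recombined chromosome is the reference interval between the end
of the selected J segment and the start of the selected V segment.

All intervals in this package are 0-based half-open (BED convention);
1-based VCF positions are converted at the I/O boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class LocusError(ValueError):
    """Domain error in locus/segment geometry."""


class BedParseError(ValueError):
    """Malformed BED input; message names the offending line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open reference interval.  Empty (start == end) allowed."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise LocusError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end < self.start:
            raise LocusError(f"end < start in {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping base pairs (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap(other) > 0


_FAMILY_PREFIX = {"IGHV": "V", "IGHD": "D", "IGHJ": "J"}


def family_from_name(name: str) -> str:
    """Infer the segment family (V/D/J) from an IGH segment name prefix."""
    for prefix, family in _FAMILY_PREFIX.items():
        if name.startswith(prefix):
            return family
    raise LocusError(f"cannot infer V/D/J family from segment name {name!r}")


@dataclass(frozen=True)
class GeneSegment:
    """One IGH gene segment (e.g. IGHJ4, IGHV3-23)."""

    name: str
    family: str
    interval: GenomicInterval
    strand: str = "-"

    def __post_init__(self) -> None:
        if self.family not in ("V", "D", "J"):
            raise LocusError(f"bad family {self.family!r} for {self.name}")
        if family_from_name(self.name) != self.family:
            raise LocusError(
                f"family {self.family!r} inconsistent with name {self.name!r}"
            )
        if self.strand not in ("+", "-"):
            raise LocusError(f"bad strand {self.strand!r} for {self.name}")
        if len(self.interval) == 0:
            raise LocusError(f"empty interval for segment {self.name}")

    @classmethod
    def from_name(
        cls, name: str, chrom: str, start: int, end: int, strand: str = "-"
    ) -> "GeneSegment":
        return cls(name, family_from_name(name), GenomicInterval(chrom, start, end), strand)


@dataclass(frozen=True)
class LocusDefinition:
    """The IGH locus span, its J/D/V sub-regions and its gene segments.

    Invariant: j_region < d_region < v_region in reference coordinates, and
    v_region.start is the 3' end of IGHV6-1 — the conventional boundary at
    which the heterozygosity analyses split the locus.
    """

    locus: GenomicInterval
    j_region: GenomicInterval
    d_region: GenomicInterval
    v_region: GenomicInterval
    segments: tuple[GeneSegment, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (
            self.j_region.end <= self.d_region.start
            and self.d_region.end <= self.v_region.start
        ):
            raise LocusError("region order must be J < D < V in reference coordinates")
        for region in (self.j_region, self.d_region, self.v_region):
            if not self.locus.contains_interval(region):
                raise LocusError(f"region {region} outside locus {self.locus}")
        for seg in self.segments:
            if not self.locus.contains_interval(seg.interval):
                raise LocusError(f"segment {seg.name} outside locus {self.locus}")

    @property
    def chrom(self) -> str:
        return self.locus.chrom

    def family(self, family: str) -> tuple[GeneSegment, ...]:
        return tuple(
            sorted(
                (s for s in self.segments if s.family == family),
                key=lambda s: s.interval.start,
            )
        )

    @property
    def j_segments(self) -> tuple[GeneSegment, ...]:
        return self.family("J")

    @property
    def d_segments(self) -> tuple[GeneSegment, ...]:
        return self.family("D")

    @property
    def v_segments(self) -> tuple[GeneSegment, ...]:
        return self.family("V")

    def segment(self, name: str) -> GeneSegment:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(f"no segment named {name!r} in locus definition")

    def with_segments(self, segments: Iterable[GeneSegment]) -> "LocusDefinition":
        return LocusDefinition(
            self.locus, self.j_region, self.d_region, self.v_region, tuple(segments)
        )


def deletion_interval(j: GeneSegment, v: GeneSegment) -> tuple[GenomicInterval, int]:
    """Somatic deletion implied by a J/V join: [j.end, v.start), size in bp.

    The excised DNA on a recombined chromosome is everything between the end
    of the selected J segment and the start (3' end on the minus strand) of
    the selected V segment.
    """
    if j.family != "J" or v.family != "V":
        raise LocusError(f"deletion_interval needs (J, V), got ({j.family}, {v.family})")
    if j.interval.chrom != v.interval.chrom:
        raise LocusError("J and V segments on different chromosomes")
    if j.interval.end > v.interval.start:
        raise LocusError(
            f"J segment {j.name} ends after V segment {v.name} starts; "
            "segments are not in J < V reference order"
        )
    iv = GenomicInterval(j.interval.chrom, j.interval.end, v.interval.start)
    return iv, len(iv)


# ---------------------------------------------------------------------------
# BED I/O

def load_segments(path: str | Path) -> list[GeneSegment]:
    """Read gene segments from a BED6 file (chrom start end name score strand).

    Records are returned in file order; the family is parsed from the name
    prefix.  Malformed lines raise :class:`BedParseError` naming the line.
    """
    segments: list[GeneSegment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"line {lineno}: expected >=4 BED columns, got {len(fields)}")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise BedParseError(f"line {lineno}: invalid interval {start}-{end}")
            strand = fields[5] if len(fields) >= 6 else "-"
            try:
                segments.append(GeneSegment.from_name(name, chrom, start, end, strand))
            except LocusError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
    return segments


def write_segments(segments: Iterable[GeneSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(
                f"{seg.interval.chrom}\t{seg.interval.start}\t{seg.interval.end}"
                f"\t{seg.name}\t0\t{seg.strand}\n"
            )


@dataclass(frozen=True)
class DeletionRecord:
    """Per-sample dominant-clone deletion, as released in the cohort BED."""

    sample_id: str
    interval: GenomicInterval
    j_name: str
    v_name: str

    @property
    def size(self) -> int:
        return len(self.interval)


def write_deletion_bed(records: Iterable[DeletionRecord], path: str | Path) -> None:
    """Write per-sample deletion intervals as BED (name = sample|J/V)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for rec in records:
            name = f"{rec.sample_id}|{rec.j_name}/{rec.v_name}"
            fh.write(
                f"{rec.interval.chrom}\t{rec.interval.start}\t{rec.interval.end}"
                f"\t{name}\t0\t-\n"
            )


def load_deletion_bed(path: str | Path) -> list[DeletionRecord]:
    records: list[DeletionRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"line {lineno}: expected >=4 BED columns")
            chrom, start_s, end_s, name = fields[:4]
            m = re.fullmatch(r"(?P<sample>[^|]+)\|(?P<j>[^/]+)/(?P<v>.+)", name)
            if m is None:
                raise BedParseError(f"line {lineno}: name {name!r} not sample|J/V")
            records.append(
                DeletionRecord(
                    m["sample"],
                    GenomicInterval(chrom, int(start_s), int(end_s)),
                    m["j"],
                    m["v"],
                )
            )
    return records


# ---------------------------------------------------------------------------
# Locus config (flat key=value) I/O

def write_locus_config(locus: LocusDefinition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"chrom={locus.chrom}\n")
        for key, region in (
            ("locus", locus.locus),
            ("j_region", locus.j_region),
            ("d_region", locus.d_region),
            ("v_region", locus.v_region),
        ):
            fh.write(f"{key}_start={region.start}\n{key}_end={region.end}\n")


def load_locus_config(
    path: str | Path, segments: Sequence[GeneSegment] = ()
) -> LocusDefinition:
    values: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise LocusError(f"{path}: line {lineno}: expected key=value")
            key, _, val = line.partition("=")
            values[key.strip()] = val.strip()
    try:
        chrom = values["chrom"]
        regions = {
            key: GenomicInterval(
                chrom, int(values[f"{key}_start"]), int(values[f"{key}_end"])
            )
            for key in ("locus", "j_region", "d_region", "v_region")
        }
    except KeyError as exc:
        raise LocusError(f"{path}: missing config key {exc}") from exc
    return LocusDefinition(
        regions["locus"],
        regions["j_region"],
        regions["d_region"],
        regions["v_region"],
        tuple(segments),
    )


# ---------------------------------------------------------------------------
# Bundled default annotation (synthetic hg38-like fixture)

#: GRCh38 IGH locus span used throughout: chr14:105,862,198-107,043,718.
IGH_LOCUS = GenomicInterval("chr14", 105_862_198, 107_043_718)
#: IGHD cluster region chr14:105,865,458-105,939,756.
IGHD_REGION = GenomicInterval("chr14", 105_865_458, 105_939_756)
#: IGHV region: starts at the 3' end of IGHV6-1 (chr14:105,939,756) and runs
#: toward the chromosome 14 telomere.
IGHV_REGION = GenomicInterval("chr14", 105_939_756, 106_883_718)
IGHJ_REGION = GenomicInterval("chr14", 105_862_198, 105_865_458)

# D segment names ordered from the J-proximal side (IGHD7-27 sits within
# 100 bp of IGHJ1) to the V-proximal side (IGHD1-1 abuts IGHV6-1).
_D_NAMES = [
    "IGHD7-27", "IGHD1-26", "IGHD6-25", "IGHD5-24", "IGHD4-23", "IGHD3-22",
    "IGHD2-21", "IGHD1-20", "IGHD6-19", "IGHD5-18", "IGHD4-17", "IGHD3-16",
    "IGHD2-15", "IGHD1-14", "IGHD6-13", "IGHD5-12", "IGHD4-11", "IGHD3-10",
    "IGHD3-9", "IGHD2-8", "IGHD1-7", "IGHD6-6", "IGHD5-5", "IGHD4-4",
    "IGHD3-3", "IGHD2-2", "IGHD1-1",
]

# V segment names ordered proximal (IGHV6-1) to distal (IGHV7-81).
_V_NAMES = [
    "IGHV6-1", "IGHV1-2", "IGHV1-3", "IGHV4-4", "IGHV2-5", "IGHV3-7",
    "IGHV1-8", "IGHV3-9", "IGHV3-11", "IGHV3-13", "IGHV3-15", "IGHV1-18",
    "IGHV3-20", "IGHV3-21", "IGHV3-23", "IGHV1-24", "IGHV2-26", "IGHV4-28",
    "IGHV3-30", "IGHV4-31", "IGHV3-33", "IGHV4-34", "IGHV4-39", "IGHV3-43",
    "IGHV1-45", "IGHV1-46", "IGHV3-48", "IGHV3-49", "IGHV5-51", "IGHV3-53",
    "IGHV1-58", "IGHV4-59", "IGHV4-61", "IGHV3-64", "IGHV3-66", "IGHV1-69",
    "IGHV2-70", "IGHV3-72", "IGHV3-73", "IGHV3-74", "IGHV7-81",
]


def default_segments() -> list[GeneSegment]:
    """Bundled synthetic gene-segment annotation (hg38-like coordinates).

    Three anchors are pinned to published GRCh38 boundaries — IGHJ1 ends at
    the IGHD region start (105,865,458), IGHV6-1 starts at the IGHV region
    start (105,939,756; its 3' end on the minus strand), and IGHV7-81 starts
    945 kb telomeric of IGHJ1's end — so that the minimal (IGHJ1/IGHV6-1)
    and maximal (IGHJ1/IGHV7-81) J-V deletions measure 74.3 and 945.0 kb.
    All remaining per-gene coordinates are plausible inventions; real
    analyses should supply their own BED.
    """
    chrom = IGH_LOCUS.chrom
    segments: list[GeneSegment] = []
    # Six J segments, 50 bp each, spaced 605 bp end-to-end; IGHJ1 is the
    # most telomeric (adjacent to the D cluster) and IGHJ6 keeps a >200 bp
    # margin above the locus start so junction-anchored read pairs exist
    # for every J within the simulated span.
    for i in range(6):
        end = IGHD_REGION.start - 605 * i
        segments.append(GeneSegment.from_name(f"IGHJ{i + 1}", chrom, end - 50, end))
    # 27 D segments. IGHD7-27 within 100 bp of IGHJ1; IGHD1-26 ~15 kb away.
    d_coords = [(105_865_530, 105_865_555), (105_880_458, 105_880_483)]
    for k in range(25):
        start = 105_883_000 + k * 2_200
        d_coords.append((start, start + 25))
    for name, (start, end) in zip(_D_NAMES, d_coords):
        segments.append(GeneSegment.from_name(name, chrom, start, end))
    # 41 V segments, ~296 bp bodies. IGHV6-1 pinned to the region start;
    # the rest spread to IGHV7-81 at 945 kb from IGHJ1's end.
    v_starts = [IGHV_REGION.start]
    distal_start = IGHJ_REGION.end + 945_000  # IGHV7-81
    n_rest = len(_V_NAMES) - 1
    for k in range(1, n_rest + 1):
        frac = k / n_rest
        v_starts.append(round(105_962_000 + frac * (distal_start - 105_962_000)))
    for name, start in zip(_V_NAMES, v_starts):
        segments.append(GeneSegment.from_name(name, chrom, start, start + 296))
    return sorted(segments, key=lambda s: s.interval.start)


def default_locus() -> LocusDefinition:
    """The bundled IGH locus definition with the synthetic default annotation."""
    return LocusDefinition(
        IGH_LOCUS, IGHJ_REGION, IGHD_REGION, IGHV_REGION, tuple(default_segments())
    )
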