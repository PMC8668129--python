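"""Synthetic LCL cohort simulator for B-cell clonality studies.

Emulates the data structure an IGH clonality analysis consumes, without
any sequence-level simulation:

* germline phased SNPs over the locus (population allele frequencies from
  a Beta distribution, genotypes under Hardy-Weinberg);
* a per-sample pool of B-cell clones, each carrying V(D)J somatic
  deletions — a full V-DJ join on one chromosome and, by default, a D-J
  join on the other (both chromosomes of a B cell are D-J joined even when
  only one completes V-DJ);
* somatic hypermutation (SHM) point changes inside the recombined V
  segment of each clone;
* paired-end fragments (2 x 150 bp, ~450 bp inserts, ~30x) drawn from each
  clone's post-deletion template and emitted as reference-coordinate
  alignment records — a fragment spanning a deletion junction maps with
  its insert inflated by the deletion size;
* emulated genotype calls from the simulated allele pileup, reproducing
  the het->hom dropouts and SHM false hets the real callset suffers.

Ground truth (clone compositions, deletions, germline genotypes) is kept
alongside so recovery tests can score every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_impact import MISSING, PhasedCallset, write_vcf
from .locus_model import (
    DeletionRecord,
    GenomicInterval,
    LocusDefinition,
    default_locus,
    write_deletion_bed,
)
from .reads import PAIR_COLUMNS, write_sam

_BASES = np.array(list("ACGT"), dtype=object)


class SimConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the cohort simulator.

    Defaults mirror a high-coverage short-read consortium dataset:
    2 x 150 bp pairs at ~450 +- 50 bp fragments and 30x coverage, one SNP
    per kb, 1-30 clones per LCL, SHM at 5e-3 per bp of recombined V
    sequence.  ``dominant_fraction`` pins the top clone's share of the cell
    pool; when None, clone fractions follow a symmetric Dirichlet.
    ``n_clones=0`` produces a germline-only (non-recombined) control
    sample.
    """

    seed: int = 0
    n_samples: int = 1
    snp_density: float = 1e-3
    allele_freq_beta: tuple[float, float] | float = (0.8, 0.8)
    n_clones: int | tuple[int, int] = (1, 30)
    dominant_fraction: float | None = None
    dirichlet_alpha: float = 1.0
    read_length: int = 150
    fragment_mean: float = 450.0
    fragment_sd: float = 50.0
    coverage: float = 30.0
    shm_rate: float = 5e-3
    second_allele_mode: str = "dj_only"
    mapq_default: int = 60
    het_threshold: float = 0.2
    min_depth: int = 4
    #: optional per-sample (n_clones, dominant_fraction) study design; when
    #: set (length n_samples) it overrides n_clones/dominant_fraction per
    #: sample, letting one cohort span clonality strata on shared germline.
    sample_clonality: tuple[tuple[int, float | None], ...] | None = None

    def __post_init__(self) -> None:
        if self.sample_clonality is not None and len(self.sample_clonality) != self.n_samples:
            raise SimConfigError("sample_clonality length must equal n_samples")
        if self.dominant_fraction is not None and not (0 < self.dominant_fraction <= 1):
            raise SimConfigError("dominant_fraction must lie in (0, 1]")
        if self.coverage <= 0:
            raise SimConfigError("coverage must be positive")
        if self.fragment_mean <= 2 * self.read_length:
            raise SimConfigError("fragment_mean must exceed 2 x read_length")
        if self.second_allele_mode not in ("dj_only", "full_vdj"):
            raise SimConfigError(f"unknown second_allele_mode {self.second_allele_mode!r}")
        if self.snp_density <= 0:
            raise SimConfigError("snp_density must be positive")


@dataclass(frozen=True)
class Clone:
    """One B-cell clone: fraction of the pool plus per-haplotype deletions.

    ``recombined_hap`` is the germline haplotype index (0/1) carrying the
    full V-DJ join; ``deletions`` is indexed by germline haplotype.
    ``shm_positions`` are 0-based reference positions mutated on the
    recombined haplotype, all inside the selected V segment.
    """

    clone_id: int
    fraction: float
    j_name: str | None
    v_name: str | None
    recombined_hap: int
    deletions: tuple[GenomicInterval | None, GenomicInterval | None]
    shm_positions: tuple[int, ...] = ()

    @property
    def vdj_deletion(self) -> GenomicInterval | None:
        return self.deletions[self.recombined_hap]


@dataclass
class SimTruth:
    """Ground truth for one simulated sample."""

    sample_id: str
    clones: tuple[Clone, ...]
    germline: np.ndarray  # (n_sites, 2) phased alleles, SHM-augmented sites = 0

    @property
    def dominant_clone(self) -> Clone:
        def key(c: Clone):
            size = len(c.vdj_deletion) if c.vdj_deletion else 0
            return (c.fraction, size, c.j_name or "", c.v_name or "")

        return max(self.clones, key=key)

    @property
    def true_deletion(self) -> GenomicInterval | None:
        return self.dominant_clone.vdj_deletion


@dataclass
class CohortSim:
    """Everything one simulation run produces."""

    config: SimConfig
    locus: LocusDefinition
    sites: pd.DataFrame  # pos (1-based), ref, alt, af, is_shm
    germline: PhasedCallset
    truths: list[SimTruth]
    pairs: pd.DataFrame  # all samples, PAIR_COLUMNS
    calls: np.ndarray  # (n_sites, n_samples) genotype codes
    called: PhasedCallset  # emulated calls, phased per germline orientation

    @property
    def sample_ids(self) -> list[str]:
        return [t.sample_id for t in self.truths]

    def sample_pairs(self, sample_id: str) -> pd.DataFrame:
        return self.pairs[self.pairs["sample_id"] == sample_id]


# ---------------------------------------------------------------------------
# Germline cohort

def simulate_germline(
    config: SimConfig,
    locus: LocusDefinition,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, PhasedCallset]:
    """Draw SNP sites and phased Hardy-Weinberg genotypes for the cohort.

    Site count is Poisson(snp_density x locus length) with positions
    uniform over the locus; per-site population allele frequency follows
    Beta(a, b) (or is fixed when ``allele_freq_beta`` is a float); each of
    the 2 x n_samples haplotypes carries the alternate allele with that
    probability, independently.
    """
    if len(locus.locus) == 0:
        raise ValueError("zero-length locus")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    length = len(locus.locus)
    n = int(rng.poisson(config.snp_density * length))
    offsets = np.sort(rng.choice(length, size=min(n, length), replace=False))
    positions = offsets + locus.locus.start + 1  # 1-based
    ref_idx = rng.integers(0, 4, size=len(positions))
    alt_idx = (ref_idx + rng.integers(1, 4, size=len(positions))) % 4
    if isinstance(config.allele_freq_beta, (int, float)):
        af = np.full(len(positions), float(config.allele_freq_beta))
    else:
        a, b = config.allele_freq_beta
        af = rng.beta(a, b, size=len(positions))
    haps = (
        rng.random((len(positions), config.n_samples, 2)) < af[:, None, None]
    ).astype(np.int8)
    sites = pd.DataFrame(
        {
            "pos": positions,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "af": af,
            "is_shm": False,
        }
    )
    callset = PhasedCallset(
        locus.chrom,
        positions,
        sites["ref"].to_numpy(),
        sites["alt"].to_numpy(),
        [f"S{i:03d}" for i in range(config.n_samples)],
        haps,
        phased=True,
    )
    return sites, callset


# ---------------------------------------------------------------------------
# Clone pools

def _clone_fractions(config: SimConfig, n_clones: int, rng: np.random.Generator) -> np.ndarray:
    if config.dominant_fraction is not None:
        f = config.dominant_fraction
        if n_clones > 1 and f < 1 / n_clones:
            raise SimConfigError(
                f"dominant_fraction {f} < 1/{n_clones}: top clone cannot be dominant"
            )
        if n_clones == 1:
            return np.array([1.0])
        rest = (1 - f) / (n_clones - 1)
        return np.array([f] + [rest] * (n_clones - 1))
    fracs = rng.dirichlet(np.full(n_clones, config.dirichlet_alpha))
    return np.sort(fracs)[::-1]


def simulate_clone_pool(
    config: SimConfig,
    locus: LocusDefinition,
    rng: np.random.Generator,
) -> list[Clone]:
    """Draw a sample's clone pool with per-clone joins, deletions and SHM.

    Each clone selects one J and one V segment uniformly for the
    recombined haplotype (deletion = [J.end, V.start)); the other
    haplotype carries either a D-J join confined to the D region
    (``dj_only``) or an independent V-DJ join (``full_vdj``).
    """
    if isinstance(config.n_clones, tuple):
        lo, hi = config.n_clones
        n_clones = int(rng.integers(lo, hi + 1))
    else:
        n_clones = config.n_clones
    if n_clones == 0:  # germline-only control sample
        return [Clone(0, 1.0, None, None, 0, (None, None))]
    j_segs, v_segs, d_segs = locus.j_segments, locus.v_segments, locus.d_segments
    if not j_segs or not v_segs:
        raise SimConfigError("locus needs >= 1 J and >= 1 V segment")
    fractions = _clone_fractions(config, n_clones, rng)
    clones: list[Clone] = []
    for cid in range(n_clones):
        j = j_segs[rng.integers(len(j_segs))]
        v = v_segs[rng.integers(len(v_segs))]
        hap_r = int(rng.integers(2))
        vdj = GenomicInterval(locus.chrom, j.interval.end, v.interval.start)
        if config.second_allele_mode == "dj_only":
            j2 = j_segs[rng.integers(len(j_segs))]
            d2 = d_segs[rng.integers(len(d_segs))] if d_segs else None
            other = (
                GenomicInterval(locus.chrom, j2.interval.end, d2.interval.start)
                if d2 is not None
                else None
            )
        else:  # full_vdj
            j2 = j_segs[rng.integers(len(j_segs))]
            v2 = v_segs[rng.integers(len(v_segs))]
            other = GenomicInterval(locus.chrom, j2.interval.end, v2.interval.start)
        deletions = [None, None]
        deletions[hap_r] = vdj
        deletions[1 - hap_r] = other
        # SHM: point changes in the recombined V segment body.
        hits = np.nonzero(rng.random(len(v.interval)) < config.shm_rate)[0]
        shm = tuple(int(v.interval.start + h) for h in hits)
        clones.append(
            Clone(cid, float(fractions[cid]), j.name, v.name, hap_r, tuple(deletions), shm)
        )
    return clones


# ---------------------------------------------------------------------------
# Read pairs

def _truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, low: float, high: float
) -> np.ndarray:
    """Normal(mean, sd) resampled into [low, high]."""
    out = rng.normal(mean, sd, size=n)
    for _ in range(100):
        bad = (out < low) | (out > high)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, low, high)


def simulate_read_pairs(
    truth: SimTruth,
    config: SimConfig,
    locus: LocusDefinition,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Emit paired-end fragments from every clone x haplotype template.

    Fragment counts are Poisson with mean proportional to clone fraction
    and post-deletion template length, so retained sequence is covered at
    ``config.coverage`` regardless of how much of the locus a clone has
    excised.  Fragments are placed in template (post-deletion) coordinates
    and mapped back to the reference.  A mate straddling the deletion
    junction is handled the way an aligner handles it — soft-clipped to
    the side carrying the majority of its bases (clipped mates span less
    than a full read length) — so no emitted mate interval ever intersects
    its template's deleted interval, while a fragment whose mates end up
    flanking the junction maps with insert = fragment length + deletion
    size.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rl = config.read_length
    length = len(locus.locus)
    chunks = []
    for clone in truth.clones:
        for hap in (0, 1):
            dele = clone.deletions[hap]
            dlen = len(dele) if dele is not None else 0
            tlen = length - dlen
            lam = config.coverage * clone.fraction * tlen / (4 * rl)
            n = int(rng.poisson(lam))
            if n == 0:
                continue
            fl = np.round(
                _truncated_normal(
                    rng, n, config.fragment_mean, config.fragment_sd, 2 * rl, tlen
                )
            ).astype(np.int64)
            start_t = np.floor(rng.random(n) * (tlen - fl + 1)).astype(np.int64)
            s1_t, e1_t = start_t, start_t + rl
            s2_t, e2_t = start_t + fl - rl, start_t + fl
            if dele is not None:
                junction = dele.start - locus.locus.start

                def clip(s: np.ndarray, e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
                    # Soft-clip a junction-crossing mate to its majority side.
                    crossing = (s < junction) & (junction < e)
                    left_share = junction - s
                    keep_left = crossing & (left_share * 2 >= rl)
                    keep_right = crossing & ~keep_left
                    e = np.where(keep_left, junction, e)
                    s = np.where(keep_right, junction, s)
                    return s, e

                s1_t, e1_t = clip(s1_t, e1_t)
                s2_t, e2_t = clip(s2_t, e2_t)

                def to_ref(t: np.ndarray) -> np.ndarray:
                    return locus.locus.start + t + np.where(t >= junction, dlen, 0)

                def end_to_ref(t: np.ndarray) -> np.ndarray:
                    # ends are exclusive: an end at the junction belongs left
                    return to_ref(t - 1) + 1

            else:

                def to_ref(t: np.ndarray) -> np.ndarray:
                    return locus.locus.start + t

                end_to_ref = to_ref

            s1, e1 = to_ref(s1_t), end_to_ref(e1_t)
            s2, e2 = to_ref(s2_t), end_to_ref(e2_t)
            chunk = pd.DataFrame(
                {
                    "sample_id": truth.sample_id,
                    "chrom": locus.chrom,
                    "start1": s1,
                    "end1": e1,
                    "mapq1": config.mapq_default,
                    "start2": s2,
                    "end2": e2,
                    "mapq2": config.mapq_default,
                    "insert_size": e2 - s1,
                    "proper": False,
                    "duplicate": False,
                    "secondary": False,
                    "clone": clone.clone_id,
                    "hap": hap,
                }
            )
            chunks.append(chunk)
    if not chunks:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    frame = pd.concat(chunks, ignore_index=True)
    frame["proper"] = frame["insert_size"] <= config.fragment_mean + 10 * config.fragment_sd
    return frame[PAIR_COLUMNS]


# ---------------------------------------------------------------------------
# Genotype-call emulation

def emulate_genotype_calls(
    pairs: pd.DataFrame,
    truth: SimTruth,
    positions0: np.ndarray,
    config: SimConfig,
) -> np.ndarray:
    """Call genotypes for one sample from its simulated allele pileup.

    Every mate contributes the germline allele of its originating
    haplotype at each covered site, flipped where the clone carries an SHM
    change.  Call rule: depth 0 -> missing; minor-allele fraction >=
    ``het_threshold`` with depth >= ``min_depth`` -> het; otherwise the
    majority allele as a homozygous call (ties below the depth floor fall
    to hom-ref).

    Returns per-site codes 0/1/2/-1 (hom-ref/het/hom-alt/missing).
    """
    positions0 = np.asarray(positions0)
    n_sites = len(positions0)
    starts = np.concatenate([pairs["start1"].to_numpy(), pairs["start2"].to_numpy()])
    ends = np.concatenate([pairs["end1"].to_numpy(), pairs["end2"].to_numpy()])
    clones = np.tile(pairs["clone"].to_numpy(), 2)
    haps = np.tile(pairs["hap"].to_numpy(), 2)
    lo = np.searchsorted(positions0, starts, side="left")
    hi = np.searchsorted(positions0, ends, side="left")
    counts = hi - lo
    total = int(counts.sum())
    codes = np.full(n_sites, MISSING, dtype=np.int8)
    if total == 0:
        return codes
    site_idx = (
        np.arange(total)
        - np.repeat(np.cumsum(counts) - counts, counts)
        + np.repeat(lo, counts)
    )
    hap_exp = np.repeat(haps, counts)
    clone_exp = np.repeat(clones, counts)
    allele = truth.germline[site_idx, hap_exp].astype(np.int64)
    for clone in truth.clones:
        if not clone.shm_positions:
            continue
        shm_mask = np.zeros(n_sites, dtype=bool)
        idx = np.searchsorted(positions0, np.array(clone.shm_positions))
        idx = idx[(idx < n_sites)]
        hit = idx[np.isin(positions0[idx], clone.shm_positions)]
        shm_mask[hit] = True
        flip = (
            (clone_exp == clone.clone_id)
            & (hap_exp == clone.recombined_hap)
            & shm_mask[site_idx]
        )
        allele ^= flip.astype(np.int64)
    depth = np.bincount(site_idx, minlength=n_sites)
    alt = np.bincount(site_idx, weights=allele, minlength=n_sites).astype(np.int64)
    ref = depth - alt
    covered = depth > 0
    minor_frac = np.divide(
        np.minimum(alt, ref), depth, out=np.zeros(n_sites), where=covered
    )
    het = covered & (depth >= config.min_depth) & (minor_frac >= config.het_threshold)
    codes[het] = 1
    hom = covered & ~het
    codes[hom] = np.where(alt[hom] > ref[hom], 2, 0)
    return codes


def called_callset(
    germline: PhasedCallset, calls: np.ndarray, sites: pd.DataFrame
) -> PhasedCallset:
    """Phase emulated calls into a callset analogous to a released panel.

    Called hets are oriented by the germline phase when the germline is
    het at the site; novel (SHM-induced) hets get alt on haplotype 0 — a
    statistical phaser has no information at a somatic singleton either.
    """
    n_sites, n_samples = calls.shape
    haps = np.full((n_sites, n_samples, 2), MISSING, dtype=np.int8)
    haps[calls == 0] = 0
    haps[calls == 2] = 1
    het = calls == 1
    germ_het = germline.haplotypes.sum(axis=2) == 1
    use_germ = het & germ_het
    haps[use_germ] = germline.haplotypes[use_germ]
    novel = het & ~germ_het
    haps[novel] = np.array([1, 0], dtype=np.int8)
    return PhasedCallset(
        germline.chrom,
        germline.positions,
        sites["ref"].to_numpy(),
        sites["alt"].to_numpy(),
        list(germline.samples),
        haps,
        phased=True,
    )


# ---------------------------------------------------------------------------
# Cohort orchestration

def simulate_cohort(
    config: SimConfig, locus: LocusDefinition | None = None
) -> CohortSim:
    """Run the full simulation: germline -> clones -> reads -> calls.

    Reproducibility: one root seed; the germline, each sample, and the SHM
    site bookkeeping use independent child streams spawned from it, so the
    run is deterministic and insensitive to per-sample parallelisation
    order.
    """
    locus = default_locus() if locus is None else locus
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_samples + 2)
    germ_rng = np.random.default_rng(children[0])
    shm_rng = np.random.default_rng(children[1])
    sample_rngs = [np.random.default_rng(c) for c in children[2:]]

    germ_sites, germ_callset = simulate_germline(config, locus, germ_rng)
    sample_ids = germ_callset.samples
    clone_pools = []
    for i in range(config.n_samples):
        cfg_i = config
        if config.sample_clonality is not None:
            n_c, dom = config.sample_clonality[i]
            cfg_i = replace(config, n_clones=n_c, dominant_fraction=dom, sample_clonality=None)
        clone_pools.append(simulate_clone_pool(cfg_i, locus, sample_rngs[i]))
    # Augment the site list with SHM positions (novel somatic variants that
    # a cohort caller would discover); population AF is 0 at these.
    shm_positions = sorted(
        {p for pool in clone_pools for c in pool for p in c.shm_positions}
        - set((germ_sites["pos"] - 1).tolist())
    )
    if shm_positions:
        ref_idx = shm_rng.integers(0, 4, size=len(shm_positions))
        alt_idx = (ref_idx + shm_rng.integers(1, 4, size=len(shm_positions))) % 4
        extra = pd.DataFrame(
            {
                "pos": np.array(shm_positions) + 1,
                "ref": _BASES[ref_idx],
                "alt": _BASES[alt_idx],
                "af": 0.0,
                "is_shm": True,
            }
        )
        sites = (
            pd.concat([germ_sites, extra], ignore_index=True)
            .sort_values("pos", kind="stable")
            .reset_index(drop=True)
        )
    else:
        sites = germ_sites
    positions = sites["pos"].to_numpy(dtype=np.int64)
    n_sites = len(positions)
    haps = np.zeros((n_sites, config.n_samples, 2), dtype=np.int8)
    germ_idx = np.searchsorted(positions, germ_sites["pos"].to_numpy())
    haps[germ_idx] = germ_callset.haplotypes
    germline = PhasedCallset(
        locus.chrom,
        positions,
        sites["ref"].to_numpy(),
        sites["alt"].to_numpy(),
        sample_ids,
        haps,
        phased=True,
    )

    positions0 = positions - 1
    truths, frames = [], []
    calls = np.full((n_sites, config.n_samples), MISSING, dtype=np.int8)
    for i, sample_id in enumerate(sample_ids):
        truth = SimTruth(sample_id, tuple(clone_pools[i]), haps[:, i, :])
        pairs = simulate_read_pairs(truth, config, locus, sample_rngs[i])
        calls[:, i] = emulate_genotype_calls(pairs, truth, positions0, config)
        truths.append(truth)
        frames.append(pairs)
    pairs_all = (
        pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=PAIR_COLUMNS)
    )
    called = called_callset(germline, calls, sites)
    return CohortSim(config, locus, sites, germline, truths, pairs_all, calls, called)


# ---------------------------------------------------------------------------
# On-disk simulation bundle

def truth_table(truths: Sequence[SimTruth]) -> pd.DataFrame:
    """Per-clone truth TSV: sample, clone, fraction, J, V, deletion span."""
    rows = []
    for t in truths:
        for c in t.clones:
            dele = c.vdj_deletion
            rows.append(
                (
                    t.sample_id, c.clone_id, c.fraction,
                    c.j_name or "", c.v_name or "",
                    dele.start if dele else -1,
                    dele.end if dele else -1,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["sample", "clone", "fraction", "J", "V", "deletion_start", "deletion_end"],
    )


def write_simulation(sim: CohortSim, outdir: str | Path) -> dict[str, Path]:
    """Write the simulation bundle: SAM reads, phased VCFs, truth TSV/BED."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sam": outdir / "reads.sam",
        "germline_vcf": outdir / "germline.vcf",
        "calls_vcf": outdir / "calls.vcf",
        "truth_tsv": outdir / "truth.tsv",
        "truth_bed": outdir / "truth_deletions.bed",
    }
    chrom_len = sim.locus.locus.end + 1000
    write_sam(sim.pairs, paths["sam"], {sim.locus.chrom: chrom_len})
    write_vcf(sim.germline, paths["germline_vcf"], contig_length=chrom_len)
    write_vcf(sim.called, paths["calls_vcf"], contig_length=chrom_len)
    truth_table(sim.truths).to_csv(paths["truth_tsv"], sep="\t", index=False)
    records = [
        DeletionRecord(
            t.sample_id, t.true_deletion, t.dominant_clone.j_name, t.dominant_clone.v_name
        )
        for t in sim.truths
        if t.true_deletion is not None
    ]
    write_deletion_bed(records, paths["truth_bed"])
    return paths
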