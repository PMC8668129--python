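import numpy as np
import pandas as pd
import pytest

from igclone import genotype_impact as gi
from igclone import locus_model as lm
from igclone import synthetic_data as sd
from igclone import vdj_detection as vd
from igclone.reads import read_sam


def truth_for(sim, sample_id):
    return next(t for t in sim.truths if t.sample_id == sample_id)


class TestSimConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(sd.SimConfigError):
            sd.SimConfig(dominant_fraction=0.0)
        with pytest.raises(sd.SimConfigError):
            sd.SimConfig(dominant_fraction=1.5)
        with pytest.raises(sd.SimConfigError):
            sd.SimConfig(coverage=0)
        with pytest.raises(sd.SimConfigError):
            sd.SimConfig(fragment_mean=250.0)
        with pytest.raises(sd.SimConfigError):
            sd.SimConfig(second_allele_mode="both")
        with pytest.raises(sd.SimConfigError):
            sd.SimConfig(n_samples=3, sample_clonality=((1, None),))

    def test_dominant_fraction_below_uniform_share_rejected(self, locus):
        config = sd.SimConfig(n_clones=10, dominant_fraction=0.05)
        rng = np.random.default_rng(0)
        with pytest.raises(sd.SimConfigError, match="cannot be dominant"):
            sd.simulate_clone_pool(config, locus, rng)


class TestGermline:
    def test_site_count_at_seed_1_frozen(self, locus):
        """~1 SNP/kb over the 1,181,520 bp locus; exact Poisson draw at
        seed 1 frozen for reproducibility."""
        config = sd.SimConfig(seed=1, n_samples=2)
        sites, callset = sd.simulate_germline(config, locus)
        assert len(sites) == 1183
        assert callset.haplotypes.shape == (1183, 2, 2)

    def test_degenerate_allele_frequency_draws_at_half(self, locus):
        config = sd.SimConfig(seed=3, n_samples=40, allele_freq_beta=0.5)
        sites, callset = sd.simulate_germline(config, locus)
        assert (sites["af"] == 0.5).all()
        # allele draws are Bernoulli(0.5): cohort-wide alt fraction near 1/2
        assert abs(callset.haplotypes.mean() - 0.5) < 0.02

    def test_same_seed_reproduces_output(self, locus):
        config = sd.SimConfig(seed=5, n_samples=3)
        s1, c1 = sd.simulate_germline(config, locus)
        s2, c2 = sd.simulate_germline(config, locus)
        pd.testing.assert_frame_equal(s1, s2)
        assert np.array_equal(c1.haplotypes, c2.haplotypes)

    def test_positions_strictly_increasing_within_locus(self, locus):
        config = sd.SimConfig(seed=9, n_samples=1)
        sites, _ = sd.simulate_germline(config, locus)
        pos = sites["pos"].to_numpy()
        assert (np.diff(pos) > 0).all()
        assert pos[0] >= locus.locus.start + 1 and pos[-1] <= locus.locus.end


class TestClonePool:
    def test_monoclonal_pool_is_single_full_fraction_clone(self, locus):
        config = sd.SimConfig(n_clones=1)
        pool = sd.simulate_clone_pool(config, locus, np.random.default_rng(0))
        assert len(pool) == 1 and pool[0].fraction == 1.0

    def test_pinned_dominant_fraction_splits_remainder_uniformly(self, locus):
        config = sd.SimConfig(n_clones=4, dominant_fraction=0.7)
        pool = sd.simulate_clone_pool(config, locus, np.random.default_rng(0))
        assert [round(c.fraction, 10) for c in pool] == [0.7, 0.1, 0.1, 0.1]

    def test_dirichlet_fractions_sum_to_one(self, locus):
        config = sd.SimConfig(n_clones=10, dirichlet_alpha=1.0)
        pool = sd.simulate_clone_pool(config, locus, np.random.default_rng(4))
        assert abs(sum(c.fraction for c in pool) - 1.0) < 1e-9

    def test_clone_geometry_invariants(self, locus):
        """Deletions inside the locus; SHM confined to the selected V
        segment on the recombined haplotype; dj_only second allele confined
        to the D region."""
        config = sd.SimConfig(n_clones=8, shm_rate=5e-3)
        pool = sd.simulate_clone_pool(config, locus, np.random.default_rng(11))
        for clone in pool:
            vdj = clone.vdj_deletion
            assert locus.locus.contains_interval(vdj)
            assert vdj.start == locus.segment(clone.j_name).interval.end
            assert vdj.end == locus.segment(clone.v_name).interval.start
            v_iv = locus.segment(clone.v_name).interval
            for pos in clone.shm_positions:
                assert v_iv.contains(pos)
            other = clone.deletions[1 - clone.recombined_hap]
            assert other.end <= locus.d_region.end  # D-J join only

    def test_range_n_clones_draws_within_bounds(self, locus):
        config = sd.SimConfig(n_clones=(1, 30))
        sizes = {
            len(sd.simulate_clone_pool(config, locus, np.random.default_rng(s)))
            for s in range(30)
        }
        assert min(sizes) >= 1 and max(sizes) <= 30 and len(sizes) > 5


class TestReadPairs:
    def test_no_mate_overlaps_its_template_deletion(self, mono_sim):
        """Hard exclusion: reads never cover DNA their cell has excised."""
        for t in mono_sim.truths:
            pairs = mono_sim.sample_pairs(t.sample_id)
            for clone in t.clones:
                for hap in (0, 1):
                    dele = clone.deletions[hap]
                    if dele is None:
                        continue
                    sub = pairs[(pairs["clone"] == clone.clone_id) & (pairs["hap"] == hap)]
                    for s_col, e_col in (("start1", "end1"), ("start2", "end2")):
                        ov = np.minimum(sub[e_col], dele.end) - np.maximum(
                            sub[s_col], dele.start
                        )
                        assert (ov <= 0).all()

    def test_junction_spanning_pairs_carry_inflated_inserts(self, mono_sim, locus):
        """A fragment whose mates flank the junction maps with insert =
        fragment length + deletion size, i.e. insert - deletion is an
        ordinary fragment length."""
        t = mono_sim.truths[0]
        clone = t.dominant_clone
        dele = clone.vdj_deletion
        pairs = mono_sim.sample_pairs(t.sample_id)
        sub = pairs[(pairs["clone"] == clone.clone_id) & (pairs["hap"] == clone.recombined_hap)]
        spanning = sub[(sub["end1"] <= dele.start) & (sub["start2"] >= dele.end)]
        assert len(spanning) > 0
        implied_fragment = spanning["insert_size"] - len(dele)
        assert (implied_fragment >= 2 * mono_sim.config.read_length).all()
        assert (implied_fragment <= 700).all()  # mean 450, sd 50

    def test_pair_count_tracks_coverage_and_is_frozen_at_seed_1(self, locus):
        config = sd.SimConfig(seed=1, n_samples=1, n_clones=1)
        sim = sd.simulate_cohort(config, locus)
        n = len(sim.pairs)
        expected = config.coverage * len(locus.locus) / (2 * config.read_length)
        # templates lose deleted bp, so the realised count sits below the
        # deletion-free expectation but within 15%
        assert abs(n - expected) / expected < 0.15
        assert n == 108_611  # exact Poisson totals at seed 1, frozen

    def test_identical_config_gives_byte_identical_outputs(self, locus, tmp_path):
        config = sd.SimConfig(seed=13, n_samples=2, n_clones=3)
        sim_a = sd.simulate_cohort(config, locus)
        sim_b = sd.simulate_cohort(config, locus)
        pd.testing.assert_frame_equal(sim_a.pairs, sim_b.pairs)
        assert np.array_equal(sim_a.calls, sim_b.calls)
        pa = sd.write_simulation(sim_a, tmp_path / "a")
        pb = sd.write_simulation(sim_b, tmp_path / "b")
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes(), key

    def test_coverage_contract_on_deletion_free_interval(self, mono_sim, locus):
        """Mean depth over DNA no clone has deleted is within 15% of the
        configured coverage."""
        distal = lm.GenomicInterval(locus.chrom, 106_900_000, 107_000_000)
        for t in mono_sim.truths[:3]:
            depth = vd.mean_depth(mono_sim.sample_pairs(t.sample_id), distal)
            assert abs(depth.mean_depth - 30.0) / 30.0 < 0.15

    def test_depth_over_dominant_deletion_decreases_with_fraction(self, locus):
        """More clonal pools lose more of the dominant clone's deleted
        interval; checked across three dominance levels with paired seeds."""
        means = []
        for f in (0.2, 0.6, 1.0):
            depths = []
            for seed in (21, 22, 23):
                n = 1 if f == 1.0 else 5
                config = sd.SimConfig(
                    seed=seed, n_samples=1, n_clones=n, dominant_fraction=f
                )
                sim = sd.simulate_cohort(config, locus)
                t = sim.truths[0]
                depths.append(
                    vd.mean_depth(sim.pairs, t.true_deletion).mean_depth
                )
            means.append(np.mean(depths))
        assert means[0] > means[1] > means[2]


class TestGenotypeEmulation:
    def test_het_site_inside_monoclonal_deletion_called_hom_or_missing(self, mono_sim):
        """Only one haplotype contributes reads over the dominant deletion,
        so truly heterozygous sites there cannot be called het."""
        callset = mono_sim.germline
        for i, t in enumerate(mono_sim.truths):
            dele = t.true_deletion
            mask = callset.site_mask(dele)
            germ_codes = callset.genotype_codes()[mask, i]
            called = mono_sim.calls[mask, i]
            het_germ = germ_codes == 1
            assert not (called[het_germ] == 1).any()

    def test_shm_can_create_het_calls_at_hom_germline_sites(self, mixed_sim):
        """SHM in the recombined V introduces alleles absent from the
        germline, surfacing as false heterozygous calls."""
        shm_sites = mixed_sim.sites["is_shm"].to_numpy()
        assert shm_sites.any()
        false_het = (mixed_sim.calls[shm_sites] == 1).sum()
        assert false_het > 0

    def test_polyclonal_sample_retains_het_calls(self, locus):
        """With a 10% dominant clone both haplotypes stay covered, so
        germline het recall away from the D region stays above 0.95."""
        config = sd.SimConfig(seed=17, n_samples=2, n_clones=10, dominant_fraction=0.1)
        sim = sd.simulate_cohort(config, locus)
        span = lm.GenomicInterval(locus.chrom, locus.v_region.start, locus.locus.end)
        mask = sim.germline.site_mask(span)
        for i in range(2):
            germ = sim.germline.genotype_codes()[mask, i]
            called = sim.calls[mask, i]
            het = germ == 1
            recall = (called[het] == 1).mean()
            assert recall > 0.95

    def test_missing_where_both_haplotypes_deleted(self, mono_sim, locus):
        """The proximal D region is excised on both chromosomes of a
        monoclonal sample, leaving no reads to genotype."""
        for i, t in enumerate(mono_sim.truths):
            shared_start = max(d.start for d in (t.clones[0].deletions) if d)
            shared_end = min(d.end for d in (t.clones[0].deletions) if d)
            if shared_start >= shared_end:
                continue
            region = lm.GenomicInterval(locus.chrom, shared_start, shared_end)
            mask = mono_sim.germline.site_mask(region)
            if not mask.any():
                continue
            assert (mono_sim.calls[mask, i] == gi.MISSING).all()


class TestRoundTrips:
    def test_sam_round_trip_preserves_pairs(self, locus, tmp_path):
        config = sd.SimConfig(seed=19, n_samples=2, n_clones=2, coverage=2.0)
        sim = sd.simulate_cohort(config, locus)
        path = tmp_path / "reads.sam"
        from igclone.reads import write_sam

        write_sam(sim.pairs, path, {locus.chrom: locus.locus.end + 1000})
        back = read_sam(path)
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True), sim.pairs.reset_index(drop=True)
        )

    def test_vcf_round_trip_preserves_genotypes(self, locus, tmp_path):
        config = sd.SimConfig(seed=19, n_samples=3)
        _, callset = sd.simulate_germline(config, locus)
        path = tmp_path / "germline.vcf"
        gi.write_vcf(callset, path, contig_length=locus.locus.end + 1000)
        back = gi.read_vcf(path)
        assert back.samples == callset.samples
        assert np.array_equal(back.positions, callset.positions)
        assert np.array_equal(back.haplotypes, callset.haplotypes)
        assert back.phased

    def test_truth_bed_parses_via_locus_model(self, mono_sim, tmp_path):
        paths = sd.write_simulation(mono_sim, tmp_path)
        records = lm.load_deletion_bed(paths["truth_bed"])
        assert len(records) == len(mono_sim.truths)
        by_sample = {r.sample_id: r for r in records}
        for t in mono_sim.truths:
            rec = by_sample[t.sample_id]
            assert rec.interval == t.true_deletion
            assert rec.j_name == t.dominant_clone.j_name
            assert rec.v_name == t.dominant_clone.v_name


class TestConservation:
    def test_clone_fractions_sum_to_one(self, mixed_sim):
        for t in mixed_sim.truths:
            assert abs(sum(c.fraction for c in t.clones) - 1.0) < 1e-9

    def test_germline_control_sample_has_no_deletions(self, locus):
        config = sd.SimConfig(seed=23, n_samples=1, n_clones=0)
        sim = sd.simulate_cohort(config, locus)
        t = sim.truths[0]
        assert t.true_deletion is None
        assert (sim.pairs["insert_size"] <= 900).all()
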