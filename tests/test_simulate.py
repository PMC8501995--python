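"""Generator correctness: determinism, state tiling, donor-copy SNP design,
TSD mechanics of planted insertions, and read/coverage behaviour."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from temkit import io, simulate
from temkit._seq import revcomp


def small_config(**kw) -> simulate.SimulationConfig:
    base = dict(seed=7, n_chromosomes=1, chromosome_length=60_000, n_genes=8)
    base.update(kw)
    return simulate.SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw, message",
        [
            (dict(te_length=700, ltr_length=400), "te_length"),
            (dict(tsd_length=-1), "tsd_length"),
            (dict(depth=0.0), "depth"),
            (dict(het_fraction=1.5), "het_fraction"),
            (dict(preference_weights={1: 0.0, 2: 0.0}), "preference_weights"),
        ],
    )
    def test_invalid_config_names_the_violated_invariant(self, kw, message):
        with pytest.raises(ValueError, match=message):
            small_config(**kw)


class TestGenome:
    def test_states_tile_every_chromosome_exactly(self):
        sim = simulate.simulate_genome(small_config())
        for chrom, seq in sim.chromosomes.items():
            segs = sorted(
                (s, e) for c, s, e, _ in sim.states.segments if c == chrom
            )
            assert segs[0][0] == 0
            assert segs[-1][1] == len(seq)
            for (_, e1), (s2, _) in zip(segs[:-1], segs[1:]):
                assert e1 == s2  # no gap, no overlap

    def test_zero_genes_still_tiles_states(self):
        sim = simulate.simulate_genome(small_config(n_genes=0))
        assert sim.annotation.genes() == []
        assert sim.states.chrom_sizes() == {"chr1": 60_000}

    def test_same_seed_is_byte_identical(self, tmp_path):
        a = simulate.simulate_genome(small_config())
        b = simulate.simulate_genome(small_config())
        assert a.chromosomes == b.chromosomes
        io.write_fasta(a.chromosomes, tmp_path / "a.fa")
        io.write_fasta(b.chromosomes, tmp_path / "b.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_equal_weight_states_cover_expected_share(self):
        cfg = simulate.SimulationConfig(
            seed=1, n_chromosomes=2, chromosome_length=200_000, n_genes=0
        )
        sim = simulate.simulate_genome(cfg)
        # oracle: direct tally of the emitted segmentation
        tallies = {s: 0 for s in range(1, 10)}
        for _, s, e, st in sim.states.segments:
            tallies[st] += e - s
        total = sum(tallies.values())
        n_segs = len(sim.states.segments)
        for st, bp in tallies.items():
            # binomial sampling error on the number of segments per state
            se = np.sqrt((1 / 9) * (8 / 9) / n_segs)
            assert abs(bp / total - 1 / 9) < 5 * se

    def test_histone_tracks_nonnegative_and_elevated_over_marked_states(self):
        cfg = small_config()
        sim = simulate.simulate_genome(cfg)
        track = sim.tracks["H3K27me3"]["chr1"]
        assert (track >= 0).all()
        state_arr = sim.states.state_array("chr1")
        marked = np.isin(state_arr, cfg.h3k27me3_states)
        if marked.any() and (~marked).any():
            assert track[marked].mean() > 3 * track[~marked].mean()


class TestDonorCopies:
    def test_zero_snps_per_copy_rejected(self):
        with pytest.raises(ValueError, match="indistinguishable"):
            simulate.make_donor_copies(small_config(snps_per_copy=0))

    def test_snp_records_count_and_unique_positions(self):
        donors = simulate.make_donor_copies(small_config())
        assert len(donors.snps) == 8 * 6
        positions = [s.position for s in donors.snps]
        assert len(set(positions)) == len(positions)

    def test_pairwise_comparison_against_consensus(self):
        cfg = small_config()
        donors = simulate.make_donor_copies(cfg)
        for copy_id, seq in donors.copies.items():
            mismatches = [
                i for i, (a, b) in enumerate(zip(seq, donors.consensus)) if a != b
            ]
            assert len(mismatches) == cfg.snps_per_copy
            # none in the LTRs
            assert all(
                cfg.ltr_length <= i < cfg.te_length - cfg.ltr_length
                for i in mismatches
            )

    def test_ltr_head_and_tail_identical_across_copies(self):
        donors = simulate.make_donor_copies(small_config())
        heads = {seq[:20] for seq in donors.copies.values()}
        tails = {seq[-20:] for seq in donors.copies.values()}
        assert heads == {donors.head}
        assert tails == {donors.tail}

    def test_interior_too_short_for_snps(self):
        with pytest.raises(ValueError, match="interior too short"):
            simulate.make_donor_copies(
                small_config(te_length=900, ltr_length=400, snps_per_copy=30)
            )


class TestPlantInsertions:
    def test_zero_insertions_is_identity(self):
        cfg = small_config()
        sim = simulate.simulate_genome(cfg)
        donors = simulate.make_donor_copies(cfg)
        line = simulate.plant_insertions(sim, donors, 0, cfg, seed=3)
        for chrom, seq in sim.chromosomes.items():
            assert line.haplotypes[chrom][0].seq == seq
            assert line.haplotypes[chrom][1].seq == seq

    def test_tsd_duplication_string_oracle(self):
        cfg = small_config(tsd_length=5, het_fraction=0.0)
        sim = simulate.simulate_genome(cfg)
        donors = simulate.make_donor_copies(cfg)
        line = simulate.plant_insertions(sim, donors, 1, cfg, seed=4)
        ins = line.insertions[0]
        assert ins.zygosity == simulate.HOMOZYGOUS
        ref = sim.chromosomes[ins.chrom]
        q = ins.position - 1
        tsd = ref[q - 5 : q]
        assert ins.tsd == tsd
        te = donors.copies[ins.donor_id]
        oriented = te if ins.strand == "+" else revcomp(te)
        expected = ref[q - 5 : q] + oriented + tsd + ref[q : q + 20]
        for hap in line.haplotypes[ins.chrom]:
            assert expected in hap.seq

    def test_preference_weights_bias_state_share(self):
        cfg = simulate.SimulationConfig(
            seed=5,
            n_chromosomes=2,
            chromosome_length=200_000,
            min_insertion_spacing=100,
            preference_weights={s: (10.0 if s == 5 else 1.0) for s in range(1, 10)},
        )
        sim = simulate.simulate_genome(cfg)
        rng = np.random.default_rng(6)
        pts = simulate.sample_insertion_sites(sim, 200, cfg, rng)
        genomic = sim.states.genome_fractions()[5]
        in_state5 = sum(
            1 for c, p in pts if sim.states.state_at(c, p - 1) == 5
        )
        res = stats.binomtest(in_state5, 200, genomic, alternative="greater")
        assert res.pvalue < 1e-6
        assert in_state5 / 200 > 2 * genomic

    def test_too_many_insertions_raises(self):
        cfg = small_config()
        sim = simulate.simulate_genome(cfg)
        donors = simulate.make_donor_copies(cfg)
        with pytest.raises(ValueError, match="exceeds available sites"):
            simulate.plant_insertions(sim, donors, 1000, cfg, seed=5)

    def test_heterozygous_modifies_exactly_one_haplotype(self):
        cfg = small_config(het_fraction=1.0)
        sim = simulate.simulate_genome(cfg)
        donors = simulate.make_donor_copies(cfg)
        line = simulate.plant_insertions(sim, donors, 2, cfg, seed=8)
        for ins in line.insertions:
            h0, h1 = line.haplotypes[ins.chrom]
            modified = sum(len(h.seq) > len(sim.chromosomes[ins.chrom]) for h in (h0, h1))
            assert modified >= 1
        total_extra = sum(
            len(h.seq) - len(sim.chromosomes[c])
            for c, (h0, h1) in line.haplotypes.items()
            for h in (h0, h1)
        )
        per_ins = cfg.te_length + cfg.tsd_length
        assert total_extra == per_ins * len(line.insertions)  # one haplotype each


class TestReads:
    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            small_config(depth=0.0)

    def test_mean_depth_close_to_requested(self):
        cfg = simulate.SimulationConfig(
            seed=11, n_chromosomes=1, chromosome_length=10_000, n_genes=0, depth=30.0
        )
        sim = simulate.simulate_genome(cfg)
        haps = {
            "chr1": (
                simulate.HaplotypeMap("chr1", sim.chromosomes["chr1"], []),
                simulate.HaplotypeMap("chr1", sim.chromosomes["chr1"], []),
            )
        }
        reads = simulate.simulate_reads(haps, cfg, seed=12)
        cov = reads.coverage()["chr1"]
        assert 25.5 <= cov.mean() <= 34.5

    def test_junction_reads_carry_ltr_head_after_flank(self, cohort):
        """Reads spanning a plus-strand 5' junction contain the LTR head
        20-mer immediately 3' of genomic flank."""
        donors = cohort["donors"]
        plus = [i for i in cohort["line"].insertions if i.strand == "+"]
        found = 0
        for ins in plus:
            ref = cohort["sim"].chromosomes[ins.chrom]
            junction = ref[ins.position - 21 : ins.position - 1] + donors.head
            for p in cohort["reads"].pairs:
                if junction in p.seq1 or junction in p.seq2 or junction in revcomp(
                    p.seq1
                ) or junction in revcomp(p.seq2):
                    found += 1
                    break
        assert found == len(plus)

    def test_same_seed_reads_identical(self):
        cfg = small_config()
        sim = simulate.simulate_genome(cfg)
        haps = {
            "chr1": (
                simulate.HaplotypeMap("chr1", sim.chromosomes["chr1"], []),
                simulate.HaplotypeMap("chr1", sim.chromosomes["chr1"], []),
            )
        }
        r1 = simulate.simulate_reads(haps, cfg, seed=13)
        r2 = simulate.simulate_reads(haps, cfg, seed=13)
        assert [p.seq1 for p in r1.pairs] == [p.seq1 for p in r2.pairs]
        assert [p.seq2 for p in r1.pairs] == [p.seq2 for p in r2.pairs]


class TestRoundTrips:
    def test_gff3_and_bed_round_trip(self, tmp_path):
        sim = simulate.simulate_genome(small_config())
        io.write_gff3(sim.annotation, tmp_path / "ann.gff3")
        back = io.read_gff3(tmp_path / "ann.gff3")
        assert len(back.features) == len(sim.annotation.features)
        for a, b in zip(sim.annotation.features, back.features):
            assert (a.feature_id, a.start, a.end, a.strand, a.kind) == (
                b.feature_id,
                b.start,
                b.end,
                b.strand,
                b.kind,
            )
            assert sorted(a.exons) == sorted(b.exons)
        io.write_states_bed(sim.states, tmp_path / "states.bed")
        back_states = io.read_states_bed(tmp_path / "states.bed")
        assert back_states.segments == sim.states.segments

    def test_bedgraph_round_trip(self, tmp_path):
        track = {"chr1": np.array([0.0, 0.0, 2.5, 2.5, 1.0, 0.0])}
        io.write_bedgraph(track, tmp_path / "t.bg")
        back = io.read_bedgraph(tmp_path / "t.bg", {"chr1": 6})
        np.testing.assert_allclose(back["chr1"], track["chr1"])

    def test_fastq_round_trip(self, tmp_path):
        cfg = small_config()
        sim = simulate.simulate_genome(cfg)
        haps = {
            "chr1": (
                simulate.HaplotypeMap("chr1", sim.chromosomes["chr1"], []),
                simulate.HaplotypeMap("chr1", sim.chromosomes["chr1"], []),
            )
        }
        reads = simulate.simulate_reads(haps, cfg, seed=20)
        io.write_fastq_pair(reads, tmp_path / "r1.fq", tmp_path / "r2.fq")
        r1 = io.read_fastq(tmp_path / "r1.fq")
        assert r1 == [p.seq1 for p in reads.pairs]
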