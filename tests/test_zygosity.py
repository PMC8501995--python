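"""Zygosity caller: alignment filtering against a brute-force oracle,
spanning-read/pair classification on ground-truthed cohorts, and the
pooled-sibling rule."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import pytest

from temkit import io, simulate, zygosity
from temkit.insertions import InsertionCall


@dataclass
class FakeAln:
    """pysam-like record for filter unit tests."""

    query_name: str = "r1"
    reference_name: str = "chr1"
    reference_start: int = 100
    reference_end: int = 250
    mapping_quality: int = 60
    template_length: int = 400
    is_unmapped: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    is_duplicate: bool = False
    is_proper_pair: bool = True
    cigartuples: tuple = ((0, 150),)


def make_call(chrom="chr1", position=5000, tsd="ACGTA") -> InsertionCall:
    return InsertionCall(chrom, position, tsd, "+", 5, 5)


class TestFilter:
    def test_mapq_threshold_is_exclusive(self):
        cfg = zygosity.ZygosityConfig()
        assert zygosity.filter_alignments([FakeAln(mapping_quality=28)], cfg) == []
        assert len(zygosity.filter_alignments([FakeAln(mapping_quality=29)], cfg)) == 1

    def test_empty_input(self):
        assert zygosity.filter_alignments([], zygosity.ZygosityConfig()) == []

    @pytest.mark.parametrize(
        "kw",
        [
            dict(is_unmapped=True),
            dict(is_secondary=True),
            dict(is_duplicate=True),
            dict(is_proper_pair=False),
            dict(template_length=100),
            dict(template_length=800),
        ],
    )
    def test_rejection_reasons(self, kw):
        assert zygosity.filter_alignments([FakeAln(**kw)], zygosity.ZygosityConfig()) == []

    def test_matches_brute_force_on_cohort(self, cohort_sam_records):
        cfg = zygosity.ZygosityConfig()
        kept = zygosity.filter_alignments(cohort_sam_records, cfg)
        brute = [
            a
            for a in cohort_sam_records
            if not a.is_unmapped
            and not a.is_secondary
            and not a.is_supplementary
            and not a.is_duplicate
            and a.is_proper_pair
            and 150 <= abs(a.template_length) <= 700
            and a.mapping_quality > 28
        ]
        assert len(kept) == len(brute)
        assert {(k.qname, k.start) for k in kept} == {
            (b.query_name, b.reference_start) for b in brute
        }


class TestClassify:
    def test_low_coverage_is_undetermined(self):
        # nine perfectly stacked unclipped reads left of the point: min
        # window coverage 0 < 10, no spanning evidence
        alns = [
            zygosity.FilteredAln(f"r{i}", "chr1", 4000, 4600, False) for i in range(9)
        ]
        call = zygosity.classify_zygosity(
            alns, make_call(), zygosity.ZygosityConfig(), {"chr1": 10_000}
        )
        assert call.verdict == zygosity.UNDETERMINED
        assert call.spanning_reads == 0

    def test_boundary_coverage_nine_is_undetermined(self):
        # uniform 9x coverage across the window, no spanning reads
        alns = []
        n = 0
        for start in range(3500, 6500, 10):
            for k in range(9):
                # alternate qnames so no two records pair up
                alns.append(
                    zygosity.FilteredAln(f"s{n}_{k}", "chr1", start, start + 10, True)
                )
            n += 1
        call = zygosity.classify_zygosity(
            alns, make_call(), zygosity.ZygosityConfig(), {"chr1": 10_000}
        )
        assert call.min_window_coverage_observed == 9
        assert call.verdict == zygosity.UNDETERMINED

    def test_cohort_verdicts_match_truth(self, cohort, cohort_sam_records):
        calls = zygosity.classify_all(
            cohort_sam_records,
            cohort["calls"],
            zygosity.ZygosityConfig(),
            contig_sizes=cohort["reads"].chrom_sizes,
        )
        truth = cohort["truth"]
        correct = sum(
            1
            for z in calls
            if z.verdict == truth[(z.insertion.chrom, z.insertion.position)].zygosity
        )
        assert correct == len(calls) == 50

    def test_heterozygous_sites_span_about_half_of_pairs(self, cohort, cohort_sam_records):
        cfg = zygosity.ZygosityConfig()
        filtered = zygosity.filter_alignments(cohort_sam_records, cfg)
        index = zygosity.AlignmentIndex(filtered, cohort["reads"].chrom_sizes)
        truth = cohort["truth"]
        for call in cohort["calls"]:
            t = truth[(call.chrom, call.position)]
            z = zygosity.classify_zygosity(index, call, cfg)
            if t.zygosity == simulate.HETEROZYGOUS:
                assert z.spanning_pairs > 0
            else:
                assert z.spanning_pairs == 0 and z.spanning_reads == 0

    def test_oracle_equivalence_brute_force(self, cohort, cohort_sam_records):
        """Verdicts equal an exhaustive per-read reimplementation."""
        cfg = zygosity.ZygosityConfig()
        filtered = zygosity.filter_alignments(cohort_sam_records, cfg)
        sizes = cohort["reads"].chrom_sizes
        index = zygosity.AlignmentIndex(filtered, sizes)
        import numpy as np

        for call in cohort["calls"][:10]:
            z = zygosity.classify_zygosity(index, call, cfg)
            point = call.position
            lo, hi = point - 1 - 1000, point - 1 + 1000
            cov = np.zeros(hi - lo)
            span_reads = 0
            by_name: dict[str, list] = {}
            for a in filtered:
                if a.chrom != call.chrom or a.end <= lo or a.start >= hi:
                    continue
                cov[max(a.start, lo) - lo : min(a.end, hi) - lo] += 1
                by_name.setdefault(a.qname, []).append(a)
                if not a.clipped and a.start + 1 < point <= a.end:
                    span_reads += 1
            span_pairs = sum(
                1
                for recs in by_name.values()
                if len(recs) == 2
                and not any(r.clipped for r in recs)
                and min(r.start for r in recs) + 1
                < point
                <= max(r.end for r in recs)
            )
            assert z.spanning_reads == span_reads
            assert z.spanning_pairs == span_pairs
            assert z.min_window_coverage_observed == cov.min()

    def test_window_truncated_near_contig_end(self):
        alns = [zygosity.FilteredAln("r", "chr1", 0, 150, False)]
        call = zygosity.classify_zygosity(
            alns, make_call(position=300), zygosity.ZygosityConfig(), {"chr1": 10_000}
        )
        assert call.window_truncated


class TestPool:
    @pytest.mark.parametrize(
        "verdicts, expected",
        [
            (["homozygous"] * 4, "homozygous"),
            (["homozygous", "heterozygous", "homozygous", "homozygous"], "heterozygous"),
            (["undetermined"] * 4, "undetermined"),
        ],
    )
    def test_pool_rule_examples(self, verdicts, expected):
        calls = [
            zygosity.ZygosityCall(make_call(), v, 0, 0, 20.0) for v in verdicts
        ]
        assert zygosity.pool_zygosity(calls).verdict == expected

    def test_pool_rule_exhaustive_over_all_verdict_vectors(self):
        """Brute force over all 3^4 sibling verdict combinations."""
        states = ["homozygous", "heterozygous", "undetermined"]
        for combo in product(states, repeat=4):
            calls = [
                zygosity.ZygosityCall(make_call(), v, 0, 0, 20.0) for v in combo
            ]
            got = zygosity.pool_zygosity(calls).verdict
            if all(v == "homozygous" for v in combo):
                assert got == "homozygous"
            elif all(v == "undetermined" for v in combo):
                assert got == "undetermined"
            else:
                assert got == "heterozygous"

    def test_mismatched_insertions_rejected(self):
        a = zygosity.ZygosityCall(make_call(position=100), "homozygous", 0, 0, 20.0)
        b = zygosity.ZygosityCall(make_call(position=200), "homozygous", 0, 0, 20.0)
        with pytest.raises(ValueError, match="same insertion"):
            zygosity.pool_zygosity([a, b])

    def test_monotonicity_spanning_read_never_rescues_homozygosity(self):
        # clipped (junction-evidence) reads provide coverage but never span
        base = [
            zygosity.FilteredAln(f"c{i}_{k}", "chr1", s, s + 200, True)
            for i, s in enumerate(range(3400, 6400, 15))
            for k in range(3)
        ]
        cfg = zygosity.ZygosityConfig()
        call = make_call()
        before = zygosity.classify_zygosity(base, call, cfg, {"chr1": 10_000})
        spanning = zygosity.FilteredAln("sp", "chr1", 4950, 5100, False)
        after = zygosity.classify_zygosity(base + [spanning], call, cfg, {"chr1": 10_000})
        assert before.verdict == zygosity.HOMOZYGOUS
        assert after.verdict == zygosity.HETEROZYGOUS


class TestSamRoundTrip:
    def test_verdicts_identical_through_sam_file(self, tmp_path, cohort):
        reads = cohort["reads"]
        path = tmp_path / "truth.sam"
        io.write_truth_sam(reads, path)
        records = io.read_sam(path)
        calls_file = zygosity.classify_all(
            records, cohort["calls"], contig_sizes=reads.chrom_sizes
        )
        calls_mem = zygosity.classify_all(
            io.sam_records(reads), cohort["calls"], contig_sizes=reads.chrom_sizes
        )
        assert [c.verdict for c in calls_file] == [c.verdict for c in calls_mem]
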