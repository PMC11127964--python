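"""RIP-seq read processing, deduplication, background subtraction, tests."""

import itertools
import math

import numpy as np
import pytest

from polvtx.genome import AlignedRead, Peak
from polvtx.ripseq import (
    ProcessedRead,
    RawRead,
    assign_to_peaks,
    deduplicate,
    extract_umi,
    normalize_abundance,
    process_raw_reads,
    rank_sum_test,
    read_length_distribution,
    subtract_background,
    trim_read,
)


class TestExtractUmi:
    def test_prefix_split_and_id_suffix(self):
        r = extract_umi(RawRead("r1", "ACGTACGTTATAGGGCCAAATTT"))
        assert r.umi == "ACGTACGT"
        assert r.sequence == "TATAGGGCCAAATTT"
        assert r.id == "r1_ACGTACGT"

    def test_read_no_longer_than_umi_discarded(self):
        assert extract_umi(RawRead("r1", "ACGTACGT")) is None


class TestTrim:
    def test_tag_and_polya_removed(self):
        p = ProcessedRead("r", "ACGTACGT", "TATAGGGCCGTTACGTACGAAAAAA")
        assert trim_read(p).sequence == "CCGTTACGTACG"

    def test_below_min_length_discarded(self):
        p = ProcessedRead("r", "ACGTACGT", "TATAGGGCCGTT")
        assert trim_read(p) is None  # 5 bases left < 10

    def test_no_tag_no_polya_is_noop(self):
        p = ProcessedRead("r", "ACGTACGT", "GGGTTTGGGTTTGG")
        assert trim_read(p).sequence == "GGGTTTGGGTTTGG"

    def test_tag_with_one_mismatch_removed(self):
        p = ProcessedRead("r", "ACGTACGT", "TATCGGGCCGTTACGTACG")
        assert trim_read(p).sequence == "CCGTTACGTACG"

    def test_exact_mode_keeps_mismatched_tag(self):
        p = ProcessedRead("r", "ACGTACGT", "TATCGGGCCGTTACGTACG")
        assert trim_read(p, max_tag_mismatch=0).sequence == "TATCGGGCCGTTACGTACG"

    def test_short_trailing_a_run_kept(self):
        p = ProcessedRead("r", "ACGTACGT", "CCGTTACGTACGAA")
        assert trim_read(p).sequence == "CCGTTACGTACGAA"

    def test_polya_with_single_interruption_removed(self):
        p = ProcessedRead("r", "ACGTACGT", "CCGTTACGTACGAAAGAAA")
        assert trim_read(p).sequence == "CCGTTACGTACG"

    def test_stage_counters_sum_to_input(self):
        reads = [
            RawRead("a", "ACGTACGTTATAGGG" + "C" * 20 + "AAAA"),
            RawRead("b", "ACGTACG"),  # too short for UMI
            RawRead("c", "ACGTACGTTATAGGGCCAAAAAAA"),  # trimmed below min length
        ]
        out, report = process_raw_reads(reads)
        c = report.counters
        assert c["input"] == 3
        assert c["surviving"] == len(out) == 1
        assert (
            c["discarded_too_short_for_umi"] + c["discarded_below_min_length"]
            + c["surviving"] == c["input"]
        )


def _read(chrom, start, end, strand="+", umi="AAAA", name=None):
    return AlignedRead(chrom, start, end, strand, name=name or f"{start}_{umi}",
                       umi=umi)


class TestDeduplicate:
    def test_same_key_collapses(self):
        reads = [_read("c", 100, 150), _read("c", 100, 150)]
        out, removed = deduplicate(reads)
        assert len(out) == 1 and removed == 1

    def test_different_umis_survive(self):
        reads = [_read("c", 100, 150, umi="AAAA"), _read("c", 100, 150, umi="AAAT")]
        out, _ = deduplicate(reads)
        assert len(out) == 2

    def test_minus_strand_keys_on_five_prime_end(self):
        # same 5' end (end coordinate) but different starts -> duplicates
        reads = [
            AlignedRead("c", 100, 150, "-", umi="AAAA"),
            AlignedRead("c", 110, 150, "-", umi="AAAA"),
        ]
        out, removed = deduplicate(reads)
        assert len(out) == 1 and removed == 1

    def test_matches_brute_force_grouping(self, rng):
        reads = [
            AlignedRead(
                "c",
                int(s),
                int(s) + 30,
                "+-"[int(st)],
                name=f"r{i}",
                umi="ACGT"[int(u)] * 4,
            )
            for i, (s, st, u) in enumerate(
                zip(rng.integers(0, 5, 60), rng.integers(0, 2, 60),
                    rng.integers(0, 3, 60))
            )
        ]
        out, removed = deduplicate(reads)
        groups = {}
        for r in reads:
            groups.setdefault((r.chrom, r.five_prime, r.strand, r.umi), r.name)
        assert {r.name for r in out} == set(groups.values())
        assert removed == len(reads) - len(groups)

    def test_idempotent(self, rng):
        reads = [_read("c", int(s), int(s) + 20) for s in rng.integers(0, 10, 30)]
        once, _ = deduplicate(reads)
        twice, removed = deduplicate(once)
        assert [r.name for r in twice] == [r.name for r in once] and removed == 0

    def test_missing_umi_is_error(self):
        with pytest.raises(ValueError):
            deduplicate([AlignedRead("c", 0, 10, "+")])


class TestSubtractBackground:
    def test_one_bp_overlap_removes(self):
        ip = [_read("c", 100, 140)]
        ctrl = [_read("c", 139, 180)]
        assert subtract_background(ip, ctrl) == []

    def test_half_open_boundary_keeps(self):
        ip = [_read("c", 100, 140)]
        ctrl = [_read("c", 140, 180)]
        assert subtract_background(ip, ctrl) == ip

    def test_empty_control_keeps_all(self):
        ip = [_read("c", 100, 140), _read("c", 300, 350)]
        assert subtract_background(ip, []) == ip

    def test_self_subtraction_is_empty(self):
        ip = [_read("c", 100, 140), _read("c", 300, 350)]
        assert subtract_background(ip, ip) == []

    def test_strand_awareness(self):
        ip = [AlignedRead("c", 100, 140, "+", umi="A")]
        ctrl = [AlignedRead("c", 120, 160, "-", umi="A")]
        assert subtract_background(ip, ctrl, strand_aware=True) == ip
        assert subtract_background(ip, ctrl, strand_aware=False) == []


class TestAssignToPeaks:
    PEAKS = [Peak("c", 100, 200, "p1"), Peak("c", 200, 300, "p2")]

    def test_read_inside_peak_counted(self):
        ts = assign_to_peaks([_read("c", 120, 160)], self.PEAKS)
        assert ts.counts.set_index("peak_id")["count"].to_dict() == {"p1": 1, "p2": 0}
        assert len(ts.reads) == 1

    def test_read_outside_dropped(self):
        ts = assign_to_peaks([_read("c", 500, 540)], self.PEAKS)
        assert len(ts.reads) == 0 and ts.n_dropped == 1

    def test_read_spanning_two_peaks_counted_in_each_once_in_total(self):
        ts = assign_to_peaks([_read("c", 180, 220)], self.PEAKS)
        assert ts.counts["count"].tolist() == [1, 1]
        assert len(ts.reads) == 1

    def test_matches_brute_force(self, rng):
        reads = [
            _read("c", int(s), int(s) + 30, name=f"r{i}")
            for i, s in enumerate(rng.integers(0, 400, 100))
        ]
        ts = assign_to_peaks(reads, self.PEAKS)
        for p in self.PEAKS:
            brute = sum(1 for r in reads if r.start < p.end and p.start < r.end)
            assert int(ts.counts.set_index("peak_id").loc[p.id, "count"]) == brute
        kept = {r.name for r in ts.reads}
        brute_kept = {
            r.name
            for r in reads
            if any(r.start < p.end and p.start < r.end for p in self.PEAKS)
        }
        assert kept == brute_kept


class TestNormalize:
    def _ts(self, count, total):
        ts = assign_to_peaks(
            [_read("c", 110, 140, name=f"r{i}") for i in range(count)],
            [Peak("c", 100, 200, "p1")],
        )
        ts.total_mapped = total
        return ts

    def test_per_million_identity(self):
        out = normalize_abundance(self._ts(10, 1_000_000))
        assert out["rpm"].iloc[0] == pytest.approx(10.0)

    def test_arithmetic(self):
        out = normalize_abundance(self._ts(7, 350_000))
        assert out["rpm"].iloc[0] == pytest.approx(20.0)

    def test_zero_total_error(self):
        with pytest.raises(ValueError):
            normalize_abundance(self._ts(1, 0))


def ranksum_p_by_enumeration(a, b):
    """Two-sided exact p: mass of assignments at least as extreme in U."""
    pooled = sorted(list(a) + list(b))
    n1, n2 = len(a), len(b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}

    def u_of(sub):
        r = sum(ranks[v] for v in sub)
        return r - n1 * (n1 + 1) / 2

    u_obs = u_of(a)
    extreme_obs = min(u_obs, n1 * n2 - u_obs)
    hits = total = 0
    for comb in itertools.combinations(pooled, n1):
        u = u_of(comb)
        total += 1
        if min(u, n1 * n2 - u) <= extreme_obs:
            hits += 1
    return hits / total


class TestRankSum:
    def test_identical_samples_p_one(self):
        _, p = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_fully_separated_two_by_two(self):
        _, p = rank_sum_test([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(1 / 3)

    def test_exact_path_matches_enumeration(self, rng):
        for na, nb in itertools.product(range(1, 7), repeat=2):
            for _ in range(4):
                pooled = rng.choice(1000, size=na + nb, replace=False).astype(float)
                a, b = pooled[:na], pooled[na:]
                _, p = rank_sum_test(a, b)
                assert p == pytest.approx(
                    ranksum_p_by_enumeration(a, b), abs=1e-12
                ), (a, b)

    def test_exact_vs_asymptotic_agree_near_boundary(self, rng):
        a = rng.normal(0.0, 1.0, 200)
        b = rng.normal(0.7, 1.0, 200)
        from scipy.stats import mannwhitneyu

        p_exact = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        _, p_impl = rank_sum_test(a, b)  # asymptotic path at this n
        assert abs(math.log(p_impl) - math.log(p_exact)) < 0.1 * abs(
            math.log(p_exact)
        )

    def test_detects_planted_length_shift(self, rng):
        a = np.round(rng.normal(60, 15, 500))
        b = np.round(rng.normal(45, 15, 500))
        _, p = rank_sum_test(a, b)
        assert p < 0.01

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestLengthDistribution:
    def test_median_of_three(self):
        ts = assign_to_peaks(
            [
                _read("c", 100, 130, name="a"),
                _read("c", 100, 140, name="b"),
                _read("c", 100, 150, name="c"),
            ],
            [Peak("c", 90, 200, "p1")],
        )
        lengths, summary = read_length_distribution(ts)
        assert summary["median"] == 40

    def test_single_read_zero_iqr(self):
        ts = assign_to_peaks([_read("c", 100, 150)], [Peak("c", 90, 200, "p1")])
        _, summary = read_length_distribution(ts)
        assert summary["median"] == 50 and summary["q3"] - summary["q1"] == 0

    def test_empty_set_error(self):
        ts = assign_to_peaks([], [Peak("c", 90, 200, "p1")])
        with pytest.raises(ValueError):
            read_length_distribution(ts)
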