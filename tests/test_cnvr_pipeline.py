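import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovicnv import cnvr_pipeline as cp
from ovicnv.core import CNVCall, CNVR, GenomeBuild
from tests.oracles import bitmap_merged_blocks, pearson_r


def call(sample, start, end, cn=1, chrom="1"):
    return CNVCall(
        sample=sample, chrom=chrom, start=start, end=end, cn=cn, num_snps=3
    )


class TestMerge:
    def test_boundary_overlap_merges_then_length_filter_removes(self):
        calls = [call("a", 100, 200), call("b", 200, 300)]
        merged = cp.merge_to_cnvrs(calls, cohort_size=2, min_len=1)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (100, 300)
        # 201 bp < 1 kb: removed under the default filter
        assert cp.merge_to_cnvrs(calls, cohort_size=2) == []

    def test_adjacent_but_not_overlapping_stay_separate(self):
        calls = [call("a", 100, 200), call("b", 201, 300)]
        merged = cp.merge_to_cnvrs(calls, cohort_size=2, min_len=1)
        assert len(merged) == 2

    def test_frequency_counts_distinct_carriers(self):
        # 18 of 48 carriers -> 37.5%; one carrier with two CNVs counts once
        calls = [call(f"s{i}", 1000, 5000) for i in range(18)]
        calls.append(call("s0", 1200, 1400))
        (region,) = cp.merge_to_cnvrs(calls, cohort_size=48)
        assert region.frequency == pytest.approx(37.5)
        assert len(region.samples) == 18

    def test_cohort_smaller_than_carriers_rejected(self):
        calls = [call("a", 1, 5000), call("b", 1, 5000)]
        with pytest.raises(ValueError, match="cohort_size"):
            cp.merge_to_cnvrs(calls, cohort_size=1)

    def test_merged_cover_matches_bitmap_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(1, 40))
            ivs = []
            for i in range(n):
                s = int(rng.integers(1, 900_000))
                e = s + int(rng.integers(0, 100_000))
                ivs.append(call(f"s{i % 5}", s, min(e, 1_000_000)))
            merged = cp.merge_to_cnvrs(ivs, cohort_size=5, min_len=1)
            oracle = bitmap_merged_blocks(
                [(c.start, c.end) for c in ivs], 1_000_000
            )
            assert [(r.start, r.end) for r in merged] == oracle

    def test_merge_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(1)
        ivs = [
            call(f"s{i % 4}", int(s), int(s) + int(l))
            for i, (s, l) in enumerate(
                zip(rng.integers(1, 500_000, 30), rng.integers(0, 50_000, 30))
            )
        ]
        a = cp.merge_to_cnvrs(ivs, cohort_size=4, min_len=1)
        b = cp.merge_to_cnvrs(list(reversed(ivs)), cohort_size=4, min_len=1)
        assert [(r.start, r.end, r.state) for r in a] == [
            (r.start, r.end, r.state) for r in b
        ]
        # re-merging the merged regions changes nothing
        pseudo = [call("x", r.start, r.end) for r in a]
        again = cp.merge_to_cnvrs(pseudo, cohort_size=1, min_len=1)
        assert [(r.start, r.end) for r in again] == [(r.start, r.end) for r in a]

    def test_outputs_pairwise_disjoint(self):
        rng = np.random.default_rng(2)
        ivs = [
            call("s", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(1, 200_000, 50), rng.integers(0, 30_000, 50))
        ]
        merged = cp.merge_to_cnvrs(ivs, cohort_size=1, min_len=1)
        for a, b in zip(merged, merged[1:]):
            assert a.end < b.start


class TestAssignState:
    def test_all_losses(self):
        assert cp.assign_state([call("a", 1, 10, cn=1), call("b", 1, 10, cn=0)]) == "loss"

    def test_mixed_is_both(self):
        assert cp.assign_state([call("a", 1, 10, cn=1), call("b", 1, 10, cn=3)]) == "both"

    def test_all_gains(self):
        assert cp.assign_state([call("a", 1, 10, cn=3), call("b", 1, 10, cn=4)]) == "gain"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cp.assign_state([])


class TestSummarize:
    def test_single_region_coverage(self):
        genome = GenomeBuild(lengths={"1": 1_000_000})
        region = CNVR(
            chrom="1", start=1, end=50_000, state="loss",
            samples=("a",), n_cnvs=1, frequency=50.0,
        )
        summ = cp.summarize([region], genome)
        row = summ.table.iloc[0]
        assert row["coverage_pct"] == pytest.approx(5.0)
        assert np.isnan(row["mean_distance"])  # <2 CNVRs

    def test_inter_cnvr_distance(self):
        genome = GenomeBuild(lengths={"1": 10_000})
        regs = [
            CNVR("1", 1, 100, "loss", ("a",), 1, 50.0),
            CNVR("1", 201, 300, "loss", ("a",), 1, 50.0),
        ]
        summ = cp.summarize(regs, genome)
        assert summ.table.iloc[0]["mean_distance"] == pytest.approx(100)

    def test_r_squared_equals_squared_pearson_oracle(self):
        rng = np.random.default_rng(3)
        lengths = rng.integers(40, 300, size=26) * 1_000_000
        genome = GenomeBuild(lengths={str(i + 1): int(l) for i, l in enumerate(lengths)})
        regs = []
        for i, l in enumerate(lengths):
            # counts roughly proportional to length plus noise
            n = max(1, int(l / 2e7 + rng.integers(0, 5)))
            for j in range(n):
                s = 1 + j * 1_000_000
                regs.append(
                    CNVR(str(i + 1), s, s + 49_999, "loss", ("a",), 1, 10.0)
                )
        summ = cp.summarize(regs, genome)
        x = summ.table["chrom_length"].to_numpy(float)
        y = summ.table["cnvr_count"].to_numpy(float)
        assert summ.r_squared == pytest.approx(pearson_r(x, y) ** 2, rel=1e-8)

    def test_histogram_fractions_sum_to_one(self):
        lengths = [1_200, 25_000, 75_000, 250_000, 800_000, 2_300_000]
        hist = cp.length_histogram(lengths)
        assert hist.sum() == pytest.approx(1.0)
        assert hist["<10"] == pytest.approx(1 / 6)
        assert hist[">1000"] == pytest.approx(1 / 6)

    def test_totals_consistent(self):
        genome = GenomeBuild(lengths={"1": 1_000_000, "2": 2_000_000})
        regs = [
            CNVR("1", 1, 10_000, "loss", ("a",), 1, 50.0),
            CNVR("2", 1, 30_000, "gain", ("a",), 1, 50.0),
        ]
        summ = cp.summarize(regs, genome)
        assert summ.table["total_cnvr_length"].sum() == sum(r.length for r in regs)
        assert summ.table["cnvr_count"].sum() == 2


@settings(max_examples=40, deadline=None)
@given(
    data=st.lists(
        st.tuples(
            st.integers(min_value=0, max_value=3),     # sample index
            st.integers(min_value=1, max_value=50_000),
            st.integers(min_value=0, max_value=20_000),
            st.sampled_from([0, 1, 3, 4]),
        ),
        min_size=1,
        max_size=25,
    )
)
def test_merge_bitmap_property(data):
    calls = [
        CNVCall(
            sample=f"s{i}", chrom="1", start=s, end=min(s + l, 60_000),
            cn=cn, num_snps=1,
        )
        for i, s, l, cn in data
    ]
    merged = cp.merge_to_cnvrs(calls, cohort_size=4, min_len=1)
    oracle = bitmap_merged_blocks([(c.start, c.end) for c in calls], 60_000)
    assert [(r.start, r.end) for r in merged] == oracle
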