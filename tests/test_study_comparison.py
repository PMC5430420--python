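import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet

from ovicnv import study_comparison as sc
from ovicnv.core import Region, StudyDataset
from ovicnv.synthetic_data import simulate_study_tables
from tests.oracles import all_pairs_hits, pairs_overlap, pca_scores_eigh


def ds(label, triples):
    return StudyDataset(label=label, regions=[Region(c, s, e) for c, s, e in triples])


class TestNovelty:
    def test_one_bp_overlap_is_known(self):
        known, counts = sc.classify_novelty(
            [Region("1", 100, 200)], [ds("ref", [("1", 200, 500)])]
        )
        assert known == [True]
        assert counts == {"ref": 1}

    def test_empty_references_all_novel(self):
        known, counts = sc.classify_novelty([Region("1", 1, 10)], [])
        assert known == [False]

    def test_counts_match_all_pairs_oracle(self):
        rng = np.random.default_rng(0)

        def random_regions(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(1, 900_000))
                out.append(Region("1", s, s + int(rng.integers(0, 80_000))))
            return out

        query = random_regions(100)
        refs = [ds("A", []), ds("B", [])]
        refs[0].regions = random_regions(50)
        refs[1].regions = random_regions(50)
        known, counts = sc.classify_novelty(query, refs)
        for label, ref in zip(("A", "B"), refs):
            oracle_hits = all_pairs_hits(
                [(q.chrom, q.start, q.end) for q in query],
                [(r.chrom, r.start, r.end) for r in ref.regions],
            )
            assert counts[label] == sum(1 for h in oracle_hits if h)
        oracle_known = [
            any(
                q.chrom == r.chrom and pairs_overlap((q.start, q.end), (r.start, r.end))
                for ref in refs
                for r in ref.regions
            )
            for q in query
        ]
        assert known == oracle_known

    def test_reference_order_irrelevant(self):
        query = [Region("1", 10, 400_000)]
        a = ds("A", [("1", 1, 20)])
        b = ds("B", [("1", 399_000, 500_000)])
        k1, _ = sc.classify_novelty(query, [a, b])
        k2, _ = sc.classify_novelty(query, [b, a])
        assert k1 == k2


class TestComposite:
    def test_identical_studies_one_region(self):
        res = sc.build_composite(
            [ds("A", [("1", 100, 200)]), ds("B", [("1", 100, 200)])]
        )
        assert len(res.regions) == 1
        assert res.presence.tolist() == [[1], [1]]

    def test_disjoint_studies_block_structure(self):
        res = sc.build_composite(
            [ds("A", [("1", 100, 200), ("1", 500, 600)]), ds("B", [("2", 100, 200)])]
        )
        assert len(res.regions) == 3
        assert res.presence.sum() == 3
        for i, reg in enumerate(res.regions):
            col = res.presence[:, i]
            assert col.sum() == 1

    def test_composite_independent_of_dataset_order(self):
        a = ds("A", [("1", 100, 5000), ("2", 1, 100)])
        b = ds("B", [("1", 4000, 9000)])
        r1 = sc.build_composite([a, b])
        r2 = sc.build_composite([b, a])
        assert [(r.chrom, r.start, r.end) for r in r1.regions] == [
            (r.chrom, r.start, r.end) for r in r2.regions
        ]

    def test_synthetic_overlap_fraction_recovered(self):
        base = [
            Region("1", 1 + i * 300_000, 150_000 + i * 300_000) for i in range(30)
        ]
        out = simulate_study_tables(base, 3, overlap_fraction=0.5, seed=8)
        res = sc.build_composite(out.datasets)
        shared_count = int((res.presence.sum(axis=0) == 3).sum())
        assert shared_count == len(out.shared) == 15


class TestOrdination:
    def test_complementary_studies_split_on_pc1(self):
        presence = np.array([[1, 1, 1, 0, 0, 0], [0, 0, 0, 1, 1, 1]])
        res = sc.ordinate(presence)
        assert res.scores[0, 0] * res.scores[1, 0] < 0

    def test_identical_rows_have_zero_jaccard_and_height(self):
        presence = np.array([[1, 0, 1], [1, 0, 1], [0, 1, 1]])
        res = sc.ordinate(presence)
        assert res.jaccard_distances[0] == 0.0
        assert res.linkage[0, 2] == 0.0

    def test_scores_match_eigh_oracle(self):
        rng = np.random.default_rng(1)
        presence = rng.integers(0, 2, size=(5, 20))
        res = sc.ordinate(presence)
        oracle = pca_scores_eigh(presence)
        k = min(res.scores.shape[1], oracle.shape[1])
        for j in range(4):  # informative components of a 5-row matrix
            a, b = res.scores[:, j], oracle[:, j]
            sign = np.sign(np.dot(a, b)) or 1.0
            np.testing.assert_allclose(a, sign * b, atol=1e-8)

    def test_components_orthonormal_and_variance_sorted(self):
        rng = np.random.default_rng(2)
        presence = rng.integers(0, 2, size=(6, 30))
        res = sc.ordinate(presence)
        gram = res.components @ res.components.T
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-10)
        assert np.all(np.diff(res.explained_variance) <= 1e-12)

    def test_dendrogram_is_ultrametric(self):
        rng = np.random.default_rng(3)
        presence = rng.integers(0, 2, size=(6, 40))
        res = sc.ordinate(presence)
        coph = cophenet(res.linkage)
        assert np.all(coph >= res.jaccard_distances.min() - 1e-12)

    def test_zero_variance_matrix_rejected(self):
        with pytest.raises(ValueError):
            sc.ordinate(np.ones((3, 4)))

    def test_newick_serialization_contains_all_labels(self):
        rng = np.random.default_rng(4)
        presence = rng.integers(0, 2, size=(4, 10))
        res = sc.ordinate(presence, study_labels=["w", "x", "y", "z"])
        nwk = sc.dendrogram_newick(res)
        assert nwk.endswith(";")
        for lab in "wxyz":
            assert lab in nwk


class TestBreedSpecific:
    def test_large_private_region_is_specific(self):
        a = ds("A", [("1", 1, 150_000)])
        b = ds("B", [("2", 1, 150_000)])
        specific, venn = sc.breed_specific([a, b])
        assert len(specific["A"]) == 1 and len(specific["B"]) == 1
        assert venn == {("A",): 1, ("B",): 1}

    def test_short_region_removed_by_filter(self):
        a = ds("A", [("1", 1, 90_000)])  # 90 kb < 100 kb
        b = ds("B", [("2", 1, 150_000)])
        specific, venn = sc.breed_specific([a, b])
        assert specific["A"] == []
        assert ("A",) not in venn

    def test_shared_region_not_specific(self):
        a = ds("A", [("1", 1, 200_000)])
        b = ds("B", [("1", 100_000, 300_000)])
        specific, venn = sc.breed_specific([a, b])
        assert specific["A"] == [] and specific["B"] == []
        assert venn == {("A", "B"): 1}

    def test_venn_counts_match_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        labels = ["A", "B", "C", "D"]
        datasets = []
        for lab in labels:
            regs = []
            for _ in range(50):
                s = int(rng.integers(1, 5_000_000))
                regs.append(Region("1", s, s + int(rng.integers(100_000, 400_000))))
            datasets.append(StudyDataset(label=lab, regions=regs))
        specific, venn = sc.breed_specific(datasets)

        # brute force: merge every filtered region globally by per-base cover,
        # then enumerate membership of each block against each breed
        from tests.oracles import bitmap_merged_blocks

        all_ivs = [
            (r.start, r.end)
            for ds_ in datasets
            for r in ds_.regions
            if r.length >= 100_000
        ]
        blocks = bitmap_merged_blocks(all_ivs, 6_000_000)
        oracle_venn: dict = {}
        for s, e in blocks:
            members = tuple(
                sorted(
                    ds_.label
                    for ds_ in datasets
                    if any(
                        r.length >= 100_000 and pairs_overlap((s, e), (r.start, r.end))
                        for r in ds_.regions
                    )
                )
            )
            oracle_venn[members] = oracle_venn.get(members, 0) + 1
        assert venn == oracle_venn

    def test_specific_sets_recovered_exactly_on_jitter_free_synthetic(self):
        base = [
            Region("1", 1 + i * 600_000, 250_000 + i * 600_000) for i in range(24)
        ]
        out = simulate_study_tables(base, 4, overlap_fraction=0.5, seed=9)
        specific, _ = sc.breed_specific(out.datasets, min_len=100_000)
        for ds_ in out.datasets:
            got = {(r.chrom, r.start, r.end) for r in specific[ds_.label]}
            expect = {
                (r.chrom, r.start, r.end)
                for r in out.private[ds_.label]
                if r.length >= 100_000
            }
            assert got == expect
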