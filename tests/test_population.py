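import numpy as np
import pytest

from panfam.io_formats import VariantCall
from panfam.population import (call_haplotypes, cluster_distribution,
                               skew_statistic)


def _variants(genos_by_pos, chrom="chr1"):
    return [VariantCall(chrom=chrom, pos=pos, ref="A", alt=["T"],
                        genotypes=dict(geno))
            for pos, geno in genos_by_pos.items()]


class TestCallHaplotypes:
    def test_enumeration_and_ranking(self):
        variants = _variants({
            10: {"l1": 0, "l2": 0, "l3": 1},
            20: {"l1": 0, "l2": 0, "l3": 1}})
        t = call_haplotypes(variants, "g", "chr1", 1, 100,
                            ["l1", "l2", "l3"], min_count=1)
        assert t.haplotypes["Hap1"] == ("00", ["l1", "l2"])
        assert t.haplotypes["Hap2"] == ("11", ["l3"])

    def test_missing_call_excludes_line(self):
        variants = _variants({10: {"l1": 0, "l2": None}})
        t = call_haplotypes(variants, "g", "chr1", 1, 100, ["l1", "l2"],
                            min_count=1)
        assert t.excluded_lines == ["l2"]
        assert sum(len(c) for _, c in t.haplotypes.values()) == 1

    def test_all_identical_single_haplotype(self):
        variants = _variants({10: {f"l{i}": 0 for i in range(6)}})
        t = call_haplotypes(variants, "g", "chr1", 1, 100,
                            [f"l{i}" for i in range(6)])
        assert list(t.haplotypes) == ["Hap1"]
        assert len(t.haplotypes["Hap1"][1]) == 6

    def test_rare_haplotypes_collapse(self):
        variants = _variants({
            10: {"l1": 0, "l2": 0, "l3": 1, "l4": 1, "l5": 0},
            20: {"l1": 0, "l2": 0, "l3": 0, "l4": 1, "l5": 1}})
        t = call_haplotypes(variants, "g", "chr1", 1, 100,
                            [f"l{i}" for i in range(1, 6)], min_count=2)
        assert "rare" in t.haplotypes
        assert sorted(t.haplotypes["rare"][1]) == ["l3", "l4", "l5"]

    def test_sites_outside_region_ignored(self):
        variants = _variants({10: {"l1": 0}, 500: {"l1": 1}})
        t = call_haplotypes(variants, "g", "chr1", 1, 100, ["l1"],
                            min_count=1)
        assert t.positions == [10]

    def test_no_sites_empty_table(self):
        t = call_haplotypes([], "g", "chr1", 1, 100, ["l1"])
        assert t.haplotypes == {}


class TestClusterDistribution:
    def _table(self):
        variants = _variants({10: {f"l{i}": (0 if i < 10 else 1)
                                   for i in range(12)}})
        return call_haplotypes(variants, "g", "chr1", 1, 100,
                               [f"l{i}" for i in range(12)])

    def test_proportions(self):
        clusters = {f"l{i}": ("HG4" if i < 8 else "HG5") for i in range(12)}
        dist = cluster_distribution(self._table(), clusters)
        hap1 = dist[dist["haplotype"] == "Hap1"].iloc[0]
        assert hap1["HG4"] == pytest.approx(0.8)
        assert hap1["HG5"] == pytest.approx(0.2)

    def test_rows_sum_to_one(self):
        clusters = {f"l{i}": f"HG{i % 3 + 1}" for i in range(12)}
        dist = cluster_distribution(self._table(), clusters)
        sums = dist[["HG1", "HG2", "HG3"]].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_cluster_renaming_permutes_columns(self):
        clusters = {f"l{i}": ("A" if i % 2 else "B") for i in range(12)}
        renamed = {k: {"A": "B", "B": "A"}[v] for k, v in clusters.items()}
        d1 = cluster_distribution(self._table(), clusters)
        d2 = cluster_distribution(self._table(), renamed)
        assert np.allclose(d1["A"], d2["B"]) and np.allclose(d1["B"], d2["A"])

    def test_unassigned_line_rejected(self):
        with pytest.raises(KeyError, match="l0"):
            cluster_distribution(self._table(), {})


class TestSkew:
    def _table_from(self, hap_of):
        variants = _variants({10: {l: h for l, h in hap_of.items()}})
        return call_haplotypes(variants, "g", "chr1", 1, 100,
                               sorted(hap_of), min_count=1)

    def test_planted_one_hot_skew_is_significant(self):
        hap_of = {f"l{i}": (0 if i < 75 else 1) for i in range(150)}
        clusters = {f"l{i}": ("HG1" if i < 75 else "HG2")
                    for i in range(150)}
        score, p = skew_statistic(self._table_from(hap_of), clusters,
                                  n_permutations=999, seed=3)
        assert p <= 0.01
        # perfect two-cluster split: max chi2 = n/2, so score = 0.5
        assert score == pytest.approx(0.5)

    def test_uniform_haplotype_not_significant(self):
        rng = np.random.default_rng(4)
        hap_of = {f"l{i}": int(rng.integers(2)) for i in range(150)}
        clusters = {f"l{i}": f"HG{i % 7 + 1}" for i in range(150)}
        score, p = skew_statistic(self._table_from(hap_of), clusters,
                                  n_permutations=499, seed=5)
        assert p > 0.05

    def test_pvalue_floor_and_reproducibility(self):
        hap_of = {f"l{i}": (0 if i < 75 else 1) for i in range(150)}
        clusters = {f"l{i}": ("HG1" if i < 75 else "HG2")
                    for i in range(150)}
        t = self._table_from(hap_of)
        s1, p1 = skew_statistic(t, clusters, n_permutations=99, seed=7)
        s2, p2 = skew_statistic(t, clusters, n_permutations=99, seed=7)
        assert (s1, p1) == (s2, p2)
        assert p1 >= 1 / 100
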