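import numpy as np
import pytest

from oracles import union_find_components
from panfam.orthogrouping import (OrthogroupSet, cluster_denovo,
                                  identity_matrix, mean_og_size,
                                  pairwise_identity, read_orthogroups_tsv,
                                  read_ogset_tsv, refine, subdivide,
                                  write_ogset_tsv)


class TestPairwiseIdentity:
    def test_identical_proteins(self):
        assert pairwise_identity("M" + "KVLA" * 12, "M" + "KVLA" * 12) == 100.0

    def test_single_mismatch_no_gap(self):
        # 4-column ungapped alignment, 3 identities
        assert pairwise_identity("AAAA", "AAAT") == pytest.approx(75.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("AAAA", "")

    def test_gap_columns_count_in_denominator(self):
        # best alignment deletes one residue: 4 identities over 5 columns
        assert pairwise_identity("MKVLA", "MKVA") == pytest.approx(80.0)

    def test_symmetry(self):
        a, b = "MKVLITAGG", "MKVITAGG"
        assert pairwise_identity(a, b) == pairwise_identity(b, a)


def _ident(pairs, members):
    out = {}
    for m in members:
        out[(m, m)] = 100.0
    for (a, b), v in pairs.items():
        out[(a, b)] = v
        out[(b, a)] = v
    return out


class TestSubdivide:
    def test_high_identity_clique_unchanged(self):
        idents = _ident({("a", "b"): 95, ("a", "c"): 95, ("b", "c"): 95},
                        "abc")
        subs, singles = subdivide(["a", "b", "c"], idents)
        assert subs == [["a", "b", "c"]] and singles == []

    def test_single_linkage_chains(self):
        idents = _ident({("a", "b"): 95, ("b", "c"): 95, ("a", "c"): 60},
                        "abc")
        subs, singles = subdivide(["a", "b", "c"], idents)
        assert subs == [["a", "b", "c"]]  # chained through b

    def test_all_dissimilar_become_singletons(self):
        idents = _ident({("a", "b"): 50, ("b", "c"): 50, ("a", "c"): 50},
                        "abc")
        subs, singles = subdivide(["a", "b", "c"], idents)
        assert subs == [] and singles == ["a", "b", "c"]

    def test_idempotent(self):
        rng = np.random.default_rng(42)
        members = [f"g{i}" for i in range(12)]
        idents = _ident({(a, b): float(rng.uniform(50, 100))
                         for i, a in enumerate(members)
                         for b in members[i + 1:]}, members)
        subs1, singles1 = subdivide(members, idents)
        again = [subdivide(s, idents) for s in subs1]
        assert all(res == ([s], []) for s, res in zip(subs1, again))

    def test_threshold_monotone_never_merges(self):
        rng = np.random.default_rng(3)
        members = [f"g{i}" for i in range(15)]
        idents = _ident({(a, b): float(rng.uniform(60, 100))
                         for i, a in enumerate(members)
                         for b in members[i + 1:]}, members)
        prev = None
        for thr in (70, 80, 90, 95):
            subs, singles = subdivide(members, idents, threshold=thr)
            comps = sorted(subs + [[s] for s in singles])
            if prev is not None:
                # each new component is contained in one previous component
                for comp in comps:
                    assert any(set(comp) <= set(p) for p in prev)
            prev = comps

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        members = [f"g{i}" for i in range(30)]
        idents = _ident({(a, b): float(rng.uniform(70, 100))
                         for i, a in enumerate(members)
                         for b in members[i + 1:]}, members)
        subs, singles = subdivide(members, idents, threshold=90)
        edges = [(a, b) for i, a in enumerate(members)
                 for b in members[i + 1:] if idents[(a, b)] >= 90]
        oracle = union_find_components(members, edges)
        assert sorted(subs + [[s] for s in singles]) == oracle


class TestClusterDenovo:
    def test_recovers_two_planted_families(self):
        core_a = "MKVLITAEGG" * 6
        core_b = "WFPNDSYHQC" * 6
        prots = {}
        for i in range(4):
            prots[f"a{i}"] = core_a[:i] + "A" + core_a[i + 1:]
            prots[f"b{i}"] = core_b[:i] + "A" + core_b[i + 1:]
        ogset = cluster_denovo(prots, threshold=90)
        families = sorted(sorted(m) for m in ogset.ogs.values())
        assert families == [[f"a{i}" for i in range(4)],
                            [f"b{i}" for i in range(4)]]
        assert ogset.singletons == []

    def test_single_gene_is_singleton(self):
        ogset = cluster_denovo({"g": "MKVLITA"})
        assert ogset.ogs == {} and ogset.singletons == ["g"]

    def test_zero_threshold_merges_everything(self):
        prots = {"a": "MKVLITA", "b": "WWWWPPP", "c": "GGGGGGG"}
        ogset = cluster_denovo(prots, threshold=0)
        assert len(ogset.ogs) == 1
        assert sorted(next(iter(ogset.ogs.values()))) == ["a", "b", "c"]

    def test_partition_property(self):
        rng = np.random.default_rng(11)
        prots = {f"g{i}": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                             size=40))
                 for i in range(12)}
        ogset = cluster_denovo(prots)
        assert ogset.n_genes == 12


class TestRefineAndIo:
    def test_refine_splits_mixed_group(self):
        prots = {"a1": "MKVLITAEGG" * 5, "a2": "MKVLITAEGG" * 5,
                 "b1": "WFPNDSYHQC" * 5, "b2": "WFPNDSYHQC" * 5,
                 "solo": "AAAAAAAAGG" * 5}
        raw = OrthogroupSet(ogs={"OG1": ["a1", "a2", "b1", "b2", "solo"]})
        ref = refine(raw, prots)
        assert sorted(map(sorted, ref.ogs.values())) == [["a1", "a2"],
                                                         ["b1", "b2"]]
        assert ref.singletons == ["solo"]
        assert ref.n_genes == 5

    def test_orthogroups_tsv_dialect(self, tmp_path):
        p = tmp_path / "Orthogroups.tsv"
        p.write_text("Orthogroup\tgenomeA\tgenomeB\n"
                     "OG1\tx1, x2\tx3\n"
                     "OG2\t\ty1\n")
        ogset = read_orthogroups_tsv(p)
        assert ogset.ogs == {"OG1": ["x1", "x2", "x3"]}
        assert ogset.singletons == ["y1"]

    def test_ogset_tsv_roundtrip(self, tmp_path):
        ogset = OrthogroupSet(ogs={"OG1": ["a", "b"], "OG2": ["c", "d"]},
                              singletons=["e"])
        p = tmp_path / "ogs.tsv"
        write_ogset_tsv(ogset, p, header="test")
        back = read_ogset_tsv(p)
        assert back.ogs == ogset.ogs and back.singletons == ogset.singletons

    def test_min_two_member_invariant_enforced(self):
        with pytest.raises(ValueError):
            OrthogroupSet(ogs={"OG1": ["a"]}).validate()


def test_mean_og_size_arithmetic():
    assert mean_og_size(1224, 16, 68) == pytest.approx(17.76, abs=0.01)
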