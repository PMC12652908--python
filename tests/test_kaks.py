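import random
import warnings

import numpy as np
import pytest

from oracles import ng86_pathways_oracle, ng86_sites_oracle
from panfam._seq import SENSE_CODONS, STOP_CODONS
from panfam.kaks import (CodonAlignment, backthread, ng86, og_kaks,
                         pair_kaks, pathway_differences, syn_site_fraction)
from panfam.orthogrouping import OrthogroupSet
from panfam import synthetic_data as sim


class TestSiteCounting:
    def test_all_sense_codons_match_oracle(self):
        for codon in SENSE_CODONS:
            s_oracle, n_oracle = ng86_sites_oracle(codon)
            s = syn_site_fraction(codon)
            assert s == pytest.approx(s_oracle, abs=1e-12), codon
            assert 3.0 - s == pytest.approx(n_oracle, abs=1e-12), codon

    def test_fourfold_degenerate_third_position(self):
        # glycine GGN: third position fully synonymous
        assert syn_site_fraction("GGG") == pytest.approx(1.0)


class TestPathways:
    def test_all_sense_codon_pairs_match_oracle(self):
        for c1 in SENSE_CODONS:
            for c2 in SENSE_CODONS:
                assert pathway_differences(c1, c2) == pytest.approx(
                    ng86_pathways_oracle(c1, c2), abs=1e-12), (c1, c2)

    def test_synonymous_single_change(self):
        assert pathway_differences("TTT", "TTC") == (1.0, 0.0)


class TestNg86:
    def test_identical_rows_ratio_undefined(self):
        res = ng86(CodonAlignment("a", "b", "ATGAAATTT", "ATGAAATTT"))
        assert res.Sd == res.Nd == 0
        assert res.Ka == res.Ks == 0.0
        assert res.ratio is None and res.status == "ks_zero"

    def test_site_conservation_and_symmetry(self):
        rng = random.Random(5)
        for _ in range(20):
            a = [rng.choice(SENSE_CODONS) for _ in range(30)]
            b = list(a)
            for _ in range(6):
                while True:
                    i = rng.randrange(30)
                    p = rng.randrange(3)
                    cand = b[i][:p] + rng.choice("ACGT") + b[i][p + 1:]
                    if cand not in STOP_CODONS:
                        b[i] = cand
                        break
            fwd = ng86(CodonAlignment("a", "b", "".join(a), "".join(b)))
            rev = ng86(CodonAlignment("b", "a", "".join(b), "".join(a)))
            assert fwd.S + fwd.N == pytest.approx(3 * fwd.n_codons, abs=1e-9)
            assert (fwd.S, fwd.N, fwd.Sd, fwd.Nd) == (rev.S, rev.N, rev.Sd,
                                                      rev.Nd)

    def test_gapped_and_ambiguous_codons_dropped(self):
        res = ng86(CodonAlignment("a", "b", "ATG---TTT", "ATGAAATTC"))
        assert res.n_codons == 2
        res2 = ng86(CodonAlignment("a", "b", "ATGNNNTTT", "ATGAAATTC"))
        assert res2.n_codons == 2

    def test_agrees_with_independent_library_estimator(self):
        # same counting family, different implementation & conventions
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        rng = random.Random(2)
        a = [rng.choice(SENSE_CODONS) for _ in range(60)]
        b = list(a)
        for _ in range(12):
            while True:
                i = rng.randrange(60)
                p = rng.randrange(3)
                cand = b[i][:p] + rng.choice("ACGT") + b[i][p + 1:]
                if cand not in STOP_CODONS:
                    b[i] = cand
                    break
        sa, sb = "".join(a), "".join(b)
        mine = ng86(CodonAlignment("a", "b", sa, sb))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dn, ds = cal_dn_ds(CodonSeq(sa), CodonSeq(sb), method="NG86")
        assert mine.Ka == pytest.approx(dn, rel=0.1)
        assert mine.Ks == pytest.approx(ds, rel=0.1)


class TestBackthread:
    def test_gap_becomes_gap_codon(self):
        aln = backthread("M-A", "MKA", "ATGGCT", "ATGAAAGCA")
        assert aln.codons_a == "ATG---GCT"
        assert aln.codons_b == "ATGAAAGCA"

    def test_gapless_identity(self):
        aln = backthread("MK", "MK", "ATGAAA", "ATGAAG")
        assert (aln.codons_a, aln.codons_b) == ("ATGAAA", "ATGAAG")

    def test_terminal_stop_trimmed(self):
        aln = backthread("MK", "MK", "ATGAAATAA", "ATGAAG")
        assert aln.codons_a == "ATGAAA"

    def test_translation_mismatch_named(self):
        with pytest.raises(ValueError, match="residue 2"):
            backthread("MK", "MK", "ATGGGG", "ATGAAA")


class TestOgKaks:
    def test_pair_count_is_cross_genome_choose_two(self):
        cds = {g: "ATGAAATTTGGG" for g in "abc"}
        prots = {g: "MKFG" for g in "abc"}
        ogset = OrthogroupSet(ogs={"OG1": ["a", "b", "c"]})
        pairs, _ = og_kaks(ogset, {"a": "g1", "b": "g2", "c": "g3"},
                           prots, cds)
        assert len(pairs) == 3

    def test_within_genome_pairs_excluded(self):
        cds = {g: "ATGAAATTTGGG" for g in "abc"}
        prots = {g: "MKFG" for g in "abc"}
        ogset = OrthogroupSet(ogs={"OG1": ["a", "b", "c"]})
        pairs, _ = og_kaks(ogset, {"a": "g1", "b": "g1", "c": "g2"},
                           prots, cds)
        assert len(pairs) == 2

    def test_planted_omega_recovery_is_monotone(self):
        """Median Ka/Ks tracks the planted dN/dS across orthogroups."""
        rng = np.random.default_rng(12)
        medians = []
        for omega in (0.2, 1.0):
            anc = sim.random_cds(200, rng)
            genes = {}
            for j in range(8):
                codons = sim.evolve_cds(anc, attempts=60, omega=omega,
                                        rng=rng)
                genes[f"g{j}"] = "".join(codons)
            ratios = []
            for i in range(8):
                for j in range(i + 1, 8):
                    res = pair_kaks(
                        _translate(genes[f"g{i}"]), _translate(genes[f"g{j}"]),
                        genes[f"g{i}"], genes[f"g{j}"])
                    if res.status == "ok":
                        ratios.append(res.ratio)
            medians.append(float(np.median(ratios)))
        assert medians[0] < medians[1]
        assert medians[0] < 0.6 and medians[1] > 0.6


def _translate(cds):
    from panfam._seq import translate_cds
    return translate_cds(cds)
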