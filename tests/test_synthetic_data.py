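import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from panfam._seq import translate_cds
from panfam.io_formats import read_domtblout, read_fasta, read_gff3
from panfam.family_scan import scan_genome
from panfam.kaks import pair_kaks
from panfam import synthetic_data as sim


def _checksum_dir(d: Path) -> dict[str, str]:
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(d.iterdir()) if p.is_file()}


class TestPanGenomeSim:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = lambda: sim.SimConfig(seed=5, n_genomes=3,
                                    og_spec=sim.small_og_spec())
        sim.simulate_pan_genome(cfg(), tmp_path / "a")
        sim.simulate_pan_genome(cfg(), tmp_path / "b")
        assert _checksum_dir(tmp_path / "a") == _checksum_dir(tmp_path / "b")

    def test_full_presence_when_p_is_one(self, tmp_path):
        spec = [sim.OgSpec("OG1", p_present=1.0, codon_length=40),
                sim.OgSpec("OG2", p_present=1.0, codon_length=40)]
        cfg = sim.SimConfig(seed=6, n_genomes=4, og_spec=spec)
        truth = sim.simulate_pan_genome(cfg, tmp_path)
        assert (truth.presence.values == 1).all()

    def test_omega_zero_yields_ka_zero(self, tmp_path):
        spec = [sim.OgSpec("OG1", omega=0.0, codon_length=80)]
        cfg = sim.SimConfig(seed=7, n_genomes=4, og_spec=spec,
                            divergence=0.05)
        truth = sim.simulate_pan_genome(cfg, tmp_path)
        genes = sorted(truth.og_of)
        cds = {}
        for gid in {truth.genome_of[g] for g in genes}:
            genome = read_fasta(tmp_path / f"{gid}.fa")
            models = read_gff3(tmp_path / f"{gid}.gff3")
            from panfam.family_scan import extract_sequences
            for g in genes:
                if truth.genome_of[g] == gid:
                    _, c, _, _ = extract_sequences(genome, models[g])
                    cds[g] = c
        for a, b in zip(genes, genes[1:]):
            res = pair_kaks(translate_cds(cds[a]), translate_cds(cds[b]),
                            cds[a], cds[b])
            assert res.Nd == 0 and (res.Ka == 0 or res.Ka is None)

    def test_emitted_files_reproduce_truth_membership(self, tmp_path):
        cfg = sim.SimConfig(seed=9, n_genomes=3, og_spec=sim.small_og_spec())
        truth = sim.simulate_pan_genome(cfg, tmp_path)
        recovered = set()
        for j in range(3):
            gid = f"line{j + 1:02d}"
            genes = scan_genome(
                gid, read_fasta(tmp_path / f"{gid}.fa"),
                read_gff3(tmp_path / f"{gid}.gff3"),
                read_domtblout(tmp_path / f"{gid}.domtbl"),
                read_domtblout(tmp_path / f"{gid}.jrl.domtbl"))
            recovered |= {g.gene_id for g in genes}
            for g in genes:
                assert g.has_jrl == (g.gene_id in truth.jrl_genes)
                assert g.on_scaffold == (g.gene_id in truth.scaffold_genes)
        assert recovered == set(truth.og_of)

    def test_presence_matches_planted_probability(self, tmp_path):
        spec = [sim.OgSpec("OG1", p_present=0.5, codon_length=30)]
        hits = 0
        n = 0
        for seed in range(10):
            cfg = sim.SimConfig(seed=seed, n_genomes=10, og_spec=spec)
            truth = sim.simulate_pan_genome(cfg, tmp_path / str(seed))
            hits += int(truth.presence.values.sum())
            n += 10
        # binomial(100, .5): 3-sigma band
        assert abs(hits / n - 0.5) < 3 * 0.05


class TestPopulationSim:
    def test_one_hot_when_skew_is_one(self, tmp_path):
        truth = sim.simulate_population(sim.PopConfig(seed=3, n_lines=140),
                                        tmp_path)
        hap_of = truth["haplotype_of"]["popg1"]
        clusters = truth["clusters"]
        for line, hap in hap_of.items():
            # cluster c owns haplotype c mod 7; with H=K=7 this is c == hap
            assert clusters[line] == f"HG{hap + 1}"

    def test_uniform_when_skew_zero(self, tmp_path):
        truth = sim.simulate_population(sim.PopConfig(seed=4, n_lines=700),
                                        tmp_path)
        hap_of = truth["haplotype_of"]["popg3"]
        counts = np.bincount(list(hap_of.values()), minlength=7)
        assert counts.min() > 0.5 * counts.mean()

    def test_deterministic_vcf(self, tmp_path):
        sim.simulate_population(sim.PopConfig(seed=5), tmp_path / "a")
        sim.simulate_population(sim.PopConfig(seed=5), tmp_path / "b")
        assert ((tmp_path / "a/population.vcf").read_bytes()
                == (tmp_path / "b/population.vcf").read_bytes())

    def test_too_few_sites_rejected(self, tmp_path):
        cfg = sim.PopConfig(seed=6, genes=[
            sim.PopGeneSpec("g", "chr1", 100, n_sites=2, n_haplotypes=5)])
        with pytest.raises(ValueError, match="distinguish"):
            sim.simulate_population(cfg, tmp_path)


class TestCountsSim:
    def test_planted_stress_lfc_recovered(self, tmp_path):
        from panfam.expression import fpkm, stress_response

        truth = sim.simulate_counts(sim.CountsConfig(seed=11), tmp_path)
        meta = truth["metadata"]
        smeta = meta[meta["treatment"] != ""]
        f = fpkm(truth["counts"], truth["lengths"])[smeta["sample"]]
        out = stress_response(f, smeta)
        salt_root = out[(out["organ"] == "root")
                        & (out["treatment"] == "salt")].set_index("gene_id")
        # NB noise at 3 reps, dispersion 0.05: log2FC sd ~ 0.27 per gene
        errs = [salt_root.loc[g, "log2fc"] - 2.0
                for g in truth["salt_induced"]]
        assert max(abs(e) for e in errs) <= 0.8      # 3 sigma per gene
        assert abs(np.mean(errs)) <= 0.25

    def test_tissue_argmax_recovery_rate(self, tmp_path):
        from panfam.expression import fpkm, tissue_profile

        truth = sim.simulate_counts(sim.CountsConfig(seed=12), tmp_path)
        meta = truth["metadata"]
        tmeta = meta[meta["tissue"] != ""]
        f = fpkm(truth["counts"], truth["lengths"])[tmeta["sample"]]
        means, _ = tissue_profile(f, tmeta)
        rooty = list(truth["root_specific"])
        correct = sum(means.loc[g].idxmax() == "root" for g in rooty)
        assert correct / len(rooty) >= 0.95

    def test_deterministic_matrix(self, tmp_path):
        t1 = sim.simulate_counts(sim.CountsConfig(seed=13), tmp_path / "a")
        t2 = sim.simulate_counts(sim.CountsConfig(seed=13), tmp_path / "b")
        assert t1["counts"].equals(t2["counts"])
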