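"""Manifest-driven pipeline: scan -> og -> pan -> kaks -> cis -> tandem
-> gwas -> hap -> expr.

The manifest is a YAML mapping with per-genome paths (fasta, gff3,
hits, optional jrl_hits), optional orthogroups / signals / vcf +
clusters + pop_genes / counts + lengths + metadata paths, an output
directory, a seed, and a ``params`` mapping.  Relative paths resolve
against the manifest's directory.  Optional inputs that are absent
skip their stage; every output TSV starts with a provenance header
(tool version, seed, stage parameters) and a JSON run report records
per-stage status and record counts.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import expression, family_scan, genome_context, kaks as kaks_mod
from . import orthogrouping, pan_matrix, population, regulatory
from .io_formats import (read_domtblout, read_fasta, read_gff3,
                         read_vcf_minimal, write_fasta, write_tsv)

logger = logging.getLogger(__name__)

STAGES = ("scan", "og", "pan", "kaks", "cis", "tandem", "gwas", "hap", "expr")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage} failed: {cause}")
        self.stage = stage


def load_manifest(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    manifest["_base"] = path.parent
    return manifest


def _resolve(manifest: dict, key_path: str | None):
    if not key_path:
        return None
    p = Path(key_path)
    return p if p.is_absolute() else Path(manifest["_base"]) / p


def run_pipeline(manifest: dict, out_dir: str | Path | None = None,
                 seed: int | None = None) -> dict:
    """Run all stages available from the manifest; return the run report."""
    out = Path(out_dir or _resolve(manifest, manifest.get("out_dir"))
               or "panfam_out")
    out.mkdir(parents=True, exist_ok=True)
    seed = int(seed if seed is not None else manifest.get("seed", 0))
    params = dict(manifest.get("params") or {})
    e_max = float(params.get("e_max", family_scan.E_MAX_DEFAULT))
    threshold = float(params.get("identity_threshold",
                                 orthogrouping.IDENTITY_THRESHOLD_DEFAULT))
    reps = int(params.get("reps", 1000))
    report: dict = {"version": __version__, "seed": seed,
                    "params": {"e_max": e_max,
                               "identity_threshold": threshold, "reps": reps},
                    "stages": {}}

    def hdr(stage: str, **kw) -> str:
        extra = " ".join(f"{k}={v}" for k, v in kw.items())
        return f"panfam={__version__} seed={seed} stage={stage} {extra}".strip()

    def record(stage: str, status: str, n: int | None = None,
               t0: float | None = None) -> None:
        entry: dict = {"status": status}
        if n is not None:
            entry["n_records"] = n
        report["stages"][stage] = entry
        if t0 is not None:
            logger.info("stage %s: %s (%d records, %.2fs)",
                        stage, status, n or 0, time.perf_counter() - t0)

    # ----- scan ------------------------------------------------------------
    t0 = time.perf_counter()
    all_genes: list = []
    try:
        for g in manifest["genomes"]:
            genome = read_fasta(_resolve(manifest, g["fasta"]))
            models = read_gff3(_resolve(manifest, g["gff3"]))
            hits = read_domtblout(_resolve(manifest, g["hits"]))
            jrl_path = _resolve(manifest, g.get("jrl_hits"))
            jrl = read_domtblout(jrl_path) if jrl_path else []
            all_genes.extend(family_scan.scan_genome(
                g["genome_id"], genome, models, hits, jrl, e_max=e_max))
    except Exception as exc:
        raise StageError("scan", exc) from exc
    write_tsv(family_scan.genes_to_frame(all_genes), out / "genes.tsv",
              hdr("scan", e_max=e_max))
    proteins = {g.gene_id: g.protein for g in all_genes}
    cds = {g.gene_id: g.cds for g in all_genes}
    upstream = {g.gene_id: g.upstream2kb for g in all_genes}
    genome_of = {g.gene_id: g.genome_id for g in all_genes}
    write_fasta(proteins, out / "proteins.fa")
    write_fasta(cds, out / "cds.fa")
    write_fasta(upstream, out / "upstream.fa")
    record("scan", "ok", len(all_genes), t0)

    # ----- og --------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        og_path = _resolve(manifest, manifest.get("orthogroups"))
        if og_path:
            raw = orthogrouping.read_orthogroups_tsv(og_path)
            ogset = orthogrouping.refine(raw, proteins, threshold)
        else:
            ogset = orthogrouping.cluster_denovo(proteins, threshold)
    except Exception as exc:
        raise StageError("og", exc) from exc
    orthogrouping.write_ogset_tsv(ogset, out / "ogs.tsv",
                                  hdr("og", threshold=threshold))
    record("og", "ok", len(ogset.ogs), t0)

    # ----- pan -------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        genome_ids = [g["genome_id"] for g in manifest["genomes"]]
        matrix = pan_matrix.build_matrix(ogset, genome_of, genome_ids)
        classes = pan_matrix.classify(matrix)
        curve = pan_matrix.saturation(matrix, reps=reps, seed=seed)
    except Exception as exc:
        raise StageError("pan", exc) from exc
    write_tsv(pan_matrix.matrix_to_frame(matrix, classes), out / "pan.tsv",
              hdr("pan"))
    write_tsv(curve.to_frame(), out / "curve.tsv",
              hdr("pan", reps=reps))
    write_tsv(pan_matrix.category_counts(classes, ogset),
              out / "categories.tsv", hdr("pan"))
    record("pan", "ok", len(matrix.og_ids), t0)

    # ----- kaks ------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        pairs, og_summary = kaks_mod.og_kaks(ogset, genome_of, proteins, cds)
    except Exception as exc:
        raise StageError("kaks", exc) from exc
    write_tsv(pairs, out / "kaks_pairs.tsv", hdr("kaks"))
    write_tsv(og_summary, out / "kaks_og.tsv", hdr("kaks"))
    record("kaks", "ok", len(pairs), t0)

    # ----- cis -------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        motifs = regulatory.load_motifs(
            _resolve(manifest, manifest.get("motifs")))
        hits_df = regulatory.scan_promoters(upstream, motifs)
        profile = regulatory.og_category_profile(hits_df, ogset, motifs)
    except Exception as exc:
        raise StageError("cis", exc) from exc
    write_tsv(hits_df.reset_index(), out / "cis_counts.tsv", hdr("cis"))
    write_tsv(profile, out / "cis_og.tsv", hdr("cis"))
    record("cis", "ok", len(hits_df), t0)

    # ----- tandem ----------------------------------------------------------
    t0 = time.perf_counter()
    try:
        og_of = ogset.og_of()
        clusters_all = []
        for gid in genome_ids:
            genes_g = [g for g in all_genes if g.genome_id == gid]
            clusters_all.extend(genome_context.find_tandem(genes_g, og_of))
    except Exception as exc:
        raise StageError("tandem", exc) from exc
    rows = [{"genome_id": c.genome_id, "chrom": c.chrom, "og_id": c.og_id,
             "n_members": len(c.members), "members": ",".join(c.members)}
            for c in clusters_all]
    write_tsv(pd.DataFrame(rows, columns=["genome_id", "chrom", "og_id",
                                          "n_members", "members"]),
              out / "tandem.tsv", hdr("tandem"))
    record("tandem", "ok", len(rows), t0)

    # ----- gwas ------------------------------------------------------------
    t0 = time.perf_counter()
    sig_path = _resolve(manifest, manifest.get("signals"))
    if sig_path and Path(sig_path).exists():
        try:
            signals = genome_context.read_signals_tsv(sig_path)
            ref_genome = manifest.get("gwas_genome", genome_ids[0])
            genes_ref = [g for g in all_genes if g.genome_id == ref_genome]
            cand = genome_context.select_candidates(genes_ref, signals)
            traits = genome_context.trait_summary(cand)
        except Exception as exc:
            raise StageError("gwas", exc) from exc
        write_tsv(pd.DataFrame([c.__dict__ for c in cand],
                               columns=["gene_id", "trait", "chrom",
                                        "signal_pos", "distance"]),
                  out / "candidates.tsv", hdr("gwas"))
        write_tsv(traits, out / "traits.tsv", hdr("gwas"))
        record("gwas", "ok", len(cand), t0)
    else:
        record("gwas", "skipped")

    # ----- hap -------------------------------------------------------------
    t0 = time.perf_counter()
    vcf_path = _resolve(manifest, manifest.get("vcf"))
    clu_path = _resolve(manifest, manifest.get("clusters"))
    reg_path = _resolve(manifest, manifest.get("pop_genes"))
    if vcf_path and clu_path and Path(vcf_path).exists():
        try:
            variants, samples = read_vcf_minimal(vcf_path)
            clusters = population.read_clusters_tsv(clu_path)
            regions = pd.read_csv(reg_path, sep="\t", comment="#")
            hap_rows = []
            for _, r in regions.iterrows():
                table = population.call_haplotypes(
                    variants, r["gene_id"], str(r["chrom"]),
                    int(r["start"]), int(r["end"]), samples)
                if not table.haplotypes:
                    continue
                score, pval = population.skew_statistic(
                    table, clusters, seed=seed)
                dist = population.cluster_distribution(table, clusters)
                for _, d in dist.iterrows():
                    row = {"gene_id": r["gene_id"], "skew_score": score,
                           "perm_p": pval}
                    row.update(d.to_dict())
                    hap_rows.append(row)
        except Exception as exc:
            raise StageError("hap", exc) from exc
        write_tsv(pd.DataFrame(hap_rows), out / "hap.tsv",
                  hdr("hap", note="skew score is a package convention"))
        record("hap", "ok", len(hap_rows), t0)
    else:
        record("hap", "skipped")

    # ----- expr ------------------------------------------------------------
    t0 = time.perf_counter()
    counts_path = _resolve(manifest, manifest.get("counts"))
    if counts_path and Path(counts_path).exists():
        try:
            counts = pd.read_csv(counts_path, sep="\t", comment="#",
                                 index_col="gene_id")
            lengths = pd.read_csv(
                _resolve(manifest, manifest["lengths"]), sep="\t",
                comment="#", index_col="gene_id")["length_bp"]
            meta = pd.read_csv(_resolve(manifest, manifest["metadata"]),
                               sep="\t", comment="#", keep_default_na=False)
            fpkm_mat = expression.fpkm(counts, lengths)
            tmeta = meta[meta["tissue"] != ""]
            smeta = meta[meta["treatment"] != ""]
            means, z = expression.tissue_profile(
                fpkm_mat[tmeta["sample"]], tmeta)
            stress = expression.stress_response(
                fpkm_mat[smeta["sample"]], smeta)
        except Exception as exc:
            raise StageError("expr", exc) from exc
        write_tsv(fpkm_mat.round(4).rename_axis("gene_id").reset_index(),
                  out / "fpkm.tsv", hdr("expr"))
        write_tsv(means.round(4).rename_axis("gene_id").reset_index(),
                  out / "tissue_means.tsv", hdr("expr"))
        write_tsv(z.round(4).rename_axis("gene_id").reset_index(),
                  out / "tissue_z.tsv", hdr("expr"))
        write_tsv(stress.round(4), out / "stress.tsv", hdr("expr"))
        record("expr", "ok", len(fpkm_mat), t0)
    else:
        record("expr", "skipped")

    (out / "report.json").write_text(json.dumps(report, indent=1,
                                                sort_keys=True) + "\n")
    return report
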