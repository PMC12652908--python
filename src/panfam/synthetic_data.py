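"""Synthetic pan-genome study generator with planted ground truth.

Emits, for a configurable panel of genomes, the same file dialects the
real pipeline consumes — per-genome FASTA + GFF3, domain-hit tables
(domtblout dialect), an Orthogroups.tsv, a minimal VCF with a
line-to-cluster table, and a read-count matrix — together with the
planted truth (orthogroup membership, presence matrix, per-OG dN/dS,
planted promoter motifs, per-line haplotypes, expression effects).

Defaults mirror the study scale the package targets: 26 genomes with
~47 family genes each arranged in 68 orthogroups of planted presence
probability, 7 breeding clusters over 150 lines, and salt/mannitol
stress count matrices.  Every knob is exposed; the seed is mandatory
and all outputs are byte-deterministic given it.

Coding sequences evolve from a per-orthogroup ancestral codon sequence
by an accept/reject codon process: each attempted single-nucleotide
change is accepted with probability 1 if synonymous and min(1, omega)
if nonsynonymous; changes creating stop codons are rejected and
redrawn.  Because attempts are uniform over positions and alternative
nucleotides (no transition/transversion bias), the realized dN/dS
matches the planted omega under the NG86 counting model for omega <= 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import CODON_TO_AA, SENSE_CODONS, STOP_CODONS, revcomp
from .regulatory import IUPAC, load_motifs

_NUCS = "ACGT"


# ---------------------------------------------------------------------------
# configuration

@dataclass
class OgSpec:
    """One planted orthogroup."""

    og_id: str
    p_present: float = 1.0      # per-genome presence probability
    copies: int = 1             # gene copies per present genome (adjacent => tandem)
    omega: float = 0.3          # planted dN/dS
    codon_length: int = 150
    has_jrl: bool = False
    on_scaffold: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_present <= 1.0:
            raise ValueError(f"{self.og_id}: p_present outside [0,1]")
        if self.omega < 0:
            raise ValueError(f"{self.og_id}: omega must be > 0")


@dataclass
class MotifPlan:
    """Planting plan: Poisson(rate) copies of a motif per promoter."""

    name: str
    iupac: str
    category: str
    rate: float
    og_ids: tuple[str, ...] | None = None  # None = all orthogroups


@dataclass
class SimConfig:
    seed: int
    n_genomes: int = 26
    og_spec: list[OgSpec] | None = None
    motif_spec: list[MotifPlan] | None = None
    n_chromosomes: int = 10
    # Substitution attempts per codon site per genome branch.  Chosen so
    # within-orthogroup protein identity sits near 95% (clearly above the
    # 90% subdivision rule) while between-orthogroup identity is random.
    divergence: float = 0.02
    promoter_bp: int = 2000
    n_decoy_hits: int = 2       # above-threshold hits per genome (filtered out)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.og_spec is None:
            self.og_spec = default_og_spec()
        if self.motif_spec is None:
            self.motif_spec = default_motif_spec(self.og_spec)


def default_og_spec(rng_seed: int = 20260923) -> list[OgSpec]:
    """68 orthogroups sized to yield ~47 family genes per genome.

    Occupancy mix: 22 core (p = 1, three of them multi-copy tandem
    arrays), 8 softcore (p = 0.94), 23 shell (p cycling 0.3-0.75) and
    15 rare/variable (p = 0.06, one on a scaffold).  The long rare tail
    makes orthogroup discovery saturate gradually over the panel, as
    pan-gene families do; ~17% of orthogroups carry the co-domain.
    """
    rng = np.random.default_rng(rng_seed)
    specs: list[OgSpec] = []
    k = 0

    def add(p, copies=1, on_scaffold=False):
        nonlocal k
        k += 1
        specs.append(OgSpec(
            og_id=f"OG{k:02d}", p_present=p, copies=copies,
            omega=float(rng.choice([0.1, 0.2, 0.3, 0.5])),
            has_jrl=bool(rng.random() < 0.17),
            on_scaffold=on_scaffold))

    for i in range(22):
        add(1.0, copies=3 if i == 0 else (2 if i in (1, 2) else 1))
    for _ in range(8):
        add(0.94)
    shell_p = [0.3, 0.45, 0.6, 0.75]
    for i in range(23):
        add(shell_p[i % 4])
    for i in range(15):
        add(0.06, on_scaffold=(i == 0))
    return specs


def small_og_spec() -> list[OgSpec]:
    """10-orthogroup spec for quick (e.g. 5-genome) smoke runs."""
    specs = []
    for k, (p, copies, scaf) in enumerate([
            (1.0, 2, False), (1.0, 1, False), (1.0, 1, False),
            (1.0, 1, False), (0.7, 1, False), (0.7, 1, False),
            (0.7, 1, False), (0.3, 1, False), (0.3, 1, False),
            (0.15, 1, True)], start=1):
        specs.append(OgSpec(
            og_id=f"OG{k:02d}", p_present=p, copies=copies,
            omega=[0.2, 0.5][k % 2], codon_length=90,
            has_jrl=(k in (1, 5)), on_scaffold=scaf))
    return specs


def default_motif_spec(og_spec: list[OgSpec]) -> list[MotifPlan]:
    """Plant the longer packaged motifs (background matches negligible).

    Stress and hormone elements are planted at a high rate in the first
    half of the orthogroups and not at all in the rest, mimicking the
    observed between-OG differentiation; light elements everywhere at a
    low rate.
    """
    ogs = [s.og_id for s in og_spec]
    half = tuple(ogs[:len(ogs) // 2])
    table = {m.name: m for m in load_motifs()}
    pick = lambda n: table[n]
    return [
        MotifPlan(pick("TCA-element").name, pick("TCA-element").iupac,
                  "hormone", rate=2.0, og_ids=half),
        MotifPlan(pick("TC-rich-repeats").name, pick("TC-rich-repeats").iupac,
                  "stress", rate=2.0, og_ids=half),
        MotifPlan(pick("AE-box").name, pick("AE-box").iupac,
                  "light", rate=0.3, og_ids=None),
        MotifPlan(pick("RY-element").name, pick("RY-element").iupac,
                  "development", rate=1.0, og_ids=None),
    ]


@dataclass
class SimTruth:
    og_of: dict[str, str] = field(default_factory=dict)       # gene -> OG
    genome_of: dict[str, str] = field(default_factory=dict)   # gene -> genome
    presence: pd.DataFrame | None = None                      # OG x genome 0/1
    omega: dict[str, float] = field(default_factory=dict)     # OG -> planted w
    motif_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    jrl_genes: set[str] = field(default_factory=set)
    scaffold_genes: set[str] = field(default_factory=set)
    tandem_ogs: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# codon evolution

def random_cds(n_codons: int, rng: np.random.Generator) -> list[str]:
    """Random sense-codon sequence starting with ATG."""
    codons = ["ATG"]
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons - 1)
    codons.extend(SENSE_CODONS[i] for i in idx)
    return codons


def evolve_cds(codons: list[str], attempts: int, omega: float,
               rng: np.random.Generator) -> list[str]:
    """Accept/reject codon evolution (see module docstring)."""
    seq = list(codons)
    for _ in range(attempts):
        for _retry in range(100):
            i = int(rng.integers(len(seq)))
            pos = int(rng.integers(3))
            old = seq[i]
            alts = [n for n in _NUCS if n != old[pos]]
            nuc = alts[int(rng.integers(3))]
            new = old[:pos] + nuc + old[pos + 1:]
            if new not in STOP_CODONS:
                break
        else:  # pragma: no cover - astronomically unlikely
            continue
        if CODON_TO_AA[new] == CODON_TO_AA[old]:
            seq[i] = new
        elif rng.random() < min(1.0, omega):
            seq[i] = new
    return seq


# ---------------------------------------------------------------------------
# promoters

def _instantiate_iupac(iupac: str, rng: np.random.Generator) -> str:
    return "".join(IUPAC[c][int(rng.integers(len(IUPAC[c])))]
                   for c in iupac.upper())


def make_promoter(length: int, plans: list[MotifPlan], og_id: str,
                  rng: np.random.Generator) -> tuple[str, dict[str, int]]:
    """Uniform background with planted motifs at non-overlapping positions."""
    seq = list("".join(_NUCS[i] for i in rng.integers(0, 4, size=length)))
    occupied: list[tuple[int, int]] = []
    planted: dict[str, int] = {}
    for plan in plans:
        if plan.og_ids is not None and og_id not in plan.og_ids:
            continue
        n = int(rng.poisson(plan.rate))
        placed = 0
        for _ in range(n):
            motif = _instantiate_iupac(plan.iupac, rng)
            for _try in range(50):
                start = int(rng.integers(0, length - len(motif) + 1))
                span = (start, start + len(motif))
                if all(span[1] <= a or span[0] >= b for a, b in occupied):
                    seq[span[0]:span[1]] = motif
                    occupied.append(span)
                    placed += 1
                    break
        if placed:
            planted[plan.name] = planted.get(plan.name, 0) + placed
    return "".join(seq), planted


# ---------------------------------------------------------------------------
# pan-genome emission

_BG_CDS = ("ATG" + "GCTGAAGTT" * 33 + "TAA")  # inert background gene CDS


def _domtbl_line(gene_id: str, domain: str, e_value: float, qlen: int,
                 ali_start: int, ali_end: int) -> str:
    f = (f"{gene_id} - {qlen} {domain} PF00000.0 {qlen} "
         f"{e_value:.2g} 100.0 0.1 1 1 {e_value:.2g} {e_value:.2g} "
         f"99.0 0.1 1 {qlen} {ali_start} {ali_end} {ali_start} {ali_end} "
         f"0.98 synthetic")
    return f


def simulate_pan_genome(config: SimConfig, outdir: str | Path) -> SimTruth:
    """Write per-genome FASTA/GFF3/domtblout files; return the truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    truth = SimTruth()
    og_spec = list(config.og_spec or [])
    genome_ids = [f"line{j + 1:02d}" for j in range(config.n_genomes)]

    # ancestral CDS per orthogroup
    ancestral = {s.og_id: random_cds(s.codon_length, rng) for s in og_spec}
    truth.omega = {s.og_id: s.omega for s in og_spec}
    truth.tandem_ogs = {s.og_id for s in og_spec if s.copies >= 2}

    # presence draws (OG x genome)
    presence = np.zeros((len(og_spec), len(genome_ids)), dtype=int)
    for i, spec in enumerate(og_spec):
        presence[i] = (rng.random(len(genome_ids)) < spec.p_present)
    truth.presence = pd.DataFrame(presence,
                                  index=[s.og_id for s in og_spec],
                                  columns=genome_ids)

    # home chromosome per OG, stable across genomes
    home_chrom = {
        s.og_id: ("scaffold_7" if s.on_scaffold
                  else f"chr{(i % config.n_chromosomes) + 1}")
        for i, s in enumerate(og_spec)}

    manifest_genomes = []
    gene_counter = 0
    for j, genome_id in enumerate(genome_ids):
        contigs: dict[str, list[str]] = {}
        gff_lines = ["##gff-version 3"]
        dom_lines = ["# synthetic domtblout"]
        jrl_lines = ["# synthetic domtblout (co-domain)"]
        positions: dict[str, int] = {}

        def append_gene(chrom: str, gene_id: str, cds: str, promoter: str,
                        strand: str) -> None:
            parts = contigs.setdefault(chrom, [])
            pos = positions.get(chrom, 0)
            spacer = "".join(_NUCS[i] for i in rng.integers(0, 4, size=300))
            if strand == "+":
                block = promoter + cds + spacer
                g_start = pos + len(promoter) + 1
                g_end = g_start + len(cds) - 1
            else:
                block = spacer + revcomp(promoter + cds)
                g_start = pos + len(spacer) + 1
                g_end = g_start + len(cds) - 1
            parts.append(block)
            positions[chrom] = pos + len(block)
            gff_lines.append(
                f"{chrom}\tpanfam_sim\tgene\t{g_start}\t{g_end}\t.\t{strand}"
                f"\t.\tID={gene_id}")
            gff_lines.append(
                f"{chrom}\tpanfam_sim\tmRNA\t{g_start}\t{g_end}\t.\t{strand}"
                f"\t.\tID={gene_id}.t1;Parent={gene_id}")
            gff_lines.append(
                f"{chrom}\tpanfam_sim\tCDS\t{g_start}\t{g_end}\t.\t{strand}"
                f"\t0\tID={gene_id}.cds;Parent={gene_id}.t1")

        def append_background(chrom: str) -> str:
            nonlocal gene_counter
            gene_counter += 1
            gid = f"{genome_id}_bg{gene_counter:05d}"
            promoter = "".join(_NUCS[i] for i in rng.integers(0, 4, size=200))
            append_gene(chrom, gid, _BG_CDS, promoter, "+")
            return gid

        decoys_left = config.n_decoy_hits
        for i, spec in enumerate(og_spec):
            if not presence[i, j]:
                continue
            chrom = home_chrom[spec.og_id]
            strand = "+" if i % 2 == 0 else "-"
            # background genes separate different OGs, never tandem copies
            for _ in range(int(rng.integers(1, 3))):
                append_background(chrom)
            n_attempts = int(rng.poisson(
                config.divergence * 3 * spec.codon_length))
            for copy in range(spec.copies):
                gene_counter += 1
                gid = f"{genome_id}_g{gene_counter:05d}"
                codons = evolve_cds(ancestral[spec.og_id], n_attempts,
                                    spec.omega, rng)
                if spec.copies > 1:  # extra divergence between copies
                    codons = evolve_cds(codons, max(1, n_attempts // 4),
                                        spec.omega, rng)
                cds = "".join(codons) + "TAA"
                promoter, planted = make_promoter(
                    config.promoter_bp, config.motif_spec or [],
                    spec.og_id, rng)
                append_gene(chrom, gid, cds, promoter, strand)
                qlen = spec.codon_length
                dom_lines.append(_domtbl_line(
                    gid, "Dirigent", 10.0 ** -float(rng.uniform(10, 30)),
                    qlen, 5, min(qlen, 120)))
                if spec.has_jrl:
                    jrl_lines.append(_domtbl_line(
                        gid, "JRL", 10.0 ** -float(rng.uniform(8, 20)),
                        qlen, 2, min(qlen, 60)))
                truth.og_of[gid] = spec.og_id
                truth.genome_of[gid] = genome_id
                truth.motif_counts[gid] = planted
                if spec.has_jrl:
                    truth.jrl_genes.add(gid)
                if spec.on_scaffold:
                    truth.scaffold_genes.add(gid)
            if decoys_left > 0:
                # above-threshold hit on a background gene: must be filtered
                decoy = append_background(chrom)
                dom_lines.append(_domtbl_line(
                    decoy, "Dirigent", float(rng.uniform(1e-4, 1e-2)),
                    100, 1, 50))
                decoys_left -= 1

        fasta_path = outdir / f"{genome_id}.fa"
        with open(fasta_path, "w") as fh:
            for chrom in sorted(contigs):
                seq = "".join(contigs[chrom])
                fh.write(f">{chrom}\n")
                for k in range(0, len(seq), 80):
                    fh.write(seq[k:k + 80] + "\n")
        (outdir / f"{genome_id}.gff3").write_text("\n".join(gff_lines) + "\n")
        (outdir / f"{genome_id}.domtbl").write_text("\n".join(dom_lines) + "\n")
        (outdir / f"{genome_id}.jrl.domtbl").write_text(
            "\n".join(jrl_lines) + "\n")
        manifest_genomes.append({
            "genome_id": genome_id, "fasta": f"{genome_id}.fa",
            "gff3": f"{genome_id}.gff3", "hits": f"{genome_id}.domtbl",
            "jrl_hits": f"{genome_id}.jrl.domtbl"})

    _write_truth(truth, og_spec, genome_ids, outdir)
    (outdir / "manifest.json").write_text(json.dumps({
        "seed": config.seed, "n_genomes": config.n_genomes,
        "n_ogs": len(og_spec), "divergence": config.divergence,
        "genomes": manifest_genomes}, indent=1) + "\n")
    return truth


def _write_truth(truth: SimTruth, og_spec: list[OgSpec],
                 genome_ids: list[str], outdir: Path) -> None:
    rows = [(g, truth.og_of[g], truth.genome_of[g]) for g in sorted(truth.og_of)]
    pd.DataFrame(rows, columns=["gene_id", "og_id", "genome_id"]).to_csv(
        outdir / "truth_og_membership.tsv", sep="\t", index=False)
    assert truth.presence is not None
    truth.presence.rename_axis("og_id").reset_index().to_csv(
        outdir / "truth_presence.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(truth.omega.items()),
                 columns=["og_id", "omega"]).to_csv(
        outdir / "truth_omega.tsv", sep="\t", index=False)
    motif_rows = [(g, m, c) for g in sorted(truth.motif_counts)
                  for m, c in sorted(truth.motif_counts[g].items())]
    pd.DataFrame(motif_rows, columns=["gene_id", "motif", "planted_count"]
                 ).to_csv(outdir / "truth_motifs.tsv", sep="\t", index=False)

    # Orthogroups.tsv dialect: per-OG row, per-genome comma-joined genes
    by_og: dict[str, dict[str, list[str]]] = {}
    for g, og in truth.og_of.items():
        by_og.setdefault(og, {}).setdefault(truth.genome_of[g], []).append(g)
    rows2 = []
    for og in sorted(by_og):
        row = {"Orthogroup": og}
        for gid in genome_ids:
            row[gid] = ", ".join(sorted(by_og[og].get(gid, [])))
        rows2.append(row)
    pd.DataFrame(rows2, columns=["Orthogroup"] + genome_ids).to_csv(
        outdir / "Orthogroups.tsv", sep="\t", index=False)


def simulate_omega_family(omega: float, n_genes: int = 20,
                          n_codons: int = 300, attempts: int = 45,
                          seed: int = 0) -> dict[str, str]:
    """One orthogroup of CDS diverged from a common ancestor at dN/dS omega.

    ``attempts`` is the number of substitution attempts per genome
    branch (star phylogeny); 45 attempts over 300 codons gives pairwise
    synonymous divergence well inside the Jukes-Cantor-correctable
    range.
    """
    rng = np.random.default_rng(seed)
    anc = random_cds(n_codons, rng)
    return {f"g{j:02d}": "".join(evolve_cds(anc, attempts, omega, rng))
            for j in range(n_genes)}


def simulate_signals(truth: SimTruth, outdir: str | Path,
                     genome_id: str = "line01") -> pd.DataFrame:
    """Association-signal table anchored on one genome's family genes.

    Plants in-window signals (one single-trait gene, one two-trait
    gene), a below-threshold decoy, and a signal on an unknown
    chromosome to exercise every filter branch.
    """
    from .io_formats import read_gff3

    outdir = Path(outdir)
    models = read_gff3(outdir / f"{genome_id}.gff3")
    fam = sorted(g for g, gid in truth.genome_of.items()
                 if gid == genome_id and g in models)
    rows = []
    if fam:
        r0 = models[fam[0]].record
        rows.append({"trait": "PH", "chrom": r0.chrom,
                     "pos": max(1, r0.start - 50_000), "score": 0.2})
        rows.append({"trait": "KW", "chrom": r0.chrom,
                     "pos": max(1, r0.start - 20_000), "score": 0.01})
    if len(fam) > 1:
        r1 = models[fam[1]].record
        rows.append({"trait": "DTA", "chrom": r1.chrom, "pos": r1.start,
                     "score": 0.1})
        rows.append({"trait": "PH", "chrom": r1.chrom,
                     "pos": min(r1.end + 80_000, r1.end + 80_000),
                     "score": 0.3})
    rows.append({"trait": "PH", "chrom": "chrUn", "pos": 1000, "score": 0.5})
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "signals.tsv", sep="\t", index=False)
    return df


def write_manifest(config: SimConfig, outdir: str | Path) -> Path:
    """YAML manifest pointing at every file the simulator emitted."""
    import yaml

    outdir = Path(outdir)
    genome_ids = [f"line{j + 1:02d}" for j in range(config.n_genomes)]
    manifest = {
        "seed": config.seed,
        "out_dir": "out",
        "genomes": [{"genome_id": g, "fasta": f"{g}.fa",
                     "gff3": f"{g}.gff3", "hits": f"{g}.domtbl",
                     "jrl_hits": f"{g}.jrl.domtbl"} for g in genome_ids],
        "orthogroups": "Orthogroups.tsv",
        "signals": "signals.tsv",
        "vcf": "population.vcf",
        "clusters": "clusters.tsv",
        "pop_genes": "pop_genes.tsv",
        "counts": "counts.tsv",
        "lengths": "lengths.tsv",
        "metadata": "metadata.tsv",
        "params": {"e_max": 1e-5, "identity_threshold": 90, "reps": 1000},
    }
    path = outdir / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path


# ---------------------------------------------------------------------------
# population

@dataclass
class PopGeneSpec:
    gene_id: str
    chrom: str
    start: int
    n_sites: int = 6
    n_haplotypes: int = 7   # = default n_clusters, so skew=1 is one-hot
    skew: float = 1.0       # 1 = cluster c draws only haplotype (c mod H)


@dataclass
class PopConfig:
    seed: int
    n_lines: int = 150
    n_clusters: int = 7
    genes: list[PopGeneSpec] | None = None
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.genes is None:
            self.genes = [
                PopGeneSpec("popg1", "chr1", 10_000, skew=1.0),
                PopGeneSpec("popg2", "chr1", 50_000, skew=1.0),
                PopGeneSpec("popg3", "chr2", 10_000, skew=0.0),
                PopGeneSpec("popg4", "chr2", 50_000, skew=0.0),
            ]


def simulate_population(config: PopConfig, outdir: str | Path
                        ) -> dict[str, object]:
    """Write a minimal VCF + cluster table; return planted truth.

    Each line draws one haplotype per gene from its cluster's
    distribution, a ``skew``-weighted mixture of a uniform component
    and a one-hot component on the cluster-owned haplotype
    (cluster c owns haplotype c mod n_haplotypes).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    lines = [f"IL{i + 1:03d}" for i in range(config.n_lines)]
    clusters = {line: f"HG{(i % config.n_clusters) + 1}"
                for i, line in enumerate(lines)}

    truth: dict[str, object] = {"clusters": clusters, "haplotype_of": {},
                                "skew": {}, "gene_regions": {}}
    records = []  # (chrom, pos, ref, alt, {line: gt_string})
    for spec in config.genes or []:
        if 2 ** spec.n_sites < spec.n_haplotypes:
            raise ValueError(
                f"{spec.gene_id}: {spec.n_sites} sites cannot distinguish "
                f"{spec.n_haplotypes} haplotypes")
        # distinct binary allele vectors
        codes = rng.permutation(2 ** spec.n_sites)[:spec.n_haplotypes]
        haps = [np.array([(c >> b) & 1 for b in range(spec.n_sites)])
                for c in codes]
        H, K = spec.n_haplotypes, config.n_clusters
        # cluster c "owns" haplotype c mod H; at skew = 1 and H = K the
        # haplotype-by-cluster table is exactly one-hot
        weights = np.full((K, H), (1.0 - spec.skew) / H)
        for c in range(K):
            weights[c, c % H] += spec.skew
        weights /= weights.sum(axis=1, keepdims=True)

        hap_of = {}
        geno = {}
        for i, line in enumerate(lines):
            c = i % K
            h = int(rng.choice(H, p=weights[c]))
            hap_of[line] = h
            geno[line] = haps[h]
        truth["haplotype_of"][spec.gene_id] = hap_of
        truth["skew"][spec.gene_id] = spec.skew
        end = spec.start + 100 * (spec.n_sites - 1)
        truth["gene_regions"][spec.gene_id] = (spec.chrom, spec.start, end)
        for s in range(spec.n_sites):
            pos = spec.start + 100 * s
            gts = {}
            for line in lines:
                if rng.random() < config.missing_rate:
                    gts[line] = "./."
                else:
                    a = int(geno[line][s])
                    gts[line] = f"{a}/{a}"
            records.append((spec.chrom, pos, "A", "T", gts))

    records.sort(key=lambda r: (r[0], r[1]))
    chroms = sorted({r[0] for r in records})
    with open(outdir / "population.vcf", "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom},length=1000000>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(lines) + "\n")
        for chrom, pos, ref, alt, gts in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts[l] for l in lines) + "\n")
    pd.DataFrame(sorted(clusters.items()), columns=["line_id", "cluster"]
                 ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    regions = [(g, *truth["gene_regions"][g])
               for g in sorted(truth["gene_regions"])]  # type: ignore[index]
    pd.DataFrame(regions, columns=["gene_id", "chrom", "start", "end"]
                 ).to_csv(outdir / "pop_genes.tsv", sep="\t", index=False)
    return truth


# ---------------------------------------------------------------------------
# expression counts

@dataclass
class CountsConfig:
    seed: int
    n_genes: int = 40
    # Background (non-family, effect-free) genes emulate the rest of the
    # transcriptome so planted effects do not perturb library sizes.
    n_background: int = 400
    n_root_specific: int = 8     # planted tissue effect
    n_salt_induced: int = 8      # planted stress effect (root, salt)
    tissue_fold: float = 8.0
    stress_log2fc: float = 2.0
    dispersion: float = 0.05
    n_reps: int = 3
    tissues: tuple[str, ...] = ("embryo", "leaf", "root", "tassel",
                                "stem", "silk")
    organs: tuple[str, ...] = ("root", "shoot")
    treatments: tuple[str, ...] = ("control", "salt", "mannitol")


def _nb_draw(mu: np.ndarray, dispersion: float,
             rng: np.random.Generator) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_counts(config: CountsConfig, outdir: str | Path
                    ) -> dict[str, object]:
    """Write counts/lengths/metadata TSVs; return planted truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genes = ([f"eg{i + 1:03d}" for i in range(config.n_genes)]
             + [f"bg{i + 1:03d}" for i in range(config.n_background)])
    n_total = len(genes)
    lengths = pd.Series(rng.integers(600, 3000, size=n_total),
                        index=genes, name="length_bp")
    base = rng.lognormal(mean=np.log(200), sigma=0.8, size=n_total)
    root_specific = set(genes[:config.n_root_specific])
    salt_induced = set(genes[config.n_root_specific:
                             config.n_root_specific + config.n_salt_induced])

    samples, meta_rows = [], []
    cols: dict[str, np.ndarray] = {}
    per_kb = lengths.values / 1000.0

    for tissue in config.tissues:
        for rep in range(1, config.n_reps + 1):
            name = f"{tissue}_r{rep}"
            mu = base * per_kb
            boost = np.array([config.tissue_fold if (g in root_specific
                              and tissue == "root") else 1.0 for g in genes])
            cols[name] = _nb_draw(mu * boost, config.dispersion, rng)
            samples.append(name)
            meta_rows.append({"sample": name, "tissue": tissue,
                              "organ": "", "treatment": ""})
    for organ in config.organs:
        for treatment in config.treatments:
            for rep in range(1, config.n_reps + 1):
                name = f"{organ}_{treatment}_r{rep}"
                fc = np.array([
                    2.0 ** config.stress_log2fc
                    if (g in salt_induced and treatment == "salt"
                        and organ == "root") else 1.0
                    for g in genes])
                cols[name] = _nb_draw(base * per_kb * fc,
                                      config.dispersion, rng)
                samples.append(name)
                meta_rows.append({"sample": name, "tissue": "",
                                  "organ": organ, "treatment": treatment})

    counts = pd.DataFrame(cols, index=genes)
    counts.rename_axis("gene_id").reset_index().to_csv(
        outdir / "counts.tsv", sep="\t", index=False)
    lengths.rename_axis("gene_id").reset_index().to_csv(
        outdir / "lengths.tsv", sep="\t", index=False)
    pd.DataFrame(meta_rows).to_csv(outdir / "metadata.tsv", sep="\t",
                                   index=False)
    return {"root_specific": root_specific, "salt_induced": salt_induced,
            "base": dict(zip(genes, base)), "counts": counts,
            "lengths": lengths,
            "metadata": pd.DataFrame(meta_rows)}
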