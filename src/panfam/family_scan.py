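"""From domain hits + annotation + genome sequence to validated family genes.

A gene enters the family when at least one domain hit passes the
E-value filter (default E <= 1e-5, inclusive, on the per-domain
independent E-value).  Each family gene carries its spliced CDS,
protein, 2 kb upstream promoter (in transcript orientation), its
passing domain hits, a co-domain (JRL) flag, and physicochemical
properties of the protein.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from ._seq import revcomp, translate_cds, trim_terminal_stop
from .io_formats import DomainHit, GeneModel

logger = logging.getLogger(__name__)

E_MAX_DEFAULT = 1e-5
UPSTREAM_BP = 2000
CHROM_REGEX_DEFAULT = r"^chr([0-9]+)$"

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

# EMBOSS pKa set; the pI is the unique zero of the monotonically
# decreasing net-charge curve over these groups.
PKA_POSITIVE = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}


@dataclass(frozen=True)
class PhysChem:
    """Protein physicochemical summary.

    mw_kda: average-mass molecular weight in kDa.
    pi: isoelectric point (bisection over the EMBOSS pKa set).
    instability: Guruprasad instability index.
    gravy: mean Kyte-Doolittle hydropathy; hydrophilic <=> gravy < 0.
    """

    mw_kda: float
    pi: float
    instability: float
    gravy: float

    @property
    def hydrophilic(self) -> bool:
        return self.gravy < 0


@dataclass
class FamilyGene:
    """One family member with its sequences, domains and properties."""

    gene_id: str
    genome_id: str
    model: GeneModel
    protein: str
    cds: str
    upstream2kb: str
    upstream_truncated: bool
    domains: list[DomainHit] = field(default_factory=list)
    has_jrl: bool = False
    properties: PhysChem | None = None
    on_scaffold: bool = False

    @property
    def record(self):
        return self.model.record


class InternalStopError(ValueError):
    """CDS translates with an internal stop codon."""


def filter_hits(hits: Iterable[DomainHit],
                e_max: float = E_MAX_DEFAULT) -> list[DomainHit]:
    """Keep domain hits with e_value <= e_max (inclusive threshold).

    A gene may retain multiple hits (tandem domain architectures are
    real in this family), so no per-gene deduplication is done.
    """
    return [h for h in hits if h.e_value <= e_max]


def flag_jrl(gene_id: str, jrl_hits: Iterable[DomainHit],
             e_max: float = E_MAX_DEFAULT) -> bool:
    """True iff the gene has >= 1 co-domain hit passing the same filter."""
    return any(h.gene_id == gene_id and h.e_value <= e_max for h in jrl_hits)


def extract_sequences(genome: Mapping[str, str], model: GeneModel
                      ) -> tuple[str, str, str, bool]:
    """Return (protein, cds, upstream2kb, upstream_truncated) for a gene.

    The CDS is spliced in transcript orientation (reverse-complemented
    per segment on the minus strand).  The promoter is the 2000 bp
    5' of the CDS start in transcript orientation, truncated (and
    flagged) at the contig edge.  A CDS with an internal stop raises
    :class:`InternalStopError`.
    """
    rec = model.record
    if rec.chrom not in genome:
        raise KeyError(f"contig {rec.chrom} missing from genome FASTA")
    contig = genome[rec.chrom]
    if not model.cds_segments:
        raise ValueError(f"gene {rec.gene_id} has no CDS")

    if rec.strand == "+":
        cds = "".join(contig[s - 1:e] for s, e in model.cds_segments)
        cds_start = model.cds_segments[0][0]          # 1-based
        up_lo = max(0, cds_start - 1 - UPSTREAM_BP)
        upstream = contig[up_lo:cds_start - 1]
        truncated = cds_start - 1 < UPSTREAM_BP
    else:
        cds = "".join(revcomp(contig[s - 1:e]) for s, e in model.cds_segments)
        cds_start = model.cds_segments[0][1]          # rightmost base
        upstream = revcomp(contig[cds_start:cds_start + UPSTREAM_BP])
        truncated = len(contig) - cds_start < UPSTREAM_BP

    coding = trim_terminal_stop(cds)
    if len(coding) % 3 != 0:
        raise ValueError(f"gene {rec.gene_id}: CDS length {len(coding)} "
                         "not divisible by 3")
    protein = translate_cds(coding)
    if "*" in protein:
        raise InternalStopError(
            f"gene {rec.gene_id}: internal stop at residue "
            f"{protein.index('*') + 1}")
    return protein, coding, upstream, truncated


def _net_charge(protein: str, ph: float) -> float:
    counts = {aa: protein.count(aa) for aa in "KRHDECY"}
    charge = 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (PKA_NEGATIVE["Cterm"] - ph))
    for aa in "KRH":
        charge += counts[aa] / (1.0 + 10 ** (ph - PKA_POSITIVE[aa]))
    for aa in "DECY":
        charge -= counts[aa] / (1.0 + 10 ** (PKA_NEGATIVE[aa] - ph))
    return charge


def isoelectric_point(protein: str, tol: float = 1e-4) -> float:
    """pI by bisection of the net charge on [0, 14] to |charge| < tol."""
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = _net_charge(protein, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def physchem(protein: str) -> PhysChem:
    """Physicochemical properties of a protein (standard 20 residues only)."""
    if not protein:
        raise ValueError("empty protein")
    bad = set(protein) - STANDARD_AA
    if bad:
        raise ValueError(f"nonstandard residue {sorted(bad)[0]!r} in protein")
    pa = ProteinAnalysis(protein)
    return PhysChem(
        mw_kda=pa.molecular_weight() / 1000.0,
        pi=isoelectric_point(protein),
        instability=pa.instability_index(),
        gravy=pa.gravy(),
    )


def scan_genome(genome_id: str,
                genome: Mapping[str, str],
                models: Mapping[str, GeneModel],
                hits: Iterable[DomainHit],
                jrl_hits: Iterable[DomainHit] = (),
                e_max: float = E_MAX_DEFAULT,
                chrom_regex: str = CHROM_REGEX_DEFAULT) -> list[FamilyGene]:
    """Assemble :class:`FamilyGene` records for one genome.

    Genes with an internal-stop CDS are excluded with a warning; genes
    whose chromosome name does not match ``chrom_regex`` (after
    lowercasing) are flagged ``on_scaffold``.
    """
    passing = filter_hits(hits, e_max)
    by_gene: dict[str, list[DomainHit]] = {}
    for h in passing:
        by_gene.setdefault(h.gene_id, []).append(h)
    jrl_list = filter_hits(jrl_hits, e_max)
    chrom_pat = re.compile(chrom_regex)

    genes: list[FamilyGene] = []
    for gene_id in sorted(by_gene):
        if gene_id not in models:
            raise KeyError(f"hit gene {gene_id} absent from annotation")
        model = models[gene_id]
        try:
            protein, cds, upstream, truncated = extract_sequences(genome, model)
        except InternalStopError as exc:
            logger.warning("excluding %s: %s", gene_id, exc)
            continue
        genes.append(FamilyGene(
            gene_id=gene_id,
            genome_id=genome_id,
            model=model,
            protein=protein,
            cds=cds,
            upstream2kb=upstream,
            upstream_truncated=truncated,
            domains=by_gene[gene_id],
            has_jrl=any(h.gene_id == gene_id for h in jrl_list),
            properties=physchem(protein),
            on_scaffold=chrom_pat.match(model.record.chrom.lower()) is None,
        ))
    return genes


def genes_to_frame(genes: Iterable[FamilyGene]) -> pd.DataFrame:
    rows = []
    for g in genes:
        r = g.record
        p = g.properties
        rows.append({
            "gene_id": g.gene_id, "genome_id": g.genome_id,
            "chrom": r.chrom, "start": r.start, "end": r.end,
            "strand": r.strand, "rank": r.rank,
            "n_domains": len(g.domains), "has_jrl": g.has_jrl,
            "on_scaffold": g.on_scaffold,
            "mw_kda": round(p.mw_kda, 2) if p else None,
            "pi": round(p.pi, 2) if p else None,
            "instability": round(p.instability, 2) if p else None,
            "gravy": round(p.gravy, 3) if p else None,
            "hydrophilic": p.hydrophilic if p else None,
            "upstream_truncated": g.upstream_truncated,
        })
    return pd.DataFrame(rows)


# --- cohort arithmetic -------------------------------------------------------

def mean_genes_per_line(total_genes: int, n_lines: int) -> float:
    """Average family size per genome."""
    if n_lines <= 0:
        raise ValueError("n_lines must be positive")
    return total_genes / n_lines


def jrl_percentage(n_jrl: int, total_genes: int) -> float:
    """Percent of family genes carrying the co-domain."""
    if total_genes <= 0:
        raise ValueError("total_genes must be positive")
    return 100.0 * n_jrl / total_genes


def scaffold_gene_count(total_genes: int, n_on_chromosomes: int) -> int:
    """Family genes on unplaced scaffolds."""
    n = total_genes - n_on_chromosomes
    if n < 0:
        raise ValueError("more genes on chromosomes than total")
    return n
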