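"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates in the data model are 1-based inclusive (the
native convention of GFF3 and VCF); readers convert at the boundary.
Strand is ``+`` or ``-``.  All tabular writers emit TSV with a single
``#``-prefixed provenance header line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO

__all__ = [
    "GeneRecord",
    "GeneModel",
    "DomainHit",
    "VariantCall",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "read_domtblout",
    "read_vcf_minimal",
    "read_tsv",
    "write_tsv",
]


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene.

    ``rank`` is the 1-based position of the gene in chromosome order
    among ALL annotated genes of that chromosome (used by the
    tandem-duplication rank-distance rule).
    """

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str
    rank: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class GeneModel:
    """A gene plus the CDS segments of its representative transcript.

    ``cds_segments`` are (start, end) pairs, 1-based inclusive, ordered
    5'->3' in transcript orientation (descending start on the minus
    strand).  The representative transcript is the one with the longest
    summed CDS; one protein per gene.
    """

    record: GeneRecord
    transcript_id: str | None = None
    cds_segments: list[tuple[int, int]] = field(default_factory=list)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM domain hit on a gene's protein."""

    gene_id: str
    domain_name: str
    e_value: float
    ali_start: int
    ali_end: int

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"negative E-value {self.e_value}")
        if self.ali_start > self.ali_end:
            raise ValueError(
                f"hit on {self.gene_id}: ali_start > ali_end")


@dataclass
class VariantCall:
    """One variant site with collapsed haploid calls for inbred lines.

    ``genotypes`` maps sample -> allele index (0 = ref) or None for
    missing; heterozygous diploid calls are treated as missing.
    """

    chrom: str
    pos: int
    ref: str
    alt: list[str]
    genotypes: dict[str, int | None]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase-sequence map.

    Raises ``ValueError`` on duplicate ids or empty records.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate id {rec.id} in {path}")
        seq = str(rec.seq).upper().replace(" ", "")
        if not seq:
            raise ValueError(f"empty record {rec.id} in {path}")
        seqs[rec.id] = seq
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str | Path) -> dict[str, GeneModel]:
    """Parse a GFF3 file with gene/mRNA/CDS features.

    Returns gene_id -> :class:`GeneModel`.  Ranks are assigned per
    chromosome by ascending gene start over ALL genes in the file; CDS
    segments of the longest-CDS transcript are ordered 5'->3' in
    transcript orientation.  A CDS whose Parent is unknown, or any
    feature with end < start, is an error.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique", force=True)

    for feat in db.all_features():
        if feat.end < feat.start:
            raise ValueError(
                f"{path}: feature {feat.id} has end {feat.end} < start {feat.start}")

    known = {f.id for f in db.all_features()}
    for cds in db.features_of_type("CDS"):
        for parent in cds.attributes.get("Parent", []):
            if parent not in known:
                raise ValueError(f"{path}: CDS with unknown Parent {parent}")

    models: dict[str, GeneModel] = {}
    per_chrom: dict[str, list[GeneRecord]] = {}
    for gene in db.features_of_type("gene"):
        rec = GeneRecord(gene_id=gene.id, chrom=gene.seqid,
                         start=gene.start, end=gene.end, strand=gene.strand)
        best: tuple[int, str, list[tuple[int, int]]] | None = None
        for mrna in db.children(gene, featuretype="mRNA"):
            segs = sorted((c.start, c.end)
                          for c in db.children(mrna, featuretype="CDS"))
            length = sum(e - s + 1 for s, e in segs)
            if segs and (best is None or length > best[0]
                         or (length == best[0] and mrna.id < best[1])):
                best = (length, mrna.id, segs)
        model = GeneModel(record=rec)
        if best is not None:
            segs = best[2]
            if rec.strand == "-":
                segs = segs[::-1]
            model.transcript_id = best[1]
            model.cds_segments = segs
        models[gene.id] = model
        per_chrom.setdefault(rec.chrom, []).append(rec)

    for chrom, recs in per_chrom.items():
        recs.sort(key=lambda r: (r.start, r.end, r.gene_id))
        for i, rec in enumerate(recs, start=1):
            object.__setattr__(rec, "rank", i)
    return models


# ---------------------------------------------------------------------------
# HMMER domtblout

_DOMTBL_MIN_FIELDS = 23


def read_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse HMMER ``--domtblout`` output into :class:`DomainHit` rows.

    The per-domain independent E-value (column 13) is stored as
    ``e_value`` — the family filter is a domain filter, not a
    full-sequence one.  Alignment coordinates are the ``ali from/to``
    columns (1-based residue positions).
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < _DOMTBL_MIN_FIELDS:
                raise ValueError(
                    f"{path}:{lineno}: truncated domtblout line "
                    f"({len(fields)} fields)")
            try:
                e_value = float(fields[12])     # i-Evalue (independent)
                ali_start = int(fields[17])
                ali_end = int(fields[18])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed numeric field: {exc}") from None
            hits.append(DomainHit(
                gene_id=fields[0], domain_name=fields[3],
                e_value=e_value, ali_start=ali_start, ali_end=ali_end))
    return hits


# ---------------------------------------------------------------------------
# VCF (GT-only minimal dialect)

def read_vcf_minimal(path: str | Path) -> tuple[list[VariantCall], list[str]]:
    """Read a VCF keeping only GT, collapsing inbred diploid calls.

    Homozygous diploid genotypes collapse to a single allele index;
    heterozygous or missing ("./." or any missing allele) become None.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"{path}: not a parseable VCF: {exc}") from None
    samples = list(vf.header.samples)
    calls: list[VariantCall] = []
    for rec in vf:
        genotypes: dict[str, int | None] = {}
        for sample in samples:
            gt = rec.samples[sample].get("GT", (None,))
            alleles = set(gt)
            if None in alleles or len(alleles) != 1:
                genotypes[sample] = None
            else:
                allele = alleles.pop()
                n_alt = len(rec.alts or ())
                if allele > n_alt:
                    raise ValueError(
                        f"{path}: allele index {allele} out of range at "
                        f"{rec.chrom}:{rec.pos}")
                genotypes[sample] = allele
        calls.append(VariantCall(
            chrom=rec.chrom, pos=rec.pos, ref=rec.ref or "",
            alt=list(rec.alts or ()), genotypes=genotypes))
    return calls, samples


# ---------------------------------------------------------------------------
# TSV tables

def write_tsv(df: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    """Write a DataFrame as TSV with an optional '#' provenance line."""
    with open(path, "w") as fh:
        if header:
            fh.write("# " + header.rstrip("\n") + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def genes_to_frame(records: Iterable[GeneRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_id, r.chrom, r.start, r.end, r.strand, r.rank)
         for r in records],
        columns=["gene_id", "chrom", "start", "end", "strand", "rank"])
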