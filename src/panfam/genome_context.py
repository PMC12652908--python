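"""Genomic context: tandem duplicates and association-signal windows.

Tandem detection uses a rank-distance rule: two family genes are a
tandem pair when they share an orthogroup and a chromosome and at most
``max_intervening`` annotated genes (over the FULL annotation, not just
family members) lie between them; clusters are the transitive closure
of that relation.

Candidate-gene selection keeps association signals at or above a score
threshold (resample model inclusion probability, default 0.05) and
reports genes whose interval, extended by the window (default 100 kb,
inclusive at both ends), contains the signal position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

SCORE_MIN_DEFAULT = 0.05
WINDOW_DEFAULT = 100_000
MAX_INTERVENING_DEFAULT = 5


@dataclass(frozen=True)
class AssociationSignal:
    trait: str
    chrom: str
    pos: int
    score: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("signal position must be >= 1")


@dataclass
class TandemCluster:
    genome_id: str
    chrom: str
    og_id: str
    members: list[str]  # ordered by rank


@dataclass(frozen=True)
class CandidateHit:
    gene_id: str
    trait: str
    chrom: str
    signal_pos: int
    distance: int  # bp to nearest gene edge; 0 when overlapping


def find_tandem(genes: Sequence, og_of: Mapping[str, str],
                max_intervening: int = MAX_INTERVENING_DEFAULT
                ) -> list[TandemCluster]:
    """Tandem clusters among one genome's family genes.

    ``genes`` are FamilyGene-like objects (gene_id, genome_id, record
    with chrom/rank).  Genes without an orthogroup (singletons) cannot
    be tandem.  Ranks must have been computed over the full annotation.
    """
    g = nx.Graph()
    info = {}
    for gene in genes:
        rec = gene.record
        if rec.rank <= 0:
            raise ValueError(f"gene {gene.gene_id} has no annotation rank")
        if gene.gene_id not in og_of:
            continue
        info[gene.gene_id] = (gene.genome_id, rec.chrom,
                              og_of[gene.gene_id], rec.rank)
        g.add_node(gene.gene_id)
    ids = sorted(info)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ga, ca, oa, ra = info[a]
            gb, cb, ob, rb = info[b]
            if ca == cb and oa == ob and abs(ra - rb) - 1 <= max_intervening:
                g.add_edge(a, b)
    clusters = []
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        members = sorted(comp, key=lambda x: info[x][3])
        genome_id, chrom, og_id, _ = info[members[0]]
        clusters.append(TandemCluster(genome_id=genome_id, chrom=chrom,
                                      og_id=og_id, members=members))
    clusters.sort(key=lambda c: (c.chrom, c.og_id, c.members))
    return clusters


def tandem_gene_counts(clusters: Iterable[TandemCluster]) -> pd.DataFrame:
    """Per-genome number of genes involved in tandem clusters."""
    rows: dict[str, int] = {}
    for c in clusters:
        rows[c.genome_id] = rows.get(c.genome_id, 0) + len(c.members)
    return pd.DataFrame(sorted(rows.items()),
                        columns=["genome_id", "n_tandem_genes"])


def select_candidates(genes: Sequence, signals: Iterable[AssociationSignal],
                      score_min: float = SCORE_MIN_DEFAULT,
                      window: int = WINDOW_DEFAULT) -> list[CandidateHit]:
    """Family genes within ``window`` bp (inclusive) of significant signals."""
    by_chrom: dict[str, list] = {}
    for gene in genes:
        by_chrom.setdefault(gene.record.chrom, []).append(gene)
    hits: list[CandidateHit] = []
    for sig in signals:
        if sig.score < score_min:
            continue
        if sig.chrom not in by_chrom:
            logger.warning("signal chromosome %s has no genes; skipped",
                           sig.chrom)
            continue
        for gene in by_chrom[sig.chrom]:
            rec = gene.record
            if rec.start - window <= sig.pos <= rec.end + window:
                if rec.start <= sig.pos <= rec.end:
                    dist = 0
                else:
                    dist = min(abs(sig.pos - rec.start),
                               abs(sig.pos - rec.end))
                hits.append(CandidateHit(
                    gene_id=gene.gene_id, trait=sig.trait, chrom=sig.chrom,
                    signal_pos=sig.pos, distance=dist))
    hits.sort(key=lambda h: (h.gene_id, h.trait, h.signal_pos))
    return hits


def trait_summary(hits: Iterable[CandidateHit]) -> pd.DataFrame:
    """Distinct-trait counts per candidate gene, single vs multi-trait."""
    traits: dict[str, set[str]] = {}
    for h in hits:
        traits.setdefault(h.gene_id, set()).add(h.trait)
    rows = [{"gene_id": g, "n_traits": len(ts),
             "traits": ",".join(sorted(ts)),
             "multi_trait": len(ts) > 1}
            for g, ts in sorted(traits.items())]
    return pd.DataFrame(rows)


def read_signals_tsv(path) -> list[AssociationSignal]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [AssociationSignal(trait=str(r["trait"]), chrom=str(r["chrom"]),
                              pos=int(r["pos"]), score=float(r["score"]))
            for _, r in df.iterrows()]
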