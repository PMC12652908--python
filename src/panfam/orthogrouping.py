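"""Orthogroup refinement by pairwise protein identity.

Orthogroups (externally supplied in Orthogroups.tsv dialect, or built
de novo) are subdivided so that every retained group is a single-linkage
component of the ">= threshold percent identity" graph (default 90%).
Groups must have at least two members; components of size one become
singletons.  Identity is computed over a global alignment (BLOSUM62,
gap open 10, gap extend 0.5) as identical columns / alignment length,
with gap columns counted in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

IDENTITY_THRESHOLD_DEFAULT = 90.0


@dataclass
class OrthogroupSet:
    """A partition of genes into orthogroups (>= 2 members) + singletons."""

    ogs: dict[str, list[str]] = field(default_factory=dict)
    singletons: list[str] = field(default_factory=list)

    def validate(self) -> None:
        seen: set[str] = set()
        for og_id, members in self.ogs.items():
            if len(members) < 2:
                raise ValueError(f"orthogroup {og_id} has < 2 members")
            for g in members:
                if g in seen:
                    raise ValueError(f"gene {g} in more than one group")
                seen.add(g)
        for g in self.singletons:
            if g in seen:
                raise ValueError(f"gene {g} both grouped and singleton")
            seen.add(g)

    @property
    def n_genes(self) -> int:
        return sum(len(m) for m in self.ogs.values()) + len(self.singletons)

    def og_of(self) -> dict[str, str]:
        return {g: og for og, members in self.ogs.items() for g in members}


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = make_aligner()


def pairwise_identity(protein_a: str, protein_b: str) -> float:
    """Percent identity of the optimal global alignment of two proteins.

    identity = 100 * identical columns / alignment length; gap columns
    count in the denominator.  Deterministic: the first optimal
    traceback of the aligner is used.
    """
    if not protein_a or not protein_b:
        raise ValueError("empty protein sequence")
    aln = _ALIGNER.align(protein_a, protein_b)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


def identity_matrix(proteins: Mapping[str, str],
                    gene_ids: Sequence[str] | None = None
                    ) -> dict[tuple[str, str], float]:
    """Symmetric percent-identity map over all unordered gene pairs."""
    ids = list(gene_ids) if gene_ids is not None else sorted(proteins)
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        out[(a, a)] = 100.0
        for b in ids[i + 1:]:
            ident = pairwise_identity(proteins[a], proteins[b])
            out[(a, b)] = ident
            out[(b, a)] = ident
    return out


def _components(members: Sequence[str],
                identities: Mapping[tuple[str, str], float],
                threshold: float) -> list[list[str]]:
    g = nx.Graph()
    g.add_nodes_from(members)
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            if identities[(a, b)] >= threshold:
                g.add_edge(a, b)
    return [sorted(c) for c in nx.connected_components(g)]


def subdivide(members: Sequence[str],
              identities: Mapping[tuple[str, str], float],
              threshold: float = IDENTITY_THRESHOLD_DEFAULT
              ) -> tuple[list[list[str]], list[str]]:
    """Split one orthogroup into single-linkage sub-groups + singletons."""
    comps = sorted(_components(members, identities, threshold))
    subs = [c for c in comps if len(c) >= 2]
    singles = [c[0] for c in comps if len(c) == 1]
    return subs, singles


def refine(ogset: OrthogroupSet,
           proteins: Mapping[str, str],
           threshold: float = IDENTITY_THRESHOLD_DEFAULT) -> OrthogroupSet:
    """Apply the subdivision rule to every orthogroup of a partition.

    Sub-group ids are ``<parent>.<k>`` when a group splits and the
    parent id when it does not; new singletons join the singleton list.
    """
    out = OrthogroupSet(singletons=list(ogset.singletons))
    for og_id in sorted(ogset.ogs):
        members = ogset.ogs[og_id]
        idents = identity_matrix(proteins, sorted(members))
        subs, singles = subdivide(sorted(members), idents, threshold)
        if len(subs) == 1 and not singles:
            out.ogs[og_id] = subs[0]
        else:
            for k, sub in enumerate(subs, start=1):
                out.ogs[f"{og_id}.{k}"] = sub
        out.singletons.extend(singles)
    out.singletons.sort()
    out.validate()
    return out


def cluster_denovo(proteins: Mapping[str, str],
                   threshold: float = IDENTITY_THRESHOLD_DEFAULT
                   ) -> OrthogroupSet:
    """Single-linkage clustering of all proteins at >= threshold identity.

    A fallback when no external orthogroup assignment is supplied; it is
    not equivalent to Markov clustering on BLAST graphs, only to the
    subdivision rule applied to one all-encompassing group.
    """
    ids = sorted(proteins)
    idents = identity_matrix(proteins, ids)
    comps = sorted(_components(ids, idents, threshold),
                   key=lambda c: (-len(c), c))
    out = OrthogroupSet()
    k = 1
    for comp in comps:
        if len(comp) >= 2:
            out.ogs[f"OG{k:04d}"] = comp
            k += 1
        else:
            out.singletons.append(comp[0])
    out.singletons.sort()
    out.validate()
    return out


def mean_og_size(total_genes: int, n_singletons: int, n_ogs: int) -> float:
    """Average number of genes per orthogroup (singletons excluded)."""
    if n_ogs <= 0:
        raise ValueError("n_ogs must be positive")
    return (total_genes - n_singletons) / n_ogs


# ---------------------------------------------------------------------------
# Orthogroups.tsv dialect (one row per OG; per-genome comma-separated genes)

def read_orthogroups_tsv(path: str | Path) -> OrthogroupSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    og_col = df.columns[0]
    out = OrthogroupSet()
    for _, row in df.iterrows():
        members: list[str] = []
        for col in df.columns[1:]:
            cell = row[col]
            if isinstance(cell, str) and cell.strip():
                members.extend(g.strip() for g in cell.split(",") if g.strip())
        if len(members) >= 2:
            out.ogs[str(row[og_col])] = sorted(members)
        elif members:
            out.singletons.append(members[0])
    out.singletons.sort()
    out.validate()
    return out


def write_ogset_tsv(ogset: OrthogroupSet, path: str | Path,
                    header: str | None = None) -> None:
    rows = [(og, g) for og in sorted(ogset.ogs) for g in ogset.ogs[og]]
    rows += [("singleton", g) for g in ogset.singletons]
    df = pd.DataFrame(rows, columns=["og_id", "gene_id"])
    with open(path, "w") as fh:
        if header:
            fh.write("# " + header + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_ogset_tsv(path: str | Path) -> OrthogroupSet:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    out = OrthogroupSet()
    for og_id, sub in df.groupby("og_id"):
        genes = sorted(sub["gene_id"])
        if og_id == "singleton":
            out.singletons.extend(genes)
        else:
            out.ogs[str(og_id)] = genes
    out.singletons.sort()
    out.validate()
    return out
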