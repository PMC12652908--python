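"""Promoter cis-element scanning against a packaged IUPAC motif table.

Promoters are the 2000 bp upstream of the CDS start.  The packaged
table (``data/motifs.tsv``) seeds ~30 canonical plant elements, each
assigned one category (hormone / stress / light / development / core);
it is an editable convention, not a clone of any web catalogue.
Matching is exact IUPAC matching of all (possibly overlapping)
occurrences on the given strand plus its reverse complement; an ``N``
in the sequence matches nothing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._seq import revcomp

CATEGORIES = ("hormone", "stress", "light", "development", "core")

# IUPAC code -> concrete nucleotide set; sequence N matches nothing.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class MotifDef:
    name: str
    iupac: str
    category: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError(f"motif {self.name}: empty pattern")
        bad = set(self.iupac.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"motif {self.name}: invalid IUPAC {bad}")
        if self.category not in CATEGORIES:
            raise ValueError(f"motif {self.name}: unknown category "
                             f"{self.category}")


def load_motifs(path: str | Path | None = None) -> list[MotifDef]:
    """Load a motif table (name, iupac, category); default = packaged."""
    if path is None:
        with resources.files("panfam.data").joinpath("motifs.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    return [MotifDef(r["name"], r["iupac"].upper(), r["category"])
            for _, r in df.iterrows()]


def _pattern(iupac: str) -> re.Pattern:
    # lookahead makes overlapping matches countable
    return re.compile("(?=" + "".join(
        f"[{IUPAC[c]}]" for c in iupac.upper()) + ")")


def count_matches(seq: str, iupac: str) -> int:
    """Overlapping exact-IUPAC matches on both strands of ``seq``."""
    seq = seq.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence contains characters outside {A,C,G,T,N}")
    pat = _pattern(iupac)
    rc_pat = _pattern(revcomp(iupac))
    return len(pat.findall(seq)) + len(rc_pat.findall(seq))


def scan(seq: str, motifs: Iterable[MotifDef]) -> dict[str, int]:
    """Per-motif both-strand match counts for one promoter."""
    return {m.name: count_matches(seq, m.iupac) for m in motifs}


def scan_promoters(promoters: Mapping[str, str],
                   motifs: Iterable[MotifDef]) -> pd.DataFrame:
    """gene x motif count table (genes as rows)."""
    motifs = list(motifs)
    rows = {gid: scan(seq, motifs) for gid, seq in promoters.items()}
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    df.index.name = "gene_id"
    return df.sort_index()


def og_category_profile(hits: pd.DataFrame, ogset,
                        motifs: Iterable[MotifDef]) -> pd.DataFrame:
    """OG x category proportion matrix.

    The proportion for (orthogroup, category) is the fraction of member
    genes with >= 1 hit to any motif of that category.
    """
    motifs = list(motifs)
    by_cat: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    for m in motifs:
        by_cat[m.category].append(m.name)
    rows = []
    for og_id in sorted(ogset.ogs):
        members = [g for g in ogset.ogs[og_id] if g in hits.index]
        row: dict[str, object] = {"og_id": og_id, "n_members": len(members)}
        for cat in CATEGORIES:
            cols = [c for c in by_cat[cat] if c in hits.columns]
            if members and cols:
                has = (hits.loc[members, cols].sum(axis=1) > 0)
                row[cat] = float(has.mean())
            else:
                row[cat] = 0.0
        rows.append(row)
    return pd.DataFrame(rows)
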