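"""Pairwise Ka/Ks by the Nei-Gojobori (NG86) counting method.

Codon alignments are built by back-threading CDS onto a global protein
alignment.  For each gap-free, unambiguous codon pair the method counts

* synonymous/nonsynonymous *sites* per codon: at each of the three
  positions, the fraction of the alternative nucleotides whose change
  is synonymous, with mutations to stop codons excluded from the
  denominator; site totals are averaged between the two sequences, so
  S + N = 3 x (compared codons) exactly;
* synonymous/nonsynonymous *differences*: for codon pairs differing at
  d positions, the d! substitution orders are averaged with equal
  weight; orders passing through a stop codon are excluded (if every
  order is excluded, all are kept as a fallback).

Proportions pS = Sd/S and pN = Nd/N are Jukes-Cantor corrected,
Ks = -(3/4) ln(1 - (4/3) pS) (same for Ka); omega = Ka/Ks.  Undefined
ratios (Ks = 0, or a saturated correction) are reported through a
status flag, never as numeric infinity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations
from math import log

import pandas as pd

from ._seq import CODON_TO_AA, SENSE_CODONS, STOP_CODONS, translate_cds, trim_terminal_stop
from .orthogrouping import make_aligner

logger = logging.getLogger(__name__)

_NUCS = "ACGT"
GAP_CODON = "---"


@dataclass
class CodonAlignment:
    """A pair of gapped codon strings (gaps in whole-codon units)."""

    id_a: str
    id_b: str
    codons_a: str
    codons_b: str

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon rows differ in length")
        if len(self.codons_a) % 3 != 0:
            raise ValueError("codon alignment length not divisible by 3")


@dataclass
class KaKsResult:
    """NG86 counts and rates for one sequence pair.

    ``ratio`` is None unless ``status == "ok"``.
    """

    id_a: str
    id_b: str
    n_codons: int          # comparable (gap-free, unambiguous) codon pairs
    S: float               # synonymous sites
    N: float               # nonsynonymous sites
    Sd: float              # synonymous differences
    Nd: float              # nonsynonymous differences
    pS: float
    pN: float
    Ks: float | None
    Ka: float | None
    ratio: float | None
    status: str            # ok | ks_zero | saturated | no_sites


@lru_cache(maxsize=None)
def syn_site_fraction(codon: str) -> float:
    """Synonymous-site count of one sense codon (0..3).

    Per position: (# synonymous alternatives) / (# non-stop
    alternatives); summed over the three positions.
    """
    aa = CODON_TO_AA[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        non_stop = 0
        for nuc in _NUCS:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            non_stop += 1
            if CODON_TO_AA[alt] == aa:
                syn += 1
        if non_stop:
            total += syn / non_stop
    return total


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, averaged over substitution orders.

    Orders whose intermediate codons are stops are excluded; if that
    excludes every order, all orders are kept.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool
             ) -> tuple[float, float] | None:
        sd = nd = 0
        cur = codon_a
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            aa_cur = CODON_TO_AA.get(cur, "*")
            aa_nxt = CODON_TO_AA.get(nxt, "*")
            if aa_cur == aa_nxt:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    orders = list(permutations(diff_pos))
    results = [r for o in orders if (r := walk(o, False)) is not None]
    if not results:
        results = [walk(o, True) for o in orders]  # type: ignore[misc]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def _jc_correct(p: float) -> float | None:
    """Jukes-Cantor multiple-hit correction; None when saturated."""
    if p >= 0.75:
        return None
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def _is_sense(codon: str) -> bool:
    return codon in CODON_TO_AA


def ng86(aln: CodonAlignment) -> KaKsResult:
    """NG86 estimate for one codon alignment (complete-pair deletion)."""
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(aln.codons_a), 3):
        ca = aln.codons_a[i:i + 3].upper()
        cb = aln.codons_b[i:i + 3].upper()
        if not (_is_sense(ca) and _is_sense(cb)):
            continue  # gapped, ambiguous or stop codons dropped pairwise
        n_codons += 1
        sa, sb = syn_site_fraction(ca), syn_site_fraction(cb)
        S += (sa + sb) / 2.0
        N += 3.0 - (sa + sb) / 2.0
        sd, nd = pathway_differences(ca, cb)
        Sd += sd
        Nd += nd

    if n_codons == 0 or S <= 0 or N <= 0:
        return KaKsResult(aln.id_a, aln.id_b, n_codons, S, N, Sd, Nd,
                          0.0, 0.0, None, None, None, "no_sites")
    pS, pN = Sd / S, Nd / N
    Ks, Ka = _jc_correct(pS), _jc_correct(pN)
    if Ks is None or Ka is None:
        return KaKsResult(aln.id_a, aln.id_b, n_codons, S, N, Sd, Nd,
                          pS, pN, Ks, Ka, None, "saturated")
    if Ks == 0.0:
        return KaKsResult(aln.id_a, aln.id_b, n_codons, S, N, Sd, Nd,
                          pS, pN, Ks, Ka, None, "ks_zero")
    return KaKsResult(aln.id_a, aln.id_b, n_codons, S, N, Sd, Nd,
                      pS, pN, Ks, Ka, Ka / Ks, "ok")


def backthread(protein_aln_a: str, protein_aln_b: str,
               cds_a: str, cds_b: str,
               id_a: str = "a", id_b: str = "b") -> CodonAlignment:
    """Thread CDS onto a protein alignment (residue -> codon, gap -> ---).

    The ungapped protein rows must equal the CDS translations
    (terminal stops trimmed first).
    """
    rows = []
    for prot_aln, cds, which in ((protein_aln_a, cds_a, id_a),
                                 (protein_aln_b, cds_b, id_b)):
        cds = trim_terminal_stop(cds.upper())
        prot = translate_cds(cds)
        if prot != prot_aln.replace("-", ""):
            mism = next((k for k, (x, y) in enumerate(
                zip(prot, prot_aln.replace("-", ""))) if x != y),
                min(len(prot), len(prot_aln.replace("-", ""))))
            raise ValueError(
                f"{which}: CDS translation does not match protein row "
                f"at residue {mism + 1}")
        out = []
        j = 0
        for aa in prot_aln:
            if aa == "-":
                out.append(GAP_CODON)
            else:
                out.append(cds[3 * j:3 * j + 3])
                j += 1
        rows.append("".join(out))
    return CodonAlignment(id_a=id_a, id_b=id_b,
                          codons_a=rows[0], codons_b=rows[1])


def pair_kaks(protein_a: str, protein_b: str, cds_a: str, cds_b: str,
              id_a: str = "a", id_b: str = "b",
              aligner=None) -> KaKsResult:
    """Align two proteins globally, back-thread, and run NG86."""
    aligner = aligner or make_aligner()
    aln = aligner.align(protein_a, protein_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    codon_aln = backthread(row_a, row_b, cds_a, cds_b, id_a, id_b)
    return ng86(codon_aln)


def og_kaks(ogset, genome_of: dict[str, str],
            proteins: dict[str, str], cds: dict[str, str],
            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All cross-genome within-orthogroup pairs + per-OG summary.

    Returns (pair table, per-OG summary with median ratio, fraction of
    defined ratios > 1, and a positive-selection flag).  Orthogroups
    with < 2 members are skipped with a log entry.
    """
    aligner = make_aligner()
    pair_rows = []
    for og_id in sorted(ogset.ogs):
        members = sorted(ogset.ogs[og_id])
        if len(members) < 2:
            logger.info("orthogroup %s has < 2 members; skipped", og_id)
            continue
        for a, b in combinations(members, 2):
            if genome_of[a] == genome_of[b]:
                continue
            res = pair_kaks(proteins[a], proteins[b], cds[a], cds[b],
                            id_a=a, id_b=b, aligner=aligner)
            pair_rows.append({
                "og_id": og_id, "gene_a": a, "gene_b": b,
                "n_codons": res.n_codons, "S": res.S, "N": res.N,
                "Sd": res.Sd, "Nd": res.Nd, "Ks": res.Ks, "Ka": res.Ka,
                "ratio": res.ratio, "status": res.status})
    pairs = pd.DataFrame(pair_rows)
    summaries = []
    if not pairs.empty:
        for og_id, sub in pairs.groupby("og_id"):
            defined = sub[sub["status"] == "ok"]["ratio"]
            summaries.append({
                "og_id": og_id,
                "n_pairs": len(sub),
                "n_defined": len(defined),
                "median_ratio": defined.median() if len(defined) else None,
                "frac_gt1": ((defined > 1).mean() if len(defined) else None),
                "positive_selection_flag": bool((defined > 1).any()),
            })
    return pairs, pd.DataFrame(summaries)
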