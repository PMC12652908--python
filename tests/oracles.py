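"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration, sharing no
code path with the implementation it checks.
"""

from __future__ import annotations

from itertools import permutations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_tab = unambiguous_dna_by_id[1]
AA = dict(_tab.forward_table)
STOPS = set(_tab.stop_codons)


def ng86_sites_oracle(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon."""
    s_total = n_total = 0.0
    for pos in range(3):
        syn = nonsyn = 0
        for nuc in "ACGT":
            if nuc == codon[pos]:
                continue
            mutant = codon[:pos] + nuc + codon[pos + 1:]
            if mutant in STOPS:
                continue
            if AA[mutant] == AA[codon]:
                syn += 1
            else:
                nonsyn += 1
        denom = syn + nonsyn
        if denom:
            s_total += syn / denom
            n_total += nonsyn / denom
    return s_total, n_total


def ng86_pathways_oracle(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) by explicit enumeration of all substitution orders."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in permutations(positions):
        steps = []
        cur = c1
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOPS:
                through_stop = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((through_stop, steps))
    usable = [steps for ts, steps in paths if not ts]
    if not usable:
        usable = [steps for _, steps in paths]
    sd = nd = 0.0
    for steps in usable:
        for cur, nxt in steps:
            aa_cur = AA.get(cur, "*")
            aa_nxt = AA.get(nxt, "*")
            if aa_cur == aa_nxt:
                sd += 1
            else:
                nd += 1
    return sd / len(usable), nd / len(usable)


def union_find_components(items: list[str],
                          edges: list[tuple[str, str]]) -> list[list[str]]:
    """Connected components by an explicit union-find."""
    parent = {x: x for x in items}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps: dict[str, list[str]] = {}
    for x in items:
        comps.setdefault(find(x), []).append(x)
    return sorted(sorted(c) for c in comps.values())


def sliding_window_motif_count(seq: str, concrete_sets: list[set[str]]) -> int:
    """Naive O(L*m) count of IUPAC matches on one strand.

    ``concrete_sets`` is the motif as a list of allowed-nucleotide sets.
    """
    m = len(concrete_sets)
    count = 0
    for i in range(len(seq) - m + 1):
        if all(seq[i + j] in concrete_sets[j] for j in range(m)):
            count += 1
    return count
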