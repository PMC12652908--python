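"""Haplotype enumeration per gene and distribution across breeding clusters.

A haplotype is the concatenation of a line's (collapsed haploid) allele
indices across the variant sites inside the gene region, in position
order.  Lines with any missing call in the region are excluded and
counted separately.  Haplotypes below ``min_count`` collapse into a
"rare" class; the rest are named Hap1, Hap2, ... by descending total
count (ties broken lexicographically by allele string).

The per-gene skew score quantifies how unevenly the most skewed
haplotype distributes over clusters: the maximum over haplotypes of the
chi-square statistic of that haplotype's cluster counts against the
cluster marginals, normalized by the number of counted lines, with a
seeded label-permutation p-value.  This statistic is an artifact
convention for a qualitative observation, and is labelled as such in
the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import VariantCall

RARE_LABEL = "rare"
MIN_COUNT_DEFAULT = 2


@dataclass
class HaplotypeTable:
    gene_id: str
    positions: list[int]
    # haplotype name -> (allele string, per-line carriers)
    haplotypes: dict[str, tuple[str, list[str]]] = field(default_factory=dict)
    excluded_lines: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {h: len(carriers) for h, (_, carriers) in self.haplotypes.items()}


def call_haplotypes(variants: list[VariantCall], gene_id: str,
                    chrom: str, start: int, end: int,
                    lines: list[str],
                    min_count: int = MIN_COUNT_DEFAULT) -> HaplotypeTable:
    """Enumerate haplotypes over the variant sites in [start, end]."""
    sites = sorted((v for v in variants
                    if v.chrom == chrom and start <= v.pos <= end),
                   key=lambda v: v.pos)
    table = HaplotypeTable(gene_id=gene_id, positions=[v.pos for v in sites])
    if not sites:
        return table

    strings: dict[str, list[str]] = {}
    for line in lines:
        alleles = [v.genotypes.get(line) for v in sites]
        if any(a is None for a in alleles):
            table.excluded_lines.append(line)
            continue
        key = "".join(str(a) for a in alleles)
        strings.setdefault(key, []).append(line)

    common = [(k, v) for k, v in strings.items() if len(v) >= min_count]
    rare = [(k, v) for k, v in strings.items() if len(v) < min_count]
    common.sort(key=lambda kv: (-len(kv[1]), kv[0]))
    for i, (key, carriers) in enumerate(common, start=1):
        table.haplotypes[f"Hap{i}"] = (key, sorted(carriers))
    if rare:
        carriers = sorted(c for _, v in rare for c in v)
        table.haplotypes[RARE_LABEL] = ("", carriers)
    return table


def cluster_distribution(table: HaplotypeTable,
                         clusters: dict[str, str]) -> pd.DataFrame:
    """Per-haplotype proportion vector over clusters (rows sum to 1)."""
    labels = sorted(set(clusters.values()))
    rows = []
    for hap, (_, carriers) in table.haplotypes.items():
        if not carriers:
            continue
        counts = dict.fromkeys(labels, 0)
        for line in carriers:
            if line not in clusters:
                raise KeyError(f"line {line} missing from cluster assignment")
            counts[clusters[line]] += 1
        total = len(carriers)
        row = {"haplotype": hap, "count": total}
        row.update({lab: counts[lab] / total for lab in labels})
        rows.append(row)
    return pd.DataFrame(rows)


def _max_hap_chi2(hap_labels: np.ndarray, cluster_idx: np.ndarray,
                  n_clusters: int) -> float:
    """Max over haplotypes of chi2(hap's cluster counts vs marginals)."""
    n = len(cluster_idx)
    marg = np.bincount(cluster_idx, minlength=n_clusters) / n
    best = 0.0
    for h in np.unique(hap_labels):
        mask = hap_labels == h
        tot = int(mask.sum())
        obs = np.bincount(cluster_idx[mask], minlength=n_clusters)
        exp = tot * marg
        nz = exp > 0
        chi2 = float((((obs[nz] - exp[nz]) ** 2) / exp[nz]).sum())
        best = max(best, chi2)
    return best


def skew_statistic(table: HaplotypeTable, clusters: dict[str, str],
                   n_permutations: int = 999, seed: int = 0
                   ) -> tuple[float, float]:
    """(normalized skew score, permutation p-value) for one gene.

    Score = max-haplotype chi-square / counted lines; p-value from
    seeded label shuffling, valid (>= 1/(perms+1)) by construction.
    """
    lines: list[str] = []
    hap_of: list[str] = []
    for hap, (_, carriers) in table.haplotypes.items():
        for line in carriers:
            lines.append(line)
            hap_of.append(hap)
    if not lines:
        raise ValueError(f"no counted lines for gene {table.gene_id}")
    labels = sorted(set(clusters.values()))
    if len(labels) < 2:
        raise ValueError("need >= 2 clusters with counted lines")
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    cluster_idx = np.array([lab_idx[clusters[l]] for l in lines])
    hap_labels = np.array(hap_of)
    n = len(lines)

    obs = _max_hap_chi2(hap_labels, cluster_idx, len(labels))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(cluster_idx)
        if _max_hap_chi2(hap_labels, perm, len(labels)) >= obs:
            exceed += 1
    pval = (1 + exceed) / (1 + n_permutations)
    return obs / n, pval


def read_clusters_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return dict(zip(df["line_id"], df["cluster"]))
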