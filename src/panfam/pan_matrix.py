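"""Orthogroup x genome presence/absence: occupancy classes and saturation.

Occupancy classes follow the pan-gene convention for a 26-genome panel:
core = all genomes, softcore = 24-25, shell = 6-23, variable = <= 5.
For other panel sizes the cut-offs generalize as soft_min = ceil(0.92 n)
and var_max = floor(0.20 n), which reproduce the absolute cut-offs
exactly at n = 26.

The saturation (rarefaction) curve reports, for each sample size s, the
expected fraction of orthogroups with at least one present genome in a
uniformly drawn s-subset of the panel.  The bootstrap estimate (default
1000 replicates) is accompanied by its closed form: an orthogroup
present in k genomes is missed by an s-subset with probability
C(n-k, s) / C(n, s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import comb

CATEGORIES = ("core", "softcore", "shell", "variable")


@dataclass
class PanMatrix:
    og_ids: list[str]
    genome_ids: list[str]
    presence: np.ndarray  # shape (n_ogs, n_genomes), {0,1}

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=np.int8)
        if self.presence.shape != (len(self.og_ids), len(self.genome_ids)):
            raise ValueError("presence shape mismatch")
        if not np.isin(self.presence, (0, 1)).all():
            raise ValueError("presence entries must be 0/1")

    @property
    def occupancy(self) -> np.ndarray:
        """Per-orthogroup genome count k_g (row sums)."""
        return self.presence.sum(axis=1)

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)


@dataclass
class SaturationCurve:
    sizes: np.ndarray            # s = 1..n
    bootstrap_mean: np.ndarray   # mean discovered fraction per s
    bootstrap_sd: np.ndarray     # sd of replicate fractions per s
    q025: np.ndarray
    q975: np.ndarray
    analytic: np.ndarray         # exact expectation per s
    reps: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n_genomes_sampled": self.sizes,
            "bootstrap_mean": self.bootstrap_mean,
            "bootstrap_sd": self.bootstrap_sd,
            "q025": self.q025, "q975": self.q975,
            "analytic_expectation": self.analytic,
        })


def build_matrix(ogset, gene_to_genome: Mapping[str, str],
                 genome_ids: list[str] | None = None) -> PanMatrix:
    """Presence[g][j] = 1 iff orthogroup g has >= 1 member from genome j.

    Singletons are excluded; every member gene must map to a genome.
    """
    if genome_ids is None:
        genome_ids = sorted(set(gene_to_genome.values()))
    gidx = {g: j for j, g in enumerate(genome_ids)}
    og_ids = sorted(ogset.ogs)
    presence = np.zeros((len(og_ids), len(genome_ids)), dtype=np.int8)
    for i, og in enumerate(og_ids):
        for gene in ogset.ogs[og]:
            if gene not in gene_to_genome:
                raise KeyError(f"gene {gene} has no genome mapping")
            presence[i, gidx[gene_to_genome[gene]]] = 1
    return PanMatrix(og_ids=og_ids, genome_ids=list(genome_ids),
                     presence=presence)


def category_thresholds(n: int) -> tuple[int, int]:
    """(soft_min, var_max) occupancy cut-offs for an n-genome panel."""
    if n == 26:
        return 24, 5
    return math.ceil(0.92 * n), math.floor(0.20 * n)


def classify(matrix: PanMatrix) -> dict[str, str]:
    """Occupancy category per orthogroup (exhaustive, mutually exclusive)."""
    n = matrix.n_genomes
    soft_min, var_max = category_thresholds(n)
    out: dict[str, str] = {}
    for og, k in zip(matrix.og_ids, matrix.occupancy):
        k = int(k)
        if k > n:
            raise ValueError(f"occupancy {k} > n_genomes {n} for {og}")
        if k == n:
            out[og] = "core"
        elif k >= soft_min:
            out[og] = "softcore"
        elif k <= var_max:
            out[og] = "variable"
        else:
            out[og] = "shell"
    return out


def category_counts(classes: Mapping[str, str],
                    ogset=None) -> pd.DataFrame:
    """Orthogroup (and, when an OrthogroupSet is given, gene) counts per class."""
    rows = []
    for cat in CATEGORIES:
        ogs = [og for og, c in classes.items() if c == cat]
        n_genes = (sum(len(ogset.ogs[og]) for og in ogs) if ogset is not None
                   else None)
        rows.append({"category": cat, "n_ogs": len(ogs), "n_genes": n_genes})
    return pd.DataFrame(rows)


def analytic_saturation(occupancy: np.ndarray, n: int,
                        sizes: np.ndarray) -> np.ndarray:
    """Exact E[fraction of OGs discovered] for each sample size.

    Per orthogroup with occupancy k: P(discovered in an s-subset)
    = 1 - C(n-k, s)/C(n, s), the term being 0 when s > n - k.
    """
    occ = np.asarray(occupancy)
    out = np.empty(len(sizes), dtype=float)
    for i, s in enumerate(sizes):
        miss = comb(n - occ, s) / comb(n, s)
        out[i] = float(np.mean(1.0 - miss))
    return out


def saturation(matrix: PanMatrix, reps: int = 1000,
               seed: int = 0) -> SaturationCurve:
    """Bootstrap saturation curve over genome subsets.

    For each s in 1..n, ``reps`` subsets of s genomes are drawn
    uniformly without replacement (with replacement across replicates);
    the discovered fraction is the share of orthogroups with >= 1
    present genome in the subset.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if len(matrix.og_ids) == 0:
        raise ValueError("empty pan matrix")
    rng = np.random.default_rng(seed)
    n = matrix.n_genomes
    n_ogs = len(matrix.og_ids)
    sizes = np.arange(1, n + 1)
    means = np.empty(n)
    sds = np.empty(n)
    q025 = np.empty(n)
    q975 = np.empty(n)
    for i, s in enumerate(sizes):
        fracs = np.empty(reps)
        for r in range(reps):
            cols = rng.choice(n, size=s, replace=False)
            fracs[r] = matrix.presence[:, cols].any(axis=1).sum() / n_ogs
        means[i] = fracs.mean()
        sds[i] = fracs.std(ddof=1) if reps > 1 else 0.0
        q025[i], q975[i] = np.quantile(fracs, [0.025, 0.975])
    analytic = analytic_saturation(matrix.occupancy, n, sizes)
    return SaturationCurve(sizes=sizes, bootstrap_mean=means,
                           bootstrap_sd=sds,
                           q025=q025, q975=q975, analytic=analytic,
                           reps=reps, seed=seed)


def find_min_s(matrix: PanMatrix, target: float = 0.9) -> int:
    """Smallest sample size whose analytic expectation reaches ``target``."""
    n = matrix.n_genomes
    sizes = np.arange(1, n + 1)
    analytic = analytic_saturation(matrix.occupancy, n, sizes)
    hit = np.nonzero(analytic >= target)[0]
    if len(hit) == 0:
        raise ValueError(f"target {target} not reached at s = n = {n}")
    return int(sizes[hit[0]])


def matrix_to_frame(matrix: PanMatrix,
                    classes: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = pd.DataFrame(matrix.presence, index=matrix.og_ids,
                      columns=matrix.genome_ids)
    df.insert(0, "og_id", matrix.og_ids)
    df["occupancy"] = matrix.occupancy
    if classes is not None:
        df["category"] = [classes[og] for og in matrix.og_ids]
    return df.reset_index(drop=True)
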