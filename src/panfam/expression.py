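"""FPKM normalization and tissue / stress expression summaries.

The artifact's boundary is the read-count matrix: library size is the
within-matrix column sum, FPKM[g][s] = counts * 1e9 / (libsize *
length_bp).  Tissue profiles are per-tissue means with per-gene
z-scores of log2(FPKM + 1) across tissues (heatmap export).  Stress
response is log2((mean treated FPKM + pseudo) / (mean control FPKM +
pseudo)) per organ; a gene is "induced" at log2FC >= lfc_min (default
1, i.e. two-fold, an explicit convention).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

LFC_MIN_DEFAULT = 1.0
PSEUDO_DEFAULT = 1.0


def fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase per million mapped fragments.

    ``counts``: gene x sample non-negative integers; ``lengths``: bp per
    gene.  Column totals are taken over all genes in the matrix.
    """
    if (counts.values < 0).any():
        raise ValueError("negative counts")
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index[0]
        raise KeyError(f"no length for gene {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals[totals <= 0].index[0]
        raise ValueError(f"zero library size in sample {bad}")
    return counts * 1e9 / totals / lengths.values[:, None]


def tissue_profile(fpkm_mat: pd.DataFrame, metadata: pd.DataFrame
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-tissue mean FPKM, per-gene z-scored log2 profile).

    ``metadata`` needs columns sample, tissue.  Z-scores are across
    tissues on log2(mean FPKM + 1); all-zero (constant) genes get null
    z-scores.
    """
    meta = metadata.set_index("sample")
    missing = [s for s in fpkm_mat.columns if s not in meta.index]
    if missing:
        raise KeyError(f"samples without metadata: {missing}")
    means = fpkm_mat.T.groupby(meta.loc[fpkm_mat.columns, "tissue"]).mean().T
    log = np.log2(means + 1.0)
    sd = log.std(axis=1, ddof=0)
    z = log.sub(log.mean(axis=1), axis=0).div(sd.where(sd > 0), axis=0)
    return means, z


def stress_response(fpkm_mat: pd.DataFrame, metadata: pd.DataFrame,
                    lfc_min: float = LFC_MIN_DEFAULT,
                    pseudo: float = PSEUDO_DEFAULT,
                    control_label: str = "control") -> pd.DataFrame:
    """Per gene x organ x treatment log2 fold-change vs control.

    ``metadata`` needs columns sample, organ, treatment; every organ
    must have control samples.
    """
    meta = metadata.set_index("sample")
    rows = []
    for organ, organ_meta in meta.groupby("organ"):
        ctrl = organ_meta[organ_meta["treatment"] == control_label].index
        ctrl = [s for s in ctrl if s in fpkm_mat.columns]
        if not ctrl:
            raise ValueError(f"no {control_label} samples for organ {organ}")
        ctrl_mean = fpkm_mat[ctrl].mean(axis=1)
        for treatment, t_meta in organ_meta.groupby("treatment"):
            if treatment == control_label:
                continue
            t_samples = [s for s in t_meta.index if s in fpkm_mat.columns]
            t_mean = fpkm_mat[t_samples].mean(axis=1)
            lfc = np.log2((t_mean + pseudo) / (ctrl_mean + pseudo))
            for gene in fpkm_mat.index:
                rows.append({
                    "gene_id": gene, "organ": organ, "treatment": treatment,
                    "log2fc": float(lfc[gene]),
                    "induced": bool(lfc[gene] >= lfc_min)})
    return pd.DataFrame(rows)
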