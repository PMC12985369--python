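"""QC filtering and normalization for cells, nuclei, and spots.

The QC rules are mode-specific (single-nucleus, single-cell, spot) with the
study's published bounds as defaults. Normalization is logTP10K with the
highly-expressed-gene exclusion: genes taking more than a set fraction of a
unit's total counts are excluded from that unit's size factor (but are still
scaled by it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass
class QCThresholds:
    min_genes_per_cell: int = 200
    max_umi_per_cell_sn: int = 15000
    max_genes_per_cell_sn: int = 5000
    max_mito_fraction_sn: float = 0.02
    max_umi_per_cell_sc: int = 25000
    max_genes_per_cell_sc: int = 6000
    max_mito_fraction_sc: float = 0.35
    spot_min_umi: int = 500
    spot_max_umi: int = 35000
    spot_max_mito: float = 0.20
    highly_expressed_gene_fraction: float = 0.05
    target_sum: float = 10000.0


def _dense(X):
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


def unit_stats(X, gene_names) -> pd.DataFrame:
    """Per-unit UMI total, detected-gene count, and mitochondrial fraction
    (computed on raw counts). Mito genes are those whose name starts 'MT-'."""
    Xc = sparse.csr_matrix(X)
    total = np.asarray(Xc.sum(axis=1)).ravel()
    n_genes = Xc.getnnz(axis=1)
    mito_mask = np.asarray([g.upper().startswith("MT-") for g in gene_names])
    mito = np.asarray(Xc[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return pd.DataFrame({"total_umi": total, "n_genes": n_genes, "mito_fraction": frac})


def qc_filter(X, gene_names, thresholds: QCThresholds, mode: str):
    """Remove units violating the mode's QC rules (strict inequalities, as
    published). Returns (filtered matrix, kept boolean mask, report frame
    with the first violated rule per unit)."""
    stats = unit_stats(X, gene_names)
    t = thresholds
    if mode == "sn":
        rules = [
            ("min_genes", stats["n_genes"] < t.min_genes_per_cell),
            ("max_umi", stats["total_umi"] > t.max_umi_per_cell_sn),
            ("max_genes", stats["n_genes"] > t.max_genes_per_cell_sn),
            ("max_mito", stats["mito_fraction"] > t.max_mito_fraction_sn),
        ]
    elif mode == "sc":
        rules = [
            ("min_genes", stats["n_genes"] < t.min_genes_per_cell),
            ("max_umi", stats["total_umi"] > t.max_umi_per_cell_sc),
            ("max_genes", stats["n_genes"] > t.max_genes_per_cell_sc),
            ("max_mito", stats["mito_fraction"] > t.max_mito_fraction_sc),
        ]
    elif mode == "spot":
        rules = [
            ("min_umi", stats["total_umi"] < t.spot_min_umi),
            ("max_umi", stats["total_umi"] > t.spot_max_umi),
            ("max_mito", stats["mito_fraction"] > t.spot_max_mito),
        ]
    else:
        raise ValueError(f"unknown QC mode {mode!r}; expected sn, sc, or spot")

    violated = pd.Series([""] * len(stats))
    for name, bad in reversed(rules):
        violated[bad.to_numpy()] = name
    keep = (violated == "").to_numpy()
    if not keep.any():
        warnings.warn("qc_filter removed every unit", stacklevel=2)
    report = stats.copy()
    report["kept"] = keep
    report["violated_rule"] = violated.to_numpy()
    Xc = sparse.csr_matrix(X)
    return Xc[keep], keep, report


def normalize_logtp10k(X, thresholds: QCThresholds | None = None,
                       exclude_highly_expressed: bool = True):
    """logTP10K: per unit, size factor = sum of counts over genes whose count
    is at most `highly_expressed_gene_fraction` of the unit total (all genes,
    including excluded ones, are then scaled by it); value =
    ln(1 + count * target_sum / size_factor).

    Units with size factor 0 (all-zero, or every count excluded) are flagged
    and excluded. Returns (normalized dense array, kept mask).
    """
    t = thresholds or QCThresholds()
    Xd = _dense(X).astype(float)
    total = Xd.sum(axis=1)
    if exclude_highly_expressed:
        cutoff = t.highly_expressed_gene_fraction * total[:, None]
        included = Xd <= cutoff
        size = np.where(included, Xd, 0.0).sum(axis=1)
    else:
        size = total
    keep = size > 0
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} unit(s) with zero size factor excluded",
            stacklevel=2,
        )
    out = np.log1p(Xd[keep] * (t.target_sum / size[keep])[:, None])
    return out, keep


def classify_pp(spot_labels, pp_label: str = "PP") -> str:
    """ILD-PP class of one sample from its annotated spots: 'high' iff the
    preserved-parenchyma fraction is >= 0.5 (inclusive boundary)."""
    labels = pd.Series(spot_labels).dropna()
    if len(labels) == 0:
        raise ValueError("sample has no annotated spots")
    frac = (labels == pp_label).mean()
    return "ILD-PP^high" if frac >= 0.5 else "ILD-PP^low"


def assign_library_fraction(type_counts, compartment_map: dict) -> str:
    """Library fraction label from per-type cell counts, applying the rules
    in order: epithelial >80%, then stromal >60%, then immune >60%, else
    whole."""
    counts = pd.Series(type_counts, dtype=float)
    unmapped = [t for t in counts.index if t not in compartment_map]
    if unmapped:
        raise ValueError(f"cell types without compartment: {unmapped}")
    total = counts.sum()
    comp = counts.groupby(counts.index.map(compartment_map)).sum() / total
    if comp.get("epithelial", 0.0) > 0.80:
        return "epithelial-enriched"
    if comp.get("stromal", 0.0) > 0.60:
        return "stromal-enriched"
    if comp.get("immune", 0.0) > 0.60:
        return "immune-enriched"
    return "whole"
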