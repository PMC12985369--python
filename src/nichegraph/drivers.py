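"""Driver prioritization: TF → ligand cascade and marker/score read-outs.

The cascade identifies transcription factors enriched in a target cell
population by expression (one-sided Wilcoxon vs an alveolar-lineage
background, adjusted p < 0.025 and log fold change >= 0.5) and by regulon
activity (mean activity difference > 0.5, adjusted p < 0.025; the variant
for the myofibroblast state uses alpha = 0.01 and intersects two atlases
plus a spatial-community activity test). The union of the two TF lists is
matched against a ligand×TF regulatory-potential prior: each TF's top-10
ligands are collected, ligands recurring >= 2 times are kept, and
candidates survive only if every receptor gene is expressed in >5% of
target cells in every supplied atlas. Marker signatures use one-vs-rest
ROC AUC; module scores use binned expression-matched control genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .colocalization import adjust_bh

log = logging.getLogger(__name__)

TF_EXPR_ALPHA = 0.025
TF_EXPR_MIN_LOGFC = 0.5
TF_ACT_ALPHA = 0.025
TF_ACT_MIN_DIFF = 0.5
MYOF_ACT_ALPHA = 0.01
LIGAND_TOP_K = 10
LIGAND_MIN_RECURRENCE = 2
RECEPTOR_MIN_FRACTION = 0.05
AUC_ATLAS = 0.65
AUC_BULK = 0.6


@dataclass
class TFCandidate:
    tf: str
    source: str  # expression | activity | both
    logfc: float = float("nan")
    activity_diff: float = float("nan")
    p_adj: float = float("nan")


def _dense(X):
    return X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)


def _wilcoxon_greater(x, y):
    res = stats.mannwhitneyu(x, y, alternative="greater", axis=0,
                             method="asymptotic")
    return np.atleast_1d(res.pvalue)


def enrich_tf_expression(values: pd.DataFrame, target_mask, background_mask,
                         tf_list, alpha: float = TF_EXPR_ALPHA,
                         min_logfc: float = TF_EXPR_MIN_LOGFC) -> pd.DataFrame:
    """TFs upregulated in the target population vs the stated background on
    log-normalized expression: one-sided Wilcoxon, BH-adjusted p < alpha
    and difference of log-space means >= min_logfc."""
    target_mask = np.asarray(target_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if background_mask.sum() == 0:
        raise ValueError("background population is empty")
    tfs = [t for t in tf_list if t in values.columns]
    if not tfs:
        return pd.DataFrame(columns=["tf", "logfc", "p", "p_adj", "selected"])
    V = values[tfs]
    x = V.loc[target_mask].to_numpy()
    y = V.loc[background_mask].to_numpy()
    p = _wilcoxon_greater(x, y)
    logfc = x.mean(axis=0) - y.mean(axis=0)
    res = pd.DataFrame({"tf": tfs, "logfc": logfc, "p": p})
    res["p_adj"] = adjust_bh(res["p"])
    res["selected"] = (res["p_adj"] < alpha) & (res["logfc"] >= min_logfc)
    return res


def read_gmt(path) -> dict:
    """GMT regulon file: TF <tab> description <tab> target genes...; a
    trailing ':weight' on a target is honored as a signed weight."""
    regs = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            targets = {}
            for tok in parts[2:]:
                if not tok:
                    continue
                if ":" in tok:
                    g, w = tok.rsplit(":", 1)
                    targets[g] = float(w)
                else:
                    targets[tok] = 1.0
            regs[parts[0]] = targets
    return regs


def regulon_activity(values: pd.DataFrame, regulons: dict,
                     min_targets: int = 3) -> pd.DataFrame:
    """Cell×TF activity: weighted mean of gene-wise z-scored expression of
    the regulon's targets (zero-variance genes z-score to 0). Regulons with
    fewer than `min_targets` resolvable targets are skipped."""
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    Z = (values - mu).div(sd.replace(0.0, np.inf), axis=1)
    acts = {}
    for tf, targets in regulons.items():
        if not isinstance(targets, dict):
            targets = {g: 1.0 for g in targets}
        resolved = {g: w for g, w in targets.items() if g in values.columns}
        if len(resolved) < min_targets:
            log.info("regulon %s: only %d resolvable targets, skipped",
                     tf, len(resolved))
            continue
        genes = list(resolved)
        w = np.asarray([resolved[g] for g in genes], dtype=float)
        acts[tf] = (Z[genes].to_numpy() * w).sum(axis=1) / np.abs(w).sum()
    return pd.DataFrame(acts, index=values.index)


def enrich_tf_activity(activity: pd.DataFrame, target_mask, background_mask,
                       alpha: float = TF_ACT_ALPHA,
                       min_diff: float = TF_ACT_MIN_DIFF) -> pd.DataFrame:
    """TFs whose regulon activity is higher in the target population:
    one-sided Wilcoxon, BH-adjusted p < alpha and mean activity difference
    > min_diff."""
    target_mask = np.asarray(target_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    x = activity.loc[target_mask].to_numpy()
    y = activity.loc[background_mask].to_numpy()
    p = _wilcoxon_greater(x, y)
    diff = x.mean(axis=0) - y.mean(axis=0)
    res = pd.DataFrame({"tf": list(activity.columns), "activity_diff": diff, "p": p})
    res["p_adj"] = adjust_bh(res["p"])
    res["selected"] = (res["p_adj"] < alpha) & (res["activity_diff"] > min_diff)
    return res


def enrich_tf_activity_multi(results: list[pd.DataFrame]) -> list[str]:
    """Intersection variant: TFs selected in every supplied activity test
    (e.g. two atlases plus a spatial-community test)."""
    sets = [set(r.loc[r["selected"], "tf"]) for r in results]
    return sorted(set.intersection(*sets)) if sets else []


def union_tfs(expression_res: pd.DataFrame, activity_res: pd.DataFrame) -> pd.DataFrame:
    """Union of expression- and activity-derived TF lists with provenance."""
    e = set(expression_res.loc[expression_res["selected"], "tf"])
    a = set(activity_res.loc[activity_res["selected"], "tf"])
    rows = []
    for tf in sorted(e | a):
        src = "both" if tf in e and tf in a else ("expression" if tf in e else "activity")
        rows.append({"tf": tf, "source": src})
    return pd.DataFrame(rows, columns=["tf", "source"])


def rank_ligands(tf_list, potential: pd.DataFrame,
                 k: int = LIGAND_TOP_K,
                 min_recurrence: int = LIGAND_MIN_RECURRENCE) -> pd.DataFrame:
    """Per TF take the top-k ligands by regulatory potential (ties broken by
    lexicographic ligand name); keep ligands recurring in >= min_recurrence
    top-k lists."""
    recurrence: dict[str, int] = {}
    for tf in tf_list:
        if tf not in potential.columns:
            log.info("TF %s absent from potential matrix, skipped", tf)
            continue
        col = potential[tf]
        order = sorted(col.index, key=lambda lg: (-col[lg], lg))
        for lg in order[:k]:
            recurrence[lg] = recurrence.get(lg, 0) + 1
    rows = [
        {"ligand": lg, "recurrence": n, "selected": n >= min_recurrence}
        for lg, n in sorted(recurrence.items())
    ]
    return pd.DataFrame(rows, columns=["ligand", "recurrence", "selected"])


def expressed_fraction(atlas, gene: str, target_mask) -> float:
    """Fraction of target cells with raw count > 0 for `gene`."""
    if gene not in set(atlas.var_names):
        raise KeyError(gene)
    j = list(atlas.var_names).index(gene)
    X = sparse.csr_matrix(atlas.X)
    col = np.asarray(X[np.asarray(target_mask, dtype=bool), j].todense()).ravel()
    return float((col > 0).mean())


def filter_receptors(candidates: pd.DataFrame, atlases: list,
                     target_masks: list, receptor_map: pd.DataFrame,
                     threshold: float = RECEPTOR_MIN_FRACTION,
                     manual_additions=()) -> pd.DataFrame:
    """Keep candidate ligands whose every receptor gene is expressed in
    > threshold of target cells in EVERY supplied atlas; manual additions
    are appended with manual=True."""
    rows = []
    sel = candidates.loc[candidates["selected"], "ligand"]
    for lg in sel:
        if lg not in receptor_map.index:
            log.info("ligand %s has no receptor mapping, dropped", lg)
            continue
        receptors = str(receptor_map.loc[lg, "receptor_genes"]).split("+")
        fracs = []
        try:
            for atlas, mask in zip(atlases, target_masks):
                fracs.extend(expressed_fraction(atlas, r, mask) for r in receptors)
        except KeyError as e:
            log.info("ligand %s: receptor %s unresolvable, dropped", lg, e)
            continue
        if all(f > threshold for f in fracs):
            rows.append({"ligand": lg, "manual": False,
                         "min_receptor_fraction": min(fracs)})
    for lg in manual_additions:
        if lg not in {r["ligand"] for r in rows}:
            rows.append({"ligand": lg, "manual": True,
                         "min_receptor_fraction": float("nan")})
    return pd.DataFrame(rows, columns=["ligand", "manual", "min_receptor_fraction"])


def auc_one_vs_rest(x_in: np.ndarray, x_out: np.ndarray) -> float:
    """ROC AUC of in-type vs rest from the Mann-Whitney U statistic
    (ties count one half)."""
    u = stats.mannwhitneyu(x_in, x_out, alternative="two-sided").statistic
    return float(u) / (len(x_in) * len(x_out))


def auc_markers(values: pd.DataFrame, cell_types,
                threshold: float = AUC_ATLAS) -> dict:
    """Per cell type, the genes whose one-vs-rest AUC >= threshold (the
    cell-type-specific gene set, CSG)."""
    cell_types = pd.Series(list(cell_types))
    types = sorted(cell_types.unique())
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    V = values.to_numpy()
    out = {}
    for t in types:
        mask = (cell_types == t).to_numpy()
        n1, n2 = int(mask.sum()), int((~mask).sum())
        res = stats.mannwhitneyu(V[mask], V[~mask], alternative="two-sided",
                                 axis=0, method="asymptotic")
        auc = np.atleast_1d(res.statistic) / (n1 * n2)
        out[t] = sorted(np.asarray(values.columns)[auc >= threshold])
    return out


def module_score(values: pd.DataFrame, gene_set, n_bins: int = 24,
                 n_ctrl: int = 100, seed: int = 0) -> pd.Series:
    """Per-unit module score: mean expression of the gene set minus the mean
    of control genes drawn, n_ctrl per set gene, from the same
    average-expression bin (bins over all genes by mean expression)."""
    genes = [g for g in gene_set if g in values.columns]
    if not genes:
        raise ValueError("gene set has no genes present in the matrix")
    rng = np.random.default_rng(seed)
    means = values.mean(axis=0)
    n_bins = min(n_bins, means.nunique())
    bins = pd.qcut(means.rank(method="first"), q=n_bins, labels=False)
    ctrl: list[str] = []
    for g in genes:
        pool = means.index[(bins == bins[g]) & (means.index != g)]
        if len(pool) == 0:
            pool = means.index[means.index != g]
        ctrl.extend(rng.choice(pool, size=min(n_ctrl, len(pool)), replace=False))
    score = values[genes].mean(axis=1) - values[sorted(set(ctrl))].mean(axis=1)
    return score
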