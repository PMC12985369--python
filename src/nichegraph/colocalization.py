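"""Cell-type colocalization (CoLS) networks.

CoLS between two cell types is the Spearman rank correlation of their
per-spot deconvolution weights within one condition. Pairs with CoLS > 0
and a Benjamini-Hochberg adjusted p below the mode's alpha (0.05 for
neighborhood calls, 0.01 for the network graph) become edges of an
undirected weighted graph, which is partitioned by Clauset-Newman-Moore
greedy modularity maximization. Per-node modularity is the node's summand
share of Q, so node scores sum to Q exactly; conditions are compared by a
two-sided Wilcoxon rank-sum test on the node-score distributions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ALPHA_NEIGHBORHOOD = 0.05
ALPHA_GRAPH = 0.01


@dataclass
class CoLSNetwork:
    graph: nx.Graph
    cols: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame
    alpha: float
    partition: dict = field(default_factory=dict)
    node_modularity: dict = field(default_factory=dict)
    Q: float = float("nan")


def _spearman_pair(a, b, exact_permutation=False):
    n = len(a)
    rho, p = stats.spearmanr(a, b)
    if exact_permutation and n <= 10:
        p = _exact_spearman_p(a, b)
    return rho, p


def _exact_spearman_p(a, b):
    """Two-sided exact permutation p for |rho| by full enumeration (n<=8 via
    itertools; n=9..10 via scipy's exhaustive permutation_test)."""
    n = len(a)
    obs = abs(stats.spearmanr(a, b).statistic)
    if n <= 8:
        b = np.asarray(b)
        count = total = 0
        for perm in itertools.permutations(range(n)):
            r = abs(stats.spearmanr(a, b[list(perm)]).statistic)
            count += r >= obs - 1e-12
            total += 1
        return count / total
    res = stats.permutation_test(
        (a, b),
        lambda x, y: stats.spearmanr(x, y).statistic,
        permutation_type="pairings",
        alternative="two-sided",
        n_resamples=math.factorial(n),
    )
    return res.pvalue


def compute_cols(weights, condition_mask=None, missing_policy: str = "zero",
                 exact_permutation: bool = False):
    """Pairwise CoLS (Spearman rho) and raw p across the spots of one
    condition subset.

    `weights` is a spot×type DataFrame, possibly containing NaN from weight
    thresholding. `missing_policy='zero'` treats masked weights as true zero
    abundance (default); `'pairwise'` drops spots with a NaN in either
    member of a pair. Constant vectors yield NaN (undefined correlation).
    """
    if missing_policy not in ("zero", "pairwise"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    W = weights if condition_mask is None else weights.loc[condition_mask]
    if len(W) < 3:
        raise ValueError("need at least 3 spots to compute CoLS")
    types = list(W.columns)
    k = len(types)
    cols = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    np.fill_diagonal(cols, 1.0)
    Wz = W.fillna(0.0) if missing_policy == "zero" else W
    for i, j in itertools.combinations(range(k), 2):
        a, b = Wz.iloc[:, i].to_numpy(), Wz.iloc[:, j].to_numpy()
        if missing_policy == "pairwise":
            m = ~(np.isnan(a) | np.isnan(b))
            a, b = a[m], b[m]
            if len(a) < 3:
                continue
        if np.all(a == a[0]) or np.all(b == b[0]):
            continue  # undefined: reported as missing
        rho, p = _spearman_pair(a, b, exact_permutation)
        cols[i, j] = cols[j, i] = rho
        pval[i, j] = pval[j, i] = p
    return (
        pd.DataFrame(cols, index=types, columns=types),
        pd.DataFrame(pval, index=types, columns=types),
    )


def adjust_bh(p):
    """Benjamini-Hochberg step-up adjustment; NaN entries propagate."""
    arr = np.asarray(p, dtype=float)
    flat = arr.ravel()
    ok = ~np.isnan(flat)
    out = np.full(flat.shape, np.nan)
    if ok.sum():
        out[ok] = multipletests(flat[ok], method="fdr_bh")[1]
    res = out.reshape(arr.shape)
    if isinstance(p, pd.DataFrame):
        return pd.DataFrame(res, index=p.index, columns=p.columns)
    if isinstance(p, pd.Series):
        return pd.Series(res, index=p.index)
    return res


def adjust_bh_pairs(p: pd.DataFrame) -> pd.DataFrame:
    """BH over the family of unordered pairs (upper triangle), mirrored back
    to a symmetric matrix."""
    types = list(p.columns)
    k = len(types)
    iu = np.triu_indices(k, 1)
    flat = p.to_numpy()[iu]
    adj = adjust_bh(flat)
    out = np.full((k, k), np.nan)
    out[iu] = adj
    out[(iu[1], iu[0])] = adj
    return pd.DataFrame(out, index=types, columns=types)


def build_network(cols: pd.DataFrame, p_adj: pd.DataFrame,
                  mode: str = "graph") -> CoLSNetwork:
    """Undirected weighted graph: edge iff CoLS > 0 and adjusted p < alpha
    (alpha 0.05 in neighborhood mode, 0.01 in graph mode); edge weight is
    the CoLS value."""
    alpha = {"neighborhood": ALPHA_NEIGHBORHOOD, "graph": ALPHA_GRAPH}.get(mode)
    if alpha is None:
        raise ValueError(f"unknown mode {mode!r}; expected neighborhood or graph")
    G = nx.Graph()
    types = sorted(cols.columns)
    G.add_nodes_from(types)
    for a, b in itertools.combinations(types, 2):
        c, q = cols.loc[a, b], p_adj.loc[a, b]
        if np.isfinite(c) and np.isfinite(q) and c > 0 and q < alpha:
            G.add_edge(a, b, weight=float(c))
    return CoLSNetwork(graph=G, cols=cols, p=None, p_adj=p_adj, alpha=alpha)


def modularity_scores(G: nx.Graph, communities) -> tuple[dict, float]:
    """Per-node modularity share and total Q on edge weights:
    node i's score is sum_j (A_ij/2m − k_i k_j/(2m)^2) over same-community j
    (including the j=i degree term); scores sum to Q."""
    nodes = sorted(G.nodes)
    comm_of = {}
    for ci, comm in enumerate(communities):
        for n in comm:
            comm_of[n] = ci
    A = nx.to_numpy_array(G, nodelist=nodes, weight="weight")
    two_m = A.sum()
    if two_m == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    k = A.sum(axis=1)
    cvec = np.asarray([comm_of[n] for n in nodes])
    same = cvec[:, None] == cvec[None, :]
    summand = (A / two_m - np.outer(k, k) / two_m**2) * same
    node_scores = summand.sum(axis=1)
    return dict(zip(nodes, node_scores)), float(node_scores.sum())


def partition_greedy(net: CoLSNetwork) -> CoLSNetwork:
    """Fast-greedy (Clauset-Newman-Moore) modularity partition; ties broken
    deterministically by feeding nodes/edges in lexicographic order."""
    G = net.graph
    if G.number_of_edges() == 0:
        raise ValueError("cannot partition an edgeless graph")
    H = nx.Graph()
    H.add_nodes_from(sorted(G.nodes))
    H.add_edges_from(
        sorted((min(u, v), max(u, v), d) for u, v, d in G.edges(data=True)),
    )
    comms = nx.algorithms.community.greedy_modularity_communities(H, weight="weight")
    comms = [sorted(c) for c in comms]
    isolated = [n for n in sorted(G.nodes) if G.degree(n) == 0]
    node_mod, Q = modularity_scores(G, comms)
    net.partition = {n: ci for ci, comm in enumerate(comms) for n in comm}
    net.node_modularity = node_mod
    net.Q = Q
    net.partition.update({n: -1 for n in isolated if n not in net.partition})
    return net


def compare_modularity(net_a: CoLSNetwork, net_b: CoLSNetwork):
    """Two-sided Wilcoxon rank-sum test on the per-node modularity
    distributions of two partitioned networks (exact for tie-free groups of
    at most 25 nodes, normal approximation otherwise)."""
    xs = [np.asarray(list(n.node_modularity.values()), dtype=float)
          for n in (net_a, net_b)]
    if any(len(x) < 2 for x in xs):
        raise ValueError("need at least 2 scored nodes per condition")
    x, y = xs
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def edge_set(net: CoLSNetwork) -> set:
    return {tuple(sorted(e)) for e in net.graph.edges}


def precision_recall(found: set, truth: set) -> tuple[float, float]:
    """Edge precision/recall of a recovered pair set against planted pairs."""
    if not found:
        return 0.0, 0.0
    tp = len(found & truth)
    return tp / len(found), tp / len(truth) if truth else 1.0
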