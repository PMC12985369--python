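"""Spatially constrained ligand-receptor signaling networks.

A gene is *relevant* for a cell type when it is upregulated in that type
versus all other cells of the condition (one-sided Wilcoxon rank-sum,
p < 0.05) and expressed (raw count > 0) in more than 10% of the type's
cells. An L-R interaction is relevant for a sender→receiver pair when every
ligand-subunit gene is relevant in the sender and every receptor-subunit
gene in the receiver. Relevant interactions are counted into a directed
weighted graph — optionally only for pairs enriched in at least one common
spatial community — and nodes are ranked by eigenvector centrality.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats

log = logging.getLogger(__name__)

DE_P = 0.05
MIN_EXPRESSED_FRACTION = 0.10


@dataclass
class LRDatabase:
    """Interaction records; ligand/receptor units are tuples of 1-4 genes
    (complexes require every subunit)."""

    records: pd.DataFrame  # columns: id, ligand_genes, receptor_genes (tuples)

    @classmethod
    def from_csv(cls, path) -> "LRDatabase":
        df = pd.read_csv(path)
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LRDatabase":
        if df.empty:
            return cls(pd.DataFrame(
                columns=["id", "ligand_genes", "receptor_genes"]))
        recs = pd.DataFrame(
            {
                "id": df["id"].astype(str),
                "ligand_genes": [tuple(str(s).split("+")) for s in df["ligand_genes"]],
                "receptor_genes": [tuple(str(s).split("+")) for s in df["receptor_genes"]],
            }
        )
        if recs["id"].duplicated().any():
            dup = recs.loc[recs["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate interaction ids: {dup}")
        for col in ("ligand_genes", "receptor_genes"):
            if any(not g for unit in recs[col] for g in unit):
                raise ValueError("empty gene name in L-R database")
            if any(not (1 <= len(unit) <= 4) for unit in recs[col]):
                raise ValueError("L-R units must have 1-4 subunit genes")
        return cls(recs)

    @classmethod
    def bundled(cls) -> "LRDatabase":
        """The small curated L-R table shipped with the package."""
        with resources.files("nichegraph.data").joinpath("lr_pairs.csv").open() as fh:
            return cls.from_csv(fh)

    def genes(self) -> set:
        out = set()
        for col in ("ligand_genes", "receptor_genes"):
            for unit in self.records[col]:
                out.update(unit)
        return out


@dataclass
class SignalingNetwork:
    graph: nx.DiGraph
    centrality: dict = field(default_factory=dict)
    interactions: pd.DataFrame | None = None


def de_gate(X, cell_types, gene_names, min_cells: int = 3) -> dict:
    """Per-type relevant-gene sets for one condition subset.

    `X` is cells×genes; expression values are used for the one-vs-rest
    Wilcoxon (greater), the >10% expressed gate uses raw counts > 0 of the
    same matrix. Types with fewer than `min_cells` cells are excluded with
    a warning.
    """
    Xd = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
    cell_types = pd.Series(list(cell_types))
    types = sorted(cell_types.unique())
    if len(types) < 2:
        raise ValueError("need at least 2 cell types for one-vs-rest DE")
    genes = np.asarray(list(gene_names))
    out = {}
    for t in types:
        mask = (cell_types == t).to_numpy()
        if mask.sum() < min_cells:
            warnings.warn(f"type {t!r} has <{min_cells} cells; excluded from DE",
                          stacklevel=2)
            continue
        x, y = Xd[mask], Xd[~mask]
        with np.errstate(invalid="ignore"):
            res = stats.mannwhitneyu(x, y, alternative="greater", axis=0,
                                     method="asymptotic")
        expressed = (x > 0).mean(axis=0)
        keep = (res.pvalue < DE_P) & (expressed > MIN_EXPRESSED_FRACTION)
        out[t] = set(genes[keep])
    return out


def score_interactions(relevant: dict, lr_db: LRDatabase,
                       sender: str, receiver: str) -> list[str]:
    """Interaction ids relevant for sender→receiver: every ligand-unit gene
    relevant in the sender and every receptor-unit gene in the receiver."""
    if sender not in relevant or receiver not in relevant:
        return []
    send_set, recv_set = relevant[sender], relevant[receiver]
    hits = []
    for _, rec in lr_db.records.iterrows():
        if all(g in send_set for g in rec["ligand_genes"]) and all(
            g in recv_set for g in rec["receptor_genes"]
        ):
            hits.append(rec["id"])
    return hits


def constrain_and_build(
    relevant: dict,
    lr_db: LRDatabase,
    community_types: dict | None = None,
    mode: str = "constrained",
) -> SignalingNetwork:
    """Directed weighted cell-type graph; edge weight = number of relevant
    interactions for the ordered pair. In constrained mode a pair is only
    scored when sender and receiver are enriched in at least one common
    community; unconstrained mode scores all ordered pairs."""
    if mode not in ("constrained", "unconstrained"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "constrained" and community_types is None:
        raise ValueError("constrained mode requires a community→types map")
    types = sorted(relevant)
    memberships = {}
    if mode == "constrained":
        for comm, tl in community_types.items():
            for t in tl:
                memberships.setdefault(t, set()).add(comm)
    G = nx.DiGraph()
    G.add_nodes_from(types)
    rows = []
    for s in types:
        for r in types:
            if mode == "constrained" and not (
                memberships.get(s, set()) & memberships.get(r, set())
            ):
                continue
            hits = score_interactions(relevant, lr_db, s, r)
            if hits:
                G.add_edge(s, r, weight=len(hits))
                rows.extend({"sender": s, "receiver": r, "interaction": h} for h in hits)
    return SignalingNetwork(
        graph=G,
        interactions=pd.DataFrame(rows, columns=["sender", "receiver", "interaction"]),
    )


def eigenvector_centrality(G, tol: float = 1e-12, max_iter: int = 10000,
                           mode: str = "symmetric") -> dict:
    """Eigenvector centrality by power iteration, normalized so the maximum
    score is 1. The default symmetrizes a directed graph (A + Aᵀ, one score
    per node); `mode='right'` scores nodes by outgoing influence on A,
    `mode='left'` by incoming influence (Aᵀ). Disconnected graphs are
    scored per connected component (flagged in the log)."""
    nodes = sorted(G.nodes)
    if not nodes:
        raise ValueError("empty network")
    A = nx.to_numpy_array(G, nodelist=nodes, weight="weight")
    if mode == "symmetric":
        A = A + A.T
    elif mode == "left":
        A = A.T.copy()
    elif mode != "right":
        raise ValueError(f"unknown mode {mode!r}")
    U = nx.Graph()
    U.add_nodes_from(nodes)
    U.add_edges_from((nodes[i], nodes[j]) for i, j in zip(*np.nonzero(A)))
    comps = list(nx.connected_components(U))
    if len(comps) > 1:
        log.info("network has %d components; centrality computed per component",
                 len(comps))
    scores = np.zeros(len(nodes))
    index = {n: i for i, n in enumerate(nodes)}
    for comp in comps:
        idx = sorted(index[n] for n in comp)
        B = A[np.ix_(idx, idx)]
        if B.sum() == 0:
            continue  # isolated node: score 0
        # positive diagonal shift: same eigenvectors, but guarantees the
        # dominant eigenvalue is unique in magnitude (bipartite components
        # would otherwise make plain power iteration oscillate)
        shift = B.sum(axis=1).max()
        Bs = B + shift * np.eye(len(idx))
        x = np.full(len(idx), 1.0 / np.sqrt(len(idx)))
        for _ in range(max_iter):
            xn = Bs @ x
            xn /= np.linalg.norm(xn)
            if np.linalg.norm(xn - x) < tol:
                x = xn
                break
            x = xn
        scores[idx] = np.abs(x)
    m = scores.max()
    if m > 0:
        scores = scores / m
    return dict(zip(nodes, scores))


def centrality(net: SignalingNetwork, tol: float = 1e-12) -> SignalingNetwork:
    net.centrality = eigenvector_centrality(net.graph, tol=tol)
    return net
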