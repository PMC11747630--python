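"""Sparse signed co-occurrence network inference over CLR profiles.

Edges are retained when the association between two variables survives
conditioning: for each candidate pair we compute partial correlations
given every subset (up to ``max_k`` variables) of a bounded candidate
neighbourhood, take the weakest evidence (largest p from a Fisher z
test), and control the FDR over all pairs with Benjamini-Hochberg.
This local-to-global scheme produces a sparse, signed association graph
in which indirect correlations mediated by a shared driver are removed.
Environmental meta-variables can be appended as extra nodes so direct
ASV-environment associations appear as edges.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "infer_network",
    "centralities",
    "write_network",
    "read_network",
]


def _fisher_z_pvalue(r: float, n: int, k: int) -> float:
    """Two-sided p-value for a (partial) correlation via Fisher's z."""
    df = n - k - 3
    if df <= 0:
        return 1.0
    r = float(np.clip(r, -0.999999, 0.999999))
    z = 0.5 * np.log((1 + r) / (1 - r)) * np.sqrt(df)
    return float(2 * stats.norm.sf(abs(z)))


def _partial_corr(corr: np.ndarray, i: int, j: int, ks: tuple[int, ...]) -> float:
    """Partial correlation of variables i, j given the set ks.

    Computed from the inverse of the sub-correlation-matrix; falls back
    to 0 when the conditioning block is singular.
    """
    if not ks:
        return corr[i, j]
    idx = [i, j, *ks]
    sub = corr[np.ix_(idx, idx)]
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        prec = np.linalg.pinv(sub)
    denom = np.sqrt(prec[0, 0] * prec[1, 1])
    if denom == 0 or not np.isfinite(denom):
        return 0.0
    return float(-prec[0, 1] / denom)


def _bh_reject(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask."""
    m = pvals.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order]
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = ranked <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        cutoff = np.max(np.nonzero(below)[0])
        reject[order[: cutoff + 1]] = True
    return reject


def infer_network(
    clr: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    max_k: int = 3,
    fdr: float = 0.05,
    n_candidates: int = 20,
    max_cond_pool: int = 10,
) -> nx.Graph:
    """Infer a sparse signed association network from CLR profiles.

    Parameters
    ----------
    clr
        Samples x ASVs CLR matrix.
    meta
        Optional numeric per-sample metadata; each column becomes a
        meta-variable node (``kind='meta'``).
    max_k
        Maximum size of conditioning subsets.
    fdr
        Benjamini-Hochberg false-discovery level for edge retention.
    n_candidates
        Candidate conditioning neighbours kept per node (strongest
        marginal |r| first).
    max_cond_pool
        Cap on the per-pair conditioning pool; the strongest candidates
        are retained deterministically when the pool exceeds it.

    Returns
    -------
    networkx.Graph
        Nodes carry ``kind`` ('asv' or 'meta'); edges carry ``weight``
        (marginal Pearson r), ``sign`` and ``q_value``.
    """
    frames = [clr]
    kinds = {c: "asv" for c in clr.columns}
    if meta is not None:
        numeric = meta.select_dtypes(include=[np.number])
        numeric = numeric.loc[clr.index.intersection(numeric.index)]
        numeric = numeric.reindex(clr.index)
        frames.append(numeric)
        kinds.update({c: "meta" for c in numeric.columns})
    data = pd.concat(frames, axis=1)
    data = data[sorted(data.columns)]

    n, p = data.shape
    if n <= max_k + 2:
        raise ValueError(f"need more than max_k + 2 = {max_k + 2} samples, got {n}")

    std = data.std(axis=0, ddof=0)
    constant = std[std == 0].index.tolist()
    if constant:
        warnings.warn(f"excluding constant variable(s): {constant}")
        data = data.drop(columns=constant)
        p = data.shape[1]

    names = list(data.columns)
    x = data.to_numpy(dtype=float)
    # pairwise-complete correlation to tolerate missing metadata values
    corr = pd.DataFrame(x).corr().to_numpy()
    np.fill_diagonal(corr, 1.0)

    # candidate conditioning neighbours: strongest marginal partners
    cand: list[np.ndarray] = []
    for i in range(p):
        order = np.argsort(-np.abs(corr[i]), kind="stable")
        order = order[order != i][:n_candidates]
        cand.append(order)

    pairs = list(combinations(range(p), 2))
    worst_p = np.ones(len(pairs))
    for e, (i, j) in enumerate(pairs):
        pool = [v for v in np.concatenate([cand[i], cand[j]]) if v not in (i, j)]
        pool = list(dict.fromkeys(pool))
        if len(pool) > max_cond_pool:
            strength = [max(abs(corr[i, v]), abs(corr[j, v])) for v in pool]
            keep = np.argsort(-np.asarray(strength), kind="stable")[:max_cond_pool]
            pool = [pool[k] for k in sorted(keep)]
        worst = _fisher_z_pvalue(corr[i, j], n, 0)
        # BH at level fdr can never retain a pair whose weakest-evidence
        # p exceeds fdr, so stop testing such pairs early.
        for k in range(1, max_k + 1):
            if worst > fdr:
                break
            for subset in combinations(pool, k):
                pr = _partial_corr(corr, i, j, subset)
                pv = _fisher_z_pvalue(pr, n, k)
                if pv > worst:
                    worst = pv
                    if worst > fdr:
                        break
        worst_p[e] = worst

    reject = _bh_reject(worst_p, fdr)
    # BH q-values for reporting
    order = np.argsort(worst_p, kind="stable")
    m = len(pairs)
    q = np.empty(m)
    ranked_q = worst_p[order] * m / np.arange(1, m + 1)
    q[order] = np.minimum.accumulate(ranked_q[::-1])[::-1]

    g = nx.Graph()
    for name in names:
        g.add_node(name, kind=kinds[name])
    for e, (i, j) in enumerate(pairs):
        if reject[e]:
            w = float(corr[i, j])
            g.add_edge(
                names[i],
                names[j],
                weight=w,
                sign=1 if w >= 0 else -1,
                q_value=float(min(q[e], 1.0)),
            )
    return g


def centralities(net: nx.Graph) -> pd.DataFrame:
    """Normalised degree centrality and shortest-path betweenness."""
    if net.number_of_nodes() == 0:
        return pd.DataFrame(columns=["degree_centrality", "betweenness"])
    deg = nx.degree_centrality(net)
    btw = nx.betweenness_centrality(net, normalized=False)
    return pd.DataFrame(
        {
            "degree_centrality": pd.Series(deg),
            "betweenness": pd.Series(btw),
        }
    ).sort_index()


def write_network(net: nx.Graph, edge_path, graphml_path=None, nodes_path=None) -> None:
    """Write edge-list TSV (and optional GraphML / node table)."""
    rows = [
        {
            "node_a": u,
            "node_b": v,
            "weight": d.get("weight", np.nan),
            "sign": d.get("sign", 0),
            "q_value": d.get("q_value", np.nan),
        }
        for u, v, d in sorted(net.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "sign", "q_value"]).to_csv(
        edge_path, sep="\t", index=False
    )
    if graphml_path is not None:
        nx.write_graphml(net, graphml_path)
    if nodes_path is not None:
        node_rows = [{"node": n, **d} for n, d in sorted(net.nodes(data=True))]
        pd.DataFrame(node_rows).to_csv(nodes_path, sep="\t", index=False)


def read_network(edge_path, nodes_path=None) -> nx.Graph:
    """Read a network written by :func:`write_network`."""
    g = nx.Graph()
    if nodes_path is not None:
        nodes = pd.read_csv(nodes_path, sep="\t")
        for _, row in nodes.iterrows():
            attrs = row.drop("node").to_dict()
            g.add_node(str(row["node"]), **attrs)
    edges = pd.read_csv(edge_path, sep="\t")
    for _, row in edges.iterrows():
        g.add_edge(
            str(row["node_a"]),
            str(row["node_b"]),
            weight=float(row["weight"]),
            sign=int(row["sign"]),
            q_value=float(row["q_value"]),
        )
    return g
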