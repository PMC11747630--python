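"""Subnetwork (module) delineation from CLR abundance profiles.

The procedure follows weighted correlation network analysis: a signed
adjacency ``a_ij = ((1 + r_ij)/2)^beta`` with soft-thresholding power
``beta`` (default 6), the topological overlap measure (TOM) on that
adjacency, average-linkage hierarchical clustering of ``1 - TOM`` with
a static cut, module eigengenes as first principal components, and
Pearson eigengene-trait correlation with a hard significance threshold
(default p < 0.005).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "signed_adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "module_trait_correlation",
    "module_contribution",
    "module_composition",
    "ModulePartition",
]


@dataclass
class ModulePartition:
    """Per-ASV module labels; 0 marks unassigned ASVs.

    Modules are numbered 1..K by descending size, so labels are stable
    under ASV permutation.
    """

    labels: pd.Series
    min_module_size: int
    cut_height: float

    @property
    def module_ids(self) -> list[int]:
        return sorted(m for m in self.labels.unique() if m != 0)

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


def signed_adjacency(clr: pd.DataFrame, beta: int = 6) -> pd.DataFrame:
    """Signed soft-threshold adjacency ((1 + r)/2)^beta.

    Anti-correlated pairs get adjacency near 0, perfectly correlated
    pairs exactly 1; ``beta`` sharpens the contrast.
    """
    if clr.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if beta < 1:
        raise ValueError("beta must be >= 1")
    std = clr.std(axis=0, ddof=0)
    dead = std[std == 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance ASV(s): {dead[:5]}")
    r = np.corrcoef(clr.to_numpy(dtype=float), rowvar=False)
    a = ((1.0 + r) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    a = np.clip((a + a.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(a, index=clr.columns, columns=clr.columns)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap measure of a signed adjacency matrix.

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    with connectivity ``k_i = sum_{u != i} a_iu``; shared neighbours
    raise the overlap beyond the direct adjacency. ``TOM_ii = 1``.
    """
    a = adj.to_numpy(dtype=float)
    if (a < 0).any() or (a > 1).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # sum_u a_iu a_uj (diagonal of a is zero)
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def _gap_cut_height(heights: np.ndarray) -> float:
    """Static cut height at the largest merge-height gap.

    Only gaps in the upper half of the sorted merge heights are
    candidates, so near-duplicate leaves at the bottom of the tree do
    not attract the cut. When every merge happens at essentially the
    same height there is no module structure and the cut falls below
    the lowest merge (everything becomes a singleton).
    """
    heights = np.sort(heights)
    if heights.size == 1 or heights[-1] - heights[0] < 1e-9:
        return heights[0] - 1e-9
    start = (heights.size - 1) // 2
    gaps = np.diff(heights)
    upper = gaps[start:]
    best = start + int(np.argmax(upper))
    return float((heights[best] + heights[best + 1]) / 2.0)


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 10,
    cut_height: float | None = None,
) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM with a static tree cut.

    With ``cut_height=None`` (default) the cut is placed in the widest
    gap of the upper merge heights, which adapts to the overall TOM
    level of the data; passing a number fixes the cut at that
    dissimilarity. Clusters smaller than ``min_module_size`` are
    labelled 0 (unassigned); surviving modules are renumbered by
    descending size (ties broken by smallest member id).
    """
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    n = dissim.shape[0]
    if n == 1:
        raw = np.array([1])
        cut_height = 0.0 if cut_height is None else cut_height
    else:
        link = hierarchy.linkage(squareform(dissim, checks=False), method="average")
        if cut_height is None:
            cut_height = _gap_cut_height(link[:, 2])
        raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=tom.index)

    sizes = labels.value_counts()
    keep = sizes[sizes >= min_module_size]
    # renumber by descending size; deterministic tie-break on member ids
    ranked = sorted(
        keep.index,
        key=lambda m: (-keep[m], min(labels.index[labels == m])),
    )
    mapping = {old: new for new, old in enumerate(ranked, start=1)}
    final = labels.map(lambda m: mapping.get(m, 0)).astype(int)
    if (final == 0).all():
        warnings.warn("no module reached min_module_size; all ASVs unassigned")
    return ModulePartition(final, min_module_size, cut_height)


def module_eigengene(
    clr: pd.DataFrame, partition: ModulePartition
) -> tuple[pd.DataFrame, pd.Series]:
    """Module eigengenes: first PC of standardized member profiles.

    Each eigengene has unit norm over samples and is sign-oriented so
    that its correlation with the module's mean standardized profile is
    non-negative. Returns (module x sample eigengenes, per-module
    variance-explained fraction). Singleton modules return their
    standardized profile and are flagged by variance explained 1.
    """
    modules = partition.module_ids
    eig = np.zeros((len(modules), clr.shape[0]))
    varex = np.zeros(len(modules))
    for mi, m in enumerate(modules):
        members = partition.members(m)
        x = clr[members].to_numpy(dtype=float)
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
        if x.shape[1] == 1:
            v = x[:, 0]
            varex[mi] = 1.0
        else:
            u, s, _ = np.linalg.svd(x, full_matrices=False)
            v = u[:, 0]
            varex[mi] = s[0] ** 2 / (s**2).sum()
        mean_profile = x.mean(axis=1)
        if np.dot(v, mean_profile) < 0:
            v = -v
        norm = np.linalg.norm(v)
        eig[mi] = v / norm if norm > 0 else v
    eigengenes = pd.DataFrame(
        eig, index=[f"Sn_{m}" for m in modules], columns=clr.index
    )
    return eigengenes, pd.Series(varex, index=eigengenes.index, name="variance_explained")


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    p_threshold: float = 0.005,
) -> pd.DataFrame:
    """Pearson eigengene-trait correlations with a hard p threshold.

    Missing trait values are pairwise-deleted; p-values come from the
    exact t transform of r. Returns a long table with columns
    (module, trait, r, p_value, n, significant).
    """
    traits = traits.select_dtypes(include=[np.number])
    shared = eigengenes.columns.intersection(traits.index)
    if len(shared) < 4:
        raise ValueError("need at least 4 shared samples")
    rows = []
    for m in eigengenes.index:
        e = eigengenes.loc[m, shared].to_numpy(dtype=float)
        for t in traits.columns:
            y = traits.loc[shared, t].to_numpy(dtype=float)
            ok = np.isfinite(y) & np.isfinite(e)
            n = int(ok.sum())
            if n < 4 or np.std(y[ok]) == 0 or np.std(e[ok]) == 0:
                rows.append((m, t, np.nan, np.nan, n, False))
                continue
            r, p = stats.pearsonr(e[ok], y[ok])
            rows.append((m, t, float(r), float(p), n, bool(p < p_threshold)))
    return pd.DataFrame(
        rows, columns=["module", "trait", "r", "p_value", "n", "significant"]
    )


def module_contribution(
    relabund: pd.DataFrame, partition: ModulePartition
) -> pd.DataFrame:
    """Per-sample summed relative abundance of each module's members.

    Rows are modules (plus ``unassigned``), columns samples; each
    column sums to 1.
    """
    groups = {f"Sn_{m}": partition.members(m) for m in partition.module_ids}
    groups["unassigned"] = list(partition.labels.index[partition.labels == 0])
    rows = {
        name: relabund[members].sum(axis=1) if members else pd.Series(0.0, index=relabund.index)
        for name, members in groups.items()
    }
    return pd.DataFrame(rows).T


def module_composition(
    relabund: pd.DataFrame,
    partition: ModulePartition,
    taxonomy: pd.DataFrame,
    rank: str = "order",
) -> pd.DataFrame:
    """Within-module relative share of each taxon at the given rank.

    Missing rank values are grouped as ``unclassified``; shares within
    each module sum to 1.
    """
    if rank not in taxonomy.columns:
        raise KeyError(f"rank {rank!r} not in taxonomy columns {list(taxonomy.columns)}")
    tax = taxonomy[rank].reindex(relabund.columns).fillna("unclassified")
    tax = tax.replace("", "unclassified")
    totals = relabund.sum(axis=0)
    out = {}
    for m in partition.module_ids:
        members = partition.members(m)
        per_taxon = totals[members].groupby(tax[members]).sum()
        total = per_taxon.sum()
        out[f"Sn_{m}"] = per_taxon / total if total > 0 else per_taxon
    return pd.DataFrame(out).fillna(0.0).T
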