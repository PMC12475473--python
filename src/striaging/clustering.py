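"""Two-tier SNN-modularity clustering and age-dominance calls.

Tier 1 clusters the pooled normalized matrix: per-gene z-scoring (capped at
+/-10), PCA (top 30 components), a shared-nearest-neighbor graph with
Jaccard edge weights, and Leiden modularity optimization at resolution
0.08. Tier 2 subsets one tier-1 cell class and re-clusters it at a higher
resolution (0.10 by default) to expose subtypes within the class. A
subcluster is called young- or aged-dominant when strictly more than 70% of
its cells come from that age group; otherwise it is "common".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import AGE_LEVELS, CountMatrix

logger = logging.getLogger("striaging")

#: Seurat-convention SNN pruning: drop Jaccard weights below 1/15
SNN_PRUNE = 1.0 / 15.0


@dataclass
class ClusterAssignment:
    """Tier-1 (and optionally tier-2) labels per cell plus the parameters used."""

    tier1: pd.Series  # cell_id -> str label
    tier2: pd.Series | None = None  # labels only for the re-clustered class
    params: dict = field(default_factory=dict)

    def with_tier2(self, tier2: pd.Series, params: dict) -> "ClusterAssignment":
        merged = dict(self.params)
        merged["tier2"] = params
        return ClusterAssignment(tier1=self.tier1, tier2=tier2, params=merged)


def _scale_cap(dense: np.ndarray, cap: float = 10.0) -> np.ndarray:
    mu = dense.mean(axis=0)
    sd = dense.std(axis=0)
    sd[sd == 0] = 1.0
    return np.clip((dense - mu) / sd, -cap, cap)


def snn_graph(pcs: np.ndarray, k_neighbors: int) -> ig.Graph:
    """KNN -> shared-nearest-neighbor graph with Jaccard weights, pruned."""
    n = pcs.shape[0]
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(pcs)
    adj = nn.kneighbors_graph(pcs, mode="connectivity")  # excludes self
    adj = adj + sp.eye(n, format="csr")  # Seurat counts the cell itself
    shared = adj @ adj.T
    shared = sp.triu(shared, k=1).tocoo()
    kk = k + 1
    jac = shared.data / (2 * kk - shared.data)
    keep = jac >= SNN_PRUNE
    edges = list(zip(shared.row[keep].tolist(), shared.col[keep].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = jac[keep].tolist()
    return g


def cluster_cells(
    norm_matrix: CountMatrix,
    n_pcs: int = 30,
    k_neighbors: int = 20,
    resolution: float = 0.08,
    seed: int = 0,
) -> ClusterAssignment:
    """PCA -> SNN graph -> Leiden modularity communities; deterministic per seed."""
    n_cells, n_genes = norm_matrix.matrix.shape
    if n_cells < k_neighbors + 1:
        raise ValueError(f"need at least k_neighbors+1={k_neighbors + 1} cells, got {n_cells}")
    max_pcs = min(n_cells - 1, n_genes)
    if n_pcs > max_pcs:
        logger.warning("reducing n_pcs from %d to %d for %d cells x %d genes",
                       n_pcs, max_pcs, n_cells, n_genes)
        n_pcs = max_pcs
    scaled = _scale_cap(norm_matrix.to_dense())
    if np.allclose(scaled, scaled[0], atol=1e-12):
        labels = pd.Series("0", index=norm_matrix.cell_ids, name="tier1")
        return ClusterAssignment(tier1=labels, params={"n_pcs": n_pcs, "degenerate": True})
    pcs = PCA(n_components=n_pcs, svd_solver="full", random_state=seed).fit_transform(scaled)
    graph = snn_graph(pcs, k_neighbors)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = pd.Series(
        [str(m) for m in part.membership], index=norm_matrix.cell_ids, name="tier1"
    )
    params = {"n_pcs": n_pcs, "k_neighbors": k_neighbors,
              "resolution": resolution, "seed": seed}
    return ClusterAssignment(tier1=labels, params=params)


def subset_recluster(
    assignment: ClusterAssignment,
    class_label: str,
    norm_matrix: CountMatrix,
    n_pcs: int = 30,
    k_neighbors: int = 20,
    resolution: float = 0.10,
    seed: int = 0,
    min_cells: int = 20,
) -> ClusterAssignment:
    """Re-cluster one tier-1 cell class; tier-1 labels are untouched."""
    if class_label not in set(assignment.tier1):
        raise ValueError(f"class {class_label!r} not present in tier-1 labels")
    mask = (assignment.tier1 == class_label).to_numpy()
    if mask.sum() < min_cells:
        raise ValueError(
            f"class {class_label!r} has only {int(mask.sum())} cells "
            f"(< {min_cells}); refusing to subcluster"
        )
    sub = norm_matrix.subset_cells(mask)
    inner = cluster_cells(sub, n_pcs=n_pcs, k_neighbors=min(k_neighbors, sub.n_cells - 1),
                          resolution=resolution, seed=seed)
    tier2 = inner.tier1.rename("tier2")
    return assignment.with_tier2(tier2, inner.params)


@dataclass
class DominanceCall:
    cluster_id: str
    n_young: int
    n_aged: int
    frac_aged: float
    label: str  # young | aged | common


def classify_dominance(
    cluster_labels: pd.Series,
    age_labels: pd.Series,
    threshold: float = 0.70,
) -> pd.DataFrame:
    """Call each cluster young/aged-dominant or common.

    A cluster is aged-dominant if strictly more than ``threshold`` of its
    cells are aged, young-dominant if strictly more than ``threshold`` are
    young, otherwise common. Ties and the exact threshold resolve to common.
    """
    bad = set(age_labels.unique()) - set(AGE_LEVELS)
    if bad:
        raise ValueError(f"age labels outside {AGE_LEVELS}: {sorted(bad)}")
    age = age_labels.reindex(cluster_labels.index)
    if age.isna().any():
        raise ValueError("every clustered cell needs an age label")
    rows = []
    for cid, grp in age.groupby(cluster_labels, observed=True):
        n = len(grp)
        if n == 0:
            logger.warning("empty cluster %s excluded from dominance calls", cid)
            continue
        n_aged = int((grp == "aged").sum())
        n_young = n - n_aged
        frac_aged = n_aged / n
        if frac_aged > threshold:
            label = "aged"
        elif (1.0 - frac_aged) > threshold:
            label = "young"
        else:
            label = "common"
        rows.append(DominanceCall(str(cid), n_young, n_aged, frac_aged, label))
    out = pd.DataFrame([vars(r) for r in rows])
    return out.sort_values("cluster_id", ignore_index=True) if len(out) else out
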