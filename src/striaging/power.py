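"""Subsampling power curves for subcluster detection.

For each target total cell number, the dataset is repeatedly subsampled
without replacement and re-clustered from scratch; a reference subtype
counts as detected in a replicate when some subsampled cluster's membership
has Jaccard overlap >= 0.5 with the subtype's subsampled members. The
detection frequency over replicates, as a function of subsample size, is
the power curve — it answers whether the dataset holds enough cells to
resolve each subtype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import cluster_cells
from .io import CountMatrix

logger = logging.getLogger("striaging")


@dataclass
class PowerCurve:
    table: pd.DataFrame  # columns: subtype, size, frequency
    n_reps: int
    seed: int
    match_jaccard: float
    cluster_params: dict


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def detection_power(
    norm_matrix: CountMatrix,
    reference_labels: pd.Series,
    size_grid,
    n_reps: int = 20,
    cluster_params: dict | None = None,
    match_jaccard: float = 0.5,
    seed: int = 0,
    subtypes: list[str] | None = None,
) -> PowerCurve:
    """Detection frequency per reference subtype over a grid of subsample sizes.

    ``reference_labels`` come from the full-data clustering (or planted
    truth); they are fixed, not re-derived per replicate. Sizes below the
    clustering neighborhood size are skipped with a warning.
    """
    params = dict(cluster_params or {})
    k_neighbors = params.get("k_neighbors", 20)
    size_grid = sorted(int(s) for s in size_grid)
    if size_grid and size_grid[-1] > norm_matrix.n_cells:
        raise ValueError("subsample sizes exceed the dataset size")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels = reference_labels.reindex(norm_matrix.cell_ids)
    if subtypes is None:
        subtypes = sorted(labels.dropna().unique())
    else:
        subtypes = list(subtypes)  # may include subtypes with zero cells
    ref_members = {s: set(labels.index[labels == s]) for s in subtypes}

    rng = np.random.default_rng(seed)
    rows = []
    for size in size_grid:
        if size < k_neighbors + 1:
            logger.warning("size %d < k_neighbors+1; skipped", size)
            continue
        detected = {s: 0 for s in subtypes}
        for _ in range(n_reps):
            idx = rng.choice(norm_matrix.n_cells, size=size, replace=False)
            sub = norm_matrix.subset_cells(np.sort(idx))
            rep_seed = int(rng.integers(0, 2**31 - 1))
            assignment = cluster_cells(sub, seed=rep_seed, **params)
            clusters = [set(assignment.tier1.index[assignment.tier1 == c])
                        for c in assignment.tier1.unique()]
            sub_ids = set(sub.cell_ids)
            for s in subtypes:
                target = ref_members[s] & sub_ids
                if not target:
                    continue
                if any(_jaccard(c, target) >= match_jaccard for c in clusters):
                    detected[s] += 1
        for s in subtypes:
            rows.append({"subtype": s, "size": size,
                         "frequency": detected[s] / n_reps})
    table = pd.DataFrame(rows, columns=["subtype", "size", "frequency"])
    return PowerCurve(table=table, n_reps=n_reps, seed=seed,
                      match_jaccard=match_jaccard, cluster_params=params)


def plot_power_curves(curve: PowerCurve, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    for s, grp in curve.table.groupby("subtype"):
        ax.plot(grp["size"], grp["frequency"], marker="o", label=str(s))
    ax.set_xlabel("subsampled cells")
    ax.set_ylabel("detection frequency")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
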