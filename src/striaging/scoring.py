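"""Per-cell composite aging score with expression-matched controls.

The score of a cell is the mean log-normalized expression of a gene module
(by default the top-20 aging DEGs) minus the mean expression of control
genes matched for expression level: all genes are cut into expression
strata (equal-frequency bins of dataset-average expression, 24 by default),
and for each module gene 100 control genes are drawn at random from its
stratum, module genes excluded. Controls are pooled across module genes and
de-duplicated before averaging. A positive score means the module is
expressed above its expression-matched background in that cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix

logger = logging.getLogger("striaging")


@dataclass
class ModuleScoreParams:
    gene_set: list[str]
    n_ctrl: int = 100
    n_bins: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.gene_set:
            raise ValueError("gene_set must be nonempty")
        if self.n_ctrl < 1 or self.n_bins < 1:
            raise ValueError("n_ctrl and n_bins must be >= 1")


def module_score(norm_matrix: CountMatrix, params: ModuleScoreParams) -> pd.Series:
    """Module mean minus pooled expression-matched control mean, per cell."""
    genes = norm_matrix.gene_ids
    missing = [g for g in params.gene_set if g not in genes]
    if missing:
        raise KeyError(f"module genes absent from matrix: {missing}")
    dense = norm_matrix.to_dense()
    avg = dense.mean(axis=0)

    # equal-frequency strata on average expression; rank-based like ntile
    n_bins = min(params.n_bins, len(genes))
    ranks = pd.Series(avg, index=genes).rank(method="first")
    strata = pd.qcut(ranks, q=n_bins, labels=False)

    module = pd.Index(params.gene_set)
    module_pos = genes.get_indexer(module)
    rng = np.random.default_rng(params.seed)
    ctrl: list[str] = []
    for g in module:
        stratum = strata[g]
        pool = strata.index[(strata == stratum) & ~strata.index.isin(module)]
        if len(pool) == 0:
            logger.warning("no control candidates in the stratum of %s; skipped", g)
            continue
        if len(pool) < params.n_ctrl:
            logger.warning(
                "stratum of %s has %d candidates < n_ctrl=%d; sampling with replacement",
                g, len(pool), params.n_ctrl,
            )
            picks = rng.choice(pool, size=params.n_ctrl, replace=True)
        else:
            picks = rng.choice(pool, size=params.n_ctrl, replace=False)
        ctrl.extend(picks)
    ctrl_pos = genes.get_indexer(pd.unique(pd.Series(ctrl)))
    if len(ctrl_pos) == 0:
        raise ValueError("no control genes could be drawn")
    score = dense[:, module_pos].mean(axis=1) - dense[:, ctrl_pos].mean(axis=1)
    return pd.Series(score, index=norm_matrix.cell_ids, name="aging_score")


def score_by_region(
    scores: pd.Series,
    bin_index: pd.Series,
    n_bins: int,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-bin mean score with a 95% bootstrap CI (seeded). Out-of-region
    cells (bin < 0) are ignored; empty bins report NA."""
    rng = np.random.default_rng(seed)
    rows = []
    bin_index = bin_index.reindex(scores.index)
    for j in range(n_bins):
        vals = scores[bin_index == j].to_numpy()
        if len(vals) == 0:
            rows.append({"bin": j, "n": 0, "mean": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan})
            continue
        boots = rng.choice(vals, size=(n_boot, len(vals)), replace=True).mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append({"bin": j, "n": len(vals), "mean": float(vals.mean()),
                     "ci_low": float(lo), "ci_high": float(hi)})
    return pd.DataFrame(rows)
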