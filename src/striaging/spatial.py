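"""Dorsal-ventral binning, the regional expression-probability statistic,
age-shift profiles, per-area densities, and a profile-difference test.

The tissue axis runs dorsal to ventral, y increasing ventrally, discretized
into half-open 500 µm bins [origin + i*h, origin + (i+1)*h) starting at a
caller-supplied dorsal reference (the base of the corpus callosum in the
motivating data). For subtype a and bin y the statistic is

    r[a, y] = n[a, y] / N[y]

(the subtype's share of all cells in the bin), which in *literal* mode is
divided by the subtype total sigma_a, and in *renormalized* mode (default)
rescaled so each subtype's profile sums to 1 across bins — making it a
probability distribution over the axis that confounds neither with overall
subtype abundance nor with per-bin cell density. Regional aging change is
the aged-minus-young difference of these profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("striaging")


@dataclass
class SubregionBinning:
    """Half-open dorsal-ventral bins starting at the dorsal reference."""

    origin_y: float
    bin_height: float = 500.0
    n_bins: int = 6

    def __post_init__(self) -> None:
        if self.origin_y is None:
            raise ValueError("origin_y must be supplied (dorsal reference, µm)")
        if self.bin_height <= 0:
            raise ValueError("bin_height must be > 0")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


OUT_OF_REGION = -1


def assign_subregions(cells: pd.DataFrame, binning: SubregionBinning) -> pd.Series:
    """Bin index per cell; cells dorsal to the origin or beyond the last
    bin edge get OUT_OF_REGION (-1)."""
    y = cells["y_um"].to_numpy(dtype=float)
    idx = np.floor((y - binning.origin_y) / binning.bin_height).astype(int)
    out = (idx < 0) | (idx >= binning.n_bins)
    idx[out] = OUT_OF_REGION
    if out.any():
        logger.info("%d cells flagged out-of-region", int(out.sum()))
    return pd.Series(idx, index=cells.index, name="subregion")


@dataclass
class SubregionCounts:
    """Per-subtype, per-bin cell counts with marginals.

    n[a, y] is the count of subtype-a cells in bin y; N[y] the bin total;
    n_a[a] the subtype total. Marginals are derived, so the consistency
    invariants hold by construction.
    """

    n: np.ndarray  # (n_subtypes, n_bins)
    subtypes: list[str]

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        if self.n.ndim != 2 or self.n.shape[0] != len(self.subtypes):
            raise ValueError("counts must be (n_subtypes, n_bins)")
        if (self.n < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def bin_totals(self) -> np.ndarray:  # N[y]
        return self.n.sum(axis=0)

    @property
    def subtype_totals(self) -> np.ndarray:  # sigma_a
        return self.n.sum(axis=1)


def count_subregions(
    subtype_labels: pd.Series, bin_index: pd.Series, n_bins: int
) -> SubregionCounts:
    """Tabulate subtype x bin counts, dropping out-of-region cells."""
    keep = bin_index >= 0
    tab = pd.crosstab(subtype_labels[keep], bin_index[keep])
    tab = tab.reindex(columns=range(n_bins), fill_value=0)
    subtypes = [str(s) for s in tab.index]
    return SubregionCounts(tab.to_numpy(dtype=float), subtypes)


@dataclass
class EnrichmentProfile:
    P: np.ndarray  # (n_subtypes, n_bins)
    subtypes: list[str]
    mode: str  # literal | renormalized

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=pd.Index(self.subtypes, name="subtype"),
                            columns=[f"bin{j}" for j in range(self.P.shape[1])])


def expression_probability(
    counts: SubregionCounts, mode: str = "renormalized"
) -> EnrichmentProfile:
    """Per-subtype regional profile.

    literal: P = (n[a,y]/N[y]) / sigma_a (the raw statistic, not summing to
    a fixed constant); renormalized (default): the bin shares r[a,y] are
    rescaled per subtype to sum to 1 across bins.
    """
    if mode not in ("literal", "renormalized"):
        raise ValueError(f"unknown mode {mode!r}")
    N = counts.bin_totals
    if (N == 0).any():
        logger.warning("%d empty bins; their shares set to 0", int((N == 0).sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(N > 0, counts.n / np.where(N > 0, N, 1.0), 0.0)
    if mode == "literal":
        sigma = counts.subtype_totals
        P = np.where(sigma[:, None] > 0, r / np.where(sigma[:, None] > 0, sigma[:, None], 1.0), 0.0)
    else:
        tot = r.sum(axis=1, keepdims=True)
        P = np.where(tot > 0, r / np.where(tot > 0, tot, 1.0), 0.0)
    return EnrichmentProfile(P, list(counts.subtypes), mode)


def age_shift(profile_young: EnrichmentProfile, profile_aged: EnrichmentProfile) -> pd.DataFrame:
    """delta[a, y] = P_aged - P_young; sums to 0 per subtype in renormalized mode."""
    if profile_young.subtypes != profile_aged.subtypes:
        raise ValueError("profiles cover different subtype sets")
    if profile_young.P.shape != profile_aged.P.shape:
        raise ValueError("profiles use different binnings")
    if profile_young.mode != profile_aged.mode:
        raise ValueError("profiles computed in different modes")
    delta = profile_aged.P - profile_young.P
    return pd.DataFrame(delta, index=pd.Index(profile_young.subtypes, name="subtype"),
                        columns=[f"bin{j}" for j in range(delta.shape[1])])


def density_per_area(
    cells: pd.DataFrame,
    marker_mask,
    binning: SubregionBinning,
    window_um: float = 500.0,
) -> np.ndarray:
    """Mean count of subset cells per window_um x window_um window, per
    dorsal-ventral bin. The x extent is tiled from the minimum x of all
    cells; bin rows shorter than one window still count as one."""
    mask = np.asarray(marker_mask, dtype=bool)
    bins = assign_subregions(cells, binning).to_numpy()
    x = cells["x_um"].to_numpy(dtype=float)
    x_span = x.max() - x.min() if len(x) else 0.0
    n_windows_x = max(1, int(np.ceil(x_span / window_um)))
    n_windows_y = max(1, int(round(binning.bin_height / window_um)))
    out = np.zeros(binning.n_bins)
    for j in range(binning.n_bins):
        out[j] = (mask & (bins == j)).sum() / (n_windows_x * n_windows_y)
    return out


def _interaction_f(Y: np.ndarray, groups: np.ndarray) -> tuple[float, float, float]:
    """F statistics (group, bin, interaction) from nested OLS fits on the
    long-form two-way layout: score ~ group * bin."""
    n_s, n_b = Y.shape
    y = Y.ravel()
    g = np.repeat(groups, n_b)
    b = np.tile(np.arange(n_b), n_s)
    Xg = (g[:, None] == np.unique(g)[1:]).astype(float)
    Xb = (b[:, None] == np.arange(1, n_b)).astype(float)
    inter = np.einsum("ij,ik->ijk", Xg, Xb).reshape(len(y), -1)
    ones = np.ones((len(y), 1))
    X_full = np.hstack([ones, Xg, Xb, inter])
    X_noint = np.hstack([ones, Xg, Xb])
    X_nog = np.hstack([ones, Xb])
    X_nob = np.hstack([ones, Xg])

    def rss(X):
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(r @ r)

    rss_full = rss(X_full)
    df_resid = len(y) - np.linalg.matrix_rank(X_full)
    ms_resid = rss_full / df_resid if df_resid > 0 else np.nan

    # guard: with exactly replicated profiles every SS is rounding noise
    tiny = 1e-12 * max(float(y.var() * len(y)), 1.0)

    def f_of(ss, df_num):
        ss = max(ss, 0.0)
        if ms_resid <= tiny / max(df_resid, 1):
            return 0.0
        return (ss / df_num) / ms_resid

    # Type II sums of squares: each main effect adjusted for the other,
    # the interaction adjusted for both main effects
    rss_noint = rss(X_noint)
    df_g, df_b, df_i = Xg.shape[1], n_b - 1, Xg.shape[1] * (n_b - 1)
    f_g = f_of(rss(X_nog) - rss_noint, df_g)
    f_b = f_of(rss(X_nob) - rss_noint, df_b)
    f_i = f_of(rss_noint - rss_full, df_i)
    return f_g, f_b, f_i


def profile_test(
    profiles: np.ndarray,
    group_labels,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Two-way (age x subregion) F test on per-sample profiles with a
    label-permutation p-value for the interaction.

    Parameters
    ----------
    profiles
        (n_samples, n_bins) per-sample profile matrix for one subtype.
    group_labels
        One age-group label per sample (two levels).

    Returns a dict with F_group, F_bin, F_interaction and p_interaction
    (permutation; NaN with a warning when a group has a single sample).
    """
    Y = np.asarray(profiles, dtype=float)
    groups = np.asarray(group_labels)
    if Y.ndim != 2 or Y.shape[0] != len(groups):
        raise ValueError("profiles must be (n_samples, n_bins) matching group_labels")
    if len(np.unique(groups)) != 2:
        raise ValueError("exactly two groups required")
    f_g, f_b, f_i = _interaction_f(Y, groups)
    counts = pd.Series(groups).value_counts()
    if counts.min() < 2:
        logger.warning("a group has a single sample; permutation p undefined")
        return {"F_group": f_g, "F_bin": f_b, "F_interaction": f_i,
                "p_interaction": np.nan, "n_perm": 0}
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        _, _, f_p = _interaction_f(Y, perm)
        if f_p >= f_i:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return {"F_group": f_g, "F_bin": f_b, "F_interaction": f_i,
            "p_interaction": p, "n_perm": n_perm}


def plot_profiles(
    profile_young: EnrichmentProfile,
    profile_aged: EnrichmentProfile,
    path,
) -> None:
    """Per-subtype young-vs-aged profile curves along the axis."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    subtypes = profile_young.subtypes
    fig, axes = plt.subplots(1, len(subtypes), figsize=(2.2 * len(subtypes), 2.4),
                             sharey=True, squeeze=False)
    xs = np.arange(profile_young.P.shape[1])
    for k, name in enumerate(subtypes):
        ax = axes[0, k]
        ax.plot(xs, profile_young.P[k], marker="o", label="young")
        ax.plot(xs, profile_aged.P[k], marker="s", label="aged")
        ax.set_title(name)
        ax.set_xlabel("DV bin")
    axes[0, 0].set_ylabel("expression probability")
    axes[0, 0].legend(frameon=False, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
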