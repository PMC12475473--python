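"""Synthetic spatial single-cell data with known ground truth.

Emulates the structure the downstream analyses assume: a striatal cell map
with transcriptomic subtypes, negative-binomial counts with subtype-specific
marker elevation, per-cell capture-efficiency (detection-rate) variation,
dorsal-ventral enrichment gradients per subtype, and an age condition that
shifts subtype proportions, gradients and a planted aging gene program.

The count model is gamma-Poisson (negative binomial) per gene with a
lognormal per-cell capture factor. Gene base means are lognormal around
``nb_mean`` so genes span expression strata (needed for expression-matched
control-gene binning downstream). The spatial model is one-dimensional:
each cell's dorsal-ventral bin is drawn from its subtype-and-age multinomial
weights, the y-coordinate uniform within the bin, x uniform across the
tissue width. Only the dorsal-ventral axis carries signal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import AGE_LEVELS, CountMatrix, write_cell_table, write_counts

logger = logging.getLogger("striaging")


class ConfigurationError(ValueError):
    """Raised for invalid simulation settings."""


def _default_props(n: int) -> np.ndarray:
    # mildly decreasing abundances, like real subtype size distributions
    w = np.linspace(1.6, 0.6, n)
    return w / w.sum()


def _default_weights(n_subtypes: int, n_bins: int, dorsal_shift: float = 0.0) -> np.ndarray:
    """Per-subtype bin weights: subtype s peaks at a bin position that walks
    dorsal→ventral across subtypes; ``dorsal_shift`` moves subtype 0's peak
    toward bin 0 (the aged condition of the default scenario)."""
    centers = np.linspace(0.5, n_bins - 1.5, n_subtypes)
    centers = centers.copy()
    centers[0] = max(0.0, centers[0] - dorsal_shift)
    bins = np.arange(n_bins)
    w = np.exp(-0.5 * ((bins[None, :] - centers[:, None]) / 1.0) ** 2)
    return w / w.sum(axis=1, keepdims=True)


@dataclass
class SimulationConfig:
    """Ground-truth parameters of one simulated two-age spatial dataset.

    Defaults mirror the study design: 7 astrocyte-like subtypes along six
    500 µm dorsal-ventral bins, 4 animals per age group, ~10 marker genes
    per subtype, a 20-gene aging program, and an aged condition in which
    subtype 0 both expands and shifts dorsally.
    """

    n_cells_per_age: int = 2000
    n_genes: int = 250
    n_subtypes: int = 7
    subtype_props_young: np.ndarray | None = None
    subtype_props_aged: np.ndarray | None = None
    spatial_weights_young: np.ndarray | None = None  # (n_subtypes, n_bins)
    spatial_weights_aged: np.ndarray | None = None
    marker_log2fc: float = 2.0
    n_markers_per_subtype: int = 10
    aging_program_genes: int = 20
    aging_log2fc: float = 1.0
    nb_mean: float = 0.8
    nb_dispersion: float = 2.0
    detection_noise_sd: float = 0.3
    n_bins: int = 6
    bin_height_um: float = 500.0
    tissue_width_um: float = 1000.0
    n_samples_per_age: int = 4
    n_mito_genes: int = 5
    frac_low_quality: float = 0.02
    mean_volume_um3: float = 100.0
    volume_sd_log: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cells_per_age, self.n_genes, self.n_subtypes,
               self.n_markers_per_subtype, self.n_bins) < 1:
            raise ConfigurationError("all counts must be >= 1")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.subtype_props_young is None:
            self.subtype_props_young = _default_props(self.n_subtypes)
        if self.subtype_props_aged is None:
            # aged condition: subtype 0 expands at the expense of the rest
            p = _default_props(self.n_subtypes).copy()
            if self.n_subtypes > 1:
                boost = min(0.10, 1.0 - p[0])
                p[1:] *= (1.0 - p[0] - boost) / p[1:].sum()
                p[0] += boost
            self.subtype_props_aged = p
        if self.spatial_weights_young is None:
            self.spatial_weights_young = _default_weights(self.n_subtypes, self.n_bins)
        if self.spatial_weights_aged is None:
            self.spatial_weights_aged = _default_weights(
                self.n_subtypes, self.n_bins, dorsal_shift=1.0
            )
        for name in ("subtype_props_young", "subtype_props_aged"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if v.shape != (self.n_subtypes,) or (v < 0).any() or abs(v.sum() - 1) > 1e-9:
                raise ConfigurationError(f"{name} is not a probability vector over subtypes")
        for name in ("spatial_weights_young", "spatial_weights_aged"):
            w = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, w)
            if w.shape != (self.n_subtypes, self.n_bins) or (w < 0).any():
                raise ConfigurationError(f"{name} must be nonnegative (n_subtypes, n_bins)")
            if np.abs(w.sum(axis=1) - 1).max() > 1e-9:
                raise ConfigurationError(f"rows of {name} must each sum to 1")
        n_special = self.n_subtypes * self.n_markers_per_subtype + self.aging_program_genes
        if n_special + self.n_mito_genes > self.n_genes:
            raise ConfigurationError(
                f"n_genes={self.n_genes} too small for {n_special} marker/program genes "
                f"plus {self.n_mito_genes} mitochondrial genes"
            )

    @classmethod
    def dorsal_shift(cls, seed: int = 0, subtype_index: int = 3,
                     shift_bins: float = 2.0, **kwargs) -> "SimulationConfig":
        """A parameter-recovery scenario: one mid-tissue subtype's spatial
        profile moves ``shift_bins`` bins dorsally in the aged condition,
        all other subtypes unchanged. A two-bin shift makes the sign of the
        regional age shift identifiable at the default sample size (the
        analytic expected profile difference exceeds sampling noise)."""
        cfg = cls(seed=seed, **kwargs)
        centers = np.linspace(0.5, cfg.n_bins - 1.5, cfg.n_subtypes)
        bins = np.arange(cfg.n_bins)
        Wy = _default_weights(cfg.n_subtypes, cfg.n_bins)
        Wa = Wy.copy()
        wa = np.exp(-0.5 * ((bins - (centers[subtype_index] - shift_bins)) / 1.0) ** 2)
        Wa[subtype_index] = wa / wa.sum()
        cfg.spatial_weights_young = Wy
        cfg.spatial_weights_aged = Wa
        return cfg

    @classmethod
    def null(cls, **kwargs) -> "SimulationConfig":
        """A configuration with every aging effect zeroed: identical subtype
        proportions, identical spatial weights, no aging-program shift."""
        cfg = cls(**kwargs)
        cfg.subtype_props_aged = cfg.subtype_props_young.copy()
        cfg.spatial_weights_aged = cfg.spatial_weights_young.copy()
        cfg.aging_log2fc = 0.0
        return cfg


@dataclass
class GroundTruth:
    """Planted labels and effects recorded alongside a simulated dataset."""

    subtype_labels: pd.Series  # cell_id -> subtype name
    markers: dict[str, list[str]]  # subtype -> marker genes
    aging_program: list[str]
    spatial_weights_young: np.ndarray
    spatial_weights_aged: np.ndarray
    subtype_props_young: np.ndarray
    subtype_props_aged: np.ndarray
    capture_factor: pd.Series  # cell_id -> per-cell capture multiplier

    def to_json(self, path: str | Path) -> None:
        payload = {
            "subtype_labels": self.subtype_labels.to_dict(),
            "markers": self.markers,
            "aging_program": list(self.aging_program),
            "spatial_weights_young": self.spatial_weights_young.tolist(),
            "spatial_weights_aged": self.spatial_weights_aged.tolist(),
            "subtype_props_young": self.subtype_props_young.tolist(),
            "subtype_props_aged": self.subtype_props_aged.tolist(),
            "capture_factor": {k: float(v) for k, v in self.capture_factor.items()},
        }
        Path(path).write_text(json.dumps(payload))


def simulate_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, CountMatrix, GroundTruth]:
    """Draw one two-age spatial dataset from the generative model.

    Returns the cell table (both age groups pooled), the sparse count
    matrix, and the ground truth. All randomness flows from ``config.seed``
    through a single :class:`numpy.random.Generator`.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_total = 2 * cfg.n_cells_per_age

    gene_ids = _gene_names(cfg)
    subtype_names = [f"A{i + 1}" for i in range(cfg.n_subtypes)]
    markers, aging_program = _assign_special_genes(cfg, gene_ids)

    # --- cell-level attributes -------------------------------------------
    ages = np.repeat(list(AGE_LEVELS), cfg.n_cells_per_age)  # young then aged
    subtype_idx = np.empty(n_total, dtype=int)
    bin_idx = np.empty(n_total, dtype=int)
    for a, (props, weights) in enumerate([
        (cfg.subtype_props_young, cfg.spatial_weights_young),
        (cfg.subtype_props_aged, cfg.spatial_weights_aged),
    ]):
        sl = slice(a * cfg.n_cells_per_age, (a + 1) * cfg.n_cells_per_age)
        s = rng.choice(cfg.n_subtypes, size=cfg.n_cells_per_age, p=props)
        subtype_idx[sl] = s
        # vectorised bin draw: per-cell categorical with subtype-specific rows
        u = rng.random(cfg.n_cells_per_age)
        cum = np.cumsum(weights, axis=1)
        bin_idx[sl] = (u[:, None] > cum[s]).sum(axis=1)

    y_um = (bin_idx + rng.random(n_total)) * cfg.bin_height_um
    x_um = rng.random(n_total) * cfg.tissue_width_um
    volume = np.exp(rng.normal(np.log(cfg.mean_volume_um3), cfg.volume_sd_log, n_total))
    capture = np.exp(rng.normal(0.0, cfg.detection_noise_sd, n_total))
    sample_id = np.array([
        f"{age}_{rng_sample + 1}"
        for age, rng_sample in zip(ages, rng.integers(0, cfg.n_samples_per_age, n_total))
    ])
    cell_ids = pd.Index([f"cell{i:06d}" for i in range(n_total)])

    # --- gene means and counts -------------------------------------------
    sd = 1.0
    base_mu = np.exp(rng.normal(np.log(cfg.nb_mean) - sd**2 / 2, sd, cfg.n_genes))
    gene_pos = pd.Index(gene_ids)
    # aging-program genes are robustly detected in real data (a program is
    # called on genes the assay sees): floor their base mean at the
    # panel-typical level so the planted shift is identifiable rather than
    # drowned in dropout. Markers keep their drawn means — their elevation
    # is strong and their background detection should stay low.
    if aging_program:
        prog_cols = gene_pos.get_indexer(aging_program)
        base_mu[prog_cols] = np.maximum(base_mu[prog_cols], cfg.nb_mean)
    mu = np.tile(base_mu, (n_total, 1))
    for k, name in enumerate(subtype_names):
        cols = gene_pos.get_indexer(markers[name])
        mu[np.ix_(subtype_idx == k, cols)] *= 2.0 ** cfg.marker_log2fc
    if aging_program:
        cols = gene_pos.get_indexer(aging_program)
        mu[np.ix_(ages == "aged", cols)] *= 2.0 ** cfg.aging_log2fc
    # low-quality cells with inflated mitochondrial load
    n_mito = cfg.n_mito_genes
    if n_mito and cfg.frac_low_quality > 0:
        lowq = rng.random(n_total) < cfg.frac_low_quality
        mito_cols = np.arange(n_mito)  # mito genes lead the panel
        mu[np.ix_(lowq, mito_cols)] *= 25.0
    mu *= capture[:, None]

    r = cfg.nb_dispersion
    lam = rng.gamma(shape=r, scale=mu / r)
    counts = rng.poisson(lam)
    matrix = sp.csr_matrix(counts, dtype=np.int64)

    subtype_labels = pd.Series(
        [subtype_names[k] for k in subtype_idx], index=cell_ids, name="subtype"
    )
    cells = pd.DataFrame({
        "cell_id": cell_ids,
        "x_um": x_um,
        "y_um": y_um,
        "volume_um3": volume,
        "sample_id": sample_id,
        "age": ages,
        "cluster": subtype_labels.to_numpy(),
    })
    truth = GroundTruth(
        subtype_labels=subtype_labels,
        markers=markers,
        aging_program=aging_program,
        spatial_weights_young=cfg.spatial_weights_young,
        spatial_weights_aged=cfg.spatial_weights_aged,
        subtype_props_young=cfg.subtype_props_young,
        subtype_props_aged=cfg.subtype_props_aged,
        capture_factor=pd.Series(capture, index=cell_ids, name="capture_factor"),
    )
    return cells, CountMatrix(matrix, cell_ids, pd.Index(gene_ids)), truth


def _gene_names(cfg: SimulationConfig) -> list[str]:
    mito = [f"mt-G{i + 1}" for i in range(cfg.n_mito_genes)]
    rest = [f"gene{i + 1:04d}" for i in range(cfg.n_genes - cfg.n_mito_genes)]
    return mito + rest


def _assign_special_genes(cfg, gene_ids) -> tuple[dict[str, list[str]], list[str]]:
    """Disjoint marker sets per subtype, then the aging program, taken from
    the non-mitochondrial tail of the panel (deterministic layout)."""
    pool = gene_ids[cfg.n_mito_genes:]
    markers: dict[str, list[str]] = {}
    cursor = 0
    for k in range(cfg.n_subtypes):
        markers[f"A{k + 1}"] = list(pool[cursor:cursor + cfg.n_markers_per_subtype])
        cursor += cfg.n_markers_per_subtype
    aging = list(pool[cursor:cursor + cfg.aging_program_genes])
    return markers, aging


def write_fixture(
    cells: pd.DataFrame,
    counts: CountMatrix,
    truth: GroundTruth,
    out_dir: str | Path,
) -> None:
    """Write a simulated dataset as MTX + TSV sidecars + metadata CSV +
    ground-truth JSON, round-trippable through :func:`striaging.io.read_counts`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_counts(counts, out_dir)
    write_cell_table(cells, out_dir / "metadata.csv")
    truth.to_json(out_dir / "ground_truth.json")
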