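"""End-to-end pipeline: QC -> clustering -> dominance -> markers -> aging
DEGs -> spatial profiles -> aging score -> optional power analysis.

Every stage writes a TSV; a JSON run report records parameters, the seed,
and the cell/gene counts surviving each filter. Any stage failure halts
with the stage name and cause.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering as cl
from . import de as de_mod
from . import qc as qc_mod
from . import scoring, spatial
from .config import PipelineConfig
from .io import CountMatrix, read_cell_table, read_counts, write_tsv
from .power import detection_power, plot_power_curves
from .simulate import GroundTruth  # noqa: F401  (re-exported for callers)

logger = logging.getLogger("striaging")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, in_dir: str | Path, out_dir: str | Path) -> dict:
    """Run every stage on a dataset directory (MTX + metadata.csv).

    Returns the run report (also written to ``report.json``).
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "platform": config.platform, "stages": []}

    def stage(name):
        report["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        stage("load")
        counts = read_counts(in_dir)
        cells = read_cell_table(in_dir / "metadata.csv",
                                require_volume=config.platform == "merfish")
        report["n_cells_in"], report["n_genes_in"] = counts.n_cells, counts.n_genes
    except Exception as exc:
        raise StageError("load", exc) from exc

    try:
        stage("qc")
        if config.platform == "merfish":
            counts, cells = qc_mod.filter_merfish(counts, cells, config.qc)
        else:
            mito = np.array([g.lower().startswith("mt-") for g in counts.gene_ids])
            counts = qc_mod.filter_scrnaseq(counts, mito, config.qc)
            cells = cells.set_index("cell_id").loc[counts.cell_ids].rename_axis("cell_id").reset_index()
        norm = qc_mod.normalize_log(counts, scale_factor=config.qc.scale_factor)
        report["n_cells_qc"], report["n_genes_qc"] = counts.n_cells, counts.n_genes
    except Exception as exc:
        raise StageError("qc", exc) from exc

    cells = cells.set_index("cell_id").loc[counts.cell_ids].rename_axis("cell_id").reset_index()
    age = pd.Series(cells["age"].to_numpy(), index=counts.cell_ids)

    try:
        stage("cluster")
        p = config.clustering
        assignment = cl.cluster_cells(norm, n_pcs=p.n_pcs, k_neighbors=p.k_neighbors,
                                      resolution=p.resolution_tier1, seed=config.seed)
        largest = assignment.tier1.value_counts().idxmax()
        try:
            assignment = cl.subset_recluster(
                assignment, largest, norm, n_pcs=p.n_pcs, k_neighbors=p.k_neighbors,
                resolution=p.resolution_tier2, seed=config.seed)
        except ValueError as exc:
            logger.warning("tier-2 reclustering skipped: %s", exc)
        out = pd.DataFrame({"cell_id": assignment.tier1.index,
                            "tier1": assignment.tier1.to_numpy()})
        out["tier2"] = assignment.tier2.reindex(out["cell_id"]).to_numpy() \
            if assignment.tier2 is not None else pd.NA
        write_tsv(out, out_dir / "clusters.tsv")
        report["n_tier1_clusters"] = int(assignment.tier1.nunique())
    except Exception as exc:
        raise StageError("cluster", exc) from exc

    try:
        stage("dominance")
        calls = cl.classify_dominance(assignment.tier1, age, config.dominance_threshold)
        write_tsv(calls, out_dir / "dominance.tsv")
        report["dominance_labels"] = calls["label"].value_counts().to_dict() if len(calls) else {}
    except Exception as exc:
        raise StageError("dominance", exc) from exc

    try:
        stage("markers")
        if assignment.tier1.nunique() >= 2:
            markers = de_mod.select_cluster_markers(
                norm, assignment.tier1, ratio_threshold=config.de.ratio_threshold,
                fdr_threshold=config.de.fdr_max, top_n=config.de.top_n_markers)
        else:
            logger.warning("single tier-1 cluster; marker selection skipped")
            markers = pd.DataFrame()
        write_tsv(markers, out_dir / "markers.tsv")
        report["n_marker_rows"] = len(markers)
    except Exception as exc:
        raise StageError("markers", exc) from exc

    try:
        stage("aging_degs")
        de_res = de_mod.hurdle_de(norm, age, test_group="aged")
        all_degs, top_degs = de_mod.select_aging_degs(
            de_res, log2fc_min=config.de.log2fc_min,
            fdr_max=config.de.fdr_max, top_k=config.de.top_k_aging)
        write_tsv(de_res.reset_index(names="gene"), out_dir / "aging_de.tsv")
        report["n_aging_degs"] = len(all_degs)
    except Exception as exc:
        raise StageError("aging_degs", exc) from exc

    try:
        stage("spatial")
        binning = spatial.SubregionBinning(
            origin_y=config.binning.origin_y, bin_height=config.binning.bin_height,
            n_bins=config.binning.n_bins)
        bin_idx = spatial.assign_subregions(cells.set_index("cell_id"), binning)
        labels = assignment.tier1
        profs = {}
        for grp in ("young", "aged"):
            m = age == grp
            sc_counts = spatial.count_subregions(labels[m], bin_idx[m.to_numpy()],
                                                 binning.n_bins)
            profs[grp] = spatial.expression_probability(sc_counts)
        common = sorted(set(profs["young"].subtypes) & set(profs["aged"].subtypes))
        for grp in ("young", "aged"):
            pr = profs[grp]
            keep = [pr.subtypes.index(s) for s in common]
            profs[grp] = spatial.EnrichmentProfile(pr.P[keep], common, pr.mode)
            write_tsv(profs[grp].as_frame().reset_index(), out_dir / f"profile_{grp}.tsv")
        delta = spatial.age_shift(profs["young"], profs["aged"])
        write_tsv(delta.reset_index(), out_dir / "age_shift.tsv")
        spatial.plot_profiles(profs["young"], profs["aged"], out_dir / "profiles.png")
    except Exception as exc:
        raise StageError("spatial", exc) from exc

    try:
        stage("aging_score")
        if top_degs:
            params = scoring.ModuleScoreParams(
                gene_set=top_degs, n_ctrl=config.score.n_ctrl,
                n_bins=config.score.n_bins, seed=config.seed)
            scores = scoring.module_score(norm, params)
            per_bin = scoring.score_by_region(scores, bin_idx, config.binning.n_bins,
                                              seed=config.seed)
            write_tsv(pd.DataFrame({"cell_id": scores.index, "score": scores.to_numpy(),
                                    "bin": bin_idx.reindex(scores.index).to_numpy()}),
                      out_dir / "aging_score.tsv")
            write_tsv(per_bin, out_dir / "aging_score_by_region.tsv")
            report["mean_aging_score_aged_minus_young"] = float(
                scores[(age == "aged").to_numpy()].mean()
                - scores[(age == "young").to_numpy()].mean())
        else:
            logger.warning("no aging DEGs; score stage skipped")
    except Exception as exc:
        raise StageError("aging_score", exc) from exc

    if config.power.enabled:
        try:
            stage("power")
            curve = detection_power(
                norm, assignment.tier1,
                size_grid=[s for s in config.power.size_grid if s <= norm.n_cells],
                n_reps=config.power.n_reps,
                cluster_params={"n_pcs": config.clustering.n_pcs,
                                "k_neighbors": config.clustering.k_neighbors,
                                "resolution": config.clustering.resolution_tier1},
                match_jaccard=config.power.match_jaccard, seed=config.seed)
            write_tsv(curve.table, out_dir / "power.tsv")
            plot_power_curves(curve, out_dir / "power.png")
        except Exception as exc:
            raise StageError("power", exc) from exc

    report["stages_completed"] = len(report["stages"])
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
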