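"""End-to-end orchestration: simulate -> extract -> cross-validate -> latent analysis.

``run_pipeline`` executes the full study analogue under one master seed:
generate (or ingest) a cohort, build the per-task feature dataset,
cross-validate the supervised VAE at the selection latent dimensionality,
pick the working dimensionality by PCA on participant latent means, retrain
at that dimensionality, fit the per-class latent Gaussians, run the
Monte-Carlo feature perturbation and the per-feature response curves, and
serialize every artifact plus a JSON run report. A failed stage aborts with
the stage name and persists a partial report.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .cohort import generate_cohort, sample_feature_table
from .config import RunConfig, _to_dict
from .exceptions import KinvaeError
from .features import FEATURE_NAMES, build_dataset
from .io import (
    save_model_bundle,
    write_features_csv,
    write_json,
    write_trajectories_csv,
)
from .latent import (
    feature_density_map,
    feature_response_curve,
    fit_class_gaussians,
    pca_explained_variance,
    perturb_feature,
    perturbation_displacements,
    project_latent,
)
from .model import VAEClassifier

logger = logging.getLogger(__name__)


class StageError(KinvaeError, RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _seed(master: int, tag: int) -> int:
    return (master * 1000003 + tag) & 0x7FFFFFFF


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; returns the run report (also written to disk)."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": _version,
        "seed": config.seed,
        "config": _to_dict(config),
        "artifacts": {},
    }
    art = report["artifacts"]
    stage = "simulate"
    try:
        cohort_cfg = dataclasses.replace(config.cohort, seed=_seed(config.seed, 1))
        if config.data_mode == "trajectories":
            logger.info("simulating trajectory cohort")
            cohort = generate_cohort(cohort_cfg)
            traj_path = outdir / "trajectories.csv"
            write_trajectories_csv(cohort, traj_path)
            art["trajectories"] = str(traj_path)
            stage = "extract"
            dataset = build_dataset(cohort)
        else:
            logger.info("sampling feature table")
            dataset = sample_feature_table(cohort_cfg)
        feat_path = outdir / "features.csv"
        write_features_csv(dataset, feat_path)
        art["features"] = str(feat_path)
        report["dataset"] = {
            "rows": dataset.n_rows,
            "features": len(FEATURE_NAMES),
            "class_counts": {int(k): int(v) for k, v in
                             zip(*np.unique(dataset.y, return_counts=True))},
            "full_cohort_rows": 2 * cohort_cfg.n_per_group * cohort_cfg.n_tasks,
        }

        stage = "cross_validation"
        sel_cfg = dataclasses.replace(config.network,
                                      latent_dim=config.selection_latent_dim)
        cv = VAEClassifier(dataset, sel_cfg).cross_validate(
            k=config.k_folds, seed=_seed(config.seed, 2))
        report["cv"] = {
            "k": cv.k,
            "fold_accuracies": cv.fold_accuracies,
            "mean_accuracy": cv.mean_accuracy,
            "sd_accuracy": cv.sd_accuracy,
            "latent_dim": config.selection_latent_dim,
        }
        logger.info("CV accuracy %.3f +/- %.3f", cv.mean_accuracy, cv.sd_accuracy)

        stage = "dimension_selection"
        selection_fit = VAEClassifier(dataset, sel_cfg).fit(seed=_seed(config.seed, 3))
        proj10 = project_latent(selection_fit, dataset)
        pca = pca_explained_variance(proj10.participant_array())
        chosen = max(2, pca.n_components_for(config.pca_threshold))
        report["pca"] = {
            "explained_variance_ratios": pca.explained_variance_ratios.tolist(),
            "threshold": config.pca_threshold,
            "selected_latent_dim": chosen,
        }
        logger.info("PCA selects %d latent variables", chosen)

        stage = "final_training"
        final_cfg = dataclasses.replace(config.network, latent_dim=chosen)
        results = VAEClassifier(dataset, final_cfg).fit(seed=_seed(config.seed, 4))
        bundle_path = outdir / "model.bundle.json"
        save_model_bundle(results.trained, bundle_path)
        art["model_bundle"] = str(bundle_path)
        projection = project_latent(results, dataset)

        stage = "class_gaussians"
        g_td, g_asd = fit_class_gaussians(projection)
        report["class_gaussians"] = {
            "TD": {"mean": g_td.mean.tolist(), "variances": g_td.variances.tolist()},
            "ASD": {"mean": g_asd.mean.tolist(), "variances": g_asd.variances.tolist()},
        }

        stage = "perturbation"
        raw_dataset = dataset  # raw feature values (standardization happens per use)
        disp = perturbation_displacements(
            results, raw_dataset, n=config.perturb_n,
            stats_scope=config.perturb_scope, seed=_seed(config.seed, 5))
        disp_path = outdir / "perturbation_displacements.csv"
        disp.to_csv(disp_path, index=False)
        art["perturbation_displacements"] = str(disp_path)
        ranking = (disp.groupby("feature")["displacement"].mean()
                   .sort_values(ascending=False))
        report["feature_displacement_ranking"] = ranking.to_dict()

        stage = "response_curves"
        curves = []
        for feat in FEATURE_NAMES:
            curve = feature_response_curve(
                results, raw_dataset, g_td, g_asd, feat,
                n_points=config.curve_points, span=config.curve_span)
            curves.append(curve)
        curve_frame = pd.concat([c.to_frame() for c in curves], ignore_index=True)
        curves_path = outdir / "response_curves.csv"
        curve_frame.to_csv(curves_path, index=False)
        art["response_curves"] = str(curves_path)

        if config.make_plots and chosen == 2:
            stage = "plots"
            from . import plotting

            plotting.plot_latent_scatter(projection, "task", outdir / "latent_tasks.png")
            plotting.plot_latent_scatter(projection, "participant",
                                         outdir / "latent_participants.png")
            plotting.plot_loss_history(results.loss_history, outdir / "loss_history.png")
            rng = np.random.default_rng(_seed(config.seed, 6))
            pids = sorted(raw_dataset.frame["participant_id"].unique())
            sample_pids = list(rng.choice(pids, size=min(10, len(pids)), replace=False))
            for feat in FEATURE_NAMES:
                traces = [perturb_feature(results, raw_dataset, pid, feat,
                                          n=config.perturb_n, seed=rng,
                                          gaussians=(g_td, g_asd))
                          for pid in sample_pids]
                H, xe, ye = feature_density_map(traces)
                plotting.plot_density_map(H, xe, ye, projection, title=feat,
                                          path=outdir / f"density_{feat}.png")
            for curve in curves:
                plotting.plot_response_curve(
                    curve, outdir / f"curve_{curve.feature_name}.png")
            art["plots_dir"] = str(outdir)
    except Exception as exc:  # persist partial report with the failing stage
        report["failed_stage"] = stage
        report["error"] = str(exc)
        write_json(report, outdir / "report.json")
        raise StageError(stage, exc) from exc

    report_path = outdir / "report.json"
    write_json(report, report_path)
    art["report"] = str(report_path)
    return report
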