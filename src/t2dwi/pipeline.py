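"""End-to-end orchestration on a phantom cohort.

Order of operations mirrors the clinical analysis: simulate (or load)
the cohort, screen voxels (noise floor + negative apparent decays),
calibrate the population T2 pair on pooled training voxels, fit all
three models per patient, summarize ROIs, and run the statistical
evaluation (paired/unpaired rank tests with Bonferroni, voxel-wise ROC
with train-to-test threshold transfer, Spearman vs tumor grade).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CostSurface, normalize_cost_surface
from .estimators import TwoComponentModel
from .fitting import FitMaps, build_exclusion_mask, fit_volume
from .phantom import Cohort, PatientRecord, simulate_cohort
from .signal_models import ComponentBasis
from .stats import (
    METRIC_COLUMNS,
    DiagnosticSummary,
    adjusted_alpha,
    paired_test,
    roi_summary,
    spearman_grade_correlation,
    threshold_transfer,
    unpaired_test,
)

from .io import PipelineConfig

log = logging.getLogger("t2dwi")

__all__ = ["PipelineResult", "run_pipeline", "pool_training_voxels", "collect_roc_voxels"]

MODELS = ("two_component", "bi_exponential", "mono")


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: Cohort
    basis: ComponentBasis
    cost_surface: CostSurface | None
    keep_masks: dict[str, np.ndarray]
    fit_maps: dict[str, dict[str, FitMaps]]  # patient -> model -> maps
    roi_table: pd.DataFrame
    comparisons: pd.DataFrame
    diagnostics: list[DiagnosticSummary]
    qc: dict


def pool_training_voxels(
    cohort: Cohort,
    keep_masks: dict[str, np.ndarray],
    max_voxels: int,
    seed: int,
) -> np.ndarray:
    """All kept box voxels of training-split patients, subsampled to a cap.

    The pooled cost is a sum, so a seeded uniform subsample changes its
    scale but not the location of the minimum in expectation.
    """
    chunks = [
        p.volume.data[keep_masks[p.patient_id]]
        for p in cohort.patients
        if p.split == "train"
    ]
    pooled = np.concatenate(chunks, axis=0)
    if len(pooled) > max_voxels:
        idx = np.random.default_rng([seed, 0xCA1]).choice(len(pooled), max_voxels, replace=False)
        pooled = pooled[np.sort(idx)]
    return pooled


def _tissue_roi_excluded_fraction(
    patients: list[PatientRecord], keep_masks: dict[str, np.ndarray]
) -> float:
    """Excluded fraction pooled over tumor/normal/BPH ROI voxels."""
    n_roi = 0
    n_excl = 0
    for p in patients:
        keep = keep_masks[p.patient_id]
        for mask in p.roi_masks.values():
            n_roi += int(mask.sum())
            n_excl += int((mask & ~keep).sum())
    return n_excl / n_roi if n_roi else float("nan")


def collect_roc_voxels(
    patients: list[PatientRecord],
    fit_maps: dict[str, dict[str, FitMaps]],
    model: str,
    split: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Valid tumor-ROI voxels vs all other valid box voxels of one split."""
    map_key, _, _ = METRIC_COLUMNS[model]
    tumor_vals: list[np.ndarray] = []
    non_vals: list[np.ndarray] = []
    for p in patients:
        if p.split != split or p.group != "cancer":
            continue
        fm = fit_maps[p.patient_id][model]
        tumor_mask = p.roi_masks["tumor"]
        tumor_vals.append(fm[map_key][fm.valid & tumor_mask])
        non_vals.append(fm[map_key][fm.valid & ~tumor_mask])
    return np.concatenate(tumor_vals), np.concatenate(non_vals)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis; optionally persist every intermediate."""
    # config.seed is the single source of randomness for the whole run
    cohort_spec = dataclasses.replace(config.cohort, seed=config.seed)
    cohort = simulate_cohort(cohort_spec, config.scheme)
    log.info("simulated %d patients (sigma=%.3f)", len(cohort.patients), cohort.sigma)

    keep_masks: dict[str, np.ndarray] = {}
    qc_per_patient: dict[str, dict] = {}
    for p in cohort.patients:
        keep, qc = build_exclusion_mask(p.volume)
        keep_masks[p.patient_id] = keep
        qc_per_patient[p.patient_id] = qc
    log.info("exclusion done; mean box excluded fraction %.3f",
             float(np.mean([q["excluded_fraction"] for q in qc_per_patient.values()])))

    # --- T2 calibration on the training split -----------------------------
    model = TwoComponentModel(
        scheme=config.scheme,
        adc_slow=config.adc_slow,
        adc_fast=config.adc_fast,
        t2_slow=config.t2_slow,
        t2_fast=config.t2_fast,
        t2_grid=config.t2_grid,
    )
    if config.t2_slow is None:
        pooled = pool_training_voxels(cohort, keep_masks, config.calibration_max_voxels, config.seed)
        model.fit(pooled)
        log.info("calibrated T2 pair: (%g, %g) ms over %d voxels",
                 model.t2_slow_, model.t2_fast_, len(pooled))
    else:
        model.fit(None)
        log.info("using fixed T2 pair: (%g, %g) ms", model.t2_slow_, model.t2_fast_)
    basis = model.basis_
    surface = model.cost_surface_

    # --- voxel-wise fits ---------------------------------------------------
    fit_maps: dict[str, dict[str, FitMaps]] = {}
    for p in cohort.patients:
        fit_maps[p.patient_id] = {
            m: fit_volume(p.volume, m, basis=basis, keep=keep_masks[p.patient_id])
            for m in MODELS
        }

    # --- ROI summaries -----------------------------------------------------
    frames = []
    for p in cohort.patients:
        meta = {
            "patient_id": p.patient_id,
            "group": p.group,
            "split": p.split,
            "zone": p.zone,
            "ggg": p.ggg,
        }
        frames.append(roi_summary(fit_maps[p.patient_id], p.roi_masks, meta))
    roi_table = pd.concat(frames, ignore_index=True)

    # --- statistics --------------------------------------------------------
    alpha = adjusted_alpha(config.alpha, config.n_comparisons)
    rows = []
    pz = roi_table[(roi_table.group == "cancer") & (roi_table.zone == "PZ")
                   & (roi_table.split == "test")]
    pz_t = pz[pz.roi == "tumor"].set_index("patient_id")
    pz_n = pz[pz.roi == "normal"].set_index("patient_id")
    common = pz_t.index.intersection(pz_n.index)
    nonpz_t = roi_table[(roi_table.group == "cancer") & (roi_table.zone == "non-PZ")
                        & (roi_table.roi == "tumor")]
    bph = roi_table[roi_table.roi == "bph"]
    test_tumors = roi_table[(roi_table.group == "cancer") & (roi_table.split == "test")
                            & (roi_table.roi == "tumor")]
    for m in MODELS:
        _, col, _ = METRIC_COLUMNS[m]
        p_pz = paired_test(pz_t.loc[common, col].to_numpy(), pz_n.loc[common, col].to_numpy())
        rows.append({"comparison": "pz_tumor_vs_normal", "metric": col, "test": "wilcoxon",
                     "n": len(common), "p_value": p_pz, "significant": p_pz < alpha})
        p_np = unpaired_test(nonpz_t[col].to_numpy(), bph[col].to_numpy())
        rows.append({"comparison": "nonpz_tumor_vs_bph", "metric": col, "test": "mann-whitney",
                     "n": len(nonpz_t) + len(bph), "p_value": p_np, "significant": p_np < alpha})
        rho, p_rho = spearman_grade_correlation(
            test_tumors[col].to_numpy(), test_tumors["ggg"].to_numpy(dtype=float)
        )
        rows.append({"comparison": "tumor_vs_ggg", "metric": col, "test": "spearman",
                     "n": len(test_tumors), "p_value": p_rho, "rho": rho,
                     "significant": p_rho < alpha})
    comparisons = pd.DataFrame(rows)
    comparisons["adjusted_alpha"] = alpha

    diagnostics = []
    for m in MODELS:
        _, col, polarity = METRIC_COLUMNS[m]
        tr_t, tr_n = collect_roc_voxels(cohort.patients, fit_maps, m, "train")
        te_t, te_n = collect_roc_voxels(cohort.patients, fit_maps, m, "test")
        diagnostics.append(
            threshold_transfer(tr_t, tr_n, te_t, te_n, polarity=polarity, metric=col)
        )

    qc = {
        "sigma": cohort.sigma,
        "per_patient": qc_per_patient,
        "tissue_roi_excluded_fraction": _tissue_roi_excluded_fraction(cohort.patients, keep_masks),
        "mean_box_excluded_fraction": float(
            np.mean([q["excluded_fraction"] for q in qc_per_patient.values()])
        ),
    }

    result = PipelineResult(
        config=config, cohort=cohort, basis=basis, cost_surface=surface,
        keep_masks=keep_masks, fit_maps=fit_maps, roi_table=roi_table,
        comparisons=comparisons, diagnostics=diagnostics, qc=qc,
    )
    if out_dir is not None:
        _persist(result, Path(out_dir))
    return result


def _persist(result: PipelineResult, out: Path) -> None:
    from .stats import roc_analysis  # local: avoid unused import at module level

    out.mkdir(parents=True, exist_ok=True)
    result.config.to_json(out / "config.json")
    result.cohort.table.to_csv(out / "cohort.csv", index=False)
    result.roi_table.to_csv(out / "roi_summary.csv", index=False)
    result.comparisons.to_csv(out / "comparisons.csv", index=False)
    pd.DataFrame([vars(d) for d in result.diagnostics]).to_csv(out / "diagnostics.csv", index=False)
    if result.cost_surface is not None:
        normalize_cost_surface(result.cost_surface).to_frame().to_csv(
            out / "cost_surface.csv", index=False
        )
        (out / "calibration.json").write_text(json.dumps({
            "t2_slow": result.basis.t2_slow, "t2_fast": result.basis.t2_fast,
            "n_voxels": result.cost_surface.n_voxels,
        }, indent=2))
    for m in MODELS:
        _, col, polarity = METRIC_COLUMNS[m]
        te_t, te_n = collect_roc_voxels(result.cohort.patients, result.fit_maps, m, "test")
        roc = roc_analysis(te_t, te_n, polarity)
        pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr, "threshold": roc.thresholds}).to_csv(
            out / f"roc_{col}.csv", index=False
        )
    (out / "qc.json").write_text(json.dumps(result.qc, indent=2, sort_keys=True))
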