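"""End-to-end pipeline: simulate -> decompose -> extract -> filter -> grade
-> screen -> fit -> cross-validated evaluation.

``run_pipeline`` orchestrates the full synthetic study: phantom nodules
exercise the imaging stages (decomposition and feature extraction), while
the per-grade feature-table simulator provides a cohort large enough for
the modeling stages (the reference cohort's images are not public).  All
randomness flows from the single top-level seed; every warning that alters
results is echoed in the run report.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .decomposition import MaterialBasis, decompose_three_material
from .errors import InvalidConfigError
from .evaluation import diagnostic_metrics, loocv_predict, roc_auc_ovr
from .features import FeatureConfig, extract_all_channels
from .model import anova_bonferroni, fit_multinomial, stepwise_select, vif_screen
from .pathology import (
    INVASIVE_PATTERNS,
    PATTERN_GRADE,
    SubtypeComposition,
    assign_grade,
)
from .reproducibility import filter_by_ccc, pairs_from_frames
from .synthetic import (
    PhantomConfig,
    TableSimConfig,
    simulate_feature_table,
    simulate_nodule_phantom,
)

logger = logging.getLogger("dectgrade")


@dataclass
class PipelineConfig:
    """All pipeline settings with defaults; unknown keys are rejected."""

    seed: int = 0
    n_phantoms: int = 6
    phantom_noise_sd: float = 5.0
    basis: dict = field(default_factory=lambda: MaterialBasis().to_dict())
    bin_width_hu: float = 1.0
    n_levels: int = 64
    g_mode: str = "spatial"
    solid_threshold_hu: float = -300.0
    apply_ccc_filter: bool = True
    ccc_threshold: float = 0.8
    retest_noise_frac: float = 0.1
    alpha_enter: float = 0.05
    alpha_remove: float = 0.05
    screen_alpha: float = 0.05
    vif_threshold: float = 10.0
    cv_mode: str = "fixed-selection"
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)


def _simulate_compositions(grades: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Subtype compositions whose predominant pattern matches each grade."""
    grade_patterns = {g: [p for p, pg in PATTERN_GRADE.items() if pg == g]
                      for g in (1, 2, 3)}
    rows = []
    for i, g in enumerate(grades):
        main = rng.choice(grade_patterns[int(g)])
        fibrosis = 5.0 * rng.integers(0, 4)
        main_pct = 5.0 * rng.integers(10, 15)  # 50-70%
        rest = 100.0 - fibrosis - main_pct
        comp = {p: 0.0 for p in INVASIVE_PATTERNS}
        comp[main] = main_pct
        others = [p for p in INVASIVE_PATTERNS if p != main]
        rng.shuffle(others)
        for p in others:
            # Minor components stay strictly below the predominant share.
            share = min(rest, 5.0 * rng.integers(0, int(main_pct / 5)))
            comp[p] += share
            rest -= share
            if rest <= 0:
                break
        comp[main] += max(0.0, rest)  # leftover goes to the main pattern
        rows.append({"tumor_id": f"T{i + 1:03d}", **comp,
                     "fibrosis": fibrosis, "histology_class": "invasive"})
    return pd.DataFrame(rows)


def grade_composition_table(comps: pd.DataFrame) -> pd.DataFrame:
    """Apply the 3-level grading rule to a composition table."""
    out = []
    for _, row in comps.iterrows():
        comp = SubtypeComposition(
            percentages={p: float(row[p]) for p in INVASIVE_PATTERNS if row.get(p, 0) > 0},
            central_fibrosis=float(row.get("fibrosis", 0.0)),
            histology_class=str(row.get("histology_class", "invasive")),
        )
        label = assign_grade(comp)
        out.append({"tumor_id": row["tumor_id"], "grade": label.grade,
                    "predominant_pattern": label.predominant_pattern,
                    "predominant_percentage": label.predominant_percentage,
                    "tie": label.tie})
    return pd.DataFrame(out)


def run_pipeline(config: PipelineConfig | None = None, out_dir=None) -> dict:
    """Execute the full synthetic workflow and return the run report.

    Artifacts (NIfTI channels, feature CSVs, fit/eval JSON, ROC SVG) are
    written under ``out_dir`` when given.  Idempotent given the seed.
    """
    config = config or PipelineConfig()
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    t0 = time.time()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "stages": {}, "warnings": []}
    rng = np.random.default_rng(config.seed)
    basis = MaterialBasis.from_dict(config.basis)
    fcfg = FeatureConfig(bin_width_hu=config.bin_width_hu, n_levels=config.n_levels,
                         g_mode=config.g_mode, solid_threshold_hu=config.solid_threshold_hu)

    # -- stage 1: phantoms through decomposition and extraction -------------
    logger.info("simulating %d phantoms", config.n_phantoms)
    phantom_rows = []
    ggo_fracs = np.linspace(0.1, 0.9, max(1, config.n_phantoms))
    for k in range(config.n_phantoms):
        pcfg = PhantomConfig(
            ggo_fraction=float(ggo_fracs[k]),
            iodine_map_spec={"kind": "uniform", "amplitude": 0.5 + 0.5 * (k % 3)},
            noise_sd=config.phantom_noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        volume, mask, gt_iodine, gt_vnc = simulate_nodule_phantom(pcfg, basis)
        channels = decompose_three_material(volume, basis)
        fv = extract_all_channels(channels, mask, fcfg, tumor_id=f"PH{k + 1:02d}")
        phantom_rows.append(fv.to_series())
        if fv.missing:
            report["warnings"].append(
                {"stage": "extract", "tumor": fv.tumor_id, "missing": fv.missing})
        if out is not None and k == 0:
            dio.write_volume(out / "phantom01_low.nii.gz", volume.low_kv, volume.spacing)
            dio.write_volume(out / "phantom01_high.nii.gz", volume.high_kv, volume.spacing)
            dio.write_mask(out / "phantom01_mask.nii.gz", mask.mask, mask.spacing)
            dio.write_volume(out / "phantom01_gt_iodine.nii.gz", gt_iodine, volume.spacing)
            dio.write_volume(out / "phantom01_gt_vnc.nii.gz", gt_vnc, volume.spacing)
    phantom_features = pd.DataFrame(phantom_rows)
    if out is not None:
        dio.write_feature_csv(out / "phantom_features.csv", phantom_features)
    report["stages"]["phantoms"] = {
        "n": config.n_phantoms, "n_features": phantom_features.shape[1] - 4}

    # -- stage 2: cohort feature table with test-retest filter --------------
    tcfg = TableSimConfig.from_reference_cohort(seed=int(rng.integers(0, 2**31 - 1)))
    truth = simulate_feature_table(tcfg)
    feat_cols = tcfg.feature_names
    pooled_sd = tcfg.feature_sds.mean(axis=0)
    noise = config.retest_noise_frac * pooled_sd
    run1 = truth.copy()
    run2 = truth.copy()
    run1[feat_cols] += rng.normal(0.0, noise, size=(len(truth), len(feat_cols)))
    run2[feat_cols] += rng.normal(0.0, noise, size=(len(truth), len(feat_cols)))

    if config.apply_ccc_filter:
        pairs = pairs_from_frames(run1[["tumor_id"] + feat_cols],
                                  run2[["tumor_id"] + feat_cols])
        retained, excluded, ccc_report = filter_by_ccc(pairs, config.ccc_threshold)
        if excluded:
            report["warnings"].append({"stage": "reproducibility",
                                       "excluded_features": excluded})
    else:
        retained, excluded = feat_cols, []
        ccc_report = pd.DataFrame()
    table = run1[["tumor_id", "patient_id", "grade"] + retained]
    if out is not None:
        dio.write_feature_csv(out / "cohort_features.csv", table)
        if len(ccc_report):
            dio.write_json(out / "ccc_report.json",
                           ccc_report.to_dict(orient="records"))
    report["stages"]["reproducibility"] = {
        "n_retained": len(retained), "n_excluded": len(excluded)}

    # -- stage 3: pathology grading join ------------------------------------
    comps = _simulate_compositions(table["grade"].to_numpy(), rng)
    grades = grade_composition_table(comps)
    merged = table.merge(grades[["tumor_id", "grade"]], on="tumor_id",
                         suffixes=("", "_pathology"))
    mismatch = int((merged["grade"] != merged["grade_pathology"]).sum())
    if mismatch:
        report["warnings"].append({"stage": "pathology",
                                   "grade_mismatches": mismatch})
    if out is not None:
        dio.write_feature_csv(out / "compositions.csv", comps)
        dio.write_feature_csv(out / "grades.csv", grades)
    report["stages"]["pathology"] = {"n_graded": len(grades),
                                     "mismatches": mismatch}

    # -- stage 4: univariate screen -----------------------------------------
    y = table["grade"].to_numpy()
    screen = {}
    for name in retained:
        res = anova_bonferroni(table[name].to_numpy(), y)
        screen[name] = res["omnibus_p"]
    candidates = [n for n in retained if screen[n] < config.screen_alpha]
    report["stages"]["screen"] = {"n_candidates": len(candidates)}

    # -- stage 5: stepwise multinomial fit ----------------------------------
    selected, trace = stepwise_select(
        table[candidates], y, alpha_enter=config.alpha_enter,
        alpha_remove=config.alpha_remove)
    fit_info: dict = {"selected": selected,
                      "trace": [list(s) for s in trace.steps]}
    if selected:
        vifs, flagged = (vif_screen(table[selected], config.vif_threshold)
                         if len(selected) >= 2 else ({selected[0]: 1.0}, []))
        if flagged:
            report["warnings"].append({"stage": "fit", "vif_flagged": flagged})
        fit = fit_multinomial(table[selected], y, reference=1,
                              raise_on_nonconvergence=False)
        fit_info.update({
            "vif": vifs, "converged": fit.converged,
            "separation": fit.separation, "loglik": fit.loglik,
            "coefficients": fit.summary().to_dict(orient="records"),
        })
        if not fit.converged or fit.separation:
            report["warnings"].append({
                "stage": "fit", "converged": fit.converged,
                "separation": fit.separation})
    if out is not None:
        dio.write_json(out / "fit.json", fit_info)
    report["stages"]["fit"] = {k: fit_info.get(k) for k in
                               ("selected", "converged", "separation")}

    # -- stage 6: LOOCV evaluation ------------------------------------------
    cv = loocv_predict(table[retained], y, selected_features=selected,
                       mode=config.cv_mode)
    if cv.failed_folds:
        report["warnings"].append({"stage": "evaluate",
                                   "failed_folds": cv.failed_folds})
    eval_info: dict = {"mode": cv.mode, "auc": {}}
    for g in (1, 2, 3):
        roc = roc_auc_ovr(cv.probabilities, y, g)
        eval_info["auc"][str(g)] = {"auc": roc.auc, "ci": list(roc.ci)}
    metrics = diagnostic_metrics(cv.probabilities, y)
    eval_info["metrics"] = {
        str(g): {name: ({"percent": m.percent, "ci": m.ci} if m.defined
                        else {"undefined": m.reason})
                 for name, m in metrics[g].items()}
        for g in (1, 2, 3)
    }
    if out is not None:
        dio.write_json(out / "evaluation.json", eval_info)
        plot_roc_curves(
            {g: roc_auc_ovr(cv.probabilities, y, g) for g in (1, 2, 3)},
            out / "roc.svg")
    report["stages"]["evaluate"] = eval_info

    report["elapsed_s"] = round(time.time() - t0, 3)
    report["seed"] = config.seed
    if out is not None:
        dio.write_json(out / "report.json", report)
    return report


def plot_roc_curves(rocs: dict, path) -> None:
    """One-vs-rest ROC curves for each grade, written as SVG/PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for g, roc in rocs.items():
        ax.plot(roc.fpr, roc.tpr, label=f"grade {g} vs rest (AUC {roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
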