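"""End-to-end pipeline: simulate -> preprocess -> habitats -> features ->
selection -> models -> evaluation -> report.

Every stage is a pure function of its inputs and the configuration;
rerunning with the same config and seed reproduces all numbers.  When
an output directory is given, each stage writes its artifacts (NIfTI,
CSV, JSON) plus a manifest with content hashes.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from habitomics.core import SEQUENCES, PreprocessedVolumeSet, SubregionLabelMap, VolumeSet
from habitomics.evaluate import (
    decision_curve,
    delong_test,
    evaluate_models,
    hosmer_lemeshow,
    km_logrank,
    youden_cutoff,
)
from habitomics.features import extract_region_features, feature_names_full
from habitomics.habitats import HabitatConfig, build_subregion_map
from habitomics.io import write_cohort
from habitomics.models import (
    DEFAULT_GRID,
    MODEL_NAMES,
    SMALL_GRID,
    ModelSuite,
    build_model_suite,
)
from habitomics.phantom import (
    MsiEffect,
    PhantomParams,
    generate_cohort,
    generate_rater_perturbation,
)
from habitomics.preprocess import PreprocessConfig, preprocess_volumeset
from habitomics.selection import run_radiomic_cascade, select_clinical_variables


@dataclass
class SelectionConfig:
    icc_enabled: bool = True
    icc_n_subjects: int = 30
    icc_threshold: float = 0.75
    univariate_alpha: float = 0.05
    correlation_threshold: float = 0.75
    lasso_folds: int = 10
    max_stepwise: int = 30


@dataclass
class PipelineConfig:
    seed: int = 0
    n_patients: int = 60
    msi_prevalence: float = 0.11
    phantom: PhantomParams = field(default_factory=PhantomParams)
    preprocess: PreprocessConfig = field(
        default_factory=lambda: PreprocessConfig(bias_correction=False)
    )
    habitat: HabitatConfig = field(default_factory=HabitatConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    model_grid: str = "default"  # "default" | "small"
    n_folds: int = 10

    def grid(self) -> Dict:
        return DEFAULT_GRID if self.model_grid == "default" else SMALL_GRID


def process_patient(
    vs: VolumeSet,
    pre_cfg: PreprocessConfig,
    hab_cfg: HabitatConfig,
    seed: int,
) -> Tuple[PreprocessedVolumeSet, SubregionLabelMap, List[Dict], Dict]:
    """Preprocess one patient and extract subregion + classical features."""
    pvs = preprocess_volumeset(vs, pre_cfg)
    cfg = dataclasses.replace(hab_cfg, seed=seed)
    labelmap = build_subregion_map(pvs, cfg)
    sub_rows = []
    for rid in labelmap.region_ids():
        row = extract_region_features(pvs, labelmap.labels, rid)
        row["patient_id"] = vs.patient_id
        row["region_id"] = rid
        sub_rows.append(row)
    classical = extract_region_features(pvs, pvs.tumor_mask, "tumor")
    classical["patient_id"] = vs.patient_id
    return pvs, labelmap, sub_rows, classical


def _icc_substudy(
    patients: List[Tuple[VolumeSet, np.ndarray]],
    table: pd.DataFrame,
    pre_cfg: PreprocessConfig,
    n_subjects: int,
    seed: int,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulated reliability substudy on training patients.

    Rater 2 and the repeat read are boundary perturbations of the
    reference mask; whole-tumor features are re-extracted under each
    mask and compared by ICC.
    """
    train_idx = np.flatnonzero((table["cohort"] == "training").to_numpy())
    rng = np.random.default_rng(seed)
    chosen = rng.choice(train_idx, size=min(n_subjects, len(train_idx)), replace=False)
    names = feature_names_full()
    tabs = {k: [] for k in ("r1", "r2", "r1r")}
    for i in chosen:
        vs = patients[i][0]
        masks = {
            "r1": vs.tumor_mask,
            "r2": generate_rater_perturbation(
                vs.tumor_mask, seed=int(rng.integers(2**31)), flip_prob=0.15
            ),
            "r1r": generate_rater_perturbation(
                vs.tumor_mask, seed=int(rng.integers(2**31)), flip_prob=0.1
            ),
        }
        for key, mask in masks.items():
            v2 = VolumeSet(
                sequences=dict(vs.sequences),
                tumor_mask=mask,
                voxel_spacing_mm=vs.voxel_spacing_mm,
                patient_id=vs.patient_id,
            )
            pvs = preprocess_volumeset(v2, pre_cfg)
            tabs[key].append(extract_region_features(pvs, pvs.tumor_mask, "tumor"))
    frames = {k: pd.DataFrame(v)[names] for k, v in tabs.items()}
    return frames["r1"], frames["r2"], frames["r1r"]


@dataclass
class PipelineResult:
    table: pd.DataFrame
    labelmaps: List[SubregionLabelMap]
    subregion_features: pd.DataFrame
    classical_features: pd.DataFrame
    selected: Dict[str, List[str]]
    clinical_or_table: pd.DataFrame
    suite: ModelSuite
    performance: pd.DataFrame
    delong: pd.DataFrame
    decision_curves: pd.DataFrame
    calibration: Dict
    survival: Dict
    traces: Dict


def run_pipeline(
    config: PipelineConfig, outdir: Optional[Path] = None
) -> PipelineResult:
    """Run the complete analysis on a simulated cohort."""
    patients, table = generate_cohort(
        config.n_patients, config.msi_prevalence, config.phantom, config.seed
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort(outdir / "cohort", patients, table)

    ss = np.random.SeedSequence(config.seed)
    pat_seeds = ss.spawn(len(patients))

    labelmaps = []
    sub_rows: List[Dict] = []
    classical_rows: List[Dict] = []
    for (vs, _truth), child in zip(patients, pat_seeds):
        _, lm, rows, classical = process_patient(
            vs,
            config.preprocess,
            config.habitat,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        labelmaps.append(lm)
        sub_rows += rows
        classical_rows.append(classical)
    subregion_features = pd.DataFrame(sub_rows)
    classical_features = pd.DataFrame(classical_rows)
    names = feature_names_full()

    # ---- selection (training rows only) -----------------------------
    clin = table.set_index("patient_id")
    train_ids = set(clin.index[clin["cohort"] == "training"])
    sub_tr = subregion_features["patient_id"].isin(train_ids).to_numpy()
    cl_tr = classical_features["patient_id"].isin(train_ids).to_numpy()

    icc_tables = None
    if config.selection.icc_enabled:
        icc_tables = _icc_substudy(
            patients,
            table,
            config.preprocess,
            config.selection.icc_n_subjects,
            seed=config.seed + 1,
        )

    y_sub = clin.loc[subregion_features["patient_id"], "msi"].to_numpy()
    y_cl = clin.loc[classical_features["patient_id"], "msi"].to_numpy()

    sel_sub, trace_sub = run_radiomic_cascade(
        subregion_features.loc[sub_tr, names],
        y_sub[sub_tr],
        icc_tables=icc_tables,
        icc_threshold=config.selection.icc_threshold,
        univariate_alpha=config.selection.univariate_alpha,
        correlation_threshold=config.selection.correlation_threshold,
        n_folds=config.selection.lasso_folds,
        seed=config.seed,
        max_stepwise=config.selection.max_stepwise,
    )
    sel_cl, trace_cl = run_radiomic_cascade(
        classical_features.loc[cl_tr, names],
        y_cl[cl_tr],
        icc_tables=icc_tables,
        icc_threshold=config.selection.icc_threshold,
        univariate_alpha=config.selection.univariate_alpha,
        correlation_threshold=config.selection.correlation_threshold,
        n_folds=config.selection.lasso_folds,
        seed=config.seed,
        max_stepwise=config.selection.max_stepwise,
    )
    sel_sub = _nonempty_fallback(sel_sub, trace_sub, subregion_features.loc[sub_tr, names], y_sub[sub_tr])
    sel_cl = _nonempty_fallback(sel_cl, trace_cl, classical_features.loc[cl_tr, names], y_cl[cl_tr])

    train_tab = table[table["cohort"] == "training"]
    sel_clin, or_table = select_clinical_variables(
        train_tab, train_tab["msi"].to_numpy()
    )

    # ---- models ------------------------------------------------------
    suite = build_model_suite(
        subregion_features,
        classical_features,
        table,
        sel_sub,
        sel_cl,
        sel_clin,
        grid=config.grid(),
        n_folds=config.n_folds,
        seed=config.seed,
    )

    # ---- evaluation --------------------------------------------------
    performance = evaluate_models(
        suite.patient_scores, MODEL_NAMES, seed=config.seed, n_boot=500
    )
    delong_rows = []
    for cohort, df in suite.patient_scores.groupby("cohort"):
        yv = df["msi"].to_numpy()
        for i, a in enumerate(MODEL_NAMES):
            for b in MODEL_NAMES[i + 1 :]:
                p = delong_test(df[a].to_numpy(), df[b].to_numpy(), yv)
                delong_rows.append((cohort, a, b, p))
    delong = pd.DataFrame(delong_rows, columns=["cohort", "model_a", "model_b", "p"])

    # decision curves (net benefit over the 0.01-0.60 threshold grid)
    dca_frames = []
    for cohort, df in suite.patient_scores.groupby("cohort"):
        for m in MODEL_NAMES:
            dc = decision_curve(df[m].to_numpy(), df["msi"].to_numpy())
            dc.insert(0, "model", m)
            dc.insert(0, "cohort", cohort)
            dca_frames.append(dc)
    decision_curves = pd.concat(dca_frames, ignore_index=True)

    # calibration of the optimal (subregion-clinicoradiological) model
    calibration = {}
    for cohort, df in suite.patient_scores.groupby("cohort"):
        try:
            chi2, p, dfree = hosmer_lemeshow(
                df["subregion_clinical"].to_numpy(), df["msi"].to_numpy(),
                n_groups=min(10, len(df) // 2),
            )
            calibration[cohort] = {"chi2": chi2, "p": p, "df": dfree}
        except ValueError as e:
            calibration[cohort] = {"error": str(e)}

    # survival stratification by predicted MSI status
    tr_scores = suite.patient_scores[suite.patient_scores["cohort"] == "training"]
    cutoff, _ = youden_cutoff(
        tr_scores["subregion_clinical"].to_numpy(), tr_scores["msi"].to_numpy()
    )
    survival = {"cutoff": cutoff, "cohorts": {}}
    merged = suite.patient_scores.merge(
        table[["patient_id", "dfs_time", "dfs_event"]], on="patient_id"
    )
    for cohort, df in merged.groupby("cohort"):
        pred = np.where(
            df["subregion_clinical"].to_numpy() >= cutoff, "pred_MSI", "pred_MSS"
        )
        if len(np.unique(pred)) < 2:
            survival["cohorts"][cohort] = {"error": "single predicted group"}
            continue
        km = km_logrank(df["dfs_time"].to_numpy(), df["dfs_event"].to_numpy(), pred)
        survival["cohorts"][cohort] = {
            "logrank_p": km["logrank_p"],
            "dfs36": {
                g: km["groups"][g]["survival_at_horizon"] for g in km["groups"]
            },
        }

    result = PipelineResult(
        table=table,
        labelmaps=labelmaps,
        subregion_features=subregion_features,
        classical_features=classical_features,
        selected={"subregion": sel_sub, "classical": sel_cl, "clinical": sel_clin},
        clinical_or_table=or_table,
        suite=suite,
        performance=performance,
        delong=delong,
        decision_curves=decision_curves,
        calibration=calibration,
        survival=survival,
        traces={"subregion": trace_sub.to_dict(), "classical": trace_cl.to_dict()},
    )
    if outdir is not None:
        _write_report(result, config, outdir)
    return result


def _nonempty_fallback(selected, trace, X, y):
    """Guarantee a nonempty model block: fall back to the strongest
    univariate feature when the cascade empties."""
    if selected:
        return selected
    warnings.warn("selection cascade kept no features; falling back to best univariate")
    from habitomics.selection import _wald_logistic_vec

    _, _, p = _wald_logistic_vec(X.to_numpy(dtype=float), y)
    j = int(np.nanargmin(p))
    return [X.columns[j]]


def _write_report(result: PipelineResult, config: PipelineConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.subregion_features.to_csv(outdir / "subregion_features.csv", index=False)
    result.classical_features.to_csv(outdir / "classical_features.csv", index=False)
    result.performance.to_csv(outdir / "performance.csv", index=False)
    result.delong.to_csv(outdir / "delong.csv", index=False)
    result.decision_curves.to_csv(outdir / "decision_curves.csv", index=False)
    result.suite.patient_scores.to_csv(outdir / "patient_scores.csv", index=False)
    result.clinical_or_table.to_csv(outdir / "clinical_odds_ratios.csv", index=False)
    summary = {
        "config": {
            "seed": config.seed,
            "n_patients": config.n_patients,
            "msi_prevalence": config.msi_prevalence,
            "model_grid": config.model_grid,
        },
        "selected_features": result.selected,
        "V_per_patient": [lm.V for lm in result.labelmaps],
        "calibration": result.calibration,
        "survival": result.survival,
        "selection_traces": result.traces,
    }
    with open(outdir / "summary.json", "w") as f:
        json.dump(summary, f, indent=1, default=float)
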