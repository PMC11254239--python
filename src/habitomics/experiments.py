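"""Monte-Carlo experiment harnesses over the synthetic cohort generator.

These functions define the package's calibration and validation
experiments: planted-habitat recovery, the subregion-vs-classical model
comparison under a habitat-level MSI signal (and its null calibration),
reliability (ICC) monotonicity under segmentation perturbation,
clinical effect-size recovery, and the type-I error / power checks of
the calibration and survival statistics.

Problem sizes are chosen so each experiment runs in minutes on one CPU
(small phantom grids, the reduced elastic-net grid); the methods note
documents the choices.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import adjusted_rand_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from habitomics.evaluate import hosmer_lemeshow, km_logrank
from habitomics.features import extract_region_features, feature_names_full
from habitomics.habitats import HabitatConfig, build_subregion_map
from habitomics.models import SMALL_GRID, fit_elasticnet_logistic
from habitomics.phantom import (
    MsiEffect,
    PhantomParams,
    generate_clinical_cohort,
    generate_cohort,
    generate_phantom,
    generate_rater_perturbation,
)
from habitomics.pipeline import process_patient
from habitomics.preprocess import PreprocessConfig, preprocess_volumeset
from habitomics.selection import (
    correlation_prune,
    lasso_select,
    select_clinical_variables,
    univariate_screen,
)

import sklearn

# inputs to the estimators are package-generated finite arrays; skip
# sklearn's per-call finiteness scans inside the Monte-Carlo loops
sklearn.set_config(assume_finite=True)

#: phantom scale for the Monte-Carlo cohorts (desk-scale tumor ~700
#: voxels); habitat count and composition vary per patient as in the
#: adaptive-V setting the pipeline targets
MC_PHANTOM = PhantomParams(grid_shape=(20, 20, 14), noise_sd=4.0, n_habitats_range=(2, 5))
MC_HABITAT = HabitatConfig(n_restarts=3)
MC_PREPROCESS = PreprocessConfig(bias_correction=False)


def _derive_seed(master: int, *salt: int) -> int:
    return int(
        np.random.SeedSequence([master, *salt]).generate_state(1)[0] % (2**31)
    )


# ---------------------------------------------------------------------------
# planted-habitat recovery
# ---------------------------------------------------------------------------

def planted_recovery(
    n_phantoms: int = 10,
    seed: int = 0,
    n_habitats: int = 3,
    separation: float = 40.0,
    noise_sd: float = 2.0,
) -> pd.DataFrame:
    """Recover planted habitats on well-separated low-noise phantoms.

    Returns one row per phantom with the recovered subregion count V
    and the adjusted Rand index of the final label map against the
    planted partition.
    """
    rows = []
    for i in range(n_phantoms):
        params = PhantomParams(
            grid_shape=(24, 24, 18),
            n_habitats_true=n_habitats,
            intensity_separation=separation,
            noise_sd=noise_sd,
            texture_amplitude=8.0,
            seed=_derive_seed(seed, 11, i),
        )
        vs, truth = generate_phantom(params, msi=0)
        pvs = preprocess_volumeset(vs, MC_PREPROCESS)
        lm = build_subregion_map(
            pvs, dataclasses.replace(MC_HABITAT, seed=_derive_seed(seed, 12, i))
        )
        m = vs.tumor_mask.astype(bool)
        rows.append(
            {
                "phantom": i,
                "V": lm.V,
                "ari": adjusted_rand_score(truth[m], lm.labels[m]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# subregion vs classical model comparison
# ---------------------------------------------------------------------------

def _reduced_cascade(X: pd.DataFrame, y: np.ndarray, seed: int) -> List[str]:
    """Per-fold radiomic selection: univariate -> correlation -> LASSO.

    The ICC filter needs the rater substudy (not simulated inside every
    Monte-Carlo fold) and the stepwise refinement adds little at these
    sample sizes, so the Monte-Carlo replicates run the three middle
    steps of the cascade.
    """
    kept, _ = univariate_screen(X, y, alpha=0.05)
    if not kept:
        return []
    kept = correlation_prune(X[kept], threshold=0.75)
    if len(kept) > 1:
        kept2, _ = lasso_select(X[kept], y, n_folds=4, seed=seed, n_lambdas=15)
        if kept2:
            kept = kept2
    return kept


def _fallback_best(X: pd.DataFrame, y: np.ndarray) -> List[str]:
    from habitomics.selection import _wald_logistic_vec

    _, _, p = _wald_logistic_vec(X.to_numpy(dtype=float), y)
    return [X.columns[int(np.nanargmin(p))]]


def subregion_vs_classical_replicate(
    seed: int,
    n_patients: int = 40,
    msi_prevalence: float = 0.25,
    msi_effect: Optional[MsiEffect] = None,
    n_eval_folds: int = 3,
) -> Dict[str, float]:
    """One replicate of the central model comparison.

    Generates a phantom cohort whose MSI signal is focal (one small
    habitat) on top of a weak diffuse component, computes out-of-fold
    patient-level predictions for the subregion model (trained on
    subregion rows, scores averaged per patient) and the classical
    whole-tumor model, and returns both held-out AUCs.  Selection and
    fitting are redone inside every fold on that fold's training
    patients only.  The comparison cohorts are case-enriched
    (25 % MSI, the usual case-control strategy for a discrimination
    experiment): at the population prevalence of ~11 % a 40-patient
    cohort carries only ~4 cases, too few to select features on.
    """
    params = MC_PHANTOM
    if msi_effect is not None:
        params = dataclasses.replace(params, msi_effect=msi_effect)
    patients, table = generate_cohort(
        n_patients, msi_prevalence, params, seed=_derive_seed(seed, 21)
    )
    names = feature_names_full()

    sub_rows: List[Dict] = []
    classical_rows: List[Dict] = []
    ss = np.random.SeedSequence([seed, 22])
    for (vs, _), child in zip(patients, ss.spawn(len(patients))):
        _, lm, rows, classical = process_patient(
            vs, MC_PREPROCESS, MC_HABITAT, seed=int(child.generate_state(1)[0] % (2**31))
        )
        sub_rows += rows
        classical_rows.append(classical)
    sub_df = pd.DataFrame(sub_rows)
    cl_df = pd.DataFrame(classical_rows)

    y_pat = table.set_index("patient_id")["msi"]
    pids = table["patient_id"].to_numpy()
    y = y_pat.loc[pids].to_numpy()

    folds = min(n_eval_folds, int(y.sum()))
    cv = StratifiedKFold(n_splits=max(2, folds), shuffle=True, random_state=seed)
    # held-out AUC = mean of per-fold AUCs: averaging instead of pooling
    # keeps the different fold models' probability calibrations from
    # contaminating one combined ranking
    auc_sub_folds = []
    auc_cl_folds = []
    for k, (tr, te) in enumerate(cv.split(pids, y)):
        tr_ids = set(pids[tr])
        s_tr = sub_df["patient_id"].isin(tr_ids).to_numpy()
        y_sub = y_pat.loc[sub_df["patient_id"]].to_numpy()

        sel = _reduced_cascade(
            sub_df.loc[s_tr, names], y_sub[s_tr], seed=_derive_seed(seed, 23, k)
        ) or _fallback_best(sub_df.loc[s_tr, names], y_sub[s_tr])
        model = fit_elasticnet_logistic(
            sub_df.loc[s_tr, sel],
            y_sub[s_tr],
            grid=SMALL_GRID,
            n_folds=4,
            seed=seed,
            groups=sub_df.loc[s_tr, "patient_id"].to_numpy(),
        )
        scores = model.score(sub_df[sel])
        per_pat = (
            pd.DataFrame({"pid": sub_df["patient_id"], "s": scores})
            .groupby("pid")["s"]
            .mean()
        )
        if len(np.unique(y[te])) == 2:
            auc_sub_folds.append(
                roc_auc_score(y[te], per_pat.loc[pids[te]].to_numpy())
            )

        c_tr = cl_df["patient_id"].isin(tr_ids).to_numpy()
        y_cl = y_pat.loc[cl_df["patient_id"]].to_numpy()
        sel_c = _reduced_cascade(
            cl_df.loc[c_tr, names], y_cl[c_tr], seed=_derive_seed(seed, 24, k)
        ) or _fallback_best(cl_df.loc[c_tr, names], y_cl[c_tr])
        model_c = fit_elasticnet_logistic(
            cl_df.loc[c_tr, sel_c], y_cl[c_tr], grid=SMALL_GRID, n_folds=4, seed=seed
        )
        sc = pd.Series(model_c.score(cl_df[sel_c]), index=cl_df["patient_id"])
        if len(np.unique(y[te])) == 2:
            auc_cl_folds.append(roc_auc_score(y[te], sc.loc[pids[te]].to_numpy()))

    return {
        "auc_subregion": float(np.mean(auc_sub_folds)),
        "auc_classical": float(np.mean(auc_cl_folds)),
        "n_msi": int(y.sum()),
    }


def subregion_vs_classical_experiment(
    n_replicates: int = 50, seed: int = 0, **kwargs
) -> pd.DataFrame:
    """Run the model-comparison replicates; one row per replicate."""
    rows = []
    for r in range(n_replicates):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = subregion_vs_classical_replicate(_derive_seed(seed, 31, r), **kwargs)
        res["replicate"] = r
        rows.append(res)
    return pd.DataFrame(rows)


def null_auc_experiment(
    n_replicates: int = 12, seed: int = 0, **kwargs
) -> pd.DataFrame:
    """Model comparison with the MSI image effect switched off."""
    return subregion_vs_classical_experiment(
        n_replicates=n_replicates, seed=seed, msi_effect=MsiEffect.null(), **kwargs
    )


# ---------------------------------------------------------------------------
# ICC monotonicity under segmentation perturbation
# ---------------------------------------------------------------------------

def icc_perturbation_experiment(
    n_subjects: int = 30, seed: int = 0
) -> Dict[str, float]:
    """Median feature ICC under mild vs strong mask perturbation.

    Re-extracts whole-tumor features from each phantom under the
    reference mask and under mild (flip 10%) and strong (flip 45%)
    boundary perturbations; returns the median ICC(2,1) of each
    condition across the feature panel.
    """
    from habitomics.selection import icc_2_1

    names = feature_names_full()
    rows = {"ref": [], "mild": [], "strong": []}
    for i in range(n_subjects):
        params = dataclasses.replace(MC_PHANTOM, seed=_derive_seed(seed, 41, i))
        vs, _ = generate_phantom(params, msi=0)
        masks = {
            "ref": vs.tumor_mask,
            "mild": generate_rater_perturbation(
                vs.tumor_mask, _derive_seed(seed, 42, i), flip_prob=0.1
            ),
            "strong": generate_rater_perturbation(
                vs.tumor_mask, _derive_seed(seed, 43, i), flip_prob=0.45, dice_floor=0.5
            ),
        }
        for key, mask in masks.items():
            from habitomics.core import VolumeSet

            v2 = VolumeSet(
                sequences=dict(vs.sequences),
                tumor_mask=mask,
                voxel_spacing_mm=vs.voxel_spacing_mm,
            )
            pvs = preprocess_volumeset(v2, MC_PREPROCESS)
            rows[key].append(
                [extract_region_features(pvs, pvs.tumor_mask, "tumor")[n] for n in names]
            )
    ref = np.asarray(rows["ref"])
    out = {}
    for key in ("mild", "strong"):
        icc = icc_2_1(np.stack([ref, np.asarray(rows[key])], axis=1))
        out[f"median_icc_{key}"] = float(np.nanmedian(icc))
    return out


# ---------------------------------------------------------------------------
# clinical effect-size recovery
# ---------------------------------------------------------------------------

def clinical_recovery_experiment(
    n_sims: int = 200,
    n_patients: int = 400,
    seed: int = 0,
    or_location_high: float = 3.0,
    or_nstage: float = 0.4,
) -> pd.DataFrame:
    """Selection-and-coverage study of the clinical variable procedure.

    Each simulated cohort carries the generator's planted odds ratios;
    the clinical selection procedure runs on its training split and we
    record whether each planted variable was retained and whether its
    95% CI covers the planted value.
    """
    rows = []
    for s in range(n_sims):
        tab = generate_clinical_cohort(
            n_patients,
            0.11,
            seed=_derive_seed(seed, 51, s),
            or_location_high=or_location_high,
            or_nstage=or_nstage,
        )
        tr = tab[tab["cohort"] == "training"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final, or_tab = select_clinical_variables(tr, tr["msi"].to_numpy())
        row = {"sim": s}
        for label, col, truth in (
            ("location", "location[high]", or_location_high),
            ("nstage", "n_stage[N1-N2]", or_nstage),
        ):
            hit = or_tab[or_tab["level"] == col]
            row[f"{label}_retained"] = bool(len(hit))
            if len(hit):
                lo, hi = float(hit["ci_low"].iloc[0]), float(hit["ci_high"].iloc[0])
                row[f"{label}_covered"] = bool(lo <= truth <= hi)
            else:
                row[f"{label}_covered"] = False
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistical calibration of the evaluation module
# ---------------------------------------------------------------------------

def hosmer_lemeshow_type1(
    n_reps: int = 1000, n: int = 500, seed: int = 0, alpha: float = 0.05
) -> float:
    """Rejection rate of the calibration test under a well-specified
    logistic model (should be ~alpha)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        x = rng.normal(size=(n, 2))
        eta = -1.0 + x @ np.array([0.8, -0.5])
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        probs = np.asarray(res.predict())
        _, p, _ = hosmer_lemeshow(probs, y)
        rejections += p < alpha
    return rejections / n_reps


def logrank_power(
    n_reps: int = 200, n: int = 200, hazard_ratio: float = 4.0, seed: int = 0
) -> float:
    """Power of the two-group log-rank test at the generator's DFS
    hazard contrast (exponential groups, uniform censoring)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        g = (rng.random(n) < 0.5).astype(int)
        lam = np.where(g == 1, 0.028 / hazard_ratio, 0.028)
        t = rng.exponential(1 / lam)
        c = np.minimum(60.0, rng.uniform(6, 60, n))
        times = np.maximum(np.minimum(t, c), 0.25)
        events = (t <= c).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            km = km_logrank(times, events, g)
        hits += km["logrank_p"] < 0.05
    return hits / n_reps
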