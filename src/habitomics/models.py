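"""The five MSI logistic models and the per-patient subregion rad-score.

All models are elastic-net logistic regressions with balanced class
weights, tuned by exhaustive grid search maximizing mean out-of-fold
AUC over stratified 10-fold cross-validation on the training cohort
only.  The subregion model is trained on subregion rows (each subregion
inherits its patient's MSI label); its patient-level score is the mean
of the patient's subregion scores:

    rad_score_subregion = (1/V) * sum_i rad_score_i

Model names: ``clinical``, ``subregion``, ``classical``,
``subregion_clinical``, ``combined``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

MODEL_NAMES = ("clinical", "subregion", "classical", "subregion_clinical", "combined")

DEFAULT_GRID = {
    "l1_ratio": (0.0, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0),
    "C": tuple(np.logspace(-3, 2, 7)),
    "max_iter": (1000, 5000),
    "tol": (1e-4,),
}

#: reduced grid for Monte-Carlo experiments (documented in the methods note)
SMALL_GRID = {
    "l1_ratio": (0.0, 1.0),
    "C": (0.01, 0.1, 1.0, 10.0),
    "max_iter": (1000,),
    "tol": (1e-4,),
}


@dataclass
class FittedModel:
    """A standardized elastic-net logistic model plus its tuning record."""

    name: str
    features: List[str]
    mean: np.ndarray
    scale: np.ndarray
    estimator: LogisticRegression
    cv_table: pd.DataFrame
    best_params: Dict

    def score(self, X: pd.DataFrame) -> np.ndarray:
        """Probability-scale score per row, in training feature order."""
        missing = [f for f in self.features if f not in X.columns]
        if missing:
            raise KeyError(f"missing feature columns: {missing}")
        Z = (X[self.features].to_numpy(dtype=float) - self.mean) / self.scale
        return self.estimator.predict_proba(Z)[:, 1]


def fit_elasticnet_logistic(
    X: pd.DataFrame,
    y: np.ndarray,
    grid: Optional[Dict] = None,
    n_folds: int = 10,
    seed: int = 0,
    groups: Optional[np.ndarray] = None,
    name: str = "model",
) -> FittedModel:
    """Grid-searched elastic-net logistic regression.

    Every grid point is scored by mean validation AUC over stratified
    folds (grouped by patient when ``groups`` is given, so one
    patient's subregions never straddle a fold boundary); the winner is
    refit on all rows.  Ties break toward stronger regularization
    (smaller C, then larger l1_ratio).  Class weights are balanced.
    """
    grid = grid or DEFAULT_GRID
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("y must contain both classes")
    Xv = X.to_numpy(dtype=float)
    mean = Xv.mean(axis=0)
    scale = Xv.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (Xv - mean) / scale

    n_pos = int(y.sum())
    folds = max(2, min(n_folds, n_pos, len(y) - n_pos))
    if groups is not None:
        cv = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
        split = list(cv.split(Z, y, groups=groups))
    else:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split = list(cv.split(Z, y))
    # grouped stratification cannot always guarantee both classes per side
    split = [
        (tr, te)
        for tr, te in split
        if len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2
    ]
    if not split:
        warnings.warn("no usable CV folds (class too rare); tuning on training AUC")
        idx = np.arange(len(y))
        split = [(idx, idx)]

    rows = []
    # scan order implements the tie-break: strongest regularization first
    for c in sorted(grid["C"]):
        for l1 in sorted(grid["l1_ratio"], reverse=True):
            for mi in grid["max_iter"]:
                for tol in grid["tol"]:
                    aucs = []
                    failed = False
                    for tr, te in split:
                        clf = _make_estimator(c, l1, mi, tol)
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            try:
                                clf.fit(Z[tr], y[tr])
                            except Exception:
                                failed = True
                                break
                        if len(np.unique(y[te])) == 2:
                            aucs.append(
                                roc_auc_score(y[te], clf.decision_function(Z[te]))
                            )
                    if failed or not aucs:
                        rows.append((c, l1, mi, tol, np.nan))
                        continue
                    rows.append((c, l1, mi, tol, float(np.mean(aucs))))
    cv_table = pd.DataFrame(rows, columns=["C", "l1_ratio", "max_iter", "tol", "cv_auc"])
    if cv_table["cv_auc"].isna().all():
        raise RuntimeError("every grid point failed to converge")
    best_idx = int(cv_table["cv_auc"].round(12).idxmax())  # first max in scan order
    best = cv_table.loc[best_idx]
    best_params = {
        "C": float(best["C"]),
        "l1_ratio": float(best["l1_ratio"]),
        "max_iter": int(best["max_iter"]),
        "tol": float(best["tol"]),
    }
    est = _make_estimator(**best_params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(Z, y)
    return FittedModel(
        name=name,
        features=list(X.columns),
        mean=mean,
        scale=scale,
        estimator=est,
        cv_table=cv_table,
        best_params=best_params,
    )


def _intercept_only(name: str, y_train: np.ndarray) -> "FittedModel":
    m = FittedModel.__new__(FittedModel)
    m.name = name
    m.features = []
    m.mean = np.zeros(0)
    m.scale = np.ones(0)
    m.estimator = None
    m.cv_table = pd.DataFrame()
    m.best_params = {}
    p = float(np.asarray(y_train).mean())
    m.score = lambda X, _p=p: np.full(len(X), _p)  # type: ignore[assignment]
    return m


def _make_estimator(C, l1_ratio, max_iter, tol) -> LogisticRegression:
    return LogisticRegression(
        penalty="elasticnet",
        solver="saga",
        C=float(C),
        l1_ratio=float(l1_ratio),
        max_iter=int(max_iter),
        tol=float(tol),
        class_weight="balanced",
        random_state=0,
    )


def score_patients(model: FittedModel, features: pd.DataFrame) -> np.ndarray:
    """Apply a fitted model; probability-scale score per row."""
    return model.score(features)


def aggregate_subregion_score(region_scores: Sequence[float]) -> float:
    """Patient-level subregion rad-score: the mean of the V region scores."""
    scores = np.asarray(list(region_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("no region scores to aggregate")
    return float(scores.mean())


@dataclass
class ModelSuite:
    """The five fitted models plus per-patient scores per cohort."""

    models: Dict[str, FittedModel]
    patient_scores: pd.DataFrame  # patient_id, cohort, msi, one column per model
    training_fingerprint: set = field(default_factory=set)

    def __post_init__(self) -> None:
        missing = [m for m in MODEL_NAMES if m not in self.models]
        if missing:
            raise ValueError(f"missing models: {missing}")


def build_model_suite(
    subregion_features: pd.DataFrame,
    classical_features: pd.DataFrame,
    clinical_table: pd.DataFrame,
    selected_subregion: List[str],
    selected_classical: List[str],
    selected_clinical: List[str],
    grid: Optional[Dict] = None,
    n_folds: int = 10,
    seed: int = 0,
) -> ModelSuite:
    """Fit the five models on the training cohort and score everyone.

    ``subregion_features`` has one row per subregion (columns: the 424
    features plus ``patient_id``); ``classical_features`` one row per
    patient; ``clinical_table`` is the cohort table.  Only rows whose
    patient is in the training cohort ever reach a fit; a leakage guard
    raises if any external-test row is seen during fitting.
    """
    from habitomics.selection import encode_clinical

    clin = clinical_table.set_index("patient_id")
    train_ids = set(clin.index[clin["cohort"] == "training"])
    test_ids = set(clin.index[clin["cohort"] == "external_test"])

    def _train_mask(ids: pd.Series) -> np.ndarray:
        leaked = set(ids) - train_ids - test_ids
        if leaked:
            raise ValueError(f"rows with unknown patients: {sorted(leaked)[:5]}")
        return ids.isin(train_ids).to_numpy()

    models: Dict[str, FittedModel] = {}

    # --- subregion model (rows = subregions, grouped CV by patient) ---
    sub_ids = subregion_features["patient_id"]
    sub_tr = _train_mask(sub_ids)
    y_sub = clin.loc[sub_ids, "msi"].to_numpy()
    X_sub = subregion_features[selected_subregion]
    models["subregion"] = fit_elasticnet_logistic(
        X_sub[sub_tr],
        y_sub[sub_tr],
        grid=grid,
        n_folds=n_folds,
        seed=seed,
        groups=sub_ids[sub_tr].to_numpy(),
        name="subregion",
    )
    region_scores = models["subregion"].score(X_sub)
    rad_sub = (
        pd.DataFrame({"patient_id": sub_ids.to_numpy(), "score": region_scores})
        .groupby("patient_id")["score"]
        .mean()
        .rename("rad_score_subregion")
    )

    # --- classical model (rows = patients) ---
    cl_ids = classical_features["patient_id"]
    cl_tr = _train_mask(cl_ids)
    y_cl = clin.loc[cl_ids, "msi"].to_numpy()
    X_cl = classical_features[selected_classical]
    models["classical"] = fit_elasticnet_logistic(
        X_cl[cl_tr], y_cl[cl_tr], grid=grid, n_folds=n_folds, seed=seed, name="classical"
    )
    rad_cl = pd.Series(
        models["classical"].score(X_cl), index=cl_ids, name="rad_score_classical"
    )

    # --- patient-level design table ---
    pat = clin.copy()
    enc = encode_clinical(pat.reset_index()).set_index(pat.index)
    pat_X = enc.join(rad_sub).join(rad_cl)
    if pat_X[["rad_score_subregion", "rad_score_classical"]].isna().any().any():
        raise ValueError("some patients lack radiomic scores")
    y_pat = pat["msi"].to_numpy()
    pat_tr = pat["cohort"].to_numpy() == "training"

    blocks = {
        "clinical": selected_clinical,
        "subregion_clinical": selected_clinical + ["rad_score_subregion"],
        "combined": selected_clinical + ["rad_score_subregion", "rad_score_classical"],
    }
    for name, cols in blocks.items():
        if not cols:
            # an empty clinical selection degrades the clinical model to
            # intercept-only (constant prevalence score)
            warnings.warn(f"model {name}: empty feature block, intercept-only fallback")
            models[name] = _intercept_only(name, y_pat[pat_tr])
            continue
        models[name] = fit_elasticnet_logistic(
            pat_X[cols][pat_tr], y_pat[pat_tr], grid=grid, n_folds=n_folds, seed=seed, name=name
        )

    scores = pd.DataFrame(
        {
            "patient_id": pat.index,
            "cohort": pat["cohort"].to_numpy(),
            "msi": y_pat,
            "subregion": rad_sub.loc[pat.index].to_numpy(),
            "classical": rad_cl.loc[pat.index].to_numpy(),
        }
    )
    for name in ("clinical", "subregion_clinical", "combined"):
        scores[name] = models[name].score(pat_X)
    return ModelSuite(
        models=models, patient_scores=scores, training_fingerprint=train_ids
    )
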