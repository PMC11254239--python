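"""Feature and clinical-variable selection.

Radiomic cascade (fixed order): ICC reliability filter -> univariate
logistic screen -> Pearson correlation pruning -> LASSO with
cross-validated penalty -> bidirectional stepwise AIC.  Each step only
ever removes features, and every elimination is recorded in a
:class:`SelectionTrace`.

Clinical variables follow the separate two-stage rule: univariate
logistic at P < 0.1, stepwise AIC, then retain multivariable Wald
P < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold


@dataclass
class SelectionTrace:
    """Per-step record of the cascade: inputs, survivors, statistics."""

    steps: List[Dict] = field(default_factory=list)

    def record(self, step: str, features_in: Sequence[str], features_out: Sequence[str], stats: Dict) -> None:
        self.steps.append(
            {
                "step": step,
                "n_in": len(features_in),
                "n_out": len(features_out),
                "features_out": list(features_out),
                "stats": stats,
            }
        )

    def to_dict(self) -> Dict:
        return {"steps": self.steps}


def icc_2_1(ratings: np.ndarray) -> np.ndarray:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` has shape (n_subjects, n_raters, n_features); returns an
    ICC per feature.  Features with zero between-subject variance yield
    NaN (undefined agreement).
    """
    y = np.asarray(ratings, dtype=np.float64)
    n, k, _ = y.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    mean_s = y.mean(axis=1)  # (n, f)
    mean_r = y.mean(axis=0)  # (k, f)
    grand = y.mean(axis=(0, 1))  # (f,)

    ss_subj = k * ((mean_s - grand) ** 2).sum(axis=0)
    ss_rater = n * ((mean_r - grand) ** 2).sum(axis=0)
    ss_total = ((y - grand) ** 2).sum(axis=(0, 1))
    ss_err = ss_total - ss_subj - ss_rater

    msr = ss_subj / (n - 1)
    msc = ss_rater / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (msr - mse) / denom
    icc[(msr <= 0) & (mse <= 0)] = np.nan
    return icc


def icc_filter(
    features_rater1: pd.DataFrame,
    features_rater2: pd.DataFrame,
    features_rater1_repeat: pd.DataFrame,
    threshold: float = 0.75,
) -> Tuple[List[str], pd.DataFrame]:
    """Keep features reliable across raters and across repeat reads.

    Inter-observer ICC(2,1) compares rater 1 vs rater 2; intra-observer
    compares rater 1 vs their repeat.  A feature survives iff both ICCs
    exceed ``threshold``; undefined ICCs (no between-subject variance)
    drop the feature with a warning.
    """
    cols = list(features_rater1.columns)
    if list(features_rater2.columns) != cols or list(features_rater1_repeat.columns) != cols:
        raise ValueError("rater tables must share columns")
    a = features_rater1.to_numpy(dtype=float)
    b = features_rater2.to_numpy(dtype=float)
    c = features_rater1_repeat.to_numpy(dtype=float)
    inter = icc_2_1(np.stack([a, b], axis=1))
    intra = icc_2_1(np.stack([a, c], axis=1))
    table = pd.DataFrame({"feature": cols, "icc_inter": inter, "icc_intra": intra})
    undefined = table[table[["icc_inter", "icc_intra"]].isna().any(axis=1)]
    if len(undefined):
        warnings.warn(f"{len(undefined)} features with undefined ICC dropped")
    kept = table[
        (table["icc_inter"] > threshold) & (table["icc_intra"] > threshold)
    ]["feature"].tolist()
    return kept, table


def _wald_logistic(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Single-covariate logistic fit; returns (beta, se, two-sided p)."""
    X = sm.add_constant(x.reshape(-1, 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except Exception:
            return np.nan, np.nan, np.nan
    beta = res.params[1]
    se = res.bse[1]
    if not np.isfinite(se) or se == 0:
        return beta, se, np.nan
    return float(beta), float(se), float(res.pvalues[1])


def _wald_logistic_vec(X: np.ndarray, y: np.ndarray, max_iter: int = 100):
    """Vectorized single-covariate logistic MLE per column.

    Newton-Raphson on the 2-parameter (intercept, slope) model, run for
    all columns simultaneously; returns (beta, se, p) arrays.  Columns
    are standardized internally for stability and the slope rescaled
    back afterwards.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)[:, None]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd_safe
    n, f = Z.shape
    a = np.zeros(f)
    b = np.zeros(f)
    for _ in range(max_iter):
        eta = np.clip(a[None, :] + b[None, :] * Z, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        r = y - p
        g_a = r.sum(axis=0)
        g_b = (Z * r).sum(axis=0)
        h_aa = w.sum(axis=0)
        h_ab = (w * Z).sum(axis=0)
        h_bb = (w * Z * Z).sum(axis=0)
        det = h_aa * h_bb - h_ab**2
        det = np.where(np.abs(det) > 1e-12, det, np.nan)
        da = (h_bb * g_a - h_ab * g_b) / det
        db = (h_aa * g_b - h_ab * g_a) / det
        da = np.nan_to_num(da)
        db = np.nan_to_num(db)
        # damp huge steps (separation)
        step = np.maximum(np.abs(da), np.abs(db))
        damp = np.where(step > 5.0, 5.0 / step, 1.0)
        a += da * damp
        b += db * damp
        if np.max(step) < 1e-10:
            break
    eta = np.clip(a[None, :] + b[None, :] * Z, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    h_aa = w.sum(axis=0)
    h_ab = (w * Z).sum(axis=0)
    h_bb = (w * Z * Z).sum(axis=0)
    det = h_aa * h_bb - h_ab**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b = h_aa / det
    se = np.sqrt(np.where(var_b > 0, var_b, np.nan))
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = b / se
    pvals = 2.0 * _norm_sf(np.abs(zstat))
    beta = b / sd_safe
    se_out = se / sd_safe
    beta[sd == 0] = np.nan
    pvals[sd == 0] = np.nan
    return beta, se_out, pvals


def _norm_sf(z: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.sf(z)


def univariate_screen(
    X: pd.DataFrame, y: np.ndarray, alpha: float = 0.05
) -> Tuple[List[str], pd.DataFrame]:
    """Per-feature univariate logistic screen (Wald test at ``alpha``).

    Constant features are dropped with a warning.  A feature that
    separates the classes completely makes the Wald statistic
    uninformative (se -> inf); such features are kept with a flag.
    """
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("y must contain both classes")
    Xv = X.to_numpy(dtype=float)
    beta, se, pvals = _wald_logistic_vec(Xv, y)

    rows = []
    kept = []
    for j, col in enumerate(X.columns):
        x = Xv[:, j]
        if np.ptp(x) == 0:
            warnings.warn(f"constant feature {col} dropped")
            rows.append((col, np.nan, np.nan, False, False))
            continue
        # complete separation: some threshold splits classes exactly
        order = np.argsort(x, kind="stable")
        sep = (np.diff(y[order]) != 0).sum() == 1
        if sep:
            rows.append((col, beta[j], 0.0, True, True))
            kept.append(col)
            continue
        p = pvals[j]
        keep = bool(np.isfinite(p) and p < alpha)
        rows.append((col, beta[j], p, keep, False))
        if keep:
            kept.append(col)
    table = pd.DataFrame(rows, columns=["feature", "beta", "p", "kept", "separation"])
    return kept, table


def correlation_prune(X: pd.DataFrame, threshold: float = 0.75) -> List[str]:
    """Iteratively remove one feature of every too-correlated pair.

    While any pair exceeds ``threshold`` in absolute Pearson r, the pair
    with the largest |r| is found and the member with the larger mean
    absolute correlation against all remaining features is removed.
    Ties break deterministically by column order.
    """
    cols = list(X.columns)
    if len(cols) < 2:
        return cols
    r = np.abs(np.corrcoef(X.to_numpy(dtype=float), rowvar=False))
    np.fill_diagonal(r, 0.0)
    r = np.nan_to_num(r)
    alive = list(range(len(cols)))
    while True:
        sub = r[np.ix_(alive, alive)]
        if sub.max() <= threshold:
            break
        i, j = np.unravel_index(sub.argmax(), sub.shape)
        mean_i = sub[i].mean()
        mean_j = sub[j].mean()
        # drop the one more correlated with everything else
        drop = i if mean_i >= mean_j else j
        del alive[drop]
    return [cols[i] for i in alive]


def lasso_select(
    X: pd.DataFrame,
    y: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 30,
    criterion: str = "1se",
) -> Tuple[List[str], pd.DataFrame]:
    """L1-penalized logistic selection with cross-validated penalty.

    The penalty grid is log-spaced; the chosen penalty is the strongest
    within one standard error of the best mean out-of-fold AUC (the
    glmnet-style 1-SE rule, ``criterion='1se'``, default), or the AUC
    maximizer itself (``'max_auc'``).  Features with nonzero
    coefficients at the chosen penalty survive.  Columns are
    standardized internally.
    """
    y = np.asarray(y)
    Xs = X.to_numpy(dtype=float)
    mu, sd = Xs.mean(axis=0), Xs.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (Xs - mu) / sd

    n_pos = int(y.sum())
    folds = max(2, min(n_folds, n_pos, len(y) - n_pos))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    split = [
        (tr, te)
        for tr, te in cv.split(Xs, y)
        if len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2
    ]
    if not split:
        warnings.warn("class too rare for CV; tuning the penalty on training AUC")
        idx = np.arange(len(y))
        split = [(idx, idx)]
    cs = np.logspace(-2.5, 1.5, n_lambdas)

    rows = []
    for c in cs:
        aucs = []
        for tr, te in split:
            clf = LogisticRegression(
                penalty="l1", C=c, solver="liblinear", max_iter=2000, random_state=0
            )
            clf.fit(Xs[tr], y[tr])
            s = clf.decision_function(Xs[te])
            aucs.append(roc_auc_score(y[te], s) if len(np.unique(y[te])) == 2 else np.nan)
        aucs = np.asarray(aucs, dtype=float)
        rows.append((c, np.nanmean(aucs), np.nanstd(aucs) / np.sqrt(folds)))
    path = pd.DataFrame(rows, columns=["C", "cv_auc", "se"])

    if criterion == "1se":
        best = path["cv_auc"].max()
        se_at = path.loc[path["cv_auc"].idxmax(), "se"]
        ok = path[path["cv_auc"] >= best - se_at]
        c_star = ok["C"].min()  # strongest penalty within 1 SE
    else:
        # tie-break toward stronger regularization (smaller C)
        c_star = path.loc[path["cv_auc"].round(12) == path["cv_auc"].max().round(12), "C"].min()

    clf = LogisticRegression(
        penalty="l1", C=float(c_star), solver="liblinear", max_iter=5000, random_state=0
    )
    clf.fit(Xs, y)
    coef = clf.coef_.ravel()
    kept = [c for c, b in zip(X.columns, coef) if b != 0.0]
    if not kept:
        warnings.warn("LASSO selected no features")
    path.attrs["C_star"] = float(c_star)
    return kept, path


def _fit_logit(X: np.ndarray, y: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.Logit(y, X).fit(disp=0, maxiter=200)


def _aic_of(cols: Tuple[int, ...], Xall: np.ndarray, y: np.ndarray) -> float:
    X = sm.add_constant(Xall[:, list(cols)], has_constant="add")
    try:
        res = _fit_logit(X, y)
    except Exception:
        return np.inf
    if not np.isfinite(res.llf):
        return np.inf
    return float(res.aic)


def stepwise_aic(
    X: pd.DataFrame, y: np.ndarray, max_candidates: int = 30
) -> Tuple[List[str], List[float]]:
    """Bidirectional stepwise logistic selection by AIC.

    Starts from the full candidate model and repeatedly applies the
    single add/drop move that lowers AIC the most, stopping when no
    move improves.  Scan order is by descending univariate |z| so the
    procedure is deterministic.
    """
    cols = list(X.columns)
    if len(cols) > max_candidates:
        raise ValueError(f"{len(cols)} candidates exceed {max_candidates}")
    y = np.asarray(y)
    Xall = X.to_numpy(dtype=float)

    # deterministic scan order: descending univariate |z|
    zs = []
    for i, col in enumerate(cols):
        beta, se, _ = _wald_logistic(Xall[:, i], y)
        z = abs(beta / se) if (np.isfinite(se) and se > 0) else np.inf
        zs.append(z)
    order = sorted(range(len(cols)), key=lambda i: (-zs[i], cols[i]))

    current = tuple(order)
    current_aic = _aic_of(current, Xall, y)
    aic_seq = [current_aic]
    while True:
        best_move, best_aic = None, current_aic
        for i in order:
            if i in current:
                cand = tuple(j for j in current if j != i)
            else:
                cand = tuple(sorted(current + (i,), key=order.index))
            a = _aic_of(cand, Xall, y)
            if a < best_aic - 1e-10:
                best_move, best_aic = cand, a
        if best_move is None:
            break
        current, current_aic = best_move, best_aic
        aic_seq.append(current_aic)
    return [cols[i] for i in current], aic_seq


def run_radiomic_cascade(
    X: pd.DataFrame,
    y: np.ndarray,
    icc_tables: Optional[Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]] = None,
    icc_threshold: float = 0.75,
    univariate_alpha: float = 0.05,
    correlation_threshold: float = 0.75,
    n_folds: int = 10,
    seed: int = 0,
    max_stepwise: int = 30,
) -> Tuple[List[str], SelectionTrace]:
    """The full radiomic feature-selection cascade.

    ``icc_tables`` supplies the (rater1, rater2, rater1_repeat) feature
    tables of the reliability substudy; when omitted the ICC step is
    skipped (all features pass).
    """
    trace = SelectionTrace()
    feats = list(X.columns)

    if icc_tables is not None:
        kept, icc_tab = icc_filter(*[t[feats] for t in icc_tables], threshold=icc_threshold)
        trace.record("icc", feats, kept, {"threshold": icc_threshold})
        feats = kept
    if not feats:
        return [], trace

    kept, uni_tab = univariate_screen(X[feats], y, alpha=univariate_alpha)
    trace.record("univariate", feats, kept, {"alpha": univariate_alpha})
    feats = kept
    if not feats:
        return [], trace

    kept = correlation_prune(X[feats], threshold=correlation_threshold)
    trace.record("correlation", feats, kept, {"threshold": correlation_threshold})
    feats = kept
    if not feats:
        return [], trace

    kept, path = lasso_select(X[feats], y, n_folds=n_folds, seed=seed)
    trace.record("lasso", feats, kept, {"C_star": path.attrs.get("C_star")})
    feats = kept
    if not feats:
        return [], trace

    if len(feats) > max_stepwise:
        # keep the strongest univariate candidates within the stepwise cap
        sub = uni_tab.set_index("feature").loc[feats]
        feats = list(sub.sort_values("p").index[:max_stepwise])
    kept, aic_seq = stepwise_aic(X[feats], y, max_candidates=max_stepwise)
    trace.record("stepwise_aic", feats, kept, {"aic_seq": aic_seq})
    return kept, trace


# ---------------------------------------------------------------------------
# clinicoradiological variables
# ---------------------------------------------------------------------------

CLINICAL_DUMMIES = {
    "age": None,  # numeric
    "sex": ("male", ["female"]),  # (reference, levels)
    "cea": ("<=5", [">5"]),
    "ca19_9": ("<=37", [">37"]),
    "location": ("low", ["middle", "high"]),
    "t_stage": ("T1-T2", ["T3-T4"]),
    "n_stage": ("N0", ["N1-N2"]),
}


def encode_clinical(table: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code the clinical covariates against their reference levels."""
    out = pd.DataFrame(index=table.index)
    for var, spec in CLINICAL_DUMMIES.items():
        if var not in table.columns:
            continue
        if spec is None:
            out[var] = table[var].astype(float)
        else:
            _, levels = spec
            for lev in levels:
                out[f"{var}[{lev}]"] = (table[var] == lev).astype(float)
    return out


def select_clinical_variables(
    table: pd.DataFrame,
    y: np.ndarray,
    alpha_univariate: float = 0.1,
    alpha_multivariable: float = 0.05,
) -> Tuple[List[str], pd.DataFrame]:
    """Two-stage clinical variable selection with OR reporting.

    Univariate logistic at P < ``alpha_univariate`` (a multi-level
    variable enters if any of its levels passes), stepwise AIC on the
    survivors, then retention of variables with multivariable Wald
    P < ``alpha_multivariable``.  Returns the retained dummy columns
    and a table of odds ratios with 95% CIs.  An empty selection falls
    back to the intercept-only model with a warning.
    """
    X = encode_clinical(table)
    y = np.asarray(y)

    uni_rows = []
    candidates = []
    var_of = {}
    for var, spec in CLINICAL_DUMMIES.items():
        if var not in table.columns:
            continue
        cols = [var] if spec is None else [f"{var}[{lev}]" for lev in spec[1]]
        for c in cols:
            var_of[c] = var
        ps = []
        for c in cols:
            _, _, p = _wald_logistic(X[c].to_numpy(), y)
            uni_rows.append((var, c, p))
            if np.isfinite(p):
                ps.append(p)
        if ps and min(ps) < alpha_univariate:
            candidates += cols
    if not candidates:
        warnings.warn("no clinical variable passed the univariate gate")
        return [], pd.DataFrame(
            columns=["variable", "level", "odds_ratio", "ci_low", "ci_high", "p"]
        )

    kept, _ = stepwise_aic(X[candidates], y)
    if not kept:
        warnings.warn("stepwise AIC emptied the clinical model")
        return [], pd.DataFrame(
            columns=["variable", "level", "odds_ratio", "ci_low", "ci_high", "p"]
        )

    Xk = sm.add_constant(X[kept].to_numpy(), has_constant="add")
    res = _fit_logit(Xk, y)
    pvals = res.pvalues[1:]
    final = [c for c, p in zip(kept, pvals) if p < alpha_multivariable]

    rows = []
    if final:
        Xf = sm.add_constant(X[final].to_numpy(), has_constant="add")
        res = _fit_logit(Xf, y)
        ci = res.conf_int()
        for i, c in enumerate(final):
            beta = res.params[i + 1]
            rows.append(
                (
                    var_of.get(c, c),
                    c,
                    float(np.exp(beta)),
                    float(np.exp(ci[i + 1, 0])),
                    float(np.exp(ci[i + 1, 1])),
                    float(res.pvalues[i + 1]),
                )
            )
    else:
        warnings.warn("no clinical variable reached multivariable significance")
    or_table = pd.DataFrame(
        rows, columns=["variable", "level", "odds_ratio", "ci_low", "ci_high", "p"]
    )
    return final, or_table
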