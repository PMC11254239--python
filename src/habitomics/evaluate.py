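"""Model comparison and prognostic statistics.

Discrimination (AUC with DeLong confidence intervals, paired DeLong
tests), threshold metrics with stratified bootstrap CIs, decision-curve
net benefit, Hosmer-Lemeshow calibration, Youden-index cutoffs, and
Kaplan-Meier / log-rank disease-free-survival stratification.
"""

from __future__ import annotations

import warnings
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats


# ---------------------------------------------------------------------------
# DeLong machinery
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """Placement values (structural components) of one score vector."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    r_all = _midrank(allv)
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n  # per positive subject
    v01 = 1.0 - (r_all[m:] - r_neg) / m  # per negative subject
    return auc, v10, v01


def roc_auc_ci(
    scores: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> Tuple[float, float, float]:
    """AUC (Mann-Whitney with tie correction) and DeLong normal CI."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y)) != 2:
        raise ValueError("need both classes for an ROC")
    auc, v10, v01 = _delong_components(scores, y)
    var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray, y: np.ndarray) -> float:
    """Two-sided paired DeLong test comparing two correlated AUCs."""
    y = np.asarray(y)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("score vectors must align with y")
    auc_a, v10_a, v01_a = _delong_components(a, y)
    auc_b, v10_b, v01_b = _delong_components(b, y)
    v10 = np.stack([v10_a, v10_b])
    v01 = np.stack([v01_a, v01_b])
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    cov = s10 / v10.shape[1] + s01 / v01.shape[1]
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        warnings.warn("zero variance of the AUC difference; p = 1")
        return 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    return float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# threshold metrics
# ---------------------------------------------------------------------------

def _metrics_at(scores: np.ndarray, y: np.ndarray, cutoff: float) -> Dict[str, float]:
    pred = (scores >= cutoff).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / len(y)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return {"f1": f1, "accuracy": acc, "sensitivity": sens, "specificity": spec}


def classification_metrics(
    scores: np.ndarray,
    y: np.ndarray,
    cutoff: float,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """F1 / accuracy / sensitivity / specificity at a cutoff, with
    stratified bootstrap percentile CIs."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    point = _metrics_at(scores, y, cutoff)
    if not (scores >= cutoff).any():
        warnings.warn("no predicted positives at this cutoff; F1 = 0")

    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    boots = {k: np.empty(n_boot) for k in point}
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, len(pos)), rng.choice(neg, len(neg))]
        )
        mb = _metrics_at(scores[idx], y[idx], cutoff)
        for k in point:
            boots[k][b] = mb[k]
    rows = []
    for k, v in point.items():
        lo, hi = np.percentile(boots[k], [100 * alpha / 2, 100 * (1 - alpha / 2)])
        rows.append((k, v, float(lo), float(hi)))
    return pd.DataFrame(rows, columns=["metric", "value", "ci_low", "ci_high"])


def decision_curve(
    scores: np.ndarray,
    y: np.ndarray,
    thresholds: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Net benefit NB(t) = TP/n - (FP/n) * t/(1-t) over a threshold grid,
    plus treat-all and treat-none reference policies."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    if thresholds is None:
        thresholds = np.arange(0.01, 0.605, 0.01)
    thresholds = np.asarray(list(thresholds), dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie in (0, 1)")
    n = len(y)
    pi = y.mean()
    rows = []
    for t in thresholds:
        pred = scores >= t
        tp = ((pred) & (y == 1)).sum() / n
        fp = ((pred) & (y == 0)).sum() / n
        odds = t / (1 - t)
        rows.append((t, tp - fp * odds, pi - (1 - pi) * odds, 0.0))
    return pd.DataFrame(
        rows, columns=["threshold", "net_benefit", "treat_all", "treat_none"]
    )


def hosmer_lemeshow(
    probs: np.ndarray, y: np.ndarray, n_groups: int = 10
) -> Tuple[float, float, int]:
    """Hosmer-Lemeshow goodness-of-fit over deciles of predicted risk.

    Returns (chi2, p, df) with df = groups - 2.  Groups whose expected
    count is zero are merged into their neighbor with a warning.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y)
    if len(y) < 2 * n_groups:
        raise ValueError("need at least 2 observations per group")
    order = np.argsort(probs, kind="stable")
    p_s, y_s = probs[order], y[order]
    edges = np.linspace(0, len(y), n_groups + 1).astype(int)
    groups = [
        (p_s[a:b], y_s[a:b]) for a, b in zip(edges[:-1], edges[1:]) if b > a
    ]
    chi2 = 0.0
    g_used = 0
    pending = None
    for p_g, y_g in groups:
        if pending is not None:
            p_g = np.concatenate([pending[0], p_g])
            y_g = np.concatenate([pending[1], y_g])
            pending = None
        n_g = len(y_g)
        e = p_g.sum()
        if e == 0 or e == n_g:
            warnings.warn("degenerate expected count; merging adjacent groups")
            pending = (p_g, y_g)
            continue
        o = y_g.sum()
        chi2 += (o - e) ** 2 / (e * (1 - e / n_g))
        g_used += 1
    df = max(g_used - 2, 1)
    return float(chi2), float(stats.chi2.sf(chi2, df)), df


def youden_cutoff(scores: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Scans midpoints between consecutive unique scores (plus outer
    sentinels); ties prefer the higher-specificity (larger) cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    uniq = np.unique(scores)
    cands = np.concatenate(
        [[uniq[0] - 1e-8], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1e-8]]
    )
    best_c, best_j = cands[0], -np.inf
    for c in cands:
        m = _metrics_at(scores, y, c)
        j = m["sensitivity"] + m["specificity"] - 1.0
        if j > best_j or (np.isclose(j, best_j) and c > best_c):
            best_c, best_j = float(c), float(j)
    return best_c, best_j


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def km_logrank(
    times: np.ndarray,
    events: np.ndarray,
    groups: np.ndarray,
    horizon: float = 36.0,
) -> Dict:
    """Kaplan-Meier curves, two-group log-rank test, and the survival
    probability at ``horizon`` (months) per group."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(groups)
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    out = {"groups": {}, "horizon": horizon}
    for lab in labels:
        sel = groups == lab
        if events[sel].sum() == 0:
            warnings.warn(f"group {lab!r} has no events")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        surv = float(kmf.predict(horizon))
        out["groups"][lab] = {
            "n": int(sel.sum()),
            "survival_at_horizon": surv,
            "curve": kmf.survival_function_.reset_index().to_numpy(),
        }
    sel0 = groups == labels[0]
    res = logrank_test(
        times[sel0], times[~sel0], event_observed_A=events[sel0], event_observed_B=events[~sel0]
    )
    out["logrank_p"] = float(res.p_value)
    out["logrank_chi2"] = float(res.test_statistic)
    return out


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def evaluate_models(
    patient_scores: pd.DataFrame,
    model_names: Sequence[str],
    seed: int = 0,
    n_boot: int = 2000,
) -> pd.DataFrame:
    """Table-style performance summary per model and cohort.

    Cutoffs are chosen by Youden's index on the training cohort and
    held fixed for the external test cohort.
    """
    rows = []
    for model in model_names:
        tr = patient_scores[patient_scores["cohort"] == "training"]
        cut, _ = youden_cutoff(tr[model].to_numpy(), tr["msi"].to_numpy())
        for cohort, df in patient_scores.groupby("cohort"):
            s = df[model].to_numpy()
            yv = df["msi"].to_numpy()
            auc, lo, hi = roc_auc_ci(s, yv)
            mets = classification_metrics(s, yv, cut, n_boot=n_boot, seed=seed)
            row = {
                "model": model,
                "cohort": cohort,
                "cutoff": cut,
                "auc": auc,
                "auc_ci_low": lo,
                "auc_ci_high": hi,
            }
            for _, r in mets.iterrows():
                row[r["metric"]] = r["value"]
                row[f"{r['metric']}_ci_low"] = r["ci_low"]
                row[f"{r['metric']}_ci_high"] = r["ci_high"]
            rows.append(row)
    return pd.DataFrame(rows)
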