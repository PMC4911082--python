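"""Diagnostic-accuracy statistics for classifier scores.

Covers the standard binary-test toolkit: contingency counts at a score
threshold (positive = score strictly above threshold), sensitivity and
specificity with exact two-sided Clopper-Pearson 95% intervals, positive
and negative likelihood ratios, ROC curves, AUC with DeLong variance-based
confidence interval and null test against 0.5, the DeLong test for two
correlated AUCs measured on the same samples, Youden-index threshold
optimization, and Spearman rank correlation with a Fisher-z interval.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import ValidationError


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValidationError("labels must be 0 (control) / 1 (case)")
    if np.unique(y).size < 2:
        raise ValidationError("need both classes present")
    return y


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are the midpoints between adjacent distinct
    scores plus sentinels outside the score range; classification is
    positive for scores strictly above the threshold.  Ties in J break
    toward the higher threshold (higher specificity).
    """
    s = np.asarray(scores, dtype=float)
    y = _check_binary(labels)
    uniq = np.unique(s)
    cands = [uniq[0] - 1.0]
    cands += [0.5 * (uniq[i] + uniq[i + 1]) for i in range(uniq.size - 1)]
    cands += [uniq[-1]]
    pos, neg = y == 1, y == 0
    best_t, best_j = cands[0], -math.inf
    for t in cands:  # ascending; equal-J candidates overwrite -> higher specificity
        sens = float(np.mean(s[pos] > t))
        spec = float(np.mean(s[neg] <= t))
        j = sens + spec - 1.0
        if j >= best_j - 1e-12:
            best_t, best_j = t, max(best_j, j)
    return float(best_t), float(best_j)


def clopper_pearson(successes: int, trials: int,
                    level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval (beta-quantile inversion)."""
    k, n = int(successes), int(trials)
    if not (0 <= k <= n) or n == 0:
        raise ValidationError(f"invalid counts {k}/{n}")
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - a, k + 1, n - k))
    return lo, hi


def likelihood_ratios(sensitivity: float, specificity: float) -> tuple[float, float]:
    """LR+ = sens/(1-spec), LR- = (1-sens)/spec; infinities at the boundaries."""
    for v in (sensitivity, specificity):
        if not (0.0 <= v <= 1.0):
            raise ValidationError("sensitivity/specificity must lie in [0, 1]")
    lr_pos = math.inf if specificity == 1.0 else sensitivity / (1.0 - specificity)
    lr_neg = math.inf if specificity == 0.0 else (1.0 - sensitivity) / specificity
    return lr_pos, lr_neg


# ---------------------------------------------------------------- DeLong ---

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and the per-observation placement components V10, V01."""
    m, n = pos.size, neg.size
    allv = np.concatenate([pos, neg])
    r_all = _midrank(allv)
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc = (np.sum(r_all[:m]) - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return float(auc), v10, v01


def _delong_cov(scores_list: list[np.ndarray], labels: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """AUCs and their DeLong covariance matrix for k score vectors on shared samples."""
    y = _check_binary(labels)
    pos_idx, neg_idx = y == 1, y == 0
    m, n = int(pos_idx.sum()), int(neg_idx.sum())
    k = len(scores_list)
    aucs = np.empty(k)
    V10 = np.empty((k, m))
    V01 = np.empty((k, n))
    for i, s in enumerate(scores_list):
        s = np.asarray(s, dtype=float)
        aucs[i], V10[i], V01[i] = _delong_components(s[pos_idx], s[neg_idx])
    def _cov(V):
        if V.shape[1] < 2:  # a single observation carries no variance information
            return np.zeros((k, k))
        return np.atleast_2d(np.cov(V)) if k > 1 else np.atleast_2d(np.var(V[0], ddof=1))

    s10 = _cov(V10)
    s01 = _cov(V01)
    cov = s10 / m + s01 / n
    return aucs, np.atleast_2d(cov)


@dataclass
class RocResult:
    points: np.ndarray          # ordered (1 - specificity, sensitivity)
    auc: float
    ci: tuple[float, float]     # DeLong 95% CI
    p_vs_half: float            # two-sided test of AUC = 0.5


def roc_auc(scores: np.ndarray, labels: np.ndarray, level: float = 0.95) -> RocResult:
    """ROC curve and AUC (pairwise concordance, ties count 1/2) with DeLong CI."""
    s = np.asarray(scores, dtype=float)
    y = _check_binary(labels)
    aucs, cov = _delong_cov([s], y)
    auc, var = float(aucs[0]), float(cov[0, 0])
    z = stats.norm.ppf(1 - (1 - level) / 2)
    se = math.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    if se > 0:
        p = float(2 * stats.norm.sf(abs(auc - 0.5) / se))
    else:
        p = 1.0 if auc == 0.5 else 0.0
    # ROC points: sweep thresholds over distinct scores, rule "score > t"
    uniq = np.unique(s)[::-1]
    pos, neg = y == 1, y == 0
    pts = [(0.0, 0.0)]
    for t in uniq:
        pts.append((float(np.mean(s[neg] > t)), float(np.mean(s[pos] > t))))
    pts[-1] = (1.0, 1.0) if pts[-1] != (1.0, 1.0) else pts[-1]
    points = np.array(sorted(set(pts)))
    return RocResult(points=points, auc=auc, ci=ci, p_vs_half=p)


def compare_auc(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray) -> float:
    """DeLong two-sided p-value for equality of two correlated AUCs."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("score vectors must have equal length")
    aucs, cov = _delong_cov([a, b], labels)
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        return 1.0 if abs(aucs[0] - aucs[1]) < 1e-12 else 0.0
    z = (aucs[0] - aucs[1]) / math.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def spearman_rho(x: np.ndarray, y: np.ndarray,
                 level: float = 0.95) -> tuple[float, tuple[float, float], float]:
    """Spearman rank correlation with Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    n = x.size
    if n < 4:
        raise ValidationError("need at least 4 observations")
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    if abs(rho) >= 1.0:
        return rho, (rho, rho), float(p)
    zq = stats.norm.ppf(1 - (1 - level) / 2)
    zr = math.atanh(rho)
    se = 1.0 / math.sqrt(n - 3)
    ci = (math.tanh(zr - zq * se), math.tanh(zr + zq * se))
    return rho, ci, float(p)


# ------------------------------------------------------- full report ------

@dataclass
class DiagnosticReport:
    """Contingency counts and derived diagnostic-accuracy statistics."""

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    lr_positive: float
    lr_negative: float
    threshold: float
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    auc_p: float | None = None
    roc: np.ndarray | None = None

    def validate(self) -> None:
        if self.tp + self.fn == 0 or self.tn + self.fp == 0:
            raise ValidationError("both groups must be non-empty")
        assert abs(self.sensitivity - self.tp / (self.tp + self.fn)) < 1e-12
        assert abs(self.specificity - self.tn / (self.tn + self.fp)) < 1e-12
        assert self.sensitivity_ci[0] <= self.sensitivity <= self.sensitivity_ci[1]
        assert self.specificity_ci[0] <= self.specificity <= self.specificity_ci[1]

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        if self.roc is not None:
            d["roc"] = self.roc.tolist()
        for k in ("lr_positive", "lr_negative"):
            if math.isinf(d[k]):
                d[k] = None  # JSON has no Infinity; null marks the boundary case
        Path(path).write_text(json.dumps(d, indent=1) + "\n")


def report_from_counts(tp: int, fn: int, tn: int, fp: int,
                       threshold: float = math.nan,
                       level: float = 0.95) -> DiagnosticReport:
    """Assemble a report directly from contingency counts."""
    if tp + fn == 0 or tn + fp == 0:
        raise ValidationError("both groups must be non-empty")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    lrp, lrn = likelihood_ratios(sens, spec)
    rep = DiagnosticReport(
        tp=tp, fn=fn, tn=tn, fp=fp, sensitivity=sens, specificity=spec,
        sensitivity_ci=clopper_pearson(tp, tp + fn, level),
        specificity_ci=clopper_pearson(tn, tn + fp, level),
        lr_positive=lrp, lr_negative=lrn, threshold=threshold)
    rep.validate()
    return rep


def contingency_report(scores: np.ndarray, labels: np.ndarray,
                       threshold: float, level: float = 0.95) -> DiagnosticReport:
    """Full diagnostic report at a fixed threshold (positive = score > threshold)."""
    s = np.asarray(scores, dtype=float)
    y = _check_binary(labels)
    pos, neg = y == 1, y == 0
    tp = int(np.sum(s[pos] > threshold))
    fn = int(pos.sum() - tp)
    fp = int(np.sum(s[neg] > threshold))
    tn = int(neg.sum() - fp)
    rep = report_from_counts(tp, fn, tn, fp, threshold=threshold, level=level)
    roc = roc_auc(s, y, level=level)
    rep.auc, rep.auc_ci, rep.auc_p, rep.roc = roc.auc, roc.ci, roc.p_vs_half, roc.points
    return rep
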