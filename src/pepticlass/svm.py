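"""RBF-kernel support-vector disease classifier scored as distance to hyperplane.

The classifier operates on log-transformed panel intensities, log(1 + a),
so that undetected peptides (a = 0) sit at a finite coordinate 0.  A
soft-margin SVM with the Gaussian kernel K(u, v) = exp(-gamma ||u - v||^2)
is fitted on the training labels; the reported *score factor* of a sample x
is its signed Euclidean distance to the maximal-margin hyperplane in the
kernel feature space,

    score(x) = ( sum_i alpha_i y_i K(x_i, x) + b ) / ||w||,
    ||w||    = sqrt( sum_ij alpha_i alpha_j y_i y_j K(x_i, x_j) ),

positive on the case side.  Model selection (C, gamma) is by leave-one-out
cross-validation over a grid, maximizing balanced accuracy at threshold 0.

The quadratic-programming dual is solved by scikit-learn's SVC (libsvm);
the model object stores support vectors, dual coefficients and bias so
scoring is self-contained and models reload bit-identically from JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .errors import ScoringError, TrainingError, ValidationError
from .model import PanelDefinition, PeptideMatrix

#: libsvm stopping tolerance; tight so that scores are stable to removal of
#: non-support vectors and to support-vector bookkeeping.
SOLVER_TOL = 1e-8


def log_transform(amplitudes: np.ndarray) -> np.ndarray:
    """Elementwise log(1 + amplitude); zeros map to exactly 0."""
    a = np.asarray(amplitudes, dtype=float)
    if np.any(a < 0):
        raise ValidationError("amplitudes must be >= 0 before log transform")
    return np.log1p(a)


def rbf_kernel(u: np.ndarray, v: np.ndarray, gamma: float) -> float:
    """Gaussian similarity exp(-gamma ||u - v||^2) in (0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValidationError(f"dimension mismatch: {u.shape} vs {v.shape}")
    d = u - v
    return float(np.exp(-gamma * np.dot(d, d)))


def _rbf_matrix(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    aa = np.sum(A * A, axis=1)[:, None]
    bb = np.sum(B * B, axis=1)[None, :]
    sq = np.maximum(aa + bb - 2.0 * A @ B.T, 0.0)
    return np.exp(-gamma * sq)


@dataclass
class ClassifierConfig:
    """Soft-margin cost and kernel width, plus an optional search grid."""

    C: float = 6.4
    gamma: float = 0.001024
    grid_C: list[float] = field(default_factory=list)
    grid_gamma: list[float] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be strictly positive")


@dataclass
class ClassifierModel:
    """A trained RBF-SVM over a peptide panel, scored as distance to hyperplane."""

    panel: PanelDefinition
    support_vectors: np.ndarray      # (n_sv, n_panel) log-intensities
    dual_coef: np.ndarray            # alpha_i * y_i, |.| <= C
    bias: float
    config: ClassifierConfig
    weight_norm: float               # ||w|| in the kernel feature space

    def decision_value(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.support_vectors.shape[1]:
            raise ScoringError(
                f"sample has {X.shape[1]} features, panel expects "
                f"{self.support_vectors.shape[1]}")
        K = _rbf_matrix(X, self.support_vectors, self.config.gamma)
        return K @ self.dual_coef + self.bias

    def score(self, x: np.ndarray) -> float:
        """Signed Euclidean distance of one log-intensity vector to the hyperplane."""
        return float(self.decision_value(np.atleast_2d(x))[0] / self.weight_norm)

    def scores(self, X: np.ndarray) -> np.ndarray:
        return self.decision_value(X) / self.weight_norm

    def to_json(self, path: str | Path) -> None:
        d = {
            "panel": {"name": self.panel.name, "peptide_ids": self.panel.peptide_ids,
                      "provenance": self.panel.provenance},
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "bias": self.bias,
            "C": self.config.C,
            "gamma": self.config.gamma,
            "weight_norm": self.weight_norm,
        }
        Path(path).write_text(json.dumps(d) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassifierModel":
        d = json.loads(Path(path).read_text())
        return cls(
            panel=PanelDefinition(name=d["panel"]["name"],
                                  peptide_ids=[int(i) for i in d["panel"]["peptide_ids"]],
                                  provenance=d["panel"].get("provenance", "")),
            support_vectors=np.array(d["support_vectors"], dtype=float),
            dual_coef=np.array(d["dual_coef"], dtype=float),
            bias=float(d["bias"]),
            config=ClassifierConfig(C=float(d["C"]), gamma=float(d["gamma"])),
            weight_norm=float(d["weight_norm"]))


def train(X_log: np.ndarray, y: np.ndarray, config: ClassifierConfig,
          panel: PanelDefinition | None = None) -> ClassifierModel:
    """Fit the soft-margin RBF-SVM on log-intensities.

    ``y`` holds +1 for cases, -1 for controls (booleans accepted).  Raises
    :class:`TrainingError` on single-class input.
    """
    X = np.asarray(X_log, dtype=float)
    yy = np.where(np.asarray(y).astype(float) > 0, 1, -1)
    if np.unique(yy).size < 2:
        raise TrainingError("training data contain a single class")
    svc = SVC(C=config.C, gamma=config.gamma, kernel="rbf", tol=SOLVER_TOL,
              shrinking=True, cache_size=64)
    svc.fit(X, yy)
    dual = svc.dual_coef_[0]           # alpha_i * y_i for classes_ = [-1, 1]
    sv = svc.support_vectors_
    K = _rbf_matrix(sv, sv, config.gamma)
    wnorm = float(np.sqrt(max(dual @ K @ dual, 0.0)))
    if wnorm <= 0:
        raise TrainingError("degenerate training set: zero weight norm")
    return ClassifierModel(
        panel=panel or PanelDefinition(name="unnamed", peptide_ids=list(range(1, X.shape[1] + 1))),
        support_vectors=sv.copy(), dual_coef=dual.copy(),
        bias=float(svc.intercept_[0]), config=config, weight_norm=wnorm)


def panel_log_matrix(matrix: PeptideMatrix, panel: PanelDefinition) -> np.ndarray:
    """Log-transformed amplitudes restricted (and ordered) to the panel columns."""
    try:
        cols = matrix.column_index(panel.peptide_ids)
    except ValidationError as exc:
        raise ScoringError(str(exc)) from exc
    return log_transform(matrix.amplitudes[:, cols])


def loo_cross_validate(X_log: np.ndarray, y: np.ndarray,
                       config: ClassifierConfig) -> tuple[np.ndarray, float, float]:
    """Leave-one-out CV: held-out score per sample, sensitivity and specificity.

    Classification of held-out samples uses threshold 0 (positive = score
    above 0).  Refuses degenerate problems with n < 4.
    """
    X = np.asarray(X_log, dtype=float)
    yy = np.where(np.asarray(y).astype(float) > 0, 1, -1)
    n = X.shape[0]
    if n < 4:
        raise TrainingError(f"leave-one-out on n={n} samples is degenerate")
    scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = train(X[mask], yy[mask], config)
        scores[i] = model.score(X[i])
    pos = yy > 0
    sens = float(np.mean(scores[pos] > 0)) if pos.any() else float("nan")
    spec = float(np.mean(scores[~pos] <= 0)) if (~pos).any() else float("nan")
    return scores, sens, spec


def grid_search(X_log: np.ndarray, y: np.ndarray, grid_C: list[float],
                grid_gamma: list[float], seed: int = 0) -> tuple[ClassifierConfig, list[dict]]:
    """Pick (C, gamma) maximizing LOO balanced accuracy.

    Ties break toward smaller C, then smaller gamma.  Returns the winning
    config and the full grid table (one dict per grid point).
    """
    if not grid_C or not grid_gamma:
        raise ValidationError("grid must be non-empty")
    table = []
    best = None
    for C in sorted(grid_C):
        for gamma in sorted(grid_gamma):
            cfg = ClassifierConfig(C=C, gamma=gamma, seed=seed)
            _, sens, spec = loo_cross_validate(X_log, y, cfg)
            bal = 0.5 * (sens + spec)
            table.append({"C": C, "gamma": gamma, "loo_sensitivity": sens,
                          "loo_specificity": spec, "balanced_accuracy": bal})
            if best is None or bal > best[0] + 1e-12:
                best = (bal, cfg)
    assert best is not None
    return best[1], table
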