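"""Biomarker definition: frequencies, rank-sum tests, FDR, differential excretion.

A peptide becomes a biomarker candidate only if it is detected in at least
70% of samples of either group (the frequency gate precedes any testing).
Gated peptides are compared between groups with the two-sided Wilcoxon
rank-sum test — zeros for undetected samples included as tied observations
— and the resulting p-values are adjusted by the Benjamini-Hochberg
step-up over the gated set only.  A peptide is selected when its adjusted
p-value falls below the significance level.

The signed differential-excretion (DE) statistic summarizes direction and
size of the group difference:  with P_case = mean(case) x freq(case) and
P_ctrl = mean(control) x freq(control), both means zero-imputed over all
samples,

    DE = P_case / P_ctrl   if P_case > P_ctrl,   else  -P_ctrl / P_case,

so |DE| >= 1 and the sign marks the direction of excretion in cases.  Note
the zero-imputed mean already carries the detection frequency once, so the
product weights frequency twice; the statistic is implemented exactly in
this product form, with a detected-only-mean variant available for
sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .model import BiomarkerRecord, PanelDefinition, PeptideMatrix

#: Largest combined sample size for which the exact rank-sum null
#: distribution is used in the no-ties case.
EXACT_N_MAX = 25

#: With ties, the exact conditional (permutation) distribution is enumerated
#: up to this combined size; beyond it the tie-corrected normal
#: approximation with continuity correction takes over.
TIED_EXACT_N_MAX = 14


@dataclass
class DiscoveryConfig:
    frequency_threshold: float = 0.70
    alpha: float = 0.05
    include_zeros_in_test: bool = True
    detected_only_de_mean: bool = False

    def __post_init__(self):
        if not (0.0 < self.frequency_threshold <= 1.0):
            raise ValueError("frequency_threshold must be in (0, 1]")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


def detection_frequency(amplitudes: np.ndarray) -> float:
    """Fraction of samples in which the peptide is detected (amplitude > 0)."""
    a = np.asarray(amplitudes, dtype=float)
    if a.size == 0:
        raise ValidationError("detection frequency of an empty vector is undefined")
    return float(np.count_nonzero(a > 0) / a.size)


def wilcoxon_rank_sum(case: np.ndarray, control: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank sum of the case group with midranks
    for ties.  The exact null distribution is used when the combined sample
    size is at most 25 and there are no ties, and the exact conditional
    permutation distribution when there are ties and the combined size is at
    most 14 (the normal approximation is unreliable for tiny tied samples);
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(case, dtype=float)
    y = np.asarray(control, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    m = x.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    ranks = stats.rankdata(pooled)
    w = float(np.sum(ranks[:m]))
    u = w - m * (m + 1) / 2.0
    if has_ties and pooled.size <= TIED_EXACT_N_MAX:
        return w, _exact_tied_p(ranks, m, u)
    method = "exact" if (pooled.size <= EXACT_N_MAX and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return w, float(res.pvalue)


def _exact_tied_p(ranks: np.ndarray, m: int, u_obs: float) -> float:
    """Exact two-sided p under the conditional permutation distribution of U.

    Enumerates all ways the m case positions can fall among the pooled
    midranks; p = min(1, 2 * min(P(U <= u), P(U >= u))).
    """
    from itertools import combinations

    n_total = ranks.size
    offset = m * (m + 1) / 2.0
    us = np.array([sum(c) - offset for c in combinations(ranks, m)])
    eps = 1e-9
    p_lo = np.mean(us <= u_obs + eps)
    p_hi = np.mean(us >= u_obs - eps)
    return float(min(1.0, 2.0 * min(p_lo, p_hi)))


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_excretion(case: np.ndarray, control: np.ndarray,
                           detected_only_mean: bool = False) -> tuple[float, bool]:
    """Signed differential-excretion ratio between case and control.

    Returns ``(de, defined)``.  ``de`` is +/-inf when exactly one group's
    mean-x-frequency product is zero and NaN (with ``defined=False``) when
    both are.  With ``detected_only_mean`` the mean is taken over detected
    samples only (the frequency then enters the product once).
    """
    x = np.asarray(case, dtype=float)
    y = np.asarray(control, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")

    def product(v: np.ndarray) -> float:
        freq = detection_frequency(v)
        if detected_only_mean:
            mean = float(np.mean(v[v > 0])) if freq > 0 else 0.0
        else:
            mean = float(np.mean(v))
        return mean * freq

    pc, pk = product(x), product(y)
    if pc == 0.0 and pk == 0.0:
        return math.nan, False
    if pk == 0.0:
        return math.inf, True
    if pc == 0.0:
        return -math.inf, True
    return (pc / pk if pc > pk else -pk / pc), True


def select_biomarkers(matrix: PeptideMatrix,
                      config: DiscoveryConfig | None = None) -> list[BiomarkerRecord]:
    """Run the full discovery procedure on a case/control matrix.

    Returns one record per matrix peptide.  The frequency gate is applied
    before testing and the BH adjustment runs over the gated set only;
    ungated peptides carry NaN p-values.
    """
    cfg = config or DiscoveryConfig()
    case_rows = matrix.group_mask("case")
    ctrl_rows = matrix.group_mask("control")
    if not case_rows.any() or not ctrl_rows.any():
        raise ValidationError("matrix must contain both case and control samples")

    n_p = matrix.n_peptides
    freqs_case = np.empty(n_p)
    freqs_ctrl = np.empty(n_p)
    gated = np.zeros(n_p, dtype=bool)
    p_raw = np.full(n_p, math.nan)
    de = np.full(n_p, math.nan)
    de_defined = np.zeros(n_p, dtype=bool)

    for j in range(n_p):
        xa = matrix.amplitudes[case_rows, j]
        ya = matrix.amplitudes[ctrl_rows, j]
        freqs_case[j] = detection_frequency(xa)
        freqs_ctrl[j] = detection_frequency(ya)
        gated[j] = max(freqs_case[j], freqs_ctrl[j]) >= cfg.frequency_threshold
        de[j], de_defined[j] = differential_excretion(
            xa, ya, detected_only_mean=cfg.detected_only_de_mean)
        if gated[j]:
            if cfg.include_zeros_in_test:
                xt, yt = xa, ya
            else:
                xt, yt = xa[xa > 0], ya[ya > 0]
                if xt.size == 0 or yt.size == 0:
                    continue  # untestable without zeros; stays NaN
            _, p_raw[j] = wilcoxon_rank_sum(xt, yt)

    tested = np.isfinite(p_raw)
    p_adj = np.full(n_p, math.nan)
    if tested.any():
        p_adj[tested] = benjamini_hochberg(p_raw[tested])
    selected = tested & (p_adj < cfg.alpha)

    return [BiomarkerRecord(
        peptide_id=matrix.peptide_ids[j],
        freq_case=float(freqs_case[j]), freq_control=float(freqs_ctrl[j]),
        p_raw=float(p_raw[j]), p_adjusted=float(p_adj[j]), de=float(de[j]),
        gated=bool(gated[j]), selected=bool(selected[j]),
        de_defined=bool(de_defined[j]))
        for j in range(n_p)]


def panel_from_records(records: list[BiomarkerRecord], name: str,
                       provenance: str = "") -> PanelDefinition:
    """Build a panel from the selected biomarkers of a discovery run."""
    ids = [r.peptide_id for r in records if r.selected]
    if not ids:
        raise ValidationError("no biomarkers selected; cannot build a panel")
    return PanelDefinition(name=name, peptide_ids=ids, provenance=provenance)
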