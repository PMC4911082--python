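"""Per-sample preprocessing and cross-sample peptide matching.

Three steps turn raw peak lists into a comparable samples x peptides
amplitude matrix:

1. **CE-time calibration** — migration times shift and stretch between
   runs.  Each sample's observed times are mapped onto a canonical time
   axis by locally weighted (LOESS, local-linear, tricube) regression of
   the known reference-peptide times on their observed times.  After
   calibration every matched reference peptide must sit within 0.35 min of
   its canonical time, otherwise the sample is flagged.

2. **Housekeeping normalization** — urine dilution and instrument response
   scale all amplitudes of a run by a common factor.  The factor is
   estimated as the median ratio of observed to reference amplitude over
   the detected housekeeping peptides, and divided out.

3. **Peptide matching (clustering)** — peaks from different samples are
   considered the same peptide when the mass deviation is below 50 ppm and
   the calibrated CE-time difference is below 0.35 min.  Matching is greedy
   centroid clustering in ascending-mass order: a peak joins the
   nearest-mass cluster whose centroid it is compatible with, centroids
   are running means, and a cluster takes at most one peak per sample
   (the peak nearer the centroid mass wins; the loser seeds a new
   cluster).  A transitive single-linkage rule could chain far beyond
   50 ppm; anchoring to the centroid keeps clusters tight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import CalibrationError, NormalizationError
from .model import HousekeepingTable, PeakList, PeptideMatrix, ReferenceTable


@dataclass
class MatchingConfig:
    """Identity tolerances for cross-sample peptide matching."""

    mass_tolerance_ppm: float = 50.0
    ce_tolerance_min: float = 0.35

    def __post_init__(self):
        if self.mass_tolerance_ppm <= 0 or self.ce_tolerance_min <= 0:
            raise ValueError("matching tolerances must be strictly positive")


#: Post-calibration QC bound on reference residuals (min); doubles as the
#: CE tolerance used in clustering.
CE_RESIDUAL_BOUND = 0.35


@dataclass
class CalibrationModel:
    """Fitted CE-time mapping for one sample."""

    sample_id: str
    matched_reference_ids: list[int]
    observed_times: np.ndarray
    true_times: np.ndarray
    bandwidth: float
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_matched(self) -> int:
        return len(self.matched_reference_ids)

    @property
    def max_residual(self) -> float:
        return float(np.max(np.abs(self.residuals))) if self.residuals.size else math.nan


def _match_by_mass(sample: PeakList, masses: np.ndarray, ppm: float) -> dict[int, int]:
    """Greedy nearest-mass matching of table entries to sample peaks.

    Returns {table index -> peak index}; each peak is used at most once,
    closer (relative) matches claiming peaks first.
    """
    cand: list[tuple[float, int, int]] = []
    pm = sample.mass
    order = np.argsort(pm)
    sorted_m = pm[order]
    for ti, m in enumerate(masses):
        tol = m * ppm * 1e-6
        lo = np.searchsorted(sorted_m, m - tol)
        hi = np.searchsorted(sorted_m, m + tol, side="right")
        for k in range(lo, hi):
            pi = int(order[k])
            cand.append((abs(pm[pi] - m) / m, ti, pi))
    cand.sort()
    used_t: set[int] = set()
    used_p: set[int] = set()
    out: dict[int, int] = {}
    for _, ti, pi in cand:
        if ti in used_t or pi in used_p:
            continue
        out[ti] = pi
        used_t.add(ti)
        used_p.add(pi)
    return out


def calibrate_ce_time(sample: PeakList, references: ReferenceTable,
                      bandwidth: float = 0.3, mass_tolerance_ppm: float = 50.0,
                      min_references: int = 10) -> tuple[PeakList, CalibrationModel]:
    """Map a sample's CE times onto the canonical axis of the reference set.

    Reference peptides are located in the sample by mass alone (within
    ``mass_tolerance_ppm``); canonical time is regressed on observed time by
    LOESS (local linear, tricube weights, span ``bandwidth``) and the fit is
    evaluated at every peak's observed time.  Raises
    :class:`CalibrationError` when fewer than ``min_references`` references
    match or when any post-calibration reference residual exceeds
    0.35 min.
    """
    matches = _match_by_mass(sample, references.masses, mass_tolerance_ppm)
    if len(matches) < min_references:
        raise CalibrationError(
            f"sample {sample.sample_id}: only {len(matches)} of "
            f"{len(references.ids)} reference peptides matched "
            f"(need >= {min_references})")
    t_idx = sorted(matches)
    obs = np.array([sample.ce_time[matches[i]] for i in t_idx])
    true = references.ce_times[np.array(t_idx)]

    order = np.argsort(obs)
    obs_s, true_s = obs[order], true[order]
    xvals = np.asarray(sample.ce_time, dtype=float)
    fitted = lowess(true_s, obs_s, frac=bandwidth, it=2, xvals=xvals)
    calibrated = np.asarray(fitted, dtype=float)

    new_peaks = sample.peaks.copy()
    new_peaks[:, 1] = calibrated
    out = sample.replace(peaks=new_peaks)

    residuals = calibrated[[matches[i] for i in t_idx]] - true
    model = CalibrationModel(sample_id=sample.sample_id,
                             matched_reference_ids=[references.ids[i] for i in t_idx],
                             observed_times=obs, true_times=true,
                             bandwidth=bandwidth, residuals=residuals)
    if model.max_residual >= CE_RESIDUAL_BOUND:
        raise CalibrationError(
            f"sample {sample.sample_id}: max reference residual "
            f"{model.max_residual:.3f} min exceeds {CE_RESIDUAL_BOUND} min after calibration")
    return out, model


def normalize_amplitudes(sample: PeakList, housekeeping: HousekeepingTable,
                         mass_tolerance_ppm: float = 50.0,
                         ce_tolerance_min: float = CE_RESIDUAL_BOUND) -> PeakList:
    """Divide all amplitudes by the housekeeping median-ratio scale factor.

    The scale is median(observed amplitude / reference amplitude) over
    housekeeping peptides found in the sample (mass within tolerance, CE
    time within tolerance).  Requires at least half the housekeeping set to
    be detected; the estimated scale is recorded in
    ``sample.metadata['normalization_scale']``.
    """
    matches = _match_by_mass(sample, housekeeping.masses, mass_tolerance_ppm)
    matches = {ti: pi for ti, pi in matches.items()
               if abs(sample.ce_time[pi] - housekeeping.ce_times[ti]) <= ce_tolerance_min}
    need = math.ceil(len(housekeeping.ids) / 2)
    if len(matches) < need:
        raise NormalizationError(
            f"sample {sample.sample_id}: only {len(matches)} of "
            f"{len(housekeeping.ids)} housekeeping peptides detected (need >= {need})")
    ratios = np.array([sample.amplitude[pi] / housekeeping.reference_amplitudes[ti]
                       for ti, pi in matches.items()])
    scale = float(np.median(ratios))
    new_peaks = sample.peaks.copy()
    new_peaks[:, 2] = new_peaks[:, 2] / scale
    meta = dict(sample.metadata)
    meta["normalization_scale"] = scale
    meta["n_housekeeping_detected"] = len(matches)
    return sample.replace(peaks=new_peaks, metadata=meta)


class _Cluster:
    __slots__ = ("mass_sum", "time_sum", "n", "members")

    def __init__(self, mass: float, time: float, sample_idx: int, amplitude: float):
        self.mass_sum = mass
        self.time_sum = time
        self.n = 1
        # sample_idx -> (peak mass, peak time, amplitude)
        self.members: dict[int, tuple[float, float, float]] = {
            sample_idx: (mass, time, amplitude)}

    @property
    def mass(self) -> float:
        return self.mass_sum / self.n

    @property
    def time(self) -> float:
        return self.time_sum / self.n

    def add(self, mass: float, time: float, sample_idx: int, amplitude: float):
        self.mass_sum += mass
        self.time_sum += time
        self.n += 1
        self.members[sample_idx] = (mass, time, amplitude)

    def remove(self, sample_idx: int):
        mass, time, _ = self.members.pop(sample_idx)
        self.mass_sum -= mass
        self.time_sum -= time
        self.n -= 1


def match_peptides(samples: list[PeakList],
                   config: MatchingConfig | None = None) -> PeptideMatrix:
    """Cluster peaks across samples into peptides and build the amplitude matrix.

    Deterministic given input order.  Peptide IDs are ascending integers
    (starting at 1) in consensus-mass order; samples lacking a peptide get
    an explicit amplitude of 0.
    """
    cfg = config or MatchingConfig()
    tol_rel = cfg.mass_tolerance_ppm * 1e-6
    tol_ce = cfg.ce_tolerance_min

    rows = []
    for si, s in enumerate(samples):
        for pi in range(len(s)):
            rows.append((s.mass[pi], s.ce_time[pi], s.amplitude[pi], si))
    if not rows:
        return PeptideMatrix(peptide_ids=[], consensus_mass=np.empty(0),
                             consensus_ce_time=np.empty(0),
                             amplitudes=np.zeros((len(samples), 0)),
                             sample_ids=[s.sample_id for s in samples],
                             groups=[s.group for s in samples])
    rows.sort(key=lambda r: (r[0], r[1], r[3]))

    clusters: list[_Cluster] = []   # kept in seeding order; masses mostly ascending
    active_from = 0                 # clusters before this index can no longer match

    def eligible(cl: _Cluster, m: float, t: float) -> bool:
        cm = cl.mass
        return abs(m - cm) / cm <= tol_rel and abs(t - cl.time) <= tol_ce

    for m, t, a, si in rows:
        # advance the frozen frontier: centroid masses of active clusters are
        # >= (current mass) * (1 - 2*tol) once sorted input has moved past them
        while active_from < len(clusters) and \
                clusters[active_from].mass < m * (1 - 4 * tol_rel):
            active_from += 1
        best: _Cluster | None = None
        best_d = math.inf
        for cl in clusters[active_from:]:
            if eligible(cl, m, t):
                d = abs(m - cl.mass)
                if d < best_d:
                    best, best_d = cl, d
        if best is None:
            clusters.append(_Cluster(m, t, si, a))
            continue
        if si in best.members:
            inc_mass, inc_time, inc_amp = best.members[si]
            # nearest to the centroid mass wins; the loser seeds a new cluster
            if abs(m - best.mass) < abs(inc_mass - best.mass):
                best.remove(si)
                best.add(m, t, si, a)
                clusters.append(_Cluster(inc_mass, inc_time, si, inc_amp))
            else:
                clusters.append(_Cluster(m, t, si, a))
        else:
            best.add(m, t, si, a)

    clusters.sort(key=lambda c: (c.mass, c.time))
    n_s, n_p = len(samples), len(clusters)
    amps = np.zeros((n_s, n_p))
    for j, cl in enumerate(clusters):
        for si, (_, _, amp) in cl.members.items():
            amps[si, j] = amp
    mat = PeptideMatrix(
        peptide_ids=list(range(1, n_p + 1)),
        consensus_mass=np.array([c.mass for c in clusters]),
        consensus_ce_time=np.array([c.time for c in clusters]),
        amplitudes=amps,
        sample_ids=[s.sample_id for s in samples],
        groups=[s.group for s in samples])
    mat.validate()
    return mat
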