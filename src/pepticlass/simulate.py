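"""Synthetic CE-MS urine cohort generator.

Emulates the statistical structure of deconvoluted urinary peptide peak
lists from a case/control study:

* a fixed catalogue of peptides with masses in ~800-3600 Da and CE
  migration times in a configurable window, with pairwise mass gaps wide
  enough that the 50 ppm clustering tolerance can in principle resolve them;
* log-normal signal amplitudes with peptide-specific baselines, a shared
  within-sample noise scale, and a per-sample multiplicative urine-dilution
  factor;
* Bernoulli detection dropout (undetected = absent from the peak list);
* a designated set of housekeeping peptides (default 29) that are always
  detected and excreted with low biological variance — the anchor for
  dilution normalization;
* a designated set of calibration reference peptides with known canonical
  CE times — the anchor for migration-time alignment;
* smooth per-sample CE-time drift plus ppm-scale mass noise;
* planted case/control marker effects: a log-fold-change of the case
  amplitude mean and an additive shift of the case detection probability.

The generator returns the cohort together with a :class:`GroundTruth`
object (planted effects, dilutions, drift parameters, housekeeping and
reference tables) so that recovery of the planted structure by the analysis
pipeline can be tested quantitatively.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np

from .errors import ConfigError
from .model import (Group, HousekeepingTable, PeakList, PeptideMatrix,
                    ReferenceTable)

#: Minimum pairwise mass separation between catalogue peptides, in ppm.
#: Kept well above the 50 ppm clustering tolerance so that planted peptides
#: are resolvable in principle; real peptidomes violate this occasionally,
#: which the clustering tie-break rules are there to absorb.
MIN_MASS_GAP_PPM = 200.0


@dataclass
class MarkerEffect:
    """A planted disease effect on one catalogue peptide."""

    peptide_index: int
    log_fold_change: float      # shift of the case log-amplitude mean
    detection_shift: float = 0.0  # additive shift of the case detection prob


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults are scaled-down study conditions: a discovery-sized cohort
    (30 + 30 samples), a few hundred peptides, 29 housekeeping peptides and
    60 calibration references, lognormal amplitudes with unit log-scale
    noise, 80% baseline detection, and mild dilution/drift/mass noise.
    """

    n_case: int = 30
    n_control: int = 30
    n_peptides: int = 300
    n_housekeeping: int = 29
    n_reference: int = 60
    mass_range: tuple[float, float] = (800.0, 3600.0)
    ce_range: tuple[float, float] = (19.0, 45.0)
    log_amplitude_mean: float = 5.0      # natural-log scale, exp(5) ~ 150 units
    log_amplitude_sd: float = 1.0        # within-sample (biological+technical) noise
    between_peptide_sd: float = 1.0      # spread of peptide-specific baselines
    housekeeping_sd: float = 0.1         # housekeeping peptides are stably excreted
    detection_prob_base: float = 0.8
    reference_detection_floor: float = 0.95  # calibrants are common peptides
    marker_spec: list[MarkerEffect] = field(default_factory=list)
    dilution_sd: float = 0.4             # log-scale sd of per-sample dilution
    ce_drift_model: str = "none"         # none | affine | smooth
    ce_drift_shift_sd: float = 0.3       # min
    ce_drift_scale_sd: float = 0.01      # relative
    ce_drift_curvature_sd: float = 0.0008  # min^-1, smooth model only
    mass_noise_ppm: float = 10.0
    ce_noise_min: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ConfigError("need at least one sample per group")
        if not (0.0 <= self.detection_prob_base <= 1.0):
            raise ConfigError("detection_prob_base must be in [0, 1]")
        if self.n_housekeeping + self.n_reference > self.n_peptides:
            raise ConfigError("housekeeping + reference peptides exceed n_peptides")
        if not (0 < self.mass_range[0] < self.mass_range[1]):
            raise ConfigError("mass_range must be positive and ordered")
        if not (0 < self.ce_range[0] < self.ce_range[1]):
            raise ConfigError("ce_range must be positive and ordered")
        if self.ce_drift_model not in ("none", "affine", "smooth"):
            raise ConfigError(f"unknown ce_drift_model {self.ce_drift_model!r}")
        n_special = self.n_housekeeping + self.n_reference
        for mk in self.marker_spec:
            if not (n_special <= mk.peptide_index < self.n_peptides):
                raise ConfigError(
                    f"marker index {mk.peptide_index} out of range "
                    f"[{n_special}, {self.n_peptides}) — housekeeping/reference "
                    "peptides cannot carry disease effects")

    def swapped(self) -> "CohortSpec":
        """Exchange case/control roles: group sizes swap, planted effects negate."""
        return dataclasses.replace(
            self,
            n_case=self.n_control,
            n_control=self.n_case,
            marker_spec=[MarkerEffect(m.peptide_index, -m.log_fold_change,
                                      -m.detection_shift) for m in self.marker_spec],
        )


@dataclass
class GroundTruth:
    """Everything planted by :func:`generate_cohort`, for recovery tests."""

    marker_ids: list[int]
    marker_log_fold_change: dict[int, float]
    marker_detection_shift: dict[int, float]
    true_mass: np.ndarray
    true_ce_time: np.ndarray
    peptide_log_mean: np.ndarray
    housekeeping_ids: list[int]
    reference_ids: list[int]
    dilution: dict[str, float]
    drift_params: dict[str, tuple[float, float, float]]

    @property
    def housekeeping_table(self) -> HousekeepingTable:
        idx = np.array(self.housekeeping_ids)
        return HousekeepingTable(
            ids=list(idx), masses=self.true_mass[idx], ce_times=self.true_ce_time[idx],
            reference_amplitudes=np.exp(self.peptide_log_mean[idx]))

    @property
    def reference_table(self) -> ReferenceTable:
        idx = np.array(self.reference_ids)
        return ReferenceTable(ids=list(idx), masses=self.true_mass[idx],
                              ce_times=self.true_ce_time[idx])

    def match_markers(self, matrix: PeptideMatrix, ppm: float = 50.0) -> dict[int, int]:
        """Map planted marker ids to matrix peptide ids by nearest consensus mass."""
        out: dict[int, int] = {}
        for mid in self.marker_ids:
            m = self.true_mass[mid]
            j = int(np.argmin(np.abs(matrix.consensus_mass - m)))
            if abs(matrix.consensus_mass[j] - m) / m * 1e6 <= ppm:
                out[mid] = matrix.peptide_ids[j]
        return out

    def to_json(self, path: str | Path) -> None:
        d = {
            "marker_ids": self.marker_ids,
            "marker_log_fold_change": {str(k): v for k, v in self.marker_log_fold_change.items()},
            "marker_detection_shift": {str(k): v for k, v in self.marker_detection_shift.items()},
            "true_mass": self.true_mass.tolist(),
            "true_ce_time": self.true_ce_time.tolist(),
            "peptide_log_mean": self.peptide_log_mean.tolist(),
            "housekeeping_ids": self.housekeeping_ids,
            "reference_ids": self.reference_ids,
            "dilution": self.dilution,
            "drift_params": {k: list(v) for k, v in self.drift_params.items()},
        }
        Path(path).write_text(json.dumps(d) + "\n")


def _draw_masses(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    """Uniform masses with pairwise gaps >= MIN_MASS_GAP_PPM (rejection resampling)."""
    masses = np.sort(rng.uniform(lo, hi, size=n))
    for _ in range(1000):
        rel_gap = np.diff(masses) / masses[:-1] * 1e6
        bad = np.where(rel_gap < MIN_MASS_GAP_PPM)[0]
        if bad.size == 0:
            return masses
        masses[bad + 1] = rng.uniform(lo, hi, size=bad.size)
        masses = np.sort(masses)
    raise ConfigError("cannot place peptide masses with the required separation; "
                      "reduce n_peptides or widen mass_range")


def _drift_fn(model: str, params: tuple[float, float, float], mid: float):
    a, b, c = params
    if model == "none":
        return lambda t: t
    if model == "affine":
        return lambda t: a + (1.0 + b) * t
    return lambda t: a + (1.0 + b) * t + c * (t - mid) ** 2


@dataclass
class Catalogue:
    """The fixed peptide universe of a study: shared across its cohorts."""

    true_mass: np.ndarray
    true_ce_time: np.ndarray
    peptide_log_mean: np.ndarray
    amp_sd: np.ndarray
    base_detection_prob: np.ndarray
    log_fold_change: np.ndarray      # case-vs-control shift per peptide
    detection_shift: np.ndarray
    housekeeping_ids: list[int]
    reference_ids: list[int]
    marker_ids: list[int]


def build_catalogue(spec: CohortSpec) -> Catalogue:
    """Draw the peptide universe (masses, times, baselines, planted effects).

    Uses an RNG stream separate from sample generation, so a discovery and a
    validation cohort with different sample seeds can share one catalogue.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 17])
    n_pep = spec.n_peptides
    hk_ids = list(range(spec.n_housekeeping))
    ref_ids = list(range(spec.n_housekeeping, spec.n_housekeeping + spec.n_reference))

    true_mass = _draw_masses(rng, n_pep, *spec.mass_range)
    true_ce = rng.uniform(*spec.ce_range, size=n_pep)
    log_mean = spec.log_amplitude_mean + spec.between_peptide_sd * rng.standard_normal(n_pep)

    lfc = np.zeros(n_pep)
    dshift = np.zeros(n_pep)
    for mk in spec.marker_spec:
        lfc[mk.peptide_index] = mk.log_fold_change
        dshift[mk.peptide_index] = mk.detection_shift

    amp_sd = np.full(n_pep, spec.log_amplitude_sd)
    amp_sd[hk_ids] = spec.housekeeping_sd

    base_p = np.full(n_pep, spec.detection_prob_base)
    base_p[hk_ids] = 1.0
    base_p[ref_ids] = np.maximum(base_p[ref_ids], spec.reference_detection_floor)

    return Catalogue(true_mass=true_mass, true_ce_time=true_ce,
                     peptide_log_mean=log_mean, amp_sd=amp_sd,
                     base_detection_prob=base_p, log_fold_change=lfc,
                     detection_shift=dshift, housekeeping_ids=hk_ids,
                     reference_ids=ref_ids,
                     marker_ids=[mk.peptide_index for mk in spec.marker_spec])


def generate_cohort(spec: CohortSpec, catalogue: Catalogue | None = None,
                    id_prefix: str = "") -> tuple[list[PeakList], GroundTruth]:
    """Generate one cohort of peak lists plus its ground truth.

    Fully deterministic given ``spec.seed``: running twice yields
    byte-identical peak lists.  Pass an explicit ``catalogue`` (e.g. the
    discovery cohort's) to sample a second cohort from the same peptide
    universe.
    """
    spec.validate()
    cat = catalogue or build_catalogue(spec)
    rng = np.random.default_rng([spec.seed, 23])
    n_pep = cat.true_mass.size
    hk_ids = cat.housekeeping_ids
    true_mass, true_ce = cat.true_mass, cat.true_ce_time
    log_mean, amp_sd = cat.peptide_log_mean, cat.amp_sd
    base_p, lfc, dshift = cat.base_detection_prob, cat.log_fold_change, cat.detection_shift

    ce_mid = 0.5 * (spec.ce_range[0] + spec.ce_range[1])
    samples: list[PeakList] = []
    dilution: dict[str, float] = {}
    drift_params: dict[str, tuple[float, float, float]] = {}

    groups: list[tuple[str, Group, int]] = [("case", "case", spec.n_case),
                                            ("control", "control", spec.n_control)]
    for prefix, group, count in groups:
        is_case = group == "case"
        for k in range(count):
            sid = f"{id_prefix}{prefix}_{k + 1:03d}"
            dil = float(np.exp(spec.dilution_sd * rng.standard_normal()))
            dp: tuple[float, float, float] = (0.0, 0.0, 0.0)
            if spec.ce_drift_model != "none":
                dp = (float(spec.ce_drift_shift_sd * rng.standard_normal()),
                      float(spec.ce_drift_scale_sd * rng.standard_normal()),
                      float(spec.ce_drift_curvature_sd * rng.standard_normal())
                      if spec.ce_drift_model == "smooth" else 0.0)
            drift = _drift_fn(spec.ce_drift_model, dp, ce_mid)

            p = np.clip(base_p + (dshift if is_case else 0.0), 0.0, 1.0)
            p[hk_ids] = 1.0
            detected = rng.random(n_pep) < p
            log_amp = (log_mean + (lfc if is_case else 0.0)
                       + amp_sd * rng.standard_normal(n_pep))
            amp = np.exp(log_amp) * dil
            obs_mass = true_mass * (1.0 + spec.mass_noise_ppm * 1e-6
                                    * rng.standard_normal(n_pep))
            obs_ce = drift(true_ce) + spec.ce_noise_min * rng.standard_normal(n_pep)

            idx = np.where(detected)[0]
            order = idx[np.argsort(obs_mass[idx], kind="stable")]
            peaks = np.column_stack([obs_mass[order], obs_ce[order], amp[order]])
            samples.append(PeakList(sample_id=sid, group=group, peaks=peaks))
            dilution[sid] = dil
            drift_params[sid] = dp

    truth = GroundTruth(
        marker_ids=list(cat.marker_ids),
        marker_log_fold_change={int(i): float(lfc[i]) for i in cat.marker_ids},
        marker_detection_shift={int(i): float(dshift[i]) for i in cat.marker_ids},
        true_mass=true_mass, true_ce_time=true_ce, peptide_log_mean=log_mean,
        housekeeping_ids=list(hk_ids), reference_ids=list(cat.reference_ids),
        dilution=dilution, drift_params=drift_params)
    return samples, truth


def default_marker_spec(n_housekeeping: int = 29, n_reference: int = 60,
                        n_markers: int = 10, log_fold_change: float = 1.5,
                        detection_shift: float = 0.2) -> list[MarkerEffect]:
    """The canonical planted-effect layout used across recovery tests.

    Half the markers are up-regulated in cases (positive log-fold-change and
    detection shift), half down-regulated, mirroring the mix of positive and
    negative differential excretion seen in real disease panels.  Marker
    indices start just after the housekeeping/reference block.
    """
    start = n_housekeeping + n_reference
    out = []
    for i in range(n_markers):
        sign = 1.0 if i % 2 == 0 else -1.0
        out.append(MarkerEffect(start + i, sign * log_fold_change,
                                sign * detection_shift))
    return out
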