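"""Domain types and file I/O for CE-MS peptide peak lists and peptide matrices.

A CE-MS run of one urine sample is reduced upstream (charge deconvolution,
signal-to-noise filtering) to a *peak list*: one record per detected peptide
carrying its molecular mass (Da), its capillary-electrophoresis migration
time (min) and a normalized signal amplitude.  Cross-sample clustering turns
a collection of peak lists into a samples x peptides amplitude matrix in
which an explicit 0 means "peptide not detected in this sample" — zero and
absent are the same state throughout the pipeline, because the differential
excretion statistic is defined over zero-imputed means.

All tabular formats are tab-separated text with a header row and '.' decimal
separator; the column mapping of peak-list files is configurable via
:class:`PeakListDialect`.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

Group = Literal["case", "control", "unlabeled"]

#: Duplicate-peak screen: two peaks in ONE sample closer than this in both
#: coordinates are considered an upstream deconvolution artefact.  Must be
#: tighter than the cross-sample clustering tolerances (50 ppm / 0.35 min).
DUPLICATE_PPM = 25.0
DUPLICATE_CE_MIN = 0.175

_FLOAT_FMT = "%.10g"


@dataclass
class PeakListDialect:
    """Column mapping and separators for peak-list text files."""

    sep: str = "\t"
    mass_column: str = "mass_da"
    ce_time_column: str = "ce_time_min"
    amplitude_column: str = "amplitude"
    mass_bounds: tuple[float, float] = (0.0, math.inf)


@dataclass
class PeakList:
    """One sample's deconvoluted CE-MS output.

    ``peaks`` is an (n, 3) float array with columns (mass [Da], CE migration
    time [min], amplitude [arbitrary normalized units]).
    """

    sample_id: str
    group: Group = "unlabeled"
    peaks: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.peaks = np.asarray(self.peaks, dtype=float)
        if self.peaks.size == 0:
            self.peaks = self.peaks.reshape(0, 3)
        if self.peaks.ndim != 2 or self.peaks.shape[1] != 3:
            raise ValidationError("peaks must be an (n, 3) array of (mass, ce_time, amplitude)")
        if self.group not in ("case", "control", "unlabeled"):
            raise ValidationError(f"unknown group label {self.group!r}")

    @property
    def mass(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def ce_time(self) -> np.ndarray:
        return self.peaks[:, 1]

    @property
    def amplitude(self) -> np.ndarray:
        return self.peaks[:, 2]

    def __len__(self) -> int:
        return self.peaks.shape[0]

    def validate(self, mass_bounds: tuple[float, float] = (0.0, math.inf)) -> None:
        """Check all invariants; raise :class:`ValidationError` listing offending rows (1-based)."""
        bad: dict[int, str] = {}
        m, t, a = self.mass, self.ce_time, self.amplitude
        for i in range(len(self)):
            if not (np.isfinite(m[i]) and mass_bounds[0] < m[i] < mass_bounds[1]):
                bad[i + 1] = f"mass {m[i]} outside ({mass_bounds[0]}, {mass_bounds[1]})"
            elif not (np.isfinite(t[i]) and t[i] > 0):
                bad[i + 1] = f"ce_time {t[i]} not a positive finite number"
            elif not (np.isfinite(a[i]) and a[i] >= 0):
                bad[i + 1] = f"amplitude {a[i]} negative or non-finite"
        if bad:
            detail = "; ".join(f"row {r}: {msg}" for r, msg in sorted(bad.items()))
            raise ValidationError(f"invalid peaks in sample {self.sample_id}: {detail}",
                                  rows=sorted(bad))
        # duplicate screen: same (mass, ce_time) within a tolerance tighter
        # than the clustering tolerance means the peak list is malformed
        order = np.lexsort((t, m))
        dup_rows = []
        for j in range(1, len(self)):
            i0, i1 = order[j - 1], order[j]
            if (abs(m[i1] - m[i0]) / m[i0] * 1e6 < DUPLICATE_PPM
                    and abs(t[i1] - t[i0]) < DUPLICATE_CE_MIN):
                dup_rows.append(int(max(i0, i1)) + 1)
        if dup_rows:
            raise ValidationError(
                f"duplicate (mass, ce_time) peaks in sample {self.sample_id}: rows {dup_rows}",
                rows=dup_rows)

    def replace(self, **kw) -> "PeakList":
        return dataclasses.replace(self, **kw)


def read_peaklist(path: str | Path, dialect: PeakListDialect | None = None,
                  sample_id: str | None = None, group: Group = "unlabeled") -> PeakList:
    """Read a peak-list text file into a validated :class:`PeakList`.

    Raises :class:`FormatError` if a declared column is missing and
    :class:`ValidationError` (with 1-based row numbers) if rows violate the
    peak invariants.
    """
    path = Path(path)
    d = dialect or PeakListDialect()
    try:
        df = pd.read_csv(path, sep=d.sep)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    for col in (d.mass_column, d.ce_time_column, d.amplitude_column):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r} (found {list(df.columns)})")
    peaks = df[[d.mass_column, d.ce_time_column, d.amplitude_column]].to_numpy(dtype=float)
    pl = PeakList(sample_id=sample_id or path.stem, group=group, peaks=peaks)
    pl.validate(mass_bounds=d.mass_bounds)
    return pl


def write_peaklist(pl: PeakList, path: str | Path, dialect: PeakListDialect | None = None) -> None:
    d = dialect or PeakListDialect()
    df = pd.DataFrame(pl.peaks, columns=[d.mass_column, d.ce_time_column, d.amplitude_column])
    df.to_csv(path, sep=d.sep, index=False, float_format=_FLOAT_FMT)


@dataclass
class PeptideMatrix:
    """Samples x clustered-peptides amplitude matrix; 0 means undetected.

    Peptide IDs are ascending integers assigned in consensus-mass order by
    the clustering step; consensus mass/CE-time are the cluster centroids.
    """

    peptide_ids: list[int]
    consensus_mass: np.ndarray
    consensus_ce_time: np.ndarray
    amplitudes: np.ndarray
    sample_ids: list[str]
    groups: list[Group]

    def __post_init__(self):
        self.consensus_mass = np.asarray(self.consensus_mass, dtype=float)
        self.consensus_ce_time = np.asarray(self.consensus_ce_time, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_peptides(self) -> int:
        return self.amplitudes.shape[1]

    def validate(self) -> None:
        n, p = self.amplitudes.shape
        if len(self.sample_ids) != n or len(self.groups) != n:
            raise ValidationError("sample labels do not match matrix rows")
        if len(self.peptide_ids) != p or self.consensus_mass.shape != (p,) \
                or self.consensus_ce_time.shape != (p,):
            raise ValidationError("peptide annotations do not match matrix columns")
        if np.any(self.amplitudes < 0) or not np.all(np.isfinite(self.amplitudes)):
            raise ValidationError("matrix amplitudes must be finite and >= 0")
        pairs = list(zip(self.consensus_mass, self.consensus_ce_time))
        if pairs != sorted(pairs):
            raise ValidationError("matrix columns must be ordered by (consensus mass, CE time)")

    def group_mask(self, group: Group) -> np.ndarray:
        return np.array([g == group for g in self.groups], dtype=bool)

    def column_index(self, peptide_ids: list[int]) -> np.ndarray:
        pos = {pid: j for j, pid in enumerate(self.peptide_ids)}
        missing = [pid for pid in peptide_ids if pid not in pos]
        if missing:
            raise ValidationError(f"peptide ids not in matrix: {missing}")
        return np.array([pos[pid] for pid in peptide_ids], dtype=int)


def write_matrix(matrix: PeptideMatrix, path: str | Path) -> None:
    """Write a :class:`PeptideMatrix` as TSV.

    Columns are headed ``pep<ID>|<consensus mass>|<consensus CE time>``;
    undetected entries are written as a literal ``0``, never blank.
    """
    matrix.validate()
    cols = [f"pep{pid}|{m:.6f}|{t:.4f}" for pid, m, t
            in zip(matrix.peptide_ids, matrix.consensus_mass, matrix.consensus_ce_time)]
    df = pd.DataFrame(matrix.amplitudes, columns=cols)
    df.insert(0, "sample_id", matrix.sample_ids)
    df.insert(1, "group", matrix.groups)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_matrix(path: str | Path) -> PeptideMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "sample_id" or df.columns[1] != "group":
        raise FormatError(f"{path}: expected leading sample_id and group columns")
    pep_cols = list(df.columns[2:])
    ids, masses, times = [], [], []
    for c in pep_cols:
        try:
            pid, m, t = c.split("|")
            ids.append(int(pid.removeprefix("pep")))
            masses.append(float(m))
            times.append(float(t))
        except Exception as exc:
            raise FormatError(f"{path}: malformed peptide column header {c!r}") from exc
    mat = PeptideMatrix(
        peptide_ids=ids,
        consensus_mass=np.array(masses),
        consensus_ce_time=np.array(times),
        amplitudes=df[pep_cols].to_numpy(dtype=float),
        sample_ids=[str(s) for s in df["sample_id"]],
        groups=[str(g) for g in df["group"]],  # type: ignore[arg-type]
    )
    mat.validate()
    return mat


@dataclass
class BiomarkerRecord:
    """Per-peptide discovery statistics.

    ``de`` is the signed differential-excretion ratio (|de| >= 1); it is
    +/-inf when one group's (mean x frequency) product is zero and NaN when
    both are (flagged via ``de_defined``).  ``p_raw``/``p_adjusted`` are NaN
    for peptides that fail the detection-frequency gate and were never
    tested.
    """

    peptide_id: int
    freq_case: float
    freq_control: float
    p_raw: float
    p_adjusted: float
    de: float
    gated: bool
    selected: bool
    de_defined: bool = True


def records_to_frame(records: list[BiomarkerRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


@dataclass
class PanelDefinition:
    """A named, ordered biomarker panel (list of matrix peptide IDs)."""

    name: str
    peptide_ids: list[int]
    provenance: str = ""

    def __post_init__(self):
        if not self.peptide_ids:
            raise ValidationError(f"panel {self.name!r} is empty")
        if len(set(self.peptide_ids)) != len(self.peptide_ids):
            raise ValidationError(f"panel {self.name!r} has duplicate peptide ids")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"name": self.name, "peptide_ids": self.peptide_ids,
             "provenance": self.provenance}, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PanelDefinition":
        d = json.loads(Path(path).read_text())
        return cls(name=d["name"], peptide_ids=[int(i) for i in d["peptide_ids"]],
                   provenance=d.get("provenance", ""))


@dataclass
class ReferenceTable:
    """Calibration reference peptides: known masses and canonical CE times."""

    ids: list[int]
    masses: np.ndarray
    ce_times: np.ndarray

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        self.ce_times = np.asarray(self.ce_times, dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"ref_id": self.ids, "mass_da": self.masses,
                      "ce_time_min": self.ce_times}).to_csv(
            path, sep="\t", index=False, float_format=_FLOAT_FMT)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceTable":
        df = pd.read_csv(path, sep="\t")
        return cls(list(df["ref_id"]), df["mass_da"].to_numpy(),
                   df["ce_time_min"].to_numpy())


@dataclass
class HousekeepingTable:
    """Stably excreted peptides used to normalize out urine dilution."""

    ids: list[int]
    masses: np.ndarray
    ce_times: np.ndarray
    reference_amplitudes: np.ndarray

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        self.ce_times = np.asarray(self.ce_times, dtype=float)
        self.reference_amplitudes = np.asarray(self.reference_amplitudes, dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"hk_id": self.ids, "mass_da": self.masses,
                      "ce_time_min": self.ce_times,
                      "reference_amplitude": self.reference_amplitudes}).to_csv(
            path, sep="\t", index=False, float_format=_FLOAT_FMT)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HousekeepingTable":
        df = pd.read_csv(path, sep="\t")
        return cls(list(df["hk_id"]), df["mass_da"].to_numpy(),
                   df["ce_time_min"].to_numpy(),
                   df["reference_amplitude"].to_numpy())
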