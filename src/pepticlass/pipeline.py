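"""End-to-end run orchestration: simulate -> preprocess -> discover -> train
-> classify -> evaluate.

A run is driven by a :class:`RunConfig` (loadable from YAML) and is
hermetic: every input is either generated from the configured seeds or read
from a file named in the config.  The discovery and validation cohorts are
disjoint; the classifier and its decision threshold are fixed on the
discovery cohort alone (threshold = Youden optimum over leave-one-out
held-out scores), and validation labels are used only to compute the final
report.  All artifacts land in the output directory together with a
manifest of content hashes, so a rerun with the same config is
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .discovery import DiscoveryConfig, panel_from_records, select_biomarkers
from .errors import ConfigError, PepticlassError, StageError
from .evaluation import contingency_report, youden_threshold
from .model import records_to_frame, write_matrix
from .preprocess import (MatchingConfig, calibrate_ce_time, match_peptides,
                         normalize_amplitudes)
from .simulate import (CohortSpec, MarkerEffect, build_catalogue,
                       default_marker_spec, generate_cohort)
from .svm import ClassifierConfig, grid_search, loo_cross_validate, panel_log_matrix, train

log = logging.getLogger("pepticlass")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    discovery_cohort: CohortSpec = field(default_factory=CohortSpec)
    validation_cohort: CohortSpec = field(default_factory=lambda: CohortSpec(
        n_case=40, n_control=40))
    matching: MatchingConfig = field(default_factory=MatchingConfig)
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    use_grid_search: bool = False
    loess_bandwidth: float = 0.3
    outdir: str = "run_output"
    seed: int = 0
    #: exploratory only: re-optimize the threshold on validation scores
    #: (leaks validation labels into the operating point; never the default)
    exploratory_validation_threshold: bool = False

    def __post_init__(self):
        # derive distinct cohort seeds from the global seed unless set apart
        if self.validation_cohort.seed == self.discovery_cohort.seed:
            self.validation_cohort = dataclasses.replace(
                self.validation_cohort, seed=self.discovery_cohort.seed + 10_000)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def build(klass, d):
            if d is None:
                return klass()
            if klass is CohortSpec and "marker_spec" in d:
                d = dict(d)
                ms = d["marker_spec"]
                if ms == "default":
                    d["marker_spec"] = default_marker_spec()
                else:
                    d["marker_spec"] = [MarkerEffect(**m) for m in ms]
            if klass is CohortSpec:
                for key in ("mass_range", "ce_range"):
                    if key in d:
                        d[key] = tuple(d[key])
            return klass(**d)

        try:
            return cls(
                discovery_cohort=build(CohortSpec, raw.get("discovery_cohort")),
                validation_cohort=build(CohortSpec, raw.get("validation_cohort",
                                                            {"n_case": 40, "n_control": 40})),
                matching=build(MatchingConfig, raw.get("matching")),
                discovery=build(DiscoveryConfig, raw.get("discovery")),
                classifier=build(ClassifierConfig, raw.get("classifier")),
                use_grid_search=bool(raw.get("use_grid_search", False)),
                loess_bandwidth=float(raw.get("loess_bandwidth", 0.3)),
                outdir=str(raw.get("outdir", "run_output")),
                seed=int(raw.get("seed", 0)),
                exploratory_validation_threshold=bool(
                    raw.get("exploratory_validation_threshold", False)),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad run configuration: {exc}") from exc

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _preprocess_cohort(samples, truth, cfg: RunConfig):
    ref = truth.reference_table
    hk = truth.housekeeping_table
    out = []
    qc = []
    for s in samples:
        s2, cal = calibrate_ce_time(s, ref, bandwidth=cfg.loess_bandwidth,
                                    mass_tolerance_ppm=cfg.matching.mass_tolerance_ppm)
        s3 = normalize_amplitudes(s2, hk,
                                  mass_tolerance_ppm=cfg.matching.mass_tolerance_ppm,
                                  ce_tolerance_min=cfg.matching.ce_tolerance_min)
        out.append(s3)
        qc.append({"sample_id": s.sample_id, "n_peaks": len(s),
                   "n_references_matched": cal.n_matched,
                   "max_reference_residual_min": cal.max_residual,
                   "normalization_scale": s3.metadata["normalization_scale"]})
    return out, qc


@dataclass
class RunResult:
    outdir: Path
    n_biomarkers: int
    threshold: float
    loo_sensitivity: float
    loo_specificity: float
    report: "object"
    manifest: dict


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full pipeline; artifacts are written under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage %s", name)
        return name

    # --- simulate -------------------------------------------------------
    st = stage("simulate")
    try:
        disc_spec = dataclasses.replace(config.discovery_cohort,
                                        seed=config.discovery_cohort.seed + config.seed)
        val_spec = dataclasses.replace(config.validation_cohort,
                                       seed=config.validation_cohort.seed + config.seed)
        # both cohorts draw samples from the same peptide universe
        catalogue = build_catalogue(disc_spec)
        disc_samples, disc_truth = generate_cohort(disc_spec, catalogue)
        val_samples, _val_truth = generate_cohort(val_spec, catalogue, id_prefix="val_")
        disc_ids = {s.sample_id for s in disc_samples}
        val_ids = {s.sample_id for s in val_samples}
        if disc_ids & val_ids:
            raise ConfigError(f"discovery/validation sample ids overlap: "
                              f"{sorted(disc_ids & val_ids)[:5]}")
    except ConfigError:
        raise
    except PepticlassError as exc:
        raise StageError(st, str(exc)) from exc

    # --- preprocess -----------------------------------------------------
    st = stage("preprocess")
    try:
        disc_pp, qc1 = _preprocess_cohort(disc_samples, disc_truth, config)
        val_pp, qc2 = _preprocess_cohort(val_samples, _val_truth, config)
        matrix = match_peptides(disc_pp + val_pp, config.matching)
        write_matrix(matrix, outdir / "matrix.tsv")
        (outdir / "qc.json").write_text(json.dumps(qc1 + qc2, indent=1) + "\n")
        log.info("preprocess: %d samples -> %d peptides",
                 matrix.n_samples, matrix.n_peptides)
    except PepticlassError as exc:
        raise StageError(st, str(exc)) from exc

    is_disc = np.array([sid in disc_ids for sid in matrix.sample_ids])
    disc_matrix = dataclasses.replace(
        matrix,
        amplitudes=matrix.amplitudes[is_disc],
        sample_ids=[s for s, d in zip(matrix.sample_ids, is_disc) if d],
        groups=[g for g, d in zip(matrix.groups, is_disc) if d])

    # --- discover -------------------------------------------------------
    st = stage("discover")
    try:
        records = select_biomarkers(disc_matrix, config.discovery)
        records_to_frame(records).to_csv(outdir / "biomarkers.tsv", sep="\t", index=False)
        panel = panel_from_records(records, name="synthetic_panel",
                                   provenance=f"discovery run seed={config.seed}")
        panel.to_json(outdir / "panel.json")
        log.info("discover: %d peptides -> %d selected biomarkers",
                 disc_matrix.n_peptides, len(panel.peptide_ids))
    except PepticlassError as exc:
        raise StageError(st, str(exc)) from exc

    # --- train ----------------------------------------------------------
    st = stage("train")
    try:
        X_disc = panel_log_matrix(disc_matrix, panel)
        y_disc = np.array([1 if g == "case" else -1 for g in disc_matrix.groups])
        clf_cfg = config.classifier
        grid_table = None
        if config.use_grid_search:
            grid_C = clf_cfg.grid_C or [0.1, 1.0, 6.4, 12.8, 100.0]
            grid_g = clf_cfg.grid_gamma or [0.000256, 0.001024, 0.004096, 0.016384]
            clf_cfg, grid_table = grid_search(X_disc, y_disc, grid_C, grid_g,
                                              seed=config.seed)
            (outdir / "grid.json").write_text(json.dumps(grid_table, indent=1) + "\n")
        model = train(X_disc, y_disc, clf_cfg, panel=panel)
        model.to_json(outdir / "model.json")
        loo_scores, loo_sens, loo_spec = loo_cross_validate(X_disc, y_disc, clf_cfg)
        thr, j = youden_threshold(loo_scores, (y_disc > 0).astype(int))
        log.info("train: C=%g gamma=%g LOO sens=%.3f spec=%.3f threshold=%.4f",
                 clf_cfg.C, clf_cfg.gamma, loo_sens, loo_spec, thr)
    except PepticlassError as exc:
        raise StageError(st, str(exc)) from exc

    # --- classify -------------------------------------------------------
    st = stage("classify")
    try:
        val_rows = ~is_disc
        val_matrix = dataclasses.replace(
            matrix,
            amplitudes=matrix.amplitudes[val_rows],
            sample_ids=[s for s, d in zip(matrix.sample_ids, val_rows) if d],
            groups=[g for g, d in zip(matrix.groups, val_rows) if d])
        X_val = panel_log_matrix(val_matrix, panel)
        val_scores = model.scores(X_val)
        y_val = np.array([1 if g == "case" else 0 for g in val_matrix.groups])
        with open(outdir / "scores.tsv", "w") as fh:
            fh.write("sample_id\tscore\tlabel\n")
            for sid, sc, lab in zip(val_matrix.sample_ids, val_scores, y_val):
                fh.write(f"{sid}\t{sc:.10g}\t{lab}\n")
    except PepticlassError as exc:
        raise StageError(st, str(exc)) from exc

    # --- evaluate -------------------------------------------------------
    st = stage("evaluate")
    try:
        eval_thr = thr
        if config.exploratory_validation_threshold:
            eval_thr, _ = youden_threshold(val_scores, y_val)
        report = contingency_report(val_scores, y_val, eval_thr)
        report.to_json(outdir / "report.json")
        with open(outdir / "roc.tsv", "w") as fh:
            fh.write("fpr\ttpr\n")
            for fpr, tpr in report.roc:
                fh.write(f"{fpr:.10g}\t{tpr:.10g}\n")
    except PepticlassError as exc:
        raise StageError(st, str(exc)) from exc

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "outputs": {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                    for p in sorted(outdir.iterdir())
                    if p.is_file() and p.name != "manifest.json"},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return RunResult(outdir=outdir, n_biomarkers=len(panel.peptide_ids),
                     threshold=thr, loo_sensitivity=loo_sens,
                     loo_specificity=loo_spec, report=report, manifest=manifest)
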