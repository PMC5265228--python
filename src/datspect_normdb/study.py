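"""End-to-end synthetic study: simulate, quantify, calibrate, threshold, evaluate.

``run_study`` executes the full grid — for every reconstruction mode,
quantifier, calibration strategy and classification rule: phantom-based
scanner characterisation, a healthy normal-database cohort, an age-dependent
normal range, classification of a mixed follow-up cohort, and diagnostic
performance (confusion counts, sensitivity/specificity, ROC AUC).

Everything is driven by a single :class:`StudyConfig` and a single seed;
repeated runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .calibrate import CalibrationSet, fit_calibration, pool_calibrated
from .errors import ConfigError
from .evaluate import ConfusionTable, RocResult, confusion, roc_auc, scan_score, \
    sensitivity, specificity
from .normdb import NormalRangeModel, ScanVerdict, classify_region, classify_scan, \
    fit_normal_range
from .quantify import SBRRecord, build_large_voi_set, build_small_voi_set, \
    large_voi_sbr, small_voi_sbr
from .synthdata import CohortParams, ReconstructionModel, StriatalGeometry, \
    SubjectSpec, PhantomSpec, default_geometry, generate_cohort, render_phantom, \
    render_subject, uniform_true_sbr

log = logging.getLogger(__name__)

QUANTIFIER_RULES: dict[str, tuple[str, ...]] = {
    "small_voi": ("striatum_either_side", "putamen_either_side"),
    "large_voi": ("southampton_striatal",),
}

QUANTIFIER_STRUCTURES: dict[str, tuple[str, ...]] = {
    "small_voi": ("caudate", "putamen", "striatum"),
    "large_voi": ("striatum",),
}


@dataclass(frozen=True)
class ScannerParams:
    """Per-scanner deviations from the nominal reconstruction model."""

    fwhm_offset_mm: float = 0.0
    scatter_scale: float = 1.0


@dataclass
class StudyConfig:
    grid_shape: tuple[int, int, int] = (64, 72, 64)
    voxel_size_mm: float = 3.0
    modes: tuple[str, ...] = ("ACSC", "IRNC", "FBP")
    quantifiers: tuple[str, ...] = ("small_voi", "large_voi")
    scanners: Mapping[str, ScannerParams] = field(
        default_factory=lambda: {
            "scanner-1": ScannerParams(-0.75, 0.93),
            "scanner-2": ScannerParams(0.0, 1.0),
            "scanner-3": ScannerParams(0.75, 1.07),
        }
    )
    phantom_true_sbrs: tuple[float, ...] = (1.0, 2.5, 4.0, 5.5, 7.0)
    phantom_repeats: int = 2
    background_concentration: float = 80.0
    n_normal_db: int = 120
    n_followup_normal: int = 34
    n_followup_abnormal: int = 43
    age_range: tuple[float, float] = (20.0, 83.0)
    healthy_intercept: float = 8.5
    healthy_slope: float = -0.04
    between_subject_sd: float = 0.40
    putamen_loss_range: tuple[float, float] = (0.40, 0.90)
    caudate_loss_range: tuple[float, float] = (0.70, 1.00)
    asymmetry_range: tuple[float, float] = (0.00, 0.30)
    erosion_voxels: int = 1
    large_margin_mm: float = 14.0
    edge_margin_mm: float = 12.0
    bound_multiplier: float = 2.0
    prediction_interval: bool = True
    seed: int = 20170124

    def __post_init__(self) -> None:
        unknown = set(self.modes) - {"ACSC", "IRNC", "FBP"}
        if unknown:
            raise ConfigError(f"unknown reconstruction modes: {sorted(unknown)}")
        unknown = set(self.quantifiers) - set(QUANTIFIER_RULES)
        if unknown:
            raise ConfigError(f"unknown quantifiers: {sorted(unknown)}")
        if not self.scanners:
            raise ConfigError("at least one scanner is required")
        if len(self.phantom_true_sbrs) < 2:
            raise ConfigError("at least two phantom true SBRs are required")

    @classmethod
    def from_dict(cls, payload: Mapping) -> "StudyConfig":
        payload = dict(payload)
        if "scanners" in payload:
            payload["scanners"] = {
                name: ScannerParams(**params)
                for name, params in payload["scanners"].items()
            }
        for key in ("grid_shape", "modes", "quantifiers", "phantom_true_sbrs",
                    "age_range", "putamen_loss_range", "caudate_loss_range",
                    "asymmetry_range"):
            if key in payload:
                payload[key] = tuple(payload[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        try:
            payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: malformed YAML: {exc}") from exc
        if not isinstance(payload, Mapping):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(payload)


@dataclass(frozen=True)
class CellResult:
    """Diagnostic performance of one strategy cell."""

    quantifier: str
    rule: str
    mode: str
    calibrated: bool
    roc: RocResult
    table: ConfusionTable
    sensitivity: float
    specificity: float
    verdicts: tuple[ScanVerdict, ...]

    @property
    def cell_id(self) -> str:
        cal = "cal" if self.calibrated else "raw"
        return f"{self.quantifier}/{self.rule}/{self.mode}/{cal}"


@dataclass
class StudyReport:
    config: StudyConfig
    cells: dict[tuple[str, str, str, bool], CellResult]
    truth: dict[str, bool]
    normal_models: list[NormalRangeModel]
    calibration: CalibrationSet

    def cell(self, quantifier: str, rule: str, mode: str, calibrated: bool) -> CellResult:
        return self.cells[quantifier, rule, mode, calibrated]

    def performance_frame(self) -> pd.DataFrame:
        rows = []
        for cell in self.cells.values():
            rows.append(
                dict(
                    quantifier=cell.quantifier,
                    rule=cell.rule,
                    mode=cell.mode,
                    calibrated=cell.calibrated,
                    auc=cell.roc.auc,
                    auc_ci_low=cell.roc.ci_low,
                    auc_ci_high=cell.roc.ci_high,
                    sensitivity=cell.sensitivity,
                    specificity=cell.specificity,
                    tp=cell.table.tp,
                    fp=cell.table.fp,
                    tn=cell.table.tn,
                    fn=cell.table.fn,
                )
            )
        return pd.DataFrame(rows).sort_values(
            ["quantifier", "rule", "calibrated", "mode"], ignore_index=True
        )

    def discordance_frame(self) -> pd.DataFrame:
        """Per-subject verdict matrix across all cells (1 = abnormal)."""
        columns: dict[str, dict[str, int]] = {}
        for cell in self.cells.values():
            columns[cell.cell_id] = {
                v.subject_id: int(v.scan_abnormal) for v in cell.verdicts
            }
        frame = pd.DataFrame(columns)
        frame.insert(0, "truth_abnormal", pd.Series(self.truth).astype(int))
        frame.index.name = "subject_id"
        return frame.sort_index()


def _scanner_recon(mode: str, params: ScannerParams) -> ReconstructionModel:
    base = ReconstructionModel.preset(mode)
    fwhm = max(base.psf_fwhm + params.fwhm_offset_mm, 0.0)
    scatter = base.scatter_fraction * params.scatter_scale if base.scatter_fraction else 0.0
    return ReconstructionModel.preset(
        mode, psf_fwhm=fwhm, scatter_fraction=scatter
    )


def _subject_seed(base_seed: int, tag: str) -> int:
    entropy = [base_seed] + [ord(ch) for ch in tag]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0])


def _quantify_subject(
    volume, spec: SubjectSpec, mode: str, quantifiers: Sequence[str],
    vois_small, vois_large, nominal_ml: Mapping[str, float],
) -> list[SBRRecord]:
    meta = dict(subject_id=spec.subject_id, age=spec.age,
                scanner_id=spec.scanner_id, mode=mode)
    records: list[SBRRecord] = []
    if "small_voi" in quantifiers:
        records.extend(small_voi_sbr(volume, vois_small, meta=meta))
    if "large_voi" in quantifiers:
        records.extend(large_voi_sbr(volume, vois_large, nominal_ml, meta=meta))
    return records


def _fit_calibration_set(
    config: StudyConfig, geometry: StriatalGeometry,
    vois_small, vois_large, nominal_ml: Mapping[str, float],
) -> CalibrationSet:
    lines = CalibrationSet()
    for scanner_id, params in config.scanners.items():
        for mode in config.modes:
            recon = _scanner_recon(mode, params)
            measured: dict[tuple[str, str], list[float]] = {}
            truths: dict[tuple[str, str], list[float]] = {}
            for true_sbr in config.phantom_true_sbrs:
                spec = PhantomSpec(
                    true_sbr=uniform_true_sbr(true_sbr),
                    background_concentration=config.background_concentration,
                    geometry=geometry,
                )
                for repeat in range(config.phantom_repeats):
                    seed = _subject_seed(
                        config.seed, f"phantom/{scanner_id}/{mode}/{true_sbr}/{repeat}"
                    )
                    volume = render_phantom(spec, recon, seed)
                    records: list[SBRRecord] = []
                    if "small_voi" in config.quantifiers:
                        records.extend(small_voi_sbr(volume, vois_small))
                    if "large_voi" in config.quantifiers:
                        records.extend(large_voi_sbr(volume, vois_large, nominal_ml))
                    for record in records:
                        key = (record.quantifier, record.structure)
                        measured.setdefault(key, []).append(record.measured_sbr)
                        truths.setdefault(key, []).append(true_sbr)
            for (quantifier, structure), values in measured.items():
                lines.add(
                    fit_calibration(
                        values, truths[quantifier, structure],
                        scanner_id=scanner_id, mode=mode,
                        quantifier=quantifier, structure=structure,
                    )
                )
    return lines


def run_study(config: StudyConfig, outdir: str | Path | None = None) -> StudyReport:
    """Execute the full study grid; optionally write report files to outdir."""
    geometry = default_geometry(config.grid_shape, config.voxel_size_mm)
    vois_small = build_small_voi_set(geometry, erosion_voxels=config.erosion_voxels)
    vois_large = build_large_voi_set(
        geometry, margin_mm=config.large_margin_mm, edge_margin_mm=config.edge_margin_mm
    )
    nominal_ml = {side: geometry.structure_volume_ml(side, "striatum")
                  for side in ("left", "right")}

    scanner_ids = tuple(config.scanners)
    cohort_common = dict(
        age_range=config.age_range,
        healthy_intercept=config.healthy_intercept,
        healthy_slope=config.healthy_slope,
        between_subject_sd=config.between_subject_sd,
        putamen_loss_range=config.putamen_loss_range,
        caudate_loss_range=config.caudate_loss_range,
        asymmetry_range=config.asymmetry_range,
        scanner_ids=scanner_ids,
    )
    normal_cohort = generate_cohort(CohortParams(
        n_normal=config.n_normal_db, n_abnormal=0,
        random_seed=config.seed + 1, **cohort_common,
    ))
    followup_cohort = generate_cohort(CohortParams(
        n_normal=config.n_followup_normal, n_abnormal=config.n_followup_abnormal,
        random_seed=config.seed + 2, **cohort_common,
    ))
    truth = {spec.subject_id: spec.disease_status == "abnormal"
             for spec in followup_cohort}

    log.info("fitting phantom calibration (%d scanners x %d modes)",
             len(config.scanners), len(config.modes))
    calibration = _fit_calibration_set(config, geometry, vois_small, vois_large,
                                       nominal_ml)

    # render and quantify each subject once per reconstruction mode
    db_records: dict[str, list[SBRRecord]] = {m: [] for m in config.modes}
    fu_records: dict[str, list[SBRRecord]] = {m: [] for m in config.modes}
    for label, cohort, bucket in (("normdb", normal_cohort, db_records),
                                  ("followup", followup_cohort, fu_records)):
        for spec in cohort:
            for mode in config.modes:
                recon = _scanner_recon(mode, config.scanners[spec.scanner_id])
                seed = _subject_seed(config.seed, f"{label}/{spec.subject_id}/{mode}")
                volume = render_subject(
                    spec, recon, geometry, seed,
                    background_concentration=config.background_concentration,
                )
                bucket[mode].extend(
                    _quantify_subject(volume, spec, mode, config.quantifiers,
                                      vois_small, vois_large, nominal_ml)
                )
        log.info("rendered and quantified %s cohort", label)

    cells: dict[tuple[str, str, str, bool], CellResult] = {}
    all_models: list[NormalRangeModel] = []
    followup_by_subject_age = {spec.subject_id: spec.age for spec in followup_cohort}

    for mode in config.modes:
        for quantifier in config.quantifiers:
            structures = QUANTIFIER_STRUCTURES[quantifier]
            db_q = [r for r in db_records[mode] if r.quantifier == quantifier]
            fu_q = [r for r in fu_records[mode] if r.quantifier == quantifier]
            for calibrated in (True, False):
                db_cal = pool_calibrated(db_q, calibration, passthrough=not calibrated)
                fu_cal = pool_calibrated(fu_q, calibration, passthrough=not calibrated)

                models: dict[tuple[str, str], NormalRangeModel] = {}
                for side in ("left", "right"):
                    for structure in structures:
                        subset = [r for r in db_cal
                                  if r.side == side and r.structure == structure]
                        models[side, structure] = fit_normal_range(
                            [r.age for r in subset],
                            [r.value for r in subset],
                            bound_multiplier=config.bound_multiplier,
                            prediction_interval=config.prediction_interval,
                            quantifier=quantifier, mode=mode,
                            calibrated=calibrated, structure=structure, side=side,
                        )
                all_models.extend(models.values())

                per_subject: dict[str, list[SBRRecord]] = {}
                for record in fu_cal:
                    per_subject.setdefault(record.subject_id, []).append(record)

                for rule in QUANTIFIER_RULES[quantifier]:
                    verdicts = []
                    scores = []
                    labels = []
                    for subject_id in sorted(per_subject):
                        records = per_subject[subject_id]
                        age = followup_by_subject_age[subject_id]
                        flags = {
                            (r.side, r.structure): classify_region(
                                r.value, models[r.side, r.structure], age
                            )
                            for r in records
                        }
                        verdicts.append(
                            classify_scan(flags, rule, subject_id=subject_id)
                        )
                        scores.append(scan_score(records, rule))
                        labels.append(truth[subject_id])
                    table = confusion(verdicts, truth)
                    cell = CellResult(
                        quantifier=quantifier, rule=rule, mode=mode,
                        calibrated=calibrated,
                        roc=roc_auc(scores, labels),
                        table=table,
                        sensitivity=sensitivity(table),
                        specificity=specificity(table),
                        verdicts=tuple(verdicts),
                    )
                    cells[quantifier, rule, mode, calibrated] = cell
                    log.info("cell %s: sens %.1f spec %.1f auc %.3f",
                             cell.cell_id, cell.sensitivity, cell.specificity,
                             cell.roc.auc)

    report = StudyReport(config=config, cells=cells, truth=truth,
                         normal_models=all_models, calibration=calibration)
    if outdir is not None:
        _write_report(report, Path(outdir), db_records, fu_records)
    return report


def _write_report(
    report: StudyReport,
    outdir: Path,
    db_records: Mapping[str, list[SBRRecord]],
    fu_records: Mapping[str, list[SBRRecord]],
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.performance_frame().to_csv(outdir / "performance.csv", index=False)
    report.discordance_frame().to_csv(outdir / "discordance.csv")
    (outdir / "calibration.json").write_text(report.calibration.to_json(),
                                             encoding="utf-8")
    models_payload = [json.loads(m.to_json()) for m in report.normal_models]
    (outdir / "normal_models.json").write_text(
        json.dumps(models_payload, indent=2), encoding="utf-8"
    )
    for mode, records in db_records.items():
        dio.save_sbr_records(records, outdir / f"normdb_sbr_{mode}.csv")
    for mode, records in fu_records.items():
        dio.save_sbr_records(records, outdir / f"followup_sbr_{mode}.csv")
    fp_fn = report.performance_frame()[
        ["quantifier", "rule", "mode", "calibrated", "fp", "fn"]
    ]
    fp_fn.to_csv(outdir / "fp_fn.csv", index=False)
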