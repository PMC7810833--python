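"""End-to-end pipeline driver.

``analyze_cohort`` runs the full analysis on in-memory subjects (QC ->
band-pass -> connectivity -> centrality -> normative fit on controls ->
abnormality detection -> statistics); ``run_pipeline`` wraps it with file
input/output and writes a manifest sufficient to re-run any subject
identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as nio
from . import stats as nstats
from .centrality import CentralityProfile, compute_profile
from .cohort import SyntheticSubject
from .connectivity import (
    Adjacency,
    SubjectExcludedError,
    ZMatrix,
    average_z,
    binarize,
    session_zmatrix,
)
from .normative import AbnormalRegions, NormativeModel, detect_abnormal, fit_normative
from .preprocess import MotionTrace, SessionSeries, bandpass, qc_session
from .records import SubjectRecord

logger = logging.getLogger("nacmap")

__version_tag__ = "nacmap-0.1.0"


@dataclass(frozen=True)
class PipelineConfig:
    cohort_dir: Optional[str] = None
    atlas_path: Optional[str] = None
    metadata_path: Optional[str] = None
    output_dir: Optional[str] = None
    tr_seconds: float = 3.0
    threshold_z: float = 1.96
    order_n: int = 20
    ess_mode: str = "lag1"
    sd_mode: str = "age_regressed"
    bin_width: float = 0.05
    match_window_years: float = 5.0
    low_hz: float = 0.01
    high_hz: float = 0.1
    seed: int = 0


@dataclass
class SubjectResult:
    record: SubjectRecord
    zmatrix: ZMatrix
    adjacency: Adjacency
    profile: CentralityProfile
    abnormal: Optional[AbnormalRegions] = None
    report: Optional[nstats.AbnormalityReport] = None
    qc_reasons: list[str] = field(default_factory=list)


@dataclass
class CohortResult:
    subjects: list[SubjectResult]
    excluded: dict[str, str]
    model: NormativeModel
    atlas: pd.DataFrame
    edges_ancova: Optional[dict]
    count_comparison: Optional[dict]
    clinical: Optional[pd.DataFrame]
    warnings: list[str] = field(default_factory=list)

    def by_group(self, group: str) -> list[SubjectResult]:
        return [s for s in self.subjects if s.record.group == group]


def process_subject(
    record: SubjectRecord,
    sessions: Sequence[SessionSeries],
    motion: Sequence[MotionTrace],
    config: PipelineConfig,
) -> SubjectResult:
    """QC, filter and reduce one subject to adjacency + centrality."""
    usable, reasons = [], []
    for series, mot in zip(sessions, motion):
        qc = qc_session(mot)
        if qc.passed:
            usable.append(series)
        else:
            reasons.append(f"{series.session_id}: {qc.reason}")
    if not usable:
        raise SubjectExcludedError(
            f"{record.subject_id}: all sessions failed motion QC ({'; '.join(reasons)})"
        )
    filtered = [bandpass(s, config.low_hz, config.high_hz) for s in usable]
    zs = [session_zmatrix(s, ess_mode=config.ess_mode) for s in filtered]
    zbar = average_z(zs)
    adj = binarize(zbar, threshold=config.threshold_z)
    profile = compute_profile(adj, order_n=config.order_n, subject_id=record.subject_id)
    return SubjectResult(
        record=record,
        zmatrix=zbar,
        adjacency=adj,
        profile=profile,
        qc_reasons=reasons,
    )


def analyze_cohort(
    subjects: Sequence[SyntheticSubject],
    atlas: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
) -> CohortResult:
    """Run the full analysis on in-memory subjects."""
    results: list[SubjectResult] = []
    excluded: dict[str, str] = {}
    warnings_log: list[str] = []
    for sub in subjects:
        try:
            res = process_subject(sub.record, sub.sessions, sub.motion, config)
        except SubjectExcludedError as exc:
            excluded[sub.record.subject_id] = str(exc)
            logger.warning("excluding subject: %s", exc)
            continue
        if res.qc_reasons:
            warnings_log.append(
                f"{sub.record.subject_id}: sessions dropped ({'; '.join(res.qc_reasons)})"
            )
        if not res.profile.is_connected:
            warnings_log.append(f"{sub.record.subject_id}: graph is disconnected")
        results.append(res)
    controls = [r for r in results if r.record.group == "control"]
    patients = [r for r in results if r.record.group == "patient"]
    if not controls:
        raise RuntimeError("normative fit impossible: no usable controls")
    model = fit_normative(
        [c.profile for c in controls],
        [c.record for c in controls],
        sd_mode=config.sd_mode,
    )
    for res in results:
        res.abnormal = detect_abnormal(res.profile, res.record, model)
        if res.abnormal.extrapolated_age:
            warnings_log.append(f"{res.record.subject_id}: age outside fitted range")

    dmn_regions = atlas.loc[atlas["is_dmn"] == 1, "region_id"].to_numpy()
    n_regions = len(atlas)
    bin_edges = nstats.default_bin_edges(config.bin_width)
    ctrl_scores0 = np.vstack([c.profile.nac0_rescaled for c in controls])
    ctrl_scores1 = np.vstack(
        [c.profile.nac1_rescaled for c in controls if c.profile.nac1 is not None]
    )
    ctrl_records = [c.record for c in controls]
    for res in results:
        p0 = p1 = None
        n_matched = None
        try:
            ref0, n_matched = nstats.matched_reference(
                ctrl_scores0, ctrl_records, res.record, bin_edges,
                window_years=config.match_window_years,
            )
            _, _, p0 = nstats.distribution_chisq(
                res.profile.nac0_rescaled, ref0, bin_edges
            )
            if res.profile.nac1 is not None and len(ctrl_scores1) == len(controls):
                ref1, _ = nstats.matched_reference(
                    ctrl_scores1, ctrl_records, res.record, bin_edges,
                    window_years=config.match_window_years,
                )
                _, _, p1 = nstats.distribution_chisq(
                    res.profile.nac1_rescaled, ref1, bin_edges
                )
        except ValueError as exc:
            warnings_log.append(f"{res.record.subject_id}: distribution test skipped ({exc})")
        res.report = nstats.subject_report(
            res.record.subject_id,
            res.adjacency,
            res.abnormal.ar0,
            res.abnormal.ar1,
            dmn_regions,
            n_regions,
            distribution_p=(p0, p1),
            n_matched_controls=n_matched,
        )

    ancova = None
    if patients:
        try:
            ancova = nstats.edges_ancova(
                [r.adjacency.n_edges for r in results],
                [r.record.group for r in results],
                [r.record.age for r in results],
            )
        except ValueError as exc:
            warnings_log.append(f"edge-count ancova skipped ({exc})")
    counts = None
    if patients:
        counts = nstats.count_comparison(
            [r.abnormal.n_ar0 for r in patients],
            [r.abnormal.n_ar0 for r in controls],
        )
    clinical = None
    if patients:
        pdf = pd.DataFrame(
            {
                "n_ar0": [r.abnormal.n_ar0 for r in patients],
                "n_ar1": [r.abnormal.n_ar1 for r in patients],
                "connection_percentage": [
                    r.report.connection_percentage for r in patients
                ],
                "duration_years": [r.record.duration_years for r in patients],
                "n_aeds": [r.record.n_aeds for r in patients],
                "qolie31": [r.record.qolie31 for r in patients],
                "lsss": [r.record.lsss for r in patients],
                "age": [r.record.age for r in patients],
            }
        )
        clinical = nstats.clinical_correlations(pdf)
    return CohortResult(
        subjects=results,
        excluded=excluded,
        model=model,
        atlas=atlas,
        edges_ancova=ancova,
        count_comparison=counts,
        clinical=clinical,
        warnings=warnings_log,
    )


def _subject_report_dict(res: SubjectResult) -> dict:
    rep = res.report
    return {
        "subject_id": res.record.subject_id,
        "group": res.record.group,
        "age": res.record.age,
        "sex": res.record.sex,
        "n_sessions_used": res.zmatrix.n_sessions_used,
        "qc_dropped": res.qc_reasons,
        "n_edges": res.adjacency.n_edges,
        "lambda_max": res.profile.lambda_max,
        "is_connected": res.profile.is_connected,
        "ar0": sorted(res.abnormal.ar0),
        "ar1": sorted(res.abnormal.ar1),
        "n_ar0": rep.n_ar0,
        "n_ar1": rep.n_ar1,
        "connection_percentage": rep.connection_percentage,
        "kappa": rep.kappa,
        "dmn_ar0": rep.dmn_ar0,
        "dmn_ar1": rep.dmn_ar1,
        "distribution_p_nac0": rep.distribution_p_nac0,
        "distribution_p_nac1": rep.distribution_p_nac1,
        "n_matched_controls": rep.n_matched_controls,
        "flags": rep.flags,
    }


def cohort_report_dict(result: CohortResult, config: PipelineConfig) -> dict:
    """Assemble the machine-readable cohort report."""
    n_tests = sum(
        1
        for r in result.subjects
        for p in (r.report.distribution_p_nac0, r.report.distribution_p_nac1)
        if p is not None
    )
    if result.clinical is not None:
        n_tests += int(result.clinical["p"].notna().sum())
    return {
        "config": asdict(config),
        "version": __version_tag__,
        "modes": {
            "ess_mode": config.ess_mode,
            "sd_mode": config.sd_mode,
            "motion_reference": "first_volume",
            "score_reduction": "row_sum",
            "histogram_scale": "max_rescaled",
        },
        "subjects": [_subject_report_dict(r) for r in result.subjects],
        "excluded": result.excluded,
        "edges_ancova": result.edges_ancova,
        "ar0_count_comparison": result.count_comparison,
        "clinical_correlations": (
            result.clinical.to_dict(orient="records")
            if result.clinical is not None
            else None
        ),
        "warnings": result.warnings,
        "n_unadjusted_tests": n_tests,
    }


def run_pipeline(config: PipelineConfig) -> CohortResult:
    """File-based pipeline: read cohort, analyze, write all outputs."""
    if not (config.cohort_dir and config.atlas_path and config.metadata_path):
        raise ValueError("cohort_dir, atlas_path and metadata_path are required")
    cohort_dir = Path(config.cohort_dir)
    atlas = nio.read_atlas(Path(config.atlas_path))
    metadata = nio.read_metadata(Path(config.metadata_path))
    records = nio.records_from_metadata(metadata)
    subjects = []
    excluded: dict[str, str] = {}
    for rec in records:
        try:
            sessions, motion = nio.read_cohort_subject(
                cohort_dir, rec.subject_id, config.tr_seconds
            )
        except nio.ParseError as exc:
            excluded[rec.subject_id] = f"unreadable: {exc}"
            logger.warning("excluding %s: %s", rec.subject_id, exc)
            continue
        subjects.append(SyntheticSubject(record=rec, sessions=sessions, motion=motion))
    result = analyze_cohort(subjects, atlas, config)
    result.excluded.update(excluded)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "subjects").mkdir(exist_ok=True)
        for res in result.subjects:
            sdir = out / "subjects" / res.record.subject_id
            sdir.mkdir(exist_ok=True)
            nio.write_zmatrix(sdir / "zmatrix.tsv", res.zmatrix)
            nio.write_adjacency_mm(sdir / "adjacency.mtx", res.adjacency)
            prof = pd.DataFrame(
                {
                    "region_id": np.arange(res.profile.n_regions),
                    "nac0": res.profile.nac0,
                    "nac1": (
                        res.profile.nac1
                        if res.profile.nac1 is not None
                        else np.full(res.profile.n_regions, np.nan)
                    ),
                    "nac0_rescaled": res.profile.nac0_rescaled,
                    "nac1_rescaled": (
                        res.profile.nac1_rescaled
                        if res.profile.nac1 is not None
                        else np.full(res.profile.n_regions, np.nan)
                    ),
                }
            )
            prof.to_csv(sdir / "centrality.tsv", sep="\t", index=False, float_format="%.17g")
        nio.write_model_tsv(out / "normative_model.tsv", result.model.to_frame())
        nio.write_report_json(out / "cohort_report.json", cohort_report_dict(result, config))
        nio.write_report_json(
            out / "manifest.json",
            {
                "version": __version_tag__,
                "config": asdict(config),
                "n_subjects": len(result.subjects),
                "excluded": result.excluded,
            },
        )
    return result
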