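"""Readers and writers for the on-disk interchange formats.

Conventions: region ids are 0-based everywhere; the atlas row order is the
canonical region order and every reader asserts it.  Time series are one
TSV per session (rows = time points, columns = regions, header row of
region ids); motion files follow the whitespace-delimited rp_*.txt
convention (3 translations in mm, then 3 rotations in rad, one row per
volume).  Matrices round-trip through TSV at 1e-12 precision; binary
adjacencies can also round-trip through Matrix Market.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .cohort import SyntheticSubject
from .connectivity import Adjacency, ZMatrix
from .preprocess import MotionTrace, SessionSeries
from .records import SubjectRecord


class ParseError(ValueError):
    """A file failed validation; the message names the file."""


# ---------------------------------------------------------------------------
# session time series


def write_session_tsv(path: Path, series: SessionSeries) -> None:
    df = pd.DataFrame(series.data.T, columns=[str(i) for i in range(series.n_regions)])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_session_tsv(
    path: Path, tr_seconds: float, subject_id: str = "", session_id: str = ""
) -> SessionSeries:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    expected = [str(i) for i in range(df.shape[1])]
    if list(df.columns) != expected:
        raise ParseError(
            f"{path}: header must be consecutive 0-based region ids, got "
            f"{list(df.columns)[:5]}..."
        )
    data = df.to_numpy(dtype=float).T
    if not np.isfinite(data).all():
        bad = np.argwhere(~np.isfinite(data.T))
        raise ParseError(f"{path}: non-finite value at line {bad[0][0] + 2}")
    return SessionSeries(
        data=data, tr_seconds=tr_seconds, subject_id=subject_id, session_id=session_id
    )


# ---------------------------------------------------------------------------
# motion


def write_motion(path: Path, motion: MotionTrace) -> None:
    np.savetxt(path, np.hstack([motion.translations, motion.rotations]), fmt="%.10g")


def read_motion(path: Path) -> MotionTrace:
    path = Path(path)
    try:
        arr = np.loadtxt(path, ndmin=2)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if arr.shape[1] != 6:
        raise ParseError(f"{path}: expected 6 columns, got {arr.shape[1]}")
    return MotionTrace(translations=arr[:, :3], rotations=arr[:, 3:])


# ---------------------------------------------------------------------------
# metadata / atlas


def write_metadata(path: Path, metadata: pd.DataFrame) -> None:
    metadata.to_csv(path, index=False, float_format="%.10g")


def read_metadata(path: Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"id", "age", "sex", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    for col in ("duration_years", "n_aeds", "qolie31", "lsss"):
        if col not in df.columns:
            df[col] = np.nan
    return df


def records_from_metadata(df: pd.DataFrame) -> list[SubjectRecord]:
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SubjectRecord(
                subject_id=str(row.id),
                age=float(row.age),
                sex=str(row.sex),
                group=str(row.group),
                duration_years=None if pd.isna(row.duration_years) else float(row.duration_years),
                n_aeds=None if pd.isna(row.n_aeds) else int(row.n_aeds),
                qolie31=None if pd.isna(row.qolie31) else float(row.qolie31),
                lsss=None if pd.isna(row.lsss) else float(row.lsss),
            )
        )
    return records


def write_atlas(path: Path, atlas: pd.DataFrame) -> None:
    atlas.to_csv(path, sep="\t", index=False)


def read_atlas(path: Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"region_id", "name", "is_dmn"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: atlas needs columns {sorted(required)}")
    ids = df["region_id"].to_numpy()
    if not np.array_equal(ids, np.arange(len(df))):
        raise ParseError(
            f"{path}: atlas rows must be the canonical 0-based region order"
        )
    if not df["is_dmn"].isin((0, 1)).all():
        raise ParseError(f"{path}: is_dmn must be 0/1")
    return df


# ---------------------------------------------------------------------------
# matrices


def write_matrix_tsv(path: Path, matrix: np.ndarray) -> None:
    n = matrix.shape[0]
    df = pd.DataFrame(matrix, columns=[str(i) for i in range(n)])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_matrix_tsv(path: Path) -> np.ndarray:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    expected = [str(i) for i in range(df.shape[1])]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: header must be consecutive 0-based region ids")
    m = df.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ParseError(f"{path}: matrix is not square ({m.shape})")
    return m


def write_zmatrix(path: Path, z: ZMatrix) -> None:
    write_matrix_tsv(path, z.z)


def read_zmatrix(path: Path, n_sessions_used: int = 1, subject_id: str = "") -> ZMatrix:
    return ZMatrix(
        z=read_matrix_tsv(path), n_sessions_used=n_sessions_used, subject_id=subject_id
    )


def write_adjacency_mm(path: Path, a: Adjacency) -> None:
    spio.mmwrite(str(path), sparse.coo_matrix(a.a))


def read_adjacency_mm(path: Path, subject_id: str = "") -> Adjacency:
    m = spio.mmread(str(path)).toarray().astype(np.int8)
    return Adjacency(a=m, subject_id=subject_id)


# ---------------------------------------------------------------------------
# normative model / reports


def write_model_tsv(path: Path, model_frame: pd.DataFrame) -> None:
    model_frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_model_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return [_jsonify(v) for v in sorted(obj)]
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report_json(path: Path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonify(report), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_report_json(path: Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# cohort layout


def session_path(cohort_dir: Path, subject_id: str, session_id: str) -> Path:
    return Path(cohort_dir) / subject_id / f"{session_id}_series.tsv"


def motion_path(cohort_dir: Path, subject_id: str, session_id: str) -> Path:
    return Path(cohort_dir) / subject_id / f"rp_{session_id}.txt"


def write_cohort(
    cohort_dir: Path,
    subjects: Sequence[SyntheticSubject],
    metadata: pd.DataFrame,
    atlas: pd.DataFrame,
) -> None:
    cohort_dir = Path(cohort_dir)
    cohort_dir.mkdir(parents=True, exist_ok=True)
    write_metadata(cohort_dir / "metadata.csv", metadata)
    write_atlas(cohort_dir / "atlas.tsv", atlas)
    hubs = {
        s.record.subject_id: sorted(s.ground_truth_hubs)
        for s in subjects
        if s.ground_truth_hubs
    }
    write_report_json(cohort_dir / "ground_truth_hubs.json", hubs)
    for sub in subjects:
        sdir = cohort_dir / sub.record.subject_id
        sdir.mkdir(exist_ok=True)
        for series, motion in zip(sub.sessions, sub.motion):
            write_session_tsv(session_path(cohort_dir, sub.record.subject_id, series.session_id), series)
            write_motion(motion_path(cohort_dir, sub.record.subject_id, series.session_id), motion)


def read_cohort_subject(
    cohort_dir: Path, subject_id: str, tr_seconds: float
) -> tuple[list[SessionSeries], list[MotionTrace]]:
    sdir = Path(cohort_dir) / subject_id
    series_files = sorted(sdir.glob("*_series.tsv"))
    if not series_files:
        raise ParseError(f"{sdir}: no session series found")
    sessions, motions = [], []
    n_regions = None
    first_file = None
    for f in series_files:
        session_id = f.name.replace("_series.tsv", "")
        s = read_session_tsv(f, tr_seconds, subject_id=subject_id, session_id=session_id)
        if n_regions is None:
            n_regions, first_file = s.n_regions, f
        elif s.n_regions != n_regions:
            raise ParseError(
                f"region-id mismatch between {first_file} ({n_regions} regions) "
                f"and {f} ({s.n_regions} regions)"
            )
        sessions.append(s)
        mfile = motion_path(cohort_dir, subject_id, session_id)
        if not mfile.exists():
            raise ParseError(f"{mfile}: missing motion file for {f}")
        motions.append(read_motion(mfile))
    return sessions, motions
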