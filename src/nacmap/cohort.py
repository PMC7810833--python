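"""Synthetic rs-fMRI cohort generator.

Real patient/control BOLD data are not distributable, so the generator
emulates the statistical structure the downstream analysis assumes:

* a control cohort spanning ages 18-84 for both sexes,
* community-structured latent correlations with a smooth age trend and a
  small sex offset on within-community coupling,
* per-subject regional heterogeneity of within-community coupling (the
  dominant source of between-subject variability in region scores),
* AR(1) temporal autocorrelation with covariance-structured innovations,
* patient subjects with injected high-centrality (hub) regions whose
  latent correlation to all other regions is boosted,
* realignment-parameter motion traces, with an optional injected
  threshold-violating session for QC tests.

All randomness flows from a single seed; regenerating a cohort with the
same configuration is bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import MotionTrace, SessionSeries
from .records import SubjectRecord


@dataclass(frozen=True)
class HubInjection:
    """Patient abnormality model: ``n_hubs`` regions get ``hub_corr_boost``
    added to their latent correlation with every other region."""

    n_hubs: int = 5
    hub_corr_boost: float = 0.3


@dataclass(frozen=True)
class CohortConfig:
    n_controls: int = 300
    n_patients: int = 10
    n_regions: int = 388
    n_dmn: int = 100
    n_sessions: int = 3
    n_volumes: int = 101
    tr_seconds: float = 3.0
    age_range: tuple[float, float] = (18.0, 84.0)
    sex_ratio: float = 0.62  # fraction female
    ar1_coeff: float = 0.3
    n_communities: int = 6
    base_within_corr: float = 0.30
    base_between_corr: float = 0.05
    age_slope: float = -0.001  # per-year change of within-community corr
    sex_shift: float = 0.02  # within-community corr offset for females
    region_strength_sd: float = 0.06  # per-subject regional coupling SD
    hub_injection: HubInjection = field(default_factory=HubInjection)
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.ar1_coeff < 1):
            raise ValueError("ar1_coeff must lie in [0, 1)")
        if self.n_dmn > self.n_regions:
            raise ValueError("n_dmn cannot exceed n_regions")
        if not (0 <= self.base_between_corr and 0 <= self.base_within_corr):
            raise ValueError("base correlations must be non-negative")
        half_span = (self.age_range[1] - self.age_range[0]) / 2.0
        peak = (
            self.base_within_corr
            + abs(self.age_slope) * half_span
            + self.sex_shift
            + self.hub_injection.hub_corr_boost
        )
        if peak > 0.95:
            raise ValueError(
                "base_within_corr + age/sex effects + hub boost may exceed 0.95; "
                "latent covariance would lose positive definiteness"
            )
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("sex_ratio must lie in [0, 1]")

    @property
    def age_midpoint(self) -> float:
        return (self.age_range[0] + self.age_range[1]) / 2.0

    def communities(self) -> np.ndarray:
        """Contiguous community label per region."""
        return np.arange(self.n_regions) * self.n_communities // self.n_regions


@dataclass
class SyntheticSubject:
    record: SubjectRecord
    sessions: list[SessionSeries]
    motion: list[MotionTrace]
    ground_truth_hubs: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.ground_truth_hubs and self.record.group != "patient":
            raise ValueError("only patients carry ground-truth hubs")


def nearest_positive_definite(m: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues, re-symmetrize, restore unit diagonal."""
    w, v = np.linalg.eigh((m + m.T) / 2.0)
    if w[0] > 0:
        return m
    w = np.clip(w, eig_floor, None)
    repaired = (v * w) @ v.T
    repaired = (repaired + repaired.T) / 2.0
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def build_latent_covariance(
    config: CohortConfig,
    age: float,
    hubs: Sequence[int] = (),
    sex: str = "M",
    region_effects: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Latent region x region correlation matrix for one subject.

    Within-community entries sit at ``base_within_corr`` plus the age
    trend, the female offset, and (when given) additive per-region
    coupling effects; between-community entries sit at
    ``base_between_corr``.  Hub rows/columns get ``hub_corr_boost`` added,
    everything is clipped to [0, 0.95], and the result is repaired to the
    nearest positive-definite correlation matrix if needed.
    """
    config.validate()
    r = config.n_regions
    hubs = list(hubs)
    if hubs and (min(hubs) < 0 or max(hubs) >= r):
        raise ValueError("hub ids must be valid region ids")
    comm = config.communities()
    same = comm[:, None] == comm[None, :]
    within = (
        config.base_within_corr
        + config.age_slope * (age - config.age_midpoint)
        + (config.sex_shift if sex == "F" else 0.0)
    )
    if region_effects is not None:
        u = np.asarray(region_effects, dtype=float)
        if u.shape != (r,):
            raise ValueError("region_effects must have one entry per region")
        w_mat = within + u[:, None] + u[None, :]
    else:
        w_mat = np.full((r, r), within)
    m = np.where(same, w_mat, config.base_between_corr)
    if hubs:
        mask = np.zeros(r, dtype=bool)
        mask[hubs] = True
        m = m + config.hub_injection.hub_corr_boost * (mask[:, None] | mask[None, :])
    m = np.clip(m, 0.0, 0.95)
    np.fill_diagonal(m, 1.0)
    m = nearest_positive_definite(m)
    w_min = float(np.linalg.eigvalsh(m)[0])
    if w_min <= 0:
        raise ValueError(
            "latent covariance is not positive definite after repair "
            f"(min eigenvalue {w_min:.3g}; within={within:.3g}, "
            f"between={config.base_between_corr}, boost="
            f"{config.hub_injection.hub_corr_boost})"
        )
    return m


def _simulate_motion(
    rng: np.random.Generator, n_volumes: int, violate: bool
) -> MotionTrace:
    trans = np.cumsum(rng.normal(0.0, 0.04, size=(n_volumes, 3)), axis=0)
    rot = np.cumsum(rng.normal(0.0, 0.0004, size=(n_volumes, 3)), axis=0)
    trans -= trans[0]
    rot -= rot[0]
    if violate:
        trans[n_volumes // 2 :, 0] += 2.5  # trips the 2 mm translation limit
    return MotionTrace(translations=trans, rotations=rot)


def simulate_subject(
    config: CohortConfig,
    record: SubjectRecord,
    hubs: Sequence[int] = (),
    seed: int = 0,
    violate_session: Optional[int] = None,
    n_volumes: Optional[int] = None,
) -> SyntheticSubject:
    """Simulate all sessions and motion traces for one subject.

    Each session is an AR(1) process x_t = phi x_{t-1} + e_t whose
    innovations share the subject's latent covariance; the process is
    started from its stationary distribution, so the session's population
    correlation equals the latent correlation for any phi.  Sessions are
    independent given the subject.  ``violate_session`` injects a
    motion-limit violation into that session's trace (for QC tests).
    """
    config.validate()
    lo, hi = config.age_range
    if not (lo <= record.age <= hi):
        raise ValueError(f"age {record.age} outside configured range {config.age_range}")
    rng = np.random.default_rng(seed)
    t = int(n_volumes if n_volumes is not None else config.n_volumes)
    u = rng.normal(0.0, config.region_strength_sd, size=config.n_regions)
    cov = build_latent_covariance(
        config, record.age, hubs=hubs, sex=record.sex, region_effects=u
    )
    chol = np.linalg.cholesky(cov)
    phi = config.ar1_coeff
    sessions: list[SessionSeries] = []
    motion: list[MotionTrace] = []
    for s in range(config.n_sessions):
        eps = rng.standard_normal((t, config.n_regions)) @ chol.T
        x = np.empty_like(eps)
        x[0] = eps[0] / np.sqrt(1.0 - phi**2)
        for i in range(1, t):
            x[i] = phi * x[i - 1] + eps[i]
        sessions.append(
            SessionSeries(
                data=x.T,
                tr_seconds=config.tr_seconds,
                subject_id=record.subject_id,
                session_id=f"ses-{s + 1}",
            )
        )
        motion.append(_simulate_motion(rng, t, violate=(violate_session == s)))
    return SyntheticSubject(
        record=record,
        sessions=sessions,
        motion=motion,
        ground_truth_hubs=frozenset(int(h) for h in hubs),
    )


def _control_records(config: CohortConfig) -> list[SubjectRecord]:
    n = config.n_controls
    n_f = int(round(config.sex_ratio * n))
    n_m = n - n_f
    lo, hi = config.age_range
    records = []
    for sex, count in (("F", n_f), ("M", n_m)):
        ages = np.linspace(lo, hi, count) if count > 1 else np.array([(lo + hi) / 2])
        for i, age in enumerate(ages[:count]):
            records.append(
                SubjectRecord(
                    subject_id=f"ctrl-{sex}{i + 1:04d}",
                    age=float(age),
                    sex=sex,
                    group="control",
                )
            )
    return records


def _patient_records(config: CohortConfig, rng: np.random.Generator) -> list[SubjectRecord]:
    lo, hi = config.age_range
    records = []
    for i in range(config.n_patients):
        age = float(rng.uniform(lo, hi))
        sex = "F" if rng.random() < config.sex_ratio else "M"
        max_dur = max(age - lo + 1.0, 2.0)
        records.append(
            SubjectRecord(
                subject_id=f"pat-{i + 1:04d}",
                age=age,
                sex=sex,
                group="patient",
                duration_years=float(rng.uniform(1.0, min(30.0, max_dur))),
                n_aeds=int(rng.integers(1, 5)),
                qolie31=float(rng.uniform(25.0, 95.0)),
                lsss=float(rng.uniform(5.0, 80.0)),
            )
        )
    return records


def make_atlas(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Atlas table: 0-based region ids, names, and DMN membership flags."""
    r = config.n_regions
    dmn = np.zeros(r, dtype=int)
    dmn[rng.choice(r, size=config.n_dmn, replace=False)] = 1
    comm = config.communities()
    names = [f"region_{c:02d}_{i:04d}" for i, c in enumerate(comm)]
    return pd.DataFrame({"region_id": np.arange(r), "name": names, "is_dmn": dmn})


def subject_seeds(config: CohortConfig, n: int) -> np.ndarray:
    """Deterministic per-subject seeds derived from the cohort seed."""
    ss = np.random.SeedSequence(config.seed)
    return ss.generate_state(n) & 0x7FFFFFFF


def generate_cohort(
    config: CohortConfig, out_dir: str | Path | None = None
) -> tuple[list[SyntheticSubject], pd.DataFrame, pd.DataFrame]:
    """Generate the full cohort: controls, patients, metadata, atlas.

    Returns ``(subjects, metadata, atlas)``; when ``out_dir`` is given the
    cohort is also written in the external interface formats (per-session
    TSV time series, rp-style motion text, metadata CSV, atlas TSV).
    """
    config.validate()
    if config.n_controls < 20:
        warnings.warn(
            f"only {config.n_controls} controls: normative fits will be unstable",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA71A5]))
    records = _control_records(config) + _patient_records(config, rng)
    atlas = make_atlas(config, rng)
    hub_sets: list[Sequence[int]] = []
    for rec in records:
        if rec.group == "patient":
            hub_sets.append(
                sorted(
                    rng.choice(
                        config.n_regions,
                        size=config.hub_injection.n_hubs,
                        replace=False,
                    ).tolist()
                )
            )
        else:
            hub_sets.append(())
    seeds = subject_seeds(config, len(records))
    subjects = [
        simulate_subject(config, rec, hubs=hubs, seed=int(seed))
        for rec, hubs, seed in zip(records, hub_sets, seeds)
    ]
    metadata = pd.DataFrame(
        {
            "id": [r.subject_id for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "group": [r.group for r in records],
            "duration_years": [r.duration_years for r in records],
            "n_aeds": [r.n_aeds for r in records],
            "qolie31": [r.qolie31 for r in records],
            "lsss": [r.lsss for r in records],
        }
    )
    if out_dir is not None:
        from . import io as _io

        _io.write_cohort(Path(out_dir), subjects, metadata, atlas)
    return subjects, metadata, atlas
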