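"""Age- and sex-resolved normative model of regional centrality scores.

For every (region, sex, measure) the control mean is an ordinary
least-squares line in age.  The age-dependent dispersion is estimated by
regressing the scaled absolute residuals |e| * sqrt(pi/2) on age (for a
Gaussian, E|e| = sigma sqrt(2/pi), so the scaling makes the fitted line an
estimate of sigma at each age); a homoscedastic pooled-SD alternative is
available.  A subject's region is abnormal when its score strictly
exceeds mean(age) + 2 SD(age).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .centrality import CentralityProfile
from .records import SubjectRecord

MEASURES = ("nac0", "nac1")
SD_MODES = ("age_regressed", "pooled")

#: Predicted SDs are floored at this fraction of the pooled residual SD so
#: near-deterministic fixtures cannot produce zero-width normative bands.
SD_FLOOR_FRACTION = 0.1

#: Relative spread of per-subject score sums tolerated before input is
#: declared mixed-scale (canonical profiles all sum to 1; a max-rescaled
#: profile slipped in among them sums to ~n_regions/max and stands out).
_SCALE_REL_TOL = 0.25


class ScaleError(ValueError):
    """Input scores are not on one consistent (canonical) scale."""


@dataclass
class _SexFit:
    mean_intercept: np.ndarray  # (n_regions,)
    mean_slope: np.ndarray
    sd_intercept: np.ndarray
    sd_slope: np.ndarray
    sd_floor: np.ndarray
    n_subjects: int
    age_min: float
    age_max: float


@dataclass
class NormativeModel:
    """Per (region, sex, measure) linear normative model."""

    fits: dict[tuple[str, str], _SexFit]  # keyed (sex, measure)
    n_regions: int
    sd_mode: str
    train_sums: dict[str, float] = field(default_factory=dict)

    def predicted_mean(self, sex: str, measure: str, age: float) -> np.ndarray:
        f = self._fit(sex, measure)
        return f.mean_intercept + f.mean_slope * age

    def predicted_sd(self, sex: str, measure: str, age: float) -> np.ndarray:
        f = self._fit(sex, measure)
        sd = f.sd_intercept + f.sd_slope * age
        return np.maximum(sd, f.sd_floor)

    def thresholds(self, sex: str, measure: str, age: float) -> np.ndarray:
        """mean(age) + 2 SD(age) for every region."""
        return self.predicted_mean(sex, measure, age) + 2.0 * self.predicted_sd(
            sex, measure, age
        )

    def is_extrapolating(self, sex: str, measure: str, age: float) -> bool:
        f = self._fit(sex, measure)
        return age < f.age_min or age > f.age_max

    def sample_scores(
        self, sex: str, measure: str, age: float, rng: np.random.Generator
    ) -> np.ndarray:
        """Draw one subject's region scores from the fitted model (null)."""
        return rng.normal(
            self.predicted_mean(sex, measure, age),
            self.predicted_sd(sex, measure, age),
        )

    def _fit(self, sex: str, measure: str) -> _SexFit:
        try:
            return self.fits[(sex, measure)]
        except KeyError:
            raise KeyError(f"no normative fit for sex={sex!r}, measure={measure!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (sex, measure), f in sorted(self.fits.items()):
            for region in range(self.n_regions):
                rows.append(
                    {
                        "region": region,
                        "sex": sex,
                        "measure": measure,
                        "mean_intercept": f.mean_intercept[region],
                        "mean_slope": f.mean_slope[region],
                        "sd_intercept": f.sd_intercept[region],
                        "sd_slope": f.sd_slope[region],
                        "sd_floor": f.sd_floor[region],
                        "n": f.n_subjects,
                        "age_min": f.age_min,
                        "age_max": f.age_max,
                    }
                )
        df = pd.DataFrame(rows)
        df.attrs["sd_mode"] = self.sd_mode
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sd_mode: str = "age_regressed") -> "NormativeModel":
        n_regions = int(df["region"].max()) + 1
        fits = {}
        for (sex, measure), grp in df.groupby(["sex", "measure"]):
            grp = grp.sort_values("region")
            fits[(sex, measure)] = _SexFit(
                mean_intercept=grp["mean_intercept"].to_numpy(),
                mean_slope=grp["mean_slope"].to_numpy(),
                sd_intercept=grp["sd_intercept"].to_numpy(),
                sd_slope=grp["sd_slope"].to_numpy(),
                sd_floor=grp["sd_floor"].to_numpy(),
                n_subjects=int(grp["n"].iloc[0]),
                age_min=float(grp["age_min"].iloc[0]),
                age_max=float(grp["age_max"].iloc[0]),
            )
        return cls(fits=fits, n_regions=n_regions, sd_mode=sd_mode)


@dataclass
class AbnormalRegions:
    """Per-subject abnormal region sets for both measures."""

    subject_id: str
    ar0: frozenset[int]
    ar1: frozenset[int]
    thresholds0: np.ndarray
    thresholds1: np.ndarray
    extrapolated_age: bool = False

    @property
    def n_ar0(self) -> int:
        return len(self.ar0)

    @property
    def n_ar1(self) -> int:
        return len(self.ar1)


def _check_same_scale(sums: np.ndarray, what: str) -> float:
    """All subjects must be on one scale; returns the reference sum."""
    ref = float(np.median(sums))
    off = np.abs(sums - ref) > _SCALE_REL_TOL * abs(ref)
    if off.any():
        raise ScaleError(
            f"{what}: score sums range {sums.min():.4g}..{sums.max():.4g}; "
            "mixed scales detected - the normative model requires every "
            "subject on the canonical (sum-to-1) scale"
        )
    return ref


def _check_against_train(total: float, ref: float, what: str) -> None:
    if abs(total - ref) > _SCALE_REL_TOL * abs(ref):
        raise ScaleError(
            f"{what} scores sum to {total:.4g} but the model was fitted on "
            f"profiles summing to {ref:.4g}: scales must match (canonical "
            "sum-to-1 scale throughout)"
        )


def _ols_lines(ages: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-column OLS of y on age: returns (intercepts, slopes, residuals)."""
    x = np.column_stack([np.ones_like(ages), ages])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return beta[0], beta[1], resid


def fit_normative(
    profiles: Sequence[CentralityProfile],
    records: Sequence[SubjectRecord],
    sd_mode: Literal["age_regressed", "pooled"] = "age_regressed",
) -> NormativeModel:
    """Fit the control normative model, separately per sex and measure."""
    if sd_mode not in SD_MODES:
        raise ValueError(f"sd_mode must be one of {SD_MODES}")
    if len(profiles) != len(records):
        raise ValueError("profiles and records must align")
    if not profiles:
        raise ValueError("no control profiles")
    n_regions = profiles[0].n_regions
    sexes = {r.sex for r in records}
    if len(sexes) < 2:
        raise ValueError("normative fit requires controls of both sexes")
    fits: dict[tuple[str, str], _SexFit] = {}
    train_sums: dict[str, list[np.ndarray]] = {m: [] for m in MEASURES}
    for sex in sorted(sexes):
        idx = [i for i, r in enumerate(records) if r.sex == sex]
        ages = np.array([records[i].age for i in idx], dtype=float)
        if np.unique(ages).size < 2:
            raise ValueError(f"degenerate ages for sex {sex}: need >= 2 distinct values")
        if len(idx) < 3:
            raise ValueError(
                f"need at least 3 controls of sex {sex} (got {len(idx)})"
            )
        if len(idx) < 10:
            warnings.warn(
                f"only {len(idx)} controls of sex {sex}; normative fit is unstable",
                UserWarning,
                stacklevel=2,
            )
        for measure in MEASURES:
            cols = []
            for i in idx:
                s = getattr(profiles[i], measure)
                if s is None:
                    raise ValueError(
                        f"control {records[i].subject_id} has undefined {measure}"
                    )
                cols.append(s)
            y = np.vstack(cols)  # (n_subjects, n_regions)
            train_sums[measure].append(y.sum(axis=1))
            b0, b1, resid = _ols_lines(ages, y)
            pooled_sd = resid.std(axis=0, ddof=2)
            floor = SD_FLOOR_FRACTION * pooled_sd
            if sd_mode == "age_regressed":
                s0, s1, _ = _ols_lines(ages, np.abs(resid) * np.sqrt(np.pi / 2.0))
            else:
                s0, s1 = pooled_sd, np.zeros(n_regions)
            fits[(sex, measure)] = _SexFit(
                mean_intercept=b0,
                mean_slope=b1,
                sd_intercept=np.asarray(s0, dtype=float),
                sd_slope=np.asarray(s1, dtype=float),
                sd_floor=floor,
                n_subjects=len(idx),
                age_min=float(ages.min()),
                age_max=float(ages.max()),
            )
    refs = {
        m: _check_same_scale(np.concatenate(v), f"{m} controls")
        for m, v in train_sums.items()
    }
    return NormativeModel(
        fits=fits, n_regions=n_regions, sd_mode=sd_mode, train_sums=refs
    )


def threshold_at(
    model: NormativeModel, region: int, sex: str, measure: str, age: float
) -> tuple[float, bool]:
    """Upper normal bound mean(age) + 2 SD(age) for one region.

    Returns ``(threshold, extrapolated)``; ages beyond the fitted range
    still yield a value but are flagged.
    """
    thr = float(model.thresholds(sex, measure, age)[region])
    return thr, model.is_extrapolating(sex, measure, age)


def detect_abnormal(
    profile: CentralityProfile,
    record: SubjectRecord,
    model: NormativeModel,
) -> AbnormalRegions:
    """Flag regions whose scores strictly exceed mean + 2 SD at the
    subject's age and sex.  Applied identically to controls and patients."""
    if "nac0" in model.train_sums:
        _check_against_train(
            float(profile.nac0.sum()), model.train_sums["nac0"],
            f"{profile.subject_id} nac0",
        )
    thr0 = model.thresholds(record.sex, "nac0", record.age)
    ar0 = frozenset(np.flatnonzero(profile.nac0 > thr0).tolist())
    thr1 = model.thresholds(record.sex, "nac1", record.age)
    if profile.nac1 is not None:
        if "nac1" in model.train_sums:
            _check_against_train(
                float(profile.nac1.sum()), model.train_sums["nac1"],
                f"{profile.subject_id} nac1",
            )
        ar1 = frozenset(np.flatnonzero(profile.nac1 > thr1).tolist())
    else:
        ar1 = frozenset()
    return AbnormalRegions(
        subject_id=profile.subject_id,
        ar0=ar0,
        ar1=ar1,
        thresholds0=thr0,
        thresholds1=thr1,
        extrapolated_age=model.is_extrapolating(record.sex, "nac0", record.age),
    )
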