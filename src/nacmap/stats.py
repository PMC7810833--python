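"""Downstream statistics on abnormal-region profiles.

Covers the per-patient summaries (score-distribution chi-square against
matched controls, abnormal-region counts, connection percentage among
abnormal regions, kappa agreement between the two measures, DMN
enrichment) and the cohort-level comparisons (edge-count ANCOVA with age
as nuisance covariate, rank-sum count comparisons, Spearman / partial
Spearman correlations with clinical scores).  p-values are reported
unadjusted; the report counts how many tests were run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectivity import Adjacency
from .records import SubjectRecord

DEFAULT_BIN_WIDTH = 0.05
DEFAULT_MATCH_WINDOW_YEARS = 5.0
MIN_MATCHED_CONTROLS = 10


# ---------------------------------------------------------------------------
# distribution comparison


def histogram_proportions(scores: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    counts, _ = np.histogram(np.clip(scores, bin_edges[0], bin_edges[-1]), bin_edges)
    return counts / counts.sum()


def default_bin_edges(bin_width: float = DEFAULT_BIN_WIDTH) -> np.ndarray:
    n = int(round(1.0 / bin_width))
    return np.linspace(0.0, 1.0, n + 1)


def merge_bins(observed: np.ndarray, expected: np.ndarray, min_expected: float = 5.0):
    """Merge adjacent bins left-to-right until every expected count is
    >= min_expected (standard chi-square validity rule)."""
    obs_m, exp_m = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(observed, expected):
        o_acc += o
        e_acc += e
        if e_acc >= min_expected:
            obs_m.append(o_acc)
            exp_m.append(e_acc)
            o_acc = e_acc = 0.0
    if e_acc > 0 or o_acc > 0:
        if exp_m:
            obs_m[-1] += o_acc
            exp_m[-1] += e_acc
        else:
            obs_m, exp_m = [o_acc], [e_acc]
    return np.array(obs_m), np.array(exp_m)


def distribution_chisq(
    subject_scores: np.ndarray,
    reference_proportions: np.ndarray,
    bin_edges: np.ndarray,
) -> tuple[float, int, float]:
    """Pearson chi-square of a subject's (max-rescaled) score histogram
    against matched-control reference proportions.

    Returns (chi2, df, p).  Adjacent bins are merged until every expected
    count reaches 5; fewer than 2 merged bins is an error.
    """
    subject_scores = np.asarray(subject_scores, dtype=float)
    reference_proportions = np.asarray(reference_proportions, dtype=float)
    if not math.isclose(reference_proportions.sum(), 1.0, abs_tol=1e-8):
        raise ValueError("reference proportions must sum to 1")
    if len(reference_proportions) != len(bin_edges) - 1:
        raise ValueError("reference proportions must match the bins")
    n = subject_scores.size
    observed, _ = np.histogram(
        np.clip(subject_scores, bin_edges[0], bin_edges[-1]), bin_edges
    )
    expected = reference_proportions * n
    obs_m, exp_m = merge_bins(observed.astype(float), expected)
    if len(obs_m) < 2:
        raise ValueError("fewer than 2 bins remain after merging; cannot test")
    chi2 = float(((obs_m - exp_m) ** 2 / exp_m).sum())
    df = len(obs_m) - 1
    p = float(sps.chi2.sf(chi2, df))
    return chi2, df, p


def matched_reference(
    control_scores: np.ndarray,
    control_records: Sequence[SubjectRecord],
    subject: SubjectRecord,
    bin_edges: np.ndarray,
    window_years: float = DEFAULT_MATCH_WINDOW_YEARS,
) -> tuple[np.ndarray, int]:
    """Mean bin proportions over age- and sex-matched controls.

    Controls of the subject's sex within ``window_years`` of the subject's
    age are used; when fewer than 10 match, the window is doubled until
    enough do (or all same-sex controls are used).  Returns
    ``(proportions, n_matched)``.
    """
    control_scores = np.asarray(control_scores, dtype=float)
    same_sex = np.array([r.sex == subject.sex for r in control_records])
    if not same_sex.any():
        raise ValueError(f"no controls of sex {subject.sex!r}")
    ages = np.array([r.age for r in control_records], dtype=float)
    w = window_years
    while True:
        sel = same_sex & (np.abs(ages - subject.age) <= w)
        if sel.sum() >= MIN_MATCHED_CONTROLS or sel.sum() == same_sex.sum():
            break
        w *= 2.0
    props = np.vstack(
        [histogram_proportions(s, bin_edges) for s in control_scores[sel]]
    ).mean(axis=0)
    return props, int(sel.sum())


# ---------------------------------------------------------------------------
# rank statistics


def count_comparison(
    patient_counts: Sequence[float], control_counts: Sequence[float]
) -> dict:
    """Wilcoxon rank-sum (Mann-Whitney) with tie-corrected normal
    approximation and no continuity correction.

    The z statistic is signed so that positive z means the first sample
    tends larger.  Returns z, two-sided p and both medians.
    """
    x = np.asarray(patient_counts, dtype=float)
    y = np.asarray(control_counts, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = ranks[:n1].sum()
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = (w - mu) / math.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return {
        "z": float(z),
        "p": p,
        "median_a": float(np.median(x)),
        "median_b": float(np.median(y)),
    }


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman correlation (Pearson on mid-ranks, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant input")
    r, p = sps.spearmanr(x, y)
    return float(r), float(p)


def spearman_partial(
    x: Sequence[float], y: Sequence[float], covar: Sequence[float]
) -> tuple[float, float]:
    """Partial Spearman correlation of x and y controlling for covar.

    All three variables are rank-transformed (mid-ranks); the first-order
    partial correlation formula is applied and tested with a t statistic
    on n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covar, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    for arr in (x, y, c):
        if np.unique(arr).size < 2:
            raise ValueError("constant input")
    rx, ry, rc = sps.rankdata(x), sps.rankdata(y), sps.rankdata(c)
    r_xy = np.corrcoef(rx, ry)[0, 1]
    r_xc = np.corrcoef(rx, rc)[0, 1]
    r_yc = np.corrcoef(ry, rc)[0, 1]
    denom = math.sqrt((1.0 - r_xc**2) * (1.0 - r_yc**2))
    if denom == 0:
        raise ValueError("covariate is perfectly correlated with an input")
    r = (r_xy - r_xc * r_yc) / denom
    df = n - 3
    r_clamped = max(min(r, 1.0 - 1e-15), -1.0 + 1e-15)
    t = r_clamped * math.sqrt(df / (1.0 - r_clamped**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return float(r), p


# ---------------------------------------------------------------------------
# graph / set statistics


def connection_percentage(a: Adjacency, regions: Sequence[int]) -> Optional[float]:
    """Percentage of possible edges C(n, 2) present among ``regions``.

    Undefined (None) for fewer than 2 regions.
    """
    ids = sorted(set(int(i) for i in regions))
    k = len(ids)
    if k < 2:
        return None
    sub = a.a[np.ix_(ids, ids)]
    edges = int(sub.sum()) // 2
    possible = k * (k - 1) // 2
    return 100.0 * edges / possible


def cohen_kappa(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Chance-corrected agreement between two binary labelings."""
    a = np.asarray(labels_a).astype(bool)
    b = np.asarray(labels_b).astype(bool)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("labelings must have equal length >= 2")
    n = a.size
    po = float((a == b).mean())
    pa, pb = a.mean(), b.mean()
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe >= 1.0:
        return 1.0  # both raters constant and identical
    return (po - pe) / (1.0 - pe)


def dmn_enrichment(
    regions: Sequence[int], dmn_regions: Sequence[int], n_regions_total: int
) -> dict:
    """Observed vs expected percentage of abnormal regions inside the DMN.

    A one-sample goodness-of-fit chi-square on the (in-DMN, out-DMN) split
    of the region set, with expected proportions n_dmn/n_total, df = 1.
    """
    ids = set(int(i) for i in regions)
    if not ids:
        raise ValueError("region set is empty")
    dmn = set(int(i) for i in dmn_regions)
    n = len(ids)
    k = len(ids & dmn)
    p_dmn = len(dmn) / n_regions_total
    observed = np.array([k, n - k], dtype=float)
    expected = np.array([n * p_dmn, n * (1.0 - p_dmn)])
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(chi2, 1))
    return {
        "observed_pct": 100.0 * k / n,
        "expected_pct": 100.0 * p_dmn,
        "n_in_dmn": k,
        "n_regions": n,
        "chi2": chi2,
        "p": p,
    }


# ---------------------------------------------------------------------------
# cohort-level models


def edges_ancova(
    edge_counts: Sequence[float], group: Sequence[str], age: Sequence[float]
) -> dict:
    """ANCOVA of edge counts on group with age as nuisance covariate.

    Fits edges ~ group + age and reports the partial F for the group main
    effect; the group x age interaction F comes from comparing against the
    full model edges ~ group * age.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame(
        {"edges": np.asarray(edge_counts, float), "group": list(group), "age": np.asarray(age, float)}
    )
    if df["group"].nunique() < 2:
        raise ValueError("both groups must be present")
    if len(df) < 6:
        raise ValueError("need at least 6 subjects")
    m_add = smf.ols("edges ~ C(group) + age", data=df).fit()
    m_full = smf.ols("edges ~ C(group) * age", data=df).fit()
    if np.linalg.matrix_rank(m_full.model.exog) < m_full.model.exog.shape[1]:
        raise ValueError("rank-deficient design")
    tbl = anova_lm(m_add, typ=2)
    f_group = float(tbl.loc["C(group)", "F"])
    p_group = float(tbl.loc["C(group)", "PR(>F)"])
    cmp_tbl = anova_lm(m_add, m_full)
    f_int = float(cmp_tbl["F"].iloc[1])
    p_int = float(cmp_tbl["Pr(>F)"].iloc[1])
    return {
        "F_group": f_group,
        "p_group": p_group,
        "df_group": 1,
        "F_interaction": f_int,
        "p_interaction": p_int,
        "df_interaction": 1,
    }


# ---------------------------------------------------------------------------
# report assembly


@dataclass
class AbnormalityReport:
    """Per-subject summary of abnormality statistics."""

    subject_id: str
    n_ar0: int
    n_ar1: int
    connection_percentage: Optional[float]
    kappa: float
    dmn_ar0: Optional[dict]
    dmn_ar1: Optional[dict]
    distribution_p_nac0: Optional[float]
    distribution_p_nac1: Optional[float]
    n_matched_controls: Optional[int] = None
    flags: list[str] = field(default_factory=list)


def subject_report(
    subject_id: str,
    adjacency: Adjacency,
    ar0: frozenset[int],
    ar1: frozenset[int],
    dmn_regions: Sequence[int],
    n_regions_total: int,
    distribution_p: tuple[Optional[float], Optional[float]] = (None, None),
    n_matched_controls: Optional[int] = None,
) -> AbnormalityReport:
    labels0 = np.zeros(n_regions_total, dtype=int)
    labels0[list(ar0)] = 1
    labels1 = np.zeros(n_regions_total, dtype=int)
    labels1[list(ar1)] = 1
    flags = []
    conn = connection_percentage(adjacency, ar0)
    if conn is None:
        flags.append("connection_percentage undefined (|aR0| < 2)")
    dmn0 = dmn_enrichment(ar0, dmn_regions, n_regions_total) if ar0 else None
    dmn1 = dmn_enrichment(ar1, dmn_regions, n_regions_total) if ar1 else None
    if dmn0 is None:
        flags.append("dmn enrichment undefined for aR0 (empty set)")
    if dmn1 is None:
        flags.append("dmn enrichment undefined for aR1 (empty set)")
    return AbnormalityReport(
        subject_id=subject_id,
        n_ar0=len(ar0),
        n_ar1=len(ar1),
        connection_percentage=conn,
        kappa=cohen_kappa(labels0, labels1),
        dmn_ar0=dmn0,
        dmn_ar1=dmn1,
        distribution_p_nac0=distribution_p[0],
        distribution_p_nac1=distribution_p[1],
        n_matched_controls=n_matched_controls,
        flags=flags,
    )


def clinical_correlations(patients: pd.DataFrame) -> pd.DataFrame:
    """Cohort table relating abnormality summaries to clinical scores.

    Duration of illness uses partial Spearman with age as nuisance
    covariate (age and duration are confounded); the other clinical
    variables use plain Spearman.  Correlations are computed on complete
    cases; the n used is reported per cell.
    """
    outcomes = ["n_ar0", "n_ar1", "connection_percentage"]
    predictors = [
        ("duration_years", "partial_spearman_age"),
        ("n_aeds", "spearman"),
        ("qolie31", "spearman"),
        ("lsss", "spearman"),
    ]
    rows = []
    for out in outcomes:
        for pred, method in predictors:
            sub = patients[[out, pred, "age"]].dropna()
            n = len(sub)
            r = p = np.nan
            if n >= 5:
                try:
                    if method == "partial_spearman_age":
                        r, p = spearman_partial(sub[out], sub[pred], sub["age"])
                    else:
                        r, p = spearman(sub[out], sub[pred])
                except ValueError:
                    pass
            rows.append(
                {"outcome": out, "predictor": pred, "method": method, "r": r, "p": p, "n": n}
            )
    return pd.DataFrame(rows)
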