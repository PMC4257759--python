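"""Exposure-wide association scan of adjusted asthma age-of-onset.

Each catalogued early-life exposure is tested one at a time by ordinary
least squares of the transformed, sex/study-adjusted onset residual on the
exposure, with pairwise deletion of missing values (the analyzable n varies
widely across questionnaire items). The reported statistic is the slope
t-statistic; a positive t means exposed subjects report a *later* onset on
the transformed scale. Family-wise correction over the battery is delegated
to :mod:`onsetscan.permutation_engine`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort_io import CohortTable, ExposureCatalog
from .exceptions import DegenerateInputError
from .permutation_engine import (
    PermutationConfig,
    PermutationResult,
    SlopeTest,
    minp_correction,
)
from .transforms import AdjustedOnset

logger = logging.getLogger(__name__)

MIN_ANALYZABLE_N = 10


@dataclass
class AssociationResult:
    """Per-exposure regression summary (Table-2-shaped row)."""

    exposure: str
    n: int
    t_stat: float
    p_uncorrected: float
    p_corrected: float | None = None

    def as_record(self) -> dict:
        return {
            "exposure": self.exposure,
            "n": self.n,
            "t_stat": self.t_stat,
            "p_uncorrected": self.p_uncorrected,
            "p_corrected": np.nan if self.p_corrected is None else self.p_corrected,
        }


def _slope_t(y: np.ndarray, X: np.ndarray, coef_index: int) -> tuple[float, float, int]:
    """t and two-sided p for one coefficient of an OLS fit (finite-capped)."""
    n, k = X.shape
    df = n - k
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    XtX_inv = np.linalg.pinv(X.T @ X)
    var = sse / df * XtX_inv[coef_index, coef_index]
    if var <= 0 or sse <= 1e-12 * float(y @ y):
        logger.warning("degenerate (perfect) fit; t capped at finite value")
        t = np.sign(beta[coef_index]) * 1e6
        return float(t), 0.0, df
    t = float(beta[coef_index] / np.sqrt(var))
    return t, float(2.0 * stats.t.sf(abs(t), df)), df


def exposure_regression(
    adjusted: AdjustedOnset,
    exposure,
    name: str = "exposure",
    min_n: int = MIN_ANALYZABLE_N,
) -> AssociationResult:
    """Simple OLS of the adjusted residual on one exposure.

    Subjects missing the exposure are dropped (pairwise deletion); the
    exposure must vary on the analyzed subset.
    """
    x = np.asarray(exposure, dtype=float)
    y = adjusted.residual
    if len(x) != len(y):
        raise ValueError("exposure vector misaligned with adjusted onset")
    mask = np.isfinite(x) & np.isfinite(y)
    m = int(mask.sum())
    if m < min_n:
        raise DegenerateInputError(
            f"exposure {name!r}: only {m} jointly non-missing subjects (< {min_n})"
        )
    xs, ys = x[mask], y[mask]
    if np.all(xs == xs[0]):
        raise DegenerateInputError(f"exposure {name!r} is constant on the analyzed subset")
    X = np.column_stack([np.ones(m), xs])
    t, p, _ = _slope_t(ys, X, 1)
    return AssociationResult(exposure=name, n=m, t_stat=t, p_uncorrected=p)


def scan_exposures(
    cohort: CohortTable,
    catalog: ExposureCatalog | None = None,
    adjusted: AdjustedOnset | None = None,
    min_n: int = MIN_ANALYZABLE_N,
) -> list[AssociationResult]:
    """One association test per catalogued exposure, sorted by |t| descending.

    Exposures failing preconditions (all-missing, constant, too few
    subjects) are skipped with a log message rather than aborting the scan.
    """
    from .transforms import adjust_onset

    if catalog is None:
        catalog = cohort.catalog
    if adjusted is None:
        adjusted = adjust_onset(cohort)
    results = []
    for var in catalog:
        try:
            results.append(
                exposure_regression(adjusted, cohort.exposure(var.name),
                                    name=var.name, min_n=min_n)
            )
        except DegenerateInputError as exc:
            logger.info("skipping exposure %r: %s", var.name, exc)
    results.sort(key=lambda r: abs(r.t_stat), reverse=True)
    return results


def correct_scan(
    cohort: CohortTable,
    results: list[AssociationResult],
    config: PermutationConfig,
    adjusted: AdjustedOnset | None = None,
) -> PermutationResult:
    """Fill ``p_corrected`` on scan results via battery-wide min-P permutation."""
    from .transforms import adjust_onset

    if adjusted is None:
        adjusted = adjust_onset(cohort)
    tests = [SlopeTest(r.exposure, cohort.exposure(r.exposure)) for r in results]
    observed = {r.exposure: r.p_uncorrected for r in results}
    outcome = adjusted.residual if config.permute == "residual" else adjusted.z
    perm = minp_correction(outcome, tests, config, observed_p=observed,
                           design=adjusted.design)
    for r in results:
        r.p_corrected = perm.p_corrected[r.exposure]
    return perm


def atopy_adjusted_regression(
    adjusted: AdjustedOnset,
    exposure,
    atopy,
    name: str = "exposure",
    min_n: int = MIN_ANALYZABLE_N,
) -> AssociationResult:
    """Exposure effect on adjusted onset, additionally controlling atopy.

    Used to ask whether an exposure acts on onset beyond any effect mediated
    through allergic sensitization. The reported t/p are for the exposure
    coefficient in ``residual ~ exposure + atopy``.
    """
    x = np.asarray(exposure, dtype=float)
    a = np.asarray(atopy, dtype=float)
    y = adjusted.residual
    mask = np.isfinite(x) & np.isfinite(a) & np.isfinite(y)
    m = int(mask.sum())
    if m < min_n:
        raise DegenerateInputError(
            f"atopy-adjusted {name!r}: only {m} complete subjects (< {min_n})"
        )
    xs, as_, ys = x[mask], a[mask], y[mask]
    if np.all(xs == xs[0]):
        raise DegenerateInputError(f"exposure {name!r} constant on the analyzed subset")
    if np.all(as_ == as_[0]):
        raise DegenerateInputError("atopy constant on the analyzed subset")
    X = np.column_stack([np.ones(m), xs, as_])
    t, p, _ = _slope_t(ys, X, 1)
    return AssociationResult(exposure=name, n=m, t_stat=t, p_uncorrected=p)


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

@dataclass
class GroupDescriptives:
    n: int
    percent_female: float
    percent_early_onset: float
    mean_onset_male: float
    mean_onset_female: float
    median_onset_male: float
    median_onset_female: float


@dataclass
class Descriptives:
    overall: GroupDescriptives
    by_study: dict[int, GroupDescriptives]
    kruskal_h: float | None
    kruskal_p: float | None


def _group_stats(onset: np.ndarray, sex: np.ndarray, cutpoint: float) -> GroupDescriptives:
    male = sex == "male"
    def _mm(v):
        return (float(np.mean(v)), float(np.median(v))) if v.size else (np.nan, np.nan)
    mean_m, med_m = _mm(onset[male])
    mean_f, med_f = _mm(onset[~male])
    return GroupDescriptives(
        n=len(onset),
        percent_female=100.0 * float(np.mean(~male)),
        percent_early_onset=100.0 * float(np.mean(onset < cutpoint)),
        mean_onset_male=mean_m,
        mean_onset_female=mean_f,
        median_onset_male=med_m,
        median_onset_female=med_f,
    )


def descriptives(cohort: CohortTable, cutpoint: float = 6.0) -> Descriptives:
    """Cohort summary: size, sex mix, early-onset share, onset by sex.

    The male/female onset comparison uses the Kruskal–Wallis rank test (the
    onset distribution is skewed, so a rank test is the appropriate
    two-group comparison). Skipped with a message for single-sex cohorts.
    """
    onset, sex, study = cohort.onset_years, cohort.sex, cohort.study
    overall = _group_stats(onset, sex, cutpoint)
    by_study = {s: _group_stats(onset[study == s], sex[study == s], cutpoint)
                for s in sorted(np.unique(study))}
    male = sex == "male"
    if 0 < male.sum() < len(male):
        h, p = stats.kruskal(onset[male], onset[~male])
        kh, kp = float(h), float(p)
    else:
        logger.info("single-sex cohort: onset-by-sex comparison skipped")
        kh = kp = None
    return Descriptives(overall=overall, by_study=by_study, kruskal_h=kh, kruskal_p=kp)
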