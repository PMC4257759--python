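"""Dichotomized early/late-onset contingency analyses.

Asthma onset is split at age six into early childhood onset (2 <= onset < 6)
and later onset (>= 6). Single exposures, exposure pairs (both-present vs
both-absent) and exposure–exposure relationships are then analyzed in 2x2
tables: odds ratio ``ad/bc``, Woolf standard error of the log odds ratio
``sqrt(1/a + 1/b + 1/c + 1/d)``, 95% CI ``exp(log OR +/- 1.96 SE)`` and a
1-df chi-square test of independence. When a cell is zero the
Haldane–Anscombe 0.5 is added to every cell for the OR/SE/CI (the chi-square
is still computed on the raw counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .cohort_io import CohortTable, ExposureCatalog
from .exceptions import DegenerateInputError

logger = logging.getLogger(__name__)

EARLY_ONSET_CUTPOINT = 6.0
Z_95 = float(stats.norm.ppf(0.975))


def dichotomize_onset(onset_years, cutpoint: float = EARLY_ONSET_CUTPOINT) -> np.ndarray:
    """Early-onset indicator: 1.0 if onset < cutpoint, 0.0 otherwise, NaN missing."""
    v = np.asarray(onset_years, dtype=float)
    obs = v[np.isfinite(v)]
    if np.any(obs < 2.0):
        raise DegenerateInputError(
            "onset below 2 years present; cohort invariant violated"
        )
    out = np.where(v < cutpoint, 1.0, 0.0)
    out[~np.isfinite(v)] = np.nan
    return out


@dataclass
class ContingencyResult:
    """2x2 table with OR, Woolf SE, 95% CI and chi-square test.

    ``table`` rows are exposed/unexposed, columns the two levels of the
    second variable (early/late onset in the dichotomized analyses).
    ``freq_exposed_early``/``freq_exposed_late`` are the percentage of
    column-1/column-2 subjects who are exposed (Table-3-style frequencies).
    """

    name_a: str
    name_b: str
    table: np.ndarray
    odds_ratio: float
    log_or_se: float
    ci95: tuple[float, float]
    chi2: float
    p: float
    freq_exposed_early: float
    freq_exposed_late: float
    haldane_adjusted: bool = False

    @property
    def n(self) -> int:
        return int(self.table.sum())

    def as_record(self) -> dict:
        a, b, c, d = self.table.ravel()
        return {
            "variable": self.name_a,
            "versus": self.name_b,
            "n": self.n,
            "n_exposed_early": int(a),
            "n_exposed_late": int(b),
            "n_unexposed_early": int(c),
            "n_unexposed_late": int(d),
            "freq_exposed_early_pct": self.freq_exposed_early,
            "freq_exposed_late_pct": self.freq_exposed_late,
            "odds_ratio": self.odds_ratio,
            "log_or_se": self.log_or_se,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "chi2": self.chi2,
            "p": self.p,
            "haldane_adjusted": self.haldane_adjusted,
        }


def contingency_from_table(
    table,
    name_a: str = "a",
    name_b: str = "b",
    continuity: bool = False,
) -> ContingencyResult:
    """Statistics for an explicit 2x2 count table ``[[a, b], [c, d]]``."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise DegenerateInputError("need a non-negative 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateInputError(
            f"{name_a} x {name_b}: zero margin in 2x2 table"
        )
    a, b, c, d = t.ravel()
    haldane = bool(np.any(t == 0))
    ta = t + 0.5 if haldane else t
    if haldane:
        logger.info("%s x %s: zero cell; Haldane-Anscombe 0.5 added for OR/SE/CI",
                    name_a, name_b)
    aa, bb, cc, dd = ta.ravel()
    or_ = (aa * dd) / (bb * cc)
    se = float(np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd))
    ci = (float(or_ * np.exp(-Z_95 * se)), float(or_ * np.exp(Z_95 * se)))
    chi2, p, _, _ = stats.chi2_contingency(t, correction=continuity)
    return ContingencyResult(
        name_a=name_a,
        name_b=name_b,
        table=t.astype(int),
        odds_ratio=float(or_),
        log_or_se=se,
        ci95=ci,
        chi2=float(chi2),
        p=float(p),
        freq_exposed_early=100.0 * float(a / (a + c)),
        freq_exposed_late=100.0 * float(b / (b + d)),
        haldane_adjusted=haldane,
    )


def contingency_analysis(
    indicator_a,
    indicator_b,
    name_a: str = "a",
    name_b: str = "b",
    continuity: bool = False,
) -> ContingencyResult:
    """Cross-tabulate two binary vectors over jointly non-missing subjects.

    ``indicator_a`` defines the rows (1 = exposed), ``indicator_b`` the
    columns (1 = first column, e.g. early onset).
    """
    x = np.asarray(indicator_a, dtype=float)
    y = np.asarray(indicator_b, dtype=float)
    if len(x) != len(y):
        raise ValueError("indicator vectors must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    xs, ys = x[mask], y[mask]
    for v, nm in ((xs, name_a), (ys, name_b)):
        if not np.all(np.isin(v, (0.0, 1.0))):
            raise DegenerateInputError(f"{nm!r} is not binary")
    table = np.array([
        [np.sum((xs == 1) & (ys == 1)), np.sum((xs == 1) & (ys == 0))],
        [np.sum((xs == 0) & (ys == 1)), np.sum((xs == 0) & (ys == 0))],
    ], dtype=float)
    return contingency_from_table(table, name_a=name_a, name_b=name_b,
                                  continuity=continuity)


def bivariate_exposure_analysis(
    exposure_a,
    exposure_b,
    early,
    name_a: str = "a",
    name_b: str = "b",
    min_n: int = 10,
    continuity: bool = False,
) -> ContingencyResult:
    """Joint-exposure contingency analysis against early onset.

    Subjects reporting both exposures are "exposed", subjects reporting
    neither are "unexposed"; subjects with exactly one of the two are
    excluded, so the comparison isolates the combined exposure.
    """
    xa = np.asarray(exposure_a, dtype=float)
    xb = np.asarray(exposure_b, dtype=float)
    joint = np.full(len(xa), np.nan)
    both = (xa == 1) & (xb == 1)
    neither = (xa == 0) & (xb == 0)
    joint[both] = 1.0
    joint[neither] = 0.0
    e = np.asarray(early, dtype=float)
    usable = np.isfinite(joint) & np.isfinite(e)
    if usable.sum() < min_n:
        raise DegenerateInputError(
            f"{name_a}+{name_b}: only {int(usable.sum())} subjects survive "
            f"the both/neither restriction (< {min_n})"
        )
    return contingency_analysis(joint, e, name_a=f"{name_a}+{name_b}",
                                name_b="early_onset", continuity=continuity)


def pairwise_exposure_association(
    catalog: ExposureCatalog,
    cohort: CohortTable,
    continuity: bool = False,
) -> dict[tuple[str, str], ContingencyResult | None]:
    """Exposure-exposure 2x2 association for every unordered binary pair.

    Quantitative catalog items are skipped with a log message; pairs with a
    degenerate margin are marked unavailable (``None``) and the run
    continues. The OR is symmetric in the pair ordering.
    """
    binary = [n for n in catalog.binary_names() if n in cohort.exposures.columns]
    if len(binary) < 2:
        raise DegenerateInputError("need at least 2 binary exposures")
    skipped = catalog.quantitative_names()
    if skipped:
        logger.info("pairwise association skips quantitative items: %s", skipped)
    out: dict[tuple[str, str], ContingencyResult | None] = {}
    for na, nb in combinations(binary, 2):
        try:
            out[(na, nb)] = contingency_analysis(
                cohort.exposure(na), cohort.exposure(nb),
                name_a=na, name_b=nb, continuity=continuity,
            )
        except DegenerateInputError as exc:
            logger.info("pair (%s, %s) unavailable: %s", na, nb, exc)
            out[(na, nb)] = None
    return out


def table_from_frequencies(
    freq_exposed_early_pct: float,
    freq_exposed_late_pct: float,
    early_fraction: float,
    n: int,
) -> np.ndarray:
    """Reconstruct integer 2x2 counts from published marginal frequencies.

    Given the percentage of early-onset and of late-onset subjects who are
    exposed, the early-onset fraction, and the total n, rebuild the count
    table (rounded to whole subjects). Used to check published odds ratios
    against their printed frequency columns.
    """
    n_early = round(n * early_fraction)
    n_late = n - n_early
    a = round(n_early * freq_exposed_early_pct / 100.0)
    b = round(n_late * freq_exposed_late_pct / 100.0)
    return np.array([[a, b], [n_early - a, n_late - b]], dtype=float)
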