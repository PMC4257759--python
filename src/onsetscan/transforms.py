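"""Outcome normalization and covariate adjustment.

Age-of-onset is strongly right-skewed, so regression-based stages operate on
a rank-based inverse normal transform of onset, residualized on sex and
study wave. The transform maps value ``v`` to

    z = Phi^-1( (rank(v) - c) / (m + 1 - 2c) )

with the Blom offset ``c = 3/8`` by default and average ranks for ties
(integer-year onsets produce many ties). Residualization is an ordinary
least-squares fit of ``z`` on an intercept plus male and study-2 indicators;
all downstream association tests use the residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import CohortTable
from .exceptions import DegenerateInputError

logger = logging.getLogger(__name__)

BLOM_OFFSET = 0.375


def inverse_normal_transform(values, c: float = BLOM_OFFSET) -> np.ndarray:
    """Rank-based inverse normal transform; missing values stay missing.

    Ties share their average rank, so equal inputs map to equal outputs and
    the transform is invariant under any strictly monotone re-labelling of
    the input. Requires at least three distinct non-missing values.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    mask = np.isfinite(v)
    m = int(mask.sum())
    if m < 3:
        raise DegenerateInputError("inverse normal transform needs >= 3 non-missing values")
    obs = v[mask]
    if np.all(obs == obs[0]):
        raise DegenerateInputError("inverse normal transform of a constant vector")
    ranks = stats.rankdata(obs, method="average")
    out[mask] = stats.norm.ppf((ranks - c) / (m + 1.0 - 2.0 * c))
    return out


@dataclass
class AdjustedOnset:
    """Transformed onset and its sex/study-adjusted residual.

    ``subject_ids`` records the alignment so downstream pairwise deletion is
    consistent; ``covariate_fit`` stores the intercept and indicator
    coefficients actually fitted (collinear columns are dropped).
    """

    subject_ids: pd.Index
    z: np.ndarray
    residual: np.ndarray
    covariate_fit: dict[str, float] = field(default_factory=dict)
    design: np.ndarray | None = None          # columns actually used in the fit
    design_names: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.z)


def residualize(z, sex, study, subject_ids=None) -> AdjustedOnset:
    """OLS of the transformed onset on sex and study indicators.

    A covariate constant in the sample (e.g. a single-sex cohort) is dropped
    with a warning rather than producing a singular fit.
    """
    z = np.asarray(z, dtype=float)
    sex = np.asarray(sex)
    study = np.asarray(study)
    if not (len(z) == len(sex) == len(study)):
        raise ValueError("z, sex and study must have equal length")
    if not np.all(np.isfinite(z)):
        raise DegenerateInputError("residualize requires non-missing z")

    male = (sex == "male").astype(float)
    study2 = (np.asarray(study, dtype=int) == 2).astype(float)
    cols = [("intercept", np.ones_like(z))]
    for name, col in (("male", male), ("study2", study2)):
        if np.all(col == col[0]):
            logger.warning("covariate %r is constant; dropped from adjustment", name)
        else:
            cols.append((name, col))
    names = [n for n, _ in cols]
    X = np.column_stack([c for _, c in cols])
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    fitted = X @ beta
    residual = z - fitted
    if subject_ids is None:
        subject_ids = pd.RangeIndex(len(z))
    return AdjustedOnset(
        subject_ids=pd.Index(subject_ids),
        z=z,
        residual=residual,
        covariate_fit=dict(zip(names, map(float, beta))),
        design=X,
        design_names=names,
    )


def adjust_onset(cohort: CohortTable, c: float = BLOM_OFFSET) -> AdjustedOnset:
    """Transform and residualize a cohort's onset in one step."""
    z = inverse_normal_transform(cohort.onset_years, c=c)
    return residualize(z, cohort.sex, cohort.study, subject_ids=cohort.subject_ids)
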