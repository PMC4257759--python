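"""Effect-modification analyses.

Two kinds of modifiers are tested:

* **Sex / study stratifiers** — the exposure effect is allowed to differ
  between the two levels of a demographic stratifier by adding a product
  term to the regression. Because the stratifier itself is being tested,
  the outcome here is the transformed onset *before* covariate adjustment.
* **SNP dosages (G×E)** — for each (SNP, exposure) pair the adjusted onset
  residual is regressed on exposure, minor-allele dosage (additive 0/1/2
  coding) and their product; the product-term t-test asks whether the
  genotype modifies the exposure effect. The whole battery is corrected
  family-wise with the same permutation min-P engine as the main scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError
from .permutation_engine import (
    PartialSlopeTest,
    PermutationConfig,
    PermutationResult,
    minp_correction,
)
from .transforms import AdjustedOnset

logger = logging.getLogger(__name__)

MIN_CELL_N = 30


# ---------------------------------------------------------------------------
# SNP catalog
# ---------------------------------------------------------------------------

def load_snp_catalog(path: str | Path | None = None) -> pd.DataFrame:
    """SNP annotation table: snp, risk_allele, gene, locus.

    Without a path, a bundled 26-row synthetic stand-in catalog is used
    (three entries carry published allergy-associated SNP names; the rest
    are synthetic placeholders for scan sizing).
    """
    if path is None:
        with resources.files("onsetscan.data").joinpath(
            "snp_catalog_synthetic.tsv"
        ).open() as fh:
            return pd.read_csv(fh, sep="\t")
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Stratified (sex / study) interaction test
# ---------------------------------------------------------------------------

@dataclass
class StratifiedEffect:
    stratifier: str
    exposure: str
    interaction_t: float
    interaction_p: float
    n: int
    stratum_effects: dict[str, float]
    stratum_ns: dict[str, int]

    def as_record(self) -> dict:
        rec = {
            "stratifier": self.stratifier,
            "exposure": self.exposure,
            "n": self.n,
            "interaction_t": self.interaction_t,
            "interaction_p": self.interaction_p,
        }
        for level, eff in self.stratum_effects.items():
            rec[f"effect_{level}"] = eff
            rec[f"n_{level}"] = self.stratum_ns[level]
        return rec


def stratified_interaction_test(
    z_onset,
    exposure,
    stratifier,
    stratifier_name: str = "stratum",
    exposure_name: str = "exposure",
    min_stratum_n: int = 10,
) -> StratifiedEffect:
    """Test whether an exposure effect differs between two strata.

    Fits ``z ~ exposure + stratum + exposure:stratum`` on the unadjusted
    transformed onset and reports t/p of the product term, plus per-stratum
    simple-effect slopes.
    """
    z = np.asarray(z_onset, dtype=float)
    x = np.asarray(exposure, dtype=float)
    s = np.asarray(stratifier)
    mask = np.isfinite(z) & np.isfinite(x)
    zs, xs, ss = z[mask], x[mask], s[mask]
    levels = sorted(pd.unique(ss).tolist(), key=str)
    if len(levels) != 2:
        raise DegenerateInputError(
            f"stratifier {stratifier_name!r} must have exactly 2 observed "
            f"levels, got {levels}"
        )
    ind = (ss == levels[1]).astype(float)
    effects, ns = {}, {}
    for lev in levels:
        in_lev = ss == lev
        ns[str(lev)] = int(in_lev.sum())
        if in_lev.sum() < min_stratum_n or np.all(xs[in_lev] == xs[in_lev][0]):
            raise DegenerateInputError(
                f"stratum {lev!r} of {stratifier_name!r}: fewer than "
                f"{min_stratum_n} subjects or constant exposure"
            )
        xl, zl = xs[in_lev], zs[in_lev]
        xlc = xl - xl.mean()
        effects[str(lev)] = float((xlc @ zl) / (xlc @ xlc))

    m = len(zs)
    X = np.column_stack([np.ones(m), xs, ind, xs * ind])
    beta, *_ = np.linalg.lstsq(X, zs, rcond=None)
    resid = zs - X @ beta
    df = m - 4
    sse = float(resid @ resid)
    cov = np.linalg.pinv(X.T @ X) * sse / df
    t = float(beta[3] / np.sqrt(cov[3, 3]))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return StratifiedEffect(
        stratifier=stratifier_name,
        exposure=exposure_name,
        interaction_t=t,
        interaction_p=p,
        n=m,
        stratum_effects=effects,
        stratum_ns=ns,
    )


# ---------------------------------------------------------------------------
# SNP x exposure interaction scan
# ---------------------------------------------------------------------------

@dataclass
class InteractionResult:
    snp: str
    exposure: str
    n: int
    t_stat: float
    p_uncorrected: float
    p_corrected: float | None = None
    risk_allele: str = ""
    gene: str = ""

    def as_record(self) -> dict:
        return {
            "snp": self.snp,
            "risk_allele": self.risk_allele,
            "gene": self.gene,
            "exposure": self.exposure,
            "n": self.n,
            "t_stat": self.t_stat,
            "p_uncorrected": self.p_uncorrected,
            "p_corrected": np.nan if self.p_corrected is None else self.p_corrected,
        }


def snp_interaction_scan(
    adjusted: AdjustedOnset,
    exposures: pd.DataFrame,
    genotypes: pd.DataFrame,
    perm_config: PermutationConfig | None = None,
    snp_catalog: pd.DataFrame | None = None,
    min_n: int = MIN_CELL_N,
) -> tuple[list[InteractionResult], PermutationResult | None]:
    """Interaction t-test for every (SNP, exposure) pair, min-P corrected.

    For each pair, subjects jointly non-missing for outcome, exposure and
    dosage enter ``residual ~ exposure + dosage + exposure:dosage``; SNP and
    exposure main effects always accompany the product term. Pairs with too
    few subjects or a monomorphic SNP are skipped with a log message; if
    more than 10% of pairs are skipped a warning is emitted. The battery is
    then corrected as one family by outcome permutation (the residual is
    permuted over the full cohort; genotypes stay fixed).
    """
    y = adjusted.residual
    anno: dict[str, dict] = {}
    if snp_catalog is not None:
        anno = {str(r["snp"]): dict(r) for _, r in snp_catalog.iterrows()}

    tests, results = [], []
    n_pairs = 0
    for snp in genotypes.columns:
        g = genotypes[snp].to_numpy(dtype=float)
        for exp_name in exposures.columns:
            n_pairs += 1
            x = exposures[exp_name].to_numpy(dtype=float)
            mask = np.isfinite(y) & np.isfinite(x) & np.isfinite(g)
            m = int(mask.sum())
            name = f"{snp}:{exp_name}"
            if m < min_n:
                logger.info("pair %s skipped: %d jointly non-missing (< %d)",
                            name, m, min_n)
                continue
            if np.all(g[mask] == g[mask][0]):
                logger.info("pair %s skipped: monomorphic SNP on analyzed subset",
                            name)
                continue
            if np.all(x[mask] == x[mask][0]):
                logger.info("pair %s skipped: constant exposure on analyzed subset",
                            name)
                continue
            cov = np.column_stack([np.ones(len(y)), x, g])
            cov[~mask] = 0.0  # rows outside the mask are never used
            prod = np.where(mask, x * g, 0.0)
            try:
                test = PartialSlopeTest(name, cov, prod, mask)
            except DegenerateInputError as exc:
                logger.info("pair %s skipped: %s", name, exc)
                continue
            t, p = test.observed(y)
            tests.append(test)
            a = anno.get(snp, {})
            results.append(InteractionResult(
                snp=snp, exposure=exp_name, n=m, t_stat=t, p_uncorrected=p,
                risk_allele=str(a.get("risk_allele", "")),
                gene=str(a.get("gene", "")),
            ))

    n_skipped = n_pairs - len(results)
    if n_pairs and n_skipped > 0.1 * n_pairs:
        logger.warning("%d of %d (SNP, exposure) pairs skipped", n_skipped, n_pairs)
    if not results:
        raise DegenerateInputError("no analyzable (SNP, exposure) pairs")

    perm = None
    if perm_config is not None:
        observed = {r.snp + ":" + r.exposure: r.p_uncorrected for r in results}
        outcome = y if perm_config.permute == "residual" else adjusted.z
        perm = minp_correction(outcome, tests, perm_config,
                               observed_p=observed, design=adjusted.design)
        for r in results:
            r.p_corrected = perm.p_corrected[r.snp + ":" + r.exposure]
    return results, perm
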