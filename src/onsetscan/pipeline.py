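"""End-to-end orchestration of the age-of-onset analysis.

Stage order follows the analysis design: load or simulate the cohort,
transform and adjust the outcome, run the exposure-wide scan with min-P
permutation correction, then the secondary analyses (dichotomized
contingency tables, bivariate exposures, exposure-pair associations,
atopy adjustment, sex/study stratified effects, and the SNP x exposure
interaction scan). By default the secondary stages analyze only exposures
that survive the corrected significance threshold, mirroring a
screen-then-characterize design; ``secondary_all`` forces all exposures
through.

Every stage writes a TSV into the output directory and the run closes with
a machine-readable ``summary.json``. With fixed seeds the outputs are
byte-identical across reruns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_io
from .association_scan import (
    atopy_adjusted_regression,
    correct_scan,
    descriptives,
    scan_exposures,
)
from .categorical_analysis import (
    bivariate_exposure_analysis,
    contingency_analysis,
    dichotomize_onset,
    pairwise_exposure_association,
)
from .cohort_io import DEFAULT_EXPOSURE_CATALOG, ExposureCatalog, load_cohort
from .exceptions import ConfigError, DegenerateInputError
from .modifier_analysis import (
    load_snp_catalog,
    snp_interaction_scan,
    stratified_interaction_test,
)
from .permutation_engine import PermutationConfig
from .synthetic_cohort import SimulationConfig, simulate_cohort
from .transforms import adjust_onset

logger = logging.getLogger(__name__)

SIGNIFICANCE_THRESHOLD = 0.05


@dataclass
class RunConfig:
    """One pipeline run: either three input paths or a simulation config."""

    out_dir: Path
    phenotype_path: Path | None = None
    exposure_path: Path | None = None
    genotype_path: Path | None = None
    simulation: SimulationConfig | None = None
    catalog: ExposureCatalog = field(
        default_factory=lambda: DEFAULT_EXPOSURE_CATALOG)
    snp_catalog_path: Path | None = None
    onset_cutpoint: float = 6.0
    n_perm: int = 10_000
    perm_seed: int = 0
    permute: str = "residual"
    secondary_all: bool = False
    precision: int = 6

    def __post_init__(self) -> None:
        has_paths = self.phenotype_path is not None
        has_sim = self.simulation is not None
        if has_paths == has_sim:
            raise ConfigError(
                "exactly one of input paths or a simulation config is required"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = None
        if "simulation" in raw:
            sim = SimulationConfig(**(raw.pop("simulation") or {}))
        catalog = DEFAULT_EXPOSURE_CATALOG
        if "catalog_path" in raw:
            catalog = ExposureCatalog.from_file(raw.pop("catalog_path"))
        paths = {k: Path(raw.pop(k)) for k in
                 ("phenotype_path", "exposure_path", "genotype_path")
                 if k in raw}
        return cls(out_dir=Path(raw.pop("out_dir", "onsetscan_out")),
                   simulation=sim, catalog=catalog, **paths, **raw)


def _perm_config(config: RunConfig) -> PermutationConfig:
    return PermutationConfig(n_perm=config.n_perm, seed=config.perm_seed,
                             permute=config.permute)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the summary dict written to summary.json."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- stage 1: cohort -------------------------------------------
    if config.simulation is not None:
        logger.info("stage simulate: n=%d seed=%d",
                    config.simulation.n_subjects, config.simulation.seed)
        cohort = simulate_cohort(config.simulation)
        cohort_io.write_cohort(cohort, out / "phenotype.tsv",
                               out / "exposures.tsv", out / "genotypes.tsv")
    else:
        logger.info("stage load: %s", config.phenotype_path)
        cohort = load_cohort(config.phenotype_path, config.exposure_path,
                             config.genotype_path, catalog=config.catalog)

    desc = descriptives(cohort, cutpoint=config.onset_cutpoint)

    # ---- stage 2: transform ----------------------------------------
    adjusted = adjust_onset(cohort)
    tdf = pd.DataFrame({
        "subject_id": adjusted.subject_ids,
        "z": adjusted.z,
        "residual": adjusted.residual,
    })
    cohort_io.write_results(tdf, out / "transformed.tsv", config.precision)

    # ---- stage 3: scan + min-P correction ---------------------------
    results = scan_exposures(cohort, adjusted=adjusted)
    if not results:
        raise DegenerateInputError("scan produced no analyzable exposures")
    correct_scan(cohort, results, _perm_config(config), adjusted=adjusted)
    cohort_io.write_results(results, out / "scan.tsv", config.precision)

    significant = [r for r in results
                   if r.p_corrected is not None
                   and r.p_corrected < SIGNIFICANCE_THRESHOLD]
    selected = results if config.secondary_all else significant
    selected_binary = [r for r in selected
                       if config.catalog[r.exposure].var_type == "binary"
                       if r.exposure in cohort.catalog.binary_names()]
    logger.info("scan: %d/%d exposures corrected-significant",
                len(significant), len(results))

    early = dichotomize_onset(cohort.onset_years, cutpoint=config.onset_cutpoint)

    # ---- stage 4: dichotomized single-exposure tables ---------------
    dichot = []
    for r in selected_binary:
        try:
            dichot.append(contingency_analysis(
                cohort.exposure(r.exposure), early,
                name_a=r.exposure, name_b="early_onset"))
        except DegenerateInputError as exc:
            logger.info("dichotomized %r skipped: %s", r.exposure, exc)
    if dichot:
        cohort_io.write_results(dichot, out / "dichotomized.tsv", config.precision)

    # ---- stage 5: bivariate exposure pairs --------------------------
    bivar = []
    for ra, rb in combinations(selected_binary, 2):
        try:
            bivar.append(bivariate_exposure_analysis(
                cohort.exposure(ra.exposure), cohort.exposure(rb.exposure),
                early, name_a=ra.exposure, name_b=rb.exposure))
        except DegenerateInputError as exc:
            logger.info("bivariate (%s, %s) skipped: %s",
                        ra.exposure, rb.exposure, exc)
    if bivar:
        cohort_io.write_results(bivar, out / "bivariate.tsv", config.precision)

    # ---- stage 6: exposure-exposure association matrix --------------
    pairs = pairwise_exposure_association(cohort.catalog, cohort)
    pair_records = [res.as_record() for res in pairs.values() if res is not None]
    if pair_records:
        cohort_io.write_results(pd.DataFrame.from_records(pair_records),
                                out / "exposure_pairs.tsv", config.precision)

    # ---- stage 7: atopy adjustment ----------------------------------
    atopy = cohort.atopy
    atopy_rows = []
    if np.isfinite(atopy).sum() >= 10:
        for r in selected:
            try:
                atopy_rows.append(atopy_adjusted_regression(
                    adjusted, cohort.exposure(r.exposure), atopy,
                    name=r.exposure))
            except DegenerateInputError as exc:
                logger.info("atopy-adjusted %r skipped: %s", r.exposure, exc)
    if atopy_rows:
        cohort_io.write_results(atopy_rows, out / "atopy_adjusted.tsv",
                                config.precision)

    # ---- stage 8: sex/study stratified effects ----------------------
    strat_rows = []
    for r in selected:
        x = cohort.exposure(r.exposure)
        for strat_name, strat in (("sex", cohort.sex), ("study", cohort.study)):
            try:
                strat_rows.append(stratified_interaction_test(
                    adjusted.z, x, strat, stratifier_name=strat_name,
                    exposure_name=r.exposure))
            except DegenerateInputError as exc:
                logger.info("stratified %s x %r skipped: %s",
                            strat_name, r.exposure, exc)
    if strat_rows:
        cohort_io.write_results(strat_rows, out / "stratified.tsv",
                                config.precision)

    # ---- stage 9: SNP x exposure interaction scan -------------------
    gxe_rows = []
    if cohort.genotypes is not None and selected:
        exp_frame = cohort.exposures[[r.exposure for r in selected]]
        try:
            gxe_rows, _ = snp_interaction_scan(
                adjusted, exp_frame, cohort.genotypes,
                perm_config=_perm_config(config),
                snp_catalog=load_snp_catalog(config.snp_catalog_path),
            )
            cohort_io.write_results(gxe_rows, out / "gxe.tsv", config.precision)
        except DegenerateInputError as exc:
            logger.info("G x E scan skipped: %s", exc)

    # ---- summary -----------------------------------------------------
    summary = {
        "n_subjects": cohort.n,
        "percent_female": round(desc.overall.percent_female, 2),
        "percent_early_onset": round(desc.overall.percent_early_onset, 2),
        "kruskal_p_onset_by_sex": desc.kruskal_p,
        "n_exposures_tested": len(results),
        "n_perm": config.n_perm,
        "significant_exposures": [
            {
                "exposure": r.exposure,
                "n": r.n,
                "t_stat": round(r.t_stat, 4),
                "p_uncorrected": r.p_uncorrected,
                "p_corrected": r.p_corrected,
                "dichotomized_or": next(
                    (round(d.odds_ratio, 4) for d in dichot
                     if d.name_a == r.exposure), None),
            }
            for r in significant
        ],
        "n_gxe_pairs_tested": len(gxe_rows),
        "min_gxe_p_corrected": (min(r.p_corrected for r in gxe_rows)
                                if gxe_rows and gxe_rows[0].p_corrected is not None
                                else None),
    }
    with (out / "summary.json").open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
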