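"""Cohort table input/output and validation.

The pipeline operates on three tab-separated tables sharing a ``subject_id``
key:

* ``phenotype.tsv`` — subject_id, onset_years, sex, study, atopy
* ``exposures.tsv`` — subject_id plus one column per catalogued exposure
* ``genotypes.tsv`` — subject_id plus one minor-allele dosage column per SNP

``load_cohort`` merges and validates them into a :class:`CohortTable`.
Missing values are written and read as ``NA`` (empty cells are also read as
missing). Subjects whose asthma began before age two are excluded at load,
because the exposure questionnaire covers the first two years of life and
exposures must precede onset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import CohortFormatError, DegenerateInputError

logger = logging.getLogger(__name__)

MISSING_TOKENS = ["", "NA"]
SEX_LEVELS = ("male", "female")
ATOPY_LEVELS = ("positive", "negative")
STUDY_LEVELS = (1, 2)

#: minimum admissible age of onset (years); earlier onsets are excluded so
#: that early-life exposures precede the disease.
MIN_ONSET_YEARS = 2.0


# ---------------------------------------------------------------------------
# Exposure catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExposureVar:
    """One questionnaire item about the first two years of life."""

    name: str
    var_type: str  # "binary" or "quantitative"
    study_coverage: str = "both"  # "both" or "study2_only"
    label: str = ""

    def __post_init__(self) -> None:
        if self.var_type not in ("binary", "quantitative"):
            raise CohortFormatError(f"unknown var_type {self.var_type!r} for {self.name}")
        if self.study_coverage not in ("both", "study2_only"):
            raise CohortFormatError(
                f"unknown study_coverage {self.study_coverage!r} for {self.name}"
            )


class ExposureCatalog:
    """Ordered collection of :class:`ExposureVar` with name lookup."""

    def __init__(self, items: Iterable[ExposureVar]):
        self._items = list(items)
        names = [v.name for v in self._items]
        if len(set(names)) != len(names):
            raise CohortFormatError("duplicate exposure names in catalog")
        self._by_name = {v.name: v for v in self._items}

    def __iter__(self):
        return iter(self._items)

    def __len__(self) -> int:
        return len(self._items)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> ExposureVar:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [v.name for v in self._items]

    def binary_names(self) -> list[str]:
        return [v.name for v in self._items if v.var_type == "binary"]

    def quantitative_names(self) -> list[str]:
        return [v.name for v in self._items if v.var_type == "quantitative"]

    def study2_only_names(self) -> list[str]:
        return [v.name for v in self._items if v.study_coverage == "study2_only"]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExposureCatalog":
        required = {"name", "var_type", "study_coverage"}
        missing = required - set(frame.columns)
        if missing:
            raise CohortFormatError(f"catalog missing columns: {sorted(missing)}")
        return cls(
            ExposureVar(
                name=str(r["name"]),
                var_type=str(r["var_type"]),
                study_coverage=str(r["study_coverage"]),
                label=str(r.get("label", "")),
            )
            for _, r in frame.iterrows()
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "ExposureCatalog":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))


#: The default catalog: 17 early-life exposure items, eight of which were
#: only asked in the second study wave (so Study-1 subjects are structurally
#: missing for them). Three items are quantitative, the rest binary.
DEFAULT_EXPOSURE_CATALOG = ExposureCatalog([
    ExposureVar("brick_house", "binary", "both", "Type of house (brick vs wood)"),
    ExposureVar("carpet", "binary", "both", "Carpet exposure at home"),
    ExposureVar("chest_illness", "binary", "both", "Serious chest illness"),
    ExposureVar("father_smoking_direct", "binary", "study2_only",
                "Direct exposure to father's smoking"),
    ExposureVar("father_smoker", "binary", "both", "Father a cigarette smoker"),
    ExposureVar("breastfed_under_6mo", "binary", "study2_only",
                "Breastfeeding as an infant (under 6 months of age)"),
    ExposureVar("house_location_city", "binary", "both",
                "Location of house (major city/town vs rural)"),
    ExposureVar("otitis_media", "binary", "study2_only", "Otitis media"),
    ExposureVar("breastfeeding_duration", "quantitative", "study2_only",
                "Duration of breastfeeding (months)"),
    ExposureVar("dog", "binary", "both", "Dog exposure"),
    ExposureVar("main_road_50m", "binary", "both",
                "House less than 50 m from a main road"),
    ExposureVar("mother_cigarettes_per_day", "quantitative", "study2_only",
                "Quantity of cigarettes smoked daily by mother"),
    ExposureVar("mother_smoking_direct", "binary", "study2_only",
                "Direct exposure to mother's smoking"),
    ExposureVar("cat", "binary", "both", "Cat exposure"),
    ExposureVar("mother_smoker_pregnancy", "binary", "study2_only",
                "Mother a cigarette smoker during pregnancy"),
    ExposureVar("father_cigarettes_per_day", "quantitative", "study2_only",
                "Quantity of cigarettes smoked daily by father"),
    ExposureVar("mother_smoker", "binary", "both", "Mother a cigarette smoker"),
])


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Validated per-subject phenotype, exposure and genotype data.

    All three frames are indexed by ``subject_id`` in identical order.
    Exposure and dosage values are floats with ``NaN`` for missing.
    """

    phenotypes: pd.DataFrame
    exposures: pd.DataFrame
    genotypes: pd.DataFrame | None
    catalog: ExposureCatalog = field(default_factory=lambda: DEFAULT_EXPOSURE_CATALOG)

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.phenotypes)

    @property
    def subject_ids(self) -> pd.Index:
        return self.phenotypes.index

    @property
    def onset_years(self) -> np.ndarray:
        return self.phenotypes["onset_years"].to_numpy(dtype=float)

    @property
    def sex(self) -> np.ndarray:
        return self.phenotypes["sex"].to_numpy()

    @property
    def study(self) -> np.ndarray:
        return self.phenotypes["study"].to_numpy(dtype=int)

    @property
    def atopy(self) -> np.ndarray:
        """Atopy coded 1.0 positive / 0.0 negative / NaN unknown."""
        s = self.phenotypes["atopy"]
        return s.map({"positive": 1.0, "negative": 0.0}).to_numpy(dtype=float)

    def exposure(self, name: str) -> np.ndarray:
        return self.exposures[name].to_numpy(dtype=float)

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        ph = self.phenotypes
        if ph.index.has_duplicates:
            dupes = ph.index[ph.index.duplicated()].unique().tolist()
            raise CohortFormatError(f"duplicate subject ids: {dupes[:5]}")
        onset = ph["onset_years"].to_numpy(dtype=float)
        if np.any(~np.isfinite(onset)):
            raise CohortFormatError("missing or non-finite onset_years in cohort")
        if np.any(onset < MIN_ONSET_YEARS):
            raise CohortFormatError(
                f"onset_years below {MIN_ONSET_YEARS} present; "
                "such subjects must be excluded at load"
            )
        bad_sex = set(ph["sex"].unique()) - set(SEX_LEVELS)
        if bad_sex:
            raise CohortFormatError(f"unknown sex levels: {sorted(bad_sex)}")
        bad_study = set(ph["study"].unique()) - set(STUDY_LEVELS)
        if bad_study:
            raise CohortFormatError(f"unknown study levels: {sorted(bad_study)}")
        atopy = ph["atopy"]
        bad_atopy = set(atopy.dropna().unique()) - set(ATOPY_LEVELS)
        if bad_atopy:
            raise CohortFormatError(f"unknown atopy levels: {sorted(bad_atopy)}")

        if not self.exposures.index.equals(ph.index):
            raise CohortFormatError("exposure table misaligned with phenotypes")
        for var in self.catalog:
            if var.name not in self.exposures.columns:
                raise CohortFormatError(f"exposure column {var.name!r} absent")
            col = self.exposures[var.name].to_numpy(dtype=float)
            obs = col[np.isfinite(col)]
            if var.var_type == "binary":
                if not np.all(np.isin(obs, (0.0, 1.0))):
                    raise CohortFormatError(
                        f"binary exposure {var.name!r} has non 0/1 values"
                    )
            else:
                if np.any(obs < 0):
                    raise CohortFormatError(
                        f"quantitative exposure {var.name!r} has negative values"
                    )

        if self.genotypes is not None:
            if not self.genotypes.index.equals(ph.index):
                raise CohortFormatError("genotype table misaligned with phenotypes")
            g = self.genotypes.to_numpy(dtype=float)
            obs = g[np.isfinite(g)]
            if not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
                raise CohortFormatError("dosages must be 0, 1, 2 or missing")

    # -- equality (used by round-trip tests) --------------------------
    def equals(self, other: "CohortTable") -> bool:
        if (self.genotypes is None) != (other.genotypes is None):
            return False
        ok = self.phenotypes.equals(other.phenotypes) and np.allclose(
            self.exposures.to_numpy(dtype=float),
            other.exposures.to_numpy(dtype=float),
            equal_nan=True,
        )
        if ok and self.genotypes is not None:
            ok = np.allclose(
                self.genotypes.to_numpy(dtype=float),
                other.genotypes.to_numpy(dtype=float),
                equal_nan=True,
            )
        return bool(ok)


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"subject_id": str},
        na_values=MISSING_TOKENS, keep_default_na=False,
    )


def load_cohort(
    phenotype_path: str | Path,
    exposure_path: str | Path,
    genotype_path: str | Path | None = None,
    catalog: ExposureCatalog = DEFAULT_EXPOSURE_CATALOG,
) -> CohortTable:
    """Read, merge and validate the cohort tables.

    Subjects with onset before age two (or a missing onset) are dropped and
    the exclusion count logged. Values recorded for a subject outside their
    study's questionnaire coverage are set to missing with a warning.
    Exposure columns not in the catalog are ignored with a warning.
    """
    ph = _read_tsv(phenotype_path)
    for col in ("subject_id", "onset_years", "sex", "study"):
        if col not in ph.columns:
            raise CohortFormatError(f"phenotype table missing column {col!r}")
    if "atopy" not in ph.columns:
        ph["atopy"] = np.nan

    onset = pd.to_numeric(ph["onset_years"], errors="coerce")
    bad = onset.isna() & ph["onset_years"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CohortFormatError(
            f"non-numeric onset_years at data row {row + 1}: "
            f"{ph['onset_years'].iloc[row]!r}"
        )
    ph["onset_years"] = onset.astype(float)
    keep = onset.notna() & (onset >= MIN_ONSET_YEARS)
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info(
            "excluded %d subject(s) with onset before age %g or missing onset",
            n_excluded, MIN_ONSET_YEARS,
        )
    ph = ph.loc[keep].copy()
    ph["study"] = pd.to_numeric(ph["study"], errors="raise").astype(int)
    ph = ph.set_index("subject_id")

    ex = _read_tsv(exposure_path)
    if "subject_id" not in ex.columns:
        raise CohortFormatError("exposure table missing column 'subject_id'")
    ex = ex.set_index("subject_id")
    unknown = [c for c in ex.columns if c not in catalog]
    if unknown:
        logger.warning("ignoring unknown exposure column(s): %s", unknown)
        ex = ex.drop(columns=unknown)
    for var in catalog:
        if var.name not in ex.columns:
            logger.warning("exposure column %r absent; treated as all-missing", var.name)
            ex[var.name] = np.nan
    ex = ex.reindex(ph.index)[catalog.names].astype(float)

    # structural coverage: study2-only items are missing for Study-1 subjects
    study1 = (ph["study"] == 1).to_numpy()
    for name in catalog.study2_only_names():
        col = ex[name].to_numpy(dtype=float)
        spurious = study1 & np.isfinite(col)
        if spurious.any():
            logger.warning(
                "exposure %r: %d Study-1 value(s) outside questionnaire "
                "coverage set to missing", name, int(spurious.sum()),
            )
            col[spurious] = np.nan
            ex[name] = col

    geno = None
    if genotype_path is not None:
        g = _read_tsv(genotype_path)
        if "subject_id" not in g.columns:
            raise CohortFormatError("genotype table missing column 'subject_id'")
        geno = g.set_index("subject_id").reindex(ph.index).astype(float)

    return CohortTable(phenotypes=ph, exposures=ex, genotypes=geno, catalog=catalog)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _fmt(value: object, precision: int) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        if np.isnan(value):
            return "NA"
        return f"{value:.{precision}g}"
    return str(value)


def write_results(results, path: str | Path, precision: int = 6) -> None:
    """Write a collection of result records as a TSV with a header.

    ``results`` may be a pandas DataFrame or a sequence of objects exposing
    ``as_record() -> dict``. Floats are rendered with ``precision``
    significant digits; missing values as ``NA``. An empty collection is an
    error — a silent empty file would mask an upstream failure.
    """
    if isinstance(results, pd.DataFrame):
        frame = results
    else:
        records = [r.as_record() for r in results]
        frame = pd.DataFrame.from_records(records)
    if frame.empty:
        raise DegenerateInputError(f"refusing to write empty results table to {path}")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(map(str, frame.columns)) + "\n")
        for _, row in frame.iterrows():
            fh.write("\t".join(_fmt(v, precision) for v in row) + "\n")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", na_values=MISSING_TOKENS, keep_default_na=False)


def write_cohort(
    cohort: CohortTable,
    phenotype_path: str | Path,
    exposure_path: str | Path,
    genotype_path: str | Path | None = None,
) -> None:
    """Write a cohort back to the three-table TSV layout read by ``load_cohort``."""
    ph = cohort.phenotypes.reset_index()
    with Path(phenotype_path).open("w") as fh:
        fh.write("subject_id\tonset_years\tsex\tstudy\tatopy\n")
        for _, r in ph.iterrows():
            atopy = r["atopy"] if isinstance(r["atopy"], str) else "NA"
            fh.write(f"{r['subject_id']}\t{r['onset_years']:g}\t{r['sex']}\t"
                     f"{int(r['study'])}\t{atopy}\n")

    def _write_matrix(frame: pd.DataFrame, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("subject_id\t" + "\t".join(frame.columns) + "\n")
            for sid, row in frame.iterrows():
                cells = ["NA" if not np.isfinite(v) else f"{v:g}" for v in row]
                fh.write(str(sid) + "\t" + "\t".join(cells) + "\n")

    _write_matrix(cohort.exposures, exposure_path)
    if genotype_path is not None and cohort.genotypes is not None:
        _write_matrix(cohort.genotypes, genotype_path)
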