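"""Twin-cohort data model, phenotype definitions and study filters.

A cohort is a flat table, one row per subject, carrying a pair identifier,
zygosity, demographics (sex, age, height), spirometric values and z-scores,
questionnaire flags and smoking history.  This module reads and writes that
table, applies the study's case definitions (fixed-ratio and
lower-limit-of-normal airflow obstruction, chronic bronchitis, clinical
COPD), performs the asthma exclusion, and assembles subjects into complete
twin pairs for the biometric models.
"""
from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger("biometwin.cohort")

# ---------------------------------------------------------------------------
# Column dictionary
# ---------------------------------------------------------------------------

ZYGOSITIES = ("MZ", "DZ_same_sex", "DZ_opposite_sex")
SEXES = ("female", "male")
SMOKING = ("current", "former", "never")

MANDATORY_COLUMNS = ("subject_id", "pair_id", "zygosity", "sex", "age")

NUMERIC_COLUMNS = (
    "age", "height", "fev1_z", "fvc_z", "ratio_z", "fev1_fvc_ratio",
    "pack_years", "bmi",
)
BOOLEAN_COLUMNS = (
    "asthma", "chronic_cough_sputum", "dyspnea", "cough", "nocturnal_symptoms",
)
CATEGORICAL_COLUMNS = {"zygosity": ZYGOSITIES, "sex": SEXES, "smoking": SMOKING}

KNOWN_COLUMNS = (
    ("subject_id", "pair_id", "zygosity", "sex", "smoking")
    + NUMERIC_COLUMNS + BOOLEAN_COLUMNS
)

#: covariates entering every mean/threshold model, in design-matrix order;
#: sex is coded female=0, male=1.
COVARIATES = ("sex", "age", "height")

_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n"}
_NA = {"", "na", "nan", "none", "null"}


@dataclass(frozen=True)
class Subject:
    """One questionnaire + spirometry record."""

    subject_id: str
    pair_id: str
    zygosity: str
    sex: str
    age: float
    height: float | None = None
    fev1_z: float | None = None
    fvc_z: float | None = None
    ratio_z: float | None = None
    fev1_fvc_ratio: float | None = None
    asthma: bool = False
    chronic_cough_sputum: bool = False
    dyspnea: bool = False
    cough: bool = False
    nocturnal_symptoms: bool = False
    smoking: str | None = None
    pack_years: float | None = None
    bmi: float | None = None

    def __post_init__(self) -> None:
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")


@dataclass(frozen=True)
class TwinPair:
    """Two subjects sharing a pair_id; member order is lexicographic by
    subject_id so pair-symmetric likelihoods are permutation-invariant."""

    pair_id: str
    zygosity: str
    first: Subject
    second: Subject
    complete: bool = True

    def __post_init__(self) -> None:
        if self.first.pair_id != self.second.pair_id:
            raise ValueError("pair members disagree on pair_id")
        if self.first.subject_id > self.second.subject_id:
            object.__setattr__(self, "first", self.second)
            object.__setattr__(self, "second", self.first)


# ---------------------------------------------------------------------------
# Phenotype criteria
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeCriterion:
    """A binary case definition.

    Airflow-obstruction (AO) criteria use either a fixed FEV1/FVC ratio
    cutoff (GOLD fixed ratio, < 0.70) or a lower-limit-of-normal z-score
    cutoff on the ratio (z < -1.96 for the 2.5th centile, z < -1.645 for
    the 5th).  COPD criteria additionally require respiratory symptoms.
    All cutoffs are strict; a value on the boundary is a non-case.
    """

    name: str
    ratio_cutoff: float | None = None
    z_cutoff: float | None = None
    requires_symptoms: bool = False

    def __post_init__(self) -> None:
        if self.name.endswith("_AO") or self.name.endswith("_COPD"):
            if (self.ratio_cutoff is None) == (self.z_cutoff is None):
                raise ValueError(
                    "exactly one of ratio_cutoff / z_cutoff must be set"
                )


CRITERIA: dict[str, PhenotypeCriterion] = {
    "FR_AO": PhenotypeCriterion("FR_AO", ratio_cutoff=0.70),
    "LLN25_AO": PhenotypeCriterion("LLN25_AO", z_cutoff=-1.96),
    "LLN5_AO": PhenotypeCriterion("LLN5_AO", z_cutoff=-1.645),
    "FR_COPD": PhenotypeCriterion("FR_COPD", ratio_cutoff=0.70,
                                  requires_symptoms=True),
    "LLN25_COPD": PhenotypeCriterion("LLN25_COPD", z_cutoff=-1.96,
                                     requires_symptoms=True),
    "LLN5_COPD": PhenotypeCriterion("LLN5_COPD", z_cutoff=-1.645,
                                    requires_symptoms=True),
    "CHRONIC_BRONCHITIS": PhenotypeCriterion("CHRONIC_BRONCHITIS"),
    "RESP_SYMPTOMS": PhenotypeCriterion("RESP_SYMPTOMS"),
}


# ---------------------------------------------------------------------------
# Cohort container and I/O
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A subject table plus a per-field missingness report.

    ``df`` holds one row per subject with the columns of the published
    data dictionary; unknown input columns are preserved untouched.
    """

    df: pd.DataFrame
    missingness: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "Cohort":
        return Cohort(self.df.copy(), dict(self.missingness),
                      list(self.warnings))


def _parse_bool(raw: pd.Series, col: str, warnings: list[str]) -> pd.Series:
    s = raw.astype("string").str.strip().str.lower()
    out = pd.Series(pd.NA, index=raw.index, dtype="boolean")
    out[s.isin(_TRUE)] = True
    out[s.isin(_FALSE)] = False
    bad = ~(s.isin(_TRUE) | s.isin(_FALSE) | s.isin(_NA) | s.isna())
    if bad.any():
        warnings.append(f"{col}: {int(bad.sum())} unparseable value(s) set missing")
    return out


def read_cohort(path, dialect: str | None = None) -> Cohort:
    """Read a cohort table from CSV/TSV.

    Parameters
    ----------
    path : str or file-like
        Delimited text, one row per subject, header row required.
    dialect : {"csv", "tsv", None}
        Field delimiter; ``None`` sniffs from the header line.

    Raises
    ------
    ValueError
        If a mandatory column (subject_id, pair_id, zygosity, sex, age)
        is absent.  Unparseable numeric cells produce a warning and a
        missing value, never an exception.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    if dialect == "tsv":
        sep = "\t"
    elif dialect == "csv":
        sep = ","
    else:
        header = text.splitlines()[0] if text else ""
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype="string",
                     keep_default_na=False)

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")

    warnings: list[str] = []
    missingness: dict[str, int] = {}
    out = pd.DataFrame(index=df.index)
    out["subject_id"] = df["subject_id"].astype(str)
    out["pair_id"] = df["pair_id"].astype(str)

    for col, allowed in CATEGORICAL_COLUMNS.items():
        if col not in df.columns:
            continue
        s = df[col].astype("string").str.strip()
        s = s.mask(s.str.lower().isin(_NA))
        bad = s.notna() & ~s.isin(allowed)
        if bad.any():
            warnings.append(
                f"{col}: {int(bad.sum())} value(s) outside {allowed} set missing")
            s = s.mask(bad)
        out[col] = s
        missingness[col] = int(s.isna().sum())

    for col in NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        raw = df[col].astype("string").str.strip()
        raw = raw.mask(raw.str.lower().isin(_NA))
        num = pd.to_numeric(raw, errors="coerce")
        bad = raw.notna() & num.isna()
        if bad.any():
            warnings.append(f"{col}: {int(bad.sum())} unparseable cell(s) set missing")
        # re-parse valid cells with float(): pandas' fast parser is not
        # correctly rounded, which would break write/read exactness
        ok = (raw.notna() & num.notna()).to_numpy()
        precise = np.full(len(raw), np.nan)
        precise[ok] = [float(v) for v in raw.to_numpy()[ok]]
        out[col] = precise
        missingness[col] = int(num.isna().sum())

    for col in BOOLEAN_COLUMNS:
        if col not in df.columns:
            continue
        b = _parse_bool(df[col], col, warnings)
        missingness[col] = int(b.isna().sum())
        out[col] = b

    for col in df.columns:          # unknown columns preserved verbatim
        if col not in KNOWN_COLUMNS:
            out[col] = df[col]

    dup = out.duplicated("subject_id")
    if dup.any():
        warnings.append(f"{int(dup.sum())} duplicate subject_id row(s) kept")
    # two subjects sharing pair_id must share zygosity
    if "zygosity" in out.columns:
        nz = out.groupby("pair_id")["zygosity"].nunique(dropna=True)
        if (nz > 1).any():
            raise ValueError(
                f"{int((nz > 1).sum())} pair(s) with inconsistent zygosity")
    for w in warnings:
        logger.warning(w)
    return Cohort(out, missingness, warnings)


def write_cohort(cohort: Cohort, path, dialect: str = "csv") -> None:
    """Write the cohort table; missing values become empty cells."""
    sep = "\t" if dialect == "tsv" else ","
    df = cohort.df.copy()
    for col in BOOLEAN_COLUMNS:
        if col in df.columns:
            df[col] = df[col].map({True: "true", False: "false"})
    # %.17g guarantees byte-exact float round-trips through read_cohort
    df.to_csv(path, sep=sep, index=False, na_rep="", float_format="%.17g",
              quoting=csv.QUOTE_MINIMAL)


# ---------------------------------------------------------------------------
# Filters and classification
# ---------------------------------------------------------------------------

def exclude_asthma(cohort: Cohort) -> Cohort:
    """Drop subjects with self-reported asthma.

    The co-twin of an excluded subject stays in the cohort as a singleton.
    A missing asthma flag counts as "no".  Idempotent.
    """
    if "asthma" not in cohort.df.columns:
        logger.info("exclude_asthma: no asthma column, cohort unchanged")
        return cohort.copy()
    flag = cohort.df["asthma"].fillna(False).astype(bool)
    kept = cohort.df.loc[~flag].reset_index(drop=True)
    logger.info("exclude_asthma: %d in, %d excluded, %d remain",
                len(cohort.df), int(flag.sum()), len(kept))
    return Cohort(kept, dict(cohort.missingness), list(cohort.warnings))


def _flag(row, name) -> bool:
    v = row.get(name) if isinstance(row, Mapping) else getattr(row, name, None)
    if isinstance(row, pd.Series):
        v = row.get(name)
    return bool(v) if v is not None and v is not pd.NA and v == v else False


def classify_respiratory_symptoms(subject) -> bool:
    """True iff the subject reports dyspnea, cough or nocturnal awakening
    due to breathlessness; missing flags count as "no"."""
    return (_flag(subject, "dyspnea") or _flag(subject, "cough")
            or _flag(subject, "nocturnal_symptoms"))


def classify_case(subject, criterion: PhenotypeCriterion | str):
    """Apply a case definition to one subject.

    Returns True / False, or ``None`` when the required spirometric
    measurement is missing.  All cutoffs are strict ``<``: a ratio of
    exactly 0.70 or a z-score of exactly -1.96 is a non-case.
    """
    if isinstance(criterion, str):
        try:
            criterion = CRITERIA[criterion]
        except KeyError:
            raise ValueError(f"unknown criterion {criterion!r}") from None
    name = criterion.name
    if name == "RESP_SYMPTOMS":
        return classify_respiratory_symptoms(subject)
    if name == "CHRONIC_BRONCHITIS":
        return _flag(subject, "chronic_cough_sputum")

    def _num(attr):
        v = (subject.get(attr) if isinstance(subject, (Mapping, pd.Series))
             else getattr(subject, attr, None))
        if v is None or v is pd.NA or (isinstance(v, float) and np.isnan(v)):
            return None
        return float(v)

    if criterion.ratio_cutoff is not None:
        val = _num("fev1_fvc_ratio")
        cut = criterion.ratio_cutoff
    else:
        val = _num("ratio_z")
        cut = criterion.z_cutoff
    if val is None:
        return None
    obstructed = val < cut
    if criterion.requires_symptoms:
        return obstructed and classify_respiratory_symptoms(subject)
    return obstructed


def classify_cohort(cohort: Cohort,
                    criteria: Iterable[str] = tuple(CRITERIA)) -> Cohort:
    """Append one nullable-boolean classification column per criterion."""
    out = cohort.copy()
    records = out.df.to_dict("records")
    for crit in criteria:
        values = [classify_case(row, crit) for row in records]
        out.df[crit] = pd.array(values, dtype="boolean")
    return out


# ---------------------------------------------------------------------------
# Internal spirometric standardization
# ---------------------------------------------------------------------------

def standardize_internal_z(cohort: Cohort, trait: str,
                           z_col: str | None = None) -> Cohort:
    """Internally standardize a raw spirometric value to a z-score.

    The z-score is the residual of an OLS regression of the trait on sex,
    age and height, divided by the residual standard deviation, so it has
    mean 0 and SD 1 on the fitting set.  This is a documented stand-in for
    external reference equations, which are accepted via the ``*_z``
    columns when available.
    """
    df = cohort.df
    sex_num = df["sex"].map({"female": 0.0, "male": 1.0}).astype(float)
    X = pd.DataFrame({"sex": sex_num, "age": df["age"].astype(float),
                      "height": df["height"].astype(float)})
    y = df[trait].astype(float)
    ok = X.notna().all(axis=1) & y.notna()
    if int(ok.sum()) < 50:
        raise ValueError(
            f"standardize_internal_z needs >=50 complete subjects, "
            f"have {int(ok.sum())}")
    Xd = sm.add_constant(X.loc[ok].to_numpy())
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError("degenerate design matrix (collinear covariates)")
    fit = sm.OLS(y.loc[ok].to_numpy(), Xd).fit()
    resid = fit.resid
    sd = float(np.std(resid))
    y_sd = float(np.std(y.loc[ok].to_numpy()))
    if sd <= 1e-10 * max(y_sd, 1.0):    # trait is exactly linear in covariates
        z = np.zeros(len(resid))
    else:
        z = resid / sd
    out = cohort.copy()
    col = z_col or f"{trait}_internal_z"
    out.df[col] = np.nan
    out.df.loc[ok, col] = z
    return out


# ---------------------------------------------------------------------------
# Pair assembly
# ---------------------------------------------------------------------------

@dataclass
class PairData:
    """Complete twin pairs arranged for likelihood evaluation.

    ``y`` is (n, 2) trait values, ``x`` is (n, 2, p) covariates in
    :data:`COVARIATES` order (sex coded female=0/male=1), ``zygosity``
    the per-pair zygosity string.  Member order within a pair is
    lexicographic by subject_id.
    """

    y: np.ndarray
    x: np.ndarray
    zygosity: np.ndarray
    pair_ids: np.ndarray
    covariate_names: tuple[str, ...] = COVARIATES

    def __len__(self) -> int:
        return len(self.y)

    @property
    def is_mz(self) -> np.ndarray:
        return self.zygosity == "MZ"

    def subset(self, mask: np.ndarray) -> "PairData":
        return PairData(self.y[mask], self.x[mask], self.zygosity[mask],
                        self.pair_ids[mask], self.covariate_names)


def _covariate_matrix(df: pd.DataFrame,
                      covariates: Sequence[str]) -> np.ndarray:
    cols = []
    for c in covariates:
        if c == "sex":
            cols.append(df["sex"].map({"female": 0.0, "male": 1.0})
                        .astype(float).to_numpy())
        else:
            cols.append(df[c].astype(float).to_numpy())
    if not cols:
        return np.zeros((len(df), 0))
    return np.column_stack(cols)


def assemble_pairs(cohort: Cohort, trait: str,
                   covariates: Sequence[str] = COVARIATES,
                   ) -> tuple[PairData, pd.DataFrame]:
    """Split a cohort into complete pairs and singletons for one trait.

    A pair is complete iff both members have a non-missing trait value and
    non-missing covariates.  Every subject lands in exactly one of the two
    outputs.  More than two subjects sharing a pair_id is an error.
    """
    df = cohort.df.sort_values(["pair_id", "subject_id"]).reset_index(drop=True)
    sizes = df.groupby("pair_id")["subject_id"].size()
    if (sizes > 2).any():
        bad = sizes[sizes > 2].index[0]
        raise ValueError(f"pair_id {bad!r} has {int(sizes[bad])} subjects")

    val = df[trait]
    cov = _covariate_matrix(df, covariates)
    usable = val.notna().to_numpy() & ~np.isnan(cov).any(axis=1)

    ok = pd.Series(usable, index=df.index)
    grp = df.assign(_ok=ok.values).groupby("pair_id")
    pair_ok = grp["_ok"].transform("all") & (grp["subject_id"].transform("size") == 2)
    paired = df.loc[pair_ok.values]
    singles = df.loc[~pair_ok.values].reset_index(drop=True)

    if len(paired):
        n = len(paired) // 2
        y = paired[trait].astype(float).to_numpy().reshape(n, 2)
        x = _covariate_matrix(paired, covariates).reshape(n, 2, len(covariates))
        zyg = paired["zygosity"].to_numpy()[::2]
        pid = paired["pair_id"].to_numpy()[::2]
    else:
        p = len(covariates)
        y = np.zeros((0, 2))
        x = np.zeros((0, 2, p))
        zyg = np.array([], dtype=object)
        pid = np.array([], dtype=object)
    return PairData(y, x, zyg, pid, tuple(covariates)), singles


def singleton_arrays(singletons: pd.DataFrame, trait: str,
                     covariates: Sequence[str] = COVARIATES,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Trait values and covariates of singletons usable in a univariate
    likelihood term (rows with missing trait or covariates dropped)."""
    val = singletons[trait]
    cov = _covariate_matrix(singletons, covariates)
    ok = val.notna().to_numpy() & ~np.isnan(cov).any(axis=1)
    return val.astype(float).to_numpy()[ok], cov[ok]


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

def summarize_cohort(cohort: Cohort,
                     groups: Mapping[str, pd.Series] | None = None
                     ) -> pd.DataFrame:
    """Descriptive table: n, sex/smoking/BMI-class percentages and means
    (SD) of age, BMI, pack-years and z-scores, overall and per subgroup."""
    df = cohort.df

    def _col(sub: pd.DataFrame) -> dict:
        d: dict[str, float] = {"n": len(sub)}
        if len(sub) == 0:
            return d
        if "sex" in sub:
            d["male_pct"] = 100.0 * (sub["sex"] == "male").mean()
        if "smoking" in sub:
            for s in SMOKING:
                d[f"smoking_{s}_pct"] = 100.0 * (sub["smoking"] == s).mean()
        if "bmi" in sub:
            bmi = sub["bmi"].astype(float)
            d["bmi_mean"] = bmi.mean()
            d["bmi_sd"] = bmi.std()
            cls = pd.cut(bmi, [0, 18.5, 25, 30, np.inf],
                         labels=["underweight", "normal", "overweight", "obese"])
            for lab in cls.cat.categories:
                d[f"bmi_{lab}_pct"] = 100.0 * (cls == lab).mean()
        for col in ("age", "pack_years", "fev1_z", "fvc_z", "ratio_z"):
            if col in sub:
                v = sub[col].astype(float)
                d[f"{col}_mean"] = v.mean()
                d[f"{col}_sd"] = v.std()
        return d

    table = {"overall": _col(df)}
    if groups:
        for name, mask in groups.items():
            table[name] = _col(df.loc[mask.fillna(False).astype(bool)])
    else:
        for crit in ("FR_AO", "LLN25_AO", "LLN5_AO"):
            if crit in df.columns:
                table[crit] = _col(df.loc[df[crit].fillna(False).astype(bool)])
    return pd.DataFrame(table)
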