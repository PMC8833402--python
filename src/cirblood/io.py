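"""Tabular input/output for the pipeline.

The sole on-disk dialect is TSV (tab-separated, UTF-8, '.' decimal).
Expression matrices are stored genes x samples with the gene symbol in the
first column; sample metadata is one row per blood sample.  Numeric values
are written with 6 significant digits, which round-trips bit-identically at
that precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VALID_DOSES = (30, 33, 36)
VALID_TIMEPOINTS = (0, 1, 2, 3)
VALID_SEX = ("male", "female")
VALID_GRADE_INITIAL = ("II", "III", "IV")
VALID_GRADE_RERT = ("III", "IV")

#: metadata columns every table must provide
REQUIRED_META_COLUMNS = (
    "sample_id", "patient_id", "timepoint", "sex", "age",
    "grade_initial", "grade_rert", "dose_total", "n_fractions",
    "survival_months", "event",
)

#: fields constant within a patient across that patient's samples
PATIENT_LEVEL_COLUMNS = (
    "sex", "age", "grade_initial", "grade_rert", "dose_total",
    "n_fractions", "survival_months", "event",
)


class FormatError(ValueError):
    """Malformed input file (structure, duplicates, non-numeric cells)."""


class ValidationError(ValueError):
    """Well-formed file whose values violate the domain invariants."""


@dataclass
class ExpressionMatrix:
    """Dense genes x samples matrix of log2 intensities.

    ``data`` is a pandas DataFrame indexed by gene symbol with sample IDs
    as columns.  Identifiers must be unique on both axes.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors -------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene identifiers: {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dup}")
        if self.data.size and not np.issubdtype(self.data.to_numpy().dtype,
                                                np.number):
            raise FormatError("expression values must be numeric")

    def require_finite(self) -> None:
        vals = self.data.to_numpy()
        if not np.all(np.isfinite(vals)):
            g, s = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite value at gene {self.data.index[g]!r}, "
                f"sample {self.data.columns[s]!r}")

    def copy_with(self, values: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(pd.DataFrame(
            values, index=self.data.index, columns=self.data.columns))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column = gene symbols)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty expression file: {path}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"expression file has no sample columns: {path}")
    # locate the first non-numeric cell for a precise error message
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise FormatError(
                f"non-numeric value at gene {gene!r}, sample {col!r}")
        df[col] = coerced
    return ExpressionMatrix(df)


def write_expression_matrix(x: ExpressionMatrix, path) -> None:
    x.data.to_csv(path, sep="\t", float_format="%.6g", index_label="gene_id")


def read_sample_metadata(path, permissive_dose: bool = False) -> pd.DataFrame:
    """Read and validate a sample metadata TSV.

    Returns one row per sample.  ``permissive_dose`` relaxes the
    30/33/36 GyRBE dose domain (the trial's three dose levels).
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty metadata file: {path}") from exc
    validate_sample_metadata(df, permissive_dose=permissive_dose)
    return df


def validate_sample_metadata(df: pd.DataFrame,
                             permissive_dose: bool = False) -> None:
    missing = [c for c in REQUIRED_META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    if df.empty:
        raise ValidationError("metadata table is empty")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample_id: {dup}")
    if df.duplicated(subset=["patient_id", "timepoint"]).any():
        dup = df.loc[df.duplicated(subset=["patient_id", "timepoint"]),
                     ["patient_id", "timepoint"]]
        raise ValidationError(
            f"duplicate (patient_id, timepoint) pairs:\n{dup}")
    bad_tp = ~df["timepoint"].isin(VALID_TIMEPOINTS)
    if bad_tp.any():
        raise ValidationError(
            f"timepoint outside 0-3: {sorted(df.loc[bad_tp, 'timepoint'].unique())}")
    if not permissive_dose:
        bad_dose = ~df["dose_total"].isin(VALID_DOSES)
        if bad_dose.any():
            raise ValidationError(
                f"dose_total not in {VALID_DOSES}: "
                f"{sorted(df.loc[bad_dose, 'dose_total'].unique())}")
    bad_sex = ~df["sex"].isin(VALID_SEX)
    if bad_sex.any():
        raise ValidationError(
            f"sex must be one of {VALID_SEX}: "
            f"{sorted(df.loc[bad_sex, 'sex'].unique())}")
    if (~df["grade_initial"].isin(VALID_GRADE_INITIAL)).any():
        raise ValidationError(f"grade_initial must be in {VALID_GRADE_INITIAL}")
    if (~df["grade_rert"].isin(VALID_GRADE_RERT)).any():
        raise ValidationError(f"grade_rert must be in {VALID_GRADE_RERT}")
    if (df["n_fractions"] * 3 != df["dose_total"]).any() and not permissive_dose:
        raise ValidationError("n_fractions x 3 GyRBE must equal dose_total")
    if (df["survival_months"] < 0).any():
        raise ValidationError("survival_months must be nonnegative")
    if (~df["event"].isin((0, 1))).any():
        raise ValidationError("event must be 0 or 1")
    # patient-level fields must not vary within a patient
    for col in PATIENT_LEVEL_COLUMNS:
        nun = df.groupby("patient_id")[col].nunique()
        incons = nun[nun > 1]
        if len(incons):
            raise ValidationError(
                f"patient-level field {col!r} differs across samples of "
                f"patient(s) {list(incons.index)}")


def patient_table(meta: pd.DataFrame) -> pd.DataFrame:
    """Collapse sample metadata to one row per patient."""
    cols = ["patient_id", *PATIENT_LEVEL_COLUMNS]
    return (meta[cols].drop_duplicates("patient_id")
            .reset_index(drop=True))


def align(x: ExpressionMatrix, meta: pd.DataFrame,
          allow_partial: bool = False) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Cross-check matrix sample IDs against metadata.

    Mismatches are a hard error unless ``allow_partial`` is set, in which
    case the intersection is used (and logged).
    """
    mat_ids = set(x.sample_ids)
    meta_ids = set(meta["sample_id"])
    if mat_ids == meta_ids:
        ordered = [s for s in x.sample_ids]
    elif allow_partial:
        common = mat_ids & meta_ids
        if not common:
            raise ValidationError("no overlapping samples between matrix and metadata")
        log.warning("partial overlap: using %d of %d matrix / %d metadata samples",
                    len(common), len(mat_ids), len(meta_ids))
        ordered = [s for s in x.sample_ids if s in common]
    else:
        raise ValidationError(
            f"sample sets differ (matrix-only: {sorted(mat_ids - meta_ids)[:5]}, "
            f"metadata-only: {sorted(meta_ids - mat_ids)[:5]}); "
            "pass allow_partial to use the intersection")
    x2 = ExpressionMatrix(x.data[ordered])
    meta2 = (meta.set_index("sample_id").loc[ordered].reset_index())
    return x2, meta2


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

def _round_half_up(v: float) -> int:
    return int(math.floor(v + 0.5))


def _age_band(age: float) -> str:
    if age < 40:
        return "<40"
    if age < 50:
        return "40-49"
    return ">=50"


def summarize_cohort(meta: pd.DataFrame) -> pd.DataFrame:
    """Patient-level cohort characteristics table.

    One row per category level of sex, age band (<40, 40-49, >=50),
    initial grade, reRT grade and total dose, with counts and
    integer-rounded (half-up) percentages of patients, plus the number of
    patients with all four timepoints.
    """
    if meta is None or len(meta) == 0:
        raise ValidationError("cannot summarize empty metadata")
    pats = patient_table(meta)
    n = len(pats)
    rows: list[tuple[str, str, int, int]] = []

    def add(variable: str, series: pd.Series, order: list[str]) -> None:
        counts = series.value_counts()
        for level in order:
            c = int(counts.get(level, 0))
            if c == 0:
                continue
            rows.append((variable, str(level), c, _round_half_up(100 * c / n)))

    rows.append(("all", "all", n, 100))
    add("sex", pats["sex"], ["male", "female"])
    add("age_band", pats["age"].map(_age_band), ["<40", "40-49", ">=50"])
    add("grade_initial", pats["grade_initial"], list(VALID_GRADE_INITIAL))
    add("grade_rert", pats["grade_rert"], list(VALID_GRADE_RERT))
    trans = (pats.loc[pats["grade_initial"] == "II"]
             .apply(lambda r: f"II->{r['grade_rert']}", axis=1))
    if len(trans):
        add("grade_transition", trans, ["II->III", "II->IV"])
    add("dose_total", pats["dose_total"].astype(int).astype(str),
        [str(d) for d in VALID_DOSES])
    n_complete = int((meta.groupby("patient_id")["timepoint"].nunique() == 4).sum())
    rows.append(("timepoints", "all_four", n_complete,
                 _round_half_up(100 * n_complete / n)))
    return pd.DataFrame(rows, columns=["variable", "level", "n", "pct"])


# ---------------------------------------------------------------------------
# packaged fixtures and result writing
# ---------------------------------------------------------------------------

def load_table1_cohort() -> pd.DataFrame:
    """Synthetic per-patient cohort table matching the published marginals.

    The study reports only aggregate patient characteristics (sex 9/5,
    age bands 2/6/6, initial grade 5/2/7, reRT grade 5/9, doses 5/6/3,
    nine patients with all four timepoints); this packaged table is a
    synthetic reconstruction consistent with every printed marginal, used
    for cohort-summary tests.  Survival times are plausible placeholders.
    """
    ref = resources.files("cirblood").joinpath("data/table1_cohort.tsv")
    with resources.as_file(ref) as p:
        return read_sample_metadata(p)


def write_result_table(df: pd.DataFrame, path, config=None,
                       seed=None, extra: str = "") -> None:
    """Write a result TSV with a header comment recording config hash + seed."""
    chash = config.hash() if config is not None else "none"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# cirblood config={chash} seed={seed}"
                 + (f" {extra}" if extra else "") + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_result_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
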