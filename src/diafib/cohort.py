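"""Patient records, cohort I/O, eligibility filtering, and summaries.

A cohort is an ordered collection of validated :class:`PatientRecord`
objects read from (or written to) delimited text with a header row.
Column names in external files may differ from the canonical field names;
a *dialect* mapping (canonical name -> file column) bridges the two.

Units follow the conventions of the liver-fibrosis literature: platelets
in 10^9/L, transaminases in IU/L, albumin in g/dL, triglycerides and
cholesterol in mg/dL, glucose as fasting mg/dL, HbA1c in percent,
alcohol intake in grams per week.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields
from typing import Iterable, Optional

import pandas as pd

from .errors import ConfigError, MissingDataError, RowError

logger = logging.getLogger(__name__)

SEXES = ("male", "female")

#: Weekly ethanol limits (grams) above which MASLD is excluded. Inclusion
#: requires intake strictly below the limit, so intake equal to the limit
#: is excluded.
ALCOHOL_LIMIT_G_PER_WEEK = {"male": 210.0, "female": 140.0}

#: Diagnostic thresholds for type 2 diabetes.
T2DM_GLUCOSE_MG_DL = 126.0  # fasting glucose at or above labels T2DM
T2DM_HBA1C_PCT = 6.5        # HbA1c strictly above labels T2DM

#: Plausible platelet range in 10^9/L; values outside suggest raw counts
#: per microlitre were supplied instead.
_PLT_SANITY = (5.0, 1000.0)


@dataclass
class PatientRecord:
    """One subject's demographics, laboratory values, flags, and biopsy stage."""

    id: str
    age: float
    sex: str
    bmi: float
    platelets: float
    ast: float
    alt: float
    albumin: float
    triglycerides: float
    hdl: float
    glucose: float
    hypertension: bool
    on_diabetes_meds: bool
    alcohol_g_per_week: float
    waist: Optional[float] = None
    ldl: Optional[float] = None
    hba1c: Optional[float] = None
    viral_hepatitis: bool = False
    other_liver_disease: bool = False
    steatogenic_meds: bool = False
    fibrosis_stage: Optional[int] = None

    def validate(self) -> None:
        """Raise :class:`RowError` on the first violated invariant."""
        for name in ("age", "bmi", "platelets", "ast", "alt"):
            v = getattr(self, name)
            if not v > 0:
                raise RowError(self.id, name, f"must be > 0, got {v!r}")
        if self.sex not in SEXES:
            raise RowError(self.id, "sex", f"must be one of {SEXES}, got {self.sex!r}")
        if self.alcohol_g_per_week < 0:
            raise RowError(self.id, "alcohol_g_per_week", "must be >= 0")
        if self.fibrosis_stage is not None and self.fibrosis_stage not in (0, 1, 2, 3, 4):
            raise RowError(self.id, "fibrosis_stage",
                           f"must be in 0..4, got {self.fibrosis_stage!r}")
        if not _PLT_SANITY[0] <= self.platelets <= _PLT_SANITY[1]:
            warnings.warn(
                f"record {self.id!r}: platelets={self.platelets} outside "
                f"{_PLT_SANITY} 10^9/L; check units (raw counts per uL?)",
                stacklevel=2,
            )

    @property
    def ast_alt_ratio(self) -> float:
        return self.ast / self.alt

    @property
    def advanced_fibrosis(self) -> bool:
        """Biopsy stage F3 (bridging fibrosis) or F4 (cirrhosis)."""
        if self.fibrosis_stage is None:
            raise MissingDataError("fibrosis_stage absent", [self.id])
        return self.fibrosis_stage >= 3


@dataclass
class Cohort:
    """Ordered collection of patient records with unique ids."""

    records: list[PatientRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ConfigError(f"duplicate record ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, keep: Iterable[PatientRecord], provenance: str | None = None) -> "Cohort":
        return Cohort(list(keep), provenance if provenance is not None else self.provenance)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = {f.name: getattr(r, f.name) for f in fields(PatientRecord)}
            rows.append(d)
        df = pd.DataFrame(rows, columns=[f.name for f in fields(PatientRecord)])
        return df


@dataclass
class CohortSummary:
    """Stage tallies and percentage breakdowns for one cohort."""

    n_total: int
    stage_counts: dict[int, int]
    n_advanced: int
    pct_advanced: Optional[float]
    pct_by_stage: dict[int, Optional[float]]


_BOOL_FIELDS = {"hypertension", "on_diabetes_meds", "viral_hepatitis",
                "other_liver_disease", "steatogenic_meds"}
_OPTIONAL_FIELDS = {"waist", "ldl", "hba1c", "fibrosis_stage"}
_REQUIRED_COLUMNS = [f.name for f in fields(PatientRecord)
                     if f.name not in _OPTIONAL_FIELDS]

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n", ""}


def _parse_bool(raw, rid, name) -> bool:
    if isinstance(raw, bool):
        return raw
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE or s == "nan":
        return False
    raise RowError(rid, name, f"unparseable boolean {raw!r}")


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and pd.isna(v)) or (
        isinstance(v, str) and v.strip() == "")


def read_cohort(path, dialect: dict[str, str] | None = None, *,
                sep: str | None = None, provenance: str | None = None) -> Cohort:
    """Read a delimited-text cohort file into a validated :class:`Cohort`.

    Parameters
    ----------
    path
        Delimited text file with a header row. Comma-separated by default;
        tab-separated files are detected automatically (or force via *sep*).
    dialect
        Optional mapping from canonical field names to the file's column
        names. Unmapped canonical names are looked up verbatim.
    sep
        Explicit field separator; when ``None`` the separator is sniffed
        from the header line (comma vs tab).

    Rows violating record invariants are rejected with a row-level
    :class:`~diafib.errors.RowError`; a missing required column raises
    :class:`~diafib.errors.ConfigError`. Extra unmapped columns are
    ignored with a logged note.
    """
    dialect = dict(dialect or {})
    if sep is None:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") > header.count(",") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    colmap = {name: dialect.get(name, name) for name in
              (f.name for f in fields(PatientRecord))}
    missing = [colmap[n] for n in _REQUIRED_COLUMNS if colmap[n] not in df.columns]
    if missing:
        raise ConfigError(f"missing required columns: {missing}")
    used = set(colmap.values()) & set(df.columns)
    extras = [c for c in df.columns if c not in used]
    if extras:
        logger.info("ignoring %d unmapped columns: %s", len(extras), extras)

    records = []
    for _, row in df.iterrows():
        rid = str(row[colmap["id"]])
        kw = {"id": rid}
        for f in fields(PatientRecord):
            name = f.name
            if name == "id":
                continue
            col = colmap[name]
            raw = row[col] if col in df.columns else None
            if name in _BOOL_FIELDS:
                kw[name] = _parse_bool(raw, rid, name)
            elif name == "sex":
                kw[name] = str(raw).strip().lower()
            elif name == "fibrosis_stage":
                if _is_missing(raw):
                    kw[name] = None
                else:
                    try:
                        kw[name] = int(float(raw))
                    except ValueError:
                        raise RowError(rid, name, f"unparseable value {raw!r}") from None
            else:
                if _is_missing(raw):
                    if name in _OPTIONAL_FIELDS:
                        kw[name] = None
                        continue
                    raise RowError(rid, name, "required value missing")
                try:
                    kw[name] = float(raw)
                except ValueError:
                    raise RowError(rid, name, f"unparseable value {raw!r}") from None
        rec = PatientRecord(**kw)
        rec.validate()
        records.append(rec)
    return Cohort(records, provenance if provenance is not None else str(path))


def write_cohort(cohort: Cohort, path, *, sep: str = ",") -> None:
    """Write a cohort as delimited text; inverse of :func:`read_cohort`."""
    df = cohort.to_dataframe()
    for b in _BOOL_FIELDS:
        df[b] = df[b].map(lambda v: "1" if v else "0")
    df["fibrosis_stage"] = df["fibrosis_stage"].map(
        lambda v: "" if v is None or pd.isna(v) else str(int(v)))
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def label_t2dm(r: PatientRecord) -> bool:
    """Type 2 diabetes label: medication use, fasting glucose >= 126 mg/dL,
    or HbA1c strictly above 6.5%.

    Records without HbA1c are labelled on the remaining two criteria and
    noted in the log.
    """
    if _is_missing(r.glucose):
        raise MissingDataError("glucose required for T2DM labeling", [r.id])
    if r.on_diabetes_meds or r.glucose >= T2DM_GLUCOSE_MG_DL:
        return True
    if r.hba1c is None:
        logger.debug("record %r: HbA1c absent, labeled on glucose/medication only", r.id)
        return False
    return r.hba1c > T2DM_HBA1C_PCT


@dataclass
class Exclusion:
    record_id: str
    rule: str


def apply_eligibility(cohort: Cohort) -> tuple[Cohort, list[Exclusion]]:
    """Apply MASLD eligibility rules, returning the retained subcohort and
    an exclusion log.

    Excluded: ethanol intake at or above 210 g/week (men) or 140 g/week
    (women) — inclusion requires intake strictly below the limit — viral
    hepatitis, other chronic liver disease, or steatogenic medication use.
    Order is preserved; the operation is idempotent.
    """
    kept, log = [], []
    for r in cohort:
        limit = ALCOHOL_LIMIT_G_PER_WEEK[r.sex]
        if r.alcohol_g_per_week >= limit:
            log.append(Exclusion(r.id, f"alcohol >= {limit:g} g/week"))
        elif r.viral_hepatitis:
            log.append(Exclusion(r.id, "viral hepatitis"))
        elif r.other_liver_disease:
            log.append(Exclusion(r.id, "other chronic liver disease"))
        elif r.steatogenic_meds:
            log.append(Exclusion(r.id, "steatogenic medication"))
        else:
            kept.append(r)
    return cohort.subset(kept), log


def write_exclusion_log(log: list[Exclusion], path, *, sep: str = ",") -> None:
    pd.DataFrame([{"id": e.record_id, "rule": e.rule} for e in log],
                 columns=["id", "rule"]).to_csv(path, sep=sep, index=False)


def summarize(cohort: Cohort) -> CohortSummary:
    """Per-stage counts and percentages; advanced fibrosis is stage >= 3.

    Percentages are rounded to one decimal; for an empty cohort they are
    reported absent rather than 0/0.
    """
    missing = [r.id for r in cohort if r.fibrosis_stage is None]
    if missing:
        raise MissingDataError("fibrosis_stage absent", missing)
    n = len(cohort)
    counts = {s: 0 for s in range(5)}
    for r in cohort:
        counts[r.fibrosis_stage] += 1
    n_adv = counts[3] + counts[4]
    if n == 0:
        return CohortSummary(0, counts, 0, None, {s: None for s in counts})
    return CohortSummary(
        n_total=n,
        stage_counts=counts,
        n_advanced=n_adv,
        pct_advanced=round(100.0 * n_adv / n, 1),
        pct_by_stage={s: round(100.0 * c / n, 1) for s, c in counts.items()},
    )


def advanced_labels(cohort: Cohort) -> list[bool]:
    """Outcome vector (stage >= 3) for every record; fails on missing stages."""
    missing = [r.id for r in cohort if r.fibrosis_stage is None]
    if missing:
        raise MissingDataError("fibrosis_stage absent", missing)
    return [r.fibrosis_stage >= 3 for r in cohort]
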