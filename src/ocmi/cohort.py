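"""Patient cohort container and CSV I/O.

A cohort is a table with one row per patient: demographics (age, menopausal
status), the two intraoperative binary findings (ascites, tumour laterality),
binary flags for the 15 surveyed metastatic sites, and an arbitrary panel of
numeric medical examination indicators (MEIs) such as CA-125 or blood counts.

The canonical CSV schema is::

    patient_id, age, menopause, ascites, laterality,
    site_BLA, ..., site_URE,      # 15 columns, one per canonical site code
    <MEI name>, ...               # one column per indicator; blank = missing

All binary fields are coded 0/1 (menopause: 0 pre / 1 post; ascites: 0 not
detected / 1 detected; laterality: 0 unilateral / 1 bilateral).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical codes for the 15 intraoperatively surveyed metastatic sites:
#: bladder, diaphragm, greater omentum, internal genital organ, large
#: intestine, liver, lymph node, mesentery, paracolic sulci, peritoneum,
#: rectouterine fossa, small intestine, spleen, stomach, ureter.
SITE_CODES: tuple[str, ...] = (
    "BLA", "DIA", "GO", "IGO", "LI", "LIV", "LYM", "MES",
    "PS", "PER", "RF", "SI", "SPL", "STO", "URE",
)

_SITE_PREFIX = "site_"
_FIXED_COLUMNS = ("patient_id", "age", "menopause", "ascites", "laterality")


class CohortError(ValueError):
    """Raised for schema or invariant violations in cohort data."""


@dataclass
class PatientRecord:
    """One patient: demographics, intraoperative findings, MEIs, site flags.

    ``mei_values`` maps indicator name to a finite float, or ``None`` when
    the value is missing from the record.  ``site_flags`` maps each of the
    15 canonical site codes to 0/1.
    """

    patient_id: str
    age: float
    menopause: int
    ascites: int
    laterality: int
    mei_values: dict[str, float | None] = field(default_factory=dict)
    site_flags: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if not (isinstance(self.age, (int, float)) and math.isfinite(self.age) and self.age > 0):
            raise CohortError(f"patient {self.patient_id!r}: age must be a positive number, got {self.age!r}")
        for name in ("menopause", "ascites", "laterality"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise CohortError(f"patient {self.patient_id!r}: {name} must be 0 or 1, got {v!r}")
        if set(self.site_flags) != set(SITE_CODES):
            raise CohortError(
                f"patient {self.patient_id!r}: site_flags must contain exactly the "
                f"15 canonical codes; got {sorted(self.site_flags)}"
            )
        for code, flag in self.site_flags.items():
            if flag not in (0, 1):
                raise CohortError(f"patient {self.patient_id!r}: site flag {code} must be 0 or 1, got {flag!r}")
        for name, value in self.mei_values.items():
            if value is not None and not math.isfinite(value):
                raise CohortError(f"patient {self.patient_id!r}: MEI {name!r} is not finite: {value!r}")


@dataclass
class CohortDataset:
    """Ordered collection of :class:`PatientRecord` sharing one MEI catalog."""

    records: list[PatientRecord]
    mei_catalog: list[str]
    site_catalog: tuple[str, ...] = SITE_CODES
    label: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def validate(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate patient_ids in cohort: {dup}")
        catalog = set(self.mei_catalog)
        for r in self.records:
            r.validate()
            if set(r.mei_values) != catalog:
                raise CohortError(
                    f"patient {r.patient_id!r}: MEI keys {sorted(r.mei_values)} "
                    f"differ from cohort catalog {sorted(catalog)}"
                )

    # -- columnar views -------------------------------------------------

    def site_matrix(self) -> pd.DataFrame:
        """15-column 0/1 DataFrame indexed by patient_id."""
        data = {c: [r.site_flags[c] for r in self.records] for c in self.site_catalog}
        return pd.DataFrame(data, index=[r.patient_id for r in self.records], dtype=int)

    def mei_frame(self) -> pd.DataFrame:
        """MEI values as a float DataFrame (missing -> NaN), patient_id index."""
        data = {
            m: [np.nan if r.mei_values[m] is None else r.mei_values[m] for r in self.records]
            for m in self.mei_catalog
        }
        return pd.DataFrame(data, index=[r.patient_id for r in self.records], dtype=float)

    def site_counts(self) -> np.ndarray:
        return np.array([count_metastatic_sites(r) for r in self.records], dtype=int)

    def column(self, name: str) -> np.ndarray:
        """One of age/menopause/ascites/laterality as an array."""
        return np.array([getattr(r, name) for r in self.records], dtype=float)

    def subset(self, indices) -> "CohortDataset":
        """New cohort containing ``records[i]`` for i in indices (records shared)."""
        return CohortDataset(
            records=[self.records[int(i)] for i in indices],
            mei_catalog=list(self.mei_catalog),
            site_catalog=self.site_catalog,
            label=self.label,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row: dict = {
                "patient_id": r.patient_id,
                "age": r.age,
                "menopause": r.menopause,
                "ascites": r.ascites,
                "laterality": r.laterality,
            }
            for code in self.site_catalog:
                row[_SITE_PREFIX + code] = r.site_flags[code]
            for m in self.mei_catalog:
                v = r.mei_values[m]
                row[m] = np.nan if v is None else v
            rows.append(row)
        columns = (
            list(_FIXED_COLUMNS)
            + [_SITE_PREFIX + c for c in self.site_catalog]
            + list(self.mei_catalog)
        )
        return pd.DataFrame(rows, columns=columns)


@dataclass
class CohortSchema:
    """Maps arbitrary CSV column names onto the canonical cohort fields.

    ``site_columns`` maps canonical site code -> column name in the file;
    ``mei_columns`` lists the MEI columns (``None`` means: every column not
    otherwise claimed is an MEI).
    """

    patient_id: str = "patient_id"
    age: str = "age"
    menopause: str = "menopause"
    ascites: str = "ascites"
    laterality: str = "laterality"
    site_columns: dict[str, str] | None = None
    mei_columns: list[str] | None = None

    def resolved_site_columns(self) -> dict[str, str]:
        if self.site_columns is not None:
            return dict(self.site_columns)
        return {c: _SITE_PREFIX + c for c in SITE_CODES}


def _parse_binary(value, row_label: str, column: str) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise CohortError(f"row {row_label}: column {column!r} is not numeric: {value!r}") from None
    if f not in (0.0, 1.0):
        raise CohortError(f"row {row_label}: column {column!r} must be 0 or 1, got {value!r}")
    return int(f)


def load_cohort(path, schema: CohortSchema | None = None, label: str = "") -> CohortDataset:
    """Read a cohort CSV, validating every row against the type invariants.

    Rows violating an invariant raise :class:`CohortError` naming the
    offending row (1-based, excluding the header) and column.  Empty MEI
    cells load as missing values.
    """
    schema = schema or CohortSchema()
    df = pd.read_csv(path, dtype={schema.patient_id: str}, float_precision="round_trip")
    site_cols = schema.resolved_site_columns()
    mandatory = [schema.patient_id, schema.age, schema.menopause, schema.ascites, schema.laterality]
    missing = [c for c in mandatory + list(site_cols.values()) if c not in df.columns]
    if missing:
        raise CohortError(f"cohort file {path} lacks mandatory columns: {missing}")

    if schema.mei_columns is not None:
        mei_cols = list(schema.mei_columns)
        absent = [c for c in mei_cols if c not in df.columns]
        if absent:
            raise CohortError(f"cohort file {path} lacks MEI columns: {absent}")
    else:
        claimed = set(mandatory) | set(site_cols.values())
        mei_cols = [c for c in df.columns if c not in claimed]

    records: list[PatientRecord] = []
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        row_label = str(pos)
        record = PatientRecord(
            patient_id=str(row[schema.patient_id]),
            age=float(row[schema.age]),
            menopause=_parse_binary(row[schema.menopause], row_label, schema.menopause),
            ascites=_parse_binary(row[schema.ascites], row_label, schema.ascites),
            laterality=_parse_binary(row[schema.laterality], row_label, schema.laterality),
            mei_values={
                m: (None if pd.isna(row[m]) else float(row[m])) for m in mei_cols
            },
            site_flags={
                code: _parse_binary(row[col], row_label, col) for code, col in site_cols.items()
            },
        )
        try:
            record.validate()
        except CohortError as exc:
            raise CohortError(f"row {row_label}: {exc}") from None
        records.append(record)

    cohort = CohortDataset(records=records, mei_catalog=mei_cols, label=label)
    cohort.validate()
    return cohort


def write_cohort(cohort: CohortDataset, path) -> None:
    """Write the canonical CSV; ``load_cohort`` of the output reproduces
    the cohort exactly (floats serialised at full round-trip precision)."""
    df = cohort.to_frame()
    # shortest decimal that round-trips each float exactly
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def count_metastatic_sites(record: PatientRecord) -> int:
    """Number of the 15 surveyed sites with metastasis (0..15)."""
    return int(sum(record.site_flags[c] for c in SITE_CODES))


def label_multi_organ(site_count: int, threshold: int = 3) -> int:
    """1 if the patient has multi-organ metastasis: strictly more than
    ``threshold`` (default 3) of the 15 sites positive."""
    if site_count < 0:
        raise ValueError(f"site_count must be non-negative, got {site_count}")
    return int(site_count > threshold)
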