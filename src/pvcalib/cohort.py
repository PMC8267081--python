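"""Examinee/cohort data model and delimited-table I/O.

A cohort is a flat one-row-per-examinee table: an opaque ``examinee_id``, a
``group`` label, one column per instrument on its native scale (raw score,
age-corrected scaled score, or T-score, per the instrument registry), and
optional demographics.  Simulated cohorts additionally carry the latent
credibility status the generator drew for each examinee.

Scores are stored as floats; instruments whose native scale is integer-valued
enforce integrality at validation time.  Missing data are permitted at the
record level — downstream composites decide their own completeness policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd
import yaml

from .errors import CohortSchemaError, ScoreParseError, ScoreRangeError

GROUPS = ("clinical", "student", "custom")
LATENT_STATUSES = ("credible", "noncredible")

ID_COL = "examinee_id"
GROUP_COL = "group"
STATUS_COL = "latent_status"
DEMOGRAPHIC_COLS = ("age", "education", "sex")


@dataclass(frozen=True)
class InstrumentMeta:
    """Scale metadata for one instrument.

    ``scale_kind`` is ``raw``, ``ACSS`` (age-corrected scaled score,
    normative mean 10 / SD 3), ``T`` (normative mean 50 / SD 10) or
    ``seconds``.  ``higher_is_better`` gives the ability direction of the
    scale; ``integer`` marks scales that only take whole-number values.
    """

    name: str
    scale_kind: str
    min: float
    max: float
    higher_is_better: bool
    integer: bool = True

    def __post_init__(self) -> None:
        if not self.min < self.max:
            raise ValueError(f"{self.name}: min must be < max")

    def validate(self, value: float, *, row: str = "?") -> None:
        if not (self.min <= value <= self.max):
            raise ScoreRangeError(
                row, self.name, value,
                f"outside declared range [{self.min}, {self.max}]",
            )
        if self.integer and not float(value).is_integer():
            raise ScoreRangeError(
                row, self.name, value, "scale is integer-valued"
            )


@lru_cache(maxsize=1)
def _builtin_registry() -> tuple[InstrumentMeta, ...]:
    text = (resources.files("pvcalib") / "config" / "instruments.yaml").read_text()
    raw = yaml.safe_load(text)
    return tuple(InstrumentMeta(**entry) for entry in raw["instruments"])


def default_registry() -> dict[str, InstrumentMeta]:
    """The instrument registry shipped with the package, keyed by name."""
    return {meta.name: meta for meta in _builtin_registry()}


def load_registry(path: str | Path) -> dict[str, InstrumentMeta]:
    """Load an instrument registry from a YAML/JSON file."""
    raw = yaml.safe_load(Path(path).read_text())
    return {m["name"]: InstrumentMeta(**m) for m in raw["instruments"]}


@dataclass
class ExamineeRecord:
    """One examinee: id, group, native-scale scores, optional metadata.

    ``scores`` holds only observed values; a missing score is an absent key.
    ``latent_status`` is populated only for simulated records.
    """

    examinee_id: str
    group: str
    scores: dict[str, float] = field(default_factory=dict)
    latent_status: str | None = None
    demographics: dict | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortSchemaError(
                f"unknown group {self.group!r} (expected one of {GROUPS})"
            )
        if self.latent_status is not None and self.latent_status not in LATENT_STATUSES:
            raise CohortSchemaError(
                f"unknown latent_status {self.latent_status!r}"
            )

    def score(self, instrument: str) -> float | None:
        return self.scores.get(instrument)


@dataclass
class CohortTable:
    """An ordered collection of :class:`ExamineeRecord` plus its registry.

    ``attrs`` carries free-form provenance (e.g. the simulator's clamping
    diagnostics); it does not round-trip through CSV.
    """

    records: list[ExamineeRecord]
    registry: dict[str, InstrumentMeta] = field(default_factory=default_registry)
    attrs: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ExamineeRecord]:
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.examinee_id for r in self.records]

    def scores(self, instrument: str) -> pd.Series:
        """Scores for one instrument as a float Series indexed by examinee id
        (NaN where missing)."""
        return pd.Series(
            [r.scores.get(instrument, math.nan) for r in self.records],
            index=self.ids, name=instrument, dtype=float,
        )

    def latent_status(self) -> pd.Series:
        return pd.Series(
            [r.latent_status for r in self.records], index=self.ids,
            name=STATUS_COL, dtype=object,
        )

    def subset(self, mask) -> "CohortTable":
        """Records for which ``mask`` (a bool per record, aligned by order or
        an id-indexed Series) is True."""
        if isinstance(mask, pd.Series):
            mask = [bool(mask.get(i, False)) for i in self.ids]
        kept = [r for r, m in zip(self.records, mask) if m]
        return CohortTable(kept, self.registry)

    def by_group(self) -> dict[str, "CohortTable"]:
        out: dict[str, CohortTable] = {}
        for g in dict.fromkeys(r.group for r in self.records):
            out[g] = CohortTable(
                [r for r in self.records if r.group == g], self.registry
            )
        return out

    def instruments(self) -> list[str]:
        """Instrument columns present in at least one record, registry order
        first, then unknown columns sorted."""
        present: set[str] = set()
        for r in self.records:
            present.update(r.scores)
        known = [n for n in self.registry if n in present]
        unknown = sorted(present - set(self.registry))
        return known + unknown

    def to_frame(self) -> pd.DataFrame:
        """Flat DataFrame view (one row per examinee)."""
        cols = self._columns()
        rows = [_record_to_row(r, cols) for r in self.records]
        return pd.DataFrame(rows, columns=cols)

    def _columns(self) -> list[str]:
        cols = [ID_COL, GROUP_COL]
        if any(r.latent_status is not None for r in self.records):
            cols.append(STATUS_COL)
        demo = [
            d for d in DEMOGRAPHIC_COLS
            if any(r.demographics and d in r.demographics for r in self.records)
        ]
        cols.extend(demo)
        cols.extend(self.instruments())
        return cols


def _record_to_row(rec: ExamineeRecord, cols: list[str]) -> dict:
    row: dict = {}
    for c in cols:
        if c == ID_COL:
            row[c] = rec.examinee_id
        elif c == GROUP_COL:
            row[c] = rec.group
        elif c == STATUS_COL:
            row[c] = rec.latent_status
        elif c in DEMOGRAPHIC_COLS:
            row[c] = (rec.demographics or {}).get(c)
        else:
            row[c] = rec.scores.get(c)
    return row


def _parse_number(cell: str, row: str, column: str) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ScoreParseError(row, column, cell) from None


def read_cohort(
    path: str | Path,
    registry: Mapping[str, InstrumentMeta] | None = None,
) -> CohortTable:
    """Read a cohort CSV, validating scores against the instrument registry.

    The file must have a header row with ``examinee_id`` and ``group``
    columns.  Empty cells become missing scores.  Columns not in the registry
    (e.g. self-report questionnaires) are carried through unvalidated.

    Raises
    ------
    CohortSchemaError
        Mandatory column missing or unknown group label.
    ScoreParseError
        Non-numeric cell in a score column (names row and column).
    ScoreRangeError
        Value outside the instrument's declared range.
    """
    registry = dict(registry) if registry is not None else default_registry()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in (ID_COL, GROUP_COL):
        if col not in df.columns:
            raise CohortSchemaError(f"mandatory column {col!r} missing")
    score_cols = [
        c for c in df.columns
        if c not in (ID_COL, GROUP_COL, STATUS_COL) and c not in DEMOGRAPHIC_COLS
    ]
    records = []
    for _, row in df.iterrows():
        rid = row[ID_COL]
        scores: dict[str, float] = {}
        for c in score_cols:
            cell = row[c].strip()
            if cell == "":
                continue
            value = _parse_number(cell, rid, c)
            meta = registry.get(c)
            if meta is not None:
                meta.validate(value, row=rid)
            scores[c] = value
        demo: dict = {}
        for d in DEMOGRAPHIC_COLS:
            if d in df.columns and row[d].strip() != "":
                demo[d] = row[d] if d == "sex" else _parse_number(row[d], rid, d)
        status = None
        if STATUS_COL in df.columns and row[STATUS_COL].strip() != "":
            status = row[STATUS_COL].strip()
        records.append(
            ExamineeRecord(
                examinee_id=rid,
                group=row[GROUP_COL].strip(),
                scores=scores,
                latent_status=status,
                demographics=demo or None,
            )
        )
    return CohortTable(records, registry)


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, str):
        return value
    v = float(value)
    if math.isnan(v):
        return ""
    if v.is_integer():
        return str(int(v))
    return repr(v)


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort table as UTF-8 CSV with a deterministic column order.

    Missing values are encoded as empty cells.  ``read_cohort(write_cohort(T))``
    reproduces ``T`` field-by-field.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty cohort table")
    df = table.to_frame()
    out = df.map(_format_cell)
    out.to_csv(path, index=False)
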