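"""Multi-cutoff ordinal recoding and composite scoring.

Validity composites (the EI-5 family) recode each constituent validity
indicator onto a four-point ordinal scale — 0 passes the most liberal
published cutoff, 3 fails the most conservative — and sum the five codes,
giving a 0–15 composite.  A total of at most 1 is an overall Pass, 2–3 is
Borderline (excluded from dichotomous analyses), and 4 or more is a Fail.

The visual-perceptual ability composite (VPA-3) uses the same machinery with
five normative bands per component (0 = Impaired … 4 = Very Superior,
2 = Average) and no Pass/Fail banding: it is a 0–12 ability scale.

The band tables ship as YAML configuration (``config/composites.yaml``) and
are the single source of truth; :func:`list_builtin_specs` parses that file.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .cohort import CohortTable, ExamineeRecord
from .errors import ConfigError, UnmappableScoreError

PASS, BORDERLINE, FAIL, NA = "Pass", "Borderline", "Fail", "NA"


@dataclass(frozen=True)
class Band:
    """One closed interval -> code mapping; ``None`` bounds are open ends."""

    code: int
    min: float | None
    max: float | None

    def contains(self, value: float) -> bool:
        lo = -math.inf if self.min is None else self.min
        hi = math.inf if self.max is None else self.max
        return lo <= value <= hi


@dataclass(frozen=True)
class OrdinalRecodeRule:
    """A per-instrument multi-cutoff band table.

    ``below_floor_code`` handles published tables whose lowest band does not
    reach the instrument floor: scores below every band extrapolate to that
    code (with a warning) instead of raising.
    """

    instrument: str
    bands: tuple[Band, ...]
    below_floor_code: int | None = None

    def __post_init__(self) -> None:
        codes = sorted(b.code for b in self.bands)
        if codes != list(range(len(codes))):
            raise ConfigError(
                f"{self.instrument}: band codes must be contiguous from 0, got {codes}"
            )

    @property
    def max_code(self) -> int:
        return max(b.code for b in self.bands)

    @property
    def floor(self) -> float:
        """Smallest finite lower bound over all bands (-inf if a band is
        open below)."""
        los = [-math.inf if b.min is None else b.min for b in self.bands]
        return min(los)


def recode_component(raw: float | None, rule: OrdinalRecodeRule) -> int | None:
    """Map a raw score to its ordinal code under ``rule``.

    Missing input (None/NaN) returns ``None``.  A score in a gap between
    bands raises :class:`UnmappableScoreError`, except below-floor scores on
    rules that declare ``below_floor_code``.
    """
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    matches = [b.code for b in rule.bands if b.contains(raw)]
    if len(matches) > 1:
        raise ConfigError(
            f"{rule.instrument}: bands overlap at {raw} (codes {matches})"
        )
    if matches:
        return matches[0]
    if rule.below_floor_code is not None and raw < rule.floor:
        warnings.warn(
            f"{rule.instrument}: score {raw} lies below the lowest published "
            f"band; extrapolating to code {rule.below_floor_code}",
            stacklevel=2,
        )
        return rule.below_floor_code
    raise UnmappableScoreError(rule.instrument, raw)


@dataclass(frozen=True)
class BandThresholds:
    """EI-5 overall banding: Pass <= pass_max, Fail >= fail_min, Borderline
    in between."""

    pass_max: int = 1
    fail_min: int = 4

    def band(self, value: int) -> str:
        if value <= self.pass_max:
            return PASS
        if value >= self.fail_min:
            return FAIL
        return BORDERLINE


@dataclass(frozen=True)
class CompositeSpec:
    """A named composite: component recoding rules plus banding/completeness
    policy.

    ``completeness`` is ``require_all`` (canonical: any missing component
    yields an incomplete result) or ``min_k`` (non-canonical: sum the scored
    components when at least ``min_k`` are present).
    """

    name: str
    components: tuple[OrdinalRecodeRule, ...]
    band_thresholds: BandThresholds | None = None
    completeness: str = "require_all"
    min_k: int | None = None

    def __post_init__(self) -> None:
        if self.completeness not in ("require_all", "min_k"):
            raise ConfigError(f"unknown completeness policy {self.completeness!r}")
        if self.completeness == "min_k" and not self.min_k:
            raise ConfigError("min_k policy requires min_k")

    @property
    def value_range(self) -> tuple[int, int]:
        return (0, sum(r.max_code for r in self.components))


@dataclass(frozen=True)
class CompositeResult:
    """Composite value, number of scored components, and band.

    ``value`` is None (band NA) when the completeness policy is unmet —
    never a silent zero.  Ability composites carry ``band=None``.
    """

    value: int | None
    n_components_scored: int
    band: str | None


def score_composite(
    record: ExamineeRecord | Mapping[str, float], spec: CompositeSpec
) -> CompositeResult:
    """Sum the recoded components of ``record`` under ``spec``."""
    scores = record.scores if isinstance(record, ExamineeRecord) else record
    codes = [
        recode_component(scores.get(rule.instrument), rule)
        for rule in spec.components
    ]
    scored = [c for c in codes if c is not None]
    n = len(scored)
    if spec.completeness == "require_all":
        complete = n == len(spec.components)
    else:
        complete = n >= (spec.min_k or 0)
    if not complete:
        return CompositeResult(None, n, NA if spec.band_thresholds else None)
    value = sum(scored)
    band = spec.band_thresholds.band(value) if spec.band_thresholds else None
    return CompositeResult(value, n, band)


def score_cohort(cohort: CohortTable, spec: CompositeSpec) -> pd.Series:
    """Per-examinee :class:`CompositeResult` Series indexed by examinee id."""
    return pd.Series(
        [score_composite(r, spec) for r in cohort.records],
        index=cohort.ids, name=spec.name, dtype=object,
    )


def _parse_spec(name: str, raw: dict) -> CompositeSpec:
    components = tuple(
        OrdinalRecodeRule(
            instrument=c["instrument"],
            bands=tuple(Band(b["code"], b["min"], b["max"]) for b in c["bands"]),
            below_floor_code=c.get("below_floor_code"),
        )
        for c in raw["components"]
    )
    thresholds = None
    bt = raw.get("band_thresholds")
    if bt:
        thresholds = BandThresholds(pass_max=bt["pass_max"], fail_min=bt["fail_min"])
    return CompositeSpec(
        name=name,
        components=components,
        band_thresholds=thresholds,
        completeness=raw.get("completeness", "require_all"),
        min_k=raw.get("min_k"),
    )


def load_composite_specs(path: str | Path) -> dict[str, CompositeSpec]:
    """Parse a composite-configuration YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    return {name: _parse_spec(name, spec) for name, spec in raw["composites"].items()}


@lru_cache(maxsize=1)
def _builtin_specs() -> dict[str, CompositeSpec]:
    text = (resources.files("pvcalib") / "config" / "composites.yaml").read_text()
    raw = yaml.safe_load(text)
    return {name: _parse_spec(name, spec) for name, spec in raw["composites"].items()}


def list_builtin_specs() -> dict[str, CompositeSpec]:
    """The shipped composite specs (EI5_MEM, EI5_PSP, VPA3).

    The returned specs are immutable; the dict itself is a fresh copy.
    """
    return dict(_builtin_specs())


def component_base_rates(cohort: CohortTable, spec: CompositeSpec) -> pd.DataFrame:
    """Per-component percentage of scoreable records at each ordinal code.

    One row per component instrument; code columns 0..K-1 plus ``n_scored``.
    Percentages sum to 100 within rounding.  A component absent from every
    record yields a NaN row with ``n_scored`` 0, not an exception.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    max_code = max(r.max_code for r in spec.components)
    rows = {}
    for rule in spec.components:
        codes = [
            recode_component(rec.scores.get(rule.instrument), rule)
            for rec in cohort.records
        ]
        scored = [c for c in codes if c is not None]
        n = len(scored)
        row = {}
        for k in range(max_code + 1):
            if k > rule.max_code or n == 0:
                row[k] = math.nan
            else:
                row[k] = 100.0 * sum(c == k for c in scored) / n
        row["n_scored"] = n
        rows[rule.instrument] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "instrument"
    return df
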