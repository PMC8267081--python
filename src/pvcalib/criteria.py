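"""Pass/Fail validity outcomes from instrument scores.

Covers the free-standing PVT rules (TOMM Trial 1, Word Choice Test with its
dual accuracy/time-to-completion cutoff), generic threshold rules used for
embedded-validity cutoff sweeps, the combined two-trial recognition rule,
below-chance detection on the forced-choice trial, and the ability-criterion
dichotomizations used when the recognition trials are evaluated as ability
measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .cohort import ExamineeRecord
from .errors import ConfigError, ScoreRangeError
from .recoding import CompositeSpec, list_builtin_specs, score_composite

PASS, FAIL, NA = "Pass", "Fail", "NA"

FAIL_IF_LE = "fail_if_le"
FAIL_IF_GE = "fail_if_ge"


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class ValidityRuleSet:
    """Free-standing PVT cutoffs.

    ``tomm1_fail_max`` has no canonical default: it must be supplied (the
    example configuration ships an illustrative placeholder).  The Word
    Choice Test fails on *either* low accuracy or slow completion.
    ``rcft_cutoffs`` is the sweep grid for the recognition-trial EVIs
    (fail iff score <= cutoff); ``chance_threshold`` is the expected
    forced-choice score under random responding.
    """

    tomm1_fail_max: int
    wct_acc_fail_max: int = 47
    wct_t2c_fail_min_s: float = 156.0
    rcft_cutoffs: tuple[int, ...] = (15, 16, 17, 18)
    chance_threshold: int = 12

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ValidityRuleSet":
        raw = yaml.safe_load(Path(path).read_text())
        try:
            return cls(
                tomm1_fail_max=raw["tomm1_fail_max"],
                wct_acc_fail_max=raw.get("wct_acc_fail_max", 47),
                wct_t2c_fail_min_s=raw.get("wct_t2c_fail_min_s", 156),
                rcft_cutoffs=tuple(raw.get("rcft_cutoffs", (15, 16, 17, 18))),
                chance_threshold=raw.get("chance_threshold", 12),
            )
        except KeyError as exc:
            raise ConfigError(f"validity rules file missing key {exc}") from None


@dataclass(frozen=True)
class ValidityOutcome:
    """A named Pass/Fail/NA decision; NA iff a required score is missing."""

    rule_id: str
    decision: str


def wct_outcome(
    accuracy: float | None, t2c: float | None, rules: ValidityRuleSet
) -> ValidityOutcome:
    """Word Choice Test decision: Fail iff accuracy <= the accuracy cutoff
    OR time-to-completion >= the time cutoff; NA only when both inputs are
    missing."""
    if not _missing(t2c) and t2c < 0:
        raise ScoreRangeError("?", "wct_t2c_s", t2c, "negative time")
    if _missing(accuracy) and _missing(t2c):
        return ValidityOutcome("WCT", NA)
    fail = False
    if not _missing(accuracy) and accuracy <= rules.wct_acc_fail_max:
        fail = True
    if not _missing(t2c) and t2c >= rules.wct_t2c_fail_min_s:
        fail = True
    return ValidityOutcome("WCT", FAIL if fail else PASS)


def threshold_outcome(
    score: float | None, cutoff: float, direction: str = FAIL_IF_LE,
    rule_id: str | None = None,
) -> ValidityOutcome:
    """Single-comparator decision engine shared by the EVI failure bands
    (fail iff score <= cutoff) and the ability-criterion rows (``fail_if_ge``
    read as "meets criterion" iff score >= cutoff)."""
    rid = rule_id or f"{direction}@{cutoff}"
    if _missing(score):
        return ValidityOutcome(rid, NA)
    if direction == FAIL_IF_LE:
        fail = score <= cutoff
    elif direction == FAIL_IF_GE:
        fail = score >= cutoff
    else:
        raise ConfigError(f"unknown direction {direction!r}")
    return ValidityOutcome(rid, FAIL if fail else PASS)


def combined_rcft_outcome(
    yn: float | None, fcr: float | None, cutoff: int
) -> ValidityOutcome:
    """Two-trial recognition rule: Pass iff either trial clears the cutoff,
    Fail iff both are at or below it.  NA if either score is missing."""
    rid = f"YN&FCR<={cutoff}"
    if _missing(yn) or _missing(fcr):
        return ValidityOutcome(rid, NA)
    fail = yn <= cutoff and fcr <= cutoff
    return ValidityOutcome(rid, FAIL if fail else PASS)


def below_chance(fcr: float, threshold: int = 12) -> bool:
    """True iff a forced-choice score is strictly below the chance
    expectation (12 of 24 two-alternative items under random choice)."""
    if _missing(fcr):
        raise ValueError("below_chance requires an observed score")
    return fcr < threshold


ABILITY_CRITERIA = ("VPA3_ge5", "CDT_ge8", "HVLTDR_ge8")


def ability_criterion(
    record: ExamineeRecord | Mapping[str, float],
    criterion: str,
    specs: Mapping[str, CompositeSpec] | None = None,
) -> bool | None:
    """Dichotomize an ability criterion: VPA-3 composite >= 5, clock-drawing
    raw >= 8, or HVLT-R delayed-recall raw >= 8.  Returns None when the
    required input is missing."""
    scores = record.scores if isinstance(record, ExamineeRecord) else record
    if criterion == "VPA3_ge5":
        specs = specs or list_builtin_specs()
        result = score_composite(scores, specs["VPA3"])
        if result.value is None:
            return None
        return result.value >= 5
    if criterion == "CDT_ge8":
        v = scores.get("cdt")
        return None if _missing(v) else v >= 8
    if criterion == "HVLTDR_ge8":
        v = scores.get("hvlt_dr_raw")
        return None if _missing(v) else v >= 8
    raise ConfigError(
        f"unknown ability criterion {criterion!r} (expected one of {ABILITY_CRITERIA})"
    )
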