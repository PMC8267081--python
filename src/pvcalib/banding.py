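"""Clinical interpretation bands for the RCFT recognition trials.

Because recognition scores at or below the validity cutoffs are specific to
non-credible responding, only the 18–24 range is interpretable as ability —
a seven-point scale.  The five-band scheme partitions the full 0–24 range:

* Invalid (0–14): essentially unobserved in credible examinees;
* Questionable (15–17): rare, failure-associated, interpret with caution;
* Inferior (18–19): mild-deficit range;
* WNL (20–22): intact / average performance;
* Superior (23–24): above average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .cohort import CohortTable
from .stats import cumulative_table

#: Raw-score range interpretable as ability once validity cutoffs are applied.
VALID_ABILITY_RANGE = (18, 24)

BAND_LABELS = ("Invalid", "Questionable", "Inferior", "WNL", "Superior")


@dataclass(frozen=True)
class BandingScheme:
    """Ordered (label, lo, hi) bands; must partition the score range."""

    bands: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        prev_hi = None
        for label, lo, hi in self.bands:
            if lo > hi:
                raise ValueError(f"band {label}: lo > hi")
            if prev_hi is not None and lo != prev_hi + 1:
                raise ValueError(f"bands must be contiguous at {label}")
            prev_hi = hi

    @property
    def min(self) -> int:
        return self.bands[0][1]

    @property
    def max(self) -> int:
        return self.bands[-1][2]


DEFAULT_SCHEME = BandingScheme(
    bands=(
        ("Invalid", 0, 14),
        ("Questionable", 15, 17),
        ("Inferior", 18, 19),
        ("WNL", 20, 22),
        ("Superior", 23, 24),
    )
)


def classify_score(score: int, scheme: BandingScheme = DEFAULT_SCHEME) -> str:
    """Band label for an integer recognition score."""
    if not float(score).is_integer():
        raise ValueError(f"banding requires an integer score, got {score!r}")
    score = int(score)
    if score < scheme.min or score > scheme.max:
        raise ValueError(
            f"score {score} outside banded range [{scheme.min}, {scheme.max}]"
        )
    for label, lo, hi in scheme.bands:
        if lo <= score <= hi:
            return label
    raise AssertionError("bands do not partition the range")  # pragma: no cover


def banded_report(
    cohorts: Mapping[str, CohortTable],
    instrument: str,
    aux: Mapping[str, pd.Series] | None = None,
    scheme: BandingScheme = DEFAULT_SCHEME,
    floor: int = 12,
) -> pd.DataFrame:
    """Banded cumulative-distribution table for one recognition trial.

    One row per raw score from ``<=floor`` (aggregated) up to the scale
    maximum; per-cohort cumulative percentages, conditional means of any
    auxiliary measures (Series indexed by examinee id; examinees without a
    value simply drop out), and the band label.
    """
    if not cohorts:
        raise ValueError("no cohorts supplied")
    aux = aux or {}
    support = list(range(scheme.min, scheme.max + 1))
    per_cohort = {}
    for label, cohort in cohorts.items():
        rows = cumulative_table(cohort.scores(instrument), support)
        per_cohort[label] = {r.score: r for r in rows}
    pooled = pd.concat([c.scores(instrument) for c in cohorts.values()])
    out = []
    for point in support:
        if point < floor:
            continue
        label = "<=%d" % floor if point == floor else str(point)
        at_point = pooled <= point if point == floor else pooled == point
        rec: dict = {"score": label}
        for cname, rows in per_cohort.items():
            rec[f"pct_cum_{cname}"] = rows[point].pct_cum
        for aname, series in aux.items():
            vals = series.reindex(pooled.index[at_point]).dropna()
            rec[f"mean_{aname}"] = float(vals.mean()) if len(vals) else float("nan")
        rec["classification"] = classify_score(point, scheme)
        out.append(rec)
    return pd.DataFrame(out)
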