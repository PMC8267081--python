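"""Classification-accuracy engine.

Cross-tabulates predictor decisions against criterion decisions (with
Borderline composite results excluded, as dichotomous analyses require),
computes sensitivity / specificity / overall accuracy and failure base
rates, sweeps cutoffs, estimates AUC with a confidence interval
(Hanley–McNeil by default, DeLong available), and applies the
specificity-first cutoff-selection policy used in performance-validity
calibration (minimum acceptable specificity .84, desirable >= .90).

Conventions: the positive class is *Fail* on the criterion; a predicted
positive is *Fail* on the predictor.  AUC equals the Mann–Whitney
probability that a randomly chosen criterion-positive examinee scores more
extreme (per the stated orientation) than a criterion-negative one, ties
counted one half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .criteria import FAIL_IF_GE, FAIL_IF_LE, ValidityOutcome, threshold_outcome
from .errors import ConfigError
from .recoding import CompositeResult

PASS, BORDERLINE, FAIL, NA = "Pass", "Borderline", "Fail", "NA"

LOWER_FAILS = "lower_fails"
HIGHER_FAILS = "higher_fails"


def _decision_series(values, name: str = "decision") -> pd.Series:
    """Normalize decisions to a string Series of Pass/Fail/Borderline/NA."""
    if isinstance(values, pd.Series):
        idx, seq = values.index, values.to_list()
    else:
        seq = list(values)
        idx = pd.RangeIndex(len(seq))
    out = []
    for v in seq:
        if isinstance(v, ValidityOutcome):
            out.append(v.decision)
        elif isinstance(v, CompositeResult):
            out.append(v.band if v.band is not None else NA)
        elif isinstance(v, str):
            out.append(v)
        elif isinstance(v, (bool, np.bool_)):
            out.append(FAIL if v else PASS)
        elif v is None or (isinstance(v, float) and math.isnan(v)):
            out.append(NA)
        else:
            raise ConfigError(f"cannot interpret decision value {v!r}")
    return pd.Series(out, index=idx, name=name, dtype=object)


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts (positive class = criterion Fail) plus exclusions."""

    tp: int
    fp: int
    tn: int
    fn: int
    n_excluded_borderline: int = 0
    n_missing: int = 0

    @property
    def n_used(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def cross_tabulate(predictor, criterion) -> ConfusionCounts:
    """Cross-tabulate aligned predictor and criterion decisions.

    Criterion ``Borderline`` results (composite values in the
    uninterpretable middle band) are excluded and counted separately;
    NA on either side counts as missing.
    """
    p = _decision_series(predictor, "predictor")
    c = _decision_series(criterion, "criterion")
    if len(p) != len(c):
        raise ConfigError("predictor and criterion lengths differ")
    if not p.index.equals(c.index):
        # a plain RangeIndex (list input) aligns positionally with anything
        if isinstance(p.index, pd.RangeIndex) or isinstance(c.index, pd.RangeIndex):
            p = p.reset_index(drop=True)
            c = c.reset_index(drop=True)
        else:
            common = p.index.intersection(c.index)
            if len(common) != len(p):
                raise ConfigError("predictor and criterion ids do not align")
            c = c.loc[p.index]
    tp = fp = tn = fn = excl = miss = 0
    for pv, cv in zip(p, c):
        if cv == BORDERLINE or pv == BORDERLINE:
            excl += 1
        elif pv == NA or cv == NA:
            miss += 1
        elif cv == FAIL:
            tp, fn = (tp + 1, fn) if pv == FAIL else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if pv == FAIL else (fp, tn + 1)
    return ConfusionCounts(tp, fp, tn, fn, excl, miss)


@dataclass(frozen=True)
class AccuracyMetrics:
    """sens = tp/(tp+fn); spec = tn/(tn+fp); acc = (sens+spec)/2;
    br_fail = predicted-positive rate among used records.  Fields are None
    when a denominator is zero."""

    sens: float | None
    spec: float | None
    acc: float | None
    br_fail: float | None


def metrics(counts: ConfusionCounts) -> AccuracyMetrics:
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else None
    acc = (sens + spec) / 2 if sens is not None and spec is not None else None
    br = (counts.tp + counts.fp) / counts.n_used if counts.n_used else None
    return AccuracyMetrics(sens, spec, acc, br)


@dataclass(frozen=True)
class AUCResult:
    """AUC with 95% CI.  ``orientation`` records which direction of the
    score predicts criterion Fail; it is never inferred from the data."""

    auc: float | None
    ci95: tuple[float, float] | None
    method: str
    orientation: str
    n_pos: int
    n_neg: int


def _hanley_mcneil_se(a: float, n_pos: int, n_neg: int) -> float:
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (
        a * (1 - a)
        + (n_pos - 1) * (q1 - a * a)
        + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def _delong_se(pos: np.ndarray, neg: np.ndarray, a: float) -> float:
    n1, n0 = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    mid = sps.rankdata(combined)
    r_pos = sps.rankdata(pos)
    r_neg = sps.rankdata(neg)
    v10 = (mid[:n1] - r_pos) / n0          # placement of each positive
    v01 = 1.0 - (mid[n1:] - r_neg) / n1    # placement of each negative
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    return math.sqrt(max(s10 / n1 + s01 / n0, 0.0))


def auc(
    scores,
    criterion,
    method: str = "hanley_mcneil",
    orientation: str = LOWER_FAILS,
) -> AUCResult:
    """Rank-based AUC of ``scores`` against dichotomous criterion decisions.

    Criterion Borderline/NA records (and records with missing scores) are
    dropped.  With fewer than one record in either class the AUC is
    undefined (None fields).
    """
    s = scores if isinstance(scores, pd.Series) else pd.Series(list(scores), dtype=float)
    c = _decision_series(criterion)
    if len(s) != len(c):
        raise ConfigError("scores and criterion lengths differ")
    s = pd.Series(np.asarray(s, dtype=float), index=c.index)
    keep = c.isin([PASS, FAIL]) & s.notna()
    s, c = s[keep], c[keep]
    pos = s[c == FAIL].to_numpy()
    neg = s[c == PASS].to_numpy()
    n1, n0 = len(pos), len(neg)
    if n1 == 0 or n0 == 0:
        return AUCResult(None, None, method, orientation, n1, n0)
    if orientation == LOWER_FAILS:
        z_pos, z_neg = -pos, -neg
    elif orientation == HIGHER_FAILS:
        z_pos, z_neg = pos, neg
    else:
        raise ConfigError(f"unknown orientation {orientation!r}")
    ranks = sps.rankdata(np.concatenate([z_pos, z_neg]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    a = u / (n1 * n0)
    if method == "hanley_mcneil":
        se = _hanley_mcneil_se(a, n1, n0)
    elif method == "delong":
        se = _delong_se(z_pos, z_neg, a)
    else:
        raise ConfigError(f"unknown AUC CI method {method!r}")
    zcrit = sps.norm.ppf(0.975)
    ci = (max(0.0, a - zcrit * se), min(1.0, a + zcrit * se))
    return AUCResult(a, ci, method, orientation, n1, n0)


@dataclass(frozen=True)
class AccuracySweepRow:
    """One cutoff's row: failure base rate over all scoreable records
    (computed before criterion alignment), then sensitivity / specificity /
    overall accuracy against the criterion."""

    cutoff: float
    direction: str
    br_fail: float | None
    sens: float | None
    spec: float | None
    acc: float | None
    n_used: int
    n_excluded_borderline: int
    n_missing: int


def cutoff_sweep(
    scores,
    criterion,
    cutoffs: Sequence[float],
    direction: str = FAIL_IF_LE,
) -> list[AccuracySweepRow]:
    """Sensitivity/specificity of ``scores`` dichotomized at each cutoff."""
    if len(cutoffs) == 0:
        raise ConfigError("empty cutoff list")
    s = scores if isinstance(scores, pd.Series) else pd.Series(list(scores), dtype=float)
    c = _decision_series(criterion)
    rows = []
    observed = s.dropna()
    for cut in cutoffs:
        decisions = pd.Series(
            [threshold_outcome(v, cut, direction).decision for v in s],
            index=s.index, dtype=object,
        )
        if len(observed):
            failed = (observed <= cut) if direction == FAIL_IF_LE else (observed >= cut)
            br = float(failed.mean())
        else:
            br = None
        counts = cross_tabulate(decisions, c)
        m = metrics(counts)
        rows.append(
            AccuracySweepRow(
                cutoff=cut, direction=direction, br_fail=br,
                sens=m.sens, spec=m.spec, acc=m.acc,
                n_used=counts.n_used,
                n_excluded_borderline=counts.n_excluded_borderline,
                n_missing=counts.n_missing,
            )
        )
    return rows


def sweep_frame(rows: Iterable[AccuracySweepRow]) -> pd.DataFrame:
    """Tidy DataFrame view of a sweep (CSV-exportable)."""
    return pd.DataFrame(
        [
            {
                "cutoff": r.cutoff, "direction": r.direction,
                "br_fail": r.br_fail, "sens": r.sens, "spec": r.spec,
                "acc": r.acc, "n": r.n_used,
                "n_excluded": r.n_excluded_borderline, "n_missing": r.n_missing,
            }
            for r in rows
        ]
    )


@dataclass(frozen=True)
class CutoffPolicy:
    """Specificity-first selection: the floor below which a cutoff is
    unacceptable, and the desirable standard."""

    min_spec: float = 0.84
    desired_spec: float = 0.90


@dataclass(frozen=True)
class CutoffRecommendation:
    cutoff: float
    sens: float | None
    spec: float
    meets_desired: bool


def select_cutoff(
    sweep: Sequence[AccuracySweepRow], policy: CutoffPolicy = CutoffPolicy()
) -> CutoffRecommendation | None:
    """Most liberal cutoff whose specificity clears ``policy.min_spec``.

    "Most liberal" maximizes sensitivity at acceptable specificity: the
    highest cutoff for fail-if-le rules, the lowest for fail-if-ge.
    Returns None when no cutoff qualifies.
    """
    if not sweep:
        raise ConfigError("empty sweep")
    ok = [r for r in sweep if r.spec is not None and r.spec >= policy.min_spec]
    if not ok:
        return None
    liberal = max if ok[0].direction == FAIL_IF_LE else min
    best = liberal(ok, key=lambda r: r.cutoff)
    return CutoffRecommendation(
        cutoff=best.cutoff, sens=best.sens, spec=best.spec,
        meets_desired=best.spec >= policy.desired_spec,
    )
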