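"""Synthetic-cohort generator with latent credibility status.

The generative model: each examinee has a latent credibility status
(Bernoulli ``p_noncredible``) and three correlated standard-normal ability
factors (memory, processing speed, visual-perceptual).  Each instrument is a
linear read-out of one factor —

    score = intercept + slope * (factor - status * delta_domain * mult) + eps

— with Gaussian residual noise, then rounded on integer scales and clamped
to the instrument range.  Suppression is additive in latent space before
discretization: non-credible examinees lose ``delta`` latent SDs on each
domain, scaled by an instrument-level congruence multiplier.  Memory-domain
suppression exceeds the other domains by default, emulating the modality
specificity of non-credible performance.  Latent status is a hidden label,
so the pipeline's composite/PVT machinery can be evaluated as an estimator
of it.

The two bundled presets emulate a disability-claim clinical sample (n=52,
high non-credible base rate) and an incentivized undergraduate sample
(n=83, low non-credible base rate but an anomalously high word-choice
failure rate).  Preset parameters were fitted once by moment matching
against the published group summary statistics (means, SDs, one
between-trial correlation and one failure base rate per group, plus the
per-component pass rates of the validity composites) and ship as data; the
cross-correlations not published anywhere are implementer-chosen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .cohort import CohortTable, ExamineeRecord, InstrumentMeta, default_registry
from .errors import ConfigError

FACTORS = ("memory", "speed", "visuoperceptual")

CREDIBLE, NONCREDIBLE = "credible", "noncredible"


@dataclass(frozen=True)
class InstrumentModel:
    """Linear read-out of one latent factor onto an instrument's native
    scale.  ``suppression_mult`` scales the domain-level suppression shift
    for this instrument; ``missing_rate`` drops scores completely at
    random (mirroring tests administered on different days)."""

    name: str
    factor: str
    intercept: float
    slope: float
    resid_sd: float
    suppression_mult: float = 1.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.factor not in FACTORS:
            raise ConfigError(f"{self.name}: unknown factor {self.factor!r}")
        if self.resid_sd < 0 or not 0 <= self.missing_rate < 1:
            raise ConfigError(f"{self.name}: invalid noise/missingness")


@dataclass(frozen=True)
class SimulationConfig:
    """Full cohort-generator configuration for one group."""

    group: str
    n: int
    p_noncredible: float
    instruments: tuple[InstrumentModel, ...]
    factor_corr: tuple[tuple[float, ...], ...] = (
        (1.0, 0.5, 0.5),
        (0.5, 1.0, 0.5),
        (0.5, 0.5, 1.0),
    )
    delta: Mapping[str, float] = field(
        default_factory=lambda: {"memory": 1.0, "speed": 0.8, "visuoperceptual": 0.8}
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_noncredible <= 1:
            raise ConfigError("p_noncredible must lie in [0, 1]")
        if any(d < 0 for d in self.delta.values()):
            raise ConfigError("suppression delta must be >= 0")
        corr = np.asarray(self.factor_corr, dtype=float)
        if corr.shape != (3, 3) or not np.allclose(corr, corr.T):
            raise ConfigError("factor_corr must be a symmetric 3x3 matrix")
        if np.linalg.eigvalsh(corr).min() < -1e-9:
            raise ConfigError("factor_corr must be positive semi-definite")

    def scaled_delta(self, scale: float) -> "SimulationConfig":
        """Copy with every domain suppression multiplied by ``scale``."""
        return replace(self, delta={k: v * scale for k, v in self.delta.items()})

    def instrument(self, name: str) -> InstrumentModel:
        for m in self.instruments:
            if m.name == name:
                return m
        raise ConfigError(f"no instrument {name!r} in config")


def _chol(config: SimulationConfig) -> np.ndarray:
    corr = np.asarray(config.factor_corr, dtype=float)
    # tiny jitter keeps semi-definite matrices factorizable
    return np.linalg.cholesky(corr + 1e-12 * np.eye(3))


def _discretize(x: np.ndarray, meta: InstrumentMeta | None) -> tuple[np.ndarray, float]:
    """Round-then-clamp to the instrument's scale; returns the clamped
    fraction for ceiling/floor diagnostics."""
    if meta is None:
        return x, 0.0
    if meta.integer:
        x = np.rint(x)
    clamped = (x < meta.min) | (x > meta.max)
    x = np.clip(x, meta.min, meta.max)
    if meta.integer:
        x = np.rint(x)
    return x, float(clamped.mean()) if len(x) else 0.0


def _instrument_column(
    rng: np.random.Generator,
    model: InstrumentModel,
    factor_values: np.ndarray,
    noncredible: np.ndarray,
    delta: Mapping[str, float],
    meta: InstrumentMeta | None,
) -> tuple[np.ndarray, float]:
    shift = delta[model.factor] * model.suppression_mult
    f_eff = factor_values - noncredible * shift
    x = model.intercept + model.slope * f_eff
    x = x + rng.standard_normal(len(f_eff)) * model.resid_sd
    return _discretize(x, meta)


def simulate_cohort(
    config: SimulationConfig,
    seed: int | None = None,
    registry: Mapping[str, InstrumentMeta] | None = None,
) -> CohortTable:
    """Draw a cohort from ``config``; reproducible given the seed.

    ``seed`` overrides ``config.seed``.  Every score is valid against the
    registry by construction; per-instrument clamped fractions are stored
    in ``table.attrs["clamp_fraction"]``.
    """
    registry = dict(registry) if registry is not None else default_registry()
    use_seed = seed if seed is not None else config.seed
    rng = np.random.default_rng(use_seed)
    n = config.n
    if n == 0:
        return CohortTable([], registry, attrs={"clamp_fraction": {}})
    status = rng.random(n) < config.p_noncredible
    factors = rng.standard_normal((n, 3)) @ _chol(config).T
    columns: dict[str, np.ndarray] = {}
    observed: dict[str, np.ndarray] = {}
    clampinfo: dict[str, float] = {}
    fidx = {f: i for i, f in enumerate(FACTORS)}
    for model in config.instruments:
        col, clamped = _instrument_column(
            rng, model, factors[:, fidx[model.factor]], status,
            config.delta, registry.get(model.name),
        )
        keep = rng.random(n) >= model.missing_rate
        columns[model.name] = col
        observed[model.name] = keep
        clampinfo[model.name] = clamped
    width = max(4, len(str(n)))
    records = []
    for i in range(n):
        scores = {
            name: float(columns[name][i])
            for name in columns
            if observed[name][i]
        }
        records.append(
            ExamineeRecord(
                examinee_id=f"{config.group}-{i:0{width}d}",
                group=config.group if config.group in ("clinical", "student") else "custom",
                scores=scores,
                latent_status=NONCREDIBLE if status[i] else CREDIBLE,
            )
        )
    return CohortTable(records, registry, attrs={"clamp_fraction": clampinfo})


@dataclass(frozen=True)
class OracleAccuracy:
    """Monte-Carlo ground-truth operating characteristics of a cutoff rule
    against latent status, with binomial standard errors."""

    sens: float
    spec: float
    se_sens: float
    se_spec: float
    n_noncredible: int
    n_credible: int


def oracle_accuracy(
    config: SimulationConfig,
    cutoff: float,
    instrument: str,
    n_mc: int = 1_000_000,
    seed: int | None = None,
    direction: str = "fail_if_le",
) -> OracleAccuracy:
    """Ground-truth sensitivity/specificity of ``score <= cutoff`` (or
    ``>=``) against latent non-credible status, by direct Monte Carlo from
    the generative model (the marginal of one factor is standard normal, so
    only the requested instrument is simulated)."""
    import warnings

    if n_mc < 1000:
        warnings.warn("n_mc < 1000 gives unstable oracle estimates", stacklevel=2)
    model = config.instrument(instrument)
    registry = default_registry()
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    status = rng.random(n_mc) < config.p_noncredible
    f = rng.standard_normal(n_mc)
    col, _ = _instrument_column(
        rng, model, f, status, config.delta, registry.get(instrument)
    )
    fail = col <= cutoff if direction == "fail_if_le" else col >= cutoff
    n1 = int(status.sum())
    n0 = n_mc - n1
    sens = float(fail[status].mean()) if n1 else math.nan
    spec = float((~fail[~status]).mean()) if n0 else math.nan
    se1 = math.sqrt(sens * (1 - sens) / n1) if n1 else math.nan
    se0 = math.sqrt(spec * (1 - spec) / n0) if n0 else math.nan
    return OracleAccuracy(sens, spec, se1, se0, n1, n0)


# ---------------------------------------------------------------------------
# Presets: parameters moment-matched to the published group summaries.
# Tuples: (factor, intercept, slope, resid_sd, suppression_mult, missing_rate)
# ---------------------------------------------------------------------------

_CLINICAL_PARAMS: dict[str, tuple[str, float, float, float, float, float]] = {
    "rcft_copy":   ("visuoperceptual", 30.066, 2.000, 3.460, 3.100, 0.0),
    "rcft_yn":     ("memory", 20.157, 0.641, 1.839, 3.300, 0.0),
    "rcft_fcr":    ("memory", 20.915, 0.761, 2.189, 5.100, 0.0),
    "tomm1":       ("memory", 48.007, 1.100, 1.910, 10.000, 0.02),
    "wct_acc":     ("memory", 49.227, 0.650, 1.130, 6.900, 0.0),
    "wct_t2c_s":   ("speed", 85.000, 12.500, 21.700, 7.000, 0.0),
    "cim":         ("memory", 11.525, 0.720, 1.430, 3.100, 0.025),
    "ds_acss":     ("memory", 8.811, 0.900, 1.790, 3.100, 0.025),
    "hvlt_fcr":    ("memory", 12.820, 0.400, 0.800, 2.250, 0.025),
    "rey15_fr":    ("memory", 14.695, 0.900, 1.790, 3.700, 0.025),
    "rey_wrt":     ("memory", 9.141, 0.900, 1.790, 3.300, 0.025),
    "animals_t":   ("speed", 41.846, 4.000, 6.930, 3.300, 0.025),
    "cd_acss":     ("speed", 7.392, 1.000, 1.730, 3.250, 0.025),
    "tmta_t":      ("speed", 42.972, 4.000, 6.930, 3.750, 0.025),
    "cpt_var_t":   ("speed", 52.864, -4.050, 8.040, 4.000, 0.025),
    "dkefs_word":  ("speed", 8.281, 1.080, 2.140, 3.700, 0.025),
    "mr_acss":     ("visuoperceptual", 8.397, 1.200, 2.080, 2.100, 0.025),
    "cdt":         ("visuoperceptual", 9.395, 0.450, 0.780, 3.300, 0.02),
    "hvlt_dr_raw": ("memory", 7.948, 1.430, 2.170, 2.200, 0.02),
    "hvlt_dr_t":   ("memory", 36.166, 4.950, 7.520, 1.600, 0.02),
}

_STUDENT_PARAMS: dict[str, tuple[str, float, float, float, float, float]] = {
    "rcft_yn":   ("memory", 21.543, 1.078, 0.985, 2.300, 0.0),
    "rcft_fcr":  ("memory", 22.617, 1.328, 1.208, 2.700, 0.0),
    "tomm1":     ("memory", 48.969, 1.000, 1.730, 10.000, 0.19),
    "wct_acc":   ("memory", 48.682, 0.950, 1.650, 3.700, 0.10),
    "wct_t2c_s": ("speed", 75.000, 10.000, 17.300, 7.500, 0.10),
}

_PRESETS = {
    "clinical_2021": ("clinical", 52, 0.404, _CLINICAL_PARAMS),
    "student_2021": ("student", 83, 0.09, _STUDENT_PARAMS),
}


def preset(name: str) -> SimulationConfig:
    """A calibrated preset configuration (``clinical_2021`` or
    ``student_2021``); override ``n``/``seed`` with ``dataclasses.replace``."""
    try:
        group, n, p_nc, params = _PRESETS[name]
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r} (expected one of {sorted(_PRESETS)})"
        ) from None
    instruments = tuple(
        InstrumentModel(
            name=iname, factor=f, intercept=a, slope=b,
            resid_sd=sd, suppression_mult=mult, missing_rate=miss,
        )
        for iname, (f, a, b, sd, mult, miss) in params.items()
    )
    return SimulationConfig(
        group=group, n=n, p_noncredible=p_nc, instruments=instruments
    )


def preset_names() -> tuple[str, ...]:
    return tuple(sorted(_PRESETS))
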