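"""Simulator: determinism, range validity, calibration and oracle checks.

Monte-Carlo assertions run at n=5000 with fixed seeds; tolerances are the
Monte-Carlo bands stated in each test.
"""

import math
from dataclasses import replace

import numpy as np
import pytest

from pvcalib.accuracy import auc
from pvcalib.cohort import default_registry
from pvcalib.errors import ConfigError
from pvcalib.recoding import component_base_rates, list_builtin_specs
from pvcalib.simulate import (
    InstrumentModel,
    SimulationConfig,
    oracle_accuracy,
    preset,
    preset_names,
    simulate_cohort,
)

SEED = 20210522


@pytest.fixture(scope="module")
def clinical_5000():
    return simulate_cohort(replace(preset("clinical_2021"), n=5000), seed=SEED)


@pytest.fixture(scope="module")
def student_5000():
    return simulate_cohort(replace(preset("student_2021"), n=5000), seed=SEED + 1)


class TestMechanics:
    def test_empty_cohort(self):
        cfg = replace(preset("clinical_2021"), n=0)
        assert len(simulate_cohort(cfg, seed=1)) == 0

    def test_same_seed_reproduces_table(self):
        cfg = replace(preset("student_2021"), n=40)
        a = simulate_cohort(cfg, seed=9)
        b = simulate_cohort(cfg, seed=9)
        assert a.to_frame().equals(b.to_frame())

    def test_different_seeds_differ(self):
        cfg = replace(preset("student_2021"), n=40)
        a = simulate_cohort(cfg, seed=9)
        b = simulate_cohort(cfg, seed=10)
        assert not a.to_frame().equals(b.to_frame())

    def test_scores_within_registry_ranges(self, clinical_5000):
        registry = default_registry()
        for name in ("rcft_fcr", "tomm1", "cdt", "cpt_var_t"):
            meta = registry[name]
            vals = clinical_5000.scores(name).dropna()
            assert vals.between(meta.min, meta.max).all()
            if meta.integer:
                assert (vals == vals.round()).all()

    def test_latent_status_populated(self, clinical_5000):
        status = clinical_5000.latent_status()
        assert set(status.unique()) <= {"credible", "noncredible"}

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigError):
            preset("nope")
        assert preset_names() == ("clinical_2021", "student_2021")

    def test_invalid_correlation_matrix_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(
                group="custom", n=5, p_noncredible=0.1,
                instruments=(InstrumentModel("rcft_fcr", "memory", 20, 1, 1),),
                factor_corr=((1, 2, 0), (2, 1, 0), (0, 0, 1)),
            )


class TestCalibration:
    """Preset marginals against the published group summaries, at n=5000
    (Monte-Carlo tolerances)."""

    def test_clinical_recognition_moments(self, clinical_5000):
        fcr = clinical_5000.scores("rcft_fcr")
        assert abs(fcr.mean() - 19.3) < 0.15
        assert abs(fcr.std(ddof=1) - 2.9) < 0.2
        yn = clinical_5000.scores("rcft_yn")
        assert abs(yn.mean() - 19.3) < 0.15
        assert abs(yn.std(ddof=1) - 2.2) < 0.2

    def test_clinical_between_trial_correlation(self, clinical_5000):
        yn = clinical_5000.scores("rcft_yn")
        fcr = clinical_5000.scores("rcft_fcr")
        r = np.corrcoef(yn, fcr)[0, 1]
        assert abs(r - 0.37) < 0.05

    def test_clinical_tomm1_failure_base_rate(self, clinical_5000):
        tomm = clinical_5000.scores("tomm1").dropna()
        br = (tomm <= 43).mean()
        assert abs(br - 0.415) < 0.03

    def test_student_recognition_moments(self, student_5000):
        fcr = student_5000.scores("rcft_fcr")
        assert abs(fcr.mean() - 22.1) < 0.15
        assert abs(fcr.std(ddof=1) - 1.8) < 0.2
        yn = student_5000.scores("rcft_yn")
        assert abs(yn.mean() - 21.3) < 0.15
        assert abs(yn.std(ddof=1) - 1.6) < 0.2

    def test_student_between_trial_correlation(self, student_5000):
        yn = student_5000.scores("rcft_yn")
        fcr = student_5000.scores("rcft_fcr")
        assert abs(np.corrcoef(yn, fcr)[0, 1] - 0.62) < 0.05

    def test_student_below_chance_rate_near_zero(self, student_5000):
        fcr = student_5000.scores("rcft_fcr")
        assert (fcr < 12).mean() < 0.005

    def test_clinical_component_pass_rates(self, clinical_5000):
        """Code-0 base rate of every validity-composite component within
        +/- 5 points of its published value."""
        targets = {
            "cim": 71.7, "ds_acss": 68.6, "hvlt_fcr": 83.0,
            "rey15_fr": 75.5, "rey_wrt": 71.7,
            "animals_t": 73.6, "cd_acss": 64.2, "tmta_t": 67.9,
            "cpt_var_t": 71.7, "dkefs_word": 69.8,
        }
        specs = list_builtin_specs()
        for comp in ("EI5_MEM", "EI5_PSP"):
            rates = component_base_rates(clinical_5000, specs[comp])
            for inst in (r.instrument for r in specs[comp].components):
                assert abs(rates.loc[inst, 0] - targets[inst]) < 5.0, inst


class TestOracle:
    def test_null_suppression_is_uninformative(self):
        cfg = replace(preset("clinical_2021"), n=4000).scaled_delta(0.0)
        table = simulate_cohort(cfg, seed=SEED)
        crit = ["Fail" if s == "noncredible" else "Pass"
                for s in table.latent_status()]
        res = auc(table.scores("rcft_fcr"), crit)
        assert abs(res.auc - 0.5) < 0.04

    def test_large_suppression_separates(self):
        cfg = preset("clinical_2021").scaled_delta(3.0)
        o = oracle_accuracy(cfg, 16, "rcft_fcr", n_mc=100_000, seed=2)
        assert o.sens >= 0.95
        assert o.spec >= 0.95

    def test_auc_monotone_in_suppression(self):
        """Raising the latent suppression never lowers the AUC of a
        suppressed instrument against latent status (within 2 MC SEs)."""
        aucs = []
        for scale in (0.0, 0.5, 1.0, 2.0):
            cfg = replace(preset("clinical_2021"), n=5000).scaled_delta(scale)
            table = simulate_cohort(cfg, seed=SEED + 3)
            crit = ["Fail" if s == "noncredible" else "Pass"
                    for s in table.latent_status()]
            aucs.append(auc(table.scores("rcft_fcr"), crit).auc)
        # AUC standard error at n=5000 is well under 0.01
        for a, b in zip(aucs, aucs[1:]):
            assert b >= a - 0.02

    def test_oracle_warns_below_1000_draws(self):
        with pytest.warns(UserWarning):
            oracle_accuracy(preset("clinical_2021"), 16, "rcft_fcr",
                            n_mc=500, seed=1)

    def test_pipeline_recovers_oracle_operating_point(self, clinical_5000):
        """Pipeline-estimated sens/spec of the forced-choice <=16 rule
        against latent status within +/- 0.03 of the Monte-Carlo oracle."""
        from pvcalib.accuracy import cross_tabulate, metrics
        from pvcalib.criteria import threshold_outcome

        scores = clinical_5000.scores("rcft_fcr")
        pred = [threshold_outcome(v, 16, "fail_if_le") for v in scores]
        crit = ["Fail" if s == "noncredible" else "Pass"
                for s in clinical_5000.latent_status()]
        m = metrics(cross_tabulate(pred, crit))
        o = oracle_accuracy(preset("clinical_2021"), 16, "rcft_fcr",
                            n_mc=200_000, seed=4)
        assert abs(m.sens - o.sens) < 0.03
        assert abs(m.spec - o.spec) < 0.03

    def test_discretization_preserves_rank_correlation(self):
        """Round-then-clamp keeps rank correlation > .5 between the latent
        factor and the observed score when residual noise is at most one
        slope-unit and clamping is light."""
        from scipy.stats import spearmanr

        from pvcalib.simulate import _instrument_column

        rng = np.random.default_rng(7)
        f = rng.standard_normal(4000)
        model = InstrumentModel("tomm1", "memory", 25.0, 5.0, 5.0)
        col, clamped = _instrument_column(
            rng, model, f, np.zeros(4000, dtype=bool),
            {"memory": 1.0}, default_registry()["tomm1"],
        )
        assert clamped < 0.01
        assert spearmanr(f, col).statistic > 0.5
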