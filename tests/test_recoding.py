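import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st

from pvcalib.cohort import CohortTable, default_registry
from pvcalib.errors import UnmappableScoreError
from pvcalib.recoding import (
    component_base_rates,
    list_builtin_specs,
    recode_component,
    score_composite,
)

from conftest import make_record

SPECS = list_builtin_specs()
EI5_MEM, EI5_PSP, VPA3 = SPECS["EI5_MEM"], SPECS["EI5_PSP"], SPECS["VPA3"]
ALL_RULES = {
    (spec.name, r.instrument): r
    for spec in SPECS.values()
    for r in spec.components
}


def rule(spec, instrument):
    return next(r for r in spec.components if r.instrument == instrument)


class TestRecodeComponent:
    @pytest.mark.parametrize(
        "spec, instrument, raw, expected",
        [
            (EI5_MEM, "ds_acss", 4, 2),
            (EI5_MEM, "ds_acss", 7, 0),
            (EI5_MEM, "ds_acss", 2, 3),
            (EI5_PSP, "cpt_var_t", 64, 0),
            (EI5_PSP, "cpt_var_t", 80, 3),
            (EI5_PSP, "cpt_var_t", 75, 2),
            (EI5_PSP, "cd_acss", 5, 1),   # printed band: exactly 5
            (EI5_PSP, "cd_acss", 6, 0),
            (VPA3, "cd_acss", 16, 4),
            (VPA3, "tmta_t", 44, 2),
            (VPA3, "mr_acss", 4, 0),
        ],
    )
    def test_published_band_examples(self, spec, instrument, raw, expected):
        assert recode_component(raw, rule(spec, instrument)) == expected

    def test_missing_score_returns_none(self):
        assert recode_component(None, rule(EI5_MEM, "cim")) is None
        assert recode_component(math.nan, rule(EI5_MEM, "cim")) is None

    def test_below_floor_extrapolates_with_warning(self):
        word = rule(EI5_PSP, "dkefs_word")
        with pytest.warns(UserWarning, match="below the lowest"):
            assert recode_component(0, word) == 3

    def test_gap_raises_unmappable(self):
        # a rule with a deliberate gap
        from pvcalib.recoding import Band, OrdinalRecodeRule

        gappy = OrdinalRecodeRule(
            "toy", bands=(Band(0, 10, None), Band(1, None, 5))
        )
        with pytest.raises(UnmappableScoreError):
            recode_component(7, gappy)


class TestMonotonicity:
    registry = default_registry()

    @pytest.mark.parametrize("key", sorted(ALL_RULES), ids="-".join)
    def test_codes_monotone_over_full_range(self, key):
        """Worsening the raw score in the instrument's deficit direction
        never decreases a validity code (and never increases an ability
        code), over every in-range integer score."""
        import warnings

        spec_name, _ = key
        r = ALL_RULES[key]
        meta = self.registry[r.instrument]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # below-floor extrapolation
            codes = [
                recode_component(v, r)
                for v in range(int(meta.min), int(meta.max) + 1)
            ]
        diffs = [b - a for a, b in zip(codes, codes[1:])]
        validity = spec_name.startswith("EI5")
        increasing_in_raw = (validity and not meta.higher_is_better) or (
            not validity and meta.higher_is_better
        )
        if increasing_in_raw:
            assert all(d >= 0 for d in diffs)
        else:
            assert all(d <= 0 for d in diffs)


class TestScoreComposite:
    def test_all_pass_gives_zero(self):
        scores = {"cim": 12, "ds_acss": 10, "hvlt_fcr": 12, "rey15_fr": 15,
                  "rey_wrt": 9}
        res = score_composite(scores, EI5_MEM)
        assert (res.value, res.band) == (0, "Pass")

    def test_hand_summed_codes_cross_band_threshold(self):
        # codes (1, 0, 0, 1, 2) -> 4 -> Fail
        scores = {"cim": 9, "ds_acss": 10, "hvlt_fcr": 12, "rey15_fr": 7,
                  "rey_wrt": 4}
        res = score_composite(scores, EI5_MEM)
        assert (res.value, res.band) == (4, "Fail")

    def test_vpa3_middle_bands(self):
        res = score_composite({"cd_acss": 8, "mr_acss": 8, "tmta_t": 44}, VPA3)
        assert res.value == 6
        assert res.band is None

    def test_missing_component_yields_na_not_zero(self):
        res = score_composite({"cim": 12}, EI5_MEM)
        assert res.value is None
        assert res.band == "NA"
        assert res.n_components_scored == 1

    def test_band_partition_of_value_range(self):
        thr = EI5_MEM.band_thresholds
        bands = [thr.band(v) for v in range(16)]
        assert bands[:2] == ["Pass", "Pass"]
        assert bands[2:4] == ["Borderline", "Borderline"]
        assert all(b == "Fail" for b in bands[4:])

    def test_composite_equals_brute_force_sum_ei5(self):
        """Composite value equals the sum of individually recoded components
        for all 4^5 code combinations."""
        # pick one representative raw score per (component, code)
        reps = []
        registry = default_registry()
        for r in EI5_MEM.components:
            meta = registry[r.instrument]
            per_code = {}
            for v in range(int(meta.min), int(meta.max) + 1):
                per_code.setdefault(recode_component(v, r), v)
            reps.append([per_code[c] for c in range(r.max_code + 1)])
        for combo in itertools.product(*(range(4) for _ in range(5))):
            scores = {
                r.instrument: reps[i][code]
                for i, (r, code) in enumerate(zip(EI5_MEM.components, combo))
            }
            assert score_composite(scores, EI5_MEM).value == sum(combo)

    def test_composite_equals_brute_force_sum_vpa3(self):
        registry = default_registry()
        reps = []
        for r in VPA3.components:
            meta = registry[r.instrument]
            per_code = {}
            for v in range(int(meta.min), int(meta.max) + 1):
                per_code.setdefault(recode_component(v, r), v)
            reps.append([per_code[c] for c in range(r.max_code + 1)])
        for combo in itertools.product(*(range(5) for _ in range(3))):
            scores = {
                r.instrument: reps[i][code]
                for i, (r, code) in enumerate(zip(VPA3.components, combo))
            }
            assert score_composite(scores, VPA3).value == sum(combo)

    def test_value_ranges(self):
        assert EI5_MEM.value_range == (0, 15)
        assert EI5_PSP.value_range == (0, 15)
        assert VPA3.value_range == (0, 12)


class TestBuiltinSpecs:
    def test_component_rosters(self):
        assert [r.instrument for r in EI5_MEM.components] == [
            "cim", "ds_acss", "hvlt_fcr", "rey15_fr", "rey_wrt"
        ]
        assert [r.instrument for r in EI5_PSP.components] == [
            "animals_t", "cd_acss", "tmta_t", "cpt_var_t", "dkefs_word"
        ]
        assert [r.instrument for r in VPA3.components] == [
            "cd_acss", "mr_acss", "tmta_t"
        ]

    def test_returns_fresh_dict(self):
        d = list_builtin_specs()
        d.pop("VPA3")
        assert "VPA3" in list_builtin_specs()


class TestComponentBaseRates:
    def test_degenerate_cohort_all_one_code(self):
        cohort = CohortTable(
            [make_record(str(i), scores={"ds_acss": 10}) for i in range(4)]
        )
        df = component_base_rates(cohort, EI5_MEM)
        assert df.loc["ds_acss", 0] == 100.0
        assert df.loc["ds_acss", 3] == 0.0
        assert df.loc["cim", "n_scored"] == 0

    def test_hand_tallied_fixture(self):
        # ds_acss values: codes 0,0,1,1,1,2,2,2,2,3 -> 20/30/40/10 %
        vals = [10, 7, 5, 6, 6, 3, 4, 3, 4, 2]
        cohort = CohortTable(
            [make_record(str(i), scores={"ds_acss": v}) for i, v in enumerate(vals)]
        )
        df = component_base_rates(cohort, EI5_MEM)
        assert [df.loc["ds_acss", k] for k in range(4)] == [20.0, 30.0, 40.0, 10.0]
        assert math.isclose(sum(df.loc["ds_acss", k] for k in range(4)), 100.0)
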