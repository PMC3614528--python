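"""The mapping and adaptive search routines, their pruning rules and strategies."""

import math

import pytest

from cuffsearch.response_metrics import DisplacementVector, ResponseRecord, TargetSpec
from cuffsearch.routines import (
    ResultsCollection,
    RoutineConfig,
    bisect_on_overshoot,
    run_mapping,
    run_search,
    run_search_dual_rate,
    run_search_with_cache,
    select_best,
    verify_stimulus,
)
from cuffsearch.plant_sim import SimulatedPlant, make_paperlike_plant
from cuffsearch.stim_space import enumerate_stimuli, sort_by_charge

from conftest import ConstantPlant, DirectionalStepPlant, RampPlant, make_step_plant


def _config(target=None, **kw):
    return RoutineConfig(target=target, **kw)


def _target(magnitude, direction, **kw):
    return TargetSpec(DisplacementVector.from_polar(magnitude, direction), **kw)


class TestRunMapping:
    def test_reference_space_gives_768_records(self, bundle):
        plant = ConstantPlant(DisplacementVector(1.0, 0.0))
        coll = run_mapping(plant, bundle.layout, bundle.constraints, bundle.grid, bundle.routine)
        assert coll.stimuli_tested == 768
        ids = [r.stimulus.key for r in coll.records]
        assert len(set(ids)) == 768

    def test_noise_free_plant_gives_zero_variability_all_included(self, small_space):
        layout, constraints, grid = small_space
        plant = ConstantPlant(DisplacementVector(2.0, 1.0))
        coll = run_mapping(plant, layout, constraints, grid, _config())
        assert all(r.variability_pct == 0.0 and r.included for r in coll.records)

    def test_zero_plant_marks_all_undefined_and_unselectable(self, small_space):
        layout, constraints, grid = small_space
        plant = ConstantPlant(DisplacementVector(0.0, 0.0))
        coll = run_mapping(plant, layout, constraints, grid, _config())
        assert all(math.isinf(r.variability_pct) for r in coll.records)
        assert coll.included_records == []
        assert select_best(coll, _target(5.0, 0.0)) is None

    def test_plant_failure_recorded_and_mapping_continues(self, small_space):
        layout, constraints, grid = small_space

        class FlakyPlant:
            def __call__(self, stimulus, t):
                if stimulus.cec.main_cathode == "BII":
                    raise RuntimeError("electrode fault")
                return DisplacementVector(1.0, 0.0)

        coll = run_mapping(FlakyPlant(), layout, constraints, grid, _config())
        failed = [r for r in coll.records if r.failed]
        assert len(failed) == 12  # one CEC's worth
        assert coll.stimuli_tested == 60

    def test_virtual_clock_advances_at_least_delay_per_repetition(self, small_space):
        layout, constraints, grid = small_space
        plant = ConstantPlant(DisplacementVector(1.0, 0.0))
        cfg = _config(n_repetitions=3, min_inter_stimulus_delay_ms=400.0,
                      processing_allowance_ms=0.0)
        coll = run_mapping(plant, layout, constraints, grid, cfg)
        assert coll.duration_s >= 60 * 3 * 0.4 - 1e-9


class TestSelectBest:
    def _collection(self, records):
        return ResultsCollection(list(records))

    def test_exact_match_wins(self, small_space):
        layout, constraints, grid = small_space
        plant = DirectionalStepPlant(
            {c: 10.0 * i for i, c in enumerate(constraints.main_cathodes)},
            {c: 5.0 for c in constraints.main_cathodes},
            {c: 3.0 for c in constraints.main_cathodes},
        )
        coll = run_mapping(plant, layout, constraints, grid, _config())
        rec = coll.records[30]
        target = TargetSpec(rec.mean)
        stim, best = select_best(coll, target)
        assert best.mean.distance_to(target.desired) == 0.0

    def test_equidistant_ties_break_on_lower_charge(self, small_space):
        layout, constraints, grid = small_space
        stimuli = sort_by_charge(enumerate_stimuli(layout, constraints, grid))
        low, high = stimuli[0], stimuli[-1]  # 0.5 nC and 16 nC
        target = _target(5.0, 0.0)
        recs = [
            ResponseRecord(high, [DisplacementVector(4.0, 0.0)] * 2, 10.0),
            ResponseRecord(low, [DisplacementVector(6.0, 0.0)] * 2, 10.0),
        ]
        stim, _ = select_best(self._collection(recs), target)
        assert stim == low

    def test_excluded_records_are_not_selectable(self, small_space):
        layout, constraints, grid = small_space
        stim = enumerate_stimuli(layout, constraints, grid)[0]
        noisy = ResponseRecord(
            stim,
            [DisplacementVector(4, 0), DisplacementVector(6, 0), DisplacementVector(5, 0)],
            10.0,  # F ≈ 13.3 > 10 → excluded
        )
        assert select_best(self._collection([noisy]), _target(5.0, 0.0)) is None


class TestRunSearchDecisions:
    def test_found_equals_mapping_plus_selection_on_step_plant(self, small_space):
        layout, constraints, grid = small_space
        plant, target_cec = make_step_plant(0, small_space)
        first_on = next(
            s
            for s in sort_by_charge(enumerate_stimuli(layout, constraints, grid))
            if s.cec.main_cathode == target_cec
            and plant.response(s).magnitude_mm > 0.9 * plant.magnitudes_mm[target_cec]
        )
        target = TargetSpec(plant.response(first_on))
        cfg = _config(target)
        res = run_search(plant, layout, constraints, grid, cfg)
        assert res.status == "found"
        mapped = run_mapping(plant, layout, constraints, grid, cfg)
        assert select_best(mapped, target)[0] == res.found_stimulus == first_on

    def test_all_cecs_excluded_after_one_charge_level(self, small_space):
        layout, constraints, grid = small_space
        plant = ConstantPlant(DisplacementVector.from_polar(5.0, 180.0))
        cfg = _config(_target(5.0, 0.0))
        res = run_search(plant, layout, constraints, grid, cfg)
        assert res.status == "all_cecs_excluded"
        assert res.stimuli_tested == 5
        min_charge = min(s.charge_nc for s in enumerate_stimuli(layout, constraints, grid))
        assert all(t.charge_nc == min_charge for t in res.trials)
        assert set(res.excluded_cecs.values()) == {"direction_deviation"}

    def test_sub_significant_plant_exhausts_full_space(self, small_space):
        layout, constraints, grid = small_space
        plant = ConstantPlant(DisplacementVector(0.1, 0.0))
        res = run_search(plant, layout, constraints, grid, _config(_target(5.0, 0.0)))
        assert res.status == "exhausted"
        assert res.stimuli_tested == 60
        assert res.excluded_cecs == {}

    def test_magnitude_overshoot_excludes_cec(self, small_space):
        layout, constraints, grid = small_space
        plant = ConstantPlant(DisplacementVector.from_polar(8.0, 0.0))
        res = run_search(plant, layout, constraints, grid, _config(_target(5.0, 0.0)))
        assert res.status == "all_cecs_excluded"
        assert set(res.excluded_cecs.values()) == {"magnitude_overshoot"}

    def test_in_tolerance_overshoot_still_succeeds(self, small_space):
        # tolerance circle extends beyond the desired magnitude: success first
        layout, constraints, grid = small_space
        plant = ConstantPlant(DisplacementVector.from_polar(5.5, 0.0))
        res = run_search(
            plant, layout, constraints, grid, _config(_target(5.0, 0.0, tolerance_pct=15.0))
        )
        assert res.status == "found"

    def test_unstable_responses_are_skipped_not_accepted(self, small_space):
        layout, constraints, grid = small_space

        class JitteryPlant:
            # alternating responses around the target: F far above 10%
            def __init__(self):
                self.flip = 1.0

            def __call__(self, stimulus, t):
                self.flip = -self.flip
                return DisplacementVector(5.0 + 2.0 * self.flip, 0.0)

        cfg = _config(_target(5.0, 0.0), exclude_on_unstable=False)
        res = run_search(JitteryPlant(), layout, constraints, grid, cfg)
        assert res.status == "exhausted"
        assert all(t.decision == "skip" for t in res.trials)

    def test_exclude_on_unstable_switch(self, small_space):
        layout, constraints, grid = small_space

        class JitteryOffTarget:
            def __init__(self):
                self.flip = 1.0

            def __call__(self, stimulus, t):
                self.flip = -self.flip
                return DisplacementVector.from_polar(6.0 + 3.0 * self.flip, 170.0)

        target = _target(5.0, 0.0)
        res_strict = run_search(
            JitteryOffTarget(), layout, constraints, grid,
            _config(target, exclude_on_unstable=True),
        )
        res_lenient = run_search(
            JitteryOffTarget(), layout, constraints, grid,
            _config(target, exclude_on_unstable=False),
        )
        assert res_strict.status == "all_cecs_excluded"
        assert res_lenient.excluded_cecs == {}

    def test_plant_failure_treated_as_skip(self, small_space):
        layout, constraints, grid = small_space

        class BrokenPlant:
            def __call__(self, stimulus, t):
                raise RuntimeError("no hardware")

        res = run_search(BrokenPlant(), layout, constraints, grid, _config(_target(5.0, 0.0)))
        assert res.status == "exhausted"
        assert all(t.decision == "skip" and t.reason == "plant_failure" for t in res.trials)

    def test_search_requires_target(self, small_space):
        layout, constraints, grid = small_space
        with pytest.raises(ValueError):
            run_search(ConstantPlant(DisplacementVector(1, 0)), layout, constraints, grid, _config())


class TestSearchInvariants:
    @pytest.mark.parametrize("seed", range(6))
    def test_charge_monotone_per_cec_and_bounded_by_mapping(self, small_space, seed):
        layout, constraints, grid = small_space
        plant, target_cec = make_step_plant(seed, small_space)
        target = TargetSpec(
            DisplacementVector.from_polar(
                plant.magnitudes_mm[target_cec], plant.directions_deg[target_cec]
            )
        )
        res = run_search(plant, layout, constraints, grid, _config(target))
        assert res.stimuli_tested <= 60
        per_cec: dict = {}
        for t in res.trials:
            per_cec.setdefault(t.stimulus.cec.main_cathode, []).append(t.charge_nc)
        for charges in per_cec.values():
            assert charges == sorted(charges)

    @pytest.mark.parametrize("seed", range(6))
    def test_excluded_cecs_contain_no_higher_charge_solution(self, small_space, seed):
        layout, constraints, grid = small_space
        plant, target_cec = make_step_plant(seed, small_space)
        target = TargetSpec(
            DisplacementVector.from_polar(
                plant.magnitudes_mm[target_cec], plant.directions_deg[target_cec]
            )
        )
        res = run_search(plant, layout, constraints, grid, _config(target))
        excluded_mains = {cid.split("|")[0] for cid in res.excluded_cecs}
        for s in enumerate_stimuli(layout, constraints, grid):
            if s.cec.main_cathode in excluded_mains:
                assert (
                    plant.response(s).distance_to(target.desired) > target.tolerance_radius_mm
                )

    def test_trial_log_replays_every_decision(self, small_space):
        from cuffsearch.response_metrics import (
            angular_deviation,
            is_significant,
            matches_target,
            variability,
        )

        layout, constraints, grid = small_space
        plant, target_cec = make_step_plant(1, small_space)
        target = TargetSpec(
            DisplacementVector.from_polar(
                plant.magnitudes_mm[target_cec], plant.directions_deg[target_cec]
            )
        )
        cfg = _config(target)
        res = run_search(plant, layout, constraints, grid, cfg)
        assert res.status in ("found", "exhausted", "all_cecs_excluded")
        for t in res.trials:
            mean = t.record.mean
            f = variability(t.record.repetitions)
            stable = f <= cfg.variability_limit_pct
            if t.decision == "accept":
                assert stable and matches_target(mean, target)
            elif t.decision == "exclude":
                assert is_significant(mean, target)
                assert (
                    angular_deviation(mean, target.desired) > target.max_direction_deviation_deg
                    or mean.magnitude_mm > target.desired.magnitude_mm
                )


class TestCache:
    def test_full_cache_hit_requires_no_plant_invocations(self, small_space):
        layout, constraints, grid = small_space
        plant, target_cec = make_step_plant(2, small_space)
        target = TargetSpec(
            DisplacementVector.from_polar(
                plant.magnitudes_mm[target_cec], plant.directions_deg[target_cec]
            )
        )
        cfg = _config(target)
        cache: dict = {}
        first = run_search_with_cache(plant, layout, constraints, grid, cfg, cache)
        second = run_search_with_cache(plant, layout, constraints, grid, cfg, cache)
        assert second.stimuli_tested == 0
        assert second.found_stimulus == first.found_stimulus

    def test_overlapping_searches_invoke_plant_once_per_union_element(self, small_space):
        layout, constraints, grid = small_space
        plant, _ = make_step_plant(3, small_space)
        cathodes = list(constraints.main_cathodes)
        t1 = TargetSpec(
            DisplacementVector.from_polar(plant.magnitudes_mm[cathodes[0]],
                                          plant.directions_deg[cathodes[0]])
        )
        t2 = TargetSpec(
            DisplacementVector.from_polar(plant.magnitudes_mm[cathodes[1]],
                                          plant.directions_deg[cathodes[1]])
        )
        cache: dict = {}
        r1 = run_search_with_cache(plant, layout, constraints, grid, _config(t1), cache)
        r2 = run_search_with_cache(plant, layout, constraints, grid, _config(t2), cache)
        union = {t.stimulus.key for t in r1.trials} | {t.stimulus.key for t in r2.trials}
        assert r1.stimuli_tested + r2.stimuli_tested == len(union)
        assert r1.stimuli_tested + r2.stimuli_tested < r1.combos_evaluated + r2.combos_evaluated \
            or r2.combos_evaluated == r2.stimuli_tested

    def test_empty_cache_identical_to_plain_search(self, small_space):
        layout, constraints, grid = small_space
        plant_a, target_cec = make_step_plant(4, small_space)
        plant_b, _ = make_step_plant(4, small_space)
        target = TargetSpec(
            DisplacementVector.from_polar(
                plant_a.magnitudes_mm[target_cec], plant_a.directions_deg[target_cec]
            )
        )
        plain = run_search(plant_a, layout, constraints, grid, _config(target))
        cached = run_search_with_cache(plant_b, layout, constraints, grid, _config(target), {})
        assert plain.found_stimulus == cached.found_stimulus
        assert [t.stimulus.key for t in plain.trials] == [t.stimulus.key for t in cached.trials]


class TestDualRate:
    def test_coarse_stepping_skips_sub_threshold_trials(self, single_cec_space):
        layout, constraints, grid = single_cec_space

        class HighThresholdPlant(DirectionalStepPlant):
            pass

        def fresh():
            return HighThresholdPlant({"BI": 0.0}, {"BI": 5.0}, {"BI": 15.0})

        target = _target(5.0, 0.0)
        base = run_search(fresh(), layout, constraints, grid, _config(target))
        dual = run_search_dual_rate(
            fresh(), layout, constraints, grid, _config(target), 4.0, 1.5
        )
        def n_subthreshold(res):
            return sum(1 for t in res.trials if t.record.mean.magnitude_mm < 0.5)

        assert dual.status == base.status == "found"
        assert n_subthreshold(dual) < n_subthreshold(base)

    def test_fine_limit_reproduces_baseline_when_always_significant(self, single_cec_space):
        layout, constraints, grid = single_cec_space
        plant = ConstantPlant(DisplacementVector.from_polar(3.0, 30.0))
        target = _target(5.0, 0.0)  # 30° off, within 60°, never matches/overshoots
        base = run_search(ConstantPlant(plant.value), layout, constraints, grid, _config(target))
        dual = run_search_dual_rate(
            ConstantPlant(plant.value), layout, constraints, grid, _config(target),
            1.0002, 1.0001,
        )
        assert [t.stimulus.key for t in dual.trials] == [t.stimulus.key for t in base.trials]

    def test_overshooting_ladder_falls_back_to_largest_and_terminates(self, single_cec_space):
        layout, constraints, grid = single_cec_space
        plant = ConstantPlant(DisplacementVector(0.1, 0.0))
        res = run_search_dual_rate(
            plant, layout, constraints, grid, _config(_target(5.0, 0.0)), 1000.0, 2.0
        )
        assert res.status == "exhausted"
        max_charge = max(s.charge_nc for s in enumerate_stimuli(layout, constraints, grid))
        assert res.trials[-1].charge_nc == max_charge
        assert res.stimuli_tested < 16


class TestBisection:
    def test_dual_rate_overshoot_recovered_by_bisection(self, single_cec_space):
        layout, constraints, grid = single_cec_space
        target = _target(6.0, 0.0)  # in tolerance only at 12 nC on the ramp below

        def fresh():
            return RampPlant(direction_deg=0.0, gain_mm_per_nc=0.5)

        without = run_search_dual_rate(
            fresh(), layout, constraints, grid, _config(target), 4.0, 2.0
        )
        assert without.status == "all_cecs_excluded"
        assert "magnitude_overshoot" in without.excluded_cecs.values()

        with_bisect = run_search_dual_rate(
            fresh(), layout, constraints, grid, _config(target), 4.0, 2.0, use_bisection=True
        )
        assert with_bisect.status == "found"
        assert with_bisect.found_stimulus.charge_nc == pytest.approx(12.0)

    def test_direction_violation_during_bisection_excludes(self, single_cec_space):
        layout, constraints, grid = single_cec_space
        stimuli = sort_by_charge(enumerate_stimuli(layout, constraints, grid))
        target = _target(6.0, 0.0)
        cfg = _config(target)

        class SidewaysPlant(RampPlant):
            def __call__(self, stimulus, t):
                # intermediate charges pull 90° off-direction
                if 9.0 < stimulus.charge_nc < 15.0:
                    return DisplacementVector.from_polar(6.0, 90.0)
                return super().__call__(stimulus, t)

        low = next(s for s in stimuli if s.charge_nc == 8.0)
        high = next(s for s in stimuli if s.charge_nc == 16.0)
        plant = SidewaysPlant()
        low_rec = ResponseRecord(low, [plant(low, 0.0)] * 2, 10.0)
        high_rec = ResponseRecord(high, [plant(high, 0.0)] * 2, 10.0)
        status, hit, trials = bisect_on_overshoot(
            plant, stimuli, (low, low_rec), (high, high_rec), target, cfg
        )
        assert status == "exclude" and hit is None
        assert trials[0].reason.endswith("direction_deviation")

    def test_adjacent_bracket_has_no_intermediate(self, single_cec_space):
        layout, constraints, grid = single_cec_space
        stimuli = sort_by_charge(enumerate_stimuli(layout, constraints, grid))
        plant = RampPlant()
        target = _target(6.0, 0.0)
        low, high = stimuli[0], stimuli[1]
        low_rec = ResponseRecord(low, [plant(low, 0.0)] * 2, 10.0)
        high_rec = ResponseRecord(high, [plant(high, 0.0)] * 2, 10.0)
        status, hit, trials = bisect_on_overshoot(
            plant, [s for s in stimuli[2:]], (low, low_rec), (high, high_rec), target,
            _config(target),
        )
        assert status == "exclude" and trials == []


class TestVerifyStimulus:
    def test_noise_free_verification_reports_zero_variability(self, small_space):
        layout, constraints, grid = small_space
        stim = enumerate_stimuli(layout, constraints, grid)[0]
        plant = ConstantPlant(DisplacementVector(3.0, 4.0))
        rec = verify_stimulus(plant, stim, _config())
        assert rec.variability_pct == 0.0
        assert rec.mean == DisplacementVector(3.0, 4.0)
        assert rec.included  # no gating applied

    def test_drift_separates_search_time_and_verification_means(self, small_space):
        layout, constraints, grid = small_space
        stim = sort_by_charge(enumerate_stimuli(layout, constraints, grid))[-1]
        plant = SimulatedPlant(make_paperlike_plant(5))
        cfg = _config()
        early = verify_stimulus(plant, stim, cfg, start_time_s=0.0)
        late = verify_stimulus(plant, stim, cfg, start_time_s=3300.0)  # ~55 virtual minutes
        rel_shift = abs(late.mean.magnitude_mm - early.mean.magnitude_mm) / early.mean.magnitude_mm
        assert rel_shift > 0.10
        assert early.variability_pct < 15.0 and late.variability_pct < 15.0

    def test_zero_response_yields_undefined_variability_sentinel(self, small_space):
        layout, constraints, grid = small_space
        stim = enumerate_stimuli(layout, constraints, grid)[0]
        rec = verify_stimulus(ConstantPlant(DisplacementVector(0, 0)), stim, _config())
        assert math.isinf(rec.variability_pct)
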