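"""The two search routines: systematic mapping and the adaptive charge-ordered search.

**Mapping** delivers every admissible (SPV, CEC) combination, repeats each
stimulus n times, and records the mean displacement and the variability F of
each; afterwards the combination whose mean lies closest to a desired
displacement can be selected.

**Automated search** orders the same stimulus space by ascending total
charge and walks it one charge level at a time across all still-active CECs,
comparing every mean response with the desired displacement:

* a stable (F within limit) response inside the tolerance circle → success,
  stop — the found stimulus is then the lowest-charge admissible solution;
* a significant response too far off-direction, or stronger than desired →
  the CEC is *excluded* from all higher charges (higher charge would only
  make the undesired activation stronger);
* an unstable response (F over limit) → the result is skipped, the CEC
  stays active;
* otherwise the walk continues to the next charge.

Three optional strategies accelerate repeated or long searches: a response
cache shared between searches (identical stimuli are never re-delivered), a
dual-rate charge ladder (coarse steps until a significant response is seen,
fine steps after), and overshoot bisection (instead of excluding a CEC whose
response overshot in the right direction, probe the geometric-mean charge
between the bracketing stimuli).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, MutableMapping, Optional, Sequence

from .response_metrics import (
    DisplacementVector,
    ResponseRecord,
    TargetSpec,
    angular_deviation,
    is_significant,
    matches_target,
)
from .stim_space import (
    CecConstraints,
    ContactConfiguration,
    ElectrodeLayout,
    SpvGrid,
    Stimulus,
    enumerate_cecs,
    enumerate_spvs,
    sort_by_charge,
)

__all__ = [
    "RoutineConfig",
    "TrialRecord",
    "ResultsCollection",
    "SearchResult",
    "VirtualClock",
    "run_mapping",
    "select_best",
    "run_search",
    "run_search_with_cache",
    "run_search_dual_rate",
    "bisect_on_overshoot",
    "verify_stimulus",
]

#: A plant responder: (stimulus, virtual time [s]) → DisplacementVector.
Responder = Callable[[Stimulus, float], DisplacementVector]


@dataclass(frozen=True)
class RoutineConfig:
    """Operator criteria shared by both routines.

    ``n_repetitions`` stimuli are delivered per (SPV, CEC) combination, at
    least ``min_inter_stimulus_delay_ms`` apart;
    ``processing_allowance_ms`` models the acquisition/processing time per
    stimulus, so the virtual clock advances by the larger of the two (the
    default reproduces an effective stimulation rate of ~1.5 Hz).
    ``variability_limit_pct`` is the F gate; ``target`` is required for
    search runs.  ``exclude_on_unstable`` controls whether the exclusion
    rules may fire on a mean whose F exceeded the limit (the gate blocks
    acceptance either way).
    """

    n_repetitions: int = 3
    min_inter_stimulus_delay_ms: float = 400.0
    variability_limit_pct: float = 10.0
    target: Optional[TargetSpec] = None
    processing_allowance_ms: float = 667.0
    exclude_on_unstable: bool = True
    variability_method: str = "mean"

    def __post_init__(self) -> None:
        if self.n_repetitions < 2:
            raise ValueError("n_repetitions must be at least 2")
        if self.min_inter_stimulus_delay_ms < 0:
            raise ValueError("inter-stimulus delay must be non-negative")
        if self.variability_limit_pct <= 0:
            raise ValueError("variability limit must be positive")

    @property
    def step_s(self) -> float:
        return max(self.min_inter_stimulus_delay_ms, self.processing_allowance_ms) / 1000.0


class VirtualClock:
    """Monotone virtual time [s]; the plant's drift process runs against it."""

    def __init__(self, t0: float = 0.0):
        self.t = t0

    def advance(self, seconds: float) -> None:
        self.t += seconds


@dataclass
class TrialRecord:
    """One delivered (or cache-served) stimulus with the decision taken on it."""

    stimulus: Stimulus
    record: ResponseRecord
    decision: str  # accept | exclude | skip | continue
    reason: str
    time_s: float
    from_cache: bool = False

    @property
    def charge_nc(self) -> float:
        return self.stimulus.charge_nc


@dataclass
class ResultsCollection:
    """Outcome of a mapping run: one ResponseRecord per enumerated stimulus.

    Records whose F exceeded the variability limit are retained in the log
    but flagged ``included=False``, removing them from the selectable set.
    """

    records: list[ResponseRecord]
    duration_s: float = 0.0

    @property
    def stimuli_tested(self) -> int:
        return len(self.records)

    @property
    def included_records(self) -> list[ResponseRecord]:
        return [r for r in self.records if r.included]

    def n_significant(self, min_magnitude_mm: float = 0.5) -> int:
        return sum(
            1 for r in self.records if not r.failed and r.mean.magnitude_mm > min_magnitude_mm
        )


@dataclass
class SearchResult:
    """Outcome of an automated search run."""

    status: str  # found | exhausted | all_cecs_excluded
    found_stimulus: Optional[Stimulus]
    found_record: Optional[ResponseRecord]
    stimuli_tested: int  # distinct (SPV, CEC) combinations delivered to the plant
    combos_evaluated: int  # including cache hits
    excluded_cecs: dict[str, str]  # cec_id → exclusion reason
    trials: list[TrialRecord]
    duration_s: float = 0.0


def _deliver(
    plant: Responder, stimulus: Stimulus, config: RoutineConfig, clock: VirtualClock
) -> ResponseRecord:
    """Deliver n repetitions, advancing the virtual clock between stimuli."""
    reps: list[DisplacementVector] = []
    try:
        for _ in range(config.n_repetitions):
            reps.append(plant(stimulus, clock.t))
            clock.advance(config.step_s)
    except Exception:
        return ResponseRecord(
            stimulus, [], config.variability_limit_pct, config.variability_method, failed=True
        )
    return ResponseRecord(stimulus, reps, config.variability_limit_pct, config.variability_method)


def run_mapping(
    plant: Responder,
    layout: ElectrodeLayout,
    constraints: CecConstraints,
    grid: SpvGrid,
    config: RoutineConfig,
) -> ResultsCollection:
    """Systematically map every (SPV, CEC) combination to its mean response.

    Each enumerated stimulus is delivered ``config.n_repetitions`` times; a
    plant failure on one combination is recorded as a failed trial and the
    mapping continues.  The collection covers every combination exactly once.
    """
    clock = VirtualClock()
    records: list[ResponseRecord] = []
    for cec_idx, cec in enumerate(enumerate_cecs(layout, constraints)):
        for spv in enumerate_spvs(grid, cec):
            stimulus = Stimulus(cec, spv, cec_index=cec_idx)
            records.append(_deliver(plant, stimulus, config, clock))
    return ResultsCollection(records, duration_s=clock.t)


def select_best(
    collection: ResultsCollection, target: TargetSpec
) -> Optional[tuple[Stimulus, ResponseRecord]]:
    """The included record whose mean lies closest to the desired displacement.

    Ties are broken by lower stimulus charge, then enumeration order; returns
    ``None`` when the selectable set is empty.
    """
    best: Optional[tuple[float, float, int, Stimulus, ResponseRecord]] = None
    for i, rec in enumerate(collection.records):
        if not rec.included or rec.failed:
            continue
        stim: Stimulus = rec.stimulus  # type: ignore[assignment]
        key = (rec.mean.distance_to(target.desired), stim.charge_nc, i)
        if best is None or key < best[:3]:
            best = (*key, stim, rec)
    if best is None:
        return None
    return best[3], best[4]


# ---------------------------------------------------------------------------
# The adaptive search engine


@dataclass
class _CecState:
    cec: ContactConfiguration
    cec_index: int
    stimuli: list[Stimulus]  # charge-ascending
    tested: set[int] = field(default_factory=set)
    excluded: bool = False
    seen_significant: bool = False
    last_charge: Optional[float] = None
    # most recent tested stimulus that did NOT overshoot: bisection's lower bracket
    last_non_overshoot: Optional[tuple[Stimulus, ResponseRecord]] = None

    def next_baseline(self) -> Optional[int]:
        for i in range(len(self.stimuli)):
            if i not in self.tested:
                return i
        return None

    def next_dual_rate(self, factor: float) -> Optional[int]:
        """Snap the charge ladder to the untested stimulus nearest last_charge×factor.

        Only stimuli at or above the last tested charge are eligible (the
        ladder ascends); a target beyond the grid falls back to the largest
        untested stimulus.
        """
        assert self.last_charge is not None
        target_q = self.last_charge * factor
        best: Optional[tuple[float, float, int]] = None
        for i, s in enumerate(self.stimuli):
            if i in self.tested or s.charge_nc < self.last_charge:
                continue
            key = (abs(s.charge_nc - target_q), s.charge_nc, i)
            if best is None or key < best:
                best = key
        return None if best is None else best[2]


def _evaluate(
    record: ResponseRecord, target: TargetSpec, config: RoutineConfig
) -> tuple[str, str]:
    """Classify one pooled response: (decision, reason).

    Decision order matters: success is checked before exclusion, so an
    in-tolerance response that overshoots the desired magnitude still
    succeeds; exclusion fires only on significant responses.
    """
    if record.failed:
        return "skip", "plant_failure"
    mean, F = record.mean, record.variability_pct
    stable = F <= config.variability_limit_pct
    if stable and matches_target(mean, target):
        return "accept", "within_tolerance"
    if is_significant(mean, target):
        direction_bad = (
            not mean.is_zero
            and angular_deviation(mean, target.desired) > target.max_direction_deviation_deg
        )
        magnitude_bad = mean.magnitude_mm > target.desired.magnitude_mm
        if (direction_bad or magnitude_bad) and (stable or config.exclude_on_unstable):
            if direction_bad:
                return "exclude", "direction_deviation"
            return "exclude", "magnitude_overshoot"
    if not stable:
        return "skip", "variability_above_limit"
    return "continue", "no_rule_fired"


def bisect_on_overshoot(
    plant: Responder,
    candidates: Sequence[Stimulus],
    low: tuple[Stimulus, ResponseRecord],
    high: tuple[Stimulus, ResponseRecord],
    target: TargetSpec,
    config: RoutineConfig,
    clock: Optional[VirtualClock] = None,
) -> tuple[str, Optional[tuple[Stimulus, ResponseRecord]], list[TrialRecord]]:
    """Probe charges between an undershooting and an overshooting stimulus.

    Preconditions: ``high``'s response overshot the desired magnitude with an
    acceptable direction, and ``low``'s charge is below ``high``'s.  The
    mid-charge stimulus — the admissible candidate nearest the geometric mean
    of the bracket charges — is delivered and the bracket narrowed until a
    response matches the target (status ``found``), the direction rule is
    violated, or no admissible intermediate remains (status ``exclude``).
    """
    clock = clock or VirtualClock()
    trials: list[TrialRecord] = []
    lo_q, hi_q = low[0].charge_nc, high[0].charge_nc
    if not lo_q < hi_q:
        raise ValueError("low bracket charge must be below high bracket charge")
    pool = {s.key: s for s in candidates}
    while True:
        inside = [s for s in pool.values() if lo_q < s.charge_nc < hi_q]
        if not inside:
            return "exclude", None, trials
        mid_q = math.sqrt(lo_q * hi_q)
        stim = min(inside, key=lambda s: (abs(s.charge_nc - mid_q), s.charge_nc))
        del pool[stim.key]
        record = _deliver(plant, stim, config, clock)
        decision, reason = _evaluate(record, target, config)
        trials.append(TrialRecord(stim, record, decision, f"bisection:{reason}", clock.t))
        if decision == "accept":
            return "found", (stim, record), trials
        if decision == "exclude" and reason == "direction_deviation":
            return "exclude", None, trials
        overshoot = (
            not record.failed and record.mean.magnitude_mm > target.desired.magnitude_mm
        )
        if overshoot:
            hi_q = stim.charge_nc
        else:
            lo_q = stim.charge_nc


def run_search(
    plant: Responder,
    layout: ElectrodeLayout,
    constraints: CecConstraints,
    grid: SpvGrid,
    config: RoutineConfig,
    *,
    cache: Optional[MutableMapping[tuple, ResponseRecord]] = None,
    coarse_factor: Optional[float] = None,
    fine_factor: Optional[float] = None,
    use_bisection: bool = False,
) -> SearchResult:
    """Adaptive search for the lowest-charge stimulus producing the target.

    The stimulus space is walked in ascending total charge across all
    non-excluded CECs (ties: shorter duration, lower amplitude, lower
    steering fraction, CEC order).  Each (SPV, CEC) combination is tested at
    most once.  See the module docstring for the decision rules; the keyword
    arguments switch on the cache, dual-rate and bisection strategies.
    """
    if config.target is None:
        raise ValueError("search requires a target in the routine config")
    if (coarse_factor is None) != (fine_factor is None):
        raise ValueError("coarse and fine factors must be given together")
    dual_rate = coarse_factor is not None
    if dual_rate and not coarse_factor > fine_factor > 1.0:
        raise ValueError("factors must satisfy coarse > fine > 1")
    target = config.target
    if target.desired.is_zero:
        raise ValueError("desired displacement must be non-zero")

    clock = VirtualClock()
    states: list[_CecState] = []
    for i, cec in enumerate(enumerate_cecs(layout, constraints)):
        stimuli = sort_by_charge(
            Stimulus(cec, spv, cec_index=i) for spv in enumerate_spvs(grid, cec)
        )
        states.append(_CecState(cec, i, stimuli))

    import heapq

    def entry(st: _CecState, idx: int) -> tuple:
        s = st.stimuli[idx]
        frac = s.spv.steering_fraction or 0.0
        return (
            s.charge_nc,
            s.spv.pulse_duration_us,
            s.spv.main_amplitude_ua,
            frac,
            st.cec_index,
            idx,
        )

    heap: list[tuple] = []
    for st in states:
        idx = st.next_baseline()
        if idx is not None:
            heapq.heappush(heap, entry(st, idx))

    trials: list[TrialRecord] = []
    excluded: dict[str, str] = {}
    tested_plant = 0
    combos = 0
    found: Optional[tuple[Stimulus, ResponseRecord]] = None

    while heap and found is None:
        *_, cec_index, idx = heapq.heappop(heap)
        st = states[cec_index]
        if st.excluded or idx in st.tested:
            continue
        stimulus = st.stimuli[idx]
        st.tested.add(idx)
        st.last_charge = stimulus.charge_nc
        combos += 1

        from_cache = cache is not None and stimulus.key in cache
        if from_cache:
            record = cache[stimulus.key]
        else:
            record = _deliver(plant, stimulus, config, clock)
            tested_plant += 1
            if cache is not None:
                cache[stimulus.key] = record

        decision, reason = _evaluate(record, target, config)
        if not record.failed and is_significant(record.mean, target):
            st.seen_significant = True

        if decision == "exclude" and use_bisection and reason == "magnitude_overshoot":
            if st.last_non_overshoot is not None:
                candidates = [
                    st.stimuli[i] for i in range(len(st.stimuli)) if i not in st.tested
                ]
                trials.append(
                    TrialRecord(stimulus, record, "bisect", reason, clock.t, from_cache)
                )
                status, hit, bis_trials = bisect_on_overshoot(
                    plant, candidates, st.last_non_overshoot, (stimulus, record),
                    target, config, clock,
                )
                for tr in bis_trials:
                    st.tested.add(st.stimuli.index(tr.stimulus))
                    tested_plant += 1
                    combos += 1
                    if cache is not None:
                        cache[tr.stimulus.key] = tr.record
                trials.extend(bis_trials)
                if status == "found":
                    found = hit
                    break
                decision, reason = "exclude", "bisection_exhausted"
            # no lower bracket: fall through to plain exclusion

        trials.append(TrialRecord(stimulus, record, decision, reason, clock.t, from_cache))

        if decision == "accept":
            found = (stimulus, record)
            break
        if decision == "exclude":
            st.excluded = True
            excluded[st.cec.cec_id] = reason
            continue
        if not record.failed and not (
            record.mean.magnitude_mm > target.desired.magnitude_mm
        ):
            st.last_non_overshoot = (stimulus, record)

        if dual_rate:
            nxt = (
                st.next_dual_rate(fine_factor)
                if st.seen_significant
                else st.next_dual_rate(coarse_factor)
            )
        else:
            nxt = st.next_baseline()
        if nxt is not None:
            heapq.heappush(heap, entry(st, nxt))

    if found is not None:
        status = "found"
    elif all(st.excluded for st in states) and states:
        status = "all_cecs_excluded"
    else:
        status = "exhausted"
    return SearchResult(
        status=status,
        found_stimulus=found[0] if found else None,
        found_record=found[1] if found else None,
        stimuli_tested=tested_plant,
        combos_evaluated=combos,
        excluded_cecs=excluded,
        trials=trials,
        duration_s=clock.t,
    )


def run_search_with_cache(
    plant: Responder,
    layout: ElectrodeLayout,
    constraints: CecConstraints,
    grid: SpvGrid,
    config: RoutineConfig,
    cache: MutableMapping[tuple, ResponseRecord],
) -> SearchResult:
    """As :func:`run_search`, reusing responses recorded by earlier searches.

    A cache hit substitutes the stored record without invoking the plant;
    ``stimuli_tested`` counts plant invocations only, and new records are
    added to the (caller-owned, shareable) cache.
    """
    return run_search(plant, layout, constraints, grid, config, cache=cache)


def run_search_dual_rate(
    plant: Responder,
    layout: ElectrodeLayout,
    constraints: CecConstraints,
    grid: SpvGrid,
    config: RoutineConfig,
    coarse_factor: float,
    fine_factor: float,
    *,
    use_bisection: bool = False,
) -> SearchResult:
    """As :func:`run_search`, with a two-speed per-CEC charge ladder.

    While a CEC has produced only insignificant responses its ladder advances
    by ``coarse_factor`` per step; after the first significant response it
    advances by ``fine_factor``; target charges snap to the nearest untested
    admissible stimulus, falling back to the largest one when the ladder
    overshoots the grid.
    """
    return run_search(
        plant, layout, constraints, grid, config,
        coarse_factor=coarse_factor, fine_factor=fine_factor, use_bisection=use_bisection,
    )


def verify_stimulus(
    plant: Responder,
    stimulus: Stimulus,
    config: RoutineConfig,
    start_time_s: float = 0.0,
) -> ResponseRecord:
    """Re-deliver one stimulus n times and report mean and F, with no gating.

    ``start_time_s`` places the verification on the plant's virtual clock, so
    a long gap since the search exposes slow response drift.
    """
    clock = VirtualClock(start_time_s)
    reps = []
    for _ in range(config.n_repetitions):
        reps.append(plant(stimulus, clock.t))
        clock.advance(config.step_s)
    return ResponseRecord(stimulus, reps, None, config.variability_method)
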