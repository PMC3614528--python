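# Methods

This note documents the models and procedures `cuffsearch` implements, the
defaults it ships, the numerical choices made, and what the synthetic plant
does and does not emulate.

## Stimulus space

A stimulus is a pair (CEC, SPV). A **CEC** assigns one of exactly four
states — cathode, anode, grounded, not connected — to every contact of the
cuff, designating one contact as the main cathode and optionally a second
contact as a cathodic or anodic steering contact. Construction enforces the
structural invariants (one main cathode in cathode state, at least one
grounded contact, steering contact distinct from the main cathode with a
state matching its polarity, everything else not connected); candidate
configurations violating them — e.g. a ground rule that grounds nothing —
are dropped during enumeration rather than raising.

An **SPV** is (pulse duration [μs], main amplitude [μA], steering fraction).
Amplitudes are stored as positive magnitudes with the sign implied by the
contact role (cathodic current is negative at the contact); this avoids sign
errors in charge arithmetic. Main and steering pulses are concurrent and
share the duration; the steering amplitude is the fraction times the main
amplitude.

**Total charge** is `duration × (main + |steering|) / 1000` nC. The steering
pulse contributes its magnitude irrespective of polarity: an anodic steering
pulse delivers charge just as a cathodic one does, and this is the only
formula consistent with the reference dataset's charge column across both
polarities.

**Ordering.** Charge ties are broken by (shorter duration, lower main
amplitude, lower steering fraction, CEC enumeration order) — an arbitrary
but fixed total order chosen for reproducibility. CEC enumeration order is
main cathode in the configured order, then the bare configuration, then
auxiliary positions by contact order with roles in the order cathodic steer,
anodic steer, grounded.

**Identity.** A grounded auxiliary contact and "no auxiliary contact" are
distinct CECs (both without a steering pulse); configurations reached by
different constraint paths that produce the same contact states and role
designations deduplicate. Under the shipped constraints this yields 40 CECs
(4 main cathodes × (1 bare + 3 positions × 3 roles)) and 768 stimuli
(24 steering CECs × 24 SPVs + 16 non-steering CECs × 12 SPVs).

The constraint model allows the auxiliary contact anywhere on the cuff; the
shipped configuration restricts it to row B, which is the only layout the
reference protocol exercised.

## Response metrics

**Displacement estimation.** Acceleration (frontal plane, m/s², sampled
≥ 1 kHz) is integrated twice by the trapezoidal rule at the native sample
rate, with velocity and position zero at stimulation onset. The reported
displacement is the sample of maximal Euclidean norm within the first 80 ms
(default window) — the *maximal* displacement, not the value at the window
end. When the two axes peak at different times the joint-norm maximum is
used; the alternative (per-axis maxima) would not form a single observed
displacement vector. Trapezoidal error for smooth traces at 1 kHz is well
below 0.1 %.

**Variability F.** Implemented as the mean of Euclidean distances of the
repetition vectors from their mean, normalized by the mean magnitude
(× 100). A root-mean-square variant is available via
`variability(..., method="rms")` for sensitivity checks; the mean-of-distances
form is the default because it is the operative verbal definition of the
statistic. F is invariant under rotation and uniform scaling and is zero iff
all repetitions coincide. A zero mean displacement makes F undefined; the
implementation returns `inf`, which fails every finite gate downstream —
a zero-mean response is never a usable result.

**Conventions and boundaries.** Direction is `atan2(y, x)` in degrees in
(−180, 180], with x = abduction positive and y = dorsiflexion positive — a
repository convention applied consistently to the metrics and the plant (the
sign convention of the original measurements is not recoverable, so
shipped reference directions are only used in convention-independent
derived quantities such as angle differences and distances). The direction
of a zero vector raises rather than silently returning 0. All threshold
comparisons — tolerance circle, significance, variability limit, direction
limit — are boundary-inclusive (≤ / ≥); this is immaterial to any claim and
fixed once for determinism.

## The routines

Shared criteria (defaults from the reference protocol): n = 3 repetitions
per stimulus, ≥ 400 ms between stimuli, variability limit 10 %; search
criteria: tolerance 15 % of the desired magnitude, significance threshold
0.5 mm, direction limit 60°.

**Virtual time.** Routines advance a virtual clock by
`max(delay, processing allowance)` per stimulus; the default processing
allowance of 667 ms reproduces an effective stimulation rate of ~1.5 Hz,
typical of acquisition-limited closed-loop rigs, and gives the plant's drift
process realistic inter-stimulus and inter-phase gaps. Wall-clock time is
never measured.

**Mapping** enumerates the space once and delivers every combination; plant
failures are logged as failed trials and the run continues. Selection
minimizes Euclidean distance of the mean response to the desired
displacement over included records, breaking ties by lower charge then
enumeration order.

**Search** walks the space in ascending charge across active CECs (outer
loop over charge levels, inner loop over CECs, realized as a priority queue
keyed by the charge sort order). Decision order per combination:

1. *Accept* if F ≤ limit and the mean is inside the tolerance circle — the
   search stops. Success is checked **before** exclusion, so an in-tolerance
   response that overshoots the desired magnitude still succeeds.
2. *Exclude* the CEC if the response is significant and its direction
   deviates more than the limit or its magnitude exceeds the desired one.
   Exclusion requires significance (the direction of near-zero noise is
   meaningless). By default exclusion also fires when F exceeded the limit
   (the gate blocks acceptance, not exclusion) — this reproduces the
   observed behaviour where a CEC was dropped after a single divergent
   low-charge response; `exclude_on_unstable=False` restricts exclusion to
   stable responses. The magnitude rule is strict (>) with no extra margin;
   the success-first ordering absorbs near-boundary cases.
3. *Skip* if F exceeds the limit (the CEC stays active). Each (SPV, CEC)
   combination is tested at most once; a skipped combination is not
   re-tested at the same charge.
4. Otherwise *continue*.

Termination: `found`, `exhausted` (sequence consumed), or
`all_cecs_excluded`; every trial is logged with charge, per-repetition
displacements, mean, F, decision and reason, so re-running the log through
the metrics reproduces every decision.

**Cache.** A caller-owned mapping from stimulus identity to response record;
hits substitute the stored record without invoking the plant.
`stimuli_tested` counts plant deliveries only. On a deterministic plant the
cached and uncached searches return identical results.

**Dual-rate ladder.** Per CEC, the next target charge is the last charge
times a coarse factor while all of the CEC's responses have been
insignificant, and times a fine factor afterwards; the target snaps to the
nearest untested admissible stimulus at or above the last charge, falling
back to the largest admissible one when the ladder overshoots the grid. As
the fine factor approaches 1 the ladder degenerates to the baseline walk.

**Overshoot bisection.** When a response overshoots the desired magnitude
with acceptable direction, the baseline rule excludes the CEC — which can
discard the solution when the ladder skipped an intermediate charge.
With bisection enabled the routine instead probes the admissible stimulus
nearest the geometric mean of the bracketing charges, narrowing the bracket
until a response matches, the direction rule is violated, or no admissible
intermediate remains. With the baseline (step-by-step) ladder every
admissible intermediate has already been tested when an overshoot occurs, so
bisection only changes behaviour under dual-rate stepping; the geometric
mean is used because grid charges are multiplicative (duration × amplitude).

**Verification** re-delivers one stimulus n times with no gating and reports
mean and F; placing it at a later virtual time exposes drift.

## The synthetic plant

No forward model of the preparation exists; the plant is the simplest model
exhibiting the phenomenology the routines must cope with:

- Each **muscle group** pulls in a fixed unit direction with contribution
  `A · σ̃((q − θ)/s)` where σ̃ is a logistic recruitment curve rescaled to be
  exactly 0 at zero charge and → A at saturation (sigmoidal recruitment is
  the standard assumption for FES recruitment curves). Responses are
  component-wise monotone in charge per muscle.
- **Selectivity**: per-main-cathode threshold offsets decide which group
  recruits first for each CEC. A steering pulse blends the steering
  contact's offsets in (cathodic) or out (anodic), scaled by steering
  strength × fraction — a minimal stand-in for steering the excitation
  region.
- **Noise**: isotropic Gaussian on the displacement, s.d. proportional to
  magnitude — the simplest model consistent with percent-variability
  reporting.
- **Drift**: a multiplicative gain `exp(X(t))` where X is an
  Ornstein–Uhlenbeck process integrated along virtual time with its exact
  transition density — smooth, stationary, seeded; large shifts across tens
  of minutes, small shifts within a 400 ms repetition train, matching the
  high between-phase / low within-phase variance pattern observed in vivo.

The `paperlike` preset has three groups (plantarflexor with slight
abduction 9 mm, dorsiflexor 5 mm, abductor 4 mm; thresholds 11/6/8 nC before
selectivity offsets of ±2.5 nC), 5 % repetition noise, and OU drift with
τ = 20 min and stationary log-s.d. 0.3 (gain shifts of ≥ 30 % over tens of
virtual minutes are routine). Thresholds were set so roughly half of the
default 768-stimulus grid evokes a significant response, different row-B
cathodes favour different groups at low charge, and charges above ~10 nC
recruit all groups into a single plantarflexion-plus-abduction
co-contraction cluster. The in-vivo drift magnitudes are known only from two
spot values, so the drift parameters are plausibility knobs, not claims.
`noise_free` is the same preset with noise and drift zeroed; it satisfies
the determinism preconditions of the search-equals-mapping property.

What the plant does **not** emulate: fatigue and staircase potentiation,
electrode movement / nerve drying, anisotropic or magnitude-dependent noise
structure, measurement bias of accelerometric displacement estimation
(reported mean errors around 24 % in vivo), or any anatomically realistic
fascicle geometry. Passing tests on this plant therefore demonstrate the
*routines'* correctness and economy under controlled response structure —
not that a real preparation satisfies that structure.

## Test-bed problem sizes

The correctness properties (search ≡ mapping + selection; exclusion
soundness; pruning economy) are verified on 20 seeded noise-free step-plants
over a reduced space of 5 CECs × 12 SPVs with recruitment thresholds kept
clear of grid charges and per-CEC directions 72° apart, so the in-tolerance
set is brute-force enumerable and the equivalence is exact. The full
768-stimulus space is exercised end-to-end by the enumeration, mapping and
preset-phenomenology tests. These sizes make the whole suite run in
seconds while leaving every decision rule exercised.

## Known limitations

- The routines assume the effector returns to its initial position between
  stimuli; sustained or overlapping responses are out of scope.
- Only one main pulse plus at most one steering pulse is modelled; arbitrary
  multi-contact current fields and biphasic charge-balanced waveform
  synthesis are not.
- Overlap analysis between effectors activated by different CECs is not
  implemented (no operational definition exists for it).
- Recruitment-curve *fitting* is not a goal; the sigmoid lives in the plant,
  not in the search.
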