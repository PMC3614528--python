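"""Synthetic effector plant: stimulus → 2D paw displacement, no hardware needed.

The plant models the stimulated nerve–muscle–paw chain as a small set of
directional muscle groups, each recruited sigmoidally with stimulus charge —
the standard recruitment-curve shape in functional electrical stimulation.
Which muscles recruit first depends on the contact configuration through a
per-contact selectivity map, steering pulses shift the recruitment thresholds,
and two stochastic processes reproduce the nuisance structure seen in vivo:

* per-repetition isotropic Gaussian noise scaled to response magnitude
  (repeat-to-repeat variability of a few percent), and
* a slow Ornstein–Uhlenbeck gain drift in virtual time (large response shifts
  between measurements taken tens of minutes apart, small shifts within a
  400 ms repetition train).

Responses are a pure function of (stimulus, virtual time, seeded noise
stream): with noise and drift disabled, identical stimuli give identical
displacements, which the search routines' correctness properties rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .response_metrics import AccelerationTrace, DisplacementVector
from .stim_space import Stimulus

__all__ = [
    "MuscleGroup",
    "PlantModel",
    "SimulatedPlant",
    "synthesize_acceleration",
    "make_paperlike_plant",
    "make_noise_free_plant",
]


def _sigmoid(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


@dataclass(frozen=True)
class MuscleGroup:
    """One directional muscle group recruited sigmoidally with charge.

    ``direction`` is the unit pull direction in the frontal plane (x =
    abduction positive, y = dorsiflexion positive); ``max_mm`` the
    displacement contribution at full recruitment; ``threshold_nc`` the
    charge at half recruitment; ``slope_nc`` the recruitment-curve width.
    """

    name: str
    direction: tuple[float, float]
    max_mm: float
    threshold_nc: float
    slope_nc: float

    def __post_init__(self) -> None:
        if self.max_mm <= 0 or self.slope_nc <= 0:
            raise ValueError("max contribution and slope must be positive")
        n = math.hypot(*self.direction)
        if not math.isclose(n, 1.0, rel_tol=1e-9):
            object.__setattr__(self, "direction", (self.direction[0] / n, self.direction[1] / n))


@dataclass(frozen=True)
class PlantModel:
    """Parameters of the simulated effector.

    ``selectivity`` maps a contact id to per-muscle threshold offsets [nC]
    applied when that contact is the main cathode; a steering pulse blends
    the steering contact's offsets in (cathodic) or out (anodic), scaled by
    ``steering_strength`` × steering fraction — a minimal model of steering
    the excitation region within the nerve.  ``noise_scale`` is the
    per-repetition Gaussian noise s.d. as a fraction of the response
    magnitude; ``drift_tau_s``/``drift_sigma`` parameterise the OU log-gain
    drift (time constant [s], stationary s.d. of the log gain).
    """

    muscles: tuple[MuscleGroup, ...]
    selectivity: Mapping[str, tuple[float, ...]] = field(default_factory=dict)
    steering_strength: float = 0.5
    noise_scale: float = 0.0
    drift_tau_s: float = 1200.0
    drift_sigma: float = 0.0
    saturation_charge_nc: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "muscles", tuple(self.muscles))
        sel = {k: tuple(v) for k, v in dict(self.selectivity).items()}
        for k, v in sel.items():
            if len(v) != len(self.muscles):
                raise ValueError(f"selectivity for {k!r} must give one offset per muscle")
        object.__setattr__(self, "selectivity", sel)
        if self.noise_scale < 0 or self.drift_sigma < 0 or self.drift_tau_s <= 0:
            raise ValueError("noise/drift parameters out of range")

    def thresholds_for(self, stimulus: Stimulus) -> list[float]:
        """Effective per-muscle recruitment thresholds [nC] for one stimulus."""
        cec = stimulus.cec
        zeros = (0.0,) * len(self.muscles)
        main_off = self.selectivity.get(cec.main_cathode, zeros)
        th = [m.threshold_nc + o for m, o in zip(self.muscles, main_off)]
        if cec.has_steering and stimulus.spv.steering_fraction is not None:
            steer_off = self.selectivity.get(cec.steering_contact, zeros)
            blend = self.steering_strength * stimulus.spv.steering_fraction
            sign = 1.0 if cec.steering_polarity == "cathodic" else -1.0
            th = [
                max(0.1, t + sign * blend * (so - mo))
                for t, so, mo in zip(th, steer_off, main_off)
            ]
        return th


class SimulatedPlant:
    """Stateful responder wrapping a :class:`PlantModel`.

    Call it (or :meth:`respond`) with a stimulus and the virtual time of
    delivery [s]; virtual times must be non-decreasing across calls so the
    drift process can be integrated forward.  Two independent seeded
    substreams drive repetition noise and drift, so e.g. disabling noise
    does not change the drift trajectory.
    """

    def __init__(self, model: PlantModel):
        self.model = model
        ss = np.random.SeedSequence(model.seed)
        noise_seed, drift_seed = ss.spawn(2)
        self._noise_rng = np.random.default_rng(noise_seed)
        self._drift_rng = np.random.default_rng(drift_seed)
        self._log_gain = 0.0
        self._last_t: Optional[float] = None
        self.n_invocations = 0

    def _drift_gain(self, t: float) -> float:
        m = self.model
        if m.drift_sigma == 0.0:
            return 1.0
        if self._last_t is None:
            self._last_t = t
            return math.exp(self._log_gain)
        dt = max(0.0, t - self._last_t)
        self._last_t = t
        # exact OU transition for the log gain
        a = math.exp(-dt / m.drift_tau_s)
        sd = m.drift_sigma * math.sqrt(1.0 - a * a)
        self._log_gain = a * self._log_gain + sd * self._drift_rng.standard_normal()
        return math.exp(self._log_gain)

    def deterministic_response(self, stimulus: Stimulus) -> DisplacementVector:
        """Noise- and drift-free recruitment response to one stimulus.

        Each muscle contributes a baseline-subtracted logistic recruitment
        term, rescaled so recruitment is exactly 0 at zero charge and
        approaches ``max_mm`` at saturation — sub-threshold stimuli produce
        near-zero displacement, as a physical recruitment curve does.
        """
        m = self.model
        q = stimulus.charge_nc
        if m.saturation_charge_nc is not None:
            q = min(q, m.saturation_charge_nc)
        x = y = 0.0
        for muscle, th in zip(m.muscles, m.thresholds_for(stimulus)):
            base = _sigmoid(-th / muscle.slope_nc)
            r = muscle.max_mm * (_sigmoid((q - th) / muscle.slope_nc) - base) / (1.0 - base)
            x += r * muscle.direction[0]
            y += r * muscle.direction[1]
        return DisplacementVector(x, y)

    def respond(self, stimulus: Stimulus, virtual_time_s: float) -> DisplacementVector:
        self.n_invocations += 1
        base = self.deterministic_response(stimulus)
        gain = self._drift_gain(virtual_time_s)
        x, y = base.x_mm * gain, base.y_mm * gain
        if self.model.noise_scale > 0.0:
            sd = self.model.noise_scale * math.hypot(x, y)
            eps = self._noise_rng.standard_normal(2) * sd
            x, y = x + eps[0], y + eps[1]
        return DisplacementVector(x, y)

    __call__ = respond


def synthesize_acceleration(
    peak: DisplacementVector,
    window_ms: float = 80.0,
    sample_rate_hz: float = 1000.0,
    mode: str = "min_jerk",
) -> AccelerationTrace:
    """Acceleration trace whose double integral reaches ``peak`` at the window end.

    ``min_jerk`` uses the minimum-jerk position profile
    p(s) = peak·(10s³ − 15s⁴ + 6s⁵), s = t/T, differentiated analytically —
    a smooth trajectory with zero initial velocity; ``constant`` applies the
    constant acceleration 2·peak/T².  Either way trapezoidal double
    integration over the window recovers ``peak`` to well within 1% at
    ≥ 1 kHz sampling, making this the round-trip partner of
    :func:`~cuffsearch.response_metrics.displacement_from_acceleration`.
    """
    if window_ms <= 0:
        raise ValueError("window must be positive")
    if sample_rate_hz < 1000.0:
        raise ValueError("sample rate must be at least 1 kHz")
    T = window_ms / 1000.0
    n = int(round(T * sample_rate_hz)) + 1
    t = np.arange(n) / sample_rate_hz
    p = peak.as_array() / 1000.0  # metres
    if mode == "min_jerk":
        s = t / T
        shape = (60.0 * s - 180.0 * s**2 + 120.0 * s**3) / T**2
    elif mode == "constant":
        shape = np.full(n, 2.0 / T**2)
    else:
        raise ValueError(f"unknown synthesis mode {mode!r}")
    samples = shape[:, None] * p[None, :]
    return AccelerationTrace(sample_rate_hz, samples)


_PAPERLIKE_MUSCLES = (
    # plantarflexor with slight abduction: dominates above ~10 nC
    MuscleGroup("plantarflexor", (0.2, -0.9798), 9.0, 11.0, 2.0),
    MuscleGroup("dorsiflexor", (0.15, 0.9887), 5.0, 6.0, 1.5),
    MuscleGroup("abductor", (1.0, 0.0), 4.0, 8.0, 1.8),
)

# Per-row-B-cathode threshold offsets [nC], order (plantarflexor, dorsiflexor,
# abductor): each cathode favours a different group at low charge; all groups
# recruit above ~10 nC from any cathode (co-contraction).  Thresholds are set
# so roughly half the default stimulus grid evokes a significant (> 0.5 mm)
# response, as in the reference session.
_PAPERLIKE_SELECTIVITY = {
    "BI": (1.5, -2.0, 2.0),
    "BII": (1.0, 2.0, -2.5),
    "BIII": (-2.0, 2.5, 1.0),
    "BIV": (0.0, -0.5, 0.0),
}


def make_paperlike_plant(seed: int = 0) -> PlantModel:
    """Preset emulating the in-vivo phenomenology of the reference experiment.

    Three directional muscle groups (plantarflexor, dorsiflexor, abductor)
    with row-B cathode selectivity at low charge, co-contraction dominated by
    plantarflexion-plus-abduction above ~10 nC, ~5% repetition noise, and an
    OU gain drift (τ = 20 min, log s.d. 0.3) capable of shifting response
    magnitudes by ≥ 30% between measurements tens of virtual minutes apart.
    """
    return PlantModel(
        muscles=_PAPERLIKE_MUSCLES,
        selectivity=_PAPERLIKE_SELECTIVITY,
        steering_strength=0.5,
        noise_scale=0.05,
        drift_tau_s=1200.0,
        drift_sigma=0.3,
        seed=seed,
    )


def make_noise_free_plant(seed: int = 0) -> PlantModel:
    """The paper-like preset with repetition noise and drift disabled."""
    return replace(make_paperlike_plant(seed), noise_scale=0.0, drift_sigma=0.0)
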