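"""Displacement vectors, the variability statistic F, and target predicates.

The effector response to one stimulus is summarised as the maximal 2D
displacement of the paw in the frontal plane within a short window after
stimulation onset: x is the add-/abduction component, y the
plantar-/dorsiflexion component (abduction and dorsiflexion positive, a
repository convention applied consistently to metrics and plant).

Repetitions of the same stimulus are pooled into a mean displacement and a
variability statistic F — the mean Euclidean distance of the individual
maximal displacements from their mean, as a percentage of the mean vector's
magnitude — which gates unstable responses out of the selectable results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "UndefinedDirectionError",
    "DisplacementVector",
    "AccelerationTrace",
    "TargetSpec",
    "ResponseRecord",
    "displacement_from_acceleration",
    "mean_displacement",
    "variability",
    "angular_deviation",
    "matches_target",
    "is_significant",
]


class UndefinedDirectionError(ValueError):
    """The direction (or variability) of a zero-magnitude displacement is undefined."""


@dataclass(frozen=True)
class DisplacementVector:
    """2D paw displacement [mm]: x = add-/abduction, y = plantar-/dorsiflexion."""

    x_mm: float
    y_mm: float

    @classmethod
    def from_polar(cls, magnitude_mm: float, direction_deg: float) -> "DisplacementVector":
        th = math.radians(direction_deg)
        return cls(magnitude_mm * math.cos(th), magnitude_mm * math.sin(th))

    @property
    def magnitude_mm(self) -> float:
        return math.hypot(self.x_mm, self.y_mm)

    @property
    def is_zero(self) -> bool:
        return self.x_mm == 0.0 and self.y_mm == 0.0

    @property
    def direction_deg(self) -> float:
        """Direction in degrees, atan2 convention, in (−180, 180].

        Raises :class:`UndefinedDirectionError` for the zero vector rather
        than silently returning 0.
        """
        if self.is_zero:
            raise UndefinedDirectionError("direction of a zero displacement is undefined")
        d = math.degrees(math.atan2(self.y_mm, self.x_mm))
        return 180.0 if d == -180.0 else d

    def distance_to(self, other: "DisplacementVector") -> float:
        return math.hypot(self.x_mm - other.x_mm, self.y_mm - other.y_mm)

    def as_array(self) -> np.ndarray:
        return np.array([self.x_mm, self.y_mm])


@dataclass(frozen=True)
class AccelerationTrace:
    """Uniformly sampled frontal-plane acceleration [m/s²] from stimulation onset.

    ``samples`` has shape (N, 2): columns are the x (add-/abduction) and y
    (plantar-/dorsiflexion) acceleration components; the first sample is at
    t = 0, when the paw is assumed at rest.
    """

    sample_rate_hz: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("samples must have shape (N, 2)")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be positive")
        object.__setattr__(self, "samples", arr)

    @property
    def duration_ms(self) -> float:
        return (self.samples.shape[0] - 1) / self.sample_rate_hz * 1000.0


def displacement_from_acceleration(
    trace: AccelerationTrace, window_ms: float = 80.0
) -> DisplacementVector:
    """Maximal displacement within the analysis window by double integration.

    Acceleration is integrated twice per axis with the trapezoidal rule,
    taking initial velocity and position as zero (the paw is at rest at
    stimulation onset).  The returned vector is the displacement sample of
    maximal Euclidean norm within the first ``window_ms`` milliseconds — the
    "maximal displacement" the routines score.
    """
    if window_ms <= 0:
        raise ValueError("window must be positive")
    a = trace.samples
    if not np.all(np.isfinite(a)):
        raise ValueError("acceleration trace contains non-finite samples")
    if trace.duration_ms < window_ms - 1e-9:
        raise ValueError(
            f"trace covers {trace.duration_ms:.1f} ms, shorter than the {window_ms:.1f} ms window"
        )
    dt = 1.0 / trace.sample_rate_hz
    n_win = int(round(window_ms / 1000.0 / dt)) + 1
    a = a[: max(n_win, 2)]
    v = cumulative_trapezoid(a, dx=dt, axis=0, initial=0.0)
    p = cumulative_trapezoid(v, dx=dt, axis=0, initial=0.0)  # metres
    norms = np.hypot(p[:, 0], p[:, 1])
    i = int(np.argmax(norms))
    return DisplacementVector(p[i, 0] * 1000.0, p[i, 1] * 1000.0)


def mean_displacement(repetitions: Sequence[DisplacementVector]) -> DisplacementVector:
    """Component-wise arithmetic mean of repetition displacements."""
    if not repetitions:
        raise ValueError("cannot average an empty list of repetitions")
    n = len(repetitions)
    return DisplacementVector(
        sum(r.x_mm for r in repetitions) / n,
        sum(r.y_mm for r in repetitions) / n,
    )


def variability(
    repetitions: Sequence[DisplacementVector], method: str = "mean"
) -> float:
    """The variability statistic F [% of the mean magnitude].

    F = (1/n) Σᵢ √((x̄−xᵢ)² + (ȳ−yᵢ)²) × 100 / √(x̄² + ȳ²): the mean
    Euclidean distance of the repetition vectors from their mean, as a
    percentage of the mean vector's magnitude.  ``method="rms"`` replaces
    the mean of distances by their root mean square, a sensitivity-check
    variant.

    A zero mean displacement makes F undefined; ``math.inf`` is returned so
    the value fails every finite variability limit downstream.
    """
    if len(repetitions) < 2:
        raise ValueError("variability needs at least two repetitions")
    if method not in ("mean", "rms"):
        raise ValueError(f"unknown variability method {method!r}")
    mean = mean_displacement(repetitions)
    if mean.magnitude_mm == 0.0:
        return math.inf
    d = np.array([mean.distance_to(r) for r in repetitions])
    spread = float(np.sqrt(np.mean(d**2))) if method == "rms" else float(np.mean(d))
    return spread * 100.0 / mean.magnitude_mm


def angular_deviation(d1: DisplacementVector, d2: DisplacementVector) -> float:
    """Absolute angular difference of two displacement directions, in [0, 180]°."""
    diff = abs(d1.direction_deg - d2.direction_deg) % 360.0
    return 360.0 - diff if diff > 180.0 else diff


@dataclass(frozen=True)
class TargetSpec:
    """The desired displacement and the acceptance / gating thresholds.

    ``tolerance_pct`` sets the radius of the tolerance circle around the
    desired displacement (as a percentage of its magnitude) inside which a
    mean response counts as success; ``min_significant_magnitude_mm`` is the
    magnitude below which a response is treated as noise; responses whose
    direction deviates from the desired one by more than
    ``max_direction_deviation_deg`` indicate activation of unwanted muscles.
    """

    desired: DisplacementVector
    tolerance_pct: float = 15.0
    min_significant_magnitude_mm: float = 0.5
    max_direction_deviation_deg: float = 60.0

    def __post_init__(self) -> None:
        if self.tolerance_pct <= 0:
            raise ValueError("tolerance must be positive")
        if self.min_significant_magnitude_mm < 0:
            raise ValueError("significance threshold must be non-negative")
        if not 0 < self.max_direction_deviation_deg <= 180:
            raise ValueError("direction deviation limit must lie in (0, 180]")

    @property
    def tolerance_radius_mm(self) -> float:
        return self.tolerance_pct / 100.0 * self.desired.magnitude_mm


def matches_target(mean: DisplacementVector, target: TargetSpec) -> bool:
    """True iff the mean lies inside the tolerance circle (boundary inclusive)."""
    return mean.distance_to(target.desired) <= target.tolerance_radius_mm


def is_significant(mean: DisplacementVector, target: TargetSpec) -> bool:
    """True iff the mean magnitude reaches the significance threshold (inclusive)."""
    return mean.magnitude_mm >= target.min_significant_magnitude_mm


@dataclass
class ResponseRecord:
    """Pooled outcome of the n repetitions of one stimulus."""

    stimulus: object  # Stimulus; typed loosely to avoid a circular import
    repetitions: list[DisplacementVector]
    variability_limit_pct: Optional[float] = None
    variability_method: str = "mean"
    failed: bool = False  # plant failure: no usable repetitions

    mean: DisplacementVector = field(init=False)
    variability_pct: float = field(init=False)
    included: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.failed or not self.repetitions:
            self.mean = DisplacementVector(0.0, 0.0)
            self.variability_pct = math.inf
            self.included = False
            self.failed = True
            return
        self.mean = mean_displacement(self.repetitions)
        if len(self.repetitions) >= 2:
            self.variability_pct = variability(self.repetitions, self.variability_method)
        else:
            self.variability_pct = 0.0
        limit = self.variability_limit_pct
        self.included = limit is None or self.variability_pct <= limit
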