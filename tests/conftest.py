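"""Shared fixtures: small stimulus spaces and constructed deterministic plants."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pytest

from cuffsearch import (
    CecConstraints,
    DisplacementVector,
    ElectrodeLayout,
    SpvGrid,
    default_config_path,
    load_config,
)
from cuffsearch.stim_space import enumerate_stimuli, sort_by_charge


@pytest.fixture(scope="session")
def bundle():
    """The shipped reference-protocol configuration (40 CECs / 768 stimuli)."""
    return load_config(default_config_path())


@pytest.fixture(scope="session")
def small_space():
    """A reduced space: 5 main cathodes, no auxiliary contact, 12 SPVs each."""
    layout = ElectrodeLayout(rows=("A", "B", "C"), contacts_per_row=5)
    constraints = CecConstraints(
        main_cathodes=tuple(layout.contact_id("B", i) for i in range(1, 6)),
        aux_roles=("none",),
    )
    grid = SpvGrid((10.0, 20.0, 40.0), (50.0, 100.0, 200.0, 400.0))
    return layout, constraints, grid


@pytest.fixture(scope="session")
def single_cec_space():
    """One CEC with a 16-SPV grid whose charges include 12 nC (30 μs × 400 μA)."""
    layout = ElectrodeLayout(rows=("A", "B", "C"), contacts_per_row=4)
    constraints = CecConstraints(main_cathodes=("BI",), aux_roles=("none",))
    grid = SpvGrid((10.0, 20.0, 30.0, 40.0), (50.0, 100.0, 200.0, 400.0))
    return layout, constraints, grid


@dataclass
class DirectionalStepPlant:
    """Noise-free plant: per-main-cathode fixed direction, steep charge recruitment.

    The response magnitude is M_c · σ((q − θ_c)/s) with a very steep slope, so
    each CEC is essentially off below its threshold and on the plateau above
    it; direction is charge-independent per CEC.  These are exactly the
    conditions under which the adaptive search is provably equivalent to
    exhaustive mapping + selection.
    """

    directions_deg: dict[str, float]
    magnitudes_mm: dict[str, float]
    thresholds_nc: dict[str, float]
    steepness_nc: float = 0.05
    calls: list = field(default_factory=list)

    def response(self, stimulus) -> DisplacementVector:
        c = stimulus.cec.main_cathode
        q = stimulus.charge_nc
        m = self.magnitudes_mm[c] / (1.0 + math.exp(-(q - self.thresholds_nc[c]) / self.steepness_nc))
        return DisplacementVector.from_polar(m, self.directions_deg[c])

    def __call__(self, stimulus, t: float) -> DisplacementVector:
        self.calls.append(stimulus.key)
        return self.response(stimulus)


@dataclass
class ConstantPlant:
    """Returns the same displacement for every stimulus."""

    value: DisplacementVector
    calls: list = field(default_factory=list)

    def __call__(self, stimulus, t: float) -> DisplacementVector:
        self.calls.append(stimulus.key)
        return self.value


@dataclass
class RampPlant:
    """Monotone plant along a fixed direction: magnitude = gain × charge."""

    direction_deg: float = 0.0
    gain_mm_per_nc: float = 0.5

    def __call__(self, stimulus, t: float) -> DisplacementVector:
        return DisplacementVector.from_polar(
            self.gain_mm_per_nc * stimulus.charge_nc, self.direction_deg
        )


def make_step_plant(seed: int, small_space) -> tuple[DirectionalStepPlant, str]:
    """A seeded step plant over the 5-CEC space plus the designated target CEC.

    Directions are spaced 72° apart (every non-target CEC violates the 60°
    direction rule relative to any target on another CEC); thresholds are
    kept ≥ 0.35 nC away from every grid charge so no stimulus lands in a
    recruitment transition.
    """
    layout, constraints, grid = small_space
    rng = np.random.default_rng(seed)
    cathodes = list(constraints.main_cathodes)
    grid_charges = sorted({s.charge_nc for s in enumerate_stimuli(layout, constraints, grid)})
    base = rng.uniform(0.0, 360.0)
    directions = {c: (base + 72.0 * i) % 360.0 - 180.0 for i, c in enumerate(cathodes)}
    thresholds = {}
    for c in cathodes:
        while True:
            th = rng.uniform(0.8, 14.0)
            if all(abs(th - g) > 0.35 for g in grid_charges):
                thresholds[c] = th
                break
    magnitudes = {c: rng.uniform(3.0, 10.0) for c in cathodes}
    target_cec = cathodes[rng.integers(len(cathodes))]
    return (
        DirectionalStepPlant(directions, magnitudes, thresholds),
        target_cec,
    )


def brute_force_in_tolerance(plant, stimuli, target):
    """All stimuli whose noise-free response lies in the tolerance circle, charge-ascending."""
    return [
        s
        for s in sort_by_charge(stimuli)
        if plant.response(s).distance_to(target.desired) <= target.tolerance_radius_mm
    ]
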