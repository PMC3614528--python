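"""Electrode model, stimulus-space enumeration and charge ordering.

A stimulus delivered through a multi-contact cuff electrode is the pairing of

* a **combination of electrode contacts** (CEC): the cathode / anode /
  grounded / not-connected role of every contact, which fixes the spatial
  current path, and
* a **set of stimulus parameter values** (SPV): pulse duration, main-pulse
  amplitude and, when a steering contact is present, the steering-pulse
  amplitude expressed as a fraction of the main amplitude.

This module enumerates every CEC admitted by operator constraints, the SPVs
admitted by a parameter grid, and orders the resulting stimuli by total
delivered charge, which is the cost axis the adaptive search routine ascends.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "ContactState",
    "ElectrodeLayout",
    "ContactConfiguration",
    "CecConstraints",
    "StimulusParameterValues",
    "SpvGrid",
    "Stimulus",
    "ConfigurationError",
    "enumerate_cecs",
    "enumerate_spvs",
    "enumerate_stimuli",
    "stimulus_charge",
    "sort_by_charge",
]

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII"]

#: Auxiliary roles a second active contact may take, in enumeration order.
AUX_ROLES = ("cathodic_steer", "anodic_steer", "grounded")


class ConfigurationError(ValueError):
    """Raised when constraints or grids reference unknown contacts or are malformed."""


class ContactState(enum.Enum):
    """State of one electrode contact during a stimulus.

    Exactly four states exist: a contact either sources cathodic current,
    sources anodic current, is tied to ground, or is left floating.
    """

    CATHODE = "cathode"
    ANODE = "anode"
    GROUNDED = "grounded"
    NOT_CONNECTED = "not_connected"


def _roman(i: int) -> str:
    if not 1 <= i <= len(_ROMAN):
        raise ConfigurationError(f"contact index {i} out of supported range 1..{len(_ROMAN)}")
    return _ROMAN[i - 1]


@dataclass(frozen=True)
class ElectrodeLayout:
    """Geometry of a cuff electrode: rows of equally many contacts.

    Contact identifiers are formed as ``row label + roman index`` (``AI`` …
    ``CIV`` for a 3-row × 4-contact cuff, the 12-contact device the default
    configuration describes).
    """

    rows: tuple[str, ...] = ("A", "B", "C")
    contacts_per_row: int = 4

    def __post_init__(self) -> None:
        if len(set(self.rows)) != len(self.rows):
            raise ConfigurationError("row labels must be unique")
        if self.contacts_per_row < 1:
            raise ConfigurationError("contacts_per_row must be positive")
        object.__setattr__(self, "rows", tuple(self.rows))

    @property
    def contacts(self) -> tuple[str, ...]:
        """All contact identifiers, row-major, index order within each row."""
        return tuple(
            f"{row}{_roman(i)}" for row in self.rows for i in range(1, self.contacts_per_row + 1)
        )

    @property
    def n_contacts(self) -> int:
        return len(self.rows) * self.contacts_per_row

    def contact_id(self, row: str, index: int) -> str:
        if row not in self.rows:
            raise ConfigurationError(f"unknown row {row!r}")
        return f"{row}{_roman(index)}"

    def split(self, contact: str) -> tuple[str, int]:
        """Decompose a contact id into (row label, 1-based index)."""
        for row in sorted(self.rows, key=len, reverse=True):
            if contact.startswith(row):
                suffix = contact[len(row):]
                if suffix in _ROMAN:
                    idx = _ROMAN.index(suffix) + 1
                    if idx <= self.contacts_per_row:
                        return row, idx
        raise ConfigurationError(f"unknown contact {contact!r}")

    def validate_contact(self, contact: str) -> None:
        if contact not in self.contacts:
            raise ConfigurationError(f"unknown contact {contact!r}")


@dataclass(frozen=True)
class ContactConfiguration:
    """A CEC: the role of every contact plus the main/steering designation.

    Invariants enforced at construction: exactly one main cathode whose state
    is cathode; at least one grounded contact; a steering contact, when
    present, is distinct from the main cathode and its state matches its
    polarity (cathodic → cathode, anodic → anode); all remaining contacts
    are not connected.
    """

    states: tuple[tuple[str, ContactState], ...]
    main_cathode: str
    steering_contact: Optional[str] = None
    steering_polarity: Optional[str] = None  # "cathodic" | "anodic" | None

    def __post_init__(self) -> None:
        smap = dict(self.states)
        if len(smap) != len(self.states):
            raise ConfigurationError("duplicate contact in state map")
        object.__setattr__(self, "states", tuple(sorted(smap.items())))
        if smap.get(self.main_cathode) is not ContactState.CATHODE:
            raise ConfigurationError("main cathode must exist and be in cathode state")
        if not any(s is ContactState.GROUNDED for s in smap.values()):
            raise ConfigurationError("at least one contact must be grounded")
        if (self.steering_contact is None) != (self.steering_polarity is None):
            raise ConfigurationError("steering contact and polarity must be given together")
        if self.steering_contact is not None:
            if self.steering_contact == self.main_cathode:
                raise ConfigurationError("steering contact must differ from main cathode")
            want = (
                ContactState.CATHODE
                if self.steering_polarity == "cathodic"
                else ContactState.ANODE
            )
            if self.steering_polarity not in ("cathodic", "anodic"):
                raise ConfigurationError(f"bad steering polarity {self.steering_polarity!r}")
            if smap.get(self.steering_contact) is not want:
                raise ConfigurationError("steering contact state inconsistent with polarity")

    @property
    def state_map(self) -> dict[str, ContactState]:
        return dict(self.states)

    @property
    def has_steering(self) -> bool:
        return self.steering_contact is not None

    @property
    def grounded_contacts(self) -> tuple[str, ...]:
        return tuple(c for c, s in self.states if s is ContactState.GROUNDED)

    @property
    def cec_id(self) -> str:
        """Compact human-readable label, e.g. ``BI|steer-:BII|gnd:AI+CI``."""
        parts = [self.main_cathode]
        if self.steering_contact is not None:
            sign = "-" if self.steering_polarity == "cathodic" else "+"
            parts.append(f"steer{sign}:{self.steering_contact}")
        parts.append("gnd:" + "+".join(self.grounded_contacts))
        return "|".join(parts)


@dataclass(frozen=True)
class CecConstraints:
    """Operator constraints from which CECs are enumerated.

    ``ground_rule`` is either the string ``"flanking_same_index"`` — ground
    the same-index contacts of the rows flanking the main cathode's row — or
    an explicit mapping of main-cathode id to the tuple of grounded contact
    ids.  ``aux_roles`` lists the roles one additional contact may take
    (any subset of :data:`AUX_ROLES` plus ``"none"`` for the no-auxiliary
    configuration); ``aux_positions`` the contacts that may serve that role.
    """

    main_cathodes: tuple[str, ...]
    ground_rule: object = "flanking_same_index"
    aux_roles: tuple[str, ...] = ("none",) + AUX_ROLES
    aux_positions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "main_cathodes", tuple(self.main_cathodes))
        object.__setattr__(self, "aux_roles", tuple(self.aux_roles))
        object.__setattr__(self, "aux_positions", tuple(self.aux_positions))
        for r in self.aux_roles:
            if r not in AUX_ROLES + ("none",):
                raise ConfigurationError(f"unknown auxiliary role {r!r}")

    def grounds_for(self, layout: ElectrodeLayout, main: str) -> tuple[str, ...]:
        if self.ground_rule == "flanking_same_index":
            row, idx = layout.split(main)
            pos = layout.rows.index(row)
            flanks = [r for j, r in enumerate(layout.rows) if abs(j - pos) == 1]
            return tuple(layout.contact_id(r, idx) for r in flanks)
        if isinstance(self.ground_rule, Mapping):
            try:
                return tuple(self.ground_rule[main])
            except KeyError:
                raise ConfigurationError(f"ground rule has no entry for {main!r}") from None
        raise ConfigurationError(f"unsupported ground rule {self.ground_rule!r}")


@dataclass(frozen=True)
class StimulusParameterValues:
    """An SPV: pulse duration [μs], main amplitude [μA], steering fraction.

    Amplitudes are stored as positive magnitudes; the cathodic sign is
    implied by the contact role.  Main and steering pulses share the same
    duration; the steering amplitude is ``steering_fraction ×
    main_amplitude`` and absent for configurations without a steering pulse.
    """

    pulse_duration_us: float
    main_amplitude_ua: float
    steering_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pulse_duration_us <= 0:
            raise ConfigurationError("pulse duration must be positive")
        if self.main_amplitude_ua <= 0:
            raise ConfigurationError("main amplitude must be positive")
        if self.steering_fraction is not None and not 0 < self.steering_fraction <= 1:
            raise ConfigurationError("steering fraction must lie in (0, 1]")

    @property
    def steering_amplitude_ua(self) -> float:
        """Steering-pulse current magnitude [μA]; 0 when no steering pulse."""
        if self.steering_fraction is None:
            return 0.0
        return self.steering_fraction * self.main_amplitude_ua


@dataclass(frozen=True)
class SpvGrid:
    """Permitted parameter values from which SPVs are enumerated."""

    durations_us: tuple[float, ...]
    main_amplitudes_ua: tuple[float, ...]
    steering_fractions: tuple[float, ...] = ()
    stimulus_type: str = "monophasic_rectangular"

    def __post_init__(self) -> None:
        object.__setattr__(self, "durations_us", tuple(self.durations_us))
        object.__setattr__(self, "main_amplitudes_ua", tuple(self.main_amplitudes_ua))
        object.__setattr__(self, "steering_fractions", tuple(self.steering_fractions))
        if not self.durations_us or not self.main_amplitudes_ua:
            raise ConfigurationError("duration and amplitude lists must be non-empty")
        if any(v <= 0 for v in self.durations_us + self.main_amplitudes_ua):
            raise ConfigurationError("durations and amplitudes must be positive")
        if any(not 0 < f <= 1 for f in self.steering_fractions):
            raise ConfigurationError("steering fractions must lie in (0, 1]")
        if self.stimulus_type not in ("monophasic_rectangular", "biphasic_rectangular"):
            raise ConfigurationError(f"unknown stimulus type {self.stimulus_type!r}")


@dataclass(frozen=True)
class Stimulus:
    """One (CEC, SPV) combination; ``charge_nc`` is the derived total charge."""

    cec: ContactConfiguration
    spv: StimulusParameterValues
    cec_index: int = 0  # position of the CEC in its enumeration; tie-break only

    def __post_init__(self) -> None:
        if self.cec.has_steering != (self.spv.steering_fraction is not None):
            raise ConfigurationError(
                "steering fraction must be present exactly when the CEC has a steering contact"
            )

    @property
    def charge_nc(self) -> float:
        return stimulus_charge(self)

    @property
    def key(self) -> tuple:
        """Identity key for caching: the full CEC plus the SPV."""
        return (self.cec, self.spv)

    @property
    def stimulus_id(self) -> str:
        s = self.spv
        frac = "" if s.steering_fraction is None else f"@{s.steering_fraction:g}"
        return f"{self.cec.cec_id}/{s.pulse_duration_us:g}us/{s.main_amplitude_ua:g}uA{frac}"


def stimulus_charge(stimulus: Stimulus) -> float:
    """Total delivered charge [nC] of one stimulus.

    Duration [μs] times the summed current magnitudes [μA] of the concurrent
    main and steering pulses (μs·μA = pC, reported in nC).  Steering polarity
    does not enter: an anodic steering pulse delivers charge just the same.
    """
    spv = stimulus.spv
    total_ua = spv.main_amplitude_ua + abs(spv.steering_amplitude_ua)
    return spv.pulse_duration_us * total_ua / 1000.0


def enumerate_cecs(layout: ElectrodeLayout, constraints: CecConstraints) -> list[ContactConfiguration]:
    """Enumerate every distinct CEC admitted by the constraints.

    Order is deterministic: main cathodes in the order given, then the
    no-auxiliary configuration, then auxiliary positions by contact order,
    each with roles in the order cathodic steer, anodic steer, grounded
    (restricted to the allowed roles).  Candidates violating a CEC invariant
    (e.g. a ground rule yielding no grounded contact) are dropped; duplicates
    reached by different constraint paths are emitted once.
    """
    for c in constraints.main_cathodes + constraints.aux_positions:
        layout.validate_contact(c)
    if isinstance(constraints.ground_rule, Mapping):
        for grounds in constraints.ground_rule.values():
            for g in grounds:
                layout.validate_contact(g)

    out: list[ContactConfiguration] = []
    seen: set = set()

    def emit(cec: ContactConfiguration) -> None:
        if cec not in seen:
            seen.add(cec)
            out.append(cec)

    role_order = [r for r in ("none",) + AUX_ROLES if r in constraints.aux_roles]
    contact_order = {c: i for i, c in enumerate(layout.contacts)}

    for main in constraints.main_cathodes:
        grounds = constraints.grounds_for(layout, main)
        base = {main: ContactState.CATHODE}
        for g in grounds:
            base.setdefault(g, ContactState.GROUNDED)

        def build(extra: dict, steer: Optional[str], pol: Optional[str]):
            smap = {c: ContactState.NOT_CONNECTED for c in layout.contacts}
            smap.update(base)
            smap.update(extra)
            try:
                return ContactConfiguration(
                    states=tuple(smap.items()),
                    main_cathode=main,
                    steering_contact=steer,
                    steering_polarity=pol,
                )
            except ConfigurationError:
                return None

        positions = sorted(
            (p for p in constraints.aux_positions if p != main),
            key=contact_order.__getitem__,
        )
        for role in role_order:
            if role == "none":
                cec = build({}, None, None)
                if cec is not None:
                    emit(cec)
        for pos in positions:
            for role in role_order:
                if role == "none":
                    continue
                if role == "cathodic_steer":
                    cec = build({pos: ContactState.CATHODE}, pos, "cathodic")
                elif role == "anodic_steer":
                    cec = build({pos: ContactState.ANODE}, pos, "anodic")
                else:  # grounded auxiliary: no steering pulse
                    cec = build({pos: ContactState.GROUNDED}, None, None)
                if cec is not None:
                    emit(cec)
    return out


def enumerate_spvs(grid: SpvGrid, cec: ContactConfiguration) -> list[StimulusParameterValues]:
    """Enumerate the SPVs applicable to one CEC.

    The Cartesian product of durations × main amplitudes × steering fractions
    when the CEC carries a steering pulse, durations × amplitudes otherwise.
    Order is deterministic: duration-major, then amplitude, then fraction.
    """
    if cec.has_steering:
        if not grid.steering_fractions:
            raise ConfigurationError(
                "grid has no steering fractions but a CEC carries a steering pulse"
            )
        fractions: Sequence[Optional[float]] = grid.steering_fractions
    else:
        fractions = (None,)
    return [
        StimulusParameterValues(d, a, f)
        for d, a, f in itertools.product(grid.durations_us, grid.main_amplitudes_ua, fractions)
    ]


def enumerate_stimuli(
    layout: ElectrodeLayout, constraints: CecConstraints, grid: SpvGrid
) -> list[Stimulus]:
    """All (CEC, SPV) combinations, CEC-major in enumeration order."""
    out: list[Stimulus] = []
    for i, cec in enumerate(enumerate_cecs(layout, constraints)):
        out.extend(Stimulus(cec, spv, cec_index=i) for spv in enumerate_spvs(grid, cec))
    return out


def _charge_sort_key(stimulus: Stimulus) -> tuple:
    spv = stimulus.spv
    return (
        stimulus.charge_nc,
        spv.pulse_duration_us,
        spv.main_amplitude_ua,
        spv.steering_fraction if spv.steering_fraction is not None else 0.0,
        stimulus.cec_index,
    )


def sort_by_charge(stimuli: Iterable[Stimulus]) -> list[Stimulus]:
    """Order stimuli by ascending total charge.

    Ties are broken by shorter duration, then lower main amplitude, then
    lower steering fraction (absent sorting first), then CEC enumeration
    order — a stable total order so equal inputs always produce equal output.
    """
    return sorted(stimuli, key=_charge_sort_key)
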