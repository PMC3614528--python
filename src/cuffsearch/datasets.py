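"""Reference measurements from the preliminary in-vivo evaluation.

The routines were first evaluated on an anesthetized rat whose sciatic nerve
was stimulated through a 12-contact cuff (3 rows A–C × 4 contacts I–IV),
paw displacement being measured by accelerometry.  This module ships the
published summary of that session as structured data: the stimulation
parameters and pooled responses of the individually discussed stimuli, and
the per-run tested-combination counts of the mapping run and the three
automated searches (desired displacements *a*, *b* and *c*).

These records serve as ground truth for charge arithmetic and as inputs for
consistency checks; they are measurements of one acute preparation, not
calibration targets for the plant simulator.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .stim_space import (
    ContactConfiguration,
    ContactState,
    ElectrodeLayout,
    Stimulus,
    StimulusParameterValues,
)

__all__ = [
    "reference_layout",
    "reference_stimuli",
    "reference_responses",
    "reference_search_counts",
]

# One row per discussed stimulus: id, duration [μs], main cathode, main
# amplitude [μA], steering contact, steering polarity, steering fraction,
# grounded contacts, and the pooled response (magnitude [mm], direction [°],
# variability F [%]).  Ids A1/A2 and C1/C2/C3 are repeat deliveries of one
# stimulus during different session phases.
_ROWS = [
    ("a",  40.0, "BI",   400.0, "BII", "cathodic", 0.5, ("AI", "CI"),            7.05, 66.2,  2.0),
    ("A1", 10.0, "BII",  200.0, None,  None,       None, ("AII", "CII"),         6.81, 68.9, 17.4),
    ("A2", 10.0, "BII",  200.0, None,  None,       None, ("AII", "CII"),         7.02, 74.9,  8.5),
    ("b",  20.0, "BIII", 400.0, "BIV", "anodic",   0.5, ("AIII", "CIII"),       12.27, -67.1, 4.2),
    ("c",  40.0, "BI",   200.0, "BII", "cathodic", 0.5, ("AI", "CI"),            7.07, -41.8, 4.7),
    ("C1", 40.0, "BIII", 400.0, None,  None,       None, ("AIII", "BIV", "CIII"), 10.25, -64.3, 0.6),
    ("C2", 40.0, "BIII", 400.0, None,  None,       None, ("AIII", "BIV", "CIII"),  6.99, -40.5, 3.1),
    ("C3", 40.0, "BIII", 400.0, None,  None,       None, ("AIII", "BIV", "CIII"),  4.77, -31.6, 4.4),
]

# Tested (SPV, CEC) combinations and significant responses per run, plus the
# published totals: 657 combinations over the three searches, which a shared
# response cache would have reduced to 266 (the size of the union).
_SEARCH_COUNTS = {
    "mapping": {"tested": 768, "significant": 362},
    "search_a": {"tested": 133, "significant": 4},
    "search_b": {"tested": 265, "significant": 58},
    "search_c": {"tested": 259, "significant": 52},
}
SEARCH_UNION_SIZE = 266


def reference_layout() -> ElectrodeLayout:
    """The 12-contact cuff: rows A, B, C of four contacts each."""
    return ElectrodeLayout(rows=("A", "B", "C"), contacts_per_row=4)


def _build_stimulus(row) -> Stimulus:
    (_, dur, main, amp, steer, pol, frac, grounds, *_rest) = row
    layout = reference_layout()
    smap = {c: ContactState.NOT_CONNECTED for c in layout.contacts}
    smap[main] = ContactState.CATHODE
    for g in grounds:
        smap[g] = ContactState.GROUNDED
    if steer is not None:
        smap[steer] = ContactState.CATHODE if pol == "cathodic" else ContactState.ANODE
    cec = ContactConfiguration(
        states=tuple(smap.items()),
        main_cathode=main,
        steering_contact=steer,
        steering_polarity=pol,
    )
    return Stimulus(cec, StimulusParameterValues(dur, amp, frac))


def reference_stimuli() -> dict[str, Stimulus]:
    """The individually discussed stimuli, keyed by their published id."""
    return {row[0]: _build_stimulus(row) for row in _ROWS}


def reference_responses() -> pd.DataFrame:
    """Stimulation parameters and pooled responses, one row per stimulus id."""
    df = pd.DataFrame(
        _ROWS,
        columns=[
            "id", "duration_us", "main_cathode", "main_ua", "steering_contact",
            "steering_polarity", "steering_fraction", "grounded",
            "magnitude_mm", "direction_deg", "variability_pct",
        ],
    ).set_index("id")
    df["charge_nc"] = [_build_stimulus(row).charge_nc for row in _ROWS]
    return df


def reference_search_counts() -> pd.DataFrame:
    """Tested-combination and significant-response counts per reference run."""
    return pd.DataFrame(_SEARCH_COUNTS).T.rename_axis("run")
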