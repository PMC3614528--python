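"""Configuration loading/validation, plant definitions, and result serialization.

Units are fixed at the file boundary and match the reporting units used
throughout the package: μs, μA, nC, mm, degrees, percent.  CSV files are
comma-separated with a header row, UTF-8, '.' decimal; nested structures are
JSON.  Floats are written at full repr precision so a write→read round trip
is lossless.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from . import plant_sim
from .plant_sim import MuscleGroup, PlantModel, SimulatedPlant
from .response_metrics import (
    AccelerationTrace,
    DisplacementVector,
    ResponseRecord,
    TargetSpec,
)
from .routines import ResultsCollection, RoutineConfig, SearchResult, TrialRecord
from .stim_space import (
    CecConstraints,
    ContactConfiguration,
    ContactState,
    ElectrodeLayout,
    SpvGrid,
    Stimulus,
    StimulusParameterValues,
    enumerate_stimuli,
)

__all__ = [
    "ConfigBundle",
    "load_config",
    "default_config_path",
    "load_plant",
    "write_results",
    "read_results",
    "write_cache",
    "read_cache",
    "stimulus_table",
    "write_trace",
    "read_trace",
]


# --------------------------------------------------------------------------
# Config schema (strict: unknown keys are errors)


class _Layout(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rows: list[str]
    contacts_per_row: int = Field(gt=0)


class _CecConstraints(BaseModel):
    model_config = ConfigDict(extra="forbid")
    main_cathodes: list[str]
    ground_rule: Union[Literal["flanking_same_index"], dict[str, list[str]]] = (
        "flanking_same_index"
    )
    aux_roles: list[Literal["none", "cathodic_steer", "anodic_steer", "grounded"]] = ["none"]
    aux_positions: list[str] = []


class _SpvGrid(BaseModel):
    model_config = ConfigDict(extra="forbid")
    durations_us: list[float]
    main_amplitudes_ua: list[float]
    steering_fractions: list[float] = []
    stimulus_type: Literal["monophasic_rectangular", "biphasic_rectangular"] = (
        "monophasic_rectangular"
    )

    @field_validator("durations_us", "main_amplitudes_ua")
    @classmethod
    def _positive(cls, v):
        if not v or any(x <= 0 for x in v):
            raise ValueError("must be a non-empty list of positive values")
        return v


class _Routine(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_repetitions: int = Field(default=3, ge=2)
    min_inter_stimulus_delay_ms: float = Field(default=400.0, ge=0)
    variability_limit_pct: float = Field(default=10.0, gt=0)
    processing_allowance_ms: float = Field(default=667.0, ge=0)
    exclude_on_unstable: bool = True
    variability_method: Literal["mean", "rms"] = "mean"


class _SearchDefaults(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tolerance_pct: float = Field(default=15.0, gt=0)
    min_significant_magnitude_mm: float = Field(default=0.5, ge=0)
    max_direction_deviation_deg: float = Field(default=60.0, gt=0, le=180)


class _Target(_SearchDefaults):
    model_config = ConfigDict(extra="forbid")
    magnitude_mm: float = Field(gt=0)
    direction_deg: float


class _ConfigFile(BaseModel):
    model_config = ConfigDict(extra="forbid")
    layout: _Layout
    cec_constraints: _CecConstraints
    spv_grid: _SpvGrid
    routine: _Routine = _Routine()
    search_defaults: _SearchDefaults = _SearchDefaults()
    target: Optional[_Target] = None


@dataclass(frozen=True)
class ConfigBundle:
    """A validated configuration: domain objects plus the raw snapshot."""

    layout: ElectrodeLayout
    constraints: CecConstraints
    grid: SpvGrid
    routine: RoutineConfig
    search_defaults: dict
    raw: dict

    def with_target(
        self, magnitude_mm: float, direction_deg: float, **overrides
    ) -> "ConfigBundle":
        """A copy whose routine config carries a target built from the defaults."""
        kw = {**self.search_defaults, **overrides}
        target = TargetSpec(DisplacementVector.from_polar(magnitude_mm, direction_deg), **kw)
        routine = RoutineConfig(
            n_repetitions=self.routine.n_repetitions,
            min_inter_stimulus_delay_ms=self.routine.min_inter_stimulus_delay_ms,
            variability_limit_pct=self.routine.variability_limit_pct,
            target=target,
            processing_allowance_ms=self.routine.processing_allowance_ms,
            exclude_on_unstable=self.routine.exclude_on_unstable,
            variability_method=self.routine.variability_method,
        )
        return ConfigBundle(
            self.layout, self.constraints, self.grid, routine, self.search_defaults, self.raw
        )


def default_config_path() -> Path:
    """Path of the shipped reference-protocol configuration."""
    return Path(resources.files("cuffsearch").joinpath("configs/reference_protocol.yaml"))


def load_config(path: Union[str, Path]) -> ConfigBundle:
    """Load and validate a YAML/JSON configuration file.

    Every structural invariant is checked (strictly: unknown keys are
    rejected); errors name the offending field and constraint.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    try:
        cfg = _ConfigFile.model_validate(data)
    except ValidationError as e:
        raise ValueError(f"invalid configuration {path}: {e}") from e

    layout = ElectrodeLayout(tuple(cfg.layout.rows), cfg.layout.contacts_per_row)
    gr = cfg.cec_constraints.ground_rule
    constraints = CecConstraints(
        main_cathodes=tuple(cfg.cec_constraints.main_cathodes),
        ground_rule=gr if isinstance(gr, str) else {k: tuple(v) for k, v in gr.items()},
        aux_roles=tuple(cfg.cec_constraints.aux_roles),
        aux_positions=tuple(cfg.cec_constraints.aux_positions),
    )
    for c in constraints.main_cathodes + constraints.aux_positions:
        layout.validate_contact(c)
    grid = SpvGrid(
        tuple(cfg.spv_grid.durations_us),
        tuple(cfg.spv_grid.main_amplitudes_ua),
        tuple(cfg.spv_grid.steering_fractions),
        cfg.spv_grid.stimulus_type,
    )
    target = None
    if cfg.target is not None:
        target = TargetSpec(
            DisplacementVector.from_polar(cfg.target.magnitude_mm, cfg.target.direction_deg),
            tolerance_pct=cfg.target.tolerance_pct,
            min_significant_magnitude_mm=cfg.target.min_significant_magnitude_mm,
            max_direction_deviation_deg=cfg.target.max_direction_deviation_deg,
        )
    routine = RoutineConfig(
        n_repetitions=cfg.routine.n_repetitions,
        min_inter_stimulus_delay_ms=cfg.routine.min_inter_stimulus_delay_ms,
        variability_limit_pct=cfg.routine.variability_limit_pct,
        target=target,
        processing_allowance_ms=cfg.routine.processing_allowance_ms,
        exclude_on_unstable=cfg.routine.exclude_on_unstable,
        variability_method=cfg.routine.variability_method,
    )
    return ConfigBundle(
        layout, constraints, grid, routine,
        cfg.search_defaults.model_dump(), data,
    )


# --------------------------------------------------------------------------
# Plant definitions

_PRESETS = {
    "paperlike": plant_sim.make_paperlike_plant,
    "noise_free": plant_sim.make_noise_free_plant,
}


class _MuscleDef(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    direction: tuple[float, float]
    max_mm: float = Field(gt=0)
    threshold_nc: float
    slope_nc: float = Field(gt=0)


class _PlantFile(BaseModel):
    model_config = ConfigDict(extra="forbid")
    preset: Optional[str] = None
    seed: int = 0
    muscles: Optional[list[_MuscleDef]] = None
    selectivity: dict[str, list[float]] = {}
    steering_strength: float = 0.5
    noise_scale: float = Field(default=0.0, ge=0)
    drift_tau_s: float = Field(default=1200.0, gt=0)
    drift_sigma: float = Field(default=0.0, ge=0)
    saturation_charge_nc: Optional[float] = None


def load_plant(spec: Union[str, Path], seed: Optional[int] = None) -> SimulatedPlant:
    """Build a plant from a preset name (``paperlike``/``noise_free``) or a YAML file."""
    from dataclasses import replace

    if isinstance(spec, str) and spec in _PRESETS:
        model = _PRESETS[spec](seed or 0)
    else:
        with open(spec, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        pf = _PlantFile.model_validate(data)
        if pf.preset is not None:
            if pf.preset not in _PRESETS:
                raise ValueError(f"unknown plant preset {pf.preset!r}")
            model = _PRESETS[pf.preset](pf.seed)
        else:
            if not pf.muscles:
                raise ValueError("plant file must give either a preset or a muscle list")
            model = PlantModel(
                muscles=tuple(
                    MuscleGroup(m.name, m.direction, m.max_mm, m.threshold_nc, m.slope_nc)
                    for m in pf.muscles
                ),
                selectivity={k: tuple(v) for k, v in pf.selectivity.items()},
                steering_strength=pf.steering_strength,
                noise_scale=pf.noise_scale,
                drift_tau_s=pf.drift_tau_s,
                drift_sigma=pf.drift_sigma,
                saturation_charge_nc=pf.saturation_charge_nc,
                seed=pf.seed,
            )
        if seed is not None:
            model = replace(model, seed=seed)
    return SimulatedPlant(model)


# --------------------------------------------------------------------------
# Serialization


def _serialize_states(cec: ContactConfiguration) -> str:
    return ";".join(f"{c}={s.value}" for c, s in cec.states)


def _parse_states(text: str) -> tuple[tuple[str, ContactState], ...]:
    out = []
    for part in text.split(";"):
        c, s = part.split("=")
        out.append((c, ContactState(s)))
    return tuple(out)


def _stimulus_row(stim: Stimulus) -> dict:
    spv = stim.spv
    return {
        "stimulus_id": stim.stimulus_id,
        "cec_id": stim.cec.cec_id,
        "cec_index": stim.cec_index,
        "contact_states": _serialize_states(stim.cec),
        "main_cathode": stim.cec.main_cathode,
        "steering_contact": stim.cec.steering_contact or "",
        "steering_polarity": stim.cec.steering_polarity or "",
        "duration_us": spv.pulse_duration_us,
        "main_ua": spv.main_amplitude_ua,
        "steer_ua": spv.steering_amplitude_ua,
        "steering_fraction": "" if spv.steering_fraction is None else spv.steering_fraction,
        "charge_nc": stim.charge_nc,
    }


def _stimulus_from_row(row) -> Stimulus:
    cec = ContactConfiguration(
        states=_parse_states(row["contact_states"]),
        main_cathode=row["main_cathode"],
        steering_contact=row["steering_contact"] or None,
        steering_polarity=row["steering_polarity"] or None,
    )
    frac = row["steering_fraction"]
    frac = None if frac in ("", None) or (isinstance(frac, float) and math.isnan(frac)) else float(frac)
    spv = StimulusParameterValues(float(row["duration_us"]), float(row["main_ua"]), frac)
    return Stimulus(cec, spv, cec_index=int(row["cec_index"]))


def stimulus_table(layout, constraints, grid) -> pd.DataFrame:
    """The enumerated stimulus space as a flat table (one row per stimulus)."""
    return pd.DataFrame([_stimulus_row(s) for s in enumerate_stimuli(layout, constraints, grid)])


def _records_frame(records: list[ResponseRecord], extra: Optional[list[dict]] = None) -> pd.DataFrame:
    rows = []
    for i, rec in enumerate(records):
        stim: Stimulus = rec.stimulus
        base = _stimulus_row(stim)
        meta = extra[i] if extra else {}
        mean = rec.mean
        common = {
            **base,
            **meta,
            "mean_x_mm": mean.x_mm,
            "mean_y_mm": mean.y_mm,
            "magnitude_mm": mean.magnitude_mm,
            "direction_deg": mean.direction_deg if not mean.is_zero else "",
            "variability_pct": rec.variability_pct,
            "included": rec.included,
            "failed": rec.failed,
        }
        if rec.repetitions:
            for j, rep in enumerate(rec.repetitions):
                rows.append({**common, "rep_index": j, "x_mm": rep.x_mm, "y_mm": rep.y_mm})
        else:
            rows.append({**common, "rep_index": -1, "x_mm": "", "y_mm": ""})
    return pd.DataFrame(rows)


def write_results(
    result: Union[ResultsCollection, SearchResult],
    out_dir: Union[str, Path],
    *,
    config_snapshot: Optional[dict] = None,
    plant_snapshot: Optional[dict] = None,
    seed: Optional[int] = None,
) -> dict[str, Path]:
    """Write a run to ``out_dir``: trial CSV, decision JSON-lines, summary, manifest.

    The trial CSV has one row per repetition with stable column order; the
    decision log (searches only) has one JSON object per evaluated stimulus;
    the manifest snapshots the inputs so a run can be replayed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": out / "trials.csv",
        "decisions": out / "decisions.jsonl",
        "summary": out / "summary.json",
        "manifest": out / "manifest.json",
    }

    if isinstance(result, SearchResult):
        extra = [
            {"decision": t.decision, "reason": t.reason, "time_s": t.time_s,
             "from_cache": t.from_cache}
            for t in result.trials
        ]
        df = _records_frame([t.record for t in result.trials], extra)
        with open(paths["decisions"], "w", encoding="utf-8") as fh:
            for t in result.trials:
                fh.write(json.dumps({
                    "stimulus_id": t.stimulus.stimulus_id,
                    "charge_nc": t.charge_nc,
                    "decision": t.decision,
                    "reason": t.reason,
                    "time_s": t.time_s,
                    "from_cache": t.from_cache,
                }) + "\n")
        summary = {
            "kind": "search",
            "status": result.status,
            "found_stimulus_id": (
                result.found_stimulus.stimulus_id if result.found_stimulus else None
            ),
            "stimuli_tested": result.stimuli_tested,
            "combos_evaluated": result.combos_evaluated,
            "excluded_cecs": result.excluded_cecs,
            "duration_s": result.duration_s,
        }
    else:
        df = _records_frame(result.records)
        summary = {
            "kind": "mapping",
            "stimuli_tested": result.stimuli_tested,
            "n_included": len(result.included_records),
            "n_significant": result.n_significant(),
            "duration_s": result.duration_s,
        }
        paths.pop("decisions")

    df.to_csv(paths["trials"], index=False)
    with open(paths["summary"], "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)

    manifest = {
        "config": config_snapshot,
        "plant": plant_snapshot,
        "seed": seed,
        "outputs": {k: p.name for k, p in paths.items()},
        "virtual_duration_s": summary["duration_s"],
    }
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return paths


def _records_from_frame(df: pd.DataFrame) -> tuple[list[ResponseRecord], list[dict]]:
    records: list[ResponseRecord] = []
    trial_meta: list[dict] = []
    if df.empty:
        return records, trial_meta
    for _, group in df.groupby("stimulus_id", sort=False):
        first = group.iloc[0]
        stim = _stimulus_from_row(first)
        failed = bool(first["failed"] in (True, "True"))
        reps = (
            []
            if failed
            else [DisplacementVector(float(r["x_mm"]), float(r["y_mm"])) for _, r in group.iterrows()]
        )
        rec = ResponseRecord(stim, reps, None, failed=failed)
        # restore the persisted gate outcome rather than re-deriving the limit
        rec.included = first["included"] in (True, "True")
        records.append(rec)
        if "decision" in group.columns:
            trial_meta.append({
                "decision": first["decision"],
                "reason": first["reason"],
                "time_s": float(first["time_s"]),
                "from_cache": first["from_cache"] in (True, "True"),
            })
    return records, trial_meta


def read_results(out_dir: Union[str, Path]):
    """Rebuild the in-memory run objects written by :func:`write_results`."""
    out = Path(out_dir)
    with open(out / "summary.json", encoding="utf-8") as fh:
        summary = json.load(fh)
    try:
        df = pd.read_csv(
            out / "trials.csv", keep_default_na=False, na_values=[],
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    records, trial_meta = _records_from_frame(df)

    if summary["kind"] == "mapping":
        return ResultsCollection(records, duration_s=summary["duration_s"])
    trials = [
        TrialRecord(r.stimulus, r, m["decision"], m["reason"], m["time_s"], m["from_cache"])
        for r, m in zip(records, trial_meta)
    ]
    found = next((t for t in trials if t.decision == "accept"), None)
    return SearchResult(
        status=summary["status"],
        found_stimulus=found.stimulus if found else None,
        found_record=found.record if found else None,
        stimuli_tested=summary["stimuli_tested"],
        combos_evaluated=summary["combos_evaluated"],
        excluded_cecs=summary["excluded_cecs"],
        trials=trials,
        duration_s=summary["duration_s"],
    )


# --------------------------------------------------------------------------
# Response cache persistence (shared between successive searches)


def write_cache(cache: dict, path: Union[str, Path]) -> None:
    """Persist a response cache (stimulus key → record) as a trial CSV."""
    df = _records_frame(list(cache.values()))
    df.to_csv(path, index=False)


def read_cache(path: Union[str, Path]) -> dict:
    """Load a response cache written by :func:`write_cache`."""
    if not Path(path).exists():
        return {}
    try:
        df = pd.read_csv(
            path, keep_default_na=False, na_values=[], float_precision="round_trip"
        )
    except pd.errors.EmptyDataError:
        return {}
    records, _ = _records_from_frame(df)
    return {rec.stimulus.key: rec for rec in records}


# --------------------------------------------------------------------------
# Acceleration traces


def write_trace(trace: AccelerationTrace, path: Union[str, Path]) -> None:
    """Write a trace as CSV: columns t_s, ax_ms2, ay_ms2 (accelerations in m/s²)."""
    t = [i / trace.sample_rate_hz for i in range(trace.samples.shape[0])]
    pd.DataFrame(
        {"t_s": t, "ax_ms2": trace.samples[:, 0], "ay_ms2": trace.samples[:, 1]}
    ).to_csv(path, index=False)


def read_trace(path: Union[str, Path], sample_rate_hz: Optional[float] = None) -> AccelerationTrace:
    """Read a delimited trace: (t_s, ax, ay) columns, or (ax, ay) plus a sample rate."""
    df = pd.read_csv(path)
    if df.shape[1] == 3:
        t = df.iloc[:, 0].to_numpy()
        dt = float(t[1] - t[0])
        rate = 1.0 / dt
        samples = df.iloc[:, 1:].to_numpy()
    elif df.shape[1] == 2:
        if sample_rate_hz is None:
            raise ValueError("two-column trace files require an explicit sample rate")
        rate = sample_rate_hz
        samples = df.to_numpy()
    else:
        raise ValueError("trace file must have 2 or 3 columns")
    return AccelerationTrace(rate, samples)
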