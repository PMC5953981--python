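"""Paced single-cell simulation of the tT04 human ventricular myocyte.

The module exposes the virtual-individual covariates (plasma ion
concentrations, heart rate, cardiomyocyte morphometry), a paced single-cell
simulator with pore-block conductance scaling, and the cellular biomarkers:
action-potential duration (APD50/APD90) and calcium-transient duration
(CaD), the latter serving as the surrogate for the end of mechanical
systole in the electromechanical-window biomarker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from . import _tt04
from .pharmacology import BlockState

__all__ = [
    "VirtualIndividual",
    "CellTrace",
    "IntegrationFailureError",
    "CELL_TYPES",
    "simulate_cell",
    "apd",
    "calcium_duration",
]

#: transmural cell types in endocardium → epicardium order
CELL_TYPES = ("endo", "mid", "epi")
_CELL_TYPE_CODE = {"endo": 0, "mid": 1, "epi": 2}

#: conventional supra-threshold stimulus for the tT04 model
STIMULUS_AMPLITUDE = -52.0  # pA/pF
STIMULUS_DURATION = 1.0  # ms


class IntegrationFailureError(RuntimeError):
    """Numerical blow-up during integration; carries the failure time (ms)."""

    def __init__(self, time_ms: float):
        self.time_ms = time_ms
        super().__init__(f"integration failed at t = {time_ms:.3f} ms")


@dataclass(frozen=True)
class VirtualIndividual:
    """Physiological covariates of one simulated subject.

    Defaults are the representative healthy adult used throughout:
    plasma ions in mM, RR interval in ms, cardiomyocyte volume/area in
    µm³/µm², electric capacitance in pF, sarcoplasmic-reticulum volume in
    µm³ and transmural string length (wall thickness) in mm.
    """

    age: float = 34.0
    k_out: float = 5.49
    na_out: float = 137.59
    ca_out: float = 2.25
    rr: float = 808.0
    cell_volume: float = 8183.0
    cell_area: float = 2274.0
    capacitance: float = 60.42
    sr_volume: float = 628.1
    string_length: float = 10.8

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not (value > 0):
                raise ValueError(f"{name} must be > 0, got {value}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "VirtualIndividual":
        return cls(**d)


@dataclass
class CellTrace:
    """Uniformly sampled membrane-potential and Ca trace of one beat.

    ``stim_time`` is the time (ms, on the trace's own clock) at which the
    pacing stimulus of the recorded beat is applied; samples before it show
    the diastolic state.
    """

    t: np.ndarray
    vm: np.ndarray
    ca: np.ndarray
    cell_type: str
    stim_time: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.vm = np.asarray(self.vm, dtype=float)
        self.ca = np.asarray(self.ca, dtype=float)
        if not (len(self.t) == len(self.vm) == len(self.ca)):
            raise ValueError("t, vm and ca must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")


def _morphometry_factors(individual: VirtualIndividual) -> tuple[float, float]:
    """Map individual morphometry onto the model's concentration-ODE terms.

    Capacitance and compartment volumes scale the published reference values
    proportionally, so the flux terms Cm/(V_c F) and V_c/V_sr follow the
    individual's cardiomyocyte geometry.
    """
    cm = _tt04.CM_REF * individual.capacitance / _tt04.CAPACITANCE_REF_PF
    vc = _tt04.VC_REF * individual.cell_volume / _tt04.CELL_VOLUME_REF_UM3
    vsr = _tt04.VSR_REF * individual.sr_volume / _tt04.SR_VOLUME_REF_UM3
    cap_over_vcf = cm / (vc * _tt04.FARADAY)
    vc_over_vsr = vc / vsr
    return cap_over_vcf, vc_over_vsr


def _block_scales(block: Optional[BlockState]) -> tuple[float, float, float, float]:
    b = block if block is not None else BlockState.identity()
    return b.get("IKr"), b.get("IKs"), b.get("INa"), b.get("ICaL")


def simulate_cell(
    cell_type: str,
    individual: Optional[VirtualIndividual] = None,
    block: Optional[BlockState] = None,
    n_beats: int = 100,
    dt: float = 0.02,
    record_dt: float = 0.1,
    pre_ms: float = 50.0,
    method: str = "euler",
    stimulate: bool = True,
    initial_states: Optional[np.ndarray] = None,
    return_final_state: bool = False,
):
    """Pace a single tT04 cell and return the final beat's trace.

    The cell is paced at cycle length ``individual.rr`` with a 1 ms,
    −52 pA/pF stimulus for ``n_beats`` beats; the returned trace covers the
    last beat plus ``pre_ms`` ms of the preceding diastole (so the
    stimulus falls at ``trace.stim_time == pre_ms``).

    ``method`` selects the gate integrator: ``"euler"`` (forward Euler,
    default) or ``"rush_larsen"`` (exponential gate update).
    """
    if cell_type not in CELL_TYPES:
        raise ValueError(f"cell_type must be one of {CELL_TYPES}, got {cell_type!r}")
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if not (0 < dt <= 0.05):
        raise ValueError(f"dt must be in (0, 0.05] ms, got {dt}")
    if method not in ("euler", "rush_larsen"):
        raise ValueError(f"unknown method {method!r}")
    individual = individual or VirtualIndividual()

    cycle_steps = max(1, int(round(individual.rr / dt)))
    stim_steps = int(round(STIMULUS_DURATION / dt)) if stimulate else 0
    n_steps = cycle_steps * n_beats
    record_stride = max(1, int(round(record_dt / dt)))
    pre_steps = int(round(pre_ms / dt))
    record_start = max(0, n_steps - cycle_steps - pre_steps)
    n_rec = (n_steps - record_start + record_stride - 1) // record_stride

    states = (
        np.array(initial_states, dtype=float).reshape(1, _tt04.N_STATES)
        if initial_states is not None
        else _tt04.initial_states(1)
    )
    cell_codes = np.array([_CELL_TYPE_CODE[cell_type]], dtype=np.int64)
    v_out = np.empty((1, n_rec))
    ca_out = np.empty((1, n_rec))
    skr, sks, sna, scal = _block_scales(block)
    cap_over_vcf, vc_over_vsr = _morphometry_factors(individual)

    fail = _tt04.run_fiber(
        states, cell_codes, dt, n_steps, cycle_steps, stim_steps,
        STIMULUS_AMPLITUDE if stimulate else 0.0, 1, 0.0,
        skr, sks, sna, scal,
        individual.k_out, individual.na_out, individual.ca_out,
        cap_over_vcf, vc_over_vsr, method == "rush_larsen",
        record_start, record_stride, v_out, ca_out,
    )
    if fail >= 0:
        raise IntegrationFailureError(fail * dt)

    t = (np.arange(n_rec) * record_stride) * dt
    stim_time = (n_steps - cycle_steps - record_start) * dt
    trace = CellTrace(
        t=t,
        vm=v_out[0],
        ca=ca_out[0],
        cell_type=cell_type,
        stim_time=stim_time if stimulate else float("nan"),
        meta={
            "dt": dt,
            "n_beats": n_beats,
            "rr": individual.rr,
            "method": method,
            "block": {k: v for k, v in (block.scale.items() if block else [])},
        },
    )
    if return_final_state:
        return trace, states[0].copy()
    return trace


def _duration_from_upstroke(
    t: np.ndarray,
    y: np.ndarray,
    fraction: float,
    diastolic: float,
) -> float:
    """Shared APD/CaD geometry: max-slope upstroke to fractional recovery.

    Returns NaN (the unmeasurable flag) when the signal never recovers below
    the repolarization threshold after its peak.
    """
    if not (0 < fraction < 100):
        raise ValueError(f"fraction must be in (0, 100), got {fraction}")
    dy = np.diff(y) / np.diff(t)
    i_up = int(np.argmax(dy))
    t_up = t[i_up]
    i_peak = i_up + int(np.argmax(y[i_up:]))
    peak = y[i_peak]
    amplitude = peak - diastolic
    if amplitude <= 0:
        return float("nan")
    threshold = peak - fraction / 100.0 * amplitude
    below = np.nonzero(y[i_peak:] < threshold)[0]
    if below.size == 0:
        return float("nan")
    k = i_peak + below[0]
    # linear interpolation between the bracketing samples
    t_cross = t[k - 1] + (threshold - y[k - 1]) * (t[k] - t[k - 1]) / (y[k] - y[k - 1])
    return float(t_cross - t_up)


def apd(trace: CellTrace, fraction: float) -> float:
    """Action-potential duration at ``fraction`` % repolarization (ms).

    Measured from the time of maximal upstroke velocity until vm first
    falls below peak − fraction%·amplitude, with the diastolic potential
    taken just before the stimulus; linear interpolation between samples.
    Returns NaN when the AP does not repolarize within the trace.
    """
    diastolic = _value_before_stimulus(trace.t, trace.vm, trace.stim_time)
    return _duration_from_upstroke(trace.t, trace.vm, fraction, diastolic)


def calcium_duration(trace: CellTrace, fraction: float) -> float:
    """Calcium-transient duration at ``fraction`` % recovery (ms).

    Same geometry as :func:`apd`, applied to the intracellular Ca series.
    """
    diastolic = _value_before_stimulus(trace.t, trace.ca, trace.stim_time)
    return _duration_from_upstroke(trace.t, trace.ca, fraction, diastolic)


def _value_before_stimulus(t: np.ndarray, y: np.ndarray, stim_time: float) -> float:
    if math.isnan(stim_time):
        return float(y[0])
    idx = np.searchsorted(t, stim_time, side="left")
    idx = max(0, min(idx, len(y) - 1))
    if t[idx] >= stim_time and idx > 0:
        idx -= 1
    return float(y[idx])
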