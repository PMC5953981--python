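"""Heterogeneous 1D ventricular fiber (monodomain cable) and pseudoECG.

The transmural wall is modeled as a string of tT04 cells ordered
endocardium → midmyocardium → epicardium (default composition 50/30/20 %),
stimulated at the endocardial end.  The far-field potential recorded by a
virtual unipolar electrode on the fiber axis beyond the epicardial end is
the pseudoECG:

    Φ(t) ∝ −∫ (∂V/∂x) · ∂(1/r)/∂x dx,   r(x) = distance from cell to electrode.

With this electrode placement a wave propagating endo→epi produces an
upright QRS, and the transmural gradient of action-potential duration
(mid cells repolarize last) produces the T wave.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _tt04
from .myocyte import (
    CELL_TYPES,
    STIMULUS_AMPLITUDE,
    STIMULUS_DURATION,
    IntegrationFailureError,
    VirtualIndividual,
    _block_scales,
    _morphometry_factors,
    simulate_cell,
)
from .pharmacology import BlockState

__all__ = [
    "FiberConfig",
    "FiberResult",
    "ConfigurationError",
    "build_fiber",
    "simulate_fiber",
    "pseudo_ecg",
    "activation_times",
]

_CODE_TO_TYPE = dict(enumerate(CELL_TYPES))

#: cable stimulus: the single-cell 1 ms pulse cannot overcome the coupling
#: load of the cable, so the fiber uses a 2 ms pulse at the same amplitude
FIBER_STIMULUS_DURATION = 2.0  # ms


class ConfigurationError(ValueError):
    """Invalid fiber configuration."""


@dataclass(frozen=True)
class FiberConfig:
    """Geometry and numerics of the 1D cable.

    ``composition`` is the (endo, mid, epi) fraction of wall thickness;
    ``dx`` the cell spacing in mm, ``diffusion`` the monodomain diffusion
    coefficient in mm²/ms, and ``electrode_distance`` the pseudoECG
    electrode's distance (mm) beyond the epicardial end on the fiber axis.
    ``length`` defaults to the virtual individual's string length.
    """

    composition: tuple[float, float, float] = (0.50, 0.30, 0.20)
    dx: float = 0.1
    diffusion: float = 0.154
    electrode_distance: float = 20.0
    length: Optional[float] = None

    def __post_init__(self) -> None:
        comp = tuple(float(c) for c in self.composition)
        if len(comp) != 3 or any(c < 0 for c in comp):
            raise ConfigurationError("composition must be three fractions >= 0")
        if abs(sum(comp) - 1.0) > 1e-9:
            raise ConfigurationError(f"composition must sum to 1, got {sum(comp)}")
        if not (self.dx > 0):
            raise ConfigurationError(f"dx must be > 0, got {self.dx}")
        if not (self.diffusion >= 0):
            raise ConfigurationError(f"diffusion must be >= 0, got {self.diffusion}")
        if not (self.electrode_distance > 0):
            raise ConfigurationError(
                f"electrode_distance must be > 0, got {self.electrode_distance}"
            )
        object.__setattr__(self, "composition", comp)

    def resolved_length(self, individual: VirtualIndividual) -> float:
        return float(self.length if self.length is not None else individual.string_length)


@dataclass
class FiberResult:
    """Final-beat space-time fields and pseudoECG of one fiber simulation."""

    t: np.ndarray
    vm_field: np.ndarray  # (cell, time), mV
    ca_field: np.ndarray  # (cell, time), mM
    pseudo_ecg: np.ndarray  # arbitrary units, over t
    cell_types: np.ndarray  # int codes per cell (0 endo, 1 mid, 2 epi)
    stim_time: float
    conduction_block: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_cells, n_t = self.vm_field.shape
        if self.ca_field.shape != (n_cells, n_t):
            raise ValueError("vm_field and ca_field shapes differ")
        if len(self.t) != n_t or len(self.pseudo_ecg) != n_t:
            raise ValueError("time axis inconsistent")
        if not np.all(np.isfinite(self.pseudo_ecg)):
            raise ValueError("pseudoECG contains non-finite values")


def build_fiber(individual: VirtualIndividual, config: FiberConfig) -> np.ndarray:
    """Deterministic transmural cell-type assignment along the cable.

    ``n = round(length/dx)`` cells are laid out endo→mid→epi with counts
    ``round(n·fraction)``; any rounding remainder is absorbed by the largest
    fraction.  Fibers shorter than 20 cells are rejected.
    """
    length = config.resolved_length(individual)
    n = int(np.floor(length / config.dx + 0.5))
    if n < 20:
        raise ConfigurationError(
            f"fiber of {n} cells is too short (need >= 20); length={length} dx={config.dx}"
        )
    counts = [int(np.floor(n * f + 0.5)) for f in config.composition]
    remainder = n - sum(counts)
    counts[int(np.argmax(config.composition))] += remainder
    if min(counts) < 0:
        raise ConfigurationError(f"composition {config.composition} is degenerate")
    return np.repeat(np.arange(3, dtype=np.int64), counts)


def activation_times(result: "FiberResult", threshold: float = -20.0) -> np.ndarray:
    """Per-cell activation time: first upward crossing of ``threshold`` (mV).

    Crossing times are linearly interpolated between samples; cells that
    never depolarize above the threshold get NaN.
    """
    t = result.t
    out = np.full(result.vm_field.shape[0], np.nan)
    for i, vm in enumerate(result.vm_field):
        above = np.nonzero(vm >= threshold)[0]
        if above.size == 0:
            continue
        k = above[0]
        if k == 0:
            out[i] = t[0]
        else:
            out[i] = t[k - 1] + (threshold - vm[k - 1]) * (t[k] - t[k - 1]) / (
                vm[k] - vm[k - 1]
            )
    return out


def pseudo_ecg(
    vm_field: np.ndarray, config: FiberConfig, length: Optional[float] = None
) -> np.ndarray:
    """Unipolar far-field pseudoECG from the membrane-potential field.

    Linear in ``vm_field``; identically zero for a spatially uniform field.
    The electrode sits on the fiber axis ``config.electrode_distance`` mm
    beyond the epicardial (last-cell) end.
    """
    vm_field = np.asarray(vm_field, dtype=float)
    n_cells = vm_field.shape[0]
    dx = config.dx
    fiber_len = length if length is not None else n_cells * dx
    x = (np.arange(n_cells) + 0.5) * dx
    x_e = fiber_len + config.electrode_distance
    r = x_e - x
    dvdx = np.gradient(vm_field, x, axis=0)
    # ∂(1/r)/∂x = +1/r² for r = x_e − x
    weights = (1.0 / r**2) * dx
    return -(weights[:, None] * dvdx).sum(axis=0)


def simulate_fiber(
    individual: Optional[VirtualIndividual] = None,
    config: Optional[FiberConfig] = None,
    block: Optional[BlockState] = None,
    n_beats: int = 2,
    dt: float = 0.02,
    prepace_beats: int = 100,
    record_dt: float = 0.2,
    pre_ms: float = 50.0,
    method: str = "euler",
    stimulate: bool = True,
) -> FiberResult:
    """Simulate the paced heterogeneous fiber and return the final beat.

    Each transmural cell type is first pre-paced to its single-cell limit
    cycle (``prepace_beats`` beats, drug block applied), the fiber is then
    assembled from those states and paced for ``n_beats`` coupled beats with
    the stimulus delivered to the first three endocardial cells.  The
    returned fields cover the last beat plus ``pre_ms`` ms of diastole.

    When no cell beyond the stimulated ones depolarizes above −20 mV the
    result carries ``conduction_block=True`` and downstream biomarkers are
    reported unmeasurable.
    """
    individual = individual or VirtualIndividual()
    config = config or FiberConfig()
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if not (0 < dt <= 0.05):
        raise ValueError(f"dt must be in (0, 0.05] ms, got {dt}")

    cell_codes = build_fiber(individual, config)
    n_cells = len(cell_codes)

    # per-type pre-pacing to pseudo-steady state (uncoupled)
    type_states = {}
    for code in np.unique(cell_codes):
        ctype = _CODE_TO_TYPE[int(code)]
        if prepace_beats >= 1:
            _, state = simulate_cell(
                ctype,
                individual,
                block,
                n_beats=prepace_beats,
                dt=dt,
                record_dt=max(1.0, individual.rr / 4),
                method=method,
                return_final_state=True,
            )
        else:
            state = _tt04.INITIAL_STATE.copy()
        type_states[int(code)] = state
    states = np.vstack([type_states[int(c)] for c in cell_codes])

    cycle_steps = max(1, int(round(individual.rr / dt)))
    stim_steps = int(round(FIBER_STIMULUS_DURATION / dt)) if stimulate else 0
    n_steps = cycle_steps * n_beats
    record_stride = max(1, int(round(record_dt / dt)))
    pre_steps = int(round(pre_ms / dt))
    record_start = max(0, n_steps - cycle_steps - pre_steps)
    n_rec = (n_steps - record_start + record_stride - 1) // record_stride

    v_out = np.empty((n_cells, n_rec))
    ca_out = np.empty((n_cells, n_rec))
    skr, sks, sna, scal = _block_scales(block)
    cap_over_vcf, vc_over_vsr = _morphometry_factors(individual)
    d_over_dx2 = config.diffusion / config.dx**2

    fail = _tt04.run_fiber(
        states, cell_codes, dt, n_steps, cycle_steps, stim_steps,
        STIMULUS_AMPLITUDE if stimulate else 0.0, 3, d_over_dx2,
        skr, sks, sna, scal,
        individual.k_out, individual.na_out, individual.ca_out,
        cap_over_vcf, vc_over_vsr, method == "rush_larsen",
        record_start, record_stride, v_out, ca_out,
    )
    if fail >= 0:
        raise IntegrationFailureError(fail * dt)

    t = (np.arange(n_rec) * record_stride) * dt
    stim_time = (n_steps - cycle_steps - record_start) * dt

    conduction_block = False
    if stimulate:
        downstream = v_out[3:, :]
        conduction_block = bool(np.max(downstream) < -20.0)

    phi = pseudo_ecg(v_out, config, length=config.resolved_length(individual))
    return FiberResult(
        t=t,
        vm_field=v_out,
        ca_field=ca_out,
        pseudo_ecg=phi,
        cell_types=cell_codes,
        stim_time=stim_time if stimulate else float("nan"),
        conduction_block=conduction_block,
        meta={
            "dt": dt,
            "n_beats": n_beats,
            "prepace_beats": prepace_beats,
            "rr": individual.rr,
            "dx": config.dx,
            "diffusion": config.diffusion,
            "composition": config.composition,
            "length": config.resolved_length(individual),
            "method": method,
            "block": {k: v for k, v in (block.scale.items() if block else [])},
        },
    )
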