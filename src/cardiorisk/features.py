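"""Classifier input representation: concentration grid and EMW/iCEB features.

Each compound is simulated over a fixed ten-point concentration grid
(0 … 500 µM); the electromechanical window and iCEB at each grid point form
the 20-dimensional feature vector EMW1-10 / iCEB1-10 (index 1 = baseline at
0 µM, raw values, not baseline deltas).  Risk labels follow the
CredibleMeds convention: only "known risk of TdP" maps to TdP(+).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .biomarkers import extract_biomarkers
from .fiber import FiberConfig, simulate_fiber
from .myocyte import VirtualIndividual
from .pharmacology import DrugProfile, block_state

__all__ = [
    "DEFAULT_GRID",
    "ConcentrationGrid",
    "FeatureVector",
    "RISK_CATEGORIES",
    "VALIDATION_PANEL",
    "featurize",
    "map_crediblemeds_label",
]

#: the fixed simulation concentrations in µM
DEFAULT_GRID = (0.0, 0.0001, 0.001, 0.01, 0.1, 1.0, 10.0, 30.0, 100.0, 500.0)

#: accepted CredibleMeds-style risk categories
RISK_CATEGORIES = ("known", "possible", "conditional", "not_mentioned")

#: the published 12-compound external validation panel with its
#: CredibleMeds categories (snapshot used for the risk labels)
VALIDATION_PANEL = {
    "fexofenadine": "not_mentioned",
    "propafenone": "not_mentioned",
    "verapamil": "not_mentioned",
    "hydrodolasetron": "possible",
    "ranolazine": "possible",
    "vardenafil": "possible",
    "amiodarone": "known",
    "citalopram": "known",
    "clarithromycin": "known",
    "dofetilide": "known",
    "moxifloxacin": "known",
    "quinidine": "known",
}


class LabelingError(ValueError):
    """Unknown risk-category string."""


@dataclass(frozen=True)
class ConcentrationGrid:
    """Strictly increasing concentration grid starting at 0 µM, length 10."""

    values: tuple[float, ...] = DEFAULT_GRID

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if len(vals) != 10:
            raise ValueError(f"grid must have 10 concentrations, got {len(vals)}")
        if vals[0] != 0.0:
            raise ValueError("grid must start at 0 µM")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("grid must be strictly increasing")
        object.__setattr__(self, "values", vals)

    def __iter__(self):
        return iter(self.values)

    def __len__(self):
        return len(self.values)


@dataclass
class FeatureVector:
    """Per-drug classifier input: EMW1-10 and iCEB1-10 plus optional label."""

    drug: str
    emw: np.ndarray
    iceb: np.ndarray
    label: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.emw = np.asarray(self.emw, dtype=float)
        self.iceb = np.asarray(self.iceb, dtype=float)
        if self.emw.shape != (10,) or self.iceb.shape != (10,):
            raise ValueError("emw and iceb must each have 10 values")
        if not (np.all(np.isfinite(self.emw)) and np.all(np.isfinite(self.iceb))):
            raise ValueError("features must be finite after imputation")
        if self.label is not None and self.label not in ("positive", "negative"):
            raise ValueError(f"label must be 'positive'/'negative', got {self.label!r}")

    def to_array(self) -> np.ndarray:
        """20-vector [EMW1..EMW10, iCEB1..iCEB10]."""
        return np.concatenate([self.emw, self.iceb])

    @staticmethod
    def feature_names() -> list[str]:
        return [f"emw_{i}" for i in range(1, 11)] + [f"iceb_{i}" for i in range(1, 11)]


def map_crediblemeds_label(category: str) -> str:
    """Binary TdP label from a CredibleMeds category.

    ``known`` → ``positive``; ``possible``, ``conditional`` and
    ``not_mentioned`` → ``negative``.
    """
    cat = str(category).strip().lower().replace(" ", "_")
    if cat not in RISK_CATEGORIES:
        raise LabelingError(
            f"unknown risk category {category!r}; accepted: {RISK_CATEGORIES}"
        )
    return "positive" if cat == "known" else "negative"


def _impute_carry_forward(values: list[float]) -> np.ndarray:
    """Replace unmeasurable (NaN) entries by the last measurable value."""
    out = np.array(values, dtype=float)
    for i in range(1, len(out)):
        if math.isnan(out[i]):
            out[i] = out[i - 1]
    return out


def featurize(
    drug: DrugProfile,
    individual: Optional[VirtualIndividual] = None,
    fiber_config: Optional[FiberConfig] = None,
    grid: Optional[ConcentrationGrid] = None,
    qtc_method: str = "fridericia",
    as_delta: bool = False,
    **sim_kwargs,
) -> FeatureVector:
    """Simulate a drug across the concentration grid and build its features.

    For every grid concentration the pore block is evaluated, the fiber
    simulated, and EMW/iCEB extracted; unmeasurable values at high
    concentrations (e.g. conduction block) are imputed by
    last-measurable-concentration carry-forward.  An unmeasurable baseline
    (0 µM) invalidates the simulation setup and raises.

    ``as_delta=True`` encodes features as changes from baseline instead of
    raw values.  Extra keyword arguments (``n_beats``, ``dt``,
    ``prepace_beats`` …) are forwarded to :func:`simulate_fiber`.
    """
    if not drug.measurements:
        raise ValueError(f"drug {drug.name!r} has no current measurements")
    individual = individual or VirtualIndividual()
    fiber_config = fiber_config or FiberConfig()
    grid = grid or ConcentrationGrid()

    emw_vals: list[float] = []
    iceb_vals: list[float] = []
    biomarker_rows = []
    for k, conc in enumerate(grid):
        blk = block_state(drug, conc)
        result = simulate_fiber(individual, fiber_config, blk, **sim_kwargs)
        bm = extract_biomarkers(result, rr=individual.rr, qtc_method=qtc_method)
        if k == 0 and not (bm.is_measurable("emw") and bm.is_measurable("iceb")):
            raise RuntimeError(
                f"baseline (0 µM) biomarkers unmeasurable for {drug.name!r}: "
                "simulation setup invalid"
            )
        emw_vals.append(bm.emw if bm.is_measurable("emw") else float("nan"))
        iceb_vals.append(bm.iceb if bm.is_measurable("iceb") else float("nan"))
        biomarker_rows.append(bm.to_dict() | {"concentration": conc})

    emw_arr = _impute_carry_forward(emw_vals)
    iceb_arr = _impute_carry_forward(iceb_vals)
    if as_delta:
        emw_arr = emw_arr - emw_arr[0]
        iceb_arr = iceb_arr - iceb_arr[0]

    label = drug.binary_label
    if label is None and drug.risk_category is not None:
        label = map_crediblemeds_label(drug.risk_category)
    return FeatureVector(
        drug=drug.name,
        emw=emw_arr,
        iceb=iceb_arr,
        label=label,
        meta={
            "grid": tuple(grid),
            "qtc_method": qtc_method,
            "as_delta": as_delta,
            "biomarkers": biomarker_rows,
            "sim_kwargs": dict(sim_kwargs),
        },
    )
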