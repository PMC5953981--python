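"""Synthetic input generators for every pipeline stage.

Two levels are generated: (a) drug IC50 profiles with a known generative
risk class, exercising the pharmacology→simulation path, and (b) direct
EMW/iCEB feature tables with a controllable dose-response signal,
exercising the classifier without any simulation.

Generative drug classes mirror the pharmacological archetypes behind TdP
risk: ``herg_selective`` (potent IKr block, weak elsewhere — torsadogenic),
``balanced_multichannel`` (comparable IKr and ICaL block, the balanced
profile that clinically offsets QT risk) and ``inert`` (no meaningful block
at any tested concentration).

The feature generator's defaults reproduce the learning-set study
conditions: 96 compounds with a 28/96 TdP(+) class balance, a monotone
EMW decline / iCEB rise across the ten concentrations for positives, and
Gaussian assay-level noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .features import FeatureVector
from .pharmacology import CurrentMeasurement, DrugProfile

__all__ = [
    "SyntheticDrugSpec",
    "SyntheticFeatureSpec",
    "generate_drugs",
    "generate_features",
]

GENERATIVE_CLASSES = ("herg_selective", "balanced_multichannel", "inert")

_DEFAULT_IC50_RANGES = {
    "herg_selective": {
        "IKr": (0.01, 1.0),
        "IKs": (100.0, 1000.0),
        "INa": (100.0, 1000.0),
        "ICaL": (100.0, 1000.0),
    },
    "balanced_multichannel": {
        "IKr": (0.1, 3.0),
        "ICaL": (0.1, 3.0),
        "IKs": (100.0, 1000.0),
        "INa": (30.0, 300.0),
    },
    "inert": {
        "IKr": (1e4, 1e5),
        "IKs": (1e4, 1e5),
        "INa": (1e4, 1e5),
        "ICaL": (1e4, 1e5),
    },
}

_CLASS_LABEL = {
    "herg_selective": "positive",
    "balanced_multichannel": "negative",
    "inert": "negative",
}


@dataclass(frozen=True)
class SyntheticDrugSpec:
    """Generative recipe for synthetic IC50 profiles of one risk archetype."""

    generative_class: str = "herg_selective"
    ic50_ranges: Optional[dict] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generative_class not in GENERATIVE_CLASSES:
            raise ValueError(
                f"generative_class must be one of {GENERATIVE_CLASSES}, "
                f"got {self.generative_class!r}"
            )
        ranges = self.ic50_ranges or _DEFAULT_IC50_RANGES[self.generative_class]
        for cur, (lo, hi) in ranges.items():
            if not (0 < lo < hi):
                raise ValueError(f"bad IC50 bounds for {cur}: ({lo}, {hi})")
        object.__setattr__(self, "ic50_ranges", dict(ranges))


@dataclass(frozen=True)
class SyntheticFeatureSpec:
    """Generative recipe for direct EMW/iCEB feature tables.

    ``emw_effect`` is the total EMW decline (ms) and ``iceb_effect`` the
    total iCEB rise (dimensionless) accumulated across the ten
    concentrations by a TdP(+) compound, in expectation; negatives are flat.
    """

    n_drugs: int = 96
    class_balance: float = 28.0 / 96.0  # fraction TdP(+)
    emw_effect: float = 40.0
    iceb_effect: float = 1.5
    emw_baseline: float = 15.0
    iceb_baseline: float = 4.3
    noise_sd_emw: float = 5.0
    noise_sd_iceb: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 4:
            raise ValueError("n_drugs must be >= 4")
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class_balance must be in (0, 1)")
        if self.noise_sd_emw < 0 or self.noise_sd_iceb < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_drugs(spec: SyntheticDrugSpec, n: int) -> list[DrugProfile]:
    """Draw ``n`` synthetic drug profiles (log-uniform IC50 per current).

    ``herg_selective`` drugs carry their lowest IC50 on IKr and the
    TdP(+) label; the other archetypes are labeled TdP(−).  Reproducible
    from the spec's seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    label = _CLASS_LABEL[spec.generative_class]
    drugs = []
    for i in range(n):
        measurements = []
        for cur, (lo, hi) in sorted(spec.ic50_ranges.items()):
            ic50 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            measurements.append(
                CurrentMeasurement(
                    current=cur,
                    ic50=ic50,
                    hill=1.0,
                    temperature=37.0,
                    source=f"synthetic:{spec.generative_class}",
                )
            )
        drugs.append(
            DrugProfile(
                name=f"{spec.generative_class}_{i:03d}",
                measurements=measurements,
                binary_label=label,
            )
        )
    return drugs


def generate_features(spec: SyntheticFeatureSpec) -> list[FeatureVector]:
    """Draw a labeled synthetic EMW1-10/iCEB1-10 feature table.

    TdP(−) compounds have concentration-flat features around the baseline;
    TdP(+) compounds add a linear ramp across indices 1→10 (EMW declining
    by ``emw_effect`` ms, iCEB rising by ``iceb_effect``) before Gaussian
    noise.  Reproducible from the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.n_drugs * spec.class_balance))
    n_pos = min(max(n_pos, 2), spec.n_drugs - 2)  # keep both classes populated
    labels = ["positive"] * n_pos + ["negative"] * (spec.n_drugs - n_pos)
    ramp = np.linspace(0.0, 1.0, 10)
    out = []
    for i, label in enumerate(labels):
        if label == "positive":
            emw_mean = spec.emw_baseline - spec.emw_effect * ramp
            iceb_mean = spec.iceb_baseline + spec.iceb_effect * ramp
        else:
            emw_mean = np.full(10, spec.emw_baseline)
            iceb_mean = np.full(10, spec.iceb_baseline)
        emw = emw_mean + rng.normal(0.0, spec.noise_sd_emw, 10)
        iceb = iceb_mean + rng.normal(0.0, spec.noise_sd_iceb, 10)
        out.append(
            FeatureVector(
                drug=f"synthetic_{label}_{i:03d}",
                emw=emw,
                iceb=iceb,
                label=label,
                meta={"generative_class": label, "seed": spec.seed},
            )
        )
    return out
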