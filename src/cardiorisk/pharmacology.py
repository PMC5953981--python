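"""Per-drug ion-current inhibition data and the pore-block drug model.

A drug is described by patch-clamp inhibition records: for each of the four
main cardiac currents (IKr/hERG, IKs, INa, ICaL) one or more IC50 values,
optionally with a Hill coefficient and the assay conditions under which the
IC50 was measured.  At a given free concentration the drug scales each
channel's maximal conductance by the simple pore-block factor

    scale = 1 / (1 + (C / IC50) ** hill)

which is 1 with no drug and 0.5 at C = IC50 for hill = 1.  When several IC50
records exist for the same current, a conservative curation rule is applied:
prefer assays run near physiological temperature, then take the lowest IC50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "MAIN_CURRENTS",
    "CURRENTS",
    "CurrentMeasurement",
    "DrugProfile",
    "BlockState",
    "conductance_scale",
    "select_ic50",
    "block_state",
    "PHYSIOLOGICAL_TEMPERATURE_BAND",
]

#: The four drug-blockable currents of the myocyte model, in conventional order.
MAIN_CURRENTS = ("IKr", "IKs", "INa", "ICaL")

#: All accepted current identifiers ("other" collects currents the myocyte
#: model does not represent; they never contribute to a BlockState).
CURRENTS = MAIN_CURRENTS + ("other",)

#: Assay temperature band (°C) treated as physiological by the IC50
#: selection policy.
PHYSIOLOGICAL_TEMPERATURE_BAND = (33.0, 38.0)


class InvalidParameterError(ValueError):
    """A pharmacological parameter is outside its admissible range."""


class MissingDataError(ValueError):
    """A required measurement is absent."""


@dataclass(frozen=True)
class CurrentMeasurement:
    """One patch-clamp inhibition record for a single current.

    Parameters
    ----------
    current : str
        One of ``IKr``, ``IKs``, ``INa``, ``ICaL`` or ``other``.
    ic50 : float
        Half-maximal inhibitory concentration in µM (> 0).
    hill : float
        Hill coefficient of the concentration-inhibition curve (> 0,
        default 1).
    temperature : float, optional
        Assay temperature in °C.
    holding_potential, depolarization_potential, repolarization_potential, \
    measurement_potential : float, optional
        Voltage-clamp protocol potentials in mV.
    source : str
        Free-text provenance of the record.
    selected : bool, optional
        Explicit curation override: when any record of a current carries
        ``selected=True``, the selection policy is bypassed for that current.
    """

    current: str
    ic50: float
    hill: float = 1.0
    temperature: Optional[float] = None
    holding_potential: Optional[float] = None
    depolarization_potential: Optional[float] = None
    repolarization_potential: Optional[float] = None
    measurement_potential: Optional[float] = None
    source: str = ""
    selected: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.current not in CURRENTS:
            raise InvalidParameterError(
                f"unknown current {self.current!r}; expected one of {CURRENTS}"
            )
        if not (self.ic50 > 0):
            raise InvalidParameterError(f"ic50 must be > 0 µM, got {self.ic50}")
        if not (self.hill > 0):
            raise InvalidParameterError(f"hill must be > 0, got {self.hill}")


@dataclass
class DrugProfile:
    """A named compound with its inhibition records and TdP risk labels.

    ``risk_category`` is the CredibleMeds-style category (``known``,
    ``possible``, ``conditional`` or ``not_mentioned``); ``binary_label`` the
    derived TdP(+)/TdP(−) class (``positive``/``negative``).
    """

    name: str
    measurements: list[CurrentMeasurement] = field(default_factory=list)
    risk_category: Optional[str] = None
    binary_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise InvalidParameterError("drug name must be non-empty")
        if self.binary_label is not None and self.binary_label not in (
            "positive",
            "negative",
        ):
            raise InvalidParameterError(
                f"binary_label must be 'positive' or 'negative', got {self.binary_label!r}"
            )
        if self.risk_category is not None and self.binary_label is not None:
            from .features import map_crediblemeds_label

            expected = map_crediblemeds_label(self.risk_category)
            if expected != self.binary_label:
                raise InvalidParameterError(
                    f"binary_label {self.binary_label!r} inconsistent with risk "
                    f"category {self.risk_category!r} (expected {expected!r})"
                )

    def measurements_for(self, current: str) -> list[CurrentMeasurement]:
        return [m for m in self.measurements if m.current == current]


@dataclass(frozen=True)
class BlockState:
    """Conductance scale factor per current; unmeasured currents stay at 1."""

    scale: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cur, s in self.scale.items():
            if cur not in CURRENTS:
                raise InvalidParameterError(f"unknown current {cur!r}")
            if not (0.0 < s <= 1.0):
                raise InvalidParameterError(
                    f"scale for {cur} must be in (0, 1], got {s}"
                )

    def get(self, current: str) -> float:
        return float(self.scale.get(current, 1.0))

    @classmethod
    def identity(cls) -> "BlockState":
        return cls({})

    def is_identity(self) -> bool:
        return all(v == 1.0 for v in self.scale.values())


def conductance_scale(concentration: float, ic50: float, hill: float = 1.0) -> float:
    """Pore-block conductance scale 1 / (1 + (C/IC50)**hill).

    Parameters are in µM (concentration ≥ 0, ic50 > 0) and dimensionless
    hill > 0.  Returns a fraction in (0, 1]: 1 at C = 0, strictly decreasing
    in C, strictly increasing in IC50.
    """
    if not (ic50 > 0):
        raise InvalidParameterError(f"ic50 must be > 0, got {ic50}")
    if not (hill > 0):
        raise InvalidParameterError(f"hill must be > 0, got {hill}")
    if concentration < 0:
        raise InvalidParameterError(f"concentration must be ≥ 0, got {concentration}")
    if concentration == 0.0:
        return 1.0
    return 1.0 / (1.0 + (concentration / ic50) ** hill)


def select_ic50(
    records: Sequence[CurrentMeasurement],
    temperature_band: tuple[float, float] = PHYSIOLOGICAL_TEMPERATURE_BAND,
) -> CurrentMeasurement:
    """Curate one IC50 record for a current.

    Policy: if any record is explicitly flagged ``selected``, choose among
    those; otherwise restrict to records whose assay temperature lies in the
    physiological band when at least one such record exists; from the
    retained subset return the record with the lowest IC50 (first occurrence
    wins ties).
    """
    records = list(records)
    if not records:
        raise MissingDataError("no measurements to select from")
    currents = {m.current for m in records}
    if len(currents) > 1:
        raise InvalidParameterError(
            f"records mix currents {sorted(currents)}; select per current"
        )
    flagged = [m for m in records if m.selected]
    if flagged:
        pool = flagged
    else:
        lo, hi = temperature_band
        physio = [
            m for m in records if m.temperature is not None and lo <= m.temperature <= hi
        ]
        pool = physio if physio else records
    return min(pool, key=lambda m: m.ic50)  # min is stable: first occurrence wins


def block_state(drug: DrugProfile, concentration: float) -> BlockState:
    """Evaluate the drug's pore block on every measured main current.

    Currents without a measurement are left unblocked (scale 1.0); at
    concentration 0 the identity block is returned for every drug.
    """
    if concentration < 0:
        raise InvalidParameterError(f"concentration must be ≥ 0, got {concentration}")
    scale: dict[str, float] = {}
    for cur in MAIN_CURRENTS:
        recs = drug.measurements_for(cur)
        if not recs:
            continue
        chosen = select_ic50(recs)
        scale[cur] = conductance_scale(concentration, chosen.ic50, chosen.hill)
    return BlockState(scale)
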