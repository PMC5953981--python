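"""Readers and writers for drug tables, labels, features, traces and configs.

CSV is the canonical interchange format (XLSX drug tables are read through
pandas/openpyxl); configs and trained models are JSON.  Every reader
collects per-row diagnostics and reports them together rather than failing
on the first bad row.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .features import ConcentrationGrid, FeatureVector, RISK_CATEGORIES
from .fiber import FiberConfig
from .myocyte import CellTrace, VirtualIndividual
from .pharmacology import CurrentMeasurement, DrugProfile

__all__ = [
    "DrugTableError",
    "RunConfig",
    "read_drug_table",
    "write_drug_table",
    "read_labels",
    "write_feature_table",
    "read_feature_table",
    "write_cell_trace",
    "read_cell_trace",
    "write_pseudo_ecg",
    "config_hash",
]

_UNIT_TO_UM = {"µm": 1.0, "um": 1.0, "µM": 1.0, "uM": 1.0, "nm": 1e-3, "nM": 1e-3,
               "mm": 1e3, "mM": 1e3, "m": 1e6, "M": 1e6}

_CURRENT_SYNONYMS = {
    "ikr": "IKr", "herg": "IKr", "kv11.1": "IKr",
    "iks": "IKs", "kvlqt1": "IKs",
    "ina": "INa", "nav1.5": "INa",
    "ical": "ICaL", "ica": "ICaL", "ica,l": "ICaL", "cav1.2": "ICaL",
    "other": "other",
}

_DRUG_TABLE_COLUMNS = [
    "drug", "current", "ic50", "ic50_unit", "hill", "temperature_c",
    "holding_mv", "depolarization_mv", "repolarization_mv", "measurement_mv",
    "source", "selected",
]


class DrugTableError(ValueError):
    """One or more rows of a drug table failed validation."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("drug table errors:\n" + "\n".join(self.errors))


class LabelFileError(ValueError):
    """Invalid risk-label file."""


@dataclass
class RunConfig:
    """Aggregated configuration of one end-to-end pipeline run."""

    individual: VirtualIndividual = field(default_factory=VirtualIndividual)
    fiber: FiberConfig = field(default_factory=FiberConfig)
    grid: ConcentrationGrid = field(default_factory=ConcentrationGrid)
    dt: float = 0.02
    n_beats: int = 2
    prepace_beats: int = 100
    qtc_method: str = "fridericia"
    t_end_method: str = "tangent"
    emw_surrogate: str = "calcium"
    imputation: str = "carry_forward"
    n_iterations: int = 10
    epsilon: float = 1.0
    threshold: float = 0.5
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold must be in (0,1), got {self.threshold}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["individual"] = self.individual.to_dict()
        d["fiber"] = dataclasses.asdict(self.fiber)
        d["grid"] = list(self.grid.values)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "individual" in d:
            d["individual"] = VirtualIndividual.from_dict(d["individual"])
        if "fiber" in d:
            fib = dict(d["fiber"])
            if "composition" in fib:
                fib["composition"] = tuple(fib["composition"])
            d["fiber"] = FiberConfig(**fib)
        if "grid" in d:
            d["grid"] = ConcentrationGrid(tuple(d["grid"]))
        return cls(**d)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _parse_current(raw: str) -> Optional[str]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    name = str(raw).strip()
    if not name:
        return None
    return _CURRENT_SYNONYMS.get(name.lower(), "other")


def read_drug_table(path) -> list[DrugProfile]:
    """Read a flat per-measurement drug table (CSV or XLSX).

    Required columns: ``drug``, ``current``, ``ic50``; optional:
    ``ic50_unit`` (µM default; nM, mM, M accepted), ``hill``,
    ``temperature_c``, the four protocol potentials, ``source`` and the
    curation override ``selected``.  IC50 values are normalized to µM on
    read.  Unrecognized current names map to ``other``; rows with missing or
    non-positive IC50, or an unknown unit, are rejected with row-numbered
    diagnostics collected across the whole file.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = {"drug", "current", "ic50"} - set(df.columns)
    if missing:
        raise DrugTableError([f"missing required columns: {sorted(missing)}"])

    errors: list[str] = []
    by_drug: dict[str, list[CurrentMeasurement]] = {}
    for idx, row in df.iterrows():
        rowno = idx + 2  # 1-based with header line
        name = str(row["drug"]).strip() if not pd.isna(row["drug"]) else ""
        if not name:
            errors.append(f"row {rowno}: missing drug name")
            continue
        current = _parse_current(row["current"])
        if current is None:
            errors.append(f"row {rowno}: missing current name")
            continue
        ic50 = row["ic50"]
        if pd.isna(ic50):
            errors.append(f"row {rowno}: missing ic50")
            continue
        unit = row.get("ic50_unit")
        if unit is None or pd.isna(unit) or not str(unit).strip():
            factor = 1.0
        else:
            factor = _UNIT_TO_UM.get(str(unit).strip())
            if factor is None:
                errors.append(f"row {rowno}: unknown unit {unit!r}")
                continue
        ic50_um = float(ic50) * factor
        if not ic50_um > 0:
            errors.append(f"row {rowno}: non-positive ic50 {ic50_um} µM")
            continue

        def _opt(col):
            v = row.get(col)
            return None if v is None or pd.isna(v) else float(v)

        hill = _opt("hill")
        sel = row.get("selected")
        selected = None if sel is None or pd.isna(sel) else bool(sel)
        try:
            m = CurrentMeasurement(
                current=current,
                ic50=ic50_um,
                hill=hill if hill is not None else 1.0,
                temperature=_opt("temperature_c"),
                holding_potential=_opt("holding_mv"),
                depolarization_potential=_opt("depolarization_mv"),
                repolarization_potential=_opt("repolarization_mv"),
                measurement_potential=_opt("measurement_mv"),
                source="" if pd.isna(row.get("source", "")) else str(row.get("source", "")),
                selected=selected,
            )
        except ValueError as exc:
            errors.append(f"row {rowno}: {exc}")
            continue
        by_drug.setdefault(name, []).append(m)
    if errors:
        raise DrugTableError(errors)
    return [DrugProfile(name=k, measurements=v) for k, v in by_drug.items()]


def write_drug_table(drugs: Sequence[DrugProfile], path) -> None:
    rows = []
    for d in drugs:
        for m in d.measurements:
            rows.append(
                {
                    "drug": d.name,
                    "current": m.current,
                    "ic50": m.ic50,
                    "ic50_unit": "uM",
                    "hill": m.hill,
                    "temperature_c": m.temperature,
                    "holding_mv": m.holding_potential,
                    "depolarization_mv": m.depolarization_potential,
                    "repolarization_mv": m.repolarization_potential,
                    "measurement_mv": m.measurement_potential,
                    "source": m.source,
                    "selected": m.selected,
                }
            )
    pd.DataFrame(rows, columns=_DRUG_TABLE_COLUMNS).to_csv(path, index=False)


def _parse_category(raw: str) -> str:
    s = str(raw).strip().lower()
    if not s or s in ("nan", "none"):
        return "not_mentioned"
    for cat in RISK_CATEGORIES:
        if s.replace(" ", "_").startswith(cat) or s.startswith(cat.split("_")[0]):
            return cat
    raise LabelFileError(
        f"unrecognized risk category {raw!r}; accepted prefixes: {RISK_CATEGORIES}"
    )


def read_labels(path) -> dict[str, str]:
    """Read a drug → CredibleMeds-category map from CSV (drug, category).

    Category strings parse case-insensitively by prefix ("Known risk of
    TdP" → ``known``).  Drugs absent from the file are treated downstream as
    ``not_mentioned``.  Duplicate drugs with conflicting categories raise.
    """
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "drug" not in df.columns or "category" not in df.columns:
        raise LabelFileError("label file needs columns: drug, category")
    out: dict[str, str] = {}
    for _, row in df.iterrows():
        name = str(row["drug"]).strip().lower()
        cat = _parse_category(row["category"])
        if name in out and out[name] != cat:
            raise LabelFileError(
                f"drug {name!r} has conflicting categories {out[name]!r} and {cat!r}"
            )
        out[name] = cat
    return out


def write_feature_table(features: Sequence[FeatureVector], path) -> None:
    """Write features as CSV: drug, label, emw_1..emw_10, iceb_1..iceb_10."""
    rows = []
    for fv in features:
        row = {"drug": fv.drug, "label": fv.label}
        for i in range(10):
            row[f"emw_{i+1}"] = fv.emw[i]
            row[f"iceb_{i+1}"] = fv.iceb[i]
        rows.append(row)
    cols = ["drug", "label"] + FeatureVector.feature_names()
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_feature_table(path) -> list[FeatureVector]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        label = row.get("label")
        out.append(
            FeatureVector(
                drug=str(row["drug"]),
                emw=np.array([row[f"emw_{i+1}"] for i in range(10)], dtype=float),
                iceb=np.array([row[f"iceb_{i+1}"] for i in range(10)], dtype=float),
                label=None if pd.isna(label) else str(label),
            )
        )
    return out


def write_cell_trace(trace: CellTrace, csv_path, sidecar_path=None) -> None:
    """Write a single-cell trace as CSV with a JSON provenance sidecar."""
    pd.DataFrame({"t_ms": trace.t, "vm_mV": trace.vm, "ca_mM": trace.ca}).to_csv(
        csv_path, index=False
    )
    sidecar = Path(sidecar_path) if sidecar_path else Path(csv_path).with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "cell_type": trace.cell_type,
                "stim_time": trace.stim_time,
                **{k: v for k, v in trace.meta.items()},
            },
            indent=2,
            default=str,
        )
    )


def read_cell_trace(csv_path, sidecar_path=None) -> CellTrace:
    df = pd.read_csv(csv_path)
    sidecar = Path(sidecar_path) if sidecar_path else Path(csv_path).with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return CellTrace(
        t=df["t_ms"].to_numpy(),
        vm=df["vm_mV"].to_numpy(),
        ca=df["ca_mM"].to_numpy() if "ca_mM" in df else np.zeros(len(df)),
        cell_type=meta.get("cell_type", "endo"),
        stim_time=float(meta.get("stim_time", 0.0)),
        meta=meta,
    )


def write_pseudo_ecg(t: np.ndarray, phi: np.ndarray, path) -> None:
    pd.DataFrame({"t_ms": t, "phi": phi}).to_csv(path, index=False)
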