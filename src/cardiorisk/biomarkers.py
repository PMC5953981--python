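"""Interval biomarkers from the pseudoECG and the fiber's cellular fields.

Extracted quantities: QRS duration, QT and rate-corrected QTc, the early
(J-Tpeak) and late (Tpeak−Tend) repolarization sub-intervals, the index of
cardiac electrophysiological balance iCEB = QT/QRS, and the signed
electromechanical window EMW = end of mechanical systole − end of
electrical systole (negative EMW, electrical outlasting mechanical, is the
proarrhythmia-associated direction).

Detector conventions:
* QRS onset/offset by a 5 %-of-peak threshold on |Φ − baseline|, with the
  baseline taken as the median of the pre-QRS window;
* T-wave end by the tangent method (steepest descending tangent of the T
  limb intersected with the baseline), falling back to a threshold crossing
  when no descending limb exists;
* mechanical-systole end by a calcium surrogate: the Ca-transient-amplitude
  weighted mean over cells of (activation time + CaD90).

Biomarkers that cannot be measured (flat signal, conduction block, no
repolarization) are flagged rather than raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .fiber import FiberResult
from .myocyte import _duration_from_upstroke

__all__ = [
    "EcgBiomarkers",
    "detect_qrs",
    "detect_t_wave",
    "qtc",
    "iceb",
    "emw",
    "delta",
    "qt_only_flag",
    "mechanical_end",
    "extract_biomarkers",
]

_NAN = float("nan")


@dataclass
class EcgBiomarkers:
    """One beat's interval biomarkers (ms except dimensionless iCEB).

    Landmark times (``q_onset`` … ``t_end``) are on the source trace's
    clock.  ``measurable`` flags each biomarker; unmeasurable values are
    NaN.
    """

    qrs: float = _NAN
    qt: float = _NAN
    qtc: float = _NAN
    jtpeak: float = _NAN
    tpeak_tend: float = _NAN
    emw: float = _NAN
    iceb: float = _NAN
    q_onset: float = _NAN
    j_point: float = _NAN
    t_peak: float = _NAN
    t_end: float = _NAN
    measurable: dict = field(default_factory=dict)

    def is_measurable(self, name: str) -> bool:
        return bool(self.measurable.get(name, False))

    def to_dict(self) -> dict:
        return {
            "qrs": self.qrs,
            "qt": self.qt,
            "qtc": self.qtc,
            "jtpeak": self.jtpeak,
            "tpeak_tend": self.tpeak_tend,
            "emw": self.emw,
            "iceb": self.iceb,
        }


def _baseline(phi: np.ndarray, t: np.ndarray, baseline_until: float) -> float:
    mask = t < baseline_until
    if not np.any(mask):
        mask = np.zeros_like(t, dtype=bool)
        mask[: max(1, len(t) // 20)] = True
    return float(np.median(phi[mask]))


def detect_qrs(
    phi: np.ndarray,
    t: np.ndarray,
    baseline_window_ms: float = 40.0,
    sustain_ms: float = 10.0,
    qrs_search_ms: float = 150.0,
) -> tuple[float, float]:
    """Locate QRS onset (Q) and offset (J point) on the pseudoECG.

    Onset is the first time |Φ − baseline| exceeds 5 % of the QRS peak
    magnitude; the J point is the first time after the QRS peak at which the
    signal falls below that threshold and stays below it for at least
    ``sustain_ms``.  Returns (NaN, NaN) when no deflection rises above
    threshold.
    """
    phi = np.asarray(phi, dtype=float)
    t = np.asarray(t, dtype=float)
    base = _baseline(phi, t, baseline_window_ms)
    a = np.abs(phi - base)
    search = t <= (baseline_window_ms + qrs_search_ms)
    if not np.any(search):
        search = np.ones_like(t, dtype=bool)
    peak = float(np.max(a[search]))
    if peak <= 0:
        return _NAN, _NAN
    thr = 0.05 * peak
    above = np.nonzero(a >= thr)[0]
    if above.size == 0:
        return _NAN, _NAN
    i_on = above[0]
    i_peak = int(np.argmax(np.where(search, a, -np.inf)))
    # J point: first sustained sub-threshold excursion after the QRS peak
    sample_dt = float(np.median(np.diff(t)))
    need = max(1, int(round(sustain_ms / sample_dt)))
    below = a < thr
    j_idx = -1
    i = i_peak + 1
    n = len(t)
    while i < n:
        if below[i]:
            end = min(n, i + need)
            if np.all(below[i:end]) and end - i >= min(need, n - i):
                j_idx = i
                break
            i = end
        else:
            i += 1
    if j_idx < 0:
        return float(t[i_on]), _NAN
    return float(t[i_on]), float(t[j_idx])


def detect_t_wave(
    phi: np.ndarray,
    t: np.ndarray,
    j_point: float,
    baseline_window_ms: float = 40.0,
    refractory_ms: float = 20.0,
) -> tuple[float, float]:
    """Locate the T-wave peak and end after a valid J point.

    The peak is the extremum of |Φ − baseline| after ``j_point`` +
    ``refractory_ms``; the end is the intersection of the steepest tangent
    on the descending T limb with the isoelectric baseline.  When the limb
    never descends toward baseline a threshold-crossing fallback (5 % of T
    amplitude) is used; a flat or monotone post-J signal is unmeasurable
    (NaN, NaN).
    """
    phi = np.asarray(phi, dtype=float)
    t = np.asarray(t, dtype=float)
    if math.isnan(j_point):
        return _NAN, _NAN
    base = _baseline(phi, t, baseline_window_ms)
    start = np.searchsorted(t, j_point + refractory_ms)
    if start >= len(t) - 2:
        return _NAN, _NAN
    seg = phi[start:] - base
    tt = t[start:]
    i_peak = int(np.argmax(np.abs(seg)))
    amp = seg[i_peak]
    if abs(amp) < 1e-12:
        return _NAN, _NAN
    t_peak = float(tt[i_peak])
    sign = 1.0 if amp > 0 else -1.0
    y = sign * seg  # upright T wave from here on
    # descending limb: from the peak until the signal first re-approaches
    # baseline (2 % of amplitude) or the trace ends
    limb_end = len(y)
    for k in range(i_peak + 1, len(y)):
        if y[k] <= 0.02 * y[i_peak]:
            limb_end = k + 1
            break
    if limb_end - i_peak < 3:
        return t_peak, _NAN
    limb_t = tt[i_peak:limb_end]
    limb_y = y[i_peak:limb_end]
    slopes = np.gradient(limb_y, limb_t)
    k_star = int(np.argmin(slopes))  # steepest descent
    slope = slopes[k_star]
    if slope >= 0:
        # no descending limb: fall back to a 5 % threshold crossing
        thr = 0.05 * y[i_peak]
        below = np.nonzero(limb_y <= thr)[0]
        if below.size == 0:
            return t_peak, _NAN
        return t_peak, float(limb_t[below[0]])
    t_end = limb_t[k_star] - limb_y[k_star] / slope  # y + slope*(t_end−t*) = 0
    if t_end < t_peak:
        return t_peak, _NAN
    return t_peak, float(t_end)


def qtc(qt: float, rr: float, method: str = "fridericia") -> float:
    """Heart-rate-corrected QT (ms): Fridericia (cube root) or Bazett."""
    if not (qt > 0 and rr > 0):
        raise ValueError("qt and rr must be > 0")
    if method == "fridericia":
        return qt / (rr / 1000.0) ** (1.0 / 3.0)
    if method == "bazett":
        return qt / (rr / 1000.0) ** 0.5
    raise ValueError(f"unknown QTc method {method!r}")


def iceb(qt: float, qrs: float) -> float:
    """Index of cardiac electrophysiological balance, iCEB = QT/QRS."""
    if not (qrs > 0):
        return _NAN
    return qt / qrs


def emw(t_end_electrical: float, t_end_mechanical: float) -> float:
    """Signed electromechanical window: mechanical end − electrical end (ms)."""
    if math.isnan(t_end_electrical) or math.isnan(t_end_mechanical):
        return _NAN
    return t_end_mechanical - t_end_electrical


def delta(biomarker_at_conc: float, biomarker_at_zero: float) -> float:
    """Drug-induced change: drug-modified value minus baseline."""
    return biomarker_at_conc - biomarker_at_zero


def qt_only_flag(delta_qtc_by_conc: Mapping[float, float], threshold_ms: float = 10.0) -> bool:
    """QT-only comparator rule: positive when max ΔQTc ≥ threshold."""
    deltas = [v for v in delta_qtc_by_conc.values() if not math.isnan(v)]
    if not deltas:
        return False
    return max(deltas) >= threshold_ms


def mechanical_end(result: FiberResult, fraction: float = 90.0) -> float:
    """Calcium-surrogate end of mechanical systole (ms, trace clock).

    Per cell: activation time (first vm crossing of −20 mV after the
    stimulus) plus the CaD at ``fraction`` % recovery; the fiber-level end is
    the Ca-amplitude-weighted mean over cells with measurable transients.
    """
    t = result.t
    ends = []
    weights = []
    for i in range(result.vm_field.shape[0]):
        vm = result.vm_field[i]
        ca = result.ca_field[i]
        above = np.nonzero(vm >= -20.0)[0]
        if above.size == 0:
            continue
        t_act = t[above[0]]
        idx0 = max(0, np.searchsorted(t, result.stim_time) - 1)
        diastolic = float(ca[idx0])
        amp = float(np.max(ca) - diastolic)
        if amp <= 0:
            continue
        cad = _duration_from_upstroke(t, ca, fraction, diastolic)
        if math.isnan(cad):
            continue
        ends.append(t_act + cad)
        weights.append(amp)
    if not ends:
        return _NAN
    return float(np.average(ends, weights=weights))


def extract_biomarkers(
    result: FiberResult,
    rr: Optional[float] = None,
    qtc_method: str = "fridericia",
    emw_fraction: float = 90.0,
) -> EcgBiomarkers:
    """Extract all interval biomarkers from one fiber beat.

    Deterministic: identical ``FiberResult`` gives identical biomarkers.
    ``rr`` defaults to the cycle length recorded in the result metadata.
    """
    rr = float(rr if rr is not None else result.meta.get("rr", 1000.0))
    bm = EcgBiomarkers()
    flags = bm.measurable
    if result.conduction_block:
        for k in ("qrs", "qt", "qtc", "jtpeak", "tpeak_tend", "emw", "iceb"):
            flags[k] = False
        return bm

    base_win = min(40.0, result.stim_time) if not math.isnan(result.stim_time) else 40.0
    q_onset, j_point = detect_qrs(result.pseudo_ecg, result.t, baseline_window_ms=base_win)
    bm.q_onset, bm.j_point = q_onset, j_point
    qrs_ok = not (math.isnan(q_onset) or math.isnan(j_point))
    flags["qrs"] = qrs_ok
    if qrs_ok:
        bm.qrs = j_point - q_onset

    t_peak, t_end = detect_t_wave(
        result.pseudo_ecg, result.t, j_point, baseline_window_ms=base_win
    )
    bm.t_peak, bm.t_end = t_peak, t_end
    t_ok = qrs_ok and not (math.isnan(t_peak) or math.isnan(t_end))
    flags["qt"] = flags["qtc"] = flags["jtpeak"] = flags["tpeak_tend"] = t_ok
    if t_ok:
        bm.qt = t_end - q_onset
        bm.qtc = qtc(bm.qt, rr, qtc_method)
        bm.jtpeak = t_peak - j_point
        bm.tpeak_tend = t_end - t_peak

    bm.iceb = iceb(bm.qt, bm.qrs) if (qrs_ok and t_ok) else _NAN
    flags["iceb"] = qrs_ok and t_ok and not math.isnan(bm.iceb)

    t_mech = mechanical_end(result, fraction=emw_fraction)
    bm.emw = emw(bm.t_end, t_mech) if t_ok else _NAN
    flags["emw"] = t_ok and not math.isnan(bm.emw)
    return bm
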