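"""Functional phenotype extraction from simulated beats and activation maps.

Per ventricle, from the pressure/volume/flow trace:

ESV, SV, EF           end-systolic volume, stroke volume, ejection fraction
V1, EF1               volume at peak outflow-valve flow and the first-phase
                      ejection fraction 100*(EDV - V1)/EDV
ESP                   pressure at outflow-valve closure
dPdtmax, dPdtmin      extrema of dP/dt (centred differences, mmHg/ms)
PeakP, tpeak          peak pressure and its time
ET, ICT, IRT, tsys    ejection time (outflow open -> close), isovolumic
                      contraction (activation trigger -> outflow open),
                      isovolumic relaxation (outflow close -> inflow open),
                      and systole duration tsys = ICT + ET

From the activation map (whole heart, not per ventricle):

QRS                   total ventricular activation span (max - min)
AT1090                time from the 10th to the 90th percentile node by
                      activation order (nearest-rank convention)
AT                    LV total activation time (max - min over LV nodes)

Incomplete simulations yield a row of missing values with the completion
flag set false; they are excluded from downstream statistics, never dropped
from the table.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .em_surrogate import ActivationMap, BeatTrace, VentricleTrace

__all__ = [
    "MECHANICAL_COLUMNS",
    "EP_COLUMNS",
    "extract_mechanical",
    "extract_ep",
    "phenotype_table",
]

MECHANICAL_COLUMNS = [
    "ESV", "SV", "EF", "V1", "EF1",
    "ESP", "dPdtmax", "dPdtmin", "PeakP", "tpeak",
    "ET", "ICT", "IRT", "tsys",
]
EP_COLUMNS = ["QRS", "AT1090", "AT"]


def _dpdt(time: np.ndarray, pressure: np.ndarray) -> np.ndarray:
    # centred differences on the uniform grid; one-sided at the endpoints
    return np.gradient(pressure, time)


def extract_mechanical(
    trace: BeatTrace, edv: float, side: str = "lv"
) -> dict[str, float]:
    """Mechanical phenotype row for one ventricle of a completed beat.

    ``edv`` is the mesh-derived end-diastolic cavity volume (mL).  For an
    incomplete trace every value is NaN.
    """
    vt: VentricleTrace = getattr(trace, side)
    if not trace.completed:
        return {c: np.nan for c in MECHANICAL_COLUMNS}
    t = trace.time
    esv = float(vt.volume.min())
    sv = edv - esv
    ef = 100.0 * sv / edv
    k1 = int(np.argmax(vt.outflow))
    v1 = float(vt.volume[k1])
    ef1 = 100.0 * (edv - v1) / edv
    dpdt = _dpdt(t, vt.pressure)
    peak_k = int(np.argmax(vt.pressure))
    ev = vt.events
    esp = float(np.interp(ev["outflow_close"], t, vt.pressure)) if "outflow_close" in ev else np.nan
    et = ev.get("outflow_close", np.nan) - ev.get("outflow_open", np.nan)
    ict = ev.get("outflow_open", np.nan) - vt.trigger_time
    irt = ev.get("inflow_open", np.nan) - ev.get("outflow_close", np.nan)
    return {
        "ESV": esv,
        "SV": sv,
        "EF": ef,
        "V1": v1,
        "EF1": ef1,
        "ESP": esp,
        "dPdtmax": float(dpdt.max()),
        "dPdtmin": float(dpdt.min()),
        "PeakP": float(vt.pressure[peak_k]),
        "tpeak": float(t[peak_k]),
        "ET": float(et),
        "ICT": float(ict),
        "IRT": float(irt),
        "tsys": float(ict + et),
    }


def extract_ep(act: ActivationMap, lv_nodes: np.ndarray,
               ventricular_nodes: Optional[np.ndarray] = None) -> dict[str, float]:
    """EP phenotypes from the activation map.

    QRS and AT1090 span all ventricular nodes; AT spans the LV only.
    AT1090 uses the nearest-rank 10th/90th percentile of the sorted
    activation times.  Raises on empty node sets or infinite times.
    """
    lv_nodes = np.asarray(lv_nodes, dtype=np.int64)
    if lv_nodes.size == 0:
        raise ValueError("LV node set is empty")
    nodes = (
        np.arange(act.times.size)
        if ventricular_nodes is None
        else np.asarray(ventricular_nodes, dtype=np.int64)
    )
    if nodes.size == 0:
        raise ValueError("ventricular node set is empty")
    times = act.times[nodes]
    if np.isinf(times).any() or np.isinf(act.times[lv_nodes]).any():
        raise ValueError("infinite activation times in the referenced node set")
    srt = np.sort(times)
    n = srt.size
    # nearest-rank order statistics
    lo = srt[min(n - 1, int(np.ceil(0.10 * n)) - 1)] if n > 1 else srt[0]
    hi = srt[min(n - 1, int(np.ceil(0.90 * n)) - 1)] if n > 1 else srt[0]
    lv_t = act.times[lv_nodes]
    return {
        "QRS": float(srt[-1] - srt[0]),
        "AT1090": float(hi - lo),
        "AT": float(lv_t.max() - lv_t.min()),
    }


def phenotype_table(
    traces: dict,
    acts: dict,
    anatomies: dict,
    lv_nodes: dict,
    ventricular_nodes: Optional[dict] = None,
) -> pd.DataFrame:
    """Assemble the full per-case phenotype table.

    Mechanical columns are suffixed ``_LV`` / ``_RV``; EP columns are whole
    heart.  ``anatomies`` maps case name -> LumpedAnatomy; ``lv_nodes`` (and
    optionally ``ventricular_nodes``) map case name -> node index arrays.
    """
    rows = []
    for case, trace in traces.items():
        row: dict = {"case": case, "completed": trace.completed}
        an = anatomies[case]
        for side in ("lv", "rv"):
            edv = an.lv.edv if side == "lv" else an.rv.edv
            mech = extract_mechanical(trace, edv, side=side)
            row.update({f"{k}_{side.upper()}": v for k, v in mech.items()})
            row[f"EDV_{side.upper()}"] = edv
        vn = None if ventricular_nodes is None else ventricular_nodes[case]
        if trace.completed:
            row.update(extract_ep(acts[case], lv_nodes[case], vn))
        else:
            row.update({c: np.nan for c in EP_COLUMNS})
        rows.append(row)
    return pd.DataFrame(rows).set_index("case")
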