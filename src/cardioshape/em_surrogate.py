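"""Lumped electromechanics surrogate: one simulated beat per anatomy.

Three coupled sub-models, mirroring the structure of organ-scale cardiac
electromechanics at desk scale:

* **Activation** — eikonal-style: activation time is the shortest traversal
  time over the mesh edge graph (edge time = length / conduction velocity),
  with a fast endocardial conduction (FEC) layer standing in for the
  Purkinje system on the endocardium up to a fraction of the apicobasal
  distance (default 70%, boundary inclusive).
* **Active stress** — the phenomenological tanh-squared time course: zero
  before the local activation time plus an electromechanical delay, then a
  contraction ramp and a relaxation ramp bounded by the peak tension.
* **Mechanics/haemodynamics** — each ventricle is a thick-walled sphere with
  conserved wall volume; cavity pressure follows a Laplace relation applied
  to the sum of an exponential passive stress (scale parameter ``a``) and
  the active tension triggered at the ventricle's mean activation time.
  Valves are ideal diodes with a forward resistance; ejection feeds a
  three-element Windkessel afterload (systemic for the LV, pulmonary for
  the RV); filling comes from a constant preload pressure.  Fixed-step
  explicit Euler integration moves the beat through its phases (filling,
  isovolumic contraction, ejection, isovolumic relaxation), which emerge
  from the diode logic rather than being imposed.

A beat that produces a non-finite state or a non-positive volume is flagged
incomplete, never raised: failing anatomies are excluded downstream, the
cohort run always finishes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .mesh import TetMesh
from .mesh_metrics import LumpedAnatomy, lumped_anatomy, unique_edges

__all__ = [
    "ActivationMap",
    "TanhStressParams",
    "CirculationParams",
    "BeatTrace",
    "simulate_activation",
    "tanh_active_stress",
    "simulate_beat",
    "run_cohort",
    "apical_endocardial_stimulus",
]

KPA_TO_MMHG = 7.50062


# ----------------------------------------------------------------------
# activation
# ----------------------------------------------------------------------
@dataclass
class ActivationMap:
    """Node activation times (ms) from a graph-eikonal solve."""

    times: np.ndarray
    stimulus: np.ndarray
    cv_myo: float
    cv_fec: float
    fec_extent: float

    def mean_time(self, node_ids: np.ndarray) -> float:
        return float(np.mean(self.times[node_ids]))


def apical_endocardial_stimulus(mesh: TetMesh, z_max: float = 0.1) -> np.ndarray:
    """Default stimulus rule: apical endocardial nodes of both ventricles."""
    endo = mesh.meta["endocardial"]
    z = mesh.meta["z_apicobasal"]
    return np.nonzero(endo & (z <= z_max))[0]


def simulate_activation(
    mesh: TetMesh,
    stimulus: np.ndarray,
    cv_myo: float = 0.6,
    cv_fec: float = 3.0,
    fec_extent: float = 0.7,
) -> ActivationMap:
    """Exact single-source (multi-seed) shortest-path activation times.

    Edge traversal time is length / CV; an edge is in the FEC layer iff both
    endpoints are endocardial with apicobasal Z <= ``fec_extent``
    (inclusive).  Disconnected nodes get infinite time with a warning.
    """
    stimulus = np.asarray(stimulus, dtype=np.int64)
    if stimulus.size == 0:
        raise ValueError("stimulus node set is empty")
    if cv_myo <= 0 or cv_fec <= 0:
        raise ValueError("conduction velocities must be > 0")
    edges = unique_edges(mesh.tets)
    lengths = np.linalg.norm(
        mesh.points[edges[:, 0]] - mesh.points[edges[:, 1]], axis=1
    )
    endo = mesh.meta["endocardial"]
    z = mesh.meta["z_apicobasal"]
    in_fec = (
        endo[edges[:, 0]]
        & endo[edges[:, 1]]
        & (z[edges[:, 0]] <= fec_extent)
        & (z[edges[:, 1]] <= fec_extent)
    )
    cv = np.where(in_fec, cv_fec, cv_myo)
    w = lengths / cv
    n = mesh.n_points
    graph = coo_matrix((w, (edges[:, 0], edges[:, 1])), shape=(n, n))
    times = dijkstra(graph, directed=False, indices=stimulus, min_only=True)
    if np.isinf(times).any():
        warnings.warn(
            f"{int(np.isinf(times).sum())} node(s) unreachable from the stimulus; "
            "infinite activation time reported",
            RuntimeWarning,
            stacklevel=2,
        )
    return ActivationMap(
        times=times, stimulus=stimulus, cv_myo=cv_myo, cv_fec=cv_fec,
        fec_extent=fec_extent,
    )


# ----------------------------------------------------------------------
# active stress
# ----------------------------------------------------------------------
@dataclass
class TanhStressParams:
    """Tanh-squared active stress time course.

    Defaults are calibration choices (stored here and in run configs, never
    scattered through the code) chosen to put the template's simulated LV
    ejection fraction in the normal physiological band.
    """

    peak_tension: float = 42.0  # kPa
    t_emd: float = 15.0  # electromechanical delay, ms
    tau_contr: float = 65.0  # contraction time constant, ms
    tau_relax: float = 33.0  # relaxation time constant, ms
    t_dur: float = 330.0  # active duration, ms
    #: force-length coupling: active tension scales with the normalised
    #: cavity stretch lambda = (V/EDV)^(1/3), linearly from 0 at
    #: ``fl_lambda0`` to 1 at lambda = 1, so contraction self-limits as the
    #: cavity empties (the surrogate's Frank-Starling mechanism).
    fl_lambda0: float = 0.6

    def __post_init__(self) -> None:
        for fld in ("peak_tension", "t_emd", "tau_contr", "tau_relax", "t_dur"):
            if getattr(self, fld) <= 0:
                raise ValueError(f"{fld} must be > 0")
        if not 0 < self.fl_lambda0 < 1:
            raise ValueError("fl_lambda0 must be in (0, 1)")


def tanh_active_stress(t, t_act: float, p: TanhStressParams):
    """Active tension (kPa) at time(s) t for a trigger time t_act.

    Zero before ``t_act + t_emd`` and after the active duration; in between
    ``peak * tanh^2(elapsed/tau_contr) * tanh^2((t_dur-elapsed)/tau_relax)``,
    continuous and bounded by the peak tension.
    """
    t = np.asarray(t, dtype=float)
    elapsed = t - t_act - p.t_emd
    active = (elapsed > 0) & (elapsed < p.t_dur)
    e = np.where(active, elapsed, 0.0)
    val = (
        p.peak_tension
        * np.tanh(e / p.tau_contr) ** 2
        * np.tanh((p.t_dur - e) / p.tau_relax) ** 2
    )
    out = np.where(active, val, 0.0)
    return out if out.ndim else float(out)


# ----------------------------------------------------------------------
# circulation
# ----------------------------------------------------------------------
@dataclass
class CirculationParams:
    """Afterload, preload, valve and passive-law parameters.

    Resistances in mmHg*ms/mL, compliances in mL/mmHg, pressures in mmHg.
    ``passive_scale_a`` (kPa) scales the exponential passive wall stress —
    the lone constitutive parameter retained from the full hyperelastic law
    so the local sensitivity analysis over it stays expressible.
    """

    sys_char_resistance: float = 50.0
    sys_peripheral_resistance: float = 1100.0
    sys_compliance: float = 1.6
    pul_char_resistance: float = 15.0
    pul_peripheral_resistance: float = 150.0
    pul_compliance: float = 5.0
    valve_resistance: float = 5.0
    preload_lv: float = 10.0
    preload_rv: float = 5.0
    arterial_pressure_sys0: float = 72.0
    arterial_pressure_pul0: float = 11.0
    passive_scale_a: float = 0.30
    passive_exponent_b: float = 5.0
    unloaded_volume_fraction: float = 1.0 / 1.45  # V0 / EDV

    def __post_init__(self) -> None:
        for fld in self.__dataclass_fields__:
            if getattr(self, fld) <= 0:
                raise ValueError(f"{fld} must be > 0")


# ----------------------------------------------------------------------
# beat trace
# ----------------------------------------------------------------------
@dataclass
class VentricleTrace:
    volume: np.ndarray  # mL
    pressure: np.ndarray  # mmHg
    inflow: np.ndarray  # mL/ms
    outflow: np.ndarray  # mL/ms
    arterial_pressure: np.ndarray  # mmHg
    events: dict  # valve open/close times (ms), linearly interpolated
    trigger_time: float  # mean activation time used for the stress onset


@dataclass
class BeatTrace:
    """One simulated beat: uniform time grid, both ventricles."""

    time: np.ndarray  # ms
    lv: VentricleTrace
    rv: VentricleTrace
    completed: bool = True


def _laplace_factor(v_ml: float, wall_ml: float) -> float:
    """2h/rm for a thick-walled sphere of cavity v and wall volume wall."""
    v = v_ml * 1000.0
    w = wall_ml * 1000.0
    ri = (3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)
    ro = (3.0 * (v + w) / (4.0 * np.pi)) ** (1.0 / 3.0)
    return 2.0 * (ro - ri) / (0.5 * (ri + ro))


def _cross(t0, t1, g0, g1) -> float:
    """Linear interpolation of the zero crossing of g between t0 and t1."""
    return t0 + (t1 - t0) * g0 / (g0 - g1)


def simulate_beat(
    anatomy: LumpedAnatomy,
    trigger_times: dict,
    stress: TanhStressParams = TanhStressParams(),
    circ: CirculationParams = CirculationParams(),
    dt: float = 0.1,
    duration: float = 800.0,
) -> BeatTrace:
    """Integrate one beat of the coupled ventricle/Windkessel system.

    ``trigger_times`` maps 'lv'/'rv' to the ventricle's mean activation time
    (ms); the activation field couples to mechanics only through this single
    trigger per ventricle.  Physiological failure (non-finite state or
    vanishing cavity volume) flags the trace incomplete rather than raising.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if duration <= 0 or duration < stress.t_dur:
        raise ValueError("duration must cover one cycle")
    nt = int(round(duration / dt)) + 1
    time = np.arange(nt) * dt

    sides = {
        "lv": dict(
            edv=anatomy.lv.edv, wall=anatomy.lv.wall_volume,
            preload=circ.preload_lv, rc=circ.sys_char_resistance,
            rp=circ.sys_peripheral_resistance, comp=circ.sys_compliance,
            pa0=circ.arterial_pressure_sys0,
        ),
        "rv": dict(
            edv=anatomy.rv.edv, wall=anatomy.rv.wall_volume,
            preload=circ.preload_rv, rc=circ.pul_char_resistance,
            rp=circ.pul_peripheral_resistance, comp=circ.pul_compliance,
            pa0=circ.arterial_pressure_pul0,
        ),
    }

    completed = True
    traces = {}
    for side, par in sides.items():
        edv, wall = par["edv"], par["wall"]
        v0 = circ.unloaded_volume_fraction * edv

        def p_cavity(v: float, t: float, t_act: float) -> float:
            sigma_p = circ.passive_scale_a * (
                np.exp(circ.passive_exponent_b * (v / v0 - 1.0)) - 1.0
            )
            lam = (v / edv) ** (1.0 / 3.0)
            fl = min(max((lam - stress.fl_lambda0) / (1.0 - stress.fl_lambda0), 0.0), 1.5)
            sigma_a = tanh_active_stress(t, t_act, stress) * fl
            return (sigma_p + max(sigma_a, 0.0)) * _laplace_factor(v, wall) * KPA_TO_MMHG

        t_act = float(trigger_times[side])
        v = np.empty(nt)
        p = np.empty(nt)
        qin = np.zeros(nt)
        qout = np.zeros(nt)
        part = np.empty(nt)
        pc = par["pa0"]
        v[0] = edv
        p[0] = p_cavity(edv, 0.0, t_act)
        events: dict = {}
        # inflow valve open at end diastole; event detection via the signed
        # pressure gradients across each valve
        g_in_prev = par["preload"] - p[0]
        g_out_prev = p[0] - pc
        part[0] = pc
        for k in range(nt - 1):
            t = time[k]
            q_in = max(0.0, (par["preload"] - p[k]) / circ.valve_resistance)
            q_out = max(0.0, (p[k] - pc) / (circ.valve_resistance + par["rc"]))
            qin[k] = q_in
            qout[k] = q_out
            part[k] = pc + q_out * par["rc"]
            v[k + 1] = v[k] + dt * (q_in - q_out)
            pc = pc + dt * (q_out - pc / par["rp"]) / par["comp"]
            if not np.isfinite(v[k + 1]) or v[k + 1] <= 0 or not np.isfinite(pc):
                completed = False
                v[k + 1 :] = v[k]
                p[k + 1 :] = p[k]
                part[k + 1 :] = part[k]
                break
            p[k + 1] = p_cavity(v[k + 1], time[k + 1], t_act)
            g_in = par["preload"] - p[k + 1]
            g_out = p[k + 1] - pc
            if g_in_prev >= 0 > g_in and "inflow_close" not in events:
                events["inflow_close"] = _cross(t, time[k + 1], g_in_prev, g_in)
            if g_in_prev < 0 <= g_in and "inflow_close" in events:
                events.setdefault("inflow_open", _cross(t, time[k + 1], g_in_prev, g_in))
            if g_out_prev < 0 <= g_out and "outflow_open" not in events:
                events["outflow_open"] = _cross(t, time[k + 1], g_out_prev, g_out)
            if g_out_prev >= 0 > g_out and "outflow_open" in events:
                events.setdefault("outflow_close", _cross(t, time[k + 1], g_out_prev, g_out))
            g_in_prev, g_out_prev = g_in, g_out
        else:
            qin[-1] = max(0.0, (par["preload"] - p[-1]) / circ.valve_resistance)
            qout[-1] = max(0.0, (p[-1] - pc) / (circ.valve_resistance + par["rc"]))
            part[-1] = pc + qout[-1] * par["rc"]
        traces[side] = VentricleTrace(
            volume=v, pressure=p, inflow=qin, outflow=qout,
            arterial_pressure=part, events=events, trigger_time=t_act,
        )
    return BeatTrace(time=time, lv=traces["lv"], rv=traces["rv"], completed=completed)


# ----------------------------------------------------------------------
# cohort runner
# ----------------------------------------------------------------------
def run_cohort(
    meshes: Sequence[TetMesh],
    stimulus_rule: Callable[[TetMesh], np.ndarray] = apical_endocardial_stimulus,
    stress: TanhStressParams = TanhStressParams(),
    circ: CirculationParams = CirculationParams(),
    dt: float = 0.1,
    duration: float = 800.0,
    cv_myo: float = 0.6,
    cv_fec: float = 3.0,
    fec_extent: float = 0.7,
    cohort_labels: Optional[Sequence[str]] = None,
) -> tuple[dict, dict, pd.DataFrame]:
    """Simulate every mesh with shared parameters; never abort on failure.

    All cases run with identical material, circulation and stimulation
    parameters so that output differences are attributable to anatomy alone.
    Returns (traces by case name, activation maps by case name, completion
    table with per-cohort finished counts, percentages and failed names).
    """
    traces: dict = {}
    acts: dict = {}
    rows = []
    labels = list(cohort_labels) if cohort_labels is not None else ["all"] * len(meshes)
    for mesh, label in zip(meshes, labels):
        act = simulate_activation(
            mesh, stimulus_rule(mesh), cv_myo=cv_myo, cv_fec=cv_fec,
            fec_extent=fec_extent,
        )
        anatomy = lumped_anatomy(mesh)
        tags = mesh.meta.get("tags", {"lv_myocardium": 1, "rv_myocardium": 2})
        trig = {}
        for side in ("lv", "rv"):
            nodes = np.unique(mesh.tets[mesh.cell_labels == tags[f"{side}_myocardium"]])
            trig[side] = act.mean_time(nodes)
        trace = simulate_beat(anatomy, trig, stress=stress, circ=circ, dt=dt,
                              duration=duration)
        if mesh.flagged:
            trace.completed = False  # geometry already flagged as inverted
        traces[mesh.name] = trace
        acts[mesh.name] = act
        rows.append({"case": mesh.name, "cohort": label,
                     "completed": trace.completed})
    status = pd.DataFrame(rows).set_index("case")
    summary = []
    for label, grp in status.groupby("cohort", sort=False):
        done = int(grp["completed"].sum())
        total = len(grp)
        summary.append({
            "cohort": label,
            "finished": done,
            "total": total,
            "summary": f"{done}/{total}({100.0 * done / total:.2f}%)",
            "failed_cases": ", ".join(grp.index[~grp["completed"]]) or "-",
        })
    completion = pd.DataFrame(summary).set_index("cohort")
    completion.attrs["per_case"] = status
    return traces, acts, completion
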