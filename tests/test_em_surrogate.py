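"""Surrogate physics: eikonal activation, tanh stress, beat integration."""

import numpy as np
import pytest

from cardioshape.mesh import TetMesh
from cardioshape.mesh_metrics import lumped_anatomy
from cardioshape.em_surrogate import (
    CirculationParams,
    TanhStressParams,
    apical_endocardial_stimulus,
    run_cohort,
    simulate_activation,
    simulate_beat,
    tanh_active_stress,
)


# ----------------------------------------------------------------------
# activation
# ----------------------------------------------------------------------
def chain_mesh(n=10, spacing=1.0):
    """Degenerate 'chain' built from thin tets so edges follow the chain."""
    pts = []
    for k in range(n):
        pts += [[k * spacing, 0, 0]]
    # add off-axis points to make tets; connectivity edges still include the
    # consecutive chain pairs
    pts += [[0, 1, 0], [0, 0, 1]]
    pts = np.array(pts, dtype=float)
    tets = [[k, k + 1, n, n + 1] for k in range(n - 1)]
    mesh = TetMesh(points=pts, tets=np.array(tets))
    mesh.meta["endocardial"] = np.zeros(len(pts), dtype=bool)
    mesh.meta["z_apicobasal"] = np.zeros(len(pts))
    return mesh


def test_chain_activation_times_analytic():
    mesh = chain_mesh(n=8, spacing=1.0)
    act = simulate_activation(mesh, np.array([0]), cv_myo=0.5, cv_fec=0.5)
    # node k lies k mm from the stimulus; at 0.5 mm/ms it activates at 2k ms
    assert np.allclose(act.times[:8], 2.0 * np.arange(8), atol=1e-9)


def test_doubling_cv_halves_all_times(template):
    stim = apical_endocardial_stimulus(template)
    a1 = simulate_activation(template, stim, cv_myo=0.6, cv_fec=3.0)
    a2 = simulate_activation(template, stim, cv_myo=1.2, cv_fec=6.0)
    assert np.allclose(a2.times, a1.times / 2.0, atol=1e-9)


def test_activation_matches_bellman_ford_oracle(rng):
    """Dijkstra solve equals an independent Bellman-Ford relaxation."""
    n = 30
    pts = rng.uniform(0, 20, (n, 3))
    tets = np.array([rng.choice(n, 4, replace=False) for _ in range(25)])
    mesh = TetMesh(points=pts, tets=tets)
    mesh.meta["endocardial"] = rng.random(n) < 0.4
    mesh.meta["z_apicobasal"] = rng.uniform(0, 1, n)
    stim = np.array([0, 5])
    act = simulate_activation(mesh, stim, cv_myo=0.7, cv_fec=2.1, fec_extent=0.7)

    # oracle: explicit edge list + Bellman-Ford
    from cardioshape.mesh_metrics import unique_edges

    edges = unique_edges(tets)
    endo, z = mesh.meta["endocardial"], mesh.meta["z_apicobasal"]
    dist = np.full(n, np.inf)
    dist[stim] = 0.0
    for _ in range(n):
        for i, j in edges:
            cv = 2.1 if (endo[i] and endo[j] and z[i] <= 0.7 and z[j] <= 0.7) else 0.7
            w = np.linalg.norm(pts[i] - pts[j]) / cv
            dist[j] = min(dist[j], dist[i] + w)
            dist[i] = min(dist[i], dist[j] + w)
    finite = np.isfinite(dist)
    assert np.allclose(act.times[finite], dist[finite], atol=1e-9)
    assert np.array_equal(np.isfinite(act.times), finite)


def test_disconnected_nodes_warn_with_infinite_time(rng):
    mesh = chain_mesh(n=4)
    extra = TetMesh(
        points=np.vstack([mesh.points, mesh.points + 1000.0]),
        tets=np.vstack([mesh.tets, mesh.tets + mesh.n_points]),
    )
    extra.meta["endocardial"] = np.zeros(extra.n_points, dtype=bool)
    extra.meta["z_apicobasal"] = np.zeros(extra.n_points)
    with pytest.warns(RuntimeWarning, match="unreachable"):
        act = simulate_activation(extra, np.array([0]))
    assert np.isinf(act.times[mesh.n_points:]).all()


def test_empty_stimulus_rejected(template):
    with pytest.raises(ValueError, match="empty"):
        simulate_activation(template, np.array([], dtype=int))


# ----------------------------------------------------------------------
# tanh active stress
# ----------------------------------------------------------------------
def test_stress_zero_before_activation_and_bounded():
    p = TanhStressParams()
    t = np.linspace(0, 1000, 20001)
    s = tanh_active_stress(t, t_act=100.0, p=p)
    assert np.all(s[t < 100.0 + p.t_emd] == 0.0)
    assert s.max() <= p.peak_tension
    assert np.all(s >= 0.0)


def test_stress_midpoint_matches_symbolic_formula():
    import sympy

    p = TanhStressParams(peak_tension=37.0, t_emd=10.0, tau_contr=50.0,
                         tau_relax=25.0, t_dur=280.0)
    e = sympy.Rational(280, 2)
    expected = float(
        37.0 * sympy.tanh(e / 50.0) ** 2 * sympy.tanh((280 - e) / 25.0) ** 2
    )
    got = tanh_active_stress(0.0 + 10.0 + 140.0, t_act=0.0, p=p)
    assert got == pytest.approx(expected, rel=1e-12)


# ----------------------------------------------------------------------
# beat integration
# ----------------------------------------------------------------------
@pytest.fixture(scope="module")
def template_beat_inputs(template):
    an = lumped_anatomy(template)
    stim = apical_endocardial_stimulus(template)
    act = simulate_activation(template, stim)
    tags = template.meta["tags"]
    trig = {
        s: act.mean_time(
            np.unique(template.tets[template.cell_labels == tags[f"{s}_myocardium"]])
        )
        for s in ("lv", "rv")
    }
    return an, trig


def test_zero_tension_means_no_ejection(template_beat_inputs):
    an, trig = template_beat_inputs
    trace = simulate_beat(an, trig, stress=TanhStressParams(peak_tension=1e-9))
    assert "outflow_open" not in trace.lv.events
    assert an.lv.edv - trace.lv.volume.min() == pytest.approx(0.0, abs=0.5)


def test_volume_conservation_within_tolerance(template_beat_inputs):
    an, trig = template_beat_inputs
    trace = simulate_beat(an, trig)
    assert trace.completed
    dt = trace.time[1] - trace.time[0]
    for vt in (trace.lv, trace.rv):
        net = np.sum(vt.inflow[:-1] - vt.outflow[:-1]) * dt
        assert abs(net - (vt.volume[-1] - vt.volume[0])) < 1e-3


def test_isovolumic_phases_have_constant_volume(template_beat_inputs):
    an, trig = template_beat_inputs
    trace = simulate_beat(an, trig)
    vt = trace.lv
    dvdt = np.diff(vt.volume) / np.diff(trace.time)
    t_mid = trace.time[:-1]
    ivc = (t_mid > vt.events["inflow_close"] + 1) & (
        t_mid < vt.events["outflow_open"] - 1
    )
    assert ivc.any()
    assert np.max(np.abs(dvdt[ivc])) < 1e-6


def test_flows_are_nonnegative_diodes(template_beat_inputs):
    an, trig = template_beat_inputs
    trace = simulate_beat(an, trig)
    for vt in (trace.lv, trace.rv):
        assert np.all(vt.inflow >= 0) and np.all(vt.outflow >= 0)


def test_halving_dt_converges_phenotypes(template_beat_inputs):
    from cardioshape.phenotypes import extract_mechanical

    an, trig = template_beat_inputs
    rows = {}
    for dt in (0.1, 0.05):
        tr = simulate_beat(an, trig, dt=dt)
        rows[dt] = extract_mechanical(tr, an.lv.edv, side="lv")
    for key, coarse in rows[0.1].items():
        fine = rows[0.05][key]
        assert fine == pytest.approx(coarse, rel=5e-3), key


def test_invalid_dt_and_duration_raise(template_beat_inputs):
    an, trig = template_beat_inputs
    with pytest.raises(ValueError):
        simulate_beat(an, trig, dt=-0.1)
    with pytest.raises(ValueError):
        simulate_beat(an, trig, duration=10.0)


# ----------------------------------------------------------------------
# cohort runner
# ----------------------------------------------------------------------
def test_identical_meshes_give_identical_phenotypes(template):
    twins = [template.copy(name="a"), template.copy(name="b")]
    traces, acts, completion = run_cohort(twins, duration=600.0)
    assert np.array_equal(traces["a"].lv.volume, traces["b"].lv.volume)
    assert np.array_equal(traces["a"].lv.pressure, traces["b"].lv.pressure)


def test_completion_table_percentage_convention(template):
    meshes = [template.copy(name=f"c{i}") for i in range(3)]
    meshes[1].flagged = True  # inverted-geometry case counts as failed
    traces, acts, completion = run_cohort(
        meshes, duration=600.0, cohort_labels=["X", "X", "X"]
    )
    assert completion.loc["X", "summary"] == "2/3(66.67%)"
    assert "c1" in completion.loc["X", "failed_cases"]


def test_scaled_cohort_preserves_volume_ordering(template):
    from cardioshape.synthetic_anatomy import AnatomyParams, deform_template

    scales = [0.92, 1.0, 1.08]
    meshes = [
        deform_template(template, AnatomyParams(scale=s), name=f"s{i}")
        for i, s in enumerate(scales)
    ]
    traces, _, _ = run_cohort(meshes, duration=600.0)
    esv = [traces[f"s{i}"].lv.volume.min() for i in range(3)]
    assert esv[0] < esv[1] < esv[2]
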