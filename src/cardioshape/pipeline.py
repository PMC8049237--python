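"""End-to-end study orchestration under a single reproducible config.

Stages, in the order of the underlying study design:

  generate   synthetic imaged cohort (template + latent-factor sampling)
  ssm        rigid alignment, shape-model fit, extreme cohorts per mode
  simulate   electromechanics surrogate on every mesh, shared parameters
  phenotypes phenotype table extraction and CSV export
  sense      range filter, correlations, GPE-based Sobol GSA, LSA battery
  report     completion table and machine-readable run manifest

Each stage writes into the run directory; failed simulations are flagged
and excluded from downstream statistics but never abort the run.  A fixed
config (all seeds explicit) regenerates byte-identical tables.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .em_surrogate import (
    CirculationParams,
    TanhStressParams,
    apical_endocardial_stimulus,
    run_cohort,
    simulate_activation,
    simulate_beat,
)
from .io_formats import write_cohort_tables, write_vtk_mesh
from .mesh_metrics import lumped_anatomy, scaled_jacobian
from .phenotypes import extract_ep, extract_mechanical, phenotype_table
from .sensitivity import (
    lsa_battery,
    mode_phenotype_correlations,
    normalized_range_filter,
    sobol_saltelli,
    train_gpes_loo,
)
from .shape_model import StatisticalShapeModel, rigid_align
from .synthetic_anatomy import CohortSpec, build_template, sample_cohort

__all__ = ["RunConfig", "run_pipeline", "average_mesh_phenotypes"]


@dataclass
class RunConfig:
    """Full study configuration; serialisable to/from YAML."""

    # cohort generation
    n_cases: int = 19
    latent_sds: Sequence[float] = (0.10, 0.07, 0.05, 0.035, 0.025)
    node_noise_sd: float = 0.25
    seed: int = 0
    template_resolution: float = 8.0
    # shape model
    variance_threshold: float = 0.9
    exclusions: Sequence[str] = ()
    extreme_multipliers: Sequence[int] = (2, 3)
    # surrogate
    dt: float = 0.1
    duration: float = 800.0
    cv_myo: float = 0.6
    cv_fec: float = 3.0
    fec_extent: float = 0.7
    peak_tension: float = 42.0
    passive_scale_a: float = 0.30
    # sensitivity
    range_threshold: float = 0.2
    sobol_n: int = 256
    gsa_phenotypes: Sequence[str] = ("SV_LV", "dPdtmax_LV")
    run_gsa: bool = True
    run_lsa: bool = False
    lsa_parameters: Sequence[str] = (
        "cv_myo", "cv_fec_ratio", "sys_peripheral_resistance",
        "pul_peripheral_resistance", "preload_lv", "preload_rv",
        "peak_tension", "passive_scale_a",
    )
    # output
    outdir: str = "runs/run"
    write_meshes: bool = False

    def __post_init__(self) -> None:
        for fld in ("latent_sds", "exclusions", "extreme_multipliers",
                    "gsa_phenotypes", "lsa_parameters"):
            setattr(self, fld, tuple(getattr(self, fld)))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(
            {k: list(v) if isinstance(v, tuple) else v
             for k, v in asdict(self).items()}
        ))
        return

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def stress(self) -> TanhStressParams:
        return TanhStressParams(peak_tension=self.peak_tension)

    def circulation(self) -> CirculationParams:
        return CirculationParams(passive_scale_a=self.passive_scale_a)


def _case_node_sets(mesh) -> tuple[np.ndarray, np.ndarray]:
    tags = mesh.meta["tags"]
    lv = np.unique(mesh.tets[mesh.cell_labels == tags["lv_myocardium"]])
    allv = np.unique(mesh.tets)
    return lv, allv


def average_mesh_phenotypes(params: dict) -> dict:
    """Run the surrogate on a template/average mesh for one parameter dict.

    The evaluation hook used by the local sensitivity battery: ``params``
    carries the perturbable scalars (conduction velocities, resistances,
    preloads, peak tension, passive scale); returns the retained phenotype
    dict or None if the beat fails.  The mesh is passed under the key
    ``_mesh`` (not a perturbable parameter).
    """
    mesh = params["_mesh"]
    # FEC CV is specified as a multiple of the myocardial CV, so perturbing
    # the myocardial CV rescales the whole conduction field (pure eikonal
    # scaling) while the ratio isolates the endocardial layer
    act = simulate_activation(
        mesh, apical_endocardial_stimulus(mesh),
        cv_myo=params["cv_myo"],
        cv_fec=params["cv_myo"] * params["cv_fec_ratio"],
        fec_extent=params.get("fec_extent", 0.7),
    )
    anatomy = lumped_anatomy(mesh)
    lv_nodes, all_nodes = _case_node_sets(mesh)
    tags = mesh.meta["tags"]
    trig = {}
    for side in ("lv", "rv"):
        nodes = np.unique(mesh.tets[mesh.cell_labels == tags[f"{side}_myocardium"]])
        trig[side] = act.mean_time(nodes)
    stress = TanhStressParams(peak_tension=params["peak_tension"])
    circ = CirculationParams(
        sys_peripheral_resistance=params["sys_peripheral_resistance"],
        pul_peripheral_resistance=params["pul_peripheral_resistance"],
        preload_lv=params["preload_lv"],
        preload_rv=params["preload_rv"],
        passive_scale_a=params["passive_scale_a"],
    )
    trace = simulate_beat(anatomy, trig, stress=stress, circ=circ,
                          dt=params.get("dt", 0.1),
                          duration=params.get("duration", 800.0))
    if not trace.completed:
        return None
    out = {}
    for side in ("lv", "rv"):
        edv = anatomy.lv.edv if side == "lv" else anatomy.rv.edv
        mech = extract_mechanical(trace, edv, side=side)
        out.update({f"{k}_{side.upper()}": v for k, v in mech.items()})
    out.update(extract_ep(act, lv_nodes, all_nodes))
    return out


def baseline_lsa_params(config: RunConfig, mesh) -> dict:
    circ = CirculationParams()
    return {
        "_mesh": mesh,
        "cv_myo": config.cv_myo,
        "cv_fec_ratio": config.cv_fec / config.cv_myo,
        "fec_extent": config.fec_extent,
        "dt": config.dt,
        "duration": config.duration,
        "peak_tension": config.peak_tension,
        "passive_scale_a": config.passive_scale_a,
        "sys_peripheral_resistance": circ.sys_peripheral_resistance,
        "pul_peripheral_resistance": circ.pul_peripheral_resistance,
        "preload_lv": circ.preload_lv,
        "preload_rv": circ.preload_rv,
    }


def run_pipeline(config: RunConfig, stages: Optional[Sequence[str]] = None) -> Path:
    """Run the study (or a prefix of it) and return the run directory."""
    all_stages = ["generate", "ssm", "simulate", "phenotypes", "sense", "report"]
    stages = list(stages) if stages else all_stages
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    def _tick(stage):
        manifest["stages"][stage] = {"started": time.time()}

    def _tock(stage, **info):
        rec = manifest["stages"][stage]
        rec["seconds"] = round(time.time() - rec.pop("started"), 3)
        rec.update(info)

    # ---------------- generate ----------------
    _tick("generate")
    template = build_template(config.template_resolution)
    spec = CohortSpec(
        n_cases=config.n_cases, latent_sds=tuple(config.latent_sds),
        node_noise_sd=config.node_noise_sd, seed=config.seed,
        template_resolution=config.template_resolution,
    )
    ct_meshes, latent = sample_cohort(spec, template=template)
    latent_df = pd.DataFrame(
        latent, index=[m.name for m in ct_meshes],
        columns=[f"factor{i + 1}" for i in range(latent.shape[1])],
    )
    latent_df.to_csv(outdir / "latent_factors.csv", index_label="case")
    if config.write_meshes:
        (outdir / "meshes").mkdir(exist_ok=True)
        for m in ct_meshes:
            write_vtk_mesh(m, outdir / "meshes" / f"{m.name}.vtk")
    _tock("generate", n_cases=len(ct_meshes))
    if stages[-1] == "generate":
        _finish(outdir, manifest)
        return outdir

    # ---------------- ssm ----------------
    _tick("ssm")
    kept = [m for m in ct_meshes if m.name not in set(config.exclusions)]
    aligned, _, rmsd = rigid_align(kept, template)
    model = StatisticalShapeModel().fit(aligned)
    n_modes_90 = model.modes_for_threshold(config.variance_threshold)
    weights_df = pd.DataFrame(
        model.subject_weights_, index=model.case_names_,
        columns=[f"mode{i + 1}" for i in range(model.modes_.shape[0])],
    )
    extremes = model.make_extreme_cohort(
        range(1, n_modes_90 + 1),
        [m for k in config.extreme_multipliers for m in (+k, -k)],
        sj_check=scaled_jacobian,
    )
    average = model.mean_mesh()
    np.save(outdir / "mode_sds.npy", model.mode_sds_)
    pd.DataFrame(
        {"explained_variance_ratio": model.explained_variance_ratio_},
        index=weights_df.columns,
    ).to_csv(outdir / "explained_variance.csv", index_label="mode")
    _tock("ssm", n_modes_90=n_modes_90, n_extreme=len(extremes))
    if stages[-1] == "ssm":
        _finish(outdir, manifest)
        return outdir

    # ---------------- simulate ----------------
    _tick("simulate")
    sim_meshes = list(kept) + [average] + extremes
    labels = (
        ["CT"] * len(kept) + ["Average"]
        + [f"Extreme{abs(int(m.name.split('_')[1][:2]))}" for m in extremes]
    )
    traces, acts, completion = run_cohort(
        sim_meshes, stress=config.stress(), circ=config.circulation(),
        dt=config.dt, duration=config.duration, cv_myo=config.cv_myo,
        cv_fec=config.cv_fec, fec_extent=config.fec_extent,
        cohort_labels=labels,
    )
    completion.to_csv(outdir / "completion_table.csv")
    _tock("simulate", n_simulated=len(sim_meshes))
    if stages[-1] == "simulate":
        _finish(outdir, manifest)
        return outdir

    # ---------------- phenotypes ----------------
    _tick("phenotypes")
    anatomies = {m.name: lumped_anatomy(m) for m in sim_meshes}
    lv_nodes, all_nodes = {}, {}
    for m in sim_meshes:
        lv_nodes[m.name], all_nodes[m.name] = _case_node_sets(m)
    phenos = phenotype_table(traces, acts, anatomies, lv_nodes, all_nodes)
    synth_names = [average.name] + [m.name for m in extremes]
    synth_weights = pd.DataFrame(
        model.transform([average] + extremes), index=synth_names,
        columns=weights_df.columns,
    )
    all_weights = pd.concat([weights_df, synth_weights])
    write_cohort_tables(all_weights, phenos, outdir, prefix="cohort")
    _tock("phenotypes", n_rows=len(phenos))
    if stages[-1] == "phenotypes":
        _finish(outdir, manifest)
        return outdir

    # ---------------- sense ----------------
    _tick("sense")
    ct_names = [m.name for m in kept]
    ct_phenos = phenos.loc[phenos.index.isin(ct_names)]
    pheno_cols = [c for c in phenos.columns
                  if c not in ("completed",) and not c.startswith("EDV")]
    nr, retained = normalized_range_filter(
        ct_phenos[pheno_cols + ["completed"]], threshold=config.range_threshold
    )
    nr.to_csv(outdir / "normalized_ranges.csv", header=True)
    corr, corr_summary = mode_phenotype_correlations(
        weights_df, ct_phenos[retained + ["completed"]]
    )
    corr.to_csv(outdir / "correlation_matrix.csv")
    corr_summary.to_csv(outdir / "correlation_summary.csv")
    gsa_rows = []
    if config.run_gsa:
        completed = phenos["completed"].astype(bool)
        data = all_weights.join(phenos[pheno_cols], how="inner")
        data = data.loc[completed.reindex(data.index, fill_value=False)]
        wcols = weights_df.columns
        # GSA input distribution: uniform over the per-mode range spanned by
        # the imaged cohort
        ranges = np.column_stack([weights_df.min(), weights_df.max()])
        for ph in config.gsa_phenotypes:
            if ph not in retained:
                continue
            sub = data.dropna(subset=[ph])
            gpe = train_gpes_loo(
                sub[wcols].to_numpy(), sub[ph].to_numpy(),
                synthetic_mask=sub.index.isin(synth_names),
                random_state=config.seed,
            )
            res = sobol_saltelli(
                gpe.predict, ranges, n=config.sobol_n, seed=config.seed
            )
            for i, mode in enumerate(wcols):
                gsa_rows.append({
                    "phenotype": ph, "mode": mode,
                    "S1": res.s1[i], "ST": res.st[i],
                    "multifactorial": res.multifactorial,
                    "mean_loo_mse": gpe.mean_loo_mse,
                })
        pd.DataFrame(gsa_rows).to_csv(outdir / "sobol_indices.csv", index=False)
    if config.run_lsa:
        base = baseline_lsa_params(config, average)
        sc = lsa_battery(average_mesh_phenotypes, base, config.lsa_parameters)
        sc.to_csv(outdir / "lsa_coefficients.csv")
    _tock("sense", n_retained=len(retained), n_gsa=len(gsa_rows))

    # ---------------- report ----------------
    _tick("report")
    _tock("report")
    _finish(outdir, manifest)
    return outdir


def _finish(outdir: Path, manifest: dict) -> None:
    manifest["outputs"] = sorted(
        p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
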