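"""Idealised biventricular cohort generator with known latent shape factors.

Generates fixed-topology, point-corresponding tetrahedral meshes of two
thick-walled truncated ellipsoidal ventricles (a thick LV shell and a
thinner, laterally offset RV shell).  A small set of latent shape factors —
global size, sphericity (long-axis shortening), LV wall thickness, whole
heart orientation and a localised septal-basal bulge — deform the template
through displacement fields that are linear in each factor (rotation
excepted, which is rigid).  Cohorts drawn from these factors stand in for an
imaged population so that shape-model recovery, extreme-mesh generation and
the downstream sensitivity pipeline can be exercised end to end.

Every generated mesh shares the template's topology exactly (node-for-node
correspondence), which is the precondition for the displacement-field PCA in
:mod:`cardioshape.shape_model`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .mesh import TetMesh
from .mesh_metrics import scaled_jacobian, tet_volumes

__all__ = [
    "AnatomyParams",
    "CohortSpec",
    "DeformationError",
    "build_template",
    "deform_template",
    "sample_cohort",
    "LATENT_FACTOR_NAMES",
    "LATENT_FACTOR_UNITS",
]

# Template wall thicknesses (mm); AnatomyParams defaults reference these.
TEMPLATE_LV_THICKNESS = 10.0
TEMPLATE_RV_THICKNESS = 4.5

#: Latent factor order used by :func:`sample_cohort`.
LATENT_FACTOR_NAMES = (
    "scale",
    "sphericity",
    "lv_wall_thickness",
    "orientation",
    "basal_bulge",
)

#: Physical amplitude of one latent unit per factor.  The units are chosen so
#: that one latent unit of each factor produces a broadly comparable RMS node
#: displacement on the template; a non-increasing latent SD vector then maps
#: to factors of genuinely decreasing anatomical variance.
LATENT_FACTOR_UNITS = {
    "scale": 1.0,  # fractional size change per unit
    "sphericity": 1.0,  # fractional long-axis shortening per unit
    "lv_wall_thickness": 20.0,  # mm of LV wall change per unit
    "orientation": 100.0,  # degrees of rotation per unit
    "basal_bulge": 40.0,  # mm of bulge amplitude per unit
}

_ROTATION_AXIS = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)


class DeformationError(ValueError):
    """Raised when a deformation inverts elements; names the factor."""


@dataclass
class AnatomyParams:
    """Latent shape factors of one synthetic anatomy.

    scale : global size factor about the centroid (1 = template).
    sphericity : long-axis modifier; the apicobasal axis is multiplied by
        ``2 - sphericity`` so the field is linear in the factor and values
        above 1 give a more spherical (shorter) heart.
    lv_wall_thickness, rv_wall_thickness : target wall thicknesses in mm;
        endocardium stays put, epicardium moves along the local normal.
    orientation : rigid rotation angle (degrees) about a fixed oblique axis.
    basal_bulge : amplitude (mm) of a Gaussian-windowed inward displacement
        of septal LV nodes near the base (apicobasal Z > 0.8).
    """

    scale: float = 1.0
    sphericity: float = 1.0
    lv_wall_thickness: float = TEMPLATE_LV_THICKNESS
    rv_wall_thickness: float = TEMPLATE_RV_THICKNESS
    orientation: float = 0.0
    basal_bulge: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.lv_wall_thickness <= 0 or self.rv_wall_thickness <= 0:
            raise ValueError("wall thicknesses must be > 0")
        if self.basal_bulge < 0:
            raise ValueError("basal_bulge must be >= 0")


@dataclass
class CohortSpec:
    """Sampling specification for a synthetic cohort."""

    n_cases: int = 19
    latent_sds: Sequence[float] = (0.10, 0.07, 0.05, 0.035, 0.025)
    node_noise_sd: float = 0.25  # mm iid per node
    seed: int = 0
    template_resolution: float = 8.0  # target mean edge length, mm

    def __post_init__(self) -> None:
        if self.n_cases < 3:
            raise ValueError("n_cases must be >= 3")
        sds = np.asarray(self.latent_sds, dtype=float)
        if np.any(sds <= 0) or np.any(np.diff(sds) > 0):
            raise ValueError("latent_sds must be strictly positive and non-increasing")
        if self.node_noise_sd < 0:
            raise ValueError("node_noise_sd must be >= 0")


# ----------------------------------------------------------------------
# template construction
# ----------------------------------------------------------------------
@dataclass
class _Shell:
    """Parameters of one truncated-ellipsoid ventricular shell."""

    a_endo: float  # short semi-axis of the endocardial ellipsoid, mm
    c_endo: float  # long semi-axis, mm
    thickness: float  # wall thickness, mm
    centre: np.ndarray  # shell centre
    theta_base: float  # polar angle of the basal truncation (rad)
    theta_last: float  # last discretised ring before the apex pole (rad)
    label: int


_LV = _Shell(27.0, 46.0, TEMPLATE_LV_THICKNESS, np.zeros(3), np.deg2rad(50.0),
             np.deg2rad(160.0), 1)
_RV = _Shell(30.0, 44.0, TEMPLATE_RV_THICKNESS, np.array([75.0, 0.0, 0.0]),
             np.deg2rad(50.0), np.deg2rad(160.0), 2)

# 5-tet decompositions of a hexahedron, alternating with corner parity so
# that face diagonals agree between neighbouring cells.
_HEX5_EVEN = [(0, 1, 3, 4), (1, 2, 3, 6), (1, 4, 5, 6), (3, 4, 6, 7), (1, 3, 4, 6)]
_HEX5_ODD = [(0, 1, 2, 5), (0, 2, 3, 7), (0, 4, 5, 7), (2, 5, 6, 7), (0, 2, 5, 7)]


def _shell_mesh(shell: _Shell, resolution: float):
    """Structured tet mesh of one shell; returns arrays and metadata."""
    if resolution > 3.0 * shell.thickness:
        raise ValueError(
            f"resolution {resolution} mm too coarse: wall of thickness "
            f"{shell.thickness} mm would have < 1 element through thickness"
        )
    mid_r = shell.a_endo + shell.thickness / 2.0
    n_phi = max(8, int(round(2 * np.pi * mid_r / resolution)))
    n_phi += n_phi % 2  # even, for the alternating hex split
    arc = (shell.c_endo + shell.thickness) * (shell.theta_last - shell.theta_base)
    n_theta = max(5, int(round(arc / resolution)))  # rings, base..last
    n_t = max(1, int(round(shell.thickness / resolution)))  # layers through wall

    thetas = np.linspace(shell.theta_base, shell.theta_last, n_theta)
    phis = 2 * np.pi * np.arange(n_phi) / n_phi
    ts = np.linspace(0.0, 1.0, n_t + 1)

    pts, meta = [], []

    def ring_point(theta, phi, t):
        a = shell.a_endo + t * shell.thickness
        c = shell.c_endo + t * shell.thickness
        return shell.centre + np.array(
            [a * np.sin(theta) * np.cos(phi), a * np.sin(theta) * np.sin(phi),
             c * np.cos(theta)]
        )

    # index maps
    idx = np.empty((n_theta, n_phi, n_t + 1), dtype=np.int64)
    z_of_theta = lambda th: (np.pi - th) / (np.pi - shell.theta_base)
    for k, t in enumerate(ts):
        for i, th in enumerate(thetas):
            for j, ph in enumerate(phis):
                idx[i, j, k] = len(pts)
                pts.append(ring_point(th, ph, t))
                # outward normal of the endocardial ellipsoid at (th, ph)
                x, y, z = ring_point(th, ph, 0.0) - shell.centre
                n = np.array([x / shell.a_endo**2, y / shell.a_endo**2,
                              z / shell.c_endo**2])
                n /= np.linalg.norm(n)
                meta.append((t, th, ph, z_of_theta(th), n))
    apex_idx = np.empty(n_t + 1, dtype=np.int64)
    for k, t in enumerate(ts):
        apex_idx[k] = len(pts)
        pts.append(shell.centre + np.array([0.0, 0.0, -(shell.c_endo + t * shell.thickness)]))
        meta.append((t, np.pi, 0.0, 0.0, np.array([0.0, 0.0, -1.0])))

    tets = []
    for k in range(n_t):
        for i in range(n_theta - 1):
            for j in range(n_phi):
                jp = (j + 1) % n_phi
                corners = [
                    idx[i, j, k], idx[i + 1, j, k], idx[i + 1, jp, k], idx[i, jp, k],
                    idx[i, j, k + 1], idx[i + 1, j, k + 1], idx[i + 1, jp, k + 1],
                    idx[i, jp, k + 1],
                ]
                split = _HEX5_EVEN if (i + j + k) % 2 == 0 else _HEX5_ODD
                for tet in split:
                    tets.append([corners[v] for v in tet])
        # apex prisms between the last ring and the pole line
        for j in range(n_phi):
            jp = (j + 1) % n_phi
            p0, p1, p2 = idx[-1, j, k], idx[-1, jp, k], apex_idx[k]
            q0, q1, q2 = idx[-1, j, k + 1], idx[-1, jp, k + 1], apex_idx[k + 1]
            tets += [[p0, p1, p2, q0], [p1, p2, q0, q1], [p2, q0, q1, q2]]

    # endocardial closed surface: shell (t=0) + apex fan + flat basal lid
    tris = []
    for i in range(n_theta - 1):
        for j in range(n_phi):
            jp = (j + 1) % n_phi
            tris.append([idx[i, j, 0], idx[i + 1, j, 0], idx[i + 1, jp, 0]])
            tris.append([idx[i, j, 0], idx[i + 1, jp, 0], idx[i, jp, 0]])
    for j in range(n_phi):
        jp = (j + 1) % n_phi
        tris.append([idx[-1, j, 0], apex_idx[0], idx[-1, jp, 0]])
    base = idx[0, :, 0]
    for j in range(1, n_phi - 1):
        tris.append([base[0], base[j], base[j + 1]])

    endo_nodes = idx[:, :, 0].ravel().tolist() + [apex_idx[0]]
    epi_nodes = idx[:, :, -1].ravel().tolist() + [apex_idx[-1]]
    return (
        np.array(pts),
        np.array(tets, dtype=np.int64),
        np.array(tris, dtype=np.int64),
        meta,
        np.array(endo_nodes),
        np.array(epi_nodes),
    )


def _orient_tets(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    vols = tet_volumes(points, tets)
    flip = vols < 0
    tets = tets.copy()
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    return tets


def _orient_surface(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    centroid, cross = points[tris].mean(axis=1), None
    p0, p1, p2 = points[tris[:, 0]], points[tris[:, 1]], points[tris[:, 2]]
    signed = np.einsum("ij,ij->", (p0 + p1 + p2) / 3.0, np.cross(p1 - p0, p2 - p0)) / 6.0
    if signed < 0:
        tris = tris[:, [0, 2, 1]]
    return tris


def build_template(resolution: float = 8.0) -> TetMesh:
    """Build the fixed-topology biventricular template mesh.

    The LV is a thick-walled truncated ellipsoidal shell; the RV a thinner
    shell offset laterally.  Node metadata (ventricle, transmural depth,
    parametric angles, apicobasal Z, endocardial normal) is stored in
    ``mesh.meta`` and reused by :func:`deform_template`.  Identical topology
    for every call at the same resolution.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    all_pts, all_tets, labels = [], [], []
    surfaces, meta_rows = {}, []
    ventricle, endo_flags = [], []
    offset = 0
    for side, shell in (("lv", _LV), ("rv", _RV)):
        pts, tets, tris, meta, endo, epi = _shell_mesh(shell, resolution)
        all_pts.append(pts)
        all_tets.append(tets + offset)
        labels.append(np.full(len(tets), shell.label))
        surfaces[f"{side}_endo"] = tris + offset
        flags = np.zeros(len(pts), dtype=bool)
        flags[endo] = True
        endo_flags.append(flags)
        ventricle += [side] * len(pts)
        meta_rows += meta
        offset += len(pts)
    points = np.vstack(all_pts)
    tets = _orient_tets(points, np.vstack(all_tets))
    for key in surfaces:
        surfaces[key] = _orient_surface(points, surfaces[key])

    trans = np.array([m[0] for m in meta_rows])
    theta = np.array([m[1] for m in meta_rows])
    phi = np.array([m[2] for m in meta_rows])
    zab = np.array([m[3] for m in meta_rows])
    normals = np.array([m[4] for m in meta_rows])
    vent = np.array(ventricle)
    uvc = np.column_stack(
        [trans, phi, zab, np.where(vent == "lv", -1.0, 1.0)]
    )
    mesh = TetMesh(
        points=points,
        tets=tets,
        cell_labels=np.concatenate(labels),
        uvc=uvc,
        name="template",
        surfaces=surfaces,
        meta={
            "transmural": trans,
            "theta": theta,
            "phi": phi,
            "z_apicobasal": zab,
            "normal": normals,
            "ventricle": vent,
            "endocardial": np.concatenate(endo_flags),
            "resolution": resolution,
            "tags": {"lv_myocardium": 1, "rv_myocardium": 2},
            "template_thickness": {
                "lv": TEMPLATE_LV_THICKNESS,
                "rv": TEMPLATE_RV_THICKNESS,
            },
        },
    )
    sj = scaled_jacobian(mesh)
    if sj.min() <= 0:
        raise RuntimeError("template construction produced degenerate elements")
    return mesh


# ----------------------------------------------------------------------
# deformation
# ----------------------------------------------------------------------
def _factor_fields(template: TetMesh, params: AnatomyParams) -> dict[str, np.ndarray]:
    """Per-factor node displacement fields, each linear in its factor."""
    pts = template.points
    meta = template.meta
    centroid = pts.mean(axis=0)
    fields: dict[str, np.ndarray] = {}

    fields["scale"] = (params.scale - 1.0) * (pts - centroid)

    d_sph = np.zeros_like(pts)
    d_sph[:, 2] = (1.0 - params.sphericity) * (pts[:, 2] - centroid[2])
    fields["sphericity"] = d_sph

    for side, target in (("lv", params.lv_wall_thickness),
                         ("rv", params.rv_wall_thickness)):
        delta = target - meta["template_thickness"][side]
        d = np.zeros_like(pts)
        sel = meta["ventricle"] == side
        d[sel] = (meta["transmural"][sel] * delta)[:, None] * meta["normal"][sel]
        fields[f"{side}_wall_thickness"] = d

    # septal-basal inward bulge: Gaussian window in (Z, phi) on LV nodes
    # facing the RV (phi near 0), restricted to Z > 0.8
    d_bulge = np.zeros_like(pts)
    if params.basal_bulge != 0.0:
        z = meta["z_apicobasal"]
        dphi = np.angle(np.exp(1j * meta["phi"]))  # wrap to (-pi, pi]
        window = np.exp(-((z - 1.0) / 0.12) ** 2 - (dphi / 0.7) ** 2)
        sel = (meta["ventricle"] == "lv") & (z > 0.8) & (np.abs(dphi) < np.pi / 2)
        d_bulge[sel] = -(params.basal_bulge * window[sel])[:, None] * meta["normal"][sel]
    fields["basal_bulge"] = d_bulge
    return fields


def deform_template(template: TetMesh, params: AnatomyParams,
                    name: Optional[str] = None) -> TetMesh:
    """Apply the latent shape factors to the template.

    The non-rigid factors act as additive displacement fields evaluated on
    the template geometry (hence exactly linear in each factor); the
    orientation factor applies a final rigid rotation about the centroid.
    Raises :class:`DeformationError` naming the first factor whose
    application inverts any element.
    """
    fields = _factor_fields(template, params)
    pts = template.points.copy()
    order = ["lv_wall_thickness", "rv_wall_thickness", "sphericity",
             "basal_bulge", "scale"]
    for factor in order:
        pts = pts + fields[factor]
        if scaled_jacobian(template.with_points(pts)).min() <= 0:
            raise DeformationError(
                f"factor '{factor}' inverts elements (scaled Jacobian <= 0)"
            )
    if params.orientation != 0.0:
        centroid = template.points.mean(axis=0)
        rot = Rotation.from_rotvec(np.deg2rad(params.orientation) * _ROTATION_AXIS)
        pts = centroid + rot.apply(pts - centroid)
    return template.with_points(pts, name=name or "deformed")


# ----------------------------------------------------------------------
# cohort sampling
# ----------------------------------------------------------------------
def _params_from_latent(latent: np.ndarray) -> AnatomyParams:
    u = LATENT_FACTOR_UNITS
    vals = dict(zip(LATENT_FACTOR_NAMES, latent))
    return AnatomyParams(
        scale=1.0 + vals.get("scale", 0.0) * u["scale"],
        sphericity=1.0 + vals.get("sphericity", 0.0) * u["sphericity"],
        lv_wall_thickness=TEMPLATE_LV_THICKNESS
        + vals.get("lv_wall_thickness", 0.0) * u["lv_wall_thickness"],
        orientation=vals.get("orientation", 0.0) * u["orientation"],
        basal_bulge=abs(vals.get("basal_bulge", 0.0)) * u["basal_bulge"],
    )


def sample_cohort(
    spec: CohortSpec, template: Optional[TetMesh] = None, max_retries: int = 5
) -> tuple[list[TetMesh], np.ndarray]:
    """Draw a cohort of meshes and return them with the true latent factors.

    Latent factors are independent zero-mean Gaussians with the spec's SDs
    (the basal-bulge draw is folded to its absolute value, since the bulge
    is an inward displacement by construction); iid node jitter of
    ``node_noise_sd`` mm is added after deformation.  Deterministic for a
    fixed seed.  Cases whose deformation inverts elements are redrawn up to
    ``max_retries`` times.
    """
    rng = np.random.default_rng(spec.seed)
    if template is None:
        template = build_template(spec.template_resolution)
    sds = np.asarray(spec.latent_sds, dtype=float)
    k = len(sds)
    meshes, factors = [], []
    for case in range(spec.n_cases):
        for attempt in range(max_retries + 1):
            latent = rng.normal(0.0, sds)
            if k > 4:
                latent[4] = abs(latent[4])  # folded bulge amplitude
            try:
                mesh = deform_template(
                    template, _params_from_latent(latent), name=f"case{case + 1:02d}"
                )
                break
            except DeformationError:
                if attempt == max_retries:
                    raise
        if spec.node_noise_sd > 0:
            mesh.points = mesh.points + rng.normal(
                0.0, spec.node_noise_sd, mesh.points.shape
            )
        meshes.append(mesh)
        factors.append(latent)
    return meshes, np.array(factors)
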