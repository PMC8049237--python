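"""Tetrahedral mesh container used throughout the package.

The anatomical unit is a labelled tetrahedral mesh in millimetres, optionally
carrying per-element fibre and sheet directions and per-point universal
ventricular coordinates (UVC).  UVC follow the convention (rho, phi, Z, V):
transmural depth, rotational angle, apicobasal position in [0, 1] and a
ventricle indicator, with the sentinel value -10 on points outside the
ventricular myocardium.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: UVC sentinel used outside the ventricular myocardium.
UVC_SENTINEL = -10.0

#: Default anatomical tag dictionary (configurable; the published cohorts use
#: their own meshing tags, which the reader preserves verbatim).
DEFAULT_TAGS = {"lv_myocardium": 1, "rv_myocardium": 2}


class MeshIntegrityError(ValueError):
    """Raised when a mesh violates a structural invariant."""


class UnsupportedElementError(ValueError):
    """Raised when a mesh contains non-tetrahedral elements."""


@dataclass
class TetMesh:
    """Labelled tetrahedral mesh with optional fibre fields and UVC.

    Parameters
    ----------
    points : (n_points, 3) float array
        Node coordinates in mm.
    tets : (n_tets, 4) int array
        0-based vertex indices per tetrahedron.
    cell_labels : (n_tets,) int array, optional
        Anatomical tag per element.
    fibre_dir, sheet_dir : (n_tets, 3) float array, optional
        Unit fibre / sheet direction per element.
    uvc : (n_points, 4) float array, optional
        Per-point (rho, phi, Z, V); -10 sentinel outside the ventricles.
    name : str
        Identifier carried through cohort tables and file names.
    surfaces : dict
        Auxiliary oriented triangle lists (point-index triples), e.g. the
        closed endocardial surfaces ``{"lv_endo": (m, 3) int, ...}`` used for
        cavity volumes.  Populated by the synthetic-anatomy generator; not
        part of the on-disk VTK layout.
    meta : dict
        Generator metadata (per-node parametric coordinates, normals, flags).
    """

    points: np.ndarray
    tets: np.ndarray
    cell_labels: Optional[np.ndarray] = None
    fibre_dir: Optional[np.ndarray] = None
    sheet_dir: Optional[np.ndarray] = None
    uvc: Optional[np.ndarray] = None
    name: str = "mesh"
    surfaces: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    flagged: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise MeshIntegrityError("points must be an (n, 3) array")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise UnsupportedElementError("tets must be an (m, 4) array")
        if self.cell_labels is not None:
            self.cell_labels = np.asarray(self.cell_labels, dtype=np.int64)
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_tets(self) -> int:
        return self.tets.shape[0]

    def validate(self) -> None:
        """Check the structural invariants; raise on violation."""
        if self.n_tets and (self.tets.min() < 0 or self.tets.max() >= self.n_points):
            raise MeshIntegrityError(
                f"tet indices must lie in [0, {self.n_points}); "
                f"found range [{self.tets.min()}, {self.tets.max()}]"
            )
        for attr in ("fibre_dir", "sheet_dir"):
            vec = getattr(self, attr)
            if vec is None:
                continue
            vec = np.asarray(vec, dtype=float)
            setattr(self, attr, vec)
            if vec.shape != (self.n_tets, 3):
                raise MeshIntegrityError(f"{attr} must be ({self.n_tets}, 3)")
            norms = np.linalg.norm(vec, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise MeshIntegrityError(f"{attr} vectors must have unit norm (1e-6)")
        if self.uvc is not None:
            self.uvc = np.asarray(self.uvc, dtype=float)
            if self.uvc.shape != (self.n_points, 4):
                raise MeshIntegrityError(f"uvc must be ({self.n_points}, 4)")
            z = self.uvc[:, 2]
            ok = ((z >= 0.0) & (z <= 1.0)) | (z == UVC_SENTINEL)
            if not np.all(ok):
                raise MeshIntegrityError(
                    "uvc Z must lie in [0, 1] or equal the -10 sentinel"
                )
        if self.cell_labels is not None and self.cell_labels.shape != (self.n_tets,):
            raise MeshIntegrityError(f"cell_labels must be ({self.n_tets},)")

    def copy(self, name: Optional[str] = None) -> "TetMesh":
        return TetMesh(
            points=self.points.copy(),
            tets=self.tets.copy(),
            cell_labels=None if self.cell_labels is None else self.cell_labels.copy(),
            fibre_dir=None if self.fibre_dir is None else self.fibre_dir.copy(),
            sheet_dir=None if self.sheet_dir is None else self.sheet_dir.copy(),
            uvc=None if self.uvc is None else self.uvc.copy(),
            name=self.name if name is None else name,
            surfaces={k: v.copy() for k, v in self.surfaces.items()},
            meta=dict(self.meta),
            flagged=self.flagged,
        )

    def with_points(self, points: np.ndarray, name: Optional[str] = None) -> "TetMesh":
        """Same topology and metadata, new node coordinates."""
        out = self.copy(name=name)
        points = np.asarray(points, dtype=float)
        if points.shape != self.points.shape:
            raise MeshIntegrityError("replacement points must match shape")
        out.points = points
        return out
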