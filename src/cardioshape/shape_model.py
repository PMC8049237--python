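"""Statistical shape model: rigid alignment + PCA on node displacement fields.

The cohort meshes share the template topology exactly, so the model is a PCA
of the n x 3N matrix of node displacements from the cohort mean.  Each
anatomy is then ``mean + sum_k w_k * mode_k`` with orthonormal modes ordered
by decreasing variance; the per-subject weights are the model's coordinate
system and feed the downstream emulation and sensitivity analyses.  Extreme
synthetic anatomies are produced at average +/- k standard deviations of a
single mode.

`StatisticalShapeModel` follows the scikit-learn estimator protocol
(fit / transform / inverse_transform, trailing-underscore fitted attributes)
and composes with sklearn model selection; the module-level functions are
thin wrappers for pipeline use.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .mesh import TetMesh

__all__ = [
    "StatisticalShapeModel",
    "rigid_align",
    "kabsch",
    "fit_ssm",
    "project",
    "reconstruct",
    "modes_for_threshold",
    "make_extreme_cohort",
]


# ----------------------------------------------------------------------
# rigid alignment
# ----------------------------------------------------------------------
def kabsch(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t mapping source -> target.

    Rotation only (det +1), no scaling: size differences survive into the
    shape model, where they become a size mode.
    """
    sc, tc = source.mean(axis=0), target.mean(axis=0)
    h = (source - sc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, tc - rot @ sc


def rigid_align(
    meshes: Sequence[TetMesh], reference: TetMesh
) -> tuple[list[TetMesh], list[dict], np.ndarray]:
    """Rigidly align each mesh to the reference (rotation + translation).

    Returns the aligned meshes, the per-case transforms and the residual
    RMSD (mm) per case.  All meshes must share the reference topology.
    """
    aligned, transforms, rmsd = [], [], []
    for mesh in meshes:
        if mesh.points.shape != reference.points.shape or not np.array_equal(
            mesh.tets, reference.tets
        ):
            raise ValueError(f"mesh {mesh.name!r} does not share reference topology")
        rot, trans = kabsch(mesh.points, reference.points)
        pts = mesh.points @ rot.T + trans
        aligned.append(mesh.with_points(pts))
        transforms.append({"rotation": rot, "translation": trans})
        rmsd.append(float(np.sqrt(np.mean(np.sum((pts - reference.points) ** 2, axis=1)))))
    return aligned, transforms, np.array(rmsd)


# ----------------------------------------------------------------------
# the model
# ----------------------------------------------------------------------
class StatisticalShapeModel(BaseEstimator, TransformerMixin):
    """PCA shape model over flattened node coordinates.

    Parameters
    ----------
    n_modes : int or None
        Number of modes to retain; None keeps every nonzero-variance mode
        (at most n_subjects - 1).

    Attributes (after ``fit``)
    --------------------------
    mean_points_ : (N, 3) cohort mean shape (mm).
    modes_ : (K, 3N) orthonormal displacement modes.  Sign convention: the
        largest-magnitude coordinate of each mode is positive.
    mode_sds_ : (K,) per-mode SD of the cohort weights (mm scale).
    explained_variance_ratio_ : (K,) non-increasing, sums to 1 over all
        nonzero modes.
    subject_weights_ : (n_subjects, K) raw weights reproducing each case.
    template_ : the TetMesh whose topology/metadata reconstructions reuse.
    """

    def __init__(self, n_modes: Optional[int] = None):
        self.n_modes = n_modes

    # -- helpers -------------------------------------------------------
    @staticmethod
    def _as_matrix(meshes: Sequence[TetMesh]) -> np.ndarray:
        return np.stack([m.points.ravel() for m in meshes])

    def fit(self, meshes: Sequence[TetMesh], y=None) -> "StatisticalShapeModel":
        if len(meshes) < 3:
            raise ValueError("shape model needs at least 3 meshes")
        x = self._as_matrix(meshes)
        n = x.shape[0]
        mean = x.mean(axis=0)
        disp = x - mean
        # SVD of the centred displacement matrix; PCA variances = s^2/(n-1)
        u, s, vt = np.linalg.svd(disp, full_matrices=False)
        nonzero = s > s[0] * 1e-12 if s.size and s[0] > 0 else s > 0
        k_all = int(nonzero.sum())
        k = k_all if self.n_modes is None else min(self.n_modes, k_all)
        modes = vt[:k_all]
        # sign convention for reproducibility
        flip = modes[np.arange(k_all), np.abs(modes).argmax(axis=1)] < 0
        modes[flip] *= -1.0
        weights = disp @ modes.T
        var = s[:k_all] ** 2 / (n - 1)
        self.n_subjects_ = n
        self.mean_points_ = mean.reshape(-1, 3)
        self.modes_ = modes[:k]
        self.mode_sds_ = np.sqrt(var[:k])
        self.explained_variance_ratio_ = (var / var.sum())[:k]
        self.subject_weights_ = weights[:, :k]
        self.case_names_ = [m.name for m in meshes]
        self.template_ = meshes[0]
        return self

    # -- projection / reconstruction -----------------------------------
    def transform(self, meshes: Sequence[TetMesh]) -> np.ndarray:
        """Project meshes (already in the model frame) onto the modes."""
        check_is_fitted(self, "modes_")
        x = self._as_matrix(meshes)
        return (x - self.mean_points_.ravel()) @ self.modes_.T

    def inverse_transform(self, weights: np.ndarray) -> list[TetMesh]:
        """Reconstruct meshes from weight vectors (raw units)."""
        check_is_fitted(self, "modes_")
        weights = np.atleast_2d(np.asarray(weights, dtype=float))
        if weights.shape[1] != self.modes_.shape[0]:
            raise ValueError(
                f"weight vectors must have length {self.modes_.shape[0]}, "
                f"got {weights.shape[1]}"
            )
        out = []
        for i, w in enumerate(weights):
            pts = self.mean_points_.ravel() + w @ self.modes_
            out.append(
                self.template_.with_points(pts.reshape(-1, 3), name=f"recon{i}")
            )
        return out

    def mean_mesh(self) -> TetMesh:
        check_is_fitted(self, "modes_")
        return self.template_.with_points(self.mean_points_.copy(), name="average")

    def weights_in_sd_units(self, weights: np.ndarray) -> np.ndarray:
        """Convert raw weights to per-mode SD units."""
        check_is_fitted(self, "modes_")
        return np.asarray(weights) / self.mode_sds_

    # -- mode selection -------------------------------------------------
    def modes_for_threshold(self, fraction: float) -> int:
        """Smallest K whose cumulative explained variance reaches fraction."""
        check_is_fitted(self, "modes_")
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        cum = np.cumsum(self.explained_variance_ratio_)
        hit = np.nonzero(cum >= fraction - 1e-12)[0]
        return int(hit[0]) + 1 if hit.size else len(cum)

    # -- extreme cohorts -------------------------------------------------
    def make_extreme_cohort(
        self,
        mode_indices: Sequence[int],
        multipliers: Sequence[int],
        sj_check=None,
    ) -> list[TetMesh]:
        """Average mesh deformed by multiplier x SD along single modes.

        ``mode_indices`` are 1-based mode numbers.  One mesh per
        (mode, signed multiplier), named ``mode{m}_{+k}sd``.  If ``sj_check``
        is given (a callable mesh -> per-element quality), meshes with any
        non-positive element are emitted flagged rather than dropped,
        mirroring how failing extreme anatomies are handled downstream.
        """
        check_is_fitted(self, "modes_")
        bad = [m for m in mode_indices if not 1 <= m <= self.modes_.shape[0]]
        if bad:
            raise ValueError(f"mode indices out of range: {bad}")
        if any(int(k) != k or abs(int(k)) > 3 for k in multipliers):
            raise ValueError("multipliers must be integers with |k| <= 3")
        out = []
        for m in mode_indices:
            for k in multipliers:
                w = np.zeros(self.modes_.shape[0])
                w[m - 1] = k * self.mode_sds_[m - 1]
                mesh = self.inverse_transform(w)[0]
                mesh.name = f"mode{m}_{k:+d}sd"
                if sj_check is not None and k != 0 and np.min(sj_check(mesh)) <= 0:
                    mesh.flagged = True
                out.append(mesh)
        return out


# ----------------------------------------------------------------------
# thin functional wrappers
# ----------------------------------------------------------------------
def fit_ssm(aligned: Sequence[TetMesh], n_modes: Optional[int] = None) -> StatisticalShapeModel:
    return StatisticalShapeModel(n_modes=n_modes).fit(aligned)


def project(mesh: TetMesh, model: StatisticalShapeModel) -> np.ndarray:
    return model.transform([mesh])[0]


def reconstruct(weights: np.ndarray, model: StatisticalShapeModel) -> TetMesh:
    return model.inverse_transform(np.atleast_2d(weights))[0]


def modes_for_threshold(model: StatisticalShapeModel, fraction: float) -> int:
    return model.modes_for_threshold(fraction)


def make_extreme_cohort(
    model: StatisticalShapeModel,
    mode_indices: Sequence[int],
    multipliers: Sequence[int],
    sj_check=None,
) -> list[TetMesh]:
    return model.make_extreme_cohort(mode_indices, multipliers, sj_check=sj_check)
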