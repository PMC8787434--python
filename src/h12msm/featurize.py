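"""Geometric featurization of coordinate trajectories.

The pipeline reduces each conformation to a two-component feature vector:
the least-squares (Kabsch) RMSD of a backbone selection to a reference
structure, and the center-of-mass distance between two atom groups (in
the receptor: helix 12 versus an anchor residue on helix 4). A reference
panel classifier assigns frames to crystal-like conformations, and a
heavy-atom PCA summarizes the dominant collective motions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .trajectory import (
    ELEMENT_MASSES,
    AtomSelection,
    CoordinateTrajectory,
    FeatureTrajectory,
)

__all__ = [
    "kabsch_superpose",
    "compute_rmsd_series",
    "compute_com_distance_series",
    "featurize",
    "FeatureSpec",
    "ReferenceEnsemble",
    "classify_by_reference",
    "PCAResult",
    "TrajectoryPCA",
    "pca_heavy_atoms",
]


def _as_coords(x: np.ndarray | CoordinateTrajectory) -> np.ndarray:
    if isinstance(x, CoordinateTrajectory):
        if x.n_frames != 1:
            raise ValueError("expected a single structure, got a multi-frame trajectory")
        return x.xyz[0]
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"structure must have shape (n_atoms, 3), got {x.shape}")
    return x


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: AtomSelection | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD over the
    selected atoms. The rotation is always proper (det = +1): if the
    best orthogonal map is a reflection, the smallest singular direction
    is flipped (standard Kabsch determinant correction).
    """
    mob = _as_coords(mobile)
    ref = _as_coords(reference)
    if mob.shape != ref.shape:
        raise ValueError("mobile and reference must have the same atom count")
    if selection is not None:
        selection.validate_for(mob.shape[0])
        mob_sel, ref_sel = mob[selection.indices], ref[selection.indices]
    else:
        mob_sel, ref_sel = mob, ref
    n = mob_sel.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    mob_c = mob_sel.mean(axis=0)
    ref_c = ref_sel.mean(axis=0)
    A = mob_sel - mob_c
    B = ref_sel - ref_c
    if np.linalg.matrix_rank(A, tol=1e-10) < 2:
        raise ValueError("selected atoms are collinear: superposition is degenerate")
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    rotated = A @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((rotated - B) ** 2, axis=1))))
    translation = ref_c - mob_c @ R.T
    return R, translation, rmsd


def compute_rmsd_series(
    traj: CoordinateTrajectory,
    reference: np.ndarray | CoordinateTrajectory,
    selection: AtomSelection | None = None,
) -> np.ndarray:
    """Per-frame minimized RMSD (Å) to ``reference`` over ``selection``.

    Each frame is independently superposed before the deviation is taken,
    so the series is invariant to global rigid motions of either input.
    """
    ref = _as_coords(reference)
    return np.array(
        [kabsch_superpose(traj.xyz[f], ref, selection)[2] for f in range(traj.n_frames)]
    )


def _centroid(
    coords: np.ndarray, selection: AtomSelection, masses: np.ndarray | None
) -> np.ndarray:
    pts = coords[selection.indices]
    if masses is None:
        return pts.mean(axis=0)
    w = masses[selection.indices]
    return (pts * w[:, None]).sum(axis=0) / w.sum()


def compute_com_distance_series(
    traj: CoordinateTrajectory,
    group_a: AtomSelection,
    group_b: AtomSelection,
    mass_weighted: bool = False,
) -> np.ndarray:
    """Per-frame Euclidean distance (Å) between two group centroids.

    Geometric centroids by default; with ``mass_weighted`` the element
    masses from the atom table are used (unknown elements fall back to
    geometric weighting for the whole calculation).
    """
    group_a.validate_for(traj.n_atoms)
    group_b.validate_for(traj.n_atoms)
    masses = None
    if mass_weighted:
        elems = traj.atoms["element"].astype(str).str.upper()
        if elems.isin(ELEMENT_MASSES).all():
            masses = elems.map(ELEMENT_MASSES).to_numpy(dtype=float)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        ca = _centroid(traj.xyz[f], group_a, masses)
        cb = _centroid(traj.xyz[f], group_b, masses)
        out[f] = np.linalg.norm(ca - cb)
    return out


@dataclass(frozen=True)
class FeatureSpec:
    """Names the selections that define the (rmsd, distance) feature pair."""

    rmsd_selection: AtomSelection
    com_group_a: AtomSelection
    com_group_b: AtomSelection
    mass_weighted: bool = False


def featurize(
    traj: CoordinateTrajectory,
    reference: np.ndarray | CoordinateTrajectory,
    spec: FeatureSpec,
) -> FeatureTrajectory:
    """Per-frame feature vector (rmsd_t, distance_t), column order fixed."""
    if traj.n_frames == 0:
        return FeatureTrajectory(
            values=np.empty((0, 2)),
            feature_names=("rmsd", "distance"),
            frame_interval=traj.frame_interval,
        )
    r = compute_rmsd_series(traj, reference, spec.rmsd_selection)
    d = compute_com_distance_series(
        traj, spec.com_group_a, spec.com_group_b, spec.mass_weighted
    )
    return FeatureTrajectory(
        values=np.column_stack([r, d]),
        feature_names=("rmsd", "distance"),
        frame_interval=traj.frame_interval,
    )


@dataclass
class ReferenceEnsemble:
    """A labeled panel of reference structures with an assignment cutoff (Å).

    A frame counts toward a reference when that reference is the nearest
    by selection RMSD after superposition and the RMSD is at most
    ``cutoff``; otherwise it is unassigned.
    """

    references: dict[str, np.ndarray]
    selection: AtomSelection | None = None
    cutoff: float = 2.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        shapes = {k: np.asarray(v).shape for k, v in self.references.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"references differ in atom count: {shapes}")


def classify_by_reference(
    traj: CoordinateTrajectory, panel: ReferenceEnsemble
) -> dict[str, float]:
    """Population fraction per reference label plus an ``unassigned`` remainder.

    Fractions sum to 1 exactly (counts over n_frames).
    """
    labels = list(panel.references)
    rmsds = np.column_stack(
        [
            compute_rmsd_series(traj, panel.references[lab], panel.selection)
            for lab in labels
        ]
    )
    nearest = rmsds.argmin(axis=1)
    assigned = rmsds[np.arange(traj.n_frames), nearest] <= panel.cutoff
    counts = {lab: 0 for lab in labels}
    for i in np.flatnonzero(assigned):
        counts[labels[nearest[i]]] += 1
    out = {lab: counts[lab] / traj.n_frames for lab in labels}
    out["unassigned"] = (traj.n_frames - int(assigned.sum())) / traj.n_frames
    return out


@dataclass
class PCAResult:
    """Principal components of superposed heavy-atom coordinates."""

    mean_structure: np.ndarray
    modes: np.ndarray  # (n_modes, 3 * n_heavy), orthonormal rows
    variance_fractions: np.ndarray
    eigenvalues: np.ndarray


class TrajectoryPCA(BaseEstimator):
    """Heavy-atom principal component analysis of a coordinate trajectory.

    Frames are superposed onto frame 0 over the heavy atoms (single-pass
    alignment, no iterative mean-structure refinement), flattened and fed
    to an exact PCA. Fitted attributes: ``mean_structure_``, ``modes_``,
    ``variance_fractions_``, ``eigenvalues_``.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, traj: CoordinateTrajectory, y=None):
        if traj.n_frames < 2:
            raise ValueError("PCA needs at least 2 frames")
        heavy = np.flatnonzero(traj.atoms["is_heavy"].to_numpy())
        if heavy.size < 3:
            raise ValueError("need at least 3 heavy atoms")
        sel = AtomSelection(indices=heavy, label="heavy")
        ref = traj.xyz[0]
        aligned = np.empty((traj.n_frames, heavy.size, 3))
        for f in range(traj.n_frames):
            R, t, _ = kabsch_superpose(traj.xyz[f], ref, sel)
            aligned[f] = traj.xyz[f][heavy] @ R.T + t
        X = aligned.reshape(traj.n_frames, -1)
        pca = PCA(n_components=None, svd_solver="full")
        scores = pca.fit_transform(X)
        k = self.n_components or pca.components_.shape[0]
        self.mean_structure_ = pca.mean_
        self.modes_ = pca.components_[:k]
        self.eigenvalues_ = pca.explained_variance_[:k]
        # fractions are over the total variance, so they sum to 1 when untruncated
        self.variance_fractions_ = pca.explained_variance_ratio_[:k]
        self.scores_ = scores[:, :k]
        self.heavy_indices_ = heavy
        return self

    def transform(self, traj: CoordinateTrajectory) -> np.ndarray:
        sel = AtomSelection(indices=self.heavy_indices_, label="heavy")
        ref = self.mean_structure_.reshape(-1, 3)
        out = np.empty((traj.n_frames, self.modes_.shape[0]))
        for f in range(traj.n_frames):
            R, t, _ = kabsch_superpose(traj.xyz[f][self.heavy_indices_], ref, None)
            x = (traj.xyz[f][self.heavy_indices_] @ R.T + t).ravel()
            out[f] = self.modes_ @ (x - self.mean_structure_)
        return out


def pca_heavy_atoms(traj: CoordinateTrajectory) -> PCAResult:
    """Functional wrapper over :class:`TrajectoryPCA` (all components)."""
    est = TrajectoryPCA().fit(traj)
    return PCAResult(
        mean_structure=est.mean_structure_,
        modes=est.modes_,
        variance_fractions=est.variance_fractions_,
        eigenvalues=est.eigenvalues_,
    )
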