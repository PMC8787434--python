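"""2D free-energy landscapes over the feature plane.

The surface is the Boltzmann inversion of a pooled 2D histogram,
``F = -kT ln(p / p_max)``, so the deepest occupied bin sits at F = 0 and
empty bins are flagged infinite. Basin detection finds local minima of F
on the grid and thins them by a minimum separation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .trajectory import FeatureTrajectory

__all__ = ["LandscapeGrid", "free_energy_2d", "locate_minima", "write_landscape"]


@dataclass
class LandscapeGrid:
    """Binned free-energy surface F(x, y) in kT units over explicit bin edges."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray
    counts: np.ndarray
    kT: float = 1.0

    def __post_init__(self) -> None:
        if self.free_energy.shape != (self.x_edges.size - 1, self.y_edges.size - 1):
            raise ValueError("free_energy shape does not match bin edges")
        finite = self.free_energy[np.isfinite(self.free_energy)]
        if finite.size and abs(finite.min()) > 1e-9:
            raise ValueError("minimum finite free energy must be zero")

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])


def free_energy_2d(
    features: list[FeatureTrajectory] | FeatureTrajectory,
    n_bins: tuple[int, int] = (80, 80),
    kT: float = 1.0,
    range_pad: float = 0.02,
) -> LandscapeGrid:
    """Pooled-histogram free energy ``F = -kT ln(p / p_max)`` on an
    ``n_bins`` grid spanning the pooled data range padded by ``range_pad``.

    Pooling is order-invariant; empty bins get ``F = inf``.
    """
    if isinstance(features, FeatureTrajectory):
        features = [features]
    if not features or all(f.n_frames == 0 for f in features):
        raise ValueError("need at least one non-empty feature trajectory")
    data = np.vstack([f.values[:, :2] for f in features if f.n_frames])
    lo = data.min(axis=0)
    hi = data.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    lo = lo - range_pad * span
    hi = hi + range_pad * span
    counts, x_edges, y_edges = np.histogram2d(
        data[:, 0], data[:, 1], bins=n_bins, range=[(lo[0], hi[0]), (lo[1], hi[1])]
    )
    with np.errstate(divide="ignore"):
        F = -kT * np.log(counts / counts.max())
    F[counts == 0] = np.inf
    return LandscapeGrid(
        x_edges=x_edges, y_edges=y_edges, free_energy=F, counts=counts, kT=kT
    )


@dataclass
class BasinSet:
    """Ordered basin centers from a landscape minima search."""

    centers: np.ndarray  # (n, 2) bin-center coordinates
    free_energies: np.ndarray
    bin_indices: np.ndarray  # (n, 2) integer grid indices
    incomplete: bool = False  # True when fewer minima than requested exist


def locate_minima(
    grid: LandscapeGrid, n_minima: int, min_separation: float = 1.0
) -> BasinSet:
    """Local minima of F (4-neighborhood), ascending in F, greedily thinned.

    A candidate closer (Euclidean, in bin-index units) than
    ``min_separation`` to an already accepted minimum is discarded. When
    fewer than ``n_minima`` survive, the result carries ``incomplete=True``.
    """
    F = grid.free_energy
    finite = np.isfinite(F)
    if finite.sum() < 1:
        raise ValueError("grid has no finite cells")
    padded = np.pad(F, 1, constant_values=np.inf)
    center = padded[1:-1, 1:-1]
    is_min = (
        finite
        & (center <= padded[:-2, 1:-1])
        & (center <= padded[2:, 1:-1])
        & (center <= padded[1:-1, :-2])
        & (center <= padded[1:-1, 2:])
    )
    ii, jj = np.nonzero(is_min)
    order = np.lexsort((jj, ii, F[ii, jj]))
    accepted: list[tuple[int, int]] = []
    for k in order:
        cand = (int(ii[k]), int(jj[k]))
        if all(
            np.hypot(cand[0] - a[0], cand[1] - a[1]) >= min_separation
            for a in accepted
        ):
            accepted.append(cand)
        if len(accepted) == n_minima:
            break
    idx = np.asarray(accepted, dtype=int).reshape(-1, 2)
    centers = np.column_stack(
        [grid.x_centers[idx[:, 0]], grid.y_centers[idx[:, 1]]]
    ) if idx.size else np.empty((0, 2))
    return BasinSet(
        centers=centers,
        free_energies=F[idx[:, 0], idx[:, 1]] if idx.size else np.empty(0),
        bin_indices=idx,
        incomplete=len(accepted) < n_minima,
    )


def write_landscape(grid: LandscapeGrid, path: str | Path) -> Path:
    """Tab-delimited F matrix plus a JSON sidecar with edges and kT."""
    path = Path(path)
    np.savetxt(path, grid.free_energy, delimiter="\t", fmt="%.8g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "x_edges": grid.x_edges.tolist(),
                "y_edges": grid.y_edges.tolist(),
                "kT": grid.kT,
            }
        )
    )
    return path
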