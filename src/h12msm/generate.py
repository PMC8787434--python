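"""Synthetic trajectory generators with planted, analytically known kinetics.

Every downstream stage of the pipeline (discretization, transition-matrix
estimation, PCCA+ coarse-graining, transition path theory) is validated
against data whose kinetic structure is known exactly:

* :func:`make_metastable_chain` plants a block-structured metastable
  Markov chain whose stationary distribution and relaxation timescales
  follow from a dense eigendecomposition.
* :func:`simulate_brownian_2d` integrates overdamped Langevin dynamics on
  a multi-well 2D potential, emulating the (RMSD, helix-12 distance)
  feature plane of a nuclear-receptor ligand-binding domain.
* :func:`make_gr_mimic_potential` builds five-well potentials whose
  ligand presets (apo / agonist / modulator / antagonist) shift the
  relative depth of the active-like and passive-antagonist-like basins.
* :func:`make_swinging_helix_trajectory` emits a toy two-segment
  coordinate trajectory whose mobile arm swings about a hinge, with
  closed-form geometry for every derived feature.

None of this replaces a molecular dynamics engine; the point is a
ground-truth oracle at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from . import _markov
from .trajectory import CoordinateTrajectory, DiscreteTrajectorySet, FeatureTrajectory

__all__ = [
    "GroundTruthChain",
    "SyntheticPotential",
    "make_metastable_chain",
    "sample_discrete_chain",
    "simulate_brownian_2d",
    "make_gr_mimic_potential",
    "make_swinging_helix_trajectory",
    "GR_PRESETS",
    "WELL_LABELS",
]


@dataclass
class GroundTruthChain:
    """A planted microstate Markov chain with known macrostate structure."""

    n_states: int
    transition_matrix: np.ndarray
    block_labels: np.ndarray
    lag_unit: float = 1.0

    def __post_init__(self) -> None:
        self.transition_matrix = _markov.assert_stochastic(
            self.transition_matrix, tol=1e-12
        )
        self.block_labels = np.asarray(self.block_labels, dtype=int)
        if self.block_labels.size != self.n_states:
            raise ValueError("block_labels must have one entry per state")

    @cached_property
    def stationary_distribution(self) -> np.ndarray:
        return _markov.stationary_distribution(self.transition_matrix)

    def implied_timescales(self, n_timescales: int) -> np.ndarray:
        return _markov.implied_timescales(
            self.transition_matrix, n_timescales, lag=self.lag_unit
        )

    @property
    def n_macrostates(self) -> int:
        return int(self.block_labels.max()) + 1

    def macro_stationary_mass(self) -> np.ndarray:
        """Analytic stationary probability mass per planted macrostate."""
        pi = self.stationary_distribution
        return np.bincount(self.block_labels, weights=pi, minlength=self.n_macrostates)


def make_metastable_chain(
    n_macro: int,
    micro_per_macro: int,
    intra_p: float,
    inter_p: float,
    seed: int,
) -> GroundTruthChain:
    """Plant a row-stochastic chain with dense intra-block and sparse inter-block mass.

    Raw weights are drawn uniformly in (0, 1] and symmetrized, intra-block
    entries scaled by ``intra_p`` and inter-block entries by ``inter_p``,
    then each row is normalized. The symmetric weight matrix makes the
    planted chain reversible (pi_i proportional to the row sums), matching
    the detailed balance that physical conformational kinetics obey;
    ``inter_p << intra_p`` yields metastability and any ``inter_p > 0``
    guarantees irreducibility.
    """
    if n_macro < 2:
        raise ValueError("n_macro must be at least 2")
    if micro_per_macro < 1:
        raise ValueError("micro_per_macro must be positive")
    if not (0 < intra_p <= 1) or not (0 <= inter_p <= 1):
        raise ValueError("intra_p must be in (0,1] and inter_p in [0,1]")
    n = n_macro * micro_per_macro
    rng = np.random.default_rng(seed)
    W = 1.0 - rng.random((n, n))  # uniform on (0, 1]
    W = 0.5 * (W + W.T)  # reversible chain: detailed balance by construction
    labels = np.repeat(np.arange(n_macro), micro_per_macro)
    same_block = labels[:, None] == labels[None, :]
    W = np.where(same_block, W * intra_p, W * inter_p)
    rowsums = W.sum(axis=1)
    if np.any(rowsums <= 0):
        raise ValueError("row normalization failed: a row has zero total weight")
    T = W / rowsums[:, None]
    return GroundTruthChain(n_states=n, transition_matrix=T, block_labels=labels)


def sample_discrete_chain(
    chain: GroundTruthChain,
    n_trajs: int,
    n_steps: int,
    seed: int,
    start: int | str = "stationary",
) -> DiscreteTrajectorySet:
    """Sample ``n_trajs`` realizations of ``n_steps`` transitions each.

    ``start`` is either a state index (all trajectories start there) or
    ``"stationary"`` (initial states drawn from the analytic stationary
    distribution). Each output sequence has ``n_steps + 1`` labels.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    rng = np.random.default_rng(seed)
    n = chain.n_states
    if isinstance(start, str):
        if start != "stationary":
            raise ValueError(f"start must be a state index or 'stationary', got {start!r}")
        pi = chain.stationary_distribution
        states = rng.choice(n, size=n_trajs, p=pi)
    else:
        start = int(start)
        if not (0 <= start < n):
            raise ValueError(f"invalid start state {start}: must be in [0, {n})")
        states = np.full(n_trajs, start, dtype=int)

    cum = np.cumsum(chain.transition_matrix, axis=1)
    cum[:, -1] = 1.0  # guard against rounding
    out = np.empty((n_trajs, n_steps + 1), dtype=int)
    out[:, 0] = states
    for t in range(1, n_steps + 1):
        u = rng.random(n_trajs)
        states = (cum[states] > u[:, None]).argmax(axis=1)
        out[:, t] = states
    return DiscreteTrajectorySet(
        trajectories=list(out),
        n_states=n,
        step_unit=chain.lag_unit,
        meta={"seed": seed, "start": str(start)},
    )


# ---------------------------------------------------------------------------
# Brownian dynamics on multi-well 2D potentials
# ---------------------------------------------------------------------------

#: basin labels in pipeline order; S0 is the source of the headline A->B analysis
WELL_LABELS = ("S0", "S1", "S2", "S3", "S4")


@dataclass
class SyntheticPotential:
    """Sum-of-Gaussian-wells 2D potential.

    ``wells`` holds ``(center_x, center_y, depth, width)`` per basin,
    depth in units of kT (positive = attractive well of that depth) and
    width the isotropic Gaussian sigma in feature units:

        U(x, y) = -sum_k depth_k * exp(-|r - c_k|^2 / (2 width_k^2))

    An optional flat-bottomed quartic confinement
    ``((x - x0)/sx)^4 + ((y - y0)/sy)^4`` keeps trajectories inside the
    physically meaningful feature range (RMSD and distances are bounded
    observables) while leaving the well region essentially untouched.
    """

    wells: list[tuple[float, float, float, float]]
    kT: float = 1.0
    diffusion_D: float = 1.0
    dt: float = 0.01
    labels: tuple[str, ...] = ()
    confinement: tuple[float, float, float, float] | None = None  # (x0, y0, sx, sy)
    harmonic: tuple[float, float, float] | None = None  # (x0, y0, k): U += k/2 r^2

    def __post_init__(self) -> None:
        for w in self.wells:
            if len(w) != 4:
                raise ValueError("each well is (center_x, center_y, depth, width)")
            if w[2] <= 0 or w[3] <= 0:
                raise ValueError("well depths and widths must be positive")
        if self.kT <= 0 or self.diffusion_D <= 0 or self.dt <= 0:
            raise ValueError("kT, diffusion_D and dt must be positive")
        if not self.labels:
            self.labels = tuple(f"S{i}" for i in range(len(self.wells)))

    def energy(self, xy: np.ndarray) -> np.ndarray:
        """U at points of shape (..., 2), in kT-compatible energy units."""
        xy = np.asarray(xy, dtype=float)
        U = np.zeros(xy.shape[:-1])
        for cx, cy, depth, width in self.wells:
            d2 = (xy[..., 0] - cx) ** 2 + (xy[..., 1] - cy) ** 2
            U -= depth * np.exp(-d2 / (2.0 * width**2))
        if self.confinement is not None:
            x0, y0, sx, sy = self.confinement
            U += ((xy[..., 0] - x0) / sx) ** 4 + ((xy[..., 1] - y0) / sy) ** 4
        if self.harmonic is not None:
            x0, y0, k = self.harmonic
            U += 0.5 * k * ((xy[..., 0] - x0) ** 2 + (xy[..., 1] - y0) ** 2)
        return U

    def gradient(self, xy: np.ndarray) -> np.ndarray:
        """dU/d(x,y) at points of shape (..., 2)."""
        xy = np.asarray(xy, dtype=float)
        g = np.zeros_like(xy)
        for cx, cy, depth, width in self.wells:
            dx = xy[..., 0] - cx
            dy = xy[..., 1] - cy
            common = (depth / width**2) * np.exp(
                -(dx**2 + dy**2) / (2.0 * width**2)
            )
            g[..., 0] += common * dx
            g[..., 1] += common * dy
        if self.confinement is not None:
            x0, y0, sx, sy = self.confinement
            g[..., 0] += 4.0 * (xy[..., 0] - x0) ** 3 / sx**4
            g[..., 1] += 4.0 * (xy[..., 1] - y0) ** 3 / sy**4
        if self.harmonic is not None:
            x0, y0, k = self.harmonic
            g[..., 0] += k * (xy[..., 0] - x0)
            g[..., 1] += k * (xy[..., 1] - y0)
        return g

    def well_centers(self) -> np.ndarray:
        return np.asarray([[w[0], w[1]] for w in self.wells])


def simulate_brownian_2d(
    potential: SyntheticPotential,
    n_trajs: int,
    n_steps: int,
    seed: int,
    burn_in_fraction: float = 0.1,
    start: np.ndarray | str = "wells",
) -> list[FeatureTrajectory]:
    """Overdamped Langevin (Euler–Maruyama) sampling of a 2D potential.

    Update per coordinate: ``x <- x - (D*dt/kT) * dU/dx + sqrt(2*D*dt) * g``
    with standard-normal ``g``. The first ``burn_in_fraction`` of steps is
    discarded. ``start`` places trajectory i at well ``i % n_wells`` center
    ("wells"), at the origin if the potential has no wells, or at explicit
    (n_trajs, 2) positions.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    if not (0 <= burn_in_fraction < 1):
        raise ValueError("burn_in_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    D, dt, kT = potential.diffusion_D, potential.dt, potential.kT
    drift = D * dt / kT
    sigma = np.sqrt(2.0 * D * dt)

    if isinstance(start, str):
        if start != "wells":
            raise ValueError("start must be 'wells' or an (n_trajs, 2) array")
        centers = potential.well_centers()
        if centers.size:
            xy = centers[np.arange(n_trajs) % len(centers)].astype(float).copy()
        else:
            xy = np.zeros((n_trajs, 2))
    else:
        xy = np.array(start, dtype=float).reshape(n_trajs, 2).copy()

    n_burn = int(burn_in_fraction * n_steps)
    n_keep = n_steps - n_burn + 1
    out = np.empty((n_trajs, n_keep, 2))
    k = 0
    for t in range(n_steps + 1):
        if t >= n_burn:
            out[:, k] = xy
            k += 1
        if t == n_steps:
            break
        noise = rng.standard_normal((n_trajs, 2))
        with np.errstate(over="ignore", invalid="ignore"):
            xy = xy - drift * potential.gradient(xy) + sigma * noise
        if not np.all(np.isfinite(xy)):
            raise FloatingPointError(
                "Brownian step produced non-finite coordinates; use a smaller dt"
            )
    return [
        FeatureTrajectory(
            values=out[i],
            feature_names=("rmsd", "distance"),
            frame_interval=dt,
        )
        for i in range(n_trajs)
    ]


# Five basins on the (RMSD-like, distance-like) plane shared by all presets.
# S0 is the compact starting basin, S3 the active/agonist-like basin (helix 12
# anchored against the body, short H12 distance in the real receptor maps here
# to the lower corridor), S4 the passive-antagonist-like basin (helix 12 folded
# into the coactivator groove). S1 and S2 are alternative intermediate
# corridors between S0 and the terminal basins.
_WELL_CENTERS = (
    (3.0, 8.0),   # S0 source basin
    (1.5, 19.0),  # S1 left-corridor intermediate
    (4.5, 19.0),  # S2 right-corridor intermediate
    (3.0, 30.0),  # S3 active-like
    (5.0, 36.0),  # S4 passive-antagonist-like
)
_WELL_WIDTH = 1.4
_CONFINEMENT = (3.0, 22.0, 2.8, 14.0)

#: per-preset well depths in kT, ordered S0..S4 — illustrative constants whose
#: only contract is qualitative: agonist deepens the active-like basin (S3) and
#: routes flux through the S1 corridor; antagonist/modulator deepen the
#: passive-antagonist-like basin (S4) and route flux through the S2 corridor.
GR_PRESETS: dict[str, tuple[float, ...]] = {
    "apo": (3.0, 2.8, 1.0, 2.0, 2.2),
    "agonist": (3.0, 3.2, 0.8, 4.5, 2.5),
    "modulator": (2.8, 1.0, 3.0, 2.0, 4.0),
    "antagonist": (3.0, 0.8, 3.2, 1.5, 4.5),
}

#: index of the passive-antagonist-like well in every preset
PASSIVE_WELL_INDEX = 4
#: index of the active/agonist-like well
ACTIVE_WELL_INDEX = 3


def make_gr_mimic_potential(preset: str) -> SyntheticPotential:
    """Five-well potential emulating ligand-dependent helix-12 landscapes.

    Presets shift basin depths only: the antagonist and modulator presets
    deepen the passive-antagonist-like basin S4, the agonist preset the
    active-like basin S3, mirroring the population shifts that different
    ligand classes induce in the receptor's conformational ensemble.
    """
    if preset not in GR_PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; valid presets: {sorted(GR_PRESETS)}"
        )
    depths = GR_PRESETS[preset]
    wells = [
        (cx, cy, depth, _WELL_WIDTH)
        for (cx, cy), depth in zip(_WELL_CENTERS, depths)
    ]
    return SyntheticPotential(
        wells=wells,
        kT=1.0,
        diffusion_D=1.0,
        dt=0.05,
        labels=WELL_LABELS,
        confinement=_CONFINEMENT,
    )


# ---------------------------------------------------------------------------
# Toy swinging-helix coordinate trajectories
# ---------------------------------------------------------------------------

_N_BODY = 20
_N_ARM = 11
_SPACING = 1.5


def _zigzag(n: int, amplitude: float = 0.5) -> np.ndarray:
    """Alternating out-of-plane offsets with exactly zero mean."""
    z = amplitude * (-1.0) ** np.arange(n)
    return z - z.mean()


def _helix_template() -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Rigid body segment along -x, arm segment along +x, hinge at the origin.

    Both segments carry a zero-mean zigzag in z so the structures are
    never collinear, while segment centroids stay exactly in the swing
    plane (z = 0), keeping the arm-distance geometry closed-form.
    """
    body = np.zeros((_N_BODY, 3))
    body[:, 0] = -_SPACING * np.arange(1, _N_BODY + 1)
    body[:, 2] = _zigzag(_N_BODY)
    arm = np.zeros((_N_ARM, 3))
    arm[:, 0] = _SPACING * np.arange(1, _N_ARM + 1)
    arm[:, 2] = _zigzag(_N_ARM)
    n = _N_BODY + _N_ARM
    atoms = pd.DataFrame(
        {
            "name": ["CA"] * n,
            "resid": np.arange(1, n + 1),
            "resname": ["BOD"] * _N_BODY + ["ARM"] * _N_ARM,
            "element": ["C"] * n,
            "is_ca": [True] * n,
            "is_heavy": [True] * n,
        }
    )
    return body, arm, atoms


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    M = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(M)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def make_swinging_helix_trajectory(
    n_frames: int | None = None,
    swing_angles: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    global_rigid_motion: bool = False,
) -> CoordinateTrajectory:
    """Toy trajectory: a fixed 20-atom body plus an 11-atom arm that swings
    in the x-y plane by ``swing_angles[t]`` about the hinge at the origin.

    ``swing_angles`` (radians) defaults to zeros of length ``n_frames``.
    Optional isotropic Gaussian coordinate noise (``noise_sd``) and a
    random global rigid motion per frame exercise superposition-invariant
    featurization.
    """
    if swing_angles is None:
        if n_frames is None or n_frames < 1:
            raise ValueError("provide swing_angles or n_frames >= 1")
        swing_angles = np.zeros(n_frames)
    swing_angles = np.asarray(swing_angles, dtype=float)
    if swing_angles.ndim != 1 or swing_angles.size == 0:
        raise ValueError("swing_angles must be a non-empty 1D sequence")
    if not np.all(np.isfinite(swing_angles)):
        raise ValueError("swing_angles must be finite")
    if n_frames is not None and n_frames != swing_angles.size:
        raise ValueError("n_frames does not match swing_angles length")

    rng = np.random.default_rng(seed)
    body, arm, atoms = _helix_template()
    frames = np.empty((swing_angles.size, _N_BODY + _N_ARM, 3))
    for t, theta in enumerate(swing_angles):
        c, s = np.cos(theta), np.sin(theta)
        Rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        coords = np.vstack([body, arm @ Rz.T])
        if noise_sd > 0:
            coords = coords + rng.normal(0.0, noise_sd, coords.shape)
        if global_rigid_motion:
            coords = coords @ _random_rotation(rng).T + rng.normal(0.0, 5.0, 3)
        frames[t] = coords
    return CoordinateTrajectory(xyz=frames, atoms=atoms)


def helix_arm_body_distance(theta: float, anchor_index: int = 0) -> float:
    """Closed-form distance between the arm centroid and a body anchor atom.

    With the arm centroid at radius r from the hinge at angle ``theta``
    (in the z = 0 plane) and the anchor at distance a along -x with
    out-of-plane offset z0, the law of cosines gives
    ``d^2 = a^2 + r^2 + 2 a r cos(theta) + z0^2``.
    """
    r = _SPACING * np.mean(np.arange(1, _N_ARM + 1))
    a = _SPACING * (anchor_index + 1)
    z0 = _zigzag(_N_BODY)[anchor_index]
    return float(np.sqrt(a**2 + r**2 + 2 * a * r * np.cos(theta) + z0**2))
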