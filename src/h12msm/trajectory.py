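"""Trajectory containers and plain-text formats.

Three in-memory containers travel through the pipeline:

* :class:`CoordinateTrajectory` — ordered frames of labeled 3D atom
  coordinates (Å), the raw conformational ensemble.
* :class:`FeatureTrajectory` — per-frame low-dimensional feature vectors
  (e.g. backbone RMSD and a helix-12 center-of-mass distance) that feed
  the free-energy landscapes and the microstate discretization.
* :class:`DiscreteTrajectorySet` — integer microstate label sequences,
  the input to transition counting.

File formats are deliberately text-only: multi-model PDB, XYZ,
tab-delimited feature tables and one-integer-per-line discrete
trajectories with a JSON sidecar.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CoordinateTrajectory",
    "AtomSelection",
    "FeatureTrajectory",
    "DiscreteTrajectorySet",
    "parse_selection",
    "read_trajectory",
    "write_trajectory",
    "read_features",
    "write_features",
    "read_dtrajs",
    "write_dtrajs",
]

# Monoisotopic-ish masses for mass-weighted centroids; anything absent
# falls back to geometric weighting.
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38,
}

_ATOM_COLUMNS = ("name", "resid", "resname", "element", "is_ca", "is_heavy")


@dataclass
class CoordinateTrajectory:
    """Ordered frames of 3D coordinates with per-atom metadata.

    Parameters
    ----------
    xyz : ndarray, shape (n_frames, n_atoms, 3)
        Coordinates in Å. All frames share one atom ordering.
    atoms : pandas.DataFrame
        One row per atom with columns ``name``, ``resid``, ``resname``,
        ``element``, ``is_ca``, ``is_heavy``.
    frame_interval : float
        Time between consecutive frames (arbitrary units).
    """

    xyz: np.ndarray
    atoms: pd.DataFrame
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise ValueError(f"xyz must have shape (n_frames, n_atoms, 3), got {self.xyz.shape}")
        if self.xyz.size and not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates contain non-finite values")
        missing = [c for c in _ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table missing columns {missing}")
        if len(self.atoms) != self.xyz.shape[1]:
            raise ValueError("atom table length does not match coordinate atom count")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[1]

    def select(self, spec: str) -> "AtomSelection":
        """Resolve a selection spec (``ca:581-777`` / ``res:754-764`` / ``idx:0,5,9-20``)."""
        return parse_selection(spec, self.atoms)


@dataclass(frozen=True)
class AtomSelection:
    """An ordered, duplicate-free set of atom indices with a label."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1 or idx.size == 0:
            raise ValueError("selection must contain at least one atom index")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("selection indices must be strictly increasing and unique")
        if idx[0] < 0:
            raise ValueError("selection indices must be non-negative")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)

    def validate_for(self, n_atoms: int) -> None:
        if self.indices[-1] >= n_atoms:
            raise ValueError(
                f"selection '{self.label}' index {self.indices[-1]} out of range "
                f"for {n_atoms} atoms"
            )


def _parse_ranges(text: str) -> list[int]:
    out: list[int] = []
    for tok in text.split(","):
        tok = tok.strip()
        if not tok:
            continue
        if "-" in tok:
            lo, hi = tok.split("-")
            out.extend(range(int(lo), int(hi) + 1))
        else:
            out.append(int(tok))
    return out


def parse_selection(spec: str, atoms: pd.DataFrame) -> AtomSelection:
    """Resolve ``ca:LO-HI`` (Cα atoms by residue id), ``res:LO-HI`` (all atoms
    by residue id) or ``idx:...`` (0-based atom indices) against an atom table."""
    m = re.fullmatch(r"(ca|res|idx)\s*:\s*([\d,\-\s]+)", spec.strip())
    if not m:
        raise ValueError(f"unrecognized selection spec {spec!r}; use ca:, res: or idx:")
    kind, body = m.group(1), m.group(2)
    values = _parse_ranges(body)
    if kind == "idx":
        idx = np.unique(np.asarray(values, dtype=int))
    else:
        mask = atoms["resid"].isin(values).to_numpy()
        if kind == "ca":
            mask &= atoms["is_ca"].to_numpy()
        idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"selection {spec!r} matched no atoms")
    return AtomSelection(indices=idx, label=spec)


@dataclass
class FeatureTrajectory:
    """Per-frame feature vectors of fixed width (finite values)."""

    values: np.ndarray
    feature_names: tuple[str, ...] = ()
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("feature values contain non-finite entries")
        if not self.feature_names:
            self.feature_names = tuple(
                f"feat_{i + 1}" for i in range(self.values.shape[1])
            )
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must match feature width")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class DiscreteTrajectorySet:
    """A set of integer microstate label sequences over a common state space."""

    trajectories: list[np.ndarray]
    n_states: int
    step_unit: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        trajs = []
        for i, t in enumerate(self.trajectories):
            t = np.asarray(t, dtype=int)
            if t.ndim != 1 or t.size == 0:
                raise ValueError(f"trajectory {i} must be a non-empty 1D label sequence")
            if t.min() < 0 or t.max() >= self.n_states:
                raise ValueError(
                    f"trajectory {i} has labels outside [0, {self.n_states})"
                )
            trajs.append(t)
        self.trajectories = trajs

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def total_frames(self) -> int:
        return int(sum(t.size for t in self.trajectories))


# ---------------------------------------------------------------------------
# Coordinate trajectory formats: multi-model PDB and XYZ
# ---------------------------------------------------------------------------

def _empty_atom_table(n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": ["X"] * n,
            "resid": np.arange(1, n + 1),
            "resname": ["UNK"] * n,
            "element": ["C"] * n,
            "is_ca": [False] * n,
            "is_heavy": [True] * n,
        }
    )


def _parse_pdb(text: str) -> CoordinateTrajectory:
    frames: list[list[tuple[float, float, float]]] = []
    atom_rows: list[dict] = []
    current: list[tuple[float, float, float]] | None = None
    in_model = False
    model_index = 0
    saw_model_record = False

    def close_model(idx: int) -> None:
        nonlocal current
        if current is None:
            return
        if frames and len(current) != len(frames[0]):
            raise ValueError(
                f"model {idx}: atom count {len(current)} differs from "
                f"model 1 ({len(frames[0])})"
            )
        if not current:
            raise ValueError(f"model {idx}: no ATOM records")
        frames.append(current)
        current = None

    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model_record = True
            if in_model:
                raise ValueError(f"model {model_index}: MODEL record before ENDMDL")
            in_model = True
            model_index += 1
            current = []
        elif rec == "ENDMDL":
            if not in_model:
                raise ValueError(
                    f"model {model_index + 1}: ENDMDL without matching MODEL"
                )
            in_model = False
            close_model(model_index)
        elif rec in ("ATOM", "HETATM"):
            if current is None:
                if saw_model_record:
                    raise ValueError(
                        f"model {model_index}: ATOM record outside MODEL/ENDMDL block"
                    )
                model_index = 1
                current = []
            try:
                x = float(line[30:38]); y = float(line[38:46]); z = float(line[46:54])
            except ValueError as exc:
                raise ValueError(f"model {model_index}: malformed coordinates: {line!r}") from exc
            current.append((x, y, z))
            if not frames:  # metadata comes from the first model
                name = line[12:16].strip()
                element = line[76:78].strip() or re.sub(r"[^A-Za-z]", "", name)[:1]
                atom_rows.append(
                    {
                        "name": name,
                        "resid": int(line[22:26]),
                        "resname": line[17:20].strip(),
                        "element": element.upper(),
                        "is_ca": name == "CA",
                        "is_heavy": element.upper() != "H",
                    }
                )
    if in_model:
        raise ValueError(f"model {model_index}: missing ENDMDL")
    if current is not None:
        close_model(model_index)
    if not frames:
        raise ValueError("no ATOM records found")
    xyz = np.asarray(frames, dtype=float)
    return CoordinateTrajectory(xyz=xyz, atoms=pd.DataFrame(atom_rows))


def _parse_xyz(text: str) -> CoordinateTrajectory:
    lines = text.splitlines()
    pos = 0
    frames = []
    elements: list[str] | None = None
    model_index = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        model_index += 1
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise ValueError(f"model {model_index}: expected atom count line") from exc
        body = lines[pos + 2 : pos + 2 + n]
        if len(body) < n:
            raise ValueError(f"model {model_index}: truncated frame ({len(body)}/{n} atoms)")
        elems, coords = [], []
        for ln in body:
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(f"model {model_index}: malformed XYZ line {ln!r}")
            elems.append(parts[0].upper())
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        if elements is None:
            elements = elems
        elif len(elems) != len(elements):
            raise ValueError(
                f"model {model_index}: atom count {len(elems)} differs from model 1 "
                f"({len(elements)})"
            )
        frames.append(coords)
        pos += 2 + n
    if not frames:
        raise ValueError("no frames found in XYZ input")
    atoms = _empty_atom_table(len(elements))
    atoms["element"] = elements
    atoms["name"] = elements
    atoms["is_heavy"] = [e != "H" for e in elements]
    return CoordinateTrajectory(xyz=np.asarray(frames, dtype=float), atoms=atoms)


def read_trajectory(path: str | Path, format: str = "pdb_multimodel") -> CoordinateTrajectory:
    """Read a coordinate trajectory from a multi-model PDB or XYZ file.

    Frames are returned in file order; PDB populates full atom metadata,
    XYZ only the element column. Inconsistent atom counts across models
    raise a parse error naming the offending model index.
    """
    text = Path(path).read_text()
    if format == "pdb_multimodel":
        return _parse_pdb(text)
    if format == "xyz":
        return _parse_xyz(text)
    raise ValueError(f"unknown trajectory format {format!r}; use pdb_multimodel or xyz")


def write_trajectory(
    traj: CoordinateTrajectory, path: str | Path, format: str = "pdb_multimodel"
) -> Path:
    """Write a trajectory as multi-model PDB (MODEL/ENDMDL) or XYZ text."""
    path = Path(path)
    lines: list[str] = []
    if format == "pdb_multimodel":
        at = traj.atoms
        for f in range(traj.n_frames):
            lines.append(f"MODEL     {f + 1:4d}")
            for i in range(traj.n_atoms):
                x, y, z = traj.xyz[f, i]
                name = str(at["name"].iat[i])
                pad = name if len(name) >= 4 else f" {name:<3s}"
                lines.append(
                    f"ATOM  {i + 1:5d} {pad:<4s} {str(at['resname'].iat[i]):<3s} A"
                    f"{int(at['resid'].iat[i]):4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{str(at['element'].iat[i]):>2s}"
                )
            lines.append("ENDMDL")
        lines.append("END")
    elif format == "xyz":
        for f in range(traj.n_frames):
            lines.append(str(traj.n_atoms))
            lines.append(f"frame {f}")
            for i in range(traj.n_atoms):
                x, y, z = traj.xyz[f, i]
                lines.append(f"{traj.atoms['element'].iat[i]} {x:.6f} {y:.6f} {z:.6f}")
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Feature and discrete-trajectory text formats
# ---------------------------------------------------------------------------

def write_features(feats: FeatureTrajectory, path: str | Path) -> Path:
    """Tab-delimited feature table: header, then frame index plus one column per feature."""
    path = Path(path)
    df = pd.DataFrame(feats.values, columns=list(feats.feature_names))
    df.insert(0, "frame", np.arange(feats.n_frames))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_features(path: str | Path, frame_interval: float = 1.0) -> FeatureTrajectory:
    df = pd.read_csv(path, sep="\t")
    names = [c for c in df.columns if c != "frame"]
    return FeatureTrajectory(
        values=df[names].to_numpy(dtype=float),
        feature_names=tuple(names),
        frame_interval=frame_interval,
    )


def write_dtrajs(dtrajs: DiscreteTrajectorySet, out_dir: str | Path, stem: str = "dtraj") -> list[Path]:
    """One integer per line, one file per trajectory, plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, t in enumerate(dtrajs.trajectories):
        p = out_dir / f"{stem}_{i:03d}.txt"
        np.savetxt(p, t, fmt="%d")
        paths.append(p)
    sidecar = out_dir / f"{stem}.json"
    sidecar.write_text(
        json.dumps(
            {
                "n_states": dtrajs.n_states,
                "step_unit": dtrajs.step_unit,
                "n_trajectories": len(dtrajs),
                "files": [p.name for p in paths],
                **dtrajs.meta,
            },
            indent=2,
        )
    )
    return paths


def read_dtrajs(out_dir: str | Path, stem: str = "dtraj") -> DiscreteTrajectorySet:
    out_dir = Path(out_dir)
    sidecar = json.loads((out_dir / f"{stem}.json").read_text())
    trajs = [
        np.loadtxt(out_dir / name, dtype=int, ndmin=1) for name in sidecar["files"]
    ]
    return DiscreteTrajectorySet(
        trajectories=trajs,
        n_states=int(sidecar["n_states"]),
        step_unit=float(sidecar["step_unit"]),
    )
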