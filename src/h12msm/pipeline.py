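"""End-to-end orchestration: generate/ingest -> featurize -> landscape ->
discretize -> validate -> estimate -> coarse-grain -> TPT -> report.

A single flat config drives every stage; all randomness derives from one
seed, so a fixed config reproduces byte-identical numeric tables. The
report bundle mirrors the analysis products of the receptor study: the
free-energy landscape, the implied-timescale scan, the CK comparison,
macrostate populations and lifetimes, and the ranked pathway table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import __version__
from .generate import (
    GR_PRESETS,
    WELL_LABELS,
    make_gr_mimic_potential,
    make_metastable_chain,
    sample_discrete_chain,
    simulate_brownian_2d,
)
from .kinetics import (
    MacrostateModel,
    PathwayDecomposition,
    coarse_grain_flux,
    decompose_pathways,
    pcca_coarse_grain,
    reactive_flux,
)
from .landscape import free_energy_2d, write_landscape
from .msm import MarkovStateModel, kmeans_discretize
from .trajectory import DiscreteTrajectorySet, read_dtrajs, write_dtrajs
from .validate import ck_test, its_scan

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "write_pathway_table",
           "label_macrostates"]

log = logging.getLogger("h12msm")


@dataclass
class PipelineConfig:
    """Flat configuration for the full analysis.

    ``mode`` is ``"synthetic"`` (Brownian dynamics on a ligand preset),
    ``"chain"`` (a planted metastable chain sampled to discrete
    trajectories, skipping featurization) or ``"dtrajs"`` (discrete
    trajectories read from ``dtraj_dir``).
    """

    mode: str = "synthetic"
    preset: str = "antagonist"
    n_traj: int = 50
    n_steps: int = 20_000
    seed: int = 0
    out_dir: str = "h12msm_out"
    # landscape
    landscape_bins: tuple[int, int] = (80, 80)
    kT: float = 1.0
    # discretization
    n_microstates: int = 100
    # validation / estimation
    lag: int = 5
    lag_scan: tuple[int, ...] = (1, 2, 5, 10, 20)
    ck_factors: tuple[int, ...] = (1, 2, 3, 4)
    bayes_samples: int = 50
    force_lag: bool = False
    # coarse-graining / TPT
    n_macrostates: int = 5
    source_label: str = "S0"
    target_label: str = "S4"
    max_paths: int = 10
    # planted-chain mode
    chain_intra_p: float = 0.2
    chain_inter_p: float = 0.002
    chain_micro_per_macro: int = 10
    dtraj_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "chain", "dtrajs"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "synthetic" and self.preset not in GR_PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.mode == "dtrajs":
            if not self.dtraj_dir or not Path(self.dtraj_dir).is_dir():
                raise ValueError(f"dtraj_dir {self.dtraj_dir!r} does not exist")
        for name in ("n_traj", "n_steps", "n_microstates", "lag", "n_macrostates",
                     "max_paths", "bayes_samples"):
            if getattr(self, name) < 0 or (name != "bayes_samples" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = tomllib.loads(Path(path).read_text())
        for key in ("landscape_bins", "lag_scan", "ck_factors"):
            if key in data:
                data[key] = tuple(data[key])
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Per-stage artifact paths plus the in-memory summary."""

    files: dict[str, Path]
    summary: dict
    macrostates: MacrostateModel
    decomposition: PathwayDecomposition
    macro_labels: tuple[str, ...]
    config: PipelineConfig


def label_macrostates(
    macro: MacrostateModel,
    micro_centers: np.ndarray,
    well_centers: np.ndarray,
    well_labels: tuple[str, ...] = WELL_LABELS,
) -> tuple[str, ...]:
    """Assign each macrostate the label of the nearest potential well.

    Macrostate positions are membership- and population-weighted means of
    the microstate centers; the macrostate-to-well matching is one-to-one
    (Hungarian assignment on squared distances) when the counts allow.
    """
    # membership-weighted mean feature position per macrostate
    weights = macro.memberships.T  # (n_macro, n_micro)
    pos = (weights @ micro_centers) / weights.sum(axis=1, keepdims=True)
    D = ((pos[:, None, :] - well_centers[None, :, :]) ** 2).sum(axis=2)
    if pos.shape[0] <= len(well_labels):
        rows, cols = linear_sum_assignment(D)
        out = [""] * pos.shape[0]
        for r, c in zip(rows, cols):
            out[r] = well_labels[c]
        return tuple(out)
    return tuple(well_labels[j] for j in D.argmin(axis=1))


def write_pathway_table(
    decomposition: PathwayDecomposition,
    labels: tuple[str, ...],
    path: str | Path,
) -> Path:
    """Ranked pathway table: ``S0→S1→S4<TAB>58.0`` rows, descending flux."""
    path = Path(path)
    rows = decomposition.as_rows(labels)
    order = np.argsort(-decomposition.fraction_of_total, kind="stable")
    lines = ["pathway\tpercent_of_total_flux"]
    lines += [f"{rows[i][0]}\t{rows[i][1]:.1f}" for i in order]
    path.write_text("\n".join(lines) + "\n")
    return path


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis under one config; see module docstring."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    timings: dict[str, float] = {}
    rng_seed = int(config.seed)

    # --- input stage -------------------------------------------------------
    t0 = _stage("input")
    micro_centers = None
    well_centers = None
    if config.mode == "synthetic":
        potential = make_gr_mimic_potential(config.preset)
        feats = simulate_brownian_2d(
            potential, config.n_traj, config.n_steps, seed=rng_seed
        )
        well_centers = potential.well_centers()
    elif config.mode == "chain":
        chain = make_metastable_chain(
            config.n_macrostates,
            config.chain_micro_per_macro,
            config.chain_intra_p,
            config.chain_inter_p,
            seed=rng_seed,
        )
        dtrajs = sample_discrete_chain(
            chain, config.n_traj, config.n_steps, seed=rng_seed + 1
        )
    else:
        dtrajs = read_dtrajs(config.dtraj_dir)
    timings["input"] = time.perf_counter() - t0

    # --- landscape + discretization (synthetic mode only) ------------------
    if config.mode == "synthetic":
        t0 = _stage("landscape")
        grid = free_energy_2d(feats, n_bins=config.landscape_bins, kT=config.kT)
        files["landscape"] = write_landscape(grid, out / "landscape.tsv")
        timings["landscape"] = time.perf_counter() - t0

        t0 = _stage("discretize")
        disc = kmeans_discretize(
            feats, k=config.n_microstates, seed=rng_seed + 2
        )
        dtrajs = disc.dtrajs
        micro_centers = disc.centers
        write_dtrajs(dtrajs, out, stem="dtraj")
        files["dtrajs"] = out / "dtraj.json"
        timings["discretize"] = time.perf_counter() - t0

    # --- validation scan ----------------------------------------------------
    t0 = _stage("its_scan")
    scan = its_scan(
        dtrajs,
        lags=config.lag_scan,
        n_timescales=min(config.n_macrostates - 1, 4),
        bayes_samples=config.bayes_samples,
        seed=rng_seed + 3,
    )
    its_path = out / "implied_timescales.tsv"
    header = "lag\t" + "\t".join(f"t{i+1}" for i in range(scan.timescales.shape[1]))
    body = [
        str(int(lag)) + "\t" + "\t".join(f"{v:.8g}" for v in row)
        for lag, row in zip(scan.lags, scan.timescales)
    ]
    its_path.write_text(header + "\n" + "\n".join(body) + "\n")
    files["implied_timescales"] = its_path
    timings["its_scan"] = time.perf_counter() - t0

    if config.lag not in set(int(l) for l in config.lag_scan) and not config.force_lag:
        raise ValueError(
            f"lag {config.lag} was not part of the validated lag scan "
            f"{tuple(config.lag_scan)}; pass force_lag/--force to override"
        )

    # --- estimation ---------------------------------------------------------
    t0 = _stage("estimate")
    est = MarkovStateModel(lag=config.lag).fit(dtrajs)
    model = est.model_
    timings["estimate"] = time.perf_counter() - t0

    # --- coarse-graining ----------------------------------------------------
    t0 = _stage("pcca")
    macro = pcca_coarse_grain(model, config.n_macrostates)
    timings["pcca"] = time.perf_counter() - t0

    # --- CK test on the macrostate groupings --------------------------------
    t0 = _stage("ck_test")
    active = model.active_set
    sets = [
        active[np.flatnonzero(macro.crisp_assignment == m)]
        for m in range(macro.n_macrostates)
    ]
    sets = [S for S in sets if S.size]
    ck = ck_test(dtrajs, base_lag=config.lag, sets=sets, factors=config.ck_factors)
    ck_path = out / "ck_test.tsv"
    with ck_path.open("w") as fh:
        fh.write("factor\tset_from\tset_to\testimated\tpredicted\tdeviation\n")
        for fi, k in enumerate(ck.factors):
            for a in range(len(sets)):
                for b in range(len(sets)):
                    fh.write(
                        f"{int(k)}\t{a}\t{b}\t{ck.estimated[fi, a, b]:.8g}\t"
                        f"{ck.predicted[fi, a, b]:.8g}\t{ck.deviations[fi, a, b]:.8g}\n"
                    )
    files["ck_test"] = ck_path
    timings["ck_test"] = time.perf_counter() - t0

    # --- macrostate labeling ------------------------------------------------
    if config.mode == "synthetic":
        centers_active = micro_centers[model.active_set]
        macro_labels = label_macrostates(macro, centers_active, well_centers)
    else:
        macro_labels = tuple(f"S{m}" for m in range(macro.n_macrostates))

    # --- TPT ----------------------------------------------------------------
    t0 = _stage("tpt")
    try:
        src = macro_labels.index(config.source_label)
        tgt = macro_labels.index(config.target_label)
    except ValueError as exc:
        raise ValueError(
            f"source/target labels {config.source_label}/{config.target_label} "
            f"not among macrostate labels {macro_labels}"
        ) from exc
    A = np.flatnonzero(macro.crisp_assignment == src)
    B = np.flatnonzero(macro.crisp_assignment == tgt)
    flux = reactive_flux(model, A, B)
    cg = coarse_grain_flux(flux, macro, labels=macro_labels)
    decomposition = decompose_pathways(cg, max_paths=config.max_paths)
    files["pathways"] = write_pathway_table(
        decomposition, macro_labels, out / "pathways.tsv"
    )
    timings["tpt"] = time.perf_counter() - t0

    # --- report -------------------------------------------------------------
    summary = {
        "mode": config.mode,
        "preset": config.preset if config.mode == "synthetic" else None,
        "n_microstates_active": int(model.n_states),
        "lag": int(config.lag),
        "lag_time": float(model.lag_time),
        "macro_labels": list(macro_labels),
        "macro_populations": {
            lab: float(p) for lab, p in zip(macro_labels, macro.macro_populations)
        },
        "macro_lifetimes": {
            lab: float(lt) for lab, lt in zip(macro_labels, macro.lifetimes)
        },
        "total_flux": float(cg.total_flux),
        "pathways": [
            {"path": name, "percent": pct}
            for name, pct in decomposition.as_rows(macro_labels)
        ],
        "pathway_residual_percent": float(
            100.0 * decomposition.residual_flux / cg.total_flux
        )
        if cg.total_flux > 0
        else 0.0,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    files["summary"] = out / "summary.json"
    provenance = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    files["provenance"] = out / "provenance.json"

    return ReportBundle(
        files=files,
        summary=summary,
        macrostates=macro,
        decomposition=decomposition,
        macro_labels=macro_labels,
        config=config,
    )
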