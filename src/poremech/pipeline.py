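"""End-to-end orchestration from a single YAML-style config.

A run config is a mapping with a ``seed``, an ``outdir`` and a
``stages`` list; each stage is a mapping with a ``kind`` and its
parameters (physical quantities carry unit suffixes in their keys).
Stage kinds: simulate_curves, analyze_curves, fit_nucleation,
simulate_umbrella, wham, pore_probability, snapshot_observables.
Every output file records the seed; re-running a config reproduces all
numbers bit-identically on one platform.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import forcecurves as fcv
from . import nucleation as nuc
from . import observables as obs
from . import pmf as pmflib
from . import synthetic as syn

log = logging.getLogger("poremech")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _params_from_block(block: dict) -> nuc.NucleationParams:
    return nuc.NucleationParams(
        gamma=block.get("gamma_nN", 6.93e-3) * 1e-9,
        spreading_pressure=block.get("spreading_pressure_N_per_m", 9.49e-3),
        tip_radius=block.get("tip_radius_nm", 20.0) * 1e-9,
        spring_constant=block.get("spring_constant_N_per_m", 0.060),
        velocity=block.get("velocity_um_per_s", 1.0) * 1e-6,
        attempt_frequency=block.get("attempt_frequency_hz", 3000.0),
        temperature=block.get("temperature_K", 298.0),
    )


def _stage_simulate_curves(cfg, outdir: Path, rng):
    params = _params_from_block(cfg)
    spec = syn.CurveSynthSpec(
        params=params,
        noise_sd=cfg.get("noise_sd_nN", 0.02),
        membrane_thickness_apparent=cfg.get("membrane_thickness_nm", 4.0),
    )
    n = cfg.get("n_curves", 100)
    curve_dir = outdir / cfg.get("dirname", "curves")
    curve_dir.mkdir(parents=True, exist_ok=True)
    truths = []
    for i in range(n):
        curve = syn.generate_force_curve(spec, seed=int(rng.integers(2**31)))
        fcv.write_force_curve(curve, curve_dir / f"curve_{i:04d}.txt")
        truths.append((i, curve.meta["true_breakthrough_force_nN"]))
    with open(curve_dir / "ground_truth.tsv", "w") as fh:
        fh.write("curve\ttrue_breakthrough_force_nN\n")
        for i, f in truths:
            fh.write(f"{i}\t{f:.6f}\n")
    return {"n_curves": n, "dir": str(curve_dir)}


def _stage_analyze_curves(cfg, outdir: Path, rng):
    curves = fcv.read_force_curves(Path(cfg["input_dir"]))
    forces, skipped = [], 0
    for curve in curves:
        try:
            _, _, events = fcv.analyze_curve(
                curve,
                derivative_threshold=cfg.get("derivative_threshold_nN_per_nm"),
                min_points=cfg.get("min_points", 3),
            )
        except (fcv.ContactNotFoundError, ValueError):
            skipped += 1
            continue
        if events:
            forces.append(events[0].yield_force)
    sample = fcv.YieldForceSample(np.array(forces), condition=cfg.get("condition", ""))
    out = outdir / cfg.get("output", "yield_forces.tsv")
    with open(out, "w") as fh:
        fh.write("yield_force_nN\n")
        for f in sample.forces:
            fh.write(f"{f:.6f}\n")
    summary = {
        "n_detected": len(sample),
        "n_skipped": skipped,
        "median_nN": sample.median if len(sample) else None,
        "boxplot": fcv.boxplot_stats(sample) if len(sample) >= 5 else None,
    }
    fcv.ecdf(sample).to_csv(outdir / "ecdf.tsv", sep="\t", index=False)
    return summary


def _stage_fit_nucleation(cfg, outdir: Path, rng):
    path = Path(cfg["forces_file"])
    forces_nN = np.loadtxt(path, skiprows=1, ndmin=1)
    fixed = _params_from_block(cfg)
    result = nuc.fit(forces_nN * 1e-9, fixed, method=cfg.get("method", "mle"))
    report = {
        "estimates": result.as_paper_units(),
        "converged": result.converged,
        "n": result.n,
        "method": result.method,
        "objective": result.objective,
    }
    with open(outdir / cfg.get("output", "fit.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _stage_simulate_umbrella(cfg, outdir: Path, rng):
    pmf_truth = syn.reference_pore_pmf(
        dg_pore=cfg.get("dg_pore_kJ_mol", 65.0),
        temperature=cfg.get("temperature_K", 323.0),
    )
    ds = syn.generate_umbrella_dataset(
        pmf_truth,
        n_per_window=cfg.get("n_per_window", 5000),
        seed=int(rng.integers(2**31)),
    )
    meta = pmflib.write_umbrella_dataset(ds, outdir / cfg.get("dirname", "umbrella"))
    return {"windows": len(ds.windows), "meta": str(meta)}


def _stage_wham(cfg, outdir: Path, rng):
    ds = pmflib.read_umbrella_dataset(
        Path(cfg["meta_file"]),
        temperature=cfg.get("temperature_K", 323.0),
        equilibration_fraction=cfg.get("equilibration_fraction", 0.0),
    )
    profile = pmflib.bayesian_bootstrap_pmf(
        ds,
        rounds=cfg.get("bootstrap_rounds", 50),
        n_bins=cfg.get("n_bins", 200),
        seed=int(rng.integers(2**31)),
    )
    profile.to_frame().to_csv(outdir / cfg.get("output", "pmf.tsv"), sep="\t", index=False)
    dg, err = pmflib.pore_free_energy(profile)
    report = {"dg_pore_kJ_mol": dg, "dg_pore_err_kJ_mol": err}
    with open(outdir / "pore_free_energy.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _stage_pore_probability(cfg, outdir: Path, rng):
    dg = cfg["dg_pore_kJ_mol"]
    temperature = cfg.get("temperature_K", 300.0)
    a_sim = cfg.get("area_sim_nm2", 45.0)
    rows = []
    for geom in cfg.get("geometries", []):
        if "sphere_radius_um" in geom:
            area = pmflib.sphere_area(geom["sphere_radius_um"] * 1e3)
            name = f"vesicle r={geom['sphere_radius_um']} um"
        elif "disc_diameter_mm" in geom:
            area = pmflib.disc_area(geom["disc_diameter_mm"] * 1e6)
            name = f"disc d={geom['disc_diameter_mm']} mm"
        else:
            area = geom["area_nm2"]
            name = f"area {area} nm^2"
        dg_exp = pmflib.area_scaled_dg(dg, area, a_sim, temperature)
        rows.append(
            {
                "geometry": name,
                "area_nm2": area,
                "dg_exp_kJ_mol": dg_exp,
                "p_open": pmflib.pore_probability(dg_exp, temperature),
            }
        )
    report = {"dg_pore_kJ_mol": dg, "temperature_K": temperature, "rows": rows}
    with open(outdir / cfg.get("output", "pore_probability.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _stage_snapshot_observables(cfg, outdir: Path, rng):
    if "input" in cfg:
        path = Path(cfg["input"])
        snap = (
            obs.read_snapshot_pdb(path)
            if path.suffix.lower() == ".pdb"
            else obs.read_snapshot_csv(path)
        )
    else:
        spec = syn.SnapshotSpec(pore_radius=cfg.get("pore_radius_nm"))
        snap = syn.generate_membrane_snapshot(spec, seed=int(rng.integers(2**31)))
    report = {
        "chain_coordinate": obs.chain_coordinate(snap),
        "thickness_nm": obs.thickness(snap),
        "area_per_lipid_nm2": obs.area_per_lipid(snap),
    }
    with open(outdir / cfg.get("output", "observables.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    return report


_STAGES = {
    "simulate_curves": _stage_simulate_curves,
    "analyze_curves": _stage_analyze_curves,
    "fit_nucleation": _stage_fit_nucleation,
    "simulate_umbrella": _stage_simulate_umbrella,
    "wham": _stage_wham,
    "pore_probability": _stage_pore_probability,
    "snapshot_observables": _stage_snapshot_observables,
}


def run_pipeline(config: dict) -> dict:
    """Execute the stages of ``config`` in order; returns the report bundle.

    Deterministic per (config, seed): every stage draws its seed from one
    child-spawning generator.  A stage failure raises StageError naming
    the stage.
    """
    outdir = Path(config.get("outdir", "poremech_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    rng = np.random.default_rng(seed)
    report = {"seed": seed, "stages": []}
    for stage_cfg in config.get("stages", []):
        kind = stage_cfg.get("kind")
        if kind not in _STAGES:
            raise StageError(str(kind), ValueError(f"unknown stage kind {kind!r}"))
        log.info("running stage %s", kind)
        try:
            result = _STAGES[kind](stage_cfg, outdir, rng)
        except StageError:
            raise
        except Exception as exc:  # structured failure naming the stage
            raise StageError(kind, exc) from exc
        report["stages"].append({"kind": kind, "result": result})
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
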