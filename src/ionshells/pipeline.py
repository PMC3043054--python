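"""End-to-end pipeline: config -> stages -> deterministic result tables.

Stages: distance/shell assignment -> residence survival + exponential fits
-> MSD/diffusion -> encounter classification and bookkeeping -> kinetics
worked example.  All outputs are CSV/JSON with fixed column order and float
precision, so re-running a manifest reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import BULK, AnalysisConfig, ShellScheme
from .diffusion import estimate_D, msd_curve
from .encounters import binding_table, classify_encounters, detect_contacts, summary_stats, transfer_counts
from .geometry import min_distance_series, unwrap_ion
from .kinetics import DSParameters, ds_rate, pseudo_first_order
from .shells import assign_shells, extract_residence_events, fit_exponential, occupancy_histogram, survival_curve
from .synthetic import gen_free_diffusion, gen_langevin_surface
from .tables import load_residue_encounter_table, summarize_encounters
from .trajectory import load_trajectory, read_internal

__all__ = ["RunManifest", "run_pipeline", "write_report", "load_config"]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    input_hashes: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict) or "input" not in cfg:
        raise ValueError("config must be a mapping with an 'input' section")
    kind = cfg["input"].get("kind")
    if kind not in ("synthetic_langevin", "synthetic_free", "internal", "md"):
        raise ValueError(f"unknown input kind {kind!r}")
    analysis = cfg.get("analysis", {})
    AnalysisConfig(**analysis)  # raises on bad boundaries etc.


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _get_trajectory(cfg: dict, seed: int, manifest: RunManifest):
    inp = cfg["input"]
    kind = inp["kind"]
    if kind == "synthetic_langevin":
        traj, _ = gen_langevin_surface(seed=seed, **inp.get("params", {}))
    elif kind == "synthetic_free":
        traj, _ = gen_free_diffusion(seed=seed, **inp.get("params", {}))
    elif kind == "internal":
        p = Path(inp["path"])
        manifest.input_hashes[str(p)] = _sha256(p)
        traj = read_internal(p)
    else:
        top, trj = Path(inp["topology"]), Path(inp["trajectory"])
        manifest.input_hashes[str(top)] = _sha256(top)
        manifest.input_hashes[str(trj)] = _sha256(trj)
        traj = load_trajectory(top, trj, inp["ion_selection"])
    return traj


def write_report(results: dict, out_dir: str | Path, fmt: str = "both") -> dict[str, str]:
    """Write result tables deterministically; returns name -> path map.

    ``results`` maps table name -> DataFrame (written as CSV) or mapping
    (written as JSON).  Floats use a fixed '%.6g' format and JSON keys are
    sorted, so identical results give byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            if fmt in ("csv", "both"):
                p = out_dir / f"{name}.csv"
                obj.to_csv(p, index=False, float_format=_FLOAT_FMT)
                written[name] = str(p)
            if fmt in ("json", "both"):
                p = out_dir / f"{name}.json"
                p.write_text(
                    json.dumps(
                        json.loads(obj.to_json(orient="records", double_precision=6)),
                        indent=1,
                        sort_keys=True,
                    )
                    + "\n"
                )
                written.setdefault(name, str(p))
        else:
            p = out_dir / f"{name}.json"
            p.write_text(json.dumps(obj, indent=1, sort_keys=True, default=float) + "\n")
            written[name] = str(p)
    return written


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> tuple[RunManifest, dict]:
    """Execute every analysis stage described by a config mapping/file.

    Returns the manifest and the in-memory results dict (also written to
    ``out_dir`` or the config's ``output_dir``).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        _validate_config(config)
    seed = int(config.get("seed", 0))
    out_dir = Path(out_dir or config.get("output_dir", "ionshells_results"))
    ana_kwargs = dict(config.get("analysis", {}))
    ana_kwargs.setdefault("seed", seed)
    if "msd_fit_window" in ana_kwargs:
        ana_kwargs["msd_fit_window"] = tuple(ana_kwargs["msd_fit_window"])
    ana = AnalysisConfig(**ana_kwargs)
    scheme = ana.shells
    manifest = RunManifest(config=config, seed=seed, version=__version__)
    results: dict = {}

    t0 = time.perf_counter()
    traj = _get_trajectory(config, seed, manifest)
    manifest.stage_seconds["load"] = round(time.perf_counter() - t0, 3)
    log.info("loaded trajectory: %d frames, %d atoms, ions %s", traj.n_frames, len(traj.atoms), traj.ions)

    has_protein = len(traj.atoms) > 0
    ion = traj.ions[0]

    if has_protein:
        t0 = time.perf_counter()
        ds = min_distance_series(traj, ion, heavy_only=ana.heavy_atoms_only)
        shells_idx = assign_shells(ds.d, scheme)
        edges, pct, cum = occupancy_histogram(ds.d)
        results["occupancy_histogram"] = pd.DataFrame(
            {"bin_left_nm": edges[:-1], "percent": pct, "cumulative_percent": cum}
        )
        occ = {
            f"shell_{s}" if s != BULK else "bulk": float(np.mean(shells_idx == s))
            for s in ([*range(1, scheme.n_shells + 1), BULK])
        }
        results["shell_occupancy"] = occ
        manifest.stage_seconds["shells"] = round(time.perf_counter() - t0, 3)

        t0 = time.perf_counter()
        events = extract_residence_events(shells_idx, traj.times, scheme, ana.grace_time, ion=ion)
        rows = []
        for s in range(1, scheme.n_shells + 1):
            evs = [e for e in events if e.shell == s]
            if not evs:
                continue
            curve = survival_curve(evs, dt=traj.dt)
            row = {"shell": scheme.label(s), "n_events": len(evs)}
            for order in (1, 2):
                try:
                    f = fit_exponential(curve, order=order, min_count=ana.min_fit_count, seed=seed)
                except (ValueError, RuntimeError):
                    continue
                if order == 1:
                    row["tau_single"] = f.taus[0]
                    row["rel_rms_error_single"] = f.rel_rms_error
                else:
                    row["tau1"], row["tau2"] = f.taus
                    row["rel_rms_error"] = f.rel_rms_error
            rows.append(row)
        results["residence_fits"] = pd.DataFrame(rows)
        manifest.stage_seconds["residence"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    unwrapped = unwrap_ion(traj, ion)
    max_lag = int(min(ana.msd_fit_window[1] * 2 / traj.dt, traj.n_frames // 4))
    curve = msd_curve(unwrapped, traj.dt, max_lag_frames=max(max_lag, 3))
    try:
        est = estimate_D(curve, ana.msd_fit_window)
        results["diffusion"] = {
            "D_cm2_s": est.D,
            "fit_window_ps": list(est.fit_window),
            "linearity_r2": est.linearity_r2,
        }
    except ValueError as e:
        log.warning("diffusion estimate skipped: %s", e)
    results["msd_curve"] = pd.DataFrame(
        {"lag_ps": curve.lags, "msd_nm2": curve.msd, "n_samples": curve.n_samples}
    )
    manifest.stage_seconds["diffusion"] = round(time.perf_counter() - t0, 3)

    if has_protein:
        t0 = time.perf_counter()
        contacts = detect_contacts(
            traj, ion, cutoff=ana.contact_cutoff, granularity="residue",
            grace_time=ana.grace_time, heavy_only=ana.heavy_atoms_only,
        )
        first_shell = shells_idx == 1
        cevents = classify_encounters(contacts, first_shell, traj.times, ana.grace_time, ion=ion)
        results["binding_table"] = binding_table(cevents)
        results["transfer_counts"] = {
            "|".join(sorted(map(str, pair))): n for pair, n in transfer_counts(cevents).items()
        }
        results["encounter_summary"] = summary_stats(cevents, traj.n_frames, traj.dt)
        manifest.stage_seconds["encounters"] = round(time.perf_counter() - t0, 3)

    kin = config.get("kinetics")
    if kin:
        t0 = time.perf_counter()
        if "k_on" in kin:
            k_on = float(kin["k_on"])
        else:
            k_on = ds_rate(DSParameters(**kin.get("ds_parameters", {})))
        pfo = pseudo_first_order(k_on, float(kin.get("concentration", 0.025)))
        results["kinetics"] = {"k_on_per_M_s": k_on, **pfo}
        manifest.stage_seconds["kinetics"] = round(time.perf_counter() - t0, 3)

    manifest.outputs = write_report(results, out_dir)
    (Path(out_dir) / "manifest.json").write_text(
        json.dumps(asdict(manifest), indent=1, sort_keys=True, default=str) + "\n"
    )
    return manifest, results
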