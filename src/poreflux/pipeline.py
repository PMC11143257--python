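"""Config-driven orchestration of the full analysis battery.

A single structured config (dict or YAML file) defines the trajectory sets
(per conformational state), the selections, and every analysis parameter —
the 5 Å contact cutoff, the 0.25 difference threshold, the 0.8 correlation
cutoff, the 4 kJ/mol basin depth, the 5000 kJ/mol/nm² ABMD spring and 0.5 nm
target, and the 1.2 kJ/mol / 0.25 / γ=8 hill protocol — so a reproduction
attempt is a one-file edit.  The report is a directory of CSV/JSON artifacts
plus a summary comparing states; content is a pure function of the config
and input files.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contacts as contacts_mod
from . import energetics, ephys, occupancy, permeation
from .io import load_system, load_trajectory, read_hills, select
from .synth import SyntheticSpec, gen_ion_channel_traj

log = logging.getLogger("poreflux.pipeline")

DEFAULTS = {
    "voltage_mV": 200.0,
    "selections": {"ions": "name K", "sf": "name N CA C O"},
    "permeation": {"lower": -1.0, "upper": 15.0, "radius": 8.0},
    "occupancy": {"z_min": -3.0, "z_max": 17.0, "n_bins": 40},
    "contacts": {"cutoff": 5.0, "threshold": 0.25, "min_resid_separation": 2},
    "fes": {"min_basin_depth": 4.0},
    "abmd": {"k": 5000.0, "target": 0.5},
}


class ConfigError(ValueError):
    pass


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(path_or_dict)
    merged = {**DEFAULTS, **cfg}
    for key in ("selections", "permeation", "occupancy", "contacts", "fes", "abmd"):
        merged[key] = {**DEFAULTS.get(key, {}), **(cfg.get(key) or {})}
    return merged


def validate_config(cfg: dict) -> None:
    if "states" not in cfg or not cfg["states"]:
        raise ConfigError("config must define at least one trajectory state")
    for name, st in cfg["states"].items():
        if "synthetic" in st:
            continue
        if "topology" not in st or "trajectories" not in st:
            raise ConfigError(f"state {name!r} needs topology+trajectories or synthetic")
        if not Path(st["topology"]).exists():
            raise ConfigError(f"state {name!r}: topology {st['topology']!r} not found")
        for t in st["trajectories"]:
            if not Path(t).exists():
                raise ConfigError(f"state {name!r}: trajectory {t!r} not found")
    if "hills" in cfg and not Path(cfg["hills"]).exists():
        raise ConfigError(f"hills log {cfg['hills']!r} not found")
    if cfg["permeation"]["lower"] >= cfg["permeation"]["upper"]:
        raise ConfigError("permeation: need lower < upper")


def _state_trajectory(cfg: dict, state: dict):
    if "synthetic" in state:
        spec = SyntheticSpec(**state["synthetic"])
        traj, _ = gen_ion_channel_traj(spec)
        return traj
    system, _ = load_system(state["topology"])
    trajs = [load_trajectory(t, system, structure_path=state["topology"])
             for t in state["trajectories"]]
    if len(trajs) == 1:
        return trajs[0]
    # concatenate replicates with continued time stamps
    times, coords, boxes = [], [], []
    t_off = 0.0
    for tr in trajs:
        times.append(tr.times + t_off)
        coords.append(tr.coords)
        boxes.append(tr.boxes)
        t_off = times[-1][-1] + (tr.times[1] - tr.times[0] if tr.n_frames > 1 else 1.0)
    from .io import Trajectory
    return Trajectory(system=trajs[0].system, times=np.concatenate(times),
                      coords=np.concatenate(coords), boxes=np.concatenate(boxes))


def run_analysis(config, output_dir=None) -> dict:
    """Run permeation → occupancy → contacts (→ difference map, FES, ABMD)
    per the config; write per-module CSV/JSON and a cross-state summary.

    Module failures are collected into a failure manifest instead of
    aborting the whole run; the report records them and callers should exit
    nonzero when it is non-empty.
    """
    cfg = load_config(config)
    validate_config(cfg)
    outdir = Path(output_dir or cfg.get("output_dir", "poreflux_report"))
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"states": {}, "failures": []}

    per_state_contacts = {}
    for name, st in cfg["states"].items():
        t0 = time.perf_counter()
        log.info("state %s: building trajectory", name)
        traj = _state_trajectory(cfg, st)
        state_out: dict = {}
        sf_idx = select(traj.system, cfg["selections"]["sf"])
        ion_idx = select(traj.system, cfg["selections"]["ions"])
        pm = cfg["permeation"]
        axis = permeation.compute_pore_axis(traj, sf_idx, radius=pm["radius"])
        try:
            events = permeation.detect_permeation_events(
                traj, ion_idx, axis, pm["lower"], pm["upper"])
            summary = permeation.PermeationSummary.from_events(
                events, traj.total_time_ns, cfg["voltage_mV"])
            pd.DataFrame([{"ion": e.ion_id, "entry_ns": e.entry_time,
                           "exit_ns": e.exit_time, "direction": e.direction,
                           "undersampled": e.undersampled} for e in events]
                         ).to_csv(outdir / f"{name}_events.csv", index=False)
            state_out["permeation"] = {"N": summary.N, "t_ns": summary.t,
                                       "V_mV": summary.V, "gamma_pS": summary.gamma}
        except Exception as exc:
            report["failures"].append({"state": name, "module": "permeation",
                                       "error": str(exc)})
        occ = cfg["occupancy"]
        try:
            z_edges = np.linspace(occ["z_min"], occ["z_max"], occ["n_bins"] + 1)
            grid = occupancy.occupancy_profile(traj, ion_idx, axis, z_edges)
            grid.to_frame().to_csv(outdir / f"{name}_occupancy_1d.csv", index=False)
            sites = occupancy.default_sites()
            site_df = occupancy.assign_sites(grid, sites, n_frames=traj.n_frames)
            site_df.to_csv(outdir / f"{name}_sites.csv", index=False)
            state_out["occupancy"] = {
                r.site: r.mean_occupancy for r in site_df.itertuples()}
        except Exception as exc:
            report["failures"].append({"state": name, "module": "occupancy",
                                       "error": str(exc)})
        cc = cfg["contacts"]
        try:
            recs = contacts_mod.contact_probability(
                traj, cutoff=cc["cutoff"],
                min_resid_separation=cc["min_resid_separation"])
            per_state_contacts[name] = recs
            pd.DataFrame([{"chain_a": r.pair[0][0], "resid_a": r.pair[0][1],
                           "chain_b": r.pair[1][0], "resid_b": r.pair[1][1],
                           "p": r.p} for r in recs]
                         ).to_csv(outdir / f"{name}_contacts.csv", index=False)
            state_out["n_contact_pairs"] = len(recs)
        except Exception as exc:
            report["failures"].append({"state": name, "module": "contacts",
                                       "error": str(exc)})
        state_out["wall_s"] = round(time.perf_counter() - t0, 3)
        report["states"][name] = state_out

    if len(per_state_contacts) == 2:
        (up_name, up_recs), (dn_name, dn_recs) = per_state_contacts.items()
        dm = contacts_mod.difference_map(up_recs, dn_recs,
                                         threshold=cfg["contacts"]["threshold"])
        dm.to_csv(outdir / "diffmap.csv", index=False)
        report["difference_map"] = {
            "states": [up_name, dn_name],
            "n_total": int(len(dm)),
            "n_inter": int((dm["class"] == "inter").sum()),
            "n_intra": int((dm["class"] == "intra").sum()),
        }

    if "hills" in cfg:
        try:
            hl = read_hills(cfg["hills"])
            fes = energetics.reconstruct_fes(hl)
            basins = energetics.find_basins(fes, cfg["fes"]["min_basin_depth"])
            pd.DataFrame({"cv1": np.repeat(fes.grid_x, len(fes.grid_y)),
                          "cv2": np.tile(fes.grid_y, len(fes.grid_x)),
                          "F_kJmol": fes.F.ravel()}
                         ).to_csv(outdir / "fes.csv", index=False)
            report["fes"] = {"n_basins": len(basins),
                             "basins": [{"cv1": b.location[0], "cv2": b.location[1],
                                         "F_min": b.f_min} for b in basins]}
        except Exception as exc:
            report["failures"].append({"module": "fes", "error": str(exc)})

    if "abmd_series" in cfg:
        try:
            df = pd.read_csv(cfg["abmd_series"])
            rec = energetics.abmd_force(df.iloc[:, 0].values, df.iloc[:, 1].values,
                                        k=cfg["abmd"]["k"], target=cfg["abmd"]["target"])
            report["abmd"] = {"total_force_abs": rec.total_force_abs,
                              "total_force_sq": rec.total_force_sq}
        except Exception as exc:
            report["failures"].append({"module": "abmd", "error": str(exc)})

    with open(outdir / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
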