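"""End-to-end orchestration over a (temperature, pressure) condition grid.

``run_pipeline`` reads a topology + annotation + one trajectory per
condition, runs the H-bond/coupling/order-parameter/fluctuation stages, and
feeds the per-condition observables into the pressure-response layer.  All
outputs are long-format CSV keyed by (temperature, pressure) so sparse
condition grids need no padding; a manifest records the configuration hash,
row counts and machine-readable warnings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import hbonds, jcoupling, methyl, pressure
from .fluct import SelectionSpec, rmsd_timeseries, rmsf_per_residue
from .model_io import (
    ConditionLabel,
    Trajectory,
    annotate_topology,
    load_trajectory,
    read_pdb,
    read_reference_table,
    select_analysis_window,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

ALL_STAGES = ("hbonds", "jcoupling", "order", "fluct", "correlate")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and context."""


@dataclass
class RunConfig:
    topology_path: str
    annotation_path: str
    trajectory_paths: dict[str, str]        # "T,p" -> path
    output_dir: str
    experimental_couplings: str | None = None
    experimental_s2: str | None = None
    methyl_table: str | None = None
    discard_time: float = 0.0               # ps of equilibration to drop
    r_cut: float = hbonds.R_CUT_ANGSTROM
    theta_min: float = hbonds.THETA_MIN_DEGREES
    n_blocks: int = 10
    delta_flag_threshold: float = jcoupling.DELTA_FLAG_THRESHOLD_HZ
    weak_rho_threshold: float = pressure.WEAK_RHO_THRESHOLD
    rmsd_first_residue: int = 1
    rmsd_last_residue: int = 10**6
    exclude_from_domains: tuple[int, ...] = ()
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0

    def condition(self, key: str) -> ConditionLabel:
        t, p = key.split(",")
        return ConditionLabel(float(t), float(p))


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_conditions(config: RunConfig, topology) -> dict[ConditionLabel, Trajectory]:
    out: dict[ConditionLabel, Trajectory] = {}
    for key, path in config.trajectory_paths.items():
        cond = config.condition(key)
        traj = load_trajectory(path, topology)
        traj.condition = cond
        if config.discard_time > 0:
            traj = select_analysis_window(traj, config.discard_time)
        out[cond] = traj
    if not out:
        raise PipelineError("no trajectories configured")
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Stage order: model_io -> hbonds -> jcoupling -> order -> fluct ->
    correlate.  A missing experimental table skips the comparison tables
    with a warning instead of failing.  Any stage error aborts with the
    stage name; partial outputs of the failed run are removed.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    tables: dict[str, int] = {}
    written: list[Path] = []

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False, float_format="%.6g")
        written.append(path)
        tables[name] = len(frame)

    stage = "model_io"
    try:
        topo_raw, _ = read_pdb(config.topology_path)
        topo = annotate_topology(topo_raw, config.annotation_path)
        conditions = _load_conditions(config, topo)
        reference_coords = next(iter(conditions.values())).coords[0]

        occupancy_rows: list[dict] = []
        event_rows: list[dict] = []
        coupling_rows: list[dict] = []
        obs_records: dict[tuple[float, float], dict[str, float]] = {
            (c.temperature, c.pressure): {} for c in conditions
        }
        candidates = hbonds.enumerate_candidates(topo)

        if "hbonds" in config.stages:
            stage = "hbonds"
            for cond, traj in conditions.items():
                key = (cond.temperature, cond.pressure)
                for cand in candidates:
                    series = hbonds.merged_series(
                        traj, cand, r_cut=config.r_cut, theta_min=config.theta_min
                    )
                    events, record = hbonds.extract_events(series)
                    occupancy_rows.append(
                        {
                            "temperature": cond.temperature,
                            "pressure": cond.pressure,
                            "label": cand.label,
                            "category": cand.category,
                            "occupancy": record.effective_occupancy,
                            "n_events": record.n_events,
                            **{
                                f"bin_{lo:g}_{hi:g}_ns": c
                                for (lo, hi), c in zip(
                                    record.bins_ns, record.lifetime_bin_counts
                                )
                            },
                        }
                    )
                    for ev in events:
                        event_rows.append(
                            {
                                "temperature": cond.temperature,
                                "pressure": cond.pressure,
                                "label": cand.label,
                                "start_ps": ev.start_frame * traj.frame_interval,
                                "end_ps": (ev.end_frame + 1) * traj.frame_interval,
                                "lifetime_ns": ev.lifetime,
                            }
                        )
                    obs_records[key][f"occ:{cand.label}"] = record.effective_occupancy
                # water bridges / hydrophobic contacts on annotated pairs
                core = sorted(topo.hydrophobic_core)
                for i, a in enumerate(core):
                    for b in core[i + 1 :]:
                        cseries, dist = hbonds.hydrophobic_contact_series(traj, (a, b))
                        label = cseries.label
                        obs_records[key][f"dist:{label}"] = float(dist.mean())
                        occupancy_rows.append(
                            {
                                "temperature": cond.temperature,
                                "pressure": cond.pressure,
                                "label": label,
                                "category": "hydrophobic-contact",
                                "occupancy": cseries.occupancy,
                                "n_events": hbonds.extract_events(cseries)[1].n_events,
                            }
                        )
            emit("hbond_occupancy", pd.DataFrame(occupancy_rows))
            emit("hbond_events", pd.DataFrame(event_rows))

        if "jcoupling" in config.stages:
            stage = "jcoupling"
            exp_table: Mapping[str, float] | None = None
            if config.experimental_couplings:
                exp_table = read_reference_table(config.experimental_couplings)
            else:
                warnings.append(
                    "no experimental coupling table: delta/validation skipped"
                )
            delta_rows = []
            for cond, traj in conditions.items():
                key = (cond.temperature, cond.pressure)
                calc: dict[str, float] = {}
                calc_blocks: dict[str, list[float]] = {}
                for cand in candidates:
                    series = hbonds.geometry_series(traj, cand)
                    result = jcoupling.ensemble_coupling(series, config.n_blocks)
                    calc[cand.label] = result.J_mean
                    calc_blocks[cand.label] = list(result.block_means)
                    coupling_rows.append(
                        {
                            "temperature": cond.temperature,
                            "pressure": cond.pressure,
                            "label": cand.label,
                            "J_calc": result.J_mean,
                            "block_se": result.block_se,
                            "n_frames": result.n_frames,
                        }
                    )
                    obs_records[key][f"J:{cand.label}"] = result.J_mean
                if exp_table is not None:
                    table, summary = jcoupling.delta_couplings(
                        calc, exp_table, config.delta_flag_threshold
                    )
                    for _, row in table.iterrows():
                        delta_rows.append(
                            {
                                "temperature": cond.temperature,
                                "pressure": cond.pressure,
                                **row.to_dict(),
                            }
                        )
            emit("couplings", pd.DataFrame(coupling_rows))
            if exp_table is not None:
                emit("delta_couplings", pd.DataFrame(delta_rows))

        if "order" in config.stages:
            stage = "order"
            if config.methyl_table:
                s2_rows = []
                exp_s2 = (
                    read_reference_table(config.experimental_s2)
                    if config.experimental_s2
                    else {}
                )
                for cond, traj in conditions.items():
                    key = (cond.temperature, cond.pressure)
                    for series in methyl.methyl_axes(traj, config.methyl_table):
                        result = methyl.order_parameter(series, config.n_blocks)
                        s2_rows.append(
                            {
                                "temperature": cond.temperature,
                                "pressure": cond.pressure,
                                "axis": result.axis_label,
                                "S2_calc": result.S2,
                                "block_se": result.block_se,
                                "S2_exp": exp_s2.get(result.axis_label, np.nan),
                            }
                        )
                        obs_records[key][f"S2:{result.axis_label}"] = result.S2
                emit("order_params", pd.DataFrame(s2_rows))
            else:
                warnings.append("no methyl table: order-parameter stage skipped")

        if "fluct" in config.stages:
            stage = "fluct"
            rmsd_rows = []
            rmsf_rows = []
            sel = SelectionSpec(
                config.rmsd_first_residue, config.rmsd_last_residue, "all-heavy"
            )
            for cond, traj in conditions.items():
                key = (cond.temperature, cond.pressure)
                _, mean_rmsd, block_sd = rmsd_timeseries(
                    traj, reference_coords, sel, config.n_blocks
                )
                rmsd_rows.append(
                    {
                        "temperature": cond.temperature,
                        "pressure": cond.pressure,
                        "mean_rmsd": mean_rmsd,
                        "block_sd": block_sd,
                    }
                )
                for atom_class in ("all-heavy", "backbone-heavy", "sidechain-heavy"):
                    table = rmsf_per_residue(
                        traj, atom_class,
                        exclude_from_domains=config.exclude_from_domains,
                    )
                    for _, row in table.domain_averages.iterrows():
                        rmsf_rows.append(
                            {
                                "temperature": cond.temperature,
                                "pressure": cond.pressure,
                                "atom_class": atom_class,
                                "ss": row["ss"],
                                "mean_rmsf": row["mean_rmsf"],
                            }
                        )
                        obs_records[key][
                            f"rmsf:{atom_class}:{row['ss']}"
                        ] = row["mean_rmsf"]
            emit("rmsd", pd.DataFrame(rmsd_rows))
            emit("rmsf_domains", pd.DataFrame(rmsf_rows))

        if "correlate" in config.stages:
            stage = "correlate"
            table = pressure.ConditionTable.from_records(obs_records)
            class_rows = []
            for label in table.observables:
                rho = {
                    t: pressure.pearson_vs_pressure(table, label, t)
                    for t in table.temperatures
                }
                if not any(np.isfinite(v) for v in rho.values()):
                    continue
                cls = pressure.classify_response(
                    rho, config.weak_rho_threshold, label=label
                )
                class_rows.append(
                    {
                        "label": label,
                        **{f"rho_{t:g}K": r for t, r in rho.items()},
                        "n_positive": cls.n_positive,
                        "n_negative": cls.n_negative,
                        "verdict": cls.verdict,
                        "fully_positive": cls.fully_positive,
                        "fully_negative": cls.fully_negative,
                        "weak": cls.weak,
                    }
                )
            emit("pressure_response", pd.DataFrame(class_rows))
            dist_labels = [
                c[5:] for c in table.observables if c.startswith("dist:")
            ]
            if dist_labels:
                renamed = pressure.ConditionTable(
                    table.frame.rename(
                        columns={f"dist:{l}": l for l in dist_labels}
                    )[["temperature", "pressure"] + dist_labels]
                )
                for t in renamed.temperatures:
                    mat = pressure.distance_pressure_matrix(renamed, t, dist_labels)
                    path = outdir / f"distance_pressure_rho_{t:g}K.csv"
                    mat.to_csv(path, float_format="%.6g")
                    written.append(path)
                    tables[path.stem] = len(mat)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": list(config.stages),
        "n_conditions": len(config.trajectory_paths),
        "tables": tables,
        "warnings": warnings,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
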