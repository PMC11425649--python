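"""End-to-end orchestration: config → full analysis → report directory.

Stages run in a fixed order (read → frame selection → convergence →
geometry → hydrogen bonds → energetics → clustering); every stage writes
CSV with fixed float formatting so identical config + seed reproduces
byte-identical outputs. A failure in any stage is logged with the stage
name; earlier outputs are preserved.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .convergence import convergence_report
from .energetics import (
    group_decomposition,
    ligand_atom_indices,
    mmgbsa_binding,
    per_residue_decomposition,
    select_pocket_residues,
)
from .geometry import (
    GeometryReference,
    angle_distance_histogram,
    cluster_orientations,
    fraction_near_reference,
    geometry_series,
)
from .hbonds import occupancy_table
from .io import read_region_map, read_topology, read_trajectory
from .model import select_frames

logger = logging.getLogger("tgsite")

FLOAT_FMT = "%.6f"


@dataclass
class RunConfig:
    structure: str
    parameters: str
    trajectory: str
    ligand_resnames: tuple[str, ...] = ()
    donor_residue: int = 2540
    acceptor_residue: int = 2573
    donor_atom: str = "OH"
    acceptor_atom: str = "CZ"
    window_ns: float = 5.0
    stride: int = 10
    frame_spacing_ps: float = 1.0
    region_map: str | None = None
    distance_cutoff: float = 3.0
    angle_cutoff: float = 135.0
    min_occupancy: float = 10.0
    pocket_cutoff: float = 10.0
    eps_in: float = 1.0
    eps_out: float = 78.5
    salt_molar: float = 0.1
    gamma_np: float = 0.005
    obc_alpha: float = 1.0
    obc_beta: float = 0.8
    obc_gamma: float = 4.8
    reference_angle: float = 76.0
    reference_distance: float = 6.4
    cluster_eps: float = 2.0
    cluster_min_samples: int = 6
    sasa_points: int = 960
    seed: int = 0
    extras: dict = dc_field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        extras = {k: v for k, v in data.items() if k not in cls.__dataclass_fields__}
        if "ligand_resnames" in known:
            known["ligand_resnames"] = tuple(known["ligand_resnames"])
        return cls(**known, extras=extras)

    def validate(self) -> None:
        for attr in ("structure", "parameters", "trajectory"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"config {attr} points to missing file: {p}")
        if self.region_map and not Path(self.region_map).exists():
            raise FileNotFoundError(f"region map file missing: {self.region_map}")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full analysis; returns the report directory."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    summary: dict = {"version": __version__, "seed": config.seed,
                     "config": {k: v for k, v in vars(config).items() if k != "extras"}}
    stage = "read"
    try:
        topology = read_topology(
            config.structure, config.parameters, ligand_resnames=config.ligand_resnames
        )
        full = read_trajectory(config.trajectory, topology, config.frame_spacing_ps)
        logger.info("read %d frames, %d atoms", full.n_frames, topology.n_atoms)

        stage = "frame_selection"
        window = min(config.window_ns, full.span_ps / 1000.0)
        traj = select_frames(full, window, config.stride) if full.n_frames > 1 else full
        summary["n_frames_analyzed"] = traj.n_frames

        stage = "convergence"
        report = convergence_report(full)
        _write_csv(
            pd.DataFrame({"time_ps": full.times, "rmsd_A": report.rmsd_series}),
            out / "rmsd.csv",
        )
        _write_csv(
            pd.DataFrame(
                {"residue": list(report.rmsf_per_residue), "rmsf_A": list(report.rmsf_per_residue.values())}
            ),
            out / "rmsf.csv",
        )
        summary["rmsd_plateau"] = bool(report.plateau)

        stage = "geometry"
        records = geometry_series(
            traj, config.donor_residue, config.acceptor_residue,
            config.donor_atom, config.acceptor_atom,
        )
        _write_csv(
            pd.DataFrame(
                {
                    "frame": [r.frame_index for r in records],
                    "angle_deg": [r.angle for r in records],
                    "reactive_distance_A": [r.reactive_distance for r in records],
                    "com_distance_A": [r.com_distance for r in records],
                }
            ),
            out / "geometry.csv",
        )
        density, a_edges, d_edges = angle_distance_histogram(records)
        rows = [
            {"angle_lo": a_edges[i], "distance_lo": d_edges[j], "density": density[i, j]}
            for i in range(density.shape[0])
            for j in range(density.shape[1])
            if density[i, j] > 0
        ]
        _write_csv(pd.DataFrame(rows), out / "histogram.csv")
        ref = GeometryReference(config.reference_angle, config.reference_distance)
        summary["fraction_near_reference"] = fraction_near_reference(records, ref)
        summary["mean_angle_deg"] = float(np.mean([r.angle for r in records]))
        summary["mean_reactive_distance_A"] = float(np.mean([r.reactive_distance for r in records]))

        stage = "hbonds"
        region_map = read_region_map(config.region_map) if config.region_map else None
        table = occupancy_table(
            traj, region_map, config.distance_cutoff, config.angle_cutoff
        )
        _write_csv(
            pd.DataFrame(
                {
                    "residue_i": [r.residue_pair[0] for r in table],
                    "residue_j": [r.residue_pair[1] for r in table],
                    "occupancy_pct": [r.occupancy for r in table],
                    "region": [r.region_id or "" for r in table],
                }
            ),
            out / "hbonds.csv",
        )
        summary["n_hbond_pairs"] = len(table)

        stage = "energetics"
        lig = ligand_atom_indices(topology)
        if lig.size:
            pocket = select_pocket_residues(traj, lig, config.pocket_cutoff)
            decomp = per_residue_decomposition(traj, lig, pocket, config.eps_in)
            _write_csv(
                pd.DataFrame(
                    {
                        "residue": [r.residue_index for r in decomp],
                        "class": [r.polarity_class for r in decomp],
                        "elec_kcal": [r.elec_mean for r in decomp],
                        "vdw_kcal": [r.vdw_mean for r in decomp],
                        "total_kcal": [r.total_mean for r in decomp],
                    }
                ),
                out / "decomposition.csv",
            )
            sums = group_decomposition(decomp)
            _write_csv(
                pd.DataFrame(
                    [
                        {
                            "charged_kcal": sums.charged,
                            "polar_nonpolar_kcal": sums.polar_nonpolar,
                            "hormonogenic_kcal": sums.hormonogenic,
                            "sum_kcal": sums.total,
                        }
                    ]
                ),
                out / "group_sums.csv",
            )
            binding = mmgbsa_binding(
                traj, lig,
                eps_in=config.eps_in, eps_out=config.eps_out,
                salt_molar=config.salt_molar, gamma_np=config.gamma_np,
                alpha=config.obc_alpha, beta=config.obc_beta, gamma=config.obc_gamma,
                sasa_points=config.sasa_points,
            )
            _write_csv(
                pd.DataFrame(
                    [{"mean_kcal": binding.mean, "sd_kcal": binding.sd, "n_frames": binding.n_frames}]
                ),
                out / "binding.csv",
            )
            summary["binding_mean_kcal"] = binding.mean
            summary["binding_sd_kcal"] = binding.sd

        stage = "clustering"
        clusters = cluster_orientations(records, config.cluster_eps, config.cluster_min_samples)
        _write_csv(
            pd.DataFrame(
                {
                    "frame": [r.frame_index for r in records],
                    "cluster": clusters.labels,
                }
            ),
            out / "clusters.csv",
        )
        summary["n_clusters"] = len(clusters.representative_frame)
        summary["representative_frames"] = {
            str(k): int(v) for k, v in clusters.representative_frame.items()
        }

        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        logger.info("pipeline complete: %s", out)
        return out
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
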