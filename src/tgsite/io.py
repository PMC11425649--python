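"""File I/O: structures, parameter tables, trajectories, region maps.

Structures and trajectories go through MDAnalysis, so multi-MODEL PDB is the
canonical text interchange format and binary formats (DCD/XTC) work wherever
MDAnalysis supports them. Per-atom parameters (partial charge, Lennard-Jones,
GB intrinsic radius) come from a plain-text table because force-field
assignment is out of scope here — parameters are data, not something this
package derives.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import MDAnalysis as mda
import numpy as np
import pandas as pd
import yaml

from .model import AtomRecord, RegionMap, Residue, Topology, TopologyError, Trajectory, assign_polarity_classes

PARAM_COLUMNS = [
    "residue_name",
    "atom_name",
    "charge_e",
    "rmin_half_A",
    "epsilon_kcal",
    "gb_radius_A",
]

_TWO_LETTER_ELEMENTS = {"CL", "BR", "NA", "MG", "ZN", "FE", "SE", "MN", "CU"}


def guess_element(atom_name: str) -> str:
    """Element from a PDB atom name (IUPAC-ish names: CG, OG, NZ, I1, F12...)."""
    stripped = "".join(c for c in atom_name if c.isalpha()).upper()
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    if stripped in _TWO_LETTER_ELEMENTS:
        return stripped.capitalize()
    return stripped[0]


def read_parameter_table(path: str | Path) -> pd.DataFrame:
    """Whitespace- or comma-separated table with the PARAM_COLUMNS header."""
    df = pd.read_csv(path, sep=r"[,\s]+", engine="python", comment="#")
    missing = set(PARAM_COLUMNS) - set(df.columns)
    if missing:
        raise TopologyError(f"parameter table {path} missing columns: {sorted(missing)}")
    return df


def write_parameter_table(topology: Topology, path: str | Path) -> None:
    res_name = {r.index: r.name for r in topology.residues}
    rows = [
        {
            "residue_name": res_name[a.residue_index],
            "atom_name": a.atom_name,
            "charge_e": a.charge,
            "rmin_half_A": a.lj_rmin_half,
            "epsilon_kcal": a.lj_epsilon,
            "gb_radius_A": a.intrinsic_radius,
        }
        for a in topology.atoms
    ]
    # one parameter row per (residue name, atom name) template, like a
    # force-field library file
    df = pd.DataFrame(rows).drop_duplicates(subset=["residue_name", "atom_name"])
    df.to_csv(path, index=False, float_format="%.6f")


def read_topology(
    structure_path: str | Path,
    parameters_path: str | Path,
    ligand_resnames: tuple[str, ...] = (),
    class_map: dict[str, str] | None = None,
    assign_classes: bool = True,
) -> Topology:
    """Build a Topology from a PDB structure and a parameter table.

    Atoms are matched to parameter rows by (residue name, atom name); a
    missing row or a duplicate atom name within a residue is an error.
    Residues whose name appears in ``ligand_resnames`` are flagged as ligand.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(structure_path))
    params = read_parameter_table(parameters_path)
    lookup: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    for row in params.itertuples(index=False):
        lookup[(str(row.residue_name), str(row.atom_name))] = (
            float(row.charge_e),
            float(row.rmin_half_A),
            float(row.epsilon_kcal),
            float(row.gb_radius_A),
        )

    atoms: list[AtomRecord] = []
    residues: list[Residue] = []
    ligand_indices: set[int] = set()
    seen_in_res: set[tuple[int, str]] = set()
    for res in u.residues:
        resid = int(res.resid)
        resname = str(res.resname).strip()
        chain = str(getattr(res.atoms[0], "chainID", "") or getattr(res, "segid", "A") or "A").strip() or "A"
        residues.append(Residue(index=resid, name=resname, chain_id=chain))
        if resname in ligand_resnames:
            ligand_indices.add(resid)
        for atom in res.atoms:
            name = str(atom.name).strip()
            key = (resid, name)
            if key in seen_in_res:
                raise TopologyError(f"duplicate atom {name} in residue {resname}{resid}")
            seen_in_res.add(key)
            try:
                charge, rmin_half, eps, gb_r = lookup[(resname, name)]
            except KeyError:
                raise TopologyError(
                    f"no parameter row for atom {name} of residue {resname}{resid}"
                ) from None
            element = getattr(atom, "element", "") or ""
            element = element.strip().capitalize() if element else guess_element(name)
            atoms.append(
                AtomRecord(
                    atom_name=name,
                    element=element,
                    residue_index=resid,
                    charge=charge,
                    lj_rmin_half=rmin_half,
                    lj_epsilon=eps,
                    intrinsic_radius=gb_r,
                )
            )
    top = Topology(atoms=atoms, residues=residues, ligand_residue_indices=ligand_indices)
    if assign_classes:
        top = assign_polarity_classes(top, class_map)
    return top


def read_trajectory(
    path: str | Path,
    topology: Topology,
    frame_spacing_ps: float = 1.0,
    structure_path: str | Path | None = None,
) -> Trajectory:
    """Read a multi-MODEL PDB (or any MDAnalysis-supported trajectory).

    Binary formats that carry no topology (DCD/XTC) need ``structure_path``.
    Frame times are assigned as ``i * frame_spacing_ps`` because plain PDB
    carries no time metadata; 1 ps is the conventional write frequency that
    makes a 20 ns run yield 500 frames under last-5-ns / stride-10 selection.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if structure_path is not None:
            u = mda.Universe(str(structure_path), str(path))
        else:
            u = mda.Universe(str(path))
    if u.atoms.n_atoms != topology.n_atoms:
        raise TopologyError(
            f"trajectory has {u.atoms.n_atoms} atoms but topology has {topology.n_atoms}"
        )
    coords = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    times = np.arange(coords.shape[0], dtype=float) * frame_spacing_ps
    return Trajectory(topology=topology, coordinates=coords, times=times)


def _build_universe(topology: Topology) -> mda.Universe:
    res_order = [r.index for r in topology.residues]
    res_pos = {idx: k for k, idx in enumerate(res_order)}
    atom_resindex = np.array([res_pos[a.residue_index] for a in topology.atoms])
    u = mda.Universe.empty(
        n_atoms=topology.n_atoms,
        n_residues=len(topology.residues),
        atom_resindex=atom_resindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.atom_name for a in topology.atoms])
    u.add_TopologyAttr("elements", [a.element for a in topology.atoms])
    u.add_TopologyAttr("resnames", [r.name for r in topology.residues])
    u.add_TopologyAttr("resids", [r.index for r in topology.residues])
    u.add_TopologyAttr("chainIDs", [topology.residues[res_pos[a.residue_index]].chain_id for a in topology.atoms])
    u.add_TopologyAttr("occupancies", np.ones(topology.n_atoms))
    u.add_TopologyAttr("tempfactors", np.zeros(topology.n_atoms))
    return u


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write frames as a multi-MODEL PDB (or any format MDAnalysis infers)."""
    u = _build_universe(trajectory.topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), trajectory.topology.n_atoms, multiframe=True) as w:
            for frame in trajectory.coordinates:
                u.atoms.positions = frame
                w.write(u.atoms)


def write_structure(topology: Topology, coordinates: np.ndarray, path: str | Path) -> None:
    """Write a single coordinate set as a one-MODEL PDB."""
    traj = Trajectory(
        topology=topology,
        coordinates=np.asarray(coordinates, dtype=float)[None, :, :],
        times=np.zeros(1),
    )
    write_trajectory(traj, path)


def read_region_map(path: str | Path) -> RegionMap:
    """YAML region map: ``{regions: {id: {residues: [...], structure: loop|helix}}}``."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    regions = {}
    structure = {}
    for rid, spec in (data.get("regions") or {}).items():
        regions[str(rid)] = set(int(i) for i in spec["residues"])
        if "structure" in spec:
            structure[str(rid)] = str(spec["structure"])
    return RegionMap(regions=regions, structure=structure)


def write_region_map(region_map: RegionMap, path: str | Path) -> None:
    data = {
        "regions": {
            rid: {
                "residues": sorted(members),
                **({"structure": region_map.structure[rid]} if rid in region_map.structure else {}),
            }
            for rid, members in region_map.regions.items()
        }
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)
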