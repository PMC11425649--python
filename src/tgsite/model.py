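"""Domain types for binding-site trajectory analysis.

Coordinates are ångström throughout, times picoseconds, charges elementary
charges, energies kcal/mol. Residue numbering follows the input file
unchanged, because published discussions refer to author numbering
(e.g. ITY2540, ITY2573, K2536).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

#: residue polarity classes used to group per-residue decomposition energies
POLARITY_CLASSES = ("polar", "nonpolar", "basic", "acidic", "hormonogenic", "ligand")

#: default residue-name -> polarity-class map (standard amino-acid chemistry;
#: includes common protonation-variant names). ITY is diiodotyrosine, the
#: hormonogenic residue. User maps may override or extend.
DEFAULT_CLASS_MAP: dict[str, str] = {
    **{n: "basic" for n in ("LYS", "ARG", "HIS", "HIE", "HID", "HIP", "LYN")},
    **{n: "acidic" for n in ("ASP", "GLU", "ASH", "GLH")},
    **{n: "polar" for n in ("SER", "THR", "ASN", "GLN", "CYS", "CYX", "TYR", "TRP")},
    **{n: "nonpolar" for n in ("ALA", "VAL", "LEU", "ILE", "MET", "PHE", "PRO", "GLY")},
    "ITY": "hormonogenic",
}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"})

#: standard atomic masses (u) for center-of-mass calculations
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "Br": 79.904,
    "I": 126.904,
}


class TopologyError(ValueError):
    """Raised for inconsistent topology input (missing parameters, duplicates)."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom with the per-atom parameters entering the nonbonded and GB sums."""

    atom_name: str
    element: str
    residue_index: int
    charge: float  # e
    lj_rmin_half: float  # Å, r_min/2
    lj_epsilon: float  # kcal/mol, well depth
    intrinsic_radius: float  # Å, GB intrinsic (e.g. mbondi2-style) radius

    def __post_init__(self) -> None:
        if self.lj_epsilon < 0:
            raise ValueError(
                f"negative LJ epsilon for {self.atom_name}: {self.lj_epsilon}"
            )


@dataclass(frozen=True)
class Residue:
    index: int
    name: str  # 3-letter code; ITY = diiodotyrosine
    chain_id: str = "A"
    polarity_class: str | None = None


@dataclass
class Topology:
    """Ordered atoms and residues; ligand residues flagged by index."""

    atoms: list[AtomRecord]
    residues: list[Residue]
    ligand_residue_indices: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        res_idx = {r.index for r in self.residues}
        for a in self.atoms:
            if a.residue_index not in res_idx:
                raise TopologyError(
                    f"atom {a.atom_name} references unknown residue {a.residue_index}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residue(self, index: int) -> Residue:
        for r in self.residues:
            if r.index == index:
                return r
        raise KeyError(f"no residue with index {index}")

    def atom_indices_of_residue(self, residue_index: int) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.residue_index == residue_index],
            dtype=int,
        )

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.residue_index == residue_index and a.atom_name == atom_name:
                return i
        raise KeyError(f"atom {atom_name} not found in residue {residue_index}")

    # parameter arrays, in atom order, for vectorised energy kernels
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    def lj_rmin_half(self) -> np.ndarray:
        return np.array([a.lj_rmin_half for a in self.atoms])

    def lj_epsilon(self) -> np.ndarray:
        return np.array([a.lj_epsilon for a in self.atoms])

    def intrinsic_radii(self) -> np.ndarray:
        return np.array([a.intrinsic_radius for a in self.atoms])

    def subset(self, atom_indices: np.ndarray) -> "Topology":
        """Topology restricted to the given atoms (keeps residue metadata)."""
        atom_indices = np.asarray(atom_indices, dtype=int)
        atoms = [self.atoms[i] for i in atom_indices]
        keep_res = {a.residue_index for a in atoms}
        residues = [r for r in self.residues if r.index in keep_res]
        return Topology(
            atoms=atoms,
            residues=residues,
            ligand_residue_indices=self.ligand_residue_indices & keep_res,
        )


@dataclass
class Trajectory:
    """Ordered frames of Cartesian coordinates with uniformly spaced times."""

    topology: Topology
    coordinates: np.ndarray  # (n_frames, n_atoms, 3) Å
    times: np.ndarray  # (n_frames,) ps, strictly increasing, uniform

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError(f"coordinates must be (frames, atoms, 3), got {self.coordinates.shape}")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.coordinates.shape[1]} != "
                f"topology atom count {self.topology.n_atoms}"
            )
        if len(self.times) != self.coordinates.shape[0]:
            raise ValueError("times length must equal number of frames")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if np.ptp(dt) > 1e-6:
                raise ValueError("frame times must be uniformly spaced (1e-6 ps)")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def span_ps(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.n_frames > 1 else 0.0


@dataclass
class RegionMap:
    """Disjoint residue-index regions with a secondary-structure tag each."""

    regions: dict[str, set[int]]
    structure: dict[str, str] = field(default_factory=dict)  # region -> loop|helix

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for rid, members in self.regions.items():
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"region {rid} overlaps earlier regions at {sorted(overlap)}")
            seen |= set(members)

    def region_of_pair(self, i: int, j: int) -> str | None:
        """Region containing both residues, or None."""
        for rid, members in self.regions.items():
            if i in members and j in members:
                return rid
        return None


def assign_polarity_classes(
    topology: Topology, class_map: dict[str, str] | None = None
) -> Topology:
    """Label every residue with its polarity class.

    Ligand residues are classed ``ligand`` regardless of name; unmapped
    residue names raise listing every offender.
    """
    cmap = dict(DEFAULT_CLASS_MAP)
    if class_map:
        cmap.update(class_map)
    missing = sorted(
        {
            r.name
            for r in topology.residues
            if r.name not in cmap and r.index not in topology.ligand_residue_indices
        }
    )
    if missing:
        raise TopologyError(f"no polarity class for residue name(s): {', '.join(missing)}")
    residues = [
        replace(
            r,
            polarity_class=(
                "ligand" if r.index in topology.ligand_residue_indices else cmap[r.name]
            ),
        )
        for r in topology.residues
    ]
    return Topology(
        atoms=topology.atoms,
        residues=residues,
        ligand_residue_indices=set(topology.ligand_residue_indices),
    )


def select_frames(trajectory: Trajectory, window_ns: float, stride: int = 1) -> Trajectory:
    """Keep frames from the final ``window_ns`` of the run, then every
    ``stride``-th of those starting at the first.

    The window is half-open: frames with time strictly greater than
    (end - window) are kept, so the boundary frame is not double-counted.
    A 20 ns run written every 1 ps with window 5 ns, stride 10 yields 500
    frames. The selected count is ceil(n_window / stride).
    """
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    window_ps = window_ns * 1000.0
    if window_ps > trajectory.span_ps + 1e-9:
        raise ValueError(
            f"window {window_ns} ns exceeds trajectory span {trajectory.span_ps / 1000.0} ns"
        )
    t_end = trajectory.times[-1]
    if window_ps >= trajectory.span_ps - 1e-9:  # whole-run window: keep all
        in_window = np.arange(trajectory.n_frames)
    else:
        in_window = np.nonzero(trajectory.times > t_end - window_ps + 1e-9)[0]
    picked = in_window[::stride]
    n_window = len(in_window)
    assert len(picked) == math.ceil(n_window / stride) if n_window else True
    return Trajectory(
        topology=trajectory.topology,
        coordinates=trajectory.coordinates[picked],
        times=trajectory.times[picked],
    )
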