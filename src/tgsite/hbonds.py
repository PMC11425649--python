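"""Hydrogen-bond detection, occupancy tables, and network comparison.

Occupancy — the percentage of analyzed frames in which a residue pair forms
at least one hydrogen bond — is the unit of the region-wise rigidity
analysis: regions of the binding site are compared between the apo system
and each ligand-bound system, since extra persistent bonds within a helix
region mean a stiffer helix-loop-helix element and hence a site less able
to rearrange for hormone synthesis.

Geometric criteria: heavy-atom donor–acceptor distance ≤ 3.0 Å and
D–H···A angle ≥ 135°. Donors are N/O/S atoms with at least one bonded
hydrogen (a hydrogen within 1.2 Å when no bond table is available);
acceptors are N/O/S and, by default, fluorine — perfluorinated tails
participate in the contact analysis. Intra-residue pairs are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .model import RegionMap, Topology, Trajectory

DONOR_ELEMENTS = frozenset({"N", "O", "S"})
ACCEPTOR_ELEMENTS = frozenset({"N", "O", "S", "F"})
BOND_INFER_CUTOFF = 1.2  # Å, H considered bonded to the nearest heavy atom


def default_region_map() -> RegionMap:
    """Helix region around the donor ITY (S2534…ITY2540); the two flanking
    loop/helix regions are system-specific and must be user-supplied."""
    return RegionMap(
        regions={"region2": set(range(2534, 2541))},
        structure={"region2": "helix"},
    )


@dataclass(frozen=True)
class HBondEvent:
    donor_atom: int  # topology atom index of the donor heavy atom
    hydrogen_atom: int
    acceptor_atom: int
    frame_index: int
    da_distance: float  # Å
    dha_angle: float  # degrees


@dataclass(frozen=True)
class OccupancyRecord:
    residue_pair: tuple[int, int]
    occupancy: float  # percent of frames, [0, 100]
    region_id: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 100.0:
            raise ValueError(f"occupancy outside [0, 100]: {self.occupancy}")


@dataclass
class NetworkDiff:
    persisting: set[tuple[int, int]]
    gained: set[tuple[int, int]]
    lost: set[tuple[int, int]]
    occupancy_delta: dict[tuple[int, int], float]  # bound - apo, percentage points


def _donor_hydrogen_pairs(coords: np.ndarray, topology: Topology):
    """(donor heavy atom, hydrogen) pairs, bond inferred by distance."""
    h_idx = [i for i, a in enumerate(topology.atoms) if a.element == "H"]
    heavy_idx = [i for i, a in enumerate(topology.atoms) if a.element in DONOR_ELEMENTS]
    pairs = []
    if h_idx and heavy_idx:
        d = cdist(coords[h_idx], coords[heavy_idx])
        for row, h in enumerate(h_idx):
            col = np.argmin(d[row])
            if d[row, col] <= BOND_INFER_CUTOFF:
                pairs.append((heavy_idx[col], h))
    return pairs


def detect_hbonds(
    coords: np.ndarray,
    topology: Topology,
    distance_cutoff: float = 3.0,
    angle_cutoff: float = 135.0,
    frame_index: int = 0,
    fluorine_acceptors: bool = True,
) -> list[HBondEvent]:
    """All donor→acceptor events in one frame meeting both criteria."""
    acceptors = [
        i
        for i, a in enumerate(topology.atoms)
        if a.element in ACCEPTOR_ELEMENTS and (fluorine_acceptors or a.element != "F")
    ]
    events = []
    for d_i, h_i in _donor_hydrogen_pairs(coords, topology):
        d_res = topology.atoms[d_i].residue_index
        for a_i in acceptors:
            if a_i == d_i or topology.atoms[a_i].residue_index == d_res:
                continue
            r_da = float(np.linalg.norm(coords[a_i] - coords[d_i]))
            if r_da > distance_cutoff:
                continue
            v1 = coords[d_i] - coords[h_i]
            v2 = coords[a_i] - coords[h_i]
            denom = np.linalg.norm(v1) * np.linalg.norm(v2)
            if denom < 1e-12:
                continue
            ang = float(np.degrees(np.arccos(np.clip(v1 @ v2 / denom, -1.0, 1.0))))
            if ang >= angle_cutoff:
                events.append(
                    HBondEvent(
                        donor_atom=d_i,
                        hydrogen_atom=h_i,
                        acceptor_atom=a_i,
                        frame_index=frame_index,
                        da_distance=r_da,
                        dha_angle=ang,
                    )
                )
    return events


def occupancy_table(
    trajectory: Trajectory,
    region_map: RegionMap | None = None,
    distance_cutoff: float = 3.0,
    angle_cutoff: float = 135.0,
    fluorine_acceptors: bool = True,
) -> list[OccupancyRecord]:
    """Percent-of-frames occupancy per residue pair.

    A pair counts in a frame if it forms >= 1 event through any atom pair
    (matching residue-pair-level reporting). Sorted by descending occupancy,
    ties by ascending residue-index pair.
    """
    top = trajectory.topology
    frames_with: dict[tuple[int, int], set[int]] = {}
    for f in range(trajectory.n_frames):
        for ev in detect_hbonds(
            trajectory.coordinates[f], top, distance_cutoff, angle_cutoff, f, fluorine_acceptors
        ):
            i = top.atoms[ev.donor_atom].residue_index
            j = top.atoms[ev.acceptor_atom].residue_index
            pair = (min(i, j), max(i, j))
            frames_with.setdefault(pair, set()).add(f)
    records = [
        OccupancyRecord(
            residue_pair=pair,
            occupancy=100.0 * len(frames) / trajectory.n_frames,
            region_id=region_map.region_of_pair(*pair) if region_map else None,
        )
        for pair, frames in frames_with.items()
    ]
    return sorted(records, key=lambda r: (-r.occupancy, r.residue_pair))


def count_region_interactions(
    table: list[OccupancyRecord], region_id: str, min_occupancy: float = 10.0
) -> int:
    """Number of pairs in the region at or above the occupancy threshold."""
    return sum(
        1 for r in table if r.region_id == region_id and r.occupancy >= min_occupancy
    )


def compare_networks(
    apo_table: list[OccupancyRecord],
    bound_table: list[OccupancyRecord],
    min_occupancy: float = 10.0,
) -> NetworkDiff:
    """Partition residue pairs into persisting / gained / lost between the
    apo and ligand-bound networks, thresholded at ``min_occupancy``."""
    apo = {r.residue_pair: r.occupancy for r in apo_table if r.occupancy >= min_occupancy}
    bound = {r.residue_pair: r.occupancy for r in bound_table if r.occupancy >= min_occupancy}
    persisting = set(apo) & set(bound)
    gained = set(bound) - set(apo)
    lost = set(apo) - set(bound)
    assert persisting | gained | lost == set(apo) | set(bound)
    assert not (persisting & gained or persisting & lost or gained & lost)
    return NetworkDiff(
        persisting=persisting,
        gained=gained,
        lost=lost,
        occupancy_delta={p: bound[p] - apo[p] for p in persisting},
    )
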