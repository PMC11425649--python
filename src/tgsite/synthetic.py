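"""Synthetic binding-site systems with known ground truth.

This module generates toy analogues of a thyroglobulin hormonogenic site:
two diiodotyrosine-like (ITY) residues whose inter-plane angle and
reactive-atom distance are drawn per frame from a configurable (possibly
bimodal) mixture of truncated normals, pocket residues of all four polarity
classes, declared hydrogen-bond pairs toggled in and out of geometric
criteria with planted occupancies, and perfluoroalkyl carboxylate/sulfonate
ligands of arbitrary chain length. Every analysis stage of the package can
therefore be validated against recorded ground truth without any external
structure.

The generated systems make no claim of physical realism beyond the planted
statistics: no energy minimisation is performed and the toy site does not
reproduce the protein's actual fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation
from scipy.stats import truncnorm

from .model import AtomRecord, Residue, Topology, Trajectory

# Fixed per-element stand-in parameters (charges are set per template).
# These are documented stand-ins chosen once for internal consistency —
# semi-empirical charge derivation is deliberately out of scope.
_LJ = {  # element -> (rmin/2 Å, epsilon kcal/mol)
    "H": (0.60, 0.0157),
    "C": (1.908, 0.086),
    "N": (1.824, 0.170),
    "O": (1.6612, 0.210),
    "F": (1.75, 0.061),
    "S": (2.00, 0.250),
    "I": (2.35, 0.400),
}
_GB_RADIUS = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.5, "F": 1.5, "S": 1.8, "I": 2.0}

DONOR_ITY_INDEX = 2540
ACCEPTOR_ITY_INDEX = 2573
LIGAND_RESIDUE_INDEX = 2999


@dataclass(frozen=True)
class PfasSpec:
    """A perfluoroalkyl acid: head group plus fluorinated-carbon count."""

    head_group: str  # "carboxylate" | "sulfonate"
    n_fluorinated_carbons: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.head_group not in ("carboxylate", "sulfonate"):
            raise ValueError(f"unknown head group {self.head_group!r}")
        if self.n_fluorinated_carbons < 1:
            raise ValueError("need at least one fluorinated carbon")


@dataclass(frozen=True)
class GeometryDistribution:
    """Mixture of truncated normals over (inter-plane angle, reactive distance).

    components: list of (weight, mean_angle deg, angle_sd deg,
    mean_distance Å, distance_sd Å). Weights must sum to 1.
    """

    components: tuple[tuple[float, float, float, float, float], ...]

    def __post_init__(self) -> None:
        w = np.array([c[0] for c in self.components])
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must be >= 0 and sum to 1, got {w}")
        for c in self.components:
            if c[2] <= 0 or c[4] <= 0:
                raise ValueError("standard deviations must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, recorded for parameter-recovery checks."""

    geometry: GeometryDistribution
    hbond_occupancy: dict[tuple[int, int], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for pair, p in self.hbond_occupancy.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"occupancy for {pair} outside [0,1]: {p}")

    def to_json(self, path: str | Path) -> None:
        data = {
            "geometry": [list(c) for c in self.geometry.components],
            "hbond_occupancy": {f"{i},{j}": p for (i, j), p in self.hbond_occupancy.items()},
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        return cls(
            geometry=GeometryDistribution(tuple(tuple(c) for c in data["geometry"])),
            hbond_occupancy={
                tuple(int(x) for x in k.split(",")): float(v)
                for k, v in data["hbond_occupancy"].items()
            },
            seed=int(data["seed"]),
        )


@dataclass
class SyntheticSite:
    """A generated site: topology, base coordinates, and bookkeeping.

    ``residue_direction`` records each pocket residue's outward radial
    direction and ``hbond_direction`` each serine's donor O–H axis; both are
    used to re-pose hydrogen-bond partners rigidly at sampling time.
    """

    topology: Topology
    base_coordinates: np.ndarray  # (n_atoms, 3) Å
    donor_residue: int = DONOR_ITY_INDEX
    acceptor_residue: int = ACCEPTOR_ITY_INDEX
    residue_direction: dict[int, np.ndarray] = field(default_factory=dict)
    hbond_direction: dict[int, np.ndarray] = field(default_factory=dict)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector ``a`` onto unit vector ``b``."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    axis = np.cross(a, b)
    s = np.linalg.norm(axis)
    c = float(a @ b)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180° about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return Rotation.from_rotvec(np.pi * perp / np.linalg.norm(perp)).as_matrix()
    return Rotation.from_rotvec(axis / s * np.arccos(np.clip(c, -1, 1))).as_matrix()


def _atom(name: str, element: str, resid: int, charge: float) -> AtomRecord:
    rmin, eps = _LJ[element]
    return AtomRecord(
        atom_name=name,
        element=element,
        residue_index=resid,
        charge=charge,
        lj_rmin_half=rmin,
        lj_epsilon=eps,
        intrinsic_radius=_GB_RADIUS[element],
    )


def _ity_template(resid: int, backbone: bool = True) -> tuple[list[AtomRecord], np.ndarray]:
    """Diiodotyrosine-like residue in local coordinates.

    Phenol ring in the z=0 plane, hydroxyl on CZ at (-2.75, 0, 0), iodines
    flanking the hydroxyl on CE1/CE2 (3,5-diiodo substitution), minimal
    backbone. The CG→I1 and CG→I2 vectors define the ring plane; their
    cross product points along +z in this frame.
    """
    r = 1.39  # aromatic C-C
    ring = {
        "CG": (r, 0.0, 0.0),
        "CD1": (r / 2, r * np.sqrt(3) / 2, 0.0),
        "CD2": (r / 2, -r * np.sqrt(3) / 2, 0.0),
        "CE1": (-r / 2, r * np.sqrt(3) / 2, 0.0),
        "CE2": (-r / 2, -r * np.sqrt(3) / 2, 0.0),
        "CZ": (-r, 0.0, 0.0),
    }
    coords = dict(ring)
    # C-I 2.09 Å along the ring-radial direction
    for iname, cname in (("I1", "CE1"), ("I2", "CE2")):
        c = np.array(ring[cname])
        coords[iname] = tuple(c + 2.09 * c / np.linalg.norm(c))
    coords["OH"] = (-2.75, 0.0, 0.0)
    coords["HH"] = (-3.31, 0.78, 0.0)
    coords["CB"] = (2.92, 0.0, 0.55)
    if backbone:
        coords["N"] = (4.30, 1.20, 1.40)
        coords["CA"] = (3.80, 0.0, 1.95)
        coords["C"] = (4.60, -1.10, 2.55)
        coords["O"] = (5.80, -1.05, 2.60)
    charges = {
        "CG": 0.05, "CD1": -0.12, "CD2": -0.12, "CE1": 0.12, "CE2": 0.12,
        "CZ": 0.40, "OH": -0.55, "HH": 0.43, "I1": -0.16, "I2": -0.16,
        "CB": -0.05, "N": -0.42, "CA": 0.03, "C": 0.60, "O": -0.57,
    }
    atoms = [_atom(n, ("I" if n.startswith("I") else n[0]), resid, charges[n]) for n in coords]
    return atoms, np.array([coords[n] for n in coords], dtype=float)


# pocket residue templates: name -> [(atom, element, charge, local xyz)]
_POCKET_TEMPLATES: dict[str, list[tuple[str, str, float, tuple[float, float, float]]]] = {
    "SER": [
        ("N", "N", -0.42, (2.6, 1.1, 0.6)),
        ("CA", "C", 0.03, (2.4, 0.0, -0.3)),
        ("C", "C", 0.60, (3.5, -1.0, -0.5)),
        ("O", "O", -0.57, (4.6, -0.8, 0.0)),
        ("CB", "C", 0.20, (1.1, -0.7, 0.0)),
        ("OG", "O", -0.65, (0.0, 0.0, 0.0)),
        ("HG", "H", 0.43, (-0.90, 0.22, 0.0)),
    ],
    "ALA": [
        ("N", "N", -0.42, (1.4, 1.2, 0.5)),
        ("CA", "C", 0.03, (1.2, 0.0, -0.4)),
        ("C", "C", 0.60, (2.3, -1.0, -0.5)),
        ("O", "O", -0.57, (3.4, -0.8, 0.0)),
        ("CB", "C", -0.10, (0.0, 0.0, 0.0)),
    ],
    "LYS": [
        ("N", "N", -0.42, (4.9, 1.2, 0.5)),
        ("CA", "C", 0.03, (4.7, 0.0, -0.4)),
        ("C", "C", 0.60, (5.8, -1.0, -0.5)),
        ("O", "O", -0.57, (6.9, -0.8, 0.0)),
        ("CB", "C", 0.00, (3.4, -0.7, 0.0)),
        ("CD", "C", 0.00, (2.2, 0.2, 0.0)),
        ("CE", "C", 0.36, (1.0, -0.5, 0.0)),
        ("NZ", "N", 0.40, (0.0, 0.4, 0.0)),
    ],
    "ASP": [
        # built pointing "forward": OD1 at the local origin is the closest
        # atom along -x, so a translated copy approaches donors OD1-first
        ("OD1", "O", -0.80, (0.0, 0.0, 0.0)),
        ("CG", "C", 0.80, (1.15, 0.55, 0.0)),
        ("OD2", "O", -0.80, (1.25, 1.80, 0.0)),
        ("CB", "C", -0.20, (2.35, -0.30, 0.0)),
        ("CA", "C", 0.03, (3.65, 0.45, 0.0)),
        ("N", "N", -0.42, (3.9, 1.6, 0.8)),
        ("C", "C", 0.60, (4.85, -0.45, 0.0)),
        ("O", "O", -0.57, (6.0, -0.1, 0.3)),
    ],
}

_CLASS_RESNAMES = (("polar", "SER"), ("nonpolar", "ALA"), ("basic", "LYS"), ("acidic", "ASP"))


def build_pfas(spec: PfasSpec) -> tuple[Topology, np.ndarray]:
    """Idealized PFCA/PFSA ligand: CF2 chain capped by CF3, anionic head.

    Template charges distribute the full -1 e over the head group
    (carboxylate C +0.7 / O -0.85 each; sulfonate S +1.1 / O -0.7 each)
    while each CFx unit is neutral (chain C +0.24, terminal C +0.36,
    F -0.12), so the net ligand charge is exactly -1 e.
    """
    n = spec.n_fluorinated_carbons
    resid = LIGAND_RESIDUE_INDEX
    resname = "PFC" if spec.head_group == "carboxylate" else "PFS"
    atoms: list[AtomRecord] = []
    coords: list[tuple[float, float, float]] = []

    # zig-zag backbone: 1.54 Å bonds, ~111° angles
    dx, dy = 1.54 * np.sin(np.deg2rad(55.5)), 1.54 * np.cos(np.deg2rad(55.5))
    if spec.head_group == "carboxylate":
        head = [("C1H", "C", 0.70, (-dx, dy, 0.0)),
                ("O1", "O", -0.85, (-dx - 0.7, dy + 1.05, 0.0)),
                ("O2", "O", -0.85, (-dx - 0.7, dy - 1.05, 0.0))]
    else:
        head = [("S", "S", 1.10, (-dx, dy, 0.0)),
                ("O1", "O", -0.70, (-dx - 0.8, dy + 1.2, 0.0)),
                ("O2", "O", -0.70, (-dx - 0.8, dy - 1.2, 0.0)),
                ("O3", "O", -0.70, (-dx + 0.4, dy + 0.2, 1.35))]
    for name, el, q, xyz in head:
        atoms.append(_atom(name, el, resid, q))
        coords.append(xyz)

    nf = 0
    for i in range(n):
        x, y = i * dx, (dy / 2) * (-1) ** i
        terminal = i == n - 1
        atoms.append(_atom(f"C{i + 1}", "C", resid, 0.36 if terminal else 0.24))
        coords.append((x, y, 0.0))
        n_f = 3 if terminal else 2
        for k in range(n_f):
            nf += 1
            ang = 2 * np.pi * k / 3 + (0.5 if i % 2 else 0.0)
            atoms.append(_atom(f"F{nf}", "F", resid, -0.12))
            coords.append((x + (0.45 if terminal and k == 2 else 0.0),
                           y + 0.45 * np.cos(ang),
                           1.28 * np.sin(ang + np.pi / 6) + (0.45 if k % 2 else -0.45)))
    top = Topology(
        atoms=atoms,
        residues=[Residue(index=resid, name=resname, chain_id="L", polarity_class="ligand")],
        ligand_residue_indices={resid},
    )
    return top, np.array(coords, dtype=float)


_SITE_CENTER = np.array([-5.0, 0.0, 0.0])
_POCKET_RADIUS = 11.0  # Å, sphere of pocket residues around the site


def _band_directions(n_needed: int, seed: int) -> np.ndarray:
    """Deterministic quasi-uniform sphere directions restricted to the band
    that leaves free corridors for the swinging acceptor ITY (along -x), the
    static donor (along +x) and the ligand channel (above the ring plane,
    +z). The seed rotates the starting point within the band."""
    n_cand = max(64, 16 * n_needed)
    k = np.arange(n_cand)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1 - 2 * (k + 0.5) / n_cand
    rho = np.sqrt(1 - z**2)
    dirs = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    band = dirs[(dirs[:, 2] <= 1e-9) & (np.abs(dirs[:, 0]) <= 0.643)]
    if len(band) < n_needed:
        raise ValueError(f"cannot place {n_needed} pocket residues without overlap")
    start = seed % len(band)
    return np.vstack([band[start:], band[:start]])


def build_site(n_pocket_residues_per_class: int, seed: int) -> SyntheticSite:
    """Toy hormonogenic site: two ITY residues plus pocket residues.

    The donor ITY sits at the origin in a fixed orientation; the acceptor
    ITY (side chain only — it is re-posed rigidly every frame by
    :func:`sample_frames`) starts in the same orientation. ``n`` pocket
    residues of each polarity class (SER/ALA/LYS/ASP) are placed on a sphere
    of radius 11 Å around the site with their side chains facing the pocket
    and bodies extending outward; placement is deterministic for a fixed
    seed. Serine hydroxyls are oriented along a verified free corridor so a
    hydrogen-bond partner can be relocated along the O–H axis without
    colliding with the rest of the system.
    """
    if n_pocket_residues_per_class < 0:
        raise ValueError("n_pocket_residues_per_class must be >= 0")
    atoms: list[AtomRecord] = []
    residues: list[Residue] = []
    coords: list[np.ndarray] = []
    residue_direction: dict[int, np.ndarray] = {}
    hbond_direction: dict[int, np.ndarray] = {}

    for resid, backbone in ((DONOR_ITY_INDEX, True), (ACCEPTOR_ITY_INDEX, False)):
        a, c = _ity_template(resid, backbone)
        atoms += a
        residues.append(Residue(index=resid, name="ITY", chain_id="A", polarity_class="hormonogenic"))
        coords.append(c)

    n = n_pocket_residues_per_class
    if n:
        dirs = _band_directions(4 * n, seed)
        placed_xyz = np.vstack(coords)
        order = [pair for pair in _CLASS_RESNAMES for _ in range(n)]
        # interleave classes so they are spatially mixed
        order = [order[i::n] for i in range(n)]
        order = [pair for chunk in order for pair in chunk]
        resid = 2600
        i_dir = 0
        for cls, resname in order:
            resid += 1
            template = _POCKET_TEMPLATES[resname]
            local = np.array([xyz for *_, xyz in template])
            while True:
                if i_dir >= len(dirs):
                    raise ValueError("ran out of collision-free pocket directions")
                d = dirs[i_dir]
                i_dir += 1
                base = _SITE_CENTER + _POCKET_RADIUS * d
                if resname == "SER":
                    # O-H axis: inward, tilted 45° toward the tangent that
                    # is perpendicular to the ITY axis and points downward,
                    # clearing both the acceptor's swept region and the
                    # ligand channel
                    t = np.cross(d, [1.0, 0.0, 0.0])
                    t /= np.linalg.norm(t)
                    if t[2] > 0:
                        t = -t
                    u = (-d + t) / np.linalg.norm(-d + t)
                    h0 = local[6] - local[5]  # HG - OG
                    rot = _rotation_between(h0, u)
                else:
                    rot = _rotation_between(np.array([1.0, 0.0, 0.0]), d)
                res_xyz = local @ rot.T + base
                if cdist(res_xyz, placed_xyz).min() < 4.0:
                    continue
                break
            atoms += [_atom(nm, el, resid, q) for nm, el, q, _ in template]
            residues.append(Residue(index=resid, name=resname, chain_id="A", polarity_class=cls))
            coords.append(res_xyz)
            placed_xyz = np.vstack([placed_xyz, res_xyz])
            residue_direction[resid] = d
            if resname == "SER":
                hbond_direction[resid] = u
    topology = Topology(atoms=atoms, residues=residues, ligand_residue_indices=set())
    return SyntheticSite(
        topology=topology,
        base_coordinates=np.vstack(coords),
        residue_direction=residue_direction,
        hbond_direction=hbond_direction,
    )


def add_ligand(site: SyntheticSite, spec: PfasSpec, offset: np.ndarray | None = None) -> SyntheticSite:
    """Merge a PFAS ligand into the site, laid along the reserved channel
    above the donor ring plane (head toward the hydroxyl end)."""
    lig_top, lig_xyz = build_pfas(spec)
    if offset is None:
        offset = np.array([0.5, 0.0, 7.0])
    topology = Topology(
        atoms=site.topology.atoms + lig_top.atoms,
        residues=site.topology.residues + lig_top.residues,
        ligand_residue_indices=site.topology.ligand_residue_indices | lig_top.ligand_residue_indices,
    )
    coords = np.vstack([site.base_coordinates, lig_xyz + offset])
    return SyntheticSite(
        topology=topology,
        base_coordinates=coords,
        residue_direction=site.residue_direction,
        hbond_direction=site.hbond_direction,
    )


def _truncnorm_draw(rng, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _hbond_pair_atoms(site: SyntheticSite, pair: tuple[int, int]):
    top = site.topology
    donor_res, acceptor_res = pair
    if top.residue(donor_res).name != "SER" or top.residue(acceptor_res).name != "ASP":
        raise ValueError(
            f"declared hydrogen-bond pair {pair} must be (SER donor, ASP acceptor)"
        )
    # the relocated aspartate body is realigned from its own outward axis
    # onto the serine's O-H corridor, so it trails away from the serine
    reorient = _rotation_between(
        site.residue_direction[acceptor_res], site.hbond_direction[donor_res]
    )
    return (
        top.atom_index(donor_res, "OG"),
        top.atom_index(donor_res, "HG"),
        top.atom_index(acceptor_res, "OD1"),
        top.atom_indices_of_residue(acceptor_res),
        reorient,
    )


def sample_frames(
    site: SyntheticSite,
    truth: GroundTruth,
    n_frames: int,
    frame_spacing_ps: float = 1.0,
    jitter_sd: float = 0.05,
) -> Trajectory:
    """Draw frames from the planted geometry and occupancy distributions.

    Per frame: a mixture component is drawn; the inter-plane angle comes
    from a normal truncated to [0°, 180°] and the reactive distance from a
    normal truncated to (0, ∞); the acceptor ITY is posed rigidly so that
    the realised angle and donor-O→acceptor-C distance equal the draws to
    within 1e-6 (translation cannot change the angle, so both constraints
    are met exactly). Declared hydrogen-bond pairs are toggled into
    (2.8 Å, 180°) or out of (5.5 Å) the geometric criteria by a Bernoulli
    draw at the planted occupancy. Pocket atoms get Gaussian jitter
    (default σ = 0.05 Å) so RMSD/RMSF are nondegenerate; the two ITY
    residues are exempt so the planted geometry stays exact.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(truth.seed)
    top = site.topology
    donor_atoms = top.atom_indices_of_residue(site.donor_residue)
    acceptor_atoms = top.atom_indices_of_residue(site.acceptor_residue)
    oh = top.atom_index(site.donor_residue, "OH")
    cz_local_pos = np.where(
        [top.atoms[i].atom_name == "CZ" for i in acceptor_atoms]
    )[0][0]
    acceptor_local = site.base_coordinates[acceptor_atoms].copy()
    donor_normal = np.array([0.0, 0.0, 1.0])  # template orientation
    approach = np.array([-1.0, 0.0, 0.0])  # acceptor placed past the hydroxyl

    # used-once validation for declared pairs
    used: set[int] = set()
    pairs = []
    for pair, p in truth.hbond_occupancy.items():
        if pair[0] in used or pair[1] in used:
            raise ValueError(f"residue reused across hydrogen-bond pairs: {pair}")
        used.update(pair)
        pairs.append((pair, p, _hbond_pair_atoms(site, pair)))

    weights = np.array([c[0] for c in truth.geometry.components])
    frames = np.empty((n_frames, top.n_atoms, 3))
    for f in range(n_frames):
        xyz = site.base_coordinates + rng.normal(0.0, jitter_sd, size=(top.n_atoms, 3))
        xyz[donor_atoms] = site.base_coordinates[donor_atoms]

        comp = truth.geometry.components[rng.choice(len(weights), p=weights)]
        _, mean_a, sd_a, mean_d, sd_d = comp
        theta = _truncnorm_draw(rng, mean_a, sd_a, 0.0, 180.0)
        dist = _truncnorm_draw(rng, mean_d, sd_d, 1e-6, np.inf)

        # rigid pose: spin about own normal, tilt normal to the drawn angle,
        # translate CZ onto the drawn distance from the donor hydroxyl O
        spin = Rotation.from_rotvec(rng.uniform(0, 2 * np.pi) * donor_normal)
        tilt = Rotation.from_rotvec(np.deg2rad(theta) * np.array([1.0, 0.0, 0.0]))
        rot = (tilt * spin).as_matrix()
        posed = acceptor_local @ rot.T
        target_cz = site.base_coordinates[oh] + dist * approach
        posed += target_cz - posed[cz_local_pos]
        xyz[acceptor_atoms] = posed

        for (pair, p, (i_d, i_h, i_a, res_atoms, reorient)) in pairs:
            bonded = rng.random() < p
            u = xyz[i_h] - xyz[i_d]
            u /= np.linalg.norm(u)
            length = 2.8 if bonded else 5.0
            target = xyz[i_d] + length * u
            # rigid re-pose: body realigned with the serine's outward axis,
            # acceptor oxygen exactly on the O-H ray
            xyz[res_atoms] = (xyz[res_atoms] - xyz[i_a]) @ reorient.T + target

        frames[f] = xyz
    times = np.arange(n_frames, dtype=float) * frame_spacing_ps
    return Trajectory(topology=top, coordinates=frames, times=times)


def default_truth(seed: int = 0, site: SyntheticSite | None = None) -> GroundTruth:
    """Reference-like conditions: single component at the cryo-EM-style
    geometry (76°, 6.4 Å) and, if the site has pocket residues, one planted
    hydrogen bond at 25% occupancy (the persistence scale discussed for the
    helix region)."""
    occupancy: dict[tuple[int, int], float] = {}
    if site is not None:
        sers = [r.index for r in site.topology.residues if r.name == "SER"]
        asps = [r.index for r in site.topology.residues if r.name == "ASP"]
        if sers and asps:
            occupancy[(sers[0], asps[0])] = 0.25
    return GroundTruth(
        geometry=GeometryDistribution(((1.0, 76.0, 5.0, 6.4, 0.5),)),
        hbond_occupancy=occupancy,
        seed=seed,
    )
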