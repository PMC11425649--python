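"""End-point binding energetics: nonbonded decomposition and MM-GBSA.

The single-trajectory end-point estimate of a ligand's binding free energy
averages, over selected frames of the complex simulation,

    ΔG = E_elec + E_vdw + ΔG_GB + ΔG_np

where E_elec/E_vdw are the receptor–ligand gas-phase nonbonded cross terms
(internal bonded terms cancel exactly when complex, receptor and ligand
snapshots come from the same frames), ΔG_GB is the change in generalized
Born polar solvation on binding, and ΔG_np = γ·ΔSASA is the nonpolar term.
The estimate ranks relative binding strengths; it is not an absolute
affinity.

The GB variant is GB-OBC: per-atom effective Born radii from the pairwise
HCT descreening integral rescaled through tanh(αΨ − βΨ² + γΨ³) with
α=1.0, β=0.8, γ=4.8, and the Still pairwise screening function
f_GB = sqrt(r² + R_iR_j exp(−r²/4R_iR_j)). Salt enters via Debye–Hückel
screening of the solvent term (default 0.1 M).

Per-residue decomposition attributes the ligand interaction to pocket
residues (within 10 Å) as gas-phase elec+vdW means; stabilizing
contributions are negative. Group sums aggregate residues by polarity
class — charged (basic+acidic) versus polar+nonpolar — with the
hormonogenic (ITY) residues reported separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .model import Topology, Trajectory

K_COULOMB = 332.0636  # kcal·Å/(mol·e²)
RT_298 = 0.0019872041 * 298.15  # kcal/mol
CLASH_DISTANCE = 0.1  # Å


@dataclass(frozen=True)
class DecompositionRecord:
    residue_index: int
    elec_mean: float  # kcal/mol
    vdw_mean: float
    polarity_class: str

    @property
    def total_mean(self) -> float:
        return self.elec_mean + self.vdw_mean


@dataclass(frozen=True)
class GroupSums:
    """Polarity-class aggregates of per-residue decomposition totals."""

    charged: float  # basic + acidic, kcal/mol
    polar_nonpolar: float  # polar + nonpolar
    hormonogenic: float = 0.0  # ITY, reported separately, outside `total`

    @property
    def total(self) -> float:
        return self.charged + self.polar_nonpolar


@dataclass(frozen=True)
class EnergyComponents:
    e_elec: float
    e_vdw: float
    g_gb: float
    g_np: float

    @property
    def total(self) -> float:
        return self.e_elec + self.e_vdw + self.g_gb + self.g_np


@dataclass(frozen=True)
class BindingEnergy:
    mean: float
    sd: float
    n_frames: int
    per_frame: tuple[float, ...]
    components: EnergyComponents | None = None  # means over frames

    def __post_init__(self) -> None:
        assert self.n_frames == len(self.per_frame)


def pairwise_nonbonded(
    coords: np.ndarray,
    topology: Topology,
    group_a: np.ndarray,
    group_b: np.ndarray,
    interior_dielectric: float = 1.0,
) -> tuple[float, float]:
    """Cross-group Coulomb and 12-6 Lennard-Jones energies (kcal/mol).

    elec = k_C Σ q_i q_j / (ε_in r_ij);
    vdw = Σ ε_ij [(r_min,ij/r)¹² − 2 (r_min,ij/r)⁶] with
    r_min,ij = r_min,i/2 + r_min,j/2 and ε_ij = sqrt(ε_i ε_j).
    No distance cutoff is applied within the selected pairs.
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("atom groups overlap")
    if group_a.size == 0 or group_b.size == 0:
        return 0.0, 0.0
    q = topology.charges()
    rmh = topology.lj_rmin_half()
    eps = topology.lj_epsilon()
    r = cdist(coords[group_a], coords[group_b])
    if np.any(r < CLASH_DISTANCE):
        raise ValueError(f"atomic clash: pair distance below {CLASH_DISTANCE} Å")
    elec = K_COULOMB * float(np.sum(np.outer(q[group_a], q[group_b]) / r)) / interior_dielectric
    rmin = rmh[group_a][:, None] + rmh[group_b][None, :]
    eij = np.sqrt(np.outer(eps[group_a], eps[group_b]))
    x6 = (rmin / r) ** 6
    vdw = float(np.sum(eij * (x6 * x6 - 2.0 * x6)))
    return elec, vdw


def ligand_atom_indices(topology: Topology) -> np.ndarray:
    return np.array(
        [
            i
            for i, a in enumerate(topology.atoms)
            if a.residue_index in topology.ligand_residue_indices
        ],
        dtype=int,
    )


def select_pocket_residues(
    trajectory: Trajectory, ligand_atoms: np.ndarray, cutoff: float = 10.0
) -> set[int]:
    """Residues whose minimum atom–atom distance to the ligand is within
    ``cutoff`` in ANY analyzed frame (union over frames)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    top = trajectory.topology
    ligand_atoms = np.asarray(ligand_atoms, dtype=int)
    pocket: set[int] = set()
    candidates = [
        r.index for r in top.residues if r.index not in top.ligand_residue_indices
    ]
    res_atoms = {ri: top.atom_indices_of_residue(ri) for ri in candidates}
    for f in range(trajectory.n_frames):
        xyz = trajectory.coordinates[f]
        lig = xyz[ligand_atoms]
        for ri in candidates:
            if ri in pocket:
                continue
            if cdist(xyz[res_atoms[ri]], lig).min() <= cutoff:
                pocket.add(ri)
    return pocket


def per_residue_decomposition(
    trajectory: Trajectory,
    ligand_atoms: np.ndarray,
    pocket_residues: set[int] | None = None,
    interior_dielectric: float = 1.0,
    cutoff: float = 10.0,
) -> list[DecompositionRecord]:
    """Mean ligand–residue nonbonded interaction per pocket residue.

    Stabilizing interactions are negative; nonstabilizing ones (typically
    like-charged acidic residues against an anionic ligand) are positive.
    """
    top = trajectory.topology
    ligand_atoms = np.asarray(ligand_atoms, dtype=int)
    if pocket_residues is None:
        pocket_residues = select_pocket_residues(trajectory, ligand_atoms, cutoff)
    records = []
    for ri in sorted(pocket_residues):
        res_atoms = top.atom_indices_of_residue(ri)
        elec = np.empty(trajectory.n_frames)
        vdw = np.empty(trajectory.n_frames)
        for f in range(trajectory.n_frames):
            elec[f], vdw[f] = pairwise_nonbonded(
                trajectory.coordinates[f], top, ligand_atoms, res_atoms, interior_dielectric
            )
        records.append(
            DecompositionRecord(
                residue_index=ri,
                elec_mean=float(elec.mean()),
                vdw_mean=float(vdw.mean()),
                polarity_class=top.residue(ri).polarity_class or "unassigned",
            )
        )
    return records


def group_decomposition(records: list[DecompositionRecord]) -> GroupSums:
    """Aggregate decomposition totals by polarity class.

    charged = Σ over basic+acidic; polar_nonpolar = Σ over polar+nonpolar;
    hormonogenic (ITY) residues are kept separate and excluded from both.
    """
    charged = sum(r.total_mean for r in records if r.polarity_class in ("basic", "acidic"))
    pn = sum(r.total_mean for r in records if r.polarity_class in ("polar", "nonpolar"))
    ity = sum(r.total_mean for r in records if r.polarity_class == "hormonogenic")
    sums = GroupSums(charged=charged, polar_nonpolar=pn, hormonogenic=ity)
    assert abs(sums.total - (charged + pn)) < 1e-9
    return sums


# ---------------------------------------------------------------------------
# generalized Born (OBC)
# ---------------------------------------------------------------------------

def _hct_integral(d: np.ndarray, rho_i: float, s: np.ndarray) -> np.ndarray:
    """Pairwise descreening integral of 1/r⁴ over neighbor spheres of radius
    ``s`` at distances ``d`` from an atom of (reduced) radius ``rho_i``,
    excluding the region inside the atom's own sphere."""
    out = np.zeros_like(d)
    active = d + s > rho_i  # otherwise the neighbor is engulfed: no descreening
    if not np.any(active):
        return out
    d_, s_ = d[active], s[active]
    L = np.maximum(np.abs(d_ - s_), rho_i)
    U = d_ + s_
    term = (
        1.0 / L
        - 1.0 / U
        + (d_ / 4.0) * (1.0 / U**2 - 1.0 / L**2)
        + (1.0 / (2.0 * d_)) * np.log(L / U)
        + (s_**2 / (4.0 * d_)) * (1.0 / L**2 - 1.0 / U**2)
    )
    inside = rho_i < s_ - d_  # atom center inside the neighbor sphere
    term[inside] += 2.0 * (1.0 / rho_i - 1.0 / L[inside])
    out[active] = 0.5 * term
    return out


def gb_effective_radii(
    coords: np.ndarray,
    topology: Topology,
    alpha: float = 1.0,
    beta: float = 0.8,
    gamma: float = 4.8,
    offset: float = 0.09,
) -> np.ndarray:
    """Per-atom effective Born radii (Å) via the OBC tanh rescaling.

    ρ̃ = ρ − offset; Ψ = ρ̃_i Σ_j H(d_ij, ρ̃_i, ρ̃_j);
    R_i⁻¹ = ρ̃_i⁻¹ − ρ_i⁻¹ tanh(αΨ − βΨ² + γΨ³).
    An isolated atom has Ψ = 0 and hence R = ρ̃ exactly.
    """
    rho = topology.intrinsic_radii()
    if np.any(rho <= 0):
        raise ValueError("all intrinsic radii must be positive for GB")
    rho_t = rho - offset
    n = len(rho)
    radii = np.empty(n)
    d = cdist(coords, coords)
    for i in range(n):
        others = np.arange(n) != i
        integral = _hct_integral(d[i, others], rho_t[i], rho_t[others]).sum()
        psi = rho_t[i] * integral
        inv = 1.0 / rho_t[i] - np.tanh(alpha * psi - beta * psi**2 + gamma * psi**3) / rho[i]
        if inv <= 0:
            warnings.warn(
                f"nonpositive effective Born radius for atom {i}; clamping to reduced radius"
            )
            radii[i] = rho_t[i]
        else:
            radii[i] = 1.0 / inv
    return radii


def debye_kappa(salt_molar: float, eps_out: float = 78.5) -> float:
    """Inverse Debye length (Å⁻¹) for a 1:1 salt at 298.15 K."""
    if salt_molar <= 0:
        return 0.0
    bjerrum = K_COULOMB / (eps_out * RT_298)  # Å
    number_density = salt_molar * 6.02214076e-4  # Å⁻³
    return float(np.sqrt(8.0 * np.pi * bjerrum * number_density))


def gb_polar_energy(
    coords: np.ndarray,
    topology: Topology,
    effective_radii: np.ndarray,
    eps_in: float = 1.0,
    eps_out: float = 78.5,
    salt_molar: float = 0.1,
) -> float:
    """Polar solvation free energy (kcal/mol) in the pairwise GB model.

    ΔG = −(k_C/2) Σ_ij q_i q_j (1/ε_in − e^{−κ f_ij}/ε_out) / f_ij over the
    full double sum including self terms (i = j, f = R_i), with
    f_GB = sqrt(r² + R_iR_j exp(−r²/4R_iR_j)). A single ion reduces to the
    Born equation."""
    q = topology.charges()
    if not np.any(q):
        return 0.0
    R = np.asarray(effective_radii, dtype=float)
    r2 = cdist(coords, coords) ** 2
    RR = np.outer(R, R)
    f = np.sqrt(r2 + RR * np.exp(-r2 / (4.0 * RR)))
    kappa = debye_kappa(salt_molar, eps_out)
    screen = 1.0 / eps_in - np.exp(-kappa * f) / eps_out
    return float(-(K_COULOMB / 2.0) * np.sum(np.outer(q, q) * screen / f))


# ---------------------------------------------------------------------------
# solvent-accessible surface area
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    rho = np.sqrt(1.0 - z**2)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa(
    coords: np.ndarray,
    topology: Topology,
    probe_radius: float = 1.4,
    n_points: int = 960,
    radii: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Shrake–Rupley solvent-accessible surface area.

    Each atom's solvent-augmented sphere (r + probe) is sampled at
    ``n_points`` deterministic sphere points; the accessible fraction gives
    the per-atom area. Atomic radii default to the topology's GB intrinsic
    radii. Returns (total Å², per-atom Å²).
    """
    if radii is None:
        radii = topology.intrinsic_radii()
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("all radii must be positive for SASA")
    unit = _sphere_points(n_points)
    n = len(radii)
    big = radii + probe_radius
    d = cdist(coords, coords)
    per_atom = np.zeros(n)
    for i in range(n):
        neighbors = np.nonzero((d[i] < big[i] + big) & (np.arange(n) != i))[0]
        pts = coords[i] + big[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            accessible &= np.linalg.norm(pts - coords[j], axis=1) >= big[j]
            if not accessible.any():
                break
        per_atom[i] = 4.0 * np.pi * big[i] ** 2 * accessible.mean()
    return float(per_atom.sum()), per_atom


# ---------------------------------------------------------------------------
# end-point binding energy
# ---------------------------------------------------------------------------

def _state_solvation(coords, topology, gb_kw, gamma_np, probe, n_points):
    radii = gb_effective_radii(coords, topology, **{k: gb_kw[k] for k in ("alpha", "beta", "gamma", "offset")})
    g_gb = gb_polar_energy(
        coords, topology, radii,
        eps_in=gb_kw["eps_in"], eps_out=gb_kw["eps_out"], salt_molar=gb_kw["salt_molar"],
    )
    area, _ = sasa(coords, topology, probe_radius=probe, n_points=n_points)
    return g_gb, gamma_np * area


def mmgbsa_binding(
    trajectory: Trajectory,
    ligand_atoms: np.ndarray | None = None,
    eps_in: float = 1.0,
    eps_out: float = 78.5,
    salt_molar: float = 0.1,
    gamma_np: float = 0.005,
    alpha: float = 1.0,
    beta: float = 0.8,
    gamma: float = 4.8,
    offset: float = 0.09,
    probe_radius: float = 1.4,
    sasa_points: int = 960,
) -> BindingEnergy:
    """Single-trajectory MM-GBSA binding energy over the analyzed frames.

    Per frame: ΔG = E_elec + E_vdw + [G_GB(C) − G_GB(R) − G_GB(L)]
    + γ_np·[SASA(C) − SASA(R) − SASA(L)], receptor and ligand coordinates
    extracted from the complex frame, so internal bonded terms cancel by
    construction. Returns mean, sample standard deviation and the per-frame
    series.
    """
    top = trajectory.topology
    if ligand_atoms is None:
        ligand_atoms = ligand_atom_indices(top)
    ligand_atoms = np.asarray(ligand_atoms, dtype=int)
    if ligand_atoms.size == 0:
        raise ValueError("empty ligand selection")
    receptor_atoms = np.setdiff1d(np.arange(top.n_atoms), ligand_atoms)
    top_rec = top.subset(receptor_atoms)
    top_lig = top.subset(ligand_atoms)
    gb_kw = dict(alpha=alpha, beta=beta, gamma=gamma, offset=offset,
                 eps_in=eps_in, eps_out=eps_out, salt_molar=salt_molar)

    per_frame = []
    comp_sums = np.zeros(4)
    for f in range(trajectory.n_frames):
        xyz = trajectory.coordinates[f]
        elec, vdw = pairwise_nonbonded(xyz, top, receptor_atoms, ligand_atoms, eps_in)
        gb_c, np_c = _state_solvation(xyz, top, gb_kw, gamma_np, probe_radius, sasa_points)
        gb_r, np_r = _state_solvation(xyz[receptor_atoms], top_rec, gb_kw, gamma_np, probe_radius, sasa_points)
        gb_l, np_l = _state_solvation(xyz[ligand_atoms], top_lig, gb_kw, gamma_np, probe_radius, sasa_points)
        g_gb = gb_c - gb_r - gb_l
        g_np = np_c - np_r - np_l
        per_frame.append(elec + vdw + g_gb + g_np)
        comp_sums += (elec, vdw, g_gb, g_np)
    arr = np.array(per_frame)
    comps = EnergyComponents(*(comp_sums / len(arr)))
    return BindingEnergy(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        n_frames=len(arr),
        per_frame=tuple(float(x) for x in arr),
        components=comps,
    )


def rank_binders(results: dict[str, BindingEnergy]) -> list[tuple[str, BindingEnergy]]:
    """Strongest binder (most negative mean ΔG) first; ties alphabetical."""
    return sorted(results.items(), key=lambda kv: (kv[1].mean, kv[0]))
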