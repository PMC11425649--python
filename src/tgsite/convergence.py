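"""Convergence diagnostics: RMSD, per-residue RMSF, plateau detection.

A trajectory is treated as analyzable when its RMSD (and, if supplied, an
energy series) has reached a plateau over the final analysis window — the
operational meaning of "converged" used before any end-point analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .model import Topology, Trajectory


@dataclass
class ConvergenceReport:
    rmsd_series: np.ndarray  # Å per frame
    rmsf_per_residue: dict[int, float]  # residue index -> Å
    plateau: bool
    plateau_window_ns: float


def backbone_selection(topology: Topology) -> np.ndarray:
    """Backbone heavy atoms (N, CA, C, O), the default RMSD selection."""
    sel = np.array(
        [i for i, a in enumerate(topology.atoms) if a.atom_name in ("N", "CA", "C", "O")],
        dtype=int,
    )
    return sel if sel.size else np.arange(topology.n_atoms)


def _superpose_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal-superposition (Kabsch) RMSD of two coordinate sets."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    _, rssd = Rotation.align_vectors(ref, mob)
    return float(rssd / np.sqrt(len(mob)))


def rmsd_series(
    trajectory: Trajectory,
    reference_frame: int = 0,
    atom_selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD (Å) of the selection onto the reference frame after
    optimal rigid-body superposition."""
    if atom_selection is None:
        atom_selection = backbone_selection(trajectory.topology)
    atom_selection = np.asarray(atom_selection, dtype=int)
    if atom_selection.size == 0:
        raise ValueError("empty atom selection")
    ref = trajectory.coordinates[reference_frame][atom_selection]
    return np.array(
        [
            _superpose_rmsd(trajectory.coordinates[f][atom_selection], ref)
            for f in range(trajectory.n_frames)
        ]
    )


def rmsf_per_residue(
    trajectory: Trajectory, atom_selection: np.ndarray | None = None
) -> dict[int, float]:
    """Per-residue RMSF (Å) about the time-averaged structure.

    Frames are first superposed onto the mean structure (two-pass: align to
    the first frame, rebuild the mean, align to it); each selected atom's
    RMS deviation from its mean position is then averaged within residues.
    """
    if atom_selection is None:
        atom_selection = np.arange(trajectory.topology.n_atoms)
    atom_selection = np.asarray(atom_selection, dtype=int)
    if atom_selection.size == 0:
        raise ValueError("empty atom selection")
    sel_coords = trajectory.coordinates[:, atom_selection, :].copy()

    def align_all(target: np.ndarray) -> np.ndarray:
        t_cent = target - target.mean(axis=0)
        out = np.empty_like(sel_coords)
        for f in range(sel_coords.shape[0]):
            x = sel_coords[f] - sel_coords[f].mean(axis=0)
            if len(x) >= 2:
                rot, _ = Rotation.align_vectors(t_cent, x)
                x = rot.apply(x)
            out[f] = x
        return out

    aligned = align_all(sel_coords[0])
    aligned = align_all(aligned.mean(axis=0) + sel_coords[0].mean(axis=0))
    mean_pos = aligned.mean(axis=0)
    per_atom = np.sqrt(((aligned - mean_pos) ** 2).sum(axis=2).mean(axis=0))

    result: dict[int, float] = {}
    res_of = [trajectory.topology.atoms[i].residue_index for i in atom_selection]
    for ri in sorted(set(res_of)):
        mask = np.array([r == ri for r in res_of])
        result[ri] = float(per_atom[mask].mean())
    return result


def plateau_check(
    series: np.ndarray,
    times_ps: np.ndarray,
    window_ns: float,
    slope_tol: float = 0.1,
    sd_tol: float = np.inf,
) -> bool:
    """True iff over the final window the least-squares slope magnitude is
    ≤ ``slope_tol`` (units/ns) and the standard deviation is ≤ ``sd_tol``."""
    series = np.asarray(series, dtype=float)
    times_ps = np.asarray(times_ps, dtype=float)
    window_ps = window_ns * 1000.0
    span = times_ps[-1] - times_ps[0]
    if window_ps > span + 1e-9:
        raise ValueError(f"window {window_ns} ns exceeds series span {span / 1000} ns")
    mask = times_ps > times_ps[-1] - window_ps + 1e-9
    y = series[mask]
    t_ns = times_ps[mask] / 1000.0
    slope = float(np.polyfit(t_ns, y, 1)[0]) if len(y) > 1 else 0.0
    return abs(slope) <= slope_tol and float(np.std(y)) <= sd_tol


def convergence_report(
    trajectory: Trajectory,
    window_ns: float = 5.0,
    slope_tol: float = 0.1,
    sd_tol: float = np.inf,
    atom_selection: np.ndarray | None = None,
) -> ConvergenceReport:
    rmsd = rmsd_series(trajectory, atom_selection=atom_selection)
    rmsf = rmsf_per_residue(trajectory, atom_selection)
    window = min(window_ns, trajectory.span_ps / 1000.0) if trajectory.n_frames > 1 else 0.0
    plateau = (
        plateau_check(rmsd, trajectory.times, window, slope_tol, sd_tol)
        if trajectory.n_frames > 1
        else True
    )
    return ConvergenceReport(
        rmsd_series=rmsd,
        rmsf_per_residue=rmsf,
        plateau=plateau,
        plateau_window_ns=window,
    )
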