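"""Structural observables: RMSD, per-residue RMSF / ΔRMSF, radius of gyration.

RMSD is computed after optimal rigid-body superposition (rotation +
translation, reflection-guarded) of the selection onto the reference;
RMSF measures each atom's RMS deviation from its time-mean position
after superposing every frame onto the iteratively refined average
structure; ΔRMSF is the per-residue excess of one condition over a
reference condition (typically zero field).  Atom correspondence is by
identity (index order), never by proximity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class StructureMetrics:
    rmsd_t: np.ndarray          # Å, per frame
    rg_t: np.ndarray            # Å, per frame
    rmsf: np.ndarray            # Å, per selected atom
    times: np.ndarray | None = None


def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix mapping centred `mobile` onto centred `ref`.

    SVD solution with a determinant guard so reflections are never
    returned.
    """
    H = mobile.T @ ref
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Rigid-body superposition of `mobile` onto `ref` (same atom order)."""
    mobile = np.asarray(mobile, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if mobile.shape != ref.shape:
        raise ValueError(
            f"atom-count mismatch: {mobile.shape[0]} vs {ref.shape[0]}")
    cm, cr = mobile.mean(axis=0), ref.mean(axis=0)
    R = _kabsch(mobile - cm, ref - cr)
    return (mobile - cm) @ R.T + cr


def rmsd(mobile: np.ndarray, ref: np.ndarray,
         superposition: bool = True) -> float:
    """RMSD between two conformations, optionally after superposition."""
    mobile = np.asarray(mobile, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if mobile.shape != ref.shape:
        raise ValueError(
            f"atom-count mismatch: {mobile.shape[0]} vs {ref.shape[0]}")
    if superposition:
        mobile = superpose(mobile, ref)
    return float(np.sqrt(np.mean(np.sum((mobile - ref) ** 2, axis=1))))


def rmsd_series(coords_list, ref, superposition: bool = True) -> np.ndarray:
    """Per-frame RMSD of a coordinate series against one reference."""
    return np.array([rmsd(c, ref, superposition=superposition)
                     for c in coords_list])


def rmsf_profile(coords_list, n_iter: int = 3) -> np.ndarray:
    """Per-atom RMSF about the time-mean structure.

    Frames are superposed onto the average structure, the average is
    recomputed, and the procedure is iterated to self-consistency
    (n_iter passes are ample for equilibrated ensembles).
    """
    coords = np.asarray(coords_list, dtype=float)
    if coords.ndim != 3:
        raise ValueError("expected a (n_frames, n_atoms, 3) coordinate array")
    ref = coords[0]
    aligned = coords
    for _ in range(n_iter):
        aligned = np.stack([superpose(c, ref) for c in coords])
        ref = aligned.mean(axis=0)
    dev = aligned - ref
    return np.sqrt(np.mean(np.sum(dev ** 2, axis=2), axis=0))


def delta_rmsf(rmsf_condition: np.ndarray,
               rmsf_reference: np.ndarray) -> np.ndarray:
    """Excess fluctuations of a condition over the reference condition."""
    a = np.asarray(rmsf_condition, dtype=float)
    b = np.asarray(rmsf_reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError("RMSF profiles must cover the same residues")
    return a - b


def radius_of_gyration(coords: np.ndarray,
                       masses: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration of one conformation, Å."""
    coords = np.asarray(coords, dtype=float)
    w = (np.ones(len(coords)) if masses is None
         else np.asarray(masses, dtype=float))
    w = w / w.sum()
    com = w @ coords
    return float(np.sqrt(np.sum(w * np.sum((coords - com) ** 2, axis=1))))


def rg_series(coords_list, masses=None) -> np.ndarray:
    return np.array([radius_of_gyration(c, masses) for c in coords_list])


def structure_metrics(traj, selection: str = "calpha",
                      reference: np.ndarray | None = None,
                      mass_weighted: bool = True) -> StructureMetrics:
    """RMSD/RMSF/Rg for a trajectory selection.

    The RMSD reference defaults to the first frame (pass crystal
    coordinates to reproduce deviation-from-crystal curves); the RMSF
    reference is always the time-averaged structure.
    """
    idx = traj.select(selection)
    if len(idx) == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    masses = None
    if mass_weighted:
        m = traj.atom_table()["mass"].to_numpy()[idx]
        if np.all(np.isfinite(m)):
            masses = m
    coords, times = [], []
    for fr in traj.frames():
        coords.append(fr.positions[idx])
        times.append(fr.time)
    coords = np.asarray(coords)
    ref = coords[0] if reference is None else np.asarray(reference, float)
    return StructureMetrics(
        rmsd_t=rmsd_series(coords, ref),
        rg_t=rg_series(coords, masses),
        rmsf=rmsf_profile(coords),
        times=np.asarray(times))
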