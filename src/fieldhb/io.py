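"""Trajectory and tabular I/O.

Reads standard MD formats (PDB topology; DCD/XTC coordinates) through
MDAnalysis, attaches per-atom partial charges from the topology or a
two-column sidecar table, resolves named atom selections, and serialises
every result table/report produced by the other modules (CSV for tables,
JSON for fit reports).

Orthorhombic cells only; all distances downstream use the minimum-image
convention.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

WATER_RESNAMES = ("TIP3", "TIP3P", "TP3", "HOH", "SOL", "WAT", "SPC")

#: default named selections in the MDAnalysis selection grammar
NAMED_SELECTIONS = {
    "protein": "protein",
    "water": "resname " + " ".join(WATER_RESNAMES),
    "water_oxygens": ("resname " + " ".join(WATER_RESNAMES)
                      + " and name O OW OH2"),
    "calpha": "protein and name CA",
    "protein_heavy": "protein and not name H*",
}


class TrajectoryError(RuntimeError):
    """Raised for unreadable, inconsistent or truncated trajectory input."""


@dataclass
class Frame:
    """One trajectory frame: positions in Å, orthorhombic box edges in Å."""
    index: int
    time: float            # ps
    positions: np.ndarray  # (n_atoms, 3) Å
    box: np.ndarray | None  # (3,) edge lengths, Å; None for non-periodic


@dataclass
class FieldSpec:
    """Applied homogeneous oscillating electric field E(t) = E0·cos(ωt)·axis."""
    E0: float                 # amplitude, mV/Å
    freq: float               # frequency f, Hz
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        if self.E0 <= 0:
            raise ValueError(f"E0 must be positive, got {self.E0}")
        if self.freq <= 0:
            raise ValueError(f"freq must be positive, got {self.freq}")
        self.axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(self.axis)
        if n == 0:
            raise ValueError("axis must be a nonzero vector")
        self.axis = self.axis / n

    @property
    def omega(self) -> float:
        """Angular frequency, rad/s."""
        return 2.0 * math.pi * self.freq

    @property
    def omega_ps(self) -> float:
        """Angular frequency, rad/ps (for time axes in ps)."""
        return self.omega * 1e-12

    @property
    def period_ps(self) -> float:
        return 1e12 / self.freq


@dataclass
class SystemGeometry:
    """Simulation-cell geometry and per-atom metadata."""
    box: np.ndarray                      # (3,) edge lengths, Å
    atom_charges: np.ndarray | None = None   # (n_atoms,) partial charges, e
    selections: dict = field(default_factory=dict)  # name -> index array

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        if self.atom_charges is not None:
            self.atom_charges = np.asarray(self.atom_charges, dtype=float)
            if not np.all(np.isfinite(self.atom_charges)):
                raise ValueError("atom charges must be finite")

    @property
    def V(self) -> float:
        """Cell volume, Å³ (orthorhombic: product of edges)."""
        return float(np.prod(self.box))


class Trajectory:
    """A loaded topology + coordinate series with charges and selections.

    Thin wrapper around an MDAnalysis Universe that yields :class:`Frame`
    objects and reports truncated coordinate files by frame index.
    """

    def __init__(self, universe, charges=None, dt=None):
        self.u = universe
        self._dt = dt
        if charges is not None:
            charges = np.asarray(charges, dtype=float)
            if len(charges) != len(universe.atoms):
                raise TrajectoryError(
                    f"charge table has {len(charges)} entries for "
                    f"{len(universe.atoms)} atoms")
            self.charges = charges
        elif hasattr(universe.atoms, "charges"):
            self.charges = np.asarray(universe.atoms.charges, dtype=float)
        else:
            self.charges = None

    @property
    def n_atoms(self) -> int:
        return len(self.u.atoms)

    @property
    def n_frames(self) -> int:
        return len(self.u.trajectory)

    def require_charges(self) -> np.ndarray:
        if self.charges is None:
            raise TrajectoryError(
                "per-atom charges are required for a dipole computation; "
                "supply them in the topology or as a sidecar table")
        return self.charges

    def select(self, selection: str) -> np.ndarray:
        """Resolve a named or MDAnalysis-grammar selection to atom indices."""
        sel = NAMED_SELECTIONS.get(selection, selection)
        return self.u.select_atoms(sel).ix

    def atom_table(self) -> pd.DataFrame:
        """Per-atom metadata table (name, resname, resid, water flag, charge)."""
        u = self.u
        names = u.atoms.names
        resnames = u.atoms.resnames
        is_water = np.isin(resnames, WATER_RESNAMES)
        try:
            masses = np.asarray(u.atoms.masses, dtype=float)
        except Exception:
            masses = np.full(len(names), np.nan)
        return pd.DataFrame({
            "name": names,
            "resname": resnames,
            "resid": u.atoms.resids,
            "is_water": is_water,
            "is_protein": ~is_water,
            "mass": masses,
            "charge": (self.charges if self.charges is not None
                       else np.full(len(names), np.nan)),
        })

    def geometry(self) -> SystemGeometry:
        dims = self.u.dimensions
        if dims is None or not np.any(dims[:3]):
            raise TrajectoryError("trajectory carries no box dimensions")
        return SystemGeometry(box=dims[:3], atom_charges=self.charges)

    def frames(self) -> Iterator[Frame]:
        """Yield frames; a mid-file truncation is reported with its index."""
        n = len(self.u.trajectory)
        it = iter(self.u.trajectory)
        for i in range(n):
            try:
                ts = next(it)
            except StopIteration:
                return
            except Exception as exc:  # truncated/corrupt frame
                raise TrajectoryError(
                    f"coordinate file truncated or unreadable at frame {i}: "
                    f"{exc}") from exc
            if self._dt is not None:
                t = i * self._dt
            else:
                t = float(ts.time)
            box = ts.dimensions[:3].copy() if ts.dimensions is not None else None
            yield Frame(index=i, time=t, positions=ts.positions.astype(float),
                        box=box)


def read_charge_sidecar(path) -> np.ndarray:
    """Two-column (atom index, charge) table, CSV, with or without header."""
    df = pd.read_csv(path, comment="#", header=None, skiprows=0)
    # tolerate a header row of strings
    try:
        float(df.iloc[0, 0])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    idx = df.iloc[:, 0].astype(int).to_numpy()
    q = df.iloc[:, 1].astype(float).to_numpy()
    out = np.full(idx.max() + 1, np.nan)
    out[idx] = q
    if np.any(np.isnan(out)):
        raise TrajectoryError("charge sidecar does not cover all atom indices")
    return out


def _check_complete_frames(universe, coords_path) -> None:
    """Reject coordinate files cut mid-frame.

    Fixed-record readers (DCD) silently drop a trailing partial frame;
    here the byte bookkeeping is checked so corruption is reported with
    the index of the incomplete frame instead of passing unnoticed.
    """
    fobj = getattr(universe.trajectory, "_file", None)
    header = getattr(fobj, "_header_size", None)
    framesize = getattr(fobj, "_framesize", None)
    if not (coords_path and header and framesize):
        return
    payload = os.path.getsize(coords_path) - header
    if payload % framesize:
        raise TrajectoryError(
            f"coordinate file {coords_path} truncated mid-frame at frame "
            f"{payload // framesize}")


def load_trajectory(topology_path, coords_path=None, charge_source=None,
                    dt=None) -> Trajectory:
    """Load a topology (+ optional coordinate series) into a :class:`Trajectory`.

    Parameters
    ----------
    charge_source
        ``None`` (use topology charges if present), a path to a two-column
        CSV sidecar, or an array of per-atom charges (e).
    dt
        Frame spacing in ps, mandatory when the coordinate format carries no
        time metadata the caller trusts.
    """
    import MDAnalysis as mda

    if not os.path.exists(topology_path):
        raise TrajectoryError(f"topology file not found: {topology_path}")
    try:
        if coords_path is None:
            u = mda.Universe(str(topology_path))
        else:
            if not os.path.exists(coords_path):
                raise TrajectoryError(f"coordinate file not found: {coords_path}")
            u = mda.Universe(str(topology_path), str(coords_path))
    except TrajectoryError:
        raise
    except Exception as exc:
        raise TrajectoryError(f"failed to load trajectory: {exc}") from exc

    _check_complete_frames(u, coords_path)

    charges = None
    if charge_source is not None:
        if isinstance(charge_source, (str, os.PathLike)):
            charges = read_charge_sidecar(charge_source)
        else:
            charges = np.asarray(charge_source, dtype=float)
    return Trajectory(u, charges=charges, dt=dt)


# ---------------------------------------------------------------------------
# result serialisation

def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_results(records, path, fmt=None) -> None:
    """Serialise a result object: DataFrame → CSV, mapping/dataclass → JSON.

    Numeric round-trip through :func:`read_results` is exact to full float
    precision (repr-based formatting).
    """
    path = str(path)
    if fmt is None:
        fmt = "csv" if path.endswith(".csv") else "json"
    if fmt == "csv":
        df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
        df.to_csv(path, index=False)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(_jsonify(records), fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unsupported format: {fmt}")


def read_results(path, fmt=None):
    path = str(path)
    if fmt is None:
        fmt = "csv" if path.endswith(".csv") else "json"
    if fmt == "csv":
        return pd.read_csv(path, comment="#")
    with open(path) as fh:
        return json.load(fh)
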