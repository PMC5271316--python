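"""Geometric hydrogen-bond detection, classification and shell statistics.

A donor–hydrogen–acceptor triple (D, H, A) is a hydrogen bond when the
minimum-image donor–acceptor distance is within the class cutoff —
3.2 Å for protein–water (PW) bonds, 3.5 Å for water–water (WW) and
protein–protein (PP) bonds — and the D–H···A angle (vertex at the
hydrogen, 180° = linear) lies in [150°, 180°].  Donors are N/O atoms
with a covalently attached hydrogen; all N/O atoms accept.  Each
(D, H, A) triple is evaluated independently, so two hydrogens of one
donor give two distinct bonds.

First-shell (S1) membership, hydrogen-bond counts and fluctuations, and
the ellipsoid-shell water-density estimate are also computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import units

BULK_WATER_DENSITY = 996.516  # kg/m³ at 27 °C, reference for excess density

DONOR_ELEMENTS = ("N", "O")
ACCEPTOR_ELEMENTS = ("N", "O")
MAX_DH_BOND = 1.25  # Å, covalent D–H attachment cutoff


@dataclass
class HBondCriteria:
    r_cut_pw: float = 3.2      # Å, protein–water donor–acceptor cutoff
    r_cut_ww_pp: float = 3.5   # Å, water–water and protein–protein cutoff
    angle_min: float = 150.0   # degrees
    angle_max: float = 180.0
    R_PW: float = 3.2          # Å, reformation cutoff for kinetics

    def __post_init__(self) -> None:
        for r in (self.r_cut_pw, self.r_cut_ww_pp):
            if not 0 < r <= 5.0:
                raise ValueError(f"distance cutoff {r} outside (0, 5] Å")
        if not 0 <= self.angle_min < self.angle_max <= 180:
            raise ValueError("need 0 <= angle_min < angle_max <= 180")

    def cutoff_for(self, donor_is_water: bool, acceptor_is_water: bool) -> float:
        if donor_is_water != acceptor_is_water:
            return self.r_cut_pw
        return self.r_cut_ww_pp


@dataclass
class ShellModel:
    """Ellipsoid first-hydration-shell model and its water density."""
    semi_axes: np.ndarray   # Å, protein ellipsoid semi-axes
    thickness: float        # Å
    shell_volume: float     # Å³
    n_waters: float
    density: float          # kg/m³
    excess_vs_bulk: float   # % relative to bulk water
    bulk_density: float = BULK_WATER_DENSITY


def _mda_box(box):
    box = np.asarray(box, dtype=float)
    return np.concatenate([box, [90.0, 90.0, 90.0]]).astype(np.float32)


def donor_hydrogen_pairs(atoms: pd.DataFrame, positions: np.ndarray,
                         box, donors=None) -> np.ndarray:
    """(donor, hydrogen) index pairs: N/O atoms with an attached H.

    When an explicit donor list is given, a donor without any hydrogen
    within the covalent attachment cutoff is an error naming the atom.
    """
    from MDAnalysis.lib import distances as mdad

    elem = atoms["name"].str[0].str.upper().to_numpy()
    h_idx = np.flatnonzero(elem == "H")
    if donors is None:
        cand = np.flatnonzero(np.isin(elem, DONOR_ELEMENTS))
        explicit = False
    else:
        cand = np.asarray(donors, dtype=int)
        explicit = True
    if len(cand) == 0 or len(h_idx) == 0:
        if explicit and len(cand):
            raise ValueError(
                f"donor atoms {cand.tolist()} have no attached hydrogens")
        return np.empty((0, 2), dtype=int)
    d = mdad.distance_array(positions[cand], positions[h_idx],
                            box=_mda_box(box))
    same_res = (atoms["resid"].to_numpy()[cand][:, None]
                == atoms["resid"].to_numpy()[h_idx][None, :])
    attached = (d <= MAX_DH_BOND) & same_res
    pairs = []
    for i, di in enumerate(cand):
        hs = h_idx[attached[i]]
        if explicit and len(hs) == 0:
            raise ValueError(
                f"donor atom {di} ({atoms['name'].iloc[di]}) has no "
                "attached hydrogen")
        pairs.extend((di, hj) for hj in hs)
    return np.asarray(pairs, dtype=int).reshape(-1, 2)


def detect_hbonds(positions: np.ndarray, box, atoms: pd.DataFrame,
                  criteria: HBondCriteria | None = None,
                  donors=None, acceptors=None,
                  frame: int = 0) -> pd.DataFrame:
    """All hydrogen bonds in one frame, with class labels PP / PW / WW.

    Minimum-image distances in an orthorhombic box.  Returns a DataFrame
    with columns ``frame, donor_atom, hydrogen_atom, acceptor_atom,
    pair_class, r_DA, angle_DHA``.
    """
    from MDAnalysis.lib import distances as mdad

    criteria = criteria or HBondCriteria()
    positions = np.asarray(positions, dtype=float)
    dh = donor_hydrogen_pairs(atoms, positions, box, donors=donors)
    elem = atoms["name"].str[0].str.upper().to_numpy()
    if acceptors is None:
        acceptors = np.flatnonzero(np.isin(elem, ACCEPTOR_ELEMENTS))
    acceptors = np.asarray(acceptors, dtype=int)
    if len(dh) == 0 or len(acceptors) == 0:
        return pd.DataFrame(columns=["frame", "donor_atom", "hydrogen_atom",
                                     "acceptor_atom", "pair_class", "r_DA",
                                     "angle_DHA"])
    is_water = atoms["is_water"].to_numpy()
    bx = _mda_box(box)
    r_da = mdad.distance_array(positions[dh[:, 0]], positions[acceptors],
                               box=bx)
    max_cut = max(criteria.r_cut_pw, criteria.r_cut_ww_pp)
    cand = np.argwhere((r_da <= max_cut)
                       & (dh[:, 0][:, None] != acceptors[None, :]))
    rows = []
    if len(cand):
        di = dh[cand[:, 0], 0]
        hi = dh[cand[:, 0], 1]
        ai = acceptors[cand[:, 1]]
        ang = np.degrees(mdad.calc_angles(
            positions[di], positions[hi], positions[ai], box=bx))
        rr = r_da[cand[:, 0], cand[:, 1]]
        for d, h, a, r, th in zip(di, hi, ai, rr, ang):
            dw, aw = bool(is_water[d]), bool(is_water[a])
            if r > criteria.cutoff_for(dw, aw):
                continue
            if not (criteria.angle_min <= th <= criteria.angle_max):
                continue
            cls = "PW" if dw != aw else ("WW" if dw else "PP")
            rows.append((frame, int(d), int(h), int(a), cls,
                         float(r), float(th)))
    return pd.DataFrame(rows, columns=["frame", "donor_atom", "hydrogen_atom",
                                       "acceptor_atom", "pair_class", "r_DA",
                                       "angle_DHA"])


def shell_membership(positions: np.ndarray, box,
                     protein_heavy: np.ndarray, water_oxygens: np.ndarray,
                     cutoff: float = 3.5) -> np.ndarray:
    """Water-oxygen indices within `cutoff` of any protein heavy atom."""
    from MDAnalysis.lib import distances as mdad

    protein_heavy = np.asarray(protein_heavy, dtype=int)
    water_oxygens = np.asarray(water_oxygens, dtype=int)
    if len(protein_heavy) == 0 or len(water_oxygens) == 0:
        return np.empty(0, dtype=int)
    d = mdad.distance_array(positions[water_oxygens],
                            positions[protein_heavy], box=_mda_box(box))
    return water_oxygens[d.min(axis=1) <= cutoff]


def hb_per_water_ratio(n_pw: float, n_ws1: float, n_waters: float) -> float:
    """(PW + WS1) hydrogen bonds per first-shell water molecule."""
    if n_waters == 0:
        warnings.warn("empty first shell: HB-per-water ratio undefined",
                      stacklevel=2)
        return float("nan")
    return (n_pw + n_ws1) / n_waters


def counts_for_frame(positions, box, atoms: pd.DataFrame,
                     criteria: HBondCriteria | None = None,
                     shell_cutoff: float = 3.5, frame: int = 0) -> dict:
    """Per-frame PP/PW/WS1 counts and first-shell water count.

    A WW bond counts as WS1 when both water molecules belong to S1.
    """
    criteria = criteria or HBondCriteria()
    rec = detect_hbonds(positions, box, atoms, criteria, frame=frame)
    elem = atoms["name"].str[0].str.upper().to_numpy()
    is_water = atoms["is_water"].to_numpy()
    heavy = np.flatnonzero(~is_water & (elem != "H"))
    wo = np.flatnonzero(is_water & (elem == "O"))
    s1 = shell_membership(positions, box, heavy, wo, cutoff=shell_cutoff)
    s1_resids = set(atoms["resid"].to_numpy()[s1].tolist())
    resid = atoms["resid"].to_numpy()

    n_pp = int((rec["pair_class"] == "PP").sum())
    n_pw = int((rec["pair_class"] == "PW").sum())
    ww = rec[rec["pair_class"] == "WW"]
    n_ws1 = int(sum(
        (resid[d] in s1_resids) and (resid[a] in s1_resids)
        for d, a in zip(ww["donor_atom"], ww["acceptor_atom"])))
    n_w = len(s1)
    return {"frame": frame, "n_PP": n_pp, "n_PW": n_pw, "n_WS1": n_ws1,
            "n_waters_S1": n_w,
            "ratio": hb_per_water_ratio(n_pw, n_ws1, n_w)}


def count_series(traj, criteria: HBondCriteria | None = None,
                 shell_cutoff: float = 3.5) -> pd.DataFrame:
    """Per-frame hydrogen-bond counts over a trajectory."""
    atoms = traj.atom_table()
    rows = []
    for fr in traj.frames():
        box = fr.box if fr.box is not None else traj.geometry().box
        rows.append(counts_for_frame(fr.positions, box, atoms, criteria,
                                     shell_cutoff=shell_cutoff,
                                     frame=fr.index))
    return pd.DataFrame(rows)


def count_fluctuations(counts, mode: str = "cumulative",
                       window: int | None = None) -> np.ndarray:
    """Time-resolved variance of a hydrogen-bond count series.

    ``cumulative`` (default): population variance of all samples from the
    window start up to each time point.  ``rolling``: variance over a
    trailing window of ``window`` samples.
    """
    x = np.asarray(counts, dtype=float)
    if mode == "cumulative":
        k = np.arange(1, len(x) + 1)
        mean = np.cumsum(x) / k
        meansq = np.cumsum(x ** 2) / k
        return meansq - mean ** 2
    if mode == "rolling":
        if not window or window < 2:
            raise ValueError("rolling mode needs a window of at least 2")
        return (pd.Series(x).rolling(window).var(ddof=0)).to_numpy()
    raise ValueError(f"unknown mode {mode!r}")


def gyration_semiaxes(positions: np.ndarray,
                      masses: np.ndarray | None = None) -> np.ndarray:
    """Ellipsoid semi-axes from the gyration tensor: aᵢ = √(5·λᵢ).

    For a uniform solid ellipsoid the gyration-tensor eigenvalues are
    aᵢ²/5, so this recovers the body's semi-axes; a uniform sphere of
    radius R gives three semi-axes ≈ R.
    """
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 4:
        raise ValueError("need at least 4 atoms for a gyration tensor")
    w = (np.ones(len(positions)) if masses is None
         else np.asarray(masses, dtype=float))
    w = w / w.sum()
    com = w @ positions
    d = positions - com
    tensor = (w[:, None] * d).T @ d
    lam = np.sort(np.linalg.eigvalsh(tensor))[::-1]
    return np.sqrt(5.0 * np.clip(lam, 0.0, None))


def shell_volume(semi_axes: np.ndarray, thickness: float) -> float:
    """Volume of the ellipsoidal shell of given thickness, Å³."""
    if thickness <= 0:
        raise ValueError(f"shell thickness must be positive, got {thickness}")
    a = np.asarray(semi_axes, dtype=float)
    return float(4.0 * np.pi / 3.0 * (np.prod(a + thickness) - np.prod(a)))


def shell_density(traj, thickness: float = 3.0, shell_cutoff: float = 3.5,
                  water_mass_amu: float = units.WATER_MASS_AMU,
                  bulk_density: float = BULK_WATER_DENSITY) -> ShellModel:
    """Time-averaged first-shell water density via the ellipsoid model.

    Per frame: protein heavy-atom gyration tensor → semi-axes aᵢ=√(5λᵢ);
    shell volume (4π/3)[Π(aᵢ+d) − Πaᵢ]; density = S1 water mass / shell
    volume.  The excess is reported relative to bulk water.
    """
    atoms = traj.atom_table()
    elem = atoms["name"].str[0].str.upper().to_numpy()
    is_water = atoms["is_water"].to_numpy()
    heavy = np.flatnonzero(~is_water & (elem != "H"))
    wo = np.flatnonzero(is_water & (elem == "O"))
    masses = atoms["mass"].to_numpy()[heavy]
    if np.any(~np.isfinite(masses)):
        masses = None

    axes_acc, dens_acc, n_acc = [], [], []
    for fr in traj.frames():
        box = fr.box if fr.box is not None else traj.geometry().box
        axes = gyration_semiaxes(fr.positions[heavy], masses)
        vol = shell_volume(axes, thickness)
        s1 = shell_membership(fr.positions, box, heavy, wo,
                              cutoff=shell_cutoff)
        dens = units.density_kg_m3(len(s1) * water_mass_amu, vol)
        axes_acc.append(axes)
        dens_acc.append(dens)
        n_acc.append(len(s1))
    semi = np.mean(axes_acc, axis=0)
    density = float(np.mean(dens_acc))
    return ShellModel(
        semi_axes=semi, thickness=thickness,
        shell_volume=shell_volume(semi, thickness),
        n_waters=float(np.mean(n_acc)), density=density,
        excess_vs_bulk=100.0 * (density - bulk_density) / bulk_density,
        bulk_density=bulk_density)
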