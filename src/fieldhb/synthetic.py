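"""Synthetic inputs with known ground truth.

Every downstream stage of the pipeline is verifiable without running
molecular dynamics:

* :func:`gen_forced_dipole` — a harmonically forced dipole signal
  A·cos(ωt) + B·sin(ωt) buried in thermal noise (white or OU-correlated),
  with replicate runs, emulating the dipole response of a driven
  component.
* :func:`gen_debye_dipole` — an overdamped (single-relaxation-time)
  dipole driven in the linear regime; its exact steady-state amplitudes
  follow the closed-form Debye curves, so the whole dielectric pipeline
  can be checked against Δε/(1+ω²τ²) and Δε·ωτ/(1+ω²τ²).
* :func:`gen_hb_trajectories` — continuous-time Markov (Gillespie)
  hydrogen-bond state trajectories from the three-state scheme
  QF′ ↔ B ↔ QF with known rates plus an irreversible escape channel that
  produces the long-time relaxation of N and F.
* :func:`gen_toy_frames` — minimal standard-format trajectories (PDB +
  DCD + charge sidecar) with exactly placed donor–H–acceptor triplets
  for the geometry and structure stages.

These are statistical stand-ins: they reproduce the generative models of
the analysis, not any real protein's hydrogen-bond network or force
field.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
import warnings

import numpy as np

from . import units
from .dielectric import DipoleSeries
from .io import FieldSpec
from .kinetics import PairStateSeries

# state codes of the kinetic scheme
B, QF, QFP, LOST = 0, 1, 2, 3


@dataclass
class ForcedDipoleSpec:
    """Ground truth for a harmonically forced dipole signal."""
    A_true: float          # in-phase amplitude, e·Å
    B_true: float          # quadrature amplitude, e·Å
    freq: float            # field frequency, Hz
    noise_sigma: float     # stationary noise s.d., e·Å
    n_periods: int
    dt: float              # frame spacing, ps
    n_replicates: int = 1
    noise_tau: float = 0.0  # noise autocorrelation time, ps; 0 = white
    seed: int = 0

    def __post_init__(self) -> None:
        if self.freq <= 0:
            raise ValueError("freq must be positive")
        period = 1e12 / self.freq
        if self.dt >= period / 2:
            raise ValueError(
                f"dt={self.dt} ps aliases a period of {period:.4g} ps")
        if self.dt >= period / 8:
            raise ValueError(
                f"dt={self.dt} ps leaves no Nyquist margin (period/8 = "
                f"{period / 8:.4g} ps)")
        if self.n_periods < 1:
            raise ValueError("n_periods must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sigma < 0 or self.noise_tau < 0:
            raise ValueError("noise parameters must be non-negative")

    @property
    def period_ps(self) -> float:
        return 1e12 / self.freq


def _ou_noise(rng, n, dt, sigma, tau):
    """Stationary Gaussian noise; exact OU discretisation when tau > 0."""
    if sigma == 0:
        return np.zeros(n)
    if tau == 0:
        return rng.normal(0.0, sigma, size=n)
    a = math.exp(-dt / tau)
    s = sigma * math.sqrt(1.0 - a * a)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma)
    z = rng.normal(0.0, 1.0, size=n - 1)
    for i in range(1, n):
        x[i] = a * x[i - 1] + s * z[i - 1]
    return x


def gen_forced_dipole(spec: ForcedDipoleSpec) -> list[DipoleSeries]:
    """Replicated series A·cos(ωt) + B·sin(ωt) + η(t).

    Replicate r draws its noise from seed ``spec.seed + r``, so fixtures
    are bitwise reproducible and replicates are independent.
    """
    period = spec.period_ps
    n = int(round(spec.n_periods * period / spec.dt)) + 1
    t = np.arange(n) * spec.dt
    w = 2.0 * math.pi / period
    base = spec.A_true * np.cos(w * t) + spec.B_true * np.sin(w * t)
    out = []
    for r in range(spec.n_replicates):
        rng = np.random.default_rng(spec.seed + r)
        eta = _ou_noise(rng, n, spec.dt, spec.noise_sigma, spec.noise_tau)
        out.append(DipoleSeries(component="synthetic", t=t, Mz=base + eta,
                                replicate_id=r,
                                meta={"ground_truth": asdict(spec)}))
    return out


def debye_amplitudes(delta_eps: float, tau_ps: float, fieldspec: FieldSpec,
                     volume_A3: float) -> tuple[float, float]:
    """Exact steady-state (A, B) in e·Å of a Debye dipole under E0·cos(ωt).

    A relaxator dM/dt = −(M − χ·E(t))/τ responds with
    A = χE0/(1+ω²τ²), B = χE0·ωτ/(1+ω²τ²) where χ = Δε·ε₀·V, i.e.
    exactly the Debye dispersion ε′−1 = Δε/(1+ω²τ²),
    ε″ = Δε·ωτ/(1+ω²τ²).
    """
    wt = fieldspec.omega * tau_ps * units.PS_TO_S
    amp = units.amplitude_from_ratio(delta_eps / (1 + wt * wt),
                                     volume_A3, fieldspec.E0)
    return amp, amp * wt


def gen_debye_dipole(delta_eps: float, tau_ps: float, fieldspec: FieldSpec,
                     volume_A3: float, temperature: float = 300.0,
                     n_periods: int = 8, samples_per_period: int = 64,
                     n_replicates: int = 20, seed: int = 0
                     ) -> list[DipoleSeries]:
    """Overdamped dipole driven by the harmonic field, in the linear regime.

    The deterministic part is the exact steady-state Debye response
    (transient already decayed); the thermal fluctuation is an OU process
    with the same relaxation time and the stationary variance the
    fluctuation–dissipation theorem assigns to a Debye dielectric,
    ⟨δM²⟩ = Δε·ε₀·V·k_B·T.
    """
    A, Bq = debye_amplitudes(delta_eps, tau_ps, fieldspec, volume_A3)
    chi = delta_eps * units.EPS0 * volume_A3 * units.A3_TO_M3
    sigma = math.sqrt(chi * units.KB * temperature) / units.EA_TO_CM
    period = fieldspec.period_ps
    spec = ForcedDipoleSpec(A_true=A, B_true=Bq, freq=fieldspec.freq,
                            noise_sigma=sigma, noise_tau=tau_ps,
                            n_periods=n_periods,
                            dt=period / samples_per_period,
                            n_replicates=n_replicates, seed=seed)
    series = gen_forced_dipole(spec)
    for s in series:
        s.meta["delta_eps"] = delta_eps
        s.meta["tau_ps"] = tau_ps
    return series


# ---------------------------------------------------------------------------
# kinetic-model hydrogen-bond trajectories

@dataclass
class KineticGroundTruth:
    """Rates of the QF′ ↔ B ↔ QF scheme plus an irreversible escape channel."""
    k1: float        # B → QF breaking rate, ps⁻¹
    k1p: float       # B → QF′ breaking rate, ps⁻¹
    k2: float        # QF → B reformation rate, ps⁻¹
    k2p: float       # QF′ → B reformation rate, ps⁻¹
    k_escape: float  # QF → lost and QF′ → lost diffusion rate, ps⁻¹
    n_pairs: int
    t_total: float   # ps
    dt: float        # ps
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k1", "k1p", "k2", "k2p", "k_escape"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_pairs < 1 or self.t_total <= 0 or self.dt <= 0:
            raise ValueError("n_pairs, t_total and dt must be positive")
        rmax = max(self.k1, self.k1p, self.k2, self.k2p, self.k_escape)
        if rmax > 0 and self.dt > 0.1 / rmax:
            warnings.warn(
                f"dt={self.dt} ps is coarse for the fastest rate "
                f"{rmax} ps⁻¹ (recommend dt <= {0.1 / rmax:.3g} ps)",
                stacklevel=2)

    @property
    def k1_total(self) -> float:
        """Total breaking rate k₁ + k₁′ (what the flux fit estimates)."""
        return self.k1 + self.k1p


def gen_hb_trajectories(truth: KineticGroundTruth,
                        escape_from_qfprime: bool = True
                        ) -> list[PairStateSeries]:
    """Exact Gillespie trajectories of the kinetic scheme, on the dt grid.

    Every pair starts bonded (state B defines t = 0); the lost state is
    absorbing.  Indicators per frame: h = [state B], H′ = [state B or
    QF], Q = [state QF′].  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(truth.seed)
    n_frames = int(round(truth.t_total / truth.dt)) + 1
    grid = np.arange(n_frames) * truth.dt

    # outgoing channels per state: (rates, destinations)
    qfp_out = ([truth.k2p, truth.k_escape] if escape_from_qfprime
               else [truth.k2p])
    qfp_dst = [B, LOST] if escape_from_qfprime else [B]
    channels = {
        B: (np.array([truth.k1, truth.k1p]), [QF, QFP]),
        QF: (np.array([truth.k2, truth.k_escape]), [B, LOST]),
        QFP: (np.array(qfp_out), qfp_dst),
    }

    out = []
    for pid in range(truth.n_pairs):
        times = [0.0]
        states = [B]
        t, s = 0.0, B
        while t < truth.t_total and s != LOST:
            rates, dests = channels[s]
            total = rates.sum()
            if total == 0:
                break
            t = t + rng.exponential(1.0 / total)
            if t >= truth.t_total:
                break
            s = dests[rng.choice(len(dests), p=rates / total)]
            times.append(t)
            states.append(s)
        ev_t = np.asarray(times)
        ev_s = np.asarray(states)
        idx = np.searchsorted(ev_t, grid, side="right") - 1
        st = ev_s[idx]
        out.append(PairStateSeries(
            pair_id=pid, t=grid,
            h=(st == B).astype(np.int8),
            Hprime=((st == B) | (st == QF)).astype(np.int8),
            Q=(st == QFP).astype(np.int8)))
    return out


def write_pair_states(pairs: list[PairStateSeries], path,
                      ground_truth: KineticGroundTruth | None = None) -> None:
    """Columnar (pair_id, t, h, Hprime, Q, r) CSV, plus a JSON sidecar."""
    import pandas as pd
    frames = []
    for p in pairs:
        frames.append(pd.DataFrame({
            "pair_id": p.pair_id, "t": p.t, "h": p.h, "Hprime": p.Hprime,
            "Q": p.Q if p.Q is not None else 0,
            "r": p.r if p.r is not None else np.nan}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    if ground_truth is not None:
        with open(str(path) + ".json", "w") as fh:
            json.dump(asdict(ground_truth), fh, indent=2)


def read_pair_states(path) -> list[PairStateSeries]:
    import pandas as pd
    df = pd.read_csv(path)
    out = []
    for pid, grp in df.groupby("pair_id", sort=True):
        r = grp["r"].to_numpy()
        out.append(PairStateSeries(
            pair_id=pid, t=grp["t"].to_numpy(),
            h=grp["h"].to_numpy(), Hprime=grp["Hprime"].to_numpy(),
            Q=grp["Q"].to_numpy(),
            r=None if np.all(np.isnan(r)) else r))
    return out


# ---------------------------------------------------------------------------
# toy trajectory frames

@dataclass
class ToyAtom:
    name: str
    resname: str
    resid: int
    charge: float = 0.0
    element: str = ""


@dataclass
class ToyFrameSpec:
    """Explicit atoms + per-frame positions for a minimal trajectory."""
    atoms: list          # list[ToyAtom]
    positions: np.ndarray  # (n_frames, n_atoms, 3) Å
    box: np.ndarray        # (3,) Å
    dt: float = 1.0        # ps

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim == 2:
            self.positions = self.positions[None]
        if self.positions.shape[1] != len(self.atoms):
            raise ValueError("positions do not match the atom list")
        for f in range(self.positions.shape[0]):
            p = self.positions[f]
            d = np.linalg.norm(p[:, None] - p[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if np.any(d < 1e-6):
                i, j = np.unravel_index(np.argmin(d), d.shape)
                raise ValueError(
                    f"overlapping atoms {i} and {j} in frame {f}")


def hbond_triplet_positions(r: float, angle_deg: float,
                            dh: float = 0.96) -> np.ndarray:
    """Donor, hydrogen, acceptor coordinates at exact D–A distance and
    D–H···A angle (vertex at the hydrogen; 180° = linear)."""
    theta = math.radians(angle_deg)
    # D at origin, H on +x; acceptor in the xy-plane at distance L from H
    # chosen so |A - D| = r:  L² − 2·dh·cosθ·L + dh² − r² = 0
    disc = (dh * math.cos(theta)) ** 2 - (dh * dh - r * r)
    if disc < 0:
        raise ValueError(f"no acceptor placement for r={r}, angle={angle_deg}")
    L = dh * math.cos(theta) + math.sqrt(disc)
    D = np.array([0.0, 0.0, 0.0])
    H = np.array([dh, 0.0, 0.0])
    A = H + L * np.array([-math.cos(theta), math.sin(theta), 0.0])
    return np.stack([D, H, A])


def gen_toy_frames(spec: ToyFrameSpec, basename) -> tuple[str, str, str]:
    """Write a toy trajectory as PDB topology + DCD coordinates + charge CSV.

    Returns the three file paths.  Readable back through
    :func:`fieldhb.io.load_trajectory`.
    """
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    n_atoms = len(spec.atoms)
    resids = [a.resid for a in spec.atoms]
    uniq = sorted(set(resids))
    resmap = {rid: i for i, rid in enumerate(uniq)}
    u = mda.Universe.empty(
        n_atoms, n_residues=len(uniq),
        atom_resindex=[resmap[r] for r in resids],
        residue_segindex=[0] * len(uniq), trajectory=True)
    u.add_TopologyAttr("names", [a.name for a in spec.atoms])
    u.add_TopologyAttr("resnames",
                       [next(a.resname for a in spec.atoms if a.resid == rid)
                        for rid in uniq])
    u.add_TopologyAttr("resids", uniq)
    u.add_TopologyAttr("segids", ["TOY"])
    elements = [a.element or a.name[0] for a in spec.atoms]
    u.add_TopologyAttr("elements", elements)
    u.add_TopologyAttr("types", elements)

    n_frames = spec.positions.shape[0]
    dims = np.tile(np.concatenate([spec.box, [90.0, 90.0, 90.0]]),
                   (n_frames, 1))
    u.load_new(spec.positions.astype(np.float32), format=MemoryReader,
               dimensions=dims, dt=spec.dt)

    pdb_path = f"{basename}.pdb"
    dcd_path = f"{basename}.dcd"
    chg_path = f"{basename}.charges.csv"
    u.trajectory[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(pdb_path)
        with mda.Writer(dcd_path, n_atoms, dt=spec.dt) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
    with open(chg_path, "w") as fh:
        fh.write("index,charge\n")
        for i, a in enumerate(spec.atoms):
            fh.write(f"{i},{a.charge}\n")
    return pdb_path, dcd_path, chg_path
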