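"""Forced-oscillation dielectric spectroscopy from dipole time series.

A homogeneous field E(t) = E0·cos(ωt) applied along one axis drives the
dipole moment of each system component k into a harmonic steady state

    M_k(ω, t) = A_k(ω)·cos(ωt) + B_k(ω)·sin(ωt),

and the in-phase / quadrature amplitudes map onto the complex dielectric
function of the component,

    ε′_k(ω) − 1 = A_k / (ε₀·V·E₀),      ε″_k(ω) = B_k / (ε₀·V·E₀).

This module computes component dipole projections from trajectories,
averages replicate runs, fits the harmonic response by ordinary least
squares (a linear problem, solved in closed form), converts amplitudes to
dielectric points, and assembles full spectra.  The ionic contribution is
excluded from totals by default, matching common dielectric-spectroscopy
practice of removing DC conductivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import units
from .io import FieldSpec, SystemGeometry, Trajectory


@dataclass
class DipoleSeries:
    """Projection of a component's dipole moment on the field axis vs time."""
    component: str
    t: np.ndarray            # ps, strictly increasing, uniform
    Mz: np.ndarray           # e·Å
    replicate_id: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.Mz = np.asarray(self.Mz, dtype=float)
        if self.t.shape != self.Mz.shape:
            raise ValueError("t and Mz must have the same length")
        if len(self.t) < 2:
            raise ValueError("a dipole series needs at least two samples")
        dts = np.diff(self.t)
        if np.any(dts <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.max(np.abs(dts - dts[0])) > 1e-9 * max(abs(dts[0]), 1e-300):
            raise ValueError("time grid must be uniformly spaced")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def span(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class HarmonicFit:
    """OLS fit of M(t) to A·cos(ωt) + B·sin(ωt) + offset."""
    A: float
    B: float
    offset: float
    se_A: float
    se_B: float
    cov_AB: np.ndarray        # (2,2) covariance of (A, B)
    residual_rms: float
    n_samples: int
    freq: float
    component: str = ""
    few_periods: bool = False  # True when the series spans < 3 periods

    def covers(self, A_true: float, B_true: float, level: float = 0.95) -> bool:
        """True when (A_true, B_true) lies inside the joint confidence ellipse."""
        d = np.array([self.A - A_true, self.B - B_true])
        q = float(d @ np.linalg.solve(self.cov_AB, d))
        return q <= stats.chi2.ppf(level, df=2)


@dataclass
class DielectricPoint:
    freq: float
    component: str
    eps_re: float
    eps_im: float
    se_re: float = 0.0
    se_im: float = 0.0
    n_replicates: int = 1


@dataclass
class Spectrum:
    """Dielectric points per component plus per-frequency totals.

    The total real part sums the (ε′_k − 1) contributions of the included
    components and adds the shared vacuum 1 exactly once; the total
    imaginary part is the plain sum of the ε″_k.
    """
    points: list
    excluded_components: tuple = ("ions",)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "freq_hz": p.freq, "component": p.component,
            "eps_re": p.eps_re, "eps_im": p.eps_im,
            "se_re": p.se_re, "se_im": p.se_im,
            "n_replicates": p.n_replicates,
        } for p in self.points])

    def totals(self) -> pd.DataFrame:
        df = self.to_frame()
        df = df[~df["component"].isin(self.excluded_components)]
        rows = []
        for freq, grp in df.groupby("freq_hz", sort=True):
            rows.append({
                "freq_hz": freq,
                "eps_re": 1.0 + float((grp["eps_re"] - 1.0).sum()),
                "eps_im": float(grp["eps_im"].sum()),
                "se_re": float(np.sqrt((grp["se_re"] ** 2).sum())),
                "se_im": float(np.sqrt((grp["se_im"] ** 2).sum())),
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------

def dipole_projection(positions: np.ndarray, charges: np.ndarray,
                      axis: np.ndarray, net_charge_tol: float = 1e-6) -> float:
    """Σ qᵢ·(rᵢ·axis) for one frame, in e·Å.

    For a selection with net charge above `net_charge_tol` the dipole is
    origin-dependent; it is then computed about the selection's center of
    charge (weights |q|), which restores translation invariance.
    """
    axis = np.asarray(axis, dtype=float)
    proj = positions @ axis
    net = float(np.sum(charges))
    if abs(net) > net_charge_tol:
        w = np.abs(charges)
        origin = float(w @ proj / np.sum(w))
        proj = proj - origin
    return float(charges @ proj)


def compute_dipole_series(traj: Trajectory, selection: str,
                          axis=(0.0, 0.0, 1.0), component: str | None = None,
                          replicate_id: int | None = None) -> DipoleSeries:
    """Per-frame dipole projection of a selection along the field axis.

    Molecules are made whole across periodic boundaries (fragment unwrap)
    before summation when the topology carries bond information.
    """
    idx = traj.select(selection)
    if len(idx) == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    charges = traj.require_charges()[idx]
    net = float(np.sum(charges))
    meta = {"selection": selection, "net_charge_e": net}
    if abs(net) > 1e-6:
        warnings.warn(
            f"selection {selection!r} has net charge {net:.4g} e; dipole "
            "computed about its center of charge", stacklevel=2)
        meta["origin"] = "center_of_charge"

    ag = traj.u.atoms[idx]
    can_unwrap = hasattr(traj.u.atoms, "bonds") and len(traj.u.atoms.bonds) > 0
    ts_list, mz = [], []
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    for fr in traj.frames():
        if can_unwrap:
            try:
                ag.unwrap(compound="fragments")
            except Exception:
                can_unwrap = False
        pos = ag.positions.astype(float) if can_unwrap else fr.positions[idx]
        ts_list.append(fr.time)
        mz.append(dipole_projection(pos, charges, axis))
    return DipoleSeries(component=component or selection,
                        t=np.array(ts_list), Mz=np.array(mz),
                        replicate_id=replicate_id, meta=meta)


def average_replicates(series_list: list[DipoleSeries]) -> DipoleSeries:
    """Pointwise mean of replicate series sharing one time grid."""
    if not series_list:
        raise ValueError("no series to average")
    ref = series_list[0]
    for s in series_list[1:]:
        if s.component != ref.component:
            raise ValueError("replicates must share a component label")
        if len(s.t) != len(ref.t) or np.max(np.abs(s.t - ref.t)) > 1e-9:
            raise ValueError("replicates must share the time grid")
    M = np.mean([s.Mz for s in series_list], axis=0)
    return DipoleSeries(component=ref.component, t=ref.t.copy(), Mz=M,
                        meta={"n_replicates": len(series_list)})


def fit_harmonic(series: DipoleSeries, fieldspec: FieldSpec) -> HarmonicFit:
    """Closed-form OLS of M(t) on {cos(ωt), sin(ωt), 1}.

    The constant term absorbs any static dipole of the component (the
    protein has a permanent one); it does not enter the dielectric
    conversion.  Requires at least one full field period of data; a span
    under three periods is flagged in the fit record.
    """
    w = fieldspec.omega_ps
    period = fieldspec.period_ps
    if series.span < period * (1 - 1e-9):
        raise ValueError(
            f"series spans {series.span:.4g} ps < one field period "
            f"({period:.4g} ps); the harmonic fit is ill-posed")
    few = series.span < 3 * period * (1 - 1e-9)

    t, y = series.t, series.Mz
    X = np.column_stack([np.cos(w * t), np.sin(w * t), np.ones_like(t)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    n, p = len(t), 3
    sigma2 = float(resid @ resid) / max(n - p, 1)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return HarmonicFit(
        A=float(coef[0]), B=float(coef[1]), offset=float(coef[2]),
        se_A=float(np.sqrt(cov[0, 0])), se_B=float(np.sqrt(cov[1, 1])),
        cov_AB=cov[:2, :2],
        residual_rms=float(np.sqrt(np.mean(resid ** 2))),
        n_samples=n, freq=fieldspec.freq, component=series.component,
        few_periods=few)


def to_dielectric(fit: HarmonicFit, fieldspec: FieldSpec,
                  geom: SystemGeometry, n_replicates: int = 1) -> DielectricPoint:
    """Convert harmonic amplitudes to one complex dielectric point.

    ε′ − 1 = A/(ε₀·V·E₀),  ε″ = B/(ε₀·V·E₀); uncertainties propagate
    linearly from the amplitude standard errors.
    """
    V = geom.V
    ratio_A = units.susceptibility_ratio(fit.A, V, fieldspec.E0)
    ratio_B = units.susceptibility_ratio(fit.B, V, fieldspec.E0)
    scale = units.susceptibility_ratio(1.0, V, fieldspec.E0)
    return DielectricPoint(
        freq=fit.freq, component=fit.component,
        eps_re=1.0 + ratio_A, eps_im=ratio_B,
        se_re=fit.se_A * scale, se_im=fit.se_B * scale,
        n_replicates=n_replicates)


def assemble_spectrum(points, excluded_components=("ions",)) -> Spectrum:
    """Collect dielectric points into a spectrum with per-frequency totals."""
    return Spectrum(points=list(points),
                    excluded_components=tuple(excluded_components))
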