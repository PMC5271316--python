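"""Hydrogen-bond kinetics: correlation functions and reactive-flux rate fits.

For every donor–hydrogen–acceptor pair that is ever bonded, a binary
state trajectory is tracked:

* ``h(t)``  — 1 while the pair is hydrogen bonded,
* ``H'(t)`` — 1 while the pair is closer than the reformation cutoff
  R_PW (quasi-free, QF: broken but able to reform),
* ``Q(t)``  — 1 while a previously bonded pair sits slightly beyond the
  cutoff, R_PW < r ≤ R_max (the QF′ state), where R_max is the distance
  recorded at the first frame after the pair's first bond breaking.

From these the four correlation functions are estimated over all bonded
time origins:

    S(t) = ⟨h(0)·H(t)⟩/⟨h⟩      continuous (strict-lifetime) correlation
    C(t) = ⟨h(0)·h(t)⟩/⟨h⟩      intermittent correlation
    N(t) = ⟨h(0)·[1−h(t)]·H'(t)⟩/⟨h⟩        quasi-free population
    F(t) = ⟨h(0)·[1−h(t)]·[1−H'(t)]·Q(t)⟩/⟨h⟩   QF′ population

with H(t) the continuously-bonded-since-origin indicator.  The reactive
flux k(t) = −dC/dt is then regressed (non-negative least squares) on

    k(t) = k₁·C(t) − k₂·N(t)                  (Luzar–Chandler)
    k(t) = k₁·C(t) − k₂·N(t) − k₂′·F(t)       (extended three-rate model)

where k₁ is the total breaking rate of the three-state scheme
QF′ ↔ B ↔ QF and ζ = 1/k₁ is the hydrogen-bond lifetime.  Multi-
exponential fits of C, N, F give the amplitude-weighted relaxation
times τ_C, τ_N, τ_F.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize


@dataclass
class PairStateSeries:
    """State indicators for one hydrogen-bonding pair on a uniform grid."""
    pair_id: object
    t: np.ndarray                 # ps
    h: np.ndarray                 # bonded indicator {0,1}
    Hprime: np.ndarray            # within-cutoff indicator {0,1}
    Q: np.ndarray | None = None   # QF' indicator {0,1}
    r: np.ndarray | None = None   # donor–acceptor distance, Å
    Rmax: float | None = None     # post-break maximum distance for this pair

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.h = np.asarray(self.h, dtype=np.int8)
        self.Hprime = np.asarray(self.Hprime, dtype=np.int8)
        if self.Q is not None:
            self.Q = np.asarray(self.Q, dtype=np.int8)
        if self.r is not None:
            self.r = np.asarray(self.r, dtype=float)
        for name in ("h", "Hprime", "Q"):
            v = getattr(self, name)
            if v is not None and not np.all((v == 0) | (v == 1)):
                raise ValueError(f"{name} must be a 0/1 indicator")
        if np.any(self.h > self.Hprime):
            raise ValueError("invariant violated: h=1 requires Hprime=1")
        if self.Q is not None and np.any((self.Q == 1) & (self.Hprime == 1)):
            raise ValueError("invariant violated: Q=1 requires Hprime=0")


@dataclass
class CorrelationSet:
    """S, C, N, F on a lag grid, with the bonded-origin count per lag."""
    lags: np.ndarray      # ps
    S: np.ndarray
    C: np.ndarray
    N: np.ndarray
    F: np.ndarray
    n_origins: np.ndarray

    def validate(self) -> None:
        """Raise on any violation of the estimator's hard invariants.

        S is non-increasing up to origin depletion: with per-lag origin
        sets the continuous-bond numerator can only shrink with lag, so
        S(ℓ+1) ≤ S(ℓ)·n(ℓ)/n(ℓ+1) always; when consecutive lags share
        their origin count this is plain monotonicity.
        """
        ok = self.n_origins > 0
        if not (abs(self.S[0] - 1) < 1e-12 and abs(self.C[0] - 1) < 1e-12):
            raise AssertionError("S(0) and C(0) must equal 1")
        if abs(self.N[0]) > 1e-12 or abs(self.F[0]) > 1e-12:
            raise AssertionError("N(0) and F(0) must equal 0")
        S, C = self.S[ok], self.C[ok]
        if np.any(S < -1e-12) or np.any(C - S < -1e-12) or np.any(C > 1 + 1e-12):
            raise AssertionError("ordering 0 <= S <= C <= 1 violated")
        n = self.n_origins[ok].astype(float)
        bound = S[:-1] * n[:-1] / n[1:]
        if np.any(S[1:] > bound + 1e-12):
            raise AssertionError("S increases beyond the origin-loss bound")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_ps": self.lags, "S": self.S, "C": self.C,
                             "N": self.N, "F": self.F,
                             "n_origins": self.n_origins})


@dataclass
class KineticFit:
    """Reactive-flux rate constants for one correlation set."""
    model: str                # "LC" | "extended"
    k1: float                 # total breaking rate, ps⁻¹
    k2: float                 # QF → B reformation rate, ps⁻¹
    k2p: float                # QF′ → B reformation rate, ps⁻¹ (0 for LC)
    fit_window: tuple
    rss: float
    cov: np.ndarray
    condition_number: float = np.nan

    @property
    def lifetime(self) -> float:
        """ζ = 1/k₁, ps."""
        return 1.0 / self.k1 if self.k1 > 0 else np.inf


@dataclass
class MultiExpFit:
    amplitudes: np.ndarray
    taus: np.ndarray          # ps
    rss: float
    weighting: str = "amplitude"

    @property
    def n_terms(self) -> int:
        return len(self.taus)

    @property
    def tau_weighted(self) -> float:
        """Σaᵢτᵢ/Σaᵢ (or Σaᵢτᵢ²/Σaᵢτᵢ for integral weighting)."""
        a, tau = self.amplitudes, self.taus
        if self.weighting == "amplitude":
            return float(np.sum(a * tau) / np.sum(a))
        return float(np.sum(a * tau ** 2) / np.sum(a * tau))

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return np.sum(self.amplitudes[:, None]
                      * np.exp(-t[None, :] / self.taus[:, None]), axis=0)


# ---------------------------------------------------------------------------
# pair-state construction

def pair_state_series(pair_id, t, h, r, cutoff, rmax=None) -> PairStateSeries:
    """Build one PairStateSeries from a bonded indicator and a distance series.

    ``cutoff`` is the reformation cutoff R_PW (the class HB distance
    cutoff: 3.2 Å for protein–water, 3.5 Å for water–water).  R_max is
    taken from the first frame after the pair's first bond breaking
    unless a global ``rmax`` is supplied.
    """
    h = np.asarray(h, dtype=np.int8)
    r = np.asarray(r, dtype=float)
    Hp = (r <= cutoff).astype(np.int8)
    Hp = np.maximum(Hp, h)  # a bonded pair is within its own class cutoff
    breaks = np.flatnonzero((h[1:] == 0) & (h[:-1] == 1)) + 1
    if rmax is None:
        Rmax = float(r[breaks[0]]) if len(breaks) else None
    else:
        Rmax = float(rmax)
    if Rmax is not None:
        Q = ((h == 0) & (Hp == 0) & (r <= Rmax)).astype(np.int8)
    else:
        Q = np.zeros_like(h)
    return PairStateSeries(pair_id=pair_id, t=np.asarray(t, dtype=float),
                           h=h, Hprime=Hp, Q=Q, r=r, Rmax=Rmax)


def pair_states_from_hbonds(bond_table: pd.DataFrame, r_series: dict,
                            t: np.ndarray, cutoff: float,
                            global_rmax: bool = False) -> list[PairStateSeries]:
    """Pair state trajectories from per-frame bond records and distances.

    Parameters
    ----------
    bond_table
        DataFrame with columns ``frame, donor_atom, hydrogen_atom,
        acceptor_atom`` listing every detected bond per frame.
    r_series
        Mapping pair key ``(donor, hydrogen, acceptor)`` → per-frame
        donor–acceptor distance array on the grid ``t``.
    cutoff
        Reformation cutoff R_PW for this bond class, Å.
    global_rmax
        Use one R_max (the largest first-post-break distance over all
        pairs) instead of per-pair values.
    """
    n = len(t)
    keys = sorted(r_series.keys())
    hmat = {k: np.zeros(n, dtype=np.int8) for k in keys}
    cols = ["donor_atom", "hydrogen_atom", "acceptor_atom"]
    for frame, d, hy, a in bond_table[["frame"] + cols].itertuples(index=False):
        key = (d, hy, a)
        if key in hmat:
            hmat[key][int(frame)] = 1
    ever = [k for k in keys if hmat[k].any()]
    if global_rmax:
        rmaxes = []
        for k in ever:
            h = hmat[k]
            br = np.flatnonzero((h[1:] == 0) & (h[:-1] == 1)) + 1
            if len(br):
                rmaxes.append(float(np.asarray(r_series[k])[br[0]]))
        rmax = max(rmaxes) if rmaxes else None
        return [pair_state_series(k, t, hmat[k], r_series[k], cutoff, rmax=rmax)
                for k in ever]
    return [pair_state_series(k, t, hmat[k], r_series[k], cutoff)
            for k in ever]


# ---------------------------------------------------------------------------
# correlation estimation

def _stack(pairs: list[PairStateSeries]):
    t = pairs[0].t
    for p in pairs[1:]:
        if len(p.t) != len(t) or np.max(np.abs(p.t - t)) > 1e-9:
            raise ValueError("all pairs must share a common time grid")
    H = np.stack([p.h for p in pairs])
    HP = np.stack([p.Hprime for p in pairs])
    Q = np.stack([p.Q if p.Q is not None else np.zeros_like(p.h)
                  for p in pairs])
    return t, H.astype(np.int64), HP.astype(np.int64), Q.astype(np.int64)


def correlate(pairs: list[PairStateSeries], max_lag: float | None = None,
              origin_stride: int = 1) -> CorrelationSet:
    """Estimate S, C, N, F over all bonded time origins.

    Every frame with h(t₀)=1 serves as an origin (``origin_stride``
    thins them); numerators and denominators are exact integer counts, so
    the estimate equals the exhaustive origin-enumeration value bitwise.
    """
    if not pairs:
        raise ValueError("no pair state series given")
    t, H, HP, Q = _stack(pairs)
    T = H.shape[1]
    dt = t[1] - t[0]
    L = T - 1 if max_lag is None else int(round(max_lag / dt))
    if L >= T:
        raise ValueError(f"max_lag {max_lag} exceeds the trajectory span")

    # forward run length: R[t] = consecutive bonded frames starting at t
    R = np.zeros_like(H)
    R[:, -1] = H[:, -1]
    for j in range(T - 2, -1, -1):
        R[:, j] = H[:, j] * (1 + R[:, j + 1])

    broken = (1 - H) * HP           # QF indicator
    qfp = (1 - H) * (1 - HP) * Q    # QF' indicator (Q already implies both)

    lags = np.arange(L + 1) * dt
    S = np.full(L + 1, np.nan)
    C = np.full(L + 1, np.nan)
    N = np.full(L + 1, np.nan)
    F = np.full(L + 1, np.nan)
    n_origins = np.zeros(L + 1, dtype=np.int64)
    sl = slice(None, None, origin_stride)
    for ell in range(L + 1):
        M = T - ell
        h0 = H[:, :M][:, sl]
        denom = int(h0.sum())
        n_origins[ell] = denom
        if denom == 0:
            continue
        C[ell] = int((h0 * H[:, ell:][:, sl]).sum()) / denom
        S[ell] = int((R[:, :M][:, sl] > ell).sum()) / denom
        N[ell] = int((h0 * broken[:, ell:][:, sl]).sum()) / denom
        F[ell] = int((h0 * qfp[:, ell:][:, sl]).sum()) / denom
    if n_origins[0] == 0:
        raise ValueError("no bonded origins: every h series is zero")
    if np.any(n_origins == 0):
        warnings.warn("some lags have no bonded origins; set to NaN",
                      stacklevel=2)
    out = CorrelationSet(lags=lags, S=S, C=C, N=N, F=F, n_origins=n_origins)
    out.validate()
    return out


def reactive_flux(corr: CorrelationSet) -> np.ndarray:
    """k(t) = −dC/dt by central finite differences (one-sided at the ends)."""
    return -np.gradient(corr.C, corr.lags)


# ---------------------------------------------------------------------------
# rate fitting

def fit_rates(corr: CorrelationSet, model: str = "extended",
              window: tuple = (0.5, 30.0)) -> KineticFit:
    """Non-negative least squares of k(t) on the kinetic model.

    LC:        k(t) = k₁·C − k₂·N
    extended:  k(t) = k₁·C − k₂·N − k₂′·F

    The fit window (ps, inclusive) excludes the lag-0 point where the
    one-sided derivative is least accurate and the noisy long-lag tail.
    """
    if model not in ("LC", "extended"):
        raise ValueError(f"unknown model {model!r}")
    k = reactive_flux(corr)
    lo, hi = window
    mask = (corr.lags >= lo - 1e-12) & (corr.lags <= hi + 1e-12)
    mask &= np.isfinite(corr.C) & np.isfinite(corr.N) & np.isfinite(k)
    if model == "extended":
        mask &= np.isfinite(corr.F)
    if mask.sum() < 4:
        raise ValueError("fit window contains fewer than 4 usable lags")
    cols = [corr.C[mask], -corr.N[mask]]
    if model == "extended":
        cols.append(-corr.F[mask])
    X = np.column_stack(cols)
    y = k[mask]
    # an identically vanishing regressor (e.g. F ≡ 0) carries no
    # information: its rate is 0 and it must not poison the conditioning
    active = np.flatnonzero(np.linalg.norm(X, axis=0) > 0)
    Xa = X[:, active]
    cond = float(np.linalg.cond(Xa)) if Xa.size else np.inf
    if cond > 1e10:
        raise ValueError(
            f"singular design for model {model}: condition number {cond:.3g}")
    beta_a, _ = optimize.nnls(Xa, y)
    beta = np.zeros(X.shape[1])
    beta[active] = beta_a
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = max(len(y) - len(active), 1)
    cov = np.full((X.shape[1], X.shape[1]), np.nan)
    try:
        cov[np.ix_(active, active)] = rss / dof * np.linalg.inv(Xa.T @ Xa)
    except np.linalg.LinAlgError:
        pass
    k2p = float(beta[2]) if model == "extended" else 0.0
    return KineticFit(model=model, k1=float(beta[0]), k2=float(beta[1]),
                      k2p=k2p, fit_window=(lo, hi), rss=rss, cov=cov,
                      condition_number=cond)


def fit_multiexp(lags, values, n_terms: int, weighting: str = "amplitude",
                 n_starts: int = 8, seed: int = 0) -> MultiExpFit:
    """Fit Σᵢ aᵢ·exp(−t/τᵢ) with separable, multi-start least squares.

    Time constants are optimised in log space; for each trial the
    amplitudes are the exact non-negative linear solution (variable
    projection), which makes the fit robust to poor τ starting values.
    Starts are log-spaced across the lag range plus deterministic jitter.
    """
    if not 1 <= n_terms <= 4:
        raise ValueError("n_terms must be in 1..4")
    t = np.asarray(lags, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = np.isfinite(y)
    t, y = t[keep], y[keep]
    if len(t) < 2 * n_terms:
        raise ValueError("not enough points for the requested number of terms")

    def amps_for(log_tau):
        tau = np.exp(log_tau)
        Phi = np.exp(-t[:, None] / tau[None, :])
        a, _ = optimize.nnls(Phi, y)
        return a, Phi

    def resid(log_tau):
        a, Phi = amps_for(log_tau)
        return Phi @ a - y

    t_lo = max(t[1] - t[0], t[t > 0].min() if np.any(t > 0) else 1e-3)
    t_hi = max(t[-1], 2 * t_lo)
    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        base = np.linspace(np.log(t_lo), np.log(t_hi), n_terms + 2)[1:-1]
        jitter = rng.normal(0, 0.4, size=n_terms) if s else 0.0
        x0 = base + jitter + 0.5 * (s % 3 - 1)
        try:
            res = optimize.least_squares(resid, x0, method="lm", max_nfev=2000)
        except Exception:
            continue
        rss = float(res.fun @ res.fun)
        if best is None or rss < best[0]:
            best = (rss, res.x, res.status > 0)
    if best is None or not best[2]:
        rss = best[0] if best else np.inf
        raise RuntimeError(
            f"multi-exponential fit failed to converge (best rss {rss:.3g})")
    rss, log_tau, _ = best
    a, _ = amps_for(log_tau)
    order = np.argsort(np.exp(log_tau))
    return MultiExpFit(amplitudes=a[order], taus=np.exp(log_tau)[order],
                       rss=rss, weighting=weighting)


def lifetimes_report(entries: list[dict]) -> pd.DataFrame:
    """Table of rates, lifetimes ζ = 1/k₁ and relaxation times per condition.

    Each entry supplies ``condition``, ``system`` (PW/WS1), rate
    constants ``k1, k2, k2p`` (ps⁻¹) and optionally ``tau_C, tau_N,
    tau_F`` (ps); the lifetime column is computed here, never taken from
    the input.
    """
    rows = []
    for e in entries:
        k1 = float(e["k1"])
        rows.append({
            "condition": e.get("condition", ""),
            "system": e.get("system", ""),
            "k1_ps_inv": k1,
            "k2_ps_inv": float(e.get("k2", np.nan)),
            "k2p_ps_inv": float(e.get("k2p", np.nan)),
            "zeta_ps": 1.0 / k1 if k1 > 0 else np.inf,
            "tau_C_ps": float(e.get("tau_C", np.nan)),
            "tau_N_ps": float(e.get("tau_N", np.nan)),
            "tau_F_ps": float(e.get("tau_F", np.nan)),
        })
    return pd.DataFrame(rows)
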