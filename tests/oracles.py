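"""Independent reference implementations used to validate the package.

Everything here is deliberately naive — exhaustive loops, closed forms,
dense matrix exponentials — and shares no code with the implementation
paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm


# ---------------------------------------------------------------- dielectric

def harmonic_normal_equations(t, y, omega):
    """Brute-force OLS of y on {cos, sin, 1} via explicit normal equations."""
    X = np.column_stack([np.cos(omega * t), np.sin(omega * t),
                         np.ones_like(t)])
    return np.linalg.solve(X.T @ X, X.T @ y)


def harmonic_amplitude_variance(sigma, n):
    """Closed-form var(Â) ≈ 2σ²/N for harmonic regression on white noise."""
    return 2.0 * sigma ** 2 / n


def debye_curves(delta_eps, tau_s, omegas):
    """Closed-form Debye dispersion (ε′−1, ε″) at angular frequencies."""
    wt = np.asarray(omegas) * tau_s
    return delta_eps / (1 + wt ** 2), delta_eps * wt / (1 + wt ** 2)


# ---------------------------------------------------------------- kinetics

def enumerate_correlations(pairs, max_lag_frames):
    """Exhaustive origin-enumeration estimate of S, C, N, F.

    Triple loops over pairs, origins and lags; integer counts divided at
    the end, so a correct estimator must agree bitwise.
    """
    T = len(pairs[0].t)
    L = max_lag_frames
    numS = np.zeros(L + 1, dtype=np.int64)
    numC = np.zeros(L + 1, dtype=np.int64)
    numN = np.zeros(L + 1, dtype=np.int64)
    numF = np.zeros(L + 1, dtype=np.int64)
    den = np.zeros(L + 1, dtype=np.int64)
    for p in pairs:
        h = np.asarray(p.h, dtype=int)
        hp = np.asarray(p.Hprime, dtype=int)
        q = (np.asarray(p.Q, dtype=int) if p.Q is not None
             else np.zeros(T, dtype=int))
        for ell in range(L + 1):
            for t0 in range(T - ell):
                den[ell] += h[t0]
                if not h[t0]:
                    continue
                numC[ell] += h[t0 + ell]
                if all(h[t0 + j] for j in range(ell + 1)):
                    numS[ell] += 1
                numN[ell] += (1 - h[t0 + ell]) * hp[t0 + ell]
                numF[ell] += ((1 - h[t0 + ell]) * (1 - hp[t0 + ell])
                              * q[t0 + ell])
    with np.errstate(invalid="ignore", divide="ignore"):
        return (numS / den, numC / den, numN / den, numF / den, den)


def two_state_curves(k1, k2, t):
    """Analytic C, N of the two-state master equation B ↔ QF, start in B."""
    t = np.asarray(t, dtype=float)
    ktot = k1 + k2
    C = k2 / ktot + k1 / ktot * np.exp(-ktot * t)
    return C, 1.0 - C


def four_state_curves(k1, k1p, k2, k2p, k_escape, t,
                      escape_from_qfprime=True):
    """Exact C, N, F of the QF′ ↔ B ↔ QF (+ escape) master equation."""
    ke2 = k_escape if escape_from_qfprime else 0.0
    G = np.array([
        [-(k1 + k1p), k1, k1p, 0.0],
        [k2, -(k2 + k_escape), 0.0, k_escape],
        [k2p, 0.0, -(k2p + ke2), ke2],
        [0.0, 0.0, 0.0, 0.0]])
    p0 = np.array([1.0, 0.0, 0.0, 0.0])
    P = np.stack([p0 @ expm(G * ti) for ti in np.asarray(t, dtype=float)])
    return P[:, 0], P[:, 1], P[:, 2]


# ---------------------------------------------------------------- geometry

def min_image(vec, box):
    box = np.asarray(box, dtype=float)
    return vec - box * np.round(vec / box)


def brute_force_hbonds(positions, box, atoms, criteria):
    """O(N³)-style triple scan over (donor, hydrogen, acceptor).

    Hand-rolled minimum-image arithmetic; returns a set of
    (donor, hydrogen, acceptor, class) tuples.
    """
    elem = [str(n)[0].upper() for n in atoms["name"]]
    resid = atoms["resid"].to_numpy()
    is_water = atoms["is_water"].to_numpy()
    n = len(elem)
    found = set()
    for d in range(n):
        if elem[d] not in ("N", "O"):
            continue
        for hyd in range(n):
            if elem[hyd] != "H" or resid[hyd] != resid[d]:
                continue
            dh = np.linalg.norm(min_image(positions[hyd] - positions[d], box))
            if dh > 1.25:
                continue
            for a in range(n):
                if a == d or elem[a] not in ("N", "O"):
                    continue
                r = np.linalg.norm(
                    min_image(positions[a] - positions[d], box))
                dw, aw = bool(is_water[d]), bool(is_water[a])
                cut = (criteria.r_cut_pw if dw != aw
                       else criteria.r_cut_ww_pp)
                if r > cut:
                    continue
                v1 = min_image(positions[d] - positions[hyd], box)
                v2 = min_image(positions[a] - positions[hyd], box)
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1)
                                           * np.linalg.norm(v2))
                ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if not criteria.angle_min <= ang <= criteria.angle_max:
                    continue
                cls = "PW" if dw != aw else ("WW" if dw else "PP")
                found.add((d, hyd, a, cls))
    return found


def brute_force_shell(positions, box, protein_heavy, water_oxygens, cutoff):
    """All-pairs minimum-image membership scan."""
    out = []
    for w in water_oxygens:
        for p in protein_heavy:
            d = np.linalg.norm(min_image(positions[w] - positions[p], box))
            if d <= cutoff:
                out.append(w)
                break
    return np.asarray(out, dtype=int)


# ---------------------------------------------------------------- statistics

def two_pass_cumulative_variance(x):
    """Population variance of x[:k] for every k, computed the slow way."""
    x = np.asarray(x, dtype=float)
    return np.array([np.mean((x[:k] - np.mean(x[:k])) ** 2)
                     for k in range(1, len(x) + 1)])


def rotation_grid_rmsd(mobile, ref, n_grid=40, seed=0, refine=True):
    """Minimum RMSD over a dense random-rotation grid (translation exact).

    A slow global search used to validate the analytic superposition:
    samples uniform random rotations, keeps the best, and polishes with
    a local grid around it.
    """
    from scipy.spatial.transform import Rotation

    mobile = mobile - mobile.mean(axis=0)
    ref = ref - ref.mean(axis=0)
    rots = Rotation.random(n_grid ** 2, random_state=seed)
    best, best_rot = np.inf, None
    for R in rots:
        val = np.sqrt(np.mean(np.sum((mobile @ R.as_matrix().T - ref) ** 2,
                                     axis=1)))
        if val < best:
            best, best_rot = val, R
    if refine and best_rot is not None:
        for scale in (0.3, 0.1, 0.03, 0.01, 0.003):
            deltas = Rotation.from_rotvec(
                np.random.default_rng(seed).normal(0, scale, size=(200, 3)))
            for dR in deltas:
                R = dR * best_rot
                val = np.sqrt(np.mean(
                    np.sum((mobile @ R.as_matrix().T - ref) ** 2, axis=1)))
                if val < best:
                    best, best_rot = val, R
    return best
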