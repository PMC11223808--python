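"""Minimum-action transition paths on a two-well harmonic energy surface.

Around each endpoint the energy is the harmonic expansion
U_A(X) = 1/2 (X - X_A)^T H_A (X - X_A) (and likewise for B), and the
combined surface is U = min(U_A + dE, U_B).  Under overdamped Langevin
dynamics the minimum-action path obeys, inside well A,

    d^2 X / dt^2 = H_A^2 (X - X_A),   X(0) = X_A,  X(t_A) = X_ts,

whose solution is the matrix-function propagator

    X(t) = X_A + f(H_A, t) (X_ts - X_A),   f(x, t) = sinh(x t) / sinh(x t_A),

with f(0, t) = t/t_A on the rigid-body kernel.  The transition state
X_ts and the time split (t_A, t_B = F - t_A) are pinned by three
continuity requirements at the well crossing:

* position — automatic, both halves end at X_ts;
* velocity — a linear system (M_A + M_B) X_ts = M_A X_A + M_B X_B with
  M = H coth(H t), solved matrix-free by conjugate gradients;
* energy — U_B(X_ts) - U_A(X_ts) = dE, enforced by a 1-D bracketed root
  find on t_A.

Matrix functions are evaluated either through a full eigendecomposition
(dense backend, small systems) or through Lanczos projection onto a
Krylov subspace, f(A)v ~ ||v|| V_m f(T_m) e_1 (krylov backend), which
only needs matrix-vector products and scales to very large networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import LinearOperator, cg

from .elastic_network import DENSE_LIMIT, HessianOperator
from .errors import NoCrossingError, SolverError

logger = logging.getLogger(__name__)

#: Krylov defaults: grow the subspace in steps up to this order
KRYLOV_M_MAX = 100
KRYLOV_M_STEP = 10
KRYLOV_TOL = 1e-8

#: clamp for tiny negative Ritz/eigen values (relative to spectral scale)
NEG_EIG_TOL = 1e-8


# ---------------------------------------------------------------------------
# scalar kernels (applied to eigenvalues / Ritz values)
# ---------------------------------------------------------------------------

def f_scalar(x, t: float, t_s: float):
    """sinh(x t)/sinh(x t_s), overflow-safe, with the x -> 0 limit t/t_s.

    Valid for 0 <= t <= t_s; monotone nondecreasing in t, with f = 0 at
    t = 0 and f = 1 at t = t_s for every x >= 0.
    """
    if t_s <= 0:
        raise ValueError(f"t_s must be positive, got {t_s}")
    if not 0 <= t <= t_s * (1 + 1e-12):
        raise ValueError(f"time {t} outside [0, {t_s}]")
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x * t_s < 1e-8
    out[small] = t / t_s
    xs = x[~small]
    # sinh ratio rewritten with decaying exponentials only
    out[~small] = (np.exp(xs * (t - t_s)) * (1.0 - np.exp(-2.0 * xs * t))
                   / (1.0 - np.exp(-2.0 * xs * t_s)))
    return out if out.ndim else float(out)


def vel_scalar(x, t_s: float):
    """x coth(x t_s) — the end-point velocity kernel; limit 1/t_s at x = 0.

    This is d/dt [sinh(x t)/sinh(x t_s)] at t = t_s, so M = H coth(H t_s)
    maps (X_ts - X_ref) to the arrival velocity of the half-trajectory.
    Always >= 1/t_s, which makes M_A + M_B strictly positive definite
    even on the rigid-body kernel.
    """
    if t_s <= 0:
        raise ValueError(f"t_s must be positive, got {t_s}")
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x * t_s < 1e-8
    out[small] = 1.0 / t_s
    xs = x[~small]
    e = np.exp(-2.0 * xs * t_s)
    out[~small] = xs * (1.0 + e) / (1.0 - e)
    return out if out.ndim else float(out)


def _clamp_spectrum(w: np.ndarray) -> np.ndarray:
    scale = max(1.0, float(np.max(np.abs(w))) if len(w) else 1.0)
    if np.any(w < -NEG_EIG_TOL * scale):
        raise ValueError(
            f"negative eigenvalue {w.min():.3e} encountered; the elastic "
            "Hessian at a reference state must be positive semidefinite")
    return np.clip(w, 0.0, None)


# ---------------------------------------------------------------------------
# Lanczos / matrix functions
# ---------------------------------------------------------------------------

@dataclass
class LanczosBasis:
    """Orthonormal Krylov basis with its tridiagonal projection.

    Satisfies A V_m = V_m T_m + beta_m v_{m+1} e_m^T columnwise.
    """

    V: np.ndarray          # (n, m)
    alpha: np.ndarray      # diagonal of T_m
    beta: np.ndarray       # subdiagonal of T_m, length m-1
    beta_m: float          # residual coefficient
    v_next: np.ndarray     # v_{m+1}
    vnorm: float

    @property
    def m(self) -> int:
        return len(self.alpha)

    def tridiagonal(self) -> np.ndarray:
        T = np.diag(self.alpha)
        if self.m > 1:
            T += np.diag(self.beta, 1) + np.diag(self.beta, -1)
        return T


def lanczos_extend(matvec, v: np.ndarray, m: int,
                   basis: LanczosBasis | None = None) -> LanczosBasis:
    """Build (or extend) a Lanczos basis with full reorthogonalization."""
    n = len(v)
    vnorm = float(np.linalg.norm(v))
    if vnorm == 0.0:
        raise ValueError("Lanczos start vector is zero")
    if basis is None:
        V = np.empty((n, m))
        V[:, 0] = v / vnorm
        alpha, beta = [], []
        w_prev = None
        start = 0
    else:
        V = np.empty((n, m))
        V[:, :basis.m] = basis.V
        alpha, beta = list(basis.alpha), list(basis.beta)
        start = basis.m
        if basis.beta_m == 0.0:
            return basis  # invariant subspace found; cannot extend
        beta.append(basis.beta_m)
        V[:, start] = basis.v_next
    j = start if basis is not None else 0
    while j < m:
        w = matvec(V[:, j])
        a = float(np.dot(V[:, j], w))
        alpha.append(a)
        w = w - a * V[:, j]
        if j > 0:
            w = w - beta[j - 1] * V[:, j - 1]
        # full reorthogonalization, twice for safety
        for _ in range(2):
            w = w - V[:, :j + 1] @ (V[:, :j + 1].T @ w)
        b = float(np.linalg.norm(w))
        if b < 1e-13 * max(1.0, abs(a)) or j == m - 1:
            if b < 1e-13 * max(1.0, abs(a)):
                return LanczosBasis(V[:, :j + 1], np.array(alpha),
                                    np.array(beta), 0.0,
                                    np.zeros(n), vnorm)
            return LanczosBasis(V[:, :m], np.array(alpha), np.array(beta),
                                b, w / b, vnorm)
        beta.append(b)
        V[:, j + 1] = w / b
        j += 1
    raise AssertionError("unreachable")


def _apply_fn_dense(H: HessianOperator, scalar_fn, v: np.ndarray) -> np.ndarray:
    w, P = H.eigendecomposition()
    return P @ (scalar_fn(w) * (P.T @ v))


def _apply_fn_krylov(H: HessianOperator, scalar_fn, v: np.ndarray,
                     m_max: int, tol: float) -> np.ndarray:
    vnorm = np.linalg.norm(v)
    if vnorm == 0.0:
        return np.zeros_like(v)
    basis: LanczosBasis | None = None
    prev = None
    m = min(KRYLOV_M_STEP, m_max, H.dim)
    while True:
        basis = lanczos_extend(H.matvec, v, m, basis)
        T = basis.tridiagonal()
        theta, S = np.linalg.eigh(T)
        theta = _clamp_spectrum(theta)
        y = basis.V @ (S @ (scalar_fn(theta) * S[0, :] * basis.vnorm))
        if prev is not None:
            delta = np.linalg.norm(y - prev) / max(1.0, np.linalg.norm(y))
            if delta < tol:
                return y
        if basis.beta_m == 0.0 or basis.m >= min(m_max, H.dim):
            if prev is not None and basis.beta_m != 0.0:
                delta = np.linalg.norm(y - prev) / max(1.0, np.linalg.norm(y))
                logger.warning("Krylov evaluation stopped at m=%d with "
                               "iterate change %.2e > tol %.2e",
                               basis.m, delta, tol)
            return y
        prev = y
        m = min(basis.m + KRYLOV_M_STEP, m_max, H.dim)


def apply_matrix_function(H: HessianOperator, scalar_fn, v: np.ndarray,
                          backend: str = "dense", m_max: int = KRYLOV_M_MAX,
                          tol: float = KRYLOV_TOL) -> np.ndarray:
    """Evaluate f(H) v for a scalar kernel f applied to the spectrum.

    ``backend="dense"`` uses the cached eigendecomposition P f(D) P^T v;
    ``backend="krylov"`` uses Lanczos projection with the subspace order
    grown adaptively until successive iterates differ by less than
    ``tol`` (or ``m_max`` is reached, with a warning).
    """
    v = np.asarray(v, dtype=float)
    if backend == "dense":
        return _apply_fn_dense(H, lambda w: scalar_fn(_clamp_spectrum(w)), v)
    if backend == "krylov":
        return _apply_fn_krylov(H, scalar_fn, v, m_max, tol)
    raise ValueError(f"unknown backend {backend!r}")


def choose_backend(dim: int, override: str | None = None) -> str:
    if override in ("dense", "krylov"):
        return override
    return "dense" if dim <= DENSE_LIMIT else "krylov"


# ---------------------------------------------------------------------------
# half-trajectories
# ---------------------------------------------------------------------------

@dataclass
class HalfPathModel:
    """One well's propagator: reference, Hessian, boundary and duration."""

    X_ref: np.ndarray
    H: HessianOperator
    X_ts: np.ndarray
    t_s: float
    backend: str = "dense"

    def frame(self, t: float) -> np.ndarray:
        if t == 0.0:
            return self.X_ref.copy()
        dv = self.X_ts - self.X_ref
        y = apply_matrix_function(self.H, lambda x: f_scalar(x, t, self.t_s),
                                  dv, backend=self.backend)
        return self.X_ref + y


def half_trajectory(hp: HalfPathModel, times) -> np.ndarray:
    """Frames of one analytic half-path at the requested times."""
    return np.array([hp.frame(float(t)) for t in times])


# ---------------------------------------------------------------------------
# transition-state search
# ---------------------------------------------------------------------------

@dataclass
class TransitionResult:
    X_ts: np.ndarray
    t_A: float
    t_B: float
    energy_gap: float
    velocity_residual: float
    outer_iterations: int
    cg_iterations: int
    energy_A: float      # U_A(X_ts)
    energy_B: float      # U_B(X_ts)
    trace: list = field(default_factory=list)


def _velocity_matrix_solve(HA: HessianOperator, HB: HessianOperator,
                           X_A: np.ndarray, X_B: np.ndarray,
                           t_A: float, t_B: float, backend: str,
                           cg_tol: float):
    """Solve (M_A + M_B) X_ts = M_A X_A + M_B X_B by conjugate gradients."""
    dim = HA.dim

    def apply_M(H, t, v):
        return apply_matrix_function(H, lambda x: vel_scalar(x, t), v,
                                     backend=backend)

    count = {"n": 0}

    def matvec(v):
        count["n"] += 1
        return apply_M(HA, t_A, v) + apply_M(HB, t_B, v)

    rhs = apply_M(HA, t_A, X_A) + apply_M(HB, t_B, X_B)
    x0 = 0.5 * (X_A + X_B)
    op = LinearOperator((dim, dim), matvec=matvec)
    X_ts, info = cg(op, rhs, x0=x0, rtol=cg_tol, atol=0.0, maxiter=10 * dim)
    if info > 0:
        raise SolverError(f"conjugate gradients did not converge "
                          f"(info={info}) for the velocity-continuity system")
    # residual of the linear system = velocity gap between the two halves
    gap = matvec(X_ts) - rhs
    vA = apply_M(HA, t_A, X_ts - X_A)
    vB = apply_M(HB, t_B, X_ts - X_B)
    scale = max(np.linalg.norm(vA), np.linalg.norm(vB), 1e-30)
    return X_ts, float(np.linalg.norm(gap) / scale), count["n"]


def solve_transition(wellA: tuple[np.ndarray, HessianOperator],
                     wellB: tuple[np.ndarray, HessianOperator],
                     F: float = 1.0, dE: float = 0.0,
                     tol_E: float | None = None, tol_v: float = 1e-4,
                     backend: str | None = None,
                     max_outer: int = 60) -> TransitionResult:
    """Find the transition state and time split on the two-well surface.

    For each trial split t_A the velocity-continuity system fixes X_ts;
    an outer bisection on t_A drives the energy gap
    g(t_A) = U_B(X_ts) - U_A(X_ts) - dE to zero.  The bracket is
    [0.02 F, 0.98 F]; absence of a sign change means the wells never
    meet with this free-energy offset.
    """
    X_A, HA = wellA
    X_B, HB = wellB
    X_A = np.asarray(X_A, dtype=float).ravel()
    X_B = np.asarray(X_B, dtype=float).ravel()
    if F <= 0:
        raise ValueError(f"total path time must be positive, got {F}")
    bk = choose_backend(HA.dim, backend)
    cross = max(HA.quadratic_energy(X_B - X_A), HB.quadratic_energy(X_A - X_B))
    if tol_E is None:
        tol_E = 1e-4 * cross + 1e-12
    cg_tol = min(1e-10, tol_v * 1e-3)

    trace: list[tuple] = []
    cg_total = {"n": 0}

    def g(t_A: float):
        t_B = F - t_A
        X_ts, vres, ncg = _velocity_matrix_solve(HA, HB, X_A, X_B, t_A, t_B,
                                                 bk, cg_tol)
        cg_total["n"] += ncg
        uA = HA.quadratic_energy(X_ts - X_A)
        uB = HB.quadratic_energy(X_ts - X_B)
        gap = uB - uA - dE
        trace.append((t_A, gap, ncg, vres))
        logger.debug("t_A=%.6f  energy gap=%.3e  cg matvecs=%d  "
                     "velocity residual=%.2e", t_A, gap, ncg, vres)
        return gap, X_ts, vres, uA, uB

    # midpoint first: exact for symmetric wells (the linear system is then
    # solved by the arithmetic mean and the energy gap vanishes identically)
    lo, hi = 0.02 * F, 0.98 * F
    mid = 0.5 * F
    gap, X_ts, vres, uA, uB = g(mid)
    best = (mid, gap, X_ts, vres, uA, uB)
    n_outer = 1
    if abs(gap) > tol_E:
        g_mid = gap
        g_lo, *_ = g(lo)
        g_hi, *_ = g(hi)
        n_outer += 2
        if np.sign(g_lo) == np.sign(g_hi):
            raise NoCrossingError(
                f"energy-continuity residual does not change sign on the time "
                f"bracket: g({lo:.3g}) = {g_lo:.4g}, g({hi:.3g}) = {g_hi:.4g}; "
                "the requested free-energy offset admits no well crossing")
        if np.sign(g_mid) == np.sign(g_lo):
            lo, g_lo = mid, g_mid
        else:
            hi = mid
        for _ in range(max_outer):
            mid = 0.5 * (lo + hi)
            gap, X_ts, vres, uA, uB = g(mid)
            n_outer += 1
            best = (mid, gap, X_ts, vres, uA, uB)
            if abs(gap) <= tol_E:
                break
            if np.sign(gap) == np.sign(g_lo):
                lo, g_lo = mid, gap
            else:
                hi = mid
        else:
            logger.warning("transition search hit the outer-iteration cap "
                           "with |energy gap| = %.3e > tol %.3e",
                           abs(best[1]), tol_E)
    t_A, gap, X_ts, vres, uA, uB = best
    if vres > tol_v:
        logger.warning("velocity continuity residual %.3e exceeds tolerance "
                       "%.3e", vres, tol_v)
    return TransitionResult(X_ts=X_ts, t_A=t_A, t_B=F - t_A, energy_gap=gap,
                            velocity_residual=vres, outer_iterations=n_outer,
                            cg_iterations=cg_total["n"], energy_A=uA,
                            energy_B=uB, trace=trace)


# ---------------------------------------------------------------------------
# full path
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    times: np.ndarray           # (n_frames,)
    frames: np.ndarray          # (n_frames, 3N)
    t_A: float
    transition: TransitionResult | None
    energies: np.ndarray        # per-frame U = min(U_A + dE, U_B)


def generate_path(wellA, wellB, F: float = 1.0, dE: float = 0.0,
                  n_frames: int = 50, backend: str | None = None,
                  tol_E: float | None = None, tol_v: float = 1e-4) -> Trajectory:
    """Full minimum-action path: endpoints exact, transition frame included.

    Frames are uniformly spaced over [0, F]; for n_frames >= 3 the
    interior grid point nearest the transition time is replaced by t_A so
    the transition state itself is a frame.  Per-frame energies follow
    the two-well rule U = min(U_A + dE, U_B).
    """
    X_A, HA = wellA
    X_B, HB = wellB
    X_A = np.asarray(X_A, dtype=float).ravel()
    X_B = np.asarray(X_B, dtype=float).ravel()
    if n_frames < 2:
        raise ValueError(f"need at least 2 frames, got {n_frames}")
    bk = choose_backend(HA.dim, backend)
    times = np.linspace(0.0, F, n_frames)

    if np.allclose(X_A, X_B, atol=1e-12):
        frames = np.tile(X_A, (n_frames, 1))
        energies = np.minimum(np.zeros(n_frames) + dE, np.zeros(n_frames))
        return Trajectory(times, frames, F / 2, None, energies)

    tr = solve_transition((X_A, HA), (X_B, HB), F=F, dE=dE, tol_E=tol_E,
                          tol_v=tol_v, backend=bk)
    if n_frames >= 3:
        idx = int(np.clip(np.argmin(np.abs(times - tr.t_A)), 1, n_frames - 2))
        times = times.copy()
        times[idx] = tr.t_A
    hpA = HalfPathModel(X_A, HA, tr.X_ts, tr.t_A, backend=bk)
    hpB = HalfPathModel(X_B, HB, tr.X_ts, tr.t_B, backend=bk)
    frames = np.empty((n_frames, len(X_A)))
    energies = np.empty(n_frames)
    for i, t in enumerate(times):
        if t <= tr.t_A:
            frames[i] = hpA.frame(float(t))
        else:
            frames[i] = hpB.frame(float(F - t))
    frames[0] = X_A
    frames[-1] = X_B
    for i in range(n_frames):
        uA = HA.quadratic_energy(frames[i] - X_A)
        uB = HB.quadratic_energy(frames[i] - X_B)
        energies[i] = min(uA + dE, uB)
    return Trajectory(times, frames, tr.t_A, tr, energies)
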