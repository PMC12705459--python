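"""Minimum control energy on a stabilized connectome-derived linear system.

The dynamics are x' = A x + B u with A the structural matrix scaled by its
largest eigenvalue plus one and shifted by -I (so every mode decays), and
B = I for uniform control. The finite-horizon controllability Gramian is
built with the Van Loan block-matrix-exponential construction; the optimal
input for a transition x0 -> xT is u*(t) = B' exp(A'(T-t)) W^{-1} delta
with delta = xT - exp(A T) x0, and regional energy is the integral of
u_i(t)^2 over the horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigvalsh, expm
from scipy.stats import spearmanr

from brainte.states import BrainStateSet

DEFAULT_T = 1.501
DEFAULT_T_GRID = np.logspace(np.log10(0.001), np.log10(10.0), 50)


@dataclass(frozen=True)
class StabilizedSystem:
    """Continuous LTI system (A_norm, B, T) ready for Gramian computation."""

    A_norm: np.ndarray
    B: np.ndarray
    T: float = DEFAULT_T

    def __post_init__(self) -> None:
        a = np.asarray(self.A_norm, dtype=float)
        b = np.asarray(self.B, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("A_norm must be square")
        if b.shape != a.shape:
            raise ValueError("B must match A_norm in shape")
        if not self.T > 0:
            raise ValueError("T must be > 0")
        object.__setattr__(self, "A_norm", a)
        object.__setattr__(self, "B", b)

    @property
    def n(self) -> int:
        return self.A_norm.shape[0]


@dataclass(frozen=True)
class Gramian:
    W: np.ndarray
    T: float
    condition_number: float


@dataclass(frozen=True)
class TransitionSpec:
    x0: np.ndarray
    xT: np.ndarray

    def __post_init__(self) -> None:
        x0 = np.asarray(self.x0, dtype=float)
        xT = np.asarray(self.xT, dtype=float)
        if x0.shape != xT.shape or x0.ndim != 1:
            raise ValueError("x0 and xT must be equal-length vectors")
        if not (np.isfinite(x0).all() and np.isfinite(xT).all()):
            raise ValueError("states must be finite")
        object.__setattr__(self, "x0", x0)
        object.__setattr__(self, "xT", xT)


@dataclass(frozen=True)
class ControlTrajectory:
    time_grid: np.ndarray
    u: np.ndarray
    x: np.ndarray
    regional_energy: np.ndarray
    total_energy: float
    total_energy_closed_form: float
    endpoint_error: float


def stabilize_system(sc: np.ndarray, T: float = DEFAULT_T, atol: float = 1e-10) -> StabilizedSystem:
    """Build the stabilized uniform-control system from a connectome.

    A_norm = sc / (lambda_max(sc) + 1) - I, which puts every eigenvalue's
    real part strictly below zero for a symmetric nonnegative input.
    """
    sc = np.asarray(sc, dtype=float)
    if sc.ndim != 2 or sc.shape[0] != sc.shape[1]:
        raise ValueError("connectome must be square")
    if not np.allclose(sc, sc.T, atol=atol):
        raise ValueError("connectome must be symmetric")
    if np.any(sc < 0):
        raise ValueError("connectome must be nonnegative")
    if not np.allclose(np.diag(sc), 0.0, atol=atol):
        raise ValueError("connectome diagonal must be zero")
    lam_max = float(eigvalsh(sc)[-1]) if sc.size > 1 else float(sc[0, 0])
    a_norm = sc / (lam_max + 1.0) - np.eye(sc.shape[0])
    return StabilizedSystem(A_norm=a_norm, B=np.eye(sc.shape[0]), T=T)


def controllability_gramian(
    system: StabilizedSystem, cond_ceiling: float = 1e12
) -> Gramian:
    """Finite-horizon Gramian W = int_0^T exp(At) B B' exp(A't) dt.

    Computed with the Van Loan block exponential
    expm([[ -A, BB'], [0, A']] T) = [[*, G], [0, F]]  ->  W = F' G,
    which avoids stiff quadrature. Raises if W is numerically singular.
    """
    a = system.A_norm
    b = system.B
    n = system.n
    block = np.zeros((2 * n, 2 * n))
    block[:n, :n] = -a
    block[:n, n:] = b @ b.T
    block[n:, n:] = a.T
    e = expm(block * system.T)
    w = e[n:, n:].T @ e[:n, n:]
    w = 0.5 * (w + w.T)
    eigs = eigvalsh(w)
    if eigs[0] <= 0:
        raise np.linalg.LinAlgError(
            f"Gramian not positive definite (min eigenvalue {eigs[0]:.3e}); "
            "increase the horizon T or regularize"
        )
    cond = float(eigs[-1] / eigs[0])
    if cond > cond_ceiling:
        raise np.linalg.LinAlgError(
            f"Gramian condition number {cond:.3e} exceeds ceiling {cond_ceiling:.1e}; "
            "increase the horizon T or regularize"
        )
    return Gramian(W=w, T=system.T, condition_number=cond)


def _min_energy_batch(
    system: StabilizedSystem,
    gramian: Gramian,
    x0: np.ndarray,
    xT: np.ndarray,
    n_steps: int,
    cost: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized minimum-energy solve for m transitions (columns).

    Returns (time_grid, u, x, regional_energy, total_closed_form,
    endpoint_error) with u and x of shape (n_steps+1, n, m).
    """
    if cost not in ("squared", "absolute"):
        raise ValueError("cost must be 'squared' or 'absolute'")
    a, b, t_h = system.A_norm, system.B, system.T
    n, m = x0.shape
    dt = t_h / n_steps
    phi_dt = expm(a * dt)
    e_at = expm(a * t_h)
    delta = xT - e_at @ x0
    factor = cho_factor(gramian.W, lower=True)
    p = cho_solve(factor, delta)  # W^{-1} delta, one column per transition
    total_closed = np.einsum("im,im->m", delta, p)

    # backward recursion: w_i = exp(A'(T - t_i)) p
    u = np.empty((n_steps + 1, n, m))
    w = p.copy()
    u[n_steps] = b.T @ w
    for i in range(n_steps - 1, -1, -1):
        w = phi_dt.T @ w
        u[i] = b.T @ w

    # forward pass with exact homogeneous step + trapezoidal forcing
    x = np.empty_like(u)
    x[0] = x0
    bu = np.einsum("ij,tjm->tim", b, u)
    for i in range(n_steps):
        x[i + 1] = phi_dt @ (x[i] + 0.5 * dt * bu[i]) + 0.5 * dt * bu[i + 1]

    integrand = u**2 if cost == "squared" else np.abs(u)
    regional = np.trapezoid(integrand, dx=dt, axis=0)
    scale = np.maximum(np.linalg.norm(xT, axis=0), np.linalg.norm(delta, axis=0))
    scale = np.where(scale == 0, 1.0, scale)
    endpoint_error = np.linalg.norm(x[-1] - xT, axis=0) / scale
    time_grid = np.linspace(0.0, t_h, n_steps + 1)
    return time_grid, u, x, regional, total_closed, endpoint_error


def min_control_energy(
    system: StabilizedSystem,
    gramian: Gramian,
    spec: TransitionSpec,
    n_steps: int = 1000,
    endpoint_tol: float = 1e-4,
    cost: str = "squared",
) -> ControlTrajectory:
    """Minimum-energy transition x0 -> xT over the system's horizon.

    Regional energy i is the trapezoidal integral of u_i(t)^2 on
    ``n_steps`` intervals (or |u_i| with cost='absolute', for sensitivity
    checks); total energy is the regional sum and is cross-checked against
    the closed form delta' W^{-1} delta.
    """
    if abs(gramian.T - system.T) > 1e-12:
        raise ValueError("gramian horizon does not match system horizon")
    x0 = spec.x0[:, None]
    xT = spec.xT[:, None]
    time_grid, u, x, regional, total_closed, ep_err = _min_energy_batch(
        system, gramian, x0, xT, n_steps, cost
    )
    err = float(ep_err[0])
    if err > endpoint_tol:
        raise RuntimeError(
            f"endpoint error {err:.3e} exceeds tolerance {endpoint_tol:.1e} "
            f"(T={system.T}, n_steps={n_steps}); refine the grid or check conditioning"
        )
    regional_v = regional[:, 0]
    return ControlTrajectory(
        time_grid=time_grid,
        u=u[:, :, 0],
        x=x[:, :, 0],
        regional_energy=regional_v,
        total_energy=float(regional_v.sum()),
        total_energy_closed_form=float(total_closed[0]),
        endpoint_error=err,
    )


def pairwise_te(
    system: StabilizedSystem,
    gramian: Gramian,
    centroids: np.ndarray,
    n_steps: int = 1000,
    endpoint_tol: float = 1e-4,
    cost: str = "squared",
) -> np.ndarray:
    """Regional transition-energy tensor, shape (N, k, k).

    Entry [i, s, t] is region i's energy for the transition from centroid
    s to centroid t; diagonal entries are persistence energies (the state
    is not an equilibrium, so they are nonzero in general).
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids.ndim != 2 or centroids.shape[1] != system.n:
        raise ValueError("centroids must be k x N with N matching the system")
    k = centroids.shape[0]
    src, dst = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    x0 = centroids[src.ravel()].T  # (N, k^2)
    xT = centroids[dst.ravel()].T
    _, _, _, regional, _, ep_err = _min_energy_batch(system, gramian, x0, xT, n_steps, cost)
    worst = float(ep_err.max())
    if worst > endpoint_tol:
        raise RuntimeError(
            f"endpoint error {worst:.3e} exceeds tolerance {endpoint_tol:.1e} in pairwise TE"
        )
    return regional.reshape(system.n, k, k)


def transition_probabilities(label_sequences: list[np.ndarray], k: int) -> np.ndarray:
    """Row-normalized pooled counts of consecutive within-subject label pairs.

    Persistence (diagonal) pairs are included. A state never observed as a
    source gets a uniform row, with a warning.
    """
    counts = np.zeros((k, k))
    for labels in label_sequences:
        labels = np.asarray(labels)
        valid = (labels[:-1] >= 0) & (labels[1:] >= 0)
        np.add.at(counts, (labels[:-1][valid], labels[1:][valid]), 1.0)
    row_sums = counts.sum(axis=1)
    probs = np.empty_like(counts)
    for s in range(k):
        if row_sums[s] == 0:
            warnings.warn(f"state {s} never observed as a source; uniform fallback", RuntimeWarning)
            probs[s] = 1.0 / k
        else:
            probs[s] = counts[s] / row_sums[s]
    return probs


def global_pairwise_te_closed_form(
    system: StabilizedSystem, centroids: np.ndarray
) -> np.ndarray:
    """k x k total (summed over regions) TE via delta' W^{-1} delta."""
    gramian = controllability_gramian(system)
    centroids = np.asarray(centroids, dtype=float)
    k = centroids.shape[0]
    e_at = expm(system.A_norm * system.T)
    factor = cho_factor(gramian.W, lower=True)
    te = np.empty((k, k))
    for s in range(k):
        deltas = centroids.T - (e_at @ centroids[s])[:, None]  # (N, k) targets
        te[s] = np.einsum("im,im->m", deltas, cho_solve(factor, deltas))
    return te


def select_time_horizon(
    states: BrainStateSet,
    label_sequences: list[np.ndarray],
    system: StabilizedSystem,
    t_grid: np.ndarray | None = None,
) -> tuple[float, "np.ndarray", "np.ndarray"]:
    """Pick the horizon with the strongest inverse TE-vs-probability link.

    For each candidate T, group-centroid pairwise global TE (closed form)
    is rank-correlated against the empirical transition-probability matrix;
    the grid point with the most negative Spearman rho wins (ties to the
    lowest index). Returns (T*, t_grid, rho_per_T).
    """
    t_grid = DEFAULT_T_GRID if t_grid is None else np.asarray(t_grid, dtype=float)
    if t_grid.size == 0 or np.any(t_grid <= 0):
        raise ValueError("t_grid must be nonempty with strictly positive horizons")
    probs = transition_probabilities(label_sequences, states.k)
    rhos = np.empty(t_grid.size)
    for i, t_h in enumerate(t_grid):
        sys_t = StabilizedSystem(A_norm=system.A_norm, B=system.B, T=float(t_h))
        te = global_pairwise_te_closed_form(sys_t, states.group_centroids)
        rho, _ = spearmanr(te.ravel(), probs.ravel())
        rhos[i] = rho
    t_star = float(t_grid[int(np.argmin(rhos))])
    return t_star, t_grid, rhos
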