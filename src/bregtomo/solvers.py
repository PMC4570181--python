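"""Sparse reconstruction solvers for the linear model A S = Phi.

All solvers target the l1-regularized least-squares objective

    J_mu(S) = mu * ||S||_1 + 1/2 * ||A S - Phi||_2^2 ,

whose sparsity prior matches the physical expectation that the light
source occupies a small part of the domain.

``lbsr_solve`` is the linearized Bregman iteration with sparse
regularization: starting from v0 = S0 = 0,

    v_{k+1} = v_k + A^T (Phi - A S_k)
    S_{k+1} = delta * shrink(v_{k+1}, mu)      (elementwise)

where shrink is soft thresholding and delta the step size. Each sweep
costs two matrix products and a scalar shrinkage, which is what makes
the method fast. The iteration stops at the first k with
||S_{k+1} - S_k|| / ||S_k|| <= epsilon (the test is skipped while
||S_k|| = 0) or at ``max_iter``.

``l2cg_solve`` (Tikhonov by conjugate gradient) and ``l1sb_solve``
(Split Bregman) are the comparison baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import LinearOperator, cg


class DivergenceError(RuntimeError):
    """Raised when an iteration produces non-finite values."""


@dataclass
class SolverConfig:
    """Parameters shared by the Bregman-type solvers.

    mu : regularization weight of the l1 term (> 0).
    delta : step size; stable for delta <= 1 / sigma_max(A)^2.
    epsilon : relative-change stopping tolerance, default 1e-3.
    max_iter : iteration cap.
    nonneg : clip negative entries after shrinkage (off by default; the
        plain algorithm carries no sign constraint).
    """

    mu: float
    delta: float
    epsilon: float = 1e-3
    max_iter: int = 5000
    nonneg: bool = False
    kicking: bool = True

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if not (0 < self.epsilon < 1):
            raise ValueError("epsilon must be in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class ReconResult:
    """A reconstructed source vector with iteration diagnostics."""

    S: np.ndarray
    iterations: int
    residual_history: np.ndarray
    rel_change_history: np.ndarray
    converged: bool
    method: str
    v_final: np.ndarray | None = None
    config: dict = field(default_factory=dict)


def shrink(x, gamma: float):
    """Soft thresholding shrink(x, gamma) = sign(x) * max(|x| - gamma, 0).

    The proximal operator of gamma * ||.||_1, applied elementwise;
    shrink(0, gamma) = 0 (removable singularity of x/|x|).
    """
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - gamma, 0.0)


def objective_value(A: np.ndarray, phi: np.ndarray, S: np.ndarray,
                    mu: float) -> float:
    """J_mu(S) = mu * ||S||_1 + 1/2 * ||A S - Phi||_2^2."""
    r = A @ S - phi
    return float(mu * np.abs(S).sum() + 0.5 * r @ r)


def estimate_sigma_max(A: np.ndarray, n_iter: int = 60,
                       seed: int = 0) -> float:
    """Largest singular value of A by fixed-count power iteration."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(A.shape[1])
    x /= np.linalg.norm(x)
    s = 0.0
    for _ in range(n_iter):
        y = A.T @ (A @ x)
        s = np.linalg.norm(y)
        if s == 0:
            return 0.0
        x = y / s
    return float(np.sqrt(s))


def default_parameters(A: np.ndarray, phi: np.ndarray,
                       solver: str = "lbsr", kappa: float = 2.0,
                       epsilon: float = 1e-3,
                       max_iter: int = 5000) -> SolverConfig:
    """Defensible default (mu, delta) when neither is otherwise known.

    delta = 1 / sigma_max(A)^2 (the stability bound), with sigma_max by
    seeded power iteration.

    The threshold mu depends on which algorithm consumes it:

    * ``solver="l1sb"`` (and any solver minimizing J_mu directly):
      mu = 0.01 * ||A^T Phi||_inf — the classical lasso heuristic, 1%
      of the smallest weight that zeroes the solution.
    * ``solver="lbsr"``: the linearized Bregman limit solves
      min mu ||S||_1 + 1/(2 delta) ||S||_2^2 s.t. A S = Phi, so the l1
      term only matters when mu * delta reaches the solution amplitude
      (exact-regularization regime). mu is therefore set to
      kappa * ||S_ls||_inf / delta, with ||S_ls||_inf the amplitude of
      a truncated LSQR least-squares estimate and kappa = 2 a safety
      factor. A small-mu choice here would reduce the iteration to a
      thresholded Landweber method and forfeit sparsity.
    """
    A = np.asarray(A, dtype=float)
    phi = np.asarray(phi, dtype=float)
    smax = estimate_sigma_max(A)
    if smax == 0:
        raise ValueError("A is zero; no sensible default parameters exist")
    delta = 1.0 / smax ** 2
    if solver == "l1sb":
        mu = 0.01 * np.abs(A.T @ phi).max()
    elif solver == "lbsr":
        from scipy.sparse.linalg import lsqr
        amp = np.abs(lsqr(A, phi, iter_lim=100, atol=0, btol=0)[0]).max()
        mu = kappa * amp / delta
    else:
        raise ValueError(f"unknown solver {solver!r}")
    if mu == 0:
        warnings.warn("A^T Phi is zero (degenerate data); using a tiny "
                      "positive mu", stacklevel=2)
        mu = np.finfo(float).tiny
    return SolverConfig(mu=float(mu), delta=float(delta),
                        epsilon=epsilon, max_iter=max_iter)


def _check_finite(S: np.ndarray, k: int, delta: float):
    if not np.all(np.isfinite(S)):
        raise DivergenceError(
            f"non-finite iterate at iteration {k}; the step size "
            f"delta={delta:g} is likely too large — use "
            "delta <= 1/sigma_max(A)^2")


def lbsr_solve(A: np.ndarray, phi: np.ndarray,
               config: SolverConfig) -> ReconResult:
    """Linearized Bregman iteration with sparse (l1) regularization.

    With ``config.kicking`` (on by default) the iteration detects exact
    stagnation — sweeps in which no component of v crosses the
    threshold, so S does not move at all — and advances the inactive
    components of v by the number of identical sweeps needed for the
    next crossing in one jump. The visited iterates coincide with those
    of the plain iteration with the stagnant sweeps removed, so every
    reported iterate still satisfies S = delta * shrink(v, mu).
    """
    A = np.asarray(A, dtype=float)
    phi = np.asarray(phi, dtype=float)
    n = A.shape[1]
    v = np.zeros(n)
    S = np.zeros(n)
    res_hist, chg_hist = [], []
    converged = False
    k = 0
    for k in range(1, config.max_iter + 1):
        r = phi - A @ S
        g = A.T @ r
        v += g
        S_new = config.delta * shrink(v, config.mu)
        if config.nonneg:
            np.maximum(S_new, 0.0, out=S_new)
        if (config.kicking and np.array_equal(S_new, S)
                and np.any(g != 0)):
            inactive = np.abs(v) < config.mu
            with np.errstate(divide="ignore", invalid="ignore"):
                steps = np.where(inactive & (g != 0),
                                 (config.mu * np.sign(g) - v) / g, np.inf)
            pos = steps[np.isfinite(steps) & (steps > 0)]
            if pos.size:
                v[inactive] += int(np.ceil(pos.min())) * g[inactive]
                S_new = config.delta * shrink(v, config.mu)
                if config.nonneg:
                    np.maximum(S_new, 0.0, out=S_new)
        _check_finite(S_new, k, config.delta)
        res_hist.append(np.linalg.norm(A @ S_new - phi))
        norm_prev = np.linalg.norm(S)
        rel = (np.linalg.norm(S_new - S) / norm_prev
               if norm_prev > 0 else np.inf)
        chg_hist.append(rel)
        stationary = np.array_equal(S_new, S) and not np.any(g)
        S = S_new
        if (norm_prev > 0 and rel <= config.epsilon) or stationary:
            converged = True
            break
    return ReconResult(
        S=S, iterations=k, residual_history=np.array(res_hist),
        rel_change_history=np.array(chg_hist), converged=converged,
        method="lbsr", v_final=v,
        config={"mu": config.mu, "delta": config.delta,
                "epsilon": config.epsilon, "max_iter": config.max_iter,
                "nonneg": config.nonneg})


def l2cg_solve(A: np.ndarray, phi: np.ndarray, lam: float = 0.0,
               cg_tol: float = 1e-8, max_iter: int = 2000) -> ReconResult:
    """Tikhonov (l2) regularization solved by conjugate gradient.

    Solves the normal equations (A^T A + lam I) S = A^T Phi with
    scipy's CG on a matrix-free operator. lam may be 0 when A^T A is
    nonsingular.
    """
    A = np.asarray(A, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    n = A.shape[1]
    b = A.T @ phi

    def mv(x):
        return A.T @ (A @ x) + lam * x

    op = LinearOperator((n, n), matvec=mv, dtype=float)
    n_it = 0

    def count(_):
        nonlocal n_it
        n_it += 1

    S, info = cg(op, b, rtol=cg_tol, atol=0.0, maxiter=max_iter,
                 callback=count)
    if info > 0:
        warnings.warn(
            f"l2-CG did not reach tolerance {cg_tol:g} within {max_iter} "
            "iterations", stacklevel=2)
    res = np.linalg.norm(A @ S - phi)
    return ReconResult(
        S=S, iterations=n_it,
        residual_history=np.array([res]), rel_change_history=np.array([]),
        converged=(info == 0), method="l2cg",
        config={"lambda": lam, "cg_tol": cg_tol, "max_iter": max_iter})


def l1sb_solve(A: np.ndarray, phi: np.ndarray, config: SolverConfig,
               penalty: float | None = None, inner_tol: float = 1e-8,
               inner_max_iter: int = 200) -> ReconResult:
    """Split Bregman solver for the l1 objective J_mu.

    The l1 coupling is split with an auxiliary variable d ~ S and a
    Bregman variable b, alternating
      (i) quadratic solve (A^T A + penalty I) S = A^T Phi + penalty (d - b)
          by conjugate gradient,
      (ii) d = shrink(S + b, mu / penalty),
      (iii) b <- b + S - d,
    under the same relative-change stopping rule as the linearized
    Bregman solver. ``penalty`` defaults to sigma_max(A)^2 / 10.
    """
    A = np.asarray(A, dtype=float)
    phi = np.asarray(phi, dtype=float)
    n = A.shape[1]
    if penalty is None:
        penalty = estimate_sigma_max(A) ** 2 / 10.0
        if penalty == 0:
            raise ValueError("A is zero")
    S = np.zeros(n)
    d = np.zeros(n)
    b = np.zeros(n)
    Atphi = A.T @ phi

    def mv(x):
        return A.T @ (A @ x) + penalty * x

    op = LinearOperator((n, n), matvec=mv, dtype=float)
    res_hist, chg_hist = [], []
    converged = False
    k = 0
    for k in range(1, config.max_iter + 1):
        rhs = Atphi + penalty * (d - b)
        S_new, _ = cg(op, rhs, x0=S, rtol=inner_tol, atol=0.0,
                      maxiter=inner_max_iter)
        _check_finite(S_new, k, config.delta)
        d = shrink(S_new + b, config.mu / penalty)
        b = b + S_new - d
        res_hist.append(np.linalg.norm(A @ S_new - phi))
        norm_prev = np.linalg.norm(S)
        rel = (np.linalg.norm(S_new - S) / norm_prev
               if norm_prev > 0 else np.inf)
        chg_hist.append(rel)
        S = S_new
        if norm_prev > 0 and rel <= config.epsilon:
            converged = True
            break
    # the auxiliary variable carries the sparsity; report it
    out = d if np.any(d) else S
    return ReconResult(
        S=out, iterations=k, residual_history=np.array(res_hist),
        rel_change_history=np.array(chg_hist), converged=converged,
        method="l1sb", v_final=b,
        config={"mu": config.mu, "penalty": penalty,
                "epsilon": config.epsilon, "max_iter": config.max_iter})
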