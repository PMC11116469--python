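"""Maximum-entropy inversion of FCS correlation curves into diffusion-time
distributions.

The diffusional part of a correlation curve is modelled as a weighted sum
over a fixed grid of diffusion times t_d,i:

    G_d(t_c) = sum_i p_i * (1 + t_c/t_d,i)^-1 (1 + t_c/(s^2 t_d,i))^-1/2

with p on the probability simplex. The weight vector minimizes the
regularized functional

    Q(p) = chi2(p) - nu * S(p),       S(p) = -sum_i p_i ln(p_i / m_i)

where chi2 is the weighted least-squares misfit written in quadratic form
chi2(p) = chi2_0 + q.p + p.H.p, S is the Kullback-Leibler relative entropy
against a uniform prior m, and nu >= 0 the regularization strength. The
minimization is an iterated quadratic program: -S is replaced by its local
quadratic model about the current iterate and each subproblem (a convex QP
over the simplex) is solved by accelerated projected gradient descent.
The regularization parameter is chosen at the corner of the L-curve traced
by (S, chi2_red) over a nu schedule.

Large nu drives p toward the uniform prior (S -> 0); small nu yields sharp,
possibly spurious, peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import CorrelationCurve

__all__ = [
    "MEMResult",
    "LCurveCorner",
    "default_td_grid",
    "mem_basis",
    "chi2_quadratic_form",
    "entropy",
    "project_simplex",
    "solve_qp_simplex",
    "minimize_regularized",
    "mem_invert",
    "lcurve_corner",
]


def default_td_grid(n: int = 101, lo_ms: float = 1e-3, hi_ms: float = 1e2) -> np.ndarray:
    """Log-spaced diffusion-time grid; 101 points over [1e-3, 1e2] ms by
    default."""
    return np.logspace(np.log10(lo_ms), np.log10(hi_ms), n)


def mem_basis(lags_ms: np.ndarray, td_grid_ms: np.ndarray, aspect_ratio: float = 5.0) -> np.ndarray:
    """Matrix of diffusional basis functions, shape (n_lags, n_grid)."""
    t_c = np.asarray(lags_ms, dtype=float)[:, None]
    t_d = np.asarray(td_grid_ms, dtype=float)[None, :]
    return 1.0 / (1.0 + t_c / t_d) / np.sqrt(1.0 + t_c / (aspect_ratio**2 * t_d))


def chi2_quadratic_form(
    curve: CorrelationCurve,
    td_grid_ms: np.ndarray,
    offset: float,
    n_particles: float,
    aspect_ratio: float = 5.0,
    bunching_amplitude: float = 0.0,
    bunching_time_ms: float = 1e-3,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Assemble chi2(p) = chi2_0 + q.p + p.H.p from data and fixed
    amplitude/photophysics parameters."""
    basis = mem_basis(curve.lags, td_grid_ms, aspect_ratio)
    a = bunching_amplitude
    bunch = 1.0 - a + a * np.exp(-curve.lags / bunching_time_ms)
    design = basis * (bunch / n_particles)[:, None]
    y = curve.values - offset
    w = curve.weights()
    chi2_0 = float(np.sum(w * y**2))
    q = -2.0 * design.T @ (w * y)
    h = design.T @ (design * w[:, None])
    return chi2_0, q, h


def entropy(p: np.ndarray, m: np.ndarray) -> float:
    """Kullback-Leibler relative entropy S(p) = -sum p ln(p/m); S <= 0,
    equal to zero only at p = m."""
    p = np.asarray(p, dtype=float)
    mask = p > 0
    return float(-np.sum(p[mask] * np.log(p[mask] / m[mask])))


def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    idx = np.arange(1, v.size + 1)
    cond = u - css / idx > 0
    rho = idx[cond][-1]
    theta = css[rho - 1] / rho
    return np.maximum(v - theta, 0.0)


def _eqp_solve(a_mat: np.ndarray, c_vec: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve min 0.5 p.A.p + c.p s.t. sum p = 1 with only coordinates
    ``idx`` free; returns (free coordinates, equality multiplier)."""
    k = idx.size
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = a_mat[np.ix_(idx, idx)]
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.concatenate([-c_vec[idx], [1.0]])
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
    return sol[:k], float(sol[k])


def solve_qp_simplex(
    a_mat: np.ndarray, c_vec: np.ndarray, p0: np.ndarray, max_iter: int = 500, tol: float = 1e-11
) -> np.ndarray:
    """Minimize 0.5 p.A.p + c.p over the probability simplex by a primal
    active-set method with exact KKT solves; A symmetric positive
    (semi)definite."""
    n = c_vec.size
    p = project_simplex(p0.copy())
    free = p > tol
    if not free.any():
        free[int(np.argmin(c_vec))] = True
    p[~free] = 0.0
    p[free] += (1.0 - p.sum()) / free.sum()
    for _ in range(max_iter):
        idx = np.where(free)[0]
        p_star, lam = _eqp_solve(a_mat, c_vec, idx)
        if np.all(p_star >= -tol):
            p_new = np.zeros(n)
            p_new[idx] = np.maximum(p_star, 0.0)
            grad = a_mat @ p_new + c_vec
            mu = grad + lam  # KKT multipliers of the bounds
            bound = ~free
            scale = max(np.abs(grad).max(), 1.0)
            if not bound.any() or mu[bound].min() >= -1e-9 * scale:
                return p_new
            j = int(np.where(bound)[0][np.argmin(mu[bound])])
            p = p_new
            free[j] = True
        else:
            # step toward the EQP solution until a coordinate hits zero
            d = np.zeros(n)
            d[idx] = p_star - p[idx]
            neg = d < -tol
            alpha = min(1.0, np.min(-p[neg] / d[neg])) if neg.any() else 1.0
            p = np.maximum(p + alpha * d, 0.0)
            blocked = free & (p <= tol)
            p[blocked] = 0.0
            free &= p > 0
            if not free.any():
                free[int(np.argmin(c_vec))] = True
                p[:] = 0.0
                p[free] = 1.0
    return p


_P_FLOOR = 1e-12  # entropy gradient regularization at p_i = 0
_HESS_FLOOR = 1e-4  # curvature cap of the local entropy model (keeps
# zero-weight grid points mobile; the line search guards the true objective)


def minimize_regularized(
    q_vec: np.ndarray,
    h_mat: np.ndarray,
    nu: float,
    m_prior: np.ndarray,
    p0: np.ndarray | None = None,
    max_outer: int = 60,
    tol: float = 1e-8,
) -> np.ndarray:
    """Minimize Q(p) = q.p + p.H.p - nu*S(p) over the simplex by iterated
    quadratic programming: -S is expanded to second order about the current
    iterate and the convex QP subproblem is solved exactly enough by
    projected gradient, with backtracking on the true objective."""
    n = q_vec.size
    p = np.full(n, 1.0 / n) if p0 is None else p0.copy()

    def objective(pv: np.ndarray) -> float:
        return float(q_vec @ pv + pv @ h_mat @ pv - nu * entropy(pv, m_prior))

    f_cur = objective(p)
    for _ in range(max_outer):
        pf = np.maximum(p, _P_FLOOR)
        grad_negS = np.log(pf / m_prior) + 1.0  # gradient of -S
        hess_negS = 1.0 / np.maximum(p, _HESS_FLOOR)  # damped Hessian of -S
        a_mat = 2.0 * h_mat + nu * np.diag(hess_negS)
        c_vec = q_vec + nu * (grad_negS - hess_negS * p)
        p_qp = solve_qp_simplex(a_mat, c_vec, p)
        # backtracking toward the QP solution on the true objective
        alpha, accepted = 1.0, False
        for _ in range(30):
            cand = p + alpha * (p_qp - p)
            f_cand = objective(cand)
            if f_cand <= f_cur + 1e-15:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
        delta = np.max(np.abs(cand - p))
        p, f_cur = cand, f_cand
        if delta < tol:
            break
    return p


@dataclass
class LCurveCorner:
    index: int
    collinear: bool = False


def lcurve_corner(path: list[tuple[float, float, float]]) -> LCurveCorner:
    """Corner of the L-curve traced by (nu, S, chi2_red) samples.

    Points are sorted by nu internally; the corner is the interior point of
    maximum discrete (Menger) curvature of the (S, log chi2_red) polyline.
    An (numerically) collinear path returns the mid index with a flag.
    """
    if len(path) < 5:
        raise ValueError("need at least 5 path points")
    order = np.argsort([nu for nu, _, _ in path])
    s = np.array([path[i][1] for i in order])
    chi = np.log(np.maximum([path[i][2] for i in order], 1e-300))
    # scale both axes to unit range so curvature is shape-based
    s_n = (s - s.min()) / max(np.ptp(s), 1e-300)
    c_n = (chi - chi.min()) / max(np.ptp(chi), 1e-300)
    pts = np.column_stack([s_n, c_n])
    curv = np.zeros(len(path))
    for k in range(1, len(path) - 1):
        a, b, c = pts[k - 1], pts[k], pts[k + 1]
        area2 = abs((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))
        la, lb, lc = np.linalg.norm(b - a), np.linalg.norm(c - b), np.linalg.norm(c - a)
        denom = la * lb * lc
        curv[k] = 2.0 * area2 / denom if denom > 0 else 0.0
    if np.all(curv < 1e-9):
        warnings.warn("L-curve path is collinear; returning mid-path index")
        return LCurveCorner(index=int(order[len(path) // 2]), collinear=True)
    k_best = int(np.argmax(curv))
    return LCurveCorner(index=int(order[k_best]), collinear=False)


@dataclass
class MEMResult:
    """Result of a maximum-entropy diffusion-time inversion."""

    td_grid_ms: np.ndarray
    p: np.ndarray  # corner-selected probabilities, sum 1
    prior: np.ndarray
    nu: float  # selected regularization
    entropy: float
    chi2_red: float
    path: list[tuple[float, float, float]]  # (nu, S, chi2_red) per schedule point
    p_path: np.ndarray  # (n_nu, n_grid)
    corner_index: int
    collinear: bool = False

    def peaks(self) -> np.ndarray:
        """Grid indices of local maxima of p (strictly above both
        neighbours, above 1% of the max)."""
        p = self.p
        idx = [
            i
            for i in range(1, p.size - 1)
            if p[i] > p[i - 1] and p[i] > p[i + 1] and p[i] > 0.01 * p.max()
        ]
        return np.array(idx, dtype=int)


def mem_invert(
    curve: CorrelationCurve,
    offset: float,
    n_particles: float,
    td_grid_ms: np.ndarray | None = None,
    aspect_ratio: float = 5.0,
    bunching_amplitude: float = 0.0,
    bunching_time_ms: float = 1e-3,
    nu_schedule: np.ndarray | None = None,
) -> MEMResult:
    """Invert a correlation curve into a diffusion-time distribution.

    ``offset``, ``n_particles`` and the photophysics parameters are fixed
    (taken from a prior parametric fit); only the simplex weights p are
    free. The full nu path is solved (warm-started, ascending) and the
    returned ``p`` is the L-curve-corner solution.
    """
    if td_grid_ms is None:
        td_grid_ms = default_td_grid()
    if nu_schedule is None:
        nu_schedule = np.logspace(-2, 4, 30)
    nu_schedule = np.sort(np.asarray(nu_schedule, dtype=float))
    if curve.errors is None or np.all(curve.errors == 0):
        warnings.warn("curve has no error column; using unit weights")
    n = td_grid_ms.size
    m_prior = np.full(n, 1.0 / n)
    chi2_0, q_vec, h_mat = chi2_quadratic_form(
        curve, td_grid_ms, offset, n_particles, aspect_ratio, bunching_amplitude, bunching_time_ms
    )
    n_pts = len(curve)

    def q_of(pv: np.ndarray, nu: float) -> float:
        return float(q_vec @ pv + pv @ h_mat @ pv - nu * entropy(pv, m_prior))

    n_nu = nu_schedule.size
    p_path = np.empty((n_nu, n))
    # forward sweep, warm-started ascending in nu
    p_cur: np.ndarray | None = None
    for k, nu in enumerate(nu_schedule):
        p_cur = minimize_regularized(q_vec, h_mat, nu, m_prior, p0=p_cur)
        p_path[k] = p_cur
    # backward sweep: re-minimize warm-started from the larger-nu neighbour
    for k in range(n_nu - 2, -1, -1):
        cand = minimize_regularized(q_vec, h_mat, nu_schedule[k], m_prior, p0=p_path[k + 1])
        if q_of(cand, nu_schedule[k]) < q_of(p_path[k], nu_schedule[k]):
            p_path[k] = cand
    # neighbour-exchange polish: ensure each p_k beats its neighbours under
    # its own objective, which makes S and chi2 monotone along the path
    for _ in range(100):
        changed = False
        for k in range(n_nu):
            nu = nu_schedule[k]
            best_q, best_j = q_of(p_path[k], nu), k
            for j in (k - 1, k + 1):
                if 0 <= j < n_nu and q_of(p_path[j], nu) < best_q - 1e-15:
                    best_q, best_j = q_of(p_path[j], nu), j
            if best_j != k:
                refined = minimize_regularized(q_vec, h_mat, nu, m_prior, p0=p_path[best_j])
                p_path[k] = refined if q_of(refined, nu) <= best_q else p_path[best_j].copy()
                changed = True
        if not changed:
            break

    path: list[tuple[float, float, float]] = []
    for k, nu in enumerate(nu_schedule):
        s_val = entropy(p_path[k], m_prior)
        chi2 = chi2_0 + q_vec @ p_path[k] + p_path[k] @ h_mat @ p_path[k]
        path.append((float(nu), s_val, float(chi2) / n_pts))
    corner = lcurve_corner(path)
    k = corner.index
    return MEMResult(
        td_grid_ms=td_grid_ms,
        p=p_path[k].copy(),
        prior=m_prior,
        nu=path[k][0],
        entropy=path[k][1],
        chi2_red=path[k][2],
        path=path,
        p_path=p_path,
        corner_index=k,
        collinear=corner.collinear,
    )
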