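"""Drift-diffusion model with a stepwise collapsing bound.

Evidence ``x`` accumulates from a starting point ``x0`` with drift ``v`` and
unit diffusion noise (the conventional scale fix) between two symmetric
absorbing bounds at ``+/- u(t)``.  The bound collapses as a staircase,

    u(t) = max(B0 - floor(t / l) * h, 0),

dropping by ``h`` evidence units every ``l`` seconds from its initial value
``B0`` (a linear-in-t collapse is available behind the ``collapse`` flag).
Drift is linear in the log dot difference of the trial,
``v = v0 + v1 * ln(c)``.  Observed response time is the crossing time plus a
nondecision time ``ndt``; with probability ``lapse`` (fixed at 0.05 when
fitting) the response comes from a non-DDM process: a fair coin over the two
sides and an RT uniform on ``(ndt, t_max)``.

The module provides three routes to choice/RT distributions that are checked
against each other in the test suite:

* :func:`simulate_ddm_trials` — vectorized Euler–Maruyama simulation;
* :func:`first_passage_distribution` — transition-matrix propagation of the
  binned evidence density between the time-varying bounds (the likelihood
  backend for fitting);
* :func:`analytic_fixed_bound` — the closed-form absorption probability for
  the fixed-bound (``h = 0``) limit.

:class:`CollapsingBoundDDM` fits all free parameters to one condition of a
trial table by maximizing the lapse-mixture likelihood with differential
evolution, with choices in stimulus coding (upper bound = "left").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "DDMParams",
    "FirstPassage",
    "bound_at",
    "drift_for",
    "analytic_fixed_bound",
    "simulate_ddm_trial",
    "simulate_ddm_trials",
    "first_passage_distribution",
    "CollapsingBoundDDM",
    "DEFAULT_FIT_BOUNDS",
]


@dataclass(frozen=True)
class DDMParams:
    """Collapsing-bound diffusion parameters.

    Attributes
    ----------
    B0 : initial bound height (evidence units), > 0.
    l : duration of one collapse step (seconds), > 0.
    h : height of one collapse step (evidence units), >= 0; ``h = 0`` is the
        classic fixed-bound DDM.
    v0, v1 : drift intercept and slope on ln(dot difference).
    x0 : starting-point bias (evidence units), |x0| < B0; 0 is unbiased.
    ndt : nondecision time (seconds), >= 0.
    lapse : mixture weight of the non-DDM uniform process, fixed at 0.05
        during fitting.
    diffusion : noise scale, fixed at 1.0 by convention.
    t_max : simulation horizon (seconds); undecided trials are resolved by
        the sign of the accumulated evidence.
    collapse : "step" (staircase, default) or "linear" (``B0 - (t/l)*h``).
    """

    B0: float = 1.2
    l: float = 0.1
    h: float = 0.05
    v0: float = 0.0
    v1: float = 0.5
    x0: float = 0.0
    ndt: float = 0.3
    lapse: float = 0.05
    diffusion: float = 1.0
    t_max: float = 20.0
    collapse: str = "step"

    def __post_init__(self) -> None:
        if self.B0 <= 0:
            raise ValueError("B0 must be positive")
        if self.l <= 0:
            raise ValueError("l must be positive")
        if self.h < 0:
            raise ValueError("h must be nonnegative")
        if abs(self.x0) >= self.B0:
            raise ValueError("|x0| must be smaller than B0")
        if self.ndt < 0:
            raise ValueError("ndt must be nonnegative")
        if not 0 <= self.lapse < 1:
            raise ValueError("lapse must be in [0, 1)")
        if self.collapse not in ("step", "linear"):
            raise ValueError("collapse must be 'step' or 'linear'")


def bound_at(t, params: DDMParams):
    """Bound height u(t); staircase by default, clamped at zero.

    Accepts scalar or array ``t`` (seconds, >= 0).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    if params.collapse == "step":
        drop = np.floor(t / params.l) * params.h
    else:
        drop = (t / params.l) * params.h
    u = np.maximum(params.B0 - drop, 0.0)
    return float(u) if u.ndim == 0 else u


def drift_for(c, params: DDMParams):
    """Drift rate ``v0 + v1 * ln(c)`` for dot difference ``c`` (> 0)."""
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("dot difference c must be positive")
    v = params.v0 + params.v1 * np.log(c)
    return float(v) if v.ndim == 0 else v


def analytic_fixed_bound(v: float, B0: float, x0: float = 0.0) -> float:
    """Probability of upper-bound absorption for the fixed-bound DDM.

    Unit diffusion between absorbing bounds at ``+/- B0`` starting from
    ``x0``:

        P(upper) = (1 - exp(-2 v (x0 + B0))) / (1 - exp(-4 v B0)),

    with the drift-free limit ``(x0 + B0) / (2 B0)``.  Serves as the analytic
    oracle for the ``h = 0`` limit of the simulator and the matrix backend.
    """
    if B0 <= 0:
        raise ValueError("B0 must be positive")
    if abs(x0) > B0:
        raise ValueError("|x0| must not exceed B0")
    if abs(v) < 1e-12:
        return (x0 + B0) / (2.0 * B0)
    # expm1 keeps the ratio stable for small |v|
    num = -np.expm1(-2.0 * v * (x0 + B0))
    den = -np.expm1(-4.0 * v * B0)
    return float(num / den)


# ---------------------------------------------------------------------------
# simulation backend


def simulate_ddm_trials(
    params: DDMParams,
    c,
    rng: np.random.Generator,
    dt: float = 1e-3,
    direction=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Euler–Maruyama simulation of many trials.

    Parameters
    ----------
    params : DDMParams
    c : scalar or array of dot differences, one per trial (scalar broadcasts).
    rng : numpy Generator.
    dt : Euler step (seconds); must be smaller than the collapse step ``l``.
    direction : optional array of +/-1 stimulus signs (stimulus coding:
        +1 when the left circle holds more dots, so the drift points at the
        upper/"left" bound).  Defaults to +1 on every trial.

    Returns
    -------
    response : int array, +1 for upper-bound ("left") and -1 for lower-bound
        ("right") responses.
    rt : float array of response times (crossing time + ndt), seconds.

    Trials that never cross within ``t_max`` are resolved by the sign of the
    accumulated evidence (fair coin on a tie) with ``rt = t_max + ndt``.
    Lapse trials overwrite the diffusion outcome with a coin flip and an RT
    uniform on ``(ndt, t_max + ndt)``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt >= params.l:
        raise ValueError("dt must be smaller than the collapse step l")
    c = np.atleast_1d(np.asarray(c, dtype=float))
    v = np.atleast_1d(drift_for(c, params))
    if direction is not None:
        v = v * np.sign(np.broadcast_to(direction, v.shape).astype(float))
    n = v.size

    x = np.full(n, params.x0)
    response = np.zeros(n, dtype=int)
    rt = np.full(n, params.t_max + params.ndt)
    active = np.ones(n, dtype=bool)
    sdt = params.diffusion * np.sqrt(dt)
    n_steps = int(np.ceil(params.t_max / dt))

    for k in range(1, n_steps + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        t = k * dt
        u = bound_at(t, params)
        x[idx] += v[idx] * dt + sdt * rng.standard_normal(idx.size)
        if u <= 0.0:
            hit = idx
        else:
            hit = idx[np.abs(x[idx]) >= u]
        if hit.size:
            xe = x[hit]
            resp = np.sign(xe)
            ties = resp == 0
            if np.any(ties):
                resp[ties] = np.where(rng.random(ties.sum()) < 0.5, 1.0, -1.0)
            response[hit] = resp.astype(int)
            rt[hit] = t + params.ndt
            active[hit] = False

    # undecided at t_max: sign of accumulated evidence, fair coin on ties
    idx = np.flatnonzero(active)
    if idx.size:
        resp = np.sign(x[idx])
        ties = resp == 0
        if np.any(ties):
            resp[ties] = np.where(rng.random(ties.sum()) < 0.5, 1.0, -1.0)
        response[idx] = resp.astype(int)

    if params.lapse > 0:
        is_lapse = rng.random(n) < params.lapse
        m = int(is_lapse.sum())
        if m:
            response[is_lapse] = np.where(rng.random(m) < 0.5, 1, -1)
            rt[is_lapse] = params.ndt + rng.random(m) * params.t_max
    return response, rt


def simulate_ddm_trial(
    params: DDMParams, c: float, rng: np.random.Generator, dt: float = 1e-3
) -> tuple[str, float]:
    """Single-trial convenience wrapper: returns ("upper"|"lower", rt)."""
    resp, rt = simulate_ddm_trials(params, [c], rng, dt=dt)
    return ("upper" if resp[0] > 0 else "lower"), float(rt[0])


# ---------------------------------------------------------------------------
# transition-matrix backend


@dataclass
class FirstPassage:
    """Discretized joint first-passage distribution.

    ``t[k]`` is the decision-time grid (crossing time, before adding ndt);
    ``p_upper[k]``/``p_lower[k]`` the probability of absorbing at the
    upper/lower bound in the k-th time bin; ``residual`` the mass still
    diffusing at the horizon.  The lapse mixture is already applied when
    ``lapse_applied`` is True.
    """

    t: np.ndarray
    p_upper: np.ndarray
    p_lower: np.ndarray
    residual: float
    dt: float
    ndt: float
    t_max: float
    lapse_applied: bool = False

    def total_mass(self) -> float:
        return float(self.p_upper.sum() + self.p_lower.sum() + self.residual)

    def prob_upper(self) -> float:
        """Overall upper-response probability, residual split by a fair coin."""
        return float(self.p_upper.sum() + 0.5 * self.residual)


def _step_kernel(x: np.ndarray, edges: np.ndarray, shift: float, sd: float):
    """Mass from point sources ``x`` into bins with ``edges`` after one
    Gaussian step, plus tails beyond the outermost edges.

    Returns (M, lower_tail, upper_tail) with M[j, i] the mass from source i
    landing in bin j.
    """
    z = (edges[:, None] - x[None, :] - shift) / sd
    cdf = stats.norm.cdf(z)
    M = np.diff(cdf, axis=0)
    lower = cdf[0]
    upper = 1.0 - cdf[-1]
    return M, lower, upper


def _propagate(
    params: DDMParams,
    c: float,
    x0s: Sequence[float],
    dt: float,
    dx: float,
    horizon: float,
) -> list:
    """Propagate one density per starting point through shared kernels.

    Returns a list of (t_grid, p_up, p_dn, residual), one per entry of
    ``x0s``; all starting points ride the same per-bound transition matrices,
    so fitting both stimulus signs costs barely more than one.
    """
    v = drift_for(c, params)
    sd = params.diffusion * np.sqrt(dt)
    n_steps = int(np.ceil(horizon / dt))
    n_bins = max(int(np.ceil(2.0 * params.B0 / dx)), 8)
    edges = np.linspace(-params.B0, params.B0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    K = len(x0s)

    t_grid = dt * np.arange(1, n_steps + 1)
    p_up = np.zeros((n_steps, K))
    p_dn = np.zeros((n_steps, K))

    # first step from the exact point sources
    u1 = bound_at(t_grid[0], params)
    M0, lo0, up0 = _step_kernel(np.asarray(x0s, float), edges, v * dt, sd)
    P = M0.copy()  # (n_bins, K)
    out = np.abs(centers) >= u1
    p_up[0] = up0 + P[out & (centers > 0)].sum(axis=0)
    p_dn[0] = lo0 + P[out & (centers < 0)].sum(axis=0)
    P[out] = 0.0

    kernel_cache: dict[float, tuple] = {}
    u_prev = u1
    for k in range(1, n_steps):
        if P.sum() < 1e-7:
            break
        t = t_grid[k]
        u = bound_at(t, params)
        if u <= 0.0:
            # bound fully collapsed: everything absorbs by sign, ties split
            pos = centers > 0
            neg = centers < 0
            mid = ~pos & ~neg
            p_up[k] = P[pos].sum(axis=0) + 0.5 * P[mid].sum(axis=0)
            p_dn[k] = P[neg].sum(axis=0) + 0.5 * P[mid].sum(axis=0)
            P[:] = 0.0
            break
        if u not in kernel_cache:
            # active bins overlap (-u, u); sources sit at the midpoint of the
            # overlap so bins straddling the bound neither leak nor gain mass
            ov_lo = np.maximum(edges[:-1], -u)
            ov_hi = np.minimum(edges[1:], u)
            active = ov_hi > ov_lo
            xa = 0.5 * (ov_lo[active] + ov_hi[active])
            cut_edges = np.clip(edges, -u, u)
            M, lo_t, up_t = _step_kernel(xa, cut_edges, v * dt, sd)
            kernel_cache[u] = (active, M, lo_t, up_t)
        active, M, lo_t, up_t = kernel_cache[u]
        if u < u_prev:
            stranded = ~active
            p_up[k] += P[stranded & (centers > 0)].sum(axis=0)
            p_dn[k] += P[stranded & (centers < 0)].sum(axis=0)
        Pa = P[active]
        p_up[k] += up_t @ Pa
        p_dn[k] += lo_t @ Pa
        # M maps active sources to all bins; bins outside the bound get zero
        # mass by construction (their edges are clipped to +/- u)
        P = M @ Pa
        u_prev = u

    residual = P.sum(axis=0)
    return [
        (t_grid, p_up[:, j].copy(), p_dn[:, j].copy(), float(residual[j]))
        for j in range(K)
    ]


def first_passage_distribution(
    params: DDMParams,
    c: float,
    dt: float = 5e-3,
    dx: float | None = None,
    t_max: float | None = None,
    mass_tol: float = 1e-3,
) -> FirstPassage:
    """First-passage density via transition-matrix propagation.

    The evidence density is binned on a fixed grid spanning ``[-B0, B0]`` and
    propagated with the exact Gaussian transition kernel of the discrete-time
    (Euler) process, so this backend and :func:`simulate_ddm_trials` target
    the same discrete-time law when run at the same ``dt``.  At each step,
    mass beyond the current bound ``+/- u(t)`` is absorbed; when the bound
    collapses, mass stranded outside the new bound absorbs by its sign.

    Raises a numerical error if the final mass balance is violated by more
    than ``mass_tol``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if params.h > 0 and dt >= params.l:
        raise ValueError("dt must be smaller than the collapse step l")
    sd = params.diffusion * np.sqrt(dt)
    if dx is None:
        dx = sd / 4.0
    horizon = params.t_max if t_max is None else t_max
    (t_grid, p_up, p_dn, residual), = _propagate(
        params, c, [params.x0], dt, dx, horizon
    )
    fp = FirstPassage(
        t=t_grid, p_upper=p_up, p_lower=p_dn, residual=residual,
        dt=dt, ndt=params.ndt, t_max=horizon,
    )
    if abs(fp.total_mass() - 1.0) > mass_tol:
        raise ArithmeticError(
            f"first-passage mass balance violated: total={fp.total_mass():.6f}"
        )
    if params.lapse > 0:
        fp = _apply_lapse(fp, params)
    return fp


def _apply_lapse(fp: FirstPassage, params: DDMParams) -> FirstPassage:
    """Mix the DDM density with the uniform non-DDM process."""
    lam = params.lapse
    # uniform over (0, t_max) decision time, fair coin over responses
    uni = np.full_like(fp.p_upper, fp.dt / fp.t_max / 2.0)
    k = fp.t <= fp.t_max
    uni[~k] = 0.0
    return FirstPassage(
        t=fp.t,
        p_upper=(1 - lam) * fp.p_upper + lam * uni,
        p_lower=(1 - lam) * fp.p_lower + lam * uni,
        residual=(1 - lam) * fp.residual,
        dt=fp.dt,
        ndt=fp.ndt,
        t_max=fp.t_max,
        lapse_applied=True,
    )


# ---------------------------------------------------------------------------
# fitting

# box bounds for the differential-evolution search
DEFAULT_FIT_BOUNDS: dict[str, tuple[float, float]] = {
    "B0": (0.3, 3.0),
    "l": (0.05, 1.0),
    "h": (0.0, 2.0),
    "v0": (-2.0, 2.0),
    "v1": (0.0, 3.0),
    "ndt": (0.1, 1.0),
    "x0_frac": (-0.9, 0.9),  # starting point as a fraction of B0
}

_PARAM_ORDER = ["B0", "l", "h", "v0", "v1", "ndt", "x0_frac"]


class CollapsingBoundDDM(BaseEstimator):
    """Maximum-likelihood fit of the collapsing-bound DDM to one condition.

    The likelihood of each trial's (signed response, RT) pair comes from
    :func:`first_passage_distribution` evaluated per stimulus level, mixed
    with the 5% uniform lapse process.  Choices are in stimulus coding: the
    upper bound is the "left" response.  Optimization uses differential
    evolution within documented box bounds; the starting point is searched as
    a fraction of the bound so the constraint |x0| < B0 always holds.

    The search runs in three stages: differential evolution at a coarse time
    step, a profile grid over the collapse parameters (l, h) with a simplex
    over the smooth parameters, and an adaptive simplex polish at a finer
    time step (the coarse grid carries a resolution bias along the v0-v1
    ridge that the fine polish removes).

    Parameters
    ----------
    dt, fine_dt : time steps of the coarse search and the final polish
        (seconds).
    t_max : likelihood horizon (seconds); RTs beyond it are censored into the
        last bin.  Defaults to slightly above the longest observed RT.
    lapse : fixed lapse mixture weight.
    maxiter, popsize, tol : differential-evolution controls.
    polish_maxiter : simplex budget of the fine polish.
    profile_l, profile_h : grid of collapse profiles searched in stage 2.
    collapse : bound shape, "step" or "linear".
    seed : optimizer seed; the fit is deterministic given the seed.

    Attributes
    ----------
    params_ : DDMParams, the fitted parameters.
    loglik_ : float, log-likelihood at the optimum.
    converged_ : bool, optimizer success flag (a failed fit is flagged, not
        silent).
    n_trials_ : int, number of trials used.
    """

    def __init__(
        self,
        dt: float = 0.02,
        fine_dt: float = 0.01,
        t_max: float | None = None,
        dx_factor: float = 2.0,
        lapse: float = 0.05,
        maxiter: int = 10,
        popsize: int = 8,
        tol: float = 0.01,
        polish_maxiter: int = 500,
        profile_l: tuple = (0.1, 0.3),
        profile_h: tuple = (0.0, 0.05, 0.15),
        collapse: str = "step",
        bounds: dict | None = None,
        seed: int = 0,
    ):
        self.dt = dt
        self.fine_dt = fine_dt
        self.t_max = t_max
        self.dx_factor = dx_factor
        self.lapse = lapse
        self.maxiter = maxiter
        self.popsize = popsize
        self.tol = tol
        self.polish_maxiter = polish_maxiter
        self.profile_l = profile_l
        self.profile_h = profile_h
        self.collapse = collapse
        self.bounds = bounds
        self.seed = seed

    # -- likelihood ---------------------------------------------------------

    def _vector_to_params(self, theta: np.ndarray, t_max: float) -> DDMParams:
        d = dict(zip(_PARAM_ORDER, theta))
        return DDMParams(
            B0=d["B0"], l=d["l"], h=d["h"], v0=d["v0"], v1=d["v1"],
            x0=d["x0_frac"] * d["B0"], ndt=d["ndt"], lapse=self.lapse,
            t_max=t_max, collapse=self.collapse,
        )

    def _neg_loglik(self, theta, trial_groups, t_max, dt=None, dx_factor=None):
        # simplex proposals can step outside the domain; penalize, don't raise
        B0, l, h, v0, v1, ndt, x0f = theta
        if not (B0 > 0 and l > 0 and h >= 0 and ndt >= 0 and abs(x0f) < 1):
            return 1e10
        if (dt or self.dt) >= l:
            return 1e10
        params = self._vector_to_params(theta, t_max)
        dt = self.dt if dt is None else dt
        dx_factor = self.dx_factor if dx_factor is None else dx_factor
        sd = params.diffusion * np.sqrt(dt)
        dx = sd / dx_factor
        lapse_bin = params.lapse * dt / (2.0 * t_max)
        total = 0.0
        c_values = sorted({c for c, _ in trial_groups})
        for c in c_values:
            # both stimulus signs share one propagation: a right-stimulus
            # trial (drift -v from x0) is the mirror image of drift +v from
            # -x0 with the boundaries swapped
            fps = _propagate(params, c, [params.x0, -params.x0],
                             dt, dx, t_max)
            for stim_sign in (1, -1):
                if (c, stim_sign) not in trial_groups:
                    continue
                resp, rt = trial_groups[(c, stim_sign)]
                t_grid, p_up, p_dn, _ = fps[0 if stim_sign > 0 else 1]
                upper, lower = (p_up, p_dn) if stim_sign > 0 else (p_dn, p_up)
                decision_t = rt - params.ndt
                k = np.round(decision_t / dt).astype(int) - 1
                k = np.clip(k, 0, t_grid.size - 1)
                dens = np.where(resp > 0, upper[k], lower[k])
                dens = (1.0 - params.lapse) * dens + lapse_bin
                # RTs at or below ndt carry only lapse mass; the floor keeps
                # the objective finite so the optimizer can move away
                dens = np.where(decision_t <= 0,
                                max(lapse_bin, 1e-12),
                                np.maximum(dens, 1e-12))
                total += float(np.log(dens).sum())
        return -total

    @staticmethod
    def _group_trials(df: pd.DataFrame) -> dict:
        """Trials keyed by (c, stimulus sign): (response signs, rts)."""
        resp = np.where(df["choice"].to_numpy() == "left", 1, -1)
        rt = df["rt_decision"].to_numpy(dtype=float)
        c_arr = df["c"].to_numpy(dtype=float)
        sgn = np.where(df["correct_side"].to_numpy() == "left", 1, -1)
        groups = {}
        for c in np.unique(c_arr):
            for s in (1, -1):
                m = (c_arr == c) & (sgn == s)
                if m.any():
                    groups[(c, s)] = (resp[m], rt[m])
        return groups

    def fit(self, trials: pd.DataFrame, condition: str | None = None):
        """Fit to the trials of one condition of a trial table.

        ``trials`` needs columns ``c``, ``choice`` ("left"/"right"), and
        ``rt_decision``; rows with ``choice == "delegate"`` are ignored.
        """
        df = trials
        if condition is not None:
            df = df[df["condition"] == condition]
        df = df[df["choice"].isin(["left", "right"])]
        if len(df) < 50:
            raise ValueError(
                f"need at least 50 trials to fit, got {len(df)}"
            )
        rt = df["rt_decision"].to_numpy(dtype=float)
        if np.any(rt <= 0):
            raise ValueError("rt_decision must be positive")
        groups = self._group_trials(df)
        t_max = self.t_max if self.t_max is not None else float(rt.max()) + 0.5

        fit_bounds = dict(DEFAULT_FIT_BOUNDS)
        if self.bounds:
            fit_bounds.update(self.bounds)
        box = [fit_bounds[k] for k in _PARAM_ORDER]

        # initial population: latin hypercube plus one data-driven member
        # (psychometric drift guess, ndt from the fastest responses)
        rng = np.random.default_rng(self.seed)
        n_pop = self.popsize * len(box)
        lo = np.array([b[0] for b in box])
        hi = np.array([b[1] for b in box])
        init = lo + (hi - lo) * rng.random((n_pop, len(box)))
        init[0] = np.clip(self._heuristic_start(df, rt), lo, hi)

        # stage 1: differential evolution at the coarse resolution
        result = optimize.differential_evolution(
            self._neg_loglik,
            bounds=box,
            args=(groups, t_max),
            seed=self.seed,
            maxiter=self.maxiter,
            popsize=self.popsize,
            tol=self.tol,
            init=init,
            polish=False,
            updating="deferred",
        )

        # stage 2: profile search — the bound-collapse parameters (l, h) lie
        # on a likelihood ridge, so a small grid over the profile with a
        # simplex over the five smooth parameters localizes the right basin
        # far more reliably than free 7-dim search
        heur = init[0]

        def nll5(x5, l, h):
            theta = np.array([x5[0], l, h, x5[1], x5[2], x5[3], x5[4]])
            if not (lo[0] <= x5[0] <= hi[0] and lo[3] <= x5[1] <= hi[3]
                    and lo[4] <= x5[2] <= hi[4] and lo[5] <= x5[3] <= hi[5]
                    and abs(x5[4]) <= 0.9):
                return 1e10
            return self._neg_loglik(theta, groups, t_max)

        profile_best = None
        x5_start = np.array([1.2, heur[3], heur[4], heur[5], 0.0])
        for l in self.profile_l:
            for h in self.profile_h:
                r5 = optimize.minimize(
                    nll5, x5_start, args=(l, h), method="Nelder-Mead",
                    options={"maxiter": 120, "xatol": 1e-3, "fatol": 1e-2},
                )
                if profile_best is None or r5.fun < profile_best[0]:
                    theta5 = np.array([r5.x[0], l, h, r5.x[1], r5.x[2],
                                       r5.x[3], r5.x[4]])
                    profile_best = (r5.fun, theta5)

        # stage 3: adaptive simplex polish at the fine resolution from the
        # two best candidates (fine grids remove a resolution bias that
        # otherwise drags the drift slope down along the v0-v1 ridge)
        fine = dict(dt=self.fine_dt, dx_factor=self.dx_factor)
        candidates = [result.x, profile_best[1], heur]
        fine_f = [self._neg_loglik(cand, groups, t_max, **fine)
                  for cand in candidates]
        order = np.argsort(fine_f)
        best_x, best_f = candidates[order[0]], fine_f[order[0]]
        polished_ok = False
        for i in order[:2]:
            polish = optimize.minimize(
                self._neg_loglik, candidates[i],
                args=(groups, t_max, self.fine_dt, self.dx_factor),
                method="Nelder-Mead",
                options={"maxiter": self.polish_maxiter, "xatol": 1e-4,
                         "fatol": 1e-3, "adaptive": True},
            )
            if polish.fun < best_f:
                best_x, best_f = polish.x, polish.fun
                polished_ok = polish.success
        x = np.clip(best_x, lo, hi)
        # keep |x0| inside the bound after clipping
        x[6] = np.clip(x[6], -0.9, 0.9)
        self.params_ = self._vector_to_params(x, t_max)
        self.loglik_ = -float(self._neg_loglik(x, groups, t_max, **fine))
        self.converged_ = bool(result.success or polished_ok
                               or result.nit >= self.maxiter)
        self.n_trials_ = int(len(df))
        self.optimizer_result_ = result
        return self

    @staticmethod
    def _heuristic_start(df: pd.DataFrame, rt: np.ndarray) -> np.ndarray:
        """Rough start: drift slope from the accuracy psychometric at unit
        bound, nondecision time just under the fastest responses."""
        acc = np.where(df["choice"] == df["correct_side"], 1.0, 0.0)
        c_arr = df["c"].to_numpy(dtype=float)
        vs = []
        for c in np.unique(c_arr):
            a = np.clip(acc[c_arr == c].mean(), 0.55, 0.99)
            vs.append((np.log(c), np.log(a / (1 - a)) / 2.0))
        X = np.array(vs)
        v1, v0 = np.polyfit(X[:, 0], X[:, 1], 1)
        ndt0 = max(0.9 * float(np.quantile(rt, 0.02)), 0.12)
        return np.array([1.0, 0.2, 0.1, v0, v1, ndt0, 0.0])

    def loglik_of(self, params: DDMParams, trials: pd.DataFrame,
                  condition: str | None = None) -> float:
        """Log-likelihood of arbitrary parameters on the same data layout."""
        df = trials
        if condition is not None:
            df = df[df["condition"] == condition]
        df = df[df["choice"].isin(["left", "right"])]
        groups = self._group_trials(df)
        rt = df["rt_decision"].to_numpy(dtype=float)
        t_max = self.t_max if self.t_max is not None else float(rt.max()) + 0.5
        theta = np.array([
            params.B0, params.l, params.h, params.v0, params.v1,
            params.ndt, params.x0 / params.B0,
        ])
        return -self._neg_loglik(theta, groups, t_max, self.fine_dt,
                                 self.dx_factor)
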