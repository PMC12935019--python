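"""Five-parameter metacognitive process model of choice and confidence.

A trial with dot difference ``c`` and correct side ``s`` (+1 = left) carries
signed sensory strength ``mu = s * ln(c)``.  The observer draws a decision
value

    y ~ Normal(mu + bias_sens, sigma_sens)

and chooses the side of ``y``.  Confidence results from a noisy, potentially
biased transformation of the absolute decision value: the metacognitive
evidence is

    z = max(m_mult * |y| + m_add, 0),

where ``m_mult`` (neutral 1) rescales evidence — values below 1 produce
underconfidence — and ``m_add`` (neutral 0) shifts it.  The evidence is
mapped to a probability-correct scale through the ideal-observer link for a
known stimulus magnitude,

    conf = 1 / (1 + exp(-2 * |mu| * z / sigma_sens**2)),

which lies in [0.5, 1] and, at neutral parameters, makes mean confidence
equal objective accuracy at every difficulty level (the calibration
identity).  Report noise ``Normal(0, sigma_meta)`` is added on the continuous
confidence scale — the dominant noise source is placed at the reporting
stage — then the value is censored to [0.5, 1] and rounded to the nearest of
the six report bins {50, 60, ..., 100}.

:class:`MetacogModel` fits all five parameters by maximum likelihood; the
choice likelihood is the psychometric function implied by
``(sigma_sens, bias_sens)`` and the confidence likelihood marginalizes the
binned report distribution over the truncated decision-value density.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "MetacogParams",
    "CONFIDENCE_BINS",
    "simulate_confidence_trial",
    "simulate_confidence_trials",
    "simulate_unbiased_counterpart",
    "MetacogModel",
]

#: report bins on the probability scale and their censoring edges
CONFIDENCE_BINS = np.array([0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
_BIN_EDGES = np.array([-np.inf, 0.55, 0.65, 0.75, 0.85, 0.95, np.inf])


@dataclass(frozen=True)
class MetacogParams:
    """Parameters of the metacognitive process model.

    sigma_sens : sensory noise (> 0); sets the psychometric slope.
    bias_sens : signed sensory bias toward one side.
    sigma_meta : report noise on the confidence scale (>= 0).
    m_mult : multiplicative evidence bias; neutral 1, < 1 underconfident.
    m_add : additive evidence bias; neutral 0, < 0 underconfident.
    """

    sigma_sens: float = 2.0
    bias_sens: float = 0.0
    sigma_meta: float = 0.1
    m_mult: float = 1.0
    m_add: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_sens <= 0:
            raise ValueError("sigma_sens must be positive")
        if self.sigma_meta < 0:
            raise ValueError("sigma_meta must be nonnegative")
        if self.m_mult <= 0:
            raise ValueError("m_mult must be positive")

    @property
    def is_neutral(self) -> bool:
        return self.m_mult == 1.0 and self.m_add == 0.0


def _link(z: np.ndarray, mu_abs: np.ndarray, sigma: float) -> np.ndarray:
    """Ideal-observer confidence for metacognitive evidence z at |mu|."""
    return 1.0 / (1.0 + np.exp(-2.0 * mu_abs * z / sigma**2))


def _bin_report(conf: np.ndarray) -> np.ndarray:
    """Censor to [0.5, 1] and round to the nearest report bin (as 50..100)."""
    conf = np.clip(conf, 0.5, 1.0)
    idx = np.argmin(np.abs(conf[:, None] - CONFIDENCE_BINS[None, :]), axis=1)
    return (CONFIDENCE_BINS[idx] * 100).astype(int)


def simulate_confidence_trials(
    params: MetacogParams,
    c,
    correct_side,
    rng: np.random.Generator,
    y: np.ndarray | None = None,
    report_noise: np.ndarray | None = None,
):
    """Vectorized simulation of choices and confidence reports.

    Parameters
    ----------
    c : array of dot differences (> 0), one per trial.
    correct_side : array of "left"/"right" (or +1/-1) per trial.
    rng : numpy Generator driving all draws.
    y, report_noise : optional pre-drawn decision values and report-noise
        deviates, used to pair biased and unbiased simulations on identical
        latent samples.

    Returns
    -------
    DataFrame with columns ``choice`` ("left"/"right"), ``accuracy``,
    ``confidence`` (report bin, 50..100), ``conf_continuous`` (pre-noise
    confidence), and ``decision_value`` (the latent y).
    """
    c = np.atleast_1d(np.asarray(c, dtype=float))
    if np.any(c <= 0):
        raise ValueError("dot difference c must be positive")
    side = np.atleast_1d(np.asarray(correct_side))
    if side.dtype.kind in "UO":
        s = np.where(side == "left", 1.0, -1.0)
    else:
        s = np.sign(side.astype(float))
    mu = s * np.log(c)
    if y is None:
        y = mu + params.bias_sens + params.sigma_sens * rng.standard_normal(c.size)
    if report_noise is None:
        report_noise = rng.standard_normal(c.size)

    choice_sign = np.where(y >= 0, 1.0, -1.0)
    z = np.maximum(params.m_mult * np.abs(y) + params.m_add, 0.0)
    conf_cont = _link(z, np.abs(mu), params.sigma_sens)
    report = conf_cont + params.sigma_meta * report_noise
    return pd.DataFrame(
        {
            "choice": np.where(choice_sign > 0, "left", "right"),
            "accuracy": (choice_sign == s).astype(int),
            "confidence": _bin_report(report),
            "conf_continuous": conf_cont,
            "decision_value": y,
        }
    )


def simulate_confidence_trial(
    params: MetacogParams, c: float, correct_side: str, rng: np.random.Generator
) -> tuple[str, int, float]:
    """Single trial: returns (choice, confidence bin, latent decision value)."""
    df = simulate_confidence_trials(params, [c], [correct_side], rng)
    return df["choice"][0], int(df["confidence"][0]), float(df["decision_value"][0])


def simulate_unbiased_counterpart(
    params: MetacogParams,
    c,
    correct_side,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired biased and bias-free simulations on shared latent samples.

    Returns ``(biased, unbiased)`` trial frames generated from identical
    sensory samples and report-noise deviates; the unbiased run forces
    ``(m_mult, m_add) = (1, 0)``.  Because the evidence biases act after the
    choice stage, accuracy is identical between the two frames; only the
    confidence columns differ.  Used for the biased-vs-unbiased simulation
    contrast that quantifies the degree of metacognitive under- or
    overconfidence.
    """
    c = np.atleast_1d(np.asarray(c, dtype=float))
    rng = np.random.default_rng(seed)
    side = np.atleast_1d(np.asarray(correct_side))
    s = np.where(side == "left", 1.0, -1.0) if side.dtype.kind in "UO" else np.sign(side.astype(float))
    mu = s * np.log(c)
    y = mu + params.bias_sens + params.sigma_sens * rng.standard_normal(c.size)
    noise = rng.standard_normal(c.size)
    neutral = replace(params, m_mult=1.0, m_add=0.0)
    biased = simulate_confidence_trials(params, c, correct_side, rng, y=y, report_noise=noise)
    unbiased = simulate_confidence_trials(neutral, c, correct_side, rng, y=y, report_noise=noise)
    return biased, unbiased


# ---------------------------------------------------------------------------
# fitting


def _report_bin_probs(pc: np.ndarray, sigma_meta: float) -> np.ndarray:
    """P(report bin | continuous confidence pc); censored normal, shape
    (len(pc), 6)."""
    if sigma_meta < 1e-6:
        idx = np.argmin(np.abs(pc[:, None] - CONFIDENCE_BINS[None, :]), axis=1)
        out = np.zeros((pc.size, 6))
        out[np.arange(pc.size), idx] = 1.0
        return out
    z = (_BIN_EDGES[None, :] - pc[:, None]) / sigma_meta
    cdf = stats.norm.cdf(z)
    return np.diff(cdf, axis=1)


class MetacogModel(BaseEstimator):
    """Maximum-likelihood fit of the five-parameter metacognitive model.

    The likelihood factorizes per trial into a choice term — the
    psychometric function ``P(left | c, side) = Phi((mu + bias)/sigma)`` —
    and a confidence term that integrates the binned report distribution
    over the decision-value density truncated to the chosen side.

    Parameters
    ----------
    n_quad : number of integration nodes over the decision value.
    n_starts : random multi-starts for the bounded quasi-Newton optimizer.
    seed : seed for the optimizer starts (the fit is deterministic given it).

    Attributes
    ----------
    params_ : MetacogParams at the optimum.
    loglik_ : float.
    se_ : dict of approximate standard errors (inverse observed information).
    conf_int_ : dict of 95% Wald intervals per parameter.
    degenerate_ : True when the confidence column is constant (the report
        noise is then pinned at its bound and flagged, not silently trusted).
    """

    _BOUNDS = [(0.2, 10.0), (-3.0, 3.0), (1e-3, 1.0), (0.05, 5.0), (-2.0, 2.0)]
    _NAMES = ["sigma_sens", "bias_sens", "sigma_meta", "m_mult", "m_add"]

    def __init__(self, n_quad: int = 61, n_starts: int = 4, seed: int = 0):
        self.n_quad = n_quad
        self.n_starts = n_starts
        self.seed = seed

    # -- likelihood ---------------------------------------------------------

    def _quad_nodes(self):
        cached = getattr(self, "_quad_cache", None)
        if cached is None or cached[0].size != self.n_quad:
            cached = np.polynomial.legendre.leggauss(self.n_quad)
            self._quad_cache = cached
        return cached

    def _neg_loglik(self, theta: np.ndarray, cells: list) -> float:
        sigma, bias, sig_m, mm, ma = theta
        total = 0.0
        for mu_signed, d, counts in cells:
            # choice stage
            p_left = stats.norm.cdf((mu_signed + bias) / sigma)
            p_choice = p_left if d > 0 else 1.0 - p_left
            p_choice = max(p_choice, 1e-12)
            # decision-value density truncated to the chosen side
            m0 = mu_signed + bias
            if d > 0:
                a, b = 0.0, max(m0 + 6 * sigma, 6 * sigma)
            else:
                a, b = min(m0 - 6 * sigma, -6 * sigma), 0.0
            nodes, w = self._quad_nodes()
            yg = 0.5 * (b - a) * nodes + 0.5 * (b + a)
            wg = 0.5 * (b - a) * w * stats.norm.pdf(yg, loc=m0, scale=sigma)
            wg_sum = wg.sum()
            if wg_sum < 1e-14:
                total += counts.sum() * np.log(1e-12)
                continue
            wg /= wg_sum
            z = np.maximum(mm * np.abs(yg) + ma, 0.0)
            pc = _link(z, abs(mu_signed), sigma)
            bin_probs = wg @ _report_bin_probs(pc, sig_m)  # (6,)
            bin_probs = np.maximum(bin_probs, 1e-12)
            total += counts @ np.log(bin_probs) + counts.sum() * np.log(p_choice)
        return -total

    @staticmethod
    def _cells_from(df: pd.DataFrame) -> list:
        """Aggregate trials into (signed mu, choice sign, confidence-bin
        counts) cells; one cell per (c, correct_side, choice)."""
        cells = []
        conf = df["confidence"].to_numpy()
        bins = (CONFIDENCE_BINS * 100).astype(int)
        for (c, side, choice), g in df.groupby(["c", "correct_side", "choice"]):
            s = 1.0 if side == "left" else -1.0
            d = 1.0 if choice == "left" else -1.0
            counts = np.array([(g["confidence"] == b).sum() for b in bins], float)
            cells.append((s * np.log(float(c)), d, counts))
        return cells

    def fit(self, trials: pd.DataFrame, condition: str | None = None):
        df = trials
        if condition is not None:
            df = df[df["condition"] == condition]
        df = df[df["choice"].isin(["left", "right"])]
        if df["confidence"].isna().any():
            raise ValueError("confidence column contains missing values")
        self.degenerate_ = df["confidence"].nunique() <= 1
        cells = self._cells_from(df)

        rng = np.random.default_rng(self.seed)
        x0s = [np.array([2.0, 0.0, 0.1, 1.0, 0.0])]
        lo = np.array([b[0] for b in self._BOUNDS])
        hi = np.array([b[1] for b in self._BOUNDS])
        for _ in range(self.n_starts - 1):
            x0s.append(lo + (hi - lo) * rng.random(5))
        best = None
        for x0 in x0s:
            res = optimize.minimize(
                self._neg_loglik, x0, args=(cells,),
                method="L-BFGS-B", bounds=self._BOUNDS,
            )
            if best is None or res.fun < best.fun:
                best = res
        theta = best.x
        self.params_ = MetacogParams(*theta)
        self.loglik_ = -float(best.fun)
        self.converged_ = bool(best.success)
        self.n_trials_ = int(len(df))
        self._fisher_intervals(theta, cells)
        return self

    def _fisher_intervals(self, theta: np.ndarray, cells: list) -> None:
        """Wald 95% intervals from the numerically observed information."""
        n = theta.size
        eps = np.maximum(1e-4, 1e-4 * np.abs(theta))
        H = np.zeros((n, n))
        f0 = self._neg_loglik(theta, cells)
        for i in range(n):
            for j in range(i, n):
                ei = np.zeros(n); ei[i] = eps[i]
                ej = np.zeros(n); ej[j] = eps[j]
                fpp = self._neg_loglik(theta + ei + ej, cells)
                fpm = self._neg_loglik(theta + ei - ej, cells)
                fmp = self._neg_loglik(theta - ei + ej, cells)
                fmm = self._neg_loglik(theta - ei - ej, cells)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps[i] * eps[j])
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(n, np.nan)
        self.se_ = dict(zip(self._NAMES, se))
        self.conf_int_ = {
            name: (theta[i] - 1.96 * se[i], theta[i] + 1.96 * se[i])
            for i, name in enumerate(self._NAMES)
        }
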