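"""Normative confidence-based model of the decision to delegate.

On each trial the agent weighs the value of delegating, Qd — the expert's
probability of being correct, approximated by the agent's confidence in the
others — against the value of leading, Ql — their own probability of being
correct, approximated by confidence in self (the reward is fixed at r = 1).
A subjective delegation preference phi_d offsets the comparison:

    Delta = Qd - Ql + phi_d,        delegate  iff  Delta > 0

(the tie Delta = 0 resolves to leading).  phi_d = 0 is reward-maximizing
under calibrated confidence; three preference variants are fit and compared:

* ``constant``:   phi_d = alpha_phi, independent of confidence;
* ``conf_self``:  phi_d = -beta_phi_mag * c_ind (the stated negative-sign
  coefficient is carried as a nonnegative magnitude, reconciling the
  direction constraint with its Uniform(0, 10) prior);
* ``combined``:   phi_d = alpha_phi - beta_phi_mag * c_ind.

A confidence-in-others coefficient (gamma_phi) exists conceptually but with
only two expert levels no model is built on it; instead alpha_phi posteriors
are compared across expert levels.

Fitting operates on per-level aggregates — the mean confidence rating and
the delegation proportion at each stimulus strength within a condition —
and converts mean Delta into a delegation proportion through a logistic with
a free positive slope (``link_scale``).  The hierarchy places subject-level
parameters around population means (Uniform(-10, 10) for alpha_phi,
Uniform(0, 10) for beta_phi_mag, half-normal scales); sampling is by an
affine-invariant ensemble MCMC, with split-R-hat flagging and a posterior
deviance trace for DIC model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

import emcee

__all__ = [
    "DelegationParams",
    "delegation_preference",
    "delegation_drive",
    "delegation_probability",
    "build_level_aggregates",
    "DelegationModel",
    "dic",
    "expected_final_accuracy",
    "loo_accuracy_prediction",
]

_VARIANTS = ("constant", "conf_self", "combined")


@dataclass(frozen=True)
class DelegationParams:
    """Delegation-preference coefficients and the aggregate choice link.

    ``alpha_phi`` — constant preference (signed; negative = lead bias);
    ``beta_phi_mag`` — magnitude (>= 0) of the confidence-in-self term,
    applied with a fixed negative sign; ``gamma_phi`` — conceptual
    confidence-in-others coefficient (>= 0), unused by the fitted variants;
    ``link_scale`` — logistic slope converting mean Delta into a delegation
    proportion (> 0; may be ``inf`` for the hard step).
    """

    variant: str = "combined"
    alpha_phi: float = 0.0
    beta_phi_mag: float = 0.0
    gamma_phi: float = 0.0
    link_scale: float = 10.0

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")
        if self.beta_phi_mag < 0:
            raise ValueError("beta_phi_mag is a magnitude and must be >= 0")
        if self.gamma_phi < 0:
            raise ValueError("gamma_phi must be >= 0")
        if not self.link_scale > 0:
            raise ValueError("link_scale must be positive")


def _check_conf(x, name: str):
    x = np.asarray(x, dtype=float)
    if np.any((x < 0.5) | (x > 1.0)):
        raise ValueError(f"{name} must lie in [0.5, 1]")
    return x


def delegation_preference(params: DelegationParams, c_ind, c_others):
    """phi_d for confidence-in-self ``c_ind`` and confidence-in-others
    ``c_others`` (both on [0.5, 1]); vectorized."""
    c_ind = _check_conf(c_ind, "c_ind")
    _check_conf(c_others, "c_others")
    if params.variant == "constant":
        phi = np.broadcast_to(params.alpha_phi, c_ind.shape).astype(float)
    elif params.variant == "conf_self":
        phi = -params.beta_phi_mag * c_ind
    else:
        phi = params.alpha_phi - params.beta_phi_mag * c_ind
    return float(phi) if phi.ndim == 0 else phi


def delegation_drive(c_ind: float, c_others: float, phi_d: float):
    """Value difference and hard-step action: Delta = Qd - Ql + phi_d with
    Qd = c_others, Ql = c_ind (r = 1); delegate iff Delta > 0, tie leads."""
    c_ind = float(_check_conf(c_ind, "c_ind"))
    c_others = float(_check_conf(c_others, "c_others"))
    delta = c_others - c_ind + phi_d
    return delta, ("delegate" if delta > 0 else "lead")


def delegation_probability(
    mean_confidence_self, params: DelegationParams, expert_level,
):
    """Aggregate delegation probability logistic(link_scale * mean Delta).

    Strictly decreasing in own mean confidence and increasing in expert
    level for any admissible parameters; ``link_scale -> inf`` recovers the
    hard step.
    """
    conf = _check_conf(mean_confidence_self, "mean_confidence_self")
    phi = delegation_preference(params, conf, expert_level)
    delta = np.asarray(expert_level, dtype=float) - conf + phi
    if not np.isfinite(params.link_scale):
        p = (delta > 0).astype(float)
    else:
        p = expit(params.link_scale * delta)
    return float(p) if np.ndim(p) == 0 else p


def build_level_aggregates(
    forced_choice: pd.DataFrame, delegation: pd.DataFrame
) -> pd.DataFrame:
    """Per-(subject, condition, expert level, c) aggregates for model fitting.

    Mean confidence comes from the forced-choice task (divided by 100 onto
    [0.5, 1]); the delegation proportion and trial count come from the
    delegation task at the matching (subject, condition, c) cell.
    """
    conf = (
        forced_choice[forced_choice["choice"].isin(["left", "right"])]
        .groupby(["subject_id", "condition", "c"])["confidence"]
        .mean()
        .div(100.0)
        .rename("mean_confidence_self")
        .reset_index()
    )
    dele = (
        delegation.assign(delegated=lambda d: (d["choice"] == "delegate"))
        .groupby(["subject_id", "condition", "expert_level", "c"])
        .agg(delegation_proportion=("delegated", "mean"),
             n_trials=("delegated", "size"))
        .reset_index()
    )
    out = dele.merge(conf, on=["subject_id", "condition", "c"], how="left")
    if out["mean_confidence_self"].isna().any():
        raise ValueError("missing forced-choice confidence for some cells")
    return out


# ---------------------------------------------------------------------------
# hierarchical fit


class DelegationModel(BaseEstimator):
    """Hierarchical Bayesian fit of one delegation-preference variant.

    Fits a single (condition, expert level) stratum of level aggregates: the
    delegated counts at each stimulus strength are binomial with probability
    ``logistic(link_scale * (expert - conf + phi_d))``, subject-level
    preference parameters are normal around population means, and the
    population means keep the stated flat priors (alpha on (-10, 10), beta
    magnitude on (0, 10)).  ``link_scale`` is a free positive parameter
    shared across subjects with a half-normal(10) prior.

    Attributes (after ``fit``)
    --------------------------
    posterior_ : DataFrame of retained population-level draws.
    summary_ : DataFrame with posterior median and 95% credible interval.
    params_ : DelegationParams at the posterior median.
    deviance_draws_ : deviance trace aligned with ``posterior_``.
    dic_, pd_ : deviance information criterion and effective parameters.
    rhat_ : split-R-hat per population parameter; ``converged_`` flags
        max R-hat <= 1.05 (a failed check is flagged, not silent).
    """

    def __init__(
        self,
        variant: str = "combined",
        n_walkers: int | None = None,
        n_steps: int = 8000,
        n_burn: int = 4000,
        thin: int = 8,
        seed: int = 0,
    ):
        self.variant = variant
        self.n_walkers = n_walkers
        self.n_steps = n_steps
        self.n_burn = n_burn
        self.thin = thin
        self.seed = seed

    # parameter layout: population block + subject block
    def _layout(self, J: int):
        names = []
        if self.variant in ("constant", "combined"):
            names += ["alpha_phi", "log_sigma_alpha"]
        if self.variant in ("conf_self", "combined"):
            names += ["beta_phi_mag", "log_sigma_beta"]
        names += ["log_link_scale"]
        n_pop = len(names)
        n_sub = J * (2 if self.variant == "combined" else 1)
        return names, n_pop, n_sub

    def _unpack(self, theta: np.ndarray, J: int):
        """theta: (W, ndim) -> population terms, subject z-scores, link.

        Subject effects are non-centered: a_j = mu_a + sigma_a * za_j (and
        likewise for the beta magnitudes), which removes the hierarchical
        funnel from the sampled geometry.
        """
        if self.variant == "constant":
            mu_a, ls_a = theta[:, 0], theta[:, 1]
            link = np.exp(theta[:, 2])
            za = theta[:, 3 : 3 + J]
            return mu_a, ls_a, None, None, za, None, link
        if self.variant == "conf_self":
            mu_b, ls_b = theta[:, 0], theta[:, 1]
            link = np.exp(theta[:, 2])
            zb = theta[:, 3 : 3 + J]
            return None, None, mu_b, ls_b, None, zb, link
        mu_a, ls_a, mu_b, ls_b = theta[:, 0], theta[:, 1], theta[:, 2], theta[:, 3]
        link = np.exp(theta[:, 4])
        za = theta[:, 5 : 5 + J]
        zb = theta[:, 5 + J : 5 + 2 * J]
        return mu_a, ls_a, mu_b, ls_b, za, zb, link

    def _log_prob(self, theta: np.ndarray, conf, n, k, expert, J):
        """Vectorized log-posterior over walkers; returns (logpost, deviance)."""
        theta = np.atleast_2d(theta)
        mu_a, ls_a, mu_b, ls_b, za, zb, link = self._unpack(theta, J)
        W = theta.shape[0]
        lp = np.zeros(W)
        ok = np.ones(W, dtype=bool)

        def halfnormal_scale(log_s, scale=1.0):
            s = np.exp(log_s)
            return -0.5 * (s / scale) ** 2 + log_s  # + Jacobian of log param

        a_j = b_j = None
        if mu_a is not None:
            ok &= (mu_a > -10) & (mu_a < 10) & (ls_a < 3)
            lp += halfnormal_scale(ls_a)
            lp += -0.5 * (za**2).sum(axis=1)
            a_j = mu_a[:, None] + np.exp(ls_a)[:, None] * za
        if mu_b is not None:
            ok &= (mu_b > 0) & (mu_b < 10) & (ls_b < 3)
            lp += halfnormal_scale(ls_b)
            lp += -0.5 * (zb**2).sum(axis=1)
            b_j = mu_b[:, None] + np.exp(ls_b)[:, None] * zb
            ok &= (b_j >= 0).all(axis=1)
        ok &= (link > 0.05) & (link < 200)
        lp += -0.5 * (link / 10.0) ** 2 + np.log(link)  # half-normal(10) + Jacobian

        # binomial likelihood on the aggregates
        phi = np.zeros((W, conf.shape[0], conf.shape[1]))
        if a_j is not None:
            phi += a_j[:, :, None]
        if b_j is not None:
            phi -= b_j[:, :, None] * conf[None, :, :]
        delta = expert - conf[None, :, :] + phi
        p = expit(link[:, None, None] * delta)
        p = np.clip(p, 1e-9, 1 - 1e-9)
        ll = (k * np.log(p) + (n - k) * np.log1p(-p)).sum(axis=(1, 2))
        dev = -2.0 * ll
        logpost = np.where(ok, lp + ll, -np.inf)
        return logpost, dev

    def fit(self, aggregates: pd.DataFrame):
        """Fit to aggregates of one (condition, expert level) stratum.

        ``aggregates`` must have columns subject_id, c,
        mean_confidence_self, delegation_proportion, n_trials, and a single
        value in each of ``condition`` and ``expert_level`` (if present).
        """
        agg = aggregates
        for col in ("condition", "expert_level"):
            if col in agg.columns and agg[col].nunique() > 1:
                raise ValueError(
                    f"fit one stratum at a time: multiple values in {col!r}"
                )
        subjects = sorted(agg["subject_id"].unique())
        levels = sorted(agg["c"].unique())
        J, L = len(subjects), len(levels)
        conf = np.zeros((J, L))
        n = np.zeros((J, L))
        k = np.zeros((J, L))
        pivot_c = agg.pivot_table(index="subject_id", columns="c",
                                  values="mean_confidence_self")
        pivot_n = agg.pivot_table(index="subject_id", columns="c",
                                  values="n_trials")
        pivot_p = agg.pivot_table(index="subject_id", columns="c",
                                  values="delegation_proportion")
        conf = pivot_c.loc[subjects, levels].to_numpy()
        n = pivot_n.loc[subjects, levels].to_numpy()
        k = np.rint(pivot_p.loc[subjects, levels].to_numpy() * n)
        expert = float(agg["expert_level"].iloc[0]) if "expert_level" in agg.columns else 0.9
        _check_conf(conf, "mean_confidence_self")

        names, n_pop, n_sub = self._layout(J)
        ndim = n_pop + n_sub
        n_walkers = self.n_walkers or max(2 * ndim + 2, 64)
        rng = np.random.default_rng(self.seed)

        # moderate starting box around neutral values
        p0 = np.zeros((n_walkers, ndim))
        col = 0
        if self.variant in ("constant", "combined"):
            p0[:, col] = rng.uniform(-1.5, 1.5, n_walkers); col += 1
            p0[:, col] = np.log(rng.uniform(0.2, 0.8, n_walkers)); col += 1
        if self.variant in ("conf_self", "combined"):
            p0[:, col] = rng.uniform(0.1, 2.0, n_walkers); col += 1
            p0[:, col] = np.log(rng.uniform(0.2, 0.8, n_walkers)); col += 1
        p0[:, col] = np.log(rng.uniform(2, 20, n_walkers)); col += 1
        # subject z-scores start standard-normal
        p0[:, col:] = rng.standard_normal((n_walkers, ndim - col))

        def log_prob(th):
            lp, _ = self._log_prob(th, conf, n, k, expert, J)
            return lp

        sampler = emcee.EnsembleSampler(
            n_walkers, ndim, log_prob, vectorize=True,
            moves=[(emcee.moves.DEMove(), 0.8),
                   (emcee.moves.DESnookerMove(), 0.2)],
        )
        sampler.random_state = np.random.RandomState(self.seed).get_state()
        sampler.run_mcmc(p0, self.n_steps, progress=False)

        chain = sampler.get_chain(discard=self.n_burn, thin=self.thin)  # (T, W, d)
        # deviance trace recomputed on the retained draws (blobs and
        # vectorized log-probs do not combine in the ensemble sampler)
        _, dev = self._log_prob(chain.reshape(-1, ndim), conf, n, k, expert, J)

        import arviz as az

        pop = chain[:, :, :n_pop]
        rhat_vals = [
            float(az.rhat(np.swapaxes(pop[:, :, i], 0, 1)))  # (chain, draw)
            for i in range(n_pop)
        ]
        self.rhat_ = dict(zip(names, rhat_vals))
        self.converged_ = bool(np.nanmax(rhat_vals) <= 1.05)

        flat = chain.reshape(-1, ndim)
        dev_flat = np.asarray(dev).reshape(-1)
        post = {}
        for i, nm in enumerate(names):
            vals = flat[:, i]
            if nm.startswith("log_"):
                post[nm.removeprefix("log_")] = np.exp(vals)
            else:
                post[nm] = vals
        self.posterior_ = pd.DataFrame(post)
        self.deviance_draws_ = dev_flat

        med = self.posterior_.median()
        lo = self.posterior_.quantile(0.025)
        hi = self.posterior_.quantile(0.975)
        self.summary_ = pd.DataFrame({"median": med, "ci_low": lo, "ci_high": hi})

        theta_mean = flat.mean(axis=0, keepdims=True)
        _, dev_at_mean = self._log_prob(theta_mean, conf, n, k, expert, J)
        self.deviance_at_mean_ = float(dev_at_mean[0])
        self.dic_, self.pd_ = dic(dev_flat, self.deviance_at_mean_)

        self.params_ = DelegationParams(
            variant=self.variant,
            alpha_phi=float(med.get("alpha_phi", 0.0)),
            beta_phi_mag=float(med.get("beta_phi_mag", 0.0)),
            link_scale=float(med["link_scale"]),
        )
        self.subjects_ = subjects
        # subject-level effects on the natural scale (from the z-scores)
        mu_a_d, ls_a_d, mu_b_d, ls_b_d, za_d, zb_d, _ = self._unpack(flat, J)
        subj = {}
        if za_d is not None:
            subj["alpha_phi"] = (
                mu_a_d[:, None] + np.exp(ls_a_d)[:, None] * za_d
            ).mean(axis=0)
        if zb_d is not None:
            subj["beta_phi_mag"] = (
                mu_b_d[:, None] + np.exp(ls_b_d)[:, None] * zb_d
            ).mean(axis=0)
        self.subject_effects_ = pd.DataFrame(subj, index=subjects)
        return self

    def predict_proportion(self, mean_confidence_self, expert_level):
        """Posterior-median delegation proportion at given mean confidence."""
        return delegation_probability(mean_confidence_self, self.params_, expert_level)


def dic(deviance_draws, deviance_at_posterior_mean: float) -> tuple[float, float]:
    """Deviance information criterion: DIC = D(theta_bar) + 2 * pD with
    pD = Var[D(theta)] / 2.  Requires at least two deviance draws."""
    d = np.asarray(deviance_draws, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 deviance draws")
    p_d = 0.5 * float(np.var(d, ddof=0))
    return float(deviance_at_posterior_mean) + 2.0 * p_d, p_d


def expected_final_accuracy(
    phi_d: float,
    confidences,
    self_accuracy,
    expert_level: float,
    weights=None,
) -> float:
    """Expected overall accuracy of the delegate-or-lead policy.

    At each stimulus level the agent delegates iff
    ``expert_level - confidence + phi_d > 0`` (hard step, tie leads), earning
    the expert's accuracy on delegated levels and own accuracy on led ones;
    the result is the trial-weighted mean.  With calibrated confidence
    (confidence = own accuracy) the neutral preference phi_d = 0 attains the
    maximum, mean(max(confidence, expert_level)).
    """
    conf = _check_conf(confidences, "confidences")
    acc = np.asarray(self_accuracy, dtype=float)
    if conf.shape != acc.shape:
        raise ValueError("confidences and self_accuracy must align")
    w = np.ones_like(conf) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    delegate = (expert_level - conf + phi_d) > 0
    per_level = np.where(delegate, expert_level, acc)
    return float((w * per_level).sum())


def loo_accuracy_prediction(features, final_accuracies):
    """Leave-one-out linear prediction of final accuracy from |phi_d|.

    For each subject a straight line is fit to all other subjects and used
    to predict the held-out one; returns ``(predictions, r)`` with r the
    Pearson correlation between predictions and truth.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(final_accuracies, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 aligned subjects")
    preds = np.empty_like(y)
    for i in range(x.size):
        mask = np.ones(x.size, dtype=bool)
        mask[i] = False
        if np.var(x[mask]) == 0:
            raise ValueError("zero variance in features: correlation undefined")
        slope, intercept = np.polyfit(x[mask], y[mask], 1)
        preds[i] = slope * x[i] + intercept
    if np.var(preds) == 0 or np.var(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(preds, y)[0, 1])
    return preds, r
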