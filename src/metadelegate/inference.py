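"""Bayesian hierarchical regressions, the IV model, and sensitivity analysis.

The statistical layer mirrors the study's regression battery: twelve
hierarchical (generalized) regressions of accuracy, confidence, log RT, and
delegation on condition, stimulus strength, and design covariates, with
Normal(0, 1) priors on intercepts and slopes — Normal(0.5, 1) on the
difficulty slope — subject-specific coefficients for every regressor except
difficulty, and three chains of 2000 retained draws by default.  Reported
per effect: posterior median, 95% credible interval, and P_MCMC (one minus
the posterior probability that the effect lies on the side of zero of its
point estimate).

The instrumental-variable model estimates the causal effect of confidence on
delegation using stimulus strength and condition as instruments: a Student-t
confidence stage on the instruments and a Bernoulli-logit delegation stage
on the instrument-predicted confidence, fit jointly per expert level with
t3(0, 1) priors on intercepts and slopes, Exponential(1) on the confidence
scale, and Gamma(2, 0.1) on the degrees of freedom.

The parameter-swap sensitivity analysis transplants a named subset of
fitted Group-condition parameters into the Self-condition parameter set,
simulates a full dataset from the hybrid, and re-runs the matching
regression to measure how much of the condition effect that subset alone
reproduces (interdependent parameters, like the collapsing bound's, are
swapped jointly).

Sampling uses an affine-invariant ensemble MCMC with differential-evolution
moves and a non-centered hierarchy; split-R-hat above 1.05 flags the fit.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

import emcee

__all__ = [
    "RegressionSpec",
    "EffectEstimate",
    "EQUATION_SPECS",
    "HierarchicalRegression",
    "IVRegression",
    "pmcmc",
    "fit_glmm",
    "fit_iv",
    "build_change_scores",
    "parameter_swap_effect",
]


@dataclass(frozen=True)
class RegressionSpec:
    """One regression of the battery.

    ``terms`` are population-level predictors; entries like ``"A:B"`` denote
    interactions of coded terms.  ``subject_varying`` lists the terms (plus
    the intercept, always) that get per-subject deviations; by design this
    is every regressor except Difficulty.  ``aggregate`` marks specs that
    operate on per-(subject, level) change scores rather than trials.
    """

    equation_id: int
    family: str  # "bernoulli_logit" | "gaussian"
    outcome: str
    terms: tuple
    subject_varying: tuple = ()
    aggregate: bool = False

    def __post_init__(self):
        if self.family not in ("bernoulli_logit", "gaussian"):
            raise ValueError("family must be bernoulli_logit or gaussian")


def _spec(eq, family, outcome, terms, aggregate=False):
    varying = tuple(t for t in terms if "Difficulty" not in t)
    return RegressionSpec(eq, family, outcome, tuple(terms), varying, aggregate)


#: the regression battery; numbering follows the order effects are reported
EQUATION_SPECS: dict[int, RegressionSpec] = {
    1: _spec(1, "bernoulli_logit", "Correct", ("Condition", "Difficulty")),
    2: _spec(2, "gaussian", "Confidence", ("Condition", "Difficulty")),
    3: _spec(3, "gaussian", "logRT", ("Condition", "Difficulty")),
    4: _spec(4, "bernoulli_logit", "Correct",
             ("Condition", "Difficulty", "Task", "Task:Condition")),
    5: _spec(5, "gaussian", "Confidence",
             ("Condition", "Difficulty", "Task", "Task:Condition")),
    6: _spec(6, "gaussian", "logRT",
             ("Condition", "Difficulty", "Task", "Task:Condition")),
    7: _spec(7, "gaussian", "Confidence", ("SimType", "Difficulty")),
    8: _spec(8, "gaussian", "Confidence",
             ("Condition", "Difficulty", "trialInd", "trialInd:Condition")),
    9: _spec(9, "gaussian", "Confidence",
             ("Difficulty", "Condition", "Resp", "Resp:Condition")),
    10: _spec(10, "bernoulli_logit", "Delegation",
              ("Condition", "Difficulty", "Expert", "Expert:Condition")),
    11: _spec(11, "bernoulli_logit", "Delegation", ("Condition", "Difficulty")),
    12: _spec(12, "gaussian", "DelegationChange",
              ("ConfidenceChange", "Difficulty"), aggregate=True),
}


@dataclass
class EffectEstimate:
    """Posterior summary of one population-level term."""

    term: str
    point: float
    ci95: tuple
    pmcmc: float
    draws: np.ndarray = field(repr=False)

    def ci_excludes_zero(self) -> bool:
        return self.ci95[0] > 0 or self.ci95[1] < 0


def pmcmc(draws, direction: str | None = None) -> float:
    """One minus the posterior probability that the effect is on the side of
    zero matching its point estimate (or the given direction).

    Lies in [0, 0.5] by the directional definition; ~0.5 for a posterior
    symmetric around zero, 0 for a unanimous one.
    """
    d = np.asarray(draws, dtype=float)
    if d.size < 100:
        warnings.warn("fewer than 100 draws: P_MCMC is imprecise", stacklevel=2)
    if direction is None:
        direction = "positive" if np.median(d) >= 0 else "negative"
    if direction == "positive":
        return float(np.mean(d <= 0))
    return float(np.mean(d >= 0))


# ---------------------------------------------------------------------------
# design-matrix construction


_BINARY_ORDER = {
    "Condition": (("Self", "Group"), ("Low", "High")),
}


def _code_column(df: pd.DataFrame, term: str) -> np.ndarray:
    """Numeric coding of one base term from trial-table columns."""
    if term == "Condition":
        vals = df["condition"].astype(str)
        for order in _BINARY_ORDER["Condition"]:
            if set(vals.unique()) <= set(order):
                return (vals == order[1]).to_numpy(float)
        codes, _ = pd.factorize(vals, sort=True)
        return codes.astype(float)
    if term == "Difficulty":
        c = df["c"].to_numpy(float)
        return (c - c.mean()) / c.std()
    if term == "trialInd":
        t = df["trial_index"].to_numpy(float)
        return (t - t.mean()) / t.std()
    if term == "Expert":
        e = df["expert_level"].to_numpy(float)
        return (e == np.max(e)).astype(float)
    if term in ("Task", "SimType", "Resp"):
        col = {"Task": "task", "SimType": "sim_type", "Resp": "resp"}[term]
        codes, _ = pd.factorize(df[col].astype(str), sort=True)
        return codes.astype(float)
    if term == "ConfidenceChange":
        return df["confidence_change"].to_numpy(float)
    raise KeyError(f"unknown term {term!r}")


def _outcome_column(df: pd.DataFrame, outcome: str) -> np.ndarray:
    if outcome == "Correct":
        return df["accuracy"].to_numpy(float)
    if outcome == "Confidence":
        x = df["confidence"].to_numpy(float)
        return (x - x.mean()) / x.std()  # standardized across the dataset
    if outcome == "logRT":
        rt = df["rt_decision"].to_numpy(float)
        if np.any(rt <= 0):
            raise ValueError("rt_decision must be positive for logRT")
        return np.log(rt)
    if outcome == "Delegation":
        return (df["choice"] == "delegate").to_numpy(float)
    if outcome == "DelegationChange":
        return df["delegation_change"].to_numpy(float)
    raise KeyError(f"unknown outcome {outcome!r}")


def build_design(df: pd.DataFrame, spec: RegressionSpec):
    """(y, X, term names, subject index, varying-term columns) for a spec."""
    base_cols = {}
    for term in spec.terms:
        for part in term.split(":"):
            if part not in base_cols:
                base_cols[part] = _code_column(df, part)
    cols = []
    for term in spec.terms:
        parts = term.split(":")
        col = base_cols[parts[0]].copy()
        for p in parts[1:]:
            col = col * base_cols[p]
        cols.append(col)
    X = np.column_stack(cols)
    y = _outcome_column(df, spec.outcome)
    subj, _ = pd.factorize(df["subject_id"], sort=True)
    varying_idx = [i for i, t in enumerate(spec.terms) if t in spec.subject_varying]
    return y, X, list(spec.terms), subj, varying_idx


# ---------------------------------------------------------------------------
# hierarchical regression


class HierarchicalRegression(BaseEstimator):
    """Bayesian hierarchical (generalized) regression for one spec.

    Population terms carry Normal(0, 1) priors — Normal(0.5, 1) for the
    difficulty slope — and every term except difficulty (plus the intercept)
    receives non-centered per-subject deviations with half-normal(1) scales.
    The Gaussian family adds a half-normal(1) residual scale.  Draws come
    from ``chains`` independent ensemble runs, each retaining
    ``draws_per_chain`` population-level draws after burn-in.

    Attributes
    ----------
    effects_ : dict term -> EffectEstimate (includes "Intercept").
    rhat_ : split-R-hat per population term across chains.
    converged_ : max R-hat <= 1.05.
    """

    def __init__(
        self,
        equation_id: int | None = None,
        spec: RegressionSpec | None = None,
        chains: int = 3,
        draws_per_chain: int = 2000,
        n_steps: int = 2500,
        n_burn: int = 1500,
        seed: int = 0,
    ):
        self.equation_id = equation_id
        self.spec = spec
        self.chains = chains
        self.draws_per_chain = draws_per_chain
        self.n_steps = n_steps
        self.n_burn = n_burn
        self.seed = seed

    def _resolve_spec(self) -> RegressionSpec:
        if self.spec is not None:
            return self.spec
        if self.equation_id is None:
            raise ValueError("provide equation_id or spec")
        return EQUATION_SPECS[self.equation_id]

    def fit(self, df: pd.DataFrame):
        spec = self._resolve_spec()
        missing = {"subject_id"} - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        y, X, terms, subj, varying_idx = build_design(df, spec)
        N, P = X.shape
        J = int(subj.max()) + 1
        V = len(varying_idx) + 1  # +1 for the subject intercept
        gaussian = spec.family == "gaussian"

        # parameter layout:
        # [alpha, beta_1..P, log_tau_1..V, (log_sigma_res), z_{J*V}]
        n_pop = 1 + P
        n_scales = V + (1 if gaussian else 0)
        ndim = n_pop + n_scales + J * V

        prior_mean = np.zeros(n_pop)
        for i, t in enumerate(terms):
            if t == "Difficulty":
                prior_mean[1 + i] = 0.5

        Xv = X[:, varying_idx] if varying_idx else np.empty((N, 0))
        Zcols = np.column_stack([np.ones(N), Xv])  # (N, V)

        def log_prob(theta):
            theta = np.atleast_2d(theta)
            W = theta.shape[0]
            pop = theta[:, :n_pop]
            log_tau = theta[:, n_pop : n_pop + V]
            ok = (np.abs(log_tau) < 4).all(axis=1)
            if gaussian:
                log_sig = theta[:, n_pop + V]
                ok &= np.abs(log_sig) < 4
                sig = np.exp(log_sig)
            z = theta[:, n_pop + n_scales :].reshape(W, J, V)

            lp = -0.5 * ((pop - prior_mean) ** 2).sum(axis=1)
            tau = np.exp(log_tau)
            lp += (-0.5 * tau**2 + log_tau).sum(axis=1)  # half-normal + Jacobian
            if gaussian:
                lp += -0.5 * sig**2 + log_sig
            lp += -0.5 * (z**2).sum(axis=(1, 2))

            u = tau[:, None, :] * z  # (W, J, V)
            eta = pop[:, 0:1] + pop[:, 1:] @ X.T  # (W, N)
            eta = eta + np.einsum("nv,wnv->wn", Zcols, u[:, subj, :])
            if gaussian:
                resid = y[None, :] - eta
                ll = (-0.5 * (resid / sig[:, None]) ** 2
                      - np.log(sig)[:, None]).sum(axis=1)
            else:
                p = expit(eta)
                p = np.clip(p, 1e-9, 1 - 1e-9)
                ll = (y[None, :] * np.log(p)
                      + (1 - y[None, :]) * np.log1p(-p)).sum(axis=1)
            out = lp + ll
            out[~ok] = -np.inf
            return out

        n_walkers = max(2 * ndim + 2, 48)
        all_draws = []
        rhat_chains = []
        for chain in range(self.chains):
            rng = np.random.default_rng(self.seed + 1000 * chain)
            p0 = 0.1 * rng.standard_normal((n_walkers, ndim))
            p0[:, :n_pop] += prior_mean
            sampler = emcee.EnsembleSampler(
                n_walkers, ndim, log_prob, vectorize=True,
                moves=[(emcee.moves.DEMove(), 0.8),
                       (emcee.moves.DESnookerMove(), 0.2)],
            )
            sampler.random_state = np.random.RandomState(
                self.seed + 1000 * chain).get_state()
            sampler.run_mcmc(p0, self.n_steps, progress=False)
            flat = sampler.get_chain(discard=self.n_burn, flat=True)
            idx = np.linspace(0, flat.shape[0] - 1, self.draws_per_chain).astype(int)
            draws = flat[idx, :n_pop]
            all_draws.append(draws)
            rhat_chains.append(draws)

        import arviz as az

        stacked = np.stack(rhat_chains)  # (chains, draws, n_pop)
        names = ["Intercept"] + terms
        if self.chains > 1:
            rhat_vals = [float(az.rhat(stacked[:, :, i])) for i in range(n_pop)]
        else:
            half = stacked.shape[1] // 2
            split = np.stack([stacked[0, :half], stacked[0, half : 2 * half]])
            rhat_vals = [float(az.rhat(split[:, :, i])) for i in range(n_pop)]
        self.rhat_ = dict(zip(names, rhat_vals))
        self.converged_ = bool(np.nanmax(rhat_vals) <= 1.05)

        pooled = np.concatenate(all_draws, axis=0)
        self.draws_ = pd.DataFrame(pooled, columns=names)
        self.effects_ = {}
        for i, nm in enumerate(names):
            d = pooled[:, i]
            self.effects_[nm] = EffectEstimate(
                term=nm,
                point=float(np.median(d)),
                ci95=(float(np.quantile(d, 0.025)), float(np.quantile(d, 0.975))),
                pmcmc=pmcmc(d),
                draws=d,
            )
        self.n_obs_ = N
        self.n_subjects_ = J
        return self

    def effect(self, term: str) -> EffectEstimate:
        return self.effects_[term]


def fit_glmm(df: pd.DataFrame, spec: RegressionSpec | int, seed: int = 0,
             **kwargs) -> dict:
    """Functional wrapper: fit a regression spec, return its effects dict."""
    if isinstance(spec, int):
        model = HierarchicalRegression(equation_id=spec, seed=seed, **kwargs)
    else:
        model = HierarchicalRegression(spec=spec, seed=seed, **kwargs)
    return model.fit(df).effects_


# ---------------------------------------------------------------------------
# instrumental-variable model


class IVRegression(BaseEstimator):
    """Hierarchical Bayesian IV model of confidence's effect on delegation.

    Stage 1 (confidence): c_i ~ Student-t(nu, a_j[i] + b_diff z1 + b_cond z2,
    sigma).  Stage 2 (delegation): y_i ~ Bernoulli(logit^-1(a'_j[i] +
    b_conf * mu_c_i)), where mu_c_i is the instrument-predicted confidence —
    the exclusion restriction lets only instrument-driven confidence
    variation reach the delegation stage.  Priors: t3(0,1) on all intercepts
    and slopes, Exponential(1) on sigma, Gamma(2, 0.1) on nu.  Fit jointly
    per expert accuracy level.

    Attributes: ``effects_`` with keys "beta_diff", "beta_cond", "beta_conf".
    """

    def __init__(self, n_steps: int = 4000, n_burn: int = 2000, thin: int = 4,
                 seed: int = 0):
        self.n_steps = n_steps
        self.n_burn = n_burn
        self.thin = thin
        self.seed = seed

    def fit(self, df: pd.DataFrame, expert_level: float | None = None):
        """``df`` needs delegate indicator rows with columns ``confidence_iv``
        (trial confidence on any fixed scale), ``c``, ``condition``,
        ``choice``, ``subject_id``; optionally filtered by expert level."""
        if expert_level is not None:
            df = df[df["expert_level"] == expert_level]
        y = (df["choice"] == "delegate").to_numpy(float)
        c_obs = df["confidence_iv"].to_numpy(float)
        z1 = _code_column(df, "Difficulty")
        z2 = _code_column(df, "Condition")
        if np.var(z1) == 0 or np.var(z2) == 0:
            raise ValueError("an instrument has zero variance")
        subj, _ = pd.factorize(df["subject_id"], sort=True)
        J = int(subj.max()) + 1
        N = len(df)

        # layout: [b_diff, b_cond, b_conf, log_sigma, log_nu, a_c_j, a_y_j]
        ndim = 5 + 2 * J

        from scipy import stats as st

        def log_prob(theta):
            theta = np.atleast_2d(theta)
            W = theta.shape[0]
            b_diff, b_cond, b_conf = theta[:, 0], theta[:, 1], theta[:, 2]
            log_sig, log_nu = theta[:, 3], theta[:, 4]
            ok = (np.abs(log_sig) < 5) & (log_nu > np.log(1.0)) & (log_nu < 6)
            sig = np.exp(log_sig)
            nu = np.exp(log_nu)
            a_c = theta[:, 5 : 5 + J]
            a_y = theta[:, 5 + J :]

            def t3_logpdf(x):
                return st.t.logpdf(x, df=3)

            lp = t3_logpdf(b_diff) + t3_logpdf(b_cond) + t3_logpdf(b_conf)
            lp += -sig + log_sig  # Exponential(1) + Jacobian
            lp += st.gamma.logpdf(nu, a=2, scale=10.0) + log_nu
            lp += t3_logpdf(a_c).sum(axis=1) + t3_logpdf(a_y).sum(axis=1)

            mu_c = (a_c[:, subj] + b_diff[:, None] * z1[None, :]
                    + b_cond[:, None] * z2[None, :])
            ll = st.t.logpdf(
                (c_obs[None, :] - mu_c) / sig[:, None], df=nu[:, None]
            ).sum(axis=1) - N * np.log(sig)
            eta = a_y[:, subj] + b_conf[:, None] * mu_c
            p = np.clip(expit(eta), 1e-9, 1 - 1e-9)
            ll += (y[None, :] * np.log(p)
                   + (1 - y[None, :]) * np.log1p(-p)).sum(axis=1)
            out = lp + ll
            out[~ok] = -np.inf
            return out

        rng = np.random.default_rng(self.seed)
        n_walkers = max(2 * ndim + 2, 64)
        p0 = 0.1 * rng.standard_normal((n_walkers, ndim))
        p0[:, 3] = np.log(np.std(c_obs) + 0.1) + 0.1 * rng.standard_normal(n_walkers)
        p0[:, 4] = np.log(10.0) + 0.3 * rng.standard_normal(n_walkers)
        p0[:, 5 : 5 + J] += np.mean(c_obs)

        sampler = emcee.EnsembleSampler(
            n_walkers, ndim, log_prob, vectorize=True,
            moves=[(emcee.moves.DEMove(), 0.8),
                   (emcee.moves.DESnookerMove(), 0.2)],
        )
        sampler.random_state = np.random.RandomState(self.seed).get_state()
        sampler.run_mcmc(p0, self.n_steps, progress=False)
        chain = sampler.get_chain(discard=self.n_burn, thin=self.thin)

        import arviz as az

        names = ["beta_diff", "beta_cond", "beta_conf", "log_sigma", "log_nu"]
        rhat_vals = [
            float(az.rhat(np.swapaxes(chain[:, :, i], 0, 1))) for i in range(3)
        ]
        self.rhat_ = dict(zip(names[:3], rhat_vals))
        self.converged_ = bool(np.nanmax(rhat_vals) <= 1.05)

        flat = chain.reshape(-1, chain.shape[-1])
        self.effects_ = {}
        for i, nm in enumerate(names[:3]):
            d = flat[:, i]
            self.effects_[nm] = EffectEstimate(
                term=nm, point=float(np.median(d)),
                ci95=(float(np.quantile(d, 0.025)), float(np.quantile(d, 0.975))),
                pmcmc=pmcmc(d), draws=d,
            )
        self.sigma_conf_ = float(np.median(np.exp(flat[:, 3])))
        self.nu_conf_ = float(np.median(np.exp(flat[:, 4])))
        return self


def fit_iv(df: pd.DataFrame, expert_level: float | None = None, seed: int = 0,
           **kwargs) -> dict:
    """Functional wrapper over :class:`IVRegression`."""
    return IVRegression(seed=seed, **kwargs).fit(df, expert_level).effects_


def build_change_scores(
    forced_choice_df: pd.DataFrame,
    delegation_df: pd.DataFrame,
    expert_level: float,
) -> pd.DataFrame:
    """Per-(subject, difficulty) condition-change scores for the
    delegation-change regression.

    ``delegation_change`` is the Group-minus-Self difference in the
    delegation proportion at each difficulty level; ``confidence_change``
    the same difference in mean standardized confidence from the
    forced-choice task.  One row per (subject, c); feed to the regression of
    delegation change on confidence change, fit separately per expert level.
    """
    fc = forced_choice_df[
        forced_choice_df["choice"].isin(["left", "right"])].copy()
    x = fc["confidence"].to_numpy(float)
    fc["conf_z"] = (x - x.mean()) / x.std()
    conf = (fc.pivot_table(index=["subject_id", "c"], columns="condition",
                           values="conf_z")
            .pipe(lambda t: (t["Group"] - t["Self"]).rename("confidence_change")))
    dl = delegation_df[delegation_df["expert_level"] == expert_level].copy()
    dl["delegated"] = (dl["choice"] == "delegate").astype(float)
    deleg = (dl.pivot_table(index=["subject_id", "c"], columns="condition",
                            values="delegated")
             .pipe(lambda t: (t["Group"] - t["Self"]).rename("delegation_change")))
    out = pd.concat([deleg, conf], axis=1).dropna().reset_index()
    if out.empty:
        raise ValueError("no overlapping (subject, c) cells across conditions")
    return out


def attach_iv_confidence(
    delegation_df: pd.DataFrame, forced_choice_df: pd.DataFrame
) -> pd.DataFrame:
    """Merge forced-choice cell-mean confidence onto delegation trials.

    The delegation task elicits no confidence, so each delegation trial
    receives the mean (standardized) confidence of the matching
    (subject, condition, difficulty) forced-choice cell as ``confidence_iv``.
    """
    fc = forced_choice_df[forced_choice_df["choice"].isin(["left", "right"])].copy()
    x = fc["confidence"].to_numpy(float)
    fc["conf_z"] = (x - x.mean()) / x.std()
    cell = (fc.groupby(["subject_id", "condition", "c"])["conf_z"]
            .mean().rename("confidence_iv").reset_index())
    out = delegation_df.merge(cell, on=["subject_id", "condition", "c"], how="left")
    if out["confidence_iv"].isna().any():
        raise ValueError("missing forced-choice confidence for some cells")
    return out


# ---------------------------------------------------------------------------
# parameter-swap sensitivity analysis


_SWAP_REGRESSION = {"ddm": 3, "metacog": 2, "delegation": 11}


def parameter_swap_effect(
    fit_self,
    fit_group,
    subset,
    simulator: str,
    n_subjects: int = 12,
    n_trials_per_level: int = 10,
    seed: int = 0,
    regression_kwargs: dict | None = None,
) -> EffectEstimate:
    """Condition effect reproduced by transplanting a parameter subset.

    Builds a hybrid Group parameter set: the Self-condition fit with the
    named ``subset`` of fields replaced by their Group-condition values
    (empty subset = no-change control; all fields = identity swap), then
    simulates a dataset whose Self condition uses the Self fit and whose
    Group condition uses the hybrid, and re-runs the regression that
    measured the original effect (log RT for the DDM, confidence for the
    metacognitive model, delegation for the delegation model).  Returns the
    Condition effect estimate.
    """
    from metadelegate.tasks import (
        AgentSpec, TaskConfig, simulate_forced_choice_dataset,
        simulate_delegation_dataset,
    )
    from metadelegate.ddm import DDMParams
    from metadelegate.metacog import MetacogParams
    from metadelegate.delegation import DelegationParams

    if simulator not in _SWAP_REGRESSION:
        raise ValueError(f"simulator must be one of {sorted(_SWAP_REGRESSION)}")
    valid = {f.name for f in dataclasses.fields(type(fit_self))}
    unknown = set(subset) - valid
    if unknown:
        raise ValueError(f"unknown parameter names: {sorted(unknown)}")
    hybrid = dataclasses.replace(
        fit_self, **{f: getattr(fit_group, f) for f in subset}
    )

    neutral_ddm = DDMParams(t_max=8.0)
    neutral_mc = MetacogParams()
    agents = {}
    for s in range(n_subjects):
        if simulator == "ddm":
            self_spec = AgentSpec(ddm=fit_self, metacog=neutral_mc)
            group_spec = AgentSpec(ddm=hybrid, metacog=neutral_mc)
        elif simulator == "metacog":
            self_spec = AgentSpec(ddm=neutral_ddm, metacog=fit_self)
            group_spec = AgentSpec(ddm=neutral_ddm, metacog=hybrid)
        else:
            self_spec = AgentSpec(ddm=neutral_ddm, metacog=neutral_mc,
                                  delegation=fit_self)
            group_spec = AgentSpec(ddm=neutral_ddm, metacog=neutral_mc,
                                   delegation=hybrid)
        agents[f"s{s:03d}"] = {"Self": self_spec, "Group": group_spec}

    if simulator == "delegation":
        config = TaskConfig(experiment_variant="delegation",
                            n_trials_per_level=n_trials_per_level,
                            expert_levels=(0.9,))
        df = simulate_delegation_dataset(agents, config, seed=seed)
    else:
        config = TaskConfig(n_trials_per_level=n_trials_per_level)
        df = simulate_forced_choice_dataset(agents, config, seed=seed)

    kwargs = dict(chains=1, draws_per_chain=1000, n_steps=1800, n_burn=1000,
                  seed=seed)
    kwargs.update(regression_kwargs or {})
    model = HierarchicalRegression(
        equation_id=_SWAP_REGRESSION[simulator], **kwargs
    ).fit(df)
    return model.effect("Condition")
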