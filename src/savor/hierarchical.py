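"""Hierarchical Bayesian random-effects fitting of the choice model.

Each subject's (transformed) parameter vector h_i is treated as a draw from
a population Gaussian with mean mu and diagonal covariance; the population
parameters are found by approximate expectation-maximization.  The E step
computes each subject's MAP estimate and a Laplace (inverse-Hessian)
approximation of the posterior covariance; the M step updates the population
moments as

    mu    <- mean_i m_i
    Sigma <- mean_i (m_i m_i^T + Sigma_i) - mu mu^T   (diagonal kept)

The transformation to h-space enforces every constraint by construction,
including the stability bound on the boosting gain: C is parameterized as
C_max(rates) * logistic(h_C), so every candidate parameter vector admits a
self-consistent aRPE solution.

The public face follows the Model/Results convention:
``AnticipationChoiceModel(trials).fit()`` returns a
:class:`HierarchicalFitResults` carrying the population prior, per-subject
fits, the EM trace and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .core import (ModelParams, InvalidParameterError, choice_probability,
                   stability_bound)

__all__ = [
    "PARAM_NAMES",
    "ModelSpec",
    "FULL_MODEL",
    "NO_BOOST_MODEL",
    "NO_ANTICIPATION_MODEL",
    "GroupPrior",
    "SubjectFit",
    "FitConfig",
    "FitResult",
    "transform_params",
    "untransform_params",
    "subject_log_likelihood",
    "fit_subject_map",
    "em_update",
    "fit_hierarchical",
    "AnticipationChoiceModel",
    "HierarchicalFitResults",
    "read_trial_table",
]

PARAM_NAMES = ("R_minus", "eta0", "C", "nu_plus", "nu_minus", "gamma", "sigma")

# clamp for parameters whose transform diverges at a domain boundary
_H_MIN = -30.0
_LOG_LIK_FLOOR = np.log(1e-12)


@dataclass(frozen=True)
class ModelSpec:
    """A model variant: which of the seven subject-level parameters are free.

    The reduced variants fix the boosting gain (``no_boost``: C = 0) or
    remove anticipation entirely (``no_anticipation``: eta0 = C = 0).  The
    count of fitted population parameters |M| is two per free parameter
    (a mean and a variance).
    """

    name: str
    free: tuple

    def __post_init__(self):
        unknown = [p for p in self.free if p not in PARAM_NAMES]
        if unknown:
            raise ValueError(f"unknown parameters {unknown}")

    @property
    def n_free(self) -> int:
        return len(self.free)

    @property
    def n_prior_params(self) -> int:
        return 2 * self.n_free


FULL_MODEL = ModelSpec("full", PARAM_NAMES)
NO_BOOST_MODEL = ModelSpec(
    "no_boost", tuple(p for p in PARAM_NAMES if p != "C"))
NO_ANTICIPATION_MODEL = ModelSpec(
    "no_anticipation", tuple(p for p in PARAM_NAMES if p not in ("C", "eta0")))


def _softplus(x):
    return np.logaddexp(0.0, x)


def _softplus_inv(y):
    y = max(float(y), 1e-13)
    # inverse of log(1 + e^x); stable for small y
    return float(y + np.log(-np.expm1(-y))) if y < 30 else float(y)


def transform_params(params: ModelParams, spec: ModelSpec = FULL_MODEL,
                     ) -> np.ndarray:
    """Map admissible parameters to the unconstrained fitting space.

    log for the rates and sigma, inverse-softplus for eta0, log(-R-) for the
    no-reward value (clamped at the R- = 0 boundary), and a logit of
    C / C_max(rates) for the boosting gain so stability holds by
    construction.
    """
    h = {}
    h["R_minus"] = max(np.log(-params.R_minus), _H_MIN) \
        if params.R_minus < 0 else _H_MIN
    h["eta0"] = max(_softplus_inv(params.eta0), _H_MIN)
    for name in ("nu_plus", "nu_minus", "gamma", "sigma"):
        v = getattr(params, name)
        if v <= 0:
            raise InvalidParameterError(f"{name} must be > 0 to transform")
        h[name] = np.log(v)
    cmax = stability_bound(params)
    frac = params.C / cmax
    if frac >= 1:
        raise InvalidParameterError("C at or above the stability bound")
    h["C"] = max(float(logit(max(frac, 1e-13))), _H_MIN)
    return np.array([h[p] for p in spec.free])


def untransform_params(h, spec: ModelSpec = FULL_MODEL) -> ModelParams:
    """Inverse of :func:`transform_params`; fixed parameters take their
    reduced-model values (C = 0, and eta0 = 0 for the no-anticipation
    variant)."""
    h = np.asarray(h, dtype=float)
    if h.shape != (spec.n_free,):
        raise ValueError(f"expected h of length {spec.n_free}")
    d = dict(zip(spec.free, h))
    kw = {
        "R_minus": -np.exp(d["R_minus"]) if "R_minus" in d else 0.0,
        "eta0": float(_softplus(d["eta0"])) if "eta0" in d else 0.0,
        "nu_plus": np.exp(d.get("nu_plus", np.log(0.2))),
        "nu_minus": np.exp(d.get("nu_minus", np.log(0.2))),
        "gamma": np.exp(d.get("gamma", np.log(0.05))),
        "sigma": np.exp(d.get("sigma", np.log(0.5))),
    }
    if "C" in d:
        base = ModelParams(C=0.0, **kw)
        kw["C"] = float(stability_bound(base) * expit(d["C"]))
    else:
        kw["C"] = 0.0
    return ModelParams(**kw)


# ---------------------------------------------------------------------------
# likelihood

@dataclass(frozen=True)
class _Counts:
    """Choice counts aggregated by unique task condition (fast likelihood)."""

    q: np.ndarray
    T: np.ndarray
    n_info: np.ndarray
    n_noinfo: np.ndarray

    @property
    def n_trials(self) -> int:
        return int(self.n_info.sum() + self.n_noinfo.sum())


INFO_CHOICE = 1  # coding of the immediate-information choice in trial tables

try:  # JIT-compiled likelihood kernel; pure-numpy fallback below
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None


def _nll_kernel_py(Rm, eta0, C, nup, num, gam, sig, q, T, n_info, n_noinfo,
                   floor):
    """Bernoulli log likelihood over aggregated conditions (R+ fixed at 1).

    Scalar re-statement of the closed-form value computation, written so it
    can be JIT compiled; equality with the numpy path is asserted in tests.
    """
    total = 0.0
    for i in range(q.shape[0]):
        t = T[i]
        qq = q[i]
        eg = np.exp(-gam * t)
        if abs(nup - gam) < 1e-9:
            a_plus = t * eg
        else:
            a_plus = (eg - np.exp(-nup * t)) / (nup - gam)
        if abs(num - gam) < 1e-9:
            a_minus = Rm * t * eg
        else:
            a_minus = Rm * (eg - np.exp(-num * t)) / (num - gam)
        b_plus = eg
        b_minus = Rm * eg
        numer = eta0 * (a_plus - a_minus) + b_plus - b_minus
        denom = 1.0 - C * ((1.0 - qq) * a_plus - qq * a_minus)
        if denom <= 0.0:
            return -1e15
        d_plus = (1.0 - qq) * numer / denom
        d_minus = -qq * numer / denom
        q_sp = (eta0 + C * abs(d_plus)) * a_plus + b_plus
        q_sm = (eta0 + C * abs(d_minus)) * a_minus + b_minus
        v_ii = qq * q_sp + (1.0 - qq) * q_sm
        v_ni = (eta0 * (qq * a_plus + (1.0 - qq) * a_minus)
                + qq * b_plus + (1.0 - qq) * b_minus)
        z = (v_ii - v_ni) / sig
        if z >= 0.0:
            logp = -np.log1p(np.exp(-z))
            log1mp = -z + logp
        else:
            log1mp = -np.log1p(np.exp(z))
            logp = z + log1mp
        if logp < floor:
            logp = floor
        if log1mp < floor:
            log1mp = floor
        total += n_info[i] * logp + n_noinfo[i] * log1mp
    return total


_nll_kernel = _njit(cache=False)(_nll_kernel_py) if _njit else _nll_kernel_py


def _aggregate(trials: pd.DataFrame) -> _Counts:
    for c in ("q", "T_s", "choice"):
        if c not in trials.columns:
            raise ValueError(f"trial table missing column {c!r}")
    g = trials.groupby(["q", "T_s"])["choice"].agg(["sum", "count"])
    q = g.index.get_level_values("q").to_numpy(dtype=float)
    T = g.index.get_level_values("T_s").to_numpy(dtype=float)
    n_info = g["sum"].to_numpy(dtype=float)
    return _Counts(q=q, T=T, n_info=n_info,
                   n_noinfo=g["count"].to_numpy(dtype=float) - n_info)


def _counts_log_likelihood(counts: _Counts, params: ModelParams) -> float:
    if params.R_plus == 1.0:
        return float(_nll_kernel(
            params.R_minus, params.eta0, params.C, params.nu_plus,
            params.nu_minus, params.gamma, params.sigma,
            counts.q, counts.T, counts.n_info, counts.n_noinfo,
            _LOG_LIK_FLOOR))
    p = np.asarray(choice_probability(params, (counts.q, counts.T)))
    logp = np.maximum(np.log(np.clip(p, 1e-300, None)), _LOG_LIK_FLOOR)
    log1mp = np.maximum(np.log(np.clip(1.0 - p, 1e-300, None)), _LOG_LIK_FLOOR)
    return float(counts.n_info @ logp + counts.n_noinfo @ log1mp)


def subject_log_likelihood(trials: pd.DataFrame, params: ModelParams) -> float:
    """Bernoulli log likelihood of one subject's choices under the model.

    Each trial contributes log p or log(1-p) with p the model's probability
    of the immediate-information choice for that trial's condition; per-trial
    terms are floored at log(1e-12).
    """
    return _counts_log_likelihood(_aggregate(trials), params)


# ---------------------------------------------------------------------------
# E step

@dataclass(frozen=True)
class GroupPrior:
    """Diagonal Gaussian population distribution over h-space parameters."""

    mean: np.ndarray
    var: np.ndarray
    spec: ModelSpec = FULL_MODEL

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "var", np.asarray(self.var, dtype=float))
        if self.mean.shape != (self.spec.n_free,) or \
                self.var.shape != (self.spec.n_free,):
            raise ValueError("prior dimension mismatch with model spec")
        if np.any(self.var <= 0):
            raise ValueError("prior variances must be positive")

    def log_pdf(self, h) -> float:
        z = (np.asarray(h) - self.mean)
        return float(-0.5 * np.sum(z * z / self.var)
                     - 0.5 * np.sum(np.log(2 * np.pi * self.var)))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.normal(self.mean, np.sqrt(self.var),
                          size=(size, self.spec.n_free))

    def mean_params(self) -> ModelParams:
        return untransform_params(self.mean, self.spec)


def default_prior(spec: ModelSpec = FULL_MODEL) -> GroupPrior:
    """Broad starting prior: mild discounting and anticipation rates, a
    boosting gain at a fifth of its stability bound, unit h-space variances."""
    base = ModelParams(R_minus=-0.5, eta0=0.5, C=0.0, nu_plus=0.2,
                       nu_minus=0.2, gamma=0.05, sigma=0.5)
    base = base.replace(C=0.2 * stability_bound(base))
    mean = transform_params(base, spec)
    return GroupPrior(mean=mean, var=np.ones(spec.n_free), spec=spec)


@dataclass
class FitConfig:
    """Optimizer, Laplace and EM controls (all unit-free)."""

    n_starts: int = 10          # optimizer restarts per subject, drawn from the prior
    optimizer_maxiter: int = 200
    hess_rel_step: float = 1e-4
    ridge: float = 1e-6
    em_tol: float = 1e-3        # max |change| of the group mean
    em_max_iter: int = 200
    var_floor: float = 1e-6


@dataclass
class SubjectFit:
    """MAP estimate with Laplace covariance for one subject."""

    subject: object
    h_map: np.ndarray
    cov: np.ndarray
    log_posterior: float
    log_likelihood: float
    params: ModelParams


def _h_to_natural(h, spec: ModelSpec) -> tuple:
    """Fast scalar version of :func:`untransform_params` used in the
    optimizer's inner loop; returns (R-, eta0, C, nu+, nu-, gamma, sigma)."""
    import math
    from .core import _branch_bound
    d = dict(zip(spec.free, h))
    r_minus = -math.exp(d["R_minus"]) if "R_minus" in d else 0.0
    if "eta0" in d:
        x = d["eta0"]
        eta0 = x if x > 30 else math.log1p(math.exp(x))
    else:
        eta0 = 0.0
    nu_plus = math.exp(d.get("nu_plus", np.log(0.2)))
    nu_minus = math.exp(d.get("nu_minus", np.log(0.2)))
    gamma = math.exp(d.get("gamma", np.log(0.05)))
    sigma = math.exp(d.get("sigma", np.log(0.5)))
    if "C" in d:
        cmax = min(_branch_bound(1.0, nu_plus, gamma),
                   _branch_bound(r_minus, nu_minus, gamma))
        x = d["C"]
        frac = 1.0 / (1.0 + math.exp(-x)) if x > -30 else math.exp(x)
        c = cmax * frac
    else:
        c = 0.0
    return r_minus, eta0, c, nu_plus, nu_minus, gamma, sigma


def _neg_log_posterior(h, counts: _Counts, prior: GroupPrior) -> float:
    h = np.asarray(h, dtype=float)
    if np.max(np.abs(h)) > 60:  # far outside any plausible prior support
        return 1e10 * float(np.max(np.abs(h)))
    r_minus, eta0, c, nu_plus, nu_minus, gamma, sigma = \
        _h_to_natural(h, prior.spec)
    ll = _nll_kernel(r_minus, eta0, c, nu_plus, nu_minus, gamma, sigma,
                     counts.q, counts.T, counts.n_info, counts.n_noinfo,
                     _LOG_LIK_FLOOR)
    return -(ll + prior.log_pdf(h))


def _numerical_hessian(f, x, rel_step: float) -> np.ndarray:
    n = len(x)
    steps = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = steps[i]
        fpp = f(x + ei); fmm = f(x - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / steps[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = steps[j]
            fij = f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            H[i, j] = H[j, i] = fij / (4 * steps[i] * steps[j])
    return H


def _laplace_cov(f, x, rel_step: float, ridge: float,
                 prior_var: np.ndarray | None = None) -> np.ndarray:
    """Inverse Hessian of the negative log posterior, regularized to
    positive definiteness.

    When the prior variances are known, the likelihood part of the curvature
    (Hessian minus the prior precision) is projected onto the PSD cone before
    inverting: the exact posterior precision can never fall below the prior
    precision, and the projection keeps flat likelihood directions from
    producing exploding covariances.
    """
    H = _numerical_hessian(f, x, rel_step)
    H = 0.5 * (H + H.T)
    eye = np.eye(len(x))
    if prior_var is not None:
        D = np.diag(1.0 / np.asarray(prior_var, dtype=float))
        A = H - D
        w, V = np.linalg.eigh(A)
        H = (V * np.clip(w, 0.0, None)) @ V.T + D
    lam = ridge
    for _ in range(40):
        try:
            cov = np.linalg.inv(H + lam * eye)
            if np.all(np.linalg.eigvalsh(cov) > 0):
                return 0.5 * (cov + cov.T)
        except np.linalg.LinAlgError:
            pass
        lam *= 10.0
    raise RuntimeError("could not regularize Hessian to positive definiteness")


def fit_subject_map(trials: pd.DataFrame, prior: GroupPrior,
                    config: FitConfig | None = None,
                    rng: np.random.Generator | None = None,
                    extra_starts=()) -> SubjectFit:
    """MAP estimate of one subject's h-space parameters under the prior.

    Multi-start quasi-Newton (L-BFGS-B) on the negative log posterior; the
    posterior covariance is the ridge-regularized inverse Hessian at the MAP
    (Laplace approximation).  With zero trials the posterior equals the
    prior and is returned without optimization.
    """
    config = config or FitConfig()
    rng = rng or np.random.default_rng()
    subject = trials["subject"].iloc[0] if ("subject" in trials.columns
                                            and len(trials)) else None
    if len(trials) == 0:
        params = untransform_params(prior.mean, prior.spec)
        return SubjectFit(subject, prior.mean.copy(), np.diag(prior.var),
                          prior.log_pdf(prior.mean), 0.0, params)
    counts = _aggregate(trials)
    nlp = lambda h: _neg_log_posterior(h, counts, prior)

    starts = [prior.mean] + [np.asarray(s, dtype=float) for s in extra_starts]
    n_random = max(0, config.n_starts - len(starts))
    if n_random:
        starts += list(prior.sample(rng, n_random))
    best = None
    for s in starts:
        res = minimize(nlp, s, method="L-BFGS-B",
                       options={"maxiter": config.optimizer_maxiter})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("all optimizer starts failed")
    h_map = best.x
    cov = _laplace_cov(nlp, h_map, config.hess_rel_step, config.ridge,
                       prior_var=prior.var)
    params = untransform_params(h_map, prior.spec)
    ll = _counts_log_likelihood(counts, params)
    return SubjectFit(subject, h_map, cov, -best.fun, ll, params)


# ---------------------------------------------------------------------------
# M step and EM loop

def em_update(subject_fits, spec: ModelSpec = FULL_MODEL,
              var_floor: float = 1e-6) -> GroupPrior:
    """Population-moment update from the subjects' Laplace posteriors.

    mu = mean of MAPs; diagonal variance = mean(m^2 + diag Sigma) - mu^2,
    floored to stay positive.
    """
    ms = np.array([f.h_map for f in subject_fits])
    diags = np.array([np.diag(f.cov) for f in subject_fits])
    mu = ms.mean(axis=0)
    var = (ms ** 2 + diags).mean(axis=0) - mu ** 2
    return GroupPrior(mean=mu, var=np.maximum(var, var_floor), spec=spec)


@dataclass
class FitResult:
    """Converged (or stopped) hierarchical fit."""

    prior: GroupPrior
    subject_fits: list
    trace: list = field(default_factory=list)   # approximate marginal log lik per iter
    converged: bool = False
    n_iter: int = 0
    seed: int | None = None
    spec: ModelSpec = FULL_MODEL
    config: "FitConfig | None" = None

    @property
    def n_choices(self) -> int:
        return sum(getattr(f, "_n_trials", 0) for f in self.subject_fits)


def _approx_marginal(fits, prior: GroupPrior) -> float:
    """Laplace approximation of the marginal log likelihood of all data."""
    total = 0.0
    d = prior.spec.n_free
    for f in fits:
        sign, logdet = np.linalg.slogdet(f.cov)
        total += (f.log_likelihood + prior.log_pdf(f.h_map)
                  + 0.5 * d * np.log(2 * np.pi) + 0.5 * logdet)
    return total


def _split_subjects(data: pd.DataFrame) -> dict:
    if "subject" not in data.columns:
        raise ValueError("trial table needs a 'subject' column")
    return {s: g for s, g in data.groupby("subject", sort=True)}


def fit_hierarchical(data: pd.DataFrame, spec: ModelSpec = FULL_MODEL,
                     config: FitConfig | None = None,
                     seed: int | None = None,
                     init_prior: GroupPrior | None = None,
                     verbose: bool = False) -> FitResult:
    """Approximate EM over the population prior for a cohort trial table.

    ``data`` holds all subjects' trials (columns: subject, q, T_s, choice,
    ...).  Alternates per-subject MAP fits (E step, warm-started from the
    previous iteration's MAP) with the moment update (M step) until the
    group mean moves less than ``em_tol``.  Deterministic given ``seed``.
    """
    config = config or FitConfig()
    rng = np.random.default_rng(seed)
    groups = _split_subjects(data)
    if len(groups) < 2:
        raise ValueError("hierarchical fit needs at least 2 subjects")
    prior = init_prior or default_prior(spec)
    if prior.spec.n_free != spec.n_free:
        raise ValueError("initial prior does not match the model spec")

    fits = None
    trace = []
    converged = False
    it = 0
    for it in range(1, config.em_max_iter + 1):
        new_fits = []
        for sid, trials in groups.items():
            extra = ()
            if fits is not None:
                extra = (next(f.h_map for f in fits if f.subject == sid),)
            f = fit_subject_map(trials, prior, config, rng, extra_starts=extra)
            f._n_trials = len(trials)
            new_fits.append(f)
        fits = new_fits
        trace.append(_approx_marginal(fits, prior))
        if not np.all(np.isfinite(prior.mean)) or not np.all(np.isfinite(prior.var)):
            raise RuntimeError(f"EM diverged (non-finite prior); trace={trace}")
        new_prior = em_update(fits, spec, config.var_floor)
        delta = np.max(np.abs(new_prior.mean - prior.mean))
        if verbose:
            print(f"EM iter {it}: marginal={trace[-1]:.2f} delta_mu={delta:.2e}")
        prior = new_prior
        if delta < config.em_tol:
            converged = True
            break
    return FitResult(prior=prior, subject_fits=fits, trace=trace,
                     converged=converged, n_iter=it, seed=seed, spec=spec,
                     config=config)


# ---------------------------------------------------------------------------
# Model / Results facade

TRIAL_COLUMNS = ("subject", "run", "trial", "q", "T_s", "choice", "outcome")


def read_trial_table(path) -> pd.DataFrame:
    """Read a tab-delimited cohort trial table with a one-line header."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("subject", "q", "T_s", "choice") if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    return df


class AnticipationChoiceModel:
    """Hierarchical anticipatory-utility choice model for a cohort.

    Parameters
    ----------
    data : DataFrame
        Trial-level table with at least subject, q, T_s and choice columns
        (choice coded 1 for the immediate-information target).
    spec : ModelSpec
        Which model variant to fit (full, no_boost, no_anticipation).

    Examples
    --------
    >>> model = AnticipationChoiceModel(trials)          # doctest: +SKIP
    >>> results = model.fit(seed=0)                      # doctest: +SKIP
    >>> print(results.summary())                         # doctest: +SKIP
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec = FULL_MODEL):
        if "choice" not in data.columns or data["choice"].isna().any():
            raise ValueError("trial table must contain observed choices")
        self.data = data
        self.spec = spec
        self.n_subjects = data["subject"].nunique()
        self.n_choices = len(data)

    @classmethod
    def from_csv(cls, path, spec: ModelSpec = FULL_MODEL):
        return cls(read_trial_table(path), spec)

    def fit(self, config: FitConfig | None = None, seed: int | None = None,
            init_prior: GroupPrior | None = None,
            verbose: bool = False) -> "HierarchicalFitResults":
        raw = fit_hierarchical(self.data, self.spec, config, seed,
                               init_prior, verbose)
        return HierarchicalFitResults(self, raw)


class HierarchicalFitResults:
    """Results of a hierarchical fit: population prior, subject fits,
    diagnostics, and derived quantities."""

    def __init__(self, model: AnticipationChoiceModel, raw: FitResult):
        self.model = model
        self.raw = raw
        self.prior = raw.prior
        self.subject_fits = raw.subject_fits
        self.converged = raw.converged
        self.n_iter = raw.n_iter
        self.trace = raw.trace
        self.spec = raw.spec

    @property
    def group_mean_h(self) -> np.ndarray:
        return self.prior.mean

    @property
    def group_var_h(self) -> np.ndarray:
        return self.prior.var

    def params_table(self) -> pd.DataFrame:
        """Per-subject MAP parameters on the natural scale."""
        rows = []
        for f in self.subject_fits:
            row = {"subject": f.subject}
            row.update({n: getattr(f.params, n) for n in PARAM_NAMES})
            row["log_likelihood"] = f.log_likelihood
            rows.append(row)
        return pd.DataFrame(rows)

    def group_table(self) -> pd.DataFrame:
        natural = self.prior.mean_params()
        return pd.DataFrame({
            "parameter": list(self.spec.free),
            "h_mean": self.prior.mean,
            "h_var": self.prior.var,
            "natural_at_mean": [getattr(natural, p) for p in self.spec.free],
        })

    def predicted_choice_rates(self) -> pd.DataFrame:
        """Model-predicted info-choice probability per subject and condition."""
        rows = []
        for f in self.subject_fits:
            trials = self.model.data[self.model.data["subject"] == f.subject]
            for (q, T), _ in trials.groupby(["q", "T_s"]):
                rows.append({"subject": f.subject, "q": q, "T_s": T,
                             "p_info": choice_probability(f.params, (q, T))})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Hierarchical anticipatory-utility choice model",
            f"  variant: {self.spec.name}  "
            f"(free parameters: {', '.join(self.spec.free)})",
            f"  subjects: {self.model.n_subjects}   "
            f"choices: {self.model.n_choices}",
            f"  EM iterations: {self.n_iter}   converged: {self.converged}",
            f"  approx. marginal log-likelihood: {self.trace[-1]:.2f}",
            "",
            self.group_table().to_string(index=False,
                                         float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)

    def plot_preference_fit(self, ax=None):
        """Observed vs model-predicted info-choice rate by delay level."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        obs = self.model.data.groupby("T_s")["choice"].mean()
        pred = self.predicted_choice_rates().groupby("T_s")["p_info"].mean()
        ax.plot(obs.index, obs.values, "ko-", label="observed")
        ax.plot(pred.index, pred.values, "bs--", label="model")
        ax.set_xlabel("delay T (s)")
        ax.set_ylabel("p(immediate information)")
        ax.set_ylim(0, 1)
        ax.legend()
        return ax

    def to_json(self) -> dict:
        return {
            "spec": self.spec.name,
            "free": list(self.spec.free),
            "group_mean_h": self.prior.mean.tolist(),
            "group_var_h": self.prior.var.tolist(),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "trace": [float(v) for v in self.trace],
            "seed": self.raw.seed,
            "config": vars(self.raw.config) if self.raw.config else None,
            "subjects": [
                {"subject": str(f.subject),
                 "h_map": f.h_map.tolist(),
                 "log_likelihood": float(f.log_likelihood)}
                for f in self.subject_fits
            ],
        }
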