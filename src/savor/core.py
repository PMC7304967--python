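"""Closed-form value computation for the boosted-anticipation choice model.

The model assigns value to a cue predicting a delayed outcome as the sum of
(i) anticipatory utility consumed while waiting ("savoring") and (ii) the
temporally discounted value of the outcome itself.  The weight on
anticipation is not constant: it is boosted above its baseline ``eta0`` in
proportion to the absolute anticipation-plus-reward prediction error (aRPE)
at the cue, with gain ``C``.  Because the aRPE itself depends on the boosted
cue values, the aRPE must be found self-consistently; with a linear boosting
rule this has a closed-form solution whenever the gain stays below a
stability bound.

All condition-wise functions accept a :class:`Condition`, a ``(q, T)`` tuple
of scalars, or a tuple of equal-length arrays, and broadcast accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ModelParams",
    "Condition",
    "ArpePair",
    "InvalidParameterError",
    "StabilityViolationError",
    "ConvergenceError",
    "anticipation_coefficient",
    "discounted_outcome",
    "stability_bound",
    "solve_arpe",
    "arpe_fixed_point",
    "cue_value",
    "target_values",
    "value_difference",
    "choice_probability",
]

# Below this |nu - gamma| the removable singularity of the anticipation
# coefficient is replaced by its analytic limit R * T * exp(-gamma T).
NU_GAMMA_EPS = 1e-9


class InvalidParameterError(ValueError):
    """A model parameter is outside its admissible domain."""


class StabilityViolationError(RuntimeError):
    """The boosting gain C is too large for a self-consistent aRPE solution."""


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to converge."""


@dataclass(frozen=True)
class ModelParams:
    """Subject-level parameters of the anticipation model.

    Parameters
    ----------
    R_minus : float
        Value of the no-reward outcome (unitless, <= 0).
    eta0 : float
        Baseline anticipation weight (unitless, >= 0).
    C : float
        Boosting gain converting |aRPE| into extra anticipation weight
        (1/value, >= 0).  Must stay below :func:`stability_bound` for the
        self-consistent solution to exist.
    nu_plus, nu_minus : float
        Anticipation rates for the positive / negative domain (1/s, > 0).
        Larger values concentrate anticipation near the outcome.
    gamma : float
        Exponential discount rate, shared across valences (1/s, >= 0).
    sigma : float
        Choice noise (temperature) of the sigmoid (value units, > 0).
    R_plus : float
        Value of the reward outcome; fixed to 1 without loss of generality.
    """

    R_minus: float = -0.5
    eta0: float = 0.5
    C: float = 0.0
    nu_plus: float = 0.2
    nu_minus: float = 0.2
    gamma: float = 0.05
    sigma: float = 0.5
    R_plus: float = 1.0

    def __post_init__(self):
        vals = [self.R_minus, self.eta0, self.C, self.nu_plus,
                self.nu_minus, self.gamma, self.sigma, self.R_plus]
        if not all(np.isfinite(v) for v in vals):
            raise InvalidParameterError(f"non-finite parameter in {vals}")
        if self.R_minus > 0:
            raise InvalidParameterError("R_minus must be <= 0")
        if self.R_plus <= 0:
            raise InvalidParameterError("R_plus must be > 0")
        if self.eta0 < 0:
            raise InvalidParameterError("eta0 must be >= 0")
        if self.C < 0:
            raise InvalidParameterError("C must be >= 0")
        if self.nu_plus <= 0 or self.nu_minus <= 0:
            raise InvalidParameterError("anticipation rates must be > 0")
        if self.gamma < 0:
            raise InvalidParameterError("gamma must be >= 0")
        if self.sigma <= 0:
            raise InvalidParameterError("sigma must be > 0")

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    def is_stable(self) -> bool:
        """Whether C is strictly below the stability bound."""
        return self.C < stability_bound(self)


@dataclass(frozen=True)
class Condition:
    """One task condition: reward probability ``q`` and delay ``T`` (s)."""

    q: float
    T: float

    def __post_init__(self):
        if not (0.0 <= self.q <= 1.0):
            raise InvalidParameterError(f"q={self.q} outside [0, 1]")
        if not self.T > 0:
            raise InvalidParameterError(f"T={self.T} must be > 0")


@dataclass(frozen=True)
class ArpePair:
    """Self-consistent aRPEs at the two predictive cues.

    ``delta_plus`` (>= 0) is elicited by the reward-predictive cue,
    ``delta_minus`` (<= 0) by the no-reward-predictive cue.  They satisfy
    q * delta_plus + (1 - q) * delta_minus = 0 for the generating q.
    """

    delta_plus: float | np.ndarray
    delta_minus: float | np.ndarray


def _cond_qt(cond):
    """Accept Condition, (q, T) scalars or arrays; return broadcastable q, T."""
    if isinstance(cond, Condition):
        return cond.q, cond.T
    q, T = cond
    q = np.asarray(q, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(q < 0) or np.any(q > 1):
        raise InvalidParameterError("q outside [0, 1]")
    if np.any(T < 0):
        raise InvalidParameterError("negative delay")
    if q.ndim == 0:
        q = float(q)
    if T.ndim == 0:
        T = float(T)
    return q, T


def _valence(params: ModelParams, valence: str):
    if valence in ("+", "plus", "pos"):
        return params.R_plus, params.nu_plus
    if valence in ("-", "minus", "neg"):
        return params.R_minus, params.nu_minus
    raise ValueError(f"valence must be '+' or '-', got {valence!r}")


def _A(R: float, nu: float, gamma: float, T):
    """Anticipation coefficient A = R/(nu-gamma) (e^{-gamma T} - e^{-nu T})."""
    T = np.asarray(T, dtype=float)
    if abs(nu - gamma) < NU_GAMMA_EPS:
        out = R * T * np.exp(-gamma * T)
    else:
        out = R / (nu - gamma) * (np.exp(-gamma * T) - np.exp(-nu * T))
    return out if out.ndim else float(out)


def anticipation_coefficient(params: ModelParams, T, valence: str = "+"):
    """Total anticipatory utility accrued over a waiting period of length T.

    This is the discounted integral of the anticipation urgency signal over
    the full delay, per unit anticipation weight.  At the removable
    singularity nu == gamma the analytic limit R * T * exp(-gamma T) is used.
    """
    R, nu = _valence(params, valence)
    return _A(R, nu, params.gamma, T)


def discounted_outcome(params: ModelParams, T, valence: str = "+"):
    """Discounted outcome value B = R * exp(-gamma T)."""
    R, _ = _valence(params, valence)
    T = np.asarray(T, dtype=float)
    out = R * np.exp(-params.gamma * T)
    return out if out.ndim else float(out)


def _branch_bound(R: float, nu: float, gamma: float) -> float:
    """Supremum of admissible C from one valence branch: 1 / max_T |A(T)|."""
    if R == 0:
        return np.inf
    R = abs(R)
    if gamma == 0:
        # |A| increases to R/nu as T -> infinity
        return nu / R
    if abs(nu - gamma) < NU_GAMMA_EPS:
        # A = R T e^{-gamma T}, maximal at T = 1/gamma
        return gamma * np.e / R
    return gamma / R * (gamma / nu) ** (nu / (gamma - nu))


def stability_bound(params: ModelParams) -> float:
    """Largest boosting gain with a stable self-consistent aRPE solution.

    The aRPE denominator 1 - C((1-q)A+ - q A-) must stay positive for every
    probability and delay; the binding cases are q=1 (|A-| maximal over T)
    and q=0 (A+ maximal over T), giving the minimum over the two valence
    branches.  A+ peaks at T = ln(gamma/nu+)/(gamma - nu+).
    """
    return min(
        _branch_bound(params.R_plus, params.nu_plus, params.gamma),
        _branch_bound(params.R_minus, params.nu_minus, params.gamma),
    )


def _arpe_parts(params: ModelParams, q, T):
    """Numerator and denominator of the closed-form aRPE solution."""
    A_plus = _A(params.R_plus, params.nu_plus, params.gamma, T)
    A_minus = _A(params.R_minus, params.nu_minus, params.gamma, T)
    B_plus = params.R_plus * np.exp(-params.gamma * np.asarray(T, dtype=float))
    B_minus = params.R_minus * np.exp(-params.gamma * np.asarray(T, dtype=float))
    num = params.eta0 * (A_plus - A_minus) + B_plus - B_minus
    den = 1.0 - params.C * ((1.0 - np.asarray(q)) * A_plus - np.asarray(q) * A_minus)
    return A_plus, A_minus, B_plus, B_minus, num, den


def solve_arpe(params: ModelParams, cond) -> ArpePair:
    """Closed-form self-consistent aRPE at the two predictive cues.

    delta+ = (1-q) * N / D and delta- = -q * N / D, where
    N = eta0 (A+ - A-) + B+ - B- and D = 1 - C((1-q)A+ - q A-).

    Raises
    ------
    StabilityViolationError
        If the denominator D is not strictly positive (gain above the
        stability bound at this condition).
    """
    q, T = _cond_qt(cond)
    *_, num, den = _arpe_parts(params, q, T)
    if np.any(np.asarray(den) <= 0):
        raise StabilityViolationError(
            f"aRPE denominator non-positive (C={params.C} too large)")
    dplus = (1.0 - q) * num / den
    dminus = -q * num / den
    if np.ndim(dplus) == 0:
        dplus, dminus = float(dplus), float(dminus)
    return ArpePair(dplus, dminus)


def arpe_fixed_point(params: ModelParams, cond, tol: float = 1e-12,
                     max_iter: int = 10000) -> ArpePair:
    """Self-consistent aRPE by direct fixed-point iteration.

    Iterates the coupled pre-reduction map (cue values recomputed from the
    current aRPE estimate) from delta = 0 with no damping.  Serves as an
    independent oracle for :func:`solve_arpe`; convergence failure signals a
    stability violation or an over-tight tolerance.
    """
    q, T = _cond_qt(cond)
    A_plus, A_minus, B_plus, B_minus, _, _ = _arpe_parts(params, q, T)
    dplus = np.zeros_like(np.asarray(q, dtype=float) * np.asarray(T, dtype=float))
    dminus = np.zeros_like(dplus)
    for _ in range(max_iter):
        q_plus = (params.eta0 + params.C * np.abs(dplus)) * A_plus + B_plus
        q_minus = (params.eta0 + params.C * np.abs(dminus)) * A_minus + B_minus
        new_plus = (1.0 - q) * (q_plus - q_minus)
        new_minus = -q * (q_plus - q_minus)
        change = max(np.max(np.abs(new_plus - dplus)),
                     np.max(np.abs(new_minus - dminus)))
        dplus, dminus = new_plus, new_minus
        if change < tol:
            if np.ndim(dplus) == 0:
                return ArpePair(float(dplus), float(dminus))
            return ArpePair(dplus, dminus)
    raise ConvergenceError(
        f"aRPE fixed point did not converge in {max_iter} iterations "
        "(unstable gain or tolerance too small)")


def cue_value(params: ModelParams, cond, cue: str):
    """Total value of a predictive cue: boosted anticipation plus outcome.

    Q = (eta0 + C |delta|) * A + B for cue 'S+' (reward-predictive) or 'S-'
    (no-reward-predictive), with delta the self-consistent aRPE.
    """
    q, T = _cond_qt(cond)
    A_plus, A_minus, B_plus, B_minus, _, _ = _arpe_parts(params, q, T)
    pair = solve_arpe(params, (q, T))
    if cue in ("S+", "plus", "+"):
        return (params.eta0 + params.C * np.abs(pair.delta_plus)) * A_plus + B_plus
    if cue in ("S-", "minus", "-"):
        return (params.eta0 + params.C * np.abs(pair.delta_minus)) * A_minus + B_minus
    raise ValueError(f"cue must be 'S+' or 'S-', got {cue!r}")


def target_values(params: ModelParams, cond):
    """Values of the immediate-information and no-information targets.

    V_II averages the two boosted cue values by their probabilities; V_NI
    carries probability-scaled, unboosted anticipation (the non-predictive
    cue elicits no prediction error) plus the expected discounted outcome.
    """
    q, T = _cond_qt(cond)
    A_plus, A_minus, B_plus, B_minus, _, _ = _arpe_parts(params, q, T)
    pair = solve_arpe(params, (q, T))
    q_splus = (params.eta0 + params.C * np.abs(pair.delta_plus)) * A_plus + B_plus
    q_sminus = (params.eta0 + params.C * np.abs(pair.delta_minus)) * A_minus + B_minus
    v_ii = q * q_splus + (1.0 - q) * q_sminus
    v_ni = (params.eta0 * (q * A_plus + (1.0 - q) * A_minus)
            + q * B_plus + (1.0 - q) * B_minus)
    return v_ii, v_ni


def value_difference(params: ModelParams, cond):
    """V_II - V_NI, the decision variable of the choice sigmoid."""
    v_ii, v_ni = target_values(params, cond)
    return v_ii - v_ni


def choice_probability(params: ModelParams, cond):
    """Probability of choosing the immediate-information target.

    p = sigmoid((V_II - V_NI) / sigma), the temperature convention: large
    sigma approaches indifference.
    """
    from scipy.special import expit
    dv = value_difference(params, cond)
    out = expit(np.asarray(dv, dtype=float) / params.sigma)
    return float(out) if out.ndim == 0 else out
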