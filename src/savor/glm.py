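"""Mass-univariate GLM fitting and the Fourier phase-randomization FWE test.

Slowly varying model regressors (value-like signals) are prone to spurious
correlations with slowly varying noise.  The phase-randomization test builds
a null distribution that preserves each regressor's power spectrum: the
tested regressor is Fourier-transformed, its phases are redrawn uniformly,
and the whole GLM is refit; second-level group statistics assembled from
random scrambles, reduced to the maximum across the channel family, give a
familywise-error-corrected p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signals import DesignMatrix

__all__ = [
    "GLMResult",
    "PermTestConfig",
    "FWETestResult",
    "fit_glm",
    "phase_scramble",
    "randomization_fwe_test",
]


@dataclass
class GLMResult:
    """Per-channel ordinary-least-squares estimates.

    ``params`` is (n_columns, n_channels); ``tvalues`` covers only the tested
    columns (rows ordered as ``tested``).
    """

    columns: list
    tested: list
    params: np.ndarray
    tvalues: np.ndarray
    resid_var: np.ndarray
    dof: int

    def beta(self, name: str) -> np.ndarray:
        return self.params[self.columns.index(name)]

    def t(self, name: str) -> np.ndarray:
        return self.tvalues[self.tested.index(name)]


def _design_array(X):
    if isinstance(X, DesignMatrix):
        return X.frame.to_numpy(), list(X.frame.columns)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])]


def _name_collinear(X: np.ndarray, names: list) -> list:
    """Columns implicated in a rank deficiency, via pivoted QR."""
    from scipy.linalg import qr
    _, r, piv = qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    tol = d.max() * max(X.shape) * np.finfo(float).eps
    return [names[p] for p in piv[d < tol]] or [names[p] for p in piv[X.shape[1] - 1:]]


def fit_glm(Y, X, tested=None) -> GLMResult:
    """Ordinary least squares of each channel on the design matrix.

    Parameters
    ----------
    Y : array (n_scans, n_channels) or (n_scans,)
    X : DesignMatrix, DataFrame or array (n_scans, n_columns)
    tested : sequence of column names to compute t-statistics for; defaults
        to the design's non-nuisance columns (all columns for raw arrays).

    Returns t = beta / se(beta) with se from the unbiased residual variance,
    per channel.
    """
    Xa, names = _design_array(X)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != Xa.shape[0]:
        raise ValueError("row counts of data and design differ")
    n, p = Xa.shape
    rank = np.linalg.matrix_rank(Xa)
    if rank < p:
        raise np.linalg.LinAlgError(
            f"design is rank deficient; collinear columns: "
            f"{_name_collinear(Xa, names)}")
    dof = n - p
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    if tested is None:
        tested = X.tested_columns() if isinstance(X, DesignMatrix) else names
    tested = list(tested)
    missing = [c for c in tested if c not in names]
    if missing:
        raise ValueError(f"tested columns not in design: {missing}")

    xtx_inv = np.linalg.inv(Xa.T @ Xa)
    beta = xtx_inv @ Xa.T @ Y
    resid = Y - Xa @ beta
    resid_var = (resid ** 2).sum(axis=0) / dof
    idx = [names.index(c) for c in tested]
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.outer(np.diag(xtx_inv)[idx], resid_var))
        tvals = np.where(se > 0, beta[idx] / se, 0.0)
    return GLMResult(columns=names, tested=tested, params=beta,
                     tvalues=tvals, resid_var=resid_var, dof=dof)


def phase_scramble(series, rng: np.random.Generator) -> np.ndarray:
    """Surrogate series with identical power spectrum and random phases.

    Phases of the positive-frequency components are redrawn uniformly on
    (-pi, pi]; the DC component (and the Nyquist term for even lengths) is
    kept real so the inverse transform is exactly real-valued.  The mean and
    the amplitude spectrum of the input are preserved.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    n = len(x)
    f = np.fft.rfft(x)
    # indices 1..m get random phases; DC (0) and the even-length Nyquist
    # term (last) stay untouched
    last = len(f) - 1 if n % 2 == 0 else len(f)
    m = last - 1
    if m > 0:
        phases = rng.uniform(-np.pi, np.pi, size=m)
        f[1:last] = np.abs(f[1:last]) * np.exp(1j * phases)
    return np.fft.irfft(f, n=n)


@dataclass
class PermTestConfig:
    """Scramble and resampling counts for the randomization test."""

    n_scrambles: int = 100     # per-subject phase scrambles of the tested column
    n_resamples: int = 1000    # second-level null assemblies
    family: list | None = None  # channel indices forming the FWE family
    statistic: str = "max"     # 'max' over the family, or 'cluster_mean'


@dataclass
class FWETestResult:
    """Observed group statistics and the max-statistic null distribution."""

    tested: str
    observed_t: np.ndarray          # per channel (or scalar for cluster_mean)
    null_max: np.ndarray            # one entry per second-level resample
    pvalues: np.ndarray             # FWE-corrected, per channel
    n_scrambles: int
    n_resamples: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "channel": np.arange(np.size(self.observed_t)),
            "observed_t": np.atleast_1d(self.observed_t),
            "fwe_p": np.atleast_1d(self.pvalues),
        })


def _one_sample_t(betas: np.ndarray, axis: int = 0) -> np.ndarray:
    n = betas.shape[axis]
    mean = betas.mean(axis=axis)
    sd = betas.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def randomization_fwe_test(Ys, designs, tested: str,
                           config: PermTestConfig | None = None,
                           rng: np.random.Generator | None = None,
                           ) -> FWETestResult:
    """Fourier phase-randomization test with max-statistic FWE correction.

    First level: for every subject the tested design column is phase
    scrambled ``n_scrambles`` times and the full GLM refit each time, all
    other columns untouched.  Second level: for each of ``n_resamples``
    assemblies one scrambled result is drawn per subject and a one-sample
    t-statistic across subjects is computed per channel; the maximum over
    the channel family enters the null distribution.  The FWE p-value per
    channel is (1 + #{null max >= observed t}) / (n_resamples + 1).

    Parameters
    ----------
    Ys : sequence of per-subject data arrays (n_scans, n_channels)
    designs : sequence of per-subject DesignMatrix/DataFrame/arrays
    tested : name of the regressor under test
    """
    config = config or PermTestConfig()
    rng = rng or np.random.default_rng()
    if len(Ys) != len(designs):
        raise ValueError("one design per subject required")
    if len(Ys) < 2:
        raise ValueError("at least 2 subjects required")
    if config.n_scrambles < 1:
        raise ValueError("scramble count must be >= 1")
    if config.n_resamples < 1:
        raise ValueError("resample count must be >= 1")

    observed_betas = []
    scrambled_betas = []
    for Y, X in zip(Ys, designs):
        Xa, names = _design_array(X)
        if tested not in names:
            raise ValueError(f"column {tested!r} not in design")
        j = names.index(tested)
        res = fit_glm(Y, Xa, tested=None)
        observed_betas.append(res.params[j])
        per_subject = np.empty((config.n_scrambles, observed_betas[-1].size))
        Xs = Xa.copy()
        for s in range(config.n_scrambles):
            Xs[:, j] = phase_scramble(Xa[:, j], rng)
            r = fit_glm(Y, Xs, tested=None)
            per_subject[s] = r.params[j]
        scrambled_betas.append(per_subject)
    observed_betas = np.asarray(observed_betas)           # (subj, ch)
    scrambled = np.asarray(scrambled_betas)               # (subj, scr, ch)
    n_subj, _, n_ch = scrambled.shape

    family = (np.asarray(config.family, dtype=int)
              if config.family is not None else np.arange(n_ch))

    observed_t = _one_sample_t(observed_betas)            # (ch,)
    picks = rng.integers(0, config.n_scrambles,
                         size=(config.n_resamples, n_subj))
    null_max = np.empty(config.n_resamples)
    if config.statistic == "cluster_mean":
        obs_stat = _one_sample_t(observed_betas[:, family].mean(axis=1)[:, None])
        observed_stat = np.atleast_1d(obs_stat)[0]
        for r in range(config.n_resamples):
            draw = scrambled[np.arange(n_subj), picks[r]][:, family].mean(axis=1)
            null_max[r] = _one_sample_t(draw[:, None])[0]
        pvals = np.array([(1 + np.sum(null_max >= observed_stat))
                          / (config.n_resamples + 1)])
        return FWETestResult(tested, np.array([observed_stat]), null_max,
                             pvals, config.n_scrambles, config.n_resamples)

    for r in range(config.n_resamples):
        draw = scrambled[np.arange(n_subj), picks[r]]     # (subj, ch)
        null_max[r] = _one_sample_t(draw)[family].max()
    pvals = (1 + (null_max[None, :] >= observed_t[:, None]).sum(axis=1)) \
        / (config.n_resamples + 1)
    return FWETestResult(tested, observed_t, null_max, pvals,
                         config.n_scrambles, config.n_resamples)
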