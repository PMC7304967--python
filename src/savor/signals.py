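"""Model-predicted time courses and GLM design-matrix construction.

During a waiting period the model predicts three time-varying signals per
valence domain: the anticipatory utility (the discounted integral of future
anticipation), the anticipation urgency (anticipation before integration),
and the discounted outcome value (the conventional expected-value signal).
At cue onsets it predicts a condition-wise self-consistent aRPE.  These are
sampled on a fine microtime grid, convolved with a canonical double-gamma
hemodynamic response function and downsampled to the scan grid to form
regressors for a mass-univariate GLM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.stats import gamma as gamma_dist

from .core import ModelParams, _cond_qt, _A, solve_arpe, discounted_outcome

__all__ = [
    "SignalTimeCourse",
    "DesignConfig",
    "DesignMatrix",
    "anticipation_timecourse",
    "urgency_timecourse",
    "discounted_reward_timecourse",
    "arpe_event_amplitudes",
    "state_prediction_error",
    "standard_rpe",
    "canonical_hrf",
    "dct_highpass_basis",
    "build_design_matrix",
    "ppi_regressor",
    "read_event_table",
    "write_design_matrix",
]

CUE_LABELS = ("S+", "S-", "NI")


@dataclass(frozen=True)
class SignalTimeCourse:
    """A labelled signal sampled on a uniform time grid (seconds)."""

    t: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        if len(self.t) != len(self.values):
            raise ValueError("time grid and values must have equal length")


def _cue_scale_eta(params: ModelParams, q: float, T: float, cue: str,
                   valence: str):
    """(scale, eta, R, nu) for one cue/valence combination.

    Predictive cues carry boosted anticipation in their own domain only;
    the non-predictive cue carries unboosted anticipation in both domains,
    scaled by the probability of that domain's outcome.
    """
    if cue not in CUE_LABELS:
        raise ValueError(f"cue must be one of {CUE_LABELS}, got {cue!r}")
    pos = valence in ("+", "plus", "pos")
    R = params.R_plus if pos else params.R_minus
    nu = params.nu_plus if pos else params.nu_minus
    if cue == "NI":
        return (q if pos else 1.0 - q), params.eta0, R, nu
    if (cue == "S+") != pos:
        return 0.0, 0.0, R, nu
    pair = solve_arpe(params, (q, T))
    delta = pair.delta_plus if pos else pair.delta_minus
    return 1.0, params.eta0 + params.C * abs(delta), R, nu


def _window(t, T):
    t = np.asarray(t, dtype=float)
    return t, ((t >= 0) & (t <= T)).astype(float)


def anticipation_timecourse(params: ModelParams, cond, cue: str, t,
                            valence: str = "+") -> SignalTimeCourse:
    """Anticipatory utility remaining at time t of the waiting period.

    V_Ant(t) = R * eta / (nu - gamma) * (e^{-gamma(T-t)} - e^{-nu(T-t)}),
    with eta boosted for predictive cues and probability-scaled for the
    non-predictive cue.  t is measured from cue onset; the signal is zero
    outside [0, T] and vanishes at t = T.
    """
    q, T = _cond_qt(cond)
    scale, eta, R, nu = _cue_scale_eta(params, q, T, cue, valence)
    t, mask = _window(t, T)
    vals = scale * eta * _A(R, nu, params.gamma, np.maximum(T - t, 0.0)) * mask
    return SignalTimeCourse(t, np.asarray(vals, dtype=float),
                            f"anticipation[{cue},{valence}]")


def urgency_timecourse(params: ModelParams, cond, cue: str, t,
                       valence: str = "+") -> SignalTimeCourse:
    """Anticipation urgency a(t) = R * eta * e^{-nu(T-t)} on the waiting period."""
    q, T = _cond_qt(cond)
    scale, eta, R, nu = _cue_scale_eta(params, q, T, cue, valence)
    t, mask = _window(t, T)
    vals = scale * eta * R * np.exp(-nu * np.maximum(T - t, 0.0)) * mask
    return SignalTimeCourse(t, np.asarray(vals, dtype=float),
                            f"urgency[{cue},{valence}]")


def discounted_reward_timecourse(params: ModelParams, cond, cue: str, t,
                                 valence: str = "+") -> SignalTimeCourse:
    """Discounted outcome value R * e^{-gamma(T-t)} during the waiting period.

    After the non-predictive cue the signal is scaled by the outcome
    probability of the corresponding domain.
    """
    q, T = _cond_qt(cond)
    if cue not in CUE_LABELS:
        raise ValueError(f"cue must be one of {CUE_LABELS}, got {cue!r}")
    pos = valence in ("+", "plus", "pos")
    R = params.R_plus if pos else params.R_minus
    if cue == "NI":
        scale = q if pos else 1.0 - q
    else:
        scale = 1.0 if (cue == "S+") == pos else 0.0
    t, mask = _window(t, T)
    vals = scale * R * np.exp(-params.gamma * np.maximum(T - t, 0.0)) * mask
    return SignalTimeCourse(t, np.asarray(vals, dtype=float),
                            f"expected_value[{cue},{valence}]")


def arpe_event_amplitudes(params: ModelParams, cond) -> dict:
    """Self-consistent aRPE amplitude at each cue; the non-predictive cue
    elicits none."""
    pair = solve_arpe(params, cond)
    return {"S+": pair.delta_plus, "S-": pair.delta_minus, "NI": 0.0}


def state_prediction_error(cond, cue: str) -> float:
    """Unsigned state prediction error at a predictive cue: |outcome - q|."""
    q, _ = _cond_qt(cond)
    if cue == "S+":
        return abs(1.0 - q)
    if cue == "S-":
        return abs(0.0 - q)
    if cue == "NI":
        return 0.0
    raise ValueError(f"cue must be one of {CUE_LABELS}, got {cue!r}")


def standard_rpe(params: ModelParams, cond, cue: str) -> float:
    """Conventional reward prediction error, i.e. the aRPE with anticipation
    switched off (eta0 = C = 0): (1-q)(B+ - B-) at S+, -q(B+ - B-) at S-."""
    q, T = _cond_qt(cond)
    bdiff = discounted_outcome(params, T, "+") - discounted_outcome(params, T, "-")
    if cue == "S+":
        return (1.0 - q) * bdiff
    if cue == "S-":
        return -q * bdiff
    if cue == "NI":
        return 0.0
    raise ValueError(f"cue must be one of {CUE_LABELS}, got {cue!r}")


def canonical_hrf(dt: float, length: float = 32.0,
                  peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                  peak_disp: float = 1.0, undershoot_disp: float = 1.0,
                  ratio: float = 6.0, offset: float = 0.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response kernel.

    Difference of two gamma densities (response minus scaled undershoot),
    sampled every ``dt`` seconds over ``length`` seconds and normalised to
    unit integral.  Defaults give the familiar ~5 s peak with a late
    undershoot.  ``offset`` shifts the sample points (``offset=dt/2`` gives
    the midpoint-rule kernel used for convolution, accurate to second order
    in dt).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, length, dt) + offset
    h = (gamma_dist.pdf(t, peak_delay / peak_disp, scale=peak_disp)
         - gamma_dist.pdf(t, undershoot_delay / undershoot_disp,
                          scale=undershoot_disp) / ratio)
    return h / (h.sum() * dt)


def _hrf_bin_kernel(dt: float, length: float = 32.0, peak_delay: float = 6.0,
                    undershoot_delay: float = 16.0, peak_disp: float = 1.0,
                    undershoot_disp: float = 1.0, ratio: float = 6.0,
                    ) -> np.ndarray:
    """Bin-averaged canonical HRF for convolving microtime bin signals.

    K[m] is the kernel's average over [(m-1) dt, m dt] computed from the
    gamma CDFs, so that sum_k col[k] K[j-k] dt is the exact continuous
    convolution of a piecewise-constant signal with the canonical kernel.
    """
    edges = np.arange(0.0, length + dt, dt)
    F = (gamma_dist.cdf(edges, peak_delay / peak_disp, scale=peak_disp)
         - gamma_dist.cdf(edges, undershoot_delay / undershoot_disp,
                          scale=undershoot_disp) / ratio)
    F = F / F[-1]   # unit-integral kernel
    K = np.empty(len(edges))
    K[0] = 0.0
    K[1:] = np.diff(F) / dt
    return K


def dct_highpass_basis(n_scans: int, tr: float, cutoff: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift basis implementing a high-pass filter.

    Returns the non-constant low-frequency cosine regressors with period
    above ``cutoff`` seconds (columns may be empty for short runs).
    """
    duration = n_scans * tr
    order = int(np.floor(2.0 * duration / cutoff))
    n = np.arange(n_scans)
    cols = [np.sqrt(2.0 / n_scans) * np.cos(np.pi * (2 * n + 1) * k / (2 * n_scans))
            for k in range(1, order + 1)]
    return np.column_stack(cols) if cols else np.empty((n_scans, 0))


@dataclass
class DesignConfig:
    """Sampling and column options for design-matrix construction."""

    tr: float = 3.36               # repetition time (s)
    dt: float = 0.1                # microtime resolution (s)
    highpass: float = 128.0        # high-pass cutoff (s)
    hrf_length: float = 32.0
    short_delay: float = 1.0       # delays <= this get a separate cue column
    mean_center: bool = True       # center parametric modulator amplitudes
    include_const_ev: bool = False  # boxcar modulated by constant expected value
    include_ramp: bool = False     # linear ramp over each waiting period
    include_spe: bool = False      # SPE-modulated cue sticks
    n_scans: int | None = None     # per run; derived from events if None
    tail: float = 20.0             # seconds of scanning after the last event


@dataclass
class DesignMatrix:
    """Scan-sampled regressor matrix with named columns.

    ``frame`` holds one row per scan (runs concatenated); ``nuisance`` names
    the columns not meant for hypothesis tests (boxcars, run intercepts,
    drift basis).
    """

    frame: pd.DataFrame
    tr: float
    highpass: float
    nuisance: list = field(default_factory=list)

    @property
    def n_scans(self) -> int:
        return len(self.frame)

    @property
    def columns(self) -> list:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def tested_columns(self) -> list:
        return [c for c in self.frame.columns if c not in self.nuisance]


REQUIRED_EVENT_COLUMNS = ("run", "onset_initial", "onset_cue", "cue",
                          "onset_outcome", "q", "T_s", "outcome")


def read_event_table(path) -> pd.DataFrame:
    """Read a tab-delimited event table with a one-line header."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    return df


def write_design_matrix(design: DesignMatrix, path) -> None:
    design.frame.to_csv(path, sep="\t", index=False)


def _validate_events(events: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    if len(events) == 0:
        return
    if (events[["onset_initial", "onset_cue", "onset_outcome"]] < 0).any().any():
        raise ValueError("negative onsets in event table")
    bad = ~((events["onset_initial"] <= events["onset_cue"])
            & (events["onset_cue"] < events["onset_outcome"]))
    if bad.any():
        raise ValueError("onsets not increasing within a trial")
    gap = events["onset_outcome"] - events["onset_cue"] - events["T_s"]
    if np.abs(gap).max() > 1e-6:
        raise ValueError("outcome onset minus cue onset must equal the delay")


def _add_stick(col: np.ndarray, onset: float, amplitude: float, dt: float):
    # delta approximated as amplitude/dt split linearly over two neighbouring
    # microtime bins; the half-bin shift compensates the bin-averaged kernel,
    # so convolution yields amplitude * hrf(t - onset) to second order in dt
    pos = max(onset / dt - 0.5, 0.0)
    i0 = int(np.floor(pos))
    frac = pos - i0
    if 0 <= i0 < len(col):
        col[i0] += amplitude * (1.0 - frac) / dt
    if 0 <= i0 + 1 < len(col) and frac > 0:
        col[i0 + 1] += amplitude * frac / dt


def _add_interval(col: np.ndarray, start: float, stop: float, dt: float,
                  func) -> None:
    """Add a continuous signal over [start, stop) to a microtime column.

    ``func`` maps time-from-interval-start to signal values.  Each microtime
    bin receives the signal at the midpoint of its overlap with the interval,
    weighted by the fractional overlap, keeping the representation accurate
    to second order in dt.
    """
    i0 = int(np.floor(start / dt))
    i1 = min(int(np.ceil(stop / dt)), len(col))
    if i1 <= i0:
        return
    bins = np.arange(i0, i1)
    ov_start = np.maximum(start, bins * dt)
    ov_end = np.minimum(stop, (bins + 1) * dt)
    w = np.maximum(ov_end - ov_start, 0.0) / dt
    t_mid = 0.5 * (ov_start + ov_end) - start
    col[bins] += w * np.asarray(func(t_mid), dtype=float)


def build_design_matrix(events: pd.DataFrame, params: ModelParams,
                        config: DesignConfig | None = None) -> DesignMatrix:
    """Assemble the scan-level GLM design matrix from an event table.

    Columns (built at microtime resolution, HRF-convolved, sampled at the TR):

    * onset sticks for initial screens, cues, cues preceding the shortest
      delay (modeled separately), and outcomes;
    * parametric modulators: condition-wise self-consistent aRPE on
      predictive-cue sticks and outcome value on outcome sticks;
    * time-varying signals over waiting periods (anticipatory utility,
      expected value and urgency, each per valence domain), with
      short-delay trials excluded to keep them separable from cue responses;
    * nuisance columns: a waiting-period boxcar, per-run intercepts and a
      discrete-cosine high-pass basis.

    Parametric modulators are mean-centered (configurable) and never
    orthogonalized against their onset sticks.
    """
    config = config or DesignConfig()
    _validate_events(events)
    events = events.sort_values(["run", "onset_initial"], kind="stable")
    runs = sorted(events["run"].unique()) if len(events) else [0]

    hrf = _hrf_bin_kernel(config.dt, config.hrf_length)
    signal_cols = ["onset_initial", "onset_cue", "onset_cue_short",
                   "onset_outcome", "pm_arpe", "pm_outcome_value",
                   "antic_pos", "antic_neg", "ev_pos", "ev_neg",
                   "urgency_pos", "urgency_neg", "box_wait"]
    if config.include_const_ev:
        signal_cols.append("pm_const_ev")
    if config.include_ramp:
        signal_cols.append("ramp_wait")
    if config.include_spe:
        signal_cols.append("pm_spe")

    run_frames = []
    nuisance = ["box_wait"]
    for run in runs:
        ev = events[events["run"] == run]
        if config.n_scans is not None:
            n_scans = config.n_scans
        elif len(ev):
            n_scans = int(np.ceil((ev["onset_outcome"].max() + config.tail)
                                  / config.tr))
        else:
            n_scans = 1
        n_micro = int(np.ceil(n_scans * config.tr / config.dt)) + 1
        cols = {name: np.zeros(n_micro) for name in signal_cols}

        arpe_amps, outcome_amps, ev_amps, spe_amps = [], [], [], []
        for _, tr_row in ev.iterrows():
            q, T, cue = float(tr_row["q"]), float(tr_row["T_s"]), tr_row["cue"]
            t_cue, t_out = float(tr_row["onset_cue"]), float(tr_row["onset_outcome"])
            short = T <= config.short_delay

            _add_stick(cols["onset_initial"], float(tr_row["onset_initial"]),
                       1.0, config.dt)
            cue_col = "onset_cue_short" if short else "onset_cue"
            _add_stick(cols[cue_col], t_cue, 1.0, config.dt)
            _add_stick(cols["onset_outcome"], t_out, 1.0, config.dt)

            outcome_amps.append((t_out, params.R_plus if tr_row["outcome"] == 1
                                 else params.R_minus))
            if cue in ("S+", "S-") and not short:
                amp = arpe_event_amplitudes(params, (q, T))[cue]
                arpe_amps.append((t_cue, amp))
            if config.include_spe and cue in ("S+", "S-") and not short:
                spe_amps.append((t_cue, state_prediction_error((q, T), cue)))

            # waiting-period content
            _add_interval(cols["box_wait"], t_cue, t_out, config.dt,
                          lambda t: np.ones_like(t))
            if config.include_ramp and not short:
                _add_interval(cols["ramp_wait"], t_cue, t_out, config.dt,
                              lambda t: t / T)
            if config.include_const_ev:
                ev_amps.append((t_cue, t_out,
                                q * params.R_plus + (1 - q) * params.R_minus))
            if short:
                continue
            for valence, suffix in (("+", "pos"), ("-", "neg")):
                _add_interval(
                    cols[f"antic_{suffix}"], t_cue, t_out, config.dt,
                    lambda t, v=valence: anticipation_timecourse(
                        params, (q, T), cue, t, v).values)
                _add_interval(
                    cols[f"ev_{suffix}"], t_cue, t_out, config.dt,
                    lambda t, v=valence: discounted_reward_timecourse(
                        params, (q, T), cue, t, v).values)
                _add_interval(
                    cols[f"urgency_{suffix}"], t_cue, t_out, config.dt,
                    lambda t, v=valence: urgency_timecourse(
                        params, (q, T), cue, t, v).values)

        for amps, col in ((arpe_amps, "pm_arpe"), (outcome_amps, "pm_outcome_value"),
                          (spe_amps, "pm_spe" if config.include_spe else None)):
            if col is None or not amps:
                continue
            a = np.array([x[1] for x in amps], dtype=float)
            if config.mean_center and len(a) > 1:
                a = a - a.mean()
            for (onset, _), amp in zip(amps, a):
                _add_stick(cols[col], onset, amp, config.dt)
        if config.include_const_ev and ev_amps:
            a = np.array([x[2] for x in ev_amps], dtype=float)
            if config.mean_center and len(a) > 1:
                a = a - a.mean()
            for (start, stop, _), amp in zip(ev_amps, a):
                _add_interval(cols["pm_const_ev"], start, stop, config.dt,
                              lambda t, a=amp: np.full_like(t, a))

        # convolve and sample at scan times (interpolated, so the sampled
        # value does not depend on how scan times align with microtime bins)
        micro_t = np.arange(n_micro) * config.dt
        scan_t = np.arange(n_scans) * config.tr
        frame = {}
        for name in signal_cols:
            if not np.any(cols[name]):
                continue
            conv = fftconvolve(cols[name], hrf)[:n_micro] * config.dt
            frame[name] = np.interp(scan_t, micro_t, conv)
        frame[f"run{run}_intercept"] = np.ones(n_scans)
        dct = dct_highpass_basis(n_scans, config.tr, config.highpass)
        for k in range(dct.shape[1]):
            frame[f"run{run}_dct{k + 1}"] = dct[:, k]
        run_frames.append(pd.DataFrame(frame))
        nuisance.extend([f"run{run}_intercept"]
                        + [f"run{run}_dct{k + 1}" for k in range(dct.shape[1])])

    full = pd.concat(run_frames, axis=0, ignore_index=True).fillna(0.0)
    # stable column order: signal columns first, then per-run nuisance
    ordered = ([c for c in signal_cols if c in full.columns]
               + [c for c in full.columns if c not in signal_cols])
    full = full[ordered]
    nuisance = [c for c in nuisance if c in full.columns]
    return DesignMatrix(frame=full, tr=config.tr, highpass=config.highpass,
                        nuisance=nuisance)


def ppi_regressor(seed_series, psych_series, zscore: bool = False) -> np.ndarray:
    """Psychophysiological-interaction regressor.

    Elementwise product of the mean-centered seed time series and the
    mean-centered (optionally z-scored) psychological series.  No
    deconvolution: the product is formed in signal space.
    """
    seed = np.asarray(seed_series, dtype=float)
    psych = np.asarray(psych_series, dtype=float)
    if seed.shape != psych.shape:
        raise ValueError("seed and psychological series must share a shape")
    seed = seed - seed.mean()
    psych = psych - psych.mean()
    if zscore:
        sd = psych.std()
        if sd > 0:
            psych = psych / sd
    return seed * psych
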