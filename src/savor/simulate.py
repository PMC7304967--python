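"""Synthetic task, choice and BOLD generation emulating the study design.

The task crosses five reward probabilities {0.05, 0.25, 0.5, 0.75, 0.95}
with five waiting delays {1, 5, 10, 20, 40} s; every run presents each of
the 25 conditions exactly once in a subject-specific random order, and each
subject completes three runs.  Choices are simulated from the model's
sigmoid; synthetic BOLD is design x weights plus low-frequency drift and
AR(1) Gaussian noise, so the whole pipeline is testable end to end without
any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Condition, ModelParams, choice_probability
from .hierarchical import GroupPrior, untransform_params
from .signals import DesignMatrix

__all__ = [
    "TaskConfig",
    "NoiseConfig",
    "condition_grid",
    "generate_trials",
    "simulate_choices",
    "simulate_cohort",
    "summarize_preferences",
    "simulate_bold",
]


@dataclass(frozen=True)
class TaskConfig:
    """Task structure: condition levels, runs and trial timing constants."""

    probabilities: tuple = (0.05, 0.25, 0.5, 0.75, 0.95)
    delays: tuple = (1.0, 5.0, 10.0, 20.0, 40.0)   # seconds
    n_runs: int = 3
    lead_in: float = 2.0           # s of scanning before the first trial
    response_window: float = 3.0   # s between initial screen and cue onset
    reward_display: float = 1.0    # s the outcome stays on screen
    blank: float = 1.0             # s of blank screen before the next trial

    def __post_init__(self):
        if not self.probabilities or not self.delays:
            raise ValueError("level sets must be non-empty")
        if any(not 0 <= p <= 1 for p in self.probabilities):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(d <= 0 for d in self.delays):
            raise ValueError("delays must be positive")
        if sorted(self.probabilities) != list(self.probabilities) or \
                sorted(self.delays) != list(self.delays):
            raise ValueError("level sets must be sorted")

    @property
    def trials_per_run(self) -> int:
        return len(self.probabilities) * len(self.delays)


def condition_grid(cfg: TaskConfig | None = None) -> list:
    """Full cross of probability and delay levels, each exactly once."""
    cfg = cfg or TaskConfig()
    return [Condition(q=q, T=d) for q in cfg.probabilities for d in cfg.delays]


def generate_trials(cfg: TaskConfig | None = None, n_subjects: int = 1,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Trial and event tables for a cohort (choices left unset).

    Per subject and run, a random permutation of the exhaustive condition
    grid; outcomes drawn Bernoulli(q); onsets laid out with the fixed task
    timing (initial screen, response window, waiting period of length T,
    outcome display, blank).
    """
    cfg = cfg or TaskConfig()
    rng = rng or np.random.default_rng()
    grid = [(c.q, c.T) for c in condition_grid(cfg)]
    rows = []
    for subj in range(n_subjects):
        for run in range(cfg.n_runs):
            order = rng.permutation(len(grid))
            t = cfg.lead_in
            for k, idx in enumerate(order):
                q, T = grid[idx]
                onset_initial = t
                onset_cue = onset_initial + cfg.response_window
                onset_outcome = onset_cue + T
                rows.append({
                    "subject": subj, "run": run, "trial": k,
                    "q": q, "T_s": T,
                    "onset_initial": onset_initial,
                    "onset_cue": onset_cue,
                    "onset_outcome": onset_outcome,
                    "outcome": int(rng.random() < q),
                    "choice": np.nan, "cue": "",
                })
                t = onset_outcome + cfg.reward_display + cfg.blank
    return pd.DataFrame(rows)


def _draw_subject_params(prior: GroupPrior, rng: np.random.Generator,
                         ) -> ModelParams:
    # the h-space transform guarantees stability, so a single draw suffices
    return untransform_params(prior.sample(rng, 1)[0], prior.spec)


def simulate_choices(params_or_prior, trials: pd.DataFrame,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Fill a trial table's choices from the model's choice sigmoid.

    ``params_or_prior`` is either one :class:`ModelParams` applied to every
    subject, a mapping subject -> ModelParams, or a :class:`GroupPrior` from
    which each subject's parameters are drawn (stability holds by
    construction of the transform).  The cue column is resolved from choice
    and outcome: predictive cues after an information choice, the
    non-predictive cue otherwise.  Returns a copy; the drawn per-subject
    parameters are attached as ``.attrs['true_params']``.
    """
    rng = rng or np.random.default_rng()
    trials = trials.copy()
    subjects = trials["subject"].unique()
    if isinstance(params_or_prior, GroupPrior):
        per_subject = {s: _draw_subject_params(params_or_prior, rng)
                       for s in subjects}
    elif isinstance(params_or_prior, ModelParams):
        per_subject = {s: params_or_prior for s in subjects}
    else:
        per_subject = dict(params_or_prior)

    choices = np.empty(len(trials), dtype=int)
    for i, (_, row) in enumerate(trials.iterrows()):
        p = choice_probability(per_subject[row["subject"]],
                               (row["q"], row["T_s"]))
        choices[i] = int(rng.random() < p)
    trials["choice"] = choices
    trials["cue"] = np.where(trials["choice"] == 1,
                             np.where(trials["outcome"] == 1, "S+", "S-"),
                             "NI")
    trials.attrs["true_params"] = per_subject
    return trials


def simulate_cohort(params_or_prior, cfg: TaskConfig | None = None,
                    n_subjects: int = 1,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate trials and simulate choices in one call."""
    rng = rng or np.random.default_rng()
    return simulate_choices(params_or_prior,
                            generate_trials(cfg, n_subjects, rng), rng)


def summarize_preferences(trials: pd.DataFrame) -> dict:
    """Mean info-choice rate by delay level and by probability level."""
    out = {}
    for key, col in (("delay", "T_s"), ("probability", "q")):
        g = trials.groupby(col)["choice"].agg(["mean", "count"])
        out[key] = g.rename(columns={"mean": "info_rate", "count": "n"}) \
                    .reset_index()
    return out


@dataclass(frozen=True)
class NoiseConfig:
    """BOLD noise model: AR(1) Gaussian noise plus low-order cosine drift."""

    sd: float = 1.0
    ar: float = 0.3
    drift_amplitude: float = 1.0
    drift_orders: int = 2


def simulate_bold(design, weights, noise_cfg: NoiseConfig | None = None,
                  rng: np.random.Generator | None = None,
                  n_channels: int | None = None) -> np.ndarray:
    """Synthetic multi-channel BOLD: Y = X w + drift + AR(1) noise.

    ``weights`` is (n_columns, n_channels) or (n_columns,) for one channel;
    zero weights give a pure-noise null dataset.  Seeded via ``rng``.
    """
    noise_cfg = noise_cfg or NoiseConfig()
    rng = rng or np.random.default_rng()
    X = design.values if isinstance(design, DesignMatrix) else np.asarray(design)
    w = np.asarray(weights, dtype=float)
    if w.ndim == 1:
        w = w[:, None]
    if n_channels is not None and w.shape[1] == 1 and n_channels > 1:
        w = np.repeat(w, n_channels, axis=1)
    n, ch = X.shape[0], w.shape[1]
    signal = X @ w

    eps = rng.normal(0.0, noise_cfg.sd, size=(n, ch))
    noise = np.empty_like(eps)
    noise[0] = eps[0]
    for t in range(1, n):
        noise[t] = noise_cfg.ar * noise[t - 1] + eps[t]

    drift = np.zeros((n, 1))
    tgrid = np.arange(n) / max(n - 1, 1)
    for k in range(1, noise_cfg.drift_orders + 1):
        phase = rng.uniform(0, 2 * np.pi, size=ch)
        drift = drift + noise_cfg.drift_amplitude * \
            np.cos(np.pi * k * tgrid[:, None] + phase[None, :])
    return signal + drift + noise
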