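"""Updated Maximum-Likelihood (UML) Bayesian adaptive procedure.

The psychometric function is a three-parameter logistic over stimulus level x
(dB of modulation/ripple depth):

    psi(x) = gamma + (1 - gamma) / (1 + exp(-beta * (x - alpha)))

with alpha the crossover (threshold), beta the slope and gamma the guess
rate (1/3 for a 3AFC oddball). After every response the posterior over a
3-D parameter grid is updated exactly (Bayes on the grid, in log space), and
the next stimulus is chosen by a sweet-point rule on the posterior-mean
function: the procedure cycles among a low and a high slope-informative
sweet point and a mid point near the steep part of the function. Crossover
estimates are posterior means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp
from scipy.stats import beta as beta_dist
from scipy.stats import norm


class SessionCompleteError(RuntimeError):
    """Raised on an update after the configured trial count is exhausted."""


@dataclass(frozen=True)
class PsychometricParams:
    """Three-parameter logistic: crossover (dB), slope (per dB), guess rate."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("slope beta must be positive")
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError("guess rate gamma must be in [0, 1)")


def psychometric_probability(x, params: PsychometricParams):
    """P(correct) at stimulus level x; lies in [gamma, 1)."""
    x = np.asarray(x, dtype=np.float64)
    with np.errstate(over="ignore"):
        core = 1.0 / (1.0 + np.exp(-params.beta * (x - params.alpha)))
    p = params.gamma + (1.0 - params.gamma) * core
    return float(p) if p.ndim == 0 else p


@dataclass(frozen=True)
class UMLConfig:
    """Parameter grids, priors and stimulus domain for a UML session.

    Defaults suit a 3AFC depth-discrimination task on a dB scale where
    larger (less negative) values are easier: alpha prior N(-18, 10) dB,
    ln-beta prior N(0, 0.5), gamma prior Beta-shaped with mean 1/3.
    """

    alpha_grid: tuple = tuple(np.linspace(-42.0, 3.0, 61))
    log_beta_grid: tuple = tuple(np.linspace(-1.5, 1.5, 21))
    gamma_grid: tuple = tuple(np.linspace(0.10, 0.60, 11))
    alpha_prior_mean: float = -18.0
    alpha_prior_sd: float = 10.0
    log_beta_prior_mean: float = 0.0
    log_beta_prior_sd: float = 0.5
    gamma_prior_a: float = 3.0
    gamma_prior_b: float = 6.0
    stimulus_min: float = -40.0
    stimulus_max: float = 0.0
    n_trials: int = 70
    mid_point_core_p: float = 0.707  # logistic-core probability of the mid sweet point

    def __post_init__(self) -> None:
        for g in (self.alpha_grid, self.log_beta_grid, self.gamma_grid):
            if len(g) == 0:
                raise ValueError("parameter grids must be non-empty")
        if not (self.alpha_prior_sd > 0 and self.log_beta_prior_sd > 0):
            raise ValueError("prior SDs must be positive")
        if self.gamma_prior_a <= 0 or self.gamma_prior_b <= 0:
            raise ValueError("gamma prior shape parameters must be positive")
        if self.stimulus_min >= self.stimulus_max:
            raise ValueError("empty stimulus domain")

    def grids(self):
        a = np.asarray(self.alpha_grid)
        lb = np.asarray(self.log_beta_grid)
        g = np.asarray(self.gamma_grid)
        return a, lb, g

    def log_prior(self) -> np.ndarray:
        """Separable log prior on the (alpha, log-beta, gamma) grid,
        normalized to sum to 1 after exponentiation."""
        a, lb, g = self.grids()
        lp_a = norm.logpdf(a, self.alpha_prior_mean, self.alpha_prior_sd)
        lp_b = norm.logpdf(lb, self.log_beta_prior_mean, self.log_beta_prior_sd)
        lp_g = beta_dist.logpdf(
            np.clip(g, 1e-9, 1 - 1e-9), self.gamma_prior_a, self.gamma_prior_b
        )
        if not np.all(np.isfinite(lp_a)) or not np.all(np.isfinite(lp_b)) or not np.all(
            np.isfinite(lp_g)
        ):
            raise ValueError("improper prior: non-finite density on the grid")
        lp = (
            lp_a[:, None, None] + lp_b[None, :, None] + lp_g[None, None, :]
        )
        return lp - logsumexp(lp)


@dataclass
class UMLState:
    """Evolving posterior and trial history of one adaptive session."""

    config: UMLConfig
    log_posterior: np.ndarray
    history: list = field(default_factory=list)  # (stimulus_db, correct)
    next_stimulus: float = 0.0

    @property
    def n_trials_done(self) -> int:
        return len(self.history)

    @property
    def complete(self) -> bool:
        return self.n_trials_done >= self.config.n_trials

    def posterior(self) -> np.ndarray:
        return np.exp(self.log_posterior - logsumexp(self.log_posterior))


def _grid_psi(config: UMLConfig, x: float) -> np.ndarray:
    """psi(x | theta) over the full parameter grid."""
    a, lb, g = config.grids()
    beta = np.exp(lb)
    with np.errstate(over="ignore"):
        core = 1.0 / (
            1.0 + np.exp(-beta[None, :, None] * (x - a[:, None, None]))
        )
    return g[None, None, :] + (1.0 - g[None, None, :]) * core


def uml_estimate(state: UMLState) -> PsychometricParams:
    """Posterior means of (alpha, beta, gamma)."""
    w = state.posterior()
    a, lb, g = state.config.grids()
    alpha = float(np.sum(w * a[:, None, None]))
    beta = float(np.sum(w * np.exp(lb)[None, :, None]))
    gamma = float(np.sum(w * g[None, None, :]))
    return PsychometricParams(alpha=alpha, beta=beta, gamma=gamma)


def _sweet_points(config: UMLConfig, params: PsychometricParams) -> tuple[float, float, float]:
    """(low, mid, high) sweet points of the given function.

    The mid point sits where the logistic core reaches
    ``mid_point_core_p``; the low/high points minimize the asymptotic
    variance of the slope estimate, psi(1-psi)/(dpsi/dbeta)^2, below and
    above the crossover (computed numerically on a dense level grid).
    """
    pc = config.mid_point_core_p
    mid = params.alpha + np.log(pc / (1.0 - pc)) / params.beta

    x = np.linspace(config.stimulus_min - 20.0, config.stimulus_max + 20.0, 801)
    with np.errstate(over="ignore"):
        core = 1.0 / (1.0 + np.exp(-params.beta * (x - params.alpha)))
    psi = params.gamma + (1.0 - params.gamma) * core
    dpsi_dbeta = (1.0 - params.gamma) * (x - params.alpha) * core * (1.0 - core)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_beta = psi * (1.0 - psi) / dpsi_dbeta**2
    var_beta[~np.isfinite(var_beta)] = np.inf

    below = x < params.alpha - 1e-9
    above = x > params.alpha + 1e-9
    low = x[below][np.argmin(var_beta[below])] if np.any(below) else params.alpha
    high = x[above][np.argmin(var_beta[above])] if np.any(above) else params.alpha

    clamp = lambda v: float(np.clip(v, config.stimulus_min, config.stimulus_max))
    return clamp(low), clamp(mid), clamp(high)


def uml_select_stimulus(state: UMLState) -> float:
    """Next stimulus: sweet points of the posterior-mean function, cycled
    mid -> high -> low by trial index, clamped to the stimulus domain."""
    if state.complete:
        raise SessionCompleteError("session already has n_trials responses")
    params = uml_estimate(state)
    low, mid, high = _sweet_points(state.config, params)
    cycle = (mid, high, low)
    return cycle[state.n_trials_done % 3]


def uml_start(config: UMLConfig) -> UMLState:
    """Initialize a session: posterior = prior; first stimulus from the
    prior-mean function."""
    state = UMLState(config=config, log_posterior=config.log_prior())
    state.next_stimulus = uml_select_stimulus(state)
    return state


def uml_update(state: UMLState, x: float, correct: bool) -> UMLState:
    """Bayes update after one response; returns a new state."""
    if state.complete:
        raise SessionCompleteError("session already has n_trials responses")
    if not (state.config.stimulus_min - 1e-9 <= x <= state.config.stimulus_max + 1e-9):
        raise ValueError("stimulus outside configured domain")
    psi = np.clip(_grid_psi(state.config, float(x)), 1e-12, 1.0 - 1e-12)
    log_lik = np.log(psi if correct else 1.0 - psi)
    log_post = state.log_posterior + log_lik
    log_post -= logsumexp(log_post)
    new = UMLState(
        config=state.config,
        log_posterior=log_post,
        history=state.history + [(float(x), bool(correct))],
    )
    if not new.complete:
        new.next_stimulus = uml_select_stimulus(new)
    return new


def run_adaptive_session(
    config: UMLConfig,
    observer: PsychometricParams,
    seed: int = 0,
    n_practice: int = 0,
) -> tuple[UMLState, PsychometricParams]:
    """Simulate a full adaptive session against a Bernoulli observer obeying
    the three-parameter logistic. Practice trials, if any, draw responses but
    do not enter the inference (mirroring task familiarization)."""
    rng = np.random.default_rng(seed)
    state = uml_start(config)
    for _ in range(n_practice):
        p = psychometric_probability(state.next_stimulus, observer)
        rng.random() < p  # response consumed, excluded from inference
    while not state.complete:
        x = state.next_stimulus
        p = psychometric_probability(x, observer)
        correct = bool(rng.random() < p)
        state = uml_update(state, x, correct)
    return state, uml_estimate(state)


def session_log(state: UMLState):
    """Trial-by-trial log as a pandas DataFrame (stimulus, response)."""
    import pandas as pd

    return pd.DataFrame(
        [(i + 1, x, c) for i, (x, c) in enumerate(state.history)],
        columns=["trial", "stimulus_db", "correct"],
    )
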