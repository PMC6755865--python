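"""Bayesian adaptive stimulus selection over discrete log-spaced grids.

Each task kind has a fixed, logarithmically spaced stimulus grid; the
first trial presents a fixed start value (which may lie off the grid —
the procedures start at 500 Hz, 90 deg, 6 dB, 6 dB), and every later
trial presents the grid value that maximises the expected information
gain about the psychometric-function parameters: the mutual information
between the upcoming binary response and the (midpoint, width, lapse)
posterior.  Responses update the posterior with a Bernoulli likelihood.

The same parameter grid doubles as the final fitting grid, so the run
engine is a pure function of (observer, grid, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .psychometrics import (
    PFFit,
    PFGrid,
    FinalEstimate,
    TrialData,
    default_fit_grid,
    finalize_estimate,
    fit_pf,
)

__all__ = [
    "StimulusGrid",
    "AdaptiveState",
    "RunResult",
    "make_grid",
    "new_state",
    "select_next",
    "update_posterior",
    "run_procedure",
    "run_interleaved_ild",
]

# kind -> (lo, hi, n_values, start, n_trials, axis, family, slope_sign)
_GRID_SPECS = {
    "ipd_fl": (125.0, 2000.0, 57, 500.0, 60, "log2_frequency", "logistic", -1),
    "ipd_jnd": (0.5, 180.0, 50, 90.0, 60, "log_ipd", "logistic", 1),
    "ild_jnd": (0.1, 16.0, 80, 6.0, 50, "log_ild", "weibull", 1),
    "int_jnd": (0.1, 10.0, 47, 6.0, 60, "log_increment", "weibull", 1),
}


@dataclass(frozen=True)
class StimulusGrid:
    """Discrete candidate stimuli for one adaptive task."""

    kind: str
    values: tuple          # natural units, strictly increasing, log-spaced
    start_value: float
    n_trials: int
    axis: str
    family: str
    slope_sign: int

    def __post_init__(self):
        v = np.asarray(self.values)
        if not np.all(np.diff(v) > 0):
            raise ValueError("grid values must be strictly increasing")


def make_grid(kind: str, start_value: float | None = None,
              n_trials: int | None = None) -> StimulusGrid:
    """The published stimulus grid for a task kind.

    ``start_value`` and ``n_trials`` may be overridden (e.g. the 250-Hz
    start used to check the chance-performance simulations, or shortened
    training runs).
    """
    if kind not in _GRID_SPECS:
        raise ValueError(f"unknown task kind {kind!r}")
    lo, hi, n, start, trials, axis, family, sign = _GRID_SPECS[kind]
    values = tuple(np.geomspace(lo, hi, n))
    return StimulusGrid(
        kind, values,
        float(start if start_value is None else start_value),
        int(trials if n_trials is None else n_trials),
        axis, family, sign,
    )


@lru_cache(maxsize=16)
def _cached_tables(kind: str):
    """(pf_grid, P, Hb(P)) for a task kind's default grids (float64)."""
    grid = make_grid(kind)
    pf_grid = default_fit_grid(grid.family, grid.axis, grid.slope_sign,
                               np.asarray(grid.values))
    p = pf_grid.prob_table(np.asarray(grid.values))
    return pf_grid, p, _binary_entropy(p)


def _binary_entropy(p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -(p * np.log(p) + (1 - p) * np.log1p(-p))


@dataclass
class AdaptiveState:
    """Posterior + history of one adaptive run."""

    grid: StimulusGrid
    pf_grid: PFGrid
    posterior: np.ndarray              # normalized, len == pf_grid.size
    history: list = field(default_factory=list)  # (trial, stimulus, correct)
    rng_seed: int | None = None
    _p_table: np.ndarray | None = None           # (n_grid_values, size)
    _h_table: np.ndarray | None = None

    @property
    def trial_index(self) -> int:
        return len(self.history) + 1

    def history_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.history, columns=["trial", "stimulus", "correct"])
        return df


def new_state(grid: StimulusGrid, seed: int | None = None) -> AdaptiveState:
    if grid.kind in _GRID_SPECS and grid.values == make_grid(grid.kind).values:
        pf_grid, p, h = _cached_tables(grid.kind)
    else:
        pf_grid = default_fit_grid(grid.family, grid.axis, grid.slope_sign,
                                   np.asarray(grid.values))
        p = pf_grid.prob_table(np.asarray(grid.values))
        h = _binary_entropy(p)
    return AdaptiveState(grid, pf_grid, pf_grid.prior().copy(),
                         rng_seed=seed, _p_table=p, _h_table=h)


def _likelihood_column(state: AdaptiveState, stimulus: float) -> np.ndarray:
    values = np.asarray(state.grid.values)
    idx = np.searchsorted(values, stimulus)
    if idx < len(values) and np.isclose(values[idx], stimulus, rtol=1e-12):
        return state._p_table[idx]
    # off-grid stimulus (e.g. the fixed start value): compute directly
    return state.pf_grid.prob_table(stimulus)[0]


def update_posterior(state: AdaptiveState, stimulus: float,
                     correct: bool) -> AdaptiveState:
    """Bayes update after one trial; returns a new state."""
    p = _likelihood_column(state, float(stimulus))
    like = p if correct else 1.0 - p
    post = state.posterior * like
    total = post.sum()
    if total <= 0:
        raise RuntimeError("posterior collapsed to zero mass")
    post = post / total
    return replace(
        state,
        posterior=post,
        history=state.history + [(state.trial_index, float(stimulus), bool(correct))],
    )


def select_next(state: AdaptiveState) -> float:
    """Next stimulus: trial 1 is the fixed start value; afterwards the
    grid value maximising expected information gain, ties toward the
    lower grid index."""
    if state.trial_index == 1:
        return state.grid.start_value
    post = state.posterior
    p_hat = state._p_table @ post                    # predictive P(correct)
    expected_h = state._h_table @ post               # E_theta H(p_theta)
    gain = _binary_entropy(p_hat) - expected_h       # mutual information
    return float(state.grid.values[int(np.argmax(gain))])


@dataclass
class RunResult:
    """One completed adaptive measurement run."""

    state: AdaptiveState
    trial_data: TrialData
    fit: PFFit
    reported: FinalEstimate

    def trials_frame(self) -> pd.DataFrame:
        return self.state.history_frame()

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "kind": self.state.grid.kind,
                "n_trials": len(self.state.history),
                "threshold75": self.fit.threshold75,
                "flags": self.fit.flags,
                "reported": self.reported.value,
                "reported_flagged": self.reported.flagged,
            }
        )


def run_procedure(observer, grid: StimulusGrid, seed,
                  estimator: str = "map") -> RunResult:
    """Execute a full adaptive run against a response-generating model.

    Deterministic given (observer, grid, seed).
    """
    from .observers import respond

    rng = np.random.default_rng(seed)
    state = new_state(grid, seed=None)
    for _ in range(grid.n_trials):
        stim = select_next(state)
        correct = respond(observer, stim, rng)
        state = update_posterior(state, stim, correct)
    data = TrialData.from_trials(
        [h[1] for h in state.history], [h[2] for h in state.history]
    )
    fit = fit_pf(data, grid.family, grid.axis, grid.slope_sign,
                 grid=state.pf_grid, estimator=estimator)
    reported = finalize_estimate(fit.threshold75, grid.kind)
    return RunResult(state, data, fit, reported)


ILD_CONDITIONS = ("no_rove", "level_rove", "ipd_level_rove")


def run_interleaved_ild(observers: dict, seed, n_trials: int = 50,
                        conditions=ILD_CONDITIONS) -> dict:
    """Three ILD adaptive runs sharing one trial stream.

    The conditions are interleaved trial by trial: each consecutive
    triple presents all conditions once in a seeded random order, as a
    round-robin.  ``observers`` maps condition name to a response model.
    """
    missing = [c for c in conditions if c not in observers]
    if missing:
        raise ValueError(f"missing observers for conditions {missing}")
    rng = np.random.default_rng(seed)
    states = {c: new_state(make_grid("ild_jnd", n_trials=n_trials)) for c in conditions}
    order = []
    for _ in range(n_trials):
        triple = list(conditions)
        rng.shuffle(triple)
        order.extend(triple)
    from .observers import respond

    for cond in order:
        state = states[cond]
        stim = select_next(state)
        correct = respond(observers[cond], stim, rng, context={"condition": cond})
        states[cond] = update_posterior(state, stim, correct)

    results = {}
    for cond, state in states.items():
        data = TrialData.from_trials(
            [h[1] for h in state.history], [h[2] for h in state.history]
        )
        fit = fit_pf(data, state.grid.family, state.grid.axis,
                     state.grid.slope_sign, grid=state.pf_grid)
        results[cond] = RunResult(state, data, fit,
                                  finalize_estimate(fit.threshold75, "ild_jnd"))
    return results
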