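"""Monte-Carlo validation of the adaptive measurement procedure.

Two simulation experiments characterise the IPD frequency-limit (FL)
procedure, and a closed-form analysis characterises the level-roved ILD
task:

* *Specificity*: running the full 60-trial adaptive FL procedure on a
  purely random responder and fitting each run — the fraction of raw
  fitted FLs below the lowest presented frequency (125 Hz) measures how
  reliably chance performance is recognised as such.
* *Sensitivity*: the same procedure applied to a poorly performing but
  genuine observer (true FL 100 Hz, six-octave-wide PF) — the fraction
  of fitted FLs below 65 Hz bounds how often a near-chance listener
  would be wrongly labelled a pure guesser.
* *Single-ear threshold*: the ILD at which an observer using only
  one ear's roved tone levels reaches 75% correct, 2R(1 - 1/sqrt(2))
  for a rove of +/-R/2 dB (11.7 dB for the +/-10-dB rove).

"Fitted FL" here is the raw psychometric fit *before* the reporting
substitutions — the substitution rules are themselves derived from
these simulations.
"""

from __future__ import annotations

import numpy as np

from .adaptive import make_grid, run_procedure
from .observers import ObserverModel, single_ear_pc, single_ear_pc_mc
from .psychometrics import pf_from_threshold

__all__ = [
    "specificity_sim",
    "sensitivity_sim",
    "single_ear_threshold",
    "simulate_fl_runs",
]

FL_GRID_MIN_HZ = 125.0
FL_SENSITIVITY_CUTOFF_HZ = 65.0


def _run_seeds(seed, n_runs: int):
    return np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)


def simulate_fl_runs(observer: ObserverModel, n_runs: int, seed,
                     start_value: float = 500.0) -> np.ndarray:
    """Raw fitted FLs (Hz) from ``n_runs`` independent adaptive runs."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    grid = make_grid("ipd_fl", start_value=start_value)
    seeds = _run_seeds(seed, n_runs)
    return np.array(
        [run_procedure(observer, grid, int(s)).fit.threshold75 for s in seeds]
    )


def specificity_sim(n_runs: int = 2000, start_value: float = 500.0,
                    seed=0) -> float:
    """Fraction of random-responder runs whose raw fitted FL falls below
    the 125-Hz grid minimum."""
    fls = simulate_fl_runs(ObserverModel("random"), n_runs, seed, start_value)
    return float(np.mean(fls < FL_GRID_MIN_HZ))


def sensitivity_sim(true_fl: float = 100.0, width_oct: float = 6.0,
                    n_runs: int = 2000, seed=0,
                    start_value: float = 500.0) -> float:
    """Fraction of fitted FLs below 65 Hz for a genuine observer with the
    given true FL (75%-correct point) and PF width in octaves."""
    if not true_fl > 0:
        raise ValueError("true_fl must be positive")
    if not width_oct > 0:
        raise ValueError("width_oct must be positive")
    pf = pf_from_threshold("logistic", "log2_frequency", true_fl, width_oct,
                           slope_sign=-1)
    fls = simulate_fl_runs(ObserverModel("pf", pf=pf), n_runs, seed, start_value)
    return float(np.mean(fls < FL_SENSITIVITY_CUTOFF_HZ))


def single_ear_threshold(rove_halfrange: float = 10.0,
                         p_target: float = 0.75) -> float:
    """Closed-form ILD (dB) at which single-ear cues reach ``p_target``.

    Solves single_ear_pc(ild) = p_target: ild = 2R(1 - sqrt(2(1-p)))
    with R = 2*rove_halfrange.
    """
    if not 0.5 <= p_target < 1.0:
        raise ValueError("p_target must lie in [0.5, 1)")
    r = 2.0 * rove_halfrange
    return 2.0 * r * (1.0 - np.sqrt(2.0 * (1.0 - p_target)))


def single_ear_threshold_mc(rove_halfrange: float = 10.0,
                            p_target: float = 0.75,
                            n_draws: int = 100_000, rng=None) -> float:
    """Monte-Carlo solve of the single-ear threshold (bisection on the
    simulated psychometric function; cross-check of the closed form)."""
    rng = np.random.default_rng(rng)
    d = rng.uniform(-rove_halfrange, rove_halfrange, size=(2, n_draws))
    diffs = d[0] - d[1]

    def pc(ild):
        stat = ild / 2.0 + diffs
        return np.mean(stat > 0) + 0.5 * np.mean(stat == 0)

    lo, hi = 0.0, 4.0 * rove_halfrange
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if pc(mid) < p_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
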