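"""Psychometric functions and Bayesian grid-posterior fitting.

Performance in a two-interval, two-alternative forced-choice (2I-2AFC)
task is modelled as

    p(x) = gamma + (1 - gamma - lambda) * S(x)

with guess rate ``gamma`` fixed at 0.5, lapse rate ``lambda`` in
[0, 0.1], and ``S`` a sigmoid on a log-transformed stimulus axis.  Two
families are supported:

* ``logistic`` — S(u) = 1 / (1 + exp(-z)),  z = sign * (u - m) / s
* ``weibull``  — a Weibull function of the raw stimulus, which becomes a
  Gumbel sigmoid on the log axis: S(u) = 1 - exp(-exp(z))

The *width* of a function is the distance, in axis units, between the
points where the core sigmoid S passes 0.06 and 0.94 — i.e. between the
53 and 97 percent-correct points of the lapse-free 2AFC curve.  On a
base-2 log-frequency axis this width is in octaves.

Fitting is Bayesian over a discrete (midpoint, width, lapse) grid with a
binomial likelihood: uniform prior on midpoint, log-uniform on width
(realised as uniform weights on a log-spaced grid), uniform on lapse.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "PsychFun",
    "PFGrid",
    "PFFit",
    "TrialData",
    "pf_eval",
    "threshold_at",
    "fit_pf",
    "finalize_estimate",
    "pf_from_threshold",
    "to_axis",
    "from_axis",
    "octaves_to_axis",
    "default_fit_grid",
]

# z-span of the core sigmoid between S = 0.06 and S = 0.94
_LOGISTIC_SPAN = 2.0 * math.log(0.94 / 0.06)                 # 5.50308
_GUMBEL_Z06 = math.log(-math.log(0.94))                      # -2.78263
_GUMBEL_Z94 = math.log(-math.log(0.06))                      # +1.03440
_GUMBEL_SPAN = _GUMBEL_Z94 - _GUMBEL_Z06                     # 3.81703

_LOG2_AXES = {"log2_frequency"}
_VALID_AXES = {"log2_frequency", "log_ipd", "log_ild", "log_increment"}
_VALID_FAMILIES = {"logistic", "weibull"}

# maximum stimulus value presented per task kind (natural units) and the
# substitution applied to near-chance frequency-limit fits
GRID_MAXIMA = {"ipd_jnd": 180.0, "ild_jnd": 16.0, "int_jnd": 10.0}
FL_LOWER_CONFIDENCE_CUTOFF = 65.0   # Hz; below this a fit is uninformative
FL_SUBSTITUTE = 100.0               # Hz; the 95%-confidence upper bound


def to_axis(x, axis: str):
    """Transform natural stimulus units to the fitting axis."""
    if axis not in _VALID_AXES:
        raise ValueError(f"unknown axis {axis!r}")
    x = np.asarray(x, dtype=float)
    return np.log2(x) if axis in _LOG2_AXES else np.log(x)


def from_axis(u, axis: str):
    """Inverse of :func:`to_axis`."""
    if axis not in _VALID_AXES:
        raise ValueError(f"unknown axis {axis!r}")
    u = np.asarray(u, dtype=float)
    return np.exp2(u) if axis in _LOG2_AXES else np.exp(u)


def octaves_to_axis(width_oct: float, axis: str) -> float:
    """Convert a width quoted in octaves to axis units.

    On a base-2 axis octaves are the native unit; on natural-log axes one
    octave corresponds to ln 2 axis units.
    """
    return float(width_oct) if axis in _LOG2_AXES else float(width_oct) * math.log(2.0)


@dataclass(frozen=True)
class PsychFun:
    """A parametric psychometric function on a log stimulus axis."""

    family: str
    axis: str
    midpoint: float        # axis units; S = 0.5 (logistic) / 1 - 1/e (weibull)
    width: float           # axis units between the 53% and 97% correct points
    guess: float = 0.5
    lapse: float = 0.0
    slope_sign: int = 1    # +1: performance grows with x; -1: declines

    def __post_init__(self):
        if self.family not in _VALID_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.axis not in _VALID_AXES:
            raise ValueError(f"unknown axis {self.axis!r}")
        if not self.guess == 0.5:
            raise ValueError("guess rate is fixed at 0.5 for 2I-2AFC")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")
        if not self.width > 0:
            raise ValueError("width must be positive")
        if self.slope_sign not in (-1, 1):
            raise ValueError("slope_sign must be +1 or -1")

    @property
    def scale(self) -> float:
        span = _LOGISTIC_SPAN if self.family == "logistic" else _GUMBEL_SPAN
        return self.width / span


def _core_sigmoid(family: str, z):
    if family == "logistic":
        return expit(z)
    return 1.0 - np.exp(-np.exp(z))


def pf_eval(pf: PsychFun, x):
    """Probability correct at stimulus value ``x`` (natural units)."""
    u = to_axis(x, pf.axis)
    z = pf.slope_sign * (u - pf.midpoint) / pf.scale
    s = _core_sigmoid(pf.family, z)
    return pf.guess + (1.0 - pf.guess - pf.lapse) * s


def threshold_at(pf: PsychFun, p_target: float = 0.75):
    """Stimulus value (natural units) at which ``pf`` reaches ``p_target``.

    Raises ``ValueError`` when the target probability is outside the open
    attainable range (guess, 1 - lapse); no silent extrapolation.
    """
    s_target = (p_target - pf.guess) / (1.0 - pf.guess - pf.lapse)
    if not 0.0 < s_target < 1.0:
        raise ValueError(
            f"p_target={p_target} unattainable for guess={pf.guess}, lapse={pf.lapse}"
        )
    if pf.family == "logistic":
        z = float(logit(s_target))
    else:
        z = math.log(-math.log(1.0 - s_target))
    u = pf.midpoint + pf.slope_sign * z * pf.scale
    return float(from_axis(u, pf.axis))


def pf_from_threshold(
    family: str,
    axis: str,
    threshold: float,
    width_oct: float,
    lapse: float = 0.0,
    slope_sign: int = 1,
    p_threshold: float = 0.75,
) -> PsychFun:
    """Construct a PF whose ``p_threshold`` point sits at ``threshold``.

    ``width_oct`` is given in octaves and converted to axis units.
    """
    width = octaves_to_axis(width_oct, axis)
    probe = PsychFun(family, axis, 0.0, width, lapse=lapse, slope_sign=slope_sign)
    # axis offset of the p_threshold point from the midpoint
    u_thr = to_axis(threshold_at(replace(probe, midpoint=0.0), p_threshold), axis)
    m = float(to_axis(threshold, axis)) - float(u_thr)
    return replace(probe, midpoint=m)


@dataclass
class TrialData:
    """Aggregated binomial trial counts per stimulus value."""

    stimulus: np.ndarray   # natural units
    n_trials: np.ndarray
    n_correct: np.ndarray

    def __post_init__(self):
        self.stimulus = np.asarray(self.stimulus, dtype=float)
        self.n_trials = np.asarray(self.n_trials, dtype=int)
        self.n_correct = np.asarray(self.n_correct, dtype=int)
        if len({len(self.stimulus), len(self.n_trials), len(self.n_correct)}) != 1:
            raise ValueError("stimulus, n_trials, n_correct must align")
        if np.any(self.n_correct < 0) or np.any(self.n_correct > self.n_trials):
            raise ValueError("need 0 <= n_correct <= n_trials")

    @classmethod
    def from_trials(cls, stimuli, correct) -> "TrialData":
        stimuli = np.asarray(stimuli, dtype=float)
        correct = np.asarray(correct, dtype=bool)
        uniq, inv = np.unique(stimuli, return_inverse=True)
        n = np.bincount(inv, minlength=len(uniq))
        k = np.bincount(inv, weights=correct.astype(float), minlength=len(uniq))
        return cls(uniq, n, k.astype(int))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stimulus": self.stimulus, "n": self.n_trials, "k": self.n_correct}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialData":
        df = pd.read_csv(path)
        return cls(df["stimulus"].values, df["n"].values, df["k"].values)


@dataclass(frozen=True)
class PFGrid:
    """Discrete (midpoint, width, lapse) parameter grid with flat priors."""

    family: str
    axis: str
    slope_sign: int
    midpoints: tuple
    widths: tuple
    lapses: tuple

    @classmethod
    def make(cls, family, axis, slope_sign, mid_lo, mid_hi,
             n_mid=41, width_oct_lo=0.1, width_oct_hi=8.0, n_width=21,
             lapses=tuple(np.round(np.arange(0.0, 0.1001, 0.01), 3))) -> "PFGrid":
        mids = np.linspace(mid_lo, mid_hi, n_mid)
        widths = octaves_to_axis(1.0, axis) * np.geomspace(
            width_oct_lo, width_oct_hi, n_width
        )
        return cls(family, axis, slope_sign, tuple(mids), tuple(widths),
                   tuple(float(l) for l in lapses))

    @property
    def size(self) -> int:
        return len(self.midpoints) * len(self.widths) * len(self.lapses)

    def param_arrays(self):
        """Flattened (midpoint, width, lapse) arrays, midpoint fastest-last.

        Flat order is C order over (midpoint, width, lapse); the flat
        index identifies one parameter combination everywhere.
        """
        m, w, l = np.meshgrid(
            self.midpoints, self.widths, self.lapses, indexing="ij"
        )
        return m.ravel(), w.ravel(), l.ravel()

    def prob_table(self, stimuli) -> np.ndarray:
        """Probability-correct table, shape (n_stimuli, grid.size)."""
        u = np.atleast_1d(to_axis(stimuli, self.axis))[:, None]
        m, w, l = self.param_arrays()
        span = _LOGISTIC_SPAN if self.family == "logistic" else _GUMBEL_SPAN
        z = self.slope_sign * (u - m[None, :]) / (w[None, :] / span)
        s = _core_sigmoid(self.family, z)
        return 0.5 + (0.5 - l[None, :]) * s

    def prior(self) -> np.ndarray:
        return np.full(self.size, 1.0 / self.size)


@dataclass
class PFFit:
    """Result of a grid-posterior psychometric fit."""

    map_params: PsychFun
    posterior: np.ndarray       # normalized weights, len == grid.size
    grid: PFGrid
    threshold75: float          # natural units
    flags: str                  # ok | below_floor | above_ceiling
    estimator: str = "map"

    def posterior_marginal(self, which: str) -> np.ndarray:
        """Marginal posterior over one parameter dimension."""
        shape = (len(self.grid.midpoints), len(self.grid.widths),
                 len(self.grid.lapses))
        cube = self.posterior.reshape(shape)
        ax = {"midpoint": (1, 2), "width": (0, 2), "lapse": (0, 1)}[which]
        return cube.sum(axis=ax)

    def to_json(self) -> str:
        return json.dumps(
            {
                "family": self.map_params.family,
                "axis": self.map_params.axis,
                "midpoint": self.map_params.midpoint,
                "width": self.map_params.width,
                "lapse": self.map_params.lapse,
                "slope_sign": self.map_params.slope_sign,
                "threshold75": self.threshold75,
                "flags": self.flags,
                "estimator": self.estimator,
            }
        )


def default_fit_grid(family: str, axis: str, slope_sign: int,
                     stimulus_values) -> PFGrid:
    """Default parameter grid for a given stimulus set.

    The midpoint range spans the stimulus grid, extended one octave on
    both sides for the logistic family (thresholds may legitimately sit
    beyond the tested range); the Weibull grid spans the stimulus range.
    """
    u = to_axis(stimulus_values, axis)
    pad = octaves_to_axis(1.0, axis) if family == "logistic" else 0.0
    return PFGrid.make(family, axis, slope_sign,
                       float(np.min(u)) - pad, float(np.max(u)) + pad)


def _grid_threshold75(grid: PFGrid) -> np.ndarray:
    """threshold75 (axis units) for every grid combination, vectorized."""
    m, w, l = grid.param_arrays()
    span = _LOGISTIC_SPAN if grid.family == "logistic" else _GUMBEL_SPAN
    s_target = 0.25 / (0.5 - l)
    if grid.family == "logistic":
        z = logit(s_target)
    else:
        z = np.log(-np.log1p(-s_target))
    return m + grid.slope_sign * z * (w / span)


def fit_pf(data: TrialData, family: str, axis: str, slope_sign: int = 1,
           grid: PFGrid | None = None, estimator: str = "map") -> PFFit:
    """Fit a psychometric function to aggregated trial data.

    Posterior over the (midpoint, width, lapse) grid with a binomial
    likelihood; the point estimate is the MAP combination by default
    (``estimator="posterior_mean"`` uses the posterior-mean threshold).
    Grid ties break toward the lowest flat index.
    """
    if len(data.stimulus) == 0:
        raise ValueError("need at least one data row")
    if grid is None:
        grid = default_fit_grid(family, axis, slope_sign, data.stimulus)
    p = grid.prob_table(data.stimulus)
    eps = 1e-12
    loglik = (data.n_correct[:, None] * np.log(p + eps)
              + (data.n_trials - data.n_correct)[:, None] * np.log(1 - p + eps)
              ).sum(axis=0)
    loglik += np.log(grid.prior())
    post = np.exp(loglik - loglik.max())
    post /= post.sum()

    i_map = int(np.argmax(post))     # first maximum -> lowest index
    m, w, l = grid.param_arrays()
    map_pf = PsychFun(grid.family, grid.axis, float(m[i_map]), float(w[i_map]),
                      lapse=float(l[i_map]), slope_sign=grid.slope_sign)

    if estimator == "map":
        thr_axis = float(_grid_threshold75(grid)[i_map])
    elif estimator == "posterior_mean":
        thr_axis = float(_grid_threshold75(grid) @ post)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    threshold75 = float(from_axis(thr_axis, grid.axis))

    # flags are performance-based: the grid edge where discrimination is
    # easy ("ceiling") is the low-midpoint edge for positive slopes and
    # the high-midpoint edge for negative slopes
    flags = "ok"
    at_low = map_pf.midpoint == grid.midpoints[0]
    at_high = map_pf.midpoint == grid.midpoints[-1]
    if at_low or at_high:
        ceiling_at_low = grid.slope_sign == 1
        at_ceiling = (at_low and ceiling_at_low) or (at_high and not ceiling_at_low)
        flags = "above_ceiling" if at_ceiling else "below_floor"
    if flags == "ok" and len(np.unique(data.stimulus)) == 1:
        # a single tested level cannot constrain midpoint and width jointly
        flags = "below_floor"
    return PFFit(map_pf, post, grid, threshold75, flags, estimator)


@dataclass(frozen=True)
class FinalEstimate:
    value: float
    flagged: bool
    reason: str = ""


def finalize_estimate(value, kind: str) -> FinalEstimate:
    """Apply the reporting rules used for human estimates.

    * ``ipd_fl`` fits below 65 Hz are based on extrapolation below the
      lowest presented frequency and are replaced with the 100-Hz
      confidence upper bound;
    * JND estimates beyond the maximum presented stimulus are substituted
      by that maximum (180 deg for IPD, 16 dB for ILD, 10 dB for the
      intensity increment).
    """
    if isinstance(value, PFFit):
        value = value.threshold75
    value = float(value)
    if kind == "ipd_fl":
        if value < FL_LOWER_CONFIDENCE_CUTOFF:
            return FinalEstimate(FL_SUBSTITUTE, True, "near_chance_upper_bound")
        return FinalEstimate(value, False)
    if kind in GRID_MAXIMA:
        vmax = GRID_MAXIMA[kind]
        if value > vmax:
            return FinalEstimate(vmax, True, "clamped_to_maximum_presented")
        return FinalEstimate(value, False)
    raise ValueError(f"unknown task kind {kind!r}")
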