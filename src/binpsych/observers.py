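"""Response-generating models standing in for human listeners.

Three observer types:

* ``pf`` — responds correctly with the probability given by its own
  psychometric function at the presented stimulus value;
* ``random`` — Bernoulli(0.5), the null model for chance performance;
* ``single_ear_ideal`` — an ideal observer that ignores binaural cues
  and compares the level of the manipulated tones between intervals
  within the louder (right) ear.  Under a level rove this decision
  statistic is ILD/2 plus the difference of two independent uniform
  roves, which is triangular; its psychometric function has a closed
  form and crosses 75% correct at 2R(1 - 1/sqrt(2)) where R is the full
  rove range (= 11.7 dB for the +/-10-dB rove).

Observers are memoryless: practice effects across repeated measurements
live in the battery/cohort layer, not here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .psychometrics import PsychFun, pf_eval

__all__ = [
    "ObserverModel",
    "respond",
    "response_probability",
    "single_ear_pc",
    "single_ear_pc_mc",
]


@dataclass(frozen=True)
class ObserverModel:
    type: str                       # pf | random | single_ear_ideal
    pf: PsychFun | None = None
    rove_halfrange: float = 10.0    # dB, for the single-ear ideal observer

    def __post_init__(self):
        if self.type not in ("pf", "random", "single_ear_ideal"):
            raise ValueError(f"unknown observer type {self.type!r}")
        if self.type == "pf" and self.pf is None:
            raise ValueError("pf observer requires a PsychFun")


def single_ear_pc(ild: float, rove_halfrange: float = 10.0) -> float:
    """Probability correct for the single-ear ideal observer.

    The statistic is ILD/2 + D with D = U1 - U2, the difference of two
    independent uniforms on +/-``rove_halfrange`` dB (triangular on
    +/-2*``rove_halfrange``); the observer picks the interval with the
    larger manipulated-tone level, ties broken at random.
    """
    ild = float(ild)
    if ild < 0:
        raise ValueError("ild must be non-negative")
    r = 2.0 * float(rove_halfrange)
    if r == 0.0:
        return 1.0 if ild > 0 else 0.5
    t = ild / 2.0
    if t >= r:
        return 1.0
    # P(D > -t) = 1 - F_triangular(-t)
    return 1.0 - (r - t) ** 2 / (2.0 * r * r)


def single_ear_pc_mc(ild: float, rove_halfrange: float = 10.0,
                     n_draws: int = 100_000, rng=None) -> float:
    """Monte-Carlo estimate of :func:`single_ear_pc` (cross-check)."""
    if ild < 0:
        raise ValueError("ild must be non-negative")
    rng = np.random.default_rng(rng)
    d = rng.uniform(-rove_halfrange, rove_halfrange, size=(2, n_draws))
    stat = ild / 2.0 + d[0] - d[1]
    wins = (stat > 0).astype(float)
    wins[stat == 0] = 0.5
    return float(wins.mean())


def response_probability(observer: ObserverModel, stimulus: float) -> float:
    """Probability of a correct response at this stimulus value."""
    if observer.type == "random":
        return 0.5
    if observer.type == "pf":
        return float(pf_eval(observer.pf, stimulus))
    return single_ear_pc(stimulus, observer.rove_halfrange)


def respond(observer: ObserverModel, stimulus: float, rng,
            context=None) -> bool:
    """One Bernoulli response draw from the observer's model."""
    p = response_probability(observer, stimulus)
    return bool(rng.random() < p)
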