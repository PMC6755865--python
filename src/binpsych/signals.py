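"""Stereo tone-sequence stimuli for the interaural discrimination tasks.

Every trial is two-interval: each interval holds four 400-ms pure tones
(50-ms raised-cosine on/off ramps) separated by 25-ms silent gaps, the
intervals separated by 400 ms.  The reference interval is diotic; in the
target interval the second and fourth tones carry the manipulation:

* ``ipd_fl``        — 180-deg IPD, rendered as -90/+90-deg phase shifts
                      in the left/right ears;
* ``ipd_jnd``       — +/-magnitude IPDs of opposite sign (tone 2
                      left-leading, tone 4 right-leading);
* ``ild_jnd``       — the level is lowered by ILD/2 on the left and
                      raised by ILD/2 on the right;
* ``int_jnd``       — a diotic level increment of ``magnitude`` dB;
* ``ild_training``  — ILD as in ``ild_jnd``, with the matching reference
                      tones raised by ILD/2 in both ears so that loudness
                      cannot cue the target.

Rove conditions (ILD task): ``level_rove`` draws one diotic offset per
tone — eight per trial — uniformly from -10 to +10 dB in 0.5-dB steps;
``ipd_level_rove`` additionally draws |IPD| uniformly from 0 to 45 deg
in 1-deg steps for the second and fourth tones of both intervals (signs
left-leading for tone 2, right-leading for tone 4).

Sign convention: positive IPD means the right ear is phase-advanced
(perceived toward the right); rendering splits an IPD into -ipd/2 on the
left and +ipd/2 on the right.  Positive ILD means the right ear is
louder.  The presentation level is an abstract dB scalar (nominally
dB SL); no real-ear calibration is modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.io import wavfile

__all__ = [
    "ToneSpec",
    "ToneSequenceSpec",
    "StereoSignal",
    "build_trial",
    "render",
    "measure_interaural",
    "write_wav",
    "tone_window",
]

TONE_DURATION = 0.400      # s
RAMP_DURATION = 0.050      # s, raised-cosine on and off
TONE_GAP = 0.025           # s
INTERVAL_GAP = 0.400       # s
SAMPLE_RATE = 48_000       # Hz
ROVE_HALFRANGE = 10.0      # dB
ROVE_STEP = 0.5            # dB
IPD_ROVE_MAX = 45          # deg, integer steps
_FULL_SCALE_LEVEL = 60.0   # dB mapped to amplitude 1.0

_MAGNITUDE_RANGES = {
    "ipd_fl": (0.0, 180.0),
    "ipd_jnd": (0.0, 180.0),
    "ild_jnd": (0.0, 16.0),
    "int_jnd": (0.0, 10.0),
    "ild_training": (0.0, 16.0),
}
_CONDITIONS = {"none", "no_rove", "level_rove", "ipd_level_rove"}


@dataclass(frozen=True)
class ToneSpec:
    frequency: float           # Hz
    duration: float = TONE_DURATION
    ramp: float = RAMP_DURATION
    ipd: float = 0.0           # deg; positive = right ear leads
    ild: float = 0.0           # dB;  positive = right ear louder
    level_offset: float = 0.0  # dB diotic rove / increment offset
    base_level: float = 30.0   # dB, abstract presentation level

    def __post_init__(self):
        if not self.frequency > 0:
            raise ValueError("frequency must be positive")
        if not self.duration > 2 * self.ramp:
            raise ValueError("duration must exceed twice the ramp time")
        if abs(self.ipd) > 180.0:
            raise ValueError("|ipd| must not exceed 180 deg")


@dataclass(frozen=True)
class ToneSequenceSpec:
    intervals: tuple           # 2 tuples of 4 ToneSpec
    target_interval: int       # 1 or 2
    interval_gap: float = INTERVAL_GAP
    tone_gap: float = TONE_GAP

    def __post_init__(self):
        if len(self.intervals) != 2 or any(len(iv) != 4 for iv in self.intervals):
            raise ValueError("need exactly 2 intervals of 4 tones each")
        if self.target_interval not in (1, 2):
            raise ValueError("target_interval must be 1 or 2")


@dataclass
class StereoSignal:
    sample_rate: int
    left: np.ndarray
    right: np.ndarray

    def __post_init__(self):
        if len(self.left) != len(self.right):
            raise ValueError("channel lengths differ")
        if max(np.abs(self.left).max(initial=0.0),
               np.abs(self.right).max(initial=0.0)) > 1.0:
            raise ValueError("peak exceeds full scale")

    @property
    def duration(self) -> float:
        return len(self.left) / self.sample_rate


def _draw_rove_offsets(rng, n=8):
    steps = int(round(2 * ROVE_HALFRANGE / ROVE_STEP))
    return rng.integers(0, steps + 1, size=n) * ROVE_STEP - ROVE_HALFRANGE


def build_trial(kind: str, condition: str, magnitude: float,
                frequency: float = 500.0, rng=None,
                base_level: float = 30.0,
                target_interval: int | None = None) -> ToneSequenceSpec:
    """Assemble the full stimulus specification for one trial."""
    if kind not in _MAGNITUDE_RANGES:
        raise ValueError(f"unknown task kind {kind!r}")
    if condition not in _CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    lo, hi = _MAGNITUDE_RANGES[kind]
    if not lo <= magnitude <= hi:
        raise ValueError(f"magnitude {magnitude} outside [{lo}, {hi}] for {kind}")
    if condition in ("level_rove", "ipd_level_rove") and rng is None:
        raise ValueError("rng required for roved conditions")
    if target_interval is None:
        target_interval = int(rng.integers(1, 3)) if rng is not None else 2

    base = ToneSpec(frequency=frequency, base_level=base_level)
    tones = [[replace(base) for _ in range(4)] for _ in range(2)]
    tgt = target_interval - 1

    if kind == "ipd_fl":
        for j in (1, 3):
            tones[tgt][j] = replace(tones[tgt][j], ipd=magnitude)
    elif kind == "ipd_jnd":
        tones[tgt][1] = replace(tones[tgt][1], ipd=-magnitude)
        tones[tgt][3] = replace(tones[tgt][3], ipd=+magnitude)
    elif kind in ("ild_jnd", "ild_training"):
        for j in (1, 3):
            tones[tgt][j] = replace(tones[tgt][j], ild=magnitude)
        if kind == "ild_training":
            # matching reference tones raised by ILD/2 in both ears
            ref = 1 - tgt
            for j in (1, 3):
                tones[ref][j] = replace(
                    tones[ref][j],
                    level_offset=tones[ref][j].level_offset + magnitude / 2.0,
                )
    elif kind == "int_jnd":
        for j in (1, 3):
            tones[tgt][j] = replace(
                tones[tgt][j],
                level_offset=tones[tgt][j].level_offset + magnitude,
            )

    if condition in ("level_rove", "ipd_level_rove"):
        offsets = _draw_rove_offsets(rng, n=8)
        k = 0
        for i in range(2):
            for j in range(4):
                tones[i][j] = replace(
                    tones[i][j],
                    level_offset=tones[i][j].level_offset + float(offsets[k]),
                )
                k += 1
    if condition == "ipd_level_rove":
        # random opposite-sign IPDs on tones 2 and 4 of both intervals
        for i in range(2):
            for j, sign in ((1, -1), (3, +1)):
                mag = float(rng.integers(0, IPD_ROVE_MAX + 1))
                tones[i][j] = replace(tones[i][j],
                                      ipd=tones[i][j].ipd + sign * mag)

    return ToneSequenceSpec(
        intervals=(tuple(tones[0]), tuple(tones[1])),
        target_interval=target_interval,
    )


def _render_tone(tone: ToneSpec, sample_rate: int):
    n = int(round(tone.duration * sample_rate))
    t = np.arange(n) / sample_rate
    nr = int(round(tone.ramp * sample_rate))
    env = np.ones(n)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
    env[:nr] = ramp
    env[-nr:] = ramp[::-1]
    phase = math.radians(tone.ipd) / 2.0
    level_l = tone.base_level + tone.level_offset - tone.ild / 2.0
    level_r = tone.base_level + tone.level_offset + tone.ild / 2.0
    amp_l = 10.0 ** ((level_l - _FULL_SCALE_LEVEL) / 20.0)
    amp_r = 10.0 ** ((level_r - _FULL_SCALE_LEVEL) / 20.0)
    w = 2 * np.pi * tone.frequency
    left = amp_l * env * np.sin(w * t - phase)
    right = amp_r * env * np.sin(w * t + phase)
    return left, right


def render(spec: ToneSequenceSpec, sample_rate: int = SAMPLE_RATE) -> StereoSignal:
    """Synthesize a trial specification into two-channel audio."""
    gap_tone = np.zeros(int(round(spec.tone_gap * sample_rate)))
    gap_interval = np.zeros(int(round(spec.interval_gap * sample_rate)))
    chunks_l, chunks_r = [], []
    for i, interval in enumerate(spec.intervals):
        if i:
            chunks_l.append(gap_interval)
            chunks_r.append(gap_interval)
        for j, tone in enumerate(interval):
            if j:
                chunks_l.append(gap_tone)
                chunks_r.append(gap_tone)
            l, r = _render_tone(tone, sample_rate)
            chunks_l.append(l)
            chunks_r.append(r)
    return StereoSignal(sample_rate, np.concatenate(chunks_l),
                        np.concatenate(chunks_r))


def tone_window(spec: ToneSequenceSpec, interval: int, tone_index: int,
                margin: float | None = None):
    """Steady-state (start, end) times of one tone in the rendered signal.

    ``interval`` and ``tone_index`` are 1-based; the window excludes the
    ramps plus an extra safety ``margin`` (default: one ramp time).
    """
    tone = spec.intervals[interval - 1][tone_index - 1]
    if margin is None:
        margin = tone.ramp
    t0 = 0.0
    for i in range(interval - 1):
        for tn in spec.intervals[i]:
            t0 += tn.duration + spec.tone_gap
        t0 += spec.interval_gap - spec.tone_gap
    t0 += (tone_index - 1) * (tone.duration + spec.tone_gap)
    return (t0 + tone.ramp + margin, t0 + tone.duration - tone.ramp - margin)


def measure_interaural(signal: StereoSignal, frequency: float, window):
    """Measured (IPD in deg, ILD in dB) over a steady-state window.

    The phase difference is taken at the probe frequency via complex
    demodulation; the level difference is the broadband RMS ratio.
    """
    t0, t1 = window
    if not (0.0 <= t0 < t1 <= signal.duration):
        raise ValueError("window outside signal")
    i0 = int(round(t0 * signal.sample_rate))
    i1 = int(round(t1 * signal.sample_rate))
    t = np.arange(i0, i1) / signal.sample_rate
    carrier = np.exp(-2j * np.pi * frequency * t)
    z_l = np.sum(signal.left[i0:i1] * carrier)
    z_r = np.sum(signal.right[i0:i1] * carrier)
    rms_l = np.sqrt(np.mean(signal.left[i0:i1] ** 2))
    rms_r = np.sqrt(np.mean(signal.right[i0:i1] ** 2))
    if rms_l == 0 or rms_r == 0:
        raise ValueError("window contains silence")
    ipd = math.degrees(np.angle(z_r * np.conj(z_l)))
    ild = 20.0 * math.log10(rms_r / rms_l)
    return ipd, ild


def write_wav(signal: StereoSignal, path) -> None:
    """Export as a 2-channel float32 WAV file."""
    data = np.stack([signal.left, signal.right], axis=1).astype(np.float32)
    wavfile.write(path, signal.sample_rate, data)


def trial_wav_name(kind: str, condition: str, magnitude: float) -> str:
    return f"{kind}_{condition}_{magnitude:g}.wav"
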