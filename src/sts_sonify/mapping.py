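"""Feature -> synthesis-parameter mappings.

The sonification model has a *fixed component* — CoM speed to flute
blowing pressure (S) and distance-from-stand to melodic pitch (P) — and a
*flexible component* — freezes to a bell strike (F) and shank jerk to a
pitch multiplier (J).  Mapping specifics:

====  ==================  ====================  =========  ========  ======  =========
id    feature             parameter             range      polarity  order   smoothing
====  ==================  ====================  =========  ========  ======  =========
S     CoM speed           flute pressure        0 - 1      ``+``     0.45    6 Hz
P     distance (d)        melodic note          A4 - A5    ``-``     0.75    none
F     freeze events       bell trigger          off - on   ``+``     1       none
J     shank jerk          pitch multiplier      1 - 10     ``+``     0.45    19 Hz
====  ==================  ====================  =========  ========  ======  =========

Every transfer is ``param = min + (max - min) * u^order`` with
``u = clip((x - lo)/(hi - lo), 0, 1)`` (inverted for ``-`` polarity).
The melodic pitch is quantized onto the eight tones of a one-octave
A major scale (A4..A5); the quantizer carries a half-step hysteresis to
prevent note chatter from postural sway, since the pitch channel is
deliberately unsmoothed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureFrames

COMBOS = ("S", "SJ", "SP", "SJF", "SPF", "SJPF")


@dataclass
class MappingSpec:
    """One feature -> parameter transfer (a Table-2 style row)."""

    feature: str
    param: str
    range: tuple
    polarity: str = "+"
    order: float = 1.0
    smoothing_fc: float | None = None
    feature_bounds: tuple = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.range[0] >= self.range[1]:
            raise ValueError("range.min must be below range.max")
        if self.order <= 0:
            raise ValueError("order must be positive")
        if self.polarity not in ("+", "-"):
            raise ValueError("polarity must be '+' or '-'")
        if self.feature_bounds[0] >= self.feature_bounds[1]:
            raise ValueError("feature_bounds.lo must be below hi")


@dataclass
class ScaleSpec:
    """One-octave equal-tempered major scale, tonic A4 by default."""

    tonic: float = 440.0
    semitones: tuple = (0, 2, 4, 5, 7, 9, 11, 12)  # major scale, tonic..octave

    @property
    def frequencies(self) -> np.ndarray:
        f = self.tonic * 2.0 ** (np.asarray(self.semitones) / 12.0)
        if not np.all(np.diff(f) > 0):
            raise ValueError("scale frequencies must ascend")
        return f

    @property
    def n_notes(self) -> int:
        return len(self.semitones)


def default_mapping_specs(speed_hi: float = 0.5,
                          speed_lo: float = 0.03,
                          jerk_threshold: float = 20000.0,
                          jerk_ceiling: float | None = None) -> dict:
    """The four shipped mappings.

    ``speed_lo``/``speed_hi`` are the CoM-speed bounds (bodylengths/s)
    between near-silence and maximum flute intensity; the small non-zero
    lower bound gates residual measurement noise so the instrument is
    silent when the body is at rest.  ``jerk_threshold``/``jerk_ceiling``
    bound the pitch-multiplier overshoot normalization (ceiling defaults
    to 4x the threshold).
    """
    if jerk_ceiling is None:
        jerk_ceiling = 4.0 * jerk_threshold
    return {
        "S": MappingSpec("com_speed", "pressure", (0.0, 1.0), "+", 0.45,
                         smoothing_fc=6.0, feature_bounds=(speed_lo, speed_hi)),
        "P": MappingSpec("d", "pitch_note", (0.0, 1.0), "-", 0.75,
                         smoothing_fc=None, feature_bounds=(0.0, 1.0)),
        "F": MappingSpec("freeze", "bell", (0.0, 1.0), "+", 1.0,
                         smoothing_fc=None),
        "J": MappingSpec("jerk", "pitch_multiplier", (1.0, 10.0), "+", 0.45,
                         smoothing_fc=19.0,
                         feature_bounds=(jerk_threshold, jerk_ceiling)),
    }


def apply_transfer(x, spec: MappingSpec):
    """Clipped, normalized, polarity-signed power-law transfer."""
    lo, hi = spec.feature_bounds
    u = np.clip((np.asarray(x, dtype=float) - lo) / (hi - lo), 0.0, 1.0)
    if spec.polarity == "-":
        u = 1.0 - u
    lo_p, hi_p = spec.range
    return lo_p + (hi_p - lo_p) * np.power(u, spec.order)


def one_pole_smooth(x: np.ndarray, fc: float, fs: float) -> np.ndarray:
    """Causal one-pole lowpass at the control rate, state = first sample.

    Step response reaches 63% of its final value at t = 1/(2*pi*fc).
    """
    alpha = 1.0 - np.exp(-2.0 * np.pi * fc / fs)
    y = np.empty_like(x, dtype=float)
    state = float(x[0])
    for i, xi in enumerate(x):
        state += alpha * (xi - state)
        y[i] = state
    return y


def speed_to_pressure(speed: np.ndarray, spec: MappingSpec,
                      fs: float) -> np.ndarray:
    """Mapping S: CoM speed -> flute blowing pressure in [0, 1]."""
    p = apply_transfer(speed, spec)
    if spec.smoothing_fc:
        p = one_pole_smooth(p, spec.smoothing_fc, fs)
    return p


def d_to_note(d: np.ndarray, spec: MappingSpec,
              scale: ScaleSpec | None = None,
              hysteresis: float | None = None) -> tuple:
    """Mapping P: distance-from-stand -> (note_index, frequency) series.

    The inverted 0.75-power transfer puts sitting (d >= 1) at the tonic
    and standing (d = 0) at the octave; the transformed value is
    quantized onto ``n_notes`` equally spaced bins, with hysteresis
    (default half a bin) so a value hovering at a bin edge does not
    chatter.  Descending notes are permitted when d increases (sit-backs).
    """
    scale = scale or ScaleSpec()
    n = scale.n_notes
    if hysteresis is None:
        hysteresis = 0.5 / n  # half a step width, in transformed units
    v = np.atleast_1d(apply_transfer(d, spec))
    width = 1.0 / n
    notes = np.empty(len(v), dtype=int)
    cur = int(min(n - 1, v[0] // width))
    for i, vi in enumerate(v):
        raw = int(min(n - 1, vi // width))
        if raw != cur:
            # leave the current bin only when clear of its (hysteresis-
            # widened) boundaries
            lo_edge = cur * width - hysteresis
            hi_edge = (cur + 1) * width + hysteresis
            if vi < lo_edge or vi >= hi_edge:
                cur = raw
        notes[i] = cur
    freqs = scale.frequencies[notes]
    return notes, freqs


def jerk_to_multiplier(jerk: np.ndarray, spec: MappingSpec,
                       fs: float) -> np.ndarray:
    """Mapping J: shank jerk -> pitch multiplier in [1, 10].

    Below-threshold jerk maps to 1; overshoot above the threshold is
    normalized by the configured ceiling and passed through the 0.45-power
    transfer, then smoothed at 19 Hz.
    """
    m = apply_transfer(jerk, spec)
    if spec.smoothing_fc:
        m = one_pole_smooth(m, spec.smoothing_fc, fs)
    return m


def freeze_to_bell(freeze_times: np.ndarray) -> np.ndarray:
    """Mapping F: one bell trigger per freeze onset (times pass through)."""
    return np.asarray(freeze_times, dtype=float)


@dataclass
class SynthControl:
    """Synthesis control streams at the control rate."""

    fs: float
    t: np.ndarray
    pressure: np.ndarray
    note_index: np.ndarray
    note_freq: np.ndarray
    pitch_multiplier: np.ndarray
    bell_times: np.ndarray
    combo: str = "SJPF"

    def validate(self) -> None:
        if np.any((self.pressure < 0) | (self.pressure > 1)):
            raise ValueError("pressure out of [0, 1]")
        if np.any((self.pitch_multiplier < 1) | (self.pitch_multiplier > 10)):
            raise ValueError("pitch multiplier out of [1, 10]")
        if np.any((self.note_freq < 440 - 1e-9) | (self.note_freq > 880 + 1e-9)):
            raise ValueError("note frequency out of [440, 880] Hz")


def features_to_controls(features: FeatureFrames,
                         specs: dict | None = None,
                         scale: ScaleSpec | None = None,
                         combo: str = "SJPF") -> SynthControl:
    """Run all four mappings, then apply the parameter-combination mask."""
    specs = specs or default_mapping_specs()
    scale = scale or ScaleSpec()
    fs = features.fs
    pressure = speed_to_pressure(features.com_speed, specs["S"], fs)
    notes, freqs = d_to_note(features.d, specs["P"], scale)
    mult = jerk_to_multiplier(features.jerk, specs["J"], fs)
    bells = freeze_to_bell(features.freeze_times)
    ctrl = SynthControl(
        fs=fs,
        t=features.t,
        pressure=pressure,
        note_index=notes,
        note_freq=freqs,
        pitch_multiplier=mult,
        bell_times=bells,
        combo="SJPF",
    )
    return combo_filter(ctrl, combo, scale)


def combo_filter(controls: SynthControl, combo: str,
                 scale: ScaleSpec | None = None) -> SynthControl:
    """Neutralize the mappings absent from a parameter combination.

    S is always present (it gates audibility); without P the pitch holds
    at the tonic, without J the multiplier is 1, without F no bell fires.
    """
    if combo not in COMBOS:
        raise ValueError(f"combo must be one of {COMBOS}, got {combo!r}")
    scale = scale or ScaleSpec()
    n = len(controls.t)
    note_index = controls.note_index
    note_freq = controls.note_freq
    mult = controls.pitch_multiplier
    bells = controls.bell_times
    if "P" not in combo:
        note_index = np.zeros(n, dtype=int)
        note_freq = np.full(n, scale.frequencies[0])
    if "J" not in combo:
        mult = np.ones(n)
    if "F" not in combo:
        bells = np.asarray([])
    return SynthControl(
        fs=controls.fs,
        t=controls.t,
        pressure=controls.pressure,
        note_index=note_index,
        note_freq=note_freq,
        pitch_multiplier=mult,
        bell_times=bells,
        combo=combo,
    )
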