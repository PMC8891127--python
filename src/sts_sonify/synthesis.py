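"""Offline audio rendering of synthesis control streams.

Two voices are rendered and mixed into 48 kHz / 24-bit stereo WAV
stimulus clips:

* **Flute** — an additive harmonic bank plus lowpassed breath noise,
  amplitude driven by the blowing pressure, fundamental = melodic note
  frequency x jerk pitch-multiplier.  The harmonic rolloff is chosen so
  that at the top of the melodic range (A5, multiplier 1) at least 90% of
  the voice's energy lies below 3 kHz, leaving the perceptually sensitive
  2-5 kHz band free for the bell and the jerk glitches.  Phase is
  accumulated sample-by-sample, so note changes are click-free, and the
  amplitude is slew-limited.
* **Bell** — a modal strike: exponentially decaying inharmonic partials
  (classic hum/prime/tierce/quint/nominal ratio set) reaching into the
  2-5 kHz band, one strike per freeze trigger; overlapping strikes sum.

These voices satisfy the spectral contracts of the sonification model
(band occupancy, broadband bell vs. harmonic flute) with plain additive /
modal synthesis; they are not waveguide physical models.
"""

from __future__ import annotations

import logging
import wave
from dataclasses import dataclass, field

import numpy as np

from .mapping import SynthControl

log = logging.getLogger(__name__)


@dataclass
class ClipParams:
    sample_rate: int = 48000
    channels: int = 2
    bit_depth: int = 24
    duration: float = 8.0

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))


@dataclass
class FluteParams:
    n_harmonics: int = 8
    harmonic_rolloff: float = 0.5     # amplitude ratio between harmonics
    noise_level: float = 0.04         # breath noise relative to harmonics
    noise_fc: float = 2500.0          # breath-noise lowpass, Hz
    max_slew_per_s: float = 50.0      # amplitude units per second


@dataclass
class BellParams:
    """Classic bell partial set relative to the strike's prime frequency."""

    prime: float = 1250.0
    ratios: tuple = (0.5, 1.0, 1.2, 1.5, 2.0, 2.67, 3.0, 3.56)
    amplitudes: tuple = (0.6, 1.0, 0.65, 0.5, 0.55, 0.35, 0.28, 0.2)
    decays: tuple = (0.45, 0.40, 0.32, 0.26, 0.22, 0.17, 0.14, 0.11)  # s
    attack: float = 0.004             # s, raised-cosine onset
    tail: float = 4.0                 # s rendered per strike
    clang_level: float = 0.6          # broadband strike transient, rel. level
    clang_decay: float = 0.03         # s
    clang_band: tuple = (2000.0, 5000.0)  # Hz


def _upsample(ctrl: np.ndarray, n_out: int, fs_ctrl: float,
              fs_audio: float) -> np.ndarray:
    """Linear interpolation of a control stream to the audio rate."""
    t_out = np.arange(n_out) / fs_audio
    t_in = np.arange(len(ctrl)) / fs_ctrl
    return np.interp(t_out, t_in, np.asarray(ctrl, dtype=float))


def _slew_limit(x: np.ndarray, max_delta: float) -> np.ndarray:
    y = np.empty_like(x)
    state = 0.0
    for i, xi in enumerate(x):
        step = np.clip(xi - state, -max_delta, max_delta)
        state += step
        y[i] = state
    return y


def render_flute(controls: SynthControl, clip: ClipParams | None = None,
                 params: FluteParams | None = None) -> np.ndarray:
    """Render the flute voice to mono float samples in [-1, 1]."""
    clip = clip or ClipParams()
    params = params or FluteParams()
    sr = clip.sample_rate
    if controls.fs > sr:
        raise ValueError("control rate exceeds the audio sample rate")
    n = clip.n_samples

    f0 = _upsample(controls.note_freq * controls.pitch_multiplier, n,
                   controls.fs, sr)
    pressure = _upsample(controls.pressure, n, controls.fs, sr)
    amp = _slew_limit(pressure, params.max_slew_per_s / sr)

    phase = 2.0 * np.pi * np.cumsum(f0) / sr
    nyquist = sr / 2.0
    tone = np.zeros(n)
    weight_total = 0.0
    dropped = False
    for k in range(1, params.n_harmonics + 1):
        a_k = params.harmonic_rolloff ** (k - 1)
        weight_total += a_k
        mask = (k * f0) < nyquist
        if not mask.all():
            dropped = True
        tone += a_k * np.where(mask, np.sin(k * phase), 0.0)
    if dropped:
        log.warning("harmonics above Nyquist dropped during render")
    tone /= weight_total

    rng = np.random.default_rng(12345)  # fixed: rendering is deterministic
    noise = rng.standard_normal(n)
    from scipy.signal import butter, lfilter

    b, a = butter(2, params.noise_fc / nyquist, btype="low")
    noise = lfilter(b, a, noise)
    noise /= max(1e-12, np.sqrt(np.mean(noise**2)))

    out = amp * (tone + params.noise_level * noise)
    peak = np.max(np.abs(out))
    if peak > 1.0:
        out = out / peak
    return out


def _bell_strike(sr: int, params: BellParams) -> np.ndarray:
    """One modal bell strike; level decays below -60 dBFS within the tail.

    The decaying inharmonic partials are preceded by a short broadband
    "clang" transient (band-limited noise in the 2-5 kHz band), which is
    what makes the strike spectrally flat relative to the harmonic flute.
    """
    n = int(params.tail * sr)
    t = np.arange(n) / sr
    out = np.zeros(n)
    for r, a, tau in zip(params.ratios, params.amplitudes, params.decays):
        f = params.prime * r
        if f >= sr / 2:
            continue
        out += a * np.exp(-t / tau) * np.sin(2.0 * np.pi * f * t)
    if params.clang_level > 0:
        from scipy.signal import butter, lfilter

        rng = np.random.default_rng(987654)  # fixed: strike is deterministic
        noise = rng.standard_normal(n)
        lo = params.clang_band[0] / (sr / 2)
        hi = min(0.99, params.clang_band[1] / (sr / 2))
        b, a = butter(2, [lo, hi], btype="band")
        noise = lfilter(b, a, noise)
        noise /= max(1e-12, np.max(np.abs(noise)))
        out += params.clang_level * noise * np.exp(-t / params.clang_decay)
    n_att = max(1, int(params.attack * sr))
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_att) / n_att))
    out[:n_att] *= ramp
    return out / np.max(np.abs(out))


def render_bell(trigger_times: np.ndarray, clip: ClipParams | None = None,
                params: BellParams | None = None,
                level: float = 0.8) -> np.ndarray:
    """Render bell strikes at the trigger times; overlapping strikes sum."""
    clip = clip or ClipParams()
    params = params or BellParams()
    sr = clip.sample_rate
    out = np.zeros(clip.n_samples)
    if len(np.atleast_1d(trigger_times)) == 0:
        return out
    strike = _bell_strike(sr, params) * level
    for t0 in np.atleast_1d(trigger_times):
        if not (0.0 <= t0 <= clip.duration):
            raise ValueError(f"trigger time {t0} s outside the clip")
        i0 = int(round(t0 * sr))
        seg = strike[: clip.n_samples - i0]
        out[i0 : i0 + len(seg)] += seg
    return out


def peak_normalize(x: np.ndarray, headroom_db: float = 1.0) -> np.ndarray:
    """Scale so the peak sits at -``headroom_db`` dBFS (silence unchanged)."""
    peak = float(np.max(np.abs(x))) if len(x) else 0.0
    if peak == 0.0:
        return x
    return x * (10.0 ** (-headroom_db / 20.0) / peak)


def write_wav_24bit(path, samples: np.ndarray, sample_rate: int = 48000,
                    channels: int = 2) -> None:
    """Write float samples in [-1, 1] as little-endian 24-bit PCM WAV.

    Mono input is duplicated across channels.  Output bytes are a pure
    function of the input samples.
    """
    x = np.asarray(samples, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("non-finite samples reached the WAV writer")
    if x.ndim == 1:
        x = np.tile(x[:, None], (1, channels))
    scaled = np.clip(np.round(x * (2**23 - 1)), -(2**23), 2**23 - 1)
    ints = scaled.astype("<i4")
    raw = ints.tobytes()
    # keep the low 3 of every 4 little-endian bytes -> packed 24-bit
    frames = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 4)[:, :3].tobytes()
    with wave.open(str(path), "wb") as wf:
        wf.setnchannels(channels)
        wf.setsampwidth(3)
        wf.setframerate(sample_rate)
        wf.writeframes(frames)


def read_wav_24bit(path) -> tuple:
    """Read a 24-bit PCM WAV back to float samples in [-1, 1].

    Returns ``(samples (n, channels), sample_rate)``.
    """
    with wave.open(str(path), "rb") as wf:
        assert wf.getsampwidth() == 3, "expected 24-bit PCM"
        sr = wf.getframerate()
        ch = wf.getnchannels()
        raw = wf.readframes(wf.getnframes())
    b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3)
    padded = np.zeros((b.shape[0], 4), dtype=np.uint8)
    padded[:, 1:] = b
    ints = padded.view("<i4")[:, 0] >> 8
    x = ints.astype(float) / (2**23 - 1)
    return x.reshape(-1, ch), sr


def mix_and_write(flute: np.ndarray, bell: np.ndarray, path,
                  clip: ClipParams | None = None) -> np.ndarray:
    """Sum the voices, peak-normalize to -1 dBFS, write the stereo WAV."""
    clip = clip or ClipParams()
    if len(flute) != len(bell):
        raise ValueError("flute and bell buffers must have equal length")
    mix = peak_normalize(flute + bell, headroom_db=1.0)
    write_wav_24bit(path, mix, clip.sample_rate, clip.channels)
    return mix


def render_clip(controls: SynthControl, path=None,
                clip: ClipParams | None = None,
                flute_params: FluteParams | None = None,
                bell_params: BellParams | None = None) -> np.ndarray:
    """Full render: flute + bell from one control stream, optional WAV."""
    clip = clip or ClipParams()
    flute = render_flute(controls, clip, flute_params)
    bell = render_bell(controls.bell_times, clip, bell_params)
    if path is not None:
        return mix_and_write(flute, bell, path, clip)
    return peak_normalize(flute + bell, headroom_db=1.0)
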