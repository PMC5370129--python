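"""Cochlear-implant stimulation current generation.

The Digisonic-SP-style implant encodes sound intensity by pulse-width
modulation (PWM): a monophasic rectangular pulse train at a fixed carrier
rate ``f_c`` (the clinical stimulation rate, ~500 pulses/s) whose per-pulse
*duration* follows the envelope of an amplitude-modulated tone at the
modulation frequency ``f_m``.  The pulse amplitude is constant; only the
active width carries the envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusConfig",
    "SampledSignal",
    "make_pwm_pulse_train",
    "contamination_fraction",
]


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled 1-D real signal.

    Parameters
    ----------
    samples : ndarray, shape (n,)
        Signal values; must be finite.
    sampling_rate_hz : float
        Sampling frequency in Hz.
    units : str
        Free-form unit label (e.g. ``"uA"``, ``"mV"``, ``"a.u."``).
    """

    samples: np.ndarray
    sampling_rate_hz: float
    units: str = "a.u."

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples must be finite")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        object.__setattr__(self, "samples", arr)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass(frozen=True)
class StimulusConfig:
    """Parameters of the PWM pulse-train stimulus.

    ``carrier_freq_hz`` is the implant stimulation rate (pulses per second),
    ``modulation_freq_hz`` the envelope frequency of the encoded AM tone and
    ``modulation_depth`` its relative depth in [0, 1].  ``base_pulse_width_s``
    is the maximum active-pulse width; the instantaneous width of the pulse
    with onset at time ``t`` is::

        w(t) = base_pulse_width_s * (1 + MD * sin(2*pi*f_m*t)) / (1 + MD)

    (``width_mapping="normalized"``, the default: the widest pulse equals the
    base width, keeping per-pulse charge bounded) or, with
    ``width_mapping="linear"``, the same numerator without the ``1 + MD``
    normalization (the base width is then the *mean* width).
    """

    carrier_freq_hz: float = 500.0
    modulation_freq_hz: float = 39.06
    modulation_depth: float = 0.75
    base_pulse_width_s: float = 100e-6
    amplitude: float = 1.0
    sampling_rate_hz: float = 10_000.0
    duration_s: float = 10.0
    seed: int = 0
    width_mapping: str = "normalized"
    units: str = "uA"

    def __post_init__(self) -> None:
        if self.carrier_freq_hz <= 0 or self.carrier_freq_hz >= self.sampling_rate_hz / 2:
            raise ValueError("carrier frequency must satisfy 0 < f_c < f_s/2")
        if not 0 < self.modulation_freq_hz < self.carrier_freq_hz:
            raise ValueError("modulation frequency must satisfy 0 < f_m < f_c")
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation depth must lie in [0, 1]")
        if not 0 < self.base_pulse_width_s < 1.0 / self.carrier_freq_hz:
            raise ValueError("base pulse width must be positive and below the pulse period")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.width_mapping not in ("normalized", "linear"):
            raise ValueError("width_mapping must be 'normalized' or 'linear'")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))


def pulse_onsets(cfg: StimulusConfig) -> np.ndarray:
    """Sample indices of pulse onsets (one per carrier period)."""
    n_pulses = int(np.floor(cfg.duration_s * cfg.carrier_freq_hz - 1e-9)) + 1
    k = np.arange(n_pulses)
    idx = np.round(k * cfg.sampling_rate_hz / cfg.carrier_freq_hz).astype(np.int64)
    return idx[idx < cfg.n_samples]


def pulse_widths(cfg: StimulusConfig) -> np.ndarray:
    """Per-pulse widths in samples (quantized, >= 1)."""
    onsets = pulse_onsets(cfg)
    t = onsets / cfg.sampling_rate_hz
    env = 1.0 + cfg.modulation_depth * np.sin(2.0 * np.pi * cfg.modulation_freq_hz * t)
    if cfg.width_mapping == "normalized":
        env = env / (1.0 + cfg.modulation_depth)
    w = cfg.base_pulse_width_s * env * cfg.sampling_rate_hz
    return np.maximum(1, np.round(w).astype(np.int64))


def make_pwm_pulse_train(cfg: StimulusConfig) -> SampledSignal:
    """Generate the PWM monophasic pulse train ``i_stim``.

    Pulses are rectangular, left-aligned at onsets spaced one carrier period
    apart, of constant amplitude; the signal is zero between pulses.

    Raises
    ------
    ValueError
        If any quantized width reaches the inter-pulse interval (the pulses
        would merge into a DC segment).
    """
    onsets = pulse_onsets(cfg)
    widths = pulse_widths(cfg)
    period = cfg.sampling_rate_hz / cfg.carrier_freq_hz
    if np.any(widths >= np.floor(period)):
        raise ValueError(
            "pulse width quantizes to >= the inter-pulse interval; "
            "reduce base_pulse_width_s or raise the sampling rate"
        )
    x = np.zeros(cfg.n_samples)
    for on, w in zip(onsets, widths):
        x[on : min(on + w, cfg.n_samples)] = cfg.amplitude
    return SampledSignal(x, cfg.sampling_rate_hz, units=cfg.units)


def contamination_fraction(artifact_span_s: float, carrier_freq_hz: float) -> float:
    """Fraction of the inter-pulse interval occupied by each pulse's artifact.

    This is the fraction of the recording a blanking approach would discard:
    ``min(1, artifact_span_s * carrier_freq_hz)``.  A 1 ms per-pulse spread at
    a 500 Hz stimulation rate occupies half of each 2 ms interval.
    """
    if artifact_span_s < 0:
        raise ValueError("artifact span must be non-negative")
    if carrier_freq_hz <= 0:
        raise ValueError("carrier frequency must be positive")
    return float(min(1.0, artifact_span_s * carrier_freq_hz))
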