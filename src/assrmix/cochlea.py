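"""Electrode-cochlea interface and auditory-nerve drive.

The stimulation current ``i_stim`` passes through a capacitive
electrode-electrolyte interface (double-layer capacitance ``C_dl`` in
parallel with a faradaic resistance ``Z_f``, in series with the cochlea's
input resistance ``R_s``).  The induced potential ``v_stim`` both

* is the time course of the artifactual dipole (what leaks to the scalp), and
* drives, through Freeman's wave-to-pulse sigmoid, the mean firing rate of
  the auditory nerve that feeds the neural-mass network.

Units: currents in microamperes, impedances in kiloohms, capacitance in
microfarads, potentials in millivolts (1 kOhm * 1 uA = 1 mV; the interface
time constant Z_f*C_dl is then in milliseconds * 1e-3 when expressed in SI
seconds as below).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional
import warnings

import numpy as np
import scipy.signal

from .stimulus import SampledSignal

__all__ = [
    "InterfaceParams",
    "SigmoidParams",
    "NoiseSpec",
    "interface_response",
    "sigmoid_rate",
    "cochlear_module",
]


@dataclass(frozen=True)
class InterfaceParams:
    """Electrode-cochlea interface: first-order impedance.

    The transfer impedance of the capacitive path is
    ``Z_ec(s) = Z_f / (1 + s * Z_f * C_dl)`` (pole at ``1/(Z_f*C_dl)``), in
    series with the resistive path ``R_s``.  Defaults give an interface time
    constant of 0.05 ms, short enough that the per-pulse potential stays a
    sparse, strongly supra-Gaussian spike train (see docs/methods.md).
    """

    C_dl_uF: float = 0.01
    Z_f_kohm: float = 5.0
    R_s_kohm: float = 3.0

    def __post_init__(self) -> None:
        if min(self.C_dl_uF, self.Z_f_kohm, self.R_s_kohm) <= 0:
            raise ValueError("interface parameters must be strictly positive")

    @property
    def tau_s(self) -> float:
        """Interface time constant Z_f*C_dl in seconds (kOhm*uF = ms)."""
        return self.Z_f_kohm * self.C_dl_uF * 1e-3


@dataclass(frozen=True)
class SigmoidParams:
    """Freeman wave-to-pulse sigmoid S(v) = 2*e0 / (1 + exp(r*(v0 - v))).

    ``2*e0`` is the maximal mean firing rate (s^-1), ``v0`` the potential at
    half-maximum rate ``e0`` (mV) and ``r`` the slope (mV^-1).  The sigmoid
    increases with depolarization; set ``increasing=False`` for the opposite
    orientation.
    """

    e0: float = 2.5
    v0: float = 6.0
    r: float = 0.56
    increasing: bool = True

    def __post_init__(self) -> None:
        if self.e0 <= 0 or self.r <= 0:
            raise ValueError("e0 and r must be strictly positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian white-noise input (mean, standard deviation, seed).

    ``std`` is specified at the reference sampling rate (10 kHz); when the
    noise is materialized at another rate the per-sample deviation is scaled
    by ``sqrt(f_s / 10 kHz)`` so that the band-limited power reaching the
    slow neural kernels is rate-independent.
    """

    mean: float = 0.0
    std: float = 0.0
    seed: int = 0
    reference_rate_hz: float = 10_000.0

    def __post_init__(self) -> None:
        if self.std < 0:
            raise ValueError("noise std must be non-negative")

    def sample(
        self,
        n: int,
        sampling_rate_hz: Optional[float] = None,
        rng: Optional[np.random.Generator] = None,
    ) -> np.ndarray:
        if rng is None:
            rng = np.random.default_rng(self.seed)
        std = self.std
        if sampling_rate_hz is not None:
            std = std * np.sqrt(sampling_rate_hz / self.reference_rate_hz)
        return self.mean + std * rng.standard_normal(n)


def interface_response(i_stim: SampledSignal, params: InterfaceParams) -> SampledSignal:
    """Potential ``v_stim`` induced by ``i_stim`` across the interface.

    The capacitive path is the first-order low-pass
    ``Z_ec(s) = Z_f/(1 + s*Z_f*C_dl)`` discretized by exact zero-order hold
    (matched exponential; stable at any sampling rate); the resistive path
    adds ``R_s * i_stim`` instantaneously.
    """
    fs = i_stim.sampling_rate_hz
    pole_hz = 1.0 / (2.0 * np.pi * params.tau_s)
    if pole_hz > fs / 4:
        warnings.warn(
            "sampling rate is low relative to the interface pole "
            f"({pole_hz:.0f} rad-equivalent Hz vs f_s={fs:.0f} Hz); "
            "the capacitive transient is under-resolved",
            stacklevel=2,
        )
    a = np.exp(-1.0 / (fs * params.tau_s))
    # ZOH discretization: DC gain b/(1-a) = Z_f.
    b = params.Z_f_kohm * (1.0 - a)
    zec = scipy.signal.lfilter([b], [1.0, -a], i_stim.samples)
    v = zec + params.R_s_kohm * i_stim.samples
    return SampledSignal(v, fs, units="mV")


def sigmoid_rate(v: np.ndarray | float, params: SigmoidParams) -> np.ndarray | float:
    """Mean firing rate S(v), strictly inside (0, 2*e0)."""
    sign = 1.0 if params.increasing else -1.0
    x = sign * params.r * (params.v0 - np.asarray(v, dtype=float))
    # exp overflow-safe: rate -> 0 for very hyperpolarized inputs
    out = 2.0 * params.e0 / (1.0 + np.exp(np.clip(x, -700, 700)))
    if np.isscalar(v):
        return float(out)
    return out


def cochlear_module(
    i_stim: SampledSignal,
    interface: InterfaceParams = InterfaceParams(),
    sigmoid: SigmoidParams = SigmoidParams(),
    residual: NoiseSpec = NoiseSpec(),
    rng: Optional[np.random.Generator] = None,
) -> tuple[SampledSignal, SampledSignal]:
    """Split the stimulus into artifact dipole dynamics and nerve drive.

    Returns ``(artifact_source, nerve_rate)``: the artifactual source is
    ``v_stim`` itself (the potential leaking to the scalp); the nerve rate is
    the sigmoid of ``v_stim`` plus residual-hearing Gaussian noise.
    """
    v_stim = interface_response(i_stim, interface)
    noise = residual.sample(v_stim.n_samples, v_stim.sampling_rate_hz, rng=rng)
    rate = sigmoid_rate(v_stim.samples + noise, sigmoid)
    return v_stim, SampledSignal(rate, v_stim.sampling_rate_hz, units="s^-1")
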