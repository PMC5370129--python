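"""Neural-mass network of the ascending auditory pathway.

Five interacting modules — brainstem (BS), left/right thalamus (Th), and
left/right primary auditory cortex (A1) — are simulated as lumped neuronal
populations.  Each cortical/thalamic module contains a principal-cell
population inhibited by a fast (GABA_A,fast) and a slow (GABA_A,slow)
interneuron population; the brainstem contains a principal population and a
single (fast) inhibitory population.  The auditory-nerve firing rate from
the cochlear module drives the brainstem, which excites thalamus and cortex
and receives excitatory feedback from all four; thalamus additionally
relays to ipsilateral cortex.  Gaussian noise on the principal-cell inputs
models non-specific excitation.

Dynamics use the standard second-order synaptic kernel
``h(t) = G * w * t * exp(-w t)`` (PSP state ``z`` obeying
``z'' = G w u - 2 w z' - w^2 z`` with presynaptic pulse density ``u``) and
Freeman's wave-to-pulse sigmoid.  Integration is Euler-Maruyama at
``dt = 1/f_s``; each module's output is the mean membrane potential of its
principal population.  The brainstem's excitatory kernel is faster (same DC
gain) so its output retains carrier-frequency content, which the slower
thalamic and cortical kernels progressively low-pass — the spectral
ordering seen in auditory steady-state data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numba import njit

from .cochlea import NoiseSpec, SigmoidParams, sigmoid_rate
from .stimulus import SampledSignal

__all__ = [
    "PopulationParams",
    "ConnectivityMatrix",
    "SourceDynamics",
    "simulate_network",
    "steady_state",
    "NEURAL_ROLES",
]

#: Row order of the neural sources everywhere in the package.
NEURAL_ROLES = ("brainstem", "thalamus_l", "thalamus_r", "a1_l", "a1_r")


@dataclass(frozen=True)
class PopulationParams:
    """Synaptic kernel constants of one module type.

    ``exc``/``slow``/``fast`` are (gain mV, rate s^-1) pairs for the
    excitatory, slow-inhibitory and fast-inhibitory PSP kernels.  Defaults
    follow the standard neural-mass constants A=3.25/a=100, B=22/b=50,
    G=10/g=500.
    """

    exc_gain: float = 3.25
    exc_rate: float = 100.0
    slow_gain: float = 22.0
    slow_rate: float = 50.0
    fast_gain: float = 10.0
    fast_rate: float = 500.0
    sigmoid: SigmoidParams = field(default_factory=SigmoidParams)

    def __post_init__(self) -> None:
        if min(self.exc_gain, self.slow_gain, self.fast_gain) < 0:
            raise ValueError("kernel gains must be non-negative")
        if min(self.exc_rate, self.slow_rate, self.fast_rate) <= 0:
            raise ValueError("kernel rate constants must be positive")


#: Brainstem kernel: 5x faster excitatory rate at equal DC gain (A*u/a).
BRAINSTEM_DEFAULT = PopulationParams(exc_gain=16.25, exc_rate=500.0)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Directed connection gains and per-module noise of the network.

    Inter-module gains scale presynaptic firing rates into postsynaptic
    pulse densities; within-module gains follow the usual convention of a
    common constant C=135 scaled per projection.  The cochlea is
    feed-forward only (no feedback to the stimulus).  Noise specs apply to
    the principal populations (left/right share a spec but draw independent
    streams).
    """

    cochlea_to_bs: float = 30.0
    bs_to_thalamus: float = 40.0
    bs_to_cortex: float = 10.0
    thalamus_to_cortex: float = 30.0
    feedback_to_bs: float = 2.0
    p_to_slow: float = 33.75
    slow_to_p: float = 33.75
    p_to_fast: float = 40.5
    fast_to_p: float = 13.5
    bs_p_to_i: float = 33.75
    bs_i_to_p: float = 13.5
    bs_noise: NoiseSpec = field(default_factory=lambda: NoiseSpec(mean=10.0, std=2.0))
    thalamus_noise: NoiseSpec = field(default_factory=lambda: NoiseSpec(mean=30.0, std=5.0))
    cortex_noise: NoiseSpec = field(default_factory=lambda: NoiseSpec(mean=90.0, std=30.0))

    def __post_init__(self) -> None:
        gains = (
            self.cochlea_to_bs, self.bs_to_thalamus, self.bs_to_cortex,
            self.thalamus_to_cortex, self.feedback_to_bs, self.p_to_slow,
            self.slow_to_p, self.p_to_fast, self.fast_to_p,
            self.bs_p_to_i, self.bs_i_to_p,
        )
        if min(gains) < 0:
            raise ValueError("connection gains must be non-negative")


@dataclass
class SourceDynamics:
    """The six dipole time courses: five neural sources plus the artifact.

    ``neural`` rows follow :data:`NEURAL_ROLES`; ``artifact`` (the
    electrode-cochlea interface potential) may be absent when only the
    network has been simulated.
    """

    sampling_rate_hz: float
    neural: np.ndarray  # (5, n)
    artifact: Optional[np.ndarray] = None  # (n,)
    roles: tuple[str, ...] = NEURAL_ROLES

    def __post_init__(self) -> None:
        self.neural = np.asarray(self.neural, dtype=float)
        if self.neural.ndim != 2 or self.neural.shape[0] != len(self.roles):
            raise ValueError("neural must be (n_roles, n_samples)")
        if not np.all(np.isfinite(self.neural)):
            raise ValueError("neural dynamics must be finite")
        if self.artifact is not None:
            self.artifact = np.asarray(self.artifact, dtype=float)
            if self.artifact.shape != (self.neural.shape[1],):
                raise ValueError("artifact length must match neural sources")

    @property
    def n_samples(self) -> int:
        return self.neural.shape[1]

    def source(self, role: str) -> np.ndarray:
        if role == "cochlea":
            if self.artifact is None:
                raise ValueError("artifact time course not set")
            return self.artifact
        return self.neural[self.roles.index(role)]

    def all_sources(self) -> dict[str, np.ndarray]:
        out = {r: self.neural[i] for i, r in enumerate(self.roles)}
        if self.artifact is not None:
            out["cochlea"] = self.artifact
        return out


# population indices
_P_BS, _I_BS = 0, 1
_MODULES = {  # role -> (P, I_fast, I_slow) population indices
    "thalamus_l": (2, 3, 4),
    "thalamus_r": (5, 6, 7),
    "a1_l": (8, 9, 10),
    "a1_r": (11, 12, 13),
}
_N_POP = 14
# external drive columns
_EXT_NERVE, _EXT_BS, _EXT_THL, _EXT_THR, _EXT_A1L, _EXT_A1R = range(6)
_N_EXT = 6


def _build_network(pops: dict[str, PopulationParams], conn: ConnectivityMatrix):
    """Assemble the synapse arrays consumed by the compiled integrator."""
    syn_target, syn_sign, syn_G, syn_w = [], [], [], []
    Wp_rows, We_rows = [], []

    def add(target, sign, gain, rate, wp, we):
        syn_target.append(target)
        syn_sign.append(sign)
        syn_G.append(gain)
        syn_w.append(rate)
        Wp_rows.append(wp)
        We_rows.append(we)

    def zeros_p():
        return np.zeros(_N_POP)

    def zeros_e():
        return np.zeros(_N_EXT)

    bs = pops["brainstem"]
    # BS principal: cochlear drive + feedback + noise (exc), I_BS (fast inh)
    wp = zeros_p()
    for role in _MODULES:
        wp[_MODULES[role][0]] = conn.feedback_to_bs
    we = zeros_e()
    we[_EXT_NERVE] = conn.cochlea_to_bs
    we[_EXT_BS] = 1.0
    add(_P_BS, 1.0, bs.exc_gain, bs.exc_rate, wp, we)
    wp = zeros_p(); wp[_I_BS] = conn.bs_i_to_p
    add(_P_BS, -1.0, bs.fast_gain, bs.fast_rate, wp, zeros_e())
    wp = zeros_p(); wp[_P_BS] = conn.bs_p_to_i
    add(_I_BS, 1.0, bs.exc_gain, bs.exc_rate, wp, zeros_e())

    ext_noise = {"thalamus_l": _EXT_THL, "thalamus_r": _EXT_THR,
                 "a1_l": _EXT_A1L, "a1_r": _EXT_A1R}
    for role, (p_idx, i_idx, s_idx) in _MODULES.items():
        pp = pops["thalamus" if role.startswith("thalamus") else "cortex"]
        # excitatory afferents onto P (+ noise); thalamo-cortical relay is
        # bilateral (each auditory cortex pools both thalami equally)
        wp = zeros_p()
        if role.startswith("thalamus"):
            wp[_P_BS] = conn.bs_to_thalamus
        else:
            wp[_P_BS] = conn.bs_to_cortex
            wp[_MODULES["thalamus_l"][0]] = conn.thalamus_to_cortex / 2.0
            wp[_MODULES["thalamus_r"][0]] = conn.thalamus_to_cortex / 2.0
        we = zeros_e(); we[ext_noise[role]] = 1.0
        add(p_idx, 1.0, pp.exc_gain, pp.exc_rate, wp, we)
        # slow inhibition onto P
        wp = zeros_p(); wp[s_idx] = conn.slow_to_p
        add(p_idx, -1.0, pp.slow_gain, pp.slow_rate, wp, zeros_e())
        # fast inhibition onto P
        wp = zeros_p(); wp[i_idx] = conn.fast_to_p
        add(p_idx, -1.0, pp.fast_gain, pp.fast_rate, wp, zeros_e())
        # P -> slow interneurons
        wp = zeros_p(); wp[p_idx] = conn.p_to_slow
        add(s_idx, 1.0, pp.exc_gain, pp.exc_rate, wp, zeros_e())
        # P -> fast interneurons
        wp = zeros_p(); wp[p_idx] = conn.p_to_fast
        add(i_idx, 1.0, pp.exc_gain, pp.exc_rate, wp, zeros_e())

    return (
        np.array(syn_target, dtype=np.int64),
        np.array(syn_sign, dtype=np.float64),
        np.array(syn_G, dtype=np.float64),
        np.array(syn_w, dtype=np.float64),
        np.array(Wp_rows, dtype=np.float64),
        np.array(We_rows, dtype=np.float64),
    )


@njit(cache=True)
def _integrate(target, sign, G, w, Wp, We, ext, dt, e0, v0, r, out_pops, guard):
    n_steps = ext.shape[0]
    n_syn = target.shape[0]
    n_pop = Wp.shape[1]
    n_ext = We.shape[1]
    z = np.zeros(n_syn)
    zd = np.zeros(n_syn)
    v = np.zeros(n_pop)
    rates = np.zeros(n_pop)
    out = np.zeros((out_pops.shape[0], n_steps))
    for t in range(n_steps):
        for p in range(n_pop):
            v[p] = 0.0
        for j in range(n_syn):
            v[target[j]] += sign[j] * z[j]
        for p in range(n_pop):
            x = r * (v0 - v[p])
            if x > 700.0:
                x = 700.0
            elif x < -700.0:
                x = -700.0
            rates[p] = 2.0 * e0 / (1.0 + np.exp(x))
            if np.abs(v[p]) > guard:
                return out, t
        for k in range(out_pops.shape[0]):
            out[k, t] = v[out_pops[k]]
        for j in range(n_syn):
            u = 0.0
            for p in range(n_pop):
                u += Wp[j, p] * rates[p]
            for e in range(n_ext):
                u += We[j, e] * ext[t, e]
            if u < 0.0:
                u = 0.0
            zdd = G[j] * w[j] * u - 2.0 * w[j] * zd[j] - w[j] * w[j] * z[j]
            zd[j] += dt * zdd
            z[j] += dt * zd[j]
    return out, -1


def default_populations() -> dict[str, PopulationParams]:
    """Per-module-type kernel constants (brainstem faster than the rest)."""
    return {
        "brainstem": BRAINSTEM_DEFAULT,
        "thalamus": PopulationParams(),
        "cortex": PopulationParams(),
    }


def simulate_network(
    nerve_rate: SampledSignal,
    pops: Optional[dict[str, PopulationParams]] = None,
    conn: Optional[ConnectivityMatrix] = None,
    duration_s: Optional[float] = None,
    seed: int = 0,
    guard_mv: float = 1e3,
) -> SourceDynamics:
    """Integrate the five-module network driven by the auditory-nerve rate.

    Noise streams for the five principal populations are drawn from a
    generator seeded with ``seed``; identical inputs and seed give
    bit-identical trajectories.  Raises if any membrane potential exceeds
    ``guard_mv`` (numeric divergence).
    """
    pops = pops or default_populations()
    conn = conn or ConnectivityMatrix()
    fs = nerve_rate.sampling_rate_hz
    n_steps = nerve_rate.n_samples
    if duration_s is not None:
        want = int(round(duration_s * fs))
        if want > n_steps:
            raise ValueError("nerve_rate does not cover the requested duration")
        n_steps = want

    rng = np.random.default_rng(seed)
    ext = np.zeros((n_steps, _N_EXT))
    ext[:, _EXT_NERVE] = nerve_rate.samples[:n_steps]
    ext[:, _EXT_BS] = conn.bs_noise.sample(n_steps, fs, rng=rng)
    ext[:, _EXT_THL] = conn.thalamus_noise.sample(n_steps, fs, rng=rng)
    ext[:, _EXT_THR] = conn.thalamus_noise.sample(n_steps, fs, rng=rng)
    ext[:, _EXT_A1L] = conn.cortex_noise.sample(n_steps, fs, rng=rng)
    ext[:, _EXT_A1R] = conn.cortex_noise.sample(n_steps, fs, rng=rng)

    target, sign, G, w, Wp, We = _build_network(pops, conn)
    sig = pops["cortex"].sigmoid
    out_pops = np.array([_P_BS] + [_MODULES[r][0] for r in NEURAL_ROLES[1:]],
                        dtype=np.int64)
    out, diverged = _integrate(
        target, sign, G, w, Wp, We, ext, 1.0 / fs,
        sig.e0, sig.v0, sig.r, out_pops, guard_mv,
    )
    if diverged >= 0:
        raise RuntimeError(
            f"network diverged at t={diverged / fs:.4f}s "
            f"(|v| > {guard_mv} mV); check gains/kernels"
        )
    return SourceDynamics(sampling_rate_hz=fs, neural=out)


def steady_state(
    pops: Optional[dict[str, PopulationParams]] = None,
    conn: Optional[ConnectivityMatrix] = None,
    constant_drive: float = 0.0,
) -> dict[str, float]:
    """Fixed point of the noise-free network under constant nerve drive.

    Solves the algebraic system obtained by zeroing the kernel derivatives
    (each synapse settles at ``z = G u / w``).  Used to validate that the
    integrator relaxes to the correct equilibrium.  Noise means are applied
    as constant inputs; raises if no root is found.
    """
    import scipy.optimize

    pops = pops or default_populations()
    conn = conn or ConnectivityMatrix()
    target, sign, G, w, Wp, We = _build_network(pops, conn)
    sig = pops["cortex"].sigmoid
    ext = np.array([
        constant_drive,
        conn.bs_noise.mean, conn.thalamus_noise.mean, conn.thalamus_noise.mean,
        conn.cortex_noise.mean, conn.cortex_noise.mean,
    ])

    n_syn = target.shape[0]

    def residual(z):
        v = np.zeros(_N_POP)
        np.add.at(v, target, sign * z)
        rates = sigmoid_rate(v, sig)
        u = np.maximum(Wp @ rates + We @ ext, 0.0)
        return (G / w) * u - z

    sol = scipy.optimize.root(residual, np.zeros(n_syn), method="hybr", tol=1e-12)
    if not sol.success:
        raise RuntimeError(f"no fixed point found: {sol.message}")
    v = np.zeros(_N_POP)
    np.add.at(v, target, sign * sol.x)
    out = {"brainstem": v[_P_BS]}
    for role, (p_idx, _, _) in _MODULES.items():
        out[role] = v[p_idx]
    return out
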