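"""ICA decomposition, artifact-component rejection, and the in-silico benchmark.

Four blind-source-separation algorithms are wrapped behind one seeded
interface: *infomax* (natural-gradient maximum likelihood for supra-Gaussian
sources), *extended infomax* (sign-switching sub/supra-Gaussian rule), *jade*
(joint diagonalization of fourth-order cumulant matrices, implemented here),
and *fastICA* (fixed-point iteration with the kurtosis-family ``cube``
contrast).  All operate on PCA-whitened data; infomax variants delegate to
``mne.preprocessing.infomax`` and fastICA to scikit-learn.

Artifactual components are flagged automatically by a dual rule — carrier-band
spectral dominance plus correlation of the component scalp map with the known
artifact topography — then zeroed and the remainder back-projected.  The
benchmark repeats simulation/decomposition/rejection/scoring over seeds and
modulation depths, scoring each algorithm by the per-electrode error of the
denoised ASSR amplitudes against the uncontaminated ground truth.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .forward import EEGDataset, ROI_FRONTOCENTRAL
from .metrics import assr_amplitude, estimation_error, negentropy
from .stimulus import SampledSignal

__all__ = [
    "ALGORITHMS",
    "ICAResult",
    "BenchmarkResult",
    "run_ica",
    "estimate_dimension",
    "classify_artifact_ics",
    "reject_and_reconstruct",
    "benchmark",
]

ALGORITHMS = ("infomax", "extended_infomax", "jade", "fastica")


@dataclass
class ICAResult:
    """One ICA decomposition.

    ``unmixing`` maps channel space to component space (sources =
    unmixing @ (data - mean)); ``mixing`` is its pseudo-inverse restricted
    to the retained subspace.  Components are ordered by the variance they
    explain in channel space.
    """

    algorithm: str
    unmixing: np.ndarray  # (n_comp, n_chan)
    mixing: np.ndarray  # (n_chan, n_comp)
    sources: np.ndarray  # (n_comp, n_samples)
    maps: np.ndarray  # (n_chan, n_comp) scalp maps (= mixing columns)
    mean: np.ndarray  # (n_chan,) channel means removed before unmixing
    n_components: int
    seed: int
    n_iter: int = -1
    converged: bool = True

    def explained_variance(self) -> np.ndarray:
        return (self.mixing**2).sum(axis=0) * self.sources.var(axis=1)


def _pca_whiten(data: np.ndarray, n_components: int):
    """Center + PCA-whiten to ``n_components`` dominant directions."""
    mean = data.mean(axis=1)
    x = data - mean[:, None]
    cov = (x @ x.T) / x.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_components]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] <= 0 or evals[-1] / evals[0] < 1e-15:
        raise ValueError(
            f"data rank below requested {n_components} components"
        )
    whitener = evecs / np.sqrt(evals)  # (chan, comp): comps = whitener.T @ x
    dewhiten = evecs * np.sqrt(evals)
    return mean, whitener.T, dewhiten  # (comp, chan), (chan, comp)


def _jade_rotation(z: np.ndarray, max_sweeps: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Orthogonal JADE rotation of whitened data ``z`` (d x N).

    Estimates the parallel set of fourth-order cumulant matrices
    ``Q_ij[k,l] = cum(z_i, z_j, z_k, z_l)`` for i <= j and jointly
    diagonalizes them with Jacobi (Givens) rotations; the angle for each
    plane maximizes the summed squared diagonals of the whole set.  The data
    must be zero-mean and white (identity covariance).
    """
    d, n = z.shape
    # cumulant matrices: E[z_i z_j z z^T] - delta_ij I - e_i e_j^T - e_j e_i^T
    mats = []
    eye = np.eye(d)
    for i in range(d):
        zi = z[i]
        for j in range(i + 1):
            w = zi * z[j]
            q = (z * w) @ z.T / n
            q -= eye if i == j else 0.0
            q[i, j] -= 1.0
            q[j, i] -= 1.0
            mats.append(q)
    mats = np.array(mats)  # (m, d, d)

    V = np.eye(d)
    for _ in range(max_sweeps):
        biggest = 0.0
        for p in range(d - 1):
            for q in range(p + 1, d):
                g1 = mats[:, p, p] - mats[:, q, q]
                g2 = mats[:, p, q] + mats[:, q, p]
                ton = (g1 * g1 - g2 * g2).sum()
                toff = 2.0 * (g1 * g2).sum()
                theta = 0.25 * np.arctan2(toff, ton + np.hypot(ton, toff))
                s, c = np.sin(theta), np.cos(theta)
                if abs(s) <= tol:
                    continue
                biggest = max(biggest, abs(s))
                # rotate rows/cols p,q of every matrix and accumulate V
                rp, rq = mats[:, p, :].copy(), mats[:, q, :].copy()
                mats[:, p, :] = c * rp + s * rq
                mats[:, q, :] = -s * rp + c * rq
                cp, cq = mats[:, :, p].copy(), mats[:, :, q].copy()
                mats[:, :, p] = c * cp + s * cq
                mats[:, :, q] = -s * cp + c * cq
                vp, vq = V[:, p].copy(), V[:, q].copy()
                V[:, p] = c * vp + s * vq
                V[:, q] = -s * vp + c * vq
        if biggest <= tol:
            break
    return V.T  # rotation: sources = V.T @ z


def run_ica(
    eeg: EEGDataset,
    algorithm: str = "infomax",
    n_components: int = 25,
    seed: int = 0,
    max_iter: int = 100,
    fit_samples: Optional[int] = None,
) -> ICAResult:
    """PCA-whiten to ``n_components`` then apply the named ICA rotation.

    ``fit_samples`` optionally estimates the unmixing on a random subsample
    of time points (the full-length component time courses are always
    returned).  Deterministic for a fixed seed; non-convergence of the
    iterative algorithms is reported on the result, never silently ignored.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; pick from {ALGORITHMS}")
    if n_components > eeg.n_channels:
        raise ValueError("n_components exceeds channel count")
    data = eeg.data
    mean, whiten, dewhiten = _pca_whiten(data, n_components)
    z_full = whiten @ (data - mean[:, None])
    rng = np.random.default_rng(seed)
    if fit_samples is not None and fit_samples < z_full.shape[1]:
        idx = np.sort(rng.choice(z_full.shape[1], size=fit_samples, replace=False))
        z_fit = z_full[:, idx]
    else:
        z_fit = z_full

    n_iter, converged = -1, True
    if algorithm in ("infomax", "extended_infomax"):
        from mne.preprocessing import infomax

        extended = algorithm == "extended_infomax"
        kwargs = {}
        if extended:
            # refresh the sub/supra-Gaussian kurtosis signs every few blocks
            # on a modest sample; the per-block default dominates runtime
            kwargs = dict(ext_blocks=5, kurt_size=2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rotation, n_iter = infomax(
                z_fit.T,
                extended=extended,
                max_iter=max_iter,
                rng=seed,
                return_n_iter=True,
                verbose="error",
                **kwargs,
            )
        converged = n_iter < max_iter
    elif algorithm == "jade":
        rotation = _jade_rotation(z_fit)
    else:  # fastica
        from sklearn.decomposition import FastICA
        from sklearn.exceptions import ConvergenceWarning

        fica = FastICA(
            n_components=n_components, whiten=False, fun="cube",
            max_iter=max_iter, random_state=seed,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fica.fit(z_fit.T)
            converged = not any(
                issubclass(w.category, ConvergenceWarning) for w in caught
            )
        rotation = fica.components_
        n_iter = fica.n_iter_

    unmixing = rotation @ whiten
    mixing = dewhiten @ np.linalg.pinv(rotation)
    sources = rotation @ z_full
    # order by explained channel-space variance
    ev = (mixing**2).sum(axis=0) * sources.var(axis=1)
    order = np.argsort(ev)[::-1]
    unmixing, mixing, sources = unmixing[order], mixing[:, order], sources[order]
    return ICAResult(
        algorithm=algorithm, unmixing=unmixing, mixing=mixing, sources=sources,
        maps=mixing.copy(), mean=mean, n_components=n_components, seed=seed,
        n_iter=int(n_iter), converged=bool(converged),
    )


def estimate_dimension(eeg: EEGDataset, eig_factor: float = 10.0) -> int:
    """Signal-subspace dimension: covariance eigenvalues above the noise floor.

    The floor rule is ``eigenvalue > eig_factor * median(eigenvalues)``; with
    white sensor noise the median eigenvalue sits on the noise shelf.  This
    is the component count the adaptive (fastICA) pipeline retains.
    """
    if eeg.n_channels < 2:
        raise ValueError("need at least 2 channels")
    x = eeg.data - eeg.data.mean(axis=1, keepdims=True)
    evals = np.linalg.eigvalsh((x @ x.T) / x.shape[1])
    return int((evals > eig_factor * np.median(evals)).sum())


def classify_artifact_ics(
    res: ICAResult,
    f_c: float,
    sampling_rate_hz: float,
    artifact_topography: np.ndarray,
    f_m: float,
    spectral_ratio: float = 5.0,
    topo_corr_threshold: float = 0.8,
    band_hz: float = 10.0,
    n_harmonics: int = 10,
) -> list[int]:
    """Flag components that look like the stimulation artifact.

    A component is flagged when (a) its spectral energy summed over the
    carrier band ``f_c +/- band_hz`` and harmonics exceeds
    ``spectral_ratio`` times its energy in the modulation band
    ``f_m +/- 2 Hz``, and (b) the absolute correlation of its scalp map with
    the supplied artifact topography exceeds ``topo_corr_threshold``.
    Returns the (possibly empty) list of flagged component indices.
    """
    if f_c >= sampling_rate_hz / 2:
        raise ValueError("carrier frequency above Nyquist")
    n = res.sources.shape[1]
    freqs = np.fft.rfftfreq(n, 1.0 / sampling_rate_hz)
    psd = np.abs(np.fft.rfft(res.sources, axis=1)) ** 2
    carrier_mask = np.zeros(freqs.shape, dtype=bool)
    h = 1
    while h <= n_harmonics and h * f_c < sampling_rate_hz / 2:
        carrier_mask |= np.abs(freqs - h * f_c) <= band_hz
        h += 1
    mod_mask = np.abs(freqs - f_m) <= 2.0
    flagged = []
    topo = artifact_topography - artifact_topography.mean()
    for k in range(res.sources.shape[0]):
        e_carrier = psd[k, carrier_mask].sum()
        e_mod = psd[k, mod_mask].sum()
        if e_mod == 0 or e_carrier / e_mod <= spectral_ratio:
            continue
        m = res.maps[:, k] - res.maps[:, k].mean()
        denom = np.linalg.norm(m) * np.linalg.norm(topo)
        if denom == 0:
            continue
        if abs(float(m @ topo)) / denom > topo_corr_threshold:
            flagged.append(k)
    return flagged


def reject_and_reconstruct(
    eeg: EEGDataset, res: ICAResult, rejected: Sequence[int]
) -> EEGDataset:
    """Zero the rejected components and back-project to channel space.

    With nothing rejected the output is the retained-subspace projection of
    the input (plus the channel means).  Rejecting every component is an
    error.
    """
    rejected = sorted(set(int(i) for i in rejected))
    if any(i < 0 or i >= res.n_components for i in rejected):
        raise ValueError("rejected component index out of range")
    if len(rejected) == res.n_components:
        raise ValueError("cannot reject every component")
    keep = [i for i in range(res.n_components) if i not in rejected]
    recon = res.mixing[:, keep] @ res.sources[keep] + res.mean[:, None]
    return EEGDataset(
        data=recon,
        sampling_rate_hz=eeg.sampling_rate_hz,
        channel_labels=eeg.channel_labels,
        kind="denoised",
        seed=eeg.seed,
        metadata={**eeg.metadata, "algorithm": res.algorithm,
                  "rejected_components": rejected},
    )


@dataclass
class BenchmarkResult:
    """Tidy tables from the in-silico ICA comparison.

    ``errors``: one row per (modulation depth, simulation, algorithm,
    electrode) with the denoised amplitude and the percent estimation error.
    ``diagnostics``: one row per (modulation depth, simulation, algorithm)
    with rejected components, negentropy summaries, convergence and runtime.
    ``failures``: runs excluded from aggregates, with the reason.
    """

    errors: pd.DataFrame
    diagnostics: pd.DataFrame
    failures: pd.DataFrame
    roi: tuple[str, ...] = tuple(ROI_FRONTOCENTRAL)

    def roi_errors(self) -> pd.DataFrame:
        return self.errors[self.errors.electrode.isin(self.roi)]

    def roi_summary(self) -> pd.DataFrame:
        """Mean / SD / mean-absolute ROI error per algorithm and depth."""
        g = self.roi_errors().groupby(["modulation_depth", "algorithm"])["error_pct"]
        out = g.agg(mean="mean", sd="std", mean_abs=lambda e: e.abs().mean())
        return out.reset_index()

    def to_tsv(self, path_prefix: str) -> None:
        self.errors.to_csv(f"{path_prefix}_errors.tsv", sep="\t", index=False)
        self.diagnostics.to_csv(f"{path_prefix}_diagnostics.tsv", sep="\t", index=False)
        if len(self.failures):
            self.failures.to_csv(f"{path_prefix}_failures.tsv", sep="\t", index=False)


def _channel_amplitudes(ds: EEGDataset, f_m: float, k: int, n_segments=None) -> np.ndarray:
    return np.array([
        assr_amplitude(SampledSignal(ds.data[i], ds.sampling_rate_hz), f_m, k, n_segments)
        for i in range(ds.n_channels)
    ])


def benchmark(
    scenario=None,
    algorithms: Sequence[str] = ALGORITHMS,
    n_sims: int = 10,
    md_values: Sequence[float] = (1.0, 0.75, 0.5, 0.2),
    seeds: Optional[Sequence[int]] = None,
    manual_rejections: Optional[dict] = None,
) -> BenchmarkResult:
    """Run the full simulation/denoising comparison.

    For every modulation depth and simulation seed the scenario is
    simulated, each algorithm decomposes the mixture, artifact components
    are flagged (or taken from ``manual_rejections[algorithm]``, capped at
    20% of the components) and removed, and the denoised per-electrode ASSR
    amplitudes are scored against the uncontaminated ground truth.  fastICA
    uses the automatically estimated component count; the other algorithms
    use the configured fixed count.  Algorithm failures are recorded and
    excluded from aggregates.  Fully reproducible from the seed list.
    """
    from .scenario import ScenarioConfig, simulate_scenario

    cfg = scenario or ScenarioConfig()
    if seeds is None:
        seeds = [cfg.seed + i for i in range(n_sims)]
    seeds = list(seeds)[:n_sims]

    err_rows, diag_rows, fail_rows = [], [], []
    for md in md_values:
        md_cfg = cfg.model_copy(deep=True)
        md_cfg.stimulus.modulation_depth = md
        for sim_idx, seed in enumerate(seeds):
            res = simulate_scenario(md_cfg, seed=seed)
            k = md_cfg.analysis.cycles_per_epoch
            nseg = md_cfg.analysis.n_segments
            neural_amp = _channel_amplitudes(res.assr, res.f_m, k, nseg)
            chan_negent = [negentropy(res.mix.data[i]) for i in range(res.mix.n_channels)]
            for algo in algorithms:
                t0 = time.perf_counter()
                try:
                    if algo == "fastica":
                        n_comp = max(2, estimate_dimension(res.mix, md_cfg.ica.dim_eig_factor))
                    else:
                        n_comp = min(md_cfg.ica.n_components, res.mix.n_channels)
                    ica = run_ica(
                        res.mix, algo, n_components=n_comp, seed=seed,
                        max_iter=md_cfg.ica.max_iter,
                        fit_samples=md_cfg.ica.fit_samples,
                    )
                    if manual_rejections and algo in manual_rejections:
                        rej = list(manual_rejections[algo])
                        cap = max(1, int(0.2 * n_comp))
                        rej = rej[:cap]
                    else:
                        rej = classify_artifact_ics(
                            ica, res.f_c, md_cfg.sampling_rate_hz,
                            res.artifact_topography(), res.f_m,
                            spectral_ratio=md_cfg.ica.spectral_ratio,
                            topo_corr_threshold=md_cfg.ica.topo_corr_threshold,
                            band_hz=md_cfg.ica.carrier_band_hz,
                        )
                    denoised = reject_and_reconstruct(res.mix, ica, rej)
                    den_amp = _channel_amplitudes(denoised, res.f_m, k, nseg)
                    errors, _ = estimation_error(den_amp, neural_amp)
                    runtime = time.perf_counter() - t0
                except Exception as exc:  # recorded, run excluded
                    fail_rows.append(dict(
                        modulation_depth=md, simulation=sim_idx, seed=seed,
                        algorithm=algo, reason=f"{type(exc).__name__}: {exc}",
                    ))
                    continue
                comp_negent = [negentropy(s) for s in ica.sources]
                for lab, amp, err in zip(res.mix.channel_labels, den_amp, errors):
                    err_rows.append(dict(
                        modulation_depth=md, simulation=sim_idx, seed=seed,
                        algorithm=algo, electrode=lab,
                        denoised_amplitude_uv=amp, error_pct=err,
                    ))
                diag_rows.append(dict(
                    modulation_depth=md, simulation=sim_idx, seed=seed,
                    algorithm=algo, n_components=ica.n_components,
                    rejected=",".join(map(str, rej)), n_rejected=len(rej),
                    mean_component_negentropy=float(np.mean(comp_negent)),
                    mean_channel_negentropy=float(np.mean(chan_negent)),
                    converged=ica.converged, n_iter=ica.n_iter,
                    runtime_s=runtime,
                ))
    return BenchmarkResult(
        errors=pd.DataFrame(err_rows),
        diagnostics=pd.DataFrame(diag_rows),
        failures=pd.DataFrame(fail_rows, columns=[
            "modulation_depth", "simulation", "seed", "algorithm", "reason"]),
    )
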