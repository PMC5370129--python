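# assrmix

Simulation of the cochlear-implant (CI) stimulation artifact mixed with
auditory steady-state responses (ASSRs) on scalp EEG — with known ground
truth — and quantitative benchmarking of ICA-based denoising algorithms
(infomax, extended infomax, JADE, fastICA) against that ground truth.

## Who this is for

Objective hearing measures in CI patients rely on detecting ASSRs: stationary
evoked potentials phase-locked to the modulation frequency f_m of a
continuous amplitude-modulated stimulus. The implant's electrical pulses leak
into the EEG as an artifact that is orders of magnitude larger than the
response and, for pulse-width-modulation (PWM) implants with temporally
spread pulses, cannot simply be blanked away (a 1 ms per-pulse spread at a
500 Hz stimulation rate already covers 50% of every inter-pulse interval).
Denoising is therefore unavoidable — but a denoiser can also deform the very
response it is supposed to preserve, and with real recordings there is no
uncontaminated reference to check against. This package provides that
reference in silico: it simulates the artifact and the neural response
*separately*, mixes them at the scalp, and scores any denoising pipeline
against the artifact-free control dataset.

## The model

- **Stimulus** (`assrmix.stimulus`): a monophasic rectangular pulse train at
  carrier rate f_c = 500 Hz whose per-pulse width follows the envelope of an
  AM tone (f_m = 39.06 Hz, modulation depth 75% by default) — the PWM coding
  strategy of pulse-duration implants.
- **Cochlea** (`assrmix.cochlea`): the current crosses a capacitive
  electrode–cochlea interface, v_stim = Z_ec·i_stim + R_s·i_stim with
  Z_ec(s) = Z_f/(1 + s·Z_f·C_dl). The resulting potential is both the
  artifact dipole's time course and — through Freeman's wave-to-pulse sigmoid
  S(v) = 2e₀/(1 + exp(r(v₀ − v))) plus residual-hearing noise — the
  auditory-nerve firing rate.
- **Neural network** (`assrmix.neuraldyn`): five neural-mass modules
  (brainstem, bilateral thalamus, bilateral primary auditory cortex) built
  from second-order synaptic kernels h(t) = G·ω·t·e^(−ωt) with fast and slow
  GABAergic interneuron populations, wired brainstem → thalamus → cortex with
  excitatory feedback, integrated by Euler–Maruyama.
- **Forward model** (`assrmix.forward`): an analytic 3-shell concentric
  sphere (brain/skull/scalp, skull at the classical 1/80 conductivity ratio)
  maps the six dipoles to a 32-channel 10–10 montage through two lead
  fields, EEG_mix = LF₁·S_n + LF₂·S_Art + b. EEG_ASSR = LF₁·S_n is the
  uncontaminated control. Externally computed (e.g. BEM) lead fields can be
  imported.
- **Metrics** (`assrmix.metrics`): epoching into integer-modulation-cycle
  segments, time-averaged ASSR amplitude at f_m, phase coherence
  PC = |Σe^{iθ_k}|/N, per-electrode amplitude estimation error,
  histogram mutual information with the (M−1)²/2N bias correction and
  Scott's-rule binning, log-cosh negentropy, Anderson–Darling normality
  screening.
- **Benchmark** (`assrmix.icabench`): PCA-whitened infomax / extended
  infomax (via MNE), fastICA (scikit-learn, kurtosis-family contrast), and
  an in-repo JADE (Jacobi joint diagonalization of fourth-order cumulant
  matrices); automatic artifact-component flagging by carrier-band spectral
  dominance plus scalp-map correlation; rejection, back-projection, and
  per-electrode scoring over seeds and modulation depths.

## Worked example

```python
from assrmix import ScenarioConfig, simulate_scenario, run_ica
from assrmix.icabench import (classify_artifact_ics, reject_and_reconstruct,
                              _channel_amplitudes)
from assrmix.metrics import estimation_error

res = simulate_scenario(ScenarioConfig(), seed=1)    # 20 kHz, 10 s, 32 ch
ica = run_ica(res.mix, "infomax", n_components=25, seed=1)
rej = classify_artifact_ics(ica, res.f_c, res.mix.sampling_rate_hz,
                            res.artifact_topography(), res.f_m)
den = reject_and_reconstruct(res.mix, ica, rej)
err, _ = estimation_error(_channel_amplitudes(den, res.f_m, 20),
                          _channel_amplitudes(res.assr, res.f_m, 20))
print(rej, round(err.mean(), 1))
```

prints

```
[0] 2.4
```

— infomax isolated the artifact into exactly one of 25 components (index 0,
the highest-variance one), and after rejecting it the denoised ASSR
amplitudes deviate from the artifact-free ground truth by ~2% on average.
For scale: the mixture's averaged artifact amplitude peaks at ~8 µV at the
electrode over the (right-side) implant, while the true response is ~1 µV at
Cz, so without denoising the error at contaminated electrodes is in the
hundreds of percent.

The same pipeline is available from the shell:

```bash
assrmix simulate --seed 1 --out runs/demo        # writes mix/assr/art .set files
assrmix bench --n-sims 10 --out runs/bench       # full algorithm comparison
assrmix metrics runs/demo/eeg_assr.set --out amplitudes.tsv
```

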