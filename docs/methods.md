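# Methods

This note documents the generative model, its default parameterization, the
estimators, and the design decisions behind them — including what the
synthetic data do and do not capture of real cochlear-implant (CI)
recordings.

## Stimulus and electrode–cochlea interface

The implant model encodes an amplitude-modulated tone by pulse-width
modulation: monophasic rectangular pulses of constant amplitude at the
clinical stimulation rate f_c = 500 Hz, whose width follows the modulation
envelope at f_m = 39.06 Hz with depth MD (default 75%). The envelope-to-width
map is `w(t) = w_base (1 + MD sin 2π f_m t)/(1 + MD)` so that the widest
pulse equals the base width and per-pulse charge stays bounded; a plain
linear variant (base width = mean width) is available. Widths are quantized
to the nearest sample with a one-sample floor and pulses are left-aligned at
onsets spaced one carrier period apart. Monophasic (not charge-balanced)
pulses are used deliberately; the slow pseudo-monophasic passive-discharge
tail of real percutaneous implants is out of scope.

**Base pulse width and interface constants.** Defaults are w_base = 100 µs,
C_dl = 0.01 µF, Z_f = 5 kΩ, R_s = 3 kΩ (units: µA/kΩ/mV/µF, so
1 kΩ × 1 µA = 1 mV), giving an interface time constant Z_f·C_dl = 0.05 ms.
These were chosen so the artifactual potential is a sparse spike train with
the strongly supra-Gaussian distribution seen in practice (excess kurtosis
≈ 15 at 20 kHz sampling, ≈ 28 at 50 kHz; wider pulses or a slower interface
smear the artifact toward kurtosis ~4, which would misrepresent the
source ICA has to isolate). The interface is the first-order system
Z_ec(s) = Z_f/(1 + s Z_f C_dl) — written with this grouping because the more
compact textbook form is dimensionally ambiguous — discretized by exact
zero-order hold (matched pole e^{−dt/τ}, DC gain Z_f), which is stable and
exact at any sampling rate. A warning is emitted when the pole frequency
1/(2πτ) exceeds f_s/4, i.e. when the capacitive transient is under-resolved;
this is expected at the 20 kHz desk scale and harmless for the benchmark
because the discretization is exact at the sample instants.

The wave-to-pulse sigmoid is Freeman's S(v) = 2e₀/(1 + exp(r(v₀ − v))) with
e₀ = 2.5 s⁻¹, v₀ = 6 mV, r = 0.56 mV⁻¹ — the standard neural-mass values.
S increases with depolarization; the orientation is configurable. Residual
hearing enters as Gaussian noise (default std 0.5 mV) added to v_stim before
the sigmoid.

## Neural-mass network

Each thalamic/cortical module contains a principal population with fast and
slow GABAergic interneuron feedback; the brainstem module has a principal
and a single (fast) inhibitory population. Synaptic kernels are the
second-order h(t) = G ω t e^{−ωt} with defaults A = 3.25 mV / a = 100 s⁻¹
(excitatory), B = 22 mV / b = 50 s⁻¹ (slow inhibition), G = 10 mV /
g = 500 s⁻¹ (fast inhibition). The brainstem excitatory kernel is five times
faster at equal DC gain (16.25 mV / 500 s⁻¹): brainstem relay neurons follow
high rates that cortical synapses cannot, which is what lets the brainstem
output retain carrier-frequency content while thalamus and cortex
progressively low-pass it. Internal gains follow the usual C = 135
convention (P→I′ and I′→P at 0.25C, P→I at 0.3C, I→P at 0.1C).

Wiring: the auditory-nerve rate drives the brainstem principal population
(gain 200); the brainstem excites both thalami (170) and, weakly, both
cortices (20); each cortex pools both thalami equally (400 split 50/50); all
four modules feed back to the brainstem (2 each). The bilateral
thalamo-cortical pooling is a deliberate simplification: with strictly
ipsilateral relays, left/right asymmetries of thalamic origin would imprint
an antisymmetric cortical scalp pattern for which the real data give no
evidence.

**Noise placement matters.** Gaussian noise enters at the brainstem
(mean 10, std 2) and — strongly — at the two cortical principal populations
(mean 90, std 100); the thalamic relays carry *no* intrinsic noise. This is
the architecture's own dependency structure: the two thalamic sources become
near-duplicates (their mutual information is ~4 nats on the default
scenario) while the cortical pair decorrelates (MI ≈ 0.1–0.2), and the scalp
mixture ends up with exactly four independent elements (artifact, the
phase-locked/brainstem-driven pair of directions, and the antisymmetric
cortical background) — which is what an adaptive ICA dimension estimate
recovers. Noise std values are specified at a 10 kHz reference rate and
scaled by √(f_s/10 kHz) per sample so the band-limited power reaching the
slow kernels is sampling-rate invariant.

Integration is Euler–Maruyama at dt = 1/f_s with pulse densities rectified
at zero; trajectories are aborted with a diagnostic if any membrane
potential exceeds 1 V (divergence guard). The first second of every
simulation is discarded as burn-in. A numba-compiled inner loop makes the
full-scale 50 kHz / 40 s run a matter of seconds.

## Forward model

The head is a 3-shell concentric sphere (radii 8.7/9.2/10 cm; brain and
scalp at 0.33 S/m, skull at 0.33/80 = 0.004125 S/m honoring the classical
ratio — the rounded 0.042 S/m variant can be selected). Potentials are
computed from the spherical-harmonic expansion: per degree n a 5×5 linear
system enforces potential/current continuity at the two inner interfaces and
the insulating outer boundary, with the free-medium dipole expansion as the
source term; the series is truncated at a 10⁻¹² relative tolerance. With
equal conductivities the solution matches the closed-form homogeneous-sphere
dipole potential to <10⁻⁶ relative error (tested against an independently
derived closed form).

Electrode positions come from the bundled standard 10–10 template (32
channels, actiCAP-style subset) projected onto the scalp sphere. Default
dipoles: midline brainstem (0, −30, −45 mm), bilateral thalamus
(±12, −19, 4 mm), bilateral auditory cortex (±52, −20, 8 mm), cochlea in the
right temporal bone (+68, −12, −30 mm). Neural orientations are
near-radial with a slight anterior tilt, which focalizes the averaged ASSR
topography fronto-centrally with its maximum at Cz; the cochlear dipole
points laterally, spreading the artifact ipsilaterally with its maximum at
T8. Only the qualitative topography is calibrated — there is no quantitative
experimental target for the orientations.

Sources are in arbitrary units; two calibration scalars map them to µV at
the scalp (defaults 0.21 neural, 0.57 artifact), set once so the averaged
ASSR amplitude is ~1 µV at Cz and the averaged artifact ~8 µV at its
ipsilateral maximum — the order-of-magnitude mismatch that makes undenoised
averaging useless in practice. Sensor noise is white Gaussian at 0.5 µV per
sample. EEG_mix = LF₁S_n + LF₂S_Art + b; EEG_ASSR = LF₁S_n is the control.

## Estimators

- **Epoching**: contiguous non-overlapping segments of k modulation cycles
  (default k = 20, i.e. D = 0.512 s); the trailing remainder is dropped.
  Because D is an integer number of cycles, f_m falls on an exact FFT bin
  and phases are leakage-free without windowing.
- **ASSR amplitude**: time-domain average of segments, then the amplitude of
  the f_m bin (scaled so a pure sinusoid of amplitude A returns A). The
  segment count defaults to "all available".
- **Phase coherence**: PC = |Σ e^{iθ_k}|/N over per-epoch phases at f_m;
  detection convention PC > 0.8 over 20-epoch sweeps. Zero-amplitude bins
  (undefined phase) are excluded with a warning.
- **Estimation error**: 100·(denoised − control)/control per electrode;
  positive = artifact residue, negative = over-removal. Zero-control
  electrodes are excluded and reported.
- **Mutual information**: equal-width 2-D histogram, plug-in estimator in
  nats, bias (M−1)²/(2N) subtracted and reported signed (slightly negative
  values for independent signals are expected — with sparse marginals the
  formula overcorrects, since many of the (M−1)² cells are structurally
  empty; conversely the expansion is first-order and needs on the order of
  a hundred samples per joint cell to be accurate). Auto binning: Scott's rule 3.49σN^{−1/3} per signal, smallest M
  across signals; the source-protocol variant takes the minimum over the six
  simulated sources. The log base (nats) is a convention; the bias formula
  as printed is base-free only up to that constant.
- **Negentropy**: J = (E[G(y)] − E[G(g)])², G(u) = log cosh(a·u)/a, a = 1,
  with y standardized first (affine invariant) and E[G(g)] = 0.37457
  computed once by quadrature. Standardization bounds J by ≈ 0.4: the
  sparse-spike limit is 0.3746² ≈ 0.140. Scale-dependent "raw" evaluation is
  available but not the default; note that comparisons of negentropy
  *between* signals are only meaningful on a common scale convention.
- **Normality screen**: Anderson–Darling with estimated mean/variance
  (p-values via statsmodels), default α = 10⁻³, plus bias-corrected excess
  kurtosis.

## ICA benchmark

All four algorithms operate on PCA-whitened, channel-centered data (25
components for the 32-channel simulations; fastICA instead uses the
data-driven dimension: covariance eigenvalues above 10× the median
eigenvalue, which sits on the white sensor-noise shelf). Unmixing is
estimated on a random 30,000-sample subset (configurable) and applied to the
full recording; infomax runs the natural-gradient rule, extended infomax the
sign-switching sub/supra-Gaussian variant (kurtosis signs refreshed every 5
blocks on 2,000 samples — the runtime-dominant setting), JADE joint-
diagonalizes the full parallel set of fourth-order cumulant matrices by
Jacobi rotations to a 10⁻⁸ rotation tolerance, and fastICA uses the
kurtosis-family `cube` contrast. Components are ordered by explained
channel-space variance. Iteration budgets defaulting to 100 are convergence
settings, not statistical parameters; non-convergence is recorded on the
result object.

Artifact components are flagged automatically when carrier-band energy
(f_c ± 10 Hz and harmonics) exceeds 5× the modulation-band energy *and* the
component's scalp map correlates with the known artifact topography above
0.8. Both thresholds are engineering choices — the original protocol was
manual rejection — and are configurable; a manual index list (capped at 20%
of components) is supported for real recordings, where no ground-truth
topography exists. Rejected components are zeroed and the remainder
back-projected (plus channel means), so an empty rejection returns the
retained-subspace projection of the input.

The benchmark grid repeats simulation → decomposition → rejection → scoring
over seeds and modulation depths and reports tidy per-electrode error tables
plus per-run diagnostics (rejected indices, negentropy summaries,
convergence, runtime). The scoring region of interest is the 12
fronto-central electrodes Fz, F3, F7, FC5, FC1, C3, Cz, C4, FC6, FC2, F4,
F8. Runtimes are recorded for reference but never asserted.

## Problem sizes

The default "quick" profile is 20 kHz / 10 s / 32 channels; the benchmark
fixture in the test suite uses 16 s mixtures, 10 seeds and modulation depths
{1.0, 0.75, 0.2} — the shortest mixtures at which the modulation-depth trend
is not masked by the separation noise of the weaker algorithms. 20 kHz is the lowest rate at which 100 µs pulse widths
quantize to several distinct sample counts — at 10 kHz every pulse collapses
to one sample and the artifact loses its modulation-frequency content
entirely. The "paper_scale" profile (50 kHz / 40 s) exercises the identical
code path. Separation quality improves with scale; at desk scale the
infomax-denoised fronto-central amplitudes are accurate to a few percent in
the mean, but individual low-amplitude electrodes (F7/F8, ~0.5 µV) can show
residue errors around 15–20%.

## Known limitations

- No passive-discharge (pseudo-monophasic) artifact shape, no RF/antenna
  artifact, and a single active electrode — the artifact is strictly rank
  one at the scalp.
- No distributed background cortical sources: outside the six dipoles the
  only broadband activity is sensor noise, which makes the mixture easier
  for ICA than a real recording and inflates the eigenvalue gap the
  dimension estimate relies on. Passing tests here demonstrate correctness
  of the pipeline and reproduction of the in-silico findings, not expected
  performance on patient data.
- The spherical head model ignores skull anisotropy and realistic geometry;
  imported BEM lead fields can replace it.
- The artifact and the response are driven by the same stimulus and are
  therefore not strictly independent — the f_m envelope is common to both.
  This is faithful to reality and is precisely why ICA separation quality,
  not the independence assumption, is the quantity under study.
- Estimation errors at low modulation depth are dominated by separation
  noise for the weaker algorithms (JADE in particular over-rejects: it
  splits the artifact across several components, all of which get flagged),
  so the error-vs-depth trend is much cleaner for infomax than for JADE at
  desk scale.
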