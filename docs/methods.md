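# Methods

This note documents the models, estimators, parameter choices, and
numerical decisions behind `phaseconn`, and what the synthetic-data tests
do and do not establish about real EEG.

## Pipeline overview

The package implements a closed loop:

1. multichannel resting-state EEG (21 channels, 10–20 montage, 400 Hz) is
   band-limited to the alpha rhythm;
2. functional connectivity is estimated pairwise with the weighted phase
   lag index (WPLI) and averaged across subjects per group;
3. a Kuramoto mean-field model coupled through a connectivity matrix
   generates simulated EEG channels, optionally after a central-region
   lesion transform;
4. three complexity estimators score every channel, aggregated into
   anterior/central/posterior regional means;
5. group comparisons (t-test or rank-sum, FDR-corrected over the 3×3
   region-by-measure grid) and a real-vs-simulated ANOVA are reported.

Because clinical recordings of this kind are not freely shareable, a
synthetic-data module generates cohorts with the statistical structure
the analysis assumes, so the whole chain is exercisable and testable.

## Alpha-band extraction

Default: discrete wavelet decomposition with `db10`, symmetric boundary
extension, reconstruction from the level-5 detail coefficients only. At
400 Hz this band spans ~6.25–12.5 Hz, the closest single-level match to
the 8–13 Hz alpha band; for other sampling rates the level is recomputed
from `fs`. Options: also keep the level-4 details (12.5–25 Hz, covering
upper alpha), or substitute a zero-phase 8–13 Hz FIR band-pass.

Measured frequency response of the default extractor (30 s sinusoidal
probes, 400 Hz): ≥ 90% variance retained at 8–10 Hz, −20 dB or better
below ~5 Hz and above ~17 Hz. The transition shoulder at 14–17 Hz
attenuates less (−7 dB at 14 Hz, −16 dB at 16 Hz); this is the finite
transition width of `db10`, and tests probe the stopband outside that
shoulder. The transform is linear and length-preserving.

## WPLI estimation

For band-limited channels x, y the instantaneous cross-spectrum is taken
from the analytic signals, S_xy(t) = z_x(t)·conj(z_y(t)), and

WPLI = |Σ_t |Im S_xy(t)|·sgn(Im S_xy(t))| / Σ_t |Im S_xy(t)|.

Numerical decisions:

* **Absolute value of the numerator.** Without it the index is signed by
  which channel leads; the absolute value keeps estimates in [0, 1],
  consistent with connectivity strengths being magnitudes.
* **Edge trimming.** 5% of samples at each end of the analytic signal are
  discarded (Hilbert edge transients); the fraction is configurable.
* **0/0 convention.** When the imaginary cross-spectrum is zero relative
  to the cross-spectrum magnitude (phase-identical signals leave only
  rounding residue, ~1e-17 of magnitude), the estimator returns 0: no
  lagged interaction is detectable. The relative tolerance is 1e-12.
* **Welch alternative.** A segment-averaged estimator (Hanning windows,
  50% overlap, summing imaginary cross-spectra over in-band FFT bins) is
  available via `estimator="welch"`.

A Monte-Carlo null for independent alpha-band noise pairs (12,000
samples) has mean WPLI ≈ 0.07; the null scale shrinks with record length,
so short records inflate WPLI floors — relevant when interpreting
absolute strengths estimated from brief synthetic cohorts.

## Kuramoto simulation and the time-unit convention

dθ_i/dt = ω_i + k Σ_j a_ij sin(θ_j − θ_i), forward Euler with step
h = 0.1, 15,000 recorded samples, the first 1,000 discarded, 15
repetitions per condition, natural frequencies drawn per run from
N(10, 2) Hz (clipped at 0.1 Hz), initial phases uniform on [0, 2π).
The coupling sum is used as written (no 1/N); a mean-field-normalized
option exists. Per-run subseeds are spawned from one master seed with
numpy's `SeedSequence`, so ensembles are reproducible run-by-run.

**Units.** Frequencies in Hz combined with a dimensionless step h leave
the unit of time open; `time_unit_scale` (seconds per time unit) fixes
it, with ω_i = 2π f_i · time_unit_scale.

* `time_unit_scale = 0.01` (module default) gives ~0.063 rad per step for
  a 10 Hz oscillator — a smooth, well-sampled oscillation. In this regime
  the coupling term (k·Σ_j a_ij ≈ 11 for dense matrices at strength
  ~0.5) dwarfs the frequency dispersion, and the network locks into
  global synchrony: every channel becomes a clean sinusoid and complexity
  differences between coupling matrices vanish.
* `time_unit_scale = 1` ("literal" units, the study pipeline default)
  makes a 10 Hz oscillator advance exactly one cycle per step: the
  recorded signal is the *stroboscopic*, once-per-cycle sampling of the
  oscillation. Equivalently, the dynamics live in the rotating frame with
  effective detunings 2π(f_i − 10)·h ≈ N(0, 1.26) rad/step against
  coupling increments ≈ 1.1 rad/step — i.e. near the synchronization
  transition, where partial, fluctuating synchrony makes the simulated
  channels structurally rich and sensitive to the coupling matrix. This
  is the regime in which the connectivity-to-complexity phenomenology
  (below) exists, and the regime the printed parameter set produces when
  taken at face value.

**Euler stability.** The locked state's discrete-map multiplier is
1 − h·k·Σ_j a_ij cos(·); beyond |1 − h·k·Σa| > 1 the map goes unstable
and the dynamics become chaotic. Growing k in literal units crosses this
bound near k ≈ 2, so coupling sweeps should be read as map dynamics, not
ODE integration, outside h·k·Σa < 2. A step-halving check in the stable
regime changes r(t) by < 5% RMS.

**Channel model.** Channel i carries sin θ_i(t). The alternative reading
that sums sine phases into a single signal is available as a diagnostic
(`summed_signal`) but would make all channels identical, contradicting
per-region analyses.

**Order parameter.** r(t) is the modulus of the mean unit phasor; for
identical phases r = 1 exactly; for uniform random phases
E[r] ≈ sqrt(π/4N) ≈ 0.19 at N = 21. Adding a common constant to all
initial phases shifts ψ(t) and leaves r(t) unchanged (verified to 1e-9);
channel-level complexity scores are only *distributionally* unchanged
under such rotations, since sin(θ_i + c) alters each waveform and its
median binarization.

## Lesion transform

All edges incident to the central channels {T3, C3, Cz, C4, T4} are set
to a constant strength (default 0.1, the lowest nonzero strength of the
averaged patient matrix). The matrix is undirected, so "edges
originating" in the region means all incident edges, applied
symmetrically. Worked arithmetic for a uniform-0.5 21-node matrix: the 5
central channels touch 5·16 + C(5,2) = 90 of the 210 edges, so the mean
strength becomes (120·0.5 + 90·0.1)/210 = 0.32857.

## Complexity estimators

* **LZC.** Binarize at the median (strictly greater → 1, ties → 0, so a
  constant signal is all-zeros), parse with the exhaustive LZ76
  production scheme (Kaspar–Schuster scan; the final incomplete word
  counts), normalize by n/log2(n). A numba-compiled scan is used when
  available, with a pure-Python substring-search implementation as
  fallback; both are cross-checked against a brute-force enumeration of
  the parsing rule. Anchors: constant signals give c = 2; `0100` parses
  to 3 words; fair-coin strings of n = 14,000 give C(n) ≈ 1.
* **HFD.** Higuchi's estimator: mean curve lengths L(k) over offsets at
  scales k = 1..k_max, unweighted least-squares slope of ln L(k) vs
  ln(1/k). The slope — not the mean curve length, which is unbounded — is
  the quantity consistent with a fractal dimension in [1, 2]: a straight
  line gives 1.00 ± 0.02 and white noise ≈ 2. Note the estimator is not
  clamped: strongly anticorrelated (rougher-than-noise) series, such as
  stroboscopically sampled oscillations, can exceed 2. k_max = 18 for
  clinical-length real EEG and 6 for simulated signals, taken as given
  constants.
* **FDispEn.** Map samples to c classes through the normal CDF (fitted
  mean/SD; zero-variance signals fall back to the middle class), embed
  with dimension m and delay d, reduce each vector to successive class
  differences, and take the Shannon entropy (natural log) of the pattern
  distribution over (2c−1)^(m−1) possibilities; optional normalization
  by the maximum. Defaults m = 3, c = 3, d = 1. Note that with c = 3 the
  extreme pattern (+2, +2) is unreachable from any class sequence, so
  the ln 25 bound is strict for real inputs. All pattern frequencies are
  cross-checked against direct enumeration.

All three measures are invariant to positive affine transforms of the
input (exactly, up to floating-point ties at the median).

## Synthetic data: what it emulates, and what it does not

`gen_connectivity_matrix` draws i.i.d. uniform edges on the configured
range and re-centers them (monotone shift + clipping, ≤ 100 rounds) onto
the target mean: 0.5575 for control-like, 0.4945 for patient-like groups,
patient edges within [0.1, 0.6]. The control upper bound 0.95 is a
package choice (no reference range exists for controls). Per-subject
matrices add symmetric truncated-Gaussian jitter (SD 0.05, ±2 SD).

`gen_synthetic_eeg` runs the package's own Kuramoto simulator on the
ground-truth matrix, one Euler step per EEG sample
(`time_unit_scale = 1/(fs·h)`), with mean-field-normalized coupling gain
3, per-oscillator phase noise (SD 1.5 rad/√unit), and additive broadband
sensor noise (SD 0.2 of the unit oscillation amplitude). The gain/noise
operating point was chosen to hold the cohort in *partial* synchrony:
strong enough that pairwise phase locking tracks edge strength, noisy
enough that the network does not collapse into global lock.

Fidelity and its limits, measured on the full generation + estimation
chain (300 s records, 20 seeds):

* pairwise alpha-band phase locking (PLV) rank-correlates with the
  ground-truth edges at Spearman ρ ≈ 0.69 (median), degrading
  monotonically with sensor noise;
* **WPLI recovers the same structure only weakly** (ρ ≈ 0.05–0.25):
  symmetric, delay-free sine coupling locks pairs at (near) zero lag, and
  WPLI by construction discounts zero-lag synchrony. Real cortical
  interactions carry conduction delays that create the consistent
  nonzero lags WPLI rewards; this generator does not model them (nor
  blinks, EMG, volume-conduction forward models, or nonstationary
  drift). Passing recovery tests therefore validate the coupling
  structure of the generator, not WPLI's sensitivity on real tissue;
* uncoupled (zero-matrix) cohorts give estimated WPLI below 0.1 for 95%
  of pairs, provided records are long enough for near-degenerate
  frequency pairs to decorrelate (150 s in the tests).

Because the WPLI estimates of these synthetic cohorts compress toward
the estimator's operating floor regardless of group, the full-study
driver defaults to coupling the ensembles through the *generated* group
matrices (which sit at the configured mean strengths); the complete
estimate-average-simulate loop remains available as a config switch.

## Group statistics

Unit of analysis: subjects for real-design comparisons, simulation runs
for simulated designs (15 per group by default). Cells are the per-unit
regional means. Real designs report Student's t with a recorded
Shapiro–Wilk normality check per group (a failing cell is flagged; a
strict mode switches that cell to the rank-sum test); simulated designs
use the Wilcoxon rank-sum test throughout. Benjamini–Hochberg FDR is
applied within each comparison's 9 cells (matching per-comparison
reporting; the scope is configurable). The real-vs-simulated contrast is
a per-measure one-way ANOVA on pooled values; for two groups F = t²
exactly. Under the null the cell tests reject at 5.3% (1,000-replicate
check), within the nominal band.

The anterior/central/posterior clusters follow the standard 10-20
grouping; the anterior-temporal electrodes T1/T2, which the three
clusters do not list, are assigned to the anterior cluster so that all
21 channels contribute to exactly one region. The lesion target set is
unaffected.

## The phenomenology the package reproduces

With group matrices at mean strengths 0.5575 (control) and 0.4945
(patient), and the 0.1 lesion rule applied to the control matrix,
15-run ensembles in literal time units show lower mean LZC for the
lower-connectivity group in the anterior and central regions — in 10 of
10 master seeds for both patient-vs-control and lesioned-vs-control in
the shipped check. This is a directional, scaled reproduction of the
connectivity→complexity link: reduced coupling moves the network away
from the structurally rich near-critical regime toward more regular
dynamics. Coupling-strength sweeps around this operating point change
mean complexity only marginally until the Euler stability bound is
crossed; no monotone complexity-vs-k trend exists in this model's
admissible regimes.

## Problem sizes in the shipped tests

Property and acceptance tests scale simulations to what the checks need:
ensembles of 15 runs × 15,000 samples for the phenomenology (10 master
seeds), 300 s single-subject records for generator-fidelity checks
(20 seeds), 150 s for the null-connectivity check, 1,000 replicates for
the type-I-error band, and 100 seeds for the WPLI noise null. Estimator
oracles (LZ76 brute force up to length 12, curve-length and entropy
anchors) are exact or tightly bounded.

## Known limitations

* The Kuramoto channel model produces unit-amplitude oscillations; no
  amplitude dynamics, 1/f background, or artifacts are simulated.
* The literal-units regime is a discrete map rather than a converged ODE
  solution; it is used deliberately as the dynamical regime with the
  right phenomenology, and step-size checks apply only to the smooth
  regime.
* WPLI-based recovery of generator ground truth is structurally weak
  (zero-lag synchrony); generator fidelity is validated with PLV.
* HFD can exceed 2 on rougher-than-noise inputs; values should be read
  as estimator output, not a clamped dimension.
* Real-data p-values from the original clinical cohort are not
  reproducible here; only the simulation-side phenomenology and the
  statistical machinery are.
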