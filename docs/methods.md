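# Methods

This note documents the models, statistics, defaults and numerical choices
behind `fpvs`, and what the synthetic-data generator does and does not
emulate.

## Stimulation schedules

**Electrophysiology.** A 70 s sequence of images at a 6 Hz base rate with a
face every fifth image, so the face (oddball) frequency is 6/5 = 1.2 Hz and
a sequence holds 84 face onsets spaced exactly 1/1.2 s apart. Contrast is
modulated sinusoidally within each base cycle (`sin²(π·6t)`: zero at image
onsets, unity mid-cycle) and a linear fade envelope ramps contrast over the
first and last 2 s. The sinusoidal form and the linear fade are modelling
choices — the paradigm only requires smooth transitions — and neither
enters any spectral statistic, which depend only on event times.

**fMRI.** A 405 s run: 44 cycles of a 2.167 s face burst (13 images at the
6 Hz rate) every 9 s (0.111 Hz), padded by 4.5 s of baseline at each end.
At TR = 1.5 s this is 270 volumes; the first 9 s (6 volumes) are treated as
dummy scans and trimmed at read time, leaving 264 volumes spanning 396 s,
so the stimulation frequency falls exactly on spectral bin 44
(df = 1/396 Hz).

## Synthetic data

**Spike trains** are drawn from an inhomogeneous Poisson process by
thinning (exact, fully reproducible given a seed):

    r(t) = clip₀[ r₀ · (1 + m·c(t)) · (1 + g·1_face(t)) ]

with baseline rate `r₀` (default 5 Hz, a typical fusiform single-unit
rate), multiplicative contrast modulation depth `m` (default 0.5), and a
signed face gain `g` applied inside a boxcar window of each face cycle
(default duration 300 ms). `g = −1` silences the unit during the window
(genuine suppression); values below −1 are clipped. The boxcar window is a
modelling choice; real neurons need not follow the contrast profile.

The response window opens at `onset + 33 ms + latency`: faces become
visible only ~33 ms (a fifth of a 6 Hz cycle, four frames at 120 Hz) after
their nominal onset because of the sinusoidal contrast ramp, and the
time-domain analysis shifts its epochs by the same amount. Anchoring the
generator to the effective onset makes `face_response_latency_s` the
quantity the analysis estimates; anchoring it to the nominal onset would
build a −33 ms bias into every recovery experiment.

**BOLD runs** are a burst boxcar convolved with a canonical double-gamma
haemodynamic impulse response (gamma shapes 6 and 16, undershoot ratio 6,
peak normalised to 1), scaled by a signed amplitude (negative = deactivated
voxel), plus a linear drift (default 0.005 signal units/volume) and white
Gaussian noise (default s.d. 0.5, amplitude 1 — roughly Z ≈ 10 at the
stimulation bin, comfortably suprathreshold like real category-selective
voxels). Ground-truth labels accompany the volumes for recovery tests.

What the generator does **not** emulate: refractory periods, bursting and
rate adaptation in spike trains; physiological (cardiac/respiratory) noise,
motion, spatial autocorrelation and field inhomogeneity in BOLD. Passing
recovery tests therefore demonstrate correctness of the analysis chain
under the stated statistical model, not robustness to every artefact of
real recordings.

## Spectral statistics on spike trains

Trains are binned at 1000 Hz (≥ 2 decades above the highest analysed
harmonic, 18 Hz; a 70 s train is 70 000 samples) and Fourier-transformed
without window or detrend; with two sequences per unit the amplitude
spectra are averaged before statistics (concatenation is available via
`aggregate="concatenate"`). The one-sided amplitude convention (interior
bins × 2/N) is used; every statistic below is scale-invariant so the
convention is cosmetic.

Face statistic: amplitudes at 1.2, 2.4, 3.6, 4.8 Hz are summed; for the
noise reference the amplitudes at offsets ±1..±10 bins (df = 1/70 Hz) are
summed position-wise across the four harmonics, giving 20 reference values
with the same distribution as the summed target. Z is the deviation of the
summed target from the reference mean in units of the reference s.d.
(population, ddof = 0, matching the hand-checkable definition). The base
statistic does the same over {6, 12} Hz (or {6} alone via
`base_mode="6"` — both readings matter when counting face-exclusive
units). A neighbour bin that coincides with a harmonic of the *other*
tagged frequency is skipped and replaced by the next bin outward; with the
default paradigm no such collision occurs within ±10 bins, so this guard
only matters for non-standard rates. Thresholds are fixed at 1.64 / 2.32 /
3.1 (one-tailed .05 / .01 / .001). The SNR spectrum divides each bin by
the mean of offsets ±2..±12 (adjacent bins excluded); bins whose
neighbourhood would cross the spectrum edge or the DC bin are reported
missing.

A target frequency must sit on a bin centre to within df/4; anything
further raises a misalignment error naming the nearest bin (a df/2 rule
would be vacuous — every frequency rounds to within df/2 of some bin).

### Calibration of the Z thresholds (measured)

The nominal p-values attached to the Z thresholds assume the target
amplitude is Gaussian with moments known exactly. Neither holds: null
amplitudes are Rayleigh-like (sums of four are closer to Gaussian but
right-skewed), and the mean and s.d. are *estimated* from 20 bins, giving
the statistic t-like tails. Monte-Carlo under the package's own null
(2000 units, `face_gain = 0`): the face-selectivity rate at Z > 1.64 is
≈ 0.073 rather than 0.05. For the single-bin BOLD statistic at Z > 3.1 the
null voxel rate is ≈ 0.011 rather than 0.001. The inflation is intrinsic —
ideal Gaussian amplitude spectra already give ≈ 0.067 and ≈ 0.004 under
20-bin moment estimation — so these thresholds should be read as mildly
anticonservative screening rules, not exact test sizes. The acceptance
suite keeps the nominal-size check and it fails by design of the
statistic; `scripts/acceptance.py` reports the measured rates.

## Time-domain characterisation

The notch filter zeroes Fourier coefficients within ±0.025 Hz of 6, 12 and
18 Hz (three bins per notch at df = 1/70 Hz) and inverse-transforms.
Epochs span [−0.166, +0.834) s around the shifted onset — a 1 s epoch
placed to include exactly one pre-onset base cycle; epochs overrunning the
sequence ends are dropped and counted (with the default schedule the first
and last onsets are dropped, retaining 82 of 84 per sequence). Smoothing
is a centred rectangular moving average; the 20 ms window is realised as
21 samples at 1000 Hz (the nearest odd length). Baseline subtraction is
per sequence (each sequence's mean rate over [−0.166, 0) s), and the
baseline s.d. is taken across the baseline samples of the averaged curve.
A bootstrap alternative (resample epochs within sequences, empirical 99%
baseline band) is available via `baseline_method="bootstrap"`.

Latency is the earliest post-onset time at which |net| exceeds
2.58 × baseline s.d. continuously for ≥ 30 ms; the crossing direction
fixes the sign, and the amplitude window [0.130, 0.300] s is closed at
both ends. With smoothing, the detected crossing leads the true step by a
few ms (the window averages future samples in); recovery experiments show
a median latency error of ~2–6 ms, well inside one smoothing window.

**Detection power.** The 2.58 s.d. / 30 ms rule on two 70 s sequences
(168 epochs) is reliable for strong modulation: at |face_gain| = 1 and a
5 Hz baseline, ~98–99% of units get the correct sign (and essentially
none the wrong one). At the weaker |face_gain| = 0.5 the expected net
change (~3 spikes/s) sits at the threshold itself, and only ~60% of units
cross it — the remainder are *undetermined*, not misclassified. Sign
recovery experiments therefore use the strong-gain regime; limited power
at small effect sizes is a property of the rule, not of the
implementation.

## BOLD branch

Runs are averaged volume-wise after dummy trimming, FFT'd per voxel
without windowing, and the amplitude at the stimulation bin is
standardised against ±1..±10 neighbouring bins (the neighbour count is a
configuration knob, not a claim). Phase follows a delay-positive
convention: a response peaking after stimulus onset has positive phase, so
haemodynamically lagged activations land in (0, π) and sign-flipped
(deactivated) responses sit π away. The reference phase φ is the centre of
the modal bin of the 20-bin phase histogram over (0, π] of voxels with
Z > 3.1 and positive phase; ties go to the bin whose members carry the
larger summed Z (deterministic, favours the stronger population). A voxel
is an activation iff its circular distance to φ is *strictly* less than
π/2 — a voxel exactly at φ + π/2 is a deactivation. Constant voxels (zero
neighbour spread, up to floating-point residue) get a missing Z and are
logged. Gaussian smoothing and other preprocessing are assumed done
upstream; only dummy trimming and run averaging happen at read time.

## Group statistics

Percentages are rounded half-up to one decimal. Note that at exact .95/.96
boundaries this differs from some published tables that truncate (99/127 →
78.0 here). Pearson χ² on 2×2 tables applies the Yates continuity
correction by default — the choice was validated by recomputing reference
p-values by hand (0.27 and 0.54 require the correction) — and can be
disabled. The latency comparison is a two-tailed percentile bootstrap of
the difference in group means, `p = 2·min(P(Δ* ≤ 0), P(Δ* ≥ 0))`, seeded;
the two resampling streams are assigned after putting the groups in a
canonical order, making the p-value exactly invariant to swapping group
labels under the same seed. The amplitude comparison is a Welch (unequal
variance) two-sample t-test on absolute amplitudes; two constant groups
with equal means return p = 1 by convention.

## Problem sizes

Monte-Carlo experiments in the test suite and acceptance script use 2000
null units, 4000 null voxels, 100-unit sign-recovery cohorts and 50 seeds
per latency condition — sizes at which the Monte-Carlo standard error is
a few per mill on the rates of interest while a full run stays in the
tens of seconds.

## Configuration and reproducibility

`PipelineConfig` collects every constant above (thresholds 1.64 / 2.32 /
3.1 / 2.58, notch width 0.05 Hz, shift 0.033 s, smoothing 0.020 s,
amplitude window [0.130, 0.300] s, bin rate, neighbour counts, simulation
parameters) with YAML overrides validated against the known keys; every
CLI run writes a provenance record (package and library versions, config,
seed) sufficient to reproduce its outputs bit-for-bit.

## Known limitations

- The Z thresholds are anticonservative as measured above; users needing
  exact test sizes should calibrate thresholds by simulation for their
  recording length.
- The latency rule has bounded power at small effect sizes (undetermined,
  not wrong, outcomes).
- The generator's noise models are idealised (see above), and the BOLD
  branch assumes the stimulation frequency is an exact spectral bin after
  trimming — acquisitions with other run lengths need their own schedule.
- Percentage rounding at .x5 boundaries follows half-up, which may differ
  from a source table's truncation by one unit in the last digit.
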