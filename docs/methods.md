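# Methods

This note documents the models and numerical choices behind `placecode`:
what the synthetic session generator emulates, how each analysis stage is
defined, and where the design was genuinely open.

## The synthetic session

A session reproduces a standard CA1 recording-day protocol — rest, familiar
exploration, sleep, novel exploration, sleep — in an 80 cm circular arena.
All generators are deterministic under a fixed seed; trajectory and LFP
seeds are independent of the genotype preset, so seed-matched preset pairs
share behaviour and field potentials exactly and neural contrasts are not
confounded by behaviour (the movement-speed difference reported for the
real animals is deliberately not emulated by default, and is available
through the trajectory parameters if wanted).

### Trajectory

An Ornstein–Uhlenbeck velocity random walk integrated on the 25.6 ms
tracking clock, reflected at the arena wall (reflection preserves the speed
distribution near walls, where a clamping rule would deflate it).
Defaults: mean speed 12 cm/s, velocity time constant 0.7 s, 10% planted
immobility bouts. A 20 min run covers ≥ 94% of in-arena 5 cm bins.

### Spiking

Waking pyramidal intensity:

    λ(t) = baseline + peak · exp(−d(t)²/2σ_f²)
           · (1 + β·(v(t) − v̄))₊
           · exp(κ·cos(θ(t) − φ_pref)) / I₀(κ)
           · g(t)

with d the distance to the field centre, v the 256 ms windowed speed, θ the
theta phase and g a shared per-assembly gain (lognormal, mean 1, redrawn
every 100 ms). Spikes are drawn by Lewis–Shedler thinning with the bound
recomputed per cell; the intensity is evaluated at candidate spike times
with positions and (unwrapped) phase linearly interpolated — holding λ
constant over 25.6 ms frames would smear ~74° of theta phase per frame and
attenuate the planted locking by ~7%, breaking parameter recovery. Because
the theta frequency wanders independently of phase, the phase occupancy is
uniform and spike phases are exactly von Mises distributed, which is what
makes the mean-vector length a clean estimator of A(κ) = I₁(κ)/I₀(κ).

Half-rectified linear speed gain is the simplest monotone model of the
speed–rate relationship. Interneurons are spatially untuned, fast-firing
(≈15 Hz), weakly theta-locked, and their SWR gain does not differ between
presets.

Sleep/rest spiking is a low constant rate (1 Hz pyramidal, 8 Hz
interneuron) multiplied inside SWR events by the preset's burst gain and a
per-event assembly gain, and modulated by von Mises theta coupling inside
REM intervals. Setting `reactivation=False` permutes assembly membership in
sleep, which destroys exploration→SWR cofiring similarity while leaving
every single-cell statistic intact — the negative control for the
reactivation analysis.

### LFP

Two channels at 1250 Hz (sufficient for the 150–250 Hz ripple band):
a pyramidal-layer channel and an above-layer reference that shares the
broadband 1/f noise but carries no ripples. Exploration and REM segments
hold a theta oscillation whose frequency wanders inside 6–10 Hz plus 30–80
Hz gamma whose amplitude is gated at a fixed theta phase (240° by default);
NREM segments are delta-dominated (2–4 Hz) noise. Sleep epochs alternate
100 s NREM / 25 s REM blocks. Ripples (160–220 Hz carriers, 50–90 ms Hann
envelopes) are injected at NREM times; their amplitude is calibrated
against the background's own ripple-band RMS statistics so an event peaks
at a requested z-score (default 10 SD), making the generator's "SNR" the
same quantity the detector thresholds.

### Genotype presets

The `control` and `tgDISC1like` presets encode directional contrasts
between a wildtype-like and a DISC1-overexpressing-like population: field
width 10 vs 7 cm, speed gain 0.020 vs 0.008 per cm/s, novel-epoch theta
concentration κ 0.8 vs 1.6, preferred-phase spread 40° vs 100°, SWR burst
gain 3.0 vs 1.5, novelty phase shift +40° vs 0°, assembly gain σ 1.0 vs
0.4. The numbers are generator choices that realise those directions at
realistic CA1 magnitudes (in-field peak rates lognormal around 15 Hz; with
markedly lower peaks the coherence > 0.5 place-cell criterion becomes
unattainable at 70×70 binning, whereas roughly half of real CA1 pyramidal
cells pass it).

## Analysis conventions

* **Speed**: distance between consecutive 25.6 ms samples, averaged over
  ten consecutive distances with zeros excluded (tracking-dropout
  suppression), times the sampling rate → one value per 256 ms window; a
  window of all-zero distances scores 0. Windows are non-overlapping.
  Immobility: fraction of non-overlapping 1 s windows travelling < 2 cm.
* **Coverage**: 5 cm binning; an empty bin with fewer than five empty
  8-neighbours is unvisited-within-arena, otherwise outside-arena. The rule
  presumes decent coverage: a single enormous unvisited region is
  indistinguishable from outside-arena space and reads as ~0 deficit.
* **Rate maps**: 70×70 bins over the arena bounding square (half-open
  intervals, bin (0,0) at lower left), 5 cm/s speed filter applied to
  samples and (interpolated) spike positions, occupancy in seconds,
  Gaussian smoothing σ = 2 bins normalised by the visited mask so edges are
  not dragged toward zero. Field size, sparsity and information are
  computed on the smoothed map; coherence on the raw map (bin rate vs mean
  of visited 8-neighbours, Pearson).
* **Index of dispersion**: passes are maximal runs of ≥ 2 consecutive
  in-field samples, the field being the smoothed map above a threshold
  fraction of peak (default levels 0.1–0.9). Note that under free foraging
  the per-pass exposure λ·T varies, so even a constant-rate Poisson cell
  has dispersion > 1; dispersion ≈ 1 is expected only when pass exposures
  are matched.
* **Decoder**: rate maps floored at 0.01 Hz so log λ is finite (decisions
  are insensitive at this scale); the log n! term is kept so the evidence
  is a true marginal likelihood; argmax ties break to the smallest
  row-major bin index; windows use the same 5 cm/s filter as the maps
  (disable with `speed_floor_cm_s=None`); maps are built over the decoded
  epoch itself (no cross-validation), matching the measure's definition.
* **Noise correlation**: IFRC window 250 ms (the window length is not
  dictated by the measure's definition; it is configurable), window
  assigned to the 20×20 bin containing its centre, ≥ 5 windows per bin and
  ≥ 3 bins per pair for stability.
* **Filters**: zero-phase symmetric FIR, three cycles at the band's low
  edge but never shorter than 150 ms (high bands still need a narrow
  transition; a 3-cycle 150 Hz filter would leak broadband noise into the
  ripple band). Theta phase comes from the analytic signal of the 5–28 Hz
  filtered trace; 0° is the positive peak, increasing with time.
* **SWR detection**: reference subtracted *before* filtering (cancels
  common-mode artifacts exactly); 10 ms sliding RMS; background mean/SD
  frozen from the first sleep session with a two-pass estimate that
  excludes > 3 SD samples, since the ripples themselves would otherwise
  inflate the baseline; events extend to the 2 SD crossings, < 30 ms events
  dropped, < 50 ms gaps merged; the centre is the peak-power time.
* **Gamma–theta coupling**: gamma-cycle peaks are taken within detected
  gamma epochs overlapping theta epochs; cycle peaks outside high-power
  periods are noise-driven and uniform in phase, so including them erases
  the coupling.
* **Circular statistics**: degrees externally, radians internally; the
  Rayleigh test (via pingouin) gates significance at p < 0.05; population
  locking strength averages all units' vector lengths (a significant-only
  variant is a flag); the Watson–Williams test applies the standard
  κ-based correction and flags r̄ < 0.45 as low-concentration. The χ²
  confidence formulas for the angular variance, transformed through
  r = 1 − S², bracket the concentration r — they are the error bars drawn
  on r, and are stored as such. The variance-ratio F test on S² treats the
  angular variance as if (n−1)S²/Σ² were χ²-distributed; for moderately
  concentrated samples S² is in fact *less* variable than that reference,
  so the test is conservative (empirical type-I ≈ 1% at κ = 1, n = 100).
  It is implemented in its classical form; treat its p-values as an upper
  bound on the attained size.
* **Reactivation**: 100 ms windows tile waking theta intervals; each SWR
  contributes one 100 ms window centred on the event (events are usually
  shorter than the window); pairs need both cells active (≥ 10 spikes,
  non-zero variance) in a condition.

## Problem sizes in the test suite

Tests and the acceptance script scale simulations to what each property
needs rather than always running the full protocol: single-operation tests
use 5–20 min single epochs; the paired preset-contrast suite uses 20 min
novel epochs with 30 pyramidal cells per session; the detector
false-positive bound uses 100 simulated event-free minutes; reactivation
comparisons use 10 min exploration + 20 min sleep with 40 cells (≈ 200 SWRs
— pairwise cofiring needs that many events before the assembly signal
clears the count noise of ~0.3-spike windows).

## What passing tests do and do not show

The generator is a statistical emulator, not a biophysical model: Gaussian
single fields (no multi-field or directional cells), linear speed gain,
sinusoidal theta with phase-gated gamma, categorical assemblies with
lognormal gains, and stage-scheduled sleep. Parameter-recovery tests
therefore demonstrate that the analysis code measures what it claims on
data whose generative process matches the analysis assumptions; they do not
validate the assumptions themselves against real tissue, nor do preset
contrasts constitute evidence about the biological genotypes they imitate.
Detector thresholds (theta/delta ratio 2, multitaper NW = 3 with 5 tapers,
gamma 2 SD, SWR 7 SD with 30 ms / 50 ms morphology rules) are standard
values exposed in each function's signature; analyses of real sessions
should revisit them against their own noise floors.
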