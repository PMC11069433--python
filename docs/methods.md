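# Methods

## The pipeline

`oddmark` treats MMN/P300 characterization as a fixed sequence of
operations, each with an explicit contract:

**Simulation.** Five oddball conditions (A, V, AV, CrA, CrV), 400 trials
each, deviant probability 0.14 (so exactly `round(0.14·400) = 56` deviants),
presented in four blocks of 100 with the deviants partitioned multinomially
across blocks and shuffled within block. Epochs span [−500, 550] ms at
1 kHz over a 64-channel extended 10-20 montage (including mastoids M1/M2).
The standard response is a modality-appropriate N100; the deviant response
adds an MMN, a P300 and an N100 adaptation-release component (see below).
All component waveforms are Gaussian bumps parameterized by peak latency,
signed amplitude and FWHM — exactly the three quantities the pipeline
measures downstream.

**Preprocessing.** Zero-phase 4th-order Butterworth band limiting
(0.1–45 Hz, high- and low-pass cascaded into a single forward–backward
pass), baseline correction over [−200, 0] ms, linked-mastoid rereferencing,
rejection of trials with any sample strictly beyond ±100 µV, and random
subsampling of standards to the deviant count. The 0.1 Hz high-pass is
meaningful only on signals much longer than its ~10 s settling time; on
1.05 s epochs it costs a few percent of amplitude at worst and does not
move peak latencies (zero phase), which is what matters here.

**Common spatial filter.** Per subject, the five condition-average
difference waveforms are time-concatenated into a (5·T) × channels matrix;
the filter is the first K = 4 eigenvectors of its channel covariance
(equivalently the right singular vectors). Channel means are removed per
condition segment, not over the concatenated axis: concatenated-axis
centering subtracts a mean vector that mixes condition-specific
topographies into the pooled covariance and measurably rotates the leading
eigenvectors even on noiseless data. Component signs are fixed
deterministically: a component whose grand-average projection is dominated
by the 100–250 ms range is oriented so its negative extremum there wins
(MMN is negative by definition); a component dominated by 250–500 ms is
oriented positive there (P300 is positive); exact ties fall back to making
the largest-|loading| channel positive. Projection averages the K component
time courses with equal weights, which is identical to projecting onto the
mean of the K loading vectors.

**Temporal characterization.** Paired t tests across subjects at every
timepoint; maximal runs with p < 0.001 lasting ≥10 ms become significant
segments (at sampling rates other than 1 kHz the 10 ms duration, not the
sample count, is held fixed). Zero-variance timepoints get p = 0 when the
mean difference is nonzero, else p = 1. Within the MMN (100–250 ms) and
P300 (250–500 ms) search ranges, a 100 ms window is centered on the
group-average extremum inside the significant segments; windows crossing an
epoch edge are shifted, never shortened. Per subject, the window minimum
(MMN) or maximum (P300) gives amplitude and latency; ties resolve to the
earliest sample. Windows default to inclusive bounds (101 samples at
1 kHz); the 100-sample convention is available via ``inclusive=False``.

**Group statistics.** One-way repeated-measures ANOVA from the textbook
sums-of-squares decomposition; partial η² = SS_cond/(SS_cond + SS_err)
(the within-subject convention consistent with the magnitudes such designs
report). Mauchly's W is computed on orthonormal Helmert contrasts with the
chi-square approximation including both standard correction terms (this
matches R's ezANOVA and pingouin to numerical precision); when sphericity
fails the F test is reported with a warning rather than auto-corrected, and
when Mauchly's prerequisites fail (n ≤ k−1 or singular contrast covariance)
the ANOVA result carries NaN sphericity fields. Post hocs are pairwise
paired t tests with Bonferroni multiplication by k(k−1)/2 (a pooled-error
variant is available).

**Source localization.** The forward model is the analytic Legendre-series
solution for a current dipole in a homogeneous conducting sphere
(radius 85 mm, conductivity 0.33 S/m), evaluated on a cubic grid (default
5 mm spacing, sources kept inside 90% of the radius where the series
converges rapidly); radial orientation is undefined at the exact center, so
that voxel's fixed-orientation gain is zero by symmetry. eLORETA weights
follow the symmetric fixed-point iteration w_j = (K_jᵀ M K_j)^{1/2} with
M = pinv(K W⁻¹ Kᵀ + αH), α = λ·tr(K W⁻¹ Kᵀ)/N_ch and H the
average-reference projector; λ defaults to 0.1. Condition maps are the
per-voxel power of the inverse-projected, average-referenced window-mean
ERP (a per-timepoint power option exists); the reported map is
deviant-minus-standard, thresholded strictly above the 99th percentile
separately per hemisphere (hemisphere = sign of x; voxels within 1 mm of
the midline belong to both).

## The synthetic generator: what it emulates, and what it does not

The generator is calibrated so that the pipeline operates in the regime the
method needs — the regime real recordings of this paradigm occupy, where
both components are detectable in all five conditions and four PCs explain
more than 80% of the difference-waveform variance.

* **Amplitude bookkeeping.** The default MMN/P300 amplitudes (e.g. MMN
  −10.91 µV in A, P300 +12.13 µV) are measurements *through* the equal-weight
  four-component average, which attenuates any single component's time
  course by 1/K. The generator therefore treats those values as
  measured-scale defaults and injects K·amplitude into channel space
  (`PROJECTION_GAIN = 4`). Between-subject variation: latency SD 20 ms,
  measured-scale amplitude SD 2 µV (measured SDs also contain extraction
  noise, so the generative SD is smaller than the tabulated ~3 µV).
* **Topographies.** Gaussian blobs on the electrode sphere (30° scale):
  P300 centro-parietal (Pz), auditory MMN fronto-central (FCz), visual MMN
  right posterior-temporal (P8), N100-modulation central (Cz). The four
  deviant-component patterns carry zero weight at the mastoids — a
  linked-mastoid reference otherwise subtracts most of any
  mastoid-adjacent pattern, which would silently delete the visual MMN
  from the filter — and are Gram–Schmidt orthogonalized, the residual side
  lobes playing the role of dipolar return fields. Spatial separability is
  what makes the equal-weight PC average a stable readout; strongly
  overlapping patterns rotate the principal axes subject by subject and
  scramble the summed projection.
* **Rank-4 signal.** Deviants additionally release the N100 from
  stimulus-repetition adaptation (75 ms, −3 µV measured scale, FWHM 50 ms,
  jitter-clipped below the 100 ms search-range floor). With only three
  signal topographies the fixed K = 4 filter would hold one arbitrary
  noise axis whose random orientation degrades the average; the fourth
  genuine component closes that gap. This extends the
  deviant = standard + MMN + P300 composition by one term.
* **Noise.** Per trial: 1/f pink noise (2.2 µV SD), spatially mixed across
  channels by a 20° Gaussian angular kernel (volume-conduction-like low
  spatial rank), plus independent white sensor noise (0.8 µV SD), both
  band-limited to 125 Hz (acquisition antialiasing) and synthesized in the
  frequency domain with analytic normalization. These scales describe
  clean, artifact-free post-rejection EEG; they put the 56-trial-average
  difference waves in the signal-dominated regime the retention rule
  (λ₁..₄ ≥ 0.8) presupposes.
* **Not emulated:** blinks and EMG artifacts (the amplitude-rejection and
  EOG-regression cleaners are exercised on constructed data instead),
  trial-to-trial latency jitter within a subject, realistic BEM head
  geometry, and any between-condition correlation structure beyond shared
  component topographies. Passing tests therefore demonstrate the
  pipeline's correctness and its behavior under controlled conditions, not
  robustness to every artifact of real recordings.

## Numerical choices

* SNR statistic: per channel, 100·(p2p − sd)/p2p with p2p the peak-to-peak
  of the ensemble-average ERP. The dispersion ``sd`` defaults to the std
  over time of the averaged prestimulus baseline ([−200, 0] ms), which
  vanishes in the noiseless limit; a whole-epoch variant
  (``dispersion="avg_epoch"``) is provided. Under the default convention
  the statistic is floored near ~84% for any stationary noise on a
  400-trial average (extreme-value geometry of p2p versus sd), so observed
  values on the synthetic cohort sit in the high 80s.
* The eLORETA fixed point is declared converged when the maximum relative
  weight change drops below 1e-6 (default), and the operator is rebuilt
  from the final weights; non-convergence is flagged, not raised.
* PCA rank is truncated at eigenvalues ≤ 1e−12 of the leading one, so
  rank-deficient input (e.g. a rank-1 toy) yields K below the requested
  count.
* Deterministic seeding throughout: Philox-style `SeedSequence` keyed by
  (seed, subject, condition, stream); identical seeds give bit-identical
  epochs, filters and manifests.
* Bulk noisy epochs are synthesized in single precision; the zero-noise
  path stays in double precision so ground-truth recovery holds to 1e−12.

## Problem sizes

Full-scale runs use the design's native sizes (21 subjects × 5 conditions
× 400 trials × 64 channels × 1051 samples). Monte-Carlo checks use reduced
sizes chosen once: the repeated-measures power study runs 100 cohorts of 21
subjects at 250 Hz with 60 trials per condition on a 17-channel montage
subset; Mauchly's type-I error uses 1,000 cohorts of n = 200, k = 3; the
inverse-solution exactness grid uses 50 voxels at 30 mm spacing.

## Known limitations

* The equal-weight component average is intrinsically sensitive to
  eigenvalue degeneracies: two components with near-equal pooled variance
  can rotate within their eigen-subspace and partially cancel in the
  average. The generator avoids that regime by construction; on real data
  the condition-specific filter (provided) is the natural robustness check.
* Latency recovery near strongly overlapping components (e.g. CrV, where
  MMN and P300 are closest) carries a small systematic bias (≲8 ms at the
  defaults) because each component's flank shifts the other's extremum.
* EDF output quantizes to 16 bits per channel with per-file physical
  scaling; round trips are exact only to the quantization step. The
  `.npz` fixture format round-trips bit-identically.
* The spherical-head forward model is exact for its geometry but is not a
  realistic head: localization results are reported in grid coordinates
  and validate the inverse algorithm, not anatomical claims.
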