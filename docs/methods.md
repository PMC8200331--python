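# Methods

This note documents the models, algorithms and numerical choices behind
`optoconn`, and what the synthetic-cohort tests do and do not establish about
real recordings.

## Signal model and preprocessing

Raw dual-wavelength intensities `I_λ(c, t)` (λ ∈ {760, 850} nm) are converted
to optical density against the mean baseline, `OD = −ln(I / mean_t I)`
(natural logarithm throughout, consistent with the exponential forward model).
The modified Beer–Lambert law relates OD changes to chromophore concentration
changes via molar extinction coefficients (Gratzer/Kollias compilation, see
`extinction.py`), the source–detector distance in cm, and differential
pathlength factors, by default 5.3 at 760 nm and 4.2 at 850 nm (assignment
configurable; concentrations reported in µM). The 2×2 system is solved per
channel and time point; forward model followed by inversion round-trips to
better than 1e−9.

**Wavelet despiking.** Sparse motion artifacts are removed in an undecimated
(shift-invariant) Daubechies-4 transform over `floor(log2 n) − 4` levels. A
detail coefficient is flagged when it exceeds 10 robust SDs (1.4826·MAD) of
its level; a flag is acted on only when it coincides — within an 8-sample
dilation — with a flag on an adjacent level, the signature of a non-stationary
transient present across frequencies. Flags inside a guard band of 8 filter
lengths at each boundary are ignored (reflection padding creates spurious
fine-scale coefficients there), and levels whose scale is below 1e−3 of the
channel's robust SD are skipped (numerically empty levels otherwise flag
harmless round-off). A clean sinusoid passes with < 1% RMS change; an injected
10-SD spike is suppressed by ≳ 90%.

**Segment selection.** Records are truncated to 5000 samples (~560 s at
8.93 Hz). The automatic strategy scans candidate windows at a stride of 10
samples and keeps the one minimising the motion score
`Σ_channels Σ_t (Δx)²` — a mechanical stand-in for the visual best-segment
selection used in practice.

**Joint nuisance regression.** Each chromophore is cleaned by a single OLS
against: sine/cosine pairs at every sampling-grid frequency `k/T` with
`0.09 Hz ≤ k/T ≤ Nyquist` (cosine only at the Nyquist bin), Legendre
polynomials of orders 0–4 evaluated on the grid and *orthonormalised on the
grid* (continuum orthogonality only holds to O(1/n²) on finite samples), and
the across-channel mean of the same chromophore (global signal regression,
GSR). The fit is computed exactly but efficiently by Frisch–Waugh–Lovell: the
Fourier block is an orthogonal basis on the grid, so its projection is applied
through the FFT, after which only the 6-column polynomial + global block needs
an explicit solve. Residuals equal the explicit-design OLS residuals to
machine precision (tested), are orthogonal to every design column, and leave
< 1% of power above 0.09 Hz.

Two inherent properties of this model are worth knowing. First, the joint OLS
*can* absorb a small fraction of genuine sub-cutoff signal through the
low-passed polynomial columns; the effect shrinks quadratically with record
length (0.3% of variance at 5000 samples, 3.5% at 1500) and is a property of
the model, not an implementation artifact. Second, GSR removes each record's
projection onto its global mean: on ~5-minute records a slow network
fluctuation can covary with the global signal by chance, in which case the
aligned fraction of that subject's network time course is genuinely removed.
Cohort-level structure is preserved (planted group maps are recovered at
|r| ≈ 0.97), but single-subject time-course recovery is only guaranteed in the
median.

## Quality assessment

Valid recordings show *antiphase* HbO/HbR dynamics. The coupling report gives
per-channel Pearson correlation and the circular mean of the instantaneous
(analytic-signal) phase difference; a subject passes when the median channel
correlation is negative. The pass threshold is a configurable default, not a
calibrated decision rule — the tool reports, a human decides. Hierarchical
channel clustering uses average linkage on `1 − r` distance.

## Robust connectivity

For z-scored series x, y the joint outlyingness of each time point is the
*whitened* (Mahalanobis) pair radius

    ρ(t) = sqrt[(x² − 2·r₀·x·y + y²) / (1 − r₀²)],

with r₀ the initial plain correlation. Weights are the Tukey biweight
`S(u) = (1 − (u/k)²)²` for `u = ρ/σ < k` (else 0), with `σ = 1.4826·MAD(ρ)`
and `k = 4.685`; both series are weighted once (no iteration) and an ordinary
Pearson correlation of the weighted pair is taken. Whitening the radius is
essential: the raw norm `sqrt(x² + y²)` is not independent of the pair's
angular position when x and y are correlated (large-radius samples align with
the major axis), so any redescending weight on it biases the estimate toward
zero by ~0.2 at r = 0.5 *on clean data*, destroying the estimator's defining
property. On the whitened radius the weight is angle-independent at the
Gaussian model: across 50 clean draws of n = 5000 the robust estimate differs
from plain Pearson by at most 0.013, under 1% contamination at 20 SD it beats
plain Pearson in ~99% of replicates, and as k → ∞ it reduces to Pearson
exactly.

One consequence: heavy-tailed *signal* (e.g. bursty neural fluctuations) is
partially down-weighted too — that is intended robust-estimator behaviour, and
it is why the generator-oracle accuracy tests plant Gaussian time courses.

`k = 4.685` is not folklore here: `tuning_constant_for_efficiency(0.95)`
solves `E[ψ²]/E[ψ′]² = 1/0.95` for the biweight ψ under the standard normal
(ψ(u) = u(1−(u/c)²)², ψ′(u) = (1−(u/c)²)(1−5(u/c)²)) and returns 4.685 to
three decimals. The companion Monte-Carlo (`relative_efficiency_mc`) measures
the one-step Newton biweight location estimate (median start, MAD scale) at
~94.8% efficiency for n = 1000 — the one-step *weighted-mean* variant, by
contrast, only reaches ~91% and was rejected for that reason.

Connectomes are Fisher r-to-z transformed (`atanh`, diagonal masked, |r| = 1
clipped to 1 − 1e−7 with a warning) and averaged within groups in z space.

## Group ICA

FastICA (parallel, tanh contrast, tol 1e−6, ≤ 500 iterations; backed by
scikit-learn) operates on features × observations matrices. Component signs
are fixed by orienting the largest-|loading| feature positive; results are
bit-reproducible for a fixed seed. Model order defaults to the smallest
number of leading principal components explaining 60% of variance, with an
optional diagnostics table (mean Iq and HbO/HbR map anticorrelation over a
window of orders) so the full criterion triple stays auditable.

**Consistency (Iq).** Components from `n_runs` random restarts are pooled and
clustered by average linkage on `1 − |corr|` between *source* estimates
(subsampled to ≤ 20 000 observations). Mixing columns live in a
low-dimensional feature space where chance |corr| between unrelated components
is large, so similarity is always computed on sources. Each cluster's
`Iq = mean intra-cluster similarity − mean similarity to outside elements`;
the centrotype (member most similar to its cluster) represents the component.
This is restart-only consistency — no bootstrap resampling. Two consequences,
verified empirically and reflected in the tests: Iq is *not* monotone in
additive noise (a fixed noise realization has stable non-Gaussianity optima of
its own), and surplus noise components are not reliably rejected by a
recurrence filter; what restart consistency does discriminate is genuine
source clusters out-scoring surplus components, and well-separated planted
sources scoring Iq > 0.9 while pure-noise decompositions average far lower.

**Temporal group ICA.** Subjects are z-normalised per channel row and
concatenated to `[2C rows] × [T·N columns]` (rows 0..C−1 HbO, C..2C−1 HbR).
FN maps are ICASSO centrotypes (or single-run mixing columns); group time
courses are the least-squares projection of the group data on the maps.
Chromophore consistency is `corr(map[HbO rows], map[HbR rows])` — ≈ −1 on
generated cohorts, as the antiphase coupling implies. Dual regression is two
least-squares stages with stage-2 regressors variance-normalised; on
noiseless `maps · timecourses` constructions both stages recover the truth to
machine precision.

**Connectome ICA.** The edge matrix has subjects as features and the 2·P
Fisher-z edges as observations; sources are edge patterns (FCCs), mixing
columns are subject weights. Edge vectors are unit-normalised (weights absorb
scale) and signed so the mean of the top-decile edges is positive. The hybrid
retention filter keeps components whose restarts match the cluster centrotype
at |corr| > 0.75 in ≥ 75% of runs. Statistics run on the raw subject weights;
the FDR family is the set of extracted components.

## Inference

One-way between-subjects F-tests (groups fixed, subjects random), BH step-up
FDR at q = 0.05 (channel family = the 46 channels of one FN and chromophore;
component family = the extracted FCCs). The JZS Bayes factor for the one-way
design against the grand-mean-only null uses the default g-prior
`β | g ~ N(0, g·σ²·(X'X/N)^{-1})` with `g ~ InvGamma(1/2, r²/2)`, r = 0.5
("medium"), giving the exact one-dimensional integral

    BF₁₀ = ∫ (1 + gN)^{−(k−1)/2} · (1 − h·R²)^{−(N−1)/2} π(g) dg,
    h = gN/(1+gN),   R² = SS_between / SS_total,

evaluated by adaptive quadrature in log space (BIC fallback, flagged, if the
quadrature ever fails). Calibration: BF₁₀ < 1/3 in ≥ 90% of null replicates
(3 × 100 subjects) and > 10 in ≥ 95% of replicates with a d = 1.5 spread at
n = 30/group. Evidence labels follow the conventional Bayes-factor ranges
(anecdotal 1–3, substantial 3–10, strong 10–30, very strong 30–100, decisive
> 100, mirrored for H0 through BF₀₁ = 1/BF₁₀), with interval bounds assigned
to the stronger bin.

## The synthetic cohort

Defaults emulate a 99-infant study: 3 groups of 36/30/33, 46 channels
(23 mirror pairs), 8.93 Hz, 6000 samples truncated to 5000 (~560 s). Per
channel c and subject:

    HbO = Σ_k a_k·L_k(c)·s_k(t) + pulsatile physiology·gain(c)
          + slow systemic·sgain(c) + drift + noise + spikes
    HbR = −γ·[network part] − scaled slow systemic
          + scaled pulsatile physiology (independent phases) + drift′ + noise′

with γ = 0.3 and per-subject log-normal amplitude jitter (σ = 0.25) on every
network — the subject-to-subject variation that connectome ICA needs to
separate components.

* **Networks.** Three bilateral Gaussian-bump networks (unit-norm loadings,
  centers at 20/50/80% of each hemisphere, amplitude 3 µM) with *bursty* time
  courses: a 4th-order Butterworth band-passed carrier multiplied by a slow
  positive envelope, z-scored, with the product confined to (0, 0.09) Hz.
  Burstiness is essential, not cosmetic: band-passed Gaussian noise is
  Gaussian, and no ICA can separate Gaussian sources — a generator built that
  way can never satisfy a planted-network recovery check.
* **Homotopic background.** Each mirror channel pair shares its own *Gaussian*
  band-limited time course (flat unit-norm profile over pairs, amplitude
  1.5 µM). Gaussianity here is equally deliberate: the coupling is fully
  present in the correlation structure (the connectome-ICA target, recovered
  with top-edge precision 1.0) while temporal ICA correctly does not spend
  components on it — with bursty per-pair sources FastICA devotes components
  to single channel pairs and the network maps degrade.
* **Physiology.** Pulsatile: cardiac 2.3 Hz (0.4 µM), respiration 0.6 Hz
  (0.25 µM), Mayer 0.1 Hz (0.3 µM), ±10% frequency jitter and random phase
  per subject, per-channel gains U(0.5, 1.5) — all above the 0.09 Hz cutoff,
  removed by the Fourier block. Slow systemic: a 0.01–0.08 Hz global
  vasomotor fluctuation (1.5 µM) moving HbO and HbR antiphase (flow-driven
  washout). This term is what GSR exists to remove; without it the sub-cutoff
  global mean is network-dominated and GSR destroys the very maps it is
  supposed to clean around (matched recovery drops from ~0.97 to ~0.2–0.4).
* **Artifacts.** Legendre drifts of orders 1–4 (coefficients N(0, 0.5²)),
  white noise (0.3 µM HbO / 0.2 µM HbR), Poisson motion spikes
  (0.2 per channel-minute, amplitude 5–8 channel SDs, echoed into HbR).
* **Ground truth** carries group labels, per-network amplitudes and time
  courses, spike locations, and the *realized* noise-free neural correlation
  matrix — the exact structure an ideal estimator would see for that subject.

Raw pooled corr(HbO, HbR) on generated subjects is ≈ −0.6, and the antiphase
state survives preprocessing.

**What passing tests show — and don't.** The generator produces linear,
stationary-in-distribution signals with known sparsity structure; real infant
fNIRS adds optode-coupling drift, sleep-stage dynamics, scalp physiology that
is neither purely global nor purely sinusoidal, and anatomical variability in
channel placement. Recovery of planted structure therefore validates the
*machinery* (conversions, filters, decompositions, statistics), not the claim
that real cohorts decompose this cleanly; consistency indices on real data are
expected to be substantially lower than the ≈ 1.0 seen on planted sources.

## Problem sizes and analysis choices

The end-to-end acceptance study runs the full default cohort
(99 × 46 × 5000). Its group decomposition uses model order 5 — the three
planted networks, the homotopic background and the residual shared mode left
by GSR — and skips ICASSO restarts where only maps are consumed; the
connectome ICA uses 5 components with 10 restarts. Unit and property tests
use reduced cohorts (16 channels, 1500–3000 samples, 6–16 subjects) sized so
each oracle isolates one mechanism; several use "oracle conditions" (Gaussian
time courses, no systemic term, no GSR, full-record window, band above the
polynomial block's reach) with the rationale stated in each test's docstring.
Statistical power examples (planted effect detected with power > 0.8 at
n = 30/group) are exercised on the statistics layer with synthetic subject
maps/weights carrying the same effect size; the full pipeline's effect path
is covered once by the planted-effect integration example.

## Known limitations

* No short-separation-channel regression (the montage has none) and no motion
  correction beyond the wavelet scheme (no spline, no tPCA).
* GSR-induced anticorrelation is visible in connectomes computed with the
  default chain — as in real data — so connectome-accuracy oracles disable it.
* The SNIRF writer covers the continuous-wave subset only; montage distances
  ride in a `metaDataTags/channelTable` TSV tag (SNIRF itself stores
  positions, not distances).
* Restart-only ICASSO (no bootstrap) yields optimistic Iq on fixed datasets;
  see the consistency section.
* The JZS Bayes factor covers the one-way design only; no covariates, no
  post-hoc pairwise tests.
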