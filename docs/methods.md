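# Methods

This note documents the models, conventions, parameter defaults and
design choices behind `oct2vf`, and what the synthetic experiments do and
do not demonstrate.

## Geometry and conventions

All analysis runs in **right-eye convention**: field coordinates in
degrees with positive x temporal and positive y superior; the blind spot
at (15, ±3). The 24-2 pattern has 54 candidate locations (rows y ∈ {±21,
±15, ±9, ±3} with 4/6/8/9 points, extended one point nasally to 27° at
y = ±3); removing the two blind-spot points leaves the 52 analyzed
locations, ordered row-major (superior→inferior, then ascending x). RNFL
profiles are 768 samples on the 3.45-mm peripapillary circle in TSNIT
order, sample k at angle k·360/768 with 0° temporal, 90° superior, 180°
nasal, 270° inferior. Left-eye data are mirrored on ingest (field x
negated; profile index k → (768−k) mod 768); both maps are involutions.

### Garway-Heath sectorization

The published six-sector correspondence (central, temporal, inferior,
inferior-nasal, superior, superior-nasal field regions ↔ optic-disc
sectors at 311–40°, 121–230°, 41–80°, 81–120°, 271–310°, 231–270°) does
not come with a machine-readable 52-point table, so the packaged config
(`oct2vf/data/garway_heath_24_2.yaml`) **encodes it via a small
retinotopic model**: each field point is projected onto the inverted
retina, fibers nasal to the disc enter radially, and fibers temporal to
the disc sweep around the macula without crossing the horizontal raphe;
the resulting disc entry angle is binned at the published sector
boundaries. This reproduces the expected topology (macular points →
temporal disc; arcuate regions → vertical poles; nasal steps →
infero/supero-nasal disc; strict vertical-hemifield separation) but is an
approximation of the original map: individual border points may differ.
The YAML is deliberately editable — replacing it with any exact
transcription changes nothing else in the pipeline.

## Synthetic cohort generator

The generator is the stand-in for a clinical registry and defines the
study conditions; its defaults are fixed and not adjusted per experiment.

**Healthy profile.** A 360°-periodic double hump: temporal base 50 µm
plus circular-Gaussian peaks of 45 µm at 80° and 280° (SD 35°). Per eye,
the supra-floor part is scaled by a lognormal subject factor (SD 0.07);
per test, smooth low-order harmonic noise (SD 2.5 µm) emulates
segmentation jitter.

**Disease.** With probability 0.7 a patient is glaucomatous; affected
eyes receive 1 + Poisson(0.7) wedge defects (centers near the vertical
poles with probability 0.8, width U(20°, 60°), depth fraction
U(0.3, 0.9), cosine-tapered edges, applied multiplicatively above the
floor) and, with probability 0.5, diffuse loss of U(5%, 30%).

**Forward model.** Each field point i pools the profile with circular-
Gaussian weights (SD σ_map = 15°) around its disc entry angle α_i (from
the same sector config), giving local thickness t_i. Noiseless
sensitivity is

    S_i = clamp( N_i(age) + 10·γ·log10( (t_i − b) / (t̄_i − b) ), 0, 40 ) dB,

with residual (non-axonal) floor b = 30 µm, γ = 1, and t̄_i the same
functional of the healthy curve. Age-corrected normals fall off with
eccentricity: N_i = 34 − 0.1·ecc_i + (−0.07)·(age − 50) dB. Threshold
noise is zero-mean Gaussian with SD σ(S) = 1.5 + 0.4·max(0, 25 − S),
capped at 8 dB — flat above the 25-dB knee and growing steeply below,
reflecting the very large perimetric variability at sensitivities under
~15 dB. Hierarchy: patients → 1–2 eyes → 1 + Poisson(0.75) visits; SAP
and OCT dates offset by U(−60, 60) days; ~8% of exams are forced to fail
one curation filter. Everything is reproducible from one seed.

**Normative tables.** Healthy exams give per-point linear age
regressions, empirical TD/PD percentiles at 5/2/1/0.5% (linear
interpolation between order statistics — chosen so tests can be exact),
and the mean profile; glaucoma exams give the pointwise 10/5/1-percentile
profiles used as simulated-defect depths.

What the generator does **not** emulate: real TSNIT shape variability
(split bundles, axis rotation), media opacity and cataract, fixation
behavior, long-term progression trends, floor effects of OCT
segmentation, and any deviation of the true human SF map from the
circular-Gaussian assumption. Passing tests therefore demonstrate that
the pipeline recovers a *known* nonlinear SF relationship from noisy
paired data at realistic scale — not that the learned map equals the
human one.

## Network and training

Architecture: conv(32, k=3) → ReLU → conv(64, k=3) → ReLU → flatten
(764·64) → dense(54) → ReLU → dense(52, linear). Unstated details were
fixed as: valid padding, stride 1, no pooling (a circular-padding option
exists but is off by default), Glorot-uniform initialization with zero
biases, inputs divided by 100 (µm → ≈[0, 2.5]), targets left in dB,
batch size 128. Adam uses β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁷, lr 10⁻³; MSE
loss; the best-validation-MSE epoch's weights are returned. Per-epoch
train MSE is the running mean of batch losses; validation MSE is a full
pass. Training is deterministic given the seed on a fixed machine
(weights, shuffling and batching are all seeded; bit-identity across
BLAS builds is not guaranteed, so tests compare at numerical tolerance).
The OLS baseline is solved by least squares on the augmented design;
with fewer rows than inputs it falls back to a small ridge penalty
(α = 10⁻³) with a warning.

## Statistics

Pointwise metrics are per-location MAE and Pearson r across test exams
(average r = mean of the 52 per-point r's; a pooled variant is available;
zero-variance points are excluded with a warning). Sector metrics average
measured and predicted fields within Garway-Heath sectors per exam first.
Confidence intervals use a cluster bootstrap resampling **patients** (the
level at which repeated measures correlate), percentile method, seeded.
Model comparison uses (a) the cluster bootstrap of the difference in
average pointwise r, with percentile-inversion p-value — a Fisher-z
statistic is reported alongside but ignores clustering and pairing — and
(b) a random-intercept (participant) linear mixed model on exam-level
mean absolute errors (statsmodels MixedLM, REML). Error structure is
summarized by MAE in 2-dB bins of measured threshold over [0, 40] dB and
by Pearson correlations of exam-level error with MD, PSD and global RNFL.

## Reports and the SF map

TD_i = threshold − (intercept + slope·age); general height = 7th-largest
TD (1-based, ties counted); PD = TD − GH; probability categories compare
deviations to the empirical normative percentiles, boundary inclusive
toward abnormal; MD is the unweighted TD mean and PSD the sample SD of
TD about MD (commercial eccentricity weightings are proprietary and
deliberately not imitated). Rendered thresholds are clamped to [0, 50] dB
for display only.

Simulated defects replace a sector's samples by min(base, P_q) with
abrupt edges — half-open [start, end) sectors so the twelve 30° sectors
tile the 768 samples exactly (64 each). The SF map feeds all 36
simulated profiles through a predictor and derives a report for each;
"abnormal" in map summaries means PD category worse than ns.

## Problem sizes and numerical choices

The benchmark study uses 1,500 patients (≈4,400 paired exams after
hierarchy sampling, ≈4,100 after filters; 15% of patients held out for
test, 15% of the rest for validation) and 30 training epochs — chosen as
the smallest scale at which the nonlinear network separates clearly from
the linear baseline while a full study completes in a few minutes on one
CPU. At this scale the network's average pointwise MAE lands below the
generator's mean noise SD ratio of 1.5 and below the OLS baseline. The
hemifield asymmetry of the trained map at the deepest defect depth is
reliable at the benchmark seed but, being a learned property at 30
epochs, can fail in one of the four pole sectors at other seeds; the
oracle-predictor map satisfies it exactly, which the suite also asserts.

Degenerate inputs: a config whose healthy local mean does not exceed the
floor b is rejected; zero-variance columns in OLS fall to the
pseudoinverse; empty sectors, missing percentile columns, unpairable
exams and missing metadata all fail loudly with reasons logged.

## Known limitations

* The Garway-Heath table is a model-based encoding, not a transcription.
* MD/PSD are unweighted variants of the commercial indices.
* The CNN's learned map is only as anatomically correct as the generator
  that produced its training data; no claim transfers to human data
  without retraining on a real registry.
* Training reproducibility is per-machine; cross-platform runs may
  differ in the last float digits and occasionally in the selected epoch.
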