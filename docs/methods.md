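# Methods

This package studies directed (effective) connectivity between eight
default-mode-network (DMN) regions of interest from multichannel
resting-state time series, using partial directed coherence (PDC) computed
from multivariate autoregressive (MVAR) models, and asks whether
group-level connectivity differences and connectivity–symptom correlations
of the kind reported for social-anxiety cohorts can be recovered end to end
from data with known ground truth. Because no recordings are deposited for
such severity studies, the package ships a calibrated synthetic-cohort
generator; everything downstream (preprocessing, model fitting, PDC, group
statistics) treats the generated data exactly as it would treat real ROI
time series.

## Connectivity model

Each subject's 8-channel series x_t follows (or is modelled as) an MVAR(p):

    x_t = Σ_{r=1..p} A_r x_{t−r} + e_t,   e_t ~ N(0, Σ)

with A_r[i, j] the lag-r influence of channel j on channel i. With

    Ā(f) = I − Σ_r A_r exp(−i 2π f r / fs)

the (column-normalised, unsquared) PDC from source j to sink i is

    π_ij(f) = |Ā_ij(f)| / sqrt(Σ_k |Ā_kj(f)|²),

so Σ_i π_ij(f)² = 1 for every source column at every frequency: PDC
measures the fraction of channel j's outflow directed at channel i,
relative to all of j's outflows. π_ij(f) is non-zero exactly when some
A_r[i, j] is non-zero, so PDC reflects direct coupling only. A squared
variant is available (`squared=True`); it changes magnitudes, not
orderings.

Band-averaged PDC is the arithmetic mean of π over the grid frequencies
(0.5-Hz spacing, 0 to Nyquist) of five bands: delta [1, 4), theta [4, 8),
alpha [8, 13), low beta [13, 22), high beta [22, 30]. The clinical
literature prints these bands with 1-Hz gaps (1–3, 4–8, 8–12, 13–21,
22–30 Hz); half-open intervals close the gaps without overlap. The
per-subject deliverable is an 8 × 8 × 5 tensor with the diagonal zeroed
for reporting (self-influence is not interpreted).

## Estimation

MVAR coefficients are estimated by stacked ordinary least squares on
zero-mean (per-channel, per-epoch) data. For a subject with several 4-s
epochs the default is a single pooled fit: regression rows from all epochs
are stacked, never straddling an epoch boundary. The alternative
(`aggregate="per_epoch"`) fits each epoch separately and averages the
band-averaged PDC across stable fits; it is retained because the two
readings of "per segment, then averaged" both occur in practice. The
pooled fit is the default because PDC is a normalised magnitude: with only
1024 samples per fit, null connections acquire a rectification noise floor
of roughly 0.1 that epoch-averaging cannot remove, whereas pooling 29
epochs drives the same floor below 0.02. The estimator-consistency tests
(mean absolute error < 0.05 against the analytic PDC of the generating
model at 29 × 4-s epochs) are attainable only under pooling.

The innovation covariance uses denominator rows − n·p. The model order is
selected once per subject by the Akaike information criterion,

    AIC(p) = N ln det(Σ̂_p) + 2 p n²,

minimised over p = 1..12 with ties towards smaller p (N = regression
rows; the penalty counts coefficients only — documented because AIC
variants differ and reproducibility requires fixing one). Stability is
checked via the spectral radius of the n·p × n·p companion matrix
(threshold 1 − 1e−6).

Fitted models on filtered data may be mildly "unstable" in this numerical
sense (see Preprocessing below); since PDC is an algebraic functional of
the coefficients, the pooled path computes PDC with a warning for radii in
[1, 1.2) and errors only beyond that.

## Synthetic cohort generator

The generator defines the emulated study conditions: 4 severity groups (control,
mild, moderate, severe; SIAS bins < 20, < 35, < 50, ≥ 50) × 22 subjects,
8 ROI channels (FZ F3 F4 | PZ | P3 P4 | CP5 CP6 — mPFC, precuneus/PCC,
lateral parietal, supramarginal; MNI centroids stored in the montage),
nominally 2048 Hz raw / 256 Hz working rate. Defaults follow the emulated study
design: 116 s of usable signal per subject (29 × 4-s epochs) is the
reference recording length; the library default of 180 s simply gives
headroom for artifact rejection.

Each group has a ground-truth MVAR(6) over the 8 channels:

* **Diagonal self-dynamics.** Every channel carries an AR(6)
  characteristic polynomial built from explicit roots. *Alpha sources*
  have a pole pair at 10 Hz (radius 0.985) plus moderate real roots;
  *delta sources* a pole pair at 2 Hz (radius 0.96); the moderate group's
  precuneus hub carries both; pure sinks get weak broadband roots
  (≤ 0.5). Source resonances shape where that source's outgoing PDC
  concentrates, because the column normalisation is dominated by the
  source's own |D_j(f)| off resonance. The delta rhythm is a 2-Hz
  resonance rather than a DC-adjacent real pole so that the generated
  spectra are sensible under a 0.4-Hz high-pass.
* **Coupling graphs.** Minimal directed templates (7–10 edges) encode the
  qualitative group claims: precuneus (PZ) is the dominant out-degree hub
  for the severe and moderate groups; the control group has elevated
  frontal (FZ/F3/F4) outflow; delta-flavoured edges exist only in the
  mild (supramarginal sources) and moderate (PZ hub + supramarginal)
  groups. Every template is a DAG, making the coupled system
  block-triangular: its eigenvalues are exactly the diagonal roots, so
  stability holds for any coupling strength.
* **Edge kernels.** Delta-flavoured edges act at lag 1. Alpha-flavoured
  edges use a two-lag differencing kernel (+s at lag 1, −s at lag 5)
  whose transfer |B(f)| = 2s|sin(4πf/fs)| vanishes at DC; without it,
  alpha coupling leaks enough into the delta band (ratio ≈ 0.6) to
  destroy the designed delta-band group ordering.
* **Calibration.** Per group, one scale per edge flavour is set by
  alternating bisection on the *analytic* band-averaged PDC of the true
  coefficients so that the mean off-diagonal alpha-band PDC equals the
  reported clinical group means (control 0.0797, mild 0.0501, moderate
  0.0776, severe 0.0587), and the delta-band mean hits design targets of
  0.045 (mild) and 0.060 (moderate). The reported delta means (up to
  0.147) are unreachable in principle for sparse graphs: column
  normalisation caps the summed PDC of a source with k out-edges at √k,
  so a 56-entry mean of 0.147 would need ≈ 8 units of total PDC from ≤ 10
  edges. The delta contrast is therefore reproduced at a scaled-down
  level that preserves the reported ordering
  (moderate ≈ mild > control ≈ severe); control and severe carry only
  leakage delta (≈ 0.008–0.013).
* **Per-subject variability.** Each subject rescales all template edges
  by a truncated-Gaussian global gain (SD 0.25, clipped to [0.6, 1.4])
  plus ±10% per-edge jitter, then re-verifies stability and the ±30%
  alpha calibration band. The gain gives subjects a genuine spread in
  true mean connectivity (relative SD ≈ 0.06–0.14 across groups,
  measured from 200 spec draws per group — the generator's own
  calibration constant).
* **SIAS scores.** score = bin centre + slope · z + noise, rounded and
  clipped to the severity bin, where z standardises the subject's true
  mean alpha-band PDC by the group reference (template analytic mean,
  relative SD 0.08). Slopes: severe +7, control −5, mild/moderate 0;
  noise SDs 3.75–5.25 points. The slope/noise ratios give a designed
  within-group correlation near ±0.8 — strong enough that the
  correlation computed from *estimated* PDC (attenuated by estimation
  noise) remains significantly positive (severe) / negative (control) at
  n = 22 in at least 80% of cohorts. Mild/moderate scores are
  independent of connectivity.
* **Recordings.** Gaussian innovations (identity covariance), 8-s
  burn-in discarded, optional 50-Hz line sinusoid. The ground truth is
  defined at the working rate; a 2048-Hz "raw" recording is the
  band-limited polyphase upsampling of the 256-Hz realization, so
  decimating it recovers the working-rate process.

What the generator does **not** emulate: volume conduction / shared scalp
reference, 1/f broadband background with realistic exponents, ocular or
muscle artifacts (only optional amplitude spikes and line noise),
non-stationarity across the recording, and non-Gaussian innovations.
Passing tests therefore demonstrate correctness of the estimation and
statistics machinery under a known stationary linear ground truth — not
robustness of PDC to the confounds of real scalp EEG.

## Preprocessing

Stage order: optional common-average reference → optional zero-phase FIR
band-pass (0.4–50 Hz) → artifact marking on 1-s spans (per-channel robust
z via median/MAD, threshold 5, plus optional absolute-amplitude
threshold) → anti-aliased decimation to 256 Hz (polyphase) → segmentation
into non-overlapping 4-s epochs on a fixed grid from the recording start
(an epoch is kept iff all its samples are artifact-free; 116 s of clean
data gives exactly 29 epochs).

Two stages are implemented, fully tested, and **off by default** in the
pipeline configuration, with the reasons below; both can be enabled per
run:

* *Common-average reference.* On an n-channel set CAR forces the channels
  to sum to zero at every sample, making the lagged MVAR design matrix
  exactly rank-deficient — the coefficients, and hence PDC, become
  unidentifiable. CAR is a scalp-montage operation; the generator emits
  reference-free ROI-level series.
* *Band-pass before the MVAR fit.* Filtering before autoregressive /
  Granger-type estimation is known to bias directed-connectivity
  estimates: on this generator it inflates the off-diagonal error against
  the analytic oracle from ≈ 0.016 to 0.06–0.10, pushes AIC order
  selection to the search cap, and occasionally yields mildly unstable
  fitted models. The filter itself (symmetric Kaiser FIR applied once by
  FFT convolution with delay compensation — exactly zero phase, ≥ 45 dB
  stopband at 0.5·low and beyond high + 10 Hz) is appropriate when drift
  or line noise is actually present; with the 50-Hz line enabled the high
  cutoff should be set slightly below 50 Hz, since a passband edge at
  exactly 50 Hz attenuates the line by only ~6 dB.

## Statistics

* One-way fixed-effects ANOVA with η² = SS_between/SS_total. Two layouts:
  *connection-level* (per group, the 64 directed pairs of the group-mean
  matrix, diagonal zeros included → df (3, 252), matching the degrees of
  freedom reported in connection-level severity analyses) and *subject-level* (one mean
  off-diagonal value per subject → df (3, 84) at 22/group). The
  connection-level layout treats connections as observations and is kept
  for comparability; the subject-level layout is the statistically
  defensible one (subjects are the sampling units) and is used for the
  design-effect tests.
* Tukey HSD post hocs (studentized range, via SciPy), Bonferroni
  correction across the five bands (reject iff p ≤ α/m).
* Normality screening by one-sample Kolmogorov–Smirnov against a normal
  with the sample's mean/SD. Estimating parameters from the sample makes
  this conservative (the Lilliefors caveat); it is advisory only and
  never gates the ANOVA.
* Pearson correlation of each subject's mean off-diagonal alpha-band PDC
  with the SIAS score, per group and pooled; two-sided p from the t
  distribution with n − 2 df.

## Numerical and design notes

* Frequency grid 0.5 Hz; band membership by half-open intervals (last
  band closed at 30 Hz).
* Diagonal zeroing happens only in the reporting tensor, never inside
  the PDC normalisation.
* Seeds fan out from the master seed through `numpy` SeedSequences keyed
  by (seed, group index, subject index, stage), so enlarging a cohort
  never perturbs existing subjects and all outputs are reproducible
  byte-for-byte given a config.
* Problem sizes in the shipped tests and the acceptance script are chosen
  for a laptop-scale run: cohorts of 22/group at 60–116 s per subject,
  fixed order 6 where the order is known, 50-cohort Monte Carlo for the
  design-effect rate. The library defaults (180 s) are used when a single
  cohort is analysed.
* Degenerate inputs fail loudly: rank-deficient regressors, zero-variance
  samples for normality tests, empty bands on a too-coarse grid, epochs
  shorter than one complete window, SIAS inputs outside [0, 1] mean PDC.

## Known limitations

* PDC magnitudes from short data carry a positive bias on null
  connections (rectified estimation noise); group *contrasts* are robust
  to it but absolute estimated means sit above the analytic values
  (≈ +0.01 at 29 epochs). Statistical thresholding of individual edges
  (asymptotic PDC null distributions) is out of scope.
* The connection-level ANOVA mixes heterogeneous connections; with
  hub-concentrated alpha graphs its power for alpha-band group
  differences is poor even when subject-level differences are large.
* The generator's delta-band contrast is a scaled-down version of the
  reported group means (see Calibration above); only the ordering is
  reproduced quantitatively.
* Band power was not a calibration target: because group templates assign
  different source resonances, the synthetic cohort shows strong
  band-power group differences, whereas connectivity-focused designs on
  real data often report none. Power tables are descriptive output here.
* No forward head modelling, source localization, or scalp-level
  simulation; the pipeline begins at ROI time series.
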