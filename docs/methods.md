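# Methods

This note documents the models, algorithms, parameter choices and
numerical details behind `minusend`, and what validation on synthetic
data does and does not establish about real microscopy data.

## Single-molecule counting by convolution-basis deconvolution

### Model

A diffraction-limited punctum containing *k* active fluorophores has
background-corrected integrated intensity equal to the sum of *k*
independent draws from the single-fluorophore intensity distribution
*f* (independent emitters, linear camera response, no quenching or
FRET).  The population intensity density is therefore a mixture

p(x) = Σ_{N=1..N_max} w_N · f^{*N}(x)

where f^{*N} is the N-fold self-convolution of *f* and w_N the fraction
of puncta with N active fluorophores.  The method estimates *f*
nonparametrically from a monomeric control imaged under identical
acquisition settings, so no distributional family is assumed at fit
time.

### Numerical construction of the basis

*f* is a normalized histogram on a uniform grid starting at 0.  The
default binning is Freedman–Diaconis on the monomer sample (2·IQR·n^{-1/3});
a fixed width or bin count can be supplied.  The basis grid spans
[0, N_max × monomer support] with the monomer bin width, so no member is
ever truncated.

The discrete N-fold self-convolution of bin-centre samples lives on
centres offset by (N−1)/2 bins; each member is shifted back onto the
shared centres by linear interpolation.  The shift is exact for odd N;
for even N the half-bin linear shift preserves the first moment exactly
and perturbs the variance by at most (bin width)²/4 — negligible
against the 2% moment-identity tolerance used in the tests.
Convolution is computed either in the frequency domain
(`scipy.signal.fftconvolve`, default) or by direct summation; both
implement the same discrete operation and agree to ~1e-16, which the
test suite asserts as an oracle check at 1e-8.

### Fit

Weights solve a nonnegativity-constrained least-squares problem between
the test-sample histogram density and Σ w_N·basis_N, with per-bin
weights 1/max(count, 1) (approximately inverse Poisson variance, so
empty tails do not dominate), then are renormalized to sum to one.
Weights below 1e-3 after renormalization are truncated to zero and the
remainder renormalized again, purely for reporting clarity.  An
unconstrained variant (`nonneg=False`) exists behind a flag; the
nonnegative, renormalized fit is the default because weights are
population fractions.  The fit raises rather than returning silent
zeros when the sample does not overlap the basis support.

The fit is invariant to a common rescaling of all intensities (the
arbitrary-units gauge), which is tested.

### Assumptions and known biases

Incomplete fluorophore maturation, photobleaching before acquisition
and blinking are **not** modelled inside the fit: the fitted w_N
estimate the distribution of *active* fluorophore counts, a lower bound
on true subunit counts.  The bias is quantified separately by the dimer
brightness diagnostic: for a dimer population with per-fluorophore
activity p and detection requiring ≥ 1 active fluorophore, the expected
dimer/monomer brightness ratio is 2p/(1−(1−p)²) — e.g. 1.538 at
p = 0.7 instead of 2.  `brightness_ratio` reports the measured ratio
with a seeded bootstrap SE (1,000 resamples).

## Spot detection

Detection is a difference-of-Gaussians band-pass (σ and 2σ), thresholded
at `snr_threshold` × a robust noise estimate, defined as 1.4826 × the
median absolute deviation of the DoG response.  Candidate maxima are
the per-component response peaks.  Two deliberate choices:

- **Component size** for the minimum-size filter is measured on the
  raw-image support mask (pixels above the image median plus
  `snr_threshold` × raw-image MAD), not on the band-pass response.  The
  band-pass smears compact objects, so its component size depends on σ;
  the intensity-threshold support reproduces the particle-analysis
  notion of "particle size" exactly on constructed inputs (a 7-px
  component is rejected by an 8-px minimum and an 8-px one kept,
  exactly).
- **Non-maximum suppression** at 2σ keeps the stronger response, making
  detections unique; detection is exactly translation-equivariant for
  integer shifts because all thresholds are global, shift-invariant
  statistics.

Sub-pixel refinement fits an isotropic 2D Gaussian plus constant offset
by `scipy.optimize.least_squares` in a window (default 11 px) around
each candidate; integrated intensity is A·2πσ².  Non-convergent or
non-positive-amplitude fits keep the crude estimate with
`fit_ok=False`; edge-clipped windows are fitted on the clipped box and
flagged, and flagged spots should be excluded from intensity statistics.

Colocalization uses mutual nearest neighbours within `max_dist`
(default 4 px — the plugin parameter this replaces is not standardized;
it must be reported with results).  Each spot matches at most once and
the operation is symmetric.  Empty inputs yield an undefined result
with a flag, never 0%.  For independent uniform point sets of density λ
the expected matched fraction is ≈ 1 − exp(−λπr²); mutual matching
depresses this by O((λπr²)²), well inside the 3-SE test band at the
densities used (λπr² ≈ 0.06).

Stretch counting thresholds the image (≥ T), restricts to a polygon
ROI, and counts 8-connected components of at least `min_size` pixels
(default 8 px, the conventional particle-analysis minimum); density is
count per µm² of rasterized ROI area.

## Event scoring

Scoring operates on per-complex event tables (one row per immobilized
complex, event times in seconds, NaN for absent events) with the
invariant t_nucleate ≤ t_bind ≤ t_growth_onset ≤ t_release, all within
the observation window; events after the window end are censored by the
generator and ignored by design (fixed-duration movies).  All scores
are deterministic ratios:

- nucleation efficiency: % active of total, per field of view, with
  mean ± s.e.m. across fields (fields are the replication unit);
- colocalization: % of active complexes with a binding event, reported
  with the pooled denominator count;
- release: % with minus-end growth onset, over all active complexes or
  over bound complexes only (both denominators are meaningful and both
  are exposed);
- re-nucleation: % of depolymerized complexes that nucleate again;
- delays: t_growth_onset − t_bind, histogrammed at 50 s (matching the
  granularity at which such delays are conventionally reported).

Capping: an end is scored capped iff its growth speed is below
`fast_growth_cutoff` (default 0.5 µm/min — the plus end is recognized
by fast growth, so a conservative low cutoff marks minus ends) **and**
some bound interval lasts ≥ `min_stable_s` (default 120 s).  Bound
intervals separated by gaps of at most one frame (default 20 s, the
typical capping-movie frame interval) are merged first, to tolerate
single-frame signal loss from blinking; this gap tolerance is a
declared choice, not a measured one.  Fast-growing ends are excluded
from the capping denominator.

`normalize_to_control` divides per-cell measurements by the mean of
control cells *from the same experiment* (pairing enforced by an
experiment key; a missing control raises, naming the experiment), so
the grand mean of normalized controls is 1.  `relative_abundance`
divides component intensities by a reference component (default GCP6),
the convention for relative iBAQ stoichiometry tables.

## Microtubule dynamics

Kymographs: the stack is sampled bilinearly at 1-px arclength steps
along a polyline, across a `width`-px band normal to the path, and
projected by maximum (default, the convention of reslice plugins) or
mean.

Track segmentation: per-sample central-difference velocities (one-sided
at the ends) are classified as growth (v > v_threshold), shrinkage
(v < −v_threshold) or pause.  Runs shorter than `min_phase_s` are
absorbed into the longer neighbouring run iteratively; same-type
neighbours are re-merged.  Phase velocities are per-phase least-squares
slopes, so a noiseless linear segment yields its slope exactly.
Defaults: v_threshold = 0.3 µm/min, min_phase_s = 3 frames.  These are
declared defaults — the thresholds in the plugins this replaces are
unpublished — and both must accompany any reported numbers.

Catastrophe frequency is pooled: f = Σ N_cat / Σ t_growth, with
t_growth the summed duration of growth phases only (pauses do not
accumulate catastrophe exposure, the field convention).  The relative
standard error is 1/√N_cat, the Poisson-count reading of the
conventional error estimate for switch frequencies; this reading is a
declared choice.  Zero catastrophes give f = 0 with the SE flagged
undefined.

Known estimator bias: shrinkage excursions shorter than `min_phase_s`
are absorbed and their catastrophes missed; with the default settings
and the simulated regime used in validation (mean shrinkage phase
100 s, min phase 6 s) the loss is a few percent, well inside the
3-relative-SE recovery band.

## Ring geometry

The reference is an ideal one-turn helical ring: subunit i at angle
2π(i−1)/13 (the 13-protofilament angular spacing is kept even for
partial rings), radius 112 Å and axial rise 9.4 Å per subunit — the
conventional 13-pf B-lattice monomer values, all overridable, and a
user-supplied ring (CSV or PDB Cα centres) bypasses the ideal ring
entirely.  At most one turn (13 subunits) is allowed.

Superposition is Kabsch least squares over all shared subunit indices
(`scipy.spatial.transform.Rotation.align_vectors`, proper rotations
only); the anchor subunit (default 6, a middle spoke) fixes index
registration but does not receive extra weight — anchoring the
registration while superposing on all subunits is a declared reading of
the ambiguous "align with anchor" workflow this replaces.  Collinear
configurations and missing anchors raise.

Displacements are computed in the reference frame: radial = distance of
the test subunit from the reference axis minus the same for the
reference subunit (positive = outside the reference radius); axial =
(test − reference) projected on the axis.  Both signed profiles and
|axial| are emitted, since either convention appears in plots.
Unshared indices are skipped and listed.  Profiles are invariant under
a common rigid motion of both rings applied before alignment (tested).

PDB input is parsed from fixed-column ATOM records so that malformed
records can be reported with their line number and chains lacking Cα
atoms listed by name; the parse is cross-checked against an independent
structure library in the tests.

## Synthetic-data generator

The generator produces every input class with ground truth attached,
and its defaults define the validation conditions:

- **Monomer intensities**: lognormal by default (right-skewed,
  nonnegative — measured single-GFP histograms are right-skewed but
  their family is not standardized, so the family and CV are
  configurable and recorded in output metadata), mean 1000 a.u.,
  CV 0.35; gamma and degenerate (delta) families for tests.
- **Oligomer puncta**: size N from the scenario weights, active count
  k ~ Binomial(N, p_active) conditioned on k ≥ 1 — all-dark puncta are
  undetectable, so they are resampled until the requested number of
  detected puncta is reached and the resample count is recorded (this
  conditioning is what produces the 2p/(1−(1−p)²) brightness ratio).
  The bimodal preset puts 37% of mass on sizes {1,2} and 36% on {4,5}.
- **Spot images**: background + isotropic Gaussian PSFs + Gaussian read
  noise; optional Poisson shot noise by flag.  16-bit TIFF output.
- **Event tables**: per-complex Bernoulli branches — nucleation per
  window (default 3%), binding given active (30%), release given bound
  (50%), depolymerization given active (20%; the depolymerization
  probability is a generator-only parameter needed so the re-nucleation
  branch has a population), re-nucleation given depolymerization (50%)
  — with a binding→growth delay drawn from Uniform(50, 350) s inside a
  600 s window.  Nucleation and binding are placed in the first tenth
  of the window each so that delayed growth onsets remain observable;
  onsets beyond the window are censored and counted.
- **Dynamics tracks**: a two-state telegraph process (growth
  2 µm/min, shrinkage 15 µm/min, catastrophe 0.004 s⁻¹, rescue
  0.02 s⁻¹) integrated exactly through switch times and sampled at dt,
  with additive Gaussian position noise; position is clamped at zero
  with a forced rescue (a microtubule cannot have negative length).

All generators are bit-reproducible given their seed.

What the generator does **not** emulate: camera pixelation/EM gain
statistics, uneven illumination, focal drift, spectral bleed-through,
aggregation, stage drift, photobleaching *during* a movie, or
correlated event processes (e.g. binding probability depending on
complex composition).  Passing recovery tests therefore demonstrates
the correctness of the estimators under the stated statistical model,
not robustness to every instrumental artefact of real data.

## Problem sizes used in validation

Validation runs use 10⁴ monomer / 2×10⁴ oligomer samples for the
counting recovery (with 10³–10⁵ for the sample-size monotonicity check
over 20 seeds), 20-spot 256×256 images at SNR 10 for detection, 2,000
points per set for the colocalization null, 5,000 complexes for event
recovery (99% binomial intervals), and 20 tracks of 3,000 s for
catastrophe recovery (≈ 200 pooled catastrophes).  These sizes make all
stochastic checks comfortably resolvable while the whole suite and the
acceptance script each complete in seconds.

## Limitations

- The mixture fit's resolution degrades as the monomer CV grows or as
  adjacent oligomer sizes both carry weight; recovery is validated at
  CV 0.35 with the dominant components two sizes apart.  N_max
  (default 8) caps the model and must be reported.
- No multi-frame particle linking, drift correction, or automatic
  kymograph tip tracing: tracks and event tables are the contract, as
  they are produced upstream (manually or by other tools).
- The capping rule's tolerance to transient signal loss (1-frame gap
  merge) and the 1/√N relative SE for catastrophe frequency are
  declared conventions, flagged as such above.
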