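# Methods

## Forward model

All geometry is in millimeters, right-handed, with the conductor center at
the origin.

**EEG.** Potentials come from the classical series solution for a current
dipole inside a concentric multi-shell spherical conductor with an
insulating exterior. Per spherical-harmonic order *n* the radial profile in
each shell is a·sⁿ + b·s^−(n+1); continuity of potential and of radial
current at every interface plus the insulated outer boundary give a small
linear system whose solution yields a surface transfer coefficient vₙ
(vₙ = (2n+1)/n for a homogeneous sphere). The electrode potential is the
source expansion Σₙ vₙ (b/R)ⁿ⁻¹ [n Pₙ(μ)(q·û) + Pₙ′(μ) q·(r̂−μû)] /
(4πσ₁R²), evaluated with stable Legendre recurrences and re-referenced to
the common average. Truncation defaults to 60 terms; the implementation
estimates the last-term ratio and warns when it exceeds 10⁻⁶ of the
accumulated sum (sources at 70 mm under electrodes at 92 mm converge to
~10⁻⁵ at 60 terms; deeper sources much faster). The equal-conductivity case
is verified in the tests against an independently derived closed form
(generating-function summation of the series).

**MEG.** The closed-form field of a dipole in a spherically symmetric
conductor. It depends only on the conductor center — shell conductivities
drop out — and makes exactly radial dipoles silent. Axial gradiometers
subtract the field at a second coil placed `baseline` (default 50 mm) along
the radial coil normal. The tests check the field against a dense
surface-quadrature evaluation of the volume-current integral and the
free-space radial-component identity.

**Sensor arrays.** Electrode and coil layouts are quasi-uniform
golden-angle packings on spherical caps: 80 EEG electrodes on the outer
shell (z/R > −0.35, a dense 10/10-style coverage), 273 MEG gradiometers on
a 110 mm helmet cap (z/R > −0.25). Counts are study defaults; the
coordinates are the package's own construction.

**Shell cascade.** Default geometry: brain 80, CSF 85, skull 90, skin
92 mm; sources on a 70 mm "cortex" sphere. Registered levels: `3C` (three
shells, no CSF: 0.33 / 0.01 / 0.43 S/m), `4C` (CSF at 1.79 S/m), `6C`
(skull split into compacta 0.0081 / spongiosa 0.025 / compacta), and
`reference` (the most detailed registered profile). Tissue anisotropy is
not representable in concentric isotropic spheres; the perturbation
mechanism below covers mismatch beyond the conductivity cascade.

**Leadfield perturbation.** Model simplification is also emulated
modality-agnostically: a random linear combination of Gaussian bumps
(length scale 10 mm, 512 centers drawn from the nodes) added to the
stacked leadfield and rescaled so ‖ΔL‖_F/‖L‖_F equals the requested level
exactly; EEG perturbations are average-referenced before scaling. The
length scale was calibrated once against the measured inter-node
normalized-gain contrast (≈0.20/0.14/0.10 at 500/1,000/2,000 nodes on the
70 mm sphere) so that the default level ladder {0, 0.02, 0.05, 0.1, 0.2}
spans sub-grid effects up to multi-centimeter mislocalization, the regime
the experiment is designed to probe.

**Source space and the offset rule.** Nodes are quasi-uniform on the
cortex sphere (seeded random rotation). For each reference source, in
index order, its nearest node is displaced along the node-minus-source
direction to exactly 0.55 mm — the midpoint of the open (0.5, 0.6) mm
band — preventing an inverse crime while bounding the best achievable
error; construction fails loudly if two sources contend for one node or a
displaced node stops being nearest. Localization error can therefore never
be below 0.5 mm, and ~0.55 mm is a perfect recovery.

## Simulation

The spike template is a biphasic difference of Gaussians: a sharp negative
transient (center 130 ms, width ≈70 ms) followed by a slower positive wave
(center 300 ms, width ≈250 ms, relative amplitude 0.45), peak-normalized,
530 ms (636 samples) at 1,200 Hz, tapering below 1 % of the peak at both
ends. The protocol simulates a single 100 nAm source firing twice (defaults
5 s and 13 s) in a 20 s (24,000-sample) measurement.

Sensor noise is white Gaussian, demeaned and rescaled per channel so the
realized sample variance equals the requested value exactly; the same seed
at two variances yields the same realization times a scalar, mirroring a
single shared noise run at two scales. Defaults: 10⁻³ and 1 µV² (EEG), 1
and 10³ fT² (MEG) for the low/high scenarios. For EEG, noise is added per
electrode first (sensor noise physically precedes referencing) and the
full measurement is then common-average referenced; channels are demeaned
before covariance estimation.

## Beamforming

The covariance is the biased 1/T outer-product average. Inversion uses a
cached symmetric eigendecomposition with eigenvalues below 10⁻¹⁰ of the
largest truncated: a common-average-referenced measurement is structurally
rank N−1 (the all-ones direction is null for both data and referenced
leadfields), and the truncated solve is the inverse on the zero-mean
subspace. A covariance deficient beyond that allowance raises an error
pointing at the optional diagonal loading flag (C + λ·trace(C)/N·I,
default off) — loading is equivalent to adding perfectly white sensor
noise and is the supported way to scan near-noiseless data.

Orientation per constraint: unit gain takes the minimal eigenvector of
A = **L**ᵀC⁻¹**L**; unit array gain the maximal generalized eigenvector of
(**L**ᵀ**L**, A); unit noise gain the maximal generalized eigenvector of
(A, **L**ᵀC⁻²**L**). These are the standard maximum-output-variance
solutions of the constrained Rayleigh quotients; a 10,000-direction grid
search arbitrates them in the tests. When the gain is numerically
rank-deficient (singular value below 10⁻⁸ of the largest — e.g. the
exactly silent radial direction of spherical MEG) the pencil is restricted
to the gain's right-singular subspace, which keeps the unit-gain variant
meaningful for MEG in a spherical conductor. When every direction is
equivalent (identity covariance) the tie-break returns the gain's largest
right singular vector. Orientation signs follow a deterministic convention
(largest-magnitude component positive); WᵀL > 0 holds for all three
filters by construction. The unit-gain filter is built from the
Frobenius-normalized gain while its orientation comes from the
unnormalized gain (normalization provably does not change the direction
problem, and this keeps one orientation definition per constraint).

Scans emit one record per node — orientation, output variance WᵀCW, and
excess kurtosis of the same filtered waveform; degenerate nodes are
reported with NaN outputs and a warning, never silently zeroed.
Localization takes the maximal node with a lowest-index tie-break, flagged
on the result.

## Error summaries

Tukey-style boxplot statistics with linear-interpolation quartiles.
The whisker rule measures the 1.5·IQR distance from the **median** — as the
study design states it — with `whisker_anchor="quartile"` available for the
conventional quartile-anchored rule; values beyond the whiskers are
outliers. The 40 mm cap and rounding to mm apply only to rendered
summaries, never to stored errors or statistics.

## Experiment driver

For every (source × orientation class × noise level × model × constraint ×
criterion) cell the driver simulates with the **reference** model at the
true source position and scans with the **simplified** model's leadfields —
the model-mismatch design. Both orientation classes (quasi-radial /
quasi-tangential: eigenvectors of the MEG gain's 3×3 Gram matrix for the
smallest/largest eigenvalue) are derived from the MEG gain and reused for
EEG. All per-row randomness derives from the master seed through a fixed
counter scheme, making the results table byte-identical across reruns and
independent of scheduling. Failures are recorded per row with a reason; the
driver always completes.

## Desk-scale problem sizes

The behavioral acceptance checks trade the full 8,000-node / 24,000-sample
protocol for sizes a laptop handles in minutes, as the package's own
default test configuration:

* grid-floor recovery: 600-node source spaces, 4 s measurements
  (two firings at 1 s and 2.6 s), all 60 sources, low noise, diagonal
  loading λ = 0.03. Loading is needed because near-noiseless covariances
  are effectively rank-deficient, and it places the unit-noise-gain
  variant in its working regime (it needs noise-like regularization to
  localize, exactly as its high-noise behavior shows). MEG runs
  quasi-tangential sources only: in a spherical conductor quasi-radial is
  *exactly* radial and hence magnetically silent — no method can localize
  it from MEG, unlike in a realistically shaped head where it is merely
  weak.
* cascade findings: EEG, quasi-tangential, high noise, 1,000 nodes, 20
  sources, 3 replicate seeds, mismatch levels {0, 0.02, 0.05, 0.1, 0.2}.
* the printed protocol constants (24,000 samples, 636-sample template,
  offset band) are asserted at full scale; the offset-band target in
  `scripts/acceptance.py` uses the full 8,000-node source space.

## What the generator does and does not emulate

The synthetic data reproduce the protocol's structure — leadfield
dimensionality and referencing, spike timing, shared scaled noise, the
offset rule, the mismatch design — on spheres with all sources at one
depth. Real heads add depth variation, non-spherical geometry, correlated
brain noise, and FEM-specific forward errors that correlate with tissue
boundaries rather than being statistically smooth. Passing tests therefore
validate the algorithms and the direction of the qualitative effects
(mismatch monotonicity, the unit-gain noise failure, noise-gain/array-gain
equivalence at high noise, kurtosis's greater sensitivity to model error),
not the subject-specific error magnitudes of a realistic FEM study. A
strictly noiseless kurtosis scan is degenerate by mathematics — with
rank-1 data every filtered waveform is a scalar multiple of the source
waveform and kurtosis is scale-invariant — which is why the "noiseless"
checks run at the protocol's low-noise setting instead.

## Known limitations

No vector beamformers, no event-related variant, no correlated-source
mitigation, no kurtosis-optimal orientation, no combined MEG+EEG, no
FEM/BEM solving or MRI/DTI handling. The conductivity cascade has no MEG
effect in spheres (spherical symmetry); MEG mismatch studies must use the
perturbation mechanism.
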