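# Methods

This note documents the models, conventions, numerical choices and
limitations behind `cprnfl`. It is organised by module; defaults are given
with units and the reasoning that fixed them.

## Coordinate conventions and calibration

Thickness maps live on an anisotropic raster: `n_bscans` rows ×
`n_ascans` columns over a physical extent (default 12 mm × 8 mm at
600 × 80, i.e. 20 µm A-scan and 100 µm B-scan spacing). Pixel (j, i) is
centred at ((i + 0.5)·Δx, (j + 0.5)·Δy) mm with the origin at the top-left
pixel centre; all sampling arithmetic is done in these continuous physical
coordinates, never in index units, so the anisotropy is handled once.

Angles follow the TSNIT convention: θ = 0° temporal, 90° superior, 180°
nasal, 270° inferior in the anatomical frame of the eye. For a right eye
(OD) temporal maps to image −x and superior to image −y (up); left eyes
are mirrored about the vertical axis at sampling time, so downstream code
only ever sees anatomical labels. Vertical sectors are therefore identical
for both eyes, and nasal/temporal swap sides, as they must.

Eccentricity is expressed as visual angle with a fixed lateral scale of
**288 µm/degree** (the adult-eye conversion of the hand-held system), so
6° ≈ 1.728 mm and 1.5 mm ≈ 5.2°. Using visual angle rather than mm makes
ring placement stable across the rapid axial-length growth of early
childhood; no per-subject axial-length rescaling is attempted.

## Polar resampling

Rings are sampled at `n_theta` = 360 evenly spaced angles (1° steps);
annuli on an (`n_r` = 8) × `n_theta` polar grid with shell-midpoint radii
and per-sample weight ∝ radius (the polar area element), so the weighted
mean converges to the true area average (for T = r over the 5–6° annulus,
the analytic centroid radius (2/3)(6³−5³)/(6²−5²) ≈ 5.515°). At the
default grid these discretisation errors are below 0.1 µm on smooth
fields. Values are obtained by bilinear interpolation over the four
neighbouring pixel centres; a sample is valid only when all four nodes are
valid and the position stays inside the pixel-centre bounding box. Bilinear
is exact on affine fields (which gives a strong test: any full ring mean of
an affine field equals the value at the ring centre) and is the
minimal-assumption choice given that the acquisition software's resampling
is closed; nearest/bicubic were considered and rejected as respectively
cruder and smoother than anything the data justify.

`theta_offset_deg` rotates the physical sampling positions while the
recorded angles (and hence quadrant labels) stay nominal. This is the hook
for compensating a known rotation of the scan frame — e.g. the
fovea-to-disc axis as a future quadrant reference — and is what makes the
rotation-equivariance property exact: a frame tilt of δ composed with an
offset of −δ reproduces the untilted quadrant means (to < 0.5 µm on
noiseless phantoms; residual error is pure interpolation noise).

Two quadrant schemes are built in: `equal90` (default; four 90° sectors
centred on 0/90/180/270°) and `gdx` (temporal 50°, superior 120°, nasal
70°, inferior 120°, the unequal proportions of the GDx-style partition).
`equal90` is the default because its boundaries are self-evident and
auditable; the GDx boundary angles in circulation vary by source, so that
scheme is provided as a labelled option and both are configurable.

## Extraction and pairing rules

A quadrant at a location is **captured** when ≥ 90% of its samples are
valid (`capture_threshold` = 0.9). The threshold is a package choice:
"captured" is a qualitative notion in clinical practice; 0.9 tolerates
edge clipping of a ring while rejecting half-missing sectors, and it is
config-exposed and recorded in every output.

A scan pair enters the reliability analysis at a location only when at
least **three quadrants are captured in both arms — the same three**. One
pair per common quadrant is emitted, plus an **Average** pair (the
unweighted mean of the four quadrant means, not the mean over all ring
samples — matching the quadrant-level granularity of the rest of the
analysis) only when all four quadrants are common. Inclusion is evaluated
per location independently (a subject can qualify at 6° but not at 4°); a
single per-pair decision gated on the first location is available as a
switch, since practice varies on this point.

## Reliability statistics

**ICC.** The default form is ICC(A,1): two-way random effects, absolute
agreement, single measures — computed from the two-way ANOVA mean squares
(MSR between subjects, MSC between arms, MSE residual) as
(MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)) with k = 2 arms. Absolute
agreement is the right default for both test–retest and interassessor
designs because a systematic offset between arms is a real disagreement;
the consistency form ICC(C,1) is computed alongside and selectable. The
95% CI uses the F-distribution method with Satterthwaite degrees of
freedom for the A,1 form and the MSR/MSE F-ratio for C,1. Zero total
variance makes the ICC undefined and is returned as a flagged degenerate
case (never silently 1.0); exact agreement with nonzero between-subject
variance returns ICC = 1 with a collapsed CI. The implementation is
validated three ways: against an explicit-loop ANOVA oracle on thousands
of random small instances (10⁻¹⁰ tolerance), against `pingouin`'s
independent implementation (value and CI), and by parameter recovery on
simulated cohorts (below).

**CoV.** Within-subject coefficient of variation, 100·S_w/grand mean with
S_w = √(Σdᵢ²/2n) over paired differences dᵢ — the root-mean-square
within-pair SD. An alternative "mean of per-pair CoVs" is behind a switch;
the two differ and the choice is reported.

**Bias.** The balanced two-way additive model value = µ + arm + subject;
with two complete arms the least-squares arm effect is exactly the mean
paired difference, so the CI and p come from the t distribution on n − 1
degrees of freedom and coincide with the paired t-test (asserted to
10⁻¹⁰ in tests). The sign convention is arm_a − arm_b (high − low
quality; assessor 1 − assessor 2). Zero difference variance is flagged
degenerate with a collapsed CI. A full random-effects mixed model is out
of scope: with one eye per subject and two fixed arms it reduces to this
model anyway.

**Bland–Altman.** Per pair, mean m and difference d; bias = mean(d), limits
of agreement bias ± 1.96·sd(d), and an OLS trend of d on m with its
p-value (a calibrated test: under additive-only noise its rejection rate
at 0.05 is ≈ 5%, checked by Monte-Carlo in the suite). No multiple-testing
correction is applied across table cells; p-values are reported raw.

`reliability_table` maps these over every (quadrant + Average) × location
cell — 25 cells for the default five locations — and `icc_sweep` extracts
the ICC-vs-location profile with CIs.

## The phantom

**Ground truth.** T(r, θ) = g · A(θ) · D(r), where A(θ) is a cosine
interpolation between temporal and nasal baseline levels plus two
raised-cosine bumps of half-width 60° centred at 90° (superior) and 270°
(inferior) — a smooth, integrable stand-in for the arcuate-bundle double
hump, whose exact functional form no study specifies; D(r) =
1/(1 + ρ·(r − 4°)) with ρ = 0.08/degree (thickness falls ~14% from 4° to
6°, a realistic peripapillary decay), clamped at the disc edge; and
g ∈ (0, 1] is the glaucoma factor (global multiplicative thinning). The
field is identically zero inside the disc (default radius 0.95°) and
strictly positive outside. The four configured thickness levels are
*defined* as the equal90 quadrant means on the 6° ring: the basis
coefficients are obtained by solving the 4 × 4 linear system that the
quadrant means at 6° are linear in, so any configuration is met exactly
(defaults 61.12 / 65.44 / 106.43 / 104.64 µm temporal/nasal/superior/
inferior — representative control-cohort values at 6°).

**Error model.** Rendered scans add, to the field sampled at pixel
centres (optionally through an in-plane `tilt_deg` rotation about the
ONH): a per-subject offset (SD 12 µm — the between-subject spread of
quadrant means), a per-acquisition scan offset (SD 3.5 µm — probe
repositioning and residual motion), a per-segmentation assessor offset
(SD 1.8 µm), and white pixel noise with SD 8 µm divided by the scan's
quality index (quality is a contrast-based ranking in acquisition
software; SD ∝ 1/quality is the simplest monotone mapping). Offsets are
global scalars, not spatially varying — deliberately matched to the
quadrant-level granularity of the analysis. Negative values are clamped
at 0. With probability `missing_quadrant_prob` (default 0.06, ≈ 6 scans
per 102) one full quadrant is masked invalid, emulating partial capture.
These defaults were chosen once so that the implied population ICCs —
test–retest 144/(144 + 12.25) ≈ 0.92, interassessor 144/(144 + 3.24) ≈
0.98 — sit inside the ranges reported for awake pediatric hand-held OCT
at 6°; the true variance components of any real cohort are unpublished,
so the generator brackets rather than equals them. An optional
`noise_ref_radius_deg` makes the pixel-noise SD decay as 1/r, reproducing
the empirical pattern that reliability improves with distance from the
nerve centre.

**Designs.** `test_retest` renders two acquisitions per subject (scan 1
high quality, scan 2 low) with independent scan offsets, segmented by one
assessor — whose offset is therefore constant within subject and folds
into the between-subject component, so with pixel noise off the population
ICC is exactly σ²_subject/(σ²_subject + σ²_scan). `interassessor`
duplicates one acquisition (same scan offset and pixel noise) under two
independent assessor offsets. Every draw comes from an RNG keyed by
(seed, role, subject, scan, assessor) via `SeedSequence`, so cohorts are
bit-reproducible and extensible without reshuffling existing subjects.

**Fast path.** `simulate_quadrant_cohort` skips rasterization: with pixel
noise off, a rendered scan's quadrant mean is exactly the truth quadrant
mean (dense polar quadrature) plus the scalar offsets, so measurement
tables can be drawn directly. A test verifies full-pipeline ≡ fast-path
equivalence on a rendered cohort (< 0.25 µm, the residual being ring
discretisation); the 500-cohort recovery studies then use the fast path.
It refuses to run with pixel noise, where the shortcut would be wrong.

## Feasibility arithmetic

Group tallies enforce the additivity eyes_possible + Σ factor counts =
eyes_attempted. Success rates are success/denominator on either basis
("possible" = imageable eyes, "attempted" = all attempts). When only
printed percentages are available, integer success counts are
reconstructed by nearest-integer rounding *before* any pooling — eyes are
integers, and pooled totals are only self-consistent under integer
pooling; the reconstruction also returns the rounding residual as a
diagnostic. Report rounding is 1 decimal, half away from zero, matching
printed-table convention; full precision is kept internally. The bundled
`data/example_feasibility.json` carries a published two-group pediatric
feasibility table in this schema and is used by tests and the acceptance
script to exercise the cross-basis and pooled-rate identities.

## Problem sizes and determinism

Default simulation sizes (51-subject cohorts for pipeline runs; 500
measurement-level cohorts per setting for recovery studies; ≥ 10⁵ pixels
for noise-law checks) were chosen so every claim is estimated with
comfortable Monte-Carlo margin while the full suite runs in well under a
minute of simulation time. All randomness flows from explicit integer
seeds; reruns are byte-identical, including written TIFF/CSV outputs
(verified in the CLI round-trip tests). Every output CSV embeds the tool
version and the SHA-256 hash of the run configuration in a leading
comment line.

## What the phantom does and does not show

Passing tests on the phantom demonstrate that the measurement chain is
geometrically correct, that the agreement statistics are implemented and
calibrated correctly, and that the pipeline recovers known variance
components without bias. They do **not** validate performance on real
scans: the phantom has no speckle, vessel shadows, axial motion
artefacts, segmentation errors beyond global assessor offsets, or
spatially structured noise, and its subject effects are global rather
than sectoral. Known limitations, by design: no automatic disc detection
(the ONH centre comes from metadata), no fovea-to-disc-axis quadrant
referencing (only the generic `theta_offset_deg` hook), no
inter-device designs, and no Shapiro–Wilk normality screening (standard
library calls, if wanted).
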