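# Methods

`tfscreen` re-implements, as a tested library, the quantitative analysis
behind a light-microscopy screen for transition-fibre proteins (TFPs) at the
base of the trypanosome flagellum: two-colour sub-pixel foci metrology, the
screen's inclusion gate, recruitment-timing and flagellum-differential
classification, flagellum-length morphometrics, and reciprocal-best-hit
(RBH) conservation bookkeeping. Because no raw image data are publicly
deposited for this kind of screen, every stage is driven and validated by a
synthetic scene generator with exactly known geometry.

## Synthetic scenes

A scene is a pair of 2D images (green = tagged candidate protein, red =
SAS-6 basal-body marker). Objects are point emitters (SAS-6-like puncta) and
annular structures (transition-fibre-like rings or filled discs of true
diameter 150–450 nm). Rendering integrates an isotropic 2D Gaussian PSF
analytically over pixel areas (difference-of-erf per axis), so sub-pixel
positions are exact and photons are conserved: the noiseless image sums to
the emitted amplitude for objects away from borders. Annuli are discretised
into 256 point sources on the ring (sub-5 nm spacing, far below any PSF
width used); discs into 16 concentric area-weighted rings of 64 points.
Noise is Poisson shot noise on the expectation plus additive Gaussian camera
noise. Each scene draws from an independent RNG stream derived from
(seed, scene index), so any scene is reproducible in isolation and renders
are bit-identical for identical inputs.

Defaults: 65 nm/px (a 6.5 µm camera pixel behind a 100× objective), PSF
sigma 0.21·λ/NA ≈ 73 nm for 510 nm emission at NA 1.46, background
5 photons/px, read noise SD 2. Exposure and SNR for this kind of instrument
are not constrained by any published numbers; amplitudes of 2000–5000
expected photons per structure were chosen once as typical for bright
endogenous fluorescent-protein tags and are configurable.

The cell-cycle fixture encodes the marker logic of trypanosome basal-body
duplication: SAS-6 marks the proximal end of every basal body, so G1 and
G1–S cells show 2 red foci and S-phase cells 4. The tagged protein's
`timing` controls the green structures: `early` places a second green
structure on the maturing basal body while only 2 red foci exist (recruited
before duplication), `late` withholds it until 4 red foci are present, and
`probasal` co-locates green with every red focus. Geometry (basal-body
spacing ~300 nm within a pair, ~800 nm between pairs, ~300 nm distal offset
of the transition-fibre annulus from SAS-6) is plausible for this organism
but schematic; the fixture exists to give classifiers exact truth labels,
not to emulate cytology.

What the generator does *not* emulate: 3D defocus, spectral bleed-through,
chromatic offset between channels, fixation artefacts, autofluorescence
texture, or clustered/overlapping cells. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated imaging model,
not performance on real micrographs.

## Foci localisation

Candidate maxima are found by topographic prominence, computed with the
standard persistence sweep (descending-intensity union-find, 8-connected):
a peak's prominence is its height above the highest saddle connecting it to
higher ground; the global maximum is measured above the image minimum. This
makes a flat image yield no peaks and makes the threshold meaningful in
photon units. Ties in height are processed in ascending (y, x) order.

Centres are refined by fitting 1D Gaussians (amplitude, centre, sigma,
offset; Levenberg–Marquardt from moment-based starts, tolerance 1e-8) to
the column-summed x-profile and row-summed y-profile of a 15×15 px window
(~1 µm — wide enough for the widest annulus plus margin). Marginal-sum
fitting is exact for noiseless Gaussian spots and unbiased for any
centrally symmetric structure, which is what makes the same centring step
valid for both puncta and annuli. Non-convergent fits are flagged invalid
and excluded downstream rather than raised. A list of seed pixels can
replace automatic detection, mirroring manual point selection.

On noiseless emitters the fitted centre is within numerical tolerance of
the truth; localisation is exactly equivariant to integer-pixel shifts; and
across 200 noisy high-SNR scenes the median centre error is ~0.04 px
(≈2.5 nm), scaling down with amplitude as expected for shot-noise-limited
localisation.

## Distance and pseudo-diameter

Each green focus is paired with its Euclidean-nearest red focus; pairs
beyond 500 nm are discarded (they are assumed to belong to different
basal-body regions). Exact distance ties — possible only with degenerate
synthetic input — resolve to the brighter red focus, then lower (y, x).

The pseudo-diameter samples intensity along 45 lines through the structure
centre at 0°, 4°, …, 176° (180° would duplicate 0°), each spanning ±600 nm
in steps of 16.25 nm (¼ px). A Gaussian is fitted per line; its SD times
`diameter_scale` (default 1.0) is the per-line *effective diameter*; lines
whose fit fails or whose effective diameter exceeds 500 nm are excluded as
outliers; the maximum over valid lines is the pseudo-diameter, with ties
resolved to the smallest angle. If all 45 lines fail the structure is
flagged unmeasurable.

Two numerical choices matter here:

* **Interpolation.** Line sampling uses cubic-spline interpolation
  (`scipy.ndimage.map_coordinates`, order 3). Bilinear sampling smooths
  anisotropically on structures only 1–2 px wide: on a noiseless isotropic
  spot the 45 effective diameters spread by ~2.9% under bilinear but ~0.3%
  under cubic, and an angle-independent measurement was judged more
  important than interpolation simplicity. Bilinear remains available via
  `interpolation_order=1`.
* **Scale.** The effective diameter is *literally* the fitted SD
  (`diameter_scale = 1.0`). The SD of a PSF-blurred annulus profile is not
  the physical diameter — a 340 nm ring under a 73 nm PSF measures
  ≈247 nm, and a blurred delta ring's radial intensity peak sits strictly
  inside the true radius (the profile is ∝ exp(−(r²+R²)/2σ²)·I₀(rR/σ²)).
  Because the measurement is used *comparatively* (wider than the
  basal-body control, monotone in true diameter), the literal reading is
  kept as default, and `calibrate_diameter_scale` renders noiseless rings
  of known diameter under the configured PSF to map measured values back to
  physical diameters when absolute sizes are wanted.

Per-protein aggregation reports mean ± s.e.m. (sample SD/√n) over cells,
flagging single-cell groups.

## Screen decision logic

The inclusion gate compares protein-level means against control proteins:
excluded as *proximal* if the mean distance to SAS-6 is ≤ the POC5 mean
(POC5 marks the mature-basal-body distal end), *distal* if ≥ the TZP150
mean (transition-zone marker), *narrow* if the mean pseudo-diameter is ≤
the BBP136 mean (a focus-like basal-body protein); otherwise included.
Boundary values are excluded (strict inequality to pass), a deliberate
convention since a candidate indistinguishable from a control carries no
evidence of transition-fibre localisation. Gating on protein-level means
rather than per-cell distributions matches how such screens summarise their
measurements; distribution-level gating is out of scope.

Recruitment timing is classified from per-cell observations
(red focus count ∈ {2, 4}, green focus count, green-on-probasal flag),
checked in the order probasal → before-duplication → after-duplication.
The decision fraction `min_fraction` defaults to 0.25: published
descriptions of this phenotype report the before/after patterns in
essentially all cells but the probasal pattern in only about a third of
early-S-phase cells, so a threshold of one quarter accommodates the
sparsest reported class while rejecting sporadic mislocalisation. At least
10 observations spanning both red-focus counts are required.

RBH orthology consumes precomputed 12-column tabular alignment hit tables
(query, subject, …, E-value, bitscore). Best hit per query = lowest
E-value, ties by higher bitscore then lexicographic subject id; a pair is
emitted iff the best hits are mutual and both E ≤ 1e-5. Malformed rows are
skipped and counted. Running the sequence search itself is out of scope.

Class summaries count every enum label on every axis. Conservation is
additionally reported collapsed by orthologue family
(`conserved_family_count`): the screen's published tally of components
conserved beyond the kinetoplastids counts the three CEP164 paralogues as
one conserved family, giving 9 conserved components over 11 conserved
records. The published per-protein assignment table ships with the package
(`tfscreen/data/tfp_assignments.csv`).

The α-helix length estimate is plain arithmetic: length =
n/(residues per turn) × pitch; 1000 residues at 5.4 Å pitch and 3.6
residues/turn give a 150 nm helical arm — the reason very long predicted
helices are structurally interesting for blade-like appendages.

## Morphometrics and statistics

Traced axonemes are measured either as segmented-line chord sums or as the
arc length of a natural cubic spline through the clicked points with
chord-length parameterisation (the conventional "fit spline" behaviour is
underdetermined; natural boundary conditions avoid endpoint oscillation).
Arc length uses 100 subdivisions per segment, keeping the error well below
0.01 µm on flagellum-scale curves (a 9-point semicircle of radius 5 µm
measures π·5 µm within 0.05 µm).

ROI intensity is the integrated density (pixel sum) over an axis-aligned
rectangle; background is subtracted from an equal-area rectangle (unequal
areas are an error, since integrated densities are then incomparable). The
default ROI is 10×10 px; the net density is invariant to global offsets.

Group comparisons use the Mann–Whitney U test via `scipy.stats.mannwhitneyu`
with an explicit method rule: exact when n₁·n₂ ≤ 400 and the pooled sample
is tie-free, otherwise the normal approximation with tie and continuity
corrections. The exact branch reproduces brute-force enumeration over all
rank splits, and the null rejection rate at α = 0.05 calibrates to
0.05 ± 0.01 over 2000 simulations at n = 20/20. Flagellum bias
(old- vs new-flagellum enrichment) requires ≥ 20 paired cells, a higher
median on the enriched side and two-sided p < α (default 0.05, two-sided;
α = 0 degenerates to "equal" by construction).

Cell-cycle staging of intensity measurements (one vs two nuclei) is taken
as an input label, not computed from DNA staining.

## Pipeline and problem sizes

`run_screen` executes simulate → detect → measure → gate → stats over a
demo cohort of four synthetic proteins (POC5, TZP150 and BBP136 controls
plus a 340 nm ring-like candidate at a 350 nm offset), derives the gate
baselines from the measured controls, and writes CSV tables, a comparisons
JSON and a manifest (config hash, seed, version, per-stage row counts). One
global seed expands into per-protein, per-cell streams; reruns are
byte-identical. Validation experiments use 200 scenes of 32×32 px for
localisation/pairing recovery and 48–64 px noiseless scenes for
pseudo-diameter properties; the demo screen images 12 cells per protein.
These sizes give stable statistics (sub-0.1 px medians, s.e.m. a few nm)
while keeping a full run in seconds.

## Known limitations

* The imaging model is 2D and noise is pixel-independent; estimator
  performance on real, defocused, bleed-through-contaminated data is not
  claimed.
* The pseudo-diameter is a comparative statistic; absolute physical
  diameters require the calibration utility and a trusted PSF width.
* Recruitment classification assumes focus counts are already correct;
  it does not model detection failure in dim cells.
* The RBH module resolves orthologue pairs from given hit tables only; it
  inherits whatever search sensitivity produced them.
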