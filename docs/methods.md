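# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generators do and do not emulate, so that passing tests can
be read for what they actually demonstrate.

## Coordinate and calibration conventions

Pixel indices are 0-based `(row = y, col = x)`; physical coordinates are
`index × pixel_size` at pixel centers. Defaults follow the imaging setup
the pipelines target: 110 nm lateral pixels, 0.5 µm z-steps, 50 ms frames
for single-particle imaging and 20 s frames for cell-scale live imaging.
Positions, trajectories and calibrated results are in µm; forces in N;
moduli in Pa.

## Spot-on-filament enrichment

**Model.** Each detected IC spot carries a raw integrated density measured
on the background-corrected projection; the enrichment ratio of one region
is R = Σ(I, on-filament) / Σ(I, all). A cell's value is the unweighted mean
of R over six equal-angle sectors about the field center (region placement
is configurable; sectors are the default because no placement protocol is
otherwise implied). R is invariant to global intensity rescaling, and
moving any off-spot onto the mask can only raise it.

**Pipeline numerics.** The three adjacent sharpest z-slices are chosen by
integrated Canny–Deriche gradient magnitude (recursive Deriche filters,
α = 1.0) applied to the Sobel magnitude image, tie-break toward smaller z.
Both channels are maximum-projected over that window. The filament channel
is band-passed (difference of Gaussians, σ = 1/10 px), the IC channel
LoG-filtered (σ = 1.5 px). Thresholds are noise-referenced rather than
Otsu: background noise is estimated robustly on the raw projection
(1.4826·MAD) and propagated through each filter's L2 kernel norm, because
the zero-clipped response histograms that Otsu would see are dominated by
their clipped mode. Spots are detected by hysteresis: components grown at
1.5σ are kept only when they contain a ≥7σ seed pixel. That threshold
trades the dimmest few percent of complexes for a false-spot rate low
enough that all-on and all-off phantoms score exactly 1 and 0; detection
is intensity-unbiased between the on and off populations, so intermediate
fractions are recovered to within the stated 0.05. The filament mask is
the band-passed channel at 3σ with speck-sized components (<30 px)
removed and a 1 px closure, and classification is mask lookup at the
spot's rounded centroid ("centroid" rule; an "overlap ≥ 50%" rule is
available).

**Known bias.** Averaging ratios over sectors slightly underweights
sectors rich in on-spots; with 48 spots per cell the sector-mean sits
~0.01–0.02 below the global intensity fraction at intermediate fractions.
This is a property of equal-weight region averaging, not of detection or
classification (which are exact to ±0.01 per region on phantoms).

**CV.** The per-experiment coefficient of variation of cell means uses the
sample (n−1) standard deviation by default (`ddof` configurable).

## Single-particle tracking and diffusion

Detection applies a difference of Gaussians (σ₁ = 3.0, σ₂ = 1.5 px) and
keeps local maxima above a robust (median + 4·MAD-sd) threshold, refining
centers with a 2D Gaussian fit in a 7×7 window (center-of-mass fallback).
Linking is two-pass linear assignment: frame-to-frame Hungarian matching
with squared-displacement cost under a 0.5 µm cap, then a gap-closing pass
joining segment ends to later starts within 0.25 µm and ≤2 missing frames
(alternative cost = cap², the standard birth/death construction). Track
filtering drops tracks below 10 localizations and tracks whose
straightness (net displacement / path length) exceeds 0.9, which removes
actively transported, internalized complexes.

MSD is time-averaged per trajectory over all ordered pairs at each lag
(gap frames contribute no pairs), and condition-level curves average
per-trajectory MSDs so every trajectory counts equally. The anomalous
exponent is the least-squares slope of log MSD vs log τ over the first
10 lags; the intercept gives log 4D. Localization noise adds a constant
4σ² offset to the MSD, which lowers the fitted α at short lags — tests
verify the offset and the unchanged long-lag slope separately. Kymographs
sample bilinear intensity along a polyline, averaging across width.

## Mobility-state decomposition

Displacement steps are modeled as a hidden-Markov mixture: step t of a
trajectory belongs to state k with isotropic per-axis variance
2·D_k·Δt (+2σ_loc² if a known localization noise sd is supplied), and
states evolve by a row-stochastic per-frame matrix T. A Gibbs sampler
alternates (i) exact forward-filter backward-sampling of state paths,
vectorized across trajectories; (ii) conjugate inverse-gamma draws of the
state variances (prior shape 3, scale set so the prior mean equals the
ensemble mean per-axis step variance); (iii) Dirichlet(1 + counts) draws
of T rows and the initial distribution. Draws are canonicalized by sorting
states on D before averaging (label switching), with defaults of 5,000
iterations, 1,000 burn-in, thinning 5, and a split-chain R-hat on D̄
(warning above 1.1).

A finite sampler run at K_max = 5 fills surplus components with copies of
true states, so the posterior summary first **merges** adjacent states
whose diffusion constants differ by less than a factor of 2 (or sit below
a 10⁻⁴ µm²/s floor) — occupancy-weighted D and outgoing transitions,
summed weights — and then **prunes** states below 2% occupancy. The
reported π are step-occupancy fractions, i.e. the stationary weights of
the fitted chain, which is what a weight fraction means operationally.
Recovery benchmarks on simulated 1-, 2- and 3-state ensembles bound the
errors: weights within ±0.1, D within ×1.5, D̄ within 25%, and unsimulated
fast↔slow transitions below 0.02.

## AFM nanoindentation

The four-sided pyramidal tip gives F = c·tanθ·E/(1 − ν²)·δ², with
c = 0.7453 (regular four-sided pyramid), θ = 18°, ν = 0.5 for
incompressible polyacrylamide (all configurable). Indentation is
δ = (z − z₀) − d for piezo displacement z and deflection d; force is k·d
(k = 0.03 N/m nominal).

**Contact point.** A linear baseline is fitted to the first tenth of the
approach; the coarse contact is the last sample before a sustained
(5-sample) rise above baseline + 3σ. Refinement scans candidates (mostly
backwards, since onset forces hide below the noise) and scores each with
the *exact* implicit model k·d = C((z − z₀) − d)², where C comes from a
median over the deepest half of the indentation — high signal-to-noise
points where errors-in-variables bias is negligible — and the baseline is
refitted per candidate so its extrapolation error cannot tilt the
residuals. On noise-free curves the index is exact; at 5% force noise it
is within a few samples.

**Modulus fit.** Least squares of force against δ² with a free intercept
(absorbing residual baseline error) over indentations up to 1 µm — the cap
motivated by the finite tip height — followed by three errors-in-variables
iterations that rebuild δ from the model-predicted deflection, which
removes the attenuation bias that measured-deflection noise otherwise
causes on stiff samples. Noise-free round trips recover E to <1% across
1–200 kPa; fitted E is invariant to baseline offset and linear drift and
rescales exactly with (1 − ν²).

**Grid protocol.** Grids are summarized as per-area mean ± sd, per-gel
means of area means, with failed fits excluded and counted. Synthetic
grids place the contact near mid-ramp (z₀ ≈ 1.25–2.5 µm of a 5 µm ramp,
2048 samples — a typical AFM sampling density) and use force noise equal
to 5% of the model force at the 1 µm fit depth, making the relative
measurement error identical across stiffnesses. Under these conditions
per-gel means land within 5% of truth over 2–180 kPa; the stiffest gels
carry the largest residual uncertainty because deflection approaches the
indentation in magnitude there.

## Morphology

Cells are segmented from smoothed F-actin intensity (Otsu by default),
keeping the largest component and filling holes; the 2D footprint is the
union over z. Area and volume are pixel/voxel counts times the
calibration. Roundness defaults to the circularity form 100·4πA/P² with
the perimeter measured on the subpixel 0.5-level contour smoothed by a
5-point moving average — raw marching-squares contours overestimate the
perimeter of curved shapes by several percent (a rasterized disk then
scores ≈99%, a square ≈80%). The ellipse axis-ratio definition is
available as an alternative. Podosome cores are thresholded components
gated by circularity ≥0.5 and area 0.05–2 µm². Filopodia are measured
automatically: the cell body is the morphological opening of the
footprint, protrusions outside it are skeletonized, and each branch's
geodesic length (8-connected, diagonal √2) is reported, discarding
branches under 0.5 µm; straight-protrusion phantoms are recovered to
±0.3 µm. This automation replaces a manual ruler protocol and is
validated against phantoms, not against hand measurements.

## Synapse metrics

Contact events use a fixed convention: a contact frame is one whose cell
centroid lies inside the SSM footprint dilated by one cell radius
(3 µm default); events are maximal contact runs with interruptions of up
to 2 frames bridged; **duration = number of frames in the run (endpoints
inclusive) × frame interval**, so contact at frames 10–20 of a 20 s movie
is 220 s. Mean velocity averages all step displacements of the whole
track (µm/min); a config flag can exclude contact frames. The NF-κB call
is the strict rule ratio = mean(p65 in nucleus) / mean(p65 in cytosol) > 1;
a uniform cell (ratio exactly 1) is not activated. Internalized antigen
clusters are 3D components of the band-passed, globally thresholded IC
channel lying entirely inside the cell volume eroded by one voxel —
touching the boundary shell means surface-bound and excluded.

## What the generators emulate — and what they do not

The generators produce: curvilinear filament masks as random smoothed
walks of uniform ~3 px width (constant-amplitude distance profile,
binarized at half max), with starting points stratified in angle so the
network covers the cell surface the way dorsal ruffles do; spots with
Gaussian PSF (σ = 1.5 px), log-normal photon budgets (σ = 0.3, mimicking
IC size heterogeneity), and Poisson noise, with SNR defined as peak
amplitude over the Poisson noise sd at the peak (default 5); off-filament
spots placed ≥5 px from the mask but within 18 px of it, so both spot
populations share the filament network's coarse spatial density;
switching-diffusion trajectories with exact per-state step statistics and
an optional reflecting circular boundary (the simplest mechanism that
produces α < 1); movies with optional global exponential bleaching;
force curves exactly consistent with the pyramidal contact model; contact
movies whose inter-frame steps stay under the linking caps; and
translocation phantoms with exact nuclear/cytosolic ratios.

They do **not** emulate: vectorial or z-anisotropic PSFs, camera EMCCD
statistics, filament depolymerization dynamics, heterogeneous bleaching,
cell shape change during migration, or drift. Tests passing on these
phantoms demonstrate that the estimators are correct and unbiased under
the stated noise models at the stated sizes; they do not certify
performance on data whose noise or structure departs from those models.

## Problem sizes

Default validation sizes were chosen to leave comfortable statistical
margins while staying desk-scale: diffusion-exponent ensembles use 1,000
trajectories × 300 frames; state-decomposition benchmarks 1,000 × 50;
enrichment recovery 20 cells × 48 spots per fraction; AFM grids 2 gels ×
4 areas × 16 curves per stiffness at 2,048 samples per curve.
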