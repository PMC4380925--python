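# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic data do and do not emulate, and the known
limitations.

## Synthetic scenes

Cell bodies are radially perturbed ellipses: the boundary radius r(θ) is an
area-preserving ellipse (axis ratio set by `eccentricity`), optionally
modulated by low-order cosine "ruffles" (`ruffle_amplitude`, modes 6–12)
and Gaussian protrusion lobes (`protrusion_count`, `protrusion_length_um`).
Colonies place cells on a true hexagonal lattice (axial-coordinate spiral)
with center spacing `packing × 2R`; at packing ≲ 0.85 the bodies cover the
triple junctions, so colony interiors contain no background holes and a
fully surrounded cell has neighbor fraction ≈ 1. Overlapping desired
outlines are resolved by assigning each contested pixel to the cell with
the deepest claim (r(θ) − distance to center), so contacting bodies abut on
a shared boundary but never overlap. Nuclei are disks of radius
`nucleus_radius_frac·R` offset by `nucleus_offset_frac·R`; validation
requires offset + radius ≤ 0.95 so the nucleus stays inside the body, and
scene construction fails (naming the colony) if any two nuclei would
overlap.

Channels are rendered at fixed plateau intensities over a low background;
the TF channel sets nuclear intensity to `ratio × cytoplasmic baseline` per
cell, with the per-cell ratio drawn as target + Gaussian noise. Ruffliness
is planted as multiplicative intensity noise in a 3-px boundary zone of the
body channel. The ground-truth table is produced by running the package's
own measurement code on the *true* masks, plus the planted per-cell
parameters as `planted_*` columns; this is the reference that re-segmented
extraction is compared against (area within 2%, NF within 0.05, TF ratio
within 5% on the 100-cell scene suite).

Not emulated: point-spread functions, shot/read noise, uneven
illumination, out-of-focus debris, 3-D structure, mitotic/apoptotic
morphologies, cell-to-cell intensity bleed. Passing tests therefore show
that the measurement definitions and pipeline plumbing are correct and
internally consistent — not that segmentation is robust to real microscopy
artifacts.

## Single-cell tables

`simulate_feature_table` draws cells from a linear-Gaussian
structural-equation model: each node's value is its morphological-state
mean (states = weighted mixture of per-feature Gaussians, giving the
multi-modal shape distributions seen in real screens) plus
coefficient-weighted, mixture-mean-centred parents plus Gaussian noise.
Centring parents at the overall mixture mean makes the OLS slope of a
child on an exogenous parent equal the planted coefficient, which the
tests exploit. Treatment acts as an additive shift on the TF log-ratio
(log10 scale throughout, matching ratio distributions that span roughly
−1 to beyond 1 in the log).

## Feature extraction

* Segmentation: nuclei by Gaussian smoothing (σ = 1 px), Otsu threshold,
  distance-transform watershed with peak markers ≥ 7 px apart; cells by
  seeded watershed from the nuclei. The flood elevation is the distance to
  the nearest nucleus rather than inverted body intensity: where a colony's
  body stain is flat, intensity carries no boundary information and
  plateau-order artifacts dominate, while the distance relief reproduces
  the equidistant boundaries that the generator's claim-depth rule creates.
  The body-channel threshold still bounds each cell's extent.
* Derived regions: membrane band = cell pixels within `w_m` = 3 px of the
  cell exterior; perinuclear ring = pixels within `w_r` = 4 px of the
  nucleus, clipped to the cell, excluding the nucleus. Both are Euclidean
  distance-transform bands, not disk-footprint morphology, which would
  undercount diagonals (a w_r = 4 ring around an r = 20 nucleus counts
  ≈ the pixelated annulus, within 5%).
* Conventions: roundness = 4π·area/perimeter² with the Crofton perimeter;
  cytoplasm for A_nuc/A_cyto is cell − nucleus; ruffliness = SD/mean of
  body-channel intensity over the membrane band; protrusions are boundary
  arcs whose radius exceeds a periodic Gaussian smoothing (σ equivalent to
  10 px of arc) of the radial profile by > 15%; NF counts boundary pixels
  whose 8-neighborhood touches another cell; adjacency is 8-connected;
  pixel coordinates are 0-based row-major; border-touching cells are
  flagged and retained. Cells without a nucleus or with a zero ring mean
  (undefined TF ratio) are dropped with a warning.
* The catalog has exactly 77 named features. The screen literature names
  the headline ones (areas, roundness, length/width, protrusions,
  ruffliness, centers distance, NF, colony size, region intensities); the
  remainder are standard region/intensity statistics chosen here as
  implementation conventions, and the 17-feature canonical subset used by
  the network stage is fixed in `catalog.py`.

## Profiling

Z-scores use the population SD (ddof = 0). PCA is covariance-PCA of the
Z matrix (full SVD; deterministic sign convention: the largest-magnitude
loading of each component is positive). Line clustering uses
1 − centered-Pearson distance with centroid linkage; centroid linkage is
formally Euclidean-only, but applying it to correlation distances mirrors
the Cluster 3.0 behavior this analysis style descends from, and the tests
pin the properties that matter (duplicate rows merge at height 0, planted
groups separate, row-order invariance). Discriminative features are chosen
by voting: per line × condition, cells in the upper vs lower quartile of
the TF log-ratio are compared per feature by Welch t-test at α = 0.01
(no multiplicity correction — replication across lines is the robustness
mechanism), and features are ranked by vote count with |t| as tie-break.

## Dependency networks

Features are discretized per column into 3 quantile bins (rank-based, so
any strictly monotone transform gives identical states). Structure search
is greedy hill-climbing (add/delete/reverse single edges, acyclicity
checked by DFS) over the BDeu score with equivalent sample size 1, with 5
restarts (first from the empty graph, the rest from seeded random DAGs);
on 3-node problems the search provably reaches the exhaustive-search
optimum in the tests. Edge confidence is the fraction of B = 100 bootstrap
resamples (cells drawn with replacement) whose learned DAG contains the
adjacency in either orientation; an edge is reported oriented only when
≥ 70% of its supporting resamples agree on direction, and an orientation
that would create a cycle among reported edges falls back to undirected.
Display threshold 0.6 marks "confident" edges in summaries, matching the
convention of reporting dependencies above 0.6 (0.9 where a stricter
cutoff is wanted). An option forbids edges out of the TF node (sink
constraint) for sensitivity analysis. Note that members of a Markov
equivalence class score identically, so orientation of covariance-
equivalent edges is data- and resampling-dependent; only adjacency
confidences are contractual.

Quantile discretization limits detectable effects: a planted parent whose
per-SD effect on the TF log-ratio is small relative to the TF noise can be
invisible after 3-level binning, and very strong chains can leak a
spurious shortcut adjacency because coarse bins do not fully screen off
the middle node. The test fixtures use signal-to-noise 1 chains, where the
true chain is the exact BDeu optimum.

## Shape-response regression

OLS with intercept on the three fold-change predictors. Reported
diagnostics: R², residual mean square ("error variance",
SSR/(n − k)), overall F-test P value, Shapiro–Wilk residual normality,
design condition number (warning above 1e4). Cross-validation: records are
sorted by condition id (making fold assignment order-invariant), split
into 10 seeded shuffled folds, and the error is the per-fold mean absolute
held-out error, reported mean ± SD (RMSE retained alongside; "average
error" is ambiguous and MAE is the documented choice). Outliers are
conditions whose observed response falls outside the 95% *prediction*
interval of the full fit — the coherent reading of an interval "of the
predicted value" for individual cases — with a 1e-8 numerical guard so
exact fits flag nothing. Fold changes enter raw (not log-transformed).

The panel generator calibrates its noise SD to a target population R² by
Monte-Carlo evaluation of the signal variance under log-normal predictor
scatter; at the screen's 176-condition scale the fitted R² concentrates
within ±0.08 of the 0.37 target across seeds, coefficient estimates fall
within 3 standard errors of truth in ≥ 95% of replicates, and ≈ 5% of
conditions fall outside the 95% prediction interval.

## Translocation dynamics

Traces rise from baseline along a quarter-sine ramp to the first peak
(exactly `amplitude` above baseline at `first_peak_time` — the phase
convention pins the first maximum there), then follow an exponentially
damped cosine with the stated period; Gaussian noise is additive. The
aliasing guard requires period > 2·dt and duration ≥ one period.

First-peak calling: `scipy.signal.find_peaks` with prominence 3× the
robust noise SD (median absolute first difference / (0.6745·√2));
amplitude is peak minus the t = 0 value (TNFα is added essentially at the
movie start, so the first sample is the pre-stimulus baseline); a trace
still rising at its final sample is reported with a boundary flag.

Wavelet analysis: linear detrend, complex Morlet CWT (center frequency
ω₀ = 6 rad, bandwidth 1.5 — chosen so the scale argmax stays within one
grid step of the true period for noiseless sinusoids across 60–120 min)
over 60 log-spaced periods spanning 30–240 min. The cone of influence
defaults to one wavelength: a period is trusted at a time point only if it
is at most the distance to the nearer trace edge (`coi_factor` exposes the
stricter Morlet e-folding cone, ≈ 0.73×, and looser settings). The
dominant period at a time is the in-cone power argmax, reported as NaN
when the best in-cone power falls below 5% of the spectrum maximum — this
suppresses meaningless short-period argmaxes near the edges and flags flat
traces. Consequence worth knowing: on a 6-h movie, 110–120 min periods are
inside the cone after ≈ t = 240 min, so per-condition period histograms
are evaluated mid-trace (t = 180 min) in the bundled analysis; evaluating
at t = 300 min as in the original figure requires either longer movies or
accepting edge-affected estimates via a looser `coi_factor`. Period
histograms use shared 15-min bins over 30–240 min, normalized to
frequencies per condition.

## Orchestration and determinism

`run_screen` derives one seed per stage from the master seed via
`numpy.random.SeedSequence.spawn`, writes every product with fixed float
formatting, and records SHA-256 hashes in the manifest; rerunning a config
reproduces every output byte-identically, which the tests assert. All
thresholds default to the analysis' stated values (confidence 0.6,
α = 0.01, 10 folds, 95% interval, 5-min sampling).

## Problem sizes

The bundled drivers and tests run at desk scale by design: 100-cell scenes
(the screen imaged hundreds of thousands of cells), 2 000 cells per
line × condition for network learning with B = 60–100 bootstraps over ≤ 6
nodes (the screen used 17 + 1), 176-condition regression panels at full
scale, and 40 traces per condition as in the live-imaging experiments.

## Limitations

* The 77-feature catalog reproduces the headline measurement definitions;
  the unpublished remainder are reasonable stand-ins, so feature-by-feature
  comparability with the original screen is not claimed.
* Bayesian networks capture dependence, not causation or feedback; the
  acyclicity constraint forbids TF→shape loops by construction.
* Centroid linkage on correlation distances can produce inversions
  (non-monotone merge heights); dendrograms are reported as-is.
* The wavelet stage estimates instantaneous periods of a single dominant
  component; superimposed oscillators at comparable power trade off in the
  argmax rather than being separated.
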