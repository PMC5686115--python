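# Methods

punctakit quantifies the spatial organisation and dynamics of small
clusters ("puncta") of tetrameric IP₃ receptors imaged by TIRF microscopy
near the plasma membrane, together with the local Ca²⁺ release events
(puffs) they produce and their geometry relative to STIM1-marked ER–PM
junctions. Every analysis stage has a matching ground-truthed generator
in `punctakit.simulate`, so the whole pipeline can be exercised and
validated end-to-end without raw microscope data. All computation is in
physical units: µm for length, s for time; pixel coordinates are 0-based
indices at pixel centres, converted through the pixel size at ingestion.

## Synthetic scenes

`SceneConfig` fixes the acquisition geometry: 0.16 µm pixels (so that
6 pixels = 0.96 µm), a 20.48 µm square field by default, 10 fps for
10 s for tracking movies, 20 fps for Ca²⁺ recordings, 30 s intervals for
the two-frame overlay, and 2 fps for FRAP. Four motion states are
simulated:

- **immobile** — localization jitter only (0.02 µm per axis by default,
  which puts the mean frame-to-frame displacement of a fixed punctum just
  below the 40 nm mobility floor, as measured for fixed cells);
- **diffusive** — 2-D Brownian motion with per-axis step variance 2·D·Δt,
  D = 0.0308 µm² s⁻¹ by default;
- **subdiffusive** — Brownian motion reflected inside a disc
  (confinement radius 0.15 µm). The paper-scale data constrain only the
  MSD plateau, and a reflecting disc is the simplest model that produces
  one;
- **directed** — constant-speed transport (0.324 µm s⁻¹, the measured
  speed of motor-driven puncta) with a uniform random heading plus a
  Brownian component (D = 0.01 µm² s⁻¹), because cargo moved by
  kinesin/dynein is never noise-free in the membrane.

The default state mixture is 21/10/62/7% (immobile/subdiffusive/
diffusive/directed), i.e. 31% immobile-or-subdiffusive, which is how the
two slow classes are reported. Movies render each punctum as an
isotropic Gaussian PSF (σ = 0.16 µm) integrated exactly over pixels, so
summed intensity above background is exactly proportional to fluorophore
count; photon noise is approximated as additive Gaussian. Trajectories
reflect at the field border so ground-truth coordinates stay in the
field.

Bleaching traces give each fluorophore an independent memoryless
per-frame survival probability exp(−k·Δt); FRAP curves follow a
single-exponential recovery F(t) = F_b + Mf·(F₀−F_b)·(1−2^(−t/t½)),
which is exactly the half-time/plateau parameterisation the analysis
estimates. Puff scenes place temporally square, spatially Gaussian
ΔF/F₀ transients (200 ms, σ = 0.5 µm) at a configurable fraction of
immobile puncta, with the remainder placed uniformly at least 1.2 µm
from any immobile punctum so the planted colocalization fraction is
unambiguous; no event starts inside the pre-stimulus baseline window.
STIM1 fields displace a partner point from each juxtaposed immobile
punctum by Normal(0.70, 0.07) µm in a random direction, over an optional
uniform Poisson background of unrelated STIM1 puncta.

Every generator is bit-reproducible from its seed.

### What the generator does not emulate

ER network geometry, TIRF evanescent-field depth, EMCCD gain statistics,
chromatic mis-registration and stage drift are all absent. Passing
round-trip tests therefore demonstrates that the estimators recover what
was planted under the stated motion, noise and placement models — not
that they are robust to every artefact of real recordings.

## Detection and tracking

Spots are detected per frame with a difference-of-Gaussians filter at
scales σ_PSF and 1.6·σ_PSF (the standard blob-detection ratio; the
filter is named but its scales are free parameters, logged). The
threshold is expressed in robust (MAD-based) SDs of the DoG response,
default 5. Sub-pixel localization uses per-axis parabolic interpolation
of the 3×3 neighbourhood; candidates within one PSF σ keep only the
brighter spot, and spots within one σ of the border are discarded
because the interpolation stencil is undefined there.

Tracking solves, per frame pair, the standard augmented linear
assignment problem: squared displacement costs gated at 400 nm, with
birth/death alternatives priced at the squared gate. The Hungarian
algorithm gives the exact optimum, which is verified in tests against an
exhaustive enumeration oracle on scenes of ≤5 particles. Gap closing
joins segment ends to starts two frames later within 600 nm (one
missing frame, per the frames-1-to-3 definition of the gap gate);
split/merge candidates within 300 nm are annotated, not fused. Tracks
shorter than 30 frames (3 s) are excluded from classification. Spots
are canonically ordered before assignment so output is independent of
input order.

## Mobility

The time-averaged MSD is computed for lags up to ¼ of the track length.
α is the log–log least-squares slope; D is the through-origin fit
MSD = 4Dτ over the first 4 lags (short-lag window minimises confinement
bias); v is the square root of the quadratic coefficient of
MSD = v²τ² + 4Dτ, reported as 0 (flagged) when the coefficient is
negative. Straightness S is net displacement over path length.

Classification is a fixed decision list: immobile if the mean
frame-to-frame displacement is ≤ 0.04 µm (the 40 nm floor measured in
fixed cells); else directed if α ≥ 0.9 **and** S ≥ 0.35; else
subdiffusive if α ≤ 0.6; else diffusive. The directed thresholds were
placed at the equal-error point between the generator's diffusive and
directed populations (grid evaluation on 800-track pure ensembles):
naive textbook thresholds such as α ≥ 1.5, S ≥ 0.6 implicitly assume
noise-free ballistic motion, but transport at 0.324 µm s⁻¹ with a
membrane-diffusion component has fine-scale straightness near 0.45, and
such thresholds label almost every genuinely directed track diffusive.
With the defaults here, per-kind accuracy is ≥ 86% on 30-frame tracks
and ≥ 97% on 100-frame tracks; all thresholds are configurable and
recorded in the run log.

The quadratic-coefficient speed estimator deserves a caveat: on pure
Brownian 10-s tracks the sampling noise of the coefficient is large
enough that roughly 40% of tracks yield a spurious v̂ > 0.05 µm s⁻¹
(median v̂ is 0). Speed estimates are therefore only meaningful averaged
over tracks already classified as directed; the class separation itself
is carried by α and S, not v̂.

A track is re-segmented into sub-trajectories when a sliding 15-frame
window classification changes label and the new label persists for ≥ 10
consecutive windows; the fraction of tracks split this way is reported
alongside the per-cell state fractions (mean ± SEM across cells).

Immobile puncta are identified operationally by overlaying two frames
taken 30 s apart: a punctum is immobile iff a punctum in the second
frame lies within 0.32 µm (≈ one punctum radius) of its position. This
is the quantitative surrogate for the visual white-overlay criterion;
the match radius is configurable.

## FRAP

Double normalization divides the bleach-ROI intensity by whole-cell
intensity per frame (cancelling acquisition bleaching — an invariance
verified by property test) and then by the pre-bleach mean.
Mf = F₃₀₀/F₀ with F₃₀₀ averaged over a 10-frame window at the plateau
time (300 s by default; configurable for the 15-min mobile/immobile
exchange variant). Note that with t½ = 62 s, 300 s is 4.8 half-lives,
so the estimator reads ~96.5% of the asymptotic recovery — planted
Mf = 0.77 is reported as ≈ 0.744. That is a property of the standard
F₃₀₀/F₀ definition, not an implementation bias. The half-time is
model-free: the post-bleach curve is projected onto the nearest monotone
curve (isotonic regression) — recovery is physically monotone — and the
half-recovery crossing is located by linear interpolation. A raw
first-crossing estimate is biased (late, at low amplitude) because the
decelerating curve lingers near the target level; the isotonic
projection removes that bias without fitting any kinetic model. At the
lowest amplitudes (Mf ≈ 0.2 at 2% noise) single-curve half-times remain
noise-limited to roughly ±25%; estimates should be averaged over
replicate bleaches, as done in the tests. D = r²γ/(4·t½) with
r = 1.84 µm and γ = 1 for a circular beam.

## Photobleaching stoichiometry

Steps are found by recursive binary segmentation: the change point
maximising the RSS reduction is accepted while the reduction exceeds a
penalty of 9·σ²·ln n, with σ the robust noise SD from successive
differences (for a noise-free staircase σ = 0 and segmentation is
exact). Downward level changes qualify as steps when they exceed 3σ and
a minimum amplitude, which defaults to half the median detected step
amplitude — the median rather than the final step alone, because two
fluorophores occasionally bleach in the same frame and a doubled final
step would otherwise suppress genuine unit steps. The fluorophore count
is n = round(F₀ / final-step amplitude), the estimator used for the
per-punctum counts; step counting itself is a cross-check (at SNR 10 it
recovers the planted count exactly in ≥ 90% of traces).

Fluorophores convert to channels through the random-assembly model:
with subtype fraction p₁ = 0.61 and fluorescent-maturation probability
p_f = 0.8, a tetramer carries on average 4·p₁·p_f = 1.952 fluorescent
subunits, so channels ≈ n/1.952; and 1−(1−p₁)⁴ ≈ 98% of tetramers
contain ≥ 1 tagged subunit (93% with the maturation factor). The
division-by-expectation conversion is a package design choice — the
source analyses state the assumptions but not the formula — and the
model is fully configurable.

## Ca²⁺ puffs

ΔF/F₀ is computed per pixel against the mean of the pre-stimulus
baseline frames. Detection smooths each frame with a 0.3 µm Gaussian,
thresholds at ΔF/F₀ ≥ 0.3 and segments 26-connected spatiotemporal
components, discarding those shorter than 2 frames; these defaults are
free parameters of the re-implemented detector and are logged. Duration
is counted at half-maximum (the metric is otherwise unspecified; events
~200 ms at 20 fps span 4 frames). The centroid is the intensity-weighted
centre of mass in the peak frame; amplitude is read from the raw (not
smoothed) ΔF/F₀ as a 3×3 mean at the peak voxel, since smoothing biases
peak amplitudes low by the ratio of profile to filter variance. Events
colocalize with an immobile punctum when the centroid lies within
0.96 µm (6 pixels); ties break to the lower punctum id. Sites are
single-linkage clusters of event centroids at 0.5 µm.

## Junction geometry

Nearest-neighbour distances are centroid-to-centroid (consistent with
the detection stage; peak-to-peak transect measurements differ by less
than the resolution limit). `fraction_within` reports the fraction of
puncta with a neighbour inside a radius — 0.3 µm and 2r (0.64–0.96 µm)
are the radii of interest. Points closer to the window border than the
queried radius are flagged so summaries can be reported with and without
them; under complete spatial randomness the fraction follows
1 − exp(−λπd²), verified by test. Translocation signals are
ΔF = (F_post − F_pre)/F_pre in discs of twice the punctum radius,
grouped by mobility label; puncta with non-positive pre-intensity are
excluded and flagged. Round-trip recovery of a planted juxtaposition
fraction assumes fields sparse enough that a neighbour's STIM1 partner
rarely falls within 2r of an unpartnered punctum (punctum densities
≲ 0.05 µm⁻², matching the peripheral fields analysed).

## Localization tessellation

For single-molecule localization tables the Voronoi tessellation
encloses each blink event in the cell equidistant between neighbours;
local density is the inverse cell area, with cells clipped to the
rectangular ROI so hull cells are finite. First-round clusters are
Voronoi-adjacency-connected components of points with density ≥ 1.2× the
ROI mean density (count/area); second-round sub-clusters re-threshold
each cluster at 1.2× its own mean density. Collinear point sets raise a
geometry error naming the failure. Cluster membership is invariant to
point order, and areas/densities scale as expected under coordinate
scaling (both tested).

## Pipeline

`run_pipeline` executes simulate → detect → track → classify and any of
the FRAP / bleach / puffs / junctions stages from a single declarative
configuration; unknown configuration keys are rejected before any
computation. Every run writes its tables as CSV, movies as multi-page
TIFF with a JSON sidecar, a summary JSON, and a log with the package
version, seed and all parameters; a fixed seed reproduces a run
byte-for-byte. The `punctakit` CLI exposes each stage as a subcommand
with exit codes 0/1/2 for success, user error and internal error.

## Problem sizes

The validation suite uses 1,000 tracks for the pooled diffusion fit,
1,500 tracks for mixture recovery, 200 tracks for the directed-speed
ensemble, 284 traces for the stoichiometry population, three simulated
cells (~280 puffs each) for puff statistics, and 250 puncta for the
junction geometry — sizes chosen to put Monte-Carlo error comfortably
inside the tolerance of each check.

## Known limitations

- The motion classifier is threshold-based and tuned to the generator's
  noise regime; a different localization precision moves the optimal
  α/S thresholds (they are configurable for that reason).
- Mf as F₃₀₀/F₀ under-reads slow recoveries (see above); no
  reaction–diffusion FRAP model is fitted.
- Step detection assumes equal unitary amplitudes and no blinking; no
  hidden-Markov photophysics.
- The puff detector is a threshold/connectivity design, not a matched
  filter; deep-SNR events below ΔF/F₀ ≈ 0.3 are not recovered.
- Pearson/Costes colocalization, STORM reconstruction and drift
  correction are out of scope; localization tables are taken as given.
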