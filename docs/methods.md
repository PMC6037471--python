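# Methods

This note documents the models, numerical choices and limitations behind
`vertexdyn`. Physical units are micrometres and seconds throughout; images
use 0-based pixel indexing with the origin at the top-left, x rightward and
y downward, and the ventral (DV) direction defaults to +y (`ventral_angle`
= 90°).

## Synthetic tissue model

The generator (`vertexdyn.synthetic`) produces a ground-truthed hexagonal
epithelium. Its defaults are the package's study conditions: pixel size
0.2 µm/px, frame interval 3 s, hexagon side 2.4 µm (cell area ≈ 15 µm²),
apical-area oscillations of fractional amplitude 0.10 with period 150 s
(periods 100–300 s where randomized), membrane line width σ = 1.3 px,
punctum σ = 1.8 px, PSF σ = 0.7 px, Poisson noise at 0.5 counts/photon plus
read noise of 1.5 counts. Oscillation amplitude is not constrained by any
measurement we reproduce; 10% area modulation is a visually realistic
default and configurable.

**Geometry.** Per-cell area programs are
A_c(t) = A_c(0)·(1 − a·cos φ_c(t)) with the ground-truth phase φ_c defined
on the analysis convention (0° at minima, ±180° at maxima). Per frame the
vertex positions solve a sparse Gauss–Newton problem: residuals are the
per-cell signed polygon-area errors (relative), per-event interface-length
errors, and a weak tether (weight 10⁻³) to a predictor; convergence is to
~10⁻⁹ relative, far inside the 1% contract. The predictor scales the
frame-0 positions about the tissue center with a per-vertex local factor
(mean √(A_target/A_0) of the adjacent cells). For spatially uniform phase
fields this predictor is an exact global scaling — every length scales with
√A, so fractional lengths are constant *by construction*, which is what
makes the generator's isotropic mode a true null for ratchet detection. An
earlier design (per-cell radial scaling about each cell's centroid with
shared-vertex re-averaging) was abandoned because the averaging term breaks
isotropy by several percent of L/P even for uniform phases, and does not
converge to the prescribed areas for out-of-phase neighbors.

**Interface events.** A sliding event prescribes, relative to the
event-free twin geometry solved in parallel, donor length L₁ − δ(t) and a
gain of δ(t)/2 on each of the four transverse interfaces, so the
"contracting + two transverse" sum is conserved exactly on *both* cell
sides (tolerance ~10⁻¹⁰ µm). A line-tension event prescribes the donor loss
with all transverse lengths held, so the triplet total drops by exactly the
donor loss. Ratchet mode attaches a sliding event to every vertical
interface with δ advancing only while the flanking cell's phase is in the
contraction half-cycle (default 0.4–0.5 µm per cycle, capped at 60% of the
initial length). A full T1 is a sliding event with δ ≈ L₁(0); geometry is
held just short of zero length (no topological surgery is performed — see
Limitations).

**Rendering.** Channel intensities are linear: background B, membrane
profile exp(−d²/2σ_m²) of the rasterized skeleton, and per-vertex Gaussian
puncta, all blurred by the PSF before noise. Amplitudes are calibrated on a
synthetic junction patch that reproduces the local lattice geometry
(including neighbor-vertex puncta) so that the *ROI-measured* junction mean
equals `junction_level` and the vertex ROI mean equals the prescribed
intensity ratio; the calibration is linear-response, exact for uniform
ratios and accurate to a few percent when ratios vary across vertices.

**Marker traces.** Vertex enrichment programs are
r(t) = base + gain·cos φ(t) (maximal at phase 0, the end of contraction),
channel 2 evaluating the common signal `lead_s` seconds ahead of channel 1.
The standalone trace generator adds a shared broadband component (Gaussian-
filtered white noise, correlation time 8 s, sd 0.3) to both channels:
without finite-correlation-time fluctuations two pure sinusoids correlate
over half an oscillation period and the positive-peak centroid is not an
informative lag estimator; the broadband term emulates the transient
recruitment fluctuations real reporters share.

## Segmentation and tracking

Seeds are regional minima of the Gaussian-smoothed (σ = 1.5 px) membrane
channel after h-minima suppression (h defaults to 10% of the robust
intensity range); the watershed runs with 1-px boundary lines and regions
under `min_cell_area` (40 px) lose their seed and are re-flooded. Vertices
are centroids of junction-pixel clusters (skeleton pixels whose
8-neighborhood touches ≥ 3 labels), clusters merged within 2 px; no
sub-pixel refinement. Tracking is overlap-based with ties broken toward the
smallest persistent id; vertices and interfaces inherit identity from their
adjacent-cell sets, so any neighbor exchange terminates the affected tracks.
Border-touching cells are excluded from downstream statistics.

A track is flagged `fully_contracting` when it terminates before the movie
end, lived ≥ 5 frames, was once at least twice the length tolerance
(2 px), and either ended below that tolerance or was followed by a merged
(≥ 4-fold) vertex spanning both flanking cells. The merged-vertex clause is
needed because the watershed cannot resolve interfaces below ~3 px: the
track ends by vertex merging slightly above the tolerance. Only the first
such track per cell pair is flagged (a later re-split of the same pair is
the same T1, not a new one).

**Areas and perimeter.** Pixel area is the label pixel count × pixel area;
contour area adds half the area of the bounding skeleton pixels (the
watershed line is shared between two cells, so raw pixel areas are biased
low by ~½ boundary pixel — on the default synthetic cells that bias is
~10%, and the contour correction brings it under 5%). The perimeter adds a
half-pixel Minkowski offset (+π px) to the region perimeter for the same
reason. Euclidean area is the shoelace area of the cell's detected vertices
ordered by angle about their mean; the shape metric is contour/Euclidean
area (> 1 = outward bulging) and is undefined below three vertices.
Interface classification (vertical/transverse/other) uses the orientation
at track start against the configured DV axis with a ±30° half-angle; the
threshold is a configurable convention.

## ROI intensity ratios

ROIs follow the distance-transform construction exactly: vertex disk
d ≤ 3 px (29 pixels), junction band d_skeleton ≤ 3 px minus the disk,
background d_skeleton ≥ 7 px, all clipped to the 41 × 41 window; vertices
within 20 px of the image border are excluded. Ratios use raw (not
background-clipped) ROI means, and are invalid when J − B falls below 1% of
the image's robust intensity range. The ratio is invariant under affine
intensity transforms by construction. Standard deviations use the
population (n) convention everywhere, matching the zero-mean/unit-sd trace
normalization contract. Time-resolved ratio distributions align movies at
the frame minimizing total vertical-interface length (a configurable proxy
for the most-contracted state, which is not otherwise defined).

## Instantaneous phase and amplitude

Areas are detrended by subtracting a Gaussian baseline (σ = 180 s); a
linear fit is removed before filtering and folded into the baseline because
a reflected Gaussian filter alone flattens ramps near the series ends. The
detrended series is smoothed with a third-order Savitzky–Golay filter whose
window is the odd frame count nearest 45 s. The phase is the angle of the
(s, ṡ/ω̄) embedding about the center of local algebraic (Kasa) circle fits
over a sliding half-period window — the osculating-circle construction,
which tolerates offset and drifting means better than the plain analytic
signal; the circle radius is the instantaneous amplitude. ṡ uses the same
SG window with a first-derivative kernel; ω̄ is the dominant spectral peak
of the detrended series, refined by parabolic interpolation on the log
spectrum (without refinement the coarse FFT bin spacing makes the embedding
elliptical and adds degree-level phase error). Monotone or flat signals are
rejected. A Hilbert-transform fallback is provided and agrees with the
osculating route within 10° circular RMSE on clean sinusoids. Cycles are
delimited at upward crossings of −180°; single-frame phase jumps above 180°
are masked and veto their cycles. Phase estimates within half a period of
the series ends use one-sided fit windows and are the least reliable.

## Kinematics

Cell-centric positions remove drift exactly under rigid translation.
Tangential displacement is Δs = r·Δθ with θ unwrapped per trajectory;
when the opposing vertex of the vertical interface is supplied, the sign is
set so that motion toward it (interface contraction) is negative.
Displacement rates difference positions over the nearest frame count to
25 s — long enough to avoid correlating localization error between
consecutive frames. Pair coupling projects each vertex's frame displacement
on the average pair axis before and after the step (positive toward the
other vertex), accumulates, differences over 25 s, and Pearson-correlates
at zero lag: mutual approach/withdrawal is positive, common translation
negative. Pair categories use the cyclic separation around the cell
(1 = adjacent, 2 = diagonal, 3 = opposed). Triplet analysis keeps fully
contracting interfaces with ≥ 5 min lifetime, takes the last 5 min aligned
to T = 0 at the contraction endpoint, and counts both cell sides' transverse
pairs as separate cases; the flatness of the triplet total over the window
classifies sliding (conserved) against line-tension shrinkage (total drops
by the L1 loss).

## Phase-space interpolation

Grids span (−180°, 180°] with node value Σwᵢvᵢ/Σwᵢ, wᵢ = exp(−d²/2h²), and
samples replicated at ±360° along every phase axis (so the −180° and +180°
nodes are identical). Defaults: spacing 5° (15° for 3D grids), bandwidth
h = 15° (20° for 3D), and nodes with Σw < 5 effective samples masked. As
h → 0 the grid approaches nearest-sample values, as h → ∞ the global mean;
both limits are tested. Interface-length maps shift each complete cycle's
trajectory to start at 0, pool both flanking cells' phase mappings, and
summarize 10° bins at 0° and 175° (their difference is the expansion-phase
change). Shape-metric maps use the phase of the Euclidean area. Vertex
angles are measured from the cell centroid against the ventral direction
(0° = ventral, ±180° = dorsal); the T1-associated band of the
angle × phase intensity map is the ±45° sector about ±90°, a configurable
convention. For three-cell phase maps, the variance of each axis's marginal
profile, normalized by the total, attributes map structure to the driving
cell.

## Cross-correlation

Rates of change (25 s window) are z-scored and cross-correlated with the
unbiased estimator (lag-k sum divided by N − |k|, default max lag 60 s);
per-pair correlation functions are averaged with equal weight (population
averaging, not pooled concatenation — the alternative is not distinguished
by any contract here and averaging matches per-vertex weighting elsewhere).
The lag is the centroid of the contiguous positive region containing the
global maximum; with no positive region the lag is undefined. Positive lag
of `normalized_xcorr(a, b)` means b lags behind a.

## Benchmark problem sizes

The benchmark suite (`vertexdyn.benchmarks`) uses a 25-cell, 100-frame
rendered movie for segmentation/tracking recovery; 100 analytic cells
(600 s at 3 s) for phase recovery; 81-cell, 130-frame tissues for ratchet
vs isotropic detection (56 vertical interfaces); 14 oscillation-free 25-cell
tissues with two separated events each (56 triplets) for conservation
classification; one 36-cell tissue (240 vertex pairs) for coupling; 50
replicates of 20 marker-trace pairs for lag recovery; and 50 runs of 30
vertex triads for three-phase attribution. These sizes were chosen as the
smallest populations at which the tested statistics are stable.

## Known limitations

- Kinematics are prescribed, not emergent: there is no force-based vertex
  model, no photobleaching, and no 3D geometry.
- The generator holds a completed T1 just above zero length instead of
  re-topologizing, so the post-exchange growth of the new transverse
  interface is not simulated.
- The render calibration is linear-response and assumes locally
  lattice-like junction geometry; strongly curved or crowded junctions in
  real data will bias measured ratios in ways the synthetic tests do not
  probe.
- Passing the synthetic benchmarks shows the measurement machinery is
  correct under the generator's assumptions (polygonal cells, Gaussian
  PSF, Poisson/read noise, sinusoidal area programs); it does not certify
  performance on real movies with segmentation artifacts, z-drift, or
  non-sinusoidal oscillations.
- Transient 4-fold vertex handling is minimal: tracks terminate and
  restart; no attempt is made to resolve the exchange ordering.
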