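# Methods

`scareulm` re-creates, at desk scale, the computational chain behind
single-capillary-reporter (SCaRe) ultrasound localization microscopy: a
synthetic cerebral vascular network with solved hemodynamics, Monte-Carlo
microbubble transits, ULM-like image synthesis with low-rank tissue/skull
clutter, SVD clutter filtering over short and long ensembles, Kalman/RTS
bubble tracking with two-stage track pairing, a 2-state hidden Markov model
that classifies single-capillary transits, and dwell-time (CHT) maps and
statistics. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic data does and does not emulate.

## Vascular network surrogate

The network is a directed graph: a binary arterial tree (artery then
arteriole edges) feeds a capillary bed, which drains into a mirrored venous
tree. The bed consists of `n_capillaries` parallel multi-hop chains of
capillary-class edges, each assigned its own z-lane so that dwelling
bubbles from different chains rarely overlap on the imaging grid, plus a
few cross-links between neighbouring chains so the closure is a single
connected mesh with multiple routes. Radii taper down the trees by
Murray's law (factor 2^(-1/3) per level, floored at the arteriole/venule
radius); capillary radii are Normal(2.0, 0.3) µm clipped to [1.5, 2.6] µm.

We deliberately give each arteriole a high fan-in (~30 chains per
terminal). By mass conservation the arteriole/capillary mean-velocity
ratio is `fan · (R_cap/R_arteriole)²`; below about 5× the U-shaped transit
signature (fast entry — slow capillary — fast exit relative to a 2 mm/s
threshold) disappears into the pulsatile modulation. Real penetrating
arterioles feed hundreds of capillaries; the fan-in stands in for that.

Hemodynamics are steady Poiseuille: edge conductance `πR⁴/(8µL)`
(viscosity constant at 3.5 mPa·s, no Fåhræus–Lindqvist correction), node
pressures from the weighted-Laplacian (Kirchhoff) solve with
pressure-driven boundary conditions, edges re-oriented along flow so the
network is a DAG. The default inlet–outlet drop (36 kPa across this small
surrogate) is chosen so capillary mean velocities sit at a median of
~0.8 mm/s (sub-2 mm/s regime, heterogeneous down to ~0.05 mm/s) while
arterioles run >10 mm/s. With chain lengths of 300–900 µm this yields
ground-truth capillary transit times with median ~1.3 s and a heavy tail
reaching several seconds — a Cauchy fit beats a Normal fit in
log-likelihood, as expected for a ratio-like quantity (length over a
broadly distributed velocity).

"Single capillary" means one maximal chain of consecutive capillary-class
edges; a stricter single-edge rule is available
(`GraphConfig.single_capillary_rule="edge"`). Path enumeration is a
deterministic DFS over the flow DAG, truncation flagged.

## Bubble transits

Bubble diameters are Normal(2, 3) µm truncated positive (Definity-like
polydispersity); a bubble wider than its path's bottleneck is re-assigned
(resample-path policy by default). Start times are uniform over the
acquisition window; the radial offset fraction is drawn area-uniformly
once per bubble and clamped per edge so the bubble fits
(`r ≤ R − d/2` — in capillaries of bubble-comparable bore the bubble is
forced to the centerline).

Instantaneous speed along the path is

    v(t, s) = 2 · v_mean(edge) · (1 − r_f²) · w(t − s/PWV)

with the parabolic-profile factor `2(1 − r_f²)` and a pulsatile waveform
`w` built from three Gaussian component pulses per cardiac cycle,
rescaled so max = 1 and min = 1 − depth. Defaults: 500 beats/min
(0.12 s period), modulation depth 0.75 under the
(peak − trough)/peak convention, pulse-wave velocity 350 cm/s delaying
the waveform along the path. Integration is explicit Euler at
dt = 0.1 ms (halving dt changes transit times by < 1%), recorded at 1 ms;
the inner loop is numba-compiled.

Ground-truth CHT is the total time the bubble spends below the 2 mm/s
threshold while on capillary-class edges; the capillary "windows" are the
maximal sub-threshold runs, so every sample inside a window is by
construction sub-threshold (pulsatility can split one anatomical transit
into several windows).

## Frame synthesis

Frames are synthesized directly in the image domain: Gaussian blobs
(FWHM = one wavelength, default λ = 150 µm on a λ/8 grid) at the
bubbles' in-plane positions, over a clutter background of
`clutter_rank = 20` static spatial patterns, each multiplied by its own
slow time course (3 sinusoids in 1–4.8 Hz, 5% modulation about a static
amplitude 30× the bubble amplitude), plus white noise (σ = 0.05).
Pattern envelopes are flattened to near-uniform local strength, as
skull/tissue clutter covers the whole aperture. One course per pattern
keeps the clutter casorati rank exactly 20; the ≥1 Hz lower bound keeps
the courses linearly independent over sub-second ensembles. This
replaces RF-level simulation and beamforming; it exercises exactly the
SVD → localization → tracking → HMM chain.

What the surrogate does not emulate: speckle statistics, diffraction
sidelobes, depth-dependent attenuation, aberration, and RF-phase effects.
Passing tests therefore validate the processing chain's logic and
thresholds, not robustness to those physical effects.

## Clutter filtering

Each pixel's slow-time series is standardized (mean removed, unit
variance where defined), the casorati matrix is decomposed, and the first
20 singular components are removed (fixed count, not adaptive). Short
ensembles are filtered independently and stitched. For large matrices a
Lanczos partial SVD of the leading components replaces the dense
decomposition (identical result to 1e-8).

The spectral report computes, per temporal singular vector, a Tukey(0.2)
periodogram and its power-weighted mean absolute frequency; the tissue
cutoff index is the first vector at or above 100 Hz, and the inflection
index is the first sign change of the second difference of the smoothed
(window 5) central-frequency curve. Frame rates ≤ 200 Hz flag the
criterion inapplicable.

## Tracking

Detections are local maxima above 4× the robust (MAD-based) noise scale
of the filtered stack, refined to subpixel by log-parabolic 3-point
interpolation per axis (exact for Gaussian blobs). Linking is greedy
nearest-neighbour frame-to-frame under a one-wavelength step bound,
deterministic tie-breaks. Each linked track passes a constant-velocity
Kalman filter — state [x, z, vx, vz], P₀ = I, Q = σI, R = εI, innovation
snapped to the localization grid `y = nint((z − Hx)/g)·g` — followed by a
Rauch–Tung–Striebel backward pass; velocities come from the cubic-spline
derivative of the smoothed positions. Defaults σ = 1.0, ε = 25 µm²
(≈ (5 µm localization noise)²); the garbled printed smoother-gain line is
implemented as the standard `C = P_f Fᵀ P_pred⁻¹`.

Track pairing is two-stage: exact endpoint coincidence first, then
chronological merging when the endpoint gap is under 100 ms and under one
wavelength in both x and z; nearest-in-time wins, merging is transitive
(single sorted sweep, O(n log n)).

## HMM classification

The classifier sees the cycle-averaged speed: a boxcar of exactly one
cardiac period (0.12 s), which nulls the periodic pulsatile component
while preserving the dwell envelope. Symbols are
`2·[speed ≥ 2 mm/s] + [|accel| ≥ a_th]` with `a_th` the batch 90th
percentile of |accel| (at the median the accelerating bit is a coin flip
and unsupervised training latches onto it instead of the velocity split).
Sequences are standardized to length 100 by nearest-index resampling for
Baum-Welch training (2 states × 4 symbols; velocity-informed start plus
random restarts, best separating likelihood kept; batched, vectorized
E-step). Decoding is Viterbi on the standardized sequence; runs shorter
than 3 standardized samples are absorbed (single-cycle flips), and the
states are mapped back to native sampling so transit times are measured
on the real time axis.

A track is accepted as a single-capillary transit when its state runs
collapse to exactly high → low → high and the low run lasts at least
0.120 s; runs shorter than 0.2 s at the extreme ends of a track are
ignored first (velocity estimates there suffer filter warm-up and
one-sided smoothing). Rejections carry reason codes (no_low, multi_low,
no_flank, too_short). CHT = (low-state samples) × (frame interval).

Known limitations: transits whose anatomical dwell is split by a genuine
above-threshold excursion (e.g. crossing a fast cross-link) decode as
multi_low and are rejected; bubbles with extreme radial offsets lack a
resolvable fast flank and are rejected (no_flank); dwells comparable to
or longer than the long ensemble are attenuated by the per-ensemble mean
removal and may fragment. These are properties of the method, not bugs —
short-ensemble processing suffers them far more strongly, which is the
point of the LE/SE comparison.

## Maps and statistics

Accepted low-state samples deposit one frame interval of dwell at their
nearest pixel on a λ/32 super-resolved grid (total dwell conserved up to
field-of-view clipping, which is counted). The density rendering
convolves the map with a Gaussian whose window is 8λ (σ = window/4).
ULM renderings accumulate per-pixel counts, mean speed, signed-z
direction, or mean amplitude. CHT statistics: maximum-likelihood Cauchy
location/scale (scipy's MLE) with a Normal-fit log-likelihood comparison;
QQ comparison at 100 matched quantile levels; percent change of per-scan
maximum CHT against baseline with a monotonicity flag. An ROI polygon
mask utility restricts analyses to a region.

## Study-condition sizes

The default pipeline scene — used by the long- vs short-ensemble
experiment — simulates 200 bubbles arriving over a 120 s window on the
default network and renders a 12 s continuous sub-window (12 000 frames
at 1 kHz, 96×128 pixels), keeping roughly 4–10 bubbles concurrently in
view, a sparsity comparable to ULM practice. Long ensembles are 6000
frames; the short-ensemble arm processes independent 0.5 s acquisitions
(filtered and tracked per ensemble, as in conventional non-continuous
ULM, where a track cannot outlive its buffer). Unit tests run smaller
scenes; the acceptance script runs the sizes stated above.
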