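# Methods

## System model

The tracking/imaging probe carries five element rows on one face
(z = 0): a central 128-element imaging row (0.3 mm pitch, elements
0.3 × 4 mm, cylindrical lens) and four unfocused 32-element tracking
rows (elements 0.3 × 1.2 mm mounted long-side along Y, so the lateral
pitch is 1.2 mm and a row spans ≈ 38.4 mm, matching the central
aperture).  Coordinates: X out-of-plane (elevational), Y lateral,
Z depth; origin at the centre of the probe face.

The elevational positions of the four tracking rows are not a
published property of the manufactured probe.  The defaults place the
two pairs at ±3 mm and ±5 mm: the central elements are 4 mm tall, so
the rows must sit beyond ±2 mm plus lens/kerf margin.  They are fully
configurable, and the Monte-Carlo accuracy numbers depend mildly on
them.

In tracking mode each of the 128 tracking elements fires in turn
(side1 → side4); a single omnidirectional hydrophone sensor inside the
needle receives every transmission at 100 MS/s.  The forward simulator
models exactly what the tracking algorithm consumes: a time-of-flight
delay `r/c` per element, `1/r` spherical spreading (unit reference
amplitude at 1 mm, clamped below 1 mm), and white Gaussian receiver
noise.  Delays are applied with an exact FFT phase-ramp fractional-
sample shift.  Few-tap interpolators were rejected deliberately:
two-tap linear interpolation carries an amplitude ripple of up to
~0.8% at half-sample offsets, which swamps the ~0.04% inter-column
1/r amplitude contrasts that drive peak-column selection; the spectral
shift is amplitude-flat at every representable frequency.  Element
directivity, frequency-dependent attenuation and scattering are out of
scope — the localiser uses only peak times and relative amplitudes.

## Coded excitation and decoding

Tracking transmissions use a 32-bit Golay complementary pair built by
recursive doubling from ([+1], [+1]).  The transmit waveform is the
zero-stuffed code (one ±1 impulse per carrier period, 25 samples at
4 MHz / 100 MS/s) convolved with a one-cycle bipolar base pulse (+1
for 12 samples, −1 for 13).  Receptions are band-pass filtered with a
5th-order Chebyshev Type I filter, 2–6 MHz passband, 0.5 dB ripple
(the ripple is not a published system parameter).  Filtering is
zero-phase (forward–backward): a causal filter's group delay would
bias every measured time of flight, and although a constant bias would
largely be absorbed by the depth estimate, zero phase removes the
issue at the source.  For signals shorter than the default filtfilt
padding, the padding shrinks to the signal length.

Decoding convolves each filtered reception with the time-reversed
oversampled code and sums the pair; the full convolution is shifted
left by (N−1)·25 samples so a scatterer at delay t decodes to a peak
at the same sample as a bipolar reception at delay t.  The
complementary property makes the compression exact: amplitude gain 2N,
range sidelobes cancelled identically (numerically < 1e−15 relative),
and the decoded temporal profile equal to the band-passed bipolar
profile.  The matched-filter SNR gain over bipolar excitation grows as
√(2N).

## Tracking algorithm

The 128 decoded sequences are split into four tracking images, one per
side row, columns = element number (h), rows = receive sample, mapped
to distance via v = sample/fs · c.

**Peak extraction.**  Two detectors are provided.  The plain
`amplitude` mode returns the global |amplitude| maximum with a 3-point
parabolic refinement of the peak sample (ties toward smaller v, then
smaller h).  The production chain uses the `envelope` mode, designed
around two numerical facts observed during development:

1. the band-passed bipolar pulse has two near-equal lobes, so raw
   |amplitude| peak timing can jump by half a carrier period with
   sub-sample arrival phase — the analytic-signal envelope is unimodal
   and its FFT-upsampled parabolic peak is phase-stable;
2. at depth, adjacent columns differ in amplitude by only ~0.04%
   (pure 1/r), so the column is ranked by windowed column energy
   (±64 samples around the peak row), which is sampling-phase
   invariant by Parseval.

Because amplitude is exactly ∝ 1/r, the inverse energy is an exactly
quadratic function of the column's lateral position; the vertex of a
parabola through 1/E at the three columns around the maximum therefore
recovers the source's lateral coordinate to sub-column precision
(clamped to ±0.75 columns; integer fallback at row edges).  The peak
time is referenced to the transmit pulse's own envelope-peak offset,
computed once from the band-passed base pulse.

**Lateral estimate.**  ỹ = (mean over the four images of h − (32−1)/2)
× 1.2 mm.  With the sub-column h this is accurate to a few µm on
noise-free simulated data; with integer h it is quantised to 0.3 mm.

**Out-of-plane / depth estimate.**  Simulated times of flight
t_s⁽ᵏ⁾(x_i, z_j) = √((X_k − x_i)² + z_j²)/c are precomputed on a
0.025 mm grid, X −20…20 mm, Z 0…80 mm (1601 × 3201 nodes).  The grid
is stored in float64: near the depth limit the objective valley is
nearly degenerate and single-precision rounding of t_s (~3 ps) is
enough to scramble the argmin along it.  Before the search, the known
lateral leg is removed from each measured TOF
(t² → t² − ((ỹ − y_column)/c)²), since the 2D t_s model contains no
lateral component; without this, the common lateral range inflation
(up to 0.6 mm column offset) biases the deep estimates.  The estimate
minimises

    Σₖ [(t_m⁽ᵏ⁾ − t_s⁽ᵏ⁾(x_i, z_j)) w⁽ᵏ⁾]² / Σₖ [w⁽ᵏ⁾]²

with the peak amplitudes as weights w⁽ᵏ⁾ (at least two must be
positive); ties break toward smaller z, then smaller x.  The
accelerated search evaluates a 0.5 mm coarse lattice and then
repeatedly minimises over a ±1 mm window recentred on each successive
argmin until the argmin is the window centre.  The objective strictly
decreases at each recentring, so the walk terminates; a fixed
refinement window was found to mis-converge on the long diagonal
valleys (slope |dx/dz| up to ~7–10) that develop at depth.  Agreement
with exhaustive evaluation at every grid node is a tested property,
and `search="exhaustive"` remains available.

For water experiments the assumed sound speed comes from the Marczak
pure-water polynomial (valid 0–95 °C; 1482.4 m/s at 20 °C); in tissue
a fixed 1540 m/s is used.

**Intrinsic grid resolution.**  The grid search's x-resolution is not
uniformly 0.025 mm: along a degenerate valley of slope s the grid
samples the valley in |s|·0.025 mm steps of x, so even with exact
times of flight an off-lattice tip can localise ~0.1–0.2 mm away in x
at deep, out-of-plane positions.  This is a property of the
grid-search method itself, not of the measurement chain.  The
forward–inverse validation therefore places its random tips on the
estimator lattice, where ε = 0 recovery is exact and any residual
error is attributable to the chain; it uses depths of 10–70 mm —
shallower than ~10 mm, the unmodelled lateral leg exceeds one grid
cell (a documented near-field limit).

## Monte-Carlo speed-of-sound study

For each node of a 5 mm grid (X −20…20, Z 10…60 mm; 99 points) a
virtual sensor sits at (x, 0, z).  Each of 1000 iterations draws one
sound speed per tracking element, uniform on 1540·(1 ± ε) m/s with
ε ∈ {1%, 5%}, forms exact times of flight from the known element–
sensor distances (one element per side array, at the column nearest
the sensor — index 15 under the tie rule), and localises with the
constant assumed 1540 m/s.  Per grid point the study reports the mean
absolute coordinate errors (X, Z) and the mean Euclidean error;
grid-wide summaries are the mean and maximum of the latter.  Draws are
seeded per grid point (`SeedSequence([seed, point_index])`), so
results are independent of evaluation order; a `shared_draw` mode
(one speed per iteration for all elements) is available for
sensitivity analysis.  The batched solver evaluates the identical
objective on the identical lattice as the per-call estimator (equal
weights cancel), with the recentring loop grouped by centre node; the
equivalence is tested.

At ε = 1% the mean error is ≈ 0.9 mm with a ≈ 2.3 mm maximum in a
deep out-of-plane corner; at ε = 5%, ≈ 4.1 mm and ≈ 9.9 mm.  Depth is
resolved better than the out-of-plane coordinate at > 90% of grid
points — the four side rows span only ±5 mm in X, so the out-of-plane
triangulation baseline is short and differential TOF errors are
geometrically amplified with depth and |X|.  Estimates are clipped to
the ±20 mm grid, which moderates the error at the X-boundary columns.
With the symmetric default geometry the ±X corners are statistically
equivalent, so the location of the maximum can land on either sign of
X depending on the seed.

## Simulated water-bath protocol

The translation protocol runs the full waveform chain (simulate →
filter → decode → localise) while moving the tip: X from 0 to 20 mm
(1 mm steps) at depths 20/40/60 mm; Z from 20 to 60 mm at
X = 0/10/20 mm; and Y at the same three depths with X = 0.  The
lateral sweep extent is not published; this package sweeps Y over
±8.5 mm (18 positions per depth), keeping the protocol at 240
positions.  The reported relative accuracy is |tracked − actual| in
the translation dimension, mirroring the stage-referenced physical
metric.  Noise-free errors are bounded by grid quantisation; mean
error grows monotonically with injected receiver noise (verified on
the X leg at three noise levels).  Sweeps use an 80 µs record (the
protocol's deepest position plus the coded transmission); the default
record is 120 µs, covering the full 80 mm range.

## SNR statistic

Per tracking image, SNR = S/σ with S the global |amplitude| maximum
and σ the amplitude standard deviation in a fixed rectangle centred at
Z = 10 mm, Y = 9.5 mm with widths 20 mm and 19 mm (16 side-array
elements); the per-position SNR is the mean over the four images.  A
zero-variance region is rejected.  On paired simulations with
identical receiver noise, Golay decoding raises the SNR relative to
bipolar excitation, as the √(2N) matched-filter gain predicts.

## What the simulator does and does not show

The generator reproduces the geometry, timing, coding and noise of
the hardware chain, so passing tests demonstrate the correctness of
the encoding/decoding algebra, the localiser, and their interaction —
including error amplification under sound-speed heterogeneity, which
is modelled explicitly.  It does not model element directivity,
frequency-dependent attenuation, reverberation, tissue motion, or
hydrophone bandwidth; physical water-bath accuracies (hardware-
limited, ~0.4 mm) and in-vivo SNR values are therefore outside what
the desk-scale studies can reproduce, and no claim about them is
made.

## Problem sizes and tolerances

Default study sizes are the full ones: 99 grid points × 1000
iterations per Monte-Carlo run, the 240-position sweep, the
1601 × 3201 TOF grid.  The test suite uses reduced sizes only where a
property does not need the full run (e.g. 200-iteration sampling-
stability checks, 25-instance search-equivalence batches).  Numerical
tie-breaks: image peaks toward smaller v then h; grid argmin toward
smaller z then x; the centre column under a lateral tie is the
smaller index (15).
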