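# Methods note

## Model

The network is a linear map on a complex state vector with one node per pixel
of an N x N image:

    x(k+1) = B x(k),      B = diag(i * omega) + eps * A

- `omega_j = omega_offset + omega_gain * p_j`, where `p_j` is the intensity of
  pixel `j` (defaults: offset 0.0, gain 0.5). Equal intensities map to equal
  intrinsic frequencies regardless of position.
- `A` is a Gaussian distance kernel on the lattice,
  `a_jk = alpha * exp(-d_jk^2 / (2 sigma^2))`, with node coordinates
  normalized to `[0, 1]` (row/(N-1), col/(N-1)) so that the printed sigma
  values are commensurate across lattice sizes. The diagonal is kept
  (`a_jj = alpha`). `eps = 1` by default.
- Initial states are random: amplitude `U[0, 1]`, phase `U[-pi, pi]`.

All computation lives in the phases `Arg x(k)` during the transient. Because
the map is linear, multiplying the state by any positive real scalar leaves
every phase unchanged; the iterator therefore rescales by the maximum
amplitude each step ("stabilization") and records the cumulative log-scale, so
raw amplitudes remain recoverable. Stabilized and raw phases agree to ~1e-15;
without stabilization the iterator raises an explicit range error once
amplitudes exceed 1e150.

### Exact spectral solution

With eigendecomposition `B = V diag(lambda) V^-1` (rows of `R = V^-1` are the
left eigenvectors), the trajectory is

    x(k) = sum_i lambda_i^k (r_i^T x(0)) v_i .

Modes are ordered by decreasing `|lambda_i|`. `spectral_solve` evaluates this
sum directly and is verified against brute-force iteration (phase agreement
< 1e-8 on random systems at k in {1, 5, 20, 60}; measured ~1e-10).
`truncated_solve` keeps the leading `rank` modes, ordered either by
`|lambda|` or by current contribution `|mu_i(k)| = |lambda_i|^k |r_i^T x(0)|`.
If the eigenbasis condition number exceeds 1e8 (e.g. near-defective coupling),
a warning is issued and the solver falls back to stabilized iteration with the
recorded amplitude scale reapplied, so results remain exact.

## Two-layer segmentation pipeline

| stage | kernel | steps | readout |
|---|---|---|---|
| layer 1 (background) | alpha 0.5, sigma 0.9 | 60 | final phases |
| layer 2 (objects) | alpha 0.5, sigma 0.0313, background masked | 200 | phase window 141–181 |

- **Background rule.** Layer 1's broad kernel drives the sheet toward two
  phase groups. Final phases are thresholded at their circular mean; the
  larger group is declared background. If the maximum angular deviation from
  the circular mean is below `min_phase_spread = 1e-8` (a uniform image), the
  image is reported as "no foreground" and segmentation returns all-background
  labels instead of inventing objects.
- **Masking.** The layer-2 connectivity zeroes the rows *and* columns of
  background nodes, and the dynamics are evolved only on the active submatrix;
  masked nodes keep zero amplitude and undefined (NaN) phase.
- **Similarity readout.** Over the window (T = 41 steps),
  `s_jk = (1/T) sum_t exp(i (phi_j(t) - phi_k(t)))`. S is Hermitian with unit
  diagonal and `|s_jk| <= 1`. The embedding projects `Re(S)` onto the real
  parts of the three leading eigenvectors of S (sorted by `|eigenvalue|`);
  K-means with 20 restarts and a fixed seed labels the foreground nodes.
  Accuracy is permutation-matched pixel accuracy over all pixels (best
  bijection between label sets via the assignment problem).
- **Seeding.** A single pipeline seed is split with `SeedSequence.spawn` into
  the layer-1 initial state, the layer-2 initial state, and the K-means seed,
  so every run is reproducible from one integer.

### Parameter provenance

Kernel widths, step counts, and the readout window are fixed domain defaults
of the method (broad kernel ~0.9 on the unit lattice for the global split;
local kernel 0.0313 ~ one pixel spacing at 32x32 for object waves). The
encoding parameters were calibrated once by a coarse grid search over
`(omega_offset, omega_gain)` on two generated two-shape images (generation
seeds 1001 and 1002, disjoint from all evaluation seeds). The accuracy surface
is flat near 1.0 over a wide plateau; within that plateau the gain was set to
0.5 because large gains create unequal per-object growth rates
(`|lambda|` of each object's dominant mode grows with its omega), letting one
object's wave leak across an overlap zone and swamp the other before the
readout window. The small gain keeps growth rates near-equal, which preserves
the intensity-difference separation behavior on overlapping objects without
changing non-overlap benchmark accuracy. The defaults are frozen in
`cvrnnseg.config` and used unchanged for every experiment.

## Synthetic generator: scope

`make_shapes` emulates a simple benchmark: 32x32 binary images containing a
triangle (36 px, 8-row base), a square (8x8, 64 px), and optionally a second,
flipped triangle, placed uniformly at random without overlap (rejection
sampling with an explicit placement error after 1000 attempts).
`make_overlapping_pair` places a triangle and square with a partial overlap
between 4 pixels and half the triangle's area — complete overlap is out of
scope — where overlap pixels take the triangle's id and intensity, and the
square's intensity can be lowered by `intensity_delta`.

This generator is an emulation, not a reproduction of any external dataset:
shape sizes and placement distributions are fixed choices. On this generator
the frozen pipeline measures a mean permutation-matched pixel accuracy of
**99.66%** on 200 two-shape images and **98.71–98.78%** on 200 three-shape
images (exact third decimal depends on the run seed). These values sit *above*
the 93% / 86% reference band the acceptance targets encode (tolerance ±5
percentage points), i.e. the corresponding acceptance tests fail by
overshooting: the emulated images are cleaner and easier than the original
benchmark data, whose shape scales and placement statistics are not public.
The generator and pipeline are deliberately not degraded to steer the number
into the band.

## Numerical choices

- Per-step positive-real rescaling for range safety (phases exact; see above).
- Eigenbasis condition threshold 1e8 for the warn-and-fall-back path.
- `min_phase_spread = 1e-8` for no-foreground detection.
- Constant-image detection in `load_image` uses `ptp == 0`, not `std == 0`
  (the std of a constant array can round to ~1e-17).
- K-means: 20 restarts, fixed `random_state`; determinism verified by test.
- All randomness flows from integer seeds through `numpy.random.default_rng` /
  `SeedSequence`; derived seeds are reduced mod 2^31.

## Known limitations

- Binary or few-level intensity images only: the intensity-to-frequency code
  gives identical frequencies to identical intensities, so textured or noisy
  objects fragment. No noise model is included.
- Same-intensity objects separate only if spatially disjoint under the local
  kernel; touching same-intensity objects merge.
- The overlap zone itself is ambiguous by construction; only the non-overlap
  pixels' separation is asserted (the overlap region joins one of the two
  clusters).
- K (number of objects) is supplied by the user, not inferred.
- The background rule assumes the background is the larger phase group; images
  with more foreground than background would invert the split.
- Fixed 32x32-centric defaults: other lattice sizes work (coordinates are
  normalized), but kernel widths and window were chosen at 32x32.
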