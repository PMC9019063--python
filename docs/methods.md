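# Methods

## Image model and conventions

Images are non-negative functions on a rectangular pixel grid
P = {0..W−1}×{0..H−1}; binary images take values in {0, 1} with **0 =
black**.  Arrays are indexed `[row, col]`; structuring-element offsets are
(dx, dy) with x the column, added componentwise.  All morphological windows
are **clipped to P** — the value at x is the min/max over (x+B)∩P or
(x−B)∩P — never padded.  This differs from the constant/reflect border
modes of common image libraries and is why the operators are implemented
directly with shifted-array min/max folds rather than through
`scipy.ndimage` (whose footprints are center-anchored and whose border
modes pad; the default square elements here are corner-growing and
asymmetric at odd indices).  The brute-force test oracles clip identically.

The default structuring elements are nested squares: B_0 = {(0,0)} and
each step glues shifted copies toward the positive quadrant (odd steps) or
negative quadrant (even steps), so B_i is an (i+1)×(i+1) square and
even-index elements are symmetric.  Arbitrary nested sequences are
accepted by every filtration entry point, but only sequences with the
shift-inclusion property (which the squares possess) guarantee nested
opening/closing level sets; nestedness is asserted whenever a filtration
is materialised, so an invalid sequence raises instead of silently
corrupting persistence input.

## Cubical persistence

Black pixels are filled closed unit squares ("top-cube" convention): black
connectivity is 8-connected, the white complement 4-connected, and a hole
is a bounded white region.  Coefficients are Z/2 — torsion-free in the
plane, so the choice only pins down determinism.  Essential classes die at
n+1, one past the last level, which is what makes the closing selection
rule's arithmetic (i_c = (n+1) − max b) come out right.

Two computation paths produce identical pairings:

* **fast** (production): dim-0 pairs by Kruskal/elder-rule union-find over
  black pixels (an edge between 8-neighbours appears at the max of their
  birth levels); dim-1 pairs by Alexander duality as dim-0 superlevel
  persistence of the 4-connected white graph augmented with a virtual
  unbounded node — a hole is born when its white region separates from the
  unbounded component (the min-weight severed edge) and dies when the
  region's last pixel turns black (the component's max value).  Constant-
  birth plateaus are contracted with a connected-component labelling
  first; merges inside a plateau are zero-persistence and drop out, so the
  contraction is lossless and the union-find graph stays small.
* **reduction** (reference): textbook Z/2 boundary-matrix reduction over
  the explicit cell complex, cells ordered by (birth, dimension,
  deterministic id).

The reduction path is what the theory prescribes; the union-find path is
the package's own engineering choice because pure-Python reduction over
the ~145 000 cells of a 190×190 image is far too slow for the hundreds of
diagram computations a denoising experiment performs.  The test suite
asserts multiset equality of the two paths on randomized filtrations,
checks Betti numbers against an independent GF(2) boundary-rank oracle
exhaustively on all 512 3×3 supports and all 3^9 two-level 3×3
filtrations, and verifies the diagram/Betti counting identity
β_k(X_m) = #{(b,d) ∈ P_k : b ≤ m < d} at every level of randomized
filtrations — the primary correctness oracle.

Zero-lifespan pairs (birth = death at the level granularity) are
discarded; they carry no information at integer resolution and no
selection rule reads them.

## The denoiser

Parameters: `size_tol` (largest admissible SE index — an upper bound on
the spatial scale of noise features; default 5), `max_iter` (maximum
number of selections; default 10), and the SE sequence (default unit-step
squares of length size_tol+1; an even-step subsequence B_0, B_2, B_4, …
can be passed for coarser scale resolution at the same index budget).

Each round computes the dim-0 diagram of the relabelled closing filtration
of the current image, applies C at the selected index, then the dim-1
diagram of the opening filtration, and applies O at its selected index.
The opening rule is restricted to finite deaths d ≤ n: an essential hole's
death n+1 indexes no structuring element and the corresponding opening
would change nothing.  A phase with no qualifying pair is **skipped**
rather than terminating the run: salt and pepper exhaust at different
rates, and once one operator family has nothing left to remove the other
may still have several scales of work.  The run stops when a selected
index exceeds size_tol, when a complete closing+opening round applies
nothing, or at max_iter selections (every selection attempt counts,
including skipped and stopping ones).  The trace records applied steps in
application order (negative = closing, positive = opening); reversing it
gives the composition-order multi-index of the composite operator, the
two serialisations of the same walk through the multifiltration.

Grayscale: all 256 global thresholds are denoised independently and the
binary outputs summed.  With the identity per-threshold step this
reconstructs the input exactly (a pixel of value v is white in exactly v
thresholded images).  The per-threshold outputs need not be nested, so
the sum can reach 256 at pixels denoised to white at every threshold;
8-bit output is clamped to 255 with the raw sum available.  Consecutive
equal thresholded images reuse the previous result — a pure optimisation
with bit-identical output.  RGB is channel-wise.

## Synthetic data

`default_phantom_spec()` is a 190×190 two-scale phantom with 6 rectangular
black components and 5 square white holes, (β0, β1) = (6, 5), emulating
the class of ground truths used to benchmark the denoiser.  Hole sides are
18 px; walls, separations, and border margins are ≥ 17 px; component
thicknesses ≥ 18 px.  The 17 px clearance is derived, not tuned: the
largest structuring element the bundled experiments apply is the 9×9
square B_8, and an attached noise feature of scale ≤ 8 px shifts a
feature's effective boundary by up to 8 px, so 8 + 9 = 17 is the smallest
clearance at which no admissible opening or closing can bridge two
features, sever a wall, or fill a hole that a *single* noise feature has
deformed.

Noise models: i.i.d. salt-and-pepper (each pixel flips to the minimum or
maximum representable value with probability d/2 each — an approximation
of the usual MATLAB-style semantics; exact replication is not attempted)
and large salt-and-pepper (uniformly placed black/white squares of sides
1–8, one size per experiment, mirroring how the larger-scale experiments
are organised).  All generators are pure functions of (spec, seed).

What the phantom does **not** emulate: curved or thin-stroke structure,
texture, grayscale gradients, and correlated noise.  Passing recovery
tests therefore demonstrates correct scale separation by the algorithm,
not performance on natural images.

## Experiment scales and known limitations

The bundled recovery experiments use 20 trials per noise family (5 seeds ×
4 densities, and 5 seeds × 4 square sizes), SizeTol 5 and MaxIter 10 for
salt-and-pepper and square sizes ≤ 4, SizeTol 8 for 8×8 squares; together
with the exhaustive oracle suites the full test run takes well under a
minute on one CPU.

Two regimes are known — and documented here deliberately — to break exact
Betti recovery, and the corresponding trials fail honestly in the test
suite:

* **Salt-and-pepper at density 0.4.**  Closings coalesce the ~20% white
  contamination inside large black regions; the merged blobs can exceed
  the SizeTol-5 opening scale, after which no admissible operator removes
  them (measured: 0/40 failures at d ≤ 0.3; ~9/40 at d = 0.4).  This is a
  property of the conservative printed selection rules, which take the
  minimal index at every step; detecting the diagram gap and jumping it
  is the natural refinement and is out of scope here.
* **8×8 square noise.**  Removing an 8×8 black stamp requires a closing at
  scale 8, whose 9×9 window also severs any wall that a single 8 px stamp
  has thinned below 9 px.  Guaranteeing 8+8+9 = 25 px of clearance around
  every one of 5 holes and 6 components does not fit a 190×190 canvas
  (one hole-bearing component then needs 25+18+25 = 68 px per axis and
  two of them side by side with margins already exceed the canvas), so
  occasional hole loss under 8×8 noise is unavoidable at this image size.
  Sizes 1–4 recover exactly by the same clearance arithmetic (17 ≥ noise
  + SE scale), up to astronomically rare chained-stamp events.

SSIM delegates to scikit-image with Gaussian 11×11 windows, σ = 1.5,
C1 = (0.01·L)², C2 = (0.03·L)², L = the reference image's dynamic range
(1.0 for a constant reference); absolute values can differ slightly from
other toolboxes.  PSNR uses the maximum of the reference image as the
peak — scale-invariant, but numerically different from toolboxes that fix
a nominal 255 when the reference does not attain it.  IOU is the Jaccard
index of black sets, defined as 1 (and logged) when both are empty.

## Design choices at genuinely open points

* Composite operators are applied rightmost-first (composition order);
  traces are stored in application order with explicit converters, since
  both conventions are natural and mixing them silently is the real risk.
* Multifiltration levels are computed lazily with an optional
  suffix-keyed memo — the full k-parameter grid is exponential in k.
* `betti()` uses connected-component labelling directly (8-connected
  black, 4-connected bounded white) rather than the persistence engine;
  the two agree by the counting identity, which is tested.
* The unit-step square sequence is the default everywhere; the even-step
  subsequence is supported (`SESequence.subsequence(2)`, CLI `--se-step 2`)
  but never silently chosen.
* Non-flat (weighted) structuring elements, 3-D voxel data, distance-
  transform operators, rank invariants and other multiparameter summaries
  beyond nondecreasing-path persistence are out of scope.
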