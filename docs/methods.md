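# Methods

## Pipeline model

The package treats trap counting as tiled small-object detection with
explicit duplicate control. For an image of width/height L scanned with
windows of side W overlapping by V pixels, windows are placed at
multiples of the stride s = W − V, with the final window in each axis
clamped to offset L − W so that every window has exactly side W and the
union of windows covers the image. The number of windows per axis is
n = ceil((L − W)/s) + 1. For the reference full-resolution geometry
(L = 6000 × 4000, W = 500, V = 100) this gives 15 × 10 = 150 windows,
and 7 × 5 = 35 for W = 1000. Clamping rather than padding was chosen
because it is the unique simple edge policy that keeps the window size
constant while producing those grid shapes.

Because V exceeds the insect diameter, any axis-aligned box with both
sides ≤ V is wholly contained in at least one window. Containment alone
is not quite enough for counting: the edge filter (below) removes boxes
within a tolerance τ of interior window borders, so the *guaranteed
countable* object size is V − 2τ per side. With the defaults (V = 100,
τ = 1) this is a 98 px box against a 60 px insect — ample margin. At
strongly reduced scales the margin shrinks proportionally and should be
checked (the CLI examples at 1/10 scale use V = 12 for 9 px insects for
exactly this reason).

### Duplicate elimination

Two distinct duplicate mechanisms arise from overlap:

* An object wholly inside two windows yields two (near-)identical global
  boxes. Global greedy NMS removes these. Suppression uses strict
  IoU > t with t = 0.5 by default; score ties are broken by input order
  so the pipeline is deterministic and window-order independent.
* An object *cut* by a window border yields a partial box whose IoU with
  the whole-object box from the neighbouring window is below any usable
  NMS threshold, so NMS cannot remove it. Such boxes are removed
  outright when any coordinate lies within τ (default 1 px, real-valued
  coordinates rarely sit exactly on a border) of a window border —
  except borders that coincide with the image boundary. Without this
  exemption every insect at the trap perimeter would be deleted from
  *all* windows and become uncountable; with it, the clipped perimeter
  boxes are identical across windows and NMS merges them. Whether the
  original procedure exempted the image boundary is not documented
  anywhere we know of; the exemption is the minimal reading that
  preserves the rule's purpose, and it is exposed as a switch.

The score threshold is applied after stitching, matching the calibration
protocol: detection and NMS run once, and candidate thresholds are swept
by re-filtering scores.

## Coordinate and matching conventions

Boxes are 0-based, half-open, real-valued (COCO-style); width is
xmax − xmin with no +1. Detection–truth matching is greedy in score
order: each detection takes the unmatched truth of highest IoU if that
IoU reaches the matching threshold; IoU ties go to the lower truth
index. AP uses the all-point sweep with the exact area under the
right-to-left precision maximum (PASCAL VOC 2010+ style) rather than
11-point interpolation, because it is exact and directly checkable
against brute-force enumeration. Precision/recall with empty
denominators raise a distinct error instead of silently returning 0.

## Counting error

The counting error is implemented as the mean absolute relative
deviation, (1/N) Σ |C_i − Ĉ_i| / C_i × 100. A signed variant (no
absolute value) is available via `counting_error(..., signed=True)`; it
is not the default because over- and under-counts would cancel and a
"0% error" could then hide large per-trap deviations. Traps with
C_i = 0 are rejected (relative error undefined) and must be excluded
upstream. Threshold calibration minimizes this error over a default
candidate grid of 0.05–0.95 in steps of 0.05, breaking ties toward the
higher threshold (the more conservative count).

## Reference detectors

The pipeline is detector-agnostic; the package deliberately ships no
trained weights. Two reference implementations make it executable:

**Blob detector.** Grayscale conversion, intensity threshold (fixed at
0.5 by default, or Otsu per tile), 8-connected components, an area
filter (min 20 px² against noise speckles; max unbounded), and a score
equal to the component's mean contrast against the tile's background
median, clipped to [0, 1]. Touching insects merge into one component and
would each merged pair cost one count, so merged blobs are split by
marker-based watershed on the distance transform: markers are distance
peaks separated by at least 0.8× the median equivalent component radius
in the tile (scale-adaptive, so a single convex blob never splits), and
components whose bounding box comes within 2 px of the tile border are
never split — a cut object must keep its single border-touching box for
the edge filter to act on. Splitting is the standard blob-analysis
treatment of touching objects and can be disabled with
`BlobConfig(split_touching=False)`.

**Noisy oracle.** Reads the ground truth and corrupts it: each truth box
is dropped with probability `miss_rate`, jittered by up to
`localization_jitter` px per coordinate, and scored from a uniform law
(default degenerate at 1.0); Poisson-distributed spurious boxes are
added per tile with a separate score law. Truth boxes only partially
inside a window are emitted clipped — what a real detector sees for a
cut insect — which is what exercises the edge filter end-to-end.
Per-tile randomness is seeded from (seed, window offset), so results are
reproducible and independent of window processing order.

## Synthetic scenes

The generator emulates the statistical structure of yellow sticky-trap
photographs: a noisy yellow background (RGB ≈ (205, 185, 60), Gaussian
noise σ = 6 in 8-bit units), dark rotated elliptical insects whose
nominal size is N(60, 6²) px at full scale (aspect ratio 0.8–1.0, so the
mean annotated box side stays within a few px of 60), and pale elongated
wing-like distractors that are rendered but never annotated. The emitted
ground-truth box of each insect is the bounding rectangle of its
actually rendered pixels — the generator is its own census, and the
annotation count equals the configured density exactly.

Placement separates two regimes. A `cluster_fraction` of insects is
placed within one body-diameter of a randomly chosen mate, producing the
overlapping clusters that dominate real counting errors; the remainder
are placed by rejection sampling with non-overlap guaranteed (circle
separation plus a 2 px gap), so a cluster-free scene is separable by
construction and the blob detector counts it exactly. The default
cluster_fraction is 0.05: with essentially every clustered insect
touching its mate, this puts a plain connected-components counter at
roughly 5% undercount and the watershed-splitting default at the 2–3%
error regime that well-configured detector pipelines achieve on real
traps — our definition of "moderate clustering". Density strata follow
the monitoring protocol: traps with fewer than 300, 300–500, and more
than 500 insects (benchmark draws of 150–299, 300–500 and 501–650
insects per trap respectively).

Scenes scale geometrically: `SceneConfig.scaled(f)` multiplies image and
insect dimensions by f, preserving the insect:window and overlap:insect
ratios. The tests and the acceptance script run at quarter scale
(1500 × 1000 px, 15 px insects, 125 px windows, 25 px overlap), which
keeps the full 15 × 10 grid structure while a whole stratified benchmark
renders and counts in seconds; full 6000 × 4000 rendering is available
by simply not scaling. Problem sizes in the acceptance script (20 oracle
scenes of 120 insects; a 3-band × 4-trap benchmark with one trap per
band used for calibration) were chosen as the smallest sets that
exercise every stratum and stage meaningfully.

What passing on synthetic scenes shows — and what it does not: the
pipeline's bookkeeping (tiling, edge filtering, NMS, counting, metrics,
calibration) is exact, and the reference detector's errors behave like
the field's (cluster-driven undercounts, threshold-sensitive counts). It
does not show that any particular trained detector reaches a given AP or
counting error on photographs; appearance variation (lighting, debris,
insect pose and decay) is deliberately not modelled.

## Numerical and degenerate-input choices

Zero-area boxes are rejected at construction; IoU of disjoint boxes is
exactly 0 and of identical boxes exactly 1. NMS at threshold 1 keeps
everything; a pair exactly at the threshold survives (strict
comparison). Empty detection lists are valid everywhere (count 0, AP 0);
AP with no ground truth and precision with no detections raise
`UndefinedMetricError`. The infeasible-density case (more insects than
rejection sampling can place) raises rather than silently overlapping.
All randomness flows through `numpy.random.default_rng` with explicit
seeds; scene generation, both detectors, and therefore end-to-end counts
are bit-reproducible for a fixed configuration.
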