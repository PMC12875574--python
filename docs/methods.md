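# Methods

## The measurement problem

A 2-D confocal scan of phalloidin-stained cortical bone shows osteocyte
cell bodies as bright, roughly elliptical blobs (lacunae are 6–12 µm
across) joined by dendritic processes 1.5–3 px wide at the 150 nm/px
digital resolution of the instrument. The optics are diffraction limited
to ~450 nm, i.e. a point-spread function of roughly 1.5 px standard
deviation, so nothing narrower than ~3 px is resolvable and thin processes
lose most of their peak intensity to blur. The package turns such an image
into (i) a 3-class semantic segmentation, (ii) a network graph with
osteocytes as nodes and dendritic connections as edges, and (iii)
per-image summary metrics that can be compared between groups.

## Threshold segmentation

Both pipelines share the same scaffold:

1. **Smoothing.** Gaussian filter, σ = 2 px, reflective boundaries, output
   rounded back to the 0–255 integer scale. Smoothing is what makes the
   fixed thresholds usable: it drives background noise (σ≈8 raw) down to
   ~1 intensity unit.
2. **Candidate split.** A fixed threshold at 70 separates osteocyte
   candidates (≥ 70) from the dendrite candidate band, which is bounded
   below by a secondary noise threshold (default 30). The physical reading
   is that large bodies retain their staining intensity through the PSF
   while 1.5–3 px processes are attenuated into the 30–70 band. A config
   flag (`invert_split`) swaps the bands for stains in which the processes
   are the brighter class.
3. **Core.** Either Otsu's threshold computed over the histogram of the
   candidate band (separating dendrite pixels from the dim band fringe),
   or Canny edge detection (gradient → non-maximum suppression →
   hysteresis with low/high thresholds 70/220) intersected with the band.
4. **Post-processing.** Morphological closing of the dendrite mask with a
   3×3 square element, then element-wise subtraction of pixels claimed by
   both classes, with the osteocyte class winning. The output classes
   therefore partition the image by construction.

Numerical conventions worth noting:

* **Otsu.** The threshold maximises the between-class variance
  ω₀ω₁(μ₀−μ₁)² over all 255 candidate splits (class 0 = intensities ≤ t);
  ties break toward the lowest threshold. The standalone operation exposes
  a `clamp_min` floor on the returned threshold and the `max_value`
  written into the foreground. Inside the pipeline the parameter pair
  (80, 255) is treated the way the conventional
  `threshold(src, thresh, maxval, OTSU)` call treats it — `thresh` is a
  placeholder overridden by the Otsu computation — because a literal ≥ 80
  floor is incompatible with a candidate band that ends at 70. Setting
  `otsu_clamp_min` to an integer restores the clamping behaviour.
* **Canny scale.** Hysteresis thresholds are quoted on the classic
  unnormalised 3×3-Sobel gradient scale; scikit-image's Sobel kernels are
  normalised by 4, so thresholds are divided by 4 before being applied.
* The optional minimum-component filter (default off, 3 px) reflects the
  ~3 px optical resolvability floor.

The pipeline contains no randomness anywhere; identical inputs and
parameters give identical masks.

## Evaluation metrics

Per class (one-vs-rest): DSC = 2|P∩G|/(|P|+|G|) and IoU = |P∩G|/|P∪G|,
linked by DSC = 2·IoU/(1+IoU). Conventions: a class empty in both masks
scores 1.0 (vacuous agreement; switchable to NaN-and-exclude); mIoU
averages the osteocyte and dendrite classes, excluding background; the
single overall DSC is the Dice of the union of foreground classes, since
a headline "DSC" admits several definitions and this one is the most
conservative aggregate. Both per-image-mean and pooled-pixel batch
reductions are provided (`evaluate_batch`, `pooled_evaluate`) because
headline accuracies are sensitive to that choice.

## Connectomics

Class masks are separated and dilated — cell bodies with the discrete
ellipse inscribed in a 4×4 box `[[0110],[1111],[1111],[0110]]`, dendrites
with the 2×2 cross `[[11],[10]]` — to merge nearby fragments that should
be one entity. Connected components (8-connectivity, so diagonally
touching dendrite pixels are one process) are then extracted per class.
For every dendrite component the set of osteocyte components it overlaps
decides its role: k ≥ 2 contacts yield one connection per contact pair
(the shared component contains no osteocyte pixels, so each pair has an
independent route that passes through no other cell — routes via
intermediate osteocytes are never added); k = 1 is a dead end of that
cell; k = 0 is an orphan, recorded but edgeless. Two distinct components
joining the same pair count as two connections (routes, not neighbours);
`unique_partners=True` gives degree-style counting instead. Dead ends are
counted per component by default, with a per-skeleton-endpoint switch.

Geometry is measured on the **undilated** dendrite pixels of each
component:

* **Length** — the component is thinned to a 1-px medial-axis skeleton;
  length is the geodesic along the 8-connected skeleton graph with
  diagonal steps weighing √2 px. For a connection, the geodesic runs
  between the skeleton pixels nearest to the two endpoint cells; for a
  free component, the longest skeleton geodesic is used. Digital √2
  weighting overestimates smooth curves by a few percent while the
  skeleton's end erosion at the cell contacts shortens them; the two
  biases largely cancel (mean error ≈ 4% on synthetic ground truth).
* **Diameter** — twice the mean Euclidean distance-transform value sampled
  along the skeleton. The EDT is evaluated on a 2× nearest-neighbour
  upsampling of the component (block maximum over each skeleton pixel)
  because the pixel-centre EDT carries a half-pixel parity bias: naively,
  an N-px ribbon measures N+1 for odd N and N−1 for even N, while on the
  upsampled grid it measures N for both.

The six per-image metrics are node count, dead ends per node, connections
per node (= 2·|edges|/|nodes|), mean connection length, mean connection
diameter, and mean network diameter (averaged over *all* dendrite
components — edges, dead ends and orphans). A zero-node mask produces
all-zero metrics with a warning. Inter-cell distances in hops are exposed
via breadth-first `shortest_path_length`, with `math.inf` for unreachable
pairs.

## Dendrite regularisers

`component_size_penalty` evaluates λ·Σ_c 1/size(c) over the connected
components of a binary dendrite mask — the discrete form of a loss
regulariser that punishes fragmented predictions, since merging components
of sizes a and b strictly lowers the sum (1/(a+b) < 1/a + 1/b). Options:
a `min_size_px` floor under which components are charged the maximal
per-component weight 1.0, and normalisation by component count (default
`none`; the normalised variant keeps the penalty scale independent of
fragment count). `dilate_labels` thickens annotation classes with a 2×2 or
3×3 square kernel; even kernels have no centre pixel, so the anchor is
fixed at the top-left element (the mask grows down-right by half a pixel),
and collisions resolve osteocyte-first, consistent with the segmentation
subtraction rule.

## Group comparison

Per-image metric lists from two groups are compared metric-by-metric with
a two-sided Mann–Whitney U test at α = 0.05. For combined n ≤ 20 without
ties the exact permutation null is used (verified against full
enumeration); otherwise the normal approximation with tie and continuity
corrections. U is reported as min(U_x, U_y). No multiple-testing
correction is applied by default (each metric is reported at its own α, as
is conventional for these per-metric figures); a Holm step-down option
exists. Group-level percentage changes,
100·(mean_ref − mean_other)/mean_ref (positive = decrease relative to the
reference), are single values and are reported descriptively without a
test. Figure-style stars: `****` for p < 10⁻⁴, `*` for p < 0.05, `n.s.`
otherwise.

## Synthetic scenes

`sample_network` places elliptical bodies (semi-major axis 20–40 px,
aspect 0.55–0.85, uniform orientation) with centre separation at least
2× the maximum semi-axis, connects pairs closer than a reach radius with
probability `connection_prob` via Catmull-Rom splines through 3–4 control
points (so skeleton lengths are exercised on genuinely curved paths), and
attaches Poisson(`deadend_rate`) dead-end dendrites per cell. Strokes are
rasterised at the 0.5-coverage threshold of an anti-aliased round-capped
line (a pixel belongs to the mask iff its centre lies within width/2 of
the centreline), which realises sub-pixel widths like 1.5 px. Dendrite
anchors are inset 1.5 px into their body so the rasterised stroke always
overlaps it; recorded ground-truth lengths cover only the path portion
outside the bodies. The image is the clean render × a linear illumination
ramp, blurred by a Gaussian PSF (default σ = 1.5 px ≈ the 450 nm
diffraction limit), plus Gaussian sensor noise, clipped to [0, 255]. The
mask is the pre-blur geometry with body pixels winning ties. Optional
distractors — a transiting blood vessel and shrunken (apoptotic-looking)
osteocytes — are drawn into the image only and remain background in the
mask, exactly the role such artefacts play in real scans.

Intensity defaults (background 12, bodies 210, dendrite base 90) are the
package's calibration of the regime the fixed thresholds assume: after the
PSF and the pipeline's own smoothing, 1.5–3 px processes peak at ~30–60
while bodies stay far above 70. Scans' true intensity statistics (SNR,
background level) are not published for this preparation, so these are
plausible-value choices, not measured ones.

Presets:

* `young_params` — the defaults with Poisson-varying counts: ~7 cells per
  500×500 field, ~21 dead ends and ~3.8 connections per cell (calibrated
  to manually-annotated reference values for healthy young bone).
* `aged_params` — osteocyte density reduced by 38% (the manually measured
  aging decrease), connection reach cut to 260 px. Connectivity per cell
  then falls ~45–55% (mostly through the density drop itself — fewer
  neighbours in reach — matching the manually measured 43% and
  model-measured 56% decreases), dendrites shorten, and the dead-end rate
  rises ~25% (direction reported, magnitude unpublished; configurable).
* `low_noise_params` — young scenes under favourable imaging (noise 3,
  near-flat illumination); the segmentation-quality testbed.
* `recovery_params` — sparse (5 cells), clean, `well_separated=True`:
  candidate dendrite paths that come within 6 px of unrelated structures
  are re-drawn and eventually dropped, and body separation is raised to 3×
  the maximum semi-axis so no connection degenerates into a few-pixel
  stub. On these scenes the rendered true mask decomposes into exactly the
  recorded graph, giving the connectomics chain an exact oracle.

Everything is a pure function of `(params, seed)`; cohort generation
derives per-scene seeds from a master seed via `SeedSequence`, so whole
studies are byte-reproducible.

### What the generator does not emulate

Physically accurate optics (anisotropic PSF, photobleaching, depth
attenuation), out-of-plane structures crossing the confocal section,
staining heterogeneity along a single process, and 3-D stacks. Passing
tests on these scenes therefore demonstrate the correctness of the
algorithms under the stated geometry and noise model, not segmentation
performance on real microscopes — where dendrite accuracy is known to be
substantially harder.

### A note on noise and dendrite detectability

Segmentation quality is not monotone in sensor noise: thin (≈1.5 px)
processes whose blurred peak sits just below the 30-intensity band floor
are invisible at low noise, while moderate noise dithers a fraction of
their pixels above the floor and *raises* dendrite DSC before heavy noise
destroys the segmentation — classic stochastic resonance in a
fixed-threshold detector. The osteocyte class, far above threshold, is
monotone; the tests assert exactly this pair of facts.

## Problem sizes

The shipped tests and the acceptance script use 20 scenes per
segmentation/recovery study, 30 images per group for the cohort
comparison, 100 cohort replicates for the discrimination rate, and 1000
null simulations for type-I calibration — sizes at which the stochastic
quantities involved are stable to well within the tolerances being
checked.

## Known limitations

* The reimplementations of earlier low-pass/adaptive-threshold and
  thinning-based segmentation pipelines, and all deep-learning models,
  are out of scope; the package covers the fully specified threshold
  methods and everything downstream of a mask.
* Graph extraction is 2-D; a confocal plane truncates the true 3-D
  network, so absolute dead-end counts and connection lengths are
  plane-bound quantities.
* The dendrite diameter estimator is accurate to ~10–15% at the 1.5–3 px
  widths of interest; at those scales genuine width changes (e.g.
  perilacunar remodelling) are below the diffraction limit anyway.
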