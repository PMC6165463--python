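# Methods

`abbt` implements an automated scoring pipeline for the Box and Blocks Test
(BBT), the clinical measure of unilateral gross manual dexterity in which a
person moves as many 25 mm wooden cubes as possible from one compartment of
a two-compartment box over a 100 mm partition in 60 seconds.  The automated
variant replaces the therapist's manual count with top-down RGB-D imaging:
a depth camera fixed 80 cm above the desk watches the receiving compartment
and counts cubes as they arrive.  This note documents the models, the
parameters that matter, and the choices made where the design was open.

## Pipeline

1. **Compartment identification** (`geometry`).  Depth pixels higher than
   `height_threshold_mm` above the desk plane are kept; after morphological
   opening and 8-connected labelling, the largest raised region is the box
   rim-plus-partition structure and its two enclosed holes are the
   compartment interiors.  The compartment whose interior contains (near)
   zero raised pixels is the empty one; its rectangle, identical in the
   registered colour image, is the counting ROI (about 330×330 px at the
   default scale).  A test stage refuses to start unless exactly one
   compartment is empty.
2. **Colour markers** (`colourlab`).  Five class prototypes — red, blue,
   yellow, green, beech background, labelled 1, 2, 3, 4 and 0 — are each a
   mean CIELab triple.  Cube markers are calibrated from scenes with five
   cubes of one colour at the four corners and centre of a compartment
   (deliberately non-uniform illumination); Canny edges delimit the cube
   boundaries and the interior pixels are averaged.  The background marker
   averages hand-picked box-floor positions.
3. **Classification** (`colourlab.nn_classify`).  Every ROI pixel receives
   the label of the nearest marker by Euclidean distance in the (a\*, b\*)
   plane:

       d² = (a*ₚᵢₓₑₗ − a*ₘₐᵣₖₑᵣ)² + (b*ₚᵢₓₑₗ − b*ₘₐᵣₖₑᵣ)²

   L\* is ignored by construction, which is what makes the labels invariant
   to uniform lightness changes (ambient light, glossy reflections).  With
   the default palette the five markers are ≥ 48 Lab units apart in the
   chroma plane while a ±15 % illumination change moves chroma by ≤ 9
   units, so the assignment has a wide margin.
4. **Counting** (`counter`).  Per colour, 8-connected regions of the label
   map are measured; regions below half a reference cube face are noise;
   each surviving region contributes `round(area / single_cube_area)` cubes
   (minimum 1), so touching groups are resolved by area.  Frame counts feed
   a per-colour running maximum: the global counter only increments, making
   it robust to frames in which a hand occludes already-counted cubes.
   Each increment is recorded as a detection event with the frame
   timestamp.
5. **Validation and outcomes** (`scoring_outcomes`).  Events closer than
   1 s to the last kept event are collapsed (a multi-cube grasp scores
   one).  The validated stream yields the stage score NC, the average
   displacement velocity `Vavg` — the slope of the least-squares line
   through the origin, `NC = Vavg·t`, i.e. `B = ΣtᵢNCᵢ / Σtᵢ²` — and the
   partial times PT between consecutive detections (mean and population
   standard deviation).
6. **Study statistics** (`study_stats`).  Packaged CSV transcriptions of
   the pilot-study tables (9 participants with Parkinson's disease × 3
   sessions × 2 hands = 54 trials) support the reliability analysis:
   per-trial error ε = (manual − automatic)/manual, per-hand mean success
   ratios, the lost-cube histogram, and Spearman rank correlations between
   automatic and manual scores and between the manual score and `Vavg`.

## Synthetic scenes

`scene_synth` stands in for the depth camera.  The projection is
orthographic top-down with a single scale (330 px per 290 mm compartment
side, i.e. one cube face ≈ 28×28 px); a perspective model would add nothing
that can be verified in closed form.  A scene is piecewise constant: desk
plane, box rim and partition raised 100 mm, compartment floors, and cubes
raising the depth surface by `layer × 25 mm`.  Illumination is a
multiplicative gain — a global scalar, an optional smooth linear gradient
across the image with a seeded random orientation, and per-cube zone gains
in calibration scenes (0.88–1.12) so the calibrated tone is averaged over
non-uniform lighting, as on a real desk.  Pixel noise is additive Gaussian
in sRGB, clipped to [0, 255].  Scripted sessions expose exact ground truth
(per-frame, per-colour cube counts), which every counting test asserts
against.

What the generator deliberately does **not** model: perspective and lens
distortion, depth sensor noise and missing-range speckle, shadows,
specular highlights, motion blur of the moving hand, and partial occlusion
geometry other than a flat skin-coloured blob.  Passing tests therefore
demonstrate the correctness and internal robustness of the algorithm (to
pixel noise, illumination gradients, transient occlusion and touching or
stacked cubes), not performance on real sensor data.

## Parameters and defaults

| parameter | default | why |
|---|---|---|
| sensor height | 800 mm | fixed camera mount above the desk |
| compartment side | 290 mm, → 330 px | physical box; design ROI size |
| cube side | 25 mm (28 px) | physical cubes |
| rim/partition height | 100 mm | physical box |
| `height_threshold_mm` | 60 | keeps the 100 mm rim, drops desk, box floor and single loose 25 mm cubes; the original threshold was tuned empirically and never published |
| `occupancy_height_mm` | 12 | about half a cube: a pixel this far above the floor is cube material |
| `emptiness_area_px` | 400 | half a cube face: below this raised area a compartment counts as empty |
| morphology radius | 1 px opening | minimal noise cleanup that cannot erase a cube |
| noise cutoff | 0.5 × cube face | smaller label regions are speckle |
| validation window | 1.0 s | a healthy cube transfer takes about a second |
| sRGB noise sd | 4 (study conditions) | moderate camera noise |
| illumination gradient | 0.85–1.15 | ambient light falling off across a desk |
| frame rate | 4 fps | throughput of the original processing loop |

## Numerical and design choices

- **Colour conversion**: sRGB → XYZ (D65, 2° observer) → CIELab via
  scikit-image; the conversion standard was not named in the original
  description and D65/2° is the sRGB default.
- **NN ties** go to the lowest label integer (background first).  Squared
  distances are compared — monotone equivalent of the Euclidean rule.
- **Canny calibration edges** are detected on the a\* and b\* channels
  (normalised to [0, 1], σ = 1, thresholds 0.02/0.05) rather than
  luminance, because a cube colour can be nearly isoluminant with the
  beech floor (yellow is) while its chroma contrast is large.
- **Reference cube area** is measured in two passes: Canny interiors give
  the marker colours; the area is then re-measured from the classified
  label map of the calibration ROI, the same measurement the counter makes
  at run time, so a single cube's area ratio is centred on 1 and a group of
  n cubes divides to n.
- **Monotone counter**: the published description says only that a global
  counter is incremented frame by frame; a per-colour running maximum is
  the only monotone rule consistent with that and with transient occlusion.
  Its price is that cubes are never un-counted — removal is out of scope
  (cubes only accumulate during a stage).
- **Group rounding** is round-half-up with a minimum of one per surviving
  region.
- **Validation anchoring**: the <1 s window is anchored to the last *kept*
  event, not a fixed grid; with a fixed grid a slow train of grasps could
  collapse incorrectly.
- **Through-origin regression**: x is detection time, y cumulative count.
  The source text swaps the axis assignment once before settling on this
  one; the settled (final) assignment is implemented.  Zero-event stages
  report `Vavg = 0` by convention rather than an undefined slope.
- **PT dispersion** is the population (divide by n) standard deviation.
- **ε recomputation**: three printed ε cells in the packaged trial table
  are typographic (0.038, 0.003, 0.008 where the counts give 0.138, 0.103,
  0.108); ε is always recomputed from the counts, which is also the only
  way the published summary statistics are reproduced.  Success per hand is
  the mean of per-trial ratios, not the pooled-count ratio.
- **Multi-cube grasps**: one test rule says extra simultaneous cubes are
  subtracted, the automated rule says they count as one; the automated rule
  (collapse to one) is implemented.
- **Empty training box**: if *both* compartments are empty (no cubes
  anywhere, as in a training stage on a cleared box) the session runner
  scores the planned target side instead of refusing — the refusal is
  reserved for the ambiguous both-occupied case.

## Known limitations

- Fully stacked cubes (a second layer directly over the first) are
  invisible from above and under-counted; the tests assert the undercount
  is never an overcount.  This mirrors the documented failure mode of the
  physical system.
- Spearman correlation between the manual score and `Vavg` recomputed from
  the packaged outcome table (3-decimal velocities) is 0.954; the published
  0.94 is not reproducible from the printed data (the mean of the per-hand
  coefficients, 0.91 and 0.96, rounds to 0.94, suggesting a different
  aggregation).  The corresponding acceptance test is kept at printed
  precision and fails; everything else in the reliability analysis
  reproduces exactly.
- The benchmark in `abbt.benchmark` (20 sessions, 1–35 cubes, 60 s at
  4 fps) uses problem sizes chosen to exercise the full score range of the
  physical test while keeping a complete run to a few minutes on one core.
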