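# abbt — Automated Box and Blocks Test

The Box and Blocks Test (BBT) is a validated clinical measure of unilateral
gross manual dexterity, widely used in neurological rehabilitation (stroke,
Parkinson's disease, multiple sclerosis): the score is the number of 25 mm
wooden cubes a person moves from one compartment of a two-compartment box
over a 100 mm partition in 60 seconds.  Manual administration is
labour-intensive and the therapist's count can err.  `abbt` implements an
automated scoring pipeline for the test, built for a top-down RGB-D camera
fixed 80 cm above the desk, together with synthetic scene generation for
validation and the reliability statistics of a 9-participant, 3-session
pilot study (54 trials).

The pipeline, per video frame:

1. **Compartment detection** — threshold depth at 60 mm above the desk,
   label the raised box structure, take its two enclosed holes as the
   compartment interiors, pick the empty one; its rectangle is the colour
   region of interest (ROI, ≈ 330×330 px).
2. **CIELab nearest-neighbour classification** — each of five calibrated
   colour markers (red, blue, yellow, green cubes and the beech floor,
   labels 1–4 and 0) is a mean (L\*, a\*, b\*); every ROI pixel gets the
   label of the marker minimising

   d² = (a\*_pixel − a\*_marker)² + (b\*_pixel − b\*_marker)²

   Lightness L\* is deliberately excluded, so the classification is
   insensitive to ambient-light changes.
3. **Area-based counting** — connected regions per colour; touching groups
   count as `round(area / single-cube area)`; a per-colour running maximum
   makes the global counter monotone under transient hand occlusion.
4. **Score validation and outcomes** — detections less than 1 s apart
   collapse to one (multi-cube grasp).  Each stage reports the cube count
   NC, the average displacement velocity `Vavg` (slope of the
   through-origin regression `NC = Vavg·t`, in cubes/s) and the partial
   times between consecutive cubes (mean ± population SD).

See `docs/methods.md` for models, parameter defaults and design decisions.

## Worked example

End-to-end synthetic run — calibrate markers, render a three-stage session
(15 s training, 60 s per hand, 6 scripted cubes per scoring stage), count:

```sh
$ abbt demo --seed 7 --cubes 6 --fps 1 --out-dir demo_out
training      NC=  0  Vavg=0.000 cubes/s  PT=- s
dominant      NC=  6  Vavg=0.720 cubes/s  PT=1.40+/-0.49 s
non_dominant  NC=  6  Vavg=0.720 cubes/s  PT=1.40+/-0.49 s
ground truth: 6 cubes per scoring stage (seed 7); artefacts in demo_out
```

All six scripted cubes are recovered in each scoring stage (NC = 6, exactly
the ground truth).  `Vavg = 0.720` cubes/s is the through-origin slope of
cumulative count against detection time; the partial times say consecutive
cubes arrived 1.40 s apart on average with 0.49 s dispersion.  Stage
results and the marker set are written as JSON.

Reliability analysis of the packaged 54-trial pilot-study tables:

```sh
$ abbt analyse
trials analysed:                 54
mean manual count:               45.8 cubes
success, dominant hand:          93.45 %
success, non-dominant hand:      94.42 %
maximum per-trial error:         13.8 %
median cubes lost per trial:     3
Spearman auto vs manual (all):   0.980  (p = 2.5e-38)
Spearman auto vs manual (DH):    0.967
Spearman auto vs manual (NDH):   0.978
Spearman manual vs velocity:     0.954
lost-cube histogram (lost: trials): 0: 5, 1: 5, 2: 13, 3: 13, 4: 12, 5: 4, 6: 1, 7: 1
```

The automatic counter only ever loses cubes (median 3 per trial, the main
cause being layer-by-layer stacking), yet its scores correlate very
strongly with the manual count (rank correlation 0.98 over all trials).

Other subcommands: `abbt simulate` (render a scripted session to PNG + CSV),
`abbt calibrate` (marker JSON from synthetic calibration scenes) and
`abbt count` (run the pipeline over a stored session; also writes the
detected compartments as JSON and the ROI as PNG).

All pipeline commands accept `--config FILE` with a JSON object of up to
two sections whose keys override the corresponding defaults — `"scene"`
(fields of `abbt.SceneConfig`: geometry in mm, `palette`,
`illumination_gain`, `illumination_gradient`, `noise_sd`, `rng_seed`, ...)
and `"geometry"` (fields of `abbt.GeometryConfig`: `height_threshold_mm`,
`min_region_area_px`, `morphology_radius_px`, ...).  For example:

```json
{"scene": {"noise_sd": 2.0, "illumination_gradient": [0.9, 1.1]},
 "geometry": {"height_threshold_mm": 55.0}}
```

Command-line `--seed`/`--noise-sd` take precedence over the file.

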