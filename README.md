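# proxhum

Three-dimensional morphometry of the normal proximal humerus on
segmented surface meshes, with simulated anteroposterior (AP)
radiographs and the reproducibility statistics that go with a
morphometric study.

Accurate prosthesis selection in shoulder arthroplasty depends on the
normal anatomy of the proximal humerus, which is classically quantified
by five parameters measured on 3-D CT reconstructions. `proxhum`
implements that measurement scheme as a tested, pose-invariant pipeline
for anyone who has a labelled bone surface (from CT segmentation or from
this package's own synthetic generator): orthopaedic researchers
validating measurement protocols, and methodologists studying the bias
of planar radiographs against 3-D measurements.

## The measurement model

Given a triangulated surface with per-vertex regions
(`articular_surface`, `greater_tuberosity`, `shaft`) and three manual
landmarks — C and D, the most superior and inferior points of the
articular margin, and E on its concave portion — the pipeline constructs:

* the **humeral shaft axis (HSA)**: the axis of the least-squares
  cylinder fitted to the shaft region, minimising
  Σᵢ (dist(pᵢ, axis) − r)² over orientation, position and radius;
* **plane 1**, the anatomic neck plane through C, D, E (normal toward
  the head);
* **plane 2** through G (most superior articular point) perpendicular to
  the HSA, and **plane 3** through the midpoint of CD with normal ∥ CD;

and measures

| parameter | definition |
|---|---|
| NSA  | neck–shaft angle, `α + 90°`, α the angle between plane 1 and the HSA |
| HHT  | humeral head thickness: distance from F (articular point furthest above plane 1) to plane 1 |
| TSH  | tuberosity-to-articular-surface height: axial offset of G above H (top of the greater tuberosity) |
| cASD | coronal articular-surface diameter, `|C − D|` |
| aASD | axial articular-surface diameter, `|I − J|`, where I, J are the crossings of plane 1 ∩ plane 3 with the articular rim |

A simulated radiograph is an orthographic projection onto the coronal
plane times a uniform film magnification (default 1.10); NSA₂, HHT₂,
TSH₂ and cASD₂ are re-measured on the projection with the usual film
conventions (shaft silhouette midline, projected neck segment).

The synthetic generator builds watertight labelled humeri (cylindrical
shaft, spherical or anteroposteriorly scaled articular cap cut by the
neck plane, lateral tuberosity) whose five parameters have closed-form
ground truth, plus cohort and rater simulators for sex comparisons,
modality comparisons, Pearson correlation structure and intra/
inter-observer ICC (two-way random effects, absolute agreement, single
measures), with Bonett-style precision planning of the reliability
subset. See `docs/methods.md` for the model details and assumptions.

## Worked example

Generate one synthetic humerus at 0.5 mm resolution, measure it in 3-D,
then re-measure its simulated AP film:

```sh
$ proxhum simulate -o demo --n 1 --seed 7 --resolution 0.5
wrote 1 bones + truth.csv to demo
$ proxhum measure demo/bone_000.ply -o demo/measured.csv
NSA 131.4 deg  HHT 19.9 mm  TSH 8.3 mm  cASD 45.8 mm  aASD 41.6 mm  -> demo/measured.csv
$ proxhum project demo/bone_000.ply -o demo/xray.csv
NSA2 131.4 deg  cASD2 50.4 mm  -> demo/xray.csv
```

The measured values match the generator's ground truth
(`demo/truth.csv`: NSA 131.40°, HHT 19.90 mm, TSH 8.33 mm, cASD
45.82 mm, aASD 41.59 mm); the film cASD₂ of 50.4 mm shows the ~10%
magnification bias of the radiograph relative to the 3-D measurement of
45.8 mm, while the projected angle is unchanged. `measured.csv` also
records the shaft-fit diagnostics and all derived landmarks, and every
run writes a `*.meta.json` with the exact configuration and seed.

`proxhum reproduce-tables --seed 0 -o out/` runs the whole study in
silico — a 54 M / 66 F cohort, both modalities, three raters with a
36-subject reliability subset — and writes the summary, comparison,
correlation and ICC tables as CSV.

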