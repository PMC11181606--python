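# Methods

## Problem and measurement model

Transtibial PCL reconstruction drills a tunnel from the anterior proximal
tibia to the tibial PCL footprint. The package simulates the standard
morphometric measurement of that tunnel on 3D bone surfaces:

* **Plateau plane.** The reference plane is defined by three tangent
  landmarks of the medial plateau rim — the most anterior, most medial and
  most posterior rim points. On a mesh these are found as extremal rim
  vertices along the anatomical AP/ML axes; after a provisional plane fit
  the extremes are re-computed once with the axes projected into that
  plane. The circumscribed circle of the three points (the manual "best-fit
  circle" aid) is retained only as a QC diagnostic. The clinical
  construction does not specify whether the circle is inscribed or merely
  tangent near the extremes; the extremal-point reading is adopted.
  The medial/lateral split of the articular surface runs through the
  sagittal plane at the centroid of the proximal articular patch
  (face normals within 25° of the superior axis, largest connected
  component) — the split itself has no published computational definition.
* **Oblique section.** For tunnel angle TTA ∈ (0°, 90°), the section plane
  contains the PCL attachment (tunnel exit), its intersection with the
  plateau plane is parallel to the ML axis (the inclination is realised in
  the lateral view), and it descends anteriorly; its normal is
  `sin(TTA)·a + cos(TTA)·n`. Angles of exactly 0° or ≥ 90° are rejected:
  the vertical limit produces a section that never reaches the anterior
  cortex, so no entry point exists.
* **Crest point and entries.** The crest ("TTA") point is the most anterior
  vertex of the oblique cortical contour; ties within 1 µm are resolved to
  the vertex nearest the middle of the tied span, which makes the choice
  deterministic on symmetric bones. The 2-cm entry offset is laid off as
  **arc length along the cortical outline** so the entries stay on bone
  (the printed protocol marks them on the cross-section outline); a
  chord-distance alternative is available (`entry_mode="chord"`) for
  sensitivity analysis, and the two coincide on flat faces.
* **Outcomes.** TTL is the Euclidean entry–exit distance; TTH the unsigned
  perpendicular distance of the entry to the plateau plane (a warning is
  emitted if an entry lies proximal to the plateau — anatomically
  impossible, so it signals bad landmarks). The nominal TTA belongs to the
  section plane; because the entries sit 2 cm off-midline the true 3D
  inclination of the tunnel axis differs slightly and is reported as a
  diagnostic column.

Internal chirality is fixed: right-handed frame, +Z proximal, +Y anterior,
+X lateral-for-right-knee. Left knees are mirrored into this convention
before processing (AM/AL labels refer to the subject's own medial/lateral
sides), which removes all side-specific code paths; mirroring a bone
without relabelling swaps AM and AL exactly, which is tested.

## Synthetic tibia generator

Real CT meshes cannot be redistributed, so the cohort is synthetic. A bone
is a loft of transverse cortical outlines: a superellipse (exponent 2.5)
whose posterior half tapers exponentially into the shaft while the anterior
half recedes **linearly** with depth, carrying a Gaussian crest bump of
constant prominence. The linear anterior profile is the load-bearing shape
choice: the per-angle entry depths implied by the reference outcome tables
(TTH 42.7 → 71.6 mm across 40–60°) correspond to an anterior cortex that
retreats almost linearly at ≈ 0.25 mm per mm of depth, which an
exponential taper cannot reproduce. The crest bump is centred on the
sagittal midline so the two arc walks from the crest are mirror-symmetric;
the AM−AL length difference is then carried entirely by the lateral offset
of the PCL attachment (5.1 mm), giving a stable 2–3 mm gap rather than one
dominated by mesh-grid noise at the crest argmax.

Ground truth is exact by construction: the plateau is the flat top cap at
z = 0 (plane normal +Z), the shaft axis leans anteriorly by the posterior
slope angle (default 7°), and the PCL attachment is an exact mesh vertex at
the configured depth (default 10 mm) below the plateau. Default mesh
resolution is 2 mm level spacing × 128 circumferential samples (~10 k
vertices); the prism oracle shows the measurement chain is exact on flat
geometry at any resolution, and landmark recovery errors at this resolution
are an order of magnitude below the 1 mm acceptance tolerance. Resolution
is a parameter (`level_mm`, `n_theta`) for convergence studies.

Base dimensions (plateau 76 × 52.7 mm, anterior share 0.52, crest
prominence 4.6 mm, anterior recession 0.25) were calibrated once by least
squares so the scale-1 bone reproduces the reference per-angle TTH/TTL
means and AM−AL gaps, then frozen.

## Cohort model

Covariates emulate the reference population: 31 male / 32 female knees,
ages ≈ N(34, 8) truncated to 18–49 y, heights N(177, 8) (male) and
N(158.2, 8) cm (female), BMI N(23.6, 3.7), random knee side. A latent
skeletal scale drives all TTL-relevant dimensions:

```
s = base(sex) · (1 + κ·(h − 167.4)/167.4 + age_effect·(age − 34) + η)
```

κ is solved so that corr(height, s) equals `height_size_corr`; η absorbs
the remaining anatomical variance up to `scale_rel_sd` (default 0.065);
`age_effect` (−0.003/yr) yields the weak negative age–TTL correlation; BMI
enters with coefficient 0, reproducing the null BMI association. Because
the residual sex factor is itself height-correlated through sex, κ, the
factor and η are solved jointly from the exact two-point-mixture moments
(fixed-point iteration), so the configured correlation is realised to
within truncation effects. `height_size_corr` defaults to 0.74: geometric
noise downstream (marking jitter, slope/depth variation, mesh
quantisation) dilutes the latent coupling, and 0.74 places the *measured*
height–TTL correlation mid-way in the reported 0.63–0.72 band.
`sex_scale_ratio` (1.086) is the male/female mean scale ratio, calibrated
so the per-angle male−female TTL gap lands in the reported 5.2–7.5 mm
range — TTL is slightly superlinear in scale (the entry deepens as the
bone grows), so the ratio is smaller than the gap alone would suggest. Small per-subject noise
(`noise_sd_mm`, 0.8 mm) perturbs the PCL depth, crest prominence, posterior
slope and AP aspect. All randomness flows from one cohort seed through
counter-derived child seeds.

What the generator does **not** emulate: real cortical shape variation
(no statistical shape model), osteophytes or plateau asymmetry, soft
tissue, and any direct bone-dimension distributions (none are published for
the reference cohort — the generator is calibrated to outcome tables, not
to anatomy). Passing tests therefore demonstrate correctness of the
measurement and statistics machinery and plausibility of the cohort-level
structure, not anatomical fidelity of individual bones.

## Observer model and ICC

The printed protocol repeats the full manual procedure twice per surgeon
plus once by a second surgeon. Here each session re-runs every
landmark-dependent stage after isotropic Gaussian jitter (σ = 0.5 mm per
axis) of the manually-placed landmarks (PCL point and the three tangent
points), with session-specific seeds. ICC(2,1) — two-way random effects,
absolute agreement, single measure, the standard model for test–retest of
continuous measurements; the variant is selectable — is computed on TTL
over all subject × approach × angle units. With 0.5 mm marking noise
against ~8 mm between-knee spread the ICC lands around 0.98, inside the
"excellent" (> 0.90) band; larger σ values push it down roughly as
σ²_b/(σ²_b + σ²_w).

## Statistical layer

* Normality screening uses the KS statistic with the Lilliefors correction
  (parameters are estimated from the sample); the naive KS p-value is an
  option. The screen gates Pearson vs Spearman per variable pair.
* Correlation strength labels partition |r| at 0.1/0.3/0.7 with intervals
  closed on the left: [0.1, 0.3) weak, [0.3, 0.7) moderate, [0.7, 1]
  strong, below 0.1 negligible.
* OLS fits (scipy) report slope, intercept, r² and residual SD
  = √(SSE/(n−2)). In the balanced design (every subject measured at every
  angle) the pooled slope equals the slope through per-angle means — an
  identity exploited to re-derive the published equation slopes from the
  published mean tables.
* Safety rate: P(predicted TTL − actual TTL ≤ 8 mm). Both an empirical
  proportion and the normal-model tail Φ(8/residual SD) are reported; the
  empirical rate is the headline since the reference computation is not
  further specified. Predictions outside 35–65° raise an extrapolation
  flag.
* Group comparisons use the pooled-variance independent t-test, two-sided,
  α = 0.05, no multiple-testing correction (matching the reference
  analysis).
* ICC requires ≥ 5 subjects and 2 complete columns; agreement bands are
  < 0.50 poor, [0.50, 0.75) moderate, [0.75, 0.90] good, > 0.90 excellent.

## Numerical choices

* Contours are polylines with linear interpolation; arc length is polyline
  length. Mesh resolution, not spline fitting, controls accuracy.
* Extremal-point ties (plateau landmarks, crest point) break to the vertex
  nearest the tie-span centre, tolerance 1e-6 mm.
* Section contours keep the outer (largest-perimeter) closed loop, oriented
  counter-clockwise about the plane normal; planarity is exact to 1e-6 mm.
* The prism oracle (`prism_expected`) is straight trigonometry worked by
  hand: the 45° section of the documented prism gives entries
  (∓20, 30, −80), TTL = √10200 ≈ 100.995 mm, TTH = 80 mm; the mesh
  pipeline must match within 0.1 mm.
* Problem sizes: the shipped analyses use the 63-knee cohort at the default
  mesh resolution (≈ 10 k vertices/bone, 15 sections/knee over three
  sessions); Monte-Carlo checks use 10 seeded cohorts, 500 regression
  replicates, and 10⁵-sample tail estimates — sizes at which the reported
  bands are stable to well under their tolerances.

## Known limitations

* The generator is outcome-calibrated; its bones are smooth idealisations
  and per-bone dimensions should not be interpreted anatomically.
* Empirical safety rates on 63-knee cohorts are coarse (n ≈ 155–160 per
  stratum ⇒ ~1-subject granularity of 0.6 %); the reference values near 99 %
  imply residual SDs (~3.4 mm) slightly below what this cohort model
  produces (~4–5 mm), so simulated rates sit a few points lower.
* The ICC depends directly on the assumed 0.5 mm marking noise; it is a
  demonstration of the reproducibility machinery, not an estimate of human
  inter-observer variability.
* No drill diameter, soft tissue, or popliteal-artery geometry is modelled;
  the 8-mm safe distance is an imported constant.
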