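# pcltunnel

In-silico surgical planning for **transtibial posterior cruciate ligament
(PCL) reconstruction**: how deep may the surgeon drill the tibial tunnel
before the bit exits the posterior cortex next to the popliteal
neurovascular bundle?

During this operation a tunnel is drilled through the anterior tibia to exit
at the tibial PCL footprint. Over-penetration is the classic mechanism of
popliteal artery injury, so the **tibial tunnel length (TTL)** — the
distance from the anterior entry point to the PCL attachment — is the
number a surgeon wants before drilling. `pcltunnel` rebuilds the 3D
measurement procedure used in morphometric CT studies of this problem and
exercises it on a fully synthetic cohort of parametric tibiae:

1. the **tibial plateau plane** is recovered from the medial plateau rim via
   its three tangent landmarks (most anterior, most medial, most posterior
   points — the "best-fit circle" construction);
2. for each **tibial tunnel angle (TTA**, 40–60°**)** an oblique section
   plane is passed through the PCL attachment, hinged parallel to the
   medio-lateral axis and inclined TTA to the plateau;
3. on the oblique cortical cross-section the most anterior **crest point**
   is found and the **anteromedial (AM)** and **anterolateral (AL)** entry
   points are placed 2 cm medial/lateral of it along the cortical outline;
4. **TTL** (entry–exit distance) and **TTH** (perpendicular entry height
   below the plateau plane) are measured;
5. the statistical layer fits the per-stratum prediction equations
   `TTL = a·TTA + b`, screens covariate correlations (normality-gated
   Pearson/Spearman), computes the 8-mm **safety rate**
   (empirically, and as Φ(8 mm / residual SD)), and quantifies
   test–retest reproducibility with **ICC(2,1)**.

Because no CT meshes are distributable, the package ships a parametric
proximal-tibia generator (lofted superellipse outlines with an anterior
crest, exact ground-truth landmarks) plus an analytic prism solid whose
tunnel geometry is known in closed form — every geometric stage is testable
against construction ground truth or hand trigonometry.

## Worked example

```sh
python analysis/02_simulate_tunnels.py --seed 0
python analysis/03_cohort_statistics.py --seed 0
```

prints, for the default 63-knee cohort (31 male / 32 female):

```
  TTA       TTL AM       TTL AL   gap     TTH
   40   55.9± 4.3   52.7± 4.4  3.12    42.7
   45   58.5± 4.7   55.7± 4.7  2.88    48.2
   50   62.2± 5.1   59.6± 5.2  2.60    54.6
   55   67.3± 5.7   65.0± 5.7  2.29    62.3
   60   74.8± 6.8   72.8± 6.9  1.94    72.3

prediction equations (TTL from TTA):
  female_AL    Y = 0.94X + 11.55  r² = 0.63
  female_AM    Y = 0.88X + 17.05  r² = 0.62
  male_AL      Y = 1.05X + 11.74  r² = 0.73
  male_AM      Y = 0.99X + 17.29  r² = 0.71
safety rates (8 mm):
  female_AL    empirical 91.2%  normal-model 94.3%
  ...
intra_observer: ICC = 0.976 (excellent)
```

Reading: a steeper tunnel is a longer tunnel (~1 mm of TTL per degree of
TTA), the AM approach runs 2–3 mm longer than AL (the PCL facet sits
slightly lateral of the crest), male tunnels are 5–8 mm longer than female
ones, and drilling to the equation-predicted depth stays clear of the 8-mm
popliteal safety margin in ≳90 % of knees. Tables land in
`results/measurements.csv`, `results/report.json` and `results/report.md`.

A `pcltunnel` console command wraps the same steps (`synth`, `measure`,
`run`, `stats`) for use on external STL/PLY meshes with a landmark JSON.

## Layout

| Path | Content |
| --- | --- |
| `src/pcltunnel/synthetic.py` | parametric tibia generator, prism oracle, cohort sampler, observer jitter |
| `src/pcltunnel/geometry.py` | anatomical frames, plateau rim extraction, tangent-point plane fit |
| `src/pcltunnel/tunnel.py` | oblique sectioning, crest point, AM/AL entries, TTL/TTH |
| `src/pcltunnel/stats.py` | correlations, OLS equations, safety rate, ICC(2,1) |
| `src/pcltunnel/pipeline.py` | cohort runs, mesh/landmark I/O, report tables |
| `src/pcltunnel/reference.py` | published reference-table values used as validation inputs |
| `analysis/` | numbered drivers writing `results/` |
| `docs/methods.md` | model assumptions, parameter choices, limitations |
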