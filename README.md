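# rdtsim

Virtual simulation of broken-instrument removal from the mesiobuccal (MB)
canal of a maxillary first molar, built to quantify how badly periapical
radiographs estimate the **minimum remaining dentin thickness (RDT)** — the
number a clinician looks at before deciding whether retrieving a separated
file risks perforating the root.

The package is aimed at endodontic researchers and at anyone who needs a
tested, seeded voxel-geometry sandbox for access-cavity planning: it
generates parametric tooth phantoms, simulates the removal procedure in 3D,
renders radiographs, and compares the three RDT estimates the clinic has
available.

## What it computes

For a (synthetic or supplied) labelled tooth volume:

1. **Fragment**: a 3 mm apical segment of a size 25, 0.06-taper rotary file
   is placed in the canal with its coronal end 3 or 5 mm below the orifice.
   Its coronal diameter follows the linear taper law
   `D_b = d_tip + taper · L = 0.25 + 0.06 × 3 = 0.43 mm`.
2. **Removal**: a Gates-Glidden #4 staging platform is carved down to the
   fragment, then an ultrasonic trough of diameter
   `D = D_b + 2 D_c = 0.43 + 2 × 0.40 = 1.23 mm` and depth 1.5 mm is carved
   around it.
3. **3D-RDT** (the gold standard): a Euclidean-distance-transform thickness
   map from the prepared cavity wall to the external root surface; its
   minimum over the trough's axial span.
4. **Pa-RDT / An-RDT**: parallel-beam digitally reconstructed radiographs at
   0° (paralleling) and at the parallax angle that frees the MB root from
   palatal-root overlap; the access corridor is summarised by a rectangle of
   width `D` and height `depth + 1.5 mm` (4.5 × 1.23 mm and 6.5 × 1.23 mm),
   and the RDT is the minimum distance from the rectangle's side to the
   root edge.
5. **Agreement statistics**: balanced two-way ANOVA (method × depth),
   Dunnett comparisons against the 3D standard, two-way single-measure ICCs
   (consistency and absolute agreement), and the coefficient of variation.

The synthetic phantom carries a furcal-side concavity of the MB root that
faces the x-ray beam of the paralleling view.  Because it is invisible in
that silhouette, the 0° radiograph systematically *overestimates* the true
minimum wall thickness; the angled view partially reveals it.

## Worked example

```bash
rdtsim run --n 2 --seed 5 --out results/demo
```

prints (values in μm; two phantoms at 60 μm voxels, so expect ±1 voxel):

```
records: 20; failed phantoms: 0
mean 3D_3mm: 523 um
mean 3D_5mm: 423 um
mean An_3mm: 579 um
mean An_5mm: 485 um
mean Pa_3mm: 628 um
mean Pa_5mm: 508 um
```

Reading it: the paralleling estimate (`Pa`) exceeds the 3D ground truth by
~100 μm at both fragment depths — an over-optimistic wall-thickness reading
exactly where perforation risk is judged — while the angled estimate (`An`)
lands between the two.  Deeper fragments (5 mm) leave less wall than
shallow ones.  `results/demo/` contains the tidy per-phantom records, the
ANOVA/Dunnett/ICC tables, the per-phantom parallax angles and a JSON
summary.

The same pipeline is available in Python:

```python
from rdtsim import RunConfig, run_pipeline
result = run_pipeline(RunConfig(n_phantoms=36, seed=1, voxel_size_um=60.0))
print(result.summary["icc_consistency"])
```

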