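# femur3d — automated 3D femoral morphometry

`femur3d` measures the two headline angles of proximal femoral anatomy from
triangulated surface models of a femur (outer cortical surface plus the
inner cortical / medullary-canal surface, mm units):

* the **neck-shaft (CCD) angle** — the full 3D angle between the femoral
  neck axis and the proximal shaft axis (≈ 122° in adults), and
* the **femoral torsion (anteversion)** — the acute angle between the neck
  axis projected into the transversal plane and the posterior intercondylar
  tangent ("table-top") line, signed positive for anteversion and negative
  for retroversion (≈ 14° in adults, with a minority of retroverted hips).

It is written for researchers in orthopedics / skeletal morphometry who
want fully automated, observer-independent angle measurements on segmented
CT bone surfaces, together with the nonparametric statistics used to
characterize these angles in large cohorts.

## The measurement model

All quantities are derived from the surface geometry alone:

1. **Bone length** `L` = distance from the tip of the greater trochanter to
   the facies patellaris saddle point (landmarks from a sidecar file, or
   heuristic detection).
2. **Proximal shaft axis** = the line through the centroids of the inner
   cortical (medullary canal) cross sections at 0.25 L and 0.35 L — below
   the lesser trochanter, above the bowed middle third.
3. **Head center** `c` = center of a least-squares sphere fitted to the
   articular head surface (algebraic fit, iterated with residual trimming).
4. **Neck isthmus** = the minimal cross section of the neck, found by an
   iterative sweep of section planes perpendicular to the current neck
   direction; its centroid `i` anchors the neck.
5. **Neck axis** = the line `i → c`.
6. **Condylar tangent** = the 2D convex-hull edge of the distal 25 % of the
   bone (projected along the shaft axis) whose outward normal points
   posterior and whose support points span both condyles.
7. The **transversal plane** is perpendicular to the shaft axis; CCD is the
   3D angle ∠(neck, shaft) without projection; torsion is the acute angle
   between the projected neck axis and the condylar tangent, signed by the
   anterior/posterior position of the projected head end. Right femurs are
   mirrored to the left-femur convention first.

A parametric synthetic-femur generator (implicit-surface union extracted by
marching cubes, watertight by construction) provides femurs whose true CCD
and torsion are known *exactly* from the construction, plus a cohort
simulator that emulates the covariate structure of a large adult left-femur
CT population. The `stats` layer reproduces the standard reporting battery:
median (IQR) summary tables by sex and ethnicity, Mann–Whitney U and
Wilcoxon signed-rank tests, Spearman correlations, retroversion and
age-band sub-analyses.

## Worked example

```python
from femur3d import SyntheticFemurSpec, generate_femur, measure_femur

bone, truth = generate_femur(SyntheticFemurSpec(ccd_deg=125.0,
                                                anteversion_deg=15.0, seed=7))
m = measure_femur(bone)
print(f"CCD {m.neck_shaft_angle:.2f} deg  torsion {m.torsion:+.2f} deg "
      f"retroverted={m.retroverted}")
```

prints

```
CCD 125.00 deg  torsion +15.00 deg retroverted=False
```

— the pipeline recovers the generator's exact ground truth to a few
thousandths of a degree on noiseless meshes at the default 1 mm voxel
resolution. The same chain runs from files:

```bash
femur3d simulate --n 5 --seed 3 --out fixtures/
femur3d cohort --dir fixtures/ --out measurements.csv
femur3d stats --table measurements.csv --out reports/
```

The numbered scripts under `analysis/` run the full study pipeline on a
simulated 1070-subject cohort: `01_simulate_cohort.py` (truth table +
fixture meshes), `02_measurement_validation.py` (angle-recovery errors;
mean ≈ 0.001°, max ≈ 0.006° on the noiseless grid),
`03_cohort_statistics.py` (summary table — e.g. median CCD 122.3°, torsion
14.5°, 6.4 % retroverted, female–male torsion gap ≈ 4.8° in the seed-42
cohort — with Mann–Whitney p-values), and `04_age_trends.py` (decade-wise
trend table and scatter). Tables land in `results/`.

Raw per-subject tables from other studies can be analyzed directly; the
reader is mapping-driven (`femur3d stats --table raw.xlsx --column-map
map.yaml`), so any column layout with a legend can be ingested.

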