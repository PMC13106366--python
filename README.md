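# phenocloud

High-throughput field phenotyping from 3-D point clouds of row-crop plots.

Breeding trials need per-plant traits — plant height, cotyledon (first) node
height, leaf count and leaf area — for hundreds of plants per plot, but field
reconstructions (e.g. from Gaussian-splat scenes of smartphone video) deliver
one tangled cloud of an entire plot: entangled canopies, a ground plane of its
own color, and sensor noise. `phenocloud` turns such a cloud into per-plant
point clouds and trait tables without any training data or manual annotation,
exploiting two stable geometric priors of seedling-stage row crops: stems stay
laterally separated even when canopies touch, and each plant's canopy fits a
cone anchored at its stem.

## Pipeline

1. **Splat sampling** (optional): a Gaussian-splat scene file — anisotropic
   Gaussians G(x) = exp(−½ (x−μ)ᵀ Σ⁻¹ (x−μ)) with Σ = R S Sᵀ Rᵀ — is turned
   into a dense colored cloud by sampling each primitive in proportion to its
   opacity and size, rejecting draws with Mahalanobis distance above a
   threshold (default 3).
2. **Preprocessing**: RANSAC ground plane ax+by+cz+d=0, quaternion rotation of
   the ground normal **n** onto **t** = (0,0,1) (q = (cos θ/2, sin θ/2·**k**),
   **k** = **n**×**t**/|**n**×**t**|), statistical outlier removal, bilateral
   smoothing, and a hue-aware cloth-simulation filter (HCSF) that splits
   ground (GS) from plants (GP): points near the settled cloth are ground
   unless their HSI hue falls in the vegetation band.
3. **Localization**: a bare-stem height layer [L_l, L_h] (default 2–6 cm) is
   sliced and DBSCAN-clustered (ε = 1.2 cm, MinPts = 6, or the density-derived
   ε = (T·MinPts·Γ(n/2+1) / (m·π^{n/2}))^{1/n}); each cluster's mean (x, y)
   pinned at L_h is the plant's localization point A_pk and registry identity.
4. **Instance segmentation**: breadth-first region growing from each stem
   cluster inside a per-plant cylinder of radius r_k = R_hk·tan(α) (R_hk =
   measured plant region height, α = 35°). A neighbor joins when it is within
   δ = 1.5 cm, its normal agrees (|n_p·n_q| ≥ τ_N = 0.85, waived on
   quasi-linear structures), and it lies in the cylinder. Points reached by
   several plants in the same synchronized round are *contested* and settled
   by local leaf-plane fits (plane distance < γ₂, curvature within γ₁σ).
5. **Traits**: per plant, FCNH = z_fn − z_gd (lowest stem/branch node minus
   local ground datum), PH = z_msv − z_gd (apex minus datum), leaf clusters by
   stem-core removal + normal-coherent region growing, and per-leaf area by
   quadratic surface fit + trimmed Delaunay triangulation.
6. **Evaluation**: greedy IoU matching against ground-truth labels → TP/FP/FN,
   recall r = 100·TP/(TP+FN), precision p = 100·TP/(TP+FP), F = 2pr/(p+r),
   mIoU; convex-hull point densities D_sur = N/A_cs, D_vol = N/V_cv.

A seeded synthetic cotton-field generator (2 m × 2 m plot geometry, 0.66 m
row / 0.10 m plant spacing, entangled canopies, exact per-point labels and
analytic trait truth) makes the whole pipeline testable without field data.

## Worked example

```python
from phenocloud import (FieldSpec, generate_field, run_field_pipeline,
                        InstanceLabeling, extract_traits)
from phenocloud.evaluate import score_labeling
from phenocloud.traits import records_to_frame

cloud, truths = generate_field(FieldSpec(rows=3, cols=3, seed=7))
res = run_field_pipeline(cloud)
m = score_labeling(res.labeling(), InstanceLabeling(labels=cloud.labels))
print(f"instances: {len(res.registry)}  r={m.r} p={m.p} F={m.f}  mIoU={m.miou:.3f}")
records = extract_traits(res.labeling_gp, res.gp, res.gs, res.registry)
print(records_to_frame(records).round(4).to_string(index=False))
```

prints

```
instances: 9  r=100.0 p=100.0 F=100.0  mIoU=0.970
variety plot  plant_index  fcnh_m   ph_m  leaf_count  leaf_area_total_m2 flags
                        1  0.0535 0.3244           6              0.0087
                        2  0.0688 0.3365           6              0.0083
                        3  0.0518 0.2668           5              0.0091
                        ...
```

All nine plants of the simulated plot are found (r = p = F = 100 at the
instance level), matched plants overlap their ground truth at mIoU 0.97, and
each row reports that plant's cotyledon node height and plant height in
meters, its leaf count, and its total one-sided leaf area in m² (e.g. plant 1:
node at 5.4 cm, 32.4 cm tall, six leaves totalling 87 cm²).

The same stages are scriptable from the shell:

```sh
phenocloud synth --rows 3 --cols 3 --seed 7 --out field.ply --truth truth.csv
phenocloud segment field.ply --out labeled.ply --report report.json
phenocloud traits labeled.ply --ground gs.ply --out traits.csv
```

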