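# mitoquant

Quantification pipelines for fluorescence microscopy of mitochondria —
the kind of analysis done when studying mitochondrial dysfunction in
Gaucher-disease models (patient fibroblasts, CBE-treated cortical
neurons): per-cell mitochondrial morphometry and fragmentation
phenotyping, object-based LC3–mitochondria colocalization (mitophagy) in
neurites, and nanoscale 3D c-Abl cluster quantification on
expansion-microscopy volumes, together with the normalization and
group-comparison statistics used on the resulting per-replicate values.
A synthetic-scene generator with recorded ground truth makes every stage
testable without raw image data.

It is aimed at cell biologists who would otherwise run these steps as
ImageJ macros and want a reproducible, scriptable, tested equivalent.

## What it computes

**Confocal morphometry** (per cell, MitoTracker or TOM20 channel):
median z-projection → median filter (disk r = 1 px) → white top-hat
(disk r = 5 px) → Triangle auto-threshold → particle analysis. Reported
per cell: mean fluorescence intensity inside the mask measured on the
*unfiltered* projection, mitochondrion count *N*, individual and mean
areas (µm²). A fragmentation score

&nbsp;&nbsp;&nbsp;&nbsp;*s* = (area in objects < 1 µm²) / (total mitochondrial area)

classifies a cell as *fragmented* (s > 0.5) or *fused/intermediate*, a
quantitative surrogate for the blinded visual call; cohorts are
summarized as % fragmented cells.

**Mitophagy readout**: in a 30 µm neurite segment, a mitochondrion
(connected component of the thresholded MitoTracker mask) is
LC3-positive when it shares ≥ 1 voxel with the LC3 mask; the readout is
100·(positive)/(total).

**Expansion microscopy**: the gel's expansion factor is measured as an
area ratio; since isotropic expansion scales areas quadratically, voxel
sizes are calibrated by the linear factor √(A_post/A_pre). On the
calibrated c-Abl/TOM20 volume: cluster density *N/V* (µm⁻³), mean
cluster volume (µm³), association ratio |cAbl ∧ mito| / |cAbl ∧ ¬mito|,
and occupancy 100·|cAbl ∧ mito| / |mito| — all at biological scale.

**Statistics**: percent-of-vehicle and densitometry normalization,
autophagic index (p62 with/without bafilomycin A1), Welch's ANOVA with
Dunnett-style comparisons on unpooled standard errors, Kruskal–Wallis
with Dunn's post hoc, one-way repeated-measures ANOVA with Tukey or
Bonferroni post hoc. Biological replicates are the statistical unit;
technical replicates are averaged first.

## Worked example

```python
import mitoquant as mq

params = mq.MorphologyParams(mode="punctate", n_objects=50)
stack, truth = mq.generate_mito_scene(params, seed=1)

cell = mq.classify_fragmentation(mq.mito_pipeline(stack, cell_id="cell01"))
print(cell.n_mitochondria, round(cell.mean_mito_area_um2, 4),
      cell.mean_mito_intensity, cell.fragmentation_score, cell.fragmentation_class)
```

prints

```
50 0.1486 110.0 1.0 fragmented
```

All 50 simulated mitochondria are recovered; their mean area is
0.149 µm² (sub-µm² puncta), the masked intensity equals the rendered
amplitude + background (100 + 10), and every object sits below the 1 µm²
cut, so the fragmentation score is 1.0 and the cell is called
fragmented — as the generator's phenotype label says it should be.

The same workflows are available from a shell:

```sh
mitoquant simulate --kind mito --seed 1 --out scene.tif --truth truth.json
mitoquant mito-morph scene.tif
mitoquant exm volume.tif --area-pre 1.0 --area-post 16.0
mitoquant stats tidy.csv --test welch --posthoc dunnett --control vehicle
```

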