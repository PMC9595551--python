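# lacuna3d

Counting and morphometry of **osteocyte lacunae** in 3D micro-CT volumes of
bone, with a synthetic bone-phantom generator that provides planted ground
truth for validating every stage.

Osteocyte lacunae (OL) are the small cavities in mineralized bone matrix
that house osteocytes. Their concentration per mm³ differs strongly between
bone compartments — the inner layer of the petrous bone carries on the
order of 95,000 lacunae per mm³, roughly three times more than mastoid or
femoral cortical bone — which matters, for example, when asking which
skeletal elements start out with the most cellular DNA. `lacuna3d`
implements the quantification chain used for such comparisons and is aimed
at bone-microstructure researchers who want the procedure as a scripted,
reproducible pipeline instead of interactive image-analysis sessions.

## Method

Given a reconstructed grayscale volume with voxel spacing (s_z, s_y, s_x)
in μm (mineral bright, voids dark):

1. **Mean-threshold (MT) segmentation** — one global threshold per volume,
   T = mean(I); voxels with I < T are void. A fixed numeric threshold can
   be supplied instead (one threshold shared across samples); the value
   used is always recorded in the run report.
2. **6-connected component labeling** — voxels belong to the same object
   iff linked by face adjacencies. Labels are dense, assigned in
   first-voxel raster order (deterministic), and cross-checked in the test
   suite against an independent BFS flood-fill oracle.
3. **Volume-window filtering** — objects are kept if their voxel volume
   lies in 10–2000 μm³ (counting) or 20–2000 μm³ (morphometry); smaller
   objects sit at the resolution limit, larger ones are vascular canals
   and cavities, not lacunae.
4. **Concentration** — number of retained labels divided by the analyzed
   volume in mm³.
5. **Morphometry** — per label: volume V = N·s_z·s_y·s_x, centroid, maximum
   Feret diameter F_max (largest caliper distance), minimum orthogonal
   Feret diameter F_min⊥ (smallest caliper width in the plane perpendicular
   to the F_max direction, by rotating calipers), and the aspect ratio
   ψ_A = F_min⊥ / F_max ∈ (0, 1].
6. **Group comparison** — per-sample summaries (counts, concentrations,
   volume and ψ_A means ± SD) and fold-changes of mean concentration
   between bone-type groups.

The phantom generator plants non-overlapping ellipsoids (log-normal
volumes, truncated-normal aspect ratios, uniform orientations) and
super-cutoff cylindrical canals in a two-level volume, optionally degraded
by Gaussian blur and additive noise, and returns the exact roster of what
it planted — so recovered counts, concentrations and shape statistics can
be compared against known truth. See `docs/methods.md` for modeling
details, parameter defaults and limitations.

## Worked example

Simulate an inner-petrous-like phantom, count it, and compare bone types:

```sh
lacuna3d simulate --preset ip --shape 200 200 200 --spacing 1.0 --seed 1 \
    --out ip.tif --truth ip_truth.csv
# planted 760 lacunae + 3 canals -> ip.tif

lacuna3d count --input ip.tif --out ip_summary.json --records ip_records.csv
# 10-2000 um^3: 760 labels, 95,000/mm^3
# 20-2000 um^3: 760 labels, 95,000/mm^3
```

The phantom spans 0.008 mm³, so 760 planted ellipsoids are exactly
95,000/mm³; on a clean two-level phantom the pipeline recovers that count
exactly, and the three canals (each > 2000 μm³) are rejected by the upper
cutoff. The same stages are available as a library:

```python
from lacuna3d import RunConfig, run_pipeline

result = run_pipeline(RunConfig(preset="ip", shape=(200, 200, 200),
                                spacing=(1, 1, 1), seed=1))
print(result.summary.concentrations_per_mm3)   # {'10-2000': 95000.0, '20-2000': 95000.0}
print(result.summary.ar_mean)                  # ~0.50 measured mean psi_A
```

The numbered scripts under `analysis/` run a study-style cohort — two
replicate phantoms each of four bone types (inner/outer petrous, mastoid,
femur), counted and measured per sample — and write the per-sample
concentration table, morphometry table, volume histograms and group
fold-changes under `results/`. With the default cohort the recovered
fold-change of inner petrous over femur is ≈ 3.5 on both windows.

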