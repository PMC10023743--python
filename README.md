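# pvvkit

Estimation of **pulmonary vessel-like volume (PVV)** from 3D binary vessel
masks on chest CT, for quantitative-imaging researchers studying
interstitial lung disease.

PVV — the total volume of structures a segmentation labels as vessels — is
a candidate imaging biomarker in idiopathic pulmonary fibrosis (IPF) and
other interstitial lung diseases, but its value depends strongly on how it
is computed.  The classical estimator sums, on every image plane, each 2D
component's cross-sectional area times the slice thickness, partitioned by
area into sub-volumes:

    PVV5   : structures with cross-sectional area < 5 mm²
    PVV10  : 5–10 mm²
    PVV10+ : > 10 mm²
    PVV    = PVV5 + PVV10 + PVV10+   (exact, by construction)

That estimator counts unconnected clutter (fibrotic reticular pattern
misclassified as vessel) in full, and a vessel oblique to the image plane
shows an area inflated by ~1/cos θ, misclassifying it across the
sub-volume bins.  `pvvkit` implements this **slice-wise ("unfiltered")**
estimator alongside a **graph-based** one that keeps only connected
branching structures: 3D component thresholding → morphological closing →
topological thinning to centerlines → Euclidean-distance-transform radii →
depth-conditioned removal of thin subpleural voxels (raised-cosine taper
anchored at the pleura) → junction/branch graph → per-branch cylinder
volume πr²L, binned by πr².

Also included:

* a **phantom generator** — Murray-law bifurcating cylinder trees
  (r³ conservation at bifurcations) rasterized onto anisotropic CT-like
  grids, with analytic ground truth and subpleural speckle clutter — so
  every estimator is validated without any imaging download;
* a **Hessian vesselness** stage (anisotropy-aware multiscale Frangi
  filter) to derive vessel masks from grayscale volumes;
* **cohort statistics** — linear mixed models with participant random
  intercepts, visit nesting and cluster-robust (bias-reduced sandwich)
  standard errors for group comparisons and covariate regressions;
* I/O for NIfTI / MetaImage / NRRD volumes, DICOM series, and per-scan
  cohort tables.

## Worked example

```python
import pvvkit as pk

# a 4-generation Murray tree (root radius 3 mm) on a 0.5 x 0.5 x 3 mm grid,
# plus 300 unconnected subpleural speckles mimicking misclassified fibrosis
tree, truth = pk.generate_tree(pk.TreeSpec(generations=4, seed=1))
mask, lung = pk.rasterize(tree)
cluttered, _ = pk.add_clutter(mask, lung, pk.ClutterSpec(n_speckles=300, seed=1))

print(f"analytic truth: {truth.total_volume/1000:.2f} mL")
print(pk.slicewise_pvv(cluttered))
result, graph = pk.graph_pvv(cluttered, lung)
print(result)
```

prints

```
analytic truth: 2.71 mL
PVV[unfiltered] total 4.01 mL (PVV5 1.42, PVV10 0.31, PVV10+ 2.29)
PVV[graph] total 2.65 mL (PVV5 0.10, PVV10 0.46, PVV10+ 2.09, lung 256.2 mL)
```

The slice-wise estimate overshoots the true 2.71 mL by almost 50%: the
speckle clutter lands in PVV5 (1.42 mL vs a true 0 mL in that bin) and
oblique branches are mis-binned.  The graph-based estimate ignores the
clutter entirely (its PVV is identical on the clean mask) and recovers the
analytic total within 3%.  The returned `graph` is a networkx multigraph
whose nodes are bifurcations/endpoints and whose edges carry length,
radius, area and volume per branch.

For cohort tables (one row per scan with cohort, participant, visit,
method, PVV fields and covariates):

```python
records, report = pk.load_cohort_table("cohort.csv")
print(pk.cohort_summary(records, "pvv_total"))
res = pk.lmm_compare(records, response="pvv_total", factor="cohort")
print(res.summary())   # IPF-minus-control difference, robust SE, 95% CI, p
```

A thin CLI mirrors the library: `pvv phantom`, `pvv vesselness`,
`pvv pvv-slicewise`, `pvv pvv-graph`, `pvv stats` (see `pvv --help`).

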