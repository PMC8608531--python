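# elbowseg

Unsupervised color-image segmentation for biomedical imaging: k-means pixel
clustering with the number of clusters chosen automatically by the elbow
criterion, plus segmented-image rendering and per-cluster pixel statistics.

The package targets workflows like prostate-cancer image analysis — NIR
fluorescence images acquired with PSMA-targeting photosensitizer conjugates,
or H&E histology tiles — where tissue compartments appear as a handful of
distinct color populations and the right number of compartments is not known
in advance. It is equally usable on any multi-region color raster.

## Method

Pixels are clustered in color space ([0, 1]³, RGB or CIELAB) by Lloyd's
k-means, minimising the within-cluster sum of squared errors

SSEWC = Σᵢ Σ_{x∈Cᵢ} ‖x − μᵢ‖²,

equivalently maximising the between-cluster sum SSEBC = Σᵢ |Cᵢ|‖μ − μᵢ‖²
(the two always add up to the total sum of squares about the grand mean μ).
Scanning k over a range and plotting SSEWC(k) yields the classic elbow
curve: steep decay while k is below the number of real color populations,
then a flat tail. The elbow — the point of highest curvature, scored on the
log-SSE curve — is selected as the number of clusters, removing the manual
choice of k. Per-cluster pixel counts and percentage shares are then
reported, with the largest ("denominator") cluster flagged. See
`docs/methods.md` for the full numerical account.

## Worked example

```python
import elbowseg as es

spec = es.SyntheticSpec(seed=0)           # 4 color populations, 128x128
pixels, truth = es.generate_image(spec)

model = es.ElbowKMeans(k_min=1, k_max=10, random_state=0).fit(pixels)
for k, s in zip(model.curve_.k_values, model.curve_.sse_values):
    print(f"{k:<2d} {s:9.2f}")
print("chosen k:", model.chosen_k_)

seg = es.render_segmentation(model.result_(), spec.height, spec.width)
table = es.compute_cluster_stats(seg.labels_flat(), model.chosen_k_, "synthetic-0")
print(table.to_frame().to_string(index=False))
```

prints

```
1    2351.11
2     800.24
3     335.29
4     121.08
5     107.17
6      97.56
7      90.19
8      84.48
9      79.62
10     75.84
chosen k: 4
 image_name  cluster_label  pixel_count  ratio_percent  denominator_flag
synthetic-0              1         3464          21.14                 0
synthetic-0              2         8604          52.52                 1
synthetic-0              3         2975          18.16                 0
synthetic-0              4         1341           8.19                 0
```

The SSEWC falls by factors of ~3 up to k = 4 (the true number of color
populations in this synthetic image) and by only a few percent per step
afterwards; the elbow detector reads k = 4 off that change in decay rate.
The stats table gives each cluster's pixel count and percentage share
(clusters numbered 1..k by ascending centroid luminance, so cluster 1 is
the darkest); the `denominator_flag` marks the largest cluster. The counts
sum to 128 × 128 = 16384 and the unrounded shares sum to exactly 100.

The same pipeline is available from the shell:

```sh
elbowseg elbow image.png -o out/           # SSE curve, plot, chosen k
elbowseg segment image.png -o out/         # segmentation at the elbow k
elbowseg segment image.png -o out/ --k 4   # or at an explicit k
elbowseg stats out/segmented_labels.png -o stats.csv
elbowseg make-fixtures -o fixtures/        # synthetic test corpus
```

`segment` writes the centroid-colored (posterized) segmentation, a
high-contrast categorical label visualization with per-cluster annotations,
a single-channel label PNG, the cluster stats CSV, and a JSON run record.
All commands are deterministic given `--seed`.

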