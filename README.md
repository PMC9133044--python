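# duratrace

Quantitative image analysis for meningeal (dural) trigeminal innervation and
dural mast-cell spatial organization.

Whole-mount meninges are commonly imaged two ways: Tubb3 (β-tubulin III)
immunofluorescence shows the trigeminal nerve fibers as bright tubular
structures in 3D confocal stacks, and toluidine-blue staining shows resident
mast cells as compact blobs in large 2D fields. `duratrace` implements the
computational side of both readouts for researchers studying meningeal
innervation and neuro-immune interactions (e.g. migraine models, lymphatic
dysfunction):

* **Innervation morphometry** — semi-automated axon tracing. The stack is
  projected (MIP), enhanced with a multiscale Frangi vesselness filter,
  normalized to `P ∈ [0, 1]` and complemented into a cost image `1 − P`. For
  each axon, marked by two seed points, the centerline is the globally
  minimal path for the accumulated cost `∫ (1 − P + ε) ds` on the
  8-connected pixel grid; an active-contour front grown from the centerline
  with speed `P` segments the axon; morphometry reports the diameter profile
  (2 × distance transform) and the centerline length in 3D (each pixel
  lifted to its brightest z-plane). Traces are fused into an innervation
  graph whose two complexity metrics are the **total axonal length** (µm)
  and the **number of axonal endpoints** (degree-1 nodes).
* **Region-level coverage** — Phansalkar local adaptive thresholding
  (`t = μ(1 + p·e^{−qμ} + k(s/r − 1))`, radius 40) for % nerve-covered area,
  mean gray value, and scale-matched LoG spot detection (10 µm) feeding a
  10×10 quadrat normality analysis.
* **Mast-cell spatial statistics** — prominence-based maxima detection
  (noise tolerance 35, edge maxima excluded), densities in cells/mm²,
  5×5 quadrat counts with a Shapiro–Wilk normality p-value per animal, and
  Ripley's K-function `K̂(r) = (A / n(n−1)) Σ_{i≠j} e_ij 1(d_ij ≤ r)` with
  translation edge correction and a Monte-Carlo CSR envelope (100
  simulations) giving a randomness verdict. Under CSR, `E K(r) = π r²`.
* **Cohort pipelines** — orchestration over groups of subjects with
  left/right hemiskull averaging, Student's t / Mann–Whitney U comparisons
  and Bonferroni adjustment, and deterministic JSON reports.

Because raw microscope data of this kind are rarely shareable, the package
ships a first-class synthetic-phantom module (`duratrace.synthgen`) that
generates tubular branching neurite stacks (1.14 × 1.14 µm² pixels, 1 µm
z-step) and planar point patterns (CSR, Thomas-clustered, hard-core) with
exact ground truth, so every stage is testable end to end.

## Worked example

```python
import numpy as np
from duratrace import synthgen, enhance, trace, graph, pointstats

# --- innervation on a phantom with known truth -------------------------
geom = synthgen.NeuriteGeometry(shape_px=(6, 256, 256), n_endpoints=5)
imaging = synthgen.ImagingSpec(gaussian_sd=10.0)      # SNR 10
stack, truth = synthgen.make_neurite_phantom(geom, imaging, seed=42)
enh = enhance.enhance_stack(stack, scales=(1.0, 2.0))

dx, dy, _ = stack.spacing
to_px = lambda p: (round(p[1] / dy), round(p[0] / dx))
root = to_px(truth.endpoints[0])
traces = [trace.trace_axon(enh, trace.SeedPair(root, to_px(ep)), stack)
          for ep in truth.endpoints[1:]]
g = graph.build_graph(traces)
print("truth length  :", round(truth.total_length, 1), "um,",
      len(truth.endpoints), "endpoints")
print("measured      :", round(g.total_length, 1), "um,",
      g.endpoint_count, "endpoints")
print("mean diameter :", round(np.mean([t.mean_diameter for t in traces]), 2), "um")

# --- mast-cell spatial statistics --------------------------------------
spec = synthgen.PointProcessSpec(kind="csr", intensity=38e-6,
                                 window=(0, 0, 3700, 2400), seed=7)
pattern = synthgen.make_point_pattern(spec)
env = pointstats.csr_envelope(pattern, n_sims=100, seed=7)
grid = pointstats.quadrat_counts(pattern, 5, 5)
print("density       :", round(pointstats.density(pattern), 1), "cells/mm^2")
print("quadrat p     :", round(pointstats.quadrat_normality(grid), 3))
print("Ripley verdict:", env.verdict)
```

Output:

```
truth length  : 404.4 um, 5 endpoints
measured      : 406.5 um, 5 endpoints
mean diameter : 3.32 um
density       : 38.7 cells/mm^2
quadrat p     : 0.112
Ripley verdict: random
```

The tracer recovers the phantom's total length within ~0.5% and its endpoint
count exactly; the CSR-simulated mast-cell field at 38 cells/mm² over the
3.7 × 2.4 mm² window shows Gaussian-compatible quadrat counts (p > 0.05) and
stays inside the Monte-Carlo envelope, so it is called spatially random.

A command line wraps the cohort pipelines:

```bash
duratrace synth     --spec spec.json --out phantom_dir/
duratrace innervate --config cfg.json --out innervation_report.json
duratrace mastcells --config cfg.json --out mastcell_report.json
```

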