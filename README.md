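# osteograph

Segmentation and connectomics of osteocyte networks in 2-D confocal
microscopy.

Osteocytes — the most abundant, mechanosensitive cells in bone — sit in
lacunae and talk to each other through thin dendritic processes running in
canaliculi. The integrity of this lacunocanalicular network degrades with
age and disease, and quantifying it from confocal scans traditionally means
many hours of manual segmentation per dataset. `osteograph` implements the
classical, fully automatic end of that analysis:

* **threshold segmentation** of greyscale scans into background, osteocyte
  and dendrite classes using two pipelines that share pre/post-processing
  (Gaussian smoothing σ = 2 px, a fixed intensity split at 70 on the 0–255
  scale, a secondary noise threshold, 3×3 morphological closing,
  osteocyte-first overlap subtraction) and differ in their dendrite core:
  **Otsu thresholding** of the dendrite candidate band, or **Canny edge
  detection** (hysteresis thresholds 70/220) restricted to it;
* **evaluation metrics**: per-class Dice score DSC = 2|P∩G|/(|P|+|G|) and
  Jaccard index IoU = |P∩G|/|P∪G| (with mIoU over the two foreground
  classes);
* **connectomics**: class masks are dilated (4×4 discrete ellipse for cell
  bodies, 2×2 cross for dendrites) to merge fragments, connected components
  become graph elements — osteocytes are nodes, each dendrite component
  touching ≥ 2 cells contributes an independent connection per pair,
  components touching exactly one cell are dead ends — and six per-image
  network metrics are computed (node count, dead ends per node, connections
  per node, mean connection length/diameter, mean network diameter), with
  lengths measured along the medial-axis skeleton (diagonal steps √2 px)
  and diameters from the distance transform sampled on the skeleton;
* **dendrite regularisers**: the discrete inverse component-size penalty
  λ·Σ 1/size(c) (merging fragments always lowers it) and label dilation
  with 2×2/3×3 kernels;
* **group statistics**: two-sided Mann–Whitney U tests at α = 0.05 (exact
  permutation null for small tie-free samples) and descriptive percentage
  changes, 100·(mean_ref − mean_other)/mean_ref;
* a **seeded synthetic-scene generator** that emulates the imaging regime
  (500×500 px at 150 nm/px, ~450 nm diffraction blur, 1.5–3 px dendrites,
  noise, illumination gradients, unlabelled blood-vessel artefacts) with
  known ground-truth masks and graphs, including young- and aged-bone
  presets — so the entire chain is testable without any microscope data.

## Worked example

```python
from osteograph import *
from osteograph.synth import low_noise_params

# a young-bone scene under favourable imaging, with ground truth
sc = make_scene(low_noise_params(seed=0))
pred = segment(sc.image, SegmentationParams(method="otsu"))
m = evaluate(pred, sc.mask)
print(f"osteocyte DSC {m.dice_per_class[1]:.3f}  "
      f"dendrite DSC {m.dice_per_class[2]:.3f}  mIoU {m.mean_iou:.3f}")
```

prints

```
osteocyte DSC 0.919  dendrite DSC 0.492  mIoU 0.588
```

— cell bodies segment far better than the thin, diffraction-limited
processes, the ordering seen on real scans. Running the graph extraction
on the true mask of a sparse, well-separated scene recovers its ground
truth exactly:

```python
sc = make_scene(recovery_params(seed=0))   # ground truth: 5 cells, 3 connections, 9 dead ends
g = build_graph(sc.mask)
print(compute_metrics(g))
```

```
ConnectomicsMetrics(n_nodes=5, deadends_per_node=1.8, connections_per_node=1.2,
                    mean_connection_length_um=23.718,
                    mean_connection_diameter_um=0.314,
                    mean_network_diameter_um=0.325)
```

(5 nodes, 2·3/5 = 1.2 connections per node, 9/5 = 1.8 dead ends per node;
the measured 23.7 µm mean connection length is within ~3% of the generator's
23.0 µm true arc length.)

Every stage is also a CLI subcommand:

```bash
osteograph simulate --out scenes/ --n 5 --seed 1
osteograph segment scenes/young_000.png pred.png --method otsu
osteograph metrics pred.png scenes/young_000_mask.png
osteograph connectome scenes/young_000_mask.png --csv conn.csv --graphml g.graphml
osteograph run config.yaml      # full simulate→segment→metrics→connectome→compare
```

## Layout

| module | role |
| --- | --- |
| `osteograph.io` | greyscale/label-mask I/O, red-channel colour reduction |
| `osteograph.synth` | synthetic scenes, ground truth, young/aged presets |
| `osteograph.segment` | shared pre/post-processing + Otsu/Canny cores |
| `osteograph.metrics` | Dice / IoU / mIoU evaluation |
| `osteograph.connectomics` | mask → graph, skeleton geometry, network metrics |
| `osteograph.regularise` | component-size penalty, label dilation |
| `osteograph.stats` | Mann–Whitney comparisons, percentage changes |
| `osteograph.cli` | subcommands and the end-to-end pipeline |

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
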