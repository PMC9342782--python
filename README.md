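# meiostorm

Analysis of multi-color dSTORM single-molecule localization data from
meiotic spread nuclei: recombination-focus detection, RAD51/DMC1
nanofocus segmentation and configuration analysis, and
synaptonemal-complex (SC) geometry.

## Who this is for

During meiotic prophase, programmed DNA double-strand breaks (DSBs) are
repaired by homologous recombination. The recombinases RAD51 and DMC1
coat the resected single-stranded DNA ends and appear in
super-resolution images as clusters of blink localizations
("nanofoci") sitting on or near the SC axes (SYCP3/HORMAD1). This
package implements the quantitative analysis such experiments need:

* **locio** — localization-table I/O (generic and ThunderSTORM CSV
  dialects), blink grouping, fiducial-bead channel registration;
* **render** — kernel-density rendering of point clouds into density
  images (localizations/nm², 5 nm pixels) and threshold masks;
* **roidetect** — semi-automatic selection of 750-nm circular regions
  of interest (ROIs) around recombinase accumulations on the axes
  (Huang thresholding, particle filters, double-positive gating, local
  maxima, 400-nm merging, declarative manual edits);
* **nanofoci** — per-ROI KDE segmentation at 0.15 loc/nm², shape
  features (area, eccentricity), DxRy configuration labels (x DMC1 and
  y RAD51 nanofoci, e.g. D1R1, D2R1), close/far role assignment;
* **geometry** — consensus rotation mapping, intra-focus distances,
  distance to the SC axes, inside/outside the lateral elements, the
  D2R1 dumbbell-to-axis angle;
* **axes** — axis polylines, arc-length projection, perpendicular
  intensity profiles with a uniform-repositioning null, SC coil
  spacing = axis length / (twists + 1);
* **nn** — nearest-neighbor distance histograms (100-nm bins, 3.5-µm
  rest class) with ROI-based (38.5%) and nanofocus-based (40%)
  subsetting controls, and the axis-projected variant;
* **synthdata** — a synthetic spread-nucleus generator with full ground
  truth (axes, DSB sites, per-nanofocus parameters) so every stage is
  testable without raw data;
* **summarize / cli** — per-nucleus and per-stage aggregation, group
  tests at a declared unit of analysis, and a `meiostorm` command-line
  pipeline.

## The model in brief

A localization *i* is a position with uncertainty σᵢ. Rendering places
a unit-mass Gaussian N(xᵢ, σᵢ²·I) per localization, so an isolated
cluster of N localizations with spread s crosses the segmentation
threshold *t* over the area

    A = 2π S² ln( N / (2π S² t) ),   S² = s² + ⟨σ²⟩,

which is how the fixed thresholds (0.05 loc/nm² for axes, 0.15 for
recombinases; ≥ 50 px = 1,250 nm² per nanofocus; ≥ 500 px = 12,500 nm²
for ROI inclusion) translate counts into segmentable objects.
Configurations are labeled DxRy from the per-channel nanofocus counts;
for D2R1/D1R2 the duplicate protein's nanofocus nearer the other
protein is "close", the other "far". Nearest-neighbor analysis of
nanofocus centers (per channel, per nucleus) exhibits two preferred
distances — ~300 nm within a DSB site and ~900 nm between sites — and
the two subsetting controls distinguish them: ROI-based subsetting
keeps intra-site pairs (short peak survives, long peak attenuates),
nanofocus-based subsetting breaks them (short peak attenuates).

## Worked example

```python
import numpy as np
from collections import Counter
from meiostorm import synthdata, nanofoci, nn

params = synthdata.GeneratorParams.preset("wild_type")
table, truth = synthdata.simulate_nucleus(params, seed=1, nucleus_id="demo")
print(f"{len(table):,} localizations, {len(truth.sites)} true DSB sites")

rois = [s.roi(nucleus_id="demo") for s in truth.sites]
segs = nanofoci.segment_rois(rois, table)
configs = [nanofoci.classify_configuration(v, "demo") for v in segs.values() if v]
kept = nanofoci.filter_rois(configs)
counts = Counter(c.label for c in kept)
print({k: f"{100 * v / len(kept):.0f}%" for k, v in counts.most_common(4)})

centers = np.array([nf.center_of_mass for c in kept
                    for nf in c.nanofoci if nf.channel == "DMC1"])
hist = nn.bin_distances([nn.nearest_neighbor_distances(centers)])
print(f"DMC1 NN: {100 * nn.band_mass(hist, 150, 450):.1f}% at 150-450 nm, "
      f"{100 * nn.band_mass(hist, 750, 1050):.1f}% at 750-1050 nm")
```

prints

```
2,033,385 localizations, 85 true DSB sites
{'D1R1': '69%', 'D2R1': '16%', 'D2R2': '11%', 'D1R2': '4%'}
DMC1 NN: 42.6% at 150-450 nm, 24.1% at 750-1050 nm
```

i.e. the pipeline recovers the generating configuration mixture
(D1R1-dominated) and the two-peak nearest-neighbor structure from the
raw localizations of a single nucleus.

The same pipeline runs from the shell:

```bash
meiostorm simulate --n-nuclei 2 --seed 1 --out sim/
meiostorm all sim/sim_0.csv sim/sim_1.csv --axes sim/sim_0_axes.json --out run/
```

writing `rois.csv`, `nanofoci.csv`, `configurations.csv`,
`geometry.csv`, per-channel NN histograms and a JSON run log to
`run/`.

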