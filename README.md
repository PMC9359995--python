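# nucfate

Chromatin compaction and cell-fate analysis for nuclear imaging of dying
neurons.

Neurons dying by apoptosis compact their chromatin well before the classic
morphological hallmark — nuclear shrinkage — becomes visible. `nucfate`
implements the computational side of that observation for two data types:

* **Two-channel nuclear time-lapse recordings** (a chromatin marker such as
  H2B::mCherry plus the fluorogenic caspase-3/7 reporter NucView, one ROI
  per nucleus, 10-min frame interval): per-frame nuclear size, Sobel edge
  count, the **chromatin compaction parameter** (CCP), and reporter
  intensity, followed by a rule-based classification of each cell's fate.
* **Single-molecule localization microscopy (SMLM) tables** (ThunderSTORM-
  style CSV): spot-width filtering, blinking-event merging, and
  **Voronoi-tessellation density analysis** of chromatin clustering.

A seeded synthetic-microscopy module generates ground-truthed time-lapse
stacks and localization tables emulating the study conditions, so the whole
pipeline is testable on a laptop without any raw data.

## The quantities

For each frame the nucleus is segmented by Otsu's threshold on the chromatin
channel (after maximum z-projection and 2x bicubic upsampling), and

```
CCP = (# Sobel-edge pixels inside the nuclear mask) / (mask area)
```

Edges are pixels whose 3x3 Sobel gradient magnitude exceeds 2.5x the median
within-mask magnitude (a scale-invariant, bulk-anchored auto-threshold); the
mask is eroded so the nuclear rim itself is not counted. All per-cell series
are normalized to the mean of the first three (baseline) frames.

Each cell then receives exactly one fate by a five-step rule set (thresholds
are the study's printed values): *surviving/dying* from the finite-difference
gradient of the normalized reporter (0.035 / 0.8), *apoptotic* if dying with
final CCP < 1.1x baseline, *necrotic* if the final nuclear size fell to
<= 75%, *granulating* if the final CCP rose by >= 0.5, otherwise *no change*,
with precedence apoptotic > necrotic > granulating > no change. A 14-fold
rise of the normalized reporter marks a caspase-activation event.

For SMLM data, each localization's **Voronoi density** is the inverse of its
Voronoi cell area (Gauss's shoelace formula on the cell vertices); densities
are divided by the nucleus's localization count, log10-transformed, and
summarized as probability-density histograms over log10 density and over
(radius from the center of mass) x (log10 density).

## Worked example

```python
import nucfate as nf

# one synthetic apoptotic nucleus, 49 frames at 10 min
stack = nf.generate_timelapse(nf.FateProgram.apoptosis(), seed=1)
traj = nf.normalize_trajectory(nf.measure_stack(stack.h2b, stack.nucview))
print(nf.classify_fate(traj).fate)          # apoptotic
print(nf.detect_apoptotic_event(traj))      # (True, 25)

aligned = nf.align_to_size_change([traj])
print(round(aligned.mean_at(-120, "norm_ccp"), 2))   # 1.46 for this cell
print(round(aligned.mean_at(120, "norm_area"), 2))   # 0.28 for this cell
```

The cell is classified apoptotic, its caspase reporter surpasses the 14-fold
threshold at frame 25, and — after aligning time to the first clear nuclear
size change — its chromatin compaction is already ~1.5-fold elevated two
hours *before* shrinkage, while nuclear size two hours *after* shrinkage has
fallen to ~0.28 of baseline (single-cell values scatter around the
population means 1.55 and 0.26).

The SMLM side:

```python
table = nf.generate_localizations(nf.StageProfile.stage(5), 8000, seed=2)
table = nf.filter_by_fwhm(nf.merge_blinking(table))
result = nf.normalize_log(nf.voronoi_density(table))
print(round(nf.summarize_group(result).mean_log10_norm_density, 2))  # -7.44
```

A command-line interface (`nucfate simulate-timelapse | simulate-smlm |
measure | classify | voronoi | report`) chains the same stages on files and
writes a YAML manifest per run; see `nucfate --help`.

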