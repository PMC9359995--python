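"""Frozen calibration constants for the synthetic-data generators.

Produced once by ``scripts/calibrate_synthetic.py`` and checked in, so the
generators are pure functions of (program, seed) at run time.

``GRANULE_COUNTS``/``GRANULE_RATIOS`` map the number of granule spots placed
in the reference nucleus (radius 24 px, 96x96 frame) to the mean measured
CCP ratio over the default measurement chain.  ``STAGE_TABLE`` holds the
per-stage localization-pattern parameters, with the effective-radius factor
tuned so that the full filter+merge+Voronoi pipeline reproduces the target
mean log10 count-normalized densities at the reference molecule count.
"""

from __future__ import annotations

import numpy as np

# mean measured CCP ratio vs total spot count (baseline speckles = 8) at the
# reference geometry (frozen output of scripts/calibrate_synthetic.py
# --granules, 48 textures)
GRANULE_COUNTS = np.array(
    [8.0, 9.0, 10.0, 11.0, 12.0, 13.0, 14.0, 15.0, 16.0, 17.0, 18.0, 19.0,
     20.0, 21.0, 22.0, 23.0, 24.0, 25.0, 26.0, 27.0, 28.0, 29.0, 30.0, 31.0,
     32.0, 33.0, 34.0, 35.0, 36.0, 37.0, 38.0, 39.0, 40.0]
)
GRANULE_RATIOS = np.array(
    [1.0, 1.138, 1.2349, 1.3187, 1.422, 1.5408, 1.628, 1.7094, 1.7982,
     1.8602, 1.9259, 2.0027, 2.093, 2.1927, 2.2728, 2.3243, 2.3697, 2.451,
     2.5122, 2.5573, 2.623, 2.6804, 2.7404, 2.7756, 2.829, 2.8721, 2.9223,
     2.9633, 3.0082, 3.0428, 3.0432, 3.0673, 3.0833]
)


# relative measured-area drift per excess spot (above the baseline speckle
# density): bright spots raise the Otsu intensity threshold and shrink the
# mask slightly; the renderer divides the disk radius by sqrt(1 + drift *
# excess) to compensate (frozen output of calibrate_synthetic.py --drift)
AREA_DRIFT_PER_SPOT = -0.0006


def ratio_to_count(ratio: float) -> float:
    """Total spot count (reference geometry) producing a target mean CCP ratio."""
    if ratio <= 1.0:
        return float(GRANULE_COUNTS[0])
    if ratio >= GRANULE_RATIOS[-1]:
        # linear extrapolation with the final calibrated slope
        slope = (GRANULE_COUNTS[-1] - GRANULE_COUNTS[-2]) / (
            GRANULE_RATIOS[-1] - GRANULE_RATIOS[-2]
        )
        return float(GRANULE_COUNTS[-1] + slope * (ratio - GRANULE_RATIOS[-1]))
    return float(np.interp(ratio, GRANULE_RATIOS, GRANULE_COUNTS))


def count_to_ratio(count: float) -> float:
    """Mean CCP ratio produced by a granule count (inverse of ratio_to_count)."""
    if count <= 0:
        return 1.0
    if count >= GRANULE_COUNTS[-1]:
        slope = (GRANULE_RATIOS[-1] - GRANULE_RATIOS[-2]) / (
            GRANULE_COUNTS[-1] - GRANULE_COUNTS[-2]
        )
        return float(GRANULE_RATIOS[-1] + slope * (count - GRANULE_COUNTS[-1]))
    return float(np.interp(count, GRANULE_COUNTS, GRANULE_RATIOS))


# per-stage localization-pattern parameters
# (radius_factor frozen by scripts/calibrate_synthetic.py --stages)
STAGE_TABLE: dict[int, dict[str, float]] = {
    1: dict(clustered_fraction=0.0, cluster_sd_nm=150.0, clusters_per_um2=2.0,
            radius_shrink_factor=1.0, radius_factor=1.2329,
            target_log10_density=-7.83),
    2: dict(clustered_fraction=0.40, cluster_sd_nm=150.0, clusters_per_um2=2.0,
            radius_shrink_factor=1.0, radius_factor=1.0311,
            target_log10_density=-7.62),
    3: dict(clustered_fraction=0.60, cluster_sd_nm=90.0, clusters_per_um2=2.0,
            radius_shrink_factor=1.0, radius_factor=1.2016,
            target_log10_density=-7.58),
    4: dict(clustered_fraction=0.70, cluster_sd_nm=70.0, clusters_per_um2=5.0,
            radius_shrink_factor=0.90, radius_factor=1.3464,
            target_log10_density=-7.60),
    5: dict(clustered_fraction=0.85, cluster_sd_nm=50.0, clusters_per_um2=10.0,
            radius_shrink_factor=0.60, radius_factor=1.7177,
            target_log10_density=-7.37),
}
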