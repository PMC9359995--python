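"""Seeded synthetic microscopy: nuclear time-lapse stacks and SMLM tables.

Two generators emulate the study's raw data so every downstream stage is
testable at desk scale without any download:

``generate_timelapse``
    Renders one nucleus as a soft-edged disk following a programmed
    relative-area trajectory, with a static low-frequency chromatin texture,
    granule spots whose density follows a programmed CCP-ratio course
    (via the frozen granule calibration), and a caspase-reporter channel
    following a programmed fold-change course.

``generate_localizations``
    Samples a Thomas-type cluster point process in a nuclear disk and turns
    each molecule into one or more blinking events in frame runs, with
    localization jitter, lognormal spot widths (deliberately spilling past
    the 65/225 nm FWHM gates) and per-event photon counts.

All randomness flows from a single integer seed; identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from ._calibration import AREA_DRIFT_PER_SPOT, STAGE_TABLE, ratio_to_count
from .errors import GeometryError, ValidationError

__all__ = [
    "Geometry",
    "FateProgram",
    "TimeLapseStack",
    "StageProfile",
    "generate_timelapse",
    "generate_replicates",
    "generate_culture",
    "generate_localizations",
    "FATES",
]

FATES = ("control", "apoptosis", "necrosis", "granulating")

FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class Geometry:
    """Image geometry of the simulated field of view."""

    shape: tuple[int, int] = (96, 96)
    pixel_size_nm: float = 111.0
    nucleus_radius_px: float = 24.0
    edge_softness_px: float = 1.0
    n_planes: int = 1


@dataclass(frozen=True)
class FateProgram:
    """Programmed single-cell dynamics for one simulated nucleus.

    The area, CCP-ratio and reporter courses are piecewise linear in time.
    ``event_time_min`` marks the onset of the nuclear-size change.  Apoptosis
    shrinks to ``apoptosis_plateau`` within 30 min of the event; necrosis
    swells through 1.12 to its ``necrosis_peak`` 20 min after the event and
    then falls to ``necrosis_final``.  Granulation (granule-texture density)
    ramps linearly from ``granulation_onset_min`` before the event so that
    the programmed CCP ratio equals ``granulation_ccp_ratio`` 2 h before the
    first frame at which the size change is detectable (event + 10 min).

    The apoptotic reporter course rises steeply through the 14-fold apoptosis
    threshold at the event and keeps rising afterwards (caspase substrate
    accumulates until the end of recording); the necrotic course drifts to
    ``necrosis_nucview_fold`` within an hour of the event and plateaus.
    """

    fate: str
    event_time_min: float = 240.0
    granulation_onset_min: float = 210.0
    granulation_ccp_ratio: float = 1.0
    apoptosis_plateau: float = 0.26
    apoptosis_fall_min: float = 30.0
    necrosis_peak: float = 1.17
    necrosis_final: float = 0.51
    nucview_peak_fold: float = 16.0
    nucview_terminal_slope_per_min: float = 0.1
    necrosis_nucview_fold: float = 1.3
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fate not in FATES:
            raise ValidationError(f"unknown fate {self.fate!r}; expected one of {FATES}")
        if self.granulation_onset_min < 0:
            raise ValidationError("granulation_onset_min must be >= 0")
        if min(self.apoptosis_plateau, self.necrosis_peak, self.necrosis_final) <= 0:
            raise ValidationError("area course values must be positive")

    # ---- factory defaults ------------------------------------------------
    @classmethod
    def control(cls, **kw) -> "FateProgram":
        return cls(fate="control", **kw)

    @classmethod
    def apoptosis(cls, **kw) -> "FateProgram":
        kw.setdefault("granulation_ccp_ratio", 1.55)
        return cls(fate="apoptosis", **kw)

    @classmethod
    def necrosis(cls, **kw) -> "FateProgram":
        kw.setdefault("granulation_ccp_ratio", 1.9)
        return cls(fate="necrosis", **kw)

    @classmethod
    def granulating(cls, **kw) -> "FateProgram":
        kw.setdefault("granulation_ccp_ratio", 1.9)
        return cls(fate="granulating", **kw)

    # ---- programmed courses ----------------------------------------------
    def area_course(self, t_min: np.ndarray) -> np.ndarray:
        """True relative nuclear cross-section area at time ``t_min``."""
        t = np.asarray(t_min, dtype=float)
        e = self.event_time_min
        if self.fate in ("control", "granulating"):
            return np.ones_like(t)
        if self.fate == "apoptosis":
            xp = [0.0, e, e + self.apoptosis_fall_min]
            fp = [1.0, 1.0, self.apoptosis_plateau]
            return np.interp(t, xp, fp)
        # necrosis: swell through an intermediate point so the first
        # alignment-detectable frame precedes the peak by one frame
        xp = [0.0, e, e + 10.0, e + 20.0, e + 130.0]
        fp = [1.0, 1.0, 1.12, self.necrosis_peak, self.necrosis_final]
        return np.interp(t, xp, fp)

    def ccp_course(self, t_min: np.ndarray) -> np.ndarray:
        """True granulation level expressed as a CCP ratio at time ``t_min``."""
        t = np.asarray(t_min, dtype=float)
        e = self.event_time_min
        if self.fate == "control" or self.granulation_ccp_ratio <= 1.0:
            return np.ones_like(t)
        onset = e - self.granulation_onset_min
        if self.fate == "apoptosis":
            # the programmed ratio is anchored 2 h before the first
            # detectable size-change frame (event + 10 min)
            anchor = e - 110.0
            if anchor <= onset:
                peak = self.granulation_ccp_ratio
            else:
                peak = 1.0 + (self.granulation_ccp_ratio - 1.0) * (
                    (e - onset) / (anchor - onset)
                )
            # hold ~2 h past the event, then granules clear as chromatin
            # condenses homogeneously; the terminal pyknotic nucleus is
            # uniformly dense, so even the baseline speckle contrast
            # dissolves (programmed ratio below 1)
            xp = [0.0, onset, e, e + 120.0, e + 180.0]
            fp = [1.0, 1.0, peak, peak, 0.2]
            return np.interp(t, xp, fp)
        xp = [0.0, onset, e]
        fp = [1.0, 1.0, self.granulation_ccp_ratio]
        return np.interp(t, xp, fp)

    def nucview_course(self, t_min: np.ndarray) -> np.ndarray:
        """True caspase-reporter fold change at time ``t_min``."""
        t = np.asarray(t_min, dtype=float)
        e = self.event_time_min
        if self.fate in ("control", "granulating"):
            return np.ones_like(t)
        if self.fate == "necrosis":
            xp = [0.0, e, e + 60.0]
            fp = [1.0, 1.0, self.necrosis_nucview_fold]
            return np.interp(t, xp, fp)
        out = np.interp(t, [0.0, e - 20.0, e + 10.0], [1.0, 1.0, self.nucview_peak_fold])
        tail = t > e + 10.0
        out = out + np.where(
            tail, self.nucview_terminal_slope_per_min * (t - (e + 10.0)), 0.0
        )
        return out


@dataclass
class TimeLapseStack:
    """Two-channel simulated time-lapse with per-frame ground truth."""

    h2b: np.ndarray
    nucview: np.ndarray
    pixel_size_nm: float = 111.0
    frame_interval_min: float = 10.0
    n_baseline_frames: int = 3
    truth: pd.DataFrame | None = None
    fate: str = "control"
    event_time_min: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.h2b.shape != self.nucview.shape:
            raise ValidationError("channels must share a shape")
        if not (np.all(np.isfinite(self.h2b)) and np.all(np.isfinite(self.nucview))):
            raise ValidationError("intensities must be finite")
        if self.h2b.min() < 0 or self.nucview.min() < 0:
            raise ValidationError("intensities must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.h2b.shape[0]

    @property
    def time_min(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) * self.frame_interval_min


# reference rendering constants; the granule calibration is tied to these
_BG_H2B = 8.0
_I0_H2B = 120.0
_TEXTURE_AMP = 0.25
_TEXTURE_SIGMA_PX = 6.0
_GRANULE_AMP = 0.9
_GRANULE_SD_PX = 1.0
_GRANULE_EXTENT = 0.92  # spots confined to this fraction of the radius
_NV_BG = 1.0
_NV_LEVEL = 30.0
_REF_RADIUS_PX = 24.0
# chromocenter-like speckles present from the first frame; granulation adds
# more spots of the same kind, so the within-mask gradient distribution stays
# bimodal (smooth field vs spot rims) and the adaptive edge threshold sits
# stably between the classes
_BASELINE_SPECKLES = 8


def _disk(shape: tuple[int, int], radius: float, softness: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    rr = np.hypot(yy - (shape[0] - 1) / 2.0, xx - (shape[1] - 1) / 2.0)
    return 1.0 / (1.0 + np.exp((rr - radius) / softness))


def _granule_field(
    shape: tuple[int, int],
    centre: tuple[float, float],
    radius: float,
    unit_xy: np.ndarray,
    count: int,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Render ``count`` granule spots from a unit-disk position pool."""
    g = np.zeros(shape)
    if count <= 0:
        return g
    pos = unit_xy[:count] * (_GRANULE_EXTENT * radius)
    for dx, dy in pos:
        ix = int(round(centre[1] + dx))
        iy = int(round(centre[0] + dy))
        if 0 <= iy < shape[0] and 0 <= ix < shape[1]:
            g[iy, ix] += 1.0
    g = ndimage.gaussian_filter(g, _GRANULE_SD_PX)
    g *= amplitude * 2.0 * np.pi * _GRANULE_SD_PX**2  # unit peak per spot
    return g


def render_static_nucleus(
    texture_seed: int,
    noise_seed: int,
    granule_count: int,
    geometry: Geometry = Geometry(),
    noise_sd: float = 0.01,
) -> np.ndarray:
    """Render one static chromatin-channel frame (used for calibration/tests).

    ``granule_count`` is the total spot count including the baseline
    chromocenter speckles (``_BASELINE_SPECKLES`` at reference size).  The
    same texture seed at baseline and elevated counts gives the granulated
    nucleus and its less-granulated base on identical chromatin structure.
    """
    rng_t = np.random.default_rng(texture_seed)
    rng_n = np.random.default_rng(noise_seed)
    shape = geometry.shape
    tex = ndimage.gaussian_filter(rng_t.standard_normal(shape), _TEXTURE_SIGMA_PX)
    tex /= tex.std()
    u = _sample_unit_disk(rng_t, max(granule_count, 1))
    disk = _disk(shape, geometry.nucleus_radius_px, geometry.edge_softness_px)
    centre = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    img = _BG_H2B + _I0_H2B * disk * (1.0 + _TEXTURE_AMP * tex)
    img += _I0_H2B * _GRANULE_AMP * disk * _granule_field(
        shape, centre, geometry.nucleus_radius_px, u, granule_count
    )
    img *= 1.0 + noise_sd * rng_n.standard_normal(shape)
    return np.clip(img, 0.0, None)


def _total_spot_count(ccp_ratio: float) -> float:
    """Total spot count (baseline speckles + granules) for a target ratio.

    Ratios below 1 describe dissolving baseline speckles (terminal
    homogeneous condensation): the count shrinks linearly to zero.
    """
    if ccp_ratio < 1.0:
        return _BASELINE_SPECKLES * max(ccp_ratio, 0.0)
    return max(ratio_to_count(ccp_ratio), float(_BASELINE_SPECKLES))


def _sample_unit_disk(rng: np.random.Generator, n: int) -> np.ndarray:
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    rad = np.sqrt(rng.uniform(0.0, 1.0, n))
    return np.column_stack([rad * np.cos(theta), rad * np.sin(theta)])


def generate_timelapse(
    program: FateProgram,
    geometry: Geometry = Geometry(),
    n_frames: int = 49,
    frame_interval_min: float = 10.0,
    seed: int | None = None,
) -> TimeLapseStack:
    """Render a two-channel nuclear time-lapse following ``program``.

    The chromatin channel is a soft disk carrying a static low-frequency
    texture plus granule spots whose count follows the programmed CCP-ratio
    course through the frozen granule calibration; the reporter channel
    follows the programmed fold-change course inside the disk.  Identical
    ``(program, seed)`` give bit-identical stacks.
    """
    seed = program.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    shape = geometry.shape
    t = np.arange(n_frames, dtype=float) * frame_interval_min

    area = program.area_course(t)
    ratio = program.ccp_course(t)
    fold = program.nucview_course(t)

    r0 = geometry.nucleus_radius_px
    r_max = r0 * math.sqrt(float(area.max()))
    if r_max + 4.0 * geometry.edge_softness_px > min(shape) / 2.0:
        raise GeometryError(
            f"nucleus radius {r_max:.1f}px does not fit frame {shape}"
        )

    tex = ndimage.gaussian_filter(rng.standard_normal(shape), _TEXTURE_SIGMA_PX)
    tex /= tex.std()
    # granule pool: nested positions (baseline speckles first) so the ramp
    # adds granules incrementally
    count_ref_max = _total_spot_count(float(ratio.max())) * (r0 / _REF_RADIUS_PX) ** 2
    pool = _sample_unit_disk(rng, int(math.ceil(count_ref_max)) + 4)
    dither = rng.uniform()  # per-cell fractional-count dither
    centre = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)

    h2b = np.empty((n_frames,) + shape)
    nucview = np.empty_like(h2b)
    for i in range(n_frames):
        r = r0 * math.sqrt(float(area[i]))
        # spot count scales with instantaneous area: constant areal density
        want = _total_spot_count(float(ratio[i])) * (r / _REF_RADIUS_PX) ** 2
        k = int(math.floor(want)) + (1 if dither < want - math.floor(want) else 0)
        # compensate the segmentation-area bias induced by bright spots
        # (brighter foreground raises the Otsu threshold, shrinking the
        # measured mask); frozen per-spot drift from the calibration script
        excess = want / float(area[i]) - _BASELINE_SPECKLES
        r /= math.sqrt(max(1.0 + AREA_DRIFT_PER_SPOT * excess, 0.5))
        disk = _disk(shape, r, geometry.edge_softness_px)
        img = _BG_H2B + _I0_H2B * disk * (1.0 + _TEXTURE_AMP * tex)
        if k > 0:
            img += _I0_H2B * _GRANULE_AMP * disk * _granule_field(
                shape, centre, r, pool, k
            )
        img *= 1.0 + program.noise_sd * rng.standard_normal(shape)
        h2b[i] = np.clip(img, 0.0, None)
        nv = _NV_BG + _NV_LEVEL * float(fold[i]) * disk
        nv *= 1.0 + program.noise_sd * rng.standard_normal(shape)
        nucview[i] = np.clip(nv, 0.0, None)

    if geometry.n_planes > 1:
        # trivial z-stack: attenuated copies so the max projection recovers
        # the rendered plane
        w = np.concatenate([[1.0], np.full(geometry.n_planes - 1, 0.6)])
        h2b = h2b[:, None, :, :] * w[None, :, None, None]
        nucview = nucview[:, None, :, :] * w[None, :, None, None]

    if program.fate in ("apoptosis", "necrosis"):
        dev = np.abs(area - 1.0) > 0.1
        event_frame = int(np.argmax(dev)) if dev.any() else -1
    else:
        event_frame = -1
    truth = pd.DataFrame(
        {
            "frame": np.arange(n_frames),
            "time_min": t,
            "area_true": area,
            "ccp_true": ratio,
            "nucview_true": fold,
        }
    )
    truth.attrs["event_frame"] = event_frame
    return TimeLapseStack(
        h2b=h2b,
        nucview=nucview,
        pixel_size_nm=geometry.pixel_size_nm,
        frame_interval_min=frame_interval_min,
        truth=truth,
        fate=program.fate,
        event_time_min=program.event_time_min if program.fate != "control" else None,
        seed=seed,
    )


def generate_replicates(
    program: FateProgram,
    n_cells: int,
    seed: int = 0,
    geometry: Geometry = Geometry(),
    n_frames: int = 49,
    frame_interval_min: float = 10.0,
) -> list[TimeLapseStack]:
    """``n_cells`` independent realizations of the same fate program."""
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(n_cells) % (2**31)
    return [
        generate_timelapse(program, geometry, n_frames, frame_interval_min, int(s))
        for s in seeds
    ]


def _largest_remainder(proportions: np.ndarray, n: int) -> np.ndarray:
    raw = proportions * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    short = n - counts.sum()
    order = np.argsort(-rem, kind="stable")
    counts[order[:short]] += 1
    return counts


def generate_culture(
    n_cells: int,
    fate_mix: dict[str, float] | tuple[float, ...] = (1.0, 0.0, 0.0, 0.0),
    noise_sd: float = 0.01,
    seed: int = 0,
    geometry: Geometry = Geometry(),
    n_frames: int = 49,
    frame_interval_min: float = 10.0,
    event_time_range_min: tuple[float, float] = (240.0, 300.0),
) -> tuple[list[TimeLapseStack], pd.DataFrame]:
    """Simulate a culture of ``n_cells`` nuclei with a programmed fate mix.

    ``fate_mix`` gives proportions over (control, apoptosis, necrosis,
    granulating); cells are allocated by largest-remainder rounding and then
    shuffled with the seed, so label counts are deterministic.  Returns the
    stacks plus a truth table (cell_id, fate, event_time_min, event_frame).
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    if isinstance(fate_mix, dict):
        props = np.array([float(fate_mix.get(f, 0.0)) for f in FATES])
    else:
        props = np.asarray(fate_mix, dtype=float)
        if props.size != len(FATES):
            raise ValidationError("fate_mix must give 4 proportions")
    if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
        raise ValidationError("fate proportions must be >= 0 and sum to 1")

    rng = np.random.default_rng(seed)
    counts = _largest_remainder(props, n_cells)
    fates = np.repeat(np.array(FATES), counts)
    fates = fates[rng.permutation(n_cells)]
    cell_seeds = np.random.SeedSequence(seed).generate_state(n_cells) % (2**31)

    stacks: list[TimeLapseStack] = []
    rows = []
    for i, fate in enumerate(fates):
        event = float(rng.uniform(*event_time_range_min))
        kw = dict(event_time_min=event, noise_sd=noise_sd, seed=int(cell_seeds[i]))
        program = getattr(FateProgram, fate)(**kw)
        stack = generate_timelapse(
            program, geometry, n_frames, frame_interval_min
        )
        stacks.append(stack)
        rows.append(
            {
                "cell_id": i,
                "fate": fate,
                "event_time_min": event if fate in ("apoptosis", "necrosis") else np.nan,
                "event_frame": stack.truth.attrs["event_frame"],
                "seed": int(cell_seeds[i]),
            }
        )
    return stacks, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# SMLM localization generator
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StageProfile:
    """Point-pattern parameters of one apoptotic chromatin stage (1-5).

    Stage 1 is a homogeneous (complete spatial randomness) pattern; with
    advancing stage an increasing fraction of molecules sits in Gaussian
    clusters of shrinking spread, and in stages 4-5 the nuclear disk itself
    shrinks.  ``radius_factor`` is the frozen calibration multiplier that
    pins the mean log10 count-normalized Voronoi density of the processed
    pattern to ``target_log10_density`` at ``reference_n_molecules``.
    """

    stage_index: int = 1
    nucleus_radius_nm: float = 4000.0
    radius_factor: float = 1.0
    radius_shrink_factor: float = 1.0
    clustered_fraction: float = 0.0
    cluster_sd_nm: float = 150.0
    clusters_per_um2: float = 2.0
    target_log10_density: float = -7.83
    fwhm_median_nm: float = 150.0
    fwhm_sigma_ln: float = 0.3
    blink_run_geom_p: float = 0.5
    blink_reblink_p: float = 0.3
    blink_off_max: int = 1
    jitter_sd_nm: float = 4.0
    n_frames: int = 20000
    reference_n_molecules: int = 20000

    def __post_init__(self) -> None:
        if not 0.0 <= self.clustered_fraction <= 1.0:
            raise ValidationError("clustered_fraction must be within [0, 1]")
        if self.nucleus_radius_nm <= 0:
            raise ValidationError("nucleus_radius_nm must be positive")

    @property
    def effective_radius_nm(self) -> float:
        return self.nucleus_radius_nm * self.radius_factor * self.radius_shrink_factor

    @classmethod
    def stage(cls, stage_index: int, **kw) -> "StageProfile":
        """Frozen calibrated profile for stage 1..5."""
        if stage_index not in STAGE_TABLE:
            raise ValidationError(f"stage_index must be 1..5, got {stage_index}")
        params = dict(STAGE_TABLE[stage_index])
        params.update(kw)
        return cls(stage_index=stage_index, **params)


LOCALIZATION_COLUMNS = [
    "frame",
    "x_nm",
    "y_nm",
    "sigma_nm",
    "intensity_photons",
    "molecule_id",
]


def generate_localizations(
    profile: StageProfile,
    n_molecules: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a blinking-event localization table for one nucleus.

    Molecule positions follow a Thomas-type cluster process: uniform parent
    points in the nuclear disk, ``clustered_fraction`` of molecules Gaussian
    scattered around parents, the remainder uniform.  Each molecule emits
    geometric runs of consecutive-frame events, optionally re-blinking after
    a 1..``blink_off_max``-frame gap; each event carries localization jitter,
    a lognormal spot width (with mass beyond the 65/225 nm FWHM gates) and a
    lognormal photon count.  Rows are sorted by frame.
    """
    if n_molecules < 0:
        raise ValidationError("n_molecules must be >= 0")
    rng = np.random.default_rng(seed)
    if n_molecules == 0:
        return pd.DataFrame(columns=LOCALIZATION_COLUMNS)

    radius = profile.effective_radius_nm
    n_clustered = int(round(profile.clustered_fraction * n_molecules))
    positions = np.empty((n_molecules, 2))
    positions[n_clustered:] = _sample_unit_disk(rng, n_molecules - n_clustered) * radius
    if n_clustered:
        area_um2 = np.pi * (radius / 1000.0) ** 2
        n_parents = max(1, int(rng.poisson(profile.clusters_per_um2 * area_um2)))
        parents = _sample_unit_disk(rng, n_parents) * radius
        assign = rng.integers(0, n_parents, n_clustered)
        pts = parents[assign] + rng.normal(0.0, profile.cluster_sd_nm, (n_clustered, 2))
        # keep clustered molecules inside the disk (resample stray offsets)
        for _ in range(20):
            out = np.hypot(pts[:, 0], pts[:, 1]) > radius
            if not out.any():
                break
            pts[out] = parents[assign[out]] + rng.normal(
                0.0, profile.cluster_sd_nm, (int(out.sum()), 2)
            )
        r = np.hypot(pts[:, 0], pts[:, 1])
        stray = r > radius
        if stray.any():  # project the rare stragglers onto the boundary
            pts[stray] *= (radius / r[stray])[:, None]
        positions[:n_clustered] = pts

    frames: list[int] = []
    mol_ids: list[int] = []
    ev_pos: list[np.ndarray] = []
    for m in range(n_molecules):
        f = int(rng.integers(1, profile.n_frames + 1))
        while True:
            run = int(rng.geometric(profile.blink_run_geom_p))
            for _ in range(run):
                if f > profile.n_frames:
                    break
                frames.append(f)
                mol_ids.append(m)
                f += 1
            if rng.uniform() >= profile.blink_reblink_p or f > profile.n_frames:
                break
            f += int(rng.integers(1, profile.blink_off_max + 1))
    n_events = len(frames)
    jitter = rng.normal(0.0, profile.jitter_sd_nm, (n_events, 2))
    xy = positions[np.asarray(mol_ids)] + jitter
    fwhm = profile.fwhm_median_nm * np.exp(
        rng.normal(0.0, profile.fwhm_sigma_ln, n_events)
    )
    sigma = fwhm / FWHM_FACTOR
    intensity = np.exp(rng.normal(np.log(1000.0), 0.4, n_events))

    table = pd.DataFrame(
        {
            "frame": np.asarray(frames, dtype=int),
            "x_nm": xy[:, 0],
            "y_nm": xy[:, 1],
            "sigma_nm": sigma,
            "intensity_photons": intensity,
            "molecule_id": np.asarray(mol_ids, dtype=int),
        }
    )
    table = table.sort_values("frame", kind="stable").reset_index(drop=True)
    return table
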