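"""SMLM localization post-processing and Voronoi density analysis.

Localization tables (one blinking event per row, coordinates in nm) are
filtered on spot width (FWHM gates), merged across consecutive frames to
collapse repeated detections of the same molecule, optionally cropped to the
nucleus, and then analyzed:

* polar transform about the center of mass of all localizations of the
  nucleus;
* planar Voronoi tessellation; each bounded cell's area via Gauss's
  (shoelace) formula on its vertex polygon, its inverse being the Voronoi
  density of that localization;
* densities divided by the localization count of the nucleus and
  log10-transformed, making nuclei with different counts comparable;
* 1D probability-density histograms of the log densities and 2D
  radius x density histograms, each normalized to unit area/volume.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi, QhullError

from .errors import FormatError, TessellationError, ValidationError

__all__ = [
    "FilterMergeParams",
    "PolarLocalizations",
    "VoronoiDensityResult",
    "DensityHistogram",
    "RadiusDensityHistogram",
    "GroupSummary",
    "read_localization_csv",
    "write_localization_csv",
    "filter_by_fwhm",
    "merge_blinking",
    "crop_to_nucleus",
    "to_polar",
    "shoelace_area",
    "voronoi_density",
    "normalize_log",
    "density_pdf",
    "radius_density_pdf",
    "summarize_group",
]

FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: ThunderSTORM-style CSV header -> canonical column name
_DIALECT = {
    "frame": "frame",
    "x [nm]": "x_nm",
    "y [nm]": "y_nm",
    "sigma [nm]": "sigma_nm",
    "intensity [photon]": "intensity_photons",
}
_REQUIRED = ["frame", "x_nm", "y_nm", "sigma_nm"]


@dataclass(frozen=True)
class FilterMergeParams:
    """Spot-width gates and blinking-merge parameters.

    FWHM gates of 65-225 nm bracket plausible point-spread widths; the merge
    links localizations within 20 nm across runs of frames broken by at most
    one off frame, with no limit on frames per molecule.
    """

    fwhm_min_nm: float = 65.0
    fwhm_max_nm: float = 225.0
    fwhm_factor: float = FWHM_FACTOR
    merge_max_distance_nm: float = 20.0
    merge_max_off_frames: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.fwhm_min_nm < self.fwhm_max_nm:
            raise ValidationError("need 0 < fwhm_min_nm < fwhm_max_nm")
        if self.merge_max_distance_nm <= 0:
            raise ValidationError("merge_max_distance_nm must be positive")


def read_localization_csv(path) -> pd.DataFrame:
    """Read a ThunderSTORM-style localization CSV into canonical columns.

    Honors the quoted unit-suffixed headers; unknown columns are preserved.
    Raises :class:`FormatError` naming a missing required column, or citing
    the (1-based, header-inclusive) line of a non-numeric coordinate.
    """
    df = pd.read_csv(path)
    df = df.rename(columns={k: v for k, v in _DIALECT.items() if k in df.columns})
    for col in _REQUIRED:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    for col in _REQUIRED + (
        ["intensity_photons"] if "intensity_photons" in df.columns else []
    ):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header line + 1-based offset
            raise FormatError(f"non-numeric value in column {col!r} at line {line}")
        df[col] = coerced
    return df.sort_values("frame", kind="stable").reset_index(drop=True)


def write_localization_csv(table: pd.DataFrame, path) -> None:
    """Write a localization table using the ThunderSTORM-style dialect."""
    inv = {v: k for k, v in _DIALECT.items()}
    table.rename(columns=inv).to_csv(path, index=False)


def filter_by_fwhm(
    table: pd.DataFrame, params: FilterMergeParams | None = None
) -> pd.DataFrame:
    """Drop localizations whose FWHM falls outside the [65, 225] nm gates.

    FWHM is ``fwhm_factor * sigma_nm``; boundary values are retained (the
    gates exclude strictly smaller/bigger widths).
    """
    p = params or FilterMergeParams()
    fwhm = p.fwhm_factor * table["sigma_nm"].to_numpy(dtype=float)
    keep = (fwhm >= p.fwhm_min_nm) & (fwhm <= p.fwhm_max_nm)
    return table.loc[keep].reset_index(drop=True)


def merge_blinking(
    table: pd.DataFrame, params: FilterMergeParams | None = None
) -> pd.DataFrame:
    """Collapse repeated detections of one molecule into a single row.

    Greedy frame-ordered linking: localizations join the nearest open chain
    whose last position lies within ``merge_max_distance_nm`` and whose last
    frame is at most ``1 + merge_max_off_frames`` behind (ties broken by
    input order; one joiner per chain per frame).  A merged row carries the
    intensity-weighted mean position, the first frame, the summed intensity
    and the event count; chains may span any number of frames.
    """
    p = params or FilterMergeParams()
    if len(table) == 0:
        return table.copy()
    if not table["frame"].is_monotonic_increasing:
        warnings.warn("merge_blinking input not sorted by frame; sorting")
        table = table.sort_values("frame", kind="stable")
    frames = table["frame"].to_numpy(dtype=int)
    x = table["x_nm"].to_numpy(dtype=float)
    y = table["y_nm"].to_numpy(dtype=float)
    if "intensity_photons" in table.columns:
        inten = table["intensity_photons"].to_numpy(dtype=float)
    else:
        inten = np.ones(len(table))
    sigma = table["sigma_nm"].to_numpy(dtype=float)
    has_mol = "molecule_id" in table.columns
    mol = table["molecule_id"].to_numpy() if has_mol else None

    last_x: list[float] = []
    last_y: list[float] = []
    last_f: list[int] = []
    sum_w: list[float] = []
    sum_wx: list[float] = []
    sum_wy: list[float] = []
    sum_ws: list[float] = []
    first_frame: list[int] = []
    first_mol: list = []
    n_events: list[int] = []
    by_frame: dict[int, list[int]] = {}  # last frame -> chain indices

    max_gap = 1 + p.merge_max_off_frames
    for i in range(len(table)):
        f = int(frames[i])
        candidates = [
            c for g in range(f - max_gap, f) for c in by_frame.get(g, ())
        ]
        best, best_d = -1, p.merge_max_distance_nm
        for c in candidates:
            d = math.hypot(x[i] - last_x[c], y[i] - last_y[c])
            if d < best_d or (d == best_d and best == -1):
                best, best_d = c, d
        w = max(inten[i], 1e-12)
        if best >= 0:
            c = best
            by_frame[last_f[c]].remove(c)
            last_x[c], last_y[c] = x[i], y[i]
            last_f[c] = f
            sum_w[c] += w
            sum_wx[c] += w * x[i]
            sum_wy[c] += w * y[i]
            sum_ws[c] += w * sigma[i]
            n_events[c] += 1
        else:
            c = len(last_x)
            last_x.append(x[i])
            last_y.append(y[i])
            last_f.append(f)
            sum_w.append(w)
            sum_wx.append(w * x[i])
            sum_wy.append(w * y[i])
            sum_ws.append(w * sigma[i])
            first_frame.append(f)
            first_mol.append(mol[i] if has_mol else None)
            n_events.append(1)
        by_frame.setdefault(f, []).append(c)

    out = pd.DataFrame(
        {
            "frame": first_frame,
            "x_nm": np.asarray(sum_wx) / np.asarray(sum_w),
            "y_nm": np.asarray(sum_wy) / np.asarray(sum_w),
            "sigma_nm": np.asarray(sum_ws) / np.asarray(sum_w),
            "intensity_photons": sum_w,
            "n_events": n_events,
        }
    )
    if has_mol:
        out["molecule_id"] = first_mol
    return out.sort_values("frame", kind="stable").reset_index(drop=True)


def crop_to_nucleus(
    table: pd.DataFrame,
    x_range: tuple[float, float],
    y_range: tuple[float, float],
) -> pd.DataFrame:
    """Keep localizations inside the closed rectangle x_range x y_range."""
    if not all(np.isfinite([*x_range, *y_range])):
        raise ValidationError("crop ranges must be finite")
    x = table["x_nm"].to_numpy(dtype=float)
    y = table["y_nm"].to_numpy(dtype=float)
    keep = (x >= x_range[0]) & (x <= x_range[1]) & (y >= y_range[0]) & (y <= y_range[1])
    out = table.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("crop_to_nucleus removed every localization")
    return out


@dataclass
class PolarLocalizations:
    """Localizations in polar coordinates about their center of mass."""

    r_nm: np.ndarray
    theta: np.ndarray
    origin: tuple[float, float]


def to_polar(table: pd.DataFrame) -> PolarLocalizations:
    """Polar transform with the (unweighted) centroid as origin."""
    if len(table) == 0:
        raise ValidationError("to_polar needs at least one localization")
    x = table["x_nm"].to_numpy(dtype=float)
    y = table["y_nm"].to_numpy(dtype=float)
    cx, cy = x.mean(), y.mean()
    dx, dy = x - cx, y - cy
    return PolarLocalizations(
        r_nm=np.hypot(dx, dy), theta=np.arctan2(dy, dx), origin=(cx, cy)
    )


def shoelace_area(vertices: np.ndarray) -> float:
    """Polygon area by Gauss's area formula on ordered vertices."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass
class VoronoiDensityResult:
    """Per-localization Voronoi cell areas and densities for one nucleus.

    ``table`` has one row per localization with ``cell_area_nm2``,
    ``raw_density`` (1/area) and ``boundary_excluded`` (convex-hull
    generators with unbounded cells carry no density); ``normalize_log``
    appends the count-normalized and log10 columns.  ``n_loc`` is the
    localization count of the nucleus used for normalization.
    """

    table: pd.DataFrame
    n_loc: int
    n_boundary_excluded: int
    group: str | None = None

    @property
    def log10_norm_density(self) -> np.ndarray:
        if "log10_norm_density" not in self.table.columns:
            raise ValidationError("call normalize_log first")
        vals = self.table["log10_norm_density"].to_numpy(dtype=float)
        return vals[~self.table["boundary_excluded"].to_numpy(dtype=bool)]


def voronoi_density(table: pd.DataFrame, group: str | None = None) -> VoronoiDensityResult:
    """Voronoi-tessellate the localizations and invert bounded cell areas.

    Cell areas come from the shoelace formula on each bounded cell's vertex
    polygon (vertices angularly ordered; Voronoi cells are convex).
    Duplicated coordinates are de-degenerated by a <= 1e-6 nm deterministic
    jitter with a warning; all-collinear input raises
    :class:`TessellationError`.
    """
    if len(table) < 4:
        raise ValidationError("voronoi_density needs at least 4 localizations")
    pts = table[["x_nm", "y_nm"]].to_numpy(dtype=float).copy()
    _, first = np.unique(pts, axis=0, return_index=True)
    dup = np.setdiff1d(np.arange(len(pts)), first)
    if dup.size:
        warnings.warn(f"{dup.size} duplicated coordinates perturbed by <=1e-6 nm")
        jit = np.random.default_rng(0).uniform(-1e-6, 1e-6, (dup.size, 2))
        pts[dup] += jit
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise TessellationError("localizations are collinear; tessellation undefined")
    try:
        vor = Voronoi(pts)
    except QhullError as err:  # pragma: no cover - degenerate qhull failures
        raise TessellationError(str(err)) from err

    n = len(pts)
    areas = np.full(n, np.nan)
    excluded = np.zeros(n, dtype=bool)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if len(region) < 3 or -1 in region:
            excluded[i] = True
            continue
        poly = vor.vertices[region]
        order = np.argsort(np.arctan2(*(poly - poly.mean(axis=0)).T[::-1]))
        areas[i] = shoelace_area(poly[order])
    out = table.copy().reset_index(drop=True)
    out["cell_area_nm2"] = areas
    with np.errstate(divide="ignore"):
        out["raw_density"] = np.where(excluded, np.nan, 1.0 / areas)
    out["boundary_excluded"] = excluded
    return VoronoiDensityResult(
        table=out,
        n_loc=n,
        n_boundary_excluded=int(excluded.sum()),
        group=group,
    )


def normalize_log(result: VoronoiDensityResult) -> VoronoiDensityResult:
    """Divide densities by the nucleus's localization count; log10-transform."""
    if result.n_loc <= 0:
        raise ValidationError("n_loc must be positive")
    t = result.table
    t["norm_density"] = t["raw_density"] / result.n_loc
    with np.errstate(divide="ignore", invalid="ignore"):
        t["log10_norm_density"] = np.log10(t["norm_density"])
    return result


@dataclass
class DensityHistogram:
    """1D probability-density histogram over log10 normalized density."""

    edges: np.ndarray
    values: np.ndarray

    @property
    def area(self) -> float:
        return float(np.sum(self.values * np.diff(self.edges)))


@dataclass
class RadiusDensityHistogram:
    """2D radius x log-density probability-density histogram.

    ``color_clip`` records the rendering color-scale limits only; the stored
    values are the full, volume-normalized probability densities.
    """

    r_edges: np.ndarray
    d_edges: np.ndarray
    values: np.ndarray  # shape (n_r_bins, n_d_bins)
    color_clip: tuple[float, float] = (1e-5, 1e-3)

    @property
    def volume(self) -> float:
        dr = np.diff(self.r_edges)[:, None]
        dd = np.diff(self.d_edges)[None, :]
        return float(np.sum(self.values * dr * dd))


def _clip_into(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    # clip out-of-limit values into the edge bins (count conserving)
    span = hi - lo
    return np.clip(values, lo, hi - 1e-9 * span)


def density_pdf(
    groups: dict[str, np.ndarray],
    bins: int = 50,
    limits: tuple[float, float] = (-10.0, -5.0),
) -> dict[str, DensityHistogram]:
    """Per-group PDF histograms of log10 normalized density on shared bins.

    Bin values are counts divided by (total count x bin width) so each
    histogram integrates to 1; out-of-limit values land in the edge bins.
    Empty groups are omitted with a warning.
    """
    edges = np.linspace(limits[0], limits[1], bins + 1)
    out: dict[str, DensityHistogram] = {}
    for name, values in groups.items():
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values)]
        if values.size == 0:
            warnings.warn(f"density_pdf: group {name!r} empty; omitted")
            continue
        counts, _ = np.histogram(_clip_into(values, *limits), bins=edges)
        width = np.diff(edges)
        out[name] = DensityHistogram(edges=edges, values=counts / (values.size * width))
    return out


def radius_density_pdf(
    polar: PolarLocalizations,
    result: VoronoiDensityResult,
    r_limits: tuple[float, float] = (0.0, 8000.0),
    d_limits: tuple[float, float] = (-10.0, -5.0),
    bins: tuple[int, int] = (64, 50),
    color_clip: tuple[float, float] = (1e-5, 1e-3),
) -> RadiusDensityHistogram:
    """2D histogram of (radius, log10 normalized density), unit volume.

    Boundary-excluded localizations are dropped; the radius and density
    arrays must be aligned row-for-row.
    """
    t = result.table
    if len(t) != len(polar.r_nm):
        raise ValidationError("polar and density tables have mismatched lengths")
    keep = ~t["boundary_excluded"].to_numpy(dtype=bool)
    r = _clip_into(polar.r_nm[keep], *r_limits)
    d = _clip_into(t["log10_norm_density"].to_numpy(dtype=float)[keep], *d_limits)
    r_edges = np.linspace(r_limits[0], r_limits[1], bins[0] + 1)
    d_edges = np.linspace(d_limits[0], d_limits[1], bins[1] + 1)
    counts, _, _ = np.histogram2d(r, d, bins=(r_edges, d_edges))
    dr = np.diff(r_edges)[:, None]
    dd = np.diff(d_edges)[None, :]
    values = counts / (counts.sum() * dr * dd)
    return RadiusDensityHistogram(
        r_edges=r_edges, d_edges=d_edges, values=values, color_clip=color_clip
    )


@dataclass
class GroupSummary:
    """Pooled descriptive summary of one experimental group."""

    mean_log10_norm_density: float
    sd_log10_norm_density: float
    n_localizations: int
    n_nuclei: int
    group: str | None = None


def summarize_group(
    results: VoronoiDensityResult | list[VoronoiDensityResult],
    group: str | None = None,
) -> GroupSummary:
    """Pooled mean +/- SD of log10 normalized density over a group of nuclei."""
    if isinstance(results, VoronoiDensityResult):
        results = [results]
    values = [r.log10_norm_density for r in results]
    pooled = np.concatenate(values) if values else np.array([])
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        raise ValidationError("summarize_group needs at least one density")
    sd = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
    return GroupSummary(
        mean_log10_norm_density=float(pooled.mean()),
        sd_log10_norm_density=sd,
        n_localizations=int(pooled.size),
        n_nuclei=len(results),
        group=group if group is not None else (results[0].group if results else None),
    )
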