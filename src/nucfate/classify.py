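"""Trajectory-level classification of neuronal nuclei.

Implements the rule-based, five-step assignment of each nucleus to one of
four fates (apoptotic, necrotic, granulating, no change) from its
baseline-normalized trajectory, the 14-fold caspase-reporter event rule,
alignment of trajectories to the first clear nuclear-size change, and
descriptive culture/stage summaries.

Step 1 labels vitality from the finite-difference gradient of the normalized
reporter signal: "surviving" if every gradient stays below 0.035, "dying" if
a gradient in the final recording window exceeds 0.8, otherwise unlabeled.
Steps 2-4 flag final-versus-first-frame changes of normalized CCP and area;
step 5 resolves the flags with precedence apoptotic > necrotic > granulating
> no change:

* apoptotic   - dying (step 1) and final CCP < 1.1x first (step 2, granules
  cleared by terminal condensation);
* necrotic    - final area <= 0.75x first (step 3), not surviving, not
  already apoptotic;
* granulating - final CCP at least 0.5 above first (step 4), not already
  assigned;
* no change   - everything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .metrics import NucleusTrajectory

__all__ = [
    "ClassifierThresholds",
    "FateLabel",
    "AlignedTrajectorySet",
    "CultureSummary",
    "nucview_gradient",
    "label_vitality",
    "classify_fate",
    "detect_apoptotic_event",
    "align_to_size_change",
    "summarize_culture",
    "summarize_by_stage",
]


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision thresholds of the five-step fate classification.

    Defaults are the study's printed values; ``end_window_frames`` (the
    length of the "end of recording" window scanned for a dying-cell
    gradient) and ``absolute_gradients`` are implementation choices.
    """

    surviving_gradient_max: float = 0.035
    dying_end_gradient_min: float = 0.8
    apoptotic_final_ccp_max_ratio: float = 1.1
    necrotic_final_size_max_ratio: float = 0.75
    granulating_final_ccp_min_increase: float = 0.5
    event_fold: float = 14.0
    end_window_frames: int = 3
    absolute_gradients: bool = False

    def __post_init__(self) -> None:
        if min(
            self.surviving_gradient_max,
            self.dying_end_gradient_min,
            self.apoptotic_final_ccp_max_ratio,
            self.necrotic_final_size_max_ratio,
            self.granulating_final_ccp_min_increase,
            self.event_fold,
        ) <= 0:
            raise ValidationError("all thresholds must be positive")
        if self.surviving_gradient_max >= self.dying_end_gradient_min:
            raise ValidationError(
                "surviving_gradient_max must be below dying_end_gradient_min"
            )


@dataclass(frozen=True)
class FateLabel:
    """Outcome of the step-wise classification for one nucleus."""

    fate: str  # apoptotic | necrotic | granulating | no_change
    vitality: str  # surviving | dying | unlabeled
    step2_no_final_granules: bool
    step3_shrunk: bool
    step4_granulating: bool
    excluded: bool = False
    exclusion_reason: str = ""


def nucview_gradient(normalized_nucview: np.ndarray) -> np.ndarray:
    """Finite-difference gradient g[i] = v[i+1] - v[i] of the reporter series."""
    v = np.asarray(normalized_nucview, dtype=float)
    if v.size < 2:
        raise ValidationError("gradient needs at least 2 frames")
    return np.diff(v)


def label_vitality(
    traj: NucleusTrajectory, thresholds: ClassifierThresholds | None = None
) -> str:
    """Step 1: 'surviving', 'dying' or 'unlabeled' from the reporter gradient."""
    th = thresholds or ClassifierThresholds()
    g = nucview_gradient(traj.norm_nucview)
    if th.absolute_gradients:
        g = np.abs(g)
    if np.all(g < th.surviving_gradient_max):
        return "surviving"
    end = g[-th.end_window_frames :]
    if np.max(end) > th.dying_end_gradient_min:
        return "dying"
    return "unlabeled"


def classify_fate(
    traj: NucleusTrajectory, thresholds: ClassifierThresholds | None = None
) -> FateLabel:
    """Steps 2-5: assign exactly one fate to a valid trajectory.

    Trajectories flagged invalid (more than one nucleus in the ROI at any
    frame) are excluded with a reason code instead of being classified.
    """
    th = thresholds or ClassifierThresholds()
    if not traj.all_valid:
        return FateLabel(
            fate="excluded",
            vitality="unlabeled",
            step2_no_final_granules=False,
            step3_shrunk=False,
            step4_granulating=False,
            excluded=True,
            exclusion_reason="multi-nucleus ROI",
        )
    vitality = label_vitality(traj, th)
    ccp_first = traj.norm_ccp[0]
    ccp_last = traj.norm_ccp[-1]
    area_first = traj.norm_area[0]
    area_last = traj.norm_area[-1]
    step2 = ccp_last < th.apoptotic_final_ccp_max_ratio * ccp_first
    step3 = area_last <= th.necrotic_final_size_max_ratio * area_first
    step4 = (ccp_last - ccp_first) >= th.granulating_final_ccp_min_increase

    if vitality == "dying" and step2:
        fate = "apoptotic"
    elif step3 and vitality != "surviving":
        fate = "necrotic"
    elif step4:
        fate = "granulating"
    else:
        fate = "no_change"
    return FateLabel(
        fate=fate,
        vitality=vitality,
        step2_no_final_granules=bool(step2),
        step3_shrunk=bool(step3),
        step4_granulating=bool(step4),
    )


def detect_apoptotic_event(
    traj: NucleusTrajectory, thresholds: ClassifierThresholds | None = None
) -> tuple[bool, int | None]:
    """14-fold reporter rule: ``True`` iff the normalized signal surpasses 14.

    Returns ``(detected, first_crossing_frame)``; the inequality is strict
    ("surpassed"), so a peak of exactly 14.0 is no event.
    """
    th = thresholds or ClassifierThresholds()
    above = traj.norm_nucview > th.event_fold
    if not above.any():
        return False, None
    return True, int(np.argmax(above))


@dataclass
class AlignedTrajectorySet:
    """Trajectories on a relative time axis anchored at the size change.

    ``t0_frame`` holds, per cell, the first frame at which the normalized
    area deviates from 1 by more than ``deviation_threshold`` for at least
    ``persistence`` consecutive frames (-1 when no change was detected;
    those cells are excluded from aligned averages).
    """

    trajectories: list[NucleusTrajectory]
    t0_frame: np.ndarray
    direction: np.ndarray  # +1 swelling, -1 shrinkage, 0 undetected
    deviation_threshold: float
    persistence: int
    frame_interval_min: float = 10.0

    @property
    def aligned(self) -> np.ndarray:
        return self.t0_frame >= 0

    def relative_time_min(self, i: int) -> np.ndarray:
        """Relative time axis of cell ``i`` (t = 0 at its size change)."""
        traj = self.trajectories[i]
        return traj.time_min - self.t0_frame[i] * self.frame_interval_min

    def mean_at(self, rel_time_min: float, series: str = "norm_area") -> float:
        """Mean of a normalized series across aligned cells at one relative time."""
        values = []
        for i, traj in enumerate(self.trajectories):
            if self.t0_frame[i] < 0:
                continue
            idx = self.t0_frame[i] + int(round(rel_time_min / self.frame_interval_min))
            if 0 <= idx < traj.n_frames:
                values.append(getattr(traj, series)[idx])
        if not values:
            raise ValidationError(f"no aligned cell covers t = {rel_time_min} min")
        return float(np.mean(values))


def align_to_size_change(
    trajs: list[NucleusTrajectory],
    deviation_threshold: float = 0.1,
    persistence: int = 2,
    frame_interval_min: float = 10.0,
) -> AlignedTrajectorySet:
    """Anchor each trajectory at its first clear, persistent size change."""
    t0 = np.full(len(trajs), -1, dtype=int)
    direction = np.zeros(len(trajs), dtype=int)
    for i, traj in enumerate(trajs):
        dev = np.abs(traj.norm_area - 1.0) > deviation_threshold
        run = 0
        for j, d in enumerate(dev):
            run = run + 1 if d else 0
            if run >= persistence:
                t0[i] = j - persistence + 1
                direction[i] = 1 if traj.norm_area[t0[i]] > 1.0 else -1
                break
    return AlignedTrajectorySet(
        trajectories=list(trajs),
        t0_frame=t0,
        direction=direction,
        deviation_threshold=deviation_threshold,
        persistence=persistence,
        frame_interval_min=frame_interval_min,
    )


@dataclass
class CultureSummary:
    """Counts and percentages of fates across one or more cultures."""

    counts: dict[str, int]
    percentages: dict[str, float]
    n_cells: int
    n_cultures: int
    percent_nucview_positive: float | None = None


def summarize_culture(
    labels: list[FateLabel],
    events: list[bool] | None = None,
    n_cultures: int = 1,
    decimals: int = 1,
) -> CultureSummary:
    """Tabulate fate counts and percentages (excluded cells are dropped).

    Percentages are ``100 * count / n_cells`` rounded to ``decimals``; the
    fraction of reporter-positive cells is included when ``events`` is given.
    """
    kept = [lab for lab in labels if not lab.excluded]
    if not kept:
        raise ValidationError("summarize_culture needs at least one labeled cell")
    n = len(kept)
    counts = {f: 0 for f in ("no_change", "apoptotic", "necrotic", "granulating")}
    for lab in kept:
        counts[lab.fate] += 1
    percentages = {f: round(100.0 * c / n, decimals) for f, c in counts.items()}
    pct_events = None
    if events is not None:
        pct_events = round(100.0 * sum(bool(e) for e in events) / len(events), decimals)
    return CultureSummary(
        counts=counts,
        percentages=percentages,
        n_cells=n,
        n_cultures=n_cultures,
        percent_nucview_positive=pct_events,
    )


def summarize_by_stage(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-stage mean +/- SEM of nuclear size and intensity metrics.

    ``measurements`` needs a ``stage`` column plus any of ``area``,
    ``edge_count``, ``h2b_mean``, ``nucview_mean``.  Stages with a single
    cell get SEM 0 and ``sem_defined=False``.
    """
    if "stage" not in measurements.columns or len(measurements) == 0:
        raise ValidationError("summarize_by_stage needs a nonempty 'stage' column")
    metrics = [
        c for c in ("area", "edge_count", "h2b_mean", "nucview_mean")
        if c in measurements.columns
    ]
    rows = []
    for stage, grp in measurements.groupby("stage"):
        row: dict[str, float] = {"stage": stage, "n": len(grp)}
        row["sem_defined"] = len(grp) > 1
        for m in metrics:
            row[f"{m}_mean"] = grp[m].mean()
            row[f"{m}_sem"] = grp[m].sem() if len(grp) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows).sort_values("stage").reset_index(drop=True)
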