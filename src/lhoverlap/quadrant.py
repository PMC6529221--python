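"""Four-quadrant valence assay and Flybowl locomotion metrics.

Groups of flies walk in a circular arena whose four 90-degree sectors can be
illuminated in opposing pairs with red light to activate CsChrimson-expressing
neurons.  The preference index at a frame is

    PI = (n flies in Q2 and Q3 - n flies in Q1 and Q4) / (total flies)

with the sector labels laid out so that Q2+Q3 and Q1+Q4 form the two
illuminable pairs.  A trial is two minutes: 30 s dark, 30 s with one pair lit,
30 s dark, 30 s with the other pair lit.  The single-value PI for a trial
averages the per-frame PI over the final 5 s of each of the two light-ON
epochs.  Locomotion deltas compare the 5 s before light onset with the first
5 s of stimulation, restricted to flies that stayed inside the lit pair for
the whole stimulation window.

Positions arrive as tracked centroid coordinates (mm); no video processing
happens here.  The tracker pixel scale is ~0.12 mm per pixel, and locomotion
metrics are reported in pixels per second to match the assay's convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: tracker pixel size, mm per pixel
MM_PER_PX = 0.12
#: displacements below this many pixels contribute zero turning (angle noise)
TURN_NOISE_FLOOR_PX = 0.5

QUADRANT_PAIRS = ((2, 3), (1, 4))


@dataclass(frozen=True)
class Epoch:
    """One stimulation-schedule interval.

    ``quadrants`` is a pair of quadrant indices for quadrant illumination,
    the string ``"whole_field"`` for Flybowl full-field epochs, or ``None``
    for dark (OFF) epochs.  ``intensity`` is in uW/mm^2.
    """

    start_s: float
    end_s: float
    quadrants: tuple[int, ...] | str | None = None
    intensity: float | None = None

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValueError(f"epoch end {self.end_s} <= start {self.start_s}")
        if isinstance(self.quadrants, list):
            object.__setattr__(self, "quadrants", tuple(self.quadrants))

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def is_on(self) -> bool:
        return self.quadrants is not None


def validate_schedule(schedule: list[Epoch]) -> None:
    """Epochs must be non-overlapping and time-ordered."""
    ordered = sorted(schedule, key=lambda e: e.start_s)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.start_s < prev.end_s - 1e-9:
            raise ValueError(
                f"overlapping schedule epochs: [{prev.start_s},{prev.end_s}) and "
                f"[{nxt.start_s},{nxt.end_s})"
            )


def schedule_to_yaml(schedule: list[Epoch], path) -> None:
    rows = []
    for e in schedule:
        row = {"start_s": float(e.start_s), "end_s": float(e.end_s)}
        if e.quadrants == "whole_field":
            row["whole_field"] = True
        elif e.quadrants is not None:
            row["quadrants"] = list(e.quadrants)
        if e.intensity is not None:
            row["intensity_uW_mm2"] = float(e.intensity)
        rows.append(row)
    Path(path).write_text(yaml.safe_dump({"epochs": rows}, sort_keys=False))


def schedule_from_yaml(path) -> list[Epoch]:
    doc = yaml.safe_load(Path(path).read_text())
    epochs = []
    for row in doc["epochs"]:
        quadrants = None
        if row.get("whole_field"):
            quadrants = "whole_field"
        elif "quadrants" in row:
            quadrants = tuple(row["quadrants"])
        epochs.append(
            Epoch(
                start_s=row["start_s"],
                end_s=row["end_s"],
                quadrants=quadrants,
                intensity=row.get("intensity_uW_mm2"),
            )
        )
    validate_schedule(epochs)
    return epochs


@dataclass(frozen=True)
class ArenaGeometry:
    """Circular arena; quadrants are the four 90-degree angular sectors."""

    diameter_mm: float = 100.0
    center_mm: tuple[float, float] = (0.0, 0.0)

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclass
class TrialTrack:
    """Per-frame fly positions for one trial.

    ``frames`` columns: ``time_s, fly_id, x_mm, y_mm``; times are strictly
    increasing within each fly and positions stay inside the arena.
    """

    frames: pd.DataFrame
    arena: ArenaGeometry
    schedule: list[Epoch]
    frame_rate: float

    def __post_init__(self):
        required = {"time_s", "fly_id", "x_mm", "y_mm"}
        missing = required - set(self.frames.columns)
        if missing:
            raise ValueError(f"track frame table missing columns {sorted(missing)}")
        validate_schedule(self.schedule)
        for fly_id, grp in self.frames.groupby("fly_id"):
            t = grp["time_s"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"times not strictly increasing for fly {fly_id}")
        cx, cy = self.arena.center_mm
        r = np.hypot(self.frames["x_mm"] - cx, self.frames["y_mm"] - cy)
        if np.any(r > self.arena.radius_mm + 1e-6):
            raise ValueError("positions outside the arena boundary")

    @property
    def n_flies(self) -> int:
        return self.frames["fly_id"].nunique()

    def to_csv(self, path) -> None:
        self.frames.to_csv(path, index=False, columns=["time_s", "fly_id", "x_mm", "y_mm"])

    @classmethod
    def from_csv(cls, path, arena: ArenaGeometry, schedule: list[Epoch], frame_rate: float):
        return cls(pd.read_csv(path), arena=arena, schedule=schedule, frame_rate=frame_rate)


def assign_quadrant(x: float, y: float, arena: ArenaGeometry) -> int:
    """Quadrant (1-4) of a point, by angular sector.

    Sectors: Q1 = [0, 90), Q2 = [90, 180), Q3 = [180, 270), Q4 = [270, 360)
    degrees, so Q2+Q3 is the left half-disk and Q1+Q4 the right — the two
    illuminable opposing pairs of the PI sign convention.  A point exactly on
    a boundary ray goes to the lower-indexed adjacent quadrant; the centre
    point goes to Q1 by convention.
    """
    cx, cy = arena.center_mm
    dx, dy = x - cx, y - cy
    if math.hypot(dx, dy) > arena.radius_mm + 1e-6:
        raise ValueError(f"point ({x}, {y}) outside arena")
    theta = math.degrees(math.atan2(dy, dx)) % 360.0
    k = theta / 90.0
    if abs(k - round(k)) < 1e-12:  # on a boundary ray
        kr = int(round(k)) % 4
        return 1 if kr == 0 else kr
    return int(k) + 1


def _quadrants_vec(frames: pd.DataFrame, arena: ArenaGeometry) -> np.ndarray:
    cx, cy = arena.center_mm
    dx = frames["x_mm"].to_numpy() - cx
    dy = frames["y_mm"].to_numpy() - cy
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0
    k = theta / 90.0
    q = (k.astype(int) + 1).astype(int)
    on_ray = np.abs(k - np.round(k)) < 1e-12
    kr = np.round(k[on_ray]).astype(int) % 4
    q[on_ray] = np.where(kr == 0, 1, kr)
    return q


def pi_timeseries(track: TrialTrack, normalize_on: bool = True, bin_s: float | None = None):
    """Per-frame preference index series.

    With ``normalize_on`` (default) the quadrant labels are aligned per ON
    epoch so the illuminated pair maps to Q2/Q3, making positive PI mean
    attraction to light in both epochs even though the assay alternates the
    lit pair.  With ``normalize_on=False`` the raw fixed-label formula is
    used, in which case illuminating Q1/Q4 and full attraction gives PI = -1.

    Returns a DataFrame with columns ``time_s, pi, n_flies`` (``pi`` is NaN,
    and flagged in ``n_flies == 0``, for frames with no tracked flies).
    Optional ``bin_s`` averages the per-frame series into time bins.
    """
    frames = track.frames
    q = _quadrants_vec(frames, track.arena)
    in_23 = np.isin(q, (2, 3))
    df = pd.DataFrame(
        {"time_s": frames["time_s"].to_numpy(), "in23": in_23.astype(int)}
    )
    grouped = df.groupby("time_s", sort=True)["in23"].agg(["sum", "count"])
    n23 = grouped["sum"].to_numpy(dtype=float)
    total = grouped["count"].to_numpy(dtype=float)
    times = grouped.index.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = (2.0 * n23 - total) / total
    if normalize_on:
        for e in track.schedule:
            if e.is_on and e.quadrants != "whole_field":
                if set(e.quadrants) == {1, 4}:
                    sel = (times >= e.start_s) & (times < e.end_s)
                    pi[sel] = -pi[sel]
    out = pd.DataFrame({"time_s": times, "pi": pi, "n_flies": total.astype(int)})
    if bin_s is not None:
        out["bin"] = np.floor(out["time_s"] / bin_s)
        out = (
            out.groupby("bin")
            .agg(time_s=("time_s", "mean"), pi=("pi", "mean"), n_flies=("n_flies", "min"))
            .reset_index(drop=True)
        )
    return out


def single_value_pi(series: pd.DataFrame, schedule: list[Epoch], window_s: float = 5.0) -> float:
    """Trial-level PI: mean over the final ``window_s`` of each of the two
    light-ON epochs, the two window means averaged with equal weight."""
    on = [e for e in schedule if e.is_on and e.quadrants != "whole_field"]
    if len(on) != 2:
        raise ValueError(f"expected exactly two ON epochs, found {len(on)}")
    means = []
    for e in on:
        if e.duration_s < window_s - 1e-9:
            raise ValueError(
                f"ON epoch [{e.start_s},{e.end_s}) shorter than the {window_s} s window"
            )
        sel = (series["time_s"] >= e.end_s - window_s) & (series["time_s"] < e.end_s)
        if not sel.any():
            raise ValueError(f"no frames in the final {window_s} s of epoch at {e.start_s}")
        means.append(float(np.nanmean(series.loc[sel, "pi"])))
    return float(np.mean(means))


# ---------------------------------------------------------------------------
# locomotion metrics
# ---------------------------------------------------------------------------

DELTA_METRICS = ("forward_locomotion", "turning", "distance_from_center")


def _interp_fly(grp: pd.DataFrame, times: np.ndarray, max_gap: int):
    """Reindex one fly's track to the full frame grid, linearly interpolating
    runs of up to ``max_gap`` missing frames.  Returns (x, y) with NaN where
    the gap was too long."""
    s = grp.set_index("time_s")
    x = s["x_mm"].reindex(times)
    y = s["y_mm"].reindex(times)
    x = x.interpolate(method="index", limit=max_gap, limit_area="inside")
    y = y.interpolate(method="index", limit=max_gap, limit_area="inside")
    return x.to_numpy(), y.to_numpy()


def _metric_series(x, y, arena: ArenaGeometry, metric: str, frame_rate: float) -> np.ndarray:
    """Per-frame value of a locomotion metric, in tracker pixels."""
    px = 1.0 / MM_PER_PX  # px per mm
    if metric == "distance_from_center":
        cx, cy = arena.center_mm
        return np.hypot(x - cx, y - cy) * px
    dx = np.diff(x)
    dy = np.diff(y)
    disp_px = np.hypot(dx, dy) * px
    if metric == "forward_locomotion":
        speed = disp_px * frame_rate  # px/s
        return np.concatenate([[np.nan], speed])
    if metric == "turning":
        heading = np.arctan2(dy, dx)
        dh = np.diff(heading)
        dh = np.degrees(np.abs(np.arctan2(np.sin(dh), np.cos(dh))))
        # sub-noise displacements would blow up the heading angle
        quiet = (disp_px[:-1] < TURN_NOISE_FLOOR_PX) | (disp_px[1:] < TURN_NOISE_FLOOR_PX)
        dh[quiet] = 0.0
        turn = dh * frame_rate  # deg/s
        return np.concatenate([[np.nan, np.nan], turn])
    raise ValueError(f"unknown metric {metric!r}; choose from {DELTA_METRICS}")


def delta_metric(
    track: TrialTrack,
    metric: str,
    schedule: list[Epoch] | None = None,
    window_s: float = 5.0,
    epoch_index: int = 0,
    max_interp_frames: int = 3,
) -> pd.DataFrame:
    """Normalised stimulus-induced change of a locomotion metric, per fly.

    For the chosen ON epoch, the metric is averaged over the ``window_s``
    immediately before light onset (pre) and the first ``window_s`` of
    stimulation (stim); delta = (stim - pre) / pre.  Only flies that remained
    in the lit quadrant pair for the entire stimulation window are included;
    excluded flies are reported with a reason.

    Returns a DataFrame with columns ``fly_id, pre_mean, stim_mean, delta,
    included, reason``; an all-excluded result is returned (not raised) so
    callers can report it.
    """
    schedule = schedule if schedule is not None else track.schedule
    on = [e for e in schedule if e.is_on and e.quadrants != "whole_field"]
    if not on:
        raise ValueError("schedule has no quadrant ON epochs")
    epoch = on[epoch_index]
    if epoch.duration_s < window_s - 1e-9:
        raise ValueError("ON epoch shorter than the analysis window")
    t0 = epoch.start_s
    times = np.unique(track.frames["time_s"].to_numpy())
    pre_sel = (times >= t0 - window_s) & (times < t0)
    stim_sel = (times >= t0) & (times < t0 + window_s)
    lit = set(epoch.quadrants)
    rows = []
    for fly_id, grp in track.frames.groupby("fly_id"):
        x, y = _interp_fly(grp, times, max_interp_frames)
        reason = None
        if np.isnan(x[pre_sel]).any() or np.isnan(x[stim_sel]).any():
            reason = "missing frames beyond interpolation limit"
        else:
            q = np.array(
                [assign_quadrant(xi, yi, track.arena) for xi, yi in
                 zip(x[stim_sel], y[stim_sel])]
            )
            if not np.all(np.isin(q, list(lit))):
                reason = "left lit quadrants during stimulation window"
        if reason is None:
            series = _metric_series(x, y, track.arena, metric, track.frame_rate)
            pre_mean = float(np.nanmean(series[pre_sel]))
            stim_mean = float(np.nanmean(series[stim_sel]))
            if pre_mean == 0.0:
                rows.append((fly_id, pre_mean, stim_mean, np.nan, False,
                             "zero pre-stimulation mean (delta undefined)"))
            else:
                delta = (stim_mean - pre_mean) / pre_mean
                rows.append((fly_id, pre_mean, stim_mean, delta, True, None))
        else:
            rows.append((fly_id, np.nan, np.nan, np.nan, False, reason))
    return pd.DataFrame(
        rows, columns=["fly_id", "pre_mean", "stim_mean", "delta", "included", "reason"]
    )


def flybowl_locomotion(
    track: TrialTrack,
    schedule: list[Epoch] | None = None,
    window: str | int = "strongest",
) -> pd.Series:
    """Per-fly mean forward locomotion (px/s) in a Flybowl ON window.

    The Flybowl schedule has three whole-field epochs of increasing LED
    intensity; by default the strongest (third) 5 s window is analysed, as in
    the assay's headline panel.  Each fly is one experimental unit — values
    are never pooled.
    """
    schedule = schedule if schedule is not None else track.schedule
    on = [e for e in schedule if e.quadrants == "whole_field"]
    if len(on) < 3 and window == "strongest":
        raise ValueError(f"expected three whole-field epochs, found {len(on)}")
    if window == "strongest":
        epoch = max(on, key=lambda e: (e.intensity if e.intensity is not None else -1))
    else:
        epoch = on[int(window)]
    times = np.unique(track.frames["time_s"].to_numpy())
    sel = (times >= epoch.start_s) & (times < epoch.end_s)
    out = {}
    for fly_id, grp in track.frames.groupby("fly_id"):
        x, y = _interp_fly(grp, times, max_gap=3)
        series = _metric_series(x, y, track.arena, "forward_locomotion", track.frame_rate)
        out[fly_id] = float(np.nanmean(series[sel]))
    return pd.Series(out, name="locomotion_px_s").rename_axis("fly_id")
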