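"""Tethered-flight wingbeat analysis.

A fixed, flying fly beats its wings while an optical wingbeat analyzer
records per-wingbeat frequency and the left/right wingbeat amplitudes at
1 kHz.  Yaw turning is the left minus right amplitude; thrust is their sum.
Each 10 s trial combines a visual condition (dark, stationary stripe, or
closed-loop stripe) with optogenetic LED stimulation (present or absent);
stimulation starts 5 s into the trial and lasts 500 ms.  Flies run six blocks
of randomly interleaved trials.

The response of a fly is computed exactly as in the assay: the mean of the
100 ms before stimulation is subtracted from every trial trace, stim and
no-stim trials are averaged separately across blocks, and the response is
the stim mean minus the no-stim mean.  Group traces average flies with equal
weight.  Significance against a control genotype is assessed per timepoint
with a two-sided Wilcoxon rank-sum test at p < 0.05, uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

PARAMETERS = ("yaw", "abs_yaw", "thrust", "freq")
VISUAL_CONDITIONS = ("dark", "stationary_stripe", "closed_loop_stripe")

#: baseline window before LED onset, seconds
BASELINE_S = 0.1


@dataclass
class WingbeatTrace:
    """One trial's wingbeat recording.

    Arrays are sampled uniformly (nominally 1 kHz); ``led_on`` marks the
    optogenetic stimulation samples (all False in no-stim trials, where
    ``stim_onset_s`` still records the nominal onset used for alignment).
    """

    time_s: np.ndarray
    freq_hz: np.ndarray
    amp_left: np.ndarray
    amp_right: np.ndarray
    led_on: np.ndarray
    visual_condition: str
    trial_id: str
    block_id: int
    fly_id: str
    has_effector: bool
    stim_onset_s: float = 5.0

    def __post_init__(self):
        n = len(self.time_s)
        for name in ("freq_hz", "amp_left", "amp_right", "led_on"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from time axis")
        dt = np.diff(self.time_s)
        if n > 1 and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("trace is not uniformly sampled")
        self.led_on = np.asarray(self.led_on, dtype=bool)

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(self.time_s[1] - self.time_s[0])

    @property
    def is_stim(self) -> bool:
        return bool(self.led_on.any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "freq_hz": self.freq_hz,
                "amp_left": self.amp_left,
                "amp_right": self.amp_right,
                "led_on": self.led_on.astype(int),
                "visual_condition": self.visual_condition,
                "trial_id": self.trial_id,
                "block_id": self.block_id,
                "fly_id": self.fly_id,
                "has_effector": int(self.has_effector),
            }
        )


def traces_to_csv(traces: list[WingbeatTrace], path) -> None:
    pd.concat([t.to_frame() for t in traces], ignore_index=True).to_csv(path, index=False)


def traces_from_csv(path, stim_onset_s: float = 5.0) -> list[WingbeatTrace]:
    df = pd.read_csv(path)
    out = []
    for (fly, trial), grp in df.groupby(["fly_id", "trial_id"], sort=False):
        out.append(
            WingbeatTrace(
                time_s=grp["time_s"].to_numpy(),
                freq_hz=grp["freq_hz"].to_numpy(),
                amp_left=grp["amp_left"].to_numpy(),
                amp_right=grp["amp_right"].to_numpy(),
                led_on=grp["led_on"].to_numpy().astype(bool),
                visual_condition=str(grp["visual_condition"].iloc[0]),
                trial_id=str(trial),
                block_id=int(grp["block_id"].iloc[0]),
                fly_id=str(fly),
                has_effector=bool(grp["has_effector"].iloc[0]),
                stim_onset_s=stim_onset_s,
            )
        )
    return out


def yaw(trace: WingbeatTrace) -> np.ndarray:
    """Yaw turning: left minus right wingbeat amplitude."""
    return np.asarray(trace.amp_left) - np.asarray(trace.amp_right)


def thrust(trace: WingbeatTrace) -> np.ndarray:
    """Thrust: sum of the left and right wingbeat amplitudes."""
    return np.asarray(trace.amp_left) + np.asarray(trace.amp_right)


def _raw_series(trace: WingbeatTrace, parameter: str) -> np.ndarray:
    if parameter in ("yaw", "abs_yaw"):
        return yaw(trace)
    if parameter == "thrust":
        return thrust(trace)
    if parameter == "freq":
        return np.asarray(trace.freq_hz)
    raise ValueError(f"unknown flight parameter {parameter!r}; choose from {PARAMETERS}")


@dataclass
class ResponseTrace:
    """Stimulation-induced change of one flight parameter.

    ``per_fly`` is an (n_flies, n_samples) array of per-fly response traces
    (stim mean minus no-stim mean after per-trial baseline subtraction);
    ``mean_response`` averages flies with equal weight.
    """

    parameter: str
    time_rel_s: np.ndarray
    mean_response: np.ndarray
    per_fly: np.ndarray
    fly_ids: list[str]
    visual_condition: str

    @property
    def n_flies(self) -> int:
        return self.per_fly.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_rel_s": self.time_rel_s, "mean": self.mean_response})
        for fly, row in zip(self.fly_ids, self.per_fly):
            df[f"fly_{fly}"] = row
        return df


def fly_response(
    trials: list[WingbeatTrace],
    parameter: str,
    visual_condition: str,
    freq_floor: float | None = None,
) -> ResponseTrace:
    """Per-fly and group-mean response traces for one visual condition.

    For every trial the mean of the 100 ms before LED onset is subtracted
    (for ``abs_yaw``, the absolute value is taken after that subtraction, the
    plotting convention for turning magnitude).  Stim and no-stim trials are
    then averaged separately within each fly, and the fly's response is their
    difference.  Trials whose wingbeat frequency drops below ``freq_floor``
    anywhere (a flight stop) are excluded whole.
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown flight parameter {parameter!r}")
    selected = [t for t in trials if t.visual_condition == visual_condition]
    if not selected:
        raise ValueError(f"no trials with visual condition {visual_condition!r}")
    if freq_floor is not None:
        selected = [t for t in selected if np.min(t.freq_hz) >= freq_floor]
        if not selected:
            raise ValueError("all trials excluded by the flight-stop frequency floor")
    per_fly, fly_ids = [], []
    time_rel = None
    for fly_id in sorted({t.fly_id for t in selected}):
        own = [t for t in selected if t.fly_id == fly_id]
        stim = [t for t in own if t.is_stim]
        nostim = [t for t in own if not t.is_stim]
        if not stim or not nostim:
            raise ValueError(
                f"fly {fly_id} lacks {'stim' if not stim else 'no-stim'} trials "
                f"for condition {visual_condition!r}"
            )
        def _baselined(trial: WingbeatTrace) -> np.ndarray:
            series = _raw_series(trial, parameter)
            pre = (trial.time_s >= trial.stim_onset_s - BASELINE_S) & (
                trial.time_s < trial.stim_onset_s
            )
            if not pre.any():
                raise ValueError("trial has no samples in the 100 ms baseline window")
            series = series - series[pre].mean()
            if parameter == "abs_yaw":
                series = np.abs(series)
            return series
        stim_mean = np.mean([_baselined(t) for t in stim], axis=0)
        nostim_mean = np.mean([_baselined(t) for t in nostim], axis=0)
        per_fly.append(stim_mean - nostim_mean)
        fly_ids.append(fly_id)
        if time_rel is None:
            time_rel = stim[0].time_s - stim[0].stim_onset_s
    per_fly = np.asarray(per_fly)
    return ResponseTrace(
        parameter=parameter,
        time_rel_s=time_rel,
        mean_response=per_fly.mean(axis=0),
        per_fly=per_fly,
        fly_ids=fly_ids,
        visual_condition=visual_condition,
    )


#: per-group size at or below which the exact rank-sum null is used
EXACT_N_MAX = 10


def per_timepoint_test(
    group_a: ResponseTrace | np.ndarray,
    group_b: ResponseTrace | np.ndarray,
    alpha: float = 0.05,
    decimate: int = 1,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test at every sample, uncorrected.

    ``group_a`` and ``group_b`` are ResponseTraces (or raw (n_flies, T)
    arrays) for the effector-expressing and control genotypes.  The exact
    rank-sum null is used for groups of up to 10 flies, the normal
    approximation with continuity correction above that.  ``decimate``
    optionally tests every k-th sample for runtime.

    Returns a DataFrame with columns ``time_rel_s`` (or sample index), ``p``
    and ``significant`` (p < alpha).
    """
    a = group_a.per_fly if isinstance(group_a, ResponseTrace) else np.asarray(group_a)
    b = group_b.per_fly if isinstance(group_b, ResponseTrace) else np.asarray(group_b)
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ValueError("need at least 3 flies per group")
    t_a = group_a.time_rel_s if isinstance(group_a, ResponseTrace) else np.arange(a.shape[1])
    step = max(1, int(decimate))
    a, b, t = a[:, ::step], b[:, ::step], t_a[::step]
    method = "exact" if max(a.shape[0], b.shape[0]) <= EXACT_N_MAX else "asymptotic"
    res = sps.mannwhitneyu(a, b, axis=0, alternative="two-sided", method=method)
    p = np.asarray(res.pvalue)
    return pd.DataFrame({"time_rel_s": t, "p": p, "significant": p < alpha})
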