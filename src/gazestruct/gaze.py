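"""Gaze-stream parsing, hit detection, inclusion rules and AOI analysis.

Raw gaze is a 500 Hz sample stream per trial (t in ms from stimulus
onset, x/y in stimulus pixels, a validity flag, and camera-to-head
distance in mm).  The module provides:

* dispersion-based (I-DT) fixation detection, keeping fixations > 50 ms;
* gaze-contingent hit detection: a trial is a hit when gaze rests inside
  the target disk for at least 100 ms starting before the 4500 ms timeout;
  latency is the onset of the first qualifying dwell;
* the inclusion rule: hits need >= 80% recorded gaze, misses need at
  least as much recorded gaze time as the median hit latency of the whole
  dataset (1240 ms in the original infant sample, used as fallback);
* a movement covariate (max within-fixation range of head distance);
* per-participant and pooled performance summaries;
* fixation counts per AOI and first-fixation rates for the
  detected-by-coincidence check (chance level 1/10).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GazeTrial",
    "Fixation",
    "TrialOutcome",
    "detect_fixations",
    "detect_hit",
    "recorded_proportion",
    "movement_covariate",
    "analyze_trial",
    "apply_inclusion",
    "performance_summary",
    "aoi_analysis",
    "read_gaze_csv",
    "write_gaze_csv",
]

SAMPLE_PERIOD_MS = 2.0  # 500 Hz
GAZE_COLUMNS = ["trial_id", "participant_id", "t_ms", "x_px", "y_px", "valid", "head_dist_mm"]


@dataclass
class GazeTrial:
    """One trial's raw samples (arrays of equal length, time-ordered)."""

    trial_id: str
    participant_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    head_dist: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.t) < 0):
            raise ValueError("sample times must be non-decreasing")


@dataclass(frozen=True)
class Fixation:
    onset: float
    offset: float
    centroid: tuple[float, float]
    head_range: float = 0.0

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class TrialOutcome:
    trial_id: str
    participant_id: str
    success: bool
    latency: float | None
    recorded_prop: float
    recorded_ms: float
    movement: float
    n_fix_to_hit: int | None
    first_fix_aoi: int | None
    n_fixations: int
    mean_fix_duration: float
    included: bool = True


def detect_fixations(
    trial: GazeTrial,
    dispersion_px: float = 40.0,
    min_dur_ms: float = 50.0,
    max_gap_ms: float = 75.0,
) -> list[Fixation]:
    """I-DT fixation detection on valid samples.

    A window grows while both the x and y ranges stay within
    ``dispersion_px``; windows lasting more than ``min_dur_ms`` are
    emitted.  Invalid samples are bridged unless the gap between valid
    samples exceeds ``max_gap_ms``, which splits the window.
    """
    v = trial.valid.astype(bool)
    t, x, y, hd = trial.t[v], trial.x[v], trial.y[v], trial.head_dist[v]
    n = len(t)
    fixations: list[Fixation] = []
    i = 0
    while i < n:
        j = i
        xmin = xmax = x[i]
        ymin = ymax = y[i]
        while j + 1 < n:
            if t[j + 1] - t[j] > max_gap_ms:
                break
            nxmin, nxmax = min(xmin, x[j + 1]), max(xmax, x[j + 1])
            nymin, nymax = min(ymin, y[j + 1]), max(ymax, y[j + 1])
            if nxmax - nxmin > dispersion_px or nymax - nymin > dispersion_px:
                break
            xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
            j += 1
        if t[j] - t[i] > min_dur_ms:
            sl = slice(i, j + 1)
            fixations.append(
                Fixation(
                    onset=float(t[i]),
                    offset=float(t[j]),
                    centroid=(float(x[sl].mean()), float(y[sl].mean())),
                    head_range=float(hd[sl].max() - hd[sl].min()) if j > i else 0.0,
                )
            )
        i = j + 1
    return fixations


def detect_hit(
    trial: GazeTrial,
    hard_mask: np.ndarray,
    dwell_ms: float = 100.0,
    timeout_ms: float = 4500.0,
) -> tuple[bool, float | None]:
    """Gaze-contingent hit rule on raw samples.

    Finds the first maximal run of valid in-target samples whose time span
    reaches ``dwell_ms`` and whose onset precedes ``timeout_ms``.  Runs may
    bridge a single missing (invalid) sample.  Returns (hit, latency); the
    latency is the run's onset time.
    """
    h, w = hard_mask.shape
    xi = np.clip(np.round(trial.x).astype(int), 0, w - 1)
    yi = np.clip(np.round(trial.y).astype(int), 0, h - 1)
    on_target = trial.valid.astype(bool) & hard_mask[yi, xi]

    n = len(on_target)
    i = 0
    while i < n:
        if not on_target[i]:
            i += 1
            continue
        j = i
        bridged = 0
        last_on = i
        while j + 1 < n:
            if on_target[j + 1]:
                j += 1
                last_on = j
                bridged = 0
            elif not trial.valid[j + 1] and bridged < 1:
                j += 1
                bridged += 1
            else:
                break
        start, end = trial.t[i], trial.t[last_on]
        if end - start >= dwell_ms and start < timeout_ms:
            return True, float(start)
        i = last_on + 1
    return False, None


def recorded_proportion(trial: GazeTrial) -> float:
    """Fraction of samples with recorded (valid) gaze; 0 for empty trials."""
    if len(trial.valid) == 0:
        return 0.0
    return float(np.mean(trial.valid.astype(bool)))


def movement_covariate(fixations: list[Fixation]) -> float:
    """Max absolute within-fixation change in head-camera distance (mm)."""
    if not fixations:
        return 0.0
    return float(max(f.head_range for f in fixations))


def _first_fix_aoi(fixations: list[Fixation], positions, radius: float) -> int | None:
    if not fixations:
        return None
    cx, cy = fixations[0].centroid
    for idx, (px, py) in enumerate(positions):
        if (cx - px) ** 2 + (cy - py) ** 2 <= radius**2:
            return idx
    return None


def analyze_trial(
    trial: GazeTrial,
    hard_mask: np.ndarray,
    positions=None,
    aoi_radius: float = 117.5,
    dwell_ms: float = 100.0,
    timeout_ms: float = 4500.0,
    dispersion_px: float = 40.0,
) -> TrialOutcome:
    """Derive the full per-trial outcome from raw samples."""
    fixations = detect_fixations(trial, dispersion_px=dispersion_px)
    hit, latency = detect_hit(trial, hard_mask, dwell_ms=dwell_ms, timeout_ms=timeout_ms)
    n_fix_to_hit = None
    if hit:
        n_fix_to_hit = sum(1 for f in fixations if f.onset <= latency) or 1
    first_aoi = _first_fix_aoi(fixations, positions, aoi_radius) if positions is not None else None
    rec_prop = recorded_proportion(trial)
    return TrialOutcome(
        trial_id=trial.trial_id,
        participant_id=trial.participant_id,
        success=hit,
        latency=latency,
        recorded_prop=rec_prop,
        recorded_ms=float(np.sum(trial.valid.astype(bool)) * SAMPLE_PERIOD_MS),
        movement=movement_covariate(fixations),
        n_fix_to_hit=n_fix_to_hit,
        first_fix_aoi=first_aoi,
        n_fixations=len(fixations),
        mean_fix_duration=float(np.mean([f.duration for f in fixations])) if fixations else float("nan"),
    )


def apply_inclusion(
    outcomes: list[TrialOutcome],
    hit_min_prop: float = 0.8,
    fallback_miss_threshold_ms: float = 1240.0,
) -> tuple[list[TrialOutcome], float]:
    """Trial inclusion rule.

    The miss threshold is the median hit latency over the whole dataset
    (``fallback_miss_threshold_ms`` if there are no hits).  Hits are kept
    when at least ``hit_min_prop`` of gaze was recorded; misses are kept
    when the summed recorded gaze time reaches the threshold.  Returns the
    outcomes (with ``included`` set) and the threshold used.
    """
    if not outcomes:
        raise ValueError("no trial outcomes supplied")
    hit_latencies = [o.latency for o in outcomes if o.success and o.latency is not None]
    miss_threshold = float(np.median(hit_latencies)) if hit_latencies else fallback_miss_threshold_ms
    for o in outcomes:
        if o.success:
            o.included = o.recorded_prop >= hit_min_prop
        else:
            o.included = o.recorded_ms >= miss_threshold
    return [o for o in outcomes if o.included], miss_threshold


def performance_summary(outcomes: list[TrialOutcome] | pd.DataFrame) -> pd.DataFrame:
    """Group performance summary: per-participant values, then pooled Md/SD/range.

    Accepts a list of TrialOutcome or an equivalent DataFrame (which may
    additionally carry ``target_location_idx`` for the first-fixation
    rate).  Rows are the performance measures; columns are median, sd,
    min, max of the per-participant values.  Empty participants yield NaN
    rows rather than raising.
    """
    df = outcomes if isinstance(outcomes, pd.DataFrame) else outcomes_to_frame(outcomes)
    per = []
    for pid, g in df.groupby("participant_id"):
        hits = g[g["success"].astype(float) > 0.5]
        per.append(
            {
                "participant_id": pid,
                "hit_rate": g["success"].astype(float).mean() if len(g) else np.nan,
                "hit_latency": hits["latency"].median() if len(hits) else np.nan,
                "n_fix_to_hit": hits["n_fix_to_hit"].mean() if len(hits) else np.nan,
                "rate_first_fix_on_target": _rate_first_fix(g),
                "recorded_prop": g["recorded_prop"].mean() if len(g) else np.nan,
                "mean_fix_duration": g["mean_fix_duration"].mean() if len(g) else np.nan,
            }
        )
    per_df = pd.DataFrame(per).set_index("participant_id")
    pooled = pd.DataFrame(
        {
            "median": per_df.median(),
            "sd": per_df.std(),
            "min": per_df.min(),
            "max": per_df.max(),
        }
    )
    pooled.attrs["per_participant"] = per_df
    return pooled


def _rate_first_fix(g: pd.DataFrame) -> float:
    m = g["first_fix_aoi"].notna()
    if "target_location_idx" in g.columns:
        landed = g[m]
        if len(landed) == 0:
            return np.nan
        return float((landed["first_fix_aoi"] == landed["target_location_idx"]).mean())
    return np.nan


def outcomes_to_frame(outcomes: list[TrialOutcome]) -> pd.DataFrame:
    return pd.DataFrame([vars(o) for o in outcomes])


def aoi_analysis(
    trial_fixations: list[tuple[str, list[Fixation], int]],
    positions,
    aoi_radius: float = 117.5,
) -> dict:
    """Fixation counts per AOI and first-fixation rates.

    ``trial_fixations`` holds (participant_id, fixations, target_location)
    per trial.  Returns per-trial counts on the target and on each empty
    AOI, the per-participant rate of first fixations landing on the target
    among those landing in any AOI, and the chance level 1/n AOIs.
    """
    n_aoi = len(positions)
    counts_rows = []
    first_by_part: dict[str, list[bool]] = {}
    for pid, fixations, tloc in trial_fixations:
        counts = np.zeros(n_aoi, dtype=int)
        for f in fixations:
            cx, cy = f.centroid
            for idx, (px, py) in enumerate(positions):
                if (cx - px) ** 2 + (cy - py) ** 2 <= aoi_radius**2:
                    counts[idx] += 1
                    break
        row = {"participant_id": pid, "target_location": tloc, "target_count": counts[tloc]}
        for idx in range(n_aoi):
            row[f"aoi_{idx}"] = counts[idx]
        counts_rows.append(row)
        first = _first_fix_aoi(fixations, positions, aoi_radius)
        if first is not None:
            first_by_part.setdefault(pid, []).append(first == tloc)
    first_rates = {
        pid: float(np.mean(hits)) for pid, hits in first_by_part.items()
    }
    return {
        "counts": pd.DataFrame(counts_rows),
        "first_fixation_rates": first_rates,
        "chance_level": 1.0 / n_aoi,
    }


def read_gaze_csv(path: str | Path) -> list[GazeTrial]:
    """Read the package's gaze CSV dialect into per-trial streams."""
    df = pd.read_csv(path)
    missing = set(GAZE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gaze CSV lacks columns: {sorted(missing)}")
    trials = []
    for (tid, pid), g in df.groupby(["trial_id", "participant_id"], sort=False):
        g = g.sort_values("t_ms")
        trials.append(
            GazeTrial(
                trial_id=str(tid),
                participant_id=str(pid),
                t=g["t_ms"].to_numpy(float),
                x=g["x_px"].to_numpy(float),
                y=g["y_px"].to_numpy(float),
                valid=g["valid"].to_numpy(bool),
                head_dist=g["head_dist_mm"].to_numpy(float),
            )
        )
    return trials


def write_gaze_csv(trials: list[GazeTrial], path: str | Path) -> None:
    frames = []
    for tr in trials:
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": tr.trial_id,
                    "participant_id": tr.participant_id,
                    "t_ms": tr.t,
                    "x_px": tr.x,
                    "y_px": tr.y,
                    "valid": tr.valid.astype(int),
                    "head_dist_mm": tr.head_dist,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
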