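"""Align video-scored behaviour with audio time and compute state time budgets.

Behaviour tracks are tables of labelled, non-overlapping intervals (state,
start_s, stop_s) from a scored observation window — relative position states
Clumping (physical contact), Close (less than one bird-length apart) and
Distance, or activity states Perching–exploring, Hopping, Preening.  The video
clock is mapped onto the audio clock by an affine fit through manually matched
anchor events, after which per-state call rates and the clumping time budget
can be computed on one common timeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BehaviorTrack",
    "AffineAlignment",
    "align_streams",
    "clumping_proportion",
    "rate_by_state",
]

POSITION_STATES = ("Clumping", "Close", "Distance")
ACTIVITY_STATES = ("Perching-exploring", "Hopping", "Preening")


@dataclass
class BehaviorTrack:
    """Scored behaviour intervals over one observation window."""

    intervals: pd.DataFrame  # columns: state, start_s, stop_s
    scored_total_s: float

    def __post_init__(self):
        df = self.intervals
        required = {"state", "start_s", "stop_s"}
        if not required.issubset(df.columns):
            raise ValueError(f"behaviour table needs columns {sorted(required)}")
        if len(df):
            if np.any(df["stop_s"].to_numpy() <= df["start_s"].to_numpy()):
                raise ValueError("every interval needs stop_s > start_s")
            s = df.sort_values("start_s")
            if np.any(s["start_s"].to_numpy()[1:] < s["stop_s"].to_numpy()[:-1] - 1e-9):
                raise ValueError("behaviour intervals overlap")
        if self.scored_total_s <= 0:
            raise ValueError("scored_total_s must be positive")

    def state_durations(self) -> pd.Series:
        if not len(self.intervals):
            return pd.Series(dtype=float)
        d = self.intervals["stop_s"] - self.intervals["start_s"]
        return d.groupby(self.intervals["state"]).sum()

    def shifted(self, offset: float, slope: float = 1.0) -> "BehaviorTrack":
        df = self.intervals.copy()
        df["start_s"] = slope * df["start_s"] + offset
        df["stop_s"] = slope * df["stop_s"] + offset
        return BehaviorTrack(df, self.scored_total_s * slope)


@dataclass
class AffineAlignment:
    """video → audio clock map: audio_s = slope * video_s + offset."""

    offset: float
    slope: float
    residuals: np.ndarray

    def apply(self, video_s):
        return self.slope * np.asarray(video_s, dtype=float) + self.offset

    def apply_track(self, track: BehaviorTrack) -> BehaviorTrack:
        return track.shifted(self.offset, self.slope)


def align_streams(anchor_pairs, max_residual_s: float = 0.5) -> AffineAlignment:
    """Least-squares affine fit through (video_s, audio_s) anchor events.

    One anchor gives a pure offset (slope fixed at 1); two or more also
    estimate clock drift.  Residuals above ``max_residual_s`` raise a warning
    — the anchors probably mismatch.
    """
    anchors = np.asarray(anchor_pairs, dtype=float)
    if anchors.ndim != 2 or anchors.shape[1] != 2 or anchors.shape[0] < 1:
        raise ValueError("need an (n, 2) array of (video_s, audio_s) anchors")
    video, audio = anchors[:, 0], anchors[:, 1]
    if anchors.shape[0] == 1:
        slope, offset = 1.0, float(audio[0] - video[0])
    else:
        slope, offset = np.polyfit(video, audio, 1)
    resid = audio - (slope * video + offset)
    if np.any(np.abs(resid) > max_residual_s):
        warnings.warn(
            f"alignment residuals up to {np.abs(resid).max():.3f} s exceed "
            f"{max_residual_s} s; check the anchor events", stacklevel=2)
    return AffineAlignment(float(offset), float(slope), resid)


def clumping_proportion(track: BehaviorTrack, state: str = "Clumping") -> tuple[float, float]:
    """Seconds spent in physical contact and its share of scored time."""
    seconds = float(track.state_durations().get(state, 0.0))
    return seconds, seconds / track.scored_total_s


def rate_by_state(
    event_onsets,
    track: BehaviorTrack,
    states: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Call rate (events/s) within each behaviour state.

    An event belongs to the interval whose half-open [start, stop) range
    contains its onset; events falling in no scored interval are counted as
    ``n_outside`` and excluded.  States with zero scored duration get rate NaN
    (missing), never 0.  Σ(rate × duration) over states equals the in-window
    event count exactly.
    """
    onsets = np.asarray(event_onsets, dtype=float)
    iv = track.intervals.sort_values("start_s").reset_index(drop=True)
    if states is None:
        states = tuple(dict.fromkeys(iv["state"]))
    durations = track.state_durations()

    counts = dict.fromkeys(states, 0)
    n_outside = 0
    if len(iv) and onsets.size:
        starts = iv["start_s"].to_numpy()
        stops = iv["stop_s"].to_numpy()
        labels = iv["state"].to_numpy()
        idx = np.searchsorted(starts, onsets, side="right") - 1
        for t, i in zip(onsets, idx):
            if i >= 0 and t < stops[i]:
                lab = labels[i]
                if lab in counts:
                    counts[lab] += 1
                else:
                    n_outside += 1
            else:
                n_outside += 1
    else:
        n_outside = int(onsets.size)

    rows = []
    for st in states:
        dur = float(durations.get(st, 0.0))
        n = counts[st]
        rate = n / dur if dur > 0 else float("nan")
        rows.append(dict(state=st, duration_s=dur, n_events=n, rate_per_s=rate))
    out = pd.DataFrame(rows)
    out.attrs["n_outside"] = n_outside
    return out
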