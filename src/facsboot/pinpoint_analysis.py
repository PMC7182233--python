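"""Judge-pinpoint window extraction and the pinpointed-vs-remainder contrast.

Judges report the times (whole seconds) at which they perceived guilt in a
video.  Each pinpoint is centred on the middle of its second — a pinpoint at
t seconds maps to the frame containing t + 0.5 s, i.e. ``floor((t+0.5)*fps)``
— and surrounded by a symmetric error margin of ``floor(0.5*fps)`` frames
(12 at 25 fps), yielding a one-second window per pinpoint.  Windows from all
judges are unioned per video and clipped at video boundaries.

Frames are then partitioned into pinpointed and remainder rows of the same
videos; frames carrying none of the retained AUs are removed from both sides
(a frame with no facial activity cannot have been judged on facial grounds).
The pinpointed set is scored against a bootstrap null built by resampling
*videos* of the remainder set, place-of-origin-matched, exactly as in the
condition contrast.
"""

from __future__ import annotations

import warnings
from math import floor
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bootstrap_contrast import BootstrapConfig, contrast_counts
from .errors import ValidationError
from .facs_io import FrameMatrix

__all__ = [
    "pinpoint_to_center_frame",
    "build_windows",
    "WindowSet",
    "partition_frames",
    "contrast_pinpoints",
    "pinpoint_summary",
]

EMOTIONS = ("guilty", "uncomfortable", "embarrassed", "surprised", "other")


def pinpoint_to_center_frame(t_seconds: float, fps: float = 25.0) -> int:
    """Frame containing time t + 0.5 s (middle of the reported second)."""
    if t_seconds < 0:
        raise ValidationError(f"pinpoint time must be >= 0, got {t_seconds}")
    return floor((t_seconds + 0.5) * fps)


class WindowSet:
    """Per-video unions of judged-guilty frame windows.

    ``frames`` maps video_id -> sorted array of frame indices inside at least
    one window; ``unique_instances`` counts distinct (video, second) pinpoints
    across judges.
    """

    def __init__(self, frames: dict[str, np.ndarray], unique_instances: int):
        self.frames = {v: np.asarray(ix, dtype=np.int64) for v, ix in frames.items()}
        self.unique_instances = unique_instances

    def mask(self, video_id: str, n_frames: int) -> np.ndarray:
        m = np.zeros(n_frames, dtype=bool)
        ix = self.frames.get(video_id)
        if ix is not None:
            m[ix[ix < n_frames]] = True
        return m

    def __len__(self) -> int:
        return len(self.frames)


def build_windows(
    pinpoints: pd.DataFrame,
    video_lengths: Mapping[str, int],
    fps: float = 25.0,
    half_width_frames: int | None = None,
    emotion: str | None = "guilty",
) -> WindowSet:
    """Union per-pinpoint frame windows into a :class:`WindowSet`.

    Each pinpoint contributes the inclusive frame range
    ``[center - hw, center + hw]`` (25 frames = 1 s at 25 fps), clipped to
    video bounds.  Pinpoints past the end of their video are dropped with a
    warning; pinpoints for unknown videos raise.  When *emotion* is given,
    only pinpoints with that label are used.
    """
    hw = floor(0.5 * fps) if half_width_frames is None else half_width_frames
    df = pinpoints.dropna(subset=["t_seconds"])
    if emotion is not None:
        df = df[df["emotion"] == emotion]
    unknown = set(df["video_id"]) - set(video_lengths)
    if unknown:
        raise ValidationError(f"pinpoints reference unknown videos: {sorted(unknown)}")
    per_video: dict[str, set[int]] = {}
    seen: set[tuple[str, int]] = set()
    for vid, t in zip(df["video_id"], df["t_seconds"]):
        t = int(t)
        n = video_lengths[vid]
        center = pinpoint_to_center_frame(t, fps)
        if center - hw >= n:
            warnings.warn(f"pinpoint at {t}s past end of video {vid}; dropped",
                          stacklevel=2)
            continue
        seen.add((vid, t))
        lo, hi = max(0, center - hw), min(n - 1, center + hw)
        per_video.setdefault(vid, set()).update(range(lo, hi + 1))
    return WindowSet(
        {v: np.array(sorted(ix)) for v, ix in per_video.items()}, len(seen)
    )


def partition_frames(
    frames: Mapping[str, FrameMatrix],
    windows: WindowSet,
    aus: Sequence[str],
    drop_zero_au: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split visible frames of the given videos into (pinpointed, remainder).

    Both partitions are long-format DataFrames (``video_id`` + one column per
    retained AU).  With *drop_zero_au*, rows whose retained-AU indicators are
    all zero are removed from BOTH partitions.
    """
    pin_parts, rem_parts = [], []
    for vid in sorted(frames):
        fm = frames[vid]
        cols = [fm.aus.index(a) for a in aus]
        sub = fm.indicators[:, cols]
        inside = windows.mask(vid, fm.n_frames)
        keep = fm.visible.copy()
        if drop_zero_au:
            keep &= sub.any(axis=1)
        for sel, parts in ((inside & keep, pin_parts), (~inside & keep, rem_parts)):
            if sel.any():
                df = pd.DataFrame(sub[sel], columns=list(aus))
                df.insert(0, "video_id", vid)
                parts.append(df)
    cols = ["video_id", *aus]
    empty = pd.DataFrame(columns=cols)
    pin = pd.concat(pin_parts, ignore_index=True) if pin_parts else empty.copy()
    rem = pd.concat(rem_parts, ignore_index=True) if rem_parts else empty.copy()
    return pin, rem


def _counts_by_video(df: pd.DataFrame, aus: Sequence[str]):
    """Per-video (sorted) AU counts and frame totals from a long partition."""
    ids = sorted(df["video_id"].unique())
    counts = np.zeros((len(ids), len(aus)), dtype=np.int64)
    totals = np.zeros(len(ids), dtype=np.int64)
    grouped = df.groupby("video_id")
    for i, vid in enumerate(ids):
        g = grouped.get_group(vid)
        counts[i] = g[list(aus)].to_numpy().sum(axis=0)
        totals[i] = len(g)
    return ids, counts, totals


def contrast_pinpoints(
    frames: Mapping[str, FrameMatrix],
    windows: WindowSet,
    meta,
    aus: Sequence[str],
    config: BootstrapConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Bootstrap contrast of pinpointed frames against remainder frames.

    The test statistic pools all pinpointed frames of the supplied videos;
    the null resamples *videos* of the remainder set with replacement,
    matched to the pinpointed videos' place-of-origin composition.  Videos
    with no remainder frames are excluded from the null with a warning.
    Run this separately for control-condition and guilt-condition videos.
    """
    config = config or BootstrapConfig()
    if isinstance(meta, Mapping):
        strata = dict(meta)
    else:
        strata = {p.participant_id: p.poo_stratum for p in meta}
    pin, rem = partition_frames(frames, windows, aus, drop_zero_au=True)
    if pin.empty or rem.empty:
        raise ValidationError("both partitions must be non-empty after filtering")
    t_ids, t_counts, t_totals = _counts_by_video(pin, aus)
    c_ids, c_counts, c_totals = _counts_by_video(rem, aus)
    lost = set(t_ids) - set(c_ids)
    if lost:
        warnings.warn(
            f"videos with no remainder frames excluded from null: {sorted(lost)}",
            stacklevel=2,
        )
    ratios: dict[str, float] = {}
    for vid in t_ids:
        s = strata[vid]
        ratios[s] = ratios.get(s, 0.0) + 1.0
    return contrast_counts(
        t_counts, t_totals, c_counts, c_totals,
        [strata[v] for v in c_ids], ratios, aus, config, rng,
    )


def pinpoint_summary(
    pinpoints: pd.DataFrame,
    ratings: pd.DataFrame | None = None,
    conditions: Mapping[str, str] | None = None,
) -> dict:
    """Descriptive report of the judge tables.

    Counts raw and unique (video, second) pinpoint instances per emotion, the
    mean pinpoints per guilt/control video, the percentage of guilt pinpoints
    co-labelled with another emotion at the same (judge, video, second), and —
    when *ratings* and *conditions* are given — Welch two-sample t-tests of
    per-video mean ratings, guilt vs control videos, per emotion.
    """
    pp = pinpoints.dropna(subset=["t_seconds"]).copy()
    pp["t_seconds"] = pp["t_seconds"].astype(int)
    out: dict = {"raw_instances": {}, "unique_instances": {}}
    for emo in pp["emotion"].unique():
        sub = pp[pp["emotion"] == emo]
        out["raw_instances"][emo] = int(len(sub))
        out["unique_instances"][emo] = int(
            sub[["video_id", "t_seconds"]].drop_duplicates().shape[0]
        )
    if conditions is not None and not pp.empty:
        g = pp[pp["emotion"] == "guilty"]
        per_video = g.groupby("video_id").size()
        for cond in ("guilt", "control"):
            vids = [v for v, c in conditions.items() if c == cond]
            n_pins = sum(int(per_video.get(v, 0)) for v in vids)
            out[f"mean_pinpoints_per_{cond}_video"] = (
                n_pins / len(vids) if vids else float("nan")
            )
    # co-labelling: a guilt pinpoint sharing (judge, video, second) with a
    # row of another emotion
    g = pp[pp["emotion"] == "guilty"]
    if len(g):
        others = pp[pp["emotion"] != "guilty"]
        other_keys = set(map(tuple, others[["judge_id", "video_id", "t_seconds"]].to_numpy()))
        co = sum(
            (j, v, t) in other_keys
            for j, v, t in g[["judge_id", "video_id", "t_seconds"]].to_numpy()
        )
        out["pct_guilt_colabelled"] = 100.0 * co / len(g)
    if ratings is not None and conditions is not None:
        rt = ratings.dropna(subset=["rating"])
        tests = {}
        for emo in rt["emotion"].unique():
            per_video = (
                rt[rt["emotion"] == emo].groupby("video_id")["rating"].mean()
            )
            a = [v for v in per_video.index if conditions.get(v) == "guilt"]
            b = [v for v in per_video.index if conditions.get(v) == "control"]
            if len(a) >= 2 and len(b) >= 2:
                res = stats.ttest_ind(per_video[a], per_video[b], equal_var=False)
                tests[emo] = {
                    "mean_guilt": float(per_video[a].mean()),
                    "mean_control": float(per_video[b].mean()),
                    "t": float(res.statistic),
                    "df": float(res.df),
                    "p": float(res.pvalue),
                }
        out["rating_welch_tests"] = tests
    return out
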