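"""Data model and readers/writers for event-coded FACS data.

Facial behaviour is coded as *events*: one row per continuous activation of
one Action Unit (AU) on one video, with onset/offset given as frame indices.
Frame indices are 0-based and intervals are half-open ``[onset, offset)``, so
an event's duration in frames is ``offset - onset`` and abutting events
concatenate without overlap.

For analysis, events are expanded into a :class:`FrameMatrix` — a frames ×
AUs binary indicator table (1 = AU present at any intensity) with a per-frame
visibility mask.  Frames on which the whole face could not be seen are
recorded in event tables as ``NotVisible`` pseudo-events and are *removed*
from every frequency computation (never zero-filled).

All tabular I/O is plain CSV with a stable column order, emulating event
exports of interactive coding software.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ParseError, ValidationError
from .ontology import DEFAULT_ONTOLOGY, NOT_VISIBLE

__all__ = [
    "AUEvent",
    "FrameMatrix",
    "ParticipantRecord",
    "StudyDataset",
    "read_event_table",
    "write_event_table",
    "read_participant_table",
    "write_participant_table",
    "events_to_frame_matrix",
    "pooled_frequency",
]

INTENSITIES = ("low", "high")

EVENT_COLUMNS = ("video_id", "au", "onset_frame", "offset_frame", "intensity")

#: PANAS items carried per participant (1–5 scores) plus scale sums.
PANAS_ITEMS = ("guilt", "shame", "distress", "pride", "nervousness")
PANAS_SCALES = ("positive", "negative")


@dataclass(frozen=True)
class AUEvent:
    """One coded activation interval of one action unit on one video."""

    video_id: str
    au: str
    onset: int
    offset: int
    intensity: str = "low"

    def __post_init__(self):
        if not (0 <= self.onset < self.offset):
            raise ValidationError(
                f"event {self.video_id}/{self.au}: need 0 <= onset < offset, "
                f"got [{self.onset}, {self.offset})"
            )
        if self.intensity not in INTENSITIES:
            raise ValidationError(
                f"event {self.video_id}/{self.au}: intensity {self.intensity!r} "
                f"not in {INTENSITIES}"
            )

    @property
    def n_frames(self) -> int:
        return self.offset - self.onset


@dataclass
class FrameMatrix:
    """Per-video frames × AUs binary indicator table with visibility mask.

    ``indicators`` has shape (n_frames, len(aus)) with entries in {0, 1};
    ``visible`` marks frames usable for frequency computations.
    """

    video_id: str
    indicators: np.ndarray
    aus: tuple[str, ...]
    visible: np.ndarray
    fps: float = 25.0

    def __post_init__(self):
        self.indicators = np.asarray(self.indicators, dtype=np.uint8)
        self.visible = np.asarray(self.visible, dtype=bool)
        if self.indicators.ndim != 2 or self.indicators.shape[1] != len(self.aus):
            raise ValidationError(
                f"{self.video_id}: indicator shape {self.indicators.shape} does "
                f"not match {len(self.aus)} AU columns"
            )
        if self.visible.shape != (self.indicators.shape[0],):
            raise ValidationError(f"{self.video_id}: visibility mask length mismatch")
        if self.indicators.max(initial=0) > 1:
            raise ValidationError(f"{self.video_id}: indicators must be 0/1")

    @property
    def n_frames(self) -> int:
        return self.indicators.shape[0]

    @property
    def n_visible(self) -> int:
        return int(self.visible.sum())

    def active_counts(self) -> np.ndarray:
        """Per-AU count of visible frames on which the AU is present."""
        return self.indicators[self.visible].sum(axis=0).astype(np.int64)

    def to_frame(self) -> pd.DataFrame:
        """Visible rows as a DataFrame (one column per AU)."""
        df = pd.DataFrame(self.indicators[self.visible], columns=list(self.aus))
        df.insert(0, "video_id", self.video_id)
        return df


@dataclass
class ParticipantRecord:
    """Experimental metadata for one participant/video.

    ``condition`` is the arm of the guilt-induction experiment; ``poo_stratum``
    the place-of-origin stratum used to ratio-match bootstrap draws; the PANAS
    mappings hold per-item 1–5 scores plus positive/negative scale sums before
    and after the induction.
    """

    participant_id: str
    condition: str
    poo_stratum: str
    panas_before: dict[str, float] = field(default_factory=dict)
    panas_after: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.condition or not self.poo_stratum:
            raise ValidationError(
                f"participant {self.participant_id}: condition and poo_stratum "
                "must be non-empty"
            )

    @property
    def guilt_change(self) -> float | None:
        """Self-reported guilt after induction minus before (None if missing)."""
        try:
            return self.panas_after["guilt"] - self.panas_before["guilt"]
        except KeyError:
            return None


@dataclass
class StudyDataset:
    """One complete study: participants, their frame codings, judge tables."""

    participants: list[ParticipantRecord]
    codings: dict[str, FrameMatrix]
    ontology: tuple[str, ...] = DEFAULT_ONTOLOGY
    pinpoints: pd.DataFrame | None = None
    ratings: pd.DataFrame | None = None

    def __post_init__(self):
        ids = {p.participant_id for p in self.participants}
        extra = set(self.codings) - ids
        if extra:
            raise ValidationError(f"codings without participants: {sorted(extra)}")

    def by_condition(self, condition: str) -> list[ParticipantRecord]:
        return [p for p in self.participants if p.condition == condition]

    def frames_for(self, participants: Iterable[ParticipantRecord]) -> dict[str, FrameMatrix]:
        return {
            p.participant_id: self.codings[p.participant_id]
            for p in participants
            if p.participant_id in self.codings
        }

    def strata(self) -> dict[str, str]:
        return {p.participant_id: p.poo_stratum for p in self.participants}


# ---------------------------------------------------------------------------
# Event tables


def _check_overlaps(events: Sequence[AUEvent]) -> None:
    by_key: dict[tuple[str, str], list[AUEvent]] = {}
    for ev in events:
        by_key.setdefault((ev.video_id, ev.au), []).append(ev)
    for (vid, au), evs in by_key.items():
        evs = sorted(evs, key=lambda e: e.onset)
        for a, b in zip(evs, evs[1:]):
            if b.onset < a.offset:
                raise ValidationError(
                    f"overlapping {au} events on {vid}: "
                    f"[{a.onset},{a.offset}) and [{b.onset},{b.offset})"
                )


def read_event_table(path, ontology=DEFAULT_ONTOLOGY) -> list[AUEvent]:
    """Read a CSV event table and return validated :class:`AUEvent` rows.

    The table must carry the header ``video_id,au,onset_frame,offset_frame,
    intensity``.  Unknown AU codes and overlapping same-AU events raise
    :class:`ValidationError`; malformed rows raise :class:`ParseError` naming
    the line.  ``NotVisible`` rows are returned like any other event and are
    interpreted by :func:`events_to_frame_matrix`.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    known = set(ontology) | {NOT_VISIBLE}
    events: list[AUEvent] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            onset, offset = int(row.onset_frame), int(row.offset_frame)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: line {i}: non-integer frame index") from exc
        if row.au not in known:
            raise ValidationError(f"{path}: line {i}: unknown AU code {row.au!r}")
        events.append(AUEvent(str(row.video_id), row.au, onset, offset, row.intensity))
    _check_overlaps(events)
    return events


def write_event_table(events: Sequence[AUEvent], path) -> None:
    """Write events as CSV; round-trips bit-exactly through read_event_table."""
    df = pd.DataFrame(
        [(e.video_id, e.au, e.onset, e.offset, e.intensity) for e in events],
        columns=list(EVENT_COLUMNS),
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Participant tables


def _panas_row(rec: ParticipantRecord) -> dict[str, object]:
    row: dict[str, object] = {
        "participant_id": rec.participant_id,
        "condition": rec.condition,
        "poo": rec.poo_stratum,
    }
    for item in (*PANAS_ITEMS, *PANAS_SCALES):
        row[f"pre_{item}"] = rec.panas_before.get(item, np.nan)
        row[f"post_{item}"] = rec.panas_after.get(item, np.nan)
    return row


def write_participant_table(participants: Sequence[ParticipantRecord], path) -> None:
    pd.DataFrame([_panas_row(p) for p in participants]).to_csv(path, index=False)


def read_participant_table(path) -> list[ParticipantRecord]:
    df = pd.read_csv(path)
    for col in ("participant_id", "condition", "poo"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    out = []
    for row in df.to_dict("records"):
        before = {
            k[4:]: float(v)
            for k, v in row.items()
            if k.startswith("pre_") and pd.notna(v)
        }
        after = {
            k[5:]: float(v)
            for k, v in row.items()
            if k.startswith("post_") and pd.notna(v)
        }
        out.append(
            ParticipantRecord(
                str(row["participant_id"]), str(row["condition"]), str(row["poo"]),
                before, after,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Frame expansion and pooling


def events_to_frame_matrix(
    events: Sequence[AUEvent],
    n_frames: int,
    fps: float = 25.0,
    aus: Sequence[str] = DEFAULT_ONTOLOGY,
    video_id: str | None = None,
) -> FrameMatrix:
    """Expand events of one video into a frames × AUs indicator matrix.

    ``indicator[f, a] = 1`` iff some event of AU *a* satisfies
    ``onset <= f < offset``; intensity is collapsed to presence.  ``NotVisible``
    events clear the visibility mask on their frames.  Events exceeding
    *n_frames* raise :class:`ValidationError`.
    """
    vids = {e.video_id for e in events}
    if video_id is None:
        if len(vids) > 1:
            raise ValidationError(f"events from multiple videos: {sorted(vids)}")
        video_id = next(iter(vids)) if vids else "<empty>"
    col = {au: j for j, au in enumerate(aus)}
    ind = np.zeros((n_frames, len(aus)), dtype=np.uint8)
    visible = np.ones(n_frames, dtype=bool)
    for ev in events:
        if ev.offset > n_frames:
            raise ValidationError(
                f"{ev.video_id}/{ev.au}: offset {ev.offset} exceeds n_frames {n_frames}"
            )
        if ev.au == NOT_VISIBLE:
            visible[ev.onset : ev.offset] = False
        elif ev.au in col:
            ind[ev.onset : ev.offset, col[ev.au]] = 1
        # events of AUs outside the requested column set are ignored
    return FrameMatrix(video_id, ind, tuple(aus), visible, fps)


def pooled_frequency(frames: Iterable[FrameMatrix] | FrameMatrix, au: str) -> float:
    """Proportion of visible frames carrying *au*, pooled over videos.

    Pooling concatenates frames, so longer videos weigh proportionally more.
    Raises :class:`EmptyInputError` if no visible frames remain (never a
    silent 0/0).
    """
    if isinstance(frames, FrameMatrix):
        frames = [frames]
    active = 0
    total = 0
    for fm in frames:
        if au not in fm.aus:
            raise ValidationError(f"{fm.video_id}: unknown AU {au!r}")
        j = fm.aus.index(au)
        vis = fm.visible
        active += int(fm.indicators[vis, j].sum())
        total += int(vis.sum())
    if total == 0:
        raise EmptyInputError(f"no visible frames to compute frequency of {au}")
    return active / total


def events_round_trip(events: Sequence[AUEvent]) -> list[AUEvent]:
    """Write events to an in-memory CSV and read them back (self-check)."""
    buf = io.StringIO()
    write_event_table(events, buf)
    buf.seek(0)
    return read_event_table(buf)
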