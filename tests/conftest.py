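import numpy as np
import pytest

import facsboot as fb

TINY_AUS = ("AU4", "AU20", "AU52", "FaceTouch", "NeckTouch")


def _fm(video_id, n_frames, active: dict[str, list[tuple[int, int]]],
        not_visible=(), fps=25.0):
    """Hand-build a FrameMatrix from AU -> [(onset, offset)] intervals."""
    events = [
        fb.AUEvent(video_id, au, a, b, "low")
        for au, spans in active.items()
        for a, b in spans
    ]
    events += [fb.AUEvent(video_id, "NotVisible", a, b) for a, b in not_visible]
    return fb.events_to_frame_matrix(events, n_frames, fps, TINY_AUS, video_id)


@pytest.fixture
def tiny_dataset():
    """Nine hand-built participants over five AUs; counts known by hand.

    Guilt: g1, g2, g3 (European), g4, g5 (EastAsian); control: c1, c2
    (European), c3, c4 (EastAsian).  AU4 is active for every guilt
    participant and no control participant; AU20 only for g1; FaceTouch for
    everyone.
    """
    def rec(pid, cond, stratum, pre_guilt, post_guilt):
        return fb.ParticipantRecord(
            pid, cond, stratum,
            {"guilt": pre_guilt, "shame": 1, "pride": 2},
            {"guilt": post_guilt, "shame": 2, "pride": 2},
        )

    participants = [
        rec("g1", "guilt", "European", 1, 3),
        rec("g2", "guilt", "European", 2, 2),
        rec("g3", "guilt", "European", 1, 4),
        rec("g4", "guilt", "EastAsian", 3, 2),
        rec("g5", "guilt", "EastAsian", 1, 5),
        rec("c1", "control", "European", 1, 1),
        rec("c2", "control", "European", 2, 1),
        rec("c3", "control", "EastAsian", 1, 1),
        rec("c4", "control", "EastAsian", 1, 2),
    ]
    codings = {
        "g1": _fm("g1", 20, {"AU4": [(0, 10)], "AU20": [(5, 8)], "FaceTouch": [(0, 20)]}),
        "g2": _fm("g2", 30, {"AU4": [(10, 20)], "FaceTouch": [(0, 5)]}),
        "g3": _fm("g3", 10, {"AU4": [(0, 2)], "FaceTouch": [(2, 4)]}),
        "g4": _fm("g4", 25, {"AU4": [(5, 10)], "FaceTouch": [(0, 1)]}),
        "g5": _fm("g5", 15, {"AU4": [(0, 15)], "FaceTouch": [(7, 9)]}),
        "c1": _fm("c1", 40, {"AU52": [(0, 10)], "FaceTouch": [(0, 8)]}),
        "c2": _fm("c2", 10, {"AU52": [(0, 5)], "FaceTouch": [(1, 2)]}),
        "c3": _fm("c3", 20, {"FaceTouch": [(0, 4)]}),
        "c4": _fm("c4", 30, {"AU52": [(10, 12)], "FaceTouch": [(0, 3)]}),
    }
    return fb.StudyDataset(participants, codings, TINY_AUS)


@pytest.fixture(scope="session")
def small_study():
    """A scaled-down synthetic study reused by read-only tests."""
    cfg = fb.GeneratorConfig(
        n_guilt=12, n_control=12,
        durations={"guilt": (20.0, 5.0, 10.0), "control": (8.0, 4.0, 2.0)},
    )
    return fb.generate_study(cfg, seed=42)
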