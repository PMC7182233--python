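"""Synthetic guilt-induction studies with the statistical structure the
analysis assumes.

The generator emulates the data-generating features that matter to the
bootstrap contrast, not faces: two conditions with very different video
durations (guilt videos average ~74 s, control ~8 s, at 25 fps), two
place-of-origin strata, per-individual expressivity variation, and
bout-structured AU activations with condition-specific elevation of the
guilt-marker AUs.

Per participant *i* and action unit *a*, the stationary frame probability is

    p_ia = logistic( logit(au_base[a]) + u_i + 1[guilt] * log(effect[a]) ),
    u_i ~ Normal(0, sigma_individual),

and frames follow a two-state Markov chain with off->on rate
``p_ia / (bout_length * (1 - p_ia))`` and on->off rate ``1 / bout_length``,
giving stationary probability p_ia and mean on-run length ``bout_length``.
Configs for which the off->on rate would exceed 1 (p > L/(L+1)) are rejected.

Judges are emulated by a Poisson number of time pinpoints per video, placed
preferentially on seconds where guilt-marker AUs are active, and by sliding
0-100 emotion ratings whose video mean is linear in the AU4 and NeckTouch
frame ratios.

Randomness: a single study seed is split into independent per-participant
streams via ``numpy.random.SeedSequence(seed, spawn_key=(group, index))``,
so enlarging one group never perturbs data already generated for earlier
participants or the other group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .errors import ValidationError
from .facs_io import (
    AUEvent,
    FrameMatrix,
    ParticipantRecord,
    StudyDataset,
)
from .ontology import DEFAULT_ONTOLOGY, GUILT_MARKER_AUS

__all__ = [
    "GeneratorConfig",
    "generate_study",
    "generate_pinpoints",
    "generate_ratings",
    "markov_bout_series",
    "frame_matrix_to_events",
]

#: Baseline per-frame AU probabilities (control-condition expected
#: frequencies of the reference study's summary table).
DEFAULT_AU_BASE: dict[str, float] = {
    "AU1": 0.51, "AU2": 0.50, "AU4": 0.08, "AU5": 0.11, "AU7": 0.32,
    "AU10": 0.23, "AU12": 0.32, "AU14": 0.24, "AU17": 0.21, "AU18": 0.13,
    "AU20": 0.02, "AU24": 0.13, "AU51": 0.29, "AU52": 0.22, "AU54": 0.18,
    "AU55": 0.23, "AU56": 0.21, "AU57": 0.25, "AU59": 0.03, "AU61": 0.15,
    "AU62": 0.15, "AU64": 0.39, "FaceTouch": 0.10, "NeckTouch": 0.001,
}

#: Odds multipliers applied in the guilt condition (observed/expected odds
#: ratios of the guilt-marker AUs).
DEFAULT_CONDITION_EFFECTS: dict[str, float] = {
    "AU4": 2.7, "AU20": 1.5, "AU52": 1.45, "AU62": 1.5, "NeckTouch": 20.0,
}

# (pre_mean, pre_sd, post_mean, post_sd) per item/scale and condition.
# Printed induction-check statistics where available; unprinted cells filled
# with values consistent with the reported between-condition differences.
DEFAULT_PANAS_MODEL: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "guilt": {
        "guilt": (1.35, 0.79, 2.70, 1.23),
        "shame": (1.33, 0.83, 2.24, 1.12),
        "distress": (1.58, 0.95, 2.42, 1.15),
        "pride": (2.35, 1.06, 1.89, 1.10),
        "nervousness": (1.80, 1.00, 2.40, 1.20),
        "positive": (29.73, 6.12, 20.27, 8.08),
        "negative": (18.61, 8.56, 21.89, 8.23),
    },
    "control": {
        "guilt": (1.30, 0.60, 1.28, 0.60),
        "shame": (1.50, 0.80, 1.87, 0.90),
        "distress": (1.72, 0.98, 1.48, 0.89),
        "pride": (2.46, 1.15, 3.40, 1.20),
        "nervousness": (1.80, 1.00, 1.77, 1.00),
        "positive": (30.46, 8.47, 25.18, 11.06),
        "negative": (21.20, 10.96, 12.88, 4.97),
    },
}

PANAS_SCALE_KEYS = ("positive", "negative")

#: (mean s, sd s, minimum s) of the truncated-normal video-duration models.
DEFAULT_DURATIONS = {"guilt": (73.66, 46.56, 10.0), "control": (7.90, 4.27, 2.0)}

#: Video-mean rating model per emotion:
#: mean = intercept + guilt_shift*1[guilt] + b_AU4*ratio_AU4 + b_NT*ratio_NeckTouch
DEFAULT_RATING_MODEL: dict[str, tuple[float, float, float, float]] = {
    "guilty": (19.0, 10.0, 30.0, 60.0),
    "uncomfortable": (20.0, 12.0, 10.0, 30.0),
    "embarrassed": (18.0, 8.0, 10.0, 20.0),
    "surprised": (21.5, 18.0, 5.0, 0.0),
    "other": (10.0, 0.0, 0.0, 0.0),
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    n_guilt: int = 66
    n_control: int = 65
    poo_probs: dict[str, float] = field(
        default_factory=lambda: {"European": 2 / 3, "EastAsian": 1 / 3}
    )
    durations: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DURATIONS)
    )
    fps: float = 25.0
    au_base: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AU_BASE))
    condition_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_EFFECTS)
    )
    sigma_individual: float = 0.3
    bout_length: float = 10.0
    #: per-stratum additive logit shift (off by default: strata are labels
    #: only, isolating the ratio-matching machinery)
    poo_effect: dict[str, float] = field(default_factory=dict)
    pinpoint_rate: float = 7.0
    control_pinpoint_rate: float = 3.0
    colabel_prob: float = 0.10
    designated_aus: tuple[str, ...] = GUILT_MARKER_AUS
    #: per-second sampling weight is 1 + scale * (#designated AUs active)
    pinpoint_weight_scale: float = 1.0
    n_judges_per_video: int = 20
    rating_model: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RATING_MODEL)
    )
    rating_noise_sd: float = 15.0
    panas_model: dict[str, dict[str, tuple[float, float, float, float]]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_PANAS_MODEL.items()}
    )
    panas_prepost_corr: float = 0.4
    ontology: tuple[str, ...] = DEFAULT_ONTOLOGY
    #: skip judge-table generation (pinpoints/ratings) entirely
    with_judges: bool = True

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_guilt < 1 or self.n_control < 1:
            raise ValidationError("participant counts must be >= 1")
        if abs(sum(self.poo_probs.values()) - 1.0) > 1e-9 or any(
            not 0 < q < 1 for q in self.poo_probs.values()
        ):
            raise ValidationError("poo_probs must lie in (0,1) and sum to 1")
        if self.bout_length < 1:
            raise ValidationError("bout_length must be >= 1 frame")
        if any(e <= 0 for e in self.condition_effects.values()):
            raise ValidationError("condition effect odds multipliers must be > 0")
        L = self.bout_length
        for cond in ("control", "guilt"):
            for au in self.ontology:
                p = self.au_base.get(au)
                if p is None:
                    raise ValidationError(f"au_base missing {au}")
                if not 0 < p < 1:
                    raise ValidationError(f"au_base[{au}] must be in (0,1)")
                if cond == "guilt":
                    p = float(expit(logit(p) + np.log(self.condition_effects.get(au, 1.0))))
                if p / (L * (1 - p)) > 1:
                    raise ValidationError(
                        f"off->on rate for {au} ({cond}) exceeds 1; "
                        f"need p <= bout_length/(bout_length+1)"
                    )


def markov_bout_series(
    rng: np.random.Generator, n_frames: int, p: float, bout_length: float
) -> np.ndarray:
    """Stationary two-state Markov chain as alternating geometric sojourns.

    On-runs are Geometric(1/bout_length), off-runs Geometric(p/(L(1-p))); the
    initial state is a stationary Bernoulli(p) draw, and by memorylessness its
    first sojourn is a fresh geometric, so the whole series is exact.
    """
    out = np.zeros(n_frames, dtype=np.uint8)
    if n_frames == 0 or p <= 0:
        return out
    if p >= 1:
        out[:] = 1
        return out
    q_on_off = 1.0 / bout_length
    q_off_on = p / (bout_length * (1.0 - p))
    if q_off_on > 1:
        raise ValidationError("off->on rate exceeds 1; invalid (p, bout_length)")
    state = bool(rng.random() < p)
    i = 0
    while i < n_frames:
        run = int(rng.geometric(q_on_off if state else q_off_on))
        if state:
            out[i : i + run] = 1
        i += run
        state = not state
    return out


def _participant_rng(seed: int, group: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(group, index)))


def _draw_duration_frames(rng, spec: tuple[float, float, float], fps: float) -> int:
    mean, sd, lo = spec
    a = (lo - mean) / sd
    d = float(truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))
    return max(1, int(round(d * fps)))


def _draw_panas(rng, model: Mapping[str, tuple[float, float, float, float]], rho: float):
    before, after = {}, {}
    for item, (m0, s0, m1, s1) in model.items():
        z0, z1 = rng.standard_normal(2)
        pre = m0 + s0 * z0
        post = m1 + s1 * (rho * z0 + np.sqrt(1 - rho**2) * z1)
        lo, hi = (10, 50) if item in PANAS_SCALE_KEYS else (1, 5)
        before[item] = float(np.clip(round(pre), lo, hi))
        after[item] = float(np.clip(round(post), lo, hi))
    return before, after


def generate_study(config: GeneratorConfig | None = None, seed: int = 0) -> StudyDataset:
    """Generate a complete synthetic study, bit-reproducible given *seed*.

    Returns a :class:`StudyDataset` whose ``pinpoints`` and ``ratings``
    attributes carry the judge tables.
    """
    config = config or GeneratorConfig()
    config.validate()
    strata_names = sorted(config.poo_probs)
    strata_p = np.array([config.poo_probs[s] for s in strata_names])
    L = config.bout_length

    participants: list[ParticipantRecord] = []
    codings: dict[str, FrameMatrix] = {}
    for group, (cond, n) in enumerate(
        [("guilt", config.n_guilt), ("control", config.n_control)]
    ):
        width = len(str(n))
        for i in range(n):
            rng = _participant_rng(seed, group, i)
            pid = f"{cond[0]}{i + 1:0{width}d}"
            stratum = strata_names[int(rng.choice(len(strata_names), p=strata_p))]
            n_frames = _draw_duration_frames(rng, config.durations[cond], config.fps)
            u_i = rng.normal(0.0, config.sigma_individual)
            shift = config.poo_effect.get(stratum, 0.0)
            ind = np.zeros((n_frames, len(config.ontology)), dtype=np.uint8)
            for j, au in enumerate(config.ontology):
                eta = logit(config.au_base[au]) + u_i + shift
                if cond == "guilt":
                    eta += np.log(config.condition_effects.get(au, 1.0))
                # clip to the bout-rate validity region; config-level values
                # are validated, individual tails are clamped
                p_ia = float(np.clip(expit(eta), 1e-9, L / (L + 1) - 1e-9))
                ind[:, j] = markov_bout_series(rng, n_frames, p_ia, L)
            before, after = _draw_panas(
                rng, config.panas_model[cond], config.panas_prepost_corr
            )
            participants.append(
                ParticipantRecord(pid, cond, stratum, before, after)
            )
            codings[pid] = FrameMatrix(
                pid, ind, tuple(config.ontology),
                np.ones(n_frames, dtype=bool), config.fps,
            )

    dataset = StudyDataset(participants, codings, tuple(config.ontology))
    if config.with_judges:
        dataset.pinpoints = generate_pinpoints(dataset, config, seed)
        dataset.ratings = generate_ratings(dataset, config, seed)
    return dataset


def _second_weights(
    fm: FrameMatrix, designated: Sequence[str], fps: float, scale: float = 1.0
) -> np.ndarray:
    """Sampling weight per whole second: 1 + scale * #designated AUs active."""
    n_seconds = int(fm.n_frames // fps)
    cols = [fm.aus.index(a) for a in designated if a in fm.aus]
    w = np.ones(n_seconds)
    for s in range(n_seconds):
        block = fm.indicators[int(s * fps) : int((s + 1) * fps), cols]
        w[s] += scale * float((block.any(axis=0)).sum())
    return w


def generate_pinpoints(
    dataset: StudyDataset, config: GeneratorConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Judge time pinpoints: Poisson-many per video, at integer seconds.

    Guilt videos draw Poisson(pinpoint_rate) pinpoints with per-second weight
    1 + the number of designated guilt AUs active in that second; control
    videos use a small fixed rate.  Videos shorter than one second are
    skipped with a warning.  A fraction of guilt pinpoints receives a
    companion row with another emotion label at the same (judge, video,
    second), emulating co-labelling.
    """
    config = config or GeneratorConfig()
    cond = {p.participant_id: p.condition for p in dataset.participants}
    other_emotions = ("embarrassed", "uncomfortable", "surprised")
    rows = []
    for vi, vid in enumerate(sorted(dataset.codings)):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2, vi)))
        fm = dataset.codings[vid]
        lam = (
            config.pinpoint_rate if cond[vid] == "guilt" else config.control_pinpoint_rate
        )
        if fm.n_frames < config.fps:
            warnings.warn(f"video {vid} shorter than 1 s; skipped", stacklevel=2)
            continue
        k = int(rng.poisson(lam))
        if k == 0:
            continue
        w = _second_weights(
            fm, config.designated_aus, config.fps, config.pinpoint_weight_scale
        )
        seconds = rng.choice(len(w), size=k, replace=True, p=w / w.sum())
        judges = rng.integers(1, config.n_judges_per_video + 1, size=k)
        for t, j in zip(seconds, judges):
            rows.append((f"J{j:03d}", vid, "guilty", int(t), np.nan))
            if rng.random() < config.colabel_prob:
                emo = other_emotions[int(rng.integers(len(other_emotions)))]
                rows.append((f"J{j:03d}", vid, emo, int(t), np.nan))
    return pd.DataFrame(
        rows, columns=["judge_id", "video_id", "emotion", "t_seconds", "rating"]
    )


def generate_ratings(
    dataset: StudyDataset, config: GeneratorConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Per-judge 0-100 emotion sliders; video means linear in AU4/NeckTouch."""
    config = config or GeneratorConfig()
    cond = {p.participant_id: p.condition for p in dataset.participants}
    rows = []
    for vi, vid in enumerate(sorted(dataset.codings)):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3, vi)))
        fm = dataset.codings[vid]
        vis = fm.visible
        denom = max(1, int(vis.sum()))

        def ratio(au: str) -> float:
            if au not in fm.aus:
                return 0.0
            return float(fm.indicators[vis, fm.aus.index(au)].sum()) / denom

        r4, rnt = ratio("AU4"), ratio("NeckTouch")
        is_guilt = cond[vid] == "guilt"
        for emotion, (b0, bg, b4, bnt) in config.rating_model.items():
            mu = b0 + bg * is_guilt + b4 * r4 + bnt * rnt
            vals = np.clip(
                mu + rng.normal(0, config.rating_noise_sd, config.n_judges_per_video),
                0, 100,
            )
            for j, v in enumerate(vals, start=1):
                rows.append((f"J{j:03d}", vid, emotion, np.nan, float(round(v, 1))))
    return pd.DataFrame(
        rows, columns=["judge_id", "video_id", "emotion", "t_seconds", "rating"]
    )


def frame_matrix_to_events(fm: FrameMatrix) -> list[AUEvent]:
    """Run-length encode a frame matrix back into AU events (low intensity)."""
    events = []
    for j, au in enumerate(fm.aus):
        col = fm.indicators[:, j].astype(np.int8)
        changes = np.flatnonzero(np.diff(np.concatenate([[0], col, [0]])))
        for on, off in zip(changes[::2], changes[1::2]):
            events.append(AUEvent(fm.video_id, au, int(on), int(off), "low"))
    return events
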