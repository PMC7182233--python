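"""End-to-end orchestration: simulate/ingest -> select -> contrast ->
pinpoints -> models, with seeded, byte-reproducible outputs.

Every stage consumes and returns plain containers (DataFrames, dicts); this
module only wires them together, derives per-stage RNG streams from the one
recorded seed, and writes per-stage CSV/JSON next to a run log.  Identical
configuration + seed yields byte-identical output files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .au_selection import SelectionConfig, select_action_units
from .bootstrap_contrast import (
    BootstrapConfig,
    contrast_conditions,
    split_by_guilt_change,
)
from .errors import ValidationError
from .facs_io import (
    StudyDataset,
    events_to_frame_matrix,
    read_event_table,
    read_participant_table,
    write_event_table,
    write_participant_table,
)
from .ontology import DEFAULT_ONTOLOGY
from .pinpoint_analysis import build_windows, contrast_pinpoints, pinpoint_summary
from .rating_stats import (
    build_video_features,
    judged_guilt_model,
    paired_affect_tests,
    selfreport_judgement_correlation,
)
from .synthetic_data import GeneratorConfig, frame_matrix_to_events, generate_study

logger = logging.getLogger("facsboot")

__all__ = ["PipelineConfig", "run_pipeline", "load_dataset", "write_dataset",
           "contrast_to_markdown"]


@dataclass
class PipelineConfig:
    """One pipeline run: either file inputs or a synthetic generator config."""

    events_path: str | None = None
    participants_path: str | None = None
    pinpoints_path: str | None = None
    ratings_path: str | None = None
    generator: GeneratorConfig | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    fps: float = 25.0
    do_select: bool = True
    do_contrasts: bool = True
    do_pinpoints: bool = True
    do_models: bool = True
    out_dir: str = "facsboot_out"
    seed: int = 0

    def __post_init__(self):
        has_paths = self.events_path is not None
        has_gen = self.generator is not None
        if has_paths == has_gen:
            raise ValidationError(
                "supply exactly one of (events/participants paths, generator config)"
            )
        if has_paths and self.participants_path is None:
            raise ValidationError("events_path requires participants_path")


def load_dataset(
    events_path,
    participants_path,
    pinpoints_path=None,
    ratings_path=None,
    fps: float = 25.0,
    ontology=DEFAULT_ONTOLOGY,
    video_lengths: Mapping[str, int] | None = None,
) -> StudyDataset:
    """Assemble a :class:`StudyDataset` from CSV inputs.

    Unless *video_lengths* is given, each video's frame count is taken as the
    maximum event offset observed for it.
    """
    events = read_event_table(events_path, ontology)
    participants = read_participant_table(participants_path)
    by_video: dict[str, list] = {}
    for ev in events:
        by_video.setdefault(ev.video_id, []).append(ev)
    codings = {}
    for p in participants:
        evs = by_video.get(p.participant_id, [])
        if video_lengths and p.participant_id in video_lengths:
            n = video_lengths[p.participant_id]
        else:
            n = max((e.offset for e in evs), default=1)
        codings[p.participant_id] = events_to_frame_matrix(
            evs, n, fps, ontology, video_id=p.participant_id
        )
    ds = StudyDataset(participants, codings, tuple(ontology))
    if pinpoints_path is not None:
        ds.pinpoints = pd.read_csv(pinpoints_path)
    if ratings_path is not None:
        ds.ratings = pd.read_csv(ratings_path)
    return ds


def write_dataset(dataset: StudyDataset, out_dir) -> dict[str, Path]:
    """Write a dataset's event, participant and judge CSVs into *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events = []
    for vid in sorted(dataset.codings):
        events.extend(frame_matrix_to_events(dataset.codings[vid]))
    paths = {
        "events": out / "events.csv",
        "participants": out / "participants.csv",
    }
    write_event_table(events, paths["events"])
    write_participant_table(dataset.participants, paths["participants"])
    if dataset.pinpoints is not None:
        paths["pinpoints"] = out / "pinpoints.csv"
        dataset.pinpoints.to_csv(paths["pinpoints"], index=False)
    if dataset.ratings is not None:
        paths["ratings"] = out / "ratings.csv"
        dataset.ratings.to_csv(paths["ratings"], index=False)
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        if np.isnan(f):
            return None
        if np.isinf(f):
            return "inf" if f > 0 else "-inf"
        return f
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(100, stage)))


def contrast_to_markdown(table: pd.DataFrame, B: int, title: str = "") -> str:
    """Human-readable contrast table; p = 0 is printed as < 1/B."""
    lines = []
    if title:
        lines += [f"### {title}", ""]
    lines.append("| AU | Observed | Expected | z | p | sig |")
    lines.append("|---|---|---|---|---|---|")
    for row in table.itertuples(index=False):
        p_str = f"<{1 / B:g}" if row.p == 0 else f"{row.p:.3f}"
        mark = "*" if row.significant else ""
        lines.append(
            f"| {row.au} | {row.observed_freq:.2f} | {row.expected_freq:.2f} "
            f"| {row.z:.2f} | {p_str} | {mark} |"
        )
    return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write per-stage outputs.

    Returns a dict of in-memory results; files land in ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    log: dict = {"seed": config.seed, "version": __version__, "stages": []}

    if config.generator is not None:
        logger.info("simulating synthetic study (seed=%d)", config.seed)
        dataset = generate_study(config.generator, config.seed)
        write_dataset(dataset, out / "inputs")
        log["stages"].append("simulate")
    else:
        logger.info("loading dataset from %s", config.events_path)
        dataset = load_dataset(
            config.events_path, config.participants_path,
            config.pinpoints_path, config.ratings_path, config.fps,
        )
        log["stages"].append("ingest")
    results["dataset"] = dataset

    aus = list(dataset.ontology)
    if config.do_select:
        aus = select_action_units(dataset, config.selection)
        pd.DataFrame({"au": aus}).to_csv(out / "selected_aus.csv", index=False)
        log["stages"].append("select")
    results["selected_aus"] = aus

    bc = config.bootstrap
    report_md = []
    if config.do_contrasts:
        guilt = dataset.by_condition("guilt")
        control = dataset.by_condition("control")
        weak, strong = split_by_guilt_change(dataset)
        jobs = [
            ("guilt_vs_control", guilt, control),
            ("weak_vs_control", weak, control),
            ("strong_vs_control", strong, control),
            ("strong_vs_weak", strong, weak),
        ]
        results["contrasts"] = {}
        for k, (name, test, ctrl) in enumerate(jobs):
            if not test or not ctrl:
                logger.warning("contrast %s skipped: empty group", name)
                continue
            try:
                table = contrast_conditions(
                    dataset.frames_for(test), dataset.frames_for(ctrl),
                    test, ctrl, aus, bc, rng=_stage_rng(config.seed, k),
                )
            except ValidationError as exc:
                # data-dependent subgroup contrasts (weak/strong) can lose a
                # stratum at small n; skip those rather than abort the run
                logger.warning("contrast %s skipped: %s", name, exc)
                continue
            table.to_csv(out / f"contrast_{name}.csv", index=False)
            report_md.append(contrast_to_markdown(table, bc.B, name))
            results["contrasts"][name] = table
        log["stages"].append("contrast")

    if config.do_pinpoints and dataset.pinpoints is not None:
        results["pinpoint_contrasts"] = {}
        for k, cond in enumerate(("control", "guilt")):
            members = dataset.by_condition(cond)
            frames = dataset.frames_for(members)
            lengths = {v: fm.n_frames for v, fm in frames.items()}
            pins = dataset.pinpoints[dataset.pinpoints["video_id"].isin(lengths)]
            windows = build_windows(pins, lengths, config.fps)
            if not len(windows):
                logger.warning("no %s-condition pinpoints; stage skipped", cond)
                continue
            table = contrast_pinpoints(
                frames, windows, members, aus, bc,
                rng=_stage_rng(config.seed, 10 + k),
            )
            table.to_csv(out / f"pinpoint_contrast_{cond}.csv", index=False)
            report_md.append(contrast_to_markdown(table, bc.B, f"pinpoints_{cond}"))
            results["pinpoint_contrasts"][cond] = table
        summary = pinpoint_summary(
            dataset.pinpoints, dataset.ratings,
            {p.participant_id: p.condition for p in dataset.participants},
        )
        _write_json(summary, out / "pinpoint_summary.json")
        results["pinpoint_summary"] = summary
        log["stages"].append("pinpoints")

    if config.do_models:
        affect = paired_affect_tests(dataset.participants)
        affect["within"].to_csv(out / "affect_within.csv", index=False)
        affect["between"].to_csv(out / "affect_between.csv", index=False)
        results["affect"] = affect
        if dataset.ratings is not None:
            features = build_video_features(dataset)
            features.to_csv(out / "video_features.csv", index=False)
            model = judged_guilt_model(features)
            _write_json(model, out / "model_report.json")
            results["judged_guilt_model"] = model
            mean_guilt = (
                dataset.ratings.dropna(subset=["rating"])
                .query("emotion == 'guilty'")
                .groupby("video_id")["rating"].mean()
            )
            corr = selfreport_judgement_correlation(
                dataset.participants, mean_guilt.to_dict()
            )
            _write_json(corr, out / "selfreport_judgement_correlation.json")
            results["selfreport_judgement_correlation"] = corr
        log["stages"].append("models")

    if report_md:
        (out / "report.md").write_text("\n".join(report_md))
    _write_json(log, out / "run_log.json")
    return results
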