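"""Stratified individual-level bootstrap contrasts of AU frame frequencies.

The test asks, per action unit, whether its pooled frame frequency in a test
group of individuals could have arisen from the control group.  A null
distribution is built by repeatedly resampling *individuals* (not frames)
from the control group with replacement — frames within an individual are
strongly autocorrelated (bouts), so individuals are the exchangeable unit —
and pooling the resampled individuals' frames.  Draws are stratified so that
each resample reproduces the test group's place-of-origin composition (e.g.
a 2-to-1 European/East-Asian ratio), apportioned by largest remainder.

Per AU the table reports the observed test-group frequency, the mean
bootstrap frequency (expected under the null), a z-score
``(observed - mean) / sd`` (sample sd, ddof=1), and an empirical p-value

    p = min(#{boot >= observed}, #{boot <= observed}) / B

with ties counted as extreme (conservative).  Under this convention p = 0.01
with positive z means exactly that in 990 of 1000 resamples the AU occurred
less frequently than in the test data.  ``two_sided_double`` doubles the
minimum tail (the textbook two-sided empirical p); the one-direction rule is
the default because it is the one the reported-p convention implies, but the
two conventions differ by a factor of two in attained level — see
docs/methods.md for the calibration consequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import floor, isclose
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .facs_io import FrameMatrix, ParticipantRecord, StudyDataset

__all__ = [
    "BootstrapConfig",
    "largest_remainder_apportionment",
    "stratified_resample_ids",
    "participant_counts",
    "contrast_counts",
    "contrast_conditions",
    "split_by_guilt_change",
]

#: Columns of a contrast table (the machine twin of the study's Tables 1-5).
CONTRAST_COLUMNS = (
    "au", "observed_freq", "expected_freq", "z", "p", "direction", "significant",
)


@dataclass
class BootstrapConfig:
    """Parameters of the bootstrap null construction.

    ``resample_size`` is the number of individuals drawn per replicate;
    ``"control_n"`` (default) uses the control group's own size, mirroring
    the variance of a control group of the same size.
    """

    B: int = 1000
    alpha: float = 0.01
    stratify_by: str = "poo_stratum"
    resample_size: int | str = "control_n"
    seed: int | None = None
    two_sided_double: bool = False

    def __post_init__(self):
        if self.B < 1:
            raise ValidationError(f"B must be >= 1, got {self.B}")
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")


def largest_remainder_apportionment(
    target_ratios: Mapping[str, float], m: int
) -> dict[str, int]:
    """Apportion m draws over strata by largest remainder.

    Quotas are ``m * ratio`` (ratios normalised to sum 1); each stratum gets
    the floor of its quota, and remaining seats go to the largest fractional
    remainders, ties broken by alphabetical stratum order.
    """
    if m < 0:
        raise ValidationError("m must be >= 0")
    total = float(sum(target_ratios.values()))
    if total <= 0:
        raise ValidationError("target ratios must have positive sum")
    strata = sorted(target_ratios)
    quotas = {s: m * target_ratios[s] / total for s in strata}
    counts = {s: floor(quotas[s]) for s in strata}
    # guard against float-representation shortfalls of exact quotas
    for s in strata:
        if isclose(quotas[s], counts[s] + 1, rel_tol=0, abs_tol=1e-9):
            counts[s] += 1
    remaining = m - sum(counts.values())
    by_remainder = sorted(strata, key=lambda s: (-(quotas[s] - counts[s]), s))
    for s in by_remainder[:remaining]:
        counts[s] += 1
    return counts


def stratified_resample_ids(
    control_strata: Mapping[str, str],
    target_ratios: Mapping[str, float],
    m: int,
    rng: np.random.Generator,
) -> list[str]:
    """Draw a size-m multiset of control ids matching the target composition.

    ``control_strata`` maps participant id -> stratum.  Within each stratum
    draws are uniform with replacement over the ids in sorted order (so the
    draw sequence does not depend on input iteration order); a participant
    drawn repeatedly contributes its frames repeatedly downstream.
    """
    pools = {}
    for pid in sorted(control_strata):
        pools.setdefault(control_strata[pid], []).append(pid)
    missing = [s for s in target_ratios if target_ratios[s] > 0 and s not in pools]
    if missing:
        raise ValidationError(
            f"strata present in test but absent from control: {missing}"
        )
    counts = largest_remainder_apportionment(target_ratios, m)
    out: list[str] = []
    for s in sorted(counts):
        k = counts[s]
        if k == 0:
            continue
        pool = pools[s]
        out.extend(pool[i] for i in rng.integers(0, len(pool), size=k))
    return out


# ---------------------------------------------------------------------------
# Count summaries and the core contrast


def participant_counts(
    frames: Mapping[str, FrameMatrix], aus: Sequence[str]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Reduce frame matrices to per-individual (active counts, visible totals).

    Returns (sorted ids, counts[n, len(aus)], totals[n]).  Pooled frequency of
    any id subset is then ``counts[rows].sum(0) / totals[rows].sum()`` — the
    exact frame-concatenation value.
    """
    ids = sorted(frames)
    counts = np.zeros((len(ids), len(aus)), dtype=np.int64)
    totals = np.zeros(len(ids), dtype=np.int64)
    for i, pid in enumerate(ids):
        fm = frames[pid]
        cols = [fm.aus.index(a) for a in aus]
        vis = fm.visible
        counts[i] = fm.indicators[np.ix_(vis, cols)].sum(axis=0)
        totals[i] = vis.sum()
        if totals[i] == 0:
            raise ValidationError(f"participant {pid} has no visible frames")
    return ids, counts, totals


def _empirical_row(obs: float, boot: np.ndarray, alpha: float, double: bool):
    mean = float(boot.mean())
    sd = float(boot.std(ddof=1)) if boot.size > 1 else 0.0
    if boot.max() == boot.min():
        sd = 0.0  # constant replicates; ignore mean-subtraction rounding fuzz
    if sd > 0:
        z = (obs - mean) / sd
    elif np.isclose(obs, mean):
        z = 0.0
    else:  # degenerate null: signed-infinity sentinel, p still from counts
        z = float(np.sign(obs - mean)) * np.inf
    B = boot.size
    p = min(int((boot >= obs).sum()), int((boot <= obs).sum())) / B
    if double:
        p = min(1.0, 2.0 * p)
    return mean, z, p


def contrast_counts(
    test_counts: np.ndarray,
    test_totals: np.ndarray,
    control_counts: np.ndarray,
    control_totals: np.ndarray,
    control_strata: Sequence[str],
    target_ratios: Mapping[str, float],
    aus: Sequence[str],
    config: BootstrapConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Bootstrap contrast on pre-reduced per-individual count summaries.

    Rows of the count arrays are individuals *in sorted-id order*; this is the
    engine shared by the condition contrast and the pinpoint contrast.
    """
    if len(aus) == 0:
        raise ValidationError("retained AU list is empty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_ctrl = control_counts.shape[0]
    if n_ctrl == 0 or test_counts.shape[0] == 0:
        raise ValidationError("both groups must be non-empty")
    m = n_ctrl if config.resample_size == "control_n" else int(config.resample_size)

    obs = test_counts.sum(axis=0) / test_totals.sum()

    strata_arr = np.asarray(control_strata)
    pools = {s: np.flatnonzero(strata_arr == s) for s in np.unique(strata_arr)}
    missing = [s for s, r in target_ratios.items() if r > 0 and s not in pools]
    if missing:
        raise ValidationError(
            f"strata present in test but absent from control: {missing}"
        )
    draw_counts = largest_remainder_apportionment(target_ratios, m)

    boot = np.empty((config.B, len(aus)))
    for b in range(config.B):
        idx_parts = []
        for s in sorted(draw_counts):
            k = draw_counts[s]
            if k:
                pool = pools[s]
                idx_parts.append(pool[rng.integers(0, len(pool), size=k)])
        idx = np.concatenate(idx_parts)
        boot[b] = control_counts[idx].sum(axis=0) / control_totals[idx].sum()

    rows = []
    for j, au in enumerate(aus):
        mean, z, p = _empirical_row(float(obs[j]), boot[:, j], config.alpha, config.two_sided_double)
        rows.append(
            {
                "au": au,
                "observed_freq": float(obs[j]),
                "expected_freq": mean,
                "z": z,
                "p": p,
                "direction": int(np.sign(z)),
                "significant": p <= config.alpha,
            }
        )
    return pd.DataFrame(rows, columns=list(CONTRAST_COLUMNS))


def _as_strata(meta) -> dict[str, str]:
    if isinstance(meta, Mapping):
        return dict(meta)
    return {p.participant_id: p.poo_stratum for p in meta}


def contrast_conditions(
    test_frames: Mapping[str, FrameMatrix],
    control_frames: Mapping[str, FrameMatrix],
    test_meta,
    control_meta,
    aus: Sequence[str],
    config: BootstrapConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-AU bootstrap contrast of a test group against a control group.

    *meta* arguments are either ``{participant_id: stratum}`` mappings or
    sequences of :class:`ParticipantRecord`.  The target stratum ratios are
    the test group's own composition.  Fully reproducible given
    ``config.seed`` (or an explicit *rng*).
    """
    config = config or BootstrapConfig()
    test_strata = _as_strata(test_meta)
    ctrl_strata = _as_strata(control_meta)
    t_ids, t_counts, t_totals = participant_counts(test_frames, aus)
    c_ids, c_counts, c_totals = participant_counts(control_frames, aus)
    ratios: dict[str, float] = {}
    for pid in t_ids:
        s = test_strata[pid]
        ratios[s] = ratios.get(s, 0.0) + 1.0
    return contrast_counts(
        t_counts, t_totals, c_counts, c_totals,
        [ctrl_strata[pid] for pid in c_ids],
        ratios, aus, config, rng,
    )


def split_by_guilt_change(
    dataset: StudyDataset, condition: str = "guilt"
) -> tuple[list[ParticipantRecord], list[ParticipantRecord]]:
    """Partition guilt-condition participants into weak / strong responders.

    weak: self-reported guilt change (after - before) <= 0; strong: > 0.
    Participants missing either PANAS guilt item are excluded with a warning.
    """
    weak, strong = [], []
    for p in dataset.by_condition(condition):
        change = p.guilt_change
        if change is None:
            warnings.warn(
                f"participant {p.participant_id} missing PANAS guilt item; excluded",
                stacklevel=2,
            )
            continue
        (weak if change <= 0 else strong).append(p)
    return weak, strong
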