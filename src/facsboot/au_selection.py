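"""Action-unit inclusion filter.

An AU/AD enters the analysis only if it is produced "more than chance" across
participants: in each condition, the number of participants producing it at
least once must reach an exact-binomial critical count (the smallest k with
P(X >= k | n, p0) <= alpha under X ~ Binomial(n, p0)).  Theory-motivated
codes (shame-linked head/eye-down movements and the self-directed behaviours)
are force-included regardless of counts.

The original study quotes a criterion of 39 producers per condition; that
number cannot be re-derived unambiguously (the n, chance probability and
sidedness behind it are unstated), so the filter accepts an explicit
``min_count`` override and otherwise computes the binomial criterion from
each condition's own n with p0 = 0.5, one-sided, alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats

from .errors import ValidationError
from .facs_io import StudyDataset
from .ontology import FORCED_INCLUDE

__all__ = [
    "SelectionConfig",
    "participants_producing",
    "binomial_min_count",
    "select_action_units",
]


@dataclass
class SelectionConfig:
    """Parameters of the producer-count inclusion filter."""

    p0: float = 0.5
    alpha: float = 0.05
    forced_include: tuple[str, ...] = FORCED_INCLUDE
    min_count: int | None = None

    def __post_init__(self):
        if not 0 < self.p0 < 1:
            raise ValidationError(f"p0 must be in (0,1), got {self.p0}")
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")


def participants_producing(dataset: StudyDataset, au: str, condition: str) -> int:
    """Number of participants in *condition* with >= 1 visible frame of *au*."""
    if au not in dataset.ontology:
        raise ValidationError(f"unknown AU {au!r}")
    members = dataset.by_condition(condition)
    if not members:
        raise ValidationError(f"no participants in condition {condition!r}")
    n = 0
    for p in members:
        fm = dataset.codings.get(p.participant_id)
        if fm is None:
            continue
        j = fm.aus.index(au)
        if fm.indicators[fm.visible, j].any():
            n += 1
    return n


def binomial_min_count(n: int, p0: float = 0.5, alpha: float = 0.05) -> int:
    """Smallest k with exact upper-tail P(X >= k | n, p0) <= alpha.

    Returns ``n + 1`` as an "unattainable" sentinel when even k = n fails.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if not 0 < p0 < 1 or not 0 < alpha < 1:
        raise ValidationError("p0 and alpha must lie in (0,1)")
    # P(X >= k) = sf(k - 1); scan upward (n is small in practice)
    for k in range(n + 1):
        if stats.binom.sf(k - 1, n, p0) <= alpha:
            return k
    return n + 1


def select_action_units(
    dataset: StudyDataset,
    config: SelectionConfig | None = None,
    conditions: tuple[str, str] = ("guilt", "control"),
) -> list[str]:
    """Retained AU list, in ontology order.

    An AU is retained iff its producer count reaches the criterion in BOTH
    conditions, or it belongs to ``forced_include``.  The criterion is the
    explicit ``min_count`` override if given, else the exact-binomial
    critical count for each condition's own participant number.
    """
    config = config or SelectionConfig()
    crits = {}
    for cond in conditions:
        n = len(dataset.by_condition(cond))
        if n == 0:
            raise ValidationError(f"no participants in condition {cond!r}")
        crits[cond] = (
            config.min_count
            if config.min_count is not None
            else binomial_min_count(n, config.p0, config.alpha)
        )
    forced = set(config.forced_include)
    retained = []
    for au in dataset.ontology:
        if au in forced or all(
            participants_producing(dataset, au, cond) >= crits[cond]
            for cond in conditions
        ):
            retained.append(au)
    return retained
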