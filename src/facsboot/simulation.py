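"""Type-I-error and power experiments for the bootstrap contrast.

These helpers run the full generate -> contrast pipeline many times to
measure the procedure's operating characteristics: the fraction of
(dataset, AU) pairs declared significant when test and control individuals
come from one identical generative model (the attained level), and the
fraction of runs flagging a planted condition effect (power).

Null datasets use the control-condition video-duration model for both
groups, so the two groups are identically distributed; judge tables are not
generated (they play no role in the contrast).
"""

from __future__ import annotations

import numpy as np

from .bootstrap_contrast import BootstrapConfig, contrast_conditions
from .synthetic_data import GeneratorConfig, generate_study

__all__ = ["null_generator_config", "null_rejection_fraction", "flag_rates"]


def _seed_streams(seed: int, n: int, which: int) -> np.ndarray:
    """Deterministic sub-seeds below 2**31 for dataset / contrast RNGs."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(which,)))
    return rng.integers(0, 2**31 - 1, size=n)


def null_generator_config(
    rng: np.random.Generator,
    n_per_group: int = 60,
    n_aus: int = 15,
    sigma_individual: float = 0.3,
    bout_length: float = 10.0,
) -> GeneratorConfig:
    """A no-effect study config: both groups share one generative model.

    Baseline frame probabilities are drawn uniformly from [0.02, 0.4] per AU;
    the two place-of-origin strata keep the canonical 2:1 ratio.
    """
    aus = tuple(f"AU{i + 1}" for i in range(n_aus))
    base = {au: float(p) for au, p in zip(aus, rng.uniform(0.02, 0.4, n_aus))}
    return GeneratorConfig(
        n_guilt=n_per_group,
        n_control=n_per_group,
        durations={"guilt": (7.90, 4.27, 2.0), "control": (7.90, 4.27, 2.0)},
        au_base=base,
        condition_effects={},
        sigma_individual=sigma_individual,
        bout_length=bout_length,
        ontology=aus,
        with_judges=False,
    )


def _one_contrast(config: GeneratorConfig, data_seed: int, boot_seed: int,
                  B: int, alpha: float):
    ds = generate_study(config, int(data_seed))
    g, c = ds.by_condition("guilt"), ds.by_condition("control")
    return contrast_conditions(
        ds.frames_for(g), ds.frames_for(c), g, c, ds.ontology,
        BootstrapConfig(B=B, alpha=alpha, seed=int(boot_seed)),
    )


def null_rejection_fraction(
    seed: int,
    n_datasets: int = 300,
    B: int = 300,
    alpha: float = 0.01,
    n_per_group: int = 60,
    n_aus: int = 15,
) -> tuple[float, int]:
    """Fraction of (dataset, AU) pairs declared significant under the null.

    Simulates *n_datasets* independent studies in which test and control
    groups are drawn from one identical generative model (fresh baseline
    probabilities per dataset), runs the stratified bootstrap contrast on
    each, and pools the per-AU significance decisions.  Returns
    ``(fraction, n_trials)`` with ``n_trials = n_datasets * n_aus``.
    """
    data_seeds = _seed_streams(seed, n_datasets, which=0)
    boot_seeds = _seed_streams(seed, n_datasets, which=1)
    base_seeds = _seed_streams(seed, n_datasets, which=2)
    rejected = 0
    for d in range(n_datasets):
        cfg = null_generator_config(
            np.random.default_rng(int(base_seeds[d])), n_per_group, n_aus
        )
        table = _one_contrast(cfg, data_seeds[d], boot_seeds[d], B, alpha)
        rejected += int(table.significant.sum())
    n_trials = n_datasets * n_aus
    return rejected / n_trials, n_trials


def flag_rates(
    seed: int,
    n_runs: int = 100,
    effects: dict[str, float] | None = None,
    B: int = 1000,
    alpha: float = 0.01,
) -> dict[str, float]:
    """Per-AU flag rate (positive z and p <= alpha) over repeated studies.

    Uses the default study conditions (66 guilt / 65 control individuals,
    long guilt videos, short control videos) with the given condition
    effects; ``effects=None`` means no effect anywhere (null).  Returns
    ``{au: fraction of runs flagged}``; a *flag* requires positive z, so this
    measures elevated-in-test detections.
    """
    data_seeds = _seed_streams(seed, n_runs, which=3)
    boot_seeds = _seed_streams(seed, n_runs, which=4)
    cfg = GeneratorConfig(condition_effects=dict(effects or {}), with_judges=False)
    counts: dict[str, int] = {au: 0 for au in cfg.ontology}
    for r in range(n_runs):
        table = _one_contrast(cfg, data_seeds[r], boot_seeds[r], B, alpha)
        for row in table.itertuples(index=False):
            if row.significant and row.z > 0:
                counts[row.au] += 1
    return {au: c / n_runs for au, c in counts.items()}
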