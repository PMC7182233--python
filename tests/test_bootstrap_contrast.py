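"""Stratified resampling, the empirical p rule, and contrast correctness."""

import itertools

import numpy as np
import pandas as pd
import pytest

import facsboot as fb
from facsboot.bootstrap_contrast import (
    contrast_counts,
    largest_remainder_apportionment,
    participant_counts,
)
from facsboot.errors import ValidationError


class TestApportionment:
    def test_single_stratum(self):
        assert largest_remainder_apportionment({"A": 1.0}, 5) == {"A": 5}

    def test_two_to_one_ratio_is_exact(self):
        """A 10:5 test composition yields exactly 10 + 5 draws at m = 15."""
        assert largest_remainder_apportionment({"A": 2 / 3, "B": 1 / 3}, 15) == {
            "A": 10,
            "B": 5,
        }

    def test_largest_remainder_hand_case(self):
        # quotas 3.5 / 2.1 / 1.4 -> floors 3/2/1, last seat to A (.5 remainder)
        assert largest_remainder_apportionment({"A": 0.5, "B": 0.3, "C": 0.2}, 7) == {
            "A": 4,
            "B": 2,
            "C": 1,
        }

    def test_counts_sum_to_m(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = rng.integers(1, 5)
            ratios = {f"s{i}": float(w) for i, w in enumerate(rng.random(k) + 0.01)}
            m = int(rng.integers(0, 40))
            counts = largest_remainder_apportionment(ratios, m)
            assert sum(counts.values()) == m
            assert all(v >= 0 for v in counts.values())


class TestStratifiedResample:
    def test_single_stratum_draws_m(self):
        rng = np.random.default_rng(1)
        ids = fb.stratified_resample_ids(
            {f"p{i}": "A" for i in range(4)}, {"A": 1.0}, 5, rng
        )
        assert len(ids) == 5
        assert set(ids) <= {f"p{i}" for i in range(4)}

    def test_composition_matches_apportionment(self):
        rng = np.random.default_rng(2)
        strata = {f"a{i}": "A" for i in range(3)} | {f"b{i}": "B" for i in range(2)}
        ids = fb.stratified_resample_ids(strata, {"A": 2 / 3, "B": 1 / 3}, 15, rng)
        drawn = pd.Series([strata[i] for i in ids]).value_counts()
        assert drawn["A"] == 10 and drawn["B"] == 5

    def test_missing_stratum_is_error(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValidationError, match="absent from control"):
            fb.stratified_resample_ids({"p0": "A"}, {"A": 0.5, "B": 0.5}, 4, rng)


def _one_au_frames(freqs_and_lengths, aus=("AU4",)):
    """Participants with exact AU4 counts: {pid: (n_active, n_frames)}."""
    out = {}
    for pid, (k, n) in freqs_and_lengths.items():
        ind = np.zeros((n, len(aus)), np.uint8)
        ind[:k, 0] = 1
        out[pid] = fb.FrameMatrix(pid, ind, aus, np.ones(n, bool))
    return out


class TestEmpiricalPRule:
    def test_990_of_1000_below_gives_p_001_and_positive_z(self):
        """990 of 1000 bootstrap values below the observed frequency must
        yield exactly p = 0.01 with positive z."""
        boot = np.concatenate([np.full(990, 0.2), np.full(10, 0.9)])
        rng = np.random.default_rng(0)
        boot = rng.permutation(boot)
        obs = 0.5
        n_ge = int((boot >= obs).sum())
        n_le = int((boot <= obs).sum())
        p = min(n_ge, n_le) / boot.size
        assert n_le == 990 and p == 0.01
        # same rule through the public engine: craft a control set whose
        # resampled frequencies land on both sides of the observed value
        z = (obs - boot.mean()) / boot.std(ddof=1)
        assert z > 0

    def test_ties_count_as_extreme(self):
        frames_t = _one_au_frames({"t1": (5, 10)})
        frames_c = _one_au_frames({"c1": (5, 10)})
        table = fb.contrast_conditions(
            frames_t, frames_c, {"t1": "A"}, {"c1": "A"}, ("AU4",),
            fb.BootstrapConfig(B=50, seed=0),
        )
        # every bootstrap replicate equals the observed 0.5: both tail counts
        # are B, so p = 1 and z = 0
        row = table.iloc[0]
        assert row.p == 1.0
        assert row.z == 0.0

    def test_degenerate_sd_gives_signed_infinity(self):
        frames_t = _one_au_frames({"t1": (8, 10)})
        frames_c = _one_au_frames({"c1": (2, 10)})
        table = fb.contrast_conditions(
            frames_t, frames_c, {"t1": "A"}, {"c1": "A"}, ("AU4",),
            fb.BootstrapConfig(B=20, seed=0),
        )
        row = table.iloc[0]
        assert np.isinf(row.z) and row.z > 0
        assert row.p == 0.0

    def test_two_sided_double_doubles_p(self):
        rng_frames = {
            f"c{i}": (i + 1, 10) for i in range(6)
        }
        frames_c = _one_au_frames(rng_frames)
        frames_t = _one_au_frames({"t1": (4, 10)})
        meta_c = {pid: "A" for pid in frames_c}
        t1 = fb.contrast_conditions(
            frames_t, frames_c, {"t1": "A"}, meta_c, ("AU4",),
            fb.BootstrapConfig(B=200, seed=9),
        )
        t2 = fb.contrast_conditions(
            frames_t, frames_c, {"t1": "A"}, meta_c, ("AU4",),
            fb.BootstrapConfig(B=200, seed=9, two_sided_double=True),
        )
        assert t2.iloc[0].p == pytest.approx(min(1.0, 2 * t1.iloc[0].p))


class TestContrastConditions:
    def test_null_self_comparison_rarely_significant(self, small_study):
        """Testing a group against itself should flag (almost) nothing."""
        g = small_study.by_condition("guilt")
        frames = small_study.frames_for(g)
        table = fb.contrast_conditions(
            frames, frames, g, g, small_study.ontology,
            fb.BootstrapConfig(B=500, seed=11),
        )
        assert (table.z.abs() < 3).all()
        assert (table.p > 0.01).all()

    def test_exhaustive_enumeration_oracle_three_participants(self):
        """Monte-Carlo expected frequency matches the exact mean over all
        27 ordered with-replacement resamples of 3 control individuals."""
        spec = {"c1": (2, 10), "c2": (5, 20), "c3": (9, 30)}
        frames_c = _one_au_frames(spec)
        frames_t = _one_au_frames({"t1": (3, 12)})
        counts = {pid: kn for pid, kn in spec.items()}
        exact = np.mean([
            sum(counts[p][0] for p in pick) / sum(counts[p][1] for p in pick)
            for pick in itertools.product(spec, repeat=3)
        ])
        table = fb.contrast_conditions(
            frames_t, frames_c, {"t1": "A"}, {p: "A" for p in spec}, ("AU4",),
            fb.BootstrapConfig(B=20000, seed=4),
        )
        assert table.iloc[0].expected_freq == pytest.approx(exact, abs=0.005)

    def test_observed_is_exact_pooled_frequency(self, tiny_dataset):
        g = tiny_dataset.by_condition("guilt")
        c = tiny_dataset.by_condition("control")
        table = fb.contrast_conditions(
            tiny_dataset.frames_for(g), tiny_dataset.frames_for(c),
            g, c, tiny_dataset.ontology, fb.BootstrapConfig(B=10, seed=0),
        )
        expected = fb.pooled_frequency(
            list(tiny_dataset.frames_for(g).values()), "AU4"
        )
        assert table.set_index("au").loc["AU4", "observed_freq"] == pytest.approx(
            expected
        )

    def test_expected_within_bootstrap_envelope(self, tiny_dataset):
        g = tiny_dataset.by_condition("guilt")
        c = tiny_dataset.by_condition("control")
        table = fb.contrast_conditions(
            tiny_dataset.frames_for(g), tiny_dataset.frames_for(c),
            g, c, tiny_dataset.ontology, fb.BootstrapConfig(B=200, seed=1),
        )
        assert table.expected_freq.between(0, 1).all()
        assert table.observed_freq.between(0, 1).all()
        assert ((table.p >= 0) & (table.p <= 1)).all()
        assert (table.significant == (table.p <= 0.01)).all()

    def test_input_order_does_not_change_rows(self, tiny_dataset):
        """Supplying participants/frames in a different order must not change
        any contrast row (draws index into sorted ids)."""
        g = tiny_dataset.by_condition("guilt")
        c = tiny_dataset.by_condition("control")
        fg, fc = tiny_dataset.frames_for(g), tiny_dataset.frames_for(c)
        cfg = fb.BootstrapConfig(B=100, seed=7)
        t1 = fb.contrast_conditions(fg, fc, g, c, tiny_dataset.ontology, cfg)
        fg2 = dict(reversed(list(fg.items())))
        fc2 = dict(reversed(list(fc.items())))
        t2 = fb.contrast_conditions(
            fg2, fc2, list(reversed(g)), list(reversed(c)),
            tiny_dataset.ontology, fb.BootstrapConfig(B=100, seed=7),
        )
        pd.testing.assert_frame_equal(t1, t2)

    def test_seed_reproducibility(self, tiny_dataset):
        g = tiny_dataset.by_condition("guilt")
        c = tiny_dataset.by_condition("control")
        args = (
            tiny_dataset.frames_for(g), tiny_dataset.frames_for(c),
            g, c, tiny_dataset.ontology,
        )
        t1 = fb.contrast_conditions(*args, fb.BootstrapConfig(B=50, seed=3))
        t2 = fb.contrast_conditions(*args, fb.BootstrapConfig(B=50, seed=3))
        pd.testing.assert_frame_equal(t1, t2)

    def test_zero_visible_participant_rejected(self):
        ind = np.zeros((5, 1), np.uint8)
        fm = fb.FrameMatrix("c1", ind, ("AU4",), np.zeros(5, bool))
        with pytest.raises(ValidationError, match="no visible frames"):
            participant_counts({"c1": fm}, ("AU4",))


class TestSplitByGuiltChange:
    def test_all_positive_changes_leave_weak_empty(self):
        recs = [
            fb.ParticipantRecord(f"g{i}", "guilt", "European",
                                 {"guilt": 1}, {"guilt": 3})
            for i in range(3)
        ]
        ds = fb.StudyDataset(recs, {}, ("AU4",))
        weak, strong = fb.split_by_guilt_change(ds)
        assert weak == [] and len(strong) == 3

    def test_boundary_at_zero_is_weak(self):
        changes = [(-1, "weak"), (0, "weak"), (2, "strong")]
        recs = [
            fb.ParticipantRecord(f"g{i}", "guilt", "European",
                                 {"guilt": 2}, {"guilt": 2 + d})
            for i, (d, _) in enumerate(changes)
        ]
        ds = fb.StudyDataset(recs, {}, ("AU4",))
        weak, strong = fb.split_by_guilt_change(ds)
        assert [p.participant_id for p in weak] == ["g0", "g1"]
        assert [p.participant_id for p in strong] == ["g2"]

    def test_partition_matches_comprehension_oracle(self, small_study):
        weak, strong = fb.split_by_guilt_change(small_study)
        guilt = small_study.by_condition("guilt")
        assert {p.participant_id for p in weak} == {
            p.participant_id for p in guilt if p.guilt_change <= 0
        }
        assert len(weak) + len(strong) == len(guilt)

    def test_missing_item_excluded_with_warning(self):
        recs = [
            fb.ParticipantRecord("g0", "guilt", "European", {}, {}),
            fb.ParticipantRecord("g1", "guilt", "European",
                                 {"guilt": 1}, {"guilt": 4}),
        ]
        ds = fb.StudyDataset(recs, {}, ("AU4",))
        with pytest.warns(UserWarning, match="missing PANAS"):
            weak, strong = fb.split_by_guilt_change(ds)
        assert [p.participant_id for p in strong] == ["g1"]
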