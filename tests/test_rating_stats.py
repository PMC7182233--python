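"""Affect checks, standardization, regressions and the judged-guilt model."""

import numpy as np
import pandas as pd
import pytest

import facsboot as fb
from facsboot.errors import EmptyInputError, ValidationError
from facsboot.rating_stats import _paired_t


def _recs(before_after, condition="guilt"):
    return [
        fb.ParticipantRecord(
            f"p{i}", condition, "European", {"guilt": b}, {"guilt": a}
        )
        for i, (b, a) in enumerate(before_after)
    ]


class TestPairedT:
    def test_no_change_gives_t0_p1(self):
        x = np.array([1.0, 2.0, 3.0])
        t, df, p = _paired_t(x, x)
        assert t == 0.0 and p == 1.0 and df == 2

    def test_hand_computed_example(self):
        """Pairs (1,2),(1,3),(2,4): diffs -1,-2,-2, mean -5/3, sd 0.577."""
        b = np.array([1.0, 1.0, 2.0])
        a = np.array([2.0, 3.0, 4.0])
        t, df, p = _paired_t(b, a)
        d = b - a
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert t == pytest.approx(expected_t)
        assert t == pytest.approx(-5.0, abs=1e-9)
        assert df == 2

    def test_constant_nonzero_shift_reports_floor_not_nan(self):
        b = np.array([1.0, 2.0, 3.0])
        t, df, p = _paired_t(b, b + 1.0)
        assert np.isinf(t) and t < 0
        assert p == 0.0

    def test_fewer_than_two_pairs_is_error(self):
        with pytest.raises(EmptyInputError):
            _paired_t(np.array([1.0]), np.array([2.0]))


class TestPairedAffectTests:
    def test_within_and_between_tables(self):
        guilt = _recs([(1, 3), (1, 4), (2, 4), (1, 2)], "guilt")
        control = _recs([(1, 1), (2, 1), (1, 2), (1, 1)], "control")
        out = fb.paired_affect_tests(guilt + control, items=("guilt",))
        within = out["within"].set_index("condition")
        assert within.loc["guilt", "mean_after"] > within.loc["guilt", "mean_before"]
        assert within.loc["guilt", "p"] < 0.05
        between = out["between"].iloc[0]
        assert between["diff"] < 0  # control reports less guilt after induction

    def test_synthetic_defaults_show_guilt_induction(self, small_study):
        """The generator's affect model reproduces a significant increase in
        self-reported guilt in the guilt condition."""
        out = fb.paired_affect_tests(small_study.participants, items=("guilt",))
        row = out["within"].set_index("condition").loc["guilt"]
        assert row["t"] < 0 and row["p"] < 0.05
        assert row["mean_after"] - row["mean_before"] > 0.5


class TestZStandardize:
    def test_basic_and_idempotent(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        z = fb.zstandardize(df, ["x"])
        assert list(z["x"]) == pytest.approx([-1.0, 0.0, 1.0])
        z2 = fb.zstandardize(z, ["x"])
        assert np.allclose(z2["x"], z["x"])

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x": rng.normal(5, 2, 40)})
        z = fb.zstandardize(df, ["x"])["x"]
        oracle = (df["x"] - df["x"].mean()) / df["x"].std(ddof=1)
        assert np.allclose(z, oracle)

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({"flat": [2.0, 2.0, 2.0]})
        with pytest.raises(ValidationError, match="flat"):
            fb.zstandardize(df, ["flat"])


def _feature_frame(rng, n=69, beta4=0.0, noise=1.0):
    df = pd.DataFrame({
        "video_id": [f"v{i}" for i in range(n)],
        "ratio_AU4": rng.uniform(0, 1, n),
        "ratio_AU10": rng.uniform(0, 1, n),
        "ratio_AU20": rng.uniform(0, 1, n),
        "ratio_NeckTouch": rng.uniform(0, 1, n),
        "condition": rng.choice(["guilt", "control"], n),
        "poo": rng.choice(["European", "EastAsian"], n),
        "guilt_change": rng.normal(1, 1, n),
    })
    df["n_of_four"] = rng.integers(0, 5, n).astype(float)
    df["guilt_rating"] = beta4 * df["ratio_AU4"] + rng.normal(0, noise, n)
    return df


class TestJudgedGuiltModel:
    def test_pure_noise_rarely_rejects(self):
        rng = np.random.default_rng(0)
        rejections = 0
        for _ in range(20):
            rep = fb.judged_guilt_model(_feature_frame(rng))
            rejections += rep["full_vs_null"]["p"] < 0.05
        assert rejections <= 4

    def test_au4_signal_recovered(self):
        rng = np.random.default_rng(1)
        rep = fb.judged_guilt_model(_feature_frame(rng, beta4=5.0))
        assert rep["full_vs_null"]["p"] < 0.001
        assert rep["deletion_tests"]["ratio_AU4"]["p"] < 0.001
        assert rep["deletion_tests"]["ratio_AU20"]["p"] > 0.001

    def test_orthogonal_design_has_unit_vifs(self):
        """A 2^3 full-factorial (orthogonal) design gives VIF = 1 exactly."""
        rows = []
        for a in (-1.0, 1.0):
            for b in (-1.0, 1.0):
                for c in (-1.0, 1.0):
                    for rep in range(2):
                        rows.append((a, b, c))
        df = pd.DataFrame(rows, columns=["x1", "x2", "x3"])
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        X = df.assign(Intercept=1.0)[["Intercept", "x1", "x2", "x3"]].to_numpy()
        vifs = [variance_inflation_factor(X, j) for j in (1, 2, 3)]
        assert vifs == pytest.approx([1.0, 1.0, 1.0])

    def test_report_invariants(self):
        rng = np.random.default_rng(2)
        rep = fb.judged_guilt_model(_feature_frame(rng, beta4=2.0))
        assert rep["full_vs_null"]["chi2"] >= 0
        assert all(d["chi2"] >= 0 for d in rep["deletion_tests"].values())
        assert rep["max_vif"] >= 1.0
        assert rep["full_vs_null"]["df"] == 5

    def test_standardization_leaves_pvalues_invariant(self):
        rng = np.random.default_rng(4)
        df = _feature_frame(rng, beta4=3.0)
        raw = fb.judged_guilt_model(df, standardize=False)
        std = fb.judged_guilt_model(df, standardize=True)
        assert raw["full_vs_null"]["p"] == pytest.approx(std["full_vs_null"]["p"])
        for term in raw["deletion_tests"]:
            assert raw["deletion_tests"][term]["p"] == pytest.approx(
                std["deletion_tests"][term]["p"]
            )

    def test_aliased_terms_reported(self):
        rng = np.random.default_rng(5)
        df = _feature_frame(rng)
        df["ratio_AU10"] = df["ratio_AU4"] * 2.0  # perfect collinearity
        with pytest.raises(ValidationError, match="aliased"):
            fb.judged_guilt_model(df)

    def test_too_few_rows(self):
        rng = np.random.default_rng(6)
        with pytest.raises(EmptyInputError):
            fb.judged_guilt_model(_feature_frame(rng, n=5))


class TestAuSelfreportRegression:
    def _dataset(self, slope=0.0, n=30, seed=0):
        rng = np.random.default_rng(seed)
        recs, codings = [], {}
        for i in range(n):
            pid = f"g{i}"
            score = float(rng.integers(1, 6))
            prop = np.clip(slope * score + rng.normal(0.2, 0.05), 0.01, 0.95)
            nf = 100
            ind = np.zeros((nf, 1), np.uint8)
            ind[: int(round(prop * nf)), 0] = 1
            codings[pid] = fb.FrameMatrix(pid, ind, ("AU4",), np.ones(nf, bool))
            recs.append(fb.ParticipantRecord(
                pid, "guilt", "European", {"shame": 1}, {"shame": score}
            ))
        return fb.StudyDataset(recs, codings, ("AU4",))

    def test_injected_slope_recovered_within_2se(self):
        ds = self._dataset(slope=0.05, seed=1)
        out = fb.au_selfreport_regression(ds, "AU4", "shame")
        assert abs(out["slope"] - 0.05) < 2 * out["se"] + 0.01

    def test_four_point_hand_example_matches_normal_equations(self):
        recs, codings = [], {}
        scores = [1, 2, 3, 4]
        props = [0.1, 0.3, 0.2, 0.4]
        for i, (s, pr) in enumerate(zip(scores, props)):
            pid = f"g{i}"
            ind = np.zeros((10, 1), np.uint8)
            ind[: int(pr * 10), 0] = 1
            codings[pid] = fb.FrameMatrix(pid, ind, ("AU4",), np.ones(10, bool))
            recs.append(fb.ParticipantRecord(
                pid, "guilt", "European", {}, {"shame": s}
            ))
        ds = fb.StudyDataset(recs, codings, ("AU4",))
        out = fb.au_selfreport_regression(ds, "AU4", "shame")
        x = np.array(scores, float)
        y = np.array(props)
        beta = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert out["slope"] == pytest.approx(beta)

    def test_constant_predictor_rejected(self):
        ds = self._dataset(seed=2)
        for p in ds.participants:
            p.panas_after["shame"] = 3
        with pytest.raises(ValidationError):
            fb.au_selfreport_regression(ds, "AU4", "shame")


class TestSelfreportJudgementCorrelation:
    def _participants(self, guilts):
        return [
            fb.ParticipantRecord(f"v{i}", "guilt", "European", {}, {"guilt": g})
            for i, g in enumerate(guilts)
        ]

    def test_perfectly_ordered_gives_r1(self):
        parts = self._participants([1, 2, 3, 4])
        ratings = {f"v{i}": 10.0 * (i + 1) for i in range(4)}
        out = fb.selfreport_judgement_correlation(parts, ratings)
        assert out["r"] == pytest.approx(1.0)

    def test_anti_ordered_gives_minus1(self):
        parts = self._participants([1, 2, 3, 4])
        ratings = {f"v{i}": 50.0 - 10.0 * i for i in range(4)}
        out = fb.selfreport_judgement_correlation(parts, ratings)
        assert out["r"] == pytest.approx(-1.0)

    def test_five_pair_hand_example(self):
        guilts = [1, 3, 2, 5, 4]
        judged = [12.0, 30.0, 15.0, 45.0, 33.0]
        parts = self._participants(guilts)
        ratings = {f"v{i}": judged[i] for i in range(5)}
        out = fb.selfreport_judgement_correlation(parts, ratings)
        x, y = np.array(guilts, float), np.array(judged)
        r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert out["r"] == pytest.approx(r)
        assert out["n"] == 5

    def test_unmatched_ids_is_error(self):
        parts = self._participants([1, 2, 3])
        with pytest.raises(ValidationError):
            fb.selfreport_judgement_correlation(parts, {"vX": 10.0})
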