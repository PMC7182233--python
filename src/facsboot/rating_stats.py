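"""Parametric stages: affect manipulation checks, AU/self-report regressions,
the self-report/judgement correlation, and the judged-guilt linear model.

The judged-guilt model is ordinary least squares with Gaussian likelihood:
the response (per-video mean judged guilt, averaged across judges) has one
row per video, so there is no grouping structure and no random effects.
Model comparison follows single-term-deletion semantics: the full model
(four AU frame ratios + how many of the four AUs appear + condition + place
of origin + self-reported guilt change) is compared to a null model holding
only the three covariates via a likelihood-ratio chi-square, and each
predictor's significance is a likelihood-ratio test against the model
without that term.  Collinearity is summarised by variance inflation
factors.  Continuous variables are z-standardized before fitting; this
rescales coefficients but leaves every test invariant.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .errors import EmptyInputError, ValidationError
from .facs_io import ParticipantRecord, StudyDataset

__all__ = [
    "paired_affect_tests",
    "zstandardize",
    "build_video_features",
    "judged_guilt_model",
    "au_selfreport_regression",
    "selfreport_judgement_correlation",
]

FEATURE_AUS = ("AU4", "AU10", "AU20", "NeckTouch")

DEFAULT_AFFECT_ITEMS = (
    "positive", "negative", "guilt", "shame", "distress", "pride", "nervousness",
)


def _paired_t(before: np.ndarray, after: np.ndarray):
    """Two-sided paired t on (before, after); exact-difference shortcut."""
    diff = before - after
    n = diff.size
    if n < 2:
        raise EmptyInputError("paired t-test needs >= 2 complete pairs")
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return 0.0, float(n - 1), 1.0
        # identical nonzero shift in every pair: |t| unbounded
        return float(np.sign(diff.mean())) * np.inf, float(n - 1), 0.0
    res = stats.ttest_rel(before, after)
    return float(res.statistic), float(n - 1), float(res.pvalue)


def paired_affect_tests(
    participants: Sequence[ParticipantRecord],
    items: Sequence[str] = DEFAULT_AFFECT_ITEMS,
) -> dict[str, pd.DataFrame]:
    """Affect manipulation checks from the PANAS tables.

    Returns ``{"within": ..., "between": ...}``.  *within*: per condition and
    item, a two-sided paired t-test of before vs after scores (negative t =
    increase, matching the reporting convention of within-subject affect
    checks).  *between*: Welch two-sample t-tests of post-induction scores,
    guilt vs control condition.
    """
    conditions = sorted({p.condition for p in participants})
    within_rows = []
    for cond in conditions:
        members = [p for p in participants if p.condition == cond]
        for item in items:
            pairs = [
                (p.panas_before[item], p.panas_after[item])
                for p in members
                if item in p.panas_before and item in p.panas_after
            ]
            if len(pairs) < 2:
                raise EmptyInputError(
                    f"{cond}/{item}: need >= 2 complete pairs, got {len(pairs)}"
                )
            b, a = map(np.asarray, zip(*pairs))
            t, df, p = _paired_t(b.astype(float), a.astype(float))
            within_rows.append(
                {
                    "condition": cond, "item": item, "n": len(pairs),
                    "mean_before": b.mean(), "mean_after": a.mean(),
                    "t": t, "df": df, "p": p,
                }
            )
    between_rows = []
    if {"guilt", "control"} <= set(conditions):
        for item in items:
            g = np.array([
                p.panas_after[item] for p in participants
                if p.condition == "guilt" and item in p.panas_after
            ], dtype=float)
            c = np.array([
                p.panas_after[item] for p in participants
                if p.condition == "control" and item in p.panas_after
            ], dtype=float)
            if len(g) >= 2 and len(c) >= 2:
                res = stats.ttest_ind(c, g, equal_var=False)
                between_rows.append(
                    {
                        "item": item, "mean_control": c.mean(), "mean_guilt": g.mean(),
                        "diff": c.mean() - g.mean(), "t": float(res.statistic),
                        "df": float(res.df), "p": float(res.pvalue),
                    }
                )
    return {
        "within": pd.DataFrame(within_rows),
        "between": pd.DataFrame(between_rows),
    }


def zstandardize(df: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Return a copy with the named columns scaled to mean 0, sample sd 1."""
    out = df.copy()
    for col in columns:
        x = out[col].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValidationError(f"column {col!r} is constant; cannot standardize")
        out[col] = (x - x.mean()) / sd
    return out


def build_video_features(
    dataset: StudyDataset, ratings: pd.DataFrame | None = None
) -> pd.DataFrame:
    """One row per video: AU frame ratios, covariates, mean judged guilt.

    Ratios are proportions of *visible* frames containing AU4, AU10, AU20 and
    NeckTouch; ``n_of_four`` counts how many of the four appear at all.
    """
    ratings = ratings if ratings is not None else dataset.ratings
    mean_guilt = None
    if ratings is not None:
        g = ratings.dropna(subset=["rating"])
        mean_guilt = (
            g[g["emotion"] == "guilty"].groupby("video_id")["rating"].mean()
        )
    rows = []
    for p in dataset.participants:
        fm = dataset.codings.get(p.participant_id)
        if fm is None:
            continue
        vis = fm.visible
        denom = int(vis.sum())
        if denom == 0:
            continue
        ratios = {
            f"ratio_{au}": float(fm.indicators[vis, fm.aus.index(au)].sum()) / denom
            for au in FEATURE_AUS
        }
        row = {
            "video_id": p.participant_id,
            "guilt_rating": (
                float(mean_guilt.get(p.participant_id, np.nan))
                if mean_guilt is not None else np.nan
            ),
            **ratios,
            "n_of_four": sum(v > 0 for v in ratios.values()),
            "condition": p.condition,
            "poo": p.poo_stratum,
            "guilt_change": p.guilt_change,
        }
        rows.append(row)
    return pd.DataFrame(rows)


TEST_PREDICTORS = (
    "ratio_AU4", "ratio_AU10", "ratio_AU20", "ratio_NeckTouch", "n_of_four",
)
NULL_PREDICTORS = ("condition", "poo", "guilt_change")


def _design(df: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    for term in terms:
        col = df[term]
        if col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col, prefix=term, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        else:
            X[term] = col.astype(float)
    X.insert(0, "Intercept", 1.0)
    return X


def _fit(y: pd.Series, X: pd.DataFrame):
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the terms whose removal restores full rank
        aliased = []
        for col in X.columns[1:]:
            if np.linalg.matrix_rank(X.drop(columns=[col]).to_numpy()) == rank:
                aliased.append(col)
        raise ValidationError(f"rank-deficient design; aliased terms: {aliased}")
    return sm.OLS(y.astype(float), X).fit()


def judged_guilt_model(features: pd.DataFrame, standardize: bool = True) -> dict:
    """Fit the judged-guilt OLS model and its deletion tests.

    Returns a report dict with the full-vs-null likelihood-ratio chi-square,
    per-predictor single-term-deletion LRTs, the coefficient table and the
    maximum variance inflation factor.
    """
    df = features.dropna(subset=["guilt_rating", "guilt_change"]).copy()
    if len(df) < 10:
        raise EmptyInputError(f"need >= 10 rows, got {len(df)}")
    continuous = [*TEST_PREDICTORS, "guilt_change"]
    if standardize:
        df = zstandardize(df, continuous)
    y = df["guilt_rating"]
    full_terms = [*TEST_PREDICTORS, *NULL_PREDICTORS]
    X_full = _design(df, full_terms)
    fit_full = _fit(y, X_full)
    fit_null = _fit(y, _design(df, list(NULL_PREDICTORS)))

    def lrt(fit_big, fit_small):
        chi2 = max(0.0, 2.0 * (fit_big.llf - fit_small.llf))
        ddf = int(fit_big.df_model - fit_small.df_model)
        return chi2, ddf, float(stats.chi2.sf(chi2, ddf)) if ddf else np.nan

    chi2, ddf, p = lrt(fit_full, fit_null)
    deletions = {}
    for term in full_terms:
        reduced = _fit(y, _design(df, [t for t in full_terms if t != term]))
        c, d, pp = lrt(fit_full, reduced)
        deletions[term] = {"chi2": c, "df": d, "p": pp}

    exog = X_full.to_numpy()
    vifs = {
        col: float(variance_inflation_factor(exog, j))
        for j, col in enumerate(X_full.columns)
        if col != "Intercept"
    }
    return {
        "n": int(len(df)),
        "coefficients": {
            name: {"estimate": float(est), "se": float(se), "p": float(pv)}
            for name, est, se, pv in zip(
                X_full.columns, fit_full.params, fit_full.bse, fit_full.pvalues
            )
        },
        "full_vs_null": {"chi2": chi2, "df": ddf, "p": p},
        "deletion_tests": deletions,
        "vif": vifs,
        "max_vif": max(vifs.values()),
        "loglik_full": float(fit_full.llf),
        "loglik_null": float(fit_null.llf),
    }


def au_selfreport_regression(
    dataset: StudyDataset, au: str, item: str, condition: str = "guilt"
) -> dict:
    """Simple OLS of per-participant AU frame proportion on a post-induction
    PANAS item score (slope on the proportion-per-scale-unit scale)."""
    xs, ys = [], []
    for p in dataset.by_condition(condition):
        if item not in p.panas_after or p.participant_id not in dataset.codings:
            continue
        fm = dataset.codings[p.participant_id]
        vis = fm.visible
        if not vis.any():
            continue
        ys.append(float(fm.indicators[vis, fm.aus.index(au)].sum()) / int(vis.sum()))
        xs.append(float(p.panas_after[item]))
    x = np.asarray(xs)
    y = np.asarray(ys)
    if x.size < 3:
        raise EmptyInputError(f"need >= 3 participants with {item!r} scores")
    if np.allclose(x.std(), 0):
        raise ValidationError(f"predictor {item!r} is constant")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return {
        "au": au, "item": item, "n": int(x.size),
        "slope": float(fit.params[1]), "se": float(fit.bse[1]),
        "p": float(fit.pvalues[1]),
    }


def selfreport_judgement_correlation(
    participants: Sequence[ParticipantRecord],
    video_ratings: Mapping[str, float],
) -> dict:
    """Pearson correlation of self-reported guilt with mean judged guilt.

    *video_ratings* maps video/participant id -> mean judged guilt.  Every
    rated video must have a matching participant with a post-induction guilt
    item; n >= 3 required.
    """
    by_id = {p.participant_id: p for p in participants}
    missing = [v for v in video_ratings if v not in by_id]
    if missing:
        raise ValidationError(f"ratings without matching participants: {sorted(missing)}")
    pairs = [
        (by_id[v].panas_after["guilt"], r)
        for v, r in sorted(video_ratings.items())
        if "guilt" in by_id[v].panas_after
    ]
    if len(pairs) < 3:
        raise EmptyInputError(f"need >= 3 matched pairs, got {len(pairs)}")
    x, y = map(np.asarray, zip(*pairs))
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "n": len(pairs), "p": float(p)}
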