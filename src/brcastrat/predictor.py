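"""Combined BRCA-state + M1-macrophage chemoresponse predictor and its
evaluation statistics.

The decision tree: tumors with a pathogenic BRCA1/2 mutation are predicted
responders; BRCA1-promoter-methylated tumors are predicted non-responders
(their deficiency state is epigenetically plastic and reverts under
genotoxin exposure); nonBRCA tumors are split on their M1-macrophage
deconvolution score at the median of the nonBRCA subset — M1-high predicts
response, M1-low non-response. A nonBRCA tumor with no M1 score is
explicitly "unpredictable", never silently defaulted.

Evaluation utilities cover responder/non-responder outcome fractions,
accuracy, Fisher exact tests, logistic (logit-link) association, Cox
proportional-hazards comparison and rank-sum comparison of 22 immune cell
scores with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .brca_state import BRCA1_METH, BRCA_MUT, NON_BRCA

LM22_CELL_TYPES = (
    "B cells naive", "B cells memory", "Plasma cells",
    "T cells CD8", "T cells CD4 naive", "T cells CD4 memory resting",
    "T cells CD4 memory activated", "T cells follicular helper",
    "T cells regulatory (Tregs)", "T cells gamma delta",
    "NK cells resting", "NK cells activated",
    "Monocytes", "Macrophages M0", "Macrophages M1", "Macrophages M2",
    "Dendritic cells resting", "Dendritic cells activated",
    "Mast cells resting", "Mast cells activated",
    "Eosinophils", "Neutrophils",
)

RESPONDER = "responder"
NON_RESPONDER = "non-responder"
UNPREDICTABLE = "unpredictable"


@dataclass
class Prediction:
    sample_id: str
    predicted: str  # responder | non-responder | unpredictable
    branch: str  # brca_mut | brca1_meth | nonbrca_m1_high | nonbrca_m1_low | nonbrca_m1_missing


@dataclass
class StatResult:
    estimate: float
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    test: str


def m1_median_split(
    m1_scores: pd.Series, states: pd.Series, nonbrca_label: str = NON_BRCA
) -> tuple[pd.Series, float]:
    """Label samples M1 high/low at the median of the nonBRCA subset.

    The median is computed over nonBRCA samples only (midpoint convention for
    even n); every scored sample is "high" iff its score is strictly above
    that median. Returns (labels, median).
    """
    nonbrca_scores = m1_scores[states == nonbrca_label].dropna()
    if nonbrca_scores.empty:
        raise ValueError("no nonBRCA samples with an M1 score")
    median = float(np.median(nonbrca_scores))
    labels = m1_scores.map(
        lambda s: np.nan if pd.isna(s) else ("high" if s > median else "low")
    )
    return labels, median


def predict_response(state: str, m1_level: str | None, sample_id: str = "sample") -> Prediction:
    """Apply the decision tree to one sample."""
    if state == BRCA_MUT:
        return Prediction(sample_id, RESPONDER, "brca_mut")
    if state == BRCA1_METH:
        return Prediction(sample_id, NON_RESPONDER, "brca1_meth")
    if state == NON_BRCA:
        if m1_level == "high":
            return Prediction(sample_id, RESPONDER, "nonbrca_m1_high")
        if m1_level == "low":
            return Prediction(sample_id, NON_RESPONDER, "nonbrca_m1_low")
        return Prediction(sample_id, UNPREDICTABLE, "nonbrca_m1_missing")
    raise ValueError(f"unknown BRCA state {state!r}")


class ResponseTreeClassifier(ClassifierMixin, BaseEstimator):
    """The combined BRCA-state + M1 decision tree as an sklearn estimator.

    fit() learns the single data-dependent quantity — the M1 median of the
    nonBRCA subset — and predict() applies the tree.
    """

    def __init__(self, nonbrca_label: str = NON_BRCA):
        self.nonbrca_label = nonbrca_label

    def fit(self, X: pd.DataFrame, y=None):
        """``X``: columns sample_id, state, m1_score."""
        _, median = m1_median_split(
            X["m1_score"], X["state"], nonbrca_label=self.nonbrca_label
        )
        self.m1_median_ = median
        self.classes_ = np.array([NON_RESPONDER, RESPONDER, UNPREDICTABLE])
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "m1_median_")
        return np.array([p.predicted for p in self.predict_detailed(X)])

    def predict_detailed(self, X: pd.DataFrame) -> list[Prediction]:
        check_is_fitted(self, "m1_median_")
        out = []
        for row in X.itertuples():
            score = getattr(row, "m1_score", None)
            if score is None or pd.isna(score):
                level = None
            else:
                level = "high" if score > self.m1_median_ else "low"
            out.append(predict_response(row.state, level, sample_id=str(row.sample_id)))
        return out


def evaluate_predictions(predictions: pd.Series, outcomes: pd.Series) -> dict:
    """Compare responder predictions against binary outcomes (e.g. pCR).

    Both series are indexed by sample; only samples with a definite
    prediction (responder / non-responder) and a non-missing outcome enter.
    Returns the outcome fraction in each predicted group (percent), overall
    accuracy (percent) and the 2x2 table
    [[resp∩outcome, resp∖outcome], [nonresp∩outcome, nonresp∖outcome]].
    """
    df = pd.DataFrame({"pred": predictions, "outcome": outcomes}).dropna()
    df = df[df["pred"].isin([RESPONDER, NON_RESPONDER])]
    if df.empty:
        raise ValueError("no samples with both a definite prediction and an outcome")
    df["outcome"] = df["outcome"].astype(bool)
    resp = df[df["pred"] == RESPONDER]
    nonresp = df[df["pred"] == NON_RESPONDER]
    table = np.array(
        [
            [int(resp["outcome"].sum()), int((~resp["outcome"]).sum())],
            [int(nonresp["outcome"].sum()), int((~nonresp["outcome"]).sum())],
        ]
    )
    correct = int(resp["outcome"].sum() + (~nonresp["outcome"]).sum())
    return {
        "responder_outcome_pct": 100.0 * resp["outcome"].mean() if len(resp) else float("nan"),
        "nonresponder_outcome_pct": 100.0 * nonresp["outcome"].mean() if len(nonresp) else float("nan"),
        "accuracy_pct": 100.0 * correct / len(df),
        "n": int(len(df)),
        "table": table,
    }


def outcome_fraction_pct(k: int, n: int) -> float:
    """Percent of samples in a predicted group achieving the outcome."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * k / n


def fisher_exact_2x2(table) -> StatResult:
    """Two-sided Fisher exact test on a 2x2 count table.

    The p-value sums the probabilities of all tables at least as extreme
    (probability <= observed) under the hypergeometric null. The reported
    odds ratio is the unconditional cross-product estimate.
    """
    table = np.asarray(table)
    if table.shape != (2, 2) or (table < 0).any() or not np.issubdtype(table.dtype, np.number):
        raise ValueError("need a 2x2 table of non-negative counts")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    a, b, c, d = table.ravel().astype(float)
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return StatResult(estimate=float(odds), ci_low=None, ci_high=None, p_value=float(p), test="fisher_exact")


def logistic_association(outcome, predictor) -> StatResult:
    """Logit-link binomial GLM of a binary outcome on one predictor.

    Returns the odds ratio exp(beta), its Wald 95% CI and two-sided Wald p.
    Complete separation is flagged by returning p_value=None.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome levels must be present")
    X = sm.add_constant(x)
    try:
        with np.errstate(all="ignore"):
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        beta = float(fit.params[1])
        se = float(fit.bse[1])
        if not np.isfinite(se) or se > 50:  # separation: SE blows up
            raise np.linalg.LinAlgError
        p = float(fit.pvalues[1])
        return StatResult(
            estimate=float(np.exp(beta)),
            ci_low=float(np.exp(beta - 1.96 * se)),
            ci_high=float(np.exp(beta + 1.96 * se)),
            p_value=p,
            test="logistic_wald",
        )
    except (np.linalg.LinAlgError, ValueError):
        return StatResult(
            estimate=float("nan"), ci_low=None, ci_high=None, p_value=None,
            test="logistic_wald (separation)",
        )


def table_to_binary(table) -> tuple[np.ndarray, np.ndarray]:
    """Expand a 2x2 [[x1y1, x1y0], [x0y1, x0y0]] table into per-subject
    predictor/outcome vectors (for GLM fits on printed contingency counts)."""
    table = np.asarray(table, dtype=int)
    x, y = [], []
    for xi, (k1, k0) in zip((1, 0), table):
        x += [xi] * (k1 + k0)
        y += [1] * k1 + [0] * k0
    return np.array(y), np.array(x)


def cox_ph(
    durations, events, covariate, strata=None, extra_covariates: pd.DataFrame | None = None
) -> StatResult:
    """Cox proportional-hazards fit; HR, 95% CI and p for ``covariate``.

    ``covariate`` may be binary group membership or continuous. Optional
    ``extra_covariates`` enter as adjustment terms.
    """
    from lifelines import CoxPHFitter

    df = pd.DataFrame({"T": np.asarray(durations, float), "E": np.asarray(events, bool)})
    df["x"] = np.asarray(covariate, float)
    if df["E"].sum() == 0:
        raise ValueError("no events observed")
    if extra_covariates is not None:
        for c in extra_covariates.columns:
            df[c] = np.asarray(extra_covariates[c], float)
    if strata is not None:
        df["_strata"] = np.asarray(strata)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="T", event_col="E", strata="_strata" if strata is not None else None)
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    return StatResult(
        estimate=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        p_value=float(cph.summary.loc["x", "p"]),
        test="cox_ph",
    )


def cibersort_group_comparison(
    profiles: pd.DataFrame, grouping: pd.Series, cell_types=LM22_CELL_TYPES
) -> pd.DataFrame:
    """Mann-Whitney rank-sum comparison of immune scores between two groups,
    Bonferroni-corrected over the panel of cell types.

    ``profiles``: samples x cell-type scores; ``grouping``: boolean per sample.
    """
    grouping = grouping.astype(bool)
    g1 = profiles.loc[grouping[grouping].index.intersection(profiles.index)]
    g0 = profiles.loc[grouping[~grouping].index.intersection(profiles.index)]
    if g1.empty or g0.empty:
        raise ValueError("both groups must be non-empty")
    n_tests = len([c for c in cell_types if c in profiles.columns])
    rows = []
    for ct in cell_types:
        if ct not in profiles.columns:
            continue
        a, b = g1[ct].dropna(), g0[ct].dropna()
        if a.nunique() <= 1 and b.nunique() <= 1 and set(a.unique()) == set(b.unique()):
            p = 1.0
        else:
            _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "cell_type": ct,
                "median_group1": float(a.median()),
                "median_group0": float(b.median()),
                "p_value": float(p),
                "p_adjusted": float(min(1.0, p * n_tests)),
            }
        )
    return pd.DataFrame(rows)


def deconvolve_scores(
    profile: pd.Series, signature_matrix: pd.DataFrame
) -> tuple[pd.Series, float]:
    """Non-negative least-squares immune deconvolution stand-in.

    Fits ``profile ≈ signature_matrix @ w`` with w >= 0 over the shared genes
    and returns weights normalised to fractions plus the relative residual
    (a high residual flags a low-confidence fit). This is a simple NNLS
    deconvolution, not the original support-vector-regression algorithm.
    """
    genes = profile.index.intersection(signature_matrix.index)
    if genes.empty:
        raise ValueError("no gene overlap between profile and signature matrix")
    A = signature_matrix.loc[genes].to_numpy(dtype=float)
    b = profile.loc[genes].to_numpy(dtype=float)
    w, rnorm = nnls(A, b)
    total = w.sum()
    fractions = w / total if total > 0 else w
    rel_residual = rnorm / np.linalg.norm(b) if np.linalg.norm(b) > 0 else float("inf")
    return pd.Series(fractions, index=signature_matrix.columns), float(rel_residual)
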