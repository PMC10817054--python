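"""Diagnostic-accuracy statistics for ordinal risk scores.

Everything needed to compare checklist scores against binary procedural
endpoints: empirical ROC curves, the Mann-Whitney (trapezoidal) AUC
with DeLong variance and paired DeLong tests, Youden-index optimal
cut-offs, Cohen's kappa for interobserver agreement, the Fisher exact
test, and two-sample location tests (Mann-Whitney U, pooled-variance
Student's t) for group-comparison tables.

The ROC machinery here is written directly from the nonparametric
definitions (placement values / structural components); SciPy is used
only for distribution functions.

Direction convention
--------------------
``direction="low"`` means low predictor values indicate the positive
class (a low complexity score predicts procedural success; cut-off
criteria render as ``<=k``).  ``direction="high"`` is the reverse
(``>k``), used when high scores predict the positive class, e.g. the
need for a non-antegrade-wiring strategy.  Orientation is explicit and
never auto-flipped: an AUC below 0.5 is reported as such.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCCurve",
    "AUCResult",
    "DeLongComparison",
    "CutoffResult",
    "roc_curve",
    "auc",
    "auc_value",
    "delong_paired_test",
    "youden_cutoff",
    "cohens_kappa",
    "fisher_exact_2x2",
    "mann_whitney_test",
    "students_t_test",
    "compare_groups",
    "accuracy_table",
    "delong_pairwise",
]

_Z975 = 1.959963984540054


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels).astype(bool)
    if y.ndim != 1:
        raise ValueError("labels must be one-dimensional")
    return y


def _split(values, labels, direction):
    if direction not in ("low", "high"):
        raise ValueError("direction must be 'low' or 'high'")
    x = np.asarray(values, dtype=float)
    y = _as_binary(labels)
    if x.shape != y.shape:
        raise ValueError("values and labels differ in length")
    if not np.all(np.isfinite(x)):
        raise ValueError("predictor values must be finite")
    pos, neg = x[y], x[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC curve over all achievable thresholds.

    ``thresholds[i]`` is the cut point of the i-th operating rule
    (``value <= t`` positive for direction 'low', ``value > t`` for
    'high'); a ``-inf`` sentinel supplies the degenerate endpoint.
    Points sweep from (sens 0, spec 1) to (sens 1, spec 0).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    direction: str
    n_pos: int
    n_neg: int


def roc_curve(values, labels, direction: str = "low") -> ROCCurve:
    """Empirical ROC curve of ``values`` against binary ``labels``."""
    pos, neg = _split(values, labels, direction)
    uniq = np.unique(np.concatenate([pos, neg]))
    if direction == "low":
        # rule: x <= t is positive; t = -inf gives (0, 1)
        thresholds = np.concatenate([[-np.inf], uniq])
        sens = np.searchsorted(np.sort(pos), thresholds, side="right") / len(pos)
        spec = 1.0 - np.searchsorted(np.sort(neg), thresholds, side="right") / len(neg)
    else:
        # rule: x > t is positive; t = -inf gives (1, 0)
        thresholds = np.concatenate([uniq[::-1], [-np.inf]])
        sens = 1.0 - np.searchsorted(np.sort(pos), thresholds, side="right") / len(pos)
        spec = np.searchsorted(np.sort(neg), thresholds, side="right") / len(neg)
    return ROCCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        direction=direction,
        n_pos=len(pos),
        n_neg=len(neg),
    )


def _placements(pos: np.ndarray, neg: np.ndarray, direction: str):
    """DeLong structural components (placement values).

    For direction 'high', ``v10[i]`` is the fraction of negatives below
    the i-th positive (ties count one half); ``v01[j]`` the fraction of
    positives above the j-th negative.  For 'low' the comparisons are
    reversed.  ``mean(v10) == mean(v01) == AUC``.
    """
    sp, sn = np.sort(pos), np.sort(neg)
    m, n = len(pos), len(neg)
    if direction == "high":
        lo = np.searchsorted(sn, pos, side="left")
        hi = np.searchsorted(sn, pos, side="right")
        v10 = (lo + 0.5 * (hi - lo)) / n
        lo = np.searchsorted(sp, neg, side="left")
        hi = np.searchsorted(sp, neg, side="right")
        v01 = ((m - hi) + 0.5 * (hi - lo)) / m
    else:
        lo = np.searchsorted(sn, pos, side="left")
        hi = np.searchsorted(sn, pos, side="right")
        v10 = ((n - hi) + 0.5 * (hi - lo)) / n
        lo = np.searchsorted(sp, neg, side="left")
        hi = np.searchsorted(sp, neg, side="right")
        v01 = (lo + 0.5 * (hi - lo)) / m
    return v10, v01


def auc_value(values, labels, direction: str = "low") -> float:
    """Point estimate of the AUC (Mann-Whitney form, ties one half)."""
    pos, neg = _split(values, labels, direction)
    v10, _ = _placements(pos, neg, direction)
    return float(np.mean(v10))


@dataclass(frozen=True)
class AUCResult:
    """AUC with DeLong variance, logit-scale 95% CI and test vs 0.5."""

    auc: float
    variance: float
    ci_low: float
    ci_high: float
    p_vs_half: float
    n_pos: int
    n_neg: int


def _delong_variance(v10, v01) -> float:
    m, n = len(v10), len(v01)
    if m < 2 or n < 2:
        return float("nan")
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def auc(values, labels, direction: str = "low") -> AUCResult:
    """AUC with DeLong standard error.

    The 95% CI is a normal interval on the logit scale (keeps the
    bounds inside [0, 1]); for a degenerate AUC of exactly 0 or 1, or a
    zero variance, the interval collapses to the point estimate.
    ``p_vs_half`` is the two-sided normal p-value for AUC = 0.5.
    """
    pos, neg = _split(values, labels, direction)
    v10, v01 = _placements(pos, neg, direction)
    a = float(np.mean(v10))
    var = _delong_variance(v10, v01)
    se = math.sqrt(var) if var == var and var > 0 else 0.0
    if se > 0 and 0.0 < a < 1.0:
        logit = math.log(a / (1 - a))
        se_logit = se / (a * (1 - a))
        lo = 1 / (1 + math.exp(-(logit - _Z975 * se_logit)))
        hi = 1 / (1 + math.exp(-(logit + _Z975 * se_logit)))
    else:
        lo = hi = a
    if se > 0:
        p = 2 * stats.norm.sf(abs(a - 0.5) / se)
    else:
        p = 1.0 if a == 0.5 else 0.0
    return AUCResult(a, var, lo, hi, float(min(p, 1.0)), len(pos), len(neg))


@dataclass(frozen=True)
class DeLongComparison:
    """Paired comparison of two AUCs measured on the same subjects."""

    auc_a: float
    auc_b: float
    difference: float
    variance_of_difference: float
    z: float
    p_two_sided: float


def delong_paired_test(
    predictor_a, predictor_b, labels, direction: str = "low"
) -> DeLongComparison:
    """Paired DeLong test for the difference of two correlated AUCs.

    Both predictors must be measured on the same subjects with the same
    labels.  The covariance of the two AUC estimates is computed from
    the per-subject structural components, and the difference is tested
    with a two-sided normal z.  If the variance of the difference is
    zero the p-value is 1 when the difference is also zero (identical
    discrimination) and 0 otherwise.
    """
    xa = np.asarray(predictor_a, dtype=float)
    xb = np.asarray(predictor_b, dtype=float)
    if xa.shape != xb.shape:
        raise ValueError("predictors differ in length")
    y = _as_binary(labels)
    pa, na = _split(xa, y, direction)
    pb, nb = _split(xb, y, direction)
    v10a, v01a = _placements(pa, na, direction)
    v10b, v01b = _placements(pb, nb, direction)
    auc_a, auc_b = float(np.mean(v10a)), float(np.mean(v10b))
    m, n = len(pa), len(na)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = float(max(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1], 0.0))
    diff = auc_a - auc_b
    if var_diff > 0:
        z = diff / math.sqrt(var_diff)
        p = float(min(2 * stats.norm.sf(abs(z)), 1.0))
    else:
        z = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        p = 1.0 if diff == 0 else 0.0
    return DeLongComparison(auc_a, auc_b, diff, var_diff, z, p)


@dataclass(frozen=True)
class CutoffResult:
    """Youden-optimal operating point in original score units."""

    criterion: str
    threshold: float
    sensitivity: float  # percent
    specificity: float  # percent
    youden_j: float


def youden_cutoff(roc: ROCCurve) -> CutoffResult:
    """Cut-off maximizing the Youden index J = sens + spec - 1.

    Ties in J are broken toward the point with higher sensitivity
    (screening use); any remaining tie goes to the less extreme
    threshold (nearest the middle of the sweep).  The criterion string
    uses the curve's direction: ``<=k`` for 'low', ``>k`` for 'high'.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    sens_best = roc.sensitivity[best]
    best = best[sens_best >= sens_best.max() - 1e-12]
    mid = (len(roc.thresholds) - 1) / 2.0
    idx = int(best[np.argmin(np.abs(best - mid))])
    t = roc.thresholds[idx]
    symbol = "<=" if roc.direction == "low" else ">"
    return CutoffResult(
        criterion=f"{symbol}{t:g}",
        threshold=float(t),
        sensitivity=float(100.0 * roc.sensitivity[idx]),
        specificity=float(100.0 * roc.specificity[idx]),
        youden_j=float(j[idx]),
    )


def cohens_kappa(ratings_a, ratings_b) -> float:
    """Cohen's chance-corrected agreement between two categorical raters.

    kappa = (p_o - p_e) / (1 - p_e) with expected agreement from the
    marginal products.  Perfect agreement on a single shared category
    (p_o = p_e = 1) returns 1 by convention.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be equal-length one-dimensional vectors")
    if len(a) == 0:
        raise ValueError("empty ratings")
    n = len(a)
    p_o = float(np.mean(a == b))
    cats = np.union1d(a, b)
    p_e = float(
        sum((np.sum(a == c) / n) * (np.sum(b == c) / n) for c in cats)
    )
    if p_e >= 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Probability-mass definition: the sum of hypergeometric
    probabilities, over all tables with the observed margins, that do
    not exceed the observed table's probability (with a small relative
    tolerance for floating-point ties).  An empty margin returns 1.
    """
    cells = (a, b, c, d)
    if any((not float(x).is_integer()) or x < 0 for x in cells):
        raise ValueError("cells must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 in (0, n) or col1 in (0, n):
        return 1.0
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    p_obs = stats.hypergeom.pmf(a, n, row1, col1)
    return float(min(pmf[pmf <= p_obs * (1 + 1e-7)].sum(), 1.0))


def _mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    sy = np.sort(y)
    lo = np.searchsorted(sy, x, side="left")
    hi = np.searchsorted(sy, x, side="right")
    return float(np.sum(lo) + 0.5 * np.sum(hi - lo))


def mann_whitney_test(x, y, exact_max_n: int = 12) -> tuple[float, float]:
    """Two-sample Mann-Whitney U test (two-sided).

    Returns ``(U, p)`` where U counts pairs with x above y (ties one
    half).  For combined sample sizes up to ``exact_max_n`` the exact
    permutation distribution of U is enumerated (valid under ties) and
    p = 2*min(P(U' <= U), P(U' >= U)) capped at 1; otherwise a
    tie-corrected normal approximation with continuity correction is
    used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    u = _mann_whitney_u(x, y)
    if n1 + n2 <= exact_max_n:
        pooled = np.concatenate([x, y])
        idx = range(n1 + n2)
        us = np.array(
            [
                _mann_whitney_u(
                    pooled[list(comb)],
                    pooled[[i for i in idx if i not in set(comb)]],
                )
                for comb in itertools.combinations(idx, n1)
            ]
        )
        tol = 1e-9
        p = 2 * min(np.mean(us <= u + tol), np.mean(us >= u - tol))
        return u, float(min(p, 1.0))
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    z = (u - mu - 0.5 * np.sign(u - mu)) / math.sqrt(sigma2)
    return u, float(min(2 * stats.norm.sf(abs(z)), 1.0))


def students_t_test(x, y) -> tuple[float, float]:
    """Pooled-variance two-sample Student's t test (two-sided).

    With zero pooled variance: equal means give (0, 1); unequal means
    give a degenerate infinite t with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / df
    diff = float(np.mean(x) - np.mean(y))
    if sp2 <= 0:
        if diff == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    t = diff / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return float(t), float(min(2 * stats.t.sf(abs(t), df), 1.0))


def _fmt_median_iqr(v: np.ndarray) -> str:
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}-{q3:.1f})"


def _fmt_mean_sd(v: np.ndarray) -> str:
    return f"{np.mean(v):.1f} ± {np.std(v, ddof=1):.1f}"


def compare_groups(
    table: pd.DataFrame,
    group: str,
    variable_types: dict[str, str],
    continuous_test: str = "mannwhitney",
) -> pd.DataFrame:
    """Two-group comparison table in the clinical-paper layout.

    ``group`` names a binary column of ``table``; ``variable_types``
    maps each variable to ``"continuous"`` or ``"categorical"``.
    Continuous variables are summarised as median (IQR) and compared
    with Mann-Whitney (or mean +/- SD with Student's t when
    ``continuous_test="ttest"``); categorical (binary) variables as
    n (%) with Fisher's exact test.  One row per variable, summary
    strings for the total cohort and both groups, plus the p-value.
    """
    if continuous_test not in ("mannwhitney", "ttest"):
        raise ValueError("continuous_test must be 'mannwhitney' or 'ttest'")
    g = _as_binary(table[group])
    rows = []
    for var, kind in variable_types.items():
        v = table[var].to_numpy()
        if kind == "continuous":
            v = v.astype(float)
            v1, v0 = v[g], v[~g]
            if continuous_test == "ttest":
                stat, p = students_t_test(v1, v0)
                fmt = _fmt_mean_sd
            else:
                stat, p = mann_whitney_test(v1, v0)
                fmt = _fmt_median_iqr
            rows.append(
                {
                    "variable": var,
                    "total": fmt(v),
                    "group_pos": fmt(v1),
                    "group_neg": fmt(v0),
                    "p_value": p,
                }
            )
        elif kind == "categorical":
            v = v.astype(bool)
            a = int(np.sum(v & g))
            b = int(np.sum(v & ~g))
            c = int(np.sum(~v & g))
            d = int(np.sum(~v & ~g))
            p = fisher_exact_2x2(a, b, c, d)

            def pct(k, m):
                return f"{k} ({100.0 * k / m:.1f}%)" if m else f"{k}"

            rows.append(
                {
                    "variable": var,
                    "total": pct(a + b, len(v)),
                    "group_pos": pct(a, a + c),
                    "group_neg": pct(b, b + d),
                    "p_value": p,
                }
            )
        else:
            raise ValueError(f"unknown variable type {kind!r} for {var!r}")
    return pd.DataFrame(rows).set_index("variable")


def accuracy_table(
    scores: pd.DataFrame,
    endpoints: pd.DataFrame,
    endpoint_directions: dict[str, str],
) -> pd.DataFrame:
    """Per score x endpoint diagnostic accuracy summary.

    ``scores`` holds one column per scoring system, ``endpoints`` one
    boolean column per endpoint (same row order);
    ``endpoint_directions`` gives the direction convention per endpoint
    ('low' when low scores predict the positive class).  Each row
    reports the AUC with its DeLong 95% CI and p vs 0.5, and the
    Youden-optimal criterion with sensitivity/specificity in percent.
    A degenerate endpoint (single class) yields a row flagged
    uncomputable.
    """
    rows = []
    for ep, direction in endpoint_directions.items():
        y = endpoints[ep].to_numpy().astype(bool)
        for sc in scores.columns:
            x = scores[sc].to_numpy().astype(float)
            base = {"endpoint": ep, "score": sc, "n_pos": int(y.sum()),
                    "n_neg": int((~y).sum())}
            if y.all() or not y.any():
                rows.append({**base, "note": "degenerate endpoint"})
                continue
            res = auc(x, y, direction)
            cut = youden_cutoff(roc_curve(x, y, direction))
            rows.append(
                {
                    **base,
                    "auc": res.auc,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "criterion": cut.criterion,
                    "sensitivity_pct": cut.sensitivity,
                    "specificity_pct": cut.specificity,
                    "youden_j": cut.youden_j,
                    "p_vs_half": res.p_vs_half,
                    "note": "",
                }
            )
    return pd.DataFrame(rows)


def delong_pairwise(
    scores: pd.DataFrame,
    labels,
    direction: str = "low",
    endpoint: str = "",
) -> pd.DataFrame:
    """All pairwise paired DeLong comparisons between score columns."""
    y = _as_binary(labels)
    rows = []
    cols = list(scores.columns)
    for i, sa in enumerate(cols):
        for sb in cols[i + 1 :]:
            cmp = delong_paired_test(
                scores[sa].to_numpy(float), scores[sb].to_numpy(float), y, direction
            )
            rows.append(
                {
                    "endpoint": endpoint,
                    "score_a": sa,
                    "score_b": sb,
                    "auc_a": cmp.auc_a,
                    "auc_b": cmp.auc_b,
                    "difference": cmp.difference,
                    "z": cmp.z,
                    "p_two_sided": cmp.p_two_sided,
                }
            )
    return pd.DataFrame(rows)
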