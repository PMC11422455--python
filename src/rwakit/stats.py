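"""Validation statistics for RWA parameters.

ROC analysis with DeLong standard errors and the paired DeLong test for
correlated ROC curves; Youden-index cut-point selection (plus the
max-sensitivity-at-full-specificity alternative that matches how visual
cut-points are usually reported); Pearson correlation; one-way ANOVA with
Bonferroni post-hoc pairwise tests; Fisher's exact test (2x2 via SciPy,
2xk via complete enumeration of tables with fixed margins); and simple OLS
regression with R^2 and the overall F test.

The standard building blocks are delegated to SciPy/statsmodels; the DeLong
variance components, cut-point rules and the 2xk exact test are implemented
here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as spstats

__all__ = [
    "RocResult",
    "roc",
    "compare_auc",
    "pearson",
    "anova_bonferroni",
    "fisher_exact",
    "linreg",
    "pool_groups",
    "cohort_report",
    "RWA_PARAMETERS",
]

RWA_PARAMETERS = ("any_pct", "tonic_pct", "phasic_pct", "auto_rwa")


@dataclass
class RocResult:
    """AUC with DeLong uncertainty and operating points.

    ``cut_point`` maximises Youden's J (ties resolved toward higher
    specificity, i.e. the higher threshold); ``cut_point_spec1`` is the
    lowest threshold achieving specificity 1.00, with its sensitivity.
    Predictions are positive when the score is >= the threshold.
    """

    auc: float
    se: float
    ci95: tuple
    cut_point: float
    sensitivity: float
    specificity: float
    cut_point_spec1: float
    sensitivity_at_spec1: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "se": self.se, "ci95": list(self.ci95),
            "cut_point": self.cut_point, "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "cut_point_spec1": self.cut_point_spec1,
            "sensitivity_at_spec1": self.sensitivity_at_spec1,
            "n_pos": self.n_pos, "n_neg": self.n_neg,
        }


# ---------------------------------------------------------------------------
# DeLong machinery
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    z = x[order]
    n = x.size
    t = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j < n and z[j] == z[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def _delong(scores: np.ndarray, labels: np.ndarray):
    """AUCs and their DeLong covariance for k score vectors on one sample.

    ``scores`` has shape (k, n); higher scores indicate the positive class.
    """
    pos = scores[:, labels == 1]
    neg = scores[:, labels == 0]
    m, n = pos.shape[1], neg.shape[1]
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    k = scores.shape[0]
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        tz = _midrank(np.concatenate([pos[r], neg[r]]))
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    def _cov(v):
        if v.shape[1] < 2:          # a single subject carries no variance
            return np.zeros((k, k))
        return np.atleast_2d(np.cov(v))

    cov = _cov(v01) / m + _cov(v10) / n
    return aucs, cov


def _check_scores(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.ndim != 1 or y.ndim != 1 or s.size != y.size:
        raise ValueError("scores and labels must be 1-D of equal length")
    if np.isnan(s).any():
        raise ValueError("scores contain missing values")
    uniq = set(np.unique(y).tolist())
    if not uniq <= {0, 1, False, True}:
        raise ValueError("labels must be binary 0/1")
    y = y.astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return s, y


def roc(scores, labels) -> RocResult:
    """ROC analysis of one score against binary labels (1 = disease).

    The AUC is the tie-corrected Mann-Whitney estimator; its standard error
    and 95 % CI come from the DeLong variance.
    """
    s, y = _check_scores(scores, labels)
    aucs, cov = _delong(s[None, :], y)
    auc = float(aucs[0])
    se = float(math.sqrt(max(cov[0, 0], 0.0)))
    ci = (max(0.0, auc - 1.959964 * se), min(1.0, auc + 1.959964 * se))

    thresholds = np.concatenate([np.unique(s), [np.inf]])
    pos, neg = s[y == 1], s[y == 0]
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    j = sens + spec - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    # among J-ties prefer the higher specificity, then the higher threshold
    best_i = max(best, key=lambda i: (spec[i], thresholds[i]))

    full = np.flatnonzero(spec >= 1.0 - 1e-12)
    spec1_i = full[np.argmax(sens[full])]

    return RocResult(
        auc=auc, se=se, ci95=ci,
        cut_point=float(thresholds[best_i]),
        sensitivity=float(sens[best_i]), specificity=float(spec[best_i]),
        cut_point_spec1=float(thresholds[spec1_i]),
        sensitivity_at_spec1=float(sens[spec1_i]),
        n_pos=int((y == 1).sum()), n_neg=int((y == 0).sum()),
    )


def compare_auc(scores_a, scores_b, labels) -> tuple:
    """Paired DeLong test for two correlated ROC curves; returns (z, p)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired design requires equal-length score vectors")
    _, y = _check_scores(a, labels)
    aucs, cov = _delong(np.vstack([a, b]), y)
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = aucs[0] - aucs[1]
    if var <= 1e-15:
        return (0.0, 1.0) if abs(diff) < 1e-12 else (math.copysign(math.inf, diff), 0.0)
    z = float(diff / math.sqrt(var))
    return z, float(2 * spstats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Classical tests
# ---------------------------------------------------------------------------

def pearson(x, y) -> tuple:
    """Product-moment correlation with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = spstats.pearsonr(x, y)
    return float(r), float(p)


def anova_bonferroni(values, groups) -> tuple:
    """One-way ANOVA plus Bonferroni-adjusted pairwise t-tests.

    Returns ``(F, p, pairwise)`` with ``pairwise[(g1, g2)]`` the classic
    two-sample t-test p multiplied by the number of pairs (capped at 1).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = list(dict.fromkeys(g.tolist()))
    arrays = {lab: v[g == lab] for lab in labels}
    if len(labels) < 2 or any(a.size < 2 for a in arrays.values()):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    F, p = spstats.f_oneway(*arrays.values())
    pairs = list(itertools.combinations(labels, 2))
    pairwise = {}
    for g1, g2 in pairs:
        _, praw = spstats.ttest_ind(arrays[g1], arrays[g2], equal_var=True)
        pairwise[(g1, g2)] = min(1.0, float(praw) * len(pairs))
    return float(F), float(p), pairwise


def fisher_exact(table) -> float:
    """Exact conditional p for a 2x2 or small 2xk contingency table."""
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("table must be 2xk")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("counts must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        raise ValueError("empty row or column margin")
    if t.shape[1] == 2:
        return float(spstats.fisher_exact(t)[1])
    return _fisher_2xk(t)


def _fisher_2xk(t: np.ndarray) -> float:
    k = t.shape[1]
    if k > 6 or t.sum() > 600:
        raise ValueError("2xk enumeration supported only for small tables")
    cols = t.sum(axis=0)
    r1 = int(t[0].sum())
    n = int(t.sum())
    log_denom = _log_comb(n, r1)

    def log_prob(a: Sequence) -> float:
        return sum(_log_comb(int(c), int(x)) for c, x in zip(cols, a)) - log_denom

    obs = log_prob(t[0])
    total = 0.0
    ranges = [range(min(int(c), r1) + 1) for c in cols[:-1]]
    for head in itertools.product(*ranges):
        last = r1 - sum(head)
        if 0 <= last <= cols[-1]:
            lp = log_prob((*head, last))
            if lp <= obs + 1e-9:
                total += math.exp(lp)
    return min(1.0, float(total))


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def linreg(x, y) -> tuple:
    """Simple OLS of y on x: (slope, intercept, r2, F, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("regression undefined for constant x")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return (float(model.params[1]), float(model.params[0]),
            float(model.rsquared), float(model.fvalue),
            float(model.f_pvalue))


# ---------------------------------------------------------------------------
# Cohort-level reporting
# ---------------------------------------------------------------------------

_POOL_PAIRS = (("HC", "PDnoRBD"), ("iRBD", "PD_RBD"))
RBD_GROUPS = ("iRBD", "PD_RBD")


def pool_groups(df: pd.DataFrame, alpha: float = 0.05,
                parameters: Sequence = RWA_PARAMETERS) -> tuple:
    """Binary RBD labels after the within-pair post-hoc homogeneity check.

    The clinical pooling {iRBD, PD+RBD} vs {HC, PDnoRBD} is applied and the
    Bonferroni post-hoc p-values inside each pooled pair are logged, flagging
    any parameter for which the pair is *not* homogeneous at ``alpha``.
    """
    labels = df["group"].isin(RBD_GROUPS).astype(int).to_numpy()
    log: dict = {"alpha": alpha, "pairs": {}}
    for param in parameters:
        if param not in df.columns:
            continue
        sub = df.dropna(subset=[param])
        _, _, pairwise = anova_bonferroni(sub[param], sub["group"])
        for g1, g2 in _POOL_PAIRS:
            p = pairwise.get((g1, g2), pairwise.get((g2, g1)))
            if p is None:
                continue
            entry = log["pairs"].setdefault(f"{g1}|{g2}", {})
            entry[param] = {"p_bonferroni": p, "homogeneous": p >= alpha}
    return labels, log


def cohort_report(df: pd.DataFrame, gold: str | None = None,
                  alpha: float = 0.05) -> dict:
    """Group summary, ROC table with comparisons to the gold parameter, and
    Bonferroni-corrected correlations of RWA with AHI/PLMI/imaging.

    ``gold`` defaults to the RWA parameter with the highest AUC.  Returns a
    JSON-serialisable nested dict.
    """
    params = [p for p in RWA_PARAMETERS if p in df.columns]
    if gold is not None and gold not in params:
        raise ValueError(f"unknown gold parameter {gold!r}; valid: {params}")
    groups = list(dict.fromkeys(df["group"].tolist()))
    if df["group"].isin(RBD_GROUPS).nunique() < 2:
        raise ValueError("both classes required: cohort has a single group")

    summary: dict = {}
    numeric = [c for c in df.columns
               if c not in ("subject", "group", "sex", "rbd")
               and pd.api.types.is_numeric_dtype(df[c])]
    for var in numeric:
        per = {}
        for g in groups:
            vals = df.loc[df["group"] == g, var].dropna()
            per[g] = {"mean": float(vals.mean()) if len(vals) else None,
                      "sd": float(vals.std(ddof=1)) if len(vals) > 1 else None,
                      "n": int(len(vals))}
        sub = df.dropna(subset=[var])
        present = [g for g in groups
                   if (sub["group"] == g).sum() >= 2]
        if len(present) >= 2:
            s2 = sub[sub["group"].isin(present)]
            F, p, _ = anova_bonferroni(s2[var], s2["group"])
        else:
            F, p = None, None
        summary[var] = {"groups": per, "anova_F": F, "anova_p": p}
    if "sex" in df.columns and len(groups) >= 2:
        table = np.array([
            [int(((df["group"] == g) & (df["sex"] == "M")).sum()) for g in groups],
            [int(((df["group"] == g) & (df["sex"] != "M")).sum()) for g in groups],
        ])
        try:
            summary["sex_male"] = {"fisher_p": fisher_exact(table)}
        except ValueError:
            summary["sex_male"] = {"fisher_p": None}

    labels, pool_log = pool_groups(df, alpha=alpha)

    roc_rows: dict = {}
    for p in params:
        mask = df[p].notna().to_numpy()
        roc_rows[p] = roc(df.loc[mask, p].to_numpy(), labels[mask])
    if gold is None:
        gold = max(roc_rows, key=lambda p: roc_rows[p].auc)
    comparisons: dict = {}
    for p in params:
        if p == gold:
            continue
        mask = (df[p].notna() & df[gold].notna()).to_numpy()
        z, pv = compare_auc(df.loc[mask, gold].to_numpy(),
                            df.loc[mask, p].to_numpy(), labels[mask])
        comparisons[p] = {"z": z, "p": pv}

    covariates = [c for c in ("ahi", "plmi", "caudate_sbr", "putamen_sbr",
                              "caudate_z", "putamen_z") if c in df.columns]
    raw: dict = {}
    for p in params:
        for c in covariates:
            sub = df.dropna(subset=[p, c])
            if len(sub) >= 3 and sub[p].nunique() > 1 and sub[c].nunique() > 1:
                r, pv = pearson(sub[p], sub[c])
                raw[(p, c)] = (r, pv, len(sub))
    m = max(len(raw), 1)
    correlations = {
        f"{p}~{c}": {"r": r, "p": pv, "p_bonferroni": min(1.0, pv * m), "n": n}
        for (p, c), (r, pv, n) in raw.items()
    }

    return {
        "n_subjects": int(len(df)),
        "groups": {g: int((df["group"] == g).sum()) for g in groups},
        "summary": summary,
        "pooling": pool_log,
        "gold_parameter": gold,
        "roc": {p: r.to_dict() for p, r in roc_rows.items()},
        "auc_vs_gold": comparisons,
        "correlations": correlations,
    }
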