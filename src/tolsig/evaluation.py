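"""Classifier evaluation: AUC with DeLong intervals, drug-confounding
diagnostics, and temporal stability tests.

The central diagnostic is the *adjusted AUC*: the predicted probability of
tolerance is regressed on the five drug-intake indicators in IS-treated
patients and the AUC recomputed on the residuals; tolerant patients (who take
no drugs) enter with their all-zero-regimen residual ``p - intercept``. When
the classifier is exploiting drug effects rather than tolerance, the
adjustment collapses its discrimination toward 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import DRUGS, DRUG_FAMILIES, ValidationError


# ---------------------------------------------------------------------------
# AUC and DeLong confidence interval
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """Two-class AUC as the Mann-Whitney pair statistic with ties counted 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both classes required for AUC")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2.0) / (len(pos) * len(neg)))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc_ci(scores, labels, level: float = 0.95) -> tuple[float, float, float]:
    """AUC with a DeLong-variance normal-approximation CI, truncated to [0,1]."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both classes required for AUC")
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


# ---------------------------------------------------------------------------
# confounding diagnostics
# ---------------------------------------------------------------------------

def _ols_coef_tests(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """OLS of y on [1, X]; returns (coef, se, p, df) for the X columns, with
    NaN for non-estimable (collinear) columns."""
    from .isie import _ols  # shared rank-aware OLS core

    Xd = np.column_stack([np.ones(len(y)), X])
    coef, se, resid_sd, df, _ = _ols(Xd, y)
    scale = np.abs(y).max() + 1.0
    if np.isfinite(resid_sd) and resid_sd < 1e-10 * scale:
        # exact linear dependence: residual variance is float noise, so the
        # t statistic is meaningless; call coefficients at their exact-
        # arithmetic values (nonzero -> p=0, zero -> p=1)
        nz = np.abs(coef[1:]) > 1e-8 * scale
        p = np.where(np.isnan(coef[1:]), np.nan, np.where(nz, 0.0, 1.0))
        return coef[1:], se[1:], p, df
    with np.errstate(invalid="ignore", divide="ignore"):
        t = coef[1:] / se[1:]
    ok = np.isfinite(t) & (se[1:] > 0) & (resid_sd > 0 if np.isfinite(resid_sd) else False)
    p = np.where(ok, 2.0 * stats.t.sf(np.abs(t), max(df, 1)), np.nan)
    return coef[1:], se[1:], p, df


def probability_drug_association(
    values,
    design: pd.DataFrame,
    families: dict[str, tuple[str, ...]] = DRUG_FAMILIES,
) -> pd.DataFrame:
    """Test association of a per-sample quantity with each drug's intake.

    OLS of the value on all five indicators simultaneously (each drug
    adjusted for the others); per-drug two-sided coefficient t-test;
    Bonferroni within the CNI and antiproliferative families. ``values`` is
    aligned to ``design`` by sample id when both carry indices.
    """
    if isinstance(values, pd.Series):
        values = values.loc[design.index]
    y = np.asarray(values, dtype=float)
    if len(y) != len(design):
        raise ValidationError("values and design must cover the same samples")
    X = design[list(DRUGS)].to_numpy(dtype=float)
    coef, se, p, _ = _ols_coef_tests(X, y)
    fam_of = {d: f for f, members in families.items() for d in members}
    fam_size = {f: len(m) for f, m in families.items()}
    rows = []
    for i, drug in enumerate(DRUGS):
        k = fam_size.get(fam_of.get(drug, drug), 1)
        rows.append({
            "drug": drug, "coef": coef[i], "se": se[i], "p": p[i],
            "p_adj": min(1.0, p[i] * k) if np.isfinite(p[i]) else np.nan,
            "family": fam_of.get(drug, drug),
            "computable": bool(np.isfinite(p[i])),
        })
    return pd.DataFrame(rows).set_index("drug")


def adjusted_auc(probabilities: pd.Series, labels: pd.Series,
                 design: pd.DataFrame) -> float:
    """Drug-adjusted AUC.

    ``design`` covers the IS-treated samples; tolerant samples are the
    ``labels == 1`` entries and carry an (implicit) all-zero regimen. The
    probability is regressed on the five indicators in treated patients;
    treated residuals are ``p - fitted`` and tolerant residuals
    ``p - intercept``; the AUC of these residuals against the labels is
    returned.
    """
    labels = labels.loc[probabilities.index]
    treated_ids = [s for s in probabilities.index if s in design.index]
    if not treated_ids:
        raise ValidationError("no treated samples found in design")
    p_tr = probabilities.loc[treated_ids].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(treated_ids)),
                         design.loc[treated_ids, list(DRUGS)].to_numpy(float)])
    from .isie import _ols

    coef, _, _, _, _ = _ols(X, p_tr)
    coef = np.nan_to_num(coef)
    resid = probabilities.copy().astype(float)
    resid.loc[treated_ids] = p_tr - X @ coef
    untreated = [s for s in probabilities.index if s not in design.index]
    resid.loc[untreated] = probabilities.loc[untreated] - coef[0]
    # snap float-noise-level residual differences to exact ties so that
    # degenerate inputs (e.g. constant probabilities) keep AUC = 1/2
    return roc_auc(np.round(resid.to_numpy(), 10), labels.to_numpy())


def auc_difference_bootstrap(
    probabilities: pd.Series,
    labels: pd.Series,
    design: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Paired bootstrap over patients for raw-minus-adjusted AUC.

    Two-sided p-value from the bootstrap distribution of the difference
    (the method is a paired nonparametric bootstrap, resampling samples with
    replacement within each class).
    """
    rng = np.random.default_rng(seed)
    labels = labels.loc[probabilities.index]
    raw = roc_auc(probabilities.to_numpy(), labels.to_numpy())
    adj = adjusted_auc(probabilities, labels, design)
    ids = np.asarray(probabilities.index)
    y = labels.to_numpy().astype(int)
    pos_ids, neg_ids = ids[y == 1], ids[y == 0]
    diffs = []
    for _ in range(n_boot):
        bs = np.concatenate([rng.choice(pos_ids, len(pos_ids), replace=True),
                             rng.choice(neg_ids, len(neg_ids), replace=True)])
        p_b = probabilities.loc[bs]
        p_b.index = pd.Index([f"b{i}" for i in range(len(bs))])
        lab_b = pd.Series(np.concatenate([np.ones(len(pos_ids), int),
                                          np.zeros(len(neg_ids), int)]),
                          index=p_b.index)
        des_rows = [s for s in bs if s in design.index]
        des_b = design.loc[des_rows].copy()
        des_b.index = pd.Index([f"b{i}" for i, s in enumerate(bs) if s in design.index])
        try:
            d = roc_auc(p_b.to_numpy(), lab_b.to_numpy()) - adjusted_auc(p_b, lab_b, des_b)
        except ValidationError:
            continue
        diffs.append(d)
    diffs = np.asarray(diffs)
    obs = raw - adj
    se = diffs.std(ddof=1) if len(diffs) > 1 else np.nan
    z = obs / se if se and se > 0 else np.nan
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    return {"raw_auc": raw, "adjusted_auc": adj, "difference": obs,
            "bootstrap_se": float(se), "p": p, "n_boot": int(len(diffs))}


# ---------------------------------------------------------------------------
# paired stability tests
# ---------------------------------------------------------------------------

def paired_wilcoxon(pre, post) -> dict:
    """Wilcoxon signed-rank test on paired values (two-sided).

    Zero differences are dropped; the exact null distribution is used for up
    to 25 nonzero untied differences, otherwise the normal approximation with
    tie correction. All-zero differences give p = 1 with a degenerate flag.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValidationError("pre and post must have equal length")
    diff = post - pre
    nz = diff[diff != 0]
    if len(nz) == 0:
        return {"statistic": 0.0, "p": 1.0, "n_pairs": int(len(diff)),
                "n_nonzero": 0, "degenerate": True}
    ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= 25 and not ties) else "approx"
    res = stats.wilcoxon(pre, post, zero_method="wilcox", method=method)
    return {"statistic": float(res.statistic), "p": float(res.pvalue),
            "n_pairs": int(len(diff)), "n_nonzero": int(len(nz)),
            "degenerate": False}


@dataclass
class McNemarResult:
    b: int          # classified tolerant at t1 only
    c: int          # classified tolerant at t2 only
    n_pairs: int
    p: float


def mcnemar_stability(class_t1, class_t2) -> McNemarResult:
    """Exact binomial McNemar test on discordant classification switches.

    Two-sided p = min(1, 2 * P(X <= min(b, c))) with X ~ Binomial(b + c, 1/2);
    no discordant pairs gives p = 1.
    """
    a1 = np.asarray(class_t1).astype(bool)
    a2 = np.asarray(class_t2).astype(bool)
    if a1.shape != a2.shape or len(a1) == 0:
        raise ValidationError("need equal-length, non-empty paired classifications")
    b = int((a1 & ~a2).sum())
    c = int((~a1 & a2).sum())
    n = b + c
    if n == 0:
        p = 1.0
    else:
        p = float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5)))
    return McNemarResult(b=b, c=c, n_pairs=int(len(a1)), p=p)
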