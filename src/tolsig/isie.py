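"""Per-gene drug-effect models and immunosuppression-independent expression.

For each gene j an ordinary least-squares model is fitted on the IS-treated
patients (stable + chronic rejector)::

    y_ij = alpha_j + cyc_i*b_cyc,j + tac_i*b_tac,j + aza_i*b_aza,j
           + mmf_i*b_mmf,j + pred_i*b_pred,j + e_ij

The residual e_ij is the IS-independent expression (IS-IE) of a treated
sample; tolerant and healthy samples, who take no drugs, are rescaled to the
same scale by subtracting the intercept alpha_j from the raw expression.
Drug intake enters as binary yes/no indicators only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from .dataio import (
    DRUGS,
    DRUG_FAMILIES,
    TREATED_GROUPS,
    UNTREATED_GROUPS,
    ValidationError,
)

_COEFS = ("intercept",) + DRUGS


@dataclass
class DrugEffectModel:
    """Per-gene OLS drug-effect model.

    ``coef``/``se`` are genes x (intercept, pred, cyc, tac, aza, mmf);
    non-estimable coefficients (rank-deficient designs) are NaN with
    ``estimable`` False. ``resid_sd`` uses the unbiased residual variance,
    ``r2`` is the fraction of expression variance explained by drugs.
    """

    coef: pd.DataFrame
    se: pd.DataFrame
    estimable: pd.DataFrame
    resid_sd: pd.Series
    n_used: pd.Series
    df_resid: pd.Series
    r2: pd.Series

    @property
    def genes(self) -> pd.Index:
        return self.coef.index

    @property
    def intercepts(self) -> pd.Series:
        return self.coef["intercept"]

    def betas(self) -> pd.DataFrame:
        """Drug coefficients with non-estimable entries as 0 (warns)."""
        b = self.coef[list(DRUGS)]
        if not self.estimable[list(DRUGS)].to_numpy().all():
            warnings.warn("non-estimable drug coefficients treated as 0",
                          stacklevel=2)
            b = b.fillna(0.0)
        return b

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coef": {g: self.coef.loc[g].to_dict() for g in self.coef.index},
            "se": {g: self.se.loc[g].to_dict() for g in self.se.index},
            "estimable": {g: self.estimable.loc[g].to_dict() for g in self.estimable.index},
            "resid_sd": self.resid_sd.to_dict(),
            "n_used": {k: int(v) for k, v in self.n_used.items()},
            "df_resid": {k: int(v) for k, v in self.df_resid.items()},
            "r2": self.r2.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                         default=float))

    @classmethod
    def from_json(cls, path: str | Path) -> "DrugEffectModel":
        d = json.loads(Path(path).read_text())
        coef = pd.DataFrame(d["coef"]).T[list(_COEFS)]
        return cls(
            coef=coef,
            se=pd.DataFrame(d["se"]).T[list(_COEFS)].reindex(coef.index),
            estimable=pd.DataFrame(d["estimable"]).T[list(_COEFS)].reindex(coef.index).astype(bool),
            resid_sd=pd.Series(d["resid_sd"]).reindex(coef.index),
            n_used=pd.Series(d["n_used"]).reindex(coef.index).astype(int),
            df_resid=pd.Series(d["df_resid"]).reindex(coef.index).astype(int),
            r2=pd.Series(d["r2"]).reindex(coef.index),
        )


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, int, float]:
    """OLS with pivoted-QR handling of rank deficiency.

    Returns (coef, se, resid_sd, df_resid, r2); non-estimable coefficients
    (beyond the numerical rank, by pivot order) are NaN in both coef and se.
    """
    n, p = X.shape
    q, r, piv = sla.qr(X, mode="economic", pivoting=True)
    tol = np.finfo(float).eps * max(n, p) * abs(r[0, 0]) if r.size else 0.0
    rank = int((np.abs(np.diag(r)) > tol).sum())
    keep = piv[:rank]
    Xk = X[:, keep]
    coef_k, _, _, _ = np.linalg.lstsq(Xk, y, rcond=None)
    fitted = Xk @ coef_k
    resid = y - fitted
    rss = float(resid @ resid)
    df = n - rank
    sigma2 = rss / df if df > 0 else np.nan
    xtx_inv = np.linalg.inv(Xk.T @ Xk)
    se_k = np.sqrt(np.maximum(np.diag(xtx_inv), 0.0) * sigma2) if df > 0 else np.full(rank, np.nan)
    coef = np.full(p, np.nan)
    se = np.full(p, np.nan)
    coef[keep] = coef_k
    se[keep] = se_k
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return coef, se, np.sqrt(sigma2) if df > 0 else np.nan, df, max(0.0, min(1.0, r2))


def fit_drug_models(expr: pd.DataFrame, design: pd.DataFrame) -> DrugEffectModel:
    """Fit the per-gene OLS drug model on treated samples.

    ``design`` must cover IS-treated samples only; samples with missing
    expression are dropped gene-wise (complete-case). Each gene needs at
    least ``len(DRUGS) + 2`` non-missing samples.
    """
    missing = [s for s in design.index if s not in expr.columns]
    if missing:
        raise ValidationError(f"design sample(s) absent from expression: {missing}")
    samples = list(design.index)
    Y = expr[samples].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(samples)), design[list(DRUGS)].to_numpy(float)])
    g = Y.shape[0]
    min_n = len(DRUGS) + 2
    obs = ~np.isnan(Y)
    too_few = obs.sum(axis=1) < min_n
    if too_few.any():
        raise ValidationError(
            f"gene(s) with fewer than {min_n} non-missing samples: "
            f"{expr.index[too_few].tolist()}"
        )

    coef = np.empty((g, len(_COEFS)))
    se = np.empty((g, len(_COEFS)))
    resid_sd = np.empty(g)
    df_resid = np.empty(g, dtype=int)
    r2 = np.empty(g)
    n_used = obs.sum(axis=1)

    complete = obs.all(axis=1)
    if complete.any():
        # shared design: factor once, solve all complete genes together
        rows = np.flatnonzero(complete)
        q, r, piv = sla.qr(X, mode="economic", pivoting=True)
        tol = np.finfo(float).eps * max(X.shape) * abs(r[0, 0])
        rank = int((np.abs(np.diag(r)) > tol).sum())
        keep = piv[:rank]
        Xk = X[:, keep]
        xtx_inv = np.linalg.inv(Xk.T @ Xk)
        B = np.linalg.lstsq(Xk, Y[rows].T, rcond=None)[0]  # rank x m
        fitted = Xk @ B
        resid = Y[rows].T - fitted
        rss = (resid ** 2).sum(axis=0)
        df = X.shape[0] - rank
        sigma2 = rss / df
        coef[rows] = np.nan
        se[rows] = np.nan
        coef[np.ix_(rows, keep)] = B.T
        se[np.ix_(rows, keep)] = np.sqrt(np.outer(sigma2, np.maximum(np.diag(xtx_inv), 0.0)))
        resid_sd[rows] = np.sqrt(sigma2)
        df_resid[rows] = df
        tss = ((Y[rows].T - Y[rows].T.mean(axis=0)) ** 2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2_rows = np.where(tss > 0, 1.0 - rss / tss, 0.0)
        r2[rows] = np.clip(r2_rows, 0.0, 1.0)
    for i in np.flatnonzero(~complete):
        m = obs[i]
        coef[i], se[i], resid_sd[i], df_resid[i], r2[i] = _ols(X[m], Y[i, m])

    genes = expr.index
    return DrugEffectModel(
        coef=pd.DataFrame(coef, index=genes, columns=list(_COEFS)),
        se=pd.DataFrame(se, index=genes, columns=list(_COEFS)),
        estimable=pd.DataFrame(~np.isnan(coef), index=genes, columns=list(_COEFS)),
        resid_sd=pd.Series(resid_sd, index=genes),
        n_used=pd.Series(n_used, index=genes),
        df_resid=pd.Series(df_resid, index=genes),
        r2=pd.Series(r2, index=genes),
    )


def _check_genes(expr: pd.DataFrame, model: DrugEffectModel) -> None:
    absent = [g for g in expr.index if g not in model.genes]
    if absent:
        raise ValidationError(f"gene(s) absent from drug model: {absent}")


def isie_transform(expr: pd.DataFrame, meta: pd.DataFrame,
                   model: DrugEffectModel) -> pd.DataFrame:
    """Rescale expression to IS-independent expression.

    Treated samples get the model residual ``y - (alpha + D @ beta)``;
    untreated (tolerant, healthy) samples get ``y - alpha``. Missing values
    stay missing.
    """
    _check_genes(expr, model)
    meta = meta.set_index("sample_id", drop=False) if "sample_id" in meta.columns else meta
    absent = [s for s in expr.columns if s not in meta.index]
    if absent:
        raise ValidationError(f"sample(s) absent from metadata: {absent}")
    sub = meta.loc[list(expr.columns)]
    treated = sub["group"].isin(TREATED_GROUPS).to_numpy()
    flags = sub[list(DRUGS)].astype(float).to_numpy()
    if np.isnan(flags[treated]).any():
        bad = sub.loc[treated].loc[np.isnan(flags[treated]).any(axis=1),
                                   "sample_id"].tolist()
        raise ValidationError(f"treated sample(s) with missing drug flags: {bad}")
    alpha = model.intercepts.loc[expr.index].to_numpy()
    betas = model.betas().loc[expr.index].to_numpy()
    correction = np.tile(alpha[:, None], (1, expr.shape[1]))
    correction[:, treated] += betas @ flags[treated].T
    out = expr.to_numpy(dtype=float) - correction
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def isie_transform_heldout(expr_t2: pd.DataFrame, meta_t2: pd.DataFrame,
                           model_t1: DrugEffectModel) -> pd.DataFrame:
    """Apply a drug model fitted at time point 1 to held-out follow-up
    samples, never refitting: same treated/untreated rescaling rule with the
    time-point-1 coefficients and the follow-up samples' own drug flags."""
    return isie_transform(expr_t2, meta_t2, model_t1)


def drug_effect_tests(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    families: dict[str, tuple[str, ...]] = DRUG_FAMILIES,
) -> pd.DataFrame:
    """Per-gene, per-drug two-sided t-tests of the OLS coefficients.

    Each drug's test is adjusted for all other drugs (they are joint
    covariates in the model); raw p-values are Bonferroni-multiplied by the
    size of the drug's family (capped at 1). Zero-residual-variance genes get
    NaN p-values with ``computable`` False.
    """
    model = fit_drug_models(expr, design)
    fam_of = {d: f for f, members in families.items() for d in members}
    fam_size = {f: len(m) for f, m in families.items()}
    rows = []
    for gene in model.genes:
        df = int(model.df_resid[gene])
        sd = model.resid_sd[gene]
        for drug in DRUGS:
            c = model.coef.loc[gene, drug]
            s = model.se.loc[gene, drug]
            ok = bool(model.estimable.loc[gene, drug]) and np.isfinite(s) and s > 0 and sd > 0
            if ok:
                t = c / s
                p = float(2.0 * stats.t.sf(abs(t), df))
            else:
                t, p = np.nan, np.nan
            k = fam_size.get(fam_of.get(drug, drug), 1)
            rows.append({
                "gene": gene, "drug": drug, "coef": c, "se": s,
                "t": t, "p": p,
                "p_adj": min(1.0, p * k) if np.isfinite(p) else np.nan,
                "family": fam_of.get(drug, drug),
                "computable": ok,
            })
    return pd.DataFrame(rows)


def drug_variance_explained(expr: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-gene fraction (and percentage) of expression variance explained by
    the 5-indicator drug model; constant genes report 0."""
    model = fit_drug_models(expr, design)
    return pd.DataFrame({"r2": model.r2, "r2_percent": 100.0 * model.r2})
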