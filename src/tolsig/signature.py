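"""Penalized-logistic tolerance signatures.

The signature is derived by elastic-net logistic regression of the tolerant
vs IS-treated contrast on (IS-IE) expression: minimize

    mean negative log-likelihood
        + lambda * [ alpha * ||w||_1 + (1 - alpha)/2 * ||w||_2^2 ]

over the slopes (intercept unpenalized), with per-gene standardization to
zero mean / unit SD on the training data. Hyperparameters are tuned by
leave-group-out resampling (repeated stratified 65/35 splits, held-out AUC
averaged over 100 iterations by default) with the grid restricted to points
whose full-data refit keeps at most ``max_genes`` genes — a hard cap imposed
for clinical applicability of the final assay.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedShuffleSplit

from .dataio import ConfigError, ValidationError
from .evaluation import roc_auc

__all__ = [
    "knn_impute", "fit_elastic_net_logistic", "ToleranceSignature",
    "TuningResult", "default_grid", "tune_signature", "fit_signature",
    "predict_probability", "select_cutoff", "CutoffResult",
    "cross_validated_auc",
]


# ---------------------------------------------------------------------------
# K-nearest-neighbor imputation
# ---------------------------------------------------------------------------

def _sample_distances(values: np.ndarray) -> np.ndarray:
    """Pairwise sample distances: RMS difference over mutually observed genes.

    Pairs with no mutually observed gene get +inf.
    """
    obs = ~np.isnan(values)
    filled = np.where(obs, values, 0.0)
    # sum over genes of (x_i - x_j)^2 restricted to mutual observations
    sq = filled ** 2
    cross = filled.T @ filled
    s_i = sq.T.astype(float) @ obs.astype(float)   # sum_i x^2 over mutual genes
    counts = obs.T.astype(float) @ obs.astype(float)
    d2 = s_i + s_i.T - 2.0 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_d2 = np.where(counts > 0, d2 / counts, np.inf)
    mean_d2 = np.maximum(mean_d2, 0.0)
    return np.sqrt(mean_d2)


def knn_impute(expr: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Impute missing entries from the k nearest samples.

    Distance between samples is the root-mean-square difference over mutually
    observed genes; each missing entry is the mean of the gene's values in
    the k nearest samples that observed it (all available if fewer than k).
    Deterministic: ties are broken by sample order.
    """
    values = expr.to_numpy(dtype=float).copy()
    n_samples = values.shape[1]
    if k >= n_samples:
        raise ConfigError(f"k={k} must be smaller than the number of samples ({n_samples})")
    obs = ~np.isnan(values)
    dead = ~obs.any(axis=1)
    if dead.any():
        raise ValidationError(f"gene(s) missing in every sample: {expr.index[dead].tolist()}")
    if obs.all():
        return expr.copy()
    dist = _sample_distances(values)
    out = values.copy()
    for gi, si in zip(*np.where(~obs)):
        donors = np.flatnonzero(obs[gi])
        order = donors[np.argsort(dist[si, donors], kind="stable")]
        nearest = order[:k]
        out[gi, si] = values[gi, nearest].mean()
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


# ---------------------------------------------------------------------------
# elastic-net logistic regression
# ---------------------------------------------------------------------------

def fit_elastic_net_logistic(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    class_weight: dict | str | None = None,
    max_iter: int = 20000,
    tol: float = 1e-8,
) -> tuple[np.ndarray, float]:
    """Fit the penalized logistic model; returns (slopes, intercept).

    ``alpha`` is the L1/L2 mixing weight, ``lam`` the penalty strength on the
    mean-log-likelihood scale. ``lam=0`` is the unpenalized maximum-likelihood
    fit. L1 selection yields exact zeros.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if not np.isfinite(X).all():
        raise ValidationError("non-finite values in X (impute first)")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError("y must contain both classes")
    if not (0.0 <= alpha <= 1.0) or lam < 0:
        raise ConfigError("need 0 <= alpha <= 1 and lam >= 0")
    n = X.shape[0]
    if lam == 0:
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=max_iter,
                                 tol=min(tol, 1e-10), class_weight=class_weight)
    else:
        clf = LogisticRegression(
            solver="saga", l1_ratio=alpha, C=1.0 / (n * lam),
            max_iter=max_iter, tol=tol,
            class_weight=class_weight, random_state=0,
        )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*max_iter.*")
        clf.fit(X, y)
    coef = clf.coef_[0].copy()
    intercept = float(clf.intercept_[0])
    if lam > 0 and not coef.any() and class_weight is None:
        # fully-penalized regime: the exact minimizer has the closed-form
        # intercept logit(mean(y)); saga's tiny step sizes stop short of it
        pbar = y.mean()
        intercept = float(np.log(pbar / (1.0 - pbar)))
    return coef, intercept


def _standardize_train(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (X - center) / scale, center, scale


def lambda_max(X_std: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest penalty that zeroes every slope (standardized X, alpha > 0)."""
    n = len(y)
    resid = y - y.mean()
    lm = np.abs(X_std.T @ resid).max() / (n * max(alpha, 1e-3))
    return float(lm)


def default_grid(X_std: np.ndarray, y: np.ndarray,
                 alphas: np.ndarray | None = None,
                 n_lambda: int = 50, decades: float = 4.0) -> list[tuple[float, float]]:
    """(alpha, lambda) grid: alpha in 0.1..1.0, lambda log-spaced per alpha
    from the all-zero penalty downward ``decades`` decades."""
    if alphas is None:
        alphas = np.round(np.arange(0.1, 1.01, 0.1), 10)
    grid = []
    for a in alphas:
        lm = lambda_max(X_std, y, a)
        lams = np.logspace(np.log10(lm), np.log10(lm) - decades, n_lambda)
        grid.extend((float(a), float(l)) for l in lams)
    return grid


# ---------------------------------------------------------------------------
# signature container
# ---------------------------------------------------------------------------

@dataclass
class ToleranceSignature:
    """A fitted tolerance classifier: selected genes, standardized-scale
    logistic coefficients, training centering/scaling constants and the
    classification cutoff (probability scale)."""

    genes: list[str]
    coef: np.ndarray
    intercept: float
    alpha: float
    lam: float
    center: np.ndarray
    scale: np.ndarray
    cutoff: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    seed: int | None = None

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if not (len(self.genes) == len(self.coef) == len(self.center) == len(self.scale)):
            raise ValidationError("signature gene/coefficient/scaling lengths differ")

    @property
    def n_genes(self) -> int:
        return int(np.count_nonzero(self.coef))

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for k in ("coef", "center", "scale"):
            d[k] = list(map(float, d[k]))
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ToleranceSignature":
        return cls(**json.loads(Path(path).read_text()))


def fit_signature(expr: pd.DataFrame, labels: pd.Series, alpha: float, lam: float,
                  drop_zero: bool = True, seed: int | None = None) -> ToleranceSignature:
    """Fit a signature at fixed hyperparameters on a (genes x samples)
    matrix; ``labels`` is 1 for tolerant, indexed by sample id."""
    labels = labels.loc[expr.columns]
    X = expr.to_numpy(dtype=float).T
    y = labels.to_numpy().astype(int)
    Xs, center, scale = _standardize_train(X)
    coef, intercept = fit_elastic_net_logistic(Xs, y, alpha, lam)
    genes = list(expr.index)
    if drop_zero:
        nz = coef != 0
        genes = [g for g, m in zip(genes, nz) if m]
        coef, center, scale = coef[nz], center[nz], scale[nz]
    return ToleranceSignature(genes=genes, coef=coef, intercept=intercept,
                              alpha=alpha, lam=lam, center=center, scale=scale,
                              seed=seed)


def predict_probability(signature: ToleranceSignature, expr: pd.DataFrame) -> pd.Series:
    """Probability of tolerance per sample: inverse-logit of the linear score
    on training-standardized expression."""
    absent = [g for g in signature.genes if g not in expr.index]
    if absent:
        raise ValidationError(f"signature gene(s) absent from expression: {absent}")
    X = expr.loc[signature.genes].to_numpy(dtype=float).T
    if np.isnan(X).any():
        raise ValidationError("missing values in signature genes (impute first)")
    Xs = (X - signature.center) / signature.scale
    eta = Xs @ signature.coef + signature.intercept
    return pd.Series(expit(eta), index=expr.columns, name="probability")


# ---------------------------------------------------------------------------
# hyperparameter tuning
# ---------------------------------------------------------------------------

@dataclass
class TuningResult:
    grid: pd.DataFrame            # alpha, lam, mean_auc, n_genes_full
    chosen_alpha: float
    chosen_lam: float
    n_iter: int
    train_frac: float
    seed: int
    n_skipped: int = 0

    def to_json(self, path: str | Path) -> None:
        d = {"grid": self.grid.to_dict(orient="records"),
             "chosen_alpha": self.chosen_alpha, "chosen_lam": self.chosen_lam,
             "n_iter": self.n_iter, "train_frac": self.train_frac,
             "seed": self.seed, "n_skipped": self.n_skipped}
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))


def _resampled_auc(X: np.ndarray, y: np.ndarray, alpha: float, lam: float,
                   splits: list[tuple[np.ndarray, np.ndarray]]) -> tuple[float, int]:
    aucs = []
    skipped = 0
    for tr, te in splits:
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            skipped += 1
            continue
        Xs, center, scale = _standardize_train(X[tr])
        coef, b0 = fit_elastic_net_logistic(Xs, y[tr], alpha, lam)
        eta = ((X[te] - center) / scale) @ coef + b0
        aucs.append(roc_auc(eta, y[te]))
    return (float(np.mean(aucs)) if aucs else np.nan), skipped


def tune_signature(
    expr: pd.DataFrame,
    labels: pd.Series,
    grid: list[tuple[float, float]] | None = None,
    train_frac: float = 0.65,
    n_iter: int = 100,
    max_genes: int = 30,
    seed: int = 0,
    k_impute: int = 5,
) -> tuple[TuningResult, ToleranceSignature]:
    """Tune (alpha, lambda) by repeated stratified 65/35 resampling.

    For each grid point the mean held-out AUC over ``n_iter`` splits is
    recorded; the chosen point maximizes mean AUC among points whose
    full-data refit selects at most ``max_genes`` genes (ties broken toward
    the sparser model: larger lambda, then larger alpha). The returned
    signature is the full-data refit at the chosen point. Deterministic for
    a fixed seed.
    """
    labels = labels.loc[expr.columns]
    if expr.isna().any().any():
        expr = knn_impute(expr, k=k_impute)
    X = expr.to_numpy(dtype=float).T
    y = labels.to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        raise ValidationError("labels must contain both classes")
    if grid is None:
        Xs_all, _, _ = _standardize_train(X)
        grid = default_grid(Xs_all, y)
    sss = StratifiedShuffleSplit(n_splits=n_iter, train_size=train_frac,
                                 random_state=seed)
    splits = [(tr, te) for tr, te in sss.split(X, y)]

    records = []
    total_skipped = 0
    for a, lam in grid:
        mean_auc, skipped = _resampled_auc(X, y, a, lam, splits)
        total_skipped += skipped
        sig = fit_signature(expr, labels, a, lam)
        records.append({"alpha": a, "lam": lam, "mean_auc": mean_auc,
                        "n_genes_full": sig.n_genes})
    table = pd.DataFrame(records)
    ok = table[(table["n_genes_full"] <= max_genes) & table["mean_auc"].notna()]
    if ok.empty:
        raise ConfigError(
            f"no grid point keeps <= {max_genes} genes; extend the lambda "
            "range toward larger penalties"
        )
    best = ok.sort_values(["mean_auc", "lam", "alpha"],
                          ascending=[False, False, False]).iloc[0]
    signature = fit_signature(expr, labels, float(best["alpha"]), float(best["lam"]),
                              seed=seed)
    assert signature.n_genes <= max_genes
    result = TuningResult(grid=table, chosen_alpha=float(best["alpha"]),
                          chosen_lam=float(best["lam"]), n_iter=n_iter,
                          train_frac=train_frac, seed=seed,
                          n_skipped=total_skipped)
    return result, signature


# ---------------------------------------------------------------------------
# cutoff selection
# ---------------------------------------------------------------------------

@dataclass
class CutoffResult:
    cutoff: float | None
    sensitivity: float | None
    specificity: float | None
    feasible: bool


def select_cutoff(probabilities: pd.Series | np.ndarray, labels: pd.Series | np.ndarray,
                  spec_min: float = 0.85, sens_min: float = 0.70) -> CutoffResult:
    """Pick a classification cutoff under safety constraints.

    Candidates are midpoints between adjacent sorted unique probabilities
    (a sample is called tolerant when probability >= cutoff). Among candidates
    with specificity >= ``spec_min`` and sensitivity >= ``sens_min``, the one
    maximizing specificity wins; ties go to higher sensitivity, then to the
    lower cutoff. Infeasibility is reported explicitly, never silently.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValidationError("labels must contain both classes")
    uniq = np.unique(p)
    if len(uniq) < 2:
        return CutoffResult(None, None, None, False)
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    for c in candidates:
        pred = p >= c
        sens = float((pred & (y == 1)).sum() / (y == 1).sum())
        spec = float((~pred & (y == 0)).sum() / (y == 0).sum())
        if spec >= spec_min and sens >= sens_min:
            key = (spec, sens, -c)
            if best is None or key > best[0]:
                best = (key, c, sens, spec)
    if best is None:
        return CutoffResult(None, None, None, False)
    _, c, sens, spec = best
    return CutoffResult(float(c), sens, spec, True)


# ---------------------------------------------------------------------------
# optimism-corrected AUC
# ---------------------------------------------------------------------------

def cross_validated_auc(
    expr: pd.DataFrame,
    labels: pd.Series,
    alpha: float,
    lam: float,
    train_frac: float = 0.65,
    n_iter: int = 100,
    seed: int = 0,
    k_impute: int = 5,
) -> tuple[float, dict]:
    """Mean held-out AUC over repeated stratified splits, with imputation
    constants, standardization and the penalized fit all re-estimated inside
    each training split. Held-out halves with a single class are skipped and
    counted in the report."""
    labels = labels.loc[expr.columns]
    Xdf = expr.T  # samples x genes
    y = labels.to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        raise ValidationError("labels must contain both classes")
    sss = StratifiedShuffleSplit(n_splits=n_iter, train_size=train_frac,
                                 random_state=seed)
    aucs = []
    skipped = 0
    for tr, te in sss.split(Xdf.to_numpy(), y):
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            skipped += 1
            continue
        Xtr = Xdf.iloc[tr].T
        if Xtr.isna().any().any():
            Xtr = knn_impute(Xtr, k=min(k_impute, Xtr.shape[1] - 1))
        train_means = Xtr.mean(axis=1)
        Xte = Xdf.iloc[te].T
        if Xte.isna().any().any():
            # held-out samples are imputed from training-gene means only
            Xte = Xte.apply(lambda col: col.fillna(train_means))
        Xs, center, scale = _standardize_train(Xtr.to_numpy(dtype=float).T)
        coef, b0 = fit_elastic_net_logistic(Xs, y[tr], alpha, lam)
        eta = ((Xte.to_numpy(dtype=float).T - center) / scale) @ coef + b0
        aucs.append(roc_auc(eta, y[te]))
    if not aucs:
        raise ValidationError("every resample had a single-class held-out set")
    return float(np.mean(aucs)), {"n_iter": n_iter, "n_used": len(aucs),
                                  "n_skipped": skipped}
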