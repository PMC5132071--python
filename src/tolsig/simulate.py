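"""Synthetic cohort generator.

Emulates the group and drug-regimen structure of a kidney-transplant
tolerance case-control study: four patient groups (tolerant, stable,
chronic rejector, healthy control) where only the two IS-treated groups
take drugs; mutually exclusive calcineurin-inhibitor (none/ciclosporin/
tacrolimus) and antiproliferative (none/azathioprine/mycophenolate)
assignment plus a binary prednisone flag; additive per-gene drug effects
and an additive tolerance effect on a gene subset, on the log2 expression
scale; Gaussian noise split into a patient-level component (shared across
repeat samples) and an idiosyncratic component.

The generative model for sample i of patient p and gene j is::

    y_ij = alpha_j + sum_d design_id * beta_dj + 1[tolerant_i] * delta_j
           + 1[healthy_i] * eta_j + u_pj + e_ij

with ``u_pj ~ N(0, rho * sigma^2)`` shared between repeat samples of the
same patient, ``e_ij ~ N(0, (1 - rho) * sigma^2)`` fresh per sample, so the
marginal noise variance is ``sigma^2 = noise_sd**2`` and the within-subject
noise correlation is ``rho = within_subject_corr``. Every generated quantity
is returned alongside as ground truth for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import (
    DRUGS,
    GROUPS,
    TREATED_GROUPS,
    ConfigError,
    validate_metadata,
    write_expression,
    write_metadata,
)

# Regimen frequencies of the default cohort (stable and chronic-rejector
# groups of a 14/190/36/12 retrospective cohort). CNI and antiproliferative
# probabilities are (none, cyc, tac) and (none, aza, mmf) respectively.
DEFAULT_REGIMENS = {
    "stable": {"cni": (0.269, 0.463, 0.268), "ap": (0.227, 0.326, 0.447), "pred": 0.416},
    "chronic_rejector": {"cni": (0.111, 0.083, 0.806), "ap": (0.222, 0.139, 0.639), "pred": 0.694},
}

OVERLAP_MODES = ("independent", "forced-overlap", "disjoint")


@dataclass
class CohortConfig:
    """Study-design knobs for the synthetic cohort.

    Effect sizes are in log2 expression units. ``frac_drug_affected`` is the
    per-drug fraction of genes carrying a nonzero effect; ``overlap_mode``
    controls how the tolerance-informative gene set relates to the
    drug-affected sets (``forced-overlap`` makes every tolerance gene
    drug-affected, with the drug effect signed opposite to the tolerance
    effect so that drug intake pushes expression away from the tolerant
    direction — the confounding scenario).
    """

    n_tolerant: int = 14
    n_stable: int = 190
    n_chronic: int = 36
    n_healthy: int = 12
    regimen_probs: dict = field(default_factory=lambda: {
        g: {k: tuple(v) if isinstance(v, (list, tuple)) else v
            for k, v in p.items()}
        for g, p in DEFAULT_REGIMENS.items()
    })
    n_genes: int = 100
    frac_drug_affected: float = 0.2
    drug_effect_sd: float = 1.0
    frac_tolerance_genes: float = 0.1
    tolerance_effect_sd: float = 1.5
    healthy_effect_sd: float = 0.0
    rejection_effect_sd: float = 0.0
    overlap_mode: str = "independent"
    noise_sd: float = 1.0
    within_subject_corr: float = 0.8
    missing_rate: float = 0.0
    baseline_mean: float = -4.0
    baseline_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_tolerant", "n_stable", "n_chronic", "n_healthy", "n_genes"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("frac_drug_affected", "frac_tolerance_genes",
                     "within_subject_corr", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("drug_effect_sd", "tolerance_effect_sd", "noise_sd",
                     "baseline_sd", "healthy_effect_sd", "rejection_effect_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.overlap_mode not in OVERLAP_MODES:
            raise ConfigError(f"overlap_mode must be one of {OVERLAP_MODES}")
        for grp, probs in self.regimen_probs.items():
            if grp not in GROUPS:
                raise ConfigError(f"unknown group in regimen_probs: {grp!r}")
            for factor in ("cni", "ap"):
                p = np.asarray(probs[factor], dtype=float)
                if p.shape != (3,) or (p < 0).any() or (p > 1).any():
                    raise ConfigError(f"{grp}/{factor} probabilities invalid: {p}")
                if abs(p.sum() - 1.0) > 1e-9:
                    raise ConfigError(f"{grp}/{factor} probabilities must sum to 1")
            if not (0.0 <= probs["pred"] <= 1.0):
                raise ConfigError(f"{grp}/pred probability invalid")
            if grp in ("tolerant", "healthy"):
                if probs["pred"] != 0 or probs["cni"][1:] != (0, 0) or probs["ap"][1:] != (0, 0):
                    raise ConfigError(f"{grp} group must have zero drug probabilities")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regimen_probs"] = {g: {k: list(v) if isinstance(v, tuple) else v
                                  for k, v in p.items()}
                              for g, p in d["regimen_probs"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "regimen_probs" in d:
            d["regimen_probs"] = {g: {k: tuple(v) if isinstance(v, list) else v
                                      for k, v in p.items()}
                                  for g, p in d["regimen_probs"].items()}
        return cls(**d)


@dataclass
class SimulationTruth:
    """Ground-truth generative parameters, for recovery tests.

    ``betas`` is genes x 5 (zero outside the drug-affected sets);
    ``shared_noise`` is the patient-level noise component of each base
    sample, reused when generating repeat time points.
    """

    intercepts: pd.Series
    betas: pd.DataFrame
    tolerance_delta: pd.Series
    healthy_delta: pd.Series
    drug_affected: pd.DataFrame
    tolerance_genes: pd.Series
    mean_matrix: pd.DataFrame
    shared_noise: pd.DataFrame

    def to_json(self, path: str | Path) -> None:
        payload = {
            "intercepts": self.intercepts.to_dict(),
            "betas": {g: self.betas.loc[g].to_dict() for g in self.betas.index},
            "tolerance_delta": self.tolerance_delta.to_dict(),
            "healthy_delta": self.healthy_delta.to_dict(),
            "drug_affected": {g: [d for d in DRUGS if self.drug_affected.loc[g, d]]
                              for g in self.drug_affected.index},
            "tolerance_genes": self.tolerance_genes[self.tolerance_genes].index.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def simulate_cohort(config: CohortConfig, rng: np.random.Generator | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw sample metadata and the drug design matrix for one cohort.

    Group sizes are exact; regimens are drawn per patient from the configured
    per-group probabilities; tolerant and healthy patients take no drugs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rows = []
    counts = {"tolerant": config.n_tolerant, "stable": config.n_stable,
              "chronic_rejector": config.n_chronic, "healthy": config.n_healthy}
    idx = 0
    for group in GROUPS:
        probs = config.regimen_probs.get(group)
        for _ in range(counts[group]):
            idx += 1
            pid = f"P{idx:04d}"
            flags = dict.fromkeys(DRUGS, 0)
            if group in TREATED_GROUPS and probs is not None:
                cni = rng.choice(3, p=np.asarray(probs["cni"], dtype=float))
                ap = rng.choice(3, p=np.asarray(probs["ap"], dtype=float))
                flags["cyc"], flags["tac"] = int(cni == 1), int(cni == 2)
                flags["aza"], flags["mmf"] = int(ap == 1), int(ap == 2)
                flags["pred"] = int(rng.random() < probs["pred"])
            rows.append({"sample_id": f"{pid}_t1", "patient_id": pid,
                         "group": group, "timepoint": "1", **flags})
    meta = pd.DataFrame(rows, columns=list(("sample_id", "patient_id", "group",
                                            "timepoint") + DRUGS))
    validate_metadata(meta)
    design = meta.set_index("sample_id")[list(DRUGS)].astype(int)
    return meta, design


def simulate_expression(
    meta: pd.DataFrame,
    design: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate the expression matrix and its generative ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    if list(design.index) != list(meta["sample_id"]):
        raise ConfigError("design rows must match metadata sample order")
    genes = _gene_ids(config.n_genes)
    g, n = len(genes), len(meta)

    alpha = rng.normal(config.baseline_mean, config.baseline_sd, size=g)
    affected = pd.DataFrame(False, index=genes, columns=list(DRUGS))
    betas = np.zeros((g, len(DRUGS)))
    for k in range(len(DRUGS)):
        hit = rng.random(g) < config.frac_drug_affected
        affected.iloc[:, k] = hit
        betas[hit, k] = rng.normal(0.0, config.drug_effect_sd, size=int(hit.sum()))

    n_tol_genes = int(round(config.frac_tolerance_genes * g))
    any_affected = affected.any(axis=1).to_numpy()
    if config.overlap_mode == "disjoint":
        pool = np.flatnonzero(~any_affected)
        if len(pool) < n_tol_genes:
            raise ConfigError("not enough drug-free genes for disjoint overlap mode")
    else:
        pool = np.arange(g)
    tol_idx = rng.choice(pool, size=n_tol_genes, replace=False) if n_tol_genes else np.array([], int)
    delta = np.zeros(g)
    delta[tol_idx] = rng.normal(0.0, config.tolerance_effect_sd, size=n_tol_genes)
    if config.overlap_mode == "forced-overlap":
        # every tolerance gene becomes drug-affected for every drug, with the
        # drug effect signed opposite to the tolerance effect (confounding)
        for k in range(len(DRUGS)):
            mag = np.abs(rng.normal(0.0, config.drug_effect_sd, size=n_tol_genes))
            betas[tol_idx, k] = -np.sign(delta[tol_idx]) * mag
            affected.iloc[tol_idx, k] = True

    eta = np.zeros(g)
    if config.healthy_effect_sd > 0:
        eta = rng.normal(0.0, config.healthy_effect_sd, size=g)
    rej = np.zeros(g)
    if config.rejection_effect_sd > 0:
        rej = rng.normal(0.0, config.rejection_effect_sd, size=g)

    D = design.to_numpy(dtype=float)  # n x 5
    mean = (alpha[:, None]
            + betas @ D.T
            + np.outer(delta, (meta["group"] == "tolerant").to_numpy(float))
            + np.outer(eta, (meta["group"] == "healthy").to_numpy(float))
            + np.outer(rej, (meta["group"] == "chronic_rejector").to_numpy(float)))

    rho, sigma = config.within_subject_corr, config.noise_sd
    shared = rng.normal(0.0, np.sqrt(rho) * sigma, size=(g, n))
    idio = rng.normal(0.0, np.sqrt(1.0 - rho) * sigma, size=(g, n))
    values = mean + shared + idio
    if config.missing_rate > 0:
        holes = rng.random(values.shape) < config.missing_rate
        values = np.where(holes, np.nan, values)

    samples = meta["sample_id"].tolist()
    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)
    truth = SimulationTruth(
        intercepts=pd.Series(alpha, index=genes),
        betas=pd.DataFrame(betas, index=genes, columns=list(DRUGS)),
        tolerance_delta=pd.Series(delta, index=genes),
        healthy_delta=pd.Series(eta, index=genes),
        drug_affected=affected,
        tolerance_genes=pd.Series(np.isin(np.arange(g), tol_idx), index=genes),
        mean_matrix=pd.DataFrame(mean, index=genes, columns=samples),
        shared_noise=pd.DataFrame(shared, index=genes, columns=samples),
    )
    return expr, truth


def simulate_longitudinal(
    meta: pd.DataFrame,
    expr: pd.DataFrame,
    truth: SimulationTruth,
    mode: str,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate paired follow-up samples for an existing cohort.

    ``timepoint2``: one repeat sample per patient, same regimen, sharing the
    patient-level noise component (within-subject correlation
    ``within_subject_corr``) with fresh idiosyncratic noise.

    ``steroid_withdrawal``: paired post-withdrawal samples for the
    prednisone-taking stable patients — the prednisone contribution is removed
    from the generative mean and the pred flag set to 0; the patient-level
    noise component is kept, idiosyncratic noise is redrawn.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    rho, sigma = config.within_subject_corr, config.noise_sd

    if mode == "timepoint2":
        sub = meta
        suffix, timepoint = "_t2", "2"
        mean2 = truth.mean_matrix.loc[:, sub["sample_id"]].to_numpy()
    elif mode == "steroid_withdrawal":
        on_pred = (meta["group"] == "stable") & (meta["pred"].astype(float) == 1)
        if not on_pred.any():
            raise ConfigError("no prednisone-taking stable patients to withdraw")
        sub = meta[on_pred]
        suffix, timepoint = "_post", "post"
        mean2 = (truth.mean_matrix.loc[:, sub["sample_id"]].to_numpy()
                 - truth.betas["pred"].to_numpy()[:, None])
    else:
        raise ConfigError(f"unknown longitudinal mode: {mode!r}")

    shared = truth.shared_noise.loc[:, sub["sample_id"]].to_numpy()
    idio = rng.normal(0.0, np.sqrt(1.0 - rho) * sigma, size=mean2.shape)
    values = mean2 + shared + idio
    if config.missing_rate > 0:
        holes = rng.random(values.shape) < config.missing_rate
        values = np.where(holes, np.nan, values)

    meta2 = sub.copy()
    meta2["sample_id"] = [pid + suffix for pid in sub["patient_id"]]
    meta2["timepoint"] = timepoint
    if mode == "steroid_withdrawal":
        meta2["pred"] = 0
    expr2 = pd.DataFrame(values, index=expr.index, columns=meta2["sample_id"].tolist())
    validate_metadata(meta2)
    return expr2, meta2.reset_index(drop=True)


def calibrate_drug_effects(
    betas: pd.DataFrame,
    design: pd.DataFrame,
    noise_sd: float,
    target_r2: float,
) -> pd.DataFrame:
    """Rescale per-gene drug effects so the drug-explained variance fraction
    over the given design equals ``target_r2`` (population R^2 of the drug
    model). Genes with no drug variance are left unchanged."""
    if not (0 <= target_r2 < 1):
        raise ConfigError("target_r2 must be in [0, 1)")
    D = design.to_numpy(dtype=float)
    out = betas.copy()
    contrib = betas.to_numpy() @ D.T  # genes x samples
    v = contrib.var(axis=1, ddof=0)
    target_var = target_r2 / (1.0 - target_r2) * noise_sd ** 2
    scale = np.ones_like(v)
    nz = v > 0
    scale[nz] = np.sqrt(target_var / v[nz])
    out.loc[:, :] = betas.to_numpy() * scale[:, None]
    return out


def save_simulation(outdir: str | Path, meta: pd.DataFrame, expr: pd.DataFrame,
                    truth: SimulationTruth) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(expr, outdir / "expression.tsv")
    write_metadata(meta, outdir / "metadata.csv")
    truth.to_json(outdir / "truth.json")
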