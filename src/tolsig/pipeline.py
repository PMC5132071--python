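"""End-to-end orchestration: simulate (or load) -> filter -> drug models ->
IS-IE -> signature -> evaluation -> optional GSA, with a seeded, auditable
run directory."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataio import (
    ConfigError,
    TREATED_GROUPS,
    encode_drug_design,
    read_expression,
    read_metadata,
    write_expression,
    write_metadata,
)
from .evaluation import (
    adjusted_auc,
    probability_drug_association,
    roc_auc_ci,
)
from .gsa import gsa_permutation_fdr, read_gmt
from .isie import fit_drug_models, isie_transform
from .signature import (
    knn_impute,
    predict_probability,
    select_cutoff,
    tune_signature,
)
from .simulate import CohortConfig, simulate_cohort, simulate_expression


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    ``mode`` selects whether the signature is trained on raw expression or on
    IS-IE values; everything stochastic is governed by ``seed``.
    """

    mode: str = "isie"                      # {"raw", "isie"}
    seed: int = 0
    simulate: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    expression_path: str | None = None
    metadata_path: str | None = None
    gmt_path: str | None = None
    min_detect_frac: float | None = None    # background filter off by default
    knn_k: int = 5
    alphas: list[float] = field(default_factory=lambda: [0.2, 0.5, 0.8, 1.0])
    n_lambda: int = 10
    lambda_decades: float = 2.0
    train_frac: float = 0.65
    n_iter: int = 100
    max_genes: int = 30
    spec_min: float = 0.85
    sens_min: float = 0.70
    gsa_n_perm: int = 1000

    def validate(self) -> None:
        if self.mode not in ("raw", "isie"):
            raise ConfigError(f"mode must be 'raw' or 'isie', got {self.mode!r}")
        if not (0 < self.train_frac < 1):
            raise ConfigError("train_frac must be in (0, 1)")
        for name in ("spec_min", "sens_min"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.max_genes < 1:
            raise ConfigError("max_genes must be >= 1")
        if self.n_iter < 1 or self.n_lambda < 1:
            raise ConfigError("n_iter and n_lambda must be >= 1")
        if not self.simulate and not (self.expression_path and self.metadata_path):
            raise ConfigError("expression_path and metadata_path required "
                              "when simulate is false")
        self.cohort.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        return cls(**d)


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 force: bool = False) -> dict:
    """Run the full analysis and write an immutable run directory.

    Stage order: cohort acquisition, optional background filter, per-gene
    drug models on treated patients, rescaling (IS-IE mode only), KNN
    imputation, signature tuning, prediction, evaluation, optional GSA.
    Returns the report dict (also written as ``report.json``).
    """
    config.validate()
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise ConfigError(f"output directory {outdir} is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)

    log: dict = {"version": __version__, "seed": config.seed,
                 "mode": config.mode, "stages": []}
    cfg_json = json.dumps(config.to_dict(), indent=2, sort_keys=True)
    (outdir / "config.json").write_text(cfg_json)
    log["config_sha256"] = hashlib.sha256(cfg_json.encode()).hexdigest()

    def stage(name, **info):
        log["stages"].append({"stage": name, **info})

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        cohort = dataclasses.replace(config.cohort, seed=config.seed)
        meta, _ = simulate_cohort(cohort)
        expr, truth = simulate_expression(meta, meta.set_index("sample_id")[
            list(("pred", "cyc", "tac", "aza", "mmf"))].astype(int), cohort)
        truth.to_json(outdir / "truth.json")
        write_expression(expr, outdir / "expression.tsv")
        write_metadata(meta, outdir / "metadata.csv")
    else:
        expr = read_expression(config.expression_path)
        meta = read_metadata(config.metadata_path)
    stage("input", n_genes=int(expr.shape[0]), n_samples=int(expr.shape[1]))

    # --- optional detection filter ---------------------------------------
    if config.min_detect_frac is not None:
        from .dataio import background_filter
        detected = expr.notna()
        expr, filt_report = background_filter(expr, detected, config.min_detect_frac)
        (outdir / "filter_report.json").write_text(
            json.dumps(filt_report, indent=2, sort_keys=True))
        stage("background_filter", n_retained=int(expr.shape[0]))

    # --- drug model and rescaling ----------------------------------------
    design, design_report = encode_drug_design(meta)
    model = fit_drug_models(expr, design)
    model.to_json(outdir / "drug_model.json")
    stage("fit_drug_models", n_treated=int(design.shape[0]),
          excluded=design_report["excluded_missing_flags"])

    working = isie_transform(expr, meta, model) if config.mode == "isie" else expr
    if working.isna().any().any():
        working = knn_impute(working, k=config.knn_k)
        stage("knn_impute", k=config.knn_k)

    # --- signature --------------------------------------------------------
    meta_idx = meta.set_index("sample_id")
    train_ids = [s for s in working.columns
                 if meta_idx.loc[s, "group"] in TREATED_GROUPS + ("tolerant",)]
    labels = pd.Series(
        (meta_idx.loc[train_ids, "group"] == "tolerant").astype(int).to_numpy(),
        index=train_ids)
    X_train = working[train_ids]
    from .signature import default_grid, _standardize_train
    Xs, _, _ = _standardize_train(X_train.to_numpy(float).T)
    grid = default_grid(Xs, labels.to_numpy(), alphas=np.asarray(config.alphas),
                        n_lambda=config.n_lambda, decades=config.lambda_decades)
    tuning, sig = tune_signature(X_train, labels, grid=grid,
                                 train_frac=config.train_frac,
                                 n_iter=config.n_iter,
                                 max_genes=config.max_genes, seed=config.seed)
    probs = predict_probability(sig, working)
    cut = select_cutoff(probs.loc[train_ids], labels,
                        spec_min=config.spec_min, sens_min=config.sens_min)
    sig.cutoff, sig.sensitivity, sig.specificity = cut.cutoff, cut.sensitivity, cut.specificity
    sig.to_json(outdir / "signature.json")
    tuning.to_json(outdir / "tuning.json")
    pred = pd.DataFrame({"sample_id": probs.index, "probability": probs.to_numpy()})
    if cut.feasible:
        pred["classified_tolerant"] = (pred["probability"] >= cut.cutoff).astype(int)
    pred.to_csv(outdir / "predictions.csv", index=False)
    stage("signature", n_genes=sig.n_genes, alpha=tuning.chosen_alpha,
          lam=tuning.chosen_lam, cutoff_feasible=cut.feasible)

    # --- evaluation -------------------------------------------------------
    auc, lo, hi = roc_auc_ci(probs.loc[train_ids].to_numpy(), labels.to_numpy())
    adj = adjusted_auc(probs.loc[train_ids], labels, design)
    stable_ids = [s for s in train_ids if meta_idx.loc[s, "group"] == "stable"
                  and s in design.index]
    assoc = probability_drug_association(probs.loc[stable_ids],
                                         design.loc[stable_ids])
    report = {
        "mode": config.mode,
        "seed": config.seed,
        "n_signature_genes": sig.n_genes,
        "auc": auc, "auc_ci": [lo, hi],
        "adjusted_auc": adj,
        "drug_association_p": {d: (None if not np.isfinite(assoc.loc[d, "p_adj"])
                                   else float(assoc.loc[d, "p_adj"]))
                               for d in assoc.index},
        "cutoff": cut.cutoff, "sensitivity": cut.sensitivity,
        "specificity": cut.specificity, "cutoff_feasible": cut.feasible,
    }
    if cut.feasible:
        stable_calls = pred.set_index("sample_id").loc[stable_ids, "classified_tolerant"]
        report["n_stable_classified_tolerant"] = int(stable_calls.sum())
        report["n_stable"] = int(len(stable_calls))
    stage("evaluation", auc=auc, adjusted_auc=adj)

    # --- optional GSA -----------------------------------------------------
    if config.gmt_path:
        sets = read_gmt(config.gmt_path)
        gsa_table = gsa_permutation_fdr(working[train_ids], labels, sets,
                                        n_perm=config.gsa_n_perm,
                                        seed=config.seed)
        gsa_table.to_csv(outdir / "gsa.tsv", sep="\t", index=False)
        report["n_gene_sets_q10"] = int((gsa_table["q"] < 0.10).sum())
        stage("gsa", n_sets=int(len(gsa_table)))

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (outdir / "log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return report
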