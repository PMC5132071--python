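"""Reading, writing and validating expression matrices, sample metadata and
drug-regimen design matrices.

Conventions
-----------
* Expression is stored genes-in-rows as a :class:`pandas.DataFrame` on the
  log2 scale (``log2(2^-dCt) = -dCt`` for qPCR data); ``NaN`` marks a missing
  measurement and the on-disk missing marker is ``"NA"``.
* Sample metadata is a DataFrame with one row per sample and columns
  ``sample_id, patient_id, group, timepoint, pred, cyc, tac, aza, mmf``.
* The drug design matrix has one row per sample and the five binary intake
  indicators in the fixed order ``(pred, cyc, tac, aza, mmf)``: prednisone,
  the two calcineurin inhibitors (ciclosporin, tacrolimus) and the two
  antiproliferatives (azathioprine, mycophenolate mofetil).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

DRUGS = ("pred", "cyc", "tac", "aza", "mmf")
#: Drug families sharing a Bonferroni correction: the calcineurin-inhibitor
#: factor has the two non-reference levels (cyc, tac), the antiproliferative
#: factor has (aza, mmf), prednisone is a 2-level factor on its own.
DRUG_FAMILIES = {"cni": ("cyc", "tac"), "ap": ("aza", "mmf"), "pred": ("pred",)}

GROUPS = ("tolerant", "stable", "chronic_rejector", "healthy")
TREATED_GROUPS = ("stable", "chronic_rejector")
UNTREATED_GROUPS = ("tolerant", "healthy")

META_COLUMNS = ("sample_id", "patient_id", "group", "timepoint") + DRUGS

MISSING = "NA"


class ParseError(ValueError):
    """A file could not be parsed into a valid container."""


class ValidationError(ValueError):
    """A container violates a structural invariant."""


class ConfigError(ValueError):
    """A configuration value is outside its documented range."""


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def validate_expression(expr: pd.DataFrame) -> None:
    """Raise :class:`ValidationError` on duplicate ids or non-finite values."""
    if expr.index.duplicated().any():
        dup = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene id(s): {dup}")
    if expr.columns.duplicated().any():
        dup = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample id(s): {dup}")
    vals = expr.to_numpy(dtype=float)
    bad = np.isinf(vals)
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise ValidationError(
            f"non-finite value at gene {expr.index[g]!r}, sample {expr.columns[s]!r}"
        )


def read_expression(path: str | Path, genes_in_rows: bool = True) -> pd.DataFrame:
    """Read a TSV/CSV expression table (first column = gene id, ``NA`` = missing)."""
    try:
        raw = pd.read_csv(
            path, sep=_sep_for(path), index_col=0, dtype=str,
            keep_default_na=False,
        )
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"{path}: {exc}") from exc
    expr = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns.astype(str),
                        dtype=float)
    for col in raw.columns:
        cells = raw[col].replace({MISSING: "nan", "": "nan"}).to_numpy()
        try:
            # numpy's parser is correctly rounded (unlike pandas' fast path),
            # keeping the write/read round trip bit-exact
            converted = cells.astype(float)
        except ValueError:
            for row, cell in zip(raw.index, cells):
                try:
                    float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric cell at row {row!r}, column {col!r}"
                    ) from None
            raise
        expr[col] = converted
    if not genes_in_rows:
        expr = expr.T
    expr.index.name = "gene_id"
    validate_expression(expr)
    return expr


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    """Write an expression matrix genes-in-rows with ``NA`` for missing."""
    validate_expression(expr)
    out = expr.copy()
    out.index.name = "gene_id"
    # %.17g keeps doubles bit-exact across a write/read round trip
    out.to_csv(path, sep=_sep_for(path), na_rep=MISSING, float_format="%.17g")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def validate_metadata(meta: pd.DataFrame) -> None:
    missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValidationError(f"metadata lacks column(s): {missing_cols}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample id(s): {dup}")
    bad_group = set(meta["group"]) - set(GROUPS)
    if bad_group:
        raise ValidationError(f"unknown group label(s): {sorted(bad_group)}")
    flags = meta[list(DRUGS)].astype(float)
    both_cni = (flags["cyc"] == 1) & (flags["tac"] == 1)
    if both_cni.any():
        sid = meta.loc[both_cni, "sample_id"].tolist()
        raise ValidationError(f"cyc and tac both 1 for sample(s): {sid}")
    both_ap = (flags["aza"] == 1) & (flags["mmf"] == 1)
    if both_ap.any():
        sid = meta.loc[both_ap, "sample_id"].tolist()
        raise ValidationError(f"aza and mmf both 1 for sample(s): {sid}")
    untreated = meta["group"].isin(UNTREATED_GROUPS)
    nonzero = (flags[untreated].fillna(1.0) != 0).any(axis=1)
    if nonzero.any():
        sid = meta.loc[untreated].loc[nonzero.to_numpy(), "sample_id"].tolist()
        raise ValidationError(
            f"tolerant/healthy sample(s) with nonzero or missing drug flags: {sid}"
        )


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, keep_default_na=False, na_values=[MISSING, ""],
                       dtype={"sample_id": str, "patient_id": str,
                              "group": str, "timepoint": str})
    validate_metadata(meta)
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    validate_metadata(meta)
    meta.to_csv(path, index=False, na_rep=MISSING)


# ---------------------------------------------------------------------------
# dCt normalization and detection filtering
# ---------------------------------------------------------------------------

def dct_normalize(ct: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    """Normalize a Ct table against a housekeeping gene.

    Returns per-sample ``-(Ct_gene - Ct_ref)``, i.e. expression on the
    ``log2(2^-dCt)`` scale; the reference row is dropped from the output.
    """
    if reference_gene not in ct.index:
        raise ValidationError(f"reference gene {reference_gene!r} not in table")
    ref = ct.loc[reference_gene]
    absent = ref.isna()
    if absent.any():
        raise ValidationError(
            "reference gene Ct missing in sample(s): "
            f"{ct.columns[absent].tolist()}"
        )
    out = -(ct.drop(index=reference_gene).sub(ref, axis=1))
    return out


def detect_from_ct(ct: pd.DataFrame, lod_cycle: float = 40.0) -> pd.DataFrame:
    """Convenience detection call for qPCR data: detected iff Ct < limit of
    detection (default cycle 40); missing Ct counts as undetected."""
    return ct.notna() & (ct < lod_cycle)


def background_filter(
    expr: pd.DataFrame,
    detected: pd.DataFrame,
    min_frac: float = 0.80,
) -> tuple[pd.DataFrame, dict]:
    """Drop genes not detected above background in at least ``min_frac`` of samples.

    ``detected`` is a boolean gene x sample matrix (platform-specific detection
    calls; see :func:`detect_from_ct` for qPCR). Returns the retained matrix and
    a report listing removed genes with their detection fractions.
    """
    if not (0 < min_frac <= 1):
        raise ConfigError(f"min_frac must be in (0, 1], got {min_frac}")
    det = detected.reindex(index=expr.index, columns=expr.columns)
    if det.isna().any().any():
        raise ValidationError("detection matrix does not cover the expression matrix")
    frac = det.mean(axis=1)
    keep = frac >= min_frac
    report = {
        "n_input": int(expr.shape[0]),
        "n_retained": int(keep.sum()),
        "min_frac": min_frac,
        "removed": {g: float(frac[g]) for g in expr.index[~keep]},
    }
    return expr.loc[keep], report


# ---------------------------------------------------------------------------
# drug design encoding
# ---------------------------------------------------------------------------

def encode_drug_design(
    meta: pd.DataFrame,
    groups: tuple[str, ...] | None = TREATED_GROUPS,
) -> tuple[pd.DataFrame, dict]:
    """Encode drug intake as a binary sample x 5 design matrix.

    Samples outside ``groups`` (default: the IS-treated stable and chronic
    rejector groups; pass ``None`` for all groups) are dropped; samples with
    any missing drug flag are excluded and listed in the report, mirroring the
    exclusion of patients with absent regimen information.
    """
    validate_metadata(meta)
    sub = meta if groups is None else meta[meta["group"].isin(groups)]
    flags = sub[list(DRUGS)].astype(float)
    incomplete = flags.isna().any(axis=1)
    excluded = sub.loc[incomplete, "sample_id"].tolist()
    kept = sub[~incomplete.to_numpy()]
    design = kept[list(DRUGS)].astype(int)
    design.index = pd.Index(kept["sample_id"], name="sample_id")
    report = {"n_samples": int(design.shape[0]), "excluded_missing_flags": excluded}
    return design, report


def save_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
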