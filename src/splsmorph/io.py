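"""Reading cohort tables and writing machine-parseable reports.

Input dialect: UTF-8 CSV with a header row; the first column is named
``subject_id``; gender is encoded as the literal strings "male"/"female".
Empty cells and "NA" are missing values and cause subject-level listwise
removal (logged with a reason, mirroring stepwise participant accounting);
any other non-numeric token is treated as corrupt data and raises.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import MorphometryTable, PhenotypeTable, GENDERS
from .validation import EvaluationReport

logger = logging.getLogger(__name__)

MISSING_TOKENS = {"", "NA"}


class ParseError(ValueError):
    """A cell could not be parsed; the message names row and column."""


def _parse_numeric_frame(df: pd.DataFrame, path) -> pd.DataFrame:
    """Parse string cells to floats; missing tokens -> NaN, junk -> ParseError."""
    out = {}
    for col in df.columns:
        vals = df[col].str.strip()
        missing = vals.isin(MISSING_TOKENS)
        parsed = pd.to_numeric(vals.where(~missing), errors="coerce")
        bad = parsed.isna() & ~missing
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: cannot parse cell at row {row + 2} (subject "
                f"{df.index[row]!r}), column {col!r}: {vals.iloc[row]!r}"
            )
        out[col] = parsed
    return pd.DataFrame(out, index=df.index)


def _read_indexed_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected subject_id plus data columns")
    if df.columns[0] != "subject_id":
        raise ValueError(
            f"{path}: first column must be named 'subject_id', "
            f"got {df.columns[0]!r}"
        )
    ids = df["subject_id"].str.strip()
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate subject ids {sorted(set(dup))}")
    df = df.drop(columns="subject_id")
    df.index = ids
    return df


def load_dataset(
    feature_path, phenotype_path, measure: str = "thickness"
) -> tuple[MorphometryTable, PhenotypeTable]:
    """Read, validate and row-align the feature and phenotype tables.

    Subjects outside the ID intersection, or with any missing feature or
    phenotype value, are removed listwise; every exclusion is logged with its
    reason.  Returns tables restricted to the surviving subjects, row-aligned
    by ID (feature-table order).
    """
    feat_raw = _read_indexed_csv(feature_path)
    feat = _parse_numeric_frame(feat_raw, feature_path)

    phen_raw = _read_indexed_csv(phenotype_path)
    for col in ("teq", "age", "gender"):
        if col not in phen_raw.columns:
            raise ValueError(f"{phenotype_path}: missing required column {col!r}")
    phen_num = _parse_numeric_frame(phen_raw[["teq", "age"]], phenotype_path)
    gender = phen_raw["gender"].str.strip()
    bad_gender = ~(gender.isin(GENDERS) | gender.isin(MISSING_TOKENS))
    if bad_gender.any():
        row = int(np.flatnonzero(bad_gender.to_numpy())[0])
        raise ParseError(
            f"{phenotype_path}: invalid gender at row {row + 2} "
            f"(subject {gender.index[row]!r}): {gender.iloc[row]!r}"
        )

    feat_ok = ~feat.isna().any(axis=1)
    for sid in feat.index[~feat_ok]:
        logger.info("excluding %s: missing feature value(s)", sid)
    phen_ok = ~phen_num.isna().any(axis=1) & gender.isin(GENDERS)
    for sid in phen_num.index[~phen_ok]:
        logger.info("excluding %s: missing phenotype value(s)", sid)

    feat_ids = [s for s, ok in zip(feat.index, feat_ok) if ok]
    phen_ids = {s for s, ok in zip(phen_num.index, phen_ok) if ok}
    common = [s for s in feat_ids if s in phen_ids]
    dropped_feat = set(feat.index) - set(common)
    dropped_phen = set(phen_num.index) - set(common)
    for sid in sorted(dropped_feat | dropped_phen):
        if sid not in dropped_feat or sid not in dropped_phen:
            logger.info("excluding %s: not present in both tables", sid)
    if not common:
        raise ValueError("no subject present and complete in both tables")
    logger.info(
        "loaded %d subjects (%d excluded)", len(common),
        len(set(feat.index) | set(phen_num.index)) - len(common),
    )

    morph = MorphometryTable(
        measure, common, list(feat.columns), feat.loc[common].to_numpy()
    )
    phen = PhenotypeTable(
        common,
        phen_num.loc[common, "teq"].to_numpy(),
        phen_num.loc[common, "age"].to_numpy(),
        gender.loc[common].tolist(),
    )
    return morph, phen


# ---------------------------------------------------------------------------
# report serialization
# ---------------------------------------------------------------------------

def _fmt(v) -> str:
    if isinstance(v, float):
        return repr(v)  # repr round-trips float64 exactly
    return str(v)


def write_report(report: EvaluationReport, path, subject_ids=None) -> Path:
    """Write a flat key-value text report plus a per-subject prediction CSV.

    The CSV (``<stem>_predictions.csv`` beside the report) holds the data
    behind an observed-vs-predicted scatter: one row per subject with the
    cross-validated prediction, the tuned keepX and the retained feature
    count of its fold.  Raises on an unpopulated report rather than writing
    an empty file.
    """
    if report is None or report.predictions is None or report.n == 0:
        raise ValueError("refusing to write an empty report")
    path = Path(path)
    cvp = report.predictions
    lines = [
        f"n = {report.n}",
        f"y_mean = {_fmt(report.y_mean)}",
        f"rmsep = {_fmt(report.rmsep)}",
        f"q2 = {_fmt(report.q2)}",
        f"r2 = {_fmt(report.r2)}",
        f"chosen_components = {report.selection.chosen}",
        "component_candidates = "
        + ",".join(str(k) for k in report.selection.candidates),
        "component_bic = " + ",".join(_fmt(float(b)) for b in report.selection.bic),
        "component_rss = " + ",".join(_fmt(float(r)) for r in report.selection.rss),
    ]
    if report.permutation_p is not None:
        lines.append(f"permutation_p = {_fmt(report.permutation_p)}")
        lines.append(f"n_permutations = {report.n_permutations}")
    lines.append(
        "note = component selection and reported metrics share the same "
        "outer-CV residuals (optimistic by construction)"
    )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:04d}" for i in range(report.n)]
    pred = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "y_obs": cvp.y_obs,
            "y_pred": cvp.y_pred,
            "keepx": cvp.keepx,
            "n_retained": cvp.n_retained,
            "fallback": cvp.fallback.astype(int),
        }
    )
    pred_path = path.with_name(path.stem + "_predictions.csv")
    pred.to_csv(pred_path, index=False, float_format=None)
    return path


def _parse_value(raw: str):
    raw = raw.strip()
    if "," in raw:
        try:
            return [float(tok) for tok in raw.split(",")]
        except ValueError:
            return raw
    for caster in (int, float):
        try:
            v = caster(raw)
            if isinstance(v, float) and not math.isfinite(v) and raw not in (
                "inf", "-inf", "nan",
            ):
                return raw
            return v
        except ValueError:
            continue
    return raw


def read_report(path) -> dict:
    """Parse a key-value report back into a dict (exact numeric round-trip).

    The companion prediction CSV, when present, is attached under the key
    ``predictions`` as a DataFrame.
    """
    path = Path(path)
    out: dict = {}
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip() or "=" not in line:
            continue
        key, raw = line.split("=", 1)
        out[key.strip()] = _parse_value(raw)
    pred_path = path.with_name(path.stem + "_predictions.csv")
    if pred_path.exists():
        out["predictions"] = pd.read_csv(pred_path)
    return out
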