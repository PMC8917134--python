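"""Readers and writers for the package's plain-text table formats.

Expression: TSV, first column ``gene_id``, one column per sample.
Survival:   TSV with ``sample_id``, ``time`` (days), ``event`` (0/1) and an
            optional ``endpoint`` label; rows with time <= 0 are dropped on
            read with a warning (zero-follow-up exclusion).
Clinical:   TSV with ``sample_id``, ``age``, ``gender``, ``grade``, ``stage``.
Pair matrix: TSV with ``pair_id`` ("GENEA|GENEB") then per-sample 0/1.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .pairs import PairMatrix, _validate_expression

logger = logging.getLogger(__name__)

SURVIVAL_COLUMNS = ("sample_id", "time", "event")
CLINICAL_COLUMNS = ("sample_id", "age", "gender", "grade", "stage")


def _require_columns(df: pd.DataFrame, required, what: str, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} file {path} missing required columns: {missing}")


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise FormatError(f"expression file {path} must start with a 'gene_id' column")
    df = df.set_index("gene_id")
    df.index.name = None
    _validate_expression(df)
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    out = expr.copy()
    out.insert(0, "gene_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, SURVIVAL_COLUMNS, "survival", path)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample IDs in survival file {path}: {dup}")
    if not df["event"].isin([0, 1]).all():
        raise FormatError(f"survival file {path}: 'event' must be 0/1")
    bad = df["time"] <= 0
    if bad.any():
        warnings.warn(
            f"dropped {int(bad.sum())} sample(s) with follow-up time <= 0 from {path}",
            stacklevel=2,
        )
        logger.info("excluded %d zero-follow-up samples from %s", int(bad.sum()), path)
        df = df.loc[~bad].reset_index(drop=True)
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    return df


def read_clinical(path, required=CLINICAL_COLUMNS) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, required, "clinical", path)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample IDs in clinical file {path}: {dup}")
    return df


def write_cohort(cohort, out_dir) -> dict[str, Path]:
    """Write a simulated cohort's tables (plus the planted truth) to a
    directory and return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "survival": out / "survival.tsv",
        "clinical": out / "clinical.tsv",
        "truth": out / "truth.json",
    }
    write_expression(cohort.expression, paths["expression"])
    cohort.survival.to_csv(paths["survival"], sep="\t", index=False)
    cohort.clinical.to_csv(paths["clinical"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(
            [{"gene_a": a, "gene_b": b, "beta": beta} for a, b, beta in cohort.truth],
            fh,
            indent=2,
        )
    return paths


def write_pair_matrix(pm: PairMatrix, path) -> None:
    out = pm.indicators.copy()
    out.insert(0, "pair_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_pair_matrix(path) -> PairMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "pair_id":
        raise FormatError(f"pair matrix file {path} must start with a 'pair_id' column")
    df = df.set_index("pair_id")
    df.index.name = None
    vals = df.to_numpy()
    if not np.isin(vals, [0, 1]).all():
        raise FormatError(f"pair matrix file {path} contains non-binary values")
    pairs = []
    for pid in df.index:
        parts = pid.split("|")
        if len(parts) != 2:
            raise FormatError(f"malformed pair_id {pid!r} in {path}")
        pairs.append((parts[0], parts[1]))
    return PairMatrix(indicators=df.astype(np.uint8), pairs=pairs)
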