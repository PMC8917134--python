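"""Within-sample binary gene-pair indicators.

The feature construction at the heart of the package: for an ordered pair
(a, b) and a sample s, the indicator is 1 when gene a is expressed strictly
above gene b in that sample and 0 otherwise (ties score 0).  Because the
indicator depends only on the within-sample ordering of two genes, it is
invariant to any strictly increasing per-sample transformation of the
expression values — the property that makes pair signatures portable across
platforms and batches.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError

logger = logging.getLogger(__name__)

#: warn when the dense indicator matrix would exceed this many cells
SIZE_GUARD_CELLS = 10**9


def pair_id(gene_a: str, gene_b: str) -> str:
    return f"{gene_a}|{gene_b}"


@dataclass
class PairMatrix:
    """Binary pair-by-sample indicator matrix.

    ``indicators`` is a pandas DataFrame indexed by pair id ("GENEA|GENEB"),
    with one column per sample and uint8 values in {0, 1}.  ``pairs`` is the
    parallel list of (gene_a, gene_b) tuples in row order.
    """

    indicators: pd.DataFrame
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.indicators):
            raise ValueError("pairs list and indicator rows disagree in length")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.indicators.columns)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def subset(self, pair_ids) -> "PairMatrix":
        """Restrict to the given pair ids, preserving the requested order."""
        missing = [p for p in pair_ids if p not in self.indicators.index]
        if missing:
            raise KeyError(f"pairs not present in matrix: {missing}")
        ind = self.indicators.loc[list(pair_ids)]
        lut = {pair_id(a, b): (a, b) for a, b in self.pairs}
        return PairMatrix(indicators=ind, pairs=[lut[p] for p in pair_ids])


def _validate_expression(expr: pd.DataFrame) -> None:
    if expr.index.has_duplicates:
        dup = expr.index[expr.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene IDs in expression matrix: {dup}")
    if expr.columns.has_duplicates:
        dup = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample IDs in expression matrix: {dup}")
    vals = expr.to_numpy()
    if np.isnan(vals).any():
        raise FormatError("expression matrix contains missing values")
    if (vals < 0).any():
        bad = expr.index[(vals < 0).any(axis=1)].tolist()
        raise FormatError(f"negative expression values for genes: {bad[:5]}")


def pair_indicators(expr: pd.DataFrame, pairs: list[tuple[str, str]]) -> PairMatrix:
    """Indicator matrix for an explicit list of ordered gene pairs.

    Used when applying a frozen signature: only the signature's own pairs are
    materialised, never the full combinatorial set.
    """
    _validate_expression(expr)
    missing = sorted({g for p in pairs for g in p} - set(expr.index))
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    a_idx = expr.index.get_indexer([a for a, _ in pairs])
    b_idx = expr.index.get_indexer([b for _, b in pairs])
    vals = expr.to_numpy(dtype=float)
    ind = (vals[a_idx] > vals[b_idx]).astype(np.uint8)
    df = pd.DataFrame(ind, index=[pair_id(a, b) for a, b in pairs], columns=expr.columns)
    return PairMatrix(indicators=df, pairs=list(pairs))


def build_pair_matrix(expr: pd.DataFrame, genes: list[str]) -> PairMatrix:
    """All unordered pair indicators over a candidate gene list.

    Pairs are oriented (a, b) with a preceding b in the supplied list, one
    row per unordered pair: m usable genes yield m*(m-1)/2 rows.  Genes
    absent from the matrix are dropped with a warning; duplicates in the
    list are an error.
    """
    _validate_expression(expr)
    if len(set(genes)) != len(genes):
        dup = sorted({g for g in genes if genes.count(g) > 1})
        raise FormatError(f"duplicate gene IDs in candidate list: {dup}")
    usable = [g for g in genes if g in expr.index]
    dropped = [g for g in genes if g not in expr.index]
    if dropped:
        warnings.warn(
            f"{len(dropped)} of {len(genes)} candidate genes not detected in the "
            f"expression matrix and dropped: {dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
    m = len(usable)
    if m < 2:
        raise FormatError(f"need at least 2 usable genes to form pairs, got {m}")
    n_pairs = m * (m - 1) // 2
    if n_pairs * expr.shape[1] > SIZE_GUARD_CELLS:
        warnings.warn(
            f"dense pair matrix has {n_pairs} pairs x {expr.shape[1]} samples; "
            "consider reducing the candidate list",
            stacklevel=2,
        )
    X = expr.loc[usable].to_numpy(dtype=float)
    ia, ib = np.triu_indices(m, k=1)
    ind = (X[ia] > X[ib]).astype(np.uint8)
    pairs = [(usable[i], usable[j]) for i, j in zip(ia, ib)]
    df = pd.DataFrame(ind, index=[pair_id(a, b) for a, b in pairs], columns=expr.columns)
    logger.info("built %d pair indicators from %d genes x %d samples", n_pairs, m, expr.shape[1])
    return PairMatrix(indicators=df, pairs=pairs)


def pair_frequency(pm: PairMatrix) -> pd.DataFrame:
    """Fraction of samples scoring 1 for each pair."""
    if pm.n_pairs == 0:
        raise FormatError("empty pair matrix")
    frac = pm.indicators.mean(axis=1)
    return pd.DataFrame(
        {
            "gene_a": [a for a, _ in pm.pairs],
            "gene_b": [b for _, b in pm.pairs],
            "fraction_ones": frac.to_numpy(),
        },
        index=pm.indicators.index,
    )


def filter_low_variation(pm: PairMatrix, max_constancy: float = 0.80) -> PairMatrix:
    """Drop near-constant pairs.

    A pair is removed iff its fraction of ones f is strictly above
    ``max_constancy`` or strictly below ``1 - max_constancy``; pairs exactly
    on either boundary are retained.  The comparison is done on integer
    counts to avoid float boundary artefacts.
    """
    if not (0.5 <= max_constancy < 1.0):
        raise ValueError(f"max_constancy must be in [0.5, 1), got {max_constancy}")
    if pm.n_pairs == 0:
        raise FormatError("empty pair matrix")
    n = len(pm.sample_ids)
    ones = pm.indicators.sum(axis=1).to_numpy(dtype=float)
    hi = max_constancy * n + 1e-9
    lo = (1.0 - max_constancy) * n - 1e-9
    keep = (ones <= hi) & (ones >= lo)
    removed = int((~keep).sum())
    logger.info("low-variation filter removed %d of %d pairs", removed, pm.n_pairs)
    ind = pm.indicators.loc[keep]
    pairs = [p for p, k in zip(pm.pairs, keep) if k]
    return PairMatrix(indicators=ind, pairs=pairs)
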