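"""Expression preprocessing and homolog-hit filtering.

Covers the arithmetic steps applied to expression data before network
construction — the expression-potential ratio used by condition-search
platforms, per-gene min–max rescaling of TPM profiles, and log2 fold
change — plus best-hit filtering of tabular (BLAST outfmt-6 style)
alignment results used to map stress/memory genes onto rice homologs.
"""

from __future__ import annotations

import math
from typing import Mapping, Union

import numpy as np
import pandas as pd

BLAST6_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "e_value", "bit_score",
]


def expression_potential_ratio(
    mean_value: float,
    signal_background: float,
    expression_potential: float,
    epsilon: float = 1.0,
) -> float:
    """Ratio of expression potential.

    ``(mean - background) / (potential - background + epsilon)``; the
    small epsilon (default 1) keeps the denominator positive when the
    expression potential and signal background (almost) coincide.
    """
    if signal_background < 0:
        raise ValueError("signal_background must be >= 0")
    if expression_potential < signal_background:
        raise ValueError(
            "expression_potential must be >= signal_background "
            f"({expression_potential} < {signal_background})"
        )
    return (mean_value - signal_background) / (
        expression_potential - signal_background + epsilon
    )


def minmax_normalize(row: np.ndarray) -> np.ndarray:
    """Rescale a profile to [0, 1]; constant profiles map to all zeros."""
    row = np.asarray(row, dtype=float)
    if row.size < 1:
        raise ValueError("row must have at least one value")
    lo, hi = row.min(), row.max()
    if hi == lo:
        return np.zeros_like(row)
    return (row - lo) / (hi - lo)


def minmax_normalize_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise min–max scaling of a genes x samples matrix."""
    scaled = matrix.apply(
        lambda r: pd.Series(minmax_normalize(r.to_numpy()), index=matrix.columns),
        axis=1,
    )
    scaled.index = matrix.index
    return scaled


def log2_fold_change(
    treatment: float, control: float, pseudocount: float = 1.0
) -> float:
    """log2((treatment + c) / (control + c)) with pseudocount c."""
    if treatment < 0 or control < 0:
        raise ValueError("expression values must be non-negative")
    return math.log2((treatment + pseudocount) / (control + pseudocount))


def filter_homologs(
    rows: pd.DataFrame,
    query_lengths: Union[Mapping[str, int], pd.Series, None] = None,
    e_max: float = 1e-5,
    min_coverage: float = 50.0,
    min_identity: float = 35.0,
) -> pd.DataFrame:
    """Best homolog per query after threshold filtering.

    Rows are kept when e-value < ``e_max`` AND query coverage
    (100 * alignment_length / query_length) > ``min_coverage`` AND
    percent identity > ``min_identity`` — all strict, matching the
    "less than"/"more than" wording of the cutoffs.  Per query the
    minimal-e-value row is selected (ties: max bit score, then
    lexicographic subject id).
    """
    df = rows.copy()
    if "query_length" not in df.columns:
        if query_lengths is None:
            raise ValueError("query_lengths required when rows lack query_length")
        lengths = pd.Series(dict(query_lengths))
        df["query_length"] = df["query_id"].map(lengths)
        missing = df.loc[df["query_length"].isna(), "query_id"].unique().tolist()
        if missing:
            raise ValueError(f"missing query_length for queries: {missing}")
    coverage = 100.0 * df["alignment_length"] / df["query_length"]
    kept = df[
        (df["e_value"] < e_max)
        & (coverage > min_coverage)
        & (df["percent_identity"] > min_identity)
    ].copy()
    kept = kept.sort_values(
        ["query_id", "e_value", "bit_score", "subject_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    return kept.groupby("query_id", sort=True).head(1).reset_index(drop=True)


def read_blast_tsv(path) -> pd.DataFrame:
    """Read a 12-column tabular alignment file (outfmt-6 dialect)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != len(BLAST6_COLUMNS):
        raise ValueError(
            f"expected {len(BLAST6_COLUMNS)} columns, found {df.shape[1]}"
        )
    df.columns = BLAST6_COLUMNS
    return df


def read_expression_tsv(path) -> pd.DataFrame:
    """Genes x samples TSV with gene ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes}")
    if df.columns.has_duplicates:
        raise ValueError("duplicate sample ids")
    return df


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6f")
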