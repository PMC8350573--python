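"""Signed dual-method co-expression edge calling and cluster detection.

For every unordered gene pair both Pearson and Spearman correlations
are computed with two-sided t-approximation p-values.  An edge is
retained when *both* methods pass the magnitude cutoff (default |r| >=
0.8) and significance cutoff (default p < 0.01) with agreeing signs;
an OR mode (either method suffices) is available.  Retained edges form
a symmetric {-1, 0, +1} matrix used for correlogram ordering (first
principal component of the correlation matrix) and for average-linkage
cluster detection with an antagonism flag for mutually negatively
correlated clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

EDGE_COLUMNS = [
    "gene_a", "gene_b", "r_pearson", "p_pearson", "r_spearman", "p_spearman",
    "sign",
]


@dataclass(frozen=True)
class BinarySignedMatrix:
    """Symmetric gene x gene matrix of {-1, 0, +1} calls."""

    genes: Tuple[str, ...]
    matrix: pd.DataFrame
    r_cut: float
    p_cut: float

    def __post_init__(self):
        values = self.matrix.to_numpy()
        if not np.array_equal(values, values.T):
            raise ValueError("binary matrix must be symmetric")
        if np.any(np.diag(values) != 0):
            raise ValueError("binary matrix must have a zero diagonal")

    def nonzero_count(self) -> int:
        """Number of called edges (each unordered pair counted once)."""
        return int(np.count_nonzero(np.triu(self.matrix.to_numpy(), k=1)))


def zero_variance_genes(matrix: pd.DataFrame) -> List[str]:
    values = matrix.to_numpy(dtype=float)
    flat = values.std(axis=1) == 0
    return [g for g, z in zip(matrix.index, flat) if z]


def _t_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values from the t transform of a correlation matrix."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return p


def pairwise_correlations(matrix: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Pearson and Spearman correlations with p-values.

    Genes are rows, samples columns (>= 3 required).  Zero-variance
    genes have no defined correlation: their pairs are excluded and the
    genes logged.  Pairs are stored once with gene_a < gene_b.
    """
    n = matrix.shape[1]
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    flagged = zero_variance_genes(matrix)
    if flagged:
        logger.warning("excluding zero-variance genes: %s", flagged)
    kept = matrix.drop(index=flagged)
    genes = sorted(kept.index.astype(str))
    if len(genes) != kept.shape[0]:
        raise ValueError("duplicate gene ids in expression matrix")
    X = kept.loc[genes].to_numpy(dtype=float)
    if len(genes) < 2:
        return pd.DataFrame(columns=EDGE_COLUMNS)

    rp = np.clip(np.corrcoef(X), -1.0, 1.0)
    pp = _t_pvalues(rp, n)
    ranks = stats.rankdata(X, axis=1, method="average")
    rs = np.clip(np.corrcoef(ranks), -1.0, 1.0)
    ps = _t_pvalues(rs, n)

    iu, ju = np.triu_indices(len(genes), k=1)
    gene_arr = np.asarray(genes)
    edges = pd.DataFrame({
        "gene_a": gene_arr[iu],
        "gene_b": gene_arr[ju],
        "r_pearson": rp[iu, ju],
        "p_pearson": pp[iu, ju],
        "r_spearman": rs[iu, ju],
        "p_spearman": ps[iu, ju],
    })
    edges["sign"] = np.sign(edges["r_pearson"]).astype(int)
    return edges


def call_edges(
    edges: pd.DataFrame,
    r_cut: float = 0.8,
    p_cut: float = 0.01,
    mode: str = "and",
) -> pd.Series:
    """Per-pair call in {-1, 0, +1} under the chosen combination rule."""
    if mode not in {"and", "or"}:
        raise ValueError(f"mode must be 'and' or 'or', got {mode!r}")
    sp = np.sign(edges["r_pearson"].to_numpy())
    ss = np.sign(edges["r_spearman"].to_numpy())
    pass_p = (np.abs(edges["r_pearson"]) >= r_cut) & (edges["p_pearson"] < p_cut)
    pass_s = (np.abs(edges["r_spearman"]) >= r_cut) & (edges["p_spearman"] < p_cut)
    if mode == "and":
        call = np.where(pass_p & pass_s & (sp == ss), sp, 0)
    else:
        call = np.zeros(len(edges))
        both = pass_p & pass_s
        call = np.where(both & (sp == ss), sp, call)
        call = np.where(pass_p & ~pass_s, sp, call)
        call = np.where(pass_s & ~pass_p, ss, call)
    return pd.Series(call.astype(int), index=edges.index, name="call")


def threshold_edges(
    edges: pd.DataFrame,
    r_cut: float = 0.8,
    p_cut: float = 0.01,
    mode: str = "and",
    genes: Sequence[str] | None = None,
) -> BinarySignedMatrix:
    """Build the symmetric signed call matrix from correlation edges."""
    calls = call_edges(edges, r_cut=r_cut, p_cut=p_cut, mode=mode)
    if genes is None:
        genes = sorted(set(edges["gene_a"]) | set(edges["gene_b"]))
    genes = tuple(str(g) for g in genes)
    index = {g: i for i, g in enumerate(genes)}
    values = np.zeros((len(genes), len(genes)), dtype=int)
    for (a, b), call in zip(
        zip(edges["gene_a"], edges["gene_b"]), calls.to_numpy()
    ):
        if call and a in index and b in index:
            i, j = index[a], index[b]
            values[i, j] = values[j, i] = call
    frame = pd.DataFrame(values, index=genes, columns=genes)
    return BinarySignedMatrix(genes=genes, matrix=frame, r_cut=r_cut, p_cut=p_cut)


def correlation_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Square Pearson correlation matrix of a genes x samples matrix."""
    values = np.corrcoef(matrix.to_numpy(dtype=float))
    values = np.nan_to_num(np.clip(values, -1.0, 1.0))
    return pd.DataFrame(values, index=matrix.index, columns=matrix.index)


def order_by_first_pc(matrix: pd.DataFrame) -> List[str]:
    """Order genes by loading on the first PC of the correlation matrix.

    Accepts either a square correlation matrix (index == columns) or a
    genes x samples expression matrix.  Orientation is fixed so the
    first input gene has a non-negative loading; genes are returned in
    descending loading order (stable).
    """
    if matrix.shape[0] < 1:
        return []
    square = matrix.shape[0] == matrix.shape[1] and list(matrix.index) == list(
        matrix.columns
    )
    corr = matrix if square else correlation_matrix(matrix)
    genes = [str(g) for g in corr.index]
    if len(genes) == 1:
        return genes
    values = corr.to_numpy(dtype=float)
    if not np.any(values):
        logger.warning("degenerate correlation matrix: keeping input order")
        return genes
    eigvals, eigvecs = np.linalg.eigh((values + values.T) / 2.0)
    loading = eigvecs[:, -1]
    first_nonzero = np.flatnonzero(loading)
    if first_nonzero.size and loading[first_nonzero[0]] < 0:
        loading = -loading
    order = np.argsort(-loading, kind="stable")
    return [genes[i] for i in order]


def detect_sign_clusters(
    binary: BinarySignedMatrix,
    corr: pd.DataFrame,
    k: int = 2,
) -> Tuple[Dict[str, int], bool]:
    """Average-linkage clusters of connected genes plus antagonism flag.

    Clustering uses distance 1 - r (Pearson) restricted to genes with at
    least one nonzero call; the antagonism flag is true when more than
    half of the nonzero inter-cluster calls are negative.  An all-zero
    matrix yields no clusters.
    """
    values = binary.matrix.to_numpy()
    active = [g for g, row in zip(binary.genes, values) if np.any(row)]
    if not active:
        return {}, False
    if len(active) <= k:
        labels = {g: i + 1 for i, g in enumerate(active)}
    else:
        sub = corr.loc[active, active].to_numpy(dtype=float)
        dist = 1.0 - (sub + sub.T) / 2.0
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(np.clip(dist, 0.0, None), checks=False)
        assignment = fcluster(linkage(condensed, method="average"), k,
                              criterion="maxclust")
        labels = {g: int(c) for g, c in zip(active, assignment)}
    frame = binary.matrix.loc[active, active]
    inter_neg = inter_nonzero = 0
    for i, a in enumerate(active):
        for b in active[i + 1:]:
            if labels[a] != labels[b] and frame.at[a, b] != 0:
                inter_nonzero += 1
                inter_neg += frame.at[a, b] < 0
    antagonism = inter_nonzero > 0 and inter_neg / inter_nonzero > 0.5
    return labels, antagonism


def write_edges_tsv(edges: pd.DataFrame, path, calls: pd.Series | None = None) -> None:
    out = edges.copy()
    if calls is not None:
        out["call"] = calls
    out.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_binary_matrix_tsv(binary: BinarySignedMatrix, path) -> None:
    binary.matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_binary_matrix_tsv(path, r_cut: float = 0.8, p_cut: float = 0.01
                           ) -> BinarySignedMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.columns = frame.columns.astype(str)
    frame.index = frame.index.astype(str)
    return BinarySignedMatrix(
        genes=tuple(frame.index), matrix=frame.astype(int),
        r_cut=r_cut, p_cut=p_cut,
    )
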