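"""Dual-method co-expression edges, thresholding, ordering, clusters."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prionome.coexpression import (
    BinarySignedMatrix,
    call_edges,
    correlation_matrix,
    detect_sign_clusters,
    order_by_first_pc,
    pairwise_correlations,
    threshold_edges,
)
from prionome.synthetic_data import gen_diurnal_matrix, two_antagonistic_modules


def textbook_pearson(x, y):
    """Plain-sum Pearson r with two-sided t p-value (independent oracle)."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, 2 * stats.t.sf(abs(t), n - 2)


def average_ranks(x):
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def edges_frame(rows):
    return pd.DataFrame(rows, columns=[
        "gene_a", "gene_b", "r_pearson", "p_pearson", "r_spearman",
        "p_spearman",
    ])


class TestPairwiseCorrelations:
    def test_identical_profiles(self):
        x = np.sin(np.linspace(0, 4 * np.pi, 48))
        matrix = pd.DataFrame([x, x], index=["a", "b"])
        edges = pairwise_correlations(matrix)
        row = edges.iloc[0]
        assert row.r_pearson == pytest.approx(1.0)
        assert row.r_spearman == pytest.approx(1.0)
        assert row.p_pearson == 0.0

    def test_anticorrelated_profiles(self):
        x = np.sin(np.linspace(0, 4 * np.pi, 48))
        matrix = pd.DataFrame([x, -x], index=["a", "b"])
        row = pairwise_correlations(matrix).iloc[0]
        assert row.r_pearson == pytest.approx(-1.0)
        assert row.r_spearman == pytest.approx(-1.0)
        assert row.sign == -1

    def test_matches_textbook_double_loop(self):
        rng = np.random.default_rng(123)
        matrix = pd.DataFrame(
            rng.normal(size=(20, 48)),
            index=[f"g{i:02d}" for i in range(20)],
        )
        edges = pairwise_correlations(matrix)
        assert len(edges) == 20 * 19 // 2
        lookup = {(r.gene_a, r.gene_b): r for r in edges.itertuples(index=False)}
        genes = sorted(matrix.index)
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                x = list(matrix.loc[a])
                y = list(matrix.loc[b])
                rp, pp = textbook_pearson(x, y)
                rs, ps = textbook_pearson(average_ranks(x), average_ranks(y))
                row = lookup[(a, b)]
                assert abs(row.r_pearson - rp) < 1e-10
                assert abs(row.p_pearson - pp) < 1e-10
                assert abs(row.r_spearman - rs) < 1e-10
                assert abs(row.p_spearman - ps) < 1e-10

    def test_zero_variance_gene_excluded(self, caplog):
        matrix = pd.DataFrame(
            [[1, 2, 3, 4], [5, 5, 5, 5], [2, 1, 4, 3]],
            index=["a", "flat", "b"],
        )
        with caplog.at_level("WARNING"):
            edges = pairwise_correlations(matrix)
        touched = set(edges["gene_a"]) | set(edges["gene_b"])
        assert "flat" not in touched
        assert "flat" in caplog.text

    def test_requires_three_samples(self):
        with pytest.raises(ValueError, match="samples"):
            pairwise_correlations(pd.DataFrame([[1, 2], [2, 1]]))


class TestThresholdEdges:
    def test_below_magnitude_cutoff_is_zero(self):
        edges = edges_frame([("a", "b", 0.79, 1e-6, 0.95, 1e-6)])
        assert call_edges(edges).iloc[0] == 0

    def test_strong_negative_pair_called(self):
        edges = edges_frame([("a", "b", -0.9, 1e-6, -0.88, 1e-6)])
        assert call_edges(edges).iloc[0] == -1

    def test_disagreeing_signs_dropped(self):
        edges = edges_frame([("a", "b", 0.9, 1e-6, -0.85, 1e-6)])
        assert call_edges(edges).iloc[0] == 0

    def test_or_mode_accepts_single_method(self):
        edges = edges_frame([("a", "b", 0.9, 1e-6, 0.5, 0.2)])
        assert call_edges(edges, mode="and").iloc[0] == 0
        assert call_edges(edges, mode="or").iloc[0] == 1

    def test_tightening_cuts_is_monotone(self, rng):
        n = 200
        edges = edges_frame([
            (f"a{i}", f"b{i}",
             rng.uniform(-1, 1), rng.uniform(0, 0.05),
             rng.uniform(-1, 1), rng.uniform(0, 0.05))
            for i in range(n)
        ])
        loose = set(np.flatnonzero(call_edges(edges, r_cut=0.7, p_cut=0.02)))
        tight_r = set(np.flatnonzero(call_edges(edges, r_cut=0.9, p_cut=0.02)))
        tight_p = set(np.flatnonzero(call_edges(edges, r_cut=0.7, p_cut=0.005)))
        assert tight_r <= loose and tight_p <= loose

    def test_matrix_symmetric_zero_diagonal(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(10, 20)),
                              index=[f"g{i}" for i in range(10)])
        binary = threshold_edges(pairwise_correlations(matrix))
        values = binary.matrix.to_numpy()
        assert np.array_equal(values, values.T)
        assert not np.any(np.diag(values))

    def test_asymmetric_matrix_rejected(self):
        frame = pd.DataFrame([[0, 1], [0, 0]], index=["a", "b"],
                             columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            BinarySignedMatrix(("a", "b"), frame, 0.8, 0.01)


class TestOrdering:
    def test_single_gene(self):
        matrix = pd.DataFrame([[1.0]], index=["g"], columns=["g"])
        assert order_by_first_pc(matrix) == ["g"]

    def test_antagonistic_blocks_are_contiguous(self):
        modules, noise_sd = two_antagonistic_modules(8, 8)
        matrix, truth = gen_diurnal_matrix(
            16, modules=modules, noise_sd=noise_sd, seed=4)
        order = order_by_first_pc(correlation_matrix(matrix))
        membership = dict(zip(truth["gene_id"], truth["module"]))
        labels = [membership[g] for g in order]
        assert labels == sorted(labels) or labels == sorted(labels, reverse=True)

    def test_orientation_rule(self):
        modules, noise_sd = two_antagonistic_modules(4, 4)
        matrix, _ = gen_diurnal_matrix(8, modules=modules, noise_sd=noise_sd,
                                       seed=9)
        corr = correlation_matrix(matrix)
        order = order_by_first_pc(corr)
        # first input gene must have non-negative loading: it sorts into
        # the top half of the ordering
        assert order.index(str(matrix.index[0])) < len(order) // 2 + 1

    def test_degenerate_matrix_keeps_input_order(self):
        frame = pd.DataFrame(np.zeros((3, 3)), index=list("abc"),
                             columns=list("abc"))
        assert order_by_first_pc(frame) == ["a", "b", "c"]


class TestSignClusters:
    def _planted(self, seed=0):
        modules, noise_sd = two_antagonistic_modules(10, 10)
        matrix, truth = gen_diurnal_matrix(
            26, modules=modules, noise_sd=noise_sd, seed=seed)
        edges = pairwise_correlations(matrix)
        binary = threshold_edges(edges, genes=sorted(matrix.index))
        return matrix, truth, binary

    def test_recovers_antagonistic_modules(self):
        matrix, truth, binary = self._planted(seed=1)
        labels, antagonism = detect_sign_clusters(
            binary, correlation_matrix(matrix))
        assert antagonism
        membership = dict(zip(truth["gene_id"], truth["module"]))
        clusters = {}
        for gene, label in labels.items():
            clusters.setdefault(label, set()).add(membership[gene])
        assert len(clusters) == 2
        assert all(len(mods) == 1 for mods in clusters.values())

    def test_single_positive_module_not_antagonistic(self):
        modules, noise_sd = two_antagonistic_modules(8, 8, cross_r=0.95)
        matrix, _ = gen_diurnal_matrix(16, modules=modules, noise_sd=noise_sd,
                                       seed=2)
        binary = threshold_edges(pairwise_correlations(matrix),
                                 genes=sorted(matrix.index))
        _, antagonism = detect_sign_clusters(binary, correlation_matrix(matrix))
        assert not antagonism

    def test_all_zero_matrix_yields_no_clusters(self):
        genes = ("a", "b", "c")
        frame = pd.DataFrame(np.zeros((3, 3), dtype=int), index=genes,
                             columns=genes)
        binary = BinarySignedMatrix(genes, frame, 0.8, 0.01)
        corr = pd.DataFrame(np.eye(3), index=genes, columns=genes)
        assert detect_sign_clusters(binary, corr) == ({}, False)
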