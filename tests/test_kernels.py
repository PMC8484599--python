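"""Microbial kernels against brute-force and reference-library oracles."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skbio import TreeNode
from skbio.diversity import beta_diversity

from microbopred.kernels import (
    DistanceMatrix, KernelError, KernelMatrix, bray_curtis, build_kernel,
    distance_to_kernel, expand_identity, kernel_from_counts, nearest_psd,
    row_normalize, weighted_unifrac,
)
from microbopred.otu_processing import OTUTable


def table(mat, prefix="s"):
    mat = np.asarray(mat, dtype=float)
    return OTUTable(pd.DataFrame(
        mat, index=[f"{prefix}{i}" for i in range(mat.shape[0])],
        columns=[f"O{j + 1:03d}" for j in range(mat.shape[1])]), stage="css")


class TestRowNormalize:
    def test_three_four_five(self):
        assert np.allclose(row_normalize(np.array([[3.0, 4.0]])), [[0.6, 0.8]])

    def test_idempotent_on_unit_rows(self, rng):
        m = row_normalize(rng.random((5, 10)) + 0.1)
        assert np.allclose(row_normalize(m), m)
        assert np.allclose(np.linalg.norm(m, axis=1), 1.0, atol=1e-12)

    def test_zero_row_rejected(self):
        with pytest.raises(KernelError, match="zero"):
            row_normalize(np.array([[0.0, 0.0]]), ids=["s0"])


class TestCrossProductKernel:
    def test_identical_and_disjoint_samples(self):
        K = kernel_from_counts(table([[1, 2, 0], [1, 2, 0], [0, 0, 5]]))
        assert K.matrix[0, 1] == pytest.approx(1.0)
        assert K.matrix[0, 2] == pytest.approx(0.0)
        assert np.allclose(np.diag(K.matrix), 1.0, atol=1e-10)

    def test_half_overlap(self):
        K = kernel_from_counts(table([[1, 1, 0], [0, 1, 1]]))
        assert K.matrix[0, 1] == pytest.approx(0.5)

    def test_equals_cosine_similarity_oracle(self, rng):
        X = rng.random((8, 15))
        K = kernel_from_counts(table(X))
        for i in range(8):
            for j in range(8):
                cos = X[i] @ X[j] / (np.linalg.norm(X[i]) * np.linalg.norm(X[j]))
                assert K.matrix[i, j] == pytest.approx(cos, abs=1e-10)


class TestBrayCurtis:
    def test_limits_and_hand_value(self):
        D = bray_curtis(table([[2, 1], [1, 1], [2, 1]]))
        assert D.matrix[0, 2] == pytest.approx(0.0)
        assert D.matrix[0, 1] == pytest.approx(0.2)  # (1+0)/(3+2)

    def test_disjoint_support_is_one(self):
        D = bray_curtis(table([[3, 0], [0, 7]]))
        assert D.matrix[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((6, 12)) * (rng.random((6, 12)) > 0.3)
        X[X.sum(axis=1) == 0, 0] = 1.0
        D = bray_curtis(table(X))
        ref = beta_diversity("braycurtis", X, ids=list(D.ids)).data
        assert np.allclose(D.matrix, ref, atol=1e-10)


def random_tree(rng, otu_ids):
    nodes = [f"{o}:{rng.exponential(0.5) + 0.01:.6f}" for o in otu_ids]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        merged = f"({nodes[i]},{nodes[j]}):{rng.exponential(0.5) + 0.01:.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return TreeNode.read(io.StringIO(nodes[0].rsplit(':', 1)[0] + ";"))


class TestWeightedUnifrac:
    def test_identical_samples_zero(self):
        t = TreeNode.read(io.StringIO("(O001:1,O002:1);"))
        D = weighted_unifrac(table([[1, 2], [2, 4]]), t)
        assert D.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_opposite_leaves_of_cherry(self):
        t = TreeNode.read(io.StringIO("(O001:1,O002:1);"))
        D = weighted_unifrac(table([[1, 0], [0, 1]]), t)
        assert D.matrix[0, 1] == pytest.approx(1.0)

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        ids = [f"O{j + 1:03d}" for j in range(6)]
        t = random_tree(rng, ids)
        X = rng.random((3, 6))
        D1 = weighted_unifrac(table(X), t)
        D2 = weighted_unifrac(table(X * np.array([[1], [7], [0.3]])), t)
        assert np.allclose(D1.matrix, D2.matrix, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_implementation(self, seed):
        rng = np.random.default_rng(100 + seed)
        p = 10
        ids = [f"O{j + 1:03d}" for j in range(p)]
        tree = random_tree(rng, ids)
        # integer counts: the reference implementation floors non-integers
        X = rng.integers(0, 20, size=(5, p)).astype(float)
        X[X.sum(axis=1) == 0, 0] = 1.0
        D = weighted_unifrac(table(X), tree)
        ref = beta_diversity("weighted_unifrac", X, ids=list(D.ids),
                             tree=tree, taxa=ids, normalized=True).data
        assert np.allclose(D.matrix, ref, atol=1e-10)

    def test_missing_leaf_reported(self):
        t = TreeNode.read(io.StringIO("(O001:1,O002:1);"))
        with pytest.raises(KernelError, match="O003"):
            weighted_unifrac(table([[1, 0, 1], [0, 1, 1]]), t)


class TestDistanceToKernel:
    def test_endpoints_and_hand_value(self):
        D = DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 1, 0.2], [1, 0, 0.5], [0.2, 0.5, 0]]),
                           metric="bray_curtis")
        K = distance_to_kernel(D)
        assert K.matrix[0, 1] == pytest.approx(0.5)   # d=1
        assert K.matrix[0, 2] == pytest.approx(0.98)  # 1 - 0.04/2
        assert np.allclose(np.diag(K.matrix), 1.0)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing(self, d1, d2):
        lo, hi = sorted([d1, d2])
        m = lambda d: 1 - d ** 2 / 2
        assert m(lo) >= m(hi)


class TestNearestPSD:
    def test_worked_2x2_example(self):
        # eigenvalues 3 and -1; dropping -1 reconstructs the rank-1 matrix
        K = KernelMatrix(["a", "b"], np.array([[1.0, 2.0], [2.0, 1.0]]))
        out = nearest_psd(K)
        assert np.allclose(out.matrix, [[1.5, 1.5], [1.5, 1.5]])

    def test_identity_unchanged_and_idempotent(self, rng):
        K = KernelMatrix(list("abc"), np.eye(3))
        assert np.allclose(nearest_psd(K).matrix, np.eye(3), atol=1e-10)
        M = rng.random((6, 6))
        K2 = nearest_psd(KernelMatrix(list("abcdef"), (M + M.T) / 2))
        assert np.linalg.eigvalsh(K2.matrix).min() >= -1e-8
        K3 = nearest_psd(K2)
        assert np.allclose(K2.matrix, K3.matrix, atol=1e-10)


class TestExpansion:
    def test_identity_block_structure_and_spectrum(self):
        K = KernelMatrix(["a", "b"], np.array([[1.0, 0.6], [0.6, 1.0]]))
        out = expand_identity(K, ["a", "b", "c", "d"])
        assert out.matrix.shape == (4, 4)
        assert out.matrix[2, 2] == 1.0 and out.matrix[2, 0] == 0.0
        ev = sorted(np.linalg.eigvalsh(out.matrix))
        expected = sorted(list(np.linalg.eigvalsh(K.matrix)) + [1.0, 1.0])
        assert np.allclose(ev, expected)

    def test_no_extra_ids_is_noop(self):
        K = KernelMatrix(["a", "b"], np.array([[1.0, 0.2], [0.2, 1.0]]))
        assert np.allclose(expand_identity(K, ["a", "b"]).matrix, K.matrix)


class TestBuildKernel:
    def test_cage_average_gives_cage_mates_identical_rows(self, study, css_table):
        design = study.design
        K = build_kernel(
            OTUTable(css_table.data.loc[design.loc[design["assessed"], "animal"]],
                     stage="css"),
            design, "M_O", "cage_average")
        un = design.loc[~design["assessed"]]
        cage = un["cage"].iloc[0]
        mates = un.loc[un["cage"] == cage, "animal"].tolist()
        if len(mates) >= 2:
            i, j = K.ids.index(mates[0]), K.ids.index(mates[1])
            row_i = np.delete(K.matrix[i], [i, j])
            row_j = np.delete(K.matrix[j], [i, j])
            assert np.allclose(row_i, row_j, atol=1e-8)

    def test_identity_block_zero_covariance_for_unassessed(self, study, css_table):
        design = study.design
        K = build_kernel(
            OTUTable(css_table.data.loc[design.loc[design["assessed"], "animal"]],
                     stage="css"),
            design, "M_O", "identity_block")
        un_animal = design.loc[~design["assessed"], "animal"].iloc[0]
        i = K.ids.index(un_animal)
        off = np.delete(K.matrix[i], i)
        assert np.allclose(off, 0.0) and K.matrix[i, i] == 1.0
        assert K.psd_repaired
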