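"""Microbial relationship (covariance) matrices between animals.

Three between-animal kernels are built from a CSS-normalized OTU table:

* ``M_O = O O'`` — cross-product of the row-normalized (unit Euclidean norm)
  CSS abundance matrix, i.e. cosine similarity of microbial profiles;
* ``M_B = 1 - B^2 / 2`` — from the Bray–Curtis distance matrix ``B``;
* ``M_U = 1 - U^2 / 2`` — from the normalized weighted UniFrac distance
  matrix ``U`` (phylogeny-aware, abundance-weighted).

Distance-derived kernels can be indefinite (distances are pairwise
constructions); they are repaired by eigendecomposition, keeping only the
non-negative part of the spectrum.  Two expansion strategies cover animals
without microbiota data: an identity block (unit variance, zero covariance)
or cage-average imputation of OTU profiles before kernel construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from .otu_processing import OTUTable, cage_average_impute

__all__ = [
    "DistanceMatrix",
    "KernelMatrix",
    "KernelError",
    "row_normalize",
    "kernel_from_counts",
    "bray_curtis",
    "weighted_unifrac",
    "distance_to_kernel",
    "nearest_psd",
    "expand_identity",
    "build_kernel",
    "METHODS",
    "EXPANSIONS",
]

METHODS = ("M_O", "M_B", "M_U")
EXPANSIONS = ("none", "identity_block", "cage_average")
_METRIC_FOR = {"M_B": "bray_curtis", "M_U": "weighted_unifrac"}


class KernelError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix in [0, 1] with zero diagonal."""

    ids: list
    matrix: np.ndarray = field(repr=False)
    metric: str = "bray_curtis"

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.ids):
            raise KernelError("distance matrix shape does not match ids")
        if not np.allclose(m, m.T, atol=1e-8):
            raise KernelError("distance matrix is not symmetric")
        if (m < -1e-12).any() or (m > 1 + 1e-8).any():
            raise KernelError(f"{self.metric} distances must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


@dataclass
class KernelMatrix:
    """Symmetric between-animal covariance due to microbial composition."""

    ids: list
    matrix: np.ndarray = field(repr=False)
    method: str = "M_O"
    expansion: str = "none"
    psd_repaired: bool = False

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise KernelError(f"unknown method {self.method!r}")
        if self.expansion not in EXPANSIONS:
            raise KernelError(f"unknown expansion {self.expansion!r}")
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.ids):
            raise KernelError("kernel shape does not match ids")
        if not np.allclose(m, m.T, atol=1e-8):
            raise KernelError("kernel is not symmetric")
        if len(set(self.ids)) != len(self.ids):
            raise KernelError("duplicate ids in kernel")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)

    def write(self, path) -> None:
        self.to_frame().rename_axis("id").to_csv(path, sep="\t")


def row_normalize(matrix: np.ndarray, ids: list | None = None) -> np.ndarray:
    """Scale each row to unit Euclidean norm."""
    matrix = np.asarray(matrix, dtype=float)
    norms = np.linalg.norm(matrix, axis=1)
    zero = norms == 0
    if zero.any():
        bad = [ids[i] if ids else i for i in np.flatnonzero(zero)]
        raise KernelError(f"all-zero rows cannot be normalized: {bad}")
    return matrix / norms[:, None]


def kernel_from_counts(css_table: OTUTable) -> KernelMatrix:
    """M_O = O O' with O the row-normalized CSS abundance matrix.

    Entries are cosine similarities of microbial profiles; the diagonal is
    exactly one and, for non-negative abundances, all entries lie in [0, 1].
    """
    O = row_normalize(css_table.values(), css_table.sample_ids)
    M = O @ O.T
    np.fill_diagonal(M, 1.0)
    return KernelMatrix(css_table.sample_ids, M, method="M_O")


def bray_curtis(css_table: OTUTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarity: sum|x-y| / sum(x+y) over OTUs."""
    vals = css_table.values()
    if (vals.sum(axis=1) == 0).any():
        bad = [s for s, v in zip(css_table.sample_ids, vals.sum(axis=1)) if v == 0]
        raise KernelError(f"all-zero samples: {bad}")
    D = squareform(pdist(vals, metric="braycurtis"))
    return DistanceMatrix(css_table.sample_ids, D, metric="bray_curtis")


def _branch_table(tree: TreeNode, otu_ids: list) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch descendant-tip indicator matrix and branch lengths.

    Returns (T, lengths) where T is branches x OTUs with T[b, j] = 1 iff
    OTU j descends through branch b.  The root's (lengthless) edge is
    excluded.
    """
    col = {o: j for j, o in enumerate(otu_ids)}
    tips_missing = [t.name for t in tree.tips() if t.name not in col]
    rows, lengths = [], []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        mask = np.zeros(len(otu_ids), dtype=bool)
        if node.is_tip():
            if node.name in col:
                mask[col[node.name]] = True
        else:
            for child in node.children:
                mask |= below[id(child)]
        below[id(node)] = mask
        if node.parent is not None:
            rows.append(mask)
            lengths.append(node.length if node.length is not None else 0.0)
    return np.array(rows, dtype=float), np.array(lengths, dtype=float)


def weighted_unifrac(
    css_table: OTUTable, tree: TreeNode, normalized: bool = True
) -> DistanceMatrix:
    """Weighted UniFrac distances between samples over a rooted OTU tree.

    For each branch b with length ``l_b`` let ``p_ib`` be the fraction of
    sample i's total abundance carried by OTUs below b.  The raw distance is
    ``sum_b l_b |p_ib - p_jb|``; the normalized variant (default, bounded in
    [0, 1]) divides by ``sum_b l_b (p_ib + p_jb)``.  Abundances enter as
    within-sample proportions, so the result is invariant to per-sample
    rescaling.
    """
    otu_ids = css_table.otu_ids
    leaf_names = {t.name for t in tree.tips()}
    vals = css_table.values()
    present = np.asarray(vals.sum(axis=0) > 0)
    missing = [o for o, p in zip(otu_ids, present) if p and o not in leaf_names]
    if missing:
        raise KernelError(f"OTUs absent from tree: {missing[:10]}"
                          + ("..." if len(missing) > 10 else ""))
    totals = vals.sum(axis=1)
    if (totals == 0).any():
        bad = [s for s, t in zip(css_table.sample_ids, totals) if t == 0]
        raise KernelError(f"all-zero samples: {bad}")
    rel = vals / totals[:, None]
    T, lengths = _branch_table(tree, otu_ids)
    P = rel @ T.T  # samples x branches: abundance fraction below each branch
    num = squareform(pdist(P, metric="minkowski", p=1, w=lengths))
    if normalized:
        t = P @ lengths
        denom = t[:, None] + t[None, :]
        with np.errstate(invalid="ignore"):
            D = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    else:
        D = num
        mx = D.max()
        if mx > 0:  # keep the [0,1] range contract for the raw variant too
            D = D / mx
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(css_table.sample_ids, D, metric="weighted_unifrac")


def distance_to_kernel(D: DistanceMatrix) -> KernelMatrix:
    """Map distances to similarities: m = 1 - d^2 / 2.

    Maps d=0 to 1 and d=1 to 0.5; monotone decreasing in d, so the kernel
    ranks pairs exactly as the distance does.
    """
    if (D.matrix > 1 + 1e-8).any():
        raise KernelError("distance not normalized to [0, 1]")
    M = 1.0 - np.minimum(D.matrix, 1.0) ** 2 / 2.0
    np.fill_diagonal(M, 1.0)
    method = {"bray_curtis": "M_B", "weighted_unifrac": "M_U"}[D.metric]
    return KernelMatrix(D.ids, M, method=method)


def nearest_psd(K: KernelMatrix, tol: float = 1e-10) -> KernelMatrix:
    """Project a symmetric kernel onto the PSD cone by spectral truncation.

    Eigendecompose, drop negative eigenvalues, reconstruct.  A matrix that
    is already PSD is returned unchanged (up to ``tol``); the operation is
    idempotent.
    """
    M = K.matrix
    if not np.allclose(M, M.T, atol=1e-8):
        raise KernelError("matrix asymmetric beyond 1e-8")
    M = (M + M.T) / 2.0
    w, V = np.linalg.eigh(M)
    if w.min() >= -tol:
        return KernelMatrix(K.ids, M, K.method, K.expansion, psd_repaired=True)
    w_clip = np.clip(w, 0.0, None)
    M_plus = (V * w_clip) @ V.T
    M_plus = (M_plus + M_plus.T) / 2.0
    return KernelMatrix(K.ids, M_plus, K.method, K.expansion, psd_repaired=True)


def expand_identity(K: KernelMatrix, all_ids: list) -> KernelMatrix:
    """Expand a kernel to ``all_ids`` with unit diagonal / zero covariance
    for the animals not present in ``K``.

    The expanded matrix is block-diagonal after permutation, so its spectrum
    is the original spectrum plus ones; PSD-ness is preserved.
    """
    if len(set(all_ids)) != len(all_ids):
        raise KernelError("duplicate ids in expansion target")
    missing = set(K.ids) - set(all_ids)
    if missing:
        raise KernelError(f"kernel ids not in target set: {sorted(missing)[:5]}")
    n = len(all_ids)
    M = np.eye(n)
    pos = {a: i for i, a in enumerate(all_ids)}
    idx = np.array([pos[a] for a in K.ids])
    M[np.ix_(idx, idx)] = K.matrix
    return KernelMatrix(list(all_ids), M, K.method, expansion="identity_block",
                        psd_repaired=K.psd_repaired)


def build_kernel(
    css_table: OTUTable,
    design: pd.DataFrame | None,
    method: str,
    expansion: str = "none",
    tree: TreeNode | None = None,
) -> KernelMatrix:
    """Build a repaired microbial kernel with the requested expansion.

    ``expansion="cage_average"`` imputes unassessed animals' CSS profiles
    with their cage average first and computes the kernel over all animals;
    ``"identity_block"`` computes the kernel over assessed animals and pads
    the rest with an identity block.  Ids are sorted for reproducible
    downstream linear algebra.

    ``design`` (columns ``animal``, ``cage``) is required for either
    expansion; ``tree`` is required for ``method="M_U"``.
    """
    if method not in METHODS:
        raise KernelError(f"unknown method {method!r}")
    if method == "M_U" and tree is None:
        raise KernelError("weighted UniFrac kernel needs a tree")
    if expansion != "none" and design is None:
        raise KernelError("expansion needs a study design")

    table = css_table
    if expansion == "cage_average":
        table = cage_average_impute(css_table, design)
    order = sorted(table.sample_ids)
    table = OTUTable(table.data.loc[order], stage=table.stage, taxonomy=table.taxonomy)

    if method == "M_O":
        K = kernel_from_counts(table)
    elif method == "M_B":
        K = distance_to_kernel(bray_curtis(table))
    else:
        K = distance_to_kernel(weighted_unifrac(table, tree))
    K = nearest_psd(K)

    if expansion == "identity_block":
        all_ids = sorted(design["animal"])
        K = expand_identity(K, all_ids)
    elif expansion == "cage_average":
        K.expansion = "cage_average"
    return K
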