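"""Sparse partial least squares regression and stable OTU selection.

The sPLS algorithm (soft-thresholded direction vectors with an active-set
PLS refit): at each component, the direction weights are

    z = X' y_res,    w_j = sign(z_j) (|z_j| - eta * max|z|)_+

so ``eta`` in (0, 1) is the sparsity knob (eta -> 0 recovers dense PLS).
The active set is the running union of non-zero supports; after each
component an ordinary PLS1 with the current number of components is refit
on the active columns and the response deflated.  Tuning of
(eta, n_components) minimizes cross-validated mean squared prediction
error; stability selection repeats tune-and-fit over 20 random seeds x 5
folds = 100 replicates and keeps variables selected in >= 80 of them.

"Relevant" OTUs for a trait are those in the extreme tails (below the 5th
or above the 95th percentile) of the loading weights *and* stably selected
under every microbial kernel model considered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SPLSModel",
    "SPLSResult",
    "SPLSError",
    "spls_fit",
    "cv_tune",
    "stability_selection",
    "relevant_otus",
    "pearson_assoc",
    "fit_microbial_effect_targets",
    "DEFAULT_ETA_GRID",
    "DEFAULT_K_GRID",
]

log = logging.getLogger(__name__)

DEFAULT_ETA_GRID = tuple(np.round(np.arange(0.1, 1.0, 0.1), 2))
DEFAULT_K_GRID = tuple(range(1, 11))


class SPLSError(ValueError):
    pass


def _pls1(X: np.ndarray, y: np.ndarray, K: int) -> np.ndarray:
    """PLS1 regression coefficients (univariate y, centred inputs)."""
    n, p = X.shape
    K = min(K, p, n - 1)
    Xr = X.copy()
    yr = y.copy()
    W = np.zeros((p, K))
    P = np.zeros((p, K))
    q = np.zeros(K)
    for k in range(K):
        w = Xr.T @ yr
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            K = k
            break
        w /= nw
        t = Xr @ w
        tt = t @ t
        if tt < 1e-12:
            K = k
            break
        P[:, k] = Xr.T @ t / tt
        q[k] = yr @ t / tt
        W[:, k] = w
        Xr = Xr - np.outer(t, P[:, k])
        yr = yr - q[k] * t
    if K == 0:
        return np.zeros(p)
    W, P, q = W[:, :K], P[:, :K], q[:K]
    return W @ np.linalg.solve(P.T @ W, q)


@dataclass
class SPLSModel:
    """A fitted sparse PLS regression."""

    eta: float
    n_components: int
    active: np.ndarray = field(repr=False)      # sorted active column indices
    coef_: np.ndarray = field(repr=False)       # per-variable, original scale
    intercept_: float = 0.0
    directions: np.ndarray | None = field(default=None, repr=False)  # p x K weights

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef_ + self.intercept_


def spls_fit(
    X: np.ndarray,
    y: np.ndarray,
    eta: float,
    K: int,
    standardize: bool = True,
) -> SPLSModel:
    """Fit sparse PLS with sparsity ``eta`` and ``K`` latent components.

    Columns are centred (and unit-scaled when ``standardize``); returned
    coefficients are on the original scale, zero outside the active set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if not 0 < eta < 1:
        raise SPLSError("eta must lie in (0, 1)")
    if K < 1 or K > min(n - 1, p):
        raise SPLSError(f"K={K} exceeds the rank bound min(n-1, p)")
    if np.std(y) == 0:
        raise SPLSError("constant response")
    xm = X.mean(axis=0)
    xs = X.std(axis=0)
    xs[xs == 0] = 1.0
    if not standardize:
        xs = np.ones(p)
    Xc = (X - xm) / xs
    ym = y.mean()
    yc = y - ym

    active = np.zeros(p, dtype=bool)
    y_res = yc.copy()
    beta_c = np.zeros(p)
    dirs = np.zeros((p, K))
    for k in range(1, K + 1):
        z = Xc.T @ y_res
        thr = eta * np.abs(z).max()
        w = np.sign(z) * np.clip(np.abs(z) - thr, 0.0, None)
        dirs[:, k - 1] = w
        active |= w != 0
        idx = np.flatnonzero(active)
        beta_c = np.zeros(p)
        beta_c[idx] = _pls1(Xc[:, idx], yc, k)
        y_res = yc - Xc @ beta_c
    coef = beta_c / xs
    intercept = ym - xm @ coef
    return SPLSModel(eta, K, np.flatnonzero(active), coef, intercept, dirs)


def cv_tune(
    X: np.ndarray,
    y: np.ndarray,
    eta_grid=DEFAULT_ETA_GRID,
    K_grid=DEFAULT_K_GRID,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[float, int]:
    """Choose (eta, K) minimizing fold-averaged MSPE.

    Ties break toward the smallest K, then the largest eta (the sparsest
    model among equally predictive ones).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < n_folds:
        raise SPLSError("fewer records than folds")
    if len(eta_grid) == 0 or len(K_grid) == 0:
        raise SPLSError("empty tuning grid")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    results = {}
    for eta, K in product(eta_grid, K_grid):
        if K > min(n - len(folds[0]) - 1, X.shape[1]):
            continue
        errs = []
        for f in folds:
            mask = np.ones(n, dtype=bool)
            mask[f] = False
            try:
                model = spls_fit(X[mask], y[mask], eta, K)
            except SPLSError:
                errs = None
                break
            errs.append(float(np.mean((y[~mask] - model.predict(X[~mask])) ** 2)))
        if errs:
            results[(eta, K)] = float(np.mean(errs))
    if not results:
        raise SPLSError("no feasible grid point")
    best = min(results.items(), key=lambda kv: (kv[1], kv[0][1], -kv[0][0]))
    return best[0]


@dataclass
class SPLSResult:
    """Aggregate of a stability-selection run."""

    counts: pd.Series = field(repr=False)       # variable -> times selected
    n_replicates: int = 0
    stable: list = field(default_factory=list)  # selected in >= threshold share
    loadings: pd.Series = field(default=None, repr=False)  # mean coefficient
    tuned: pd.DataFrame = field(default=None, repr=False)  # per-replicate eta, K
    val_correlations: list = field(default_factory=list)

    def stable_at(self, share: float = 0.8) -> list:
        return list(self.counts.index[self.counts >= share * self.n_replicates])


def stability_selection(
    X: np.ndarray,
    y: np.ndarray,
    var_names=None,
    n_repeats: int = 20,
    n_folds: int = 5,
    seed: int = 0,
    eta_grid=DEFAULT_ETA_GRID,
    K_grid=DEFAULT_K_GRID,
    stable_share: float = 0.8,
) -> SPLSResult:
    """Repeat tune-and-fit over ``n_repeats x n_folds`` replicates.

    In each replicate one fold is held out for validation; (eta, K) are
    tuned by internal cross-validation on the learning folds, the model is
    refit there, and the active set, coefficients and validation
    correlation are recorded.  The stable set holds variables active in at
    least ``stable_share`` of replicates.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    names = list(var_names) if var_names is not None else list(range(p))
    counts = np.zeros(p)
    coef_sum = np.zeros(p)
    tuned_rows = []
    val_corrs = []
    rep = 0
    for r in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        perm = rng.permutation(n)
        folds = np.array_split(perm, n_folds)
        for f in folds:
            mask = np.ones(n, dtype=bool)
            mask[f] = False
            eta, K = cv_tune(X[mask], y[mask], eta_grid, K_grid,
                             n_folds=n_folds, seed=int(rng.integers(2**31)))
            model = spls_fit(X[mask], y[mask], eta, K)
            counts[model.active] += 1
            coef_sum += model.coef_
            pred = model.predict(X[~mask])
            if np.std(pred) > 0 and np.std(y[~mask]) > 0:
                val_corrs.append(float(np.corrcoef(y[~mask], pred)[0, 1]))
            tuned_rows.append({"replicate": rep, "eta": eta, "K": K})
            rep += 1
    counts_s = pd.Series(counts, index=names)
    loadings = pd.Series(coef_sum / rep, index=names)
    result = SPLSResult(counts_s, rep, [], loadings,
                        pd.DataFrame(tuned_rows), val_corrs)
    result.stable = result.stable_at(stable_share)
    return result


def relevant_otus(
    loadings: dict[str, pd.Series],
    stable_sets: dict[str, list] | None = None,
    lower_q: float = 0.05,
    upper_q: float = 0.95,
) -> tuple[list, pd.DataFrame]:
    """OTUs with tail loading weights under *every* kernel model.

    Per model, flag OTUs whose loading weight falls below the ``lower_q``
    or above the ``upper_q`` quantile of that model's loadings; intersect
    the flags (restricted to each model's stable set when given) across
    models.  Returns the relevant OTU list and the per-model flag table.
    """
    keys = list(loadings)
    base_index = loadings[keys[0]].index
    for k in keys[1:]:
        if not loadings[k].index.equals(base_index):
            raise SPLSError("loading vectors cover different OTU sets")
    flags = {}
    for k in keys:
        lv = loadings[k]
        lo, hi = lv.quantile(lower_q), lv.quantile(upper_q)
        flagged = (lv < lo) | (lv > hi)
        if stable_sets is not None:
            flagged &= lv.index.isin(stable_sets.get(k, []))
        flags[k] = flagged
    table = pd.DataFrame(flags)
    relevant = list(base_index[table.all(axis=1)])
    return relevant, table


def pearson_assoc(otu_abundances, trait_values) -> tuple[float, float]:
    """Pearson r and two-sided t-test p between an OTU and a trait."""
    x = np.asarray(otu_abundances, dtype=float)
    y = np.asarray(trait_values, dtype=float)
    if len(x) < 3:
        raise SPLSError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        log.warning("constant input to pearson_assoc; returning NaN")
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def fit_microbial_effect_targets(
    otu_matrix: np.ndarray,
    otu_ids,
    targets: dict[str, np.ndarray],
    **selection_kwargs,
) -> dict[str, SPLSResult]:
    """Stability selection against mixed-model microbial-effect solutions.

    ``targets`` maps a kernel label (e.g. ``"M_O"``) to the posterior means
    (or BLUPs) of per-animal microbial effects from the corresponding M2
    fit; each is regressed on the CSS OTU matrix by stability selection.
    Feed the resulting loadings and stable sets to :func:`relevant_otus`.
    """
    out = {}
    for label, target in targets.items():
        out[label] = stability_selection(otu_matrix, np.asarray(target, dtype=float),
                                         var_names=otu_ids, **selection_kwargs)
    return out
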