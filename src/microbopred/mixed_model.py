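"""Pedigree + microbiome mixed ('animal') models.

The model for a vector of phenotypes y is

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, K_k sigma_k^2),
    e ~ N(0, I sigma_e^2)

with random terms drawn from {additive (K = A, the numerator relationship
matrix), litter (K = I), cage (K = I), microbial (K = M, a microbial
kernel)}.  Model M1 omits the microbial term; M2 includes it.

Two estimation routes are provided:

* :func:`em_reml` — expectation-maximization REML, iterating the closed-form
  EM updates in the n x n phenotypic-covariance parameterization
  (V = sum_k sigma_k^2 Z_k K_k Z_k' + sigma_e^2 I), which keeps per-iteration
  cost at O(n^3) regardless of the number of effect levels.
* :func:`gibbs_sample` — a systematic-scan Gibbs sampler drawing each effect
  block from its multivariate-normal full conditional and each variance from
  its scaled inverse chi-square full conditional under flat priors.  Each
  term's conditional precision Z'Z/sigma_e^2 + K^-1/sigma_k^2 is
  diagonalized once via the generalized eigenproblem (Z'Z, K^-1), so a
  block draw costs two matrix-vector products per sweep.

Variance ratios: h2 = sigma_A^2/sigma_P^2 (heritability), l2, c2, and
m2 = sigma_M^2/sigma_P^2 (microbiability).  For individual traits sigma_P^2
is the plain sum of components; for cage-average traits the residual is a
cage-mean residual, so it is multiplied by the average number of animals per
cage (default 7) to refer it back to individual records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "ChainConfig",
    "VarianceEstimates",
    "MixedModelFit",
    "MixedModelError",
    "assemble_mme",
    "em_reml",
    "gibbs_sample",
    "variance_ratios",
    "blup_predict",
    "effective_sample_size",
]

log = logging.getLogger(__name__)

RATIO_NAMES = {"additive": "h2", "litter": "l2", "cage": "c2", "microbial": "m2"}


class MixedModelError(ValueError):
    pass


@dataclass
class RandomTerm:
    """One random effect: incidence matrix, covariance kernel, level labels.

    ``kernel=None`` means an identity covariance.  The kernel may cover more
    levels than the records reference (e.g. validation animals); their BLUPs
    are then obtained through the kernel covariance.
    """

    name: str
    Z: np.ndarray = field(repr=False)
    kernel: np.ndarray | None = field(default=None, repr=False)
    levels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        q = self.Z.shape[1]
        if self.levels and len(self.levels) != q:
            raise MixedModelError(f"term {self.name}: levels/Z mismatch")
        if self.kernel is not None and self.kernel.shape != (q, q):
            raise MixedModelError(f"term {self.name}: kernel/Z dim mismatch")

    @property
    def n_levels(self) -> int:
        return self.Z.shape[1]

    def K(self) -> np.ndarray:
        return np.eye(self.n_levels) if self.kernel is None else self.kernel


@dataclass
class ModelSpec:
    """A single-trait mixed model: response, fixed effects, random terms."""

    trait: str
    y: np.ndarray = field(repr=False)
    X: np.ndarray = field(repr=False)
    terms: list[RandomTerm] = field(default_factory=list)
    trait_kind: str = "individual"
    record_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.y)
        if self.X.shape[0] != n:
            raise MixedModelError("X rows != records")
        for t in self.terms:
            if t.Z.shape[0] != n:
                raise MixedModelError(f"term {t.name}: Z rows != records")
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise MixedModelError("duplicate random-term names")

    @property
    def include_microbial(self) -> bool:
        return any(t.name == "microbial" for t in self.terms)

    def drop_term(self, name: str) -> "ModelSpec":
        return ModelSpec(self.trait, self.y, self.X,
                         [t for t in self.terms if t.name != name],
                         self.trait_kind, self.record_ids)


@dataclass
class ChainConfig:
    """Gibbs chain settings (desk-scale defaults)."""

    n_iter: int = 50_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise MixedModelError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise MixedModelError("thin must be >= 1")


@dataclass
class VarianceEstimates:
    """Variance components, their ratios, and the phenotypic variance."""

    components: dict[str, float]
    ratios: dict[str, float]
    sigma_p: float
    component_sds: dict[str, float] | None = None
    ratio_sds: dict[str, float] | None = None
    method: str = "em_reml"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, v in self.components.items():
            rows.append({"parameter": f"sigma2_{k}", "mean": v,
                         "sd": (self.component_sds or {}).get(k, np.nan)})
        for k, v in self.ratios.items():
            rows.append({"parameter": k, "mean": v,
                         "sd": (self.ratio_sds or {}).get(k, np.nan)})
        rows.append({"parameter": "sigma2_P", "mean": self.sigma_p, "sd": np.nan})
        return pd.DataFrame(rows)


@dataclass
class MixedModelFit:
    """Converged variance components plus BLUE/BLUP solutions."""

    spec: ModelSpec
    estimates: VarianceEstimates
    beta: np.ndarray = field(repr=False)
    u: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    converged: bool = True
    n_iter: int = 0
    samples: pd.DataFrame | None = field(default=None, repr=False)

    def fitted(self) -> np.ndarray:
        out = self.spec.X @ self.beta
        for t in self.spec.terms:
            out = out + t.Z @ self.u[t.name]
        return out

    def predict(self, X_new: np.ndarray, Z_new: dict[str, np.ndarray]) -> np.ndarray:
        """Predict new records from fitted effects.

        ``Z_new`` maps term name to an incidence matrix over the *same*
        level sets as the training spec; levels only seen in validation
        carry whatever BLUP the kernel covariance propagated to them (zero
        for identity kernels and identity-block expansions).
        """
        out = X_new @ self.beta
        for t in self.spec.terms:
            if t.name in Z_new:
                out = out + Z_new[t.name] @ self.u[t.name]
        return out


def _stable_inv(K: np.ndarray, jitter_scale: float = 1e-6) -> np.ndarray:
    """Inverse via Cholesky, adding diagonal jitter for singular kernels."""
    n = K.shape[0]
    base = jitter_scale * float(np.mean(np.diag(K)) or 1.0)
    jitter = 0.0
    for _ in range(8):
        try:
            c, low = linalg.cho_factor(K + jitter * np.eye(n), lower=True)
            return linalg.cho_solve((c, low), np.eye(n))
        except linalg.LinAlgError:
            jitter = base if jitter == 0.0 else jitter * 10.0
    raise MixedModelError("kernel not invertible even with jitter")


def assemble_mme(
    spec: ModelSpec, variances: dict[str, float]
) -> tuple[np.ndarray, np.ndarray, dict[str, slice]]:
    """Henderson's mixed-model equations for given variance components.

    Returns the symmetric coefficient matrix
    ``[[X'X, X'Z], [Z'X, Z'Z + blockdiag(K_k^-1 lambda_k)]]`` (with
    ``lambda_k = sigma_e^2 / sigma_k^2``), the right-hand side, and a map of
    term name -> slice into the solution vector ('fixed' for beta).
    """
    sig_e = variances["residual"]
    for t in spec.terms:
        if variances[t.name] <= 0:
            raise MixedModelError(f"non-positive variance for {t.name}")
    W = np.hstack([spec.X] + [t.Z for t in spec.terms])
    C = W.T @ W
    rhs = W.T @ spec.y
    p = spec.X.shape[1]
    if np.linalg.matrix_rank(spec.X) < p:
        raise MixedModelError("singular fixed-effect block; drop a level")
    slices = {"fixed": slice(0, p)}
    off = p
    for t in spec.terms:
        q = t.n_levels
        lam = sig_e / variances[t.name]
        Kinv = np.eye(q) if t.kernel is None else _stable_inv(t.kernel)
        C[off:off + q, off:off + q] += lam * Kinv
        slices[t.name] = slice(off, off + q)
        off += q
    return C, rhs, slices


def _v_matrices(spec: ModelSpec) -> list[np.ndarray]:
    """Per-term phenotypic covariance contributions G_k = Z_k K_k Z_k'."""
    out = []
    for t in spec.terms:
        if t.kernel is None:
            out.append(t.Z @ t.Z.T)
        else:
            out.append(t.Z @ t.kernel @ t.Z.T)
    return out


def em_reml(
    spec: ModelSpec,
    tol: float = 1e-8,
    max_iter: int = 5000,
    init: dict[str, float] | None = None,
    cage_factor: float = 7.0,
    ratio_reference: str = "prior",
) -> MixedModelFit:
    """Variance components by EM-REML, with BLUE/BLUP solutions.

    Iterates, to relative change < ``tol`` in every component, the EM
    updates

        sigma_k^2 <- sigma_k^2 + sigma_k^4 (y'P G_k P y - tr(P G_k)) / q_k

    where P is the REML projection matrix of V and G_k = Z_k K_k Z_k'.
    Non-convergence at ``max_iter`` logs a warning and returns the last
    iterate flagged ``converged=False``.
    """
    y = np.asarray(spec.y, dtype=float)
    n = len(y)
    X = spec.X
    p = X.shape[1]
    if n <= p:
        raise MixedModelError("more fixed-effect levels than records")
    Gs = _v_matrices(spec)
    names = [t.name for t in spec.terms]
    qs = [t.n_levels for t in spec.terms]
    var_y = float(np.var(y)) or 1.0
    k = len(names) + 1
    sig = {nm: var_y / k for nm in names}
    sig["residual"] = var_y / k
    if init:
        sig.update(init)

    converged = False
    it = 0
    history: list[dict[str, float]] = []
    for it in range(1, max_iter + 1):
        V = sig["residual"] * np.eye(n)
        for nm, G in zip(names, Gs):
            V += sig[nm] * G
        Vinv = np.linalg.inv(V)
        XtVi = X.T @ Vinv
        XtViX_inv = np.linalg.inv(XtVi @ X)
        P = Vinv - XtVi.T @ XtViX_inv @ XtVi
        Py = P @ y
        new = {}
        for nm, G, q in zip(names, Gs, qs):
            s = sig[nm]
            new[nm] = s + s * s * float(Py @ G @ Py - np.sum(P * G)) / q
        s = sig["residual"]
        new["residual"] = s + s * s * float(Py @ Py - np.trace(P)) / n
        floor = 1e-10 * var_y
        new = {nm: max(v, floor) for nm, v in new.items()}
        # convergence measured against the total variance: components
        # crawling to the zero boundary (EM is sublinear there) should not
        # hold up an otherwise converged fit
        total = sum(new.values())
        rel = max(abs(new[nm] - sig[nm]) for nm in new) / total
        sig = new
        if rel < tol:
            converged = True
            break
        # Aitken extrapolation every few sweeps: EM's component sequences
        # converge geometrically, so jump ahead along the fitted geometric
        # tail (kept within a x10 move and strictly positive).
        history.append(dict(sig))
        if len(history) >= 3 and it % 5 == 0 and rel > 50 * tol:
            t1, t2, t3 = history[-3], history[-2], history[-1]
            accel = {}
            for nm in sig:
                d1, d2 = t2[nm] - t1[nm], t3[nm] - t2[nm]
                if d1 != 0 and 0 < d2 / d1 < 0.98:
                    r = d2 / d1
                    accel[nm] = t3[nm] + d2 * r / (1.0 - r)
                else:
                    accel[nm] = t3[nm]
            if all(0.1 * sig[nm] < accel[nm] < 10.0 * sig[nm] + floor for nm in sig):
                sig = {nm: max(accel[nm], floor) for nm in sig}
                history.clear()
    if not converged:
        log.warning("EM-REML did not converge in %d iterations (last rel change %.2e)",
                    max_iter, rel)

    V = sig["residual"] * np.eye(n)
    for nm, G in zip(names, Gs):
        V += sig[nm] * G
    Vinv = np.linalg.inv(V)
    XtVi = X.T @ Vinv
    beta = np.linalg.solve(XtVi @ X, XtVi @ y)
    P = Vinv - XtVi.T @ np.linalg.inv(XtVi @ X) @ XtVi
    Py = P @ y
    u = {}
    for t, nm in zip(spec.terms, names):
        ZtPy = t.Z.T @ Py
        u[nm] = sig[nm] * (ZtPy if t.kernel is None else t.kernel @ ZtPy)

    comps = dict(sig)
    scales = sample_reference_scales(spec) if ratio_reference == "sample" else None
    ratios, sig_p = variance_ratios(comps, spec.trait_kind, cage_factor, scales)
    est = VarianceEstimates(comps, ratios, sig_p, method="em_reml")
    return MixedModelFit(spec, est, beta, u, converged, it)


def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the initial positive sequence of autocorrelations."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for lag in range(1, n // 2):
        if acf[lag] <= 0:
            break
        s += acf[lag]
    return float(n / (1.0 + 2.0 * s))


def gibbs_sample(
    spec: ModelSpec,
    chain: ChainConfig,
    cage_factor: float = 7.0,
    jitter_scale: float = 1e-6,
    ratio_reference: str = "prior",
) -> MixedModelFit:
    """Bayesian estimation by a systematic-scan Gibbs sampler.

    Flat (improper, bounded at zero) priors on variances and on fixed
    effects; effect priors u_k ~ N(0, K_k sigma_k^2).  Location blocks are
    drawn jointly per term from their multivariate-normal full
    conditionals; variances from scaled inverse chi-square full
    conditionals.  Posterior means and SDs of components and ratios are
    computed from the kept (post burn-in, thinned) samples; the full sample
    trace is attached to the returned fit for diagnostics.
    """
    rng = np.random.default_rng(chain.seed)
    y = np.asarray(spec.y, dtype=float)
    n = len(y)
    X = spec.X
    names = [t.name for t in spec.terms]

    # Precompute per-term simultaneous diagonalization of (Z'Z, K^-1):
    # columns W with W' K^-1 W = I and W' Z'Z W = diag(mu).
    Ws, mus = [], []
    for t in spec.terms:
        ZtZ = t.Z.T @ t.Z
        Kinv = np.eye(t.n_levels) if t.kernel is None else _stable_inv(t.kernel, jitter_scale)
        Kinv = (Kinv + Kinv.T) / 2.0
        mu, W = linalg.eigh(ZtZ, Kinv)
        Ws.append(W)
        mus.append(np.clip(mu, 0.0, None))

    XtX = X.T @ X
    cXtX = linalg.cho_factor(XtX)
    XtX_inv_chol = np.linalg.cholesky(np.linalg.inv(XtX))

    var_y = float(np.var(y)) or 1.0
    k = len(names) + 1
    sig = {nm: var_y / k for nm in names}
    sig["residual"] = var_y / k
    beta = np.zeros(X.shape[1])
    v_coef = [np.zeros(t.n_levels) for t in spec.terms]  # in W-coordinates
    contrib = [np.zeros(n) for _ in spec.terms]
    fitted = X @ beta

    kept: list[dict[str, float]] = []
    kept_u_sum = [np.zeros(t.n_levels) for t in spec.terms]
    kept_beta_sum = np.zeros(X.shape[1])
    scales = sample_reference_scales(spec) if ratio_reference == "sample" else None

    for it in range(chain.n_iter):
        # fixed effects
        y_adj = y - (fitted - X @ beta)
        mean_b = linalg.cho_solve(cXtX, X.T @ y_adj)
        beta = mean_b + np.sqrt(sig["residual"]) * (XtX_inv_chol @ rng.standard_normal(len(beta)))
        fitted = X @ beta + sum(contrib)

        # random-effect blocks
        for j, t in enumerate(spec.terms):
            y_adj = y - (fitted - contrib[j])
            r_v = Ws[j].T @ (t.Z.T @ y_adj) / sig["residual"]
            prec = mus[j] / sig["residual"] + 1.0 / sig[t.name]
            v = r_v / prec + rng.standard_normal(t.n_levels) / np.sqrt(prec)
            v_coef[j] = v
            u_j = Ws[j] @ v
            contrib[j] = t.Z @ u_j
            fitted = X @ beta + sum(contrib)
            # u' K^-1 u = v'v in the W basis
            S = float(v @ v)
            df = max(t.n_levels - 2, 1)
            sig[t.name] = max(S / rng.chisquare(df), 1e-12 * var_y)

        e = y - fitted
        sig["residual"] = max(float(e @ e) / rng.chisquare(max(n - 2, 1)), 1e-12 * var_y)
        if sig["residual"] > 1e12 * var_y or any(sig[nm] > 1e12 * var_y for nm in names):
            raise MixedModelError(f"divergent chain at iteration {it}")

        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
            row = {f"sigma2_{nm}": sig[nm] for nm in names}
            row["sigma2_residual"] = sig["residual"]
            ratios, sig_p = variance_ratios(dict(sig), spec.trait_kind, cage_factor, scales)
            row.update(ratios)
            row["sigma2_P"] = sig_p
            kept.append(row)
            for j in range(len(spec.terms)):
                kept_u_sum[j] += Ws[j] @ v_coef[j]
            kept_beta_sum += beta

    samples = pd.DataFrame(kept)
    n_kept = len(samples)
    comp_mean = {nm: float(samples[f"sigma2_{nm}"].mean()) for nm in names}
    comp_mean["residual"] = float(samples["sigma2_residual"].mean())
    comp_sd = {nm: float(samples[f"sigma2_{nm}"].std()) for nm in names}
    comp_sd["residual"] = float(samples["sigma2_residual"].std())
    ratio_cols = [c for c in samples.columns if c in RATIO_NAMES.values()]
    ratio_mean = {c: float(samples[c].mean()) for c in ratio_cols}
    ratio_sd = {c: float(samples[c].std()) for c in ratio_cols}
    est = VarianceEstimates(comp_mean, ratio_mean, float(samples["sigma2_P"].mean()),
                            comp_sd, ratio_sd, method="gibbs")
    u = {nm: kept_u_sum[j] / n_kept for j, nm in enumerate(names)}
    return MixedModelFit(spec, est, kept_beta_sum / n_kept, u,
                         converged=True, n_iter=chain.n_iter, samples=samples)


def variance_ratios(
    components: dict[str, float],
    trait_kind: str,
    cage_factor: float = 7.0,
    scales: dict[str, float] | None = None,
) -> tuple[dict[str, float], float]:
    """Heritability, litter, cage and microbiability ratios.

    Individual traits: sigma_P^2 is the sum of all components.  Cage-average
    traits: the residual is a cage-mean residual, so it is multiplied by
    ``cage_factor`` (average animals per cage) before entering sigma_P^2.

    ``scales`` (from :func:`sample_reference_scales`) optionally converts
    each kernel term's prior-scale variance to the variance it actually
    expresses *across the sampled animals*.  Kernels with a large common
    (near-constant) component — microbial similarity matrices in
    particular — have prior-scale variances far above the realized
    between-animal variance, which inflates the phenotypic variance and
    distorts the ratios; sample-referencing makes estimates comparable
    across kernels and to simulation ground truth.
    """
    if all(v <= 0 for v in components.values()):
        raise MixedModelError("all variance components are zero")
    eff = dict(components)
    if scales:
        for k, s in scales.items():
            if k in eff and k != "residual":
                eff[k] = eff[k] * s
    resid_mult = 1.0 if trait_kind == "individual" else cage_factor
    sig_p = sum(v for k, v in eff.items() if k != "residual")
    sig_p += resid_mult * eff.get("residual", 0.0)
    ratios = {RATIO_NAMES[k]: eff[k] / sig_p for k in eff if k in RATIO_NAMES}
    return ratios, sig_p


def sample_reference_scales(spec: ModelSpec) -> dict[str, float]:
    """Per-term factors converting prior-scale variances to realized
    between-record variances.

    For term k with record-level covariance structure G_k = Z_k K_k Z_k',
    the variance the effect expresses across the sampled records is
    sigma_k^2 (mean diag G_k - mean offdiag G_k): the common component of
    the kernel shifts all animals together and is absorbed by the
    intercept, not seen as between-animal variance.
    """
    scales = {}
    for t, G in zip(spec.terms, _v_matrices(spec)):
        n = G.shape[0]
        dg = float(np.trace(G)) / n
        off = (float(G.sum()) - float(np.trace(G))) / (n * (n - 1)) if n > 1 else 0.0
        scales[t.name] = dg - off
    return scales


def blup_predict(
    fit: MixedModelFit, X_new: np.ndarray, Z_new: dict[str, np.ndarray]
) -> np.ndarray:
    """Predicted phenotypes for new records (see :meth:`MixedModelFit.predict`)."""
    return fit.predict(X_new, Z_new)
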