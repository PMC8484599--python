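"""Cross-validation assessment of predictive ability, M1 vs M2.

Predictive ability is the across-replicate average Pearson correlation
between predicted and observed phenotypes in a held-out validation set.
Individual traits use 0.9/0.1 train/validation splits constrained so that
every validation animal's litter and cage also appear in training; cage
traits assign whole cages to sets with probabilities 0.8/0.2, stratified
within batch.  Model comparisons use an empirical bootstrap paired t test
(resampling mean-centred paired differences under the null) with Bonferroni
or Benjamini-Hochberg adjustment, plus the share of replicates in which the
microbial model wins outright.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .mixed_model import ModelSpec, RandomTerm, em_reml

__all__ = [
    "CVResult",
    "ValidationError",
    "split_individual",
    "split_cage",
    "predictive_ability",
    "bootstrap_paired_ttest",
    "adjust_pvalues",
    "replicate_win_rate",
    "run_cv_experiment",
]

log = logging.getLogger(__name__)


class ValidationError(ValueError):
    pass


@dataclass
class CVResult:
    """Per-replicate paired correlations and their summary statistics."""

    correlations: pd.DataFrame = field(repr=False)  # replicate, corr_m1, corr_m2
    p_value: float = np.nan
    p_adjusted: float = np.nan
    win_rate: float = np.nan
    declared_superior: bool = False

    def summary(self) -> dict:
        c = self.correlations
        return {
            "mean_m1": float(c["corr_m1"].mean()), "sd_m1": float(c["corr_m1"].std()),
            "mean_m2": float(c["corr_m2"].mean()), "sd_m2": float(c["corr_m2"].std()),
            "p_value": self.p_value, "p_adjusted": self.p_adjusted,
            "win_rate": self.win_rate, "declared_superior": self.declared_superior,
        }


def split_individual(
    design: pd.DataFrame, p_train: float = 0.9, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/validation split of animals with litter/cage coverage.

    Each animal lands in validation with probability ``1 - p_train``, then
    any validation animal whose litter or cage would otherwise vanish from
    training is forced back into training, so every validation animal's
    litter and cage are represented in the training set.
    """
    rng = np.random.default_rng(seed)
    animals = design["animal"].to_numpy()
    in_val = rng.random(len(animals)) > p_train
    lit = design["litter"].to_numpy()
    cage = design["cage"].to_numpy()
    for fac in (lit, cage):
        for lev in np.unique(fac):
            members = fac == lev
            if in_val[members].all():
                # keep at least one member in training
                idx = np.flatnonzero(members)
                in_val[rng.choice(idx)] = False
    if in_val.sum() == 0:
        log.warning("empty validation set after constraint forcing")
    return animals[~in_val], animals[in_val]


def split_cage(
    design: pd.DataFrame, p_train: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Assign cages to train/validation independently, stratified by batch.

    If all of a batch's cages fall in one set the batch is resampled once;
    a persisting degenerate batch is left as drawn, with a warning.
    """
    rng = np.random.default_rng(seed)
    cages = design[["cage", "batch"]].drop_duplicates()
    train, val = [], []
    for batch, grp in cages.groupby("batch"):
        ids = grp["cage"].to_numpy()
        if len(ids) < 2:
            raise ValidationError(f"batch {batch} has <2 cages")
        for attempt in range(2):
            in_train = rng.random(len(ids)) < p_train
            if 0 < in_train.sum() < len(ids) or attempt == 1:
                if in_train.all() or not in_train.any():
                    log.warning("batch %s: all cages in one set after resample", batch)
                break
        train.extend(ids[in_train])
        val.extend(ids[~in_train])
    return np.array(train), np.array(val)


def predictive_ability(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation between observed and predicted phenotypes."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if len(observed) < 3:
        raise ValidationError("need at least 3 pairs")
    if observed.std() == 0 or predicted.std() == 0:
        log.warning("zero variance in correlation input; returning NaN")
        return np.nan
    return float(np.corrcoef(observed, predicted)[0, 1])


def bootstrap_paired_ttest(
    corrs_1: np.ndarray, corrs_2: np.ndarray, n_boot: int = 1000, seed: int = 0
) -> float:
    """One-sided empirical bootstrap p for mean(corrs_2 - corrs_1) > 0.

    Differences are centred to mean zero (the null), resampled with
    replacement ``n_boot`` times; p is the share of bootstrap means greater
    than or equal to the observed mean difference.
    """
    c1 = np.asarray(corrs_1, dtype=float)
    c2 = np.asarray(corrs_2, dtype=float)
    if len(c1) != len(c2):
        raise ValidationError("paired vectors differ in length")
    d = c2 - c1
    obs = d.mean()
    centred = d - obs
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(d), size=(n_boot, len(d)))
    boot_means = centred[idx].mean(axis=1)
    return float(np.mean(boot_means >= obs))


def adjust_pvalues(p_list, method: str = "bonferroni") -> np.ndarray:
    """Bonferroni (min(1, m p)) or Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p_list, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "bh_fdr": "fdr_bh"}[method]
    return multipletests(p, method=key)[1]


def replicate_win_rate(corrs_1, corrs_2) -> float:
    """Fraction of replicates where the second model's correlation is
    strictly higher."""
    c1 = np.asarray(corrs_1, dtype=float)
    c2 = np.asarray(corrs_2, dtype=float)
    if len(c1) != len(c2):
        raise ValidationError("paired vectors differ in length")
    return float(np.mean(c2 > c1))


def _subset_spec(spec: ModelSpec, mask: np.ndarray) -> ModelSpec:
    terms = [RandomTerm(t.name, t.Z[mask], t.kernel, t.levels) for t in spec.terms]
    ids = [r for r, m in zip(spec.record_ids, mask) if m] if spec.record_ids else []
    return ModelSpec(spec.trait, spec.y[mask], spec.X[mask], terms, spec.trait_kind, ids)


def run_cv_experiment(
    spec: ModelSpec,
    design: pd.DataFrame,
    n_replicates: int = 100,
    seed: int = 0,
    p_train: float | None = None,
    n_boot: int = 1000,
    adjust: str = "bonferroni",
    n_comparisons: int = 1,
    reml_kwargs: dict | None = None,
) -> CVResult:
    """Compare M2 (``spec``) with M1 (``spec`` minus the microbial term).

    Per replicate: draw the constrained split, train both models by EM-REML
    on the training records only, predict the validation records through the
    fitted effects (kernel covariance carries microbial and additive effects
    across), and record both correlations.  Summarised with the bootstrap
    paired t test (adjusted for ``n_comparisons``) and the strict win rate;
    ``declared_superior`` requires adjusted p < 0.05 *and* win rate >= 0.8.
    """
    if not spec.include_microbial:
        raise ValidationError("spec must include the microbial term (M2)")
    reml_kwargs = reml_kwargs or {}
    spec_m1 = spec.drop_term("microbial")
    if p_train is None:
        p_train = 0.9 if spec.trait_kind == "individual" else 0.8
    rows = []
    rec_ids = np.asarray(spec.record_ids)
    sub = design[design["animal"].isin(rec_ids)] if spec.trait_kind == "individual" else design
    for rep in range(n_replicates):
        rep_seed = seed * 100_000 + rep
        if spec.trait_kind == "individual":
            _, val_ids = split_individual(sub, p_train=p_train, seed=rep_seed)
        else:
            _, val_ids = split_cage(design, p_train=p_train, seed=rep_seed)
        val_mask = np.isin(rec_ids, val_ids)
        if val_mask.sum() < 3 or val_mask.sum() == len(rec_ids):
            log.warning("replicate %d: degenerate split, skipped", rep)
            continue
        train_mask = ~val_mask
        corr = {}
        for label, s in (("corr_m1", spec_m1), ("corr_m2", spec)):
            fit = em_reml(_subset_spec(s, train_mask), **reml_kwargs)
            Z_val = {t.name: t.Z[val_mask] for t in s.terms}
            pred = fit.predict(s.X[val_mask], Z_val)
            corr[label] = predictive_ability(spec.y[val_mask], pred)
        rows.append({"replicate": rep, **corr})
    df = pd.DataFrame(rows).dropna()
    if len(df) < 3:
        raise ValidationError("too few usable replicates")
    p = bootstrap_paired_ttest(df["corr_m1"].to_numpy(), df["corr_m2"].to_numpy(),
                               n_boot=n_boot, seed=seed)
    # cross-experiment BH adjustment is applied by the caller over all traits;
    # here only the per-trait Bonferroni factor is known
    p_adj = min(1.0, n_comparisons * p) if adjust == "bonferroni" else p
    wr = replicate_win_rate(df["corr_m1"].to_numpy(), df["corr_m2"].to_numpy())
    return CVResult(df, p, p_adj, wr, declared_superior=(p_adj < 0.05 and wr >= 0.8))
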