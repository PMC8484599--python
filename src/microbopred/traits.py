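"""Growth and feed-efficiency trait derivation, and incidence matrices.

Five analysis traits are derived from raw records:

* ``ADG_AL`` / ``ADG_R`` (g/day) — individual average daily gain: the OLS
  slope of an animal's body-weight records on age in days, computed
  separately per feeding regime (ad libitum vs restricted).
* ``ADFI_AL`` (g/day) — cage-average daily feed intake: total cage feed
  intake over the fattening period divided by days and by kits per cage.
* ``ADRFI_AL`` (g/day) — cage-average residual feed intake: the residual of
  a batch-nested regression of ADFI on cage-average gain and cage-average
  mid-period metabolic weight (BW^0.75).
* ``ADFCR_AL`` — cage-average feed conversion ratio: ADFI over cage-average
  gain.

Incidence matrices for the mixed models are indicator (0/1) matrices for
individual traits; for cage-average traits each row holds the *proportion*
of the cage's animals carrying each factor level, so rows sum to one per
factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TraitError",
    "PhenotypeSet",
    "DesignMatrices",
    "compute_adg",
    "compute_adfi",
    "compute_mw",
    "compute_adrfi",
    "compute_adfcr",
    "derive_phenotypes",
    "build_design_matrices",
]

log = logging.getLogger(__name__)

INDIVIDUAL_TRAITS = ("adg_al", "adg_r")
CAGE_TRAITS = ("adfi_al", "adrfi_al", "adfcr_al")


class TraitError(ValueError):
    pass


@dataclass
class PhenotypeSet:
    """Derived phenotypes: per-animal growth and per-cage feed efficiency."""

    individual: pd.DataFrame = field(repr=False)  # animal, trait, value
    cage: pd.DataFrame = field(repr=False)        # cage, trait, value

    def trait(self, name: str) -> pd.Series:
        name = name.lower()
        if name in INDIVIDUAL_TRAITS:
            df = self.individual[self.individual["trait"] == name]
            return df.set_index("animal")["value"]
        if name in CAGE_TRAITS:
            df = self.cage[self.cage["trait"] == name]
            return df.set_index("cage")["value"]
        raise TraitError(f"unknown trait {name!r}")

    def summary(self) -> pd.DataFrame:
        """N / mean / SD / IQR per trait."""
        frames = []
        for kind, df in (("individual", self.individual), ("cage", self.cage)):
            for t, grp in df.groupby("trait"):
                v = grp["value"].dropna()
                frames.append({
                    "trait": t, "kind": kind, "N": len(v), "mean": v.mean(),
                    "SD": v.std(), "IQR": v.quantile(0.75) - v.quantile(0.25),
                })
        return pd.DataFrame(frames)


def compute_adg(bw_records: pd.DataFrame) -> pd.Series:
    """Per-animal average daily gain: OLS slope of BW (g) on age (days).

    ``bw_records`` needs columns ``animal``, ``age_days``, ``bw_g``.
    Animals with fewer than two distinct ages get NaN (and a log entry).
    """
    out = {}
    for animal, grp in bw_records.groupby("animal"):
        ages = grp["age_days"].to_numpy(dtype=float)
        bw = grp["bw_g"].to_numpy(dtype=float)
        if len(np.unique(ages)) < 2:
            log.warning("animal %s: <2 distinct ages, ADG missing", animal)
            out[animal] = np.nan
            continue
        x = ages - ages.mean()
        out[animal] = float(x @ (bw - bw.mean()) / (x @ x))
    return pd.Series(out, name="adg")


def compute_adfi(total_cage_fi: float, n_days: float, n_kits: float) -> float:
    """Cage-average daily feed intake: total FI / (days * kits)."""
    if n_days <= 0 or n_kits <= 0:
        raise TraitError("n_days and n_kits must be positive")
    return total_cage_fi / (n_days * n_kits)


def compute_mw(mid_period_bw: float | np.ndarray, exponent: float = 0.75):
    """Metabolic weight BW^exponent (Kleiber scaling by default)."""
    bw = np.asarray(mid_period_bw, dtype=float)
    if (bw <= 0).any():
        raise TraitError("body weight must be positive")
    out = bw ** exponent
    return float(out) if out.ndim == 0 else out


def compute_adrfi(
    cage_df: pd.DataFrame, min_cages_per_batch: int = 4
) -> pd.Series:
    """Residual feed intake per cage: batch-nested OLS residuals.

    Within each batch, ADFI is regressed on cage-average gain and
    cage-average mid-period metabolic weight; the residuals are returned.
    Per-batch residuals sum to zero and are orthogonal to the regressors.
    ``cage_df`` needs columns ``cage``, ``batch``, ``adfi``, ``adg_bar``,
    ``mw_bar``.  Batches with fewer than ``min_cages_per_batch`` cages are
    flagged and their cages get NaN.
    """
    out = pd.Series(np.nan, index=cage_df["cage"], name="adrfi", dtype=float)
    for batch, grp in cage_df.groupby("batch"):
        if len(grp) < min_cages_per_batch:
            log.warning("batch %s: only %d cages, ADRFI skipped", batch, len(grp))
            continue
        X = np.column_stack([
            np.ones(len(grp)),
            grp["adg_bar"].to_numpy(dtype=float),
            grp["mw_bar"].to_numpy(dtype=float),
        ])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise TraitError(f"rank-deficient regressors in batch {batch}")
        y = grp["adfi"].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        out.loc[grp["cage"]] = y - X @ beta
    return out


def compute_adfcr(adfi: float, adg_bar: float) -> float:
    """Feed conversion ratio: cage ADFI over cage-average gain."""
    if adg_bar == 0:
        log.warning("zero cage-average gain, ADFCR missing")
        return np.nan
    return adfi / adg_bar


def derive_phenotypes(
    design: pd.DataFrame,
    bw_records: pd.DataFrame,
    cage_fi: pd.DataFrame | None = None,
) -> PhenotypeSet:
    """Derive all five traits from raw records.

    ``design`` needs columns ``animal``, ``cage``, ``batch``, ``regime``
    (``AL``/``R``).  ``cage_fi`` holds weekly cage intake (``cage``,
    ``week``, ``fi_g``) for ad-libitum cages; cage traits are skipped when
    it is None.  The mid-period metabolic weight uses each animal's recorded
    BW nearest the midpoint of its age span.
    """
    adg = compute_adg(bw_records)
    regime = design.set_index("animal")["regime"]
    indiv = pd.DataFrame({
        "animal": adg.index,
        "trait": ["adg_al" if regime.get(a) == "AL" else "adg_r" for a in adg.index],
        "value": adg.to_numpy(),
    })

    cage_rows = []
    if cage_fi is not None and len(cage_fi):
        cage_of = design.set_index("animal")["cage"]
        al_cages = set(design.loc[design["regime"] == "AL", "cage"])
        # mid-period BW per animal
        mid_bw = {}
        for animal, grp in bw_records.groupby("animal"):
            ages = grp["age_days"].to_numpy(dtype=float)
            mid = (ages.min() + ages.max()) / 2.0
            mid_bw[animal] = float(grp["bw_g"].iloc[int(np.argmin(np.abs(ages - mid)))])
        span = bw_records.groupby("animal")["age_days"].agg(["min", "max"])
        n_days_of = (span["max"] - span["min"]).groupby(cage_of.reindex(span.index)).mean()

        recs = []
        for cage, grp in cage_fi.groupby("cage"):
            if cage not in al_cages:
                continue
            members = design.loc[design["cage"] == cage, "animal"]
            n_kits = len(members)
            n_days = float(n_days_of.get(cage, 7 * grp["week"].nunique()))
            adfi = compute_adfi(grp["fi_g"].sum(), n_days, n_kits)
            adg_bar = adg.reindex(members).mean()
            mw_bar = compute_mw(np.array([mid_bw[a] for a in members if a in mid_bw])).mean()
            batch = design.loc[design["cage"] == cage, "batch"].iloc[0]
            recs.append({"cage": cage, "batch": batch, "adfi": adfi,
                         "adg_bar": adg_bar, "mw_bar": mw_bar})
        cages = pd.DataFrame(recs)
        if len(cages):
            adrfi = compute_adrfi(cages)
            for _, r in cages.iterrows():
                cage_rows.append({"cage": r["cage"], "trait": "adfi_al", "value": r["adfi"]})
                cage_rows.append({"cage": r["cage"], "trait": "adrfi_al",
                                  "value": adrfi.loc[r["cage"]]})
                cage_rows.append({"cage": r["cage"], "trait": "adfcr_al",
                                  "value": compute_adfcr(r["adfi"], r["adg_bar"])})
    cage_df = pd.DataFrame(cage_rows, columns=["cage", "trait", "value"])
    return PhenotypeSet(individual=indiv, cage=cage_df)


@dataclass
class DesignMatrices:
    """Fixed and random-effect incidence matrices for one trait's records.

    ``X`` is full-rank (intercept + treatment-coded batch + size).  ``Z``
    maps factor name (``additive``, ``litter``, ``cage``, ``microbial``) to
    a records x levels matrix; ``levels`` gives the column labels.  For
    individual traits Z rows are one-hot; for cage traits they hold the
    within-cage proportions of each level and sum to one per factor.
    """

    record_ids: list
    X: np.ndarray = field(repr=False)
    x_names: list = field(default_factory=list)
    Z: dict = field(default_factory=dict, repr=False)
    levels: dict = field(default_factory=dict)


def _fixed_effects(batch: pd.Series, size_big: pd.Series) -> tuple[np.ndarray, list]:
    batches = sorted(batch.unique())
    cols = [np.ones(len(batch))]
    names = ["intercept"]
    for b in batches[1:]:  # drop first level for identifiability
        cols.append((batch == b).to_numpy(dtype=float))
        names.append(f"batch_{b}")
    cols.append(size_big.to_numpy(dtype=float))
    names.append("size_big")
    return np.column_stack(cols), names


def build_design_matrices(
    design: pd.DataFrame,
    trait_kind: str,
    record_ids: list,
    microbial_levels: list | None = None,
) -> DesignMatrices:
    """Build X and all Z matrices for a trait's records.

    ``design`` needs columns ``animal``, ``litter``, ``cage``, ``batch``,
    ``size`` (``big``/``small``).  ``record_ids`` are animals (individual
    traits) or cages (cage traits), defining row order.  ``microbial_levels``
    defaults to the animals appearing in the records.
    """
    req = {"animal", "litter", "cage", "batch", "size"}
    if not req.issubset(design.columns):
        raise TraitError(f"design needs columns {sorted(req)}")
    d = design.set_index("animal")

    if trait_kind == "individual":
        missing = [a for a in record_ids if a not in d.index]
        if missing:
            raise TraitError(f"animals missing from design: {missing[:5]}")
        sub = d.loc[record_ids]
        X, x_names = _fixed_effects(sub["batch"], (sub["size"] == "big"))
        Z, levels = {}, {}
        for name, col in (("additive", None), ("litter", "litter"),
                          ("cage", "cage"), ("microbial", None)):
            vals = list(record_ids) if col is None else sub[col].tolist()
            lv = sorted(set(vals))
            if name == "microbial" and microbial_levels is not None:
                lv = list(microbial_levels)
            pos = {l: j for j, l in enumerate(lv)}
            Zm = np.zeros((len(record_ids), len(lv)))
            for i, v in enumerate(vals):
                Zm[i, pos[v]] = 1.0
            Z[name], levels[name] = Zm, lv
        return DesignMatrices(list(record_ids), X, x_names, Z, levels)

    if trait_kind != "cage":
        raise TraitError(f"unknown trait kind {trait_kind!r}")

    groups = {c: design[design["cage"] == c] for c in record_ids}
    for c, g in groups.items():
        if len(g) == 0:
            raise TraitError(f"cage {c} has no animals in design")
    batch = pd.Series({c: g["batch"].iloc[0] for c, g in groups.items()})
    prop_big = pd.Series({c: (g["size"] == "big").mean() for c, g in groups.items()})
    X, x_names = _fixed_effects(batch.loc[record_ids], prop_big.loc[record_ids])
    x_names[-1] = "prop_big"

    animals = sorted(design["animal"])
    litters = sorted(design["litter"].unique())
    m_levels = list(microbial_levels) if microbial_levels is not None else animals
    Z, levels = {}, {}
    for name, lv, col in (("additive", animals, "animal"),
                          ("litter", litters, "litter"),
                          ("microbial", m_levels, "animal")):
        pos = {l: j for j, l in enumerate(lv)}
        Zm = np.zeros((len(record_ids), len(lv)))
        for i, c in enumerate(record_ids):
            g = groups[c]
            w = 1.0 / len(g)
            for v in g[col]:
                Zm[i, pos[v]] += w
        Z[name], levels[name] = Zm, lv
    return DesignMatrices(list(record_ids), X, x_names, Z, levels)
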