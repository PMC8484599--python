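"""Synthetic study generator with known ground truth.

Emulates the structure of a rabbit growth / feed-efficiency experiment:
a multi-generation pedigree; fattening cages of 6-8 kits with at most two
kits per litter per cage; five batches; two feeding regimes (ad libitum
vs restricted); cecal microbiota assessed in ~2 kits per cage; overdispersed
compositional OTU counts on a random phylogeny; and phenotypes built from
additive-genetic, litter, cage, microbial and residual effects with
user-specified variance fractions.

Default parameters mirror the emulated study's scale: a pedigree of a few
thousand animals, ~190 cages across 5 batches, 963 OTUs, sequencing depth
in the tens of thousands of reads, ad-libitum daily gain averaging ~55
g/day with phenotypic variance ~41 (g/day)^2.

The microbial effect is linear in the row-normalized CSS abundances,
``m = O_norm b``, with the OTU effect vector ``b`` rescaled so that the
realized variance of ``m`` matches its target exactly — ground truth is
known by construction, which is what makes the downstream variance
partitioning and selection machinery testable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .otu_processing import OTUTable, css_normalize
from .pedigree import Pedigree, numerator_relationship

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedStudy",
    "SimulationError",
    "simulate_pedigree",
    "simulate_design",
    "simulate_tree",
    "simulate_otu_counts",
    "simulate_phenotypes",
    "mask_microbiota",
    "simulate_study",
    "restricted_feed_offer",
]

BW_AGES = (32, 39, 46, 53, 60, 66)


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate the study conditions."""

    n_founders: int = 80
    n_generations: int = 2
    n_batches: int = 5
    cage_size: int = 8
    kits_per_litter_mean: float = 8.0
    frac_regime_restricted: float = 0.5
    assessed_per_cage: int = 2
    n_otus: int = 963
    mean_depth: float = 35_000.0
    depth_log_sd: float = 0.3
    baseline_log_sd: float = 1.5
    cage_shift_sd: float = 0.5
    indiv_noise_sd: float = 0.5
    variance_fractions: dict = field(
        default_factory=lambda: {"h2": 0.2, "l2": 0.1, "c2": 0.1, "m2": 0.4})
    sigma_p2: float = 41.0
    trait_mean: float = 55.0
    regime_effect_restricted: float = -19.0
    size_effect_big: float = 4.0
    batch_effect_sd: float = 3.0
    bw_noise_sd: float = 10.0
    sparse_otu_effects: int | None = None  # None = dense effect vector b
    seed: int = 0

    def __post_init__(self) -> None:
        vf = self.variance_fractions
        if any(not (0 <= vf[k] <= 1) for k in vf) or sum(vf.values()) > 1 + 1e-12:
            raise SimulationError("variance fractions must lie in [0,1] and sum <= 1")
        if not (6 <= self.cage_size <= 8):
            raise SimulationError("cage_size must be 6-8")
        if not (1 <= self.assessed_per_cage <= self.cage_size):
            raise SimulationError("need cage_size >= assessed_per_cage >= 1")
        if self.n_founders < 2 or self.n_generations < 1:
            raise SimulationError("need n_founders >= 2 and n_generations >= 1")

    def residual_fraction(self) -> float:
        return 1.0 - sum(self.variance_fractions.values())


@dataclass
class GroundTruth:
    """True simulated effects and variance components, for testing."""

    effects: pd.DataFrame = field(repr=False)  # index animal: a, l, c, m, e, gain
    b: np.ndarray = field(repr=False)          # OTU effect vector
    components: dict = field(default_factory=dict)
    batch_effects: dict = field(default_factory=dict)


@dataclass
class SimulatedStudy:
    """Everything one study run produces."""

    config: SimulationConfig
    pedigree: Pedigree
    design: pd.DataFrame
    tree: TreeNode
    otu_counts: OTUTable
    bw_records: pd.DataFrame
    cage_fi: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        """Write all fixtures as plain-text files (TSV / Newick / YAML)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.pedigree.write(out / "pedigree.tsv")
        self.design.to_csv(out / "design.tsv", sep="\t", index=False)
        self.otu_counts.write(out / "otu_counts.tsv")
        self.bw_records.to_csv(out / "bw_records.tsv", sep="\t", index=False)
        self.cage_fi.to_csv(out / "cage_fi.tsv", sep="\t", index=False)
        self.tree.write(str(out / "tree.nwk"), format="newick")
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(asdict(self.config), fh)


def _rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, salt]))


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Multi-generation pedigree by random monogamous pairing.

    Founders (generation 0, unknown parents) are split evenly by sex; each
    generation pairs the previous generation's males and females at random,
    one litter per pair with 1 + Poisson(mean - 1) kits of random sex.  The
    final generation is the fattening cohort used by :func:`simulate_design`.
    """
    rng = _rng(config.seed, 1)
    records: list[tuple[int, int, int]] = []
    sexes: dict[int, str] = {}
    next_id = 1
    gen: list[int] = []
    for _ in range(config.n_founders):
        records.append((next_id, 0, 0))
        sexes[next_id] = "M" if next_id % 2 else "F"
        gen.append(next_id)
        next_id += 1
    generations = [list(gen)]
    for _ in range(config.n_generations):
        males = [a for a in gen if sexes[a] == "M"]
        females = [a for a in gen if sexes[a] == "F"]
        if not males or not females:
            raise SimulationError("one sex absent; cannot form matings")
        rng.shuffle(males)
        rng.shuffle(females)
        newgen: list[int] = []
        for sire, dam in zip(males, females):
            n_kits = 1 + rng.poisson(max(config.kits_per_litter_mean - 1.0, 0.0))
            for _ in range(n_kits):
                records.append((next_id, sire, dam))
                sexes[next_id] = rng.choice(["M", "F"])
                newgen.append(next_id)
                next_id += 1
        gen = newgen
        generations.append(list(gen))
    ped = Pedigree(pd.DataFrame(records, columns=["animal", "sire", "dam"]))
    ped.final_generation = generations[-1]  # type: ignore[attr-defined]
    return ped


def simulate_design(pedigree: Pedigree, config: SimulationConfig) -> pd.DataFrame:
    """Assign the final-generation kits to cages, batches, and regimes.

    Every cage holds ``cage_size`` kits (a few may hold up to one extra so
    that no kit is left stranded), all on one feeding regime, with at most
    two kits per litter per cage.  Kits are labelled big/small by a median
    split on simulated weaning body weight.  Microbiota-assessed flags are
    added by :func:`mask_microbiota`.
    """
    rng = _rng(config.seed, 2)
    kits = getattr(pedigree, "final_generation", None)
    if kits is None:
        parents = set(pedigree.records["sire"]) | set(pedigree.records["dam"])
        kits = [a for a in pedigree.animals if a not in parents]
    recs = pedigree.records.set_index("animal")
    litters = {}
    for k in kits:
        key = (int(recs.loc[k, "sire"]), int(recs.loc[k, "dam"]))
        litters.setdefault(key, []).append(k)

    n_kits = len(kits)
    n_cages = n_kits // config.cage_size
    if n_cages < 1:
        raise SimulationError(
            f"only {n_kits} kits for cages of {config.cage_size}: not enough kits")
    capacity = np.full(n_cages, config.cage_size)
    extra = n_kits - capacity.sum()
    for i in range(extra):  # spread the remainder, never beyond 8+1 of a litter pair
        capacity[i % n_cages] += 1

    cage_members: list[list[int]] = [[] for _ in range(n_cages)]
    cage_litters: list[dict[tuple, int]] = [{} for _ in range(n_cages)]
    litter_items = sorted(litters.items(), key=lambda kv: -len(kv[1]))
    dropped: list[int] = []
    for key, members in litter_items:
        members = list(members)
        rng.shuffle(members)
        chunks = [members[i:i + 2] for i in range(0, len(members), 2)]
        for chunk in chunks:
            # most-space-first among cages not already holding 2 of this litter
            order = np.argsort([-(capacity[c] - len(cage_members[c])) for c in range(n_cages)])
            placed = False
            for c in order:
                if cage_litters[c].get(key, 0) + len(chunk) <= 2 and \
                        len(cage_members[c]) + len(chunk) <= capacity[c]:
                    cage_members[c].extend(chunk)
                    cage_litters[c][key] = cage_litters[c].get(key, 0) + len(chunk)
                    placed = True
                    break
            if not placed:
                dropped.extend(chunk)
    # second pass: stranded pairs often fit as singles (any cage with space
    # and fewer than two kits of the litter)
    still_dropped: list[int] = []
    for kit in dropped:
        key = next(k2 for k2, members in litters.items() if kit in members)
        order = np.argsort([-(capacity[c] - len(cage_members[c])) for c in range(n_cages)])
        for c in order:
            if cage_litters[c].get(key, 0) < 2 and len(cage_members[c]) < capacity[c]:
                cage_members[c].append(kit)
                cage_litters[c][key] = cage_litters[c].get(key, 0) + 1
                break
        else:
            still_dropped.append(kit)
    dropped = still_dropped
    if dropped and len(dropped) > 0.05 * n_kits:
        raise SimulationError(
            f"max-two-kits-per-litter-per-cage unsatisfiable: {len(dropped)} kits unplaced")

    cage_ids = [f"C{c + 1:04d}" for c in range(n_cages)]
    batch_of = {cid: (c % config.n_batches) + 1 for c, cid in enumerate(cage_ids)}
    n_restricted = int(round(config.frac_regime_restricted * n_cages))
    restricted = set(rng.choice(n_cages, size=n_restricted, replace=False))

    rows = []
    litter_label = {key: f"L{j + 1:04d}" for j, (key, _) in enumerate(litter_items)}
    key_of = {k: key for key, members in litters.items() for k in members}
    for c, cid in enumerate(cage_ids):
        regime = "R" if c in restricted else "AL"
        for a in cage_members[c]:
            rows.append({"animal": a, "litter": litter_label[key_of[a]], "cage": cid,
                         "batch": batch_of[cid], "regime": regime})
    design = pd.DataFrame(rows).sort_values("animal").reset_index(drop=True)
    design["weaning_bw"] = rng.normal(700.0, 120.0, size=len(design)).round(0)
    design["size"] = np.where(design["weaning_bw"] > design["weaning_bw"].median(),
                              "big", "small")
    return mask_microbiota(design, config.assessed_per_cage, config.seed)


def mask_microbiota(design: pd.DataFrame, assessed_per_cage: int, seed: int) -> pd.DataFrame:
    """Flag exactly ``assessed_per_cage`` random animals per cage (all, if
    the cage is smaller) as microbiota-assessed."""
    rng = _rng(seed, 3)
    design = design.copy()
    design["assessed"] = False
    for cage, grp in design.groupby("cage"):
        k = min(assessed_per_cage, len(grp))
        chosen = rng.choice(grp.index.to_numpy(), size=k, replace=False)
        design.loc[chosen, "assessed"] = True
    return design


def simulate_tree(n_otus: int, seed: int = 0) -> TreeNode:
    """Random rooted binary tree over ``n_otus`` leaves.

    Random-join topology (coalescent-style) with exponential branch
    lengths; all branch lengths strictly positive.
    """
    if n_otus < 2:
        raise SimulationError("need at least 2 OTUs for a tree")
    rng = _rng(seed, 4)
    nodes = [f"OTU{j + 1:04d}:{rng.exponential(0.1) + 1e-3:.6f}" for j in range(n_otus)]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        length = rng.exponential(0.1) + 1e-3
        merged = f"({a},{b}):{length:.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    newick = nodes[0].rsplit(":", 1)[0] + ";"
    return TreeNode.read(io.StringIO(newick))


def simulate_otu_counts(
    design: pd.DataFrame, tree: TreeNode, config: SimulationConfig
) -> OTUTable:
    """Overdispersed compositional OTU counts for every animal.

    Per-animal compositions are softmax(log-normal baseline + cage-level
    shift + individual noise); counts are multinomial at a log-normally
    distributed depth.  Rows are generated for *all* animals — the assessed
    mask is applied downstream, so ground truth exists for everyone.
    """
    rng = _rng(config.seed, 5)
    otu_ids = sorted(t.name for t in tree.tips())
    if len(otu_ids) != config.n_otus:
        raise SimulationError("tree leaf count != n_otus")
    p = config.n_otus
    base = rng.normal(0.0, config.baseline_log_sd, size=p)
    cages = sorted(design["cage"].unique())
    shift = {c: rng.normal(0.0, config.cage_shift_sd, size=p) for c in cages}
    animals = design["animal"].tolist()
    counts = np.zeros((len(animals), p), dtype=int)
    cage_of = design.set_index("animal")["cage"]
    for i, a in enumerate(animals):
        eta = base + shift[cage_of[a]] + rng.normal(0.0, config.indiv_noise_sd, size=p)
        eta -= eta.max()
        comp = np.exp(eta)
        comp /= comp.sum()
        depth = int(np.round(rng.lognormal(np.log(config.mean_depth), config.depth_log_sd)))
        if depth <= 0:
            raise SimulationError("non-positive sequencing depth drawn")
        counts[i] = rng.multinomial(depth, comp)
    df = pd.DataFrame(counts, index=animals, columns=otu_ids)
    df.index.name = "sample_id"
    return OTUTable(df, stage="raw_counts")


def restricted_feed_offer(
    al_weekly_mean_fi: float, uplift: float = 0.10, fraction: float = 0.75
) -> float:
    """Offered feed for a restricted cage in a given week:
    ``fraction`` times the previous week's mean ad-libitum intake of the
    same batch, plus ``uplift`` to track growth."""
    return fraction * al_weekly_mean_fi * (1.0 + uplift)


def simulate_phenotypes(
    design: pd.DataFrame,
    pedigree: Pedigree,
    otu_table: OTUTable,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Body-weight series, weekly cage feed intake, and ground truth.

    The latent daily gain of animal i is

        gain_i = mu + batch + size + regime + a_i + l_i + c_i + m_i + e_i

    with Var(a) = h2 sigma_P^2 via the pedigree (a ~ N(0, A sigma_A^2)),
    litter and cage effects iid normal, the microbial effect linear in the
    row-normalized CSS abundances with the OTU effect vector rescaled so the
    realized Var(m) hits its target, and iid residuals.  Weekly BW records
    are linear in age plus measurement noise, so the fitted ADG slope
    recovers the latent gain.  Weekly feed intake is emitted for ad-libitum
    cages; restricted cages get the offered amount from the 0.75-of-AL rule.

    Returns ``(bw_records, cage_fi, truth)``.
    """
    rng = _rng(config.seed, 6)
    animals = design["animal"].tolist()
    n = len(animals)
    vf = config.variance_fractions
    sp2 = config.sigma_p2
    comp = {"additive": vf["h2"] * sp2, "litter": vf["l2"] * sp2,
            "cage": vf["c2"] * sp2, "microbial": vf["m2"] * sp2,
            "residual": config.residual_fraction() * sp2}

    def scale_to(x: np.ndarray, target: float) -> np.ndarray:
        # pin the realized (per-animal) variance to its target exactly, so
        # the configured fractions are the fractions actually simulated
        v = x.var()
        if target <= 0 or v == 0:
            return np.zeros_like(x) if target <= 0 else x
        return x * np.sqrt(target / v)

    # additive effects through the pedigree submatrix of the cohort
    if comp["additive"] > 0:
        A, _ = numerator_relationship(pedigree, ids=animals)
        w, V = np.linalg.eigh(A)
        if w.min() < -1e-8:
            raise SimulationError("relationship matrix not PSD")
        L = V * np.sqrt(np.clip(w, 0, None))
        a = scale_to(L @ rng.standard_normal(n), comp["additive"])
    else:
        a = np.zeros(n)

    litter_ids = design["litter"].tolist()
    cage_ids = design["cage"].tolist()
    l_eff = {x: rng.normal(0, 1.0) for x in sorted(set(litter_ids))}
    c_eff = {x: rng.normal(0, 1.0) for x in sorted(set(cage_ids))}
    l = scale_to(np.array([l_eff[x] for x in litter_ids]), comp["litter"])
    c = scale_to(np.array([c_eff[x] for x in cage_ids]), comp["cage"])

    # microbial effect: linear in row-normalized CSS abundances
    css = css_normalize(otu_table, scaling_quantile=0.5)
    O = css.data.loc[animals].to_numpy(dtype=float)
    O = O / np.linalg.norm(O, axis=1, keepdims=True)
    p = O.shape[1]
    if config.sparse_otu_effects:
        b = np.zeros(p)
        idx = rng.choice(p, size=config.sparse_otu_effects, replace=False)
        b[idx] = rng.standard_normal(config.sparse_otu_effects)
    else:
        b = rng.standard_normal(p)
    m = O @ b
    if comp["microbial"] > 0:
        sd = m.std()
        if sd == 0:
            raise SimulationError("degenerate microbial effect (constant profiles)")
        b *= np.sqrt(comp["microbial"]) / sd
        m = m - m.mean()
        m *= np.sqrt(comp["microbial"]) / m.std()
    else:
        b = np.zeros(p)
        m = np.zeros(n)
    e = scale_to(rng.standard_normal(n), comp["residual"])

    batch_eff = {bt: rng.normal(0, config.batch_effect_sd)
                 for bt in sorted(design["batch"].unique())}
    d = design.set_index("animal")
    fixed = np.array([
        config.trait_mean + batch_eff[d.loc[x, "batch"]]
        + (config.size_effect_big if d.loc[x, "size"] == "big" else 0.0)
        + (config.regime_effect_restricted if d.loc[x, "regime"] == "R" else 0.0)
        for x in animals])
    gain = fixed + a + l + c + m + e

    # weekly BW records, linear in age
    ages_full = BW_AGES
    bw_rows = []
    for i, x in enumerate(animals):
        w0 = d.loc[x, "weaning_bw"]
        for t in ages_full:
            bw = w0 + gain[i] * (t - ages_full[0])
            if config.bw_noise_sd > 0:
                bw += rng.normal(0, config.bw_noise_sd)
            bw_rows.append({"animal": x, "age_days": int(t), "bw_g": float(bw)})
    bw_records = pd.DataFrame(bw_rows)

    # weekly cage feed intake (measured for AL; offered by rule for R)
    n_weeks = len(ages_full) - 1
    gain_s = pd.Series(gain, index=animals)
    fi_rows = []
    al_weekly: dict[tuple, list[float]] = {}
    for cage, grp in design.groupby("cage"):
        if grp["regime"].iloc[0] != "AL":
            continue
        members = grp["animal"]
        mid_bw = d.loc[members, "weaning_bw"].to_numpy() + \
            gain_s.loc[members].to_numpy() * (ages_full[-1] - ages_full[0]) / 2.0
        daily = 1.8 * gain_s.loc[members].to_numpy() + 0.22 * np.abs(mid_bw) ** 0.75
        batch = grp["batch"].iloc[0]
        for wk in range(1, n_weeks + 1):
            fi = float(daily.sum() * 7 * (0.85 + 0.3 * wk / n_weeks)
                       + rng.normal(0, 50.0))
            fi_rows.append({"cage": cage, "week": wk, "fi_g": round(max(fi, 0.0), 1),
                            "kind": "measured"})
            al_weekly.setdefault((batch, wk), []).append(fi / len(members))
    for cage, grp in design.groupby("cage"):
        if grp["regime"].iloc[0] != "R":
            continue
        batch = grp["batch"].iloc[0]
        for wk in range(2, n_weeks + 1):
            prev = al_weekly.get((batch, wk - 1))
            if not prev:
                continue
            offer = restricted_feed_offer(float(np.mean(prev))) * len(grp)
            fi_rows.append({"cage": cage, "week": wk, "fi_g": round(offer, 1),
                            "kind": "offered"})
    cage_fi = pd.DataFrame(fi_rows)

    effects = pd.DataFrame({"a": a, "l": l, "c": c, "m": m, "e": e, "gain": gain},
                           index=pd.Index(animals, name="animal"))
    truth = GroundTruth(effects=effects, b=b, components=comp, batch_effects=batch_eff)
    return bw_records, cage_fi, truth


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run the full generator: pedigree -> design -> tree -> counts -> phenotypes."""
    ped = simulate_pedigree(config)
    design = simulate_design(ped, config)
    tree = simulate_tree(config.n_otus, config.seed)
    counts = simulate_otu_counts(design, tree, config)
    bw, fi, truth = simulate_phenotypes(design, ped, counts, config)
    return SimulatedStudy(config, ped, design, tree, counts, bw, fi, truth)
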