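"""Generator contracts: determinism, design constraints, variance targets."""

import numpy as np
import pandas as pd
import pytest

from microbopred.pedigree import inbreeding, validate_pedigree
from microbopred.synthetic_data import (
    SimulationConfig, SimulationError, mask_microbiota, restricted_feed_offer,
    simulate_design, simulate_otu_counts, simulate_phenotypes, simulate_pedigree,
    simulate_tree, simulate_study,
)
from microbopred.traits import compute_adg


def small_cfg(**kw):
    base = dict(n_founders=24, n_generations=2, n_otus=40, mean_depth=2000,
                seed=5, cage_shift_sd=0.8, indiv_noise_sd=0.3)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_variance_fraction_validation(self):
        with pytest.raises(SimulationError):
            SimulationConfig(variance_fractions={"h2": 0.8, "l2": 0.3, "c2": 0, "m2": 0})

    def test_cage_size_bounds(self):
        with pytest.raises(SimulationError):
            SimulationConfig(cage_size=12)


class TestPedigree:
    def test_deterministic_under_seed(self):
        p1 = simulate_pedigree(small_cfg())
        p2 = simulate_pedigree(small_cfg())
        pd.testing.assert_frame_equal(p1.records, p2.records)

    def test_valid_with_nonnegative_inbreeding(self):
        cfg = SimulationConfig(n_founders=40, n_generations=3, n_otus=10)
        ped = simulate_pedigree(cfg)
        validate_pedigree(ped)  # no exception
        F = inbreeding(ped)
        assert F.mean() >= 0

    def test_founders_unknown_parents(self):
        ped = simulate_pedigree(small_cfg())
        founders = ped.records[ped.records["sire"] == 0]
        assert len(founders) == 24
        assert (founders["dam"] == 0).all()


class TestDesign:
    def test_constraints(self):
        cfg = small_cfg()
        design = simulate_design(simulate_pedigree(cfg), cfg)
        sizes = design.groupby("cage").size()
        assert sizes.between(6, 9).all()
        # litter-in-cage constraint
        per = design.groupby(["cage", "litter"]).size()
        assert per.max() <= 2
        # one regime per cage
        assert (design.groupby("cage")["regime"].nunique() == 1).all()
        # every kit appears exactly once
        assert design["animal"].is_unique

    def test_all_ad_libitum_when_fraction_zero(self):
        cfg = small_cfg(frac_regime_restricted=0.0)
        design = simulate_design(simulate_pedigree(cfg), cfg)
        assert (design["regime"] == "AL").all()

    def test_assessed_two_per_cage(self):
        cfg = small_cfg(assessed_per_cage=2)
        design = simulate_design(simulate_pedigree(cfg), cfg)
        per_cage = design.groupby("cage")["assessed"].sum()
        assert (per_cage == 2).all()

    def test_mask_all_means_no_masking(self):
        cfg = small_cfg()
        design = simulate_design(simulate_pedigree(cfg), cfg)
        full = mask_microbiota(design, assessed_per_cage=9, seed=0)
        assert full["assessed"].all()

    def test_mask_deterministic(self):
        cfg = small_cfg()
        design = simulate_design(simulate_pedigree(cfg), cfg)
        m1 = mask_microbiota(design, 2, seed=9)["assessed"]
        m2 = mask_microbiota(design, 2, seed=9)["assessed"]
        assert (m1 == m2).all()


class TestTree:
    def test_two_leaves_cherry(self):
        t = simulate_tree(2, seed=0)
        assert len(list(t.tips())) == 2

    def test_deterministic_newick(self):
        assert str(simulate_tree(10, seed=3)) == str(simulate_tree(10, seed=3))

    def test_fifty_leaves_positive_lengths(self):
        t = simulate_tree(50, seed=1)
        tips = list(t.tips())
        assert len(tips) == 50
        lengths = [n.length for n in t.traverse() if n.length is not None]
        assert all(l > 0 for l in lengths)

    def test_too_few_otus(self):
        with pytest.raises(SimulationError):
            simulate_tree(1)


class TestCounts:
    def test_counts_sum_to_depth_and_cover_all_animals(self):
        cfg = small_cfg()
        ped = simulate_pedigree(cfg)
        design = simulate_design(ped, cfg)
        tree = simulate_tree(cfg.n_otus, cfg.seed)
        counts = simulate_otu_counts(design, tree, cfg)
        assert counts.shape[0] == len(design)
        depths = counts.data.sum(axis=1)
        assert (depths > 0).all()  # multinomial conservation: row sum == drawn depth

    def test_degenerate_limit_shares_one_composition(self):
        cfg = small_cfg(cage_shift_sd=0.0, indiv_noise_sd=0.0, mean_depth=200000,
                        depth_log_sd=0.0)
        ped = simulate_pedigree(cfg)
        design = simulate_design(ped, cfg)
        tree = simulate_tree(cfg.n_otus, cfg.seed)
        counts = simulate_otu_counts(design, tree, cfg)
        rel = counts.values() / counts.values().sum(axis=1, keepdims=True)
        # all samples estimate the same baseline composition
        assert np.max(rel.std(axis=0) / (rel.mean(axis=0) + 1e-12)) < 0.2

    def test_cage_structure_in_bray_curtis(self):
        from microbopred.kernels import bray_curtis
        cfg = small_cfg(cage_shift_sd=1.2, indiv_noise_sd=0.2)
        ped = simulate_pedigree(cfg)
        design = simulate_design(ped, cfg)
        tree = simulate_tree(cfg.n_otus, cfg.seed)
        counts = simulate_otu_counts(design, tree, cfg)
        D = bray_curtis(counts).matrix
        cages = design.set_index("animal").loc[counts.sample_ids, "cage"].to_numpy()
        same = cages[:, None] == cages[None, :]
        mask = ~np.eye(len(cages), dtype=bool)
        assert D[same & mask].mean() < D[~same].mean()


class TestPhenotypes:
    def test_h2_zero_gives_zero_additive_effect(self):
        cfg = small_cfg(variance_fractions={"h2": 0.0, "l2": 0.1, "c2": 0.1, "m2": 0.2})
        study = simulate_study(cfg)
        assert np.allclose(study.truth.effects["a"], 0.0)

    def test_noise_free_bw_recovers_latent_gain_exactly(self):
        cfg = small_cfg(bw_noise_sd=0.0)
        study = simulate_study(cfg)
        adg = compute_adg(study.bw_records)
        truth = study.truth.effects["gain"].reindex(adg.index)
        assert np.allclose(adg.to_numpy(), truth.to_numpy(), atol=1e-9)

    def test_variance_fractions_recovered_empirically(self):
        # ~1000 animals: sample variances of the simulated effects near targets
        cfg = SimulationConfig(
            n_founders=64, n_generations=2, n_otus=60, mean_depth=2000,
            variance_fractions={"h2": 0.2, "l2": 0.1, "c2": 0.1, "m2": 0.4}, seed=8)
        study = simulate_study(cfg)
        eff = study.truth.effects
        n = len(eff)
        assert n >= 900
        sp2 = cfg.sigma_p2
        # iid-effect targets within ~3 Monte-Carlo SEs; m is exact by scaling
        for col, frac in (("l", 0.1), ("c", 0.1), ("e", 0.1)):
            target = frac * sp2 if col != "e" else (1 - 0.8) * sp2
            se = target * np.sqrt(2 / max(eff[col].nunique() - 1, 10))
            assert abs(eff[col].var() - target) < 3.5 * se
        assert eff["m"].var(ddof=0) == pytest.approx(0.4 * sp2, rel=1e-6)

    def test_restricted_offer_rule(self):
        assert restricted_feed_offer(100.0) == pytest.approx(82.5)

    def test_restricted_cages_have_offered_feed_rows(self):
        study = simulate_study(small_cfg(frac_regime_restricted=0.5))
        kinds = study.cage_fi.groupby("kind").size()
        assert kinds.get("offered", 0) > 0 and kinds.get("measured", 0) > 0


class TestStudyBundle:
    def test_seed_determinism_end_to_end(self):
        s1 = simulate_study(small_cfg())
        s2 = simulate_study(small_cfg())
        pd.testing.assert_frame_equal(s1.design, s2.design)
        pd.testing.assert_frame_equal(s1.otu_counts.data, s2.otu_counts.data)
        pd.testing.assert_frame_equal(s1.bw_records, s2.bw_records)
        assert str(s1.tree) == str(s2.tree)

    def test_write_fixtures(self, tmp_path):
        study = simulate_study(small_cfg())
        study.write(tmp_path)
        for name in ("pedigree.tsv", "design.tsv", "otu_counts.tsv",
                     "bw_records.tsv", "cage_fi.tsv", "tree.nwk", "config.yaml"):
            assert (tmp_path / name).exists()
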