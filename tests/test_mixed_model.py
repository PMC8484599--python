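"""Mixed-model engine: MME assembly, EM-REML, Gibbs, ratios, prediction."""

import numpy as np
import pandas as pd
import pytest

from microbopred.kernels import build_kernel
from microbopred.mixed_model import (
    ChainConfig, MixedModelError, ModelSpec, RandomTerm, assemble_mme, em_reml,
    gibbs_sample, sample_reference_scales, variance_ratios,
)
from microbopred.otu_processing import OTUTable
from microbopred.pipeline import make_model_spec


def one_way_spec(rng, g=10, n_per=10, sig_b=4.0, sig_e=1.0):
    b = rng.normal(0, np.sqrt(sig_b), g)
    y = np.repeat(b, n_per) + rng.normal(0, np.sqrt(sig_e), g * n_per)
    Z = np.kron(np.eye(g), np.ones((n_per, 1)))
    X = np.ones((g * n_per, 1))
    return ModelSpec("toy", y, X, [RandomTerm("litter", Z, None, list(range(g)))])


class TestAssembleMME:
    def test_symmetric(self, rng):
        spec = one_way_spec(rng)
        C, rhs, slices = assemble_mme(spec, {"litter": 2.0, "residual": 1.0})
        assert np.allclose(C, C.T)
        assert set(slices) == {"fixed", "litter"}

    def test_lambda_to_zero_reproduces_ols(self, rng):
        spec = one_way_spec(rng, g=5, n_per=8)
        C, rhs, _ = assemble_mme(spec, {"litter": 1e10, "residual": 1.0})
        sol = np.linalg.solve(C, rhs)
        W = np.hstack([spec.X, spec.terms[0].Z])
        ols, *_ = np.linalg.lstsq(W, spec.y, rcond=None)
        # fits agree even though coefficients are only identified jointly
        assert np.allclose(W @ sol, W @ ols, atol=1e-4)

    def test_lambda_to_infinity_shrinks_to_zero(self, rng):
        spec = one_way_spec(rng, g=5, n_per=8)
        C, rhs, slices = assemble_mme(spec, {"litter": 1e-10, "residual": 1.0})
        sol = np.linalg.solve(C, rhs)
        assert np.allclose(sol[slices["litter"]], 0.0, atol=1e-6)


class TestEMREML:
    def test_balanced_one_way_closed_form(self, rng):
        spec = one_way_spec(rng, g=10, n_per=10)
        fit = em_reml(spec, tol=1e-12, max_iter=10000)
        y = spec.y.reshape(10, 10)
        mse_within = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum() / (100 - 10)
        msb = 10 * ((y.mean(axis=1) - y.mean()) ** 2).sum() / 9
        sig_b = (msb - mse_within) / 10
        assert fit.estimates.components["residual"] == pytest.approx(mse_within, abs=1e-6)
        assert fit.estimates.components["litter"] == pytest.approx(sig_b, abs=1e-6)

    def test_duplicating_records_leaves_ratios_unchanged(self, rng):
        spec = one_way_spec(rng, g=8, n_per=6)
        fit1 = em_reml(spec, tol=1e-10)
        t = spec.terms[0]
        spec2 = ModelSpec("toy", np.tile(spec.y, 2), np.tile(spec.X, (2, 1)),
                          [RandomTerm("litter", np.tile(t.Z, (2, 1)), None, t.levels)])
        fit2 = em_reml(spec2, tol=1e-10)
        r1 = fit1.estimates.components["litter"] / fit1.estimates.components["residual"]
        r2 = fit2.estimates.components["litter"] / fit2.estimates.components["residual"]
        # doubled data halves the residual's denominator role but the
        # variance *ratio* stays put (within REML's finite-sample wobble)
        assert r2 == pytest.approx(r1, rel=0.15)

    def test_zero_microbial_variance_estimated_near_zero(self, study, css_table):
        # engine-level null check: response has no microbial signal
        rng = np.random.default_rng(5)
        design = study.design
        assessed = design.loc[design["assessed"], "animal"]
        css = OTUTable(css_table.data.loc[assessed], stage="css")
        kern = build_kernel(css, design, "M_O", "none")
        d = design.set_index("animal").loc[list(kern.ids)]
        y = pd.Series(rng.normal(50, 3, len(kern.ids)), index=kern.ids)
        spec = make_model_spec("null", y, design, study.pedigree, kern, "individual")
        fit = em_reml(spec, tol=1e-6, max_iter=400, ratio_reference="sample")
        assert fit.estimates.ratios["m2"] < 0.1


class TestGibbs:
    def test_seed_determinism(self, rng):
        spec = one_way_spec(rng)
        cc = ChainConfig(n_iter=500, burn_in=100, thin=2, seed=42)
        f1 = gibbs_sample(spec, cc)
        f2 = gibbs_sample(spec, cc)
        pd.testing.assert_frame_equal(f1.samples, f2.samples)

    def test_agrees_with_reml_on_one_way_data(self, rng):
        spec = one_way_spec(rng, g=20, n_per=10)
        reml = em_reml(spec, tol=1e-10)
        gibbs = gibbs_sample(spec, ChainConfig(n_iter=4000, burn_in=1000, thin=3, seed=7))
        post_mean = gibbs.estimates.components["litter"]
        post_sd = gibbs.estimates.component_sds["litter"]
        assert abs(post_mean - reml.estimates.components["litter"]) < 2 * post_sd

    def test_divergence_guard(self, rng):
        spec = one_way_spec(rng)
        cc = ChainConfig(n_iter=50, burn_in=10, thin=1, seed=0)
        fit = gibbs_sample(spec, cc)  # healthy data: no divergence
        assert fit.samples.shape[0] == 40


class TestVarianceRatios:
    def test_individual_equal_components(self):
        comps = {"additive": 1, "litter": 1, "cage": 1, "microbial": 1, "residual": 1}
        ratios, sig_p = variance_ratios(comps, "individual")
        assert sig_p == 5
        assert all(v == pytest.approx(0.2) for v in ratios.values())

    def test_cage_trait_residual_times_seven(self):
        comps = {"additive": 1, "litter": 1, "microbial": 1, "residual": 1}
        ratios, sig_p = variance_ratios(comps, "cage", cage_factor=7)
        assert sig_p == 10
        assert ratios["h2"] == ratios["m2"] == ratios["l2"] == pytest.approx(0.1)

    def test_scale_invariance(self):
        comps = {"additive": 2.0, "litter": 1.0, "residual": 3.0}
        r1, _ = variance_ratios(comps, "individual")
        r2, _ = variance_ratios({k: 10 * v for k, v in comps.items()}, "individual")
        assert r1 == pytest.approx(r2)

    def test_all_zero_rejected(self):
        with pytest.raises(MixedModelError):
            variance_ratios({"additive": 0.0, "residual": 0.0}, "individual")

    def test_sample_reference_scales_identity_terms(self, rng):
        spec = one_way_spec(rng, g=10, n_per=3)
        scales = sample_reference_scales(spec)
        # grouped identity kernel: diag 1, off-diagonal share ~ (n_per-1)/(n-1)
        assert scales["litter"] == pytest.approx(1.0, abs=0.1)


class TestPrediction:
    def test_training_prediction_reproduces_fitted(self, rng):
        spec = one_way_spec(rng)
        fit = em_reml(spec, tol=1e-10)
        pred = fit.predict(spec.X, {"litter": spec.terms[0].Z})
        assert np.allclose(pred, fit.fitted(), atol=1e-8)

    def test_identity_block_validation_microbial_effect_zero(self, rng):
        # kernel covers 6 levels: 4 training (correlated block), 2 identity
        n_train = 12
        K = np.eye(6)
        K[:4, :4] = 0.5 + 0.5 * np.eye(4)
        Z = np.zeros((n_train, 6))
        Z[np.arange(n_train), np.arange(n_train) % 4] = 1.0
        y = rng.normal(0, 1, n_train)
        spec = ModelSpec("t", y, np.ones((n_train, 1)),
                         [RandomTerm("microbial", Z, K, list(range(6)))])
        fit = em_reml(spec, tol=1e-8)
        assert np.allclose(fit.u["microbial"][4:], 0.0, atol=1e-10)

    def test_identical_profiles_get_identical_predicted_effects(self, rng):
        # validation level 4 duplicates training level 0's kernel row
        n_train = 12
        K = np.eye(5) * 0.4 + 0.6
        K[4, :] = K[0, :]
        K[:, 4] = K[:, 0]
        K[4, 4] = K[0, 0]
        Z = np.zeros((n_train, 5))
        Z[np.arange(n_train), np.arange(n_train) % 4] = 1.0
        y = rng.normal(0, 1, n_train)
        spec = ModelSpec("t", y, np.ones((n_train, 1)),
                         [RandomTerm("microbial", Z, K, list(range(5)))])
        fit = em_reml(spec, tol=1e-8)
        assert fit.u["microbial"][4] == pytest.approx(fit.u["microbial"][0], abs=1e-10)
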