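import dataclasses

import numpy as np
import pytest

from tapermix import (
    FixedParams,
    RandomSpec,
    ValidationError,
    VarComp,
    compare_models,
    default_mixed_config,
    fit_foce,
    fit_gls,
    fit_ols,
    generate,
    screen_active,
)
from tapermix.data_io import TaperDataset
from tapermix.estimation import FitResult


def _noise_free_config(**overrides):
    from tapermix import load_coefficient_set

    cs = load_coefficient_set("asturias-mm3")
    vc = VarComp(sigma2=1e-30, D_p=np.zeros((2, 2)), D_t=np.zeros((2, 2)), delta=0.0)
    return default_mixed_config(params=cs.params, varcomp=vc, **overrides)


class TestOls:
    def test_recovers_generating_coefficients_from_noise_free_data(self, mm3_set):
        data, _ = generate(_noise_free_config(n_plots=5, trees_per_plot=3, seed=11))
        fit = fit_ols(data)
        got = fit.params.as_array()
        want = mm3_set.params.as_array()
        assert np.allclose(got, want, rtol=1e-5, atol=1e-7)
        assert fit.sigma2 < 1e-12

    def test_underdetermined_dataset_rejected(self):
        from tests.conftest import make_tree

        data = TaperDataset((make_tree(sections=((1.0, 22.0), (5.0, 18.0), (9.0, 9.0))),))
        with pytest.raises(ValidationError):
            fit_ols(data)

    def test_information_criteria_identities(self, small_data):
        data, _, _ = small_data
        fit = fit_ols(data)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k, abs=1e-10)
        assert fit.bic == pytest.approx(
            -2 * fit.loglik + np.log(fit.n_obs) * fit.k, abs=1e-10)


class TestGls:
    def test_reduces_to_ols_without_variance_or_correlation(self, small_data):
        data, _, _ = small_data
        a = fit_ols(data)
        b = fit_gls(data, variance=False, car1=False)
        assert np.allclose(a.params.as_array(), b.params.as_array(), atol=1e-8)

    def test_likelihood_no_worse_than_nested_submodel(self, small_data):
        data, _, _ = small_data
        sub = fit_gls(data, variance=False, car1=False)
        full = fit_gls(data, variance=True, car1=True)
        assert full.loglik >= sub.loglik - 1e-6

    def test_recovers_variance_and_correlation_parameters(self):
        # moderate-size single replicate; +/-0.12 is ~4 sampling SEs here
        from tapermix import load_coefficient_set

        cs = load_coefficient_set("asturias-mm3")
        vc = VarComp(sigma2=6.117e-3, D_p=np.zeros((2, 2)), D_t=np.zeros((2, 2)),
                     delta=0.7, phi=0.5)
        cfg = default_mixed_config(n_plots=25, trees_per_plot=6, seed=77,
                                   params=cs.params, varcomp=vc)
        data, _ = generate(cfg)
        fit = fit_gls(data, variance=True, car1=True)
        assert fit.varcomp.delta == pytest.approx(0.7, abs=0.12)
        assert fit.varcomp.phi == pytest.approx(0.5, abs=0.12)


class TestFoce:
    def test_pinned_zero_covariances_reduce_to_gls(self):
        cfg = default_mixed_config(n_plots=6, trees_per_plot=3, seed=5)
        data, _ = generate(cfg)
        foce0 = fit_foce(data, cfg.spec, criterion="ML", variance=True,
                         car1=False, zero_d=True)
        gls = fit_gls(data, variance=True, car1=False)
        assert np.allclose(foce0.params.as_array(), gls.params.as_array(),
                           rtol=1e-3, atol=1e-4)
        assert foce0.varcomp.delta == pytest.approx(gls.varcomp.delta, abs=1e-2)

    def test_linear_random_intercept_matches_closed_form_lmm(self):
        # with only a0 active the profile is f = a0, so the fit is a two-level
        # random-intercept model; oracle = dense-algebra ML maximization
        params = FixedParams(a0=20.0, active=("a0",))
        vc = VarComp(sigma2=0.25, D_p=np.array([[2.0]]), D_t=np.array([[1.0]]))
        cfg = default_mixed_config(n_plots=6, trees_per_plot=3, seed=3,
                                   params=params, spec=RandomSpec(("a0",)),
                                   varcomp=vc)
        data, _ = generate(cfg)
        fit = fit_foce(data, cfg.spec, active=("a0",), criterion="ML",
                       variance=False, car1=False)

        # oracle: -2 log L of y_ij = mu + b_i + b_ij + eps, V per plot dense
        plots = list(data.plots().values())
        ys = [np.concatenate([t.section_diameters for t in trees]) for trees in plots]
        blocks = [[len(t.sections) for t in trees] for trees in plots]

        def neg2ll(theta):
            vp, vt, s2 = np.exp(theta)
            tot, logdet, quad, wsum = 0.0, 0.0, 0.0, 0.0
            ssum = 0.0
            # profile the mean out via GLS
            num = den = 0.0
            Vs = []
            for y, ns in zip(ys, blocks):
                n = sum(ns)
                V = np.full((n, n), vp)
                at = 0
                for nj in ns:
                    V[at:at + nj, at:at + nj] += vt
                    at += nj
                V[np.diag_indices(n)] += s2
                Vi = np.linalg.inv(V)
                one = np.ones(n)
                num += one @ Vi @ y
                den += one @ Vi @ one
                Vs.append((y, V))
            mu = num / den
            out = 0.0
            for y, V in Vs:
                r = y - mu
                sign, ld = np.linalg.slogdet(V)
                out += ld + r @ np.linalg.solve(V, r) + len(y) * np.log(2 * np.pi)
            return out, mu

        from scipy import optimize

        res = optimize.minimize(lambda th: neg2ll(th)[0], np.log([1.0, 1.0, 0.2]),
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxfev": 20000})
        n2l_oracle, mu_oracle = neg2ll(res.x)
        assert fit.params.a0 == pytest.approx(mu_oracle, abs=1e-4)
        assert -2 * fit.loglik == pytest.approx(n2l_oracle, abs=1e-3)

    def test_eblups_average_near_zero(self, small_foce_fit):
        for level in ("plot", "tree"):
            effs = np.array([[v["a1"], v["b3"]]
                             for v in small_foce_fit.eblups[level].values()])
            mean = effs.mean(axis=0)
            sd = effs.std(axis=0) + 1e-12
            assert np.all(np.abs(mean) < sd)

    def test_eblup_norms_shrink_as_covariances_scale_to_zero(
        self, small_data, small_foce_fit
    ):
        from tapermix import TaperMixedModel, calibrate

        data, _, cfg = small_data
        fit = small_foce_fit
        trees = list(data.plots()[data.plot_ids[0]])
        norms = []
        for scale in (1.0, 0.3, 0.1, 0.01):
            vc = VarComp(sigma2=fit.varcomp.sigma2,
                         D_p=scale * fit.varcomp.D_p,
                         D_t=scale * fit.varcomp.D_t,
                         delta=fit.varcomp.delta)
            mm = TaperMixedModel(fit.params, cfg.spec, vc)
            cal = calibrate(mm, trees)
            b = np.concatenate(
                [list(cal.plot_effects.values())]
                + [list(v.values()) for v in cal.tree_effects.values()])
            norms.append(np.linalg.norm(b))
        assert norms == sorted(norms, reverse=True)


class TestModelComparison:
    def test_identical_models_give_zero_lrt(self, small_data):
        data, _, _ = small_data
        fit = fit_ols(data)
        table, lrt = compare_models([fit, fit], names=["m", "m"], nested=[(0, 1)])
        assert lrt.loc[0, "stat"] == 0.0 and lrt.loc[0, "pvalue"] == 1.0
        assert list(table["aic"]) == [fit.aic, fit.aic]

    def test_reml_with_different_fixed_structures_refused(self, small_foce_fit):
        reduced = dataclasses.replace(
            small_foce_fit,
            params=FixedParams(a0=1.0, a1=0.9, active=("a0", "a1")),
            method="FOCE-REML",
        )
        with pytest.raises(ValueError, match="REML"):
            compare_models([reduced, small_foce_fit], nested=[(0, 1)])

    def test_different_datasets_refused(self, small_data):
        data, _, _ = small_data
        fit = fit_ols(data)
        other = dataclasses.replace(fit, n_obs=fit.n_obs + 1)
        with pytest.raises(ValueError):
            compare_models([fit, other])


class TestScreening:
    def test_drops_null_coefficient_and_refit_recovers_rest(self, mm3_set):
        # generate from a model whose b5 is exactly zero, then fit with b5
        # free: screening must discard it and keep the informative ones
        params = mm3_set.params.with_values(["b5"], [0.0])
        vc = VarComp(sigma2=0.3, D_p=np.zeros((2, 2)), D_t=np.zeros((2, 2)))
        cfg = default_mixed_config(n_plots=12, trees_per_plot=6, seed=42,
                                   params=params, varcomp=vc)
        data, _ = generate(cfg)
        fit = fit_ols(data)
        keep = screen_active(fit)
        assert "b5" not in keep
        assert {"a0", "a1", "b3"} <= set(keep)
        refit = fit_ols(data, active=keep)
        assert refit.params.b5 == 0.0
        assert refit.params.a1 == pytest.approx(params.a1, abs=0.05)
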