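import numpy as np
import pytest
from scipy import optimize

from tapermix import (
    FixedParams,
    RandomSpec,
    TaperDataset,
    TaperMixedModel,
    VarComp,
    assemble_calibration_system,
    calibrate,
    calibration_height_sweep,
    predict_diameter,
    subject_specific_predict,
)
from tests.conftest import make_tree


def _a0_model(vp=4.0, vt=1.0, sigma2=0.25, delta=0.0, a0=20.0):
    """Single expanded coefficient a0; with only a0 active the profile is
    f = a0, so the effect enters exactly linearly."""
    params = FixedParams(a0=a0, active=("a0",))
    vc = VarComp(sigma2=sigma2, D_p=np.array([[vp]]), D_t=np.array([[vt]]),
                 delta=delta)
    return TaperMixedModel(params, RandomSpec(("a0",)), vc)


class TestCalibrate:
    def test_zero_covariances_give_zero_effects_in_one_pass(self, mm3_model):
        vc0 = VarComp(sigma2=mm3_model.varcomp.sigma2,
                      D_p=np.zeros((2, 2)), D_t=np.zeros((2, 2)),
                      delta=mm3_model.varcomp.delta)
        mm0 = TaperMixedModel(mm3_model.params, mm3_model.spec, vc0)
        cal = calibrate(mm0, [make_tree(sections=((7.0, 12.0),))])
        assert cal.iterations == 1 and cal.converged
        assert all(v == 0.0 for v in cal.plot_effects.values())
        assert all(v == 0.0 for v in cal.tree_effects["T1"].values())

    def test_scalar_closed_form_with_linear_effect(self):
        # one tree, one observation, n_r = 1, f linear in the effect:
        # b_tot = (vp+vt) z r / (z^2 (vp+vt) + sigma2 g^2), split prop. vp:vt
        vp, vt, s2, delta = 4.0, 1.0, 0.25, 0.4
        mm = _a0_model(vp, vt, s2, delta)
        y, d = 23.0, 24.0
        tree = make_tree(d=d, sections=((5.0, y),))
        cal = calibrate(mm, [tree])
        z = 1.0  # df/da0 for f = a0
        r = y - 20.0
        g2 = d ** (2 * delta)
        b_tot = (vp + vt) * z * r / (z**2 * (vp + vt) + s2 * g2)
        assert cal.converged and cal.iterations <= 2
        assert cal.plot_effects["a0"] == pytest.approx(b_tot * vp / (vp + vt), rel=1e-10)
        assert cal.tree_effects["T1"]["a0"] == pytest.approx(b_tot * vt / (vp + vt), rel=1e-10)

    def test_observation_on_mean_curve_gives_null_effects(self, mm3_model):
        di = predict_diameter(mm3_model.params, None, 24.0, 14.0, 7.0)
        cal = calibrate(mm3_model, [make_tree(sections=((7.0, di),))])
        assert abs(cal.plot_effects["a1"]) < 1e-6
        assert abs(cal.tree_effects["T1"]["b3"]) < 1e-6

    def test_linear_case_matches_dense_blup_in_one_step(self):
        # two trees of one plot; Z is constant so a single update must land
        # exactly on D Z' (Z D Z' + R)^{-1} r from dense algebra
        mm = _a0_model()
        trees = [make_tree(tree="T1", sections=((2.0, 21.5), (7.0, 18.0))),
                 make_tree(tree="T2", d=30, h=17, sections=((4.0, 24.0),))]
        D, Z, R, r = assemble_calibration_system(mm, trees)
        expected = D @ Z.T @ np.linalg.solve(Z @ D @ Z.T + R, r)
        cal = calibrate(mm, trees)
        got = np.array([cal.plot_effects["a0"],
                        cal.tree_effects["T1"]["a0"],
                        cal.tree_effects["T2"]["a0"]])
        assert cal.iterations <= 2
        assert np.allclose(got, expected, atol=1e-12)

    def test_fixed_point_matches_penalized_criterion_minimum(self, mm3_model):
        # joint-posterior oracle: direct numerical minimization of
        # ||y - f(b)||^2_{R^-1} + b' D^-1 b on a 2-tree, 5-observation system
        trees = [make_tree(tree="T1", sections=((2.0, 21.0), (7.0, 15.5))),
                 make_tree(tree="T2", d=30, h=17,
                           sections=((3.0, 26.0), (9.0, 18.0), (12.0, 11.0)))]
        cal = calibrate(mm3_model, trees)
        names = mm3_model.spec.expanded
        b_hat = np.concatenate([[cal.plot_effects[n] for n in names]]
                               + [[cal.tree_effects[t.tree_id][n] for n in names]
                                  for t in trees])

        def penalized(b):
            D, Z, R, resid = assemble_calibration_system(mm3_model, trees, b)
            return resid @ np.linalg.solve(R, resid) + b @ np.linalg.solve(D, b)

        res = optimize.minimize(penalized, np.zeros(6), method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-16,
                                         "maxiter": 40000, "maxfev": 40000})
        assert np.max(np.abs(res.x - b_hat)) < 1e-4

    def test_refitting_all_observations_reproduces_stored_eblups(
        self, small_data, small_foce_fit
    ):
        data, _, cfg = small_data
        fit = small_foce_fit
        mm = fit.mixed_model()
        for plot_id, trees in list(data.plots().items())[:4]:
            cal = calibrate(mm, list(trees), tol=1e-10)
            for name in cfg.spec.expanded:
                assert cal.plot_effects[name] == pytest.approx(
                    fit.eblups["plot"][plot_id][name], abs=1e-4)
            for t in trees:
                for name in cfg.spec.expanded:
                    assert cal.tree_effects[t.tree_id][name] == pytest.approx(
                        fit.eblups["tree"][(plot_id, t.tree_id)][name], abs=1e-4)


class TestSubjectSpecificPredict:
    def test_zero_effects_equal_mean_response(self, mm3_model):
        vc0 = VarComp(sigma2=1e-3, D_p=np.zeros((2, 2)), D_t=np.zeros((2, 2)))
        mm0 = TaperMixedModel(mm3_model.params, mm3_model.spec, vc0)
        tree = make_tree()
        cal = calibrate(mm0, [tree])
        grid = np.linspace(0.5, 13.5, 20)
        ss = subject_specific_predict(mm0, cal, tree, grid, level="tree")
        assert np.allclose(ss, predict_diameter(mm3_model.params, None, 24, 14, grid))

    def test_unknown_tree_rejected(self, mm3_model):
        tree = make_tree()
        cal = calibrate(mm3_model, [tree])
        with pytest.raises(KeyError):
            subject_specific_predict(mm3_model, cal, make_tree(tree="T9"), [5.0])

    def test_tree_minus_plot_prediction_follows_effect_sign(self):
        mm = _a0_model()
        for y in (22.0, 18.0):  # above / below the mean level a0 = 20
            tree = make_tree(sections=((5.0, y),))
            cal = calibrate(mm, [tree])
            ss_tree = subject_specific_predict(mm, cal, tree, [5.0], level="tree")
            ss_plot = subject_specific_predict(mm, cal, tree, [5.0], level="plot")
            diff = float(ss_tree[0] - ss_plot[0])
            assert np.sign(diff) == np.sign(cal.tree_effects["T1"]["a0"])


class TestSweep:
    def test_noise_free_mean_response_tree_scores_zero(self, mm3_model):
        heights = np.array([1.0, 3.0, 5.0, 7.0, 9.0, 11.0])
        di = predict_diameter(mm3_model.params, None, 24.0, 14.0, heights)
        tree = make_tree(sections=tuple(zip(heights, di)))
        data = TaperDataset((tree,))
        sw = calibration_height_sweep(mm3_model, data, volumes=False)
        covered = sw.table.dropna(subset=["rmse_d"])
        assert len(covered) > 0
        assert (covered["rmse_d"] < 1e-6).all()

    def test_uncovered_classes_reported_missing(self, mm3_model):
        # sections only in the upper half: lower classes must appear with n=0
        heights = np.array([8.0, 10.0, 12.0])
        di = predict_diameter(mm3_model.params, None, 24.0, 14.0, heights)
        tree = make_tree(sections=tuple(zip(heights, di)))
        sw = calibration_height_sweep(mm3_model, TaperDataset((tree,)), volumes=False)
        low = sw.table[sw.table["class_high"] <= 0.5]
        assert (low["n_d"] == 0).all()
        assert low["rmse_d"].isna().all()
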