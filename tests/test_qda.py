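"""Quadratic discriminant classifier: fitting, posteriors, gating."""

import numpy as np
import pytest

import mirfluid as mf
from tests.conftest import make_separated_profiles, random_mvn_params


def _profiles_1d(panel, points_by_class):
    profiles = []
    for fluid, pts in points_by_class.items():
        for i, v in enumerate(pts):
            profiles.append(
                mf.DeltaCqProfile(f"{fluid}{i}", np.array([float(v)]),
                                  np.ones(1, bool), fluid)
            )
    return profiles


@pytest.fixture
def panel_1d():
    return mf.MarkerPanel(
        target_markers=("mA",), reference_markers=("ref",),
        fluid_classes=("fluidX", "fluidY"),
    )


class TestFitQDA:
    def test_two_1d_classes_hand_arithmetic(self, panel_1d):
        profiles = _profiles_1d(panel_1d, {"fluidX": [0, 2], "fluidY": [10, 12]})
        model = mf.fit_qda(profiles, panel_1d, ridge=0.0)
        assert model.classes == ("fluidX", "fluidY")
        np.testing.assert_allclose([c.mean[0] for c in model.components], [1.0, 11.0])
        # unbiased variance of {0,2} and {10,12} is 2
        np.testing.assert_allclose(
            [c.covariance[0, 0] for c in model.components], [2.0, 2.0]
        )

    def test_uniform_priors_over_eight_classes(self, panel):
        profiles = make_separated_profiles(panel, n_per_class=12, seed=0)
        model, _ = mf.train_model(profiles, panel, seed=0)
        assert len(model.classes) == 8  # 7 fluids + Other
        np.testing.assert_allclose(model.priors, np.full(8, 0.125))

    def test_empirical_priors_proportional_to_counts(self, panel_1d):
        profiles = _profiles_1d(
            panel_1d, {"fluidX": [0, 1, 2], "fluidY": [10, 11, 12, 13, 14, 15]}
        )
        model = mf.fit_qda(profiles, panel_1d, priors_mode="empirical")
        np.testing.assert_allclose(model.priors, [1 / 3, 2 / 3])

    def test_covariance_matches_two_pass_oracle(self, panel):
        rng = np.random.default_rng(21)
        profiles = make_separated_profiles(panel, n_per_class=20, seed=4)
        model = mf.fit_qda(profiles, panel, ridge=0.0)
        for cls, comp in zip(model.classes, model.components):
            X = np.vstack([p.values for p in profiles if p.fluid_label == cls])
            mu = X.sum(axis=0) / len(X)  # independent two-pass computation
            S = np.zeros((7, 7))
            for row in X:
                S += np.outer(row - mu, row - mu)
            S /= len(X) - 1
            np.testing.assert_allclose(comp.covariance, S, atol=1e-12)

    def test_class_below_minimum_count_names_class(self, panel_1d):
        profiles = _profiles_1d(panel_1d, {"fluidX": [0, 2], "fluidY": [10]})
        with pytest.raises(mf.TrainingError, match="fluidY"):
            mf.fit_qda(profiles, panel_1d)


class TestPosterior:
    def test_midpoint_of_mirror_symmetric_classes(self, panel_1d):
        profiles = _profiles_1d(panel_1d, {"fluidX": [-3, -1], "fluidY": [1, 3]})
        model = mf.fit_qda(profiles, panel_1d)
        np.testing.assert_allclose(mf.posterior(model, np.array([0.0])), [0.5, 0.5])

    def test_dominance_at_far_separated_mean(self, panel_1d):
        profiles = _profiles_1d(
            panel_1d, {"fluidX": [-0.5, 0.0, 0.5], "fluidY": [99.5, 100.0, 100.5]}
        )
        model = mf.fit_qda(profiles, panel_1d)
        p = mf.posterior(model, np.array([0.0]))
        assert p[0] > 0.999

    def test_matches_direct_density_oracle(self):
        # brute force: explicit determinant + inverse, no log space
        rng = np.random.default_rng(33)
        d, K = 3, 4
        panel = mf.MarkerPanel(
            target_markers=tuple(f"m{i}" for i in range(d)),
            reference_markers=("ref",),
            fluid_classes=tuple(f"f{k}" for k in range(K)),
        )
        comps = [random_mvn_params(d, rng) for _ in range(K)]
        priors = rng.dirichlet(np.ones(K))
        priors = priors / priors.sum()
        model = mf.QDAModel(panel=panel, classes=panel.fluid_classes,
                            components=tuple(comps), priors=priors)
        for _ in range(100):
            x = rng.normal(size=d) * 2
            direct = np.array(
                [
                    pi
                    * np.exp(-0.5 * (x - c.mean) @ np.linalg.inv(c.covariance) @ (x - c.mean))
                    / np.sqrt((2 * np.pi) ** d * np.linalg.det(c.covariance))
                    for pi, c in zip(priors, comps)
                ]
            )
            direct /= direct.sum()
            np.testing.assert_allclose(mf.posterior(model, x), direct, atol=1e-10)

    def test_stable_far_from_all_classes(self, panel_1d):
        # every raw density underflows; log-space posteriors stay normalized
        profiles = _profiles_1d(panel_1d, {"fluidX": [0, 1, 2], "fluidY": [5, 6, 7]})
        model = mf.fit_qda(profiles, panel_1d)
        p = mf.posterior(model, np.array([1e4]))
        assert np.all(np.isfinite(p))
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_class_posterior_is_one(self, panel_1d):
        model = mf.QDAModel(
            panel=panel_1d,
            classes=("fluidX",),
            components=(mf.MVNParams(np.zeros(1), np.eye(1)),),
            priors=np.array([1.0]),
        )
        for x in [-5.0, 0.0, 40.0]:
            assert mf.posterior(model, np.array([x]))[0] == 1.0
            assert mf.classify(model, np.array([x])).predicted == "fluidX"

    def test_non_finite_input_rejected(self, panel_1d):
        profiles = _profiles_1d(panel_1d, {"fluidX": [0, 1], "fluidY": [5, 6]})
        model = mf.fit_qda(profiles, panel_1d)
        with pytest.raises(mf.ValidationError):
            mf.posterior(model, np.array([np.nan]))


class TestClassify:
    def test_confident_argmax_reported(self, panel_1d):
        profiles = _profiles_1d(panel_1d, {"fluidX": [0, 1], "fluidY": [10, 11]})
        model = mf.fit_qda(profiles, panel_1d)
        res = mf.classify(model, np.array([0.5]))
        assert res.predicted == "fluidX"
        assert res.max_posterior == pytest.approx(max(res.posteriors))

    def test_sub_threshold_is_inconclusive(self, panel_1d):
        profiles = _profiles_1d(panel_1d, {"fluidX": [-3, -1], "fluidY": [1, 3]})
        model = mf.fit_qda(profiles, panel_1d, threshold=0.6)
        res = mf.classify(model, np.array([0.0]))  # posteriors (0.5, 0.5)
        assert res.predicted == "inconclusive"

    def test_exact_tie_at_threshold_takes_earlier_class(self, panel_1d):
        profiles = _profiles_1d(panel_1d, {"fluidX": [-3, -1], "fluidY": [1, 3]})
        model = mf.fit_qda(profiles, panel_1d, threshold=0.5)
        res = mf.classify(model, np.array([0.0]))
        assert res.posteriors[0] == pytest.approx(0.5)
        assert res.predicted == "fluidX"  # first in canonical order wins

    def test_gate_disabled_always_reports_argmax(self, panel_1d):
        profiles = _profiles_1d(panel_1d, {"fluidX": [-3, -1], "fluidY": [1, 3]})
        model = mf.fit_qda(profiles, panel_1d, threshold=0.9)
        res = mf.classify(model, np.array([0.1]), gate=False)
        assert res.predicted in ("fluidX", "fluidY")


class TestOpenSetBehavior:
    def test_far_outside_points_classified_other(self, panel):
        profiles = make_separated_profiles(panel, n_per_class=40, seed=9)
        model, pooled = mf.train_model(profiles, panel, seed=9)
        # points well beyond the 3.5 ellipsoid of the pooled fit
        X = mf.generate_other(pooled, 200, radius=6.0, inflation=3.0, seed=10)
        results = [mf.classify(model, x, gate=False) for x in X]
        frac_other = np.mean([r.predicted == panel.other_label for r in results])
        assert frac_other >= 0.95


class TestReferenceImplementationAgreement:
    def test_labels_match_sklearn_qda(self, panel):
        sklearn_qda = pytest.importorskip(
            "sklearn.discriminant_analysis"
        ).QuadraticDiscriminantAnalysis
        rng = np.random.default_rng(55)
        profiles = make_separated_profiles(panel, n_per_class=30, separation=3.0,
                                           seed=12)
        model = mf.fit_qda(profiles, panel, ridge=0.0)
        X = np.vstack([p.values for p in profiles])
        y = np.array([p.fluid_label for p in profiles])
        ref = sklearn_qda(priors=np.full(7, 1 / 7), store_covariance=True)
        ref.fit(X, y)
        Q = rng.normal(size=(1000, 7)) * 2 + X.mean(axis=0)
        ours = np.array([mf.classify(model, q, gate=False).predicted for q in Q])
        theirs = ref.predict(Q)
        post = mf.posterior_many(model, Q)
        top2 = np.sort(post, axis=1)[:, -2:]
        decisive = (top2[:, 1] - top2[:, 0]) > 1e-8
        assert (ours[decisive] == theirs[decisive]).all()
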