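"""Node-splitting, comparison-adjusted funnels, and Egger regression."""

import math

import numpy as np
import pandas as pd
import pytest

import propnma as P


def two_arm(study, effect, var, pair=("A", "B")):
    a, b = pair
    return P.PairwiseContrast(study, a, b, "accuracy", effect, var / 2, var / 2,
                              (var / 2, var / 2))


class TestNodeSplit:
    def test_constructed_agreement_gives_z_zero(self):
        # indirect path A-C-B built to equal the direct A-B contrast exactly
        cons = [
            two_arm("s1", 0.5, 0.2, ("A", "B")),
            two_arm("s2", 0.2, 0.2, ("A", "C")),
            two_arm("s3", 0.3, 0.2, ("C", "B")),
        ]
        model = P.NetworkMetaAnalysis(cons, reference="A")
        ns = P.node_split(model, ("A", "B"), tau2=0.0)
        assert ns.z == pytest.approx(0.0, abs=1e-12)
        assert ns.p == pytest.approx(1.0, abs=1e-12)

    def test_no_indirect_evidence_flagged(self):
        cons = [two_arm("s1", 0.5, 0.2), two_arm("s2", 0.6, 0.2)]
        model = P.NetworkMetaAnalysis(cons, reference="A")
        ns = P.node_split(model, ("A", "B"), tau2=0.0)
        assert not ns.splittable
        assert ns.p is None
        assert "no indirect" in ns.note

    def test_fixture_splittable_set(self, accuracy_model, accuracy_fit):
        """In the evidence network only the CNN/DenseNet/ResNet triangle has
        both direct and indirect evidence; every SVM spoke (CNN-SVM
        included) is a bridge whose removal severs the pair, so those
        comparisons carry no indirect information."""
        assert P.splittable_comparisons(accuracy_model) == [
            ("CNN", "DenseNet"), ("CNN", "ResNet"), ("DenseNet", "ResNet"),
        ]
        ns = P.node_split(accuracy_model, ("CNN", "SVM"), tau2=accuracy_fit.tau2)
        assert not ns.splittable
        assert "no indirect" in ns.note
        for pair in [("CNN", "DenseNet"), ("DenseNet", "ResNet")]:
            ns = P.node_split(accuracy_model, pair, tau2=accuracy_fit.tau2)
            assert ns.splittable
            assert math.isfinite(ns.z) and 0.0 <= ns.p <= 1.0

    def test_z_definition(self, triangle_model):
        res = triangle_model.fit("random")
        ns = P.node_split(triangle_model, ("A", "B"), tau2=res.tau2)
        z = (ns.direct_effect - ns.indirect_effect) / math.sqrt(
            ns.direct_se**2 + ns.indirect_se**2
        )
        assert ns.z == pytest.approx(z, abs=1e-12)

    def test_direct_indirect_combination_recovers_network(self, triangle_model):
        """Inverse-variance recombination of the split halves must give back
        the full-network estimate on consistent data."""
        res = triangle_model.fit("random")
        for pair in [("A", "B"), ("A", "C"), ("B", "C")]:
            ns = P.node_split(triangle_model, pair, tau2=res.tau2)
            wd, wi = ns.direct_se**-2, ns.indirect_se**-2
            combined = (wd * ns.direct_effect + wi * ns.indirect_effect) / (wd + wi)
            assert combined == pytest.approx(res.contrast(*pair)[0], abs=1e-6)


class TestFunnel:
    def test_symmetric_pair_centres_symmetrically(self):
        cons = [two_arm("s1", 0.5, 0.2), two_arm("s2", -0.5, 0.2)]
        pts = P.funnel_data(P.NetworkMetaAnalysis(cons, reference="A"))
        assert sorted(pts["effect"]) == pytest.approx([-0.5, 0.5], abs=1e-12)

    def test_identical_studies_centre_to_zero(self):
        cons = [two_arm(f"s{i}", 0.7, 0.3) for i in range(4)]
        pts = P.funnel_data(P.NetworkMetaAnalysis(cons, reference="A"))
        assert np.allclose(pts["effect"], 0.0, atol=1e-12)

    def test_weighted_centering_invariant(self, accuracy_model):
        pts = P.funnel_data(accuracy_model)
        for _, grp in pts.groupby("comparison"):
            w = 1.0 / grp["se"] ** 2
            assert float(np.sum(w * grp["effect"])) == pytest.approx(0.0, abs=1e-9)

    def test_fixture_point_counts(self, fixture_studies, accuracy_model):
        # full accuracy network: 9 two-arm contrasts + 3 from the 3-arm study
        all_cons = P.contrasts_from_studies(fixture_studies, "accuracy")
        assert len(all_cons) == 12
        # the analysed (SVM-connected) component excludes the FFR-NN edge
        assert len(P.funnel_data(accuracy_model)) == 11


class TestEgger:
    def test_too_few_points_rejected(self):
        pts = pd.DataFrame({"effect": [0.1, -0.2], "se": [0.2, 0.3]})
        with pytest.raises(ValueError, match="insufficient contrasts"):
            P.egger_test(pts)

    def test_symmetric_funnel_null(self):
        se = np.repeat([0.1, 0.2, 0.3, 0.4], 2)
        eff = np.tile([0.25, -0.25], 4)
        res = P.egger_test(pd.DataFrame({"effect": eff, "se": se}))
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-9)

    def test_weighted_regression_identity(self, accuracy_model):
        """OLS of effect/se on 1/se equals WLS of effect on se with 1/se^2
        weights (the classic algebraic identity)."""
        pts = P.funnel_data(accuracy_model)
        res = P.egger_test(pts)
        y = pts["effect"].to_numpy()
        se = pts["se"].to_numpy()
        X = np.column_stack([se, np.ones_like(se)])  # slope column = intercept of Egger
        w = 1.0 / se**2
        A = X * np.sqrt(w)[:, None]
        coef, *_ = np.linalg.lstsq(A, y * np.sqrt(w), rcond=None)
        assert res.intercept == pytest.approx(coef[0], abs=1e-10)
        assert res.slope == pytest.approx(coef[1], abs=1e-10)

    def test_planted_small_study_effect_detected(self):
        # effects proportional to se: a textbook small-study effect
        rng = np.random.default_rng(5)
        se = np.linspace(0.05, 0.6, 60)
        eff = 2.0 * se + rng.normal(0, se)
        eff -= np.sum(eff / se**2) / np.sum(1 / se**2)  # centre like a funnel
        res = P.egger_test(pd.DataFrame({"effect": eff, "se": se}))
        assert res.intercept > 0
        assert res.p < 0.01
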