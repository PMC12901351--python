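"""Network engine: WLS fits, DL tau2, Q decomposition, league table,
contribution matrix, and the pairwise-reduction oracle."""

import math

import numpy as np
import pytest

import propnma as P
from conftest import pairwise_dl_oracle


def two_arm(study, effect, var, pair=("A", "B")):
    a, b = pair
    return P.PairwiseContrast(study, a, b, "accuracy", effect, var / 2, var / 2,
                              (var / 2, var / 2))


class TestFixedFit:
    def test_single_study_passthrough(self):
        res = P.NetworkMetaAnalysis([two_arm("s1", 0.7, 0.09)], reference="B").fit("fixed")
        est, se = res.contrast("A", "B")
        assert est == pytest.approx(0.7, abs=1e-12)
        assert se == pytest.approx(0.3, abs=1e-12)

    def test_two_study_inverse_variance_pooling(self):
        cons = [two_arm("s1", 0.2, 0.1), two_arm("s2", 0.8, 0.4)]
        res = P.NetworkMetaAnalysis(cons, reference="B").fit("fixed")
        pooled = (0.2 / 0.1 + 0.8 / 0.4) / (1 / 0.1 + 1 / 0.4)
        assert res.contrast("A", "B")[0] == pytest.approx(pooled, abs=1e-12)

    def test_consistent_triangle_recovered(self):
        cons = [
            two_arm("s1", 1.0, 1e-8, ("A", "B")),
            two_arm("s2", 1.0, 1e-8, ("B", "C")),
            two_arm("s3", 2.0, 1e-8, ("A", "C")),
        ]
        res = P.NetworkMetaAnalysis(cons, reference="C").fit("fixed")
        assert res.contrast("A", "B")[0] == pytest.approx(1.0, abs=1e-6)
        assert res.contrast("A", "C")[0] == pytest.approx(2.0, abs=1e-6)

    def test_disconnected_network_lists_components(self, fixture_studies):
        cons = P.contrasts_from_studies(fixture_studies, "accuracy")
        with pytest.raises(P.DisconnectedNetworkError, match="FFR, NN"):
            P.NetworkMetaAnalysis(cons, reference="SVM")

    def test_underdetermined_network(self):
        with pytest.raises(P.UnderdeterminedNetworkError):
            P.NetworkMetaAnalysis([], reference="A")


class TestRandomFit:
    def test_tau2_zero_equals_fixed(self, triangle_model):
        fixed = triangle_model.fit("fixed")
        random = triangle_model.fit("random", tau2=0.0)
        assert random.contrast("B", "C") == pytest.approx(fixed.contrast("B", "C"))

    def test_huge_tau2_equalizes_weights(self):
        cons = [two_arm("s1", 0.0, 0.01), two_arm("s2", 1.0, 2.0)]
        res = P.NetworkMetaAnalysis(cons, reference="B").fit("random", tau2=1e6)
        assert res.contrast("A", "B")[0] == pytest.approx(0.5, abs=1e-3)

    def test_negative_tau2_rejected(self, triangle_model):
        with pytest.raises(ValueError):
            triangle_model.fit("random", tau2=-0.1)


class TestPairwiseReduction:
    """On any two-treatment dataset the network engine must reproduce the
    independently coded textbook pairwise meta-analysis to 1e-10."""

    def test_random_datasets(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            k = int(rng.integers(2, 9))
            d = rng.normal(0, 1, k)
            v = rng.uniform(0.01, 0.5, k)
            cons = [two_arm(f"s{i}", d[i], v[i]) for i in range(k)]
            model = P.NetworkMetaAnalysis(cons, reference="B")
            oracle = pairwise_dl_oracle(d, v)
            fixed = model.fit("fixed")
            rand = model.fit("random")
            assert fixed.contrast("A", "B")[0] == pytest.approx(oracle["mu_fixed"], abs=1e-10)
            assert fixed.contrast("A", "B")[1] == pytest.approx(oracle["se_fixed"], abs=1e-10)
            assert fixed.Q_total == pytest.approx(oracle["q"], abs=1e-10)
            assert rand.tau2_dl == pytest.approx(oracle["tau2"], abs=1e-10)
            assert rand.contrast("A", "B")[0] == pytest.approx(oracle["mu_random"], abs=1e-10)
            assert rand.contrast("A", "B")[1] == pytest.approx(oracle["se_random"], abs=1e-10)

    def test_matches_metafor_reference_implementation(self, tmp_path):
        """Cross-check against metafor's rma(method='DL') as an external
        reference for the two-treatment reduction."""
        import subprocess

        yi = [-0.8, 0.9, 0.1, 1.5, 0.3]
        vi = [0.05, 0.10, 0.08, 0.20, 0.12]
        script = tmp_path / "dl.R"
        script.write_text(
            "suppressMessages(library(metafor))\n"
            f"fit <- rma(yi=c({','.join(map(str, yi))}), "
            f"vi=c({','.join(map(str, vi))}), method='DL')\n"
            'cat(sprintf("%.12f %.12f %.12f\\n", fit$b[1], fit$se, fit$tau2))\n'
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True).stdout.split()
        mu_r, se_r, tau2_r = map(float, out)
        cons = [two_arm(f"s{i}", yi[i], vi[i]) for i in range(len(yi))]
        res = P.NetworkMetaAnalysis(cons, reference="B").fit("random")
        assert res.tau2_dl == pytest.approx(tau2_r, abs=1e-10)
        assert res.contrast("A", "B")[0] == pytest.approx(mu_r, abs=1e-10)
        assert res.contrast("A", "B")[1] == pytest.approx(se_r, abs=1e-10)

    def test_identical_studies_give_zero_tau2(self):
        cons = [two_arm(f"s{i}", 0.5, 0.2) for i in range(4)]
        res = P.NetworkMetaAnalysis(cons, reference="B").fit("random")
        assert res.Q_total == pytest.approx(0.0, abs=1e-12)
        assert res.tau2_dl == 0.0


class TestHeterogeneity:
    def test_homogeneous_network_band(self):
        cons = [two_arm(f"s{i}", 0.5, 0.2) for i in range(3)]
        res = P.NetworkMetaAnalysis(cons, reference="B").fit("fixed")
        assert res.I2_network == 0.0
        assert res.heterogeneity_band == "unimportant heterogeneity"

    @pytest.mark.parametrize(
        "i2, band",
        [
            (10.0, "unimportant heterogeneity"),
            (48.0, "moderate heterogeneity"),
            (60.0, "large heterogeneity"),
            (90.0, "important heterogeneity"),
        ],
    )
    def test_band_intervals(self, i2, band):
        assert P.heterogeneity_band(i2) == band

    def test_single_design_has_no_between_design_q(self):
        cons = [two_arm(f"s{i}", e, 0.2) for i, e in enumerate([0.1, 0.6, 0.9])]
        res = P.NetworkMetaAnalysis(cons, reference="B").fit("fixed")
        assert res.Q_between_design == pytest.approx(0.0, abs=1e-12)
        assert res.Q_within_design == pytest.approx(res.Q_total, abs=1e-12)

    def test_q_decomposition_adds_up(self, accuracy_fit):
        assert accuracy_fit.Q_within_design + accuracy_fit.Q_between_design == pytest.approx(
            accuracy_fit.Q_total, abs=1e-9
        )
        assert accuracy_fit.df_within + accuracy_fit.df_between == accuracy_fit.df_total


class TestLeagueTable:
    def test_diagonal_and_antisymmetry(self, accuracy_fit):
        league = accuracy_fit.league_table().set_index(["treat_a", "treat_b"])
        for a in accuracy_fit.treatments:
            assert league.loc[(a, a), "OR"] == pytest.approx(1.0, abs=1e-12)
            for b in accuracy_fit.treatments:
                ab, ba = league.loc[(a, b)], league.loc[(b, a)]
                assert ab["OR"] * ba["OR"] == pytest.approx(1.0, rel=1e-10)
                assert ab["ci_low"] == pytest.approx(1.0 / ba["ci_high"], rel=1e-10)

    def test_known_effect_recovered(self):
        cons = [two_arm(f"s{i}", math.log(2.0), 1e-9) for i in range(3)]
        res = P.NetworkMetaAnalysis(cons, reference="B").fit("random")
        entry = res.odds_ratio("A", "B")
        assert entry["OR"] == pytest.approx(2.0, abs=1e-4)

    def test_reference_invariance(self, fixture_studies):
        fits = [
            P.NetworkMetaAnalysis.from_studies(
                fixture_studies, "accuracy", reference=ref, component="SVM"
            ).fit("random")
            for ref in ("SVM", "CNN")
        ]
        a, b = fits
        assert a.tau2 == pytest.approx(b.tau2, abs=1e-12)
        for x, y in [("ResNet", "CNN"), ("Bayes", "LDS"), ("DenseNet", "SVM")]:
            assert a.contrast(x, y)[0] == pytest.approx(b.contrast(x, y)[0], abs=1e-12)
            assert a.contrast(x, y)[1] == pytest.approx(b.contrast(x, y)[1], abs=1e-12)

    def test_consistency_equations_all_triples(self, accuracy_fit):
        eff = accuracy_fit.effects
        ts = accuracy_fit.treatments
        for a in ts:
            for b in ts:
                for c in ts:
                    dab = eff[a] - eff[b]
                    dbc = eff[b] - eff[c]
                    dac = eff[a] - eff[c]
                    assert dab + dbc == pytest.approx(dac, abs=1e-12)


class TestContributionMatrix:
    def test_two_treatment_single_entry(self):
        res = P.NetworkMetaAnalysis([two_arm("s1", 0.5, 0.1)], reference="B").fit("fixed")
        cm = res.contribution_matrix()
        assert cm.shape == (1, 1)
        assert cm.iloc[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_rows_sum_to_one_on_fixture(self, accuracy_fit):
        cm = accuracy_fit.contribution_matrix()
        assert np.allclose(cm.sum(axis=1), 1.0, atol=1e-9)
        assert (cm.to_numpy() >= 0).all()

    def test_star_leaf_comparison_uses_only_its_spokes(self):
        # 3-leaf star around hub H: the B-vs-C estimate flows only
        # through the H-B and H-C spokes, never through H-A
        cons = [
            two_arm("s1", 0.1, 0.2, ("A", "H")),
            two_arm("s2", 0.2, 0.2, ("B", "H")),
            two_arm("s3", 0.3, 0.2, ("C", "H")),
        ]
        res = P.NetworkMetaAnalysis(cons, reference="H").fit("fixed")
        cm = res.contribution_matrix()
        row = cm.loc["B vs C"]
        assert row["A vs H"] == pytest.approx(0.0, abs=1e-12)
        assert row["B vs H"] == pytest.approx(0.5, abs=1e-12)
        assert row["C vs H"] == pytest.approx(0.5, abs=1e-12)


class TestSummary:
    def test_summary_mentions_key_quantities(self, accuracy_fit):
        text = accuracy_fit.summary()
        assert "tau^2" in text and "I^2" in text and "SVM" in text

    def test_geometry_counts(self, accuracy_model):
        geo = accuracy_model.geometry()
        assert len(geo["nodes"]) == 9
        svm = next(n for n in geo["nodes"] if n["treatment"] == "SVM")
        assert svm["n_studies"] == 7
        bayes_edge = next(
            e for e in geo["edges"] if {e["treat_a"], e["treat_b"]} == {"Bayes", "SVM"}
        )
        assert bayes_edge["n_studies"] == 2
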