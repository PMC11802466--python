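import numpy as np
import pytest
import xgboost as xgb

from histoswarm import boosting
from histoswarm.boosting import BoosterParams
from histoswarm.evaluation import BoosterModel, train_final
from histoswarm.explain import (_TreeEnsemble, bin_importance,
                                contribution_frequency_correlation,
                                decompose_prediction, explain_genes,
                                region_importance)
from histoswarm.patterns import Pattern, build_feature_matrix


def leaf_sum_logit(model, X):
    """Independent float64 reference: base logit plus the booster's own
    leaf assignments (pred_leaf) looked up in the tree table."""
    d = xgb.DMatrix(np.asarray(X, float), feature_names=model.feature_names)
    leaves = model.booster.predict(d, pred_leaf=True).astype(int)
    if leaves.ndim == 1:
        leaves = leaves[:, None]
    df = model.booster.trees_to_dataframe()
    value = {(t, n): g for t, n, g in zip(df["Tree"], df["Node"], df["Gain"])}
    out = np.full(len(X), model.base_logit())
    for i in range(len(X)):
        for t in range(leaves.shape[1]):
            out[i] += value[(t, leaves[i, t])]
    return out


@pytest.fixture
def counts_model(rng):
    patterns = [Pattern(k % 5, [0.1, 0.9, 0.2 + 0.05 * k], 0.7, name=f"pattern_{k}")
                for k in range(4)]
    X = rng.poisson(4, size=(250, 4)).astype(float)
    y = (X[:, 0] - 0.5 * X[:, 1] + rng.normal(0, 1, 250) > 2).astype(int)
    model = train_final(patterns, BoosterParams(num_boost_round=40, max_depth=3),
                        X, y, seed=9)
    return model, X, y


class TestDecomposition:
    def test_sum_identity_on_every_gene(self, counts_model):
        model, X, _ = counts_model
        reference = leaf_sum_logit(model, X)
        probs = model.predict_from_features(X)
        ens = _TreeEnsemble(model)
        for i in range(len(X)):
            e = decompose_prediction(model, X[i], _ensemble=ens)
            assert abs(e.logit - reference[i]) < 1e-6
            assert abs(e.probability - probs[i]) < 1e-6

    def test_agrees_with_brute_force_on_shallow_trees(self, rng):
        # depth <= 3 ensemble, explicit per-tree enumeration oracle
        patterns = [Pattern(0, [0.1, 0.9], 0.7, name="pattern_0"),
                    Pattern(1, [0.9, 0.1], 0.7, name="pattern_1")]
        X = rng.poisson(3, size=(120, 2)).astype(float)
        y = (X[:, 0] > 3).astype(int)
        booster = boosting.fit_booster(X, y, num_boost_round=5, eta=0.3, seed=1,
                                       feature_names=["pattern_0", "pattern_1"],
                                       extra_params={"max_depth": 3})
        model = BoosterModel(booster=booster, params=BoosterParams(), patterns=patterns)
        df = booster.trees_to_dataframe()

        def oracle(x):
            contrib = np.zeros(2)
            intercept = model.base_logit()
            for t, tdf in df.groupby("Tree"):
                nodes = tdf.set_index("ID").to_dict("index")

                def expected(nid):
                    nd = nodes[nid]
                    if nd["Feature"] == "Leaf":
                        return nd["Gain"]
                    cy, cn = nodes[nd["Yes"]]["Cover"], nodes[nd["No"]]["Cover"]
                    return (cy * expected(nd["Yes"]) + cn * expected(nd["No"])) / (cy + cn)

                nid = f"{t}-0"
                intercept += expected(nid)
                while nodes[nid]["Feature"] != "Leaf":
                    nd = nodes[nid]
                    fi = 0 if nd["Feature"] == "pattern_0" else 1
                    child = nd["Yes"] if x[fi] < nd["Split"] else nd["No"]
                    contrib[fi] += expected(child) - expected(nid)
                    nid = child
            return intercept, contrib

        for i in range(0, 120, 7):
            e = decompose_prediction(model, X[i])
            oi, oc = oracle(X[i])
            assert e.intercept == pytest.approx(oi)
            assert np.allclose(e.contributions, oc)

    def test_depth_one_stump_contribution_by_hand(self, rng):
        X = rng.poisson(3, size=(60, 1)).astype(float)
        y = (X[:, 0] > 3).astype(int)
        booster = boosting.fit_booster(X, y, num_boost_round=1, eta=0.3, seed=0,
                                       feature_names=["pattern_0"],
                                       extra_params={"max_depth": 1})
        model = BoosterModel(booster=booster, params=BoosterParams(),
                             patterns=[Pattern(0, [0.1, 0.9], 0.7, name="pattern_0")])
        leaves = booster.trees_to_dataframe().query("Feature == 'Leaf'")
        (vy, vn), (cy, cn) = leaves["Gain"].to_numpy(), leaves["Cover"].to_numpy()
        root_expected = (cy * vy + cn * vn) / (cy + cn)
        split = float(booster.trees_to_dataframe()["Split"].iloc[0])
        x_high = np.array([split + 5.0])
        e = decompose_prediction(model, x_high)
        assert e.contributions[0] == pytest.approx(vn - root_expected)
        assert e.intercept == pytest.approx(model.base_logit() + root_expected)

    def test_zero_tree_model_is_intercept_only(self):
        X = np.array([[1.0], [2.0]])
        booster = boosting.fit_booster(X, np.array([0, 1]), num_boost_round=0,
                                       feature_names=["pattern_0"])
        model = BoosterModel(booster=booster, params=BoosterParams(),
                             patterns=[Pattern(0, [0.1, 0.9], 0.7, name="pattern_0")])
        e = decompose_prediction(model, X[0])
        assert e.contributions.tolist() == [0.0]
        assert e.intercept == pytest.approx(model.base_logit())
        assert e.probability == pytest.approx(0.5)

    def test_wrong_length_rejected(self, counts_model):
        model, _, _ = counts_model
        with pytest.raises(ValueError, match="length"):
            decompose_prediction(model, np.zeros(9))


class TestBinImportance:
    def test_single_pattern_mass_uniform_over_matched_bins(self, small_dataset):
        motif = small_dataset.config.motif
        motif.name = "pattern_0"
        profiles = small_dataset.profiles.subset(small_dataset.gene_ids[:100])
        F = build_feature_matrix(profiles, [motif])
        y = small_dataset.labels.iloc[:100].to_numpy()
        model = train_final([motif], BoosterParams(num_boost_round=20),
                            F.to_numpy(), y, seed=0)
        contribs, _ = explain_genes(model, F)
        heat = bin_importance([(model, contribs, profiles)],
                              n_marks=profiles.n_marks, n_bins=profiles.n_bins)
        assert heat.sum() == pytest.approx(1.0)
        assert (heat >= 0).all()
        # all mass on the planted mark
        assert heat[motif.mark].sum() == pytest.approx(1.0)

    def test_importance_mass_concentrates_in_planting_window(self, small_dataset):
        cfg = small_dataset.config
        motif = cfg.motif
        motif.name = "pattern_0"
        profiles = small_dataset.profiles
        F = build_feature_matrix(profiles, [motif])
        y = small_dataset.labels.to_numpy()
        model = train_final([motif], BoosterParams(num_boost_round=20),
                            F.to_numpy(), y, seed=0)
        contribs, _ = explain_genes(model, F)
        heat = bin_importance([(model, contribs, profiles)],
                              n_marks=profiles.n_marks, n_bins=profiles.n_bins)
        share = region_importance(heat, mark=cfg.motif_mark,
                                  lo_label=cfg.placement_lo,
                                  hi_label=cfg.placement_hi)
        assert share > 0.8

    def test_no_contributions_rejected(self, small_dataset):
        motif = small_dataset.config.motif
        motif.name = "pattern_0"
        profiles = small_dataset.profiles.subset(small_dataset.gene_ids[:5])
        F = build_feature_matrix(profiles, [motif])
        contribs = F * 0.0
        model = train_final([motif], BoosterParams(num_boost_round=10),
                            F.to_numpy(), np.array([0, 1, 0, 1, 0]), seed=0)
        with pytest.raises(ValueError, match="non-zero"):
            bin_importance([(model, contribs, profiles)],
                           n_marks=profiles.n_marks, n_bins=profiles.n_bins)


class TestContributionCorrelation:
    def test_monotone_contribution_gives_rho_one(self):
        import pandas as pd
        patterns = [Pattern(0, [0.1, 0.9], 0.7, name="pattern_0")]
        freq = pd.DataFrame({"pattern_0": [1.0, 2, 3, 4, 5]})
        contrib = pd.DataFrame({"pattern_0": [0.1, 0.3, 0.5, 0.7, 0.9]})
        per_pattern, per_mark = contribution_frequency_correlation(
            contrib, freq, patterns)
        assert per_pattern["rho"].iloc[0] == pytest.approx(1.0)
        assert per_mark["n"].iloc[0] == 1

    def test_constant_frequency_pattern_skipped(self):
        import pandas as pd
        patterns = [Pattern(0, [0.1, 0.9], 0.7, name="pattern_0"),
                    Pattern(1, [0.9, 0.1], 0.7, name="pattern_1")]
        freq = pd.DataFrame({"pattern_0": [2.0, 2, 2, 2],
                             "pattern_1": [1.0, 2, 3, 4]})
        contrib = pd.DataFrame({"pattern_0": [0.1, 0.2, 0.3, 0.4],
                                "pattern_1": [0.5, 0.4, 0.2, 0.1]})
        per_pattern, _ = contribution_frequency_correlation(contrib, freq, patterns)
        assert per_pattern["pattern"].tolist() == [1]

    def test_activating_motif_correlates_positively(self, small_dataset):
        motif = small_dataset.config.motif
        motif.name = "pattern_0"
        profiles = small_dataset.profiles
        F = build_feature_matrix(profiles, [motif])
        y = small_dataset.labels.to_numpy()
        model = train_final([motif], BoosterParams(num_boost_round=30),
                            F.to_numpy(), y, seed=0)
        contribs, _ = explain_genes(model, F)
        per_pattern, per_mark = contribution_frequency_correlation(
            contribs, F, [motif])
        assert per_pattern["rho"].iloc[0] > 0.5
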