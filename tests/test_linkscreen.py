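"""Edge importance, pseudo-link balancing and the link classifiers."""

import numpy as np
import pandas as pd
import pytest

from shipflow import (ScreenConfig, build_edge_features, edge_importance, fully_connect,
                      sample_pseudo_links, screen_links, searoute_distance,
                      train_link_classifier)
from shipflow.geo import GeoPoint
from shipflow.linkscreen import LinkScreen

from conftest import make_network


class TestEdgeImportance:
    def test_hand_computed_minmax_fixture(self):
        # 4 ports along the equator; real edges with weights 1..4 and distinct
        # spans, plus constant-0.1 pseudo edges after augmentation.
        net = make_network(
            {("a", "b"): 1, ("b", "c"): 2, ("c", "d"): 3, ("a", "d"): 4},
            coords={"a": (0, 0), "b": (0, 1), "c": (0, 2), "d": (0, 3)},
        )
        full = fully_connect(net)
        eps = 1e-6
        imp = edge_importance(full, eps=eps)
        w = {e: full.weight(*e) for e in full.graph.edges()}
        d = {e: full.distance(*e) for e in full.graph.edges()}
        wmin, wmax = min(w.values()), max(w.values())
        dmin, dmax = min(d.values()), max(d.values())
        for e in w:
            what = (w[e] - wmin) / (wmax - wmin)
            dhat = (d[e] - dmin) / (dmax - dmin)
            assert imp[e] == pytest.approx(what / (dhat + eps), rel=1e-12)

    def test_direct_substitution_values(self):
        # normalised w-hat = 0.5 at d-hat = 0.5 gives importance 1 as eps -> 0
        assert 0.5 / (0.5 + 0.0) == 1.0
        assert 1.0 / (0.0 + 1e-6) == pytest.approx(1e6)

    def test_requires_augmented_network(self):
        net = make_network({("a", "b"): 1})
        with pytest.raises(ValueError):
            edge_importance(net)

    def test_degenerate_weights_warn(self):
        net = make_network({}, coords={"a": (0, 0), "b": (0, 1), "c": (0, 5)},
                           extra_ports=["a", "b", "c"])
        full = fully_connect(net)  # all weights 0.1 -> degenerate normalisation
        with pytest.warns(UserWarning):
            imp = edge_importance(full)
        assert all(v == 0.0 for v in imp.values())


class TestSeaRoute:
    def test_identical_points_zero(self):
        p = GeoPoint(10, 20)
        assert searoute_distance(p, p).km == 0.0

    def test_fallback_antipodal_value(self):
        d = searoute_distance(GeoPoint(0, 0), GeoPoint(0, 180))
        assert not d.routed
        assert d.km == pytest.approx(1.15 * np.pi * 6371.0, rel=1e-9)

    def test_routed_never_below_haversine(self):
        from shipflow.geo import haversine
        rng = np.random.default_rng(2)
        provider = lambda a, b: haversine(a, b) * (1 + rng.uniform(0, 0.5))
        for _ in range(100):
            a = GeoPoint(float(rng.uniform(-80, 80)), float(rng.uniform(-179, 180)))
            b = GeoPoint(float(rng.uniform(-80, 80)), float(rng.uniform(-179, 180)))
            assert searoute_distance(a, b, provider).km >= haversine(a, b) - 1e-9


def _feature_frame(n_real, n_pseudo, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_real + n_pseudo):
        real = i < n_real
        d = rng.uniform(100, 15000)
        rows.append({
            "source": f"s{i % 13}", "dest": f"d{i}",
            "d_haversine": d, "d_searoute": d * 1.15,
            "edge_importance": rng.uniform(0.5, 2.0) if real else rng.uniform(0, 0.05),
            "label": "real" if real else "pseudo",
            "source_region": f"R{i % 4}",
        })
    return pd.DataFrame(rows)


class TestPseudoSampling:
    def test_ratio_one_to_one(self):
        out = sample_pseudo_links(_feature_frame(10, 1000), seed=0)
        assert (out["label"] == "real").sum() == 10
        assert (out["label"] == "pseudo").sum() == 10

    def test_deterministic_under_seed(self):
        df = _feature_frame(25, 500)
        a = sample_pseudo_links(df, seed=9)
        b = sample_pseudo_links(df, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_no_duplicates_and_reals_kept(self):
        df = _feature_frame(30, 400)
        out = sample_pseudo_links(df, seed=1)
        pseudo = out[out["label"] == "pseudo"]
        assert pseudo["dest"].is_unique
        assert set(df[df["label"] == "real"]["dest"]) <= set(out["dest"])

    def test_stratum_counts_near_proportional(self):
        df = _feature_frame(100, 2000, seed=3)
        out = sample_pseudo_links(df, seed=4)
        pseudo_all = df[df["label"] == "pseudo"].copy()
        dec = pd.qcut(pseudo_all["d_haversine"].rank(method="first"), 10, labels=False)
        pseudo_all["_dec"] = dec.astype(int)
        chosen = out[out["label"] == "pseudo"].merge(
            pseudo_all[["dest", "_dec"]], on="dest")
        for (d, r), grp in pseudo_all.groupby(["_dec", "source_region"]):
            expected = 100 * len(grp) / len(pseudo_all)
            got = len(chosen[(chosen["_dec"] == d) & (chosen["source_region"] == r)])
            assert abs(got - expected) <= 1.0


class TestClassifiers:
    def test_separable_fixture_perfect_tree_accuracy(self):
        rows = _feature_frame(300, 3000, seed=5)
        balanced = sample_pseudo_links(rows, seed=5)
        cfg = ScreenConfig(seed=5, classifier_menu=("decision_tree", "random_forest"))
        _, report = train_link_classifier(balanced, cfg)
        assert (report["validation_accuracy"] == 1.0).all()

    def test_shuffled_labels_near_chance(self):
        rows = _feature_frame(1000, 1000, seed=6)
        rng = np.random.default_rng(6)
        rows["label"] = rng.permutation(rows["label"].to_numpy())
        cfg = ScreenConfig(seed=6, classifier_menu=("logistic",))
        _, report = train_link_classifier(rows, cfg)
        acc = report.loc["logistic", "validation_accuracy"]
        assert 0.4 <= acc <= 0.6

    def test_single_class_rejected(self):
        rows = _feature_frame(50, 0)
        with pytest.raises(ValueError):
            train_link_classifier(rows, ScreenConfig(seed=0))

    def test_report_reproducible_under_seed(self):
        rows = sample_pseudo_links(_feature_frame(80, 800, seed=7), seed=7)
        cfg = ScreenConfig(seed=7, classifier_menu=("logistic", "random_forest"))
        _, r1 = train_link_classifier(rows, cfg)
        _, r2 = train_link_classifier(rows, cfg)
        pd.testing.assert_frame_equal(r1, r2)


class _Constant:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)


class TestScreenLinks:
    def test_always_real_retains_all_pairs(self, small_world, small_world_net):
        full = fully_connect(small_world_net)
        feats = build_edge_features(full, provider=small_world.route_provider)
        screen = LinkScreen(_Constant(1), ["d_haversine", "d_searoute"], "const")
        n = small_world_net.n_ports()
        assert len(screen_links(full, screen, feats)) == n * (n - 1)

    def test_always_pseudo_retains_none(self, small_world, small_world_net):
        full = fully_connect(small_world_net)
        feats = build_edge_features(full, provider=small_world.route_provider)
        screen = LinkScreen(_Constant(0), ["d_haversine", "d_searoute"], "const")
        assert screen_links(full, screen, feats) == set()

    def test_trained_filter_recall_on_stable_links(self, small_world, small_world_net):
        """The deployed filter must recover nearly all links with >= 3 trips;
        dropped links should be the unstable 1-2-trip ones."""
        full = fully_connect(small_world_net)
        feats = build_edge_features(full, provider=small_world.route_provider)
        balanced = sample_pseudo_links(feats, seed=11)
        screen, _ = train_link_classifier(balanced, ScreenConfig(seed=11))
        retained = screen_links(full, screen, feats)
        stable = {(u, v) for u, v in small_world_net.real_edges()
                  if small_world_net.weight(u, v) >= 3}
        recall = len(stable & retained) / len(stable)
        assert recall >= 0.9
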