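"""Region encoding and gravity feature assembly."""

import numpy as np
import pandas as pd
import pytest

from shipflow import (FEATURE_NAMES, GeoPoint, Port, assemble_samples, build_network,
                      encode_regions, haversine, scale_features)
from shipflow.features import ODSample, fit_scaler, samples_from_jsonl, samples_to_jsonl
from shipflow.regions import default_region_mapping


class TestEncodeRegions:
    def test_default_mapping_known_countries(self):
        ports = [
            Port("suez", "As Suways", GeoPoint(29.97, 32.55), "Egypt"),
            Port("kep", "Keppel", GeoPoint(1.26, 103.84), "Singapore"),
        ]
        table = encode_regions(ports)
        assert table.country_to_region["Egypt"] == "Northern Africa"
        assert table.country_to_region["Singapore"] == "South-eastern Asia"

    def test_default_mapping_has_at_most_17_regions(self):
        assert default_region_mapping()["region"].nunique() <= 17

    def test_unmapped_country_listed(self):
        ports = [Port("x", "X", GeoPoint(0, 0), "Atlantis")]
        with pytest.raises(KeyError, match="Atlantis"):
            encode_regions(ports)

    def test_centroid_of_equator_symmetric_ports(self):
        ports = [
            Port("n", "N", GeoPoint(40, 7), "Fantasia"),
            Port("s", "S", GeoPoint(-40, 7), "Fantasia"),
        ]
        mapping = pd.DataFrame({"country": ["Fantasia"], "region": ["R"]})
        table = encode_regions(ports, mapping)
        assert table.centroids["R"].lat == pytest.approx(0.0, abs=1e-9)

    def test_region_cap_enforced(self):
        mapping = pd.DataFrame({
            "country": [f"c{i}" for i in range(18)],
            "region": [f"r{i}" for i in range(18)],
        })
        with pytest.raises(ValueError, match="17"):
            encode_regions([], mapping)


def _fixture():
    coords = {"a": (0, 0), "b": (0, 2), "c": (0, 10), "d": (0, 12), "e": (0, 14)}
    countries = {"a": "U", "b": "U", "c": "V", "d": "V", "e": "V"}
    ports = [Port(p, p.upper(), GeoPoint(*coords[p]), countries[p]) for p in coords]
    trips = pd.DataFrame(
        [("a", "c", 5), ("a", "d", 3), ("a", "b", 2), ("c", "a", 4)],
        columns=["source", "dest", "count"],
    )
    net = build_network(trips, ports)
    mapping = pd.DataFrame({"country": ["U", "V"], "region": ["RU", "RV"]})
    table = encode_regions(ports, mapping)
    metrics = pd.DataFrame(
        {
            "betweenness": [3.0, 0.0, 1.0, 0.5, 0.25],
            "closeness": [0.9, 0.2, 0.6, 0.4, 0.3],
            "pagerank": [0.4, 0.1, 0.3, 0.1, 0.1],
        },
        index=["a", "b", "c", "d", "e"],
    )
    trade = pd.DataFrame(
        [("U", "V", 100.0), ("V", "U", 50.0)], columns=["exporter", "importer", "usd"]
    )
    return net, metrics, table, trade


class TestAssembleSamples:
    def test_shape_contract_two_regions(self):
        net, metrics, table, trade = _fixture()
        samples = assemble_samples(net, metrics, table, trade,
                                   {("a", "b"), ("a", "c"), ("a", "d")})
        (s,) = samples
        assert s.regions == ["RU", "RV"]
        assert s.X.shape == (2, 10)
        assert s.O_i == 10
        assert list(s.y) == [2.0, 8.0]

    def test_hand_computed_feature_matrix(self):
        net, metrics, table, trade = _fixture()
        (s,) = assemble_samples(net, metrics, table, trade,
                                {("a", "b"), ("a", "c"), ("a", "d")})
        # region fluxes: into RU = c->a (4) + a->b (2) = 6; into RV = 5 + 3 = 8
        d_ru = haversine(GeoPoint(0, 0), GeoPoint(0, 1))
        d_rv = haversine(GeoPoint(0, 0), GeoPoint(0, 12))
        expected = np.array([
            # O_i, influx, dist, trade, btw_o, btw_med, clo_o, clo_med, pr_o, pr_med
            [10, 6, d_ru, 0.0, 3.0, 1.5, 0.9, 0.55, 0.4, 0.25],
            [10, 8, d_rv, 100.0, 3.0, 0.5, 0.9, 0.4, 0.4, 0.1],
        ])
        np.testing.assert_allclose(s.X, expected, rtol=1e-9)

    def test_same_country_trade_is_zero(self):
        net, metrics, table, trade = _fixture()
        (s,) = assemble_samples(net, metrics, table, trade, {("a", "b")})
        assert s.regions == ["RU"]
        assert s.X[0, FEATURE_NAMES.index("bilateral_trade_usd")] == 0.0

    def test_flows_conserved_when_all_links_retained(self):
        net, metrics, table, trade = _fixture()
        retained = set(net.real_edges())
        for s in assemble_samples(net, metrics, table, trade, retained):
            assert s.y.sum() == pytest.approx(s.O_i)

    def test_missing_metrics_rejected(self):
        net, metrics, table, trade = _fixture()
        with pytest.raises(KeyError):
            assemble_samples(net, metrics.drop(index="c"), table, trade, {("a", "c")})

    def test_feature_order_is_frozen(self):
        assert FEATURE_NAMES == (
            "origin_flux", "dest_region_flux", "distance_km", "bilateral_trade_usd",
            "origin_betweenness", "region_median_betweenness",
            "origin_closeness", "region_median_closeness",
            "origin_pagerank", "region_median_pagerank",
        )


class TestScaling:
    def _samples(self, seed=0, n=6):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            k = int(rng.integers(2, 5))
            y = rng.integers(1, 10, k).astype(float)
            out.append(ODSample(f"s{i}", [f"R{j}" for j in range(k)],
                                rng.normal(5, 3, (k, 10)), float(y.sum()), y))
        return out

    def test_scaled_training_moments(self):
        scaled, _ = scale_features(self._samples())
        rows = np.vstack([s.X for s in scaled])
        np.testing.assert_allclose(rows.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(rows.std(axis=0), 1.0, atol=1e-9)

    def test_inverse_roundtrip(self):
        samples = self._samples(1)
        scaled, scaler = scale_features(samples)
        for raw, sc in zip(samples, scaled):
            np.testing.assert_allclose(scaler.inverse_transform(sc.X), raw.X, atol=1e-12)

    def test_constant_feature_passthrough(self):
        samples = self._samples(2)
        for s in samples:
            s.X[:, 3] = 7.0
        scaler = fit_scaler(samples)
        assert scaler.constant[3]
        scaled, _ = scale_features(samples, scaler)
        assert np.all(np.vstack([s.X for s in scaled])[:, 3] == 7.0)

    def test_jsonl_roundtrip(self, tmp_path):
        samples = self._samples(3)
        samples_to_jsonl(samples, tmp_path / "s.jsonl")
        back = samples_from_jsonl(tmp_path / "s.jsonl")
        assert len(back) == len(samples)
        for a, b in zip(samples, back):
            assert a.source == b.source and a.regions == b.regions
            np.testing.assert_allclose(a.X, b.X)
            np.testing.assert_allclose(a.y, b.y)
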