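"""Entrance clustering, the 70% assignment rule, usage and comparison."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tunnelwater.geometry import TunnelSnapshot
from tunnelwater.network import (
    TunnelEndpoint, assign_event_to_tunnel, cluster_endpoints,
    compare_variants, usage_table,
)
from tunnelwater.synthetic import generate_endpoint_blobs
from .conftest import make_event


def endpoints_at(points):
    return [TunnelEndpoint(i, f"T{i}", p) for i, p in enumerate(points)]


class TestClusterEndpoints:
    def test_two_distant_blobs_form_two_clusters(self):
        rng = np.random.default_rng(0)
        pts = np.concatenate([rng.normal(0, 0.2, (10, 3)),
                              rng.normal(100, 0.2, (10, 3))])
        result = cluster_endpoints(endpoints_at(pts))
        assert result.n_clusters == 2
        assert not result.noise

    def test_few_isolated_points_are_noise(self):
        result = cluster_endpoints(endpoints_at(
            [[0, 0, 0], [50, 0, 0], [0, 50, 0]]))
        assert result.n_clusters == 0
        assert len(result.noise) == 3

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_endpoints([])

    def test_recovers_planted_blobs(self):
        """Planted sigma=0.3 blobs >= 10 A apart: ARI >= 0.99."""
        centers = [(0, 0, 0), (12, 0, 0), (0, 15, 0), (-10, -10, 5)]
        endpoints, truth = generate_endpoint_blobs(centers, n_per_blob=25,
                                                   sigma=0.3, seed=4)
        result = cluster_endpoints(endpoints)
        labels = result.labels_for(endpoints)
        kept = labels >= 0
        assert kept.mean() > 0.95
        assert adjusted_rand_score(truth[kept], labels[kept]) >= 0.99

    def test_single_blob_allowed(self):
        endpoints, _ = generate_endpoint_blobs([(0, 0, 0)], n_per_blob=20,
                                               sigma=0.3, seed=1)
        result = cluster_endpoints(endpoints)
        assert result.n_clusters == 1


class TestAssignEvent:
    @staticmethod
    def _event(n_matched, n_total, tunnel="T", others=()):
        frames = np.arange(n_total)
        oxy = np.zeros((n_total, 3))
        matched = []
        for i in range(n_total):
            flags = set(others)
            if i < n_matched:
                flags.add(tunnel)
            matched.append(frozenset(flags))
        return make_event(frames, oxy, matched=matched)

    def test_seventy_percent_inclusive(self):
        assert assign_event_to_tunnel(self._event(70, 100)) == "T"

    def test_below_threshold_unassigned(self):
        assert assign_event_to_tunnel(self._event(69, 100)) is None

    def test_tied_tunnels_unassigned(self):
        ev = self._event(80, 100, tunnel="A")
        tied = [frozenset(s | {"B"}) if "A" in s else s
                for s in ev.matched_tunnels]
        ev.matched_tunnels = tied
        assert assign_event_to_tunnel(ev) is None

    def test_monotone_in_min_fraction(self):
        """Raising the threshold can only lose assignments."""
        rng = np.random.default_rng(9)
        events = [self._event(int(rng.integers(0, 101)), 100)
                  for _ in range(60)]
        assigned = [
            sum(assign_event_to_tunnel(e, f) is not None for e in events)
            for f in (0.5, 0.6, 0.7, 0.8, 0.9)
        ]
        assert assigned == sorted(assigned, reverse=True)


class TestUsageTable:
    def test_percentages_match_counts(self):
        assignments = {f"E{i}": t for i, t in enumerate(
            ["A"] * 50 + ["B"] * 30 + ["C"] * 20)}
        table = usage_table(assignments)
        assert table.loc["A", "percent"] == pytest.approx(50.0)
        assert table.loc["B", "percent"] == pytest.approx(30.0)
        assert table.loc["C", "percent"] == pytest.approx(20.0)
        assert table["percent"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_single_tunnel_is_everything(self):
        table = usage_table({"E1": "A", "E2": "A"})
        assert table.loc["A", "percent"] == pytest.approx(100.0)

    def test_matches_hand_computed_random_sets(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            labels = rng.choice(["A", "B", "C", "D"],
                                size=rng.integers(1, 200))
            assignments = {f"E{i}": t for i, t in enumerate(labels)}
            table = usage_table(assignments)
            for t in set(labels):
                expected = (labels == t).sum()
                assert table.loc[t, "count"] == expected
                assert table.loc[t, "percent"] == pytest.approx(
                    100 * expected / len(labels))

    def test_permutation_invariant(self):
        labels = ["A"] * 5 + ["B"] * 15
        fwd = usage_table({f"E{i}": t for i, t in enumerate(labels)})
        rev = usage_table({f"E{i}": t
                           for i, t in enumerate(reversed(labels))})
        pd.testing.assert_frame_equal(fwd, rev)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            usage_table({})

    def test_bottleneck_stats_with_jackknife(self):
        snaps = {
            sim: [TunnelSnapshot(f, "A", [[0, 0, 0], [0, 0, 1]],
                                 [2.0, 1.0 + 0.1 * i])
                  for f in range(3)]
            for i, sim in enumerate(["S0", "S1", "S2"])
        }
        table = usage_table({"E1": "A"}, snaps)
        assert table.loc["A", "avg_bottleneck"] == pytest.approx(1.1)
        assert table.loc["A", "n_sims"] == 3
        assert table.loc["A", "jackknife_var"] > 0


class TestCompareVariants:
    @staticmethod
    def _table(percents):
        df = pd.DataFrame({"percent": pd.Series(percents, dtype=float)})
        df.index.name = "tunnel"
        return df

    def test_printed_usage_columns_reproduce_difference(self):
        """Wild-type vs mutant epoxide-hydrolase usage columns: the
        difference column follows from the two percentages."""
        wt = self._table({"Tm2": 0.83, "Tcap1": 0.00, "Tg": 0.76,
                          "Tcap4": 0.09})
        mut = self._table({"Tm2": 2.45, "Tcap1": 2.27, "Tg": 1.40,
                           "Tcap4": 0.04})
        diff = compare_variants(wt, mut)
        assert diff.loc["Tm2", "difference"] == pytest.approx(-1.62)
        assert diff.loc["Tcap1", "difference"] == pytest.approx(-2.27)
        assert diff.loc["Tg", "difference"] == pytest.approx(-0.64)
        assert diff.loc["Tcap4", "difference"] == pytest.approx(0.05)

    def test_identical_tables_zero(self):
        t = self._table({"A": 60.0, "B": 40.0})
        diff = compare_variants(t, t)
        assert np.allclose(diff["difference"], 0.0)

    def test_antisymmetry(self):
        a = self._table({"A": 60.0, "B": 30.0, "C": 10.0})
        b = self._table({"A": 20.0, "B": 50.0, "D": 30.0})
        ab = compare_variants(a, b).sort_index()
        ba = compare_variants(b, a).sort_index()
        assert np.allclose(ab["difference"], -ba["difference"])

    def test_missing_tunnel_counts_as_zero(self):
        a = self._table({"A": 100.0})
        b = self._table({"B": 100.0})
        diff = compare_variants(a, b)
        assert diff.loc["A", "difference"] == pytest.approx(100.0)
        assert diff.loc["B", "difference"] == pytest.approx(-100.0)

    def test_duplicate_labels_rejected(self):
        dup = pd.DataFrame({"percent": [1.0, 2.0]}, index=["A", "A"])
        with pytest.raises(ValueError, match="duplicate"):
            compare_variants(dup, self._table({"A": 1.0}))
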