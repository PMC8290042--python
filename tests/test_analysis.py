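"""Transforms, correlations, decay fits, and regression models."""

import numpy as np
import pandas as pd
import pytest

from placeconn import (
    AnalysisError,
    EdgeList,
    boundary_regression,
    correlate,
    fit_distance_decay,
    focal_association,
    log_transform,
    pair_edges,
    per_origin_stats,
)


def _edges(kind, triples):
    return EdgeList(
        kind=kind,
        df=pd.DataFrame(triples, columns=["place_i", "place_j", "value"]),
    )


class TestLogTransform:
    def test_pci_scaling(self):
        v, dropped = log_transform([1.0, 0.001], kind="pci")
        assert v.tolist() == [3.0, 0.0]
        assert dropped == 0

    def test_zero_dropped_with_tally(self):
        v, dropped = log_transform([10.0, 0.0, 100.0], kind="plain")
        assert v.tolist() == [1.0, 2.0] and dropped == 1

    def test_all_dropped_is_error(self):
        with pytest.raises(AnalysisError):
            log_transform([0.0, -1.0], kind="plain")


class TestPairEdges:
    def test_inner_join_on_unordered_pairs(self):
        a = _edges("pci", [("a", "b", 0.1), ("a", "c", 0.2)])
        b = _edges("person_days", [("a", "b", 5.0), ("b", "c", 7.0)])
        t = pair_edges(a, b)
        assert len(t) == 1
        assert t.loc[0, ["place_i", "place_j", "x", "y"]].tolist() == ["a", "b", 0.1, 5.0]

    def test_self_join_gives_equal_columns(self):
        a = _edges("pci", [("a", "b", 0.1), ("b", "c", 0.3)])
        t = pair_edges(a, a)
        assert (t["x"] == t["y"]).all()

    def test_decorations(self):
        a = _edges("pci", [("a", "b", 0.1), ("a", "c", 0.2)])
        d = _edges("distance_miles", [("a", "b", 10.0), ("a", "c", 250.0)])
        t = pair_edges(a, a, distances=d, parent_map={"a": "s1", "b": "s1", "c": "s2"})
        row = t.set_index(["place_i", "place_j"])
        assert row.loc[("a", "b"), "same_parent"] == 1
        assert row.loc[("a", "c"), "same_parent"] == 0
        assert row.loc[("a", "c"), "distance_miles"] == 250.0


class TestCorrelate:
    def test_exact_linear(self):
        t = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [3.0, 5.0, 7.0, 9.0]})
        r, n = correlate(t)
        assert r == pytest.approx(1.0) and n == 4

    def test_exact_negative(self):
        t = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [-1.0, -2.0, -3.0]})
        assert correlate(t)[0] == pytest.approx(-1.0)

    def test_independent_uniform_near_zero(self):
        rng = np.random.default_rng(314)
        t = pd.DataFrame({"x": rng.uniform(size=10000), "y": rng.uniform(size=10000)})
        r, n = correlate(t)
        assert abs(r) < 0.05 and n == 10000

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame({"x": rng.normal(size=50), "y": rng.normal(size=50)})
        r0, _ = correlate(t)
        t2 = pd.DataFrame({"x": 3.0 * t["x"] + 7.0, "y": 0.5 * t["y"] - 2.0})
        assert correlate(t2)[0] == pytest.approx(r0, rel=1e-12)

    def test_too_few_records(self):
        t = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]})
        with pytest.raises(AnalysisError):
            correlate(t)


class TestPerOriginStats:
    def test_exact_slope_per_origin(self):
        t = pd.DataFrame(
            {
                "place_i": ["o", "o", "o"],
                "place_j": ["a", "b", "c"],
                "x": [1.0, 2.0, 3.0],
                "y": [3.0, 6.0, 9.0],
            }
        )
        stats, omitted = per_origin_stats(t)
        row = stats.set_index("origin").loc["o"]
        assert row["ols_slope"] == pytest.approx(3.0)
        assert row["pearson_r"] == pytest.approx(1.0)

    def test_origins_with_too_few_edges_omitted(self):
        t = pd.DataFrame(
            {
                "place_i": ["o", "o", "o", "q"],
                "place_j": ["a", "b", "c", "z"],
                "x": [1.0, 2.0, 3.0, 1.0],
                "y": [1.0, 2.0, 3.5, 1.0],
            }
        )
        stats, omitted = per_origin_stats(t)
        assert "o" in set(stats["origin"])
        # a,b,c,q,z all have <3 incident pairs
        assert omitted == 5

    def test_slope_vs_covariate_association(self):
        # construct origins whose slopes equal their log population
        rng = np.random.default_rng(9)
        rows = []
        pops = {}
        for k in range(12):
            origin = f"o{k:02d}"
            pops[origin] = 10 ** (3 + k / 4)
            slope = np.log10(pops[origin])
            for j in range(6):
                x = rng.uniform(1, 2)
                rows.append((origin, f"d{k}{j}", x, slope * x))
        t = pd.DataFrame(rows, columns=["place_i", "place_j", "x", "y"])
        stats, _ = per_origin_stats(t)
        stats = stats[stats["origin"].str.startswith("o")]
        joined = pd.DataFrame(
            {
                "x": stats["ols_slope"].to_numpy(),
                "y": [np.log10(pops[o]) for o in stats["origin"]],
            }
        )
        r, _ = correlate(joined)
        assert r == pytest.approx(1.0, abs=1e-9)


class TestDistanceDecay:
    def test_noiseless_exact_recovery(self):
        d = np.linspace(10, 500, 40)
        y = 5.0 * d ** (-1.7)
        fit = fit_distance_decay(d, y)
        assert fit.exponent == pytest.approx(1.7, abs=1e-9)
        assert fit.amplitude == pytest.approx(5.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert not fit.fallback

    def test_loglog_initialization_equals_full_fit_when_noiseless(self):
        d = np.linspace(10, 500, 40)
        y = 5.0 * d ** (-1.7)
        assert fit_distance_decay(d, y, method="loglog").exponent == pytest.approx(
            1.7, abs=1e-12
        )

    def test_constant_response_flat(self):
        fit = fit_distance_decay([10.0, 50.0, 90.0], [2.0, 2.0, 2.0])
        assert fit.exponent == 0.0

    def test_noisy_recovery_within_band(self):
        rng = np.random.default_rng(500)
        d = rng.uniform(10, 1000, size=500)
        y = 5.0 * d ** (-1.7) * np.exp(rng.normal(0, 0.1, size=500))
        fit = fit_distance_decay(d, y)
        assert 1.6 <= fit.exponent <= 1.8

    def test_too_few_pairs(self):
        with pytest.raises(AnalysisError):
            fit_distance_decay([1.0, 2.0], [1.0, 0.5])


class TestBoundaryRegression:
    def _table(self, seed, coef_same=0.05, n=1000):
        rng = np.random.default_rng(seed)
        same = rng.integers(0, 2, size=n)
        dist = rng.uniform(20, 2000, size=n)
        y = 0.01 + coef_same * same - 1e-6 * dist + rng.normal(0, 0.001, size=n)
        return pd.DataFrame(
            {
                "place_i": "a",
                "place_j": [f"b{k}" for k in range(n)],
                "y": y,
                "same_parent": same,
                "distance_miles": dist,
            }
        )

    def test_coefficient_recovery(self):
        s = boundary_regression(self._table(21))
        assert 0.045 <= s.coefficient("same_parent") <= 0.055
        assert s.p_value("same_parent") < 0.01

    def test_recovery_bias_small_across_worlds(self):
        coefs = [
            boundary_regression(self._table(seed)).coefficient("same_parent")
            for seed in range(100)
        ]
        assert abs(np.mean(coefs) - 0.05) < 0.05 * 0.05

    def test_type_one_error_controlled(self):
        rejections = sum(
            boundary_regression(self._table(seed, coef_same=0.0)).p_value("same_parent")
            < 0.05
            for seed in range(100)
        )
        assert 0.02 <= rejections / 100 <= 0.10

    def test_constant_same_parent_is_collinear(self):
        t = self._table(3)
        t["same_parent"] = 0
        with pytest.raises(AnalysisError, match="collinear"):
            boundary_regression(t)

    def test_summary_table_layout(self):
        text = boundary_regression(self._table(21)).to_text()
        assert "same_parent" in text and "distance" in text
        assert "Adjusted R2" in text and "Observations: 1000" in text
        assert "***" in text


class TestFocalAssociation:
    def _edges_to_focal(self, n=20):
        return _edges(
            "pci",
            [(min("f", f"c{k:02d}"), max("f", f"c{k:02d}"), 0.001 * (k + 1)) for k in range(n)],
        )

    def test_exact_recovery(self):
        conn = self._edges_to_focal()
        outcomes = pd.DataFrame(
            {
                "place_id": [f"c{k:02d}" for k in range(20)],
                "outcome": [2 + 0.2 * (1000 * 0.001 * (k + 1)) for k in range(20)],
            }
        )
        s = focal_association(outcomes, conn, focal="f")
        assert s.coefficient("connectivity") == pytest.approx(0.2, rel=1e-9)
        assert s.adjusted_r_squared == pytest.approx(1.0, abs=1e-9)

    def test_null_outcome_flat(self):
        rng = np.random.default_rng(77)
        conn = self._edges_to_focal(500)

        outcomes = pd.DataFrame(
            {
                "place_id": [f"c{k:02d}" for k in range(500)],
                "outcome": rng.normal(size=500),
            }
        )
        # ids above c99 collide lexicographically; rebuild cleanly
        conn = _edges(
            "pci",
            [("c%03d" % k, "f", 0.001 * (k + 1)) for k in range(500)],
        )
        outcomes["place_id"] = ["c%03d" % k for k in range(500)]
        s = focal_association(outcomes, conn, focal="f")
        assert abs(s.adjusted_r_squared) < 0.02
        assert s.p_value("connectivity") > 0.001

    def test_too_few_rows(self):
        conn = self._edges_to_focal(5)
        outcomes = pd.DataFrame(
            {"place_id": [f"c{k:02d}" for k in range(5)], "outcome": 1.0}
        )
        with pytest.raises(AnalysisError):
            focal_association(outcomes, conn, focal="f")
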