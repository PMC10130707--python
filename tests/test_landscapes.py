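import numpy as np
import pytest

from knotph.landscapes import (PersistenceLandscape, average_landscape,
                               diagram_to_landscape, landscape_distance,
                               local_maxima, peak_to_pair, zero_landscape)
from knotph.rips_persistence import PersistenceDiagram
from conftest import random_diagram
from oracles import landscape_layer_on_grid


def tent(b, d, max_scale=20.0):
    return diagram_to_landscape(
        PersistenceDiagram(pairs=[[b, d]], max_scale=max_scale), 5)


class TestConstruction:
    def test_single_pair_tent(self):
        ls = tent(2, 6)
        assert ls.num_layers == 1
        t, v = ls.layers[0]
        np.testing.assert_allclose(t, [2, 4, 6])
        np.testing.assert_allclose(v, [0, 2, 0])

    def test_empty_diagram_zero_landscape(self):
        dgm = PersistenceDiagram(pairs=np.empty((0, 2)), max_scale=1.0)
        assert diagram_to_landscape(dgm, 3).num_layers == 0

    def test_second_layer_overlap(self):
        dgm = PersistenceDiagram(pairs=[[0, 6], [1, 3]], max_scale=10.0)
        ls = diagram_to_landscape(dgm, 5)
        assert ls.evaluate(2, 2.0)[0] == pytest.approx(1.0)

    def test_max_layers_cap(self):
        dgm = PersistenceDiagram(pairs=[[0, 4]] * 5, max_scale=10.0)
        assert diagram_to_landscape(dgm, 2).num_layers == 2

    def test_max_layers_validation(self):
        dgm = PersistenceDiagram(pairs=[[0, 4]], max_scale=10.0)
        with pytest.raises(ValueError):
            diagram_to_landscape(dgm, 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_kth_largest_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dgm = random_diagram(rng)
        ls = diagram_to_landscape(dgm, 6)
        grid = np.sort(rng.uniform(-1, 13, 250))
        for k in range(1, 7):
            np.testing.assert_allclose(
                ls.evaluate(k, grid),
                landscape_layer_on_grid(dgm.pairs, k, grid),
                atol=1e-9,
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_layers_ordered_and_slopes_unit(self, seed):
        rng = np.random.default_rng(50 + seed)
        dgm = random_diagram(rng)
        ls = diagram_to_landscape(dgm, 6)
        grid = np.sort(rng.uniform(0, 12, 200))
        prev = None
        for k in range(1, ls.num_layers + 1):
            cur = ls.evaluate(k, grid)
            assert np.all(cur >= -1e-12)
            if prev is not None:
                assert np.all(prev >= cur - 1e-9)
            prev = cur
            t, v = ls.layers[k - 1]
            slopes = np.diff(v) / np.diff(t)
            assert np.all(np.isin(np.round(slopes, 6), [-1.0, 0.0, 1.0]))


class TestAverage:
    def test_average_of_identical_is_identity(self):
        ls = tent(1, 5)
        avg = average_landscape([ls, ls, ls])
        grid = np.linspace(0, 6, 50)
        np.testing.assert_allclose(avg.evaluate(1, grid),
                                   ls.evaluate(1, grid), atol=1e-12)

    def test_average_with_zero_halves(self):
        ls = tent(0, 4)
        avg = average_landscape([ls, zero_landscape()])
        grid = np.linspace(-1, 5, 60)
        np.testing.assert_allclose(avg.evaluate(1, grid),
                                   0.5 * ls.evaluate(1, grid), atol=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_landscape([])

    @pytest.mark.parametrize("seed", range(5))
    def test_pointwise_mean_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        members = [diagram_to_landscape(random_diagram(rng), 5)
                   for _ in range(4)]
        avg = average_landscape(members)
        ts = rng.uniform(-1, 13, 100)
        for k in range(1, 6):
            expected = np.mean([m.evaluate(k, ts) for m in members], axis=0)
            np.testing.assert_allclose(avg.evaluate(k, ts), expected,
                                       atol=1e-9)


class TestDistance:
    def test_l1_tent_vs_zero(self):
        assert landscape_distance(tent(0, 2), zero_landscape(), "L1") == \
            pytest.approx(1.0, abs=1e-9)

    def test_sup_tent_vs_zero(self):
        assert landscape_distance(tent(0, 2), zero_landscape(), "sup") == \
            pytest.approx(1.0, abs=1e-12)

    def test_metric_axioms(self):
        rng = np.random.default_rng(9)
        a = diagram_to_landscape(random_diagram(rng), 5)
        b = diagram_to_landscape(random_diagram(rng), 5)
        assert landscape_distance(a, a, "L1") == pytest.approx(0.0, abs=1e-12)
        assert landscape_distance(a, b, "L1") == \
            pytest.approx(landscape_distance(b, a, "L1"), abs=1e-12)

    def test_unknown_norm(self):
        with pytest.raises(ValueError, match="norm"):
            landscape_distance(tent(0, 2), tent(0, 2), "L7")

    @pytest.mark.parametrize("seed", range(8))
    def test_l1_matches_numerical_integration(self, seed):
        rng = np.random.default_rng(300 + seed)
        a = diagram_to_landscape(random_diagram(rng), 6)
        b = diagram_to_landscape(random_diagram(rng), 6)
        exact = landscape_distance(a, b, "L1")
        grid = np.linspace(-1, 14, 200_001)
        approx = 0.0
        for k in range(1, 7):
            diff = np.abs(a.evaluate(k, grid) - b.evaluate(k, grid))
            approx += np.trapezoid(diff, grid)
        assert exact == pytest.approx(approx, abs=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(400 + seed)
        a, b, c = (diagram_to_landscape(random_diagram(rng), 5)
                   for _ in range(3))
        dab = landscape_distance(a, b, "L1")
        dbc = landscape_distance(b, c, "L1")
        dac = landscape_distance(a, c, "L1")
        assert dac <= dab + dbc + 1e-9

    def test_layer_filter(self):
        dgm = PersistenceDiagram(pairs=[[0, 6], [1, 3]], max_scale=10.0)
        ls = diagram_to_landscape(dgm, 5)
        full = landscape_distance(ls, zero_landscape(), "L1")
        only2 = landscape_distance(ls, zero_landscape(), "L1", layers=[2])
        assert 0 < only2 < full


class TestPeakToPair:
    def test_inverts_single_tent(self):
        assert peak_to_pair(tent(2, 6), 1, (0, 10)) == \
            pytest.approx((2.0, 6.0))

    def test_second_layer_peak(self):
        dgm = PersistenceDiagram(pairs=[[0, 6], [1, 3]], max_scale=10.0)
        ls = diagram_to_landscape(dgm, 5)
        assert peak_to_pair(ls, 2, (0, 6)) == pytest.approx((1.0, 3.0))

    def test_window_selects_peak(self):
        dgm = PersistenceDiagram(pairs=[[0, 4], [6, 10]], max_scale=12.0)
        ls = diagram_to_landscape(dgm, 5)
        assert peak_to_pair(ls, 1, (5, 12)) == pytest.approx((6.0, 10.0))

    def test_no_peak_in_window_errors(self):
        with pytest.raises(ValueError, match="maximum"):
            peak_to_pair(tent(2, 6), 1, (7, 9))

    @pytest.mark.parametrize("seed", range(6))
    def test_round_trip_on_separated_tents(self, seed):
        rng = np.random.default_rng(500 + seed)
        n = int(rng.integers(2, 5))
        births = np.cumsum(rng.uniform(3, 5, n))
        deaths = births + rng.uniform(0.5, 2.0, n)
        dgm = PersistenceDiagram(pairs=np.stack([births, deaths], 1),
                                 max_scale=50.0)
        ls = diagram_to_landscape(dgm, 3)
        for b, d in dgm.pairs:
            got = peak_to_pair(ls, 1, ((b + d) / 2 - 0.2, (b + d) / 2 + 0.2))
            assert got == pytest.approx((b, d), abs=1e-9)

    def test_plateau_midpoint(self):
        layer = (np.array([0.0, 1.0, 2.0, 3.0]),
                 np.array([0.0, 1.0, 1.0, 0.0]))
        ls = PersistenceLandscape(layers=(layer,))
        b, d = peak_to_pair(ls, 1, (0, 3))
        assert (b + d) / 2 == pytest.approx(1.5)
        assert local_maxima(ls, 1)[0][0] == pytest.approx(1.5)


class TestJsonRoundTrip:
    def test_round_trip(self):
        rng = np.random.default_rng(77)
        ls = diagram_to_landscape(random_diagram(rng), 4)
        back = PersistenceLandscape.from_json(ls.to_json())
        grid = np.linspace(0, 12, 97)
        for k in range(1, ls.num_layers + 1):
            np.testing.assert_allclose(back.evaluate(k, grid),
                                       ls.evaluate(k, grid), atol=1e-12)
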