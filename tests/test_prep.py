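"""Unit values, Fisher indices, instruments, Stone indices, quartiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from easidemand import prep


def _households(rows):
    return pd.DataFrame(rows, columns=["hh", "wave", "cluster", "stratum"])


def _records(rows):
    return pd.DataFrame(
        rows, columns=["hh", "wave", "group", "item", "quantity", "value",
                       "source"])


class TestUnitValues:
    def test_purchase_is_value_over_quantity(self):
        hw = _households([(0, 1, 0, 0)])
        rec = _records([(0, 1, "g", "a", 4.0, 12.0, "purchase")])
        uv = prep.unit_values(rec, hw, min_count=1)
        assert uv.loc[uv.hh == 0, "unit_value"].item() == pytest.approx(3.0)
        assert uv.loc[uv.hh == 0, "impute_level"].item() == "own"

    def test_cluster_median_for_nonpurchasers(self):
        hw = _households([(i, 1, 0, 0) for i in range(4)])
        rec = _records([
            (0, 1, "g", "a", 1.0, 2.0, "purchase"),
            (1, 1, "g", "a", 1.0, 3.0, "purchase"),
            (2, 1, "g", "a", 1.0, 10.0, "purchase"),
            (3, 1, "g", "a", 1.0, 5.0, "own_production"),
        ])
        uv = prep.unit_values(rec, hw, min_count=3)
        got = uv.loc[uv.hh == 3].iloc[0]
        assert got["unit_value"] == pytest.approx(3.0)  # median of {2,3,10}
        assert got["impute_level"] == "cluster"

    def test_falls_through_to_stratum_below_min_count(self):
        hw = _households([(0, 1, 0, 0), (1, 1, 0, 0), (2, 1, 1, 0)])
        rec = _records([
            (0, 1, "g", "a", 1.0, 2.0, "purchase"),   # one cluster-0 purchase
            (2, 1, "g", "a", 1.0, 6.0, "purchase"),
        ])
        uv = prep.unit_values(rec, hw, min_count=2)
        got = uv.loc[uv.hh == 1].iloc[0]
        assert got["impute_level"] == "stratum"
        assert got["unit_value"] == pytest.approx(4.0)  # median of {2, 6}

    def test_never_purchased_item_raises(self):
        hw = _households([(0, 1, 0, 0)])
        rec = _records([(0, 1, "g", "a", 1.0, 2.0, "gift"),
                        (0, 1, "g", "b", 1.0, 2.0, "purchase")])
        with pytest.raises(ValueError, match="never purchased.*a"):
            prep.unit_values(rec, hw)


class TestFisherIndex:
    def _grid(self, price_map, hw):
        rows = []
        for (hh, wave), prices in price_map.items():
            c = hw.loc[(hw.hh == hh) & (hw.wave == wave)].iloc[0]
            for item, p in prices.items():
                rows.append((hh, wave, c.cluster, c.stratum, item, "g", p,
                             "own"))
        return pd.DataFrame(rows, columns=["hh", "wave", "cluster", "stratum",
                                           "item", "group", "unit_value",
                                           "impute_level"])

    def test_uniform_doubling_gives_two(self):
        hw = _households([(0, 1, 0, 0), (0, 2, 0, 0)])
        grid = self._grid({(0, 1): {"a": 1.0, "b": 2.0},
                           (0, 2): {"a": 2.0, "b": 4.0}}, hw)
        rec = _records([(0, 1, "g", "a", 1.0, 1.0, "purchase"),
                        (0, 1, "g", "b", 3.0, 6.0, "purchase"),
                        (0, 2, "g", "a", 1.0, 2.0, "purchase")])
        lnp, _ = prep.fisher_group_index(grid, rec)
        assert np.exp(lnp.loc[lnp.wave == 2, "g"].item()) == pytest.approx(2.0)

    def test_single_item_group_equals_price_relative(self):
        hw = _households([(0, 1, 0, 0), (0, 2, 0, 0)])
        grid = self._grid({(0, 1): {"a": 2.0}, (0, 2): {"a": 3.0}}, hw)
        rec = _records([(0, 1, "g", "a", 1.0, 2.0, "purchase")])
        lnp, _ = prep.fisher_group_index(grid, rec)
        assert np.exp(lnp.loc[lnp.wave == 2, "g"].item()) == pytest.approx(1.5)

    def test_worked_laspeyres_paasche_example(self):
        """base p=(1,1), q=(1,1); current p=(2,1), q=(1,3):
        Laspeyres 1.5, Paasche 1.25, Fisher ~1.36931."""
        hw = _households([(0, 1, 0, 0), (0, 2, 0, 0)])
        grid = self._grid({(0, 1): {"a": 1.0, "b": 1.0},
                           (0, 2): {"a": 2.0, "b": 1.0}}, hw)
        rec = _records([(0, 1, "g", "a", 1.0, 1.0, "purchase"),
                        (0, 1, "g", "b", 1.0, 1.0, "purchase"),
                        (0, 2, "g", "a", 1.0, 2.0, "purchase"),
                        (0, 2, "g", "b", 3.0, 3.0, "purchase")])
        lnp, _ = prep.fisher_group_index(grid, rec)
        fisher = np.exp(lnp.loc[lnp.wave == 2, "g"].item())
        assert fisher == pytest.approx(np.sqrt(1.5 * 1.25), abs=1e-10)
        assert fisher == pytest.approx(1.369306, abs=1e-5)

    def test_invariant_to_splitting_an_item(self):
        hw = _households([(0, 1, 0, 0), (0, 2, 0, 0)])
        grid1 = self._grid({(0, 1): {"a": 1.0, "b": 1.5},
                            (0, 2): {"a": 2.0, "b": 1.8}}, hw)
        rec1 = _records([(0, 1, "g", "a", 2.0, 2.0, "purchase"),
                         (0, 1, "g", "b", 1.0, 1.5, "purchase"),
                         (0, 2, "g", "a", 1.0, 2.0, "purchase"),
                         (0, 2, "g", "b", 2.0, 3.6, "purchase")])
        # split item "a" into two identical half-items a1, a2
        grid2 = self._grid({(0, 1): {"a1": 1.0, "a2": 1.0, "b": 1.5},
                            (0, 2): {"a1": 2.0, "a2": 2.0, "b": 1.8}}, hw)
        rec2 = _records([(0, 1, "g", "a1", 1.0, 1.0, "purchase"),
                         (0, 1, "g", "a2", 1.0, 1.0, "purchase"),
                         (0, 1, "g", "b", 1.0, 1.5, "purchase"),
                         (0, 2, "g", "a1", 0.5, 1.0, "purchase"),
                         (0, 2, "g", "a2", 0.5, 1.0, "purchase"),
                         (0, 2, "g", "b", 2.0, 3.6, "purchase")])
        l1, _ = prep.fisher_group_index(grid1, rec1)
        l2, _ = prep.fisher_group_index(grid2, rec2)
        assert l1.loc[l1.wave == 2, "g"].item() == pytest.approx(
            l2.loc[l2.wave == 2, "g"].item(), abs=1e-12)

    def test_nonpositive_price_raises(self):
        hw = _households([(0, 1, 0, 0)])
        grid = self._grid({(0, 1): {"a": -1.0}}, hw)
        rec = _records([(0, 1, "g", "a", 1.0, 1.0, "purchase")])
        with pytest.raises(ValueError, match="price"):
            prep.fisher_group_index(grid, rec)


class TestNeighbourInstrument:
    def _lnp(self, rows):
        df = pd.DataFrame(rows, columns=["hh", "wave", "g"])
        return df

    def test_two_household_swap(self):
        hw = _households([(0, 1, 0, 0), (1, 1, 0, 0)])
        out = prep.neighbour_price_instrument(
            self._lnp([(0, 1, 0.2), (1, 1, 0.4)]), hw)
        assert out.loc[out.hh == 0, "nbr_g"].item() == pytest.approx(0.4)
        assert out.loc[out.hh == 1, "nbr_g"].item() == pytest.approx(0.2)

    def test_identical_prices_degenerate(self):
        hw = _households([(i, 1, 0, 0) for i in range(3)])
        out = prep.neighbour_price_instrument(
            self._lnp([(i, 1, 0.3) for i in range(3)]), hw)
        assert np.allclose(out["nbr_g"], 0.3)

    def test_leave_one_out_mean(self):
        hw = _households([(i, 1, 0, 0) for i in range(3)])
        out = prep.neighbour_price_instrument(
            self._lnp([(0, 1, 0.1), (1, 1, 0.2), (2, 1, 0.6)]), hw)
        assert out.loc[out.hh == 0, "nbr_g"].item() == pytest.approx(0.4)

    def test_singleton_cluster_falls_back_to_stratum(self):
        hw = _households([(0, 1, 0, 0), (1, 1, 1, 0), (2, 1, 1, 0)])
        out = prep.neighbour_price_instrument(
            self._lnp([(0, 1, 0.1), (1, 1, 0.2), (2, 1, 0.6)]), hw)
        got = out.loc[out.hh == 0].iloc[0]
        assert got["nbr_level"] == "stratum"
        assert got["nbr_g"] == pytest.approx(0.4)


class TestStoneIndex:
    def test_zero_prices(self):
        assert prep.stone_index([0.5, 0.5, 0.0], [0.0, 0.0]) == 0.0

    def test_identity_at_common_price(self):
        ln2 = np.log(2.0)
        assert prep.stone_index([0.5, 0.5, 0.0], [ln2, ln2]) == \
            pytest.approx(ln2)

    def test_dot_product(self):
        assert prep.stone_index([0.3, 0.2, 0.5], [0.1, -0.2]) == \
            pytest.approx(-0.01)

    def test_average_share_identity(self):
        """Own-share minus average-share Stone index equals
        sum_k (w_k - wbar_k) ln p_k."""
        rng = np.random.default_rng(0)
        w = rng.dirichlet(np.ones(4), 20)
        wbar = w.mean(axis=0)
        lnp = rng.normal(0, 0.3, (20, 3))
        lhs = prep.stone_index(w, lnp) - prep.avg_share_stone_index(wbar, lnp)
        rhs = np.einsum("nj,nj->n", w[:, :3] - wbar[:3], lnp)
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestExpenditureGroups:
    def test_adult_equivalents_scale(self):
        roster = pd.DataFrame({"hh": [0, 0, 0], "member": [0, 1, 2],
                               "age": [30.0, 10.0, 65.0],
                               "sex": ["m", "f", "f"]})
        assert prep.adult_equivalents(roster).loc[0] == pytest.approx(2.3)

    @pytest.mark.parametrize("x,label", [
        (1.50, "Q1"), (2.50, "Q2"), (6.00, "Q4"), (1.90, "Q2"),
        (3.20, "Q3"), (5.50, "Q4"), (0.0, "Q1")])
    def test_quartile_boundaries(self, x, label):
        assert prep.assign_quartile([x])[0] == label

    @given(st.lists(st.floats(min_value=0, max_value=50,
                              allow_nan=False), min_size=1, max_size=30))
    def test_quartile_partition(self, xs):
        labels = prep.assign_quartile(xs)
        assert set(labels) <= {"Q1", "Q2", "Q3", "Q4"}
        assert len(labels) == len(xs)

    def test_increasing_cutoffs_enforced(self):
        with pytest.raises(ValueError):
            prep.QuartileScheme(cutoffs=(3.2, 1.9, 5.5))


def test_prepare_invariants(small_bundle):
    _, _, _, data = small_bundle
    assert np.allclose(data.w.sum(axis=1), 1.0, atol=1e-12)
    assert np.all((data.w >= 0) & (data.w <= 1))
    assert np.all(np.isfinite(data.lnp))
    assert np.all(data.ae > 0)
    assert data.cmeans.shape[1] == data.n_groups + 4
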