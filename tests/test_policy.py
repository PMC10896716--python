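"""Cash-transfer and price-discount simulations, costs, sufficiency curves."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from easidemand import model, policy, prep
from easidemand.prep import WEEKS_PER_MONTH
from .conftest import random_admissible


def _cd_setup(small_bundle, shares=(0.15, 0.2, 0.1, 0.1)):
    """Cobb-Douglas predictor over the small panel's observation table."""
    _, _, panel, data = small_bundle
    params = model.EASIParameters.cobb_douglas(
        np.array(shares), n_z=data.z.shape[1],
        group_names=list(data.group_names))

    def predict(d):
        w, _ = params.solve(d.lnp, d.lnx, z=d.z)
        return w

    return data, params, predict


class TestCashTransfer:
    def test_transfer_sizing(self, small_bundle):
        *_, data = small_bundle
        t = policy.ct_transfer(data, share=0.20)
        q1 = data.x_week[data.quartile == "Q1"]
        assert t == pytest.approx(0.2 * np.median(q1) * WEEKS_PER_MONTH)

    def test_null_transfer_is_baseline(self, small_bundle):
        data, params, predict = _cd_setup(small_bundle)
        ct = policy.CTConfig(transfer_monthly=0.0)
        out = policy.simulate_cash_transfer(None, data, ct,
                                            predict_fn=predict)
        df = out.households
        for c in [c for c in df.columns if c.endswith("_pre")]:
            post = c[:-4] + "_post"
            assert (df[c] == df[post]).all()

    def test_cobb_douglas_mpc_equals_food_share(self, small_bundle):
        shares = (0.15, 0.2, 0.1, 0.1)
        data, params, predict = _cd_setup(small_bundle, shares)
        ct = policy.CTConfig(transfer_monthly=10.0, kappa=0.7)
        out = policy.simulate_cash_transfer(None, data, ct,
                                            predict_fn=predict)
        assert np.abs(out.households["mpc_food"] - sum(shares)).max() < 1e-10

    def test_q1_de_sufficiency_strictly_rises(self, clean_fit):
        cfg, prefs, panel, data, dataT, res = clean_fit
        ct = policy.CTConfig(transfer_monthly=policy.ct_transfer(data))
        out = policy.simulate_cash_transfer(res, data, ct)
        df = out.households
        q1 = df[df.quartile == "Q1"]
        assert q1["suff_energy_kcal_post"].mean() > \
            q1["suff_energy_kcal_pre"].mean()


class TestPriceDiscount:
    def test_null_discount_is_baseline(self, small_bundle):
        data, params, predict = _cd_setup(small_bundle)
        out = policy.simulate_price_discount(
            None, data, policy.PDConfig(category="PN", discount=0.0),
            predict_fn=predict)
        assert np.array_equal(out.qty_pre, out.qty_post)
        assert (out.households["cost_monthly"] == 0).all()

    def test_cobb_douglas_quantity_factor(self, small_bundle):
        """Unit-elastic demand: spending on each group is unchanged, so
        the discounted groups' quantities scale by 1/(1-delta)."""
        data, params, predict = _cd_setup(small_bundle)
        pdc = policy.PDConfig(category="PN", discount=0.25)
        idx = pdc.groups(list(data.group_names))
        out = policy.simulate_price_discount(None, data, pdc,
                                             predict_fn=predict)
        ratio = out.qty_post[:, idx] / out.qty_pre[:, idx]
        assert np.abs(ratio - 1 / 0.75).max() < 1e-10
        other = [j for j in range(data.n_groups) if j not in idx]
        assert np.abs(out.qty_post[:, other] - out.qty_pre[:, other]).max() \
            < 1e-10

    def test_cobb_douglas_cost_closed_form(self, small_bundle):
        """Redeemed value = (delta/(1-delta)) * category spending, i.e.
        one third of monthly category expenditure at delta = 0.25."""
        shares = (0.15, 0.2, 0.1, 0.1)
        data, params, predict = _cd_setup(small_bundle, shares)
        pdc = policy.PDConfig(category="PN", discount=0.25)
        idx = pdc.groups(list(data.group_names))
        out = policy.simulate_price_discount(None, data, pdc,
                                             predict_fn=predict)
        w_c = sum(shares[j] for j in idx)
        expect = w_c * data.x_week * WEEKS_PER_MONTH / 3.0
        assert np.abs(out.households["cost_monthly"].values - expect).max() \
            < 1e-8

    def test_cost_matches_recomputation(self, clean_fit):
        cfg, prefs, panel, data, dataT, res = clean_fit
        pdc = policy.PDConfig(category="SG", discount=0.25)
        out = policy.simulate_price_discount(res, data, pdc)
        idx = pdc.groups(list(data.group_names))
        manual = (0.25 * data.gprice[:, idx] * out.qty_post[:, idx]) \
            .sum(axis=1) * WEEKS_PER_MONTH
        assert np.allclose(out.households["cost_monthly"], manual)

    def test_small_discount_first_order_in_elasticities(self):
        """For a 1% discount the quantity response agrees with the
        elasticity first-order approximation."""
        from easidemand import elasticity
        from .conftest import random_obs

        prefs, params = random_admissible(seed=4, n_groups=3)
        d = random_obs(prefs, seed=4, n=8)
        es = elasticity.compute_elasticities(params, d)
        delta = 0.01
        k = 0
        w0, _ = params.solve(d.lnp, d.lnx, z=d.z)
        lp1 = d.lnp.copy(); lp1[:, k] += np.log1p(-delta)
        w1, _ = params.solve(lp1, d.lnx, z=d.z)
        dlnq = np.log(w1[:, :3]) - np.log(w0[:, :3])
        dlnq[:, k] -= np.log1p(-delta)
        approx = es.E_marsh[:, :3, k] * np.log1p(-delta)
        rel = np.abs(dlnq - approx) / np.maximum(np.abs(approx), 1e-4)
        assert np.median(rel) < 0.05

    def test_unmapped_category_raises(self, small_bundle):
        *_, data = small_bundle
        with pytest.raises(ValueError, match="no food group"):
            policy.PDConfig(category="FFV").groups(list(data.group_names))


class TestScenarioConsistency:
    def test_baseline_identical_across_scenarios(self, clean_fit):
        cfg, prefs, panel, data, dataT, res = clean_fit
        ct = policy.CTConfig(transfer_monthly=policy.ct_transfer(data))
        o1 = policy.simulate_cash_transfer(res, data, ct)
        o2 = policy.simulate_price_discount(res, data,
                                            policy.PDConfig(category="SG"))
        o3 = policy.simulate_price_discount(res, data,
                                            policy.PDConfig(category="PN"))
        pre_cols = [c for c in o1.households.columns if c.endswith("_pre")]
        for o in (o2, o3):
            pd.testing.assert_frame_equal(o1.households[pre_cols],
                                          o.households[pre_cols])
        assert np.array_equal(o2.qty_pre, o3.qty_pre)

    def test_household_order_invariance(self, small_bundle):
        data, params, predict = _cd_setup(small_bundle)
        ct = policy.CTConfig(transfer_monthly=5.0)
        out1 = policy.simulate_cash_transfer(None, data, ct,
                                             predict_fn=predict)
        rng = np.random.default_rng(1)
        perm = rng.permutation(data.n_obs)
        d2 = replace(data)
        for f in ("hh", "wave", "cluster", "stratum", "w", "lnp", "lnx",
                  "x_week", "z", "cmeans", "lnp_nbr", "stone_avg", "ae",
                  "quartile", "gprice", "gqty"):
            setattr(d2, f, getattr(data, f)[perm])
        out2 = policy.simulate_cash_transfer(None, d2, ct,
                                             predict_fn=predict)
        s1 = out1.quartile_summary().set_index("quartile")
        s2 = out2.quartile_summary().set_index("quartile")
        pd.testing.assert_frame_equal(s1, s2, check_exact=False, atol=1e-12)


class TestSufficiencyCurve:
    def test_all_sufficient_gives_flat_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1.0, 0.5, 300)
        grid, curve = policy.sufficiency_curve(np.ones(300), x)
        assert np.nanmax(np.abs(curve - 1.0)) < 1e-12

    def test_local_mean_identity(self):
        """With flags independent of x, the smoother reproduces the
        global mean at interior grid points."""
        rng = np.random.default_rng(1)
        x = np.linspace(0, 1, 2001)
        s = (np.arange(2001) % 2).astype(float)  # alternating 0/1
        grid, curve = policy.sufficiency_curve(s, x, bandwidth=0.2)
        inner = (grid > 0.3) & (grid < 0.7)
        assert np.abs(curve[inner] - 0.5).max() < 1e-3

    def test_post_ct_curve_weakly_above(self, clean_fit):
        cfg, prefs, panel, data, dataT, res = clean_fit
        ct = policy.CTConfig(transfer_monthly=policy.ct_transfer(data))
        out = policy.simulate_cash_transfer(res, data, ct)
        lnx_ae = np.log(data.daily_per_ae())
        grid, pre = policy.sufficiency_curve(
            out.households["suff_energy_kcal_pre"].values, lnx_ae)
        _, post = policy.sufficiency_curve(
            out.households["suff_energy_kcal_post"].values, lnx_ae)
        ok = np.isfinite(pre) & np.isfinite(post)
        assert np.all(post[ok] >= pre[ok] - 1e-9)

    def test_needs_support(self):
        with pytest.raises(ValueError):
            policy.sufficiency_curve(np.ones(10), np.zeros(10))
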