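"""Implicit utility, the share fixed point, censoring stage, estimation."""

import numpy as np
import pytest
from scipy.optimize import brentq

from easidemand import demand, model, prep, synth
from .conftest import ObsData, random_admissible, truth_parameters


class TestImplicitUtility:
    def test_zero_prices_gives_lnx(self):
        w = np.array([[0.3, 0.3, 0.4]])
        lnp = np.zeros((1, 2))
        assert demand.implicit_utility([2.0], w, lnp, utility="stone") == \
            pytest.approx(2.0)
        A = np.array([[0.1, -0.05], [-0.05, 0.2]])
        assert demand.implicit_utility([2.0], w, lnp, A, 0 * A,
                                       "exact") == pytest.approx(2.0)

    def test_stone_deflation_example(self):
        w = np.array([[0.5, 0.5, 0.0]])
        lnp = np.array([[1.0, 1.0]])
        assert demand.implicit_utility([2.0], w, lnp, utility="stone") == \
            pytest.approx(1.0)

    def test_common_price_shift_lowers_y_by_constant(self):
        """Shifting every log price (numeraire included) by c lowers the
        Stone-deflated y by exactly c because shares sum to one; with a
        zero numeraire share the shift acts on the food block alone."""
        rng = np.random.default_rng(1)
        w_food = rng.dirichlet(np.ones(3), 5)
        w = np.column_stack([w_food, np.zeros(5)])
        lnp = rng.normal(0, 0.2, (5, 3))
        lnx = rng.normal(4, 0.5, 5)
        c = 0.37
        y0 = demand.implicit_utility(lnx, w, lnp, utility="stone")
        y1 = demand.implicit_utility(lnx, w, lnp + c, utility="stone")
        assert np.allclose(y1, y0 - c, atol=1e-12)


class TestPredictShares:
    def test_fixed_point_matches_scalar_root_solver(self):
        """The damped joint iteration agrees with a brute-force 1-D root
        solve of the implicit-utility equation."""
        prefs, params = random_admissible(seed=12, n_groups=3)
        rng = np.random.default_rng(3)
        for i in range(5):
            lnp = rng.normal(0, 0.25, (1, 3))
            lnx = np.array([prefs.y_ref + rng.normal(0, 0.6)])
            z = np.array([[1.2, 1.0, 0.4]])
            w, y = params.solve(lnp, lnx, z=z, tol=1e-12)

            def resid(yv):
                wf = demand.latent_food_shares(
                    params.b, params.A, params.D, params.G, None,
                    np.array([yv]), lnp, z)
                w_full = np.column_stack([wf, 1 - wf.sum(1)])
                return yv - demand.implicit_utility(lnx, w_full, lnp,
                                                    params.A, params.D)[0]

            y_oracle = brentq(resid, y[0] - 2, y[0] + 2, xtol=1e-12)
            assert y[0] == pytest.approx(y_oracle, abs=1e-8)

    def test_cobb_douglas_shares_constant(self):
        params = model.EASIParameters.cobb_douglas([0.2, 0.3, 0.1])
        rng = np.random.default_rng(0)
        w, _ = params.solve(rng.normal(0, 0.5, (10, 3)),
                            rng.normal(4, 1, 10))
        assert np.allclose(w, [0.2, 0.3, 0.1, 0.4], atol=1e-12)

    def test_base_price_case_needs_no_iteration(self):
        prefs, params = random_admissible(seed=2, n_groups=3)
        lnx = np.array([prefs.y_ref])
        w, y = params.solve(np.zeros((1, 3)), lnx, z=np.zeros((1, 3)))
        assert y[0] == pytest.approx(lnx[0], abs=1e-12)


class TestCensoringStage:
    def test_probit_fields_in_range(self, small_bundle):
        cfg, prefs, panel, data = small_bundle
        m = model.EASIDemandModel(data, degree=2)
        Phi, phi, coefs, censored, rates, notes = m.fit_censoring_stage()
        assert np.all((Phi > 0) & (Phi <= 1))
        assert np.all(np.isfinite(phi)) and np.all(phi >= 0)
        assert censored.any() and (rates[censored] > 0).all()

    def test_classification_beats_base_rate(self, small_bundle):
        cfg, prefs, panel, data = small_bundle
        m = model.EASIDemandModel(data, degree=2)
        Phi, phi, coefs, censored, rates, _ = m.fit_censoring_stage()
        j = int(np.argmax(rates * censored))
        pos = data.w[:, j] > 0
        acc = ((Phi[:, j] > 0.5) == pos).mean()
        base = max(pos.mean(), 1 - pos.mean())
        assert acc > base

    def test_fully_consumed_group_is_degenerate(self):
        cfg = synth.SynthConfig(n_households=150, n_waves=2, n_clusters=10,
                                n_groups=3, seed=21, share_error_scale=0.05)
        prefs = synth.generate_preferences(cfg)
        panel = synth.generate_panel(cfg, prefs)
        data = prep.prepare(panel)
        never_zero = np.flatnonzero((data.w[:, :3] > 0).all(axis=0))
        if never_zero.size == 0:
            pytest.skip("draw produced zeros in every group")
        m = model.EASIDemandModel(data, degree=1)
        Phi, phi, _, censored, _, _ = m.fit_censoring_stage()
        j = never_zero[0]
        assert not censored[j]
        assert np.all(Phi[:, j] == 1.0) and np.all(phi[:, j] == 0.0)


class TestEstimation:
    def test_noiseless_recovery(self):
        """With the latent error, confounding and censoring switched off,
        the restricted IV estimator recovers the generating parameters."""
        cfg = synth.SynthConfig(n_households=400, n_waves=2, n_clusters=25,
                                seed=3, share_error_scale=0.0,
                                quality_loading=0.0, search_loading=0.0,
                                item_price_noise=0.0, cluster_taste_scale=0.0,
                                expenditure_lognormal=(0.956, 0.35),
                                price_dispersion=0.15)
        prefs = synth.generate_preferences(cfg)
        panel = synth.generate_panel(cfg, prefs)
        assert (panel.truth["w_obs"][:, :6] == 0).sum() == 0
        data = synth.prepared_from_truth(panel)
        res = model.EASIDemandModel(data, degree=2, censor=False).fit()
        assert np.abs(res.params.A - prefs.A).max() < 1e-4
        assert np.abs(res.params.b - prefs.b).max() < 1e-4
        assert np.abs(res.params.D - prefs.D).max() < 1e-4

    def test_restrictions_imposed(self, small_fit):
        *_, res = small_fit
        assert np.allclose(res.params.A, res.params.A.T, atol=1e-12)
        assert np.allclose(res.params.D, res.params.D.T, atol=1e-12)
        Afull = res.params.A_full()
        assert np.allclose(Afull.sum(axis=1), 0.0, atol=1e-10)

    def test_iv_beats_no_instrument_on_default_draw(self, default_fit):
        cfg, prefs, panel, data, res = default_fit
        res_ols = model.EASIDemandModel(data, degree=2, instrument=False) \
            .fit(compute_cov=False)
        assert np.linalg.norm(res.params.A - prefs.A) < \
            np.linalg.norm(res_ols.params.A - prefs.A)

    def test_first_stage_instruments_relevant(self, small_fit):
        *_, res = small_fit
        assert res.report.first_stage_F
        assert min(res.report.first_stage_F.values()) > 10.0

    def test_predicted_shares_sum_to_one(self, small_fit):
        *_, res = small_fit
        w = res.predict_shares()
        assert np.abs(w.sum(axis=1) - 1).max() < 1e-10
        w_lat = res.predict_shares(adjusted=False)
        assert np.abs(w_lat.sum(axis=1) - 1).max() < 1e-10

    def test_save_load_round_trip(self, small_fit, tmp_path):
        *_, data, res = small_fit[-2], small_fit[-1]
        res = small_fit[-1]
        res.save(tmp_path / "m")
        loaded = model.EASIDemandResults.load(tmp_path / "m")
        assert np.allclose(loaded.params.A, res.params.A)
        assert np.allclose(loaded.beta, res.beta)
        w1 = res.predict_shares(small_fit[3])
        w2 = loaded.predict_shares(small_fit[3])
        assert np.allclose(w1, w2, atol=1e-12)

    def test_needs_two_waves(self, small_bundle):
        cfg, prefs, panel, data = small_bundle
        from dataclasses import replace
        one = replace(data)
        keep = data.wave == 1
        for f in ("hh", "wave", "cluster", "stratum", "w", "lnp", "lnx",
                  "x_week", "z", "cmeans", "lnp_nbr", "stone_avg", "ae",
                  "quartile", "gprice", "gqty"):
            setattr(one, f, getattr(data, f)[keep])
        with pytest.raises(ValueError, match="waves"):
            model.EASIDemandModel(one, degree=1)

    def test_relabelling_groups_permutes_estimates(self, small_bundle):
        """The estimator is equivariant to relabelling the food groups."""
        cfg, prefs, panel, data = small_bundle
        from dataclasses import replace
        perm = np.array([2, 0, 3, 1])
        J = data.n_groups
        d2 = replace(data)
        d2.w = np.column_stack([data.w[:, perm], data.w[:, J]])
        d2.lnp = data.lnp[:, perm]
        d2.lnp_nbr = data.lnp_nbr[:, perm]
        d2.gprice = data.gprice[:, perm]
        d2.gqty = data.gqty[:, perm]
        d2.group_names = [data.group_names[p] for p in perm]
        cm = data.cmeans.copy()
        cm[:, :J] = cm[:, perm]
        d2.cmeans = cm
        r1 = model.EASIDemandModel(data, degree=1).fit(compute_cov=False)
        r2 = model.EASIDemandModel(d2, degree=1).fit(compute_cov=False)
        assert np.allclose(r2.params.A, r1.params.A[np.ix_(perm, perm)],
                           atol=1e-6)
        assert np.allclose(r2.params.b, r1.params.b[perm], atol=1e-6)


class TestDegreeSelection:
    def test_linear_truth_selected(self):
        """A DGP with linear Engel curvature is identified as degree 1 in
        most replications (scaled-down repeated-simulation oracle)."""
        hits = 0
        for seed in (31, 32, 33):
            cfg = synth.SynthConfig(n_households=400, n_waves=2,
                                    n_clusters=25, n_groups=4,
                                    poly_degree_true=1, seed=seed)
            prefs = synth.generate_preferences(cfg)
            panel = synth.generate_panel(cfg, prefs)
            data = prep.prepare(panel)
            res = model.select_degree(data, degrees=(1, 2, 3))
            assert {"bic_R1", "bic_R2", "bic_R3"} <= \
                set(res.report.criterion_values)
            hits += res.report.criterion_values["selected_degree"] == 1
        assert hits >= 2
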