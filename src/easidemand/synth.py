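"""Synthetic household consumption panels with a known demand-generating process.

The generator emulates the structure of LSMS-style integrated household
surveys: a panel of households observed over several waves, 7-day recall
of at-home food consumption by item and source, cluster-by-wave price
variation, zero consumption of some food groups (censoring), and
household-level price heterogeneity from item quality choice and price
search.  Preferences follow the same EASI share equations the estimator
fits, so parameter recovery and policy simulations can be checked
against ground truth.

Units: quantities are kg (or litre) per 7 days, values and expenditures
are weekly US$ PPP, prices are US$ PPP per kg.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import demand
from .nutrients import NUTRIENTS, ATWATER

__all__ = [
    "SynthConfig", "TruePreferences", "HouseholdPanel",
    "generate_preferences", "generate_panel", "default_composition",
    "GROUP_ARCHETYPES",
]


@dataclass
class SynthConfig:
    """Configuration of the synthetic data-generating process.

    Defaults are the study conditions used throughout the test suite:
    2,000 households x 3 waves, six food groups plus the numeraire,
    quadratic Engel curvature, ~15% censoring, and quality/search price
    confounding with loadings of 0.1.
    """

    n_households: int = 2000
    n_waves: int = 3
    n_clusters: int = 100
    n_groups: int = 6
    n_items_per_group: int = 3
    poly_degree_true: int = 2
    #: (mu, sigma) of log per-adult-equivalent daily expenditures, US$ PPP.
    #: exp(mu) ~ 2.6 $/AE/day puts roughly a third of households under the
    #: 1.90 $ extreme poverty line, in the range of the surveyed countries.
    expenditure_lognormal: tuple = (0.956, 0.8)
    price_dispersion: float = 0.20
    quality_loading: float = 0.10
    search_loading: float = 0.10
    share_error_scale: float = 0.25
    item_price_noise: float = 0.10
    cluster_taste_scale: float = 0.02
    own_production_fraction: float = 0.35
    clusters_per_stratum: int = 5
    seed: int = 0

    def validate(self):
        for name in ("n_households", "n_waves", "n_clusters",
                     "n_items_per_group", "clusters_per_stratum"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_groups < 2:
            raise ValueError("n_groups must be >= 2")
        if self.poly_degree_true < 1:
            raise ValueError("poly_degree_true must be >= 1")
        for name in ("price_dispersion", "quality_loading", "search_loading",
                     "share_error_scale", "item_price_noise",
                     "cluster_taste_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.expenditure_lognormal[1] < 0:
            raise ValueError("expenditure sigma must be >= 0")
        if not 0 <= self.own_production_fraction <= 0.9:
            raise ValueError("own_production_fraction must be in [0, 0.9]")
        return self


#: archetype name, then per-100g contents in the order of NUTRIENTS
GROUP_ARCHETYPES = [
    ("staple_grain",
     [360, 75, 8, 2, 2.0, 1.5, 0, 25, 7.0, 0, 0.3, 15, 90, 280, 0.4, 1.0, 5]),
    ("starchy_staple",
     [160, 38, 1.4, 0.3, 0.3, 0.3, 1, 27, 1.8, 20, 0.2, 16, 21, 271, 0.1, 1.7, 14]),
    ("pulses_nuts",
     [340, 60, 22, 1.5, 6.5, 3.0, 1, 400, 15.0, 2, 0.5, 100, 140, 1300, 0.2, 2.0, 15]),
    ("animal_source",
     [200, 0.5, 20, 13, 2.5, 4.0, 90, 10, 0.0, 1, 0.5, 50, 20, 280, 5.0, 0.3, 80]),
    ("fruits_veg",
     [50, 11, 1.2, 0.3, 0.8, 0.3, 150, 40, 2.5, 35, 0.8, 30, 20, 250, 0.05, 6.0, 8]),
    ("fats_oils",
     [880, 0.1, 0.1, 98, 0.1, 0.1, 30, 0, 0.0, 0, 12, 1, 1, 5, 15.0, 0.0, 2]),
    ("sugar_beverages",
     [387, 96.7, 0.0, 0.0, 0.1, 0.0, 0, 0, 0.0, 0, 0.0, 1, 1, 2, 0.0, 95.0, 1]),
    ("other_cereals",
     [350, 72, 10, 2.5, 3.0, 2.0, 0, 40, 8.0, 0, 0.5, 25, 110, 350, 0.5, 1.0, 6]),
]


def default_composition(n_groups: int, seed: int = 0) -> pd.DataFrame:
    """A documented toy food-composition table (synthetic stand-in).

    Rows are food groups built from dietary archetypes (starchy staple,
    pulse, animal-source, fruit/vegetable, ...), cycled and seed-jittered
    when ``n_groups`` exceeds the archetype list.  Macronutrients are
    jittered first and energy is recomputed from Atwater factors (times
    a factor in [1.00, 1.04]) so stated energy stays consistent with
    macronutrient-derived energy.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    rng = np.random.default_rng([seed, 0xC0])
    rows, names = [], []
    for g in range(n_groups):
        base_name, base = GROUP_ARCHETYPES[g % len(GROUP_ARCHETYPES)]
        vals = dict(zip(NUTRIENTS, map(float, base)))
        if g >= len(GROUP_ARCHETYPES):
            jit = np.exp(rng.normal(0.0, 0.05, len(NUTRIENTS)))
            vals = {k: v * j for (k, v), j in zip(vals.items(), jit)}
            name = f"{base_name}_{g // len(GROUP_ARCHETYPES) + 1}"
        else:
            name = base_name
        atwater = sum(vals[m] * f for m, f in ATWATER.items())
        vals["energy_kcal"] = max(atwater, 1e-6) * float(rng.uniform(1.0, 1.04))
        rows.append(vals)
        names.append(name)
    comp = pd.DataFrame(rows, index=pd.Index(names, name="group"))
    return comp[NUTRIENTS]


@dataclass
class TruePreferences:
    """Ground-truth EASI parameters of the data-generating process.

    ``b`` holds polynomial coefficients on powers of implicit utility y
    for the J food equations; ``A`` and ``D`` are the symmetric food
    blocks of the log-price and price-utility interaction matrices (the
    numeraire row/column follow from homogeneity and adding-up);
    ``G`` are shifter loadings on z = (log household size, urban flag,
    head age / 100); ``Sigma_e`` is the latent-share error covariance.
    """

    b: np.ndarray
    A: np.ndarray
    D: np.ndarray
    G: np.ndarray
    Sigma_e: np.ndarray
    group_names: list
    z_ref: np.ndarray
    y_ref: float
    target_shares: np.ndarray

    @property
    def n_groups(self):
        return self.A.shape[0]

    def solve(self, lnp, lnx, z=None, errors=None, utility="exact", **kw):
        """Latent shares and implicit utility at given demand determinants."""
        return demand.solve_shares(self.b, self.A, self.D, self.G, None,
                                   lnp, lnx, z=z, errors=errors,
                                   utility=utility, **kw)


@dataclass
class HouseholdPanel:
    """Container for the synthetic survey tables.

    ``households``: one row per household-wave (ids, cluster, stratum,
    urban flag, non-food expenditure, weight).  ``roster``: one row per
    member.  ``records``: item-level consumption (quantity kg/week,
    value US$/week, source).  ``composition``: per-group nutrient table.
    ``truth``: ground-truth arrays (latent shares, prices, errors) kept
    for oracle tests; not part of the survey-facing CSV dictionary.
    """

    households: pd.DataFrame
    roster: pd.DataFrame
    records: pd.DataFrame
    composition: pd.DataFrame
    group_names: list
    truth: dict = field(default_factory=dict, repr=False)

    def write_csv(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.households.to_csv(outdir / "households.csv", index=False)
        self.roster.to_csv(outdir / "roster.csv", index=False)
        self.records.to_csv(outdir / "records.csv", index=False)
        self.composition.to_csv(outdir / "composition.csv")
        return outdir

    @classmethod
    def read_csv(cls, indir):
        indir = Path(indir)
        comp = pd.read_csv(indir / "composition.csv", index_col="group")
        return cls(
            households=pd.read_csv(indir / "households.csv"),
            roster=pd.read_csv(indir / "roster.csv"),
            records=pd.read_csv(indir / "records.csv"),
            composition=comp,
            group_names=list(comp.index),
        )


#: direction of the Engel slope (share response to living standard)
_ENGEL_SIGNS = {
    "staple_grain": -1.0, "starchy_staple": -1.0, "other_cereals": -1.0,
    "pulses_nuts": 1.0, "animal_source": 1.0, "fruits_veg": 1.0,
    "fats_oils": 0.0, "sugar_beverages": 1.0,
}


def _engel_slope_sign(group_name):
    for prefix, s in _ENGEL_SIGNS.items():
        if group_name.startswith(prefix):
            return s
    return 0.0


#: US$ PPP per 1,000 kcal by dietary archetype (jittered per draw)
_ENERGY_PRICE_RATES = {
    "staple_grain": 0.40, "other_cereals": 0.45, "starchy_staple": 0.55,
    "pulses_nuts": 0.80, "animal_source": 3.50, "fruits_veg": 3.00,
    "fats_oils": 0.35, "sugar_beverages": 0.60,
}


def _price_per_1000kcal(group_name, rng):
    rate = 1.0
    for prefix, r in _ENERGY_PRICE_RATES.items():
        if group_name.startswith(prefix):
            rate = r
            break
    return rate * float(np.exp(rng.normal(0.0, 0.15)))


def prepared_from_truth(panel: "HouseholdPanel"):
    """Estimation-ready table built from ground-truth arrays.

    Bypasses unit-value imputation and the Fisher index, using the exact
    group log prices and shares of the data-generating process.  Used to
    test the estimator in isolation from the survey-preparation stage
    (price-index base constants shift the implicit-utility quadratic, so
    end-to-end recovery is only approximate even without noise).
    """
    from . import prep as _prep

    t = panel.truth
    J = len(panel.group_names)
    cfg = t["config"]
    order = np.lexsort((t["wave"], t["hh"]))
    hh = t["hh"][order]; wave = t["wave"][order]
    cluster = t["cluster"][order]
    stratum = cluster // cfg["clusters_per_stratum"]
    w = t["w_obs"][order]; lnp = t["lnp"][order]
    lnx = t["lnx"][order]; x_week = t["x_week"][order]
    ae = t["ae"][order]; z3 = t["z"][order]
    waves = np.unique(wave)
    wdum = np.column_stack([(wave == wv).astype(float) for wv in waves[1:]]) \
        if len(waves) > 1 else np.empty((len(wave), 0))
    z = np.column_stack([z3, wdum])
    z_names = ["log_size", "urban", "head_age"] + \
        [f"wave_{wv}" for wv in waves[1:]]
    cm_src = np.column_stack([lnp, lnx, z3])
    cm = pd.DataFrame(cm_src).groupby(cluster).transform("mean").values
    lnp_df = pd.DataFrame(lnp, columns=panel.group_names)
    lnp_df.insert(0, "hh", hh); lnp_df.insert(1, "wave", wave)
    hw = pd.DataFrame({"hh": hh, "wave": wave, "cluster": cluster,
                       "stratum": stratum})
    nbr = _prep.neighbour_price_instrument(lnp_df, hw,
                                           group_cols=list(panel.group_names))
    lnp_nbr = nbr[[f"nbr_{g}" for g in panel.group_names]].values
    wbar = w.mean(axis=0)
    gprice = t["group_price"][order]
    with np.errstate(divide="ignore", invalid="ignore"):
        gqty = np.where(gprice > 0, w[:, :J] * x_week[:, None] / gprice, 0.0)
    return _prep.PreparedData(
        hh=hh, wave=wave, cluster=cluster, stratum=stratum, w=w, lnp=lnp,
        lnx=lnx, x_week=x_week, z=z, z_names=z_names, cmeans=cm,
        cmeans_names=[f"lnp_{g}" for g in panel.group_names] + ["lnx",
                      "log_size", "urban", "head_age"],
        lnp_nbr=lnp_nbr, stone_avg=_prep.avg_share_stone_index(wbar, lnp),
        wbar=wbar, ae=ae,
        quartile=_prep.assign_quartile(x_week / (7.0 * ae)),
        gprice=gprice, gqty=gqty, group_names=list(panel.group_names),
        composition=panel.composition, roster=panel.roster,
        meta={"source": "truth", "taste": t["taste"][order]},
    )


def _shift_poly(coefs_centered, y_ref):
    """Re-express a polynomial in (y - y_ref) as coefficients on powers of y."""
    P = np.polynomial.Polynomial(coefs_centered)
    shifted = P(np.polynomial.Polynomial([-y_ref, 1.0]))
    out = np.zeros(len(coefs_centered))
    out[: len(shifted.coef)] = shifted.coef
    return out


def generate_preferences(config: SynthConfig, max_attempts: int = 200) -> TruePreferences:
    """Draw admissible ground-truth preferences for the DGP.

    Rejection-resamples until (i) latent budget shares at the reference
    household (median expenditures, unit prices) lie in (0.01, 0.6) for
    every group including the numeraire and (ii) the share fixed point
    converges to sane values on a scan of random demand determinants.
    """
    config.validate()
    J, R = config.n_groups, config.poly_degree_true
    rng = np.random.default_rng([config.seed, 0xA1])
    mu, sigma = config.expenditure_lognormal
    # reference household: AE ~ 3, weekly expenditures = daily-per-AE * 7 * AE
    y_ref = mu + np.log(7 * 3.0)
    z_ref = np.array([np.log(4.0), 0.3, 0.45])
    names = default_composition(J, config.seed).index.tolist()

    for attempt in range(max_attempts):
        food_total = rng.uniform(0.45, 0.60)
        t = rng.dirichlet(np.full(J, 3.0)) * food_total
        if t.min() < 0.02 or t.max() > 0.55:
            continue
        # polynomial drawn centred at y_ref, then shifted to raw powers of
        # y; Engel slopes carry textbook signs (staple shares fall with
        # living standard, animal-source/produce/pulse shares rise)
        slope_sign = np.array([_engel_slope_sign(g) for g in names])
        b = np.zeros((J, R + 1))
        G = rng.normal(0.0, 0.02, size=(J, 3))
        # Engel's law: total food share drifts down ~10 pp per log point
        # of real expenditures, spread over groups by budget weight; the
        # archetype component is strong enough that animal-source,
        # produce and pulse demand stays expenditure-elastic net of the
        # drift while staples are firmly inelastic
        engel_drift = -0.10 * t / t.sum()
        for j in range(J):
            cc = np.zeros(R + 1)
            cc[1] = slope_sign[j] * 0.30 * t[j] + engel_drift[j] \
                + rng.normal(0.0, 0.08 * t[j])
            if R >= 2:
                cc[2] = rng.normal(0.0, 0.05 * t[j])
            if R >= 3:
                cc[3:] = rng.normal(0.0, 0.01 * t[j], R - 2)
            cc[0] = t[j] - float(G[j] @ z_ref)
            b[j] = _shift_poly(cc, y_ref)
        scale = np.sqrt(np.outer(t, t))
        A = rng.normal(0.0, 0.12, (J, J)) * scale
        A = 0.5 * (A + A.T)
        np.fill_diagonal(A, rng.uniform(-0.25, 0.45, J) * t)
        Dm = rng.normal(0.0, 0.04, (J, J)) * scale
        Dm = 0.5 * (Dm + Dm.T)
        sig = config.share_error_scale * np.sqrt(t * (1 - t))
        Sigma_e = np.diag(sig ** 2)

        prefs = TruePreferences(b, A, Dm, G, Sigma_e, names, z_ref,
                                float(y_ref), t)
        # (i) shares at the reference point equal the targets by construction
        w_ref, _ = prefs.solve(np.zeros((1, J)), [y_ref],
                               z=z_ref[None, :], damping=1.0)
        if not (np.all(w_ref > 0.01) and np.all(w_ref < 0.6)):
            continue
        # (ii) robustness scan over random demand determinants
        n_chk = 50
        lnx_chk = rng.normal(y_ref, sigma, n_chk)
        lnp_chk = rng.normal(0.0, max(config.price_dispersion, 0.15), (n_chk, J))
        z_chk = np.column_stack([
            np.log(rng.integers(1, 10, n_chk)),
            rng.integers(0, 2, n_chk).astype(float),
            rng.uniform(0.2, 0.8, n_chk),
        ])
        try:
            w_chk, _ = prefs.solve(lnp_chk, lnx_chk, z=z_chk)
        except RuntimeError:
            continue
        if not np.all(np.isfinite(w_chk)):
            continue
        if w_chk[:, :J].min() < -0.5 or w_chk[:, :J].max() > 0.9:
            continue
        if w_chk[:, J].min() < 0.02:
            continue
        return prefs

    raise RuntimeError(
        f"no admissible preference draw in {max_attempts} attempts: could not "
        "satisfy share bounds (0.01, 0.6) at the reference household together "
        "with a bounded-share robustness scan")


def generate_panel(config: SynthConfig, prefs: TruePreferences,
                   composition: pd.DataFrame | None = None,
                   max_retries: int = 50) -> HouseholdPanel:
    """Simulate the household panel from ground-truth preferences.

    Latent shares solve the EASI fixed point with MVN latent errors
    (plus a cluster-level taste component correlated with cluster
    prices); negative latent shares are censored at zero with the
    removed mass assigned to the numeraire.  Item prices carry quality
    (log-expenditure) and price-search (preference-error) loadings, so
    unit values are endogenous by construction and the neighbour-price
    and average-share instruments are genuinely needed.
    """
    config.validate()
    J = config.n_groups
    if prefs.n_groups != J:
        raise ValueError("preferences inconsistent with config dimensions")
    if composition is None:
        composition = default_composition(J, config.seed)
    T, H, C = config.n_waves, config.n_households, config.n_clusters
    I = config.n_items_per_group
    rng = np.random.default_rng([config.seed, 0xB2])
    mu, sigma = config.expenditure_lognormal

    # --- households and rosters -------------------------------------------
    cluster = rng.permutation(H) % C
    stratum = cluster // config.clusters_per_stratum
    urban = (rng.random(H) < 0.3).astype(int)
    sizes = np.minimum(1 + rng.poisson(3.0, H), 12)
    roster_rows = []
    head_age = rng.uniform(22, 75, H)
    for h in range(H):
        ages = [head_age[h]]
        for _ in range(sizes[h] - 1):
            u = rng.random()
            if u < 0.45:
                ages.append(rng.uniform(0.5, 14))
            elif u < 0.90:
                ages.append(rng.uniform(15, 59))
            else:
                ages.append(rng.uniform(60, 85))
        for m, a in enumerate(ages):
            roster_rows.append((h, m, float(a), "m" if rng.random() < 0.5 else "f"))
    roster = pd.DataFrame(roster_rows, columns=["hh", "member", "age", "sex"])
    # adult equivalents with the default age scale (same scale used in prep)
    ae_w = np.where(roster["age"] < 15, 0.5, np.where(roster["age"] >= 60, 0.8, 1.0))
    AE = pd.Series(ae_w).groupby(roster["hh"].values).sum().reindex(range(H)).values

    # z shifters: log household size, urban flag, head age / 100
    z_hh = np.column_stack([np.log(sizes), urban.astype(float), head_age / 100.0])

    # --- expenditures ------------------------------------------------------
    u_h = rng.normal(0, 1, H)
    v_ht = rng.normal(0, 1, (H, T))
    ln_daily_ae = mu + sigma * (0.8 * u_h[:, None] + 0.6 * v_ht)
    x_week = np.exp(ln_daily_ae) * 7.0 * AE[:, None]          # (H, T)
    lnx = np.log(x_week)

    # --- prices ------------------------------------------------------------
    # base price levels anchored to energy density: staples are cheap per
    # calorie, animal-source foods and produce expensive, matching the
    # stylised price structure of African food markets
    rate = np.array([_price_per_1000kcal(g, rng) for g in prefs.group_names])
    kcal_per_kg = composition["energy_kcal"].values * 10.0
    ln_pi = np.log(rate * kcal_per_kg / 1000.0)                # $/kg levels
    item_offsets = rng.normal(0.0, 0.10, (J, I))
    base_cw = ln_pi[None, None, :] + rng.normal(
        0.0, config.price_dispersion, (C, T, J))               # cluster x wave x group

    # cluster taste correlated with cluster average prices (what the
    # correlated-random-effects device is meant to absorb)
    base_cmean = base_cw.mean(axis=1)                           # (C, J)
    zb = (base_cmean - base_cmean.mean(0)) / np.maximum(base_cmean.std(0), 1e-12)
    taste_c = config.cluster_taste_scale * (0.6 * zb + 0.8 * rng.normal(0, 1, (C, J)))

    sig_e = np.sqrt(np.diag(prefs.Sigma_e))
    zx = (lnx - lnx.mean()) / max(lnx.std(), 1e-12)             # (H, T)

    hh_rows, rec_rows = [], []
    truth = {k: [] for k in ("hh", "wave", "lnp", "lnx", "z", "w_latent",
                             "w_obs", "y", "errors", "taste", "x_week", "ae",
                             "cluster", "group_price")}
    dir_w = rng.dirichlet(np.full(I, 5.0), J)                   # item expenditure splits

    for t_idx in range(T):
        e = rng.multivariate_normal(np.zeros(J), prefs.Sigma_e, H) \
            if np.any(prefs.Sigma_e) else np.zeros((H, J))
        err = e + taste_c[cluster]
        # item and group prices faced by each household
        std_e = np.where(sig_e > 0, e / np.where(sig_e > 0, sig_e, 1.0), 0.0)
        qual = config.quality_loading * zx[:, t_idx][:, None] \
            + config.search_loading * std_e                     # (H, J)
        item_noise = rng.normal(0.0, config.item_price_noise, (H, J, I))
        ln_item = (base_cw[cluster, t_idx][:, :, None]
                   + item_offsets[None, :, :] + qual[:, :, None] + item_noise)
        lnp_hh = ln_item.mean(axis=2)                           # (H, J) levels
        # preferences are parameterised on deviations from group base price
        # levels, so lnp = 0 means "unit (base) prices"
        lnp_dev = lnp_hh - ln_pi[None, :]

        for retry in range(max_retries + 1):
            w_lat, y = demand.solve_shares(
                prefs.b, prefs.A, prefs.D, prefs.G, None,
                lnp_dev, lnx[:, t_idx], z=z_hh, errors=err)
            w_food = np.maximum(w_lat[:, :J], 0.0)
            dead = w_food.sum(axis=1) <= 0
            if not dead.any():
                break
            if retry == max_retries or not np.any(prefs.Sigma_e):
                raise RuntimeError(
                    f"{dead.sum()} households with all-zero food consumption "
                    f"after {retry} error redraws in wave {t_idx + 1}")
            redraw = rng.multivariate_normal(np.zeros(J), prefs.Sigma_e,
                                             int(dead.sum()))
            e[dead] = redraw
            err = e + taste_c[cluster]
            std_e = np.where(sig_e > 0, e / np.where(sig_e > 0, sig_e, 1.0), 0.0)
            qual = config.quality_loading * zx[:, t_idx][:, None] \
                + config.search_loading * std_e
            ln_item = (base_cw[cluster, t_idx][:, :, None]
                       + item_offsets[None, :, :] + qual[:, :, None] + item_noise)
            lnp_hh = ln_item.mean(axis=2)
            lnp_dev = lnp_hh - ln_pi[None, :]

        # censor: truncate negatives, removed mass goes to the numeraire
        w_num = 1.0 - w_food.sum(axis=1)
        low = w_num < 0.01
        if low.any():  # rare: keep the numeraire share weakly positive
            w_food[low] *= ((1.0 - 0.01) / w_food[low].sum(axis=1))[:, None]
            w_num[low] = 0.01
        w_obs = np.column_stack([w_food, w_num])

        group_exp = w_food * x_week[:, t_idx][:, None]          # (H, J)
        values = group_exp[:, :, None] * dir_w[None, :, :]      # (H, J, I)
        qty = values / np.exp(ln_item)
        nonfood = w_num * x_week[:, t_idx]

        src_draw = rng.random((H, J, I))
        f_own = config.own_production_fraction
        wave = t_idx + 1
        for h in range(H):
            hh_rows.append((h, wave, int(cluster[h]), int(stratum[h]),
                            int(urban[h]), float(nonfood[h]), 1.0))
        pos = np.argwhere(values > 1e-12)
        for h, g, i in pos:
            s = src_draw[h, g, i]
            source = ("purchase" if s < 1 - f_own - 0.05
                      else "own_production" if s < 1 - 0.05 else "gift")
            rec_rows.append((int(h), wave, prefs.group_names[g],
                             f"{prefs.group_names[g]}_item{i + 1}",
                             float(qty[h, g, i]), float(values[h, g, i]),
                             source))
        truth["hh"].append(np.arange(H)); truth["wave"].append(np.full(H, wave))
        truth["lnp"].append(lnp_dev); truth["lnx"].append(lnx[:, t_idx])
        truth["z"].append(z_hh); truth["w_latent"].append(w_lat)
        truth["w_obs"].append(w_obs); truth["y"].append(y)
        truth["errors"].append(err); truth["taste"].append(taste_c[cluster])
        truth["x_week"].append(x_week[:, t_idx])
        truth["ae"].append(AE); truth["cluster"].append(cluster)
        qsum = qty.sum(axis=2)
        gp = np.where(qsum > 0, group_exp / np.where(qsum > 0, qsum, 1.0),
                      np.exp(lnp_hh))
        truth["group_price"].append(gp)

    households = pd.DataFrame(
        hh_rows, columns=["hh", "wave", "cluster", "stratum", "urban",
                          "nonfood_value", "weight"])
    records = pd.DataFrame(
        rec_rows, columns=["hh", "wave", "group", "item", "quantity",
                           "value", "source"])
    truth_arrays = {}
    for k, v in truth.items():
        truth_arrays[k] = np.concatenate(v) if np.ndim(v[0]) == 1 \
            else np.vstack(v)
    truth_arrays["prefs"] = prefs
    truth_arrays["config"] = asdict(config)
    return HouseholdPanel(households, roster, records, composition,
                          list(prefs.group_names), truth_arrays)
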