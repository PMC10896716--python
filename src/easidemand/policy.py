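"""Cash-transfer and price-discount microsimulation with cost accounting.

Two stylised interventions are pushed through the fitted demand system:

* **CT** — a flat cash transfer of 20% of the median Q1 (extreme-poor)
  household's monthly expenditures; a fraction kappa (default 1) raises
  weekly total expenditures and demand is re-solved at unchanged prices.
* **PD** — a 25% price discount on one of five food categories (SG
  staple grains, SS starchy staples, PN pulses and nuts, FFV fresh
  fruits and vegetables, ASF animal-source foods); demand is re-solved
  at unchanged expenditures and the programme cost equals the redeemed
  value delta * p0 * q_post.

Producer prices, wages and all other equilibrium feedbacks are held
fixed by assumption.  Pre-intervention columns are computed once from
the same predictor, so they are bit-identical across scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import diet
from .demand import censored_mean_shares
from .prep import WEEKS_PER_MONTH, PreparedData

__all__ = [
    "CTConfig", "PDConfig", "SimulationOutcome", "default_category_map",
    "ct_transfer", "simulate_cash_transfer", "simulate_price_discount",
    "pd_cost", "sufficiency_curve", "truth_predictor",
]

PD_CATEGORIES = ("SG", "SS", "PN", "FFV", "ASF")

_CATEGORY_PREFIX = {
    "SG": ("staple_grain", "other_cereals"),
    "SS": ("starchy_staple",),
    "PN": ("pulses_nuts",),
    "FFV": ("fruits_veg",),
    "ASF": ("animal_source",),
}


def default_category_map(group_names) -> pd.DataFrame:
    """Food-group -> discount-category mapping for the default groups."""
    rows = []
    for g in group_names:
        cat = ""
        for c, prefixes in _CATEGORY_PREFIX.items():
            if any(g.startswith(p) for p in prefixes):
                cat = c
                break
        rows.append({"group": g, "category": cat})
    return pd.DataFrame(rows)


@dataclass
class CTConfig:
    """Cash transfer: flat per household, not scaled by size/composition."""

    transfer_monthly: float          # US$ PPP per household per month
    kappa: float = 1.0               # fraction spent on total expenditures

    def __post_init__(self):
        # zero is allowed as the null intervention (baseline identity)
        if self.transfer_monthly < 0:
            raise ValueError("transfer must be nonnegative")
        if not 0 < self.kappa <= 1:
            raise ValueError("kappa must be in (0, 1]")

    @property
    def transfer_weekly(self):
        return self.transfer_monthly / WEEKS_PER_MONTH


@dataclass
class PDConfig:
    """Price discount on one food category."""

    category: str
    discount: float = 0.25
    mapping: pd.DataFrame | None = None

    def __post_init__(self):
        # zero is allowed as the null intervention (baseline identity)
        if not 0 <= self.discount < 1:
            raise ValueError("discount must be in [0, 1)")

    def groups(self, group_names):
        mapping = self.mapping if self.mapping is not None \
            else default_category_map(group_names)
        sel = mapping.loc[mapping["category"] == self.category, "group"]
        idx = [group_names.index(g) for g in sel if g in group_names]
        if not idx:
            raise ValueError(
                f"category {self.category} maps to no food group")
        return idx


def ct_transfer(data: PreparedData, share: float = 0.20) -> float:
    """Transfer size: ``share`` of median Q1 monthly household expenditures."""
    q1 = data.x_week[data.quartile == "Q1"]
    if q1.size == 0:
        raise ValueError("no Q1 households in the sample")
    return share * float(np.median(q1)) * WEEKS_PER_MONTH


@dataclass
class SimulationOutcome:
    """Pre/post tables of one scenario."""

    scenario: str
    households: pd.DataFrame         # per-observation pre/post fields
    w_pre: np.ndarray
    w_post: np.ndarray
    qty_pre: np.ndarray
    qty_post: np.ndarray
    data: PreparedData = field(repr=False, default=None)
    config: object = None

    def quartile_summary(self) -> pd.DataFrame:
        """Sufficiency shares pre/post, costs and MPC by quartile."""
        df = self.households
        rows = []
        for q, g in df.groupby("quartile", sort=True):
            row = {"quartile": q, "n": len(g)}
            for c in df.columns:
                if c.startswith("suff_") and c.endswith("_pre"):
                    base = c[5:-4]
                    row[f"suff_{base}_pre"] = g[c].mean()
                    row[f"suff_{base}_post"] = g[f"suff_{base}_post"].mean()
            if "mpc_food" in df:
                row["mpc_food_median"] = g["mpc_food"].median()
            if "cost_monthly" in df:
                row["cost_monthly_median"] = g["cost_monthly"].median()
                row["cost_monthly_mean"] = g["cost_monthly"].mean()
            row["nrfi_pre_median"] = g["nrfi_pre"].median()
            row["nrfi_post_median"] = g["nrfi_post"].median()
            rows.append(row)
        return pd.DataFrame(rows)

    def balance_summary(self) -> pd.DataFrame:
        """Share of households below/above each WHO macronutrient range."""
        df = self.households
        rows = []
        for q, g in df.groupby("quartile", sort=True):
            for macro in ("carbohydrate", "fat", "protein"):
                for when in ("pre", "post"):
                    cl = g[f"class_{macro}_{when}"]
                    rows.append({
                        "quartile": q, "macronutrient": macro, "when": when,
                        "below": (cl == "below").mean(),
                        "within": (cl == "within").mean(),
                        "above": (cl == "above").mean(),
                    })
        return pd.DataFrame(rows)


def _diet_fields(w, data, composition, requirements, roster):
    """Quantities, intakes, sufficiency, balance and NRFI from shares."""
    J = data.n_groups
    exp_g = w[:, :J] * data.x_week[:, None]
    qty = np.where(data.gprice > 0, exp_g / data.gprice, 0.0)
    rep = diet.diet_quality_report(qty, composition, roster, data.hh,
                                   requirements)
    return qty, rep


def _simulate(predict_fn, data: PreparedData, scenario, dlnx=0.0, dlnp=None,
              composition=None, requirements=None) -> SimulationOutcome:
    comp = composition if composition is not None else data.composition
    roster = data.roster
    data_cf = data.shifted(dlnx=dlnx, dlnp=dlnp)
    w_pre = predict_fn(data)
    w_post = predict_fn(data_cf)
    qty_pre, rep_pre = _diet_fields(w_pre, data, comp, requirements, roster)
    qty_post, rep_post = _diet_fields(w_post, data_cf, comp, requirements,
                                      roster)
    df = pd.DataFrame({"hh": data.hh, "wave": data.wave,
                       "quartile": data.quartile,
                       "x_week_pre": data.x_week,
                       "x_week_post": data_cf.x_week})
    keep = [c for c in rep_pre.columns
            if c.startswith(("suff_", "intake_", "share_", "class_"))
            or c == "nrfi"]
    for c in keep:
        df[f"{c}_pre"] = rep_pre[c].values
        df[f"{c}_post"] = rep_post[c].values
    J = data.n_groups
    df["food_exp_pre"] = (w_pre[:, :J] * data.x_week[:, None]).sum(axis=1)
    df["food_exp_post"] = (w_post[:, :J] * data_cf.x_week[:, None]).sum(axis=1)
    return SimulationOutcome(scenario=scenario, households=df,
                             w_pre=w_pre, w_post=w_post,
                             qty_pre=qty_pre, qty_post=qty_post, data=data)


def simulate_cash_transfer(results, data: PreparedData | None = None,
                           ct: CTConfig | None = None,
                           composition=None, requirements=None,
                           predict_fn=None) -> SimulationOutcome:
    """Re-solve demand at x + kappa*CT (weekly basis), prices unchanged.

    MPC on food is the change in total food expenditure divided by the
    spent transfer.
    """
    data = data if data is not None else results.data
    if ct is None:
        ct = CTConfig(transfer_monthly=ct_transfer(data))
    predict = predict_fn or (lambda d: results.predict_shares(d))
    add = ct.kappa * ct.transfer_weekly
    dlnx = np.log1p(add / data.x_week)
    out = _simulate(predict, data, "CT", dlnx=dlnx,
                    composition=composition, requirements=requirements)
    df = out.households
    df["mpc_food"] = (df["food_exp_post"] - df["food_exp_pre"]) / add \
        if add > 0 else 0.0
    df["cost_monthly"] = ct.transfer_monthly
    out.config = ct
    return out


def simulate_price_discount(results, data: PreparedData | None = None,
                            pd_config: PDConfig | None = None,
                            composition=None, requirements=None,
                            predict_fn=None) -> SimulationOutcome:
    """Re-solve demand at discounted category prices, x unchanged."""
    data = data if data is not None else results.data
    if pd_config is None:
        pd_config = PDConfig(category="PN")
    idx = pd_config.groups(list(data.group_names))
    dlnp = np.zeros(data.n_groups)
    dlnp[idx] = np.log1p(-pd_config.discount)
    predict = predict_fn or (lambda d: results.predict_shares(d))
    out = _simulate(predict, data, f"PD_{pd_config.category}", dlnp=dlnp,
                    composition=composition, requirements=requirements)
    out.config = pd_config
    out.households["cost_monthly"] = pd_cost(out, pd_config)
    return out


def pd_cost(outcome: SimulationOutcome, pd_config: PDConfig) -> np.ndarray:
    """Monthly redeemed value per household: sum_cat delta * p0 * q_post.

    p0 is the pre-discount price level, q_post the post-discount weekly
    quantity; weekly values convert to monthly by 365.25/12/7.
    """
    data = outcome.data
    idx = pd_config.groups(list(data.group_names))
    weekly = (pd_config.discount * data.gprice[:, idx]
              * outcome.qty_post[:, idx]).sum(axis=1)
    return weekly * WEEKS_PER_MONTH


def sufficiency_curve(sufficient, ln_x_per_ae, grid=None, bandwidth=0.25,
                      min_weight=1e-3):
    """Local-averaging (Gaussian kernel) sufficiency probability curve.

    Smooths the binary sufficiency flag on log expenditures per adult
    equivalent over a fixed grid; grid points with negligible kernel
    mass are trimmed (returned as NaN).
    """
    s = np.asarray(sufficient, float)
    x = np.asarray(ln_x_per_ae, float)
    if s.size < 100:
        raise ValueError("need at least 100 households for the curve")
    if grid is None:
        grid = np.linspace(np.quantile(x, 0.01), np.quantile(x, 0.99), 60)
    d = (x[None, :] - grid[:, None]) / bandwidth
    K = np.exp(-0.5 * d * d)
    wsum = K.sum(axis=1)
    with np.errstate(invalid="ignore"):
        curve = (K @ s) / wsum
    curve[wsum < min_weight * s.size] = np.nan
    return grid, curve


def truth_predictor(prefs, data: PreparedData):
    """Ground-truth censored-mean share predictor for oracle checks.

    Solves the latent system under the true preferences (conditioning on
    the cluster taste component when the data carry it, but integrating
    over the idiosyncratic draws) and applies the censored-mean
    transform with the true latent error scales, mirroring what the
    fitted model's adjusted predictor estimates.
    """
    J = prefs.n_groups
    sig = np.sqrt(np.diag(prefs.Sigma_e))
    taste = data.meta.get("taste") if isinstance(data.meta, dict) else None

    def predict(d: PreparedData):
        z3 = d.z[:, :3]
        w_lat, _ = prefs.solve(d.lnp, d.lnx, z=z3, errors=taste)
        w_food = censored_mean_shares(w_lat[:, :J], sig)
        w = np.column_stack([w_food, 1.0 - w_food.sum(axis=1)])
        wc = np.clip(w, 0.0, None)
        return wc / wc.sum(axis=1, keepdims=True)

    return predict
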