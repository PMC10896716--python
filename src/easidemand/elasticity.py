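"""Expenditure, price and nutrient-intake elasticities of the fitted system.

Elasticities are total derivatives of the latent fixed-point demand
(through the implicit-utility channel) evaluated at each observation.
At interior observations they satisfy the demand-theory identities to
machine precision:

* Engel aggregation        sum_j w_j eta_j = 1
* Cournot aggregation      sum_j w_j eps_jk = -w_k
* homogeneity              sum_k eps_jk + eta_j = 0
* Hicksian Slutsky         w_j eps^H_jk = w_k eps^H_kj

Nutrient-intake elasticities weight the food elasticities by each
observation's nutrient source shares s_nj (the share of nutrient n
obtained from food group j), and the effect of a staple price can be
decomposed into its own-price and cross-price channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import demand

__all__ = [
    "ElasticitySet", "NutrientElasticitySet", "compute_elasticities",
    "expenditure_elasticities", "price_elasticities",
    "simulate_standard_errors", "nutrient_source_shares",
    "nutrient_elasticities", "decompose_price_effect",
]

SHARE_FLOOR = 1e-4


@dataclass
class ElasticitySet:
    """Per-observation elasticities of the J+1 goods (numeraire last)."""

    eta: np.ndarray              # (N, J+1) expenditure elasticities
    E_marsh: np.ndarray          # (N, J+1, J+1) Marshallian
    E_hicks: np.ndarray          # (N, J+1, J+1) Hicksian
    w: np.ndarray                # (N, J+1) latent shares used
    stable: np.ndarray           # (N, J+1) share above floor
    quartile: np.ndarray | None = None
    group_names: list = field(default_factory=list)
    eta_se: np.ndarray | None = None
    E_marsh_se: np.ndarray | None = None
    E_hicks_se: np.ndarray | None = None
    se_meta: dict = field(default_factory=dict)

    @property
    def n_obs(self):
        return len(self.eta)

    def median_by_quartile(self, kind="expenditure"):
        """Median elasticity per expenditure group, unstable cells excluded.

        ``kind``: "expenditure" gives a (quartile x good) table of eta;
        "own_price" the Marshallian diagonal; "price" the full matrix
        stacked long.
        """
        if self.quartile is None:
            raise ValueError("no quartile labels attached")
        names = list(self.group_names) + ["numeraire"]
        qs = pd.unique(pd.Series(self.quartile).sort_values())
        rows = {}
        for q in qs:
            mask = self.quartile == q
            if kind == "expenditure":
                vals = np.where(self.stable[mask], self.eta[mask], np.nan)
            elif kind == "own_price":
                diag = np.einsum("njj->nj", self.E_marsh[mask])
                vals = np.where(self.stable[mask], diag, np.nan)
            elif kind == "price":
                ok = self.stable[mask][:, :, None] & np.isfinite(
                    self.E_marsh[mask])
                vals = np.where(ok, self.E_marsh[mask], np.nan)
                rows[q] = np.nanmedian(vals, axis=0)
                continue
            else:
                raise ValueError(kind)
            rows[q] = np.nanmedian(vals, axis=0)
        if kind == "price":
            out = []
            for q, m in rows.items():
                df = pd.DataFrame(m, index=names, columns=names)
                df.insert(0, "quartile", q)
                out.append(df.rename_axis("good").reset_index())
            return pd.concat(out, ignore_index=True)
        return pd.DataFrame(rows, index=names).T.rename_axis("quartile")


def _solve_point(params, data):
    cmeans = data.cmeans if params.M.size else None
    z = data.z if params.G.size else None
    return params.solve(data.lnp, data.lnx, z=z, cmeans=cmeans)


def compute_elasticities(params, data, share_floor=SHARE_FLOOR,
                         w=None, y=None) -> ElasticitySet:
    """Analytic elasticities of the latent demand at every observation."""
    if w is None or y is None:
        w, y = _solve_point(params, data)
    dw_dlnx, dw_dlnp, _, _ = demand.share_derivatives(
        params.b, params.A, params.D, y, w, data.lnp, utility=params.utility)
    stable = w > share_floor
    wsafe = np.where(np.abs(w) > share_floor, w, np.nan)
    eta, E_m, E_h = demand.elasticities_from_derivatives(wsafe, dw_dlnx,
                                                         dw_dlnp)
    return ElasticitySet(eta=eta, E_marsh=E_m, E_hicks=E_h, w=w,
                         stable=stable,
                         quartile=getattr(data, "quartile", None),
                         group_names=list(getattr(data, "group_names", [])))


def expenditure_elasticities(params, data, **kw):
    """eta_j = 1 + (dw_j/dlnx)/w_j through the y fixed point."""
    return compute_elasticities(params, data, **kw).eta


def price_elasticities(params, data, **kw):
    es = compute_elasticities(params, data, **kw)
    return es.E_marsh, es.E_hicks


def simulate_standard_errors(results, data=None, n_draws: int = 1000,
                             seed: int = 0, share_floor=SHARE_FLOOR):
    """Simulation standard errors for every elasticity cell.

    Draws parameter vectors from N(beta_hat, Cov_hat) (cross-equation
    restrictions hold by construction of the free parameterisation),
    recomputes all elasticities per draw, and attaches the draw standard
    deviations to a fresh ElasticitySet.  Welford accumulation keeps
    memory at two copies of the elasticity arrays.
    """
    data = data if data is not None else results.data
    base = compute_elasticities(results.params, data, share_floor)
    acc = {}

    def upd(key, x):
        """Per-cell Welford update; a cell that is unstable (NaN) in one
        draw keeps accumulating over the draws where it is finite."""
        if key not in acc:
            acc[key] = [np.zeros_like(x), np.zeros_like(x),
                        np.zeros(x.shape)]
        mean, m2, n = acc[key]
        ok = np.isfinite(x)
        n += ok
        d = np.where(ok, x - mean, 0.0)
        mean += np.where(ok, d / np.maximum(n, 1), 0.0)
        m2 += np.where(ok, d * (x - mean), 0.0)

    for p in results.simulate_params(n_draws, seed=seed):
        try:
            es = compute_elasticities(p, data, share_floor)
        except RuntimeError:
            continue  # inadmissible draw: fixed point diverged
        upd("eta", es.eta)
        upd("E_marsh", es.E_marsh)
        upd("E_hicks", es.E_hicks)

    def se(key):
        mean, m2, n = acc[key]
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.sqrt(m2 / np.maximum(n - 1, 1))
        out[n < 2] = np.nan
        return out

    base.eta_se = se("eta")
    base.E_marsh_se = se("E_marsh")
    base.E_hicks_se = se("E_hicks")
    base.se_meta = {"n_draws": n_draws, "seed": seed}
    return base


# ---------------------------------------------------------------------------
# nutrient elasticities

def nutrient_source_shares(quantities, composition):
    """s_nj: share of nutrient n intake obtained from food group j.

    ``quantities`` (N, J) in kg; ``composition`` per 100 g, so intake of
    nutrient n is sum_j 10 * q_j * c_nj.  Observations with zero total
    intake of a nutrient get NaN shares and are flagged.
    """
    q = np.atleast_2d(np.asarray(quantities, float))
    if np.any(q < 0):
        raise ValueError("negative quantities")
    C = composition.values.T  # (n_nutrients, J)
    contrib = q[:, None, :] * C[None, :, :]          # (N, n_nut, J)
    total = contrib.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = contrib / total[:, :, None]
    s[total == 0] = np.nan
    return s, total == 0


def nutrient_elasticities(s_n, eta, E_marsh):
    """Weighted-sum nutrient-intake elasticities.

    e_n_x = sum_j s_nj eta_j ;  e_n_p[k] = sum_j s_nj eps_jk.
    ``s_n`` may be (n_nut, J) for one observation or (N, n_nut, J);
    ``eta``/``E_marsh`` must carry matching leading dimensions and may
    include the numeraire (extra trailing entries are ignored for
    sourcing, but price effects are returned for all J+1 prices).
    """
    s = np.asarray(s_n, float)
    one_obs = s.ndim == 2
    if one_obs:
        s = s[None]
        eta = np.asarray(eta, float)[None]
        E_marsh = np.asarray(E_marsh, float)[None]
    J = s.shape[2]
    if eta.shape[1] < J or E_marsh.shape[1] < J:
        raise ValueError("elasticity dimensions do not match source shares")
    e_x = np.einsum("xnj,xj->xn", s, eta[:, :J])
    e_p = np.einsum("xnj,xjk->xnk", s, E_marsh[:, :J, :])
    if one_obs:
        return e_x[0], e_p[0]
    return e_x, e_p


def decompose_price_effect(s_n, E_marsh, k):
    """Own- vs cross-price channel of nutrient response to price k.

    own = s_nk eps_kk (the nutrient obtained from the staple itself);
    cross = sum_{j != k} s_nj eps_jk; own + cross equals the total
    nutrient-price elasticity e_n_p[k].
    """
    s = np.asarray(s_n, float)
    one_obs = s.ndim == 2
    if one_obs:
        s = s[None]
        E_marsh = np.asarray(E_marsh, float)[None]
    own = s[:, :, k] * E_marsh[:, k, k][:, None]
    total = np.einsum("xnj,xj->xn", s, E_marsh[:, :s.shape[2], k])
    cross = total - own
    if one_obs:
        return own[0], cross[0]
    return own, cross


@dataclass
class NutrientElasticitySet:
    """Nutrient-intake elasticities per observation."""

    source_shares: np.ndarray    # (N, n_nut, J)
    e_x: np.ndarray              # (N, n_nut)
    e_p: np.ndarray              # (N, n_nut, J+1)
    zero_intake: np.ndarray      # (N, n_nut) flags
    nutrient_names: list
    group_names: list
    quartile: np.ndarray | None = None

    def median_by_quartile(self):
        rows = []
        qs = pd.unique(pd.Series(self.quartile).sort_values())
        for q in qs:
            m = self.quartile == q
            med_x = np.nanmedian(self.e_x[m], axis=0)
            med_p = np.nanmedian(self.e_p[m], axis=0)
            for i, n in enumerate(self.nutrient_names):
                row = {"quartile": q, "nutrient": n,
                       "expenditure": med_x[i]}
                for j, g in enumerate(self.group_names):
                    row[f"p_{g}"] = med_p[i, j]
                rows.append(row)
        return pd.DataFrame(rows)


def compute_nutrient_elasticities(es: ElasticitySet, quantities,
                                  composition) -> NutrientElasticitySet:
    s, zero = nutrient_source_shares(quantities, composition)
    e_x, e_p = nutrient_elasticities(s, es.eta, es.E_marsh)
    return NutrientElasticitySet(
        source_shares=s, e_x=e_x, e_p=e_p, zero_intake=zero,
        nutrient_names=list(composition.columns),
        group_names=list(composition.index), quartile=es.quartile)
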