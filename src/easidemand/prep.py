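"""Survey preparation: unit values, Fisher group price indices, instruments,
expenditure aggregates and expenditure-group assignment.

Turns raw item-level consumption records into the estimation-ready
observation table: J food-group budget shares plus a numeraire share,
log Fisher group price indices (quality-adjusted within groups),
log total weekly expenditures, demand shifters, cluster means for the
correlated-random-effects device, and the two instrument sets
(leave-one-out neighbour log prices; the average-share Stone index).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_AE_SCALE", "QuartileScheme", "PreparedData",
    "adult_equivalents", "assign_quartile", "unit_values",
    "fisher_group_index", "neighbour_price_instrument",
    "stone_index", "avg_share_stone_index", "prepare",
    "WEEKS_PER_MONTH",
]

#: weekly -> monthly conversion factor
WEEKS_PER_MONTH = (365.25 / 12.0) / 7.0

#: (age_lo, age_hi, weight): children under 15 count 0.5, elderly 0.8
DEFAULT_AE_SCALE = [(0.0, 15.0, 0.5), (15.0, 60.0, 1.0), (60.0, np.inf, 0.8)]


@dataclass(frozen=True)
class QuartileScheme:
    """Expenditure-group cutoffs in US$ PPP per adult equivalent per day.

    The defaults are the international extreme poverty line (1.90), the
    international poverty line (3.20) and the upper-middle-income line
    (5.50); intervals are half-open and lower-inclusive.
    """
    cutoffs: tuple = (1.90, 3.20, 5.50)
    labels: tuple = ("Q1", "Q2", "Q3", "Q4")

    def __post_init__(self):
        if not all(a < b for a, b in zip(self.cutoffs, self.cutoffs[1:])):
            raise ValueError("cutoffs must be strictly increasing")
        if len(self.labels) != len(self.cutoffs) + 1:
            raise ValueError("need one more label than cutoffs")


def adult_equivalents(roster: pd.DataFrame, scale=None) -> pd.Series:
    """Adult equivalents per household from the member age roster."""
    if roster.empty:
        raise ValueError("roster is empty")
    scale = scale or DEFAULT_AE_SCALE
    age = roster["age"].values
    w = np.full(len(roster), np.nan)
    for lo, hi, wt in scale:
        w = np.where((age >= lo) & (age < hi), wt, w)
    if np.isnan(w).any():
        raise ValueError("ages not covered by the adult-equivalent scale")
    ae = pd.Series(w, index=roster["hh"].values).groupby(level=0).sum()
    ae.index.name = "hh"
    return ae


def assign_quartile(daily_per_ae, scheme: QuartileScheme | None = None):
    """Expenditure-group label per observation (half-open, lower-inclusive)."""
    scheme = scheme or QuartileScheme()
    x = np.asarray(daily_per_ae, float)
    if np.any(x < 0):
        raise ValueError("negative expenditures")
    idx = np.searchsorted(np.asarray(scheme.cutoffs), x, side="right")
    return np.asarray(scheme.labels, object)[idx]


def unit_values(records: pd.DataFrame, households: pd.DataFrame,
                min_count: int = 5) -> pd.DataFrame:
    """Item-level unit values for every household-wave x item cell.

    Purchased records keep their own value/quantity; everything else is
    imputed with the median purchaser unit value at the smallest
    geography (cluster, then stratum, then national) holding at least
    ``min_count`` purchase observations (national requires only one).
    The imputation level is recorded in ``impute_level``.
    """
    hw = households[["hh", "wave", "cluster", "stratum"]].drop_duplicates()
    items = records[["item", "group"]].drop_duplicates()

    purch = records.loc[(records["source"] == "purchase")
                        & (records["quantity"] > 0)].copy()
    if purch.empty:
        raise ValueError("no purchase records in the sample")
    purch["uv"] = purch["value"] / purch["quantity"]
    purch = purch.merge(hw, on=["hh", "wave"], how="left")

    def med(by):
        g = purch.groupby(by)["uv"].agg(["median", "size"]).reset_index()
        return g

    mc = med(["wave", "item", "cluster"])
    mc = mc.loc[mc["size"] >= min_count].rename(columns={"median": "uv_cluster"})
    ms = med(["wave", "item", "stratum"])
    ms = ms.loc[ms["size"] >= min_count].rename(columns={"median": "uv_stratum"})
    mn = med(["wave", "item"]).rename(columns={"median": "uv_national"})

    missing = (items.merge(pd.DataFrame({"wave": households["wave"].unique()}),
                           how="cross")
               .merge(mn[["wave", "item"]].assign(_ok=1),
                      on=["wave", "item"], how="left"))
    never = missing.loc[missing["_ok"].isna(), ["item", "wave"]]
    if len(never):
        raise ValueError(
            "items never purchased anywhere in a wave: "
            + "; ".join(f"{r.item} (wave {r.wave})" for r in never.itertuples()))

    grid = hw.merge(items, how="cross")
    own = purch.groupby(["hh", "wave", "item"], as_index=False)["uv"] \
        .median().rename(columns={"uv": "uv_own"})
    grid = (grid.merge(own, on=["hh", "wave", "item"], how="left")
            .merge(mc[["wave", "item", "cluster", "uv_cluster"]],
                   on=["wave", "item", "cluster"], how="left")
            .merge(ms[["wave", "item", "stratum", "uv_stratum"]],
                   on=["wave", "item", "stratum"], how="left")
            .merge(mn[["wave", "item", "uv_national"]],
                   on=["wave", "item"], how="left"))
    level = np.select(
        [grid["uv_own"].notna(), grid["uv_cluster"].notna(),
         grid["uv_stratum"].notna()],
        ["own", "cluster", "stratum"], default="national")
    uv = (grid["uv_own"].fillna(grid["uv_cluster"]).fillna(grid["uv_stratum"])
          .fillna(grid["uv_national"]))
    out = grid[["hh", "wave", "cluster", "stratum", "item", "group"]].copy()
    out["unit_value"] = uv
    out["impute_level"] = level
    if np.any(out["unit_value"] <= 0) or out["unit_value"].isna().any():
        raise ValueError("nonpositive or missing unit value after imputation")
    return out


def fisher_group_index(uv_grid: pd.DataFrame, records: pd.DataFrame,
                       base_wave: int = 1):
    """Fisher Ideal price index per household-wave at the food-group level.

    The base is the sample mean of item unit values and item quantities
    in ``base_wave``, so indices are comparable across waves.  Items a
    household did not consume contribute through imputed unit values:
    the Laspeyres leg weights all items by base quantities, the Paasche
    leg by the household's current quantities (falling back to the
    Laspeyres leg when the household consumed nothing in the group).

    Returns ``(lnp_df, base)`` where ``lnp_df`` has one row per
    household-wave and one log-index column per group.
    """
    item_order = uv_grid[["item", "group"]].drop_duplicates().sort_values("item")
    items = item_order["item"].tolist()
    groups = sorted(item_order["group"].unique())

    P = uv_grid.pivot_table(index=["hh", "wave"], columns="item",
                            values="unit_value")[items]
    if P.isna().any().any() or (P.values <= 0).any():
        raise ValueError("nonpositive price in unit-value grid")
    qrec = records.groupby(["hh", "wave", "item"])["quantity"].sum()
    Q = qrec.unstack("item").reindex(index=P.index, columns=items).fillna(0.0)

    base_rows = P.index.get_level_values("wave") == base_wave
    if not base_rows.any():
        raise ValueError(f"no observations in base wave {base_wave}")
    p0 = P.values[base_rows].mean(axis=0)
    q0 = Q.values[base_rows].mean(axis=0)

    lnp = {}
    gmask = {g: item_order["group"].values == g for g in groups}
    for g in groups:
        m = gmask[g]
        l_den = float(p0[m] @ q0[m])
        if l_den <= 0:
            raise ValueError(f"group {g} has no positive base expenditure")
        lasp = (P.values[:, m] @ q0[m]) / l_den
        pa_num = (P.values[:, m] * Q.values[:, m]).sum(axis=1)
        pa_den = Q.values[:, m] @ p0[m]
        paasche = np.where(pa_den > 0, pa_num / np.where(pa_den > 0, pa_den, 1.0),
                           lasp)
        lnp[g] = 0.5 * (np.log(lasp) + np.log(paasche))
    lnp_df = pd.DataFrame(lnp, index=P.index).reset_index()
    base = {"p0": dict(zip(items, p0)), "q0": dict(zip(items, q0)),
            "wave": base_wave}
    return lnp_df, base


def neighbour_price_instrument(lnp_df: pd.DataFrame, households: pd.DataFrame,
                               group_cols=None):
    """Leave-one-out cluster-wave mean log group prices per household.

    Singleton cluster-waves fall back to the leave-one-out stratum-wave
    mean and are flagged in the ``nbr_level`` column.
    """
    group_cols = group_cols or [c for c in lnp_df.columns
                                if c not in ("hh", "wave")]
    df = lnp_df.merge(households[["hh", "wave", "cluster", "stratum"]]
                      .drop_duplicates(), on=["hh", "wave"])
    out = df[["hh", "wave"]].copy()
    vals = df[group_cols].values

    def loo(keys):
        grp = df.groupby(keys)[group_cols]
        s = grp.transform("sum").values
        n = grp.transform("size").values[:, None].astype(float)
        with np.errstate(invalid="ignore"):
            return (s - vals) / (n - 1.0), n[:, 0]

    m_c, n_c = loo(["cluster", "wave"])
    m_s, _ = loo(["stratum", "wave"])
    single = n_c < 2
    inst = np.where(single[:, None], m_s, m_c)
    if np.isnan(inst).any():
        raise ValueError("singleton stratum-wave: cannot build price instrument")
    for i, c in enumerate(group_cols):
        out[f"nbr_{c}"] = inst[:, i]
    out["nbr_level"] = np.where(single, "stratum", "cluster")
    return out


def stone_index(w, lnp):
    """Stone price index sum_k w_k ln p_k (numeraire log price is zero)."""
    w = np.atleast_2d(np.asarray(w, float))
    lnp = np.atleast_2d(np.asarray(lnp, float))
    if w.shape[1] == lnp.shape[1] + 1:
        w = w[:, :-1]
    out = np.einsum("nj,nj->n", w, lnp)
    return out if out.size > 1 else float(out[0])


def avg_share_stone_index(wbar, lnp):
    """Stone index using sample-average budget shares (the instrument)."""
    wbar = np.asarray(wbar, float)
    lnp = np.atleast_2d(np.asarray(lnp, float))
    if wbar.size == lnp.shape[1] + 1:
        wbar = wbar[:-1]
    out = lnp @ wbar
    return out if out.size > 1 else float(out[0])


@dataclass
class PreparedData:
    """Estimation-ready observation table plus aligned numpy views.

    One row per household-wave; shares include the numeraire (last).
    ``z`` stacks the core shifters (log household size, urban flag,
    head age/100) and wave dummies; ``cmeans`` holds cluster means of
    (ln p, ln x, core z) for the correlated-random-effects device.
    """

    hh: np.ndarray
    wave: np.ndarray
    cluster: np.ndarray
    stratum: np.ndarray
    w: np.ndarray            # (N, J+1)
    lnp: np.ndarray          # (N, J)
    lnx: np.ndarray
    x_week: np.ndarray
    z: np.ndarray
    z_names: list
    cmeans: np.ndarray
    cmeans_names: list
    lnp_nbr: np.ndarray
    stone_avg: np.ndarray
    wbar: np.ndarray         # (J+1,) sample-average shares
    ae: np.ndarray
    quartile: np.ndarray
    gprice: np.ndarray       # (N, J) group price levels, $/kg
    gqty: np.ndarray         # (N, J) group quantities, kg/week
    group_names: list
    composition: pd.DataFrame | None = None
    roster: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_obs(self):
        return len(self.lnx)

    @property
    def n_groups(self):
        return self.lnp.shape[1]

    def daily_per_ae(self):
        return self.x_week / (7.0 * self.ae)

    def shifted(self, dlnx=0.0, dlnp=None):
        """Counterfactual copy with shifted expenditures and/or prices.

        ``dlnx`` may be scalar or (N,); ``dlnp`` scalar/(J,)/(N, J) in
        log points.  Derived fields (average-share Stone index,
        neighbour instruments, price levels) shift consistently.  The
        cluster-mean (correlated-random-effects) regressors and the
        quartile labels stay at baseline: the former proxy
        time-invariant preference heterogeneity, the latter identify
        the pre-intervention targeting groups.
        """
        dlnx = np.broadcast_to(np.asarray(dlnx, float), self.lnx.shape).copy()
        if dlnp is None:
            dlnp = np.zeros_like(self.lnp)
        dlnp = np.broadcast_to(np.asarray(dlnp, float), self.lnp.shape).copy()
        new = replace(self)
        new.lnx = self.lnx + dlnx
        new.x_week = self.x_week * np.exp(dlnx)
        new.lnp = self.lnp + dlnp
        new.lnp_nbr = self.lnp_nbr + dlnp
        new.gprice = self.gprice * np.exp(dlnp)
        new.stone_avg = self.stone_avg + dlnp @ self.wbar[:-1]
        return new

    def to_frame(self) -> pd.DataFrame:
        J = self.n_groups
        d = {"hh": self.hh, "wave": self.wave, "cluster": self.cluster,
             "stratum": self.stratum, "lnx": self.lnx, "x_week": self.x_week,
             "ae": self.ae, "quartile": self.quartile,
             "stone_avg": self.stone_avg}
        for j, g in enumerate(self.group_names):
            d[f"w_{g}"] = self.w[:, j]
            d[f"lnp_{g}"] = self.lnp[:, j]
            d[f"nbr_{g}"] = self.lnp_nbr[:, j]
            d[f"price_{g}"] = self.gprice[:, j]
            d[f"qty_{g}"] = self.gqty[:, j]
        d["w_numeraire"] = self.w[:, J]
        for i, n in enumerate(self.z_names):
            d[f"z_{n}"] = self.z[:, i]
        for i, n in enumerate(self.cmeans_names):
            d[f"cm_{n}"] = self.cmeans[:, i]
        return pd.DataFrame(d)

    def to_csv(self, path):
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)


def prepare(panel, min_count: int = 5, ae_scale=None, base_wave: int = 1,
            scheme: QuartileScheme | None = None) -> PreparedData:
    """Build the estimation-ready table from a household panel."""
    households, roster, records = panel.households, panel.roster, panel.records
    groups = list(panel.group_names)
    J = len(groups)

    uv = unit_values(records, households, min_count=min_count)
    lnp_df, base = fisher_group_index(uv, records, base_wave=base_wave)

    # food expenditures valued at unit values (all sources)
    qrec = records.groupby(["hh", "wave", "group", "item"], as_index=False)[
        "quantity"].sum()
    val = qrec.merge(uv[["hh", "wave", "item", "unit_value"]],
                     on=["hh", "wave", "item"])
    val["value_uv"] = val["quantity"] * val["unit_value"]
    gv = (val.groupby(["hh", "wave", "group"])[["value_uv", "quantity"]].sum()
          .unstack("group").fillna(0.0))
    hw = households.set_index(["hh", "wave"]).sort_index()
    gval = gv["value_uv"].reindex(index=hw.index, columns=groups).fillna(0.0)
    gqty = gv["quantity"].reindex(index=hw.index, columns=groups).fillna(0.0)

    food = gval.sum(axis=1).values
    nonfood = hw["nonfood_value"].values
    x_week = food + nonfood
    if np.any(x_week <= 0):
        raise ValueError("nonpositive total expenditures")
    w_food = gval.values / x_week[:, None]
    w = np.column_stack([w_food, nonfood / x_week])

    lnp_df = lnp_df.set_index(["hh", "wave"]).reindex(hw.index).reset_index()
    lnp = lnp_df[groups].values

    nbr = neighbour_price_instrument(lnp_df[["hh", "wave"] + groups],
                                     households, group_cols=groups)
    nbr = nbr.set_index(["hh", "wave"]).reindex(hw.index)
    lnp_nbr = nbr[[f"nbr_{g}" for g in groups]].values

    ae = adult_equivalents(roster, scale=ae_scale)
    hh_idx = hw.index.get_level_values("hh")
    ae_v = ae.reindex(hh_idx).values
    sizes = roster.groupby("hh").size()
    head = roster.sort_values("member").groupby("hh").first()

    waves = np.sort(households["wave"].unique())
    z_core = np.column_stack([
        np.log(sizes.reindex(hh_idx).values.astype(float)),
        hw["urban"].values.astype(float),
        head["age"].reindex(hh_idx).values / 100.0,
    ])
    z_names = ["log_size", "urban", "head_age"]
    wave_arr = hw.index.get_level_values("wave").values
    wdum = np.column_stack([(wave_arr == wv).astype(float)
                            for wv in waves[1:]]) if len(waves) > 1 else \
        np.empty((len(wave_arr), 0))
    z = np.column_stack([z_core, wdum])
    z_names = z_names + [f"wave_{wv}" for wv in waves[1:]]

    lnx = np.log(x_week)
    cluster = hw["cluster"].values
    cm_src = np.column_stack([lnp, lnx, z_core])
    cm = pd.DataFrame(cm_src).groupby(cluster).transform("mean").values
    cmeans_names = [f"lnp_{g}" for g in groups] + ["lnx"] + ["log_size",
                                                             "urban", "head_age"]

    wbar = w.mean(axis=0)
    stone_avg = avg_share_stone_index(wbar, lnp)
    quart = assign_quartile(x_week / (7.0 * ae_v), scheme)

    # group price levels for quantity conversion (expenditure per kg)
    with np.errstate(invalid="ignore", divide="ignore"):
        gp = gval.values / gqty.values
    gp_df = pd.DataFrame(gp, columns=groups)
    gp_df["cluster"] = cluster
    gp_df["wave"] = wave_arr
    filled = gp_df.groupby(["cluster", "wave"])[groups].transform("median")
    nat = gp_df.groupby("wave")[groups].transform("median")
    gp = np.where(np.isfinite(gp), gp,
                  np.where(np.isfinite(filled.values), filled.values, nat.values))

    return PreparedData(
        hh=hh_idx.values, wave=wave_arr, cluster=cluster,
        stratum=hw["stratum"].values, w=w, lnp=lnp, lnx=lnx, x_week=x_week,
        z=z, z_names=z_names, cmeans=cm, cmeans_names=cmeans_names,
        lnp_nbr=lnp_nbr, stone_avg=stone_avg, wbar=wbar, ae=ae_v,
        quartile=quart, gprice=gp, gqty=gqty.values, group_names=groups,
        composition=panel.composition, roster=roster,
        meta={"base": base, "min_count": min_count, "base_wave": base_wave},
    )
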