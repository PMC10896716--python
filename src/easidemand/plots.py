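"""Figure helpers: elasticity heat maps, sufficiency curves, balance bars.

Matplotlib is imported lazily so the estimation stack has no hard
plotting dependency at import time.
"""

from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def elasticity_heatmap(es, quartile="Q1", ax=None, vmax=None):
    """Median Marshallian price-elasticity matrix for one quartile."""
    plt = _plt()
    names = list(es.group_names) + ["numeraire"]
    mask = es.quartile == quartile
    vals = np.where(es.stable[mask][:, :, None], es.E_marsh[mask], np.nan)
    M = np.nanmedian(vals, axis=0)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    vmax = vmax or np.nanmax(np.abs(M))
    im = ax.imshow(M, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(names)), names, rotation=60, ha="right",
                  fontsize=7)
    ax.set_yticks(range(len(names)), names, fontsize=7)
    ax.set_xlabel("price of")
    ax.set_ylabel("demand for")
    ax.set_title(f"median price elasticities, {quartile}")
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax


def sufficiency_curve_plot(grid, pre, post, cutoffs=(1.90, 3.20, 5.50),
                           ax=None, nutrient="dietary energy"):
    """Pre/post probability-of-sufficiency curves on log expenditures."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(grid, pre, post, alpha=0.3, color="tab:blue",
                    label="simulated gain")
    ax.plot(grid, pre, color="tab:blue", label="pre")
    ax.plot(grid, post, color="tab:blue", ls="--", label="post")
    for c in cutoffs:
        ax.axvline(np.log(c), color="grey", ls=":", lw=0.8)
    ax.set_xlabel("log expenditures per adult equivalent per day (US$ PPP)")
    ax.set_ylabel(f"share with sufficient {nutrient}")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    return ax


def balance_bars(balance_df, ax=None):
    """Share of households above/below the WHO macronutrient ranges."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    macros = ["carbohydrate", "fat", "protein"]
    width = 0.35
    for i, macro in enumerate(macros):
        sub = balance_df[balance_df.macronutrient == macro]
        for j, when in enumerate(("pre", "post")):
            row = sub[sub.when == when].mean(numeric_only=True)
            x = i + (j - 0.5) * width
            ax.bar(x, row["above"], width, color="tab:red",
                   alpha=0.8 if when == "pre" else 0.4)
            ax.bar(x, -row["below"], width, color="tab:orange",
                   alpha=0.8 if when == "pre" else 0.4)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xticks(range(3), macros)
    ax.set_ylabel("share above (+) / below (-) WHO range")
    return ax
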