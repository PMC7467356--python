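"""Country-level (ecological) correlation of glycan traits with
development indicators, with Bonferroni multiplicity control.

Samples are first aggregated to one summary value per country; each
(trait, indicator) pair is then tested with Pearson's product-moment
correlation, the two-sided p-value from t = r sqrt((n-2)/(1-r^2)) on
n-2 degrees of freedom, and p-values multiplied by the number of tests
actually performed (capped at 1).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "aggregate_by_country",
    "correlate_with_indicators",
    "plot_indicator_scatter",
]


def aggregate_by_country(traits: pd.DataFrame, metadata: pd.DataFrame,
                         statistic: str = "mean",
                         country: str = "country") -> pd.DataFrame:
    """Per-country summary (mean by default, median optional) of each trait."""
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    countries = metadata.reindex(traits.index)[country]
    if countries.isna().any():
        missing = traits.index[countries.isna()]
        raise ValueError(f"samples without a country: {list(missing[:5])}")
    grouped = traits.groupby(countries.to_numpy())
    out = grouped.mean() if statistic == "mean" else grouped.median()
    empty = set(pd.unique(metadata[country])) - set(out.index)
    if empty:
        warnings.warn(f"countries with no samples dropped: {sorted(empty)}")
    out.index.name = country
    return out


def correlate_with_indicators(country_traits: pd.DataFrame,
                              indicators: pd.DataFrame,
                              m_tests: int | None = None,
                              min_countries: int = 3) -> pd.DataFrame:
    """Pearson correlation of every trait against every indicator.

    Returns one row per pair with r, the raw two-sided p-value and the
    Bonferroni-adjusted p-value min(1, m x p), where m defaults to the
    number of tests actually performed in this call.  Pairs with fewer
    than ``min_countries`` complete observations, or zero variance in
    either vector, are marked undefined (NaN statistics).
    """
    common = country_traits.index.intersection(indicators.index)
    traits_aligned = country_traits.loc[common]
    ind_aligned = indicators.loc[common]
    rows = []
    n_performed = 0
    for trait_col in traits_aligned.columns:
        for ind_col in ind_aligned.columns:
            x = traits_aligned[trait_col].to_numpy(dtype=float)
            y = ind_aligned[ind_col].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            row = {
                "trait": trait_col if not isinstance(trait_col, tuple) else trait_col[-1],
                "subclass": trait_col[0] if isinstance(trait_col, tuple) else "",
                "indicator": ind_col, "n": n,
                "r": np.nan, "pvalue": np.nan, "status": "ok",
            }
            if n < min_countries:
                row["status"] = "too_few_countries"
            elif np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                row["status"] = "zero_variance"
            else:
                r, p = stats.pearsonr(x[ok], y[ok])
                row["r"], row["pvalue"] = float(r), float(p)
                n_performed += 1
            rows.append(row)
    out = pd.DataFrame(rows)
    m = m_tests if m_tests is not None else max(n_performed, 1)
    out["m_tests"] = m
    out["pvalue_bonferroni"] = np.minimum(out["pvalue"] * m, 1.0)
    return out


def plot_indicator_scatter(country_traits: pd.DataFrame,
                           indicators: pd.DataFrame,
                           trait, indicator: str, path=None):
    """Minimal country-level scatter of one trait against one indicator."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    common = country_traits.index.intersection(indicators.index)
    x = indicators.loc[common, indicator]
    y = country_traits.loc[common, trait]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y)
    for name in common:
        ax.annotate(str(name), (x[name], y[name]), fontsize=7,
                    xytext=(2, 2), textcoords="offset points")
    r, p = stats.pearsonr(x, y)
    ax.set_xlabel(indicator)
    label = trait if not isinstance(trait, tuple) else " ".join(map(str, trait))
    ax.set_ylabel(str(label))
    ax.set_title(f"r = {r:.2f}, p = {p:.2g} (n = {len(common)})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
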