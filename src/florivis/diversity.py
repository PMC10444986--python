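"""Shannon diversity of resource-supplying vs. insect-visited flowering species.

For each site and study year, the annual contribution vector of a measure
(nectar sugar, pollen, or visits by a pollinator group) gives a proportion
p_i per species; Shannon diversity H' = −Σ p_i ln p_i (nats) and Pielou
evenness J' = H'/ln(S) summarize how evenly that measure is spread over
species. Category codes follow community-ecology convention here:

    Sug — nectar-sugar supply    Pol — pollen supply
    AP  — all wild insect visits WB — wild bees & wasps
    HF  — hoverflies             BF — butterflies

Differences in H' between categories (sites as replicates, per year) are
tested with Tukey's HSD on a one-way layout; adjusted p-values use the
studentized-range distribution and results carry a compact letter display.
"""

from __future__ import annotations

import itertools
import logging
import math
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORY_BY_MEASURE",
    "shannon_diversity",
    "evenness",
    "annual_diversity_panel",
    "tukey_compare",
    "TukeyComparison",
]

CATEGORY_BY_MEASURE = {
    "sugar": "Sug",
    "pollen": "Pol",
    "visits_all": "AP",
    "visits_bee_wasp": "WB",
    "visits_hoverfly": "HF",
    "visits_butterfly": "BF",
}


def shannon_diversity(proportions, tol: float = 1e-6) -> float:
    """Shannon index H' = −Σ_{p>0} p ln p in nats.

    `proportions` must be nonnegative and sum to 1 within `tol`.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be >= 0")
    total = p.sum()
    if abs(total - 1.0) > tol:
        raise ValueError(f"proportions sum to {total}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def evenness(h_prime: float, richness: int) -> float:
    """Pielou evenness J' = H'/ln(S); NaN (undefined) when S = 1."""
    if richness < 1:
        raise ValueError("richness must be >= 1")
    if richness == 1:
        return float("nan")
    return h_prime / math.log(richness)


def annual_diversity_panel(
    annual_contributions: pd.DataFrame,
    richness_mode: str = "category",
    site_richness: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One DiversityResult row per (site, study_year, category).

    `annual_contributions` is a year-period contribution table
    (site, period, measure, species_id, proportion). Richness S is the
    number of species with nonzero share in the category
    (``richness_mode="category"``, default); with ``"site_total"`` the
    evenness denominator instead uses the site/year observed richness
    supplied in `site_richness` (columns site, study_year, richness).
    """
    if richness_mode not in {"category", "site_total"}:
        raise ValueError("richness_mode must be 'category' or 'site_total'")
    if richness_mode == "site_total" and site_richness is None:
        raise ValueError("site_total mode requires a site_richness table")
    rows = []
    for (site, year, measure), grp in annual_contributions.groupby(
        ["site", "period", "measure"], observed=True
    ):
        p = grp["proportion"].to_numpy()
        h = shannon_diversity(p)
        s_cat = int((p > 0).sum())
        if richness_mode == "category":
            s_even = s_cat
        else:
            match = site_richness.query("site == @site and study_year == @year")
            if not len(match):
                raise ValueError(f"no site_richness row for {site} year {year}")
            s_even = int(match["richness"].iloc[0])
        rows.append(
            {
                "site": site,
                "study_year": int(year),
                "category": CATEGORY_BY_MEASURE[measure],
                "H_prime": h,
                "richness": s_cat,
                "J_prime": evenness(h, s_even) if s_even >= 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tukey HSD

@dataclass
class TukeyComparison:
    """Tukey HSD over categories for one study year."""

    study_year: int
    pairs: pd.DataFrame  # cat_a, cat_b, diff, se, q, p_adj
    letters: dict[str, str] = field(default_factory=dict)
    group_means: dict[str, float] = field(default_factory=dict)
    alpha: float = 0.05

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.pairs[self.pairs["p_adj"] < self.alpha]
        return list(zip(sig["cat_a"], sig["cat_b"]))


def _compact_letters(
    groups: list[str], sig: set[frozenset[str]], means: dict[str, float]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different; every
    significant pair is separated.
    """
    order = sorted(groups, key=lambda g: -means[g])
    letter_sets: list[set[str]] = [set(order)]
    for a, b in [tuple(s) for s in sig]:
        for i, ls in enumerate(list(letter_sets)):
            if a in ls and b in ls:
                letter_sets.remove(ls)
                new_a, new_b = ls - {b}, ls - {a}
                for new in (new_a, new_b):
                    if not any(new <= other for other in letter_sets):
                        letter_sets.append(new)
    # drop absorbed subsets, order sets by the best mean they contain
    letter_sets = [ls for ls in letter_sets if ls and not any(
        ls < other for other in letter_sets
    )]
    letter_sets.sort(key=lambda ls: min(order.index(g) for g in ls))
    out = {g: "" for g in groups}
    for letter, ls in zip(string.ascii_lowercase, letter_sets):
        for g in order:
            if g in ls:
                out[g] += letter
    return out


def tukey_compare(
    panel: pd.DataFrame,
    study_year: int,
    value_col: str = "H_prime",
    alpha: float = 0.05,
) -> TukeyComparison:
    """Tukey HSD across categories with sites as replicates.

    One-way layout: factor = category, replicates = sites within
    `study_year`. For each pair, q = |m_a − m_b| / sqrt(MSE/2·(1/n_a+1/n_b))
    with MSE the pooled within-category variance on N − k df; adjusted p is
    the studentized-range tail probability at k groups.
    """
    sub = panel[panel["study_year"] == study_year]
    cats = sorted(sub["category"].unique())
    if len(cats) < 2:
        raise ValueError("Tukey comparison needs >= 2 categories")
    values = {c: sub.loc[sub["category"] == c, value_col].to_numpy() for c in cats}
    ns = {c: len(v) for c, v in values.items()}
    if min(ns.values()) < 2:
        raise ValueError("Tukey comparison needs >= 2 replicates per category")
    k = len(cats)
    n_total = sum(ns.values())
    df_err = n_total - k
    means = {c: float(v.mean()) for c, v in values.items()}
    sse = sum(((v - means[c]) ** 2).sum() for c, v in values.items())
    mse = sse / df_err
    rows = []
    for a, b in itertools.combinations(cats, 2):
        diff = means[a] - means[b]
        se = math.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        if se == 0:
            q = 0.0 if diff == 0 else float("inf")
        else:
            q = abs(diff) / se
        p_adj = float(studentized_range.sf(q, k, df_err)) if math.isfinite(q) else 0.0
        rows.append({"cat_a": a, "cat_b": b, "diff": diff, "se": se, "q": q,
                     "p_adj": min(max(p_adj, 0.0), 1.0)})
    pairs = pd.DataFrame(rows)
    sig = {
        frozenset((r["cat_a"], r["cat_b"]))
        for _, r in pairs.iterrows()
        if r["p_adj"] < alpha
    }
    letters = _compact_letters(cats, sig, means)
    return TukeyComparison(
        study_year=study_year, pairs=pairs, letters=letters,
        group_means=means, alpha=alpha,
    )
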