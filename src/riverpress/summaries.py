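"""Grouped result tables: impact prevalence, pressure combinations, GPI
distributions, typology cross-tabs and population-density contrasts.

All computation is done unrounded; :meth:`SummaryTable.display` applies the
1-decimal display rounding used for reporting.  Sites whose relevant
quantity is missing are excluded per table, with the surviving count
reported in ``n_sites``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import COMBINATIONS, IMPACT_THRESHOLD
from .typology import RIVER_TYPES

log = logging.getLogger(__name__)

GROUPINGS = ("ecoregion", "river_type", "none")
INDEX_NAMES = ("HPI", "MPI", "WQPI", "CPI")


@dataclass
class SummaryTable:
    """A grouped aggregate with its provenance.

    ``table`` is indexed by group label (or ``"all"`` for ungrouped) and
    always carries an ``n_sites`` column counting the sites that survive
    the stated filter.
    """

    grouping: str
    table: pd.DataFrame
    filter_description: str = ""
    excluded: int = 0

    def display(self, decimals: int = 1) -> pd.DataFrame:
        out = self.table.copy()
        num = out.select_dtypes(include=[float]).columns
        out[num] = out[num].round(decimals)
        return out


def _grouped(scores: pd.DataFrame, by: str | None):
    by = "none" if by is None else by
    if by not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}, got {by!r}")
    if by == "none":
        return by, [("all", scores)]
    if by not in scores.columns:
        raise ValueError(f"scores table has no {by!r} column")
    keep = scores[scores[by].notna()]
    dropped = len(scores) - len(keep)
    if dropped:
        log.warning("%d sites without %s dropped from summary", dropped, by)
    return by, list(keep.groupby(by, sort=True))


def percent_impacted(scores: pd.DataFrame, group: str, by: str | None = "ecoregion") -> SummaryTable:
    """Fraction of sites with the chosen group index ≥ 3, per group label.

    Two denominators are reported: sites where the index is assessable
    (``frac_impacted``) and all sites in the row (``frac_impacted_all``).
    """
    if group not in INDEX_NAMES:
        raise ValueError(f"group must be one of {INDEX_NAMES}, got {group!r}")
    by, parts = _grouped(scores, by)
    rows = {}
    for label, part in parts:
        assessable = part[part[group].notna()]
        if assessable.empty:
            log.warning("no site with assessable %s in group %r; row omitted", group, label)
            continue
        n_imp = int((assessable[group] >= IMPACT_THRESHOLD).sum())
        rows[label] = {
            "n_sites": len(part),
            "n_assessable": len(assessable),
            "n_impacted": n_imp,
            "frac_impacted": n_imp / len(assessable),
            "frac_impacted_all": n_imp / len(part),
        }
    return SummaryTable(by, pd.DataFrame.from_dict(rows, orient="index"),
                        filter_description=f"{group} assessable")


def impact_overview(scores: pd.DataFrame, by: str | None = "ecoregion") -> SummaryTable:
    """Percent impacted for all four indices side by side (bar-chart layout)."""
    by_, parts = _grouped(scores, by)
    rows = {}
    for label, part in parts:
        row: dict[str, float] = {"n_sites": len(part)}
        for name in INDEX_NAMES:
            assessable = part[part[name].notna()]
            row[f"{name}_pct"] = (
                100.0 * float((assessable[name] >= IMPACT_THRESHOLD).mean())
                if len(assessable) else np.nan
            )
        rows[label] = row
    return SummaryTable(by_, pd.DataFrame.from_dict(rows, orient="index"),
                        filter_description="per-index assessable denominator")


def combination_proportions(scores: pd.DataFrame, by: str | None = "ecoregion") -> SummaryTable:
    """Proportions of NoP / W / HMC / W+HMC per group label (rows sum to 1)."""
    by, parts = _grouped(scores, by)
    rows = {}
    for label, part in parts:
        scorable = part[part["combination"].isin(COMBINATIONS)]
        if scorable.empty:
            log.warning("no scorable site in group %r; row omitted", label)
            continue
        counts = scorable["combination"].value_counts()
        n = len(scorable)
        rows[label] = {c: counts.get(c, 0) / n for c in COMBINATIONS}
        rows[label]["n_sites"] = n
    return SummaryTable(by, pd.DataFrame.from_dict(rows, orient="index"),
                        filter_description="scorable sites")


def gpi_statistics(scores: pd.DataFrame, by: str | None = "ecoregion",
                   impacted_only: bool = True) -> SummaryTable:
    """Min / max / mean / median of the GPI per group label.

    ``impacted_only`` keeps sites with GPI ≥ 3 (so minima are always ≥ 3),
    mirroring summaries restricted to impacted sites.
    """
    by, parts = _grouped(scores, by)
    rows = {}
    for label, part in parts:
        g = part["GPI"].dropna()
        if impacted_only:
            g = g[g >= IMPACT_THRESHOLD]
        if g.empty:
            log.warning("no GPI value in group %r after filtering; row omitted", label)
            continue
        rows[label] = {
            "min": float(g.min()), "max": float(g.max()),
            "mean": float(g.mean()), "median": float(g.median()),
            "n_sites": len(g),
        }
    return SummaryTable(by, pd.DataFrame.from_dict(rows, orient="index"),
                        filter_description="impacted only (GPI >= 3)" if impacted_only else "all scorable")


def gpi_class_histogram(scores: pd.DataFrame, by: str | None = None) -> SummaryTable:
    """Counts and fractions of GPI classes 0–4."""
    by, parts = _grouped(scores, by)
    rows = {}
    for label, part in parts:
        cls = part.loc[part["GPI_class"].isin(range(5)), "GPI_class"]
        if cls.empty:
            log.warning("no classifiable site in group %r; row omitted", label)
            continue
        counts = cls.value_counts()
        n = len(cls)
        row: dict[str, float] = {}
        for k in range(5):
            row[f"class_{k}_n"] = int(counts.get(k, 0))
            row[f"class_{k}_frac"] = counts.get(k, 0) / n
        row["n_sites"] = n
        rows[label] = row
    return SummaryTable(by, pd.DataFrame.from_dict(rows, orient="index"),
                        filter_description="classifiable sites")


def crosstab_ecoregion_rt(scores: pd.DataFrame) -> SummaryTable:
    """Row-normalised percentage of each river type within each ecoregion."""
    needed = scores[scores["ecoregion"].notna() & scores["river_type"].notna()]
    excluded = len(scores) - len(needed)
    ct = pd.crosstab(needed["ecoregion"], needed["river_type"])
    for rt in RIVER_TYPES:
        if rt not in ct.columns:
            ct[rt] = 0
    ct = ct[sorted(RIVER_TYPES)]
    n = ct.sum(axis=1)
    pct = 100.0 * ct.div(n, axis=0)
    pct["n_sites"] = n
    return SummaryTable("ecoregion", pct, filter_description="sites with river type",
                        excluded=excluded)


def density_by_combination(scores: pd.DataFrame) -> SummaryTable:
    """n, median and quartiles of population density per combination category."""
    if "pop_density" not in scores.columns or scores["pop_density"].notna().sum() == 0:
        raise ValueError("no population-density values available")
    rows = {}
    for comb in COMBINATIONS:
        dens = scores.loc[scores["combination"] == comb, "pop_density"].dropna()
        if dens.empty:
            log.warning("no density value for combination %r; row omitted", comb)
            continue
        rows[comb] = {
            "n": len(dens),
            "q1": float(dens.quantile(0.25)),
            "median": float(dens.median()),
            "q3": float(dens.quantile(0.75)),
        }
    return SummaryTable("none", pd.DataFrame.from_dict(rows, orient="index"),
                        filter_description="sites with population density")


#: CLI table keys → builder callables
TABLE_BUILDERS = {
    "fig2": lambda scores, by: impact_overview(scores, by or "ecoregion"),
    "fig3": lambda scores, by: combination_proportions(scores, by or "ecoregion"),
    "fig4": lambda scores, by: combination_proportions(scores, by or "river_type"),
    "fig5": lambda scores, by: gpi_class_histogram(scores, by),
    "table4": lambda scores, by: crosstab_ecoregion_rt(scores),
    "table5": lambda scores, by: gpi_statistics(scores, by or "ecoregion", impacted_only=True),
    "table6": lambda scores, by: gpi_statistics(scores, by or "river_type", impacted_only=True),
    "fig6": lambda scores, by: density_by_combination(scores),
}


def plot_summary(summary: SummaryTable, path: str, kind: str = "bar") -> None:
    """Write a simple bar chart of a summary table to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    num = summary.table.select_dtypes(include=[float, int]).drop(
        columns=[c for c in ("n_sites", "n_assessable", "n_impacted") if c in summary.table.columns],
        errors="ignore",
    )
    ax = num.plot(kind=kind, figsize=(9, 4.5))
    ax.set_xlabel(summary.grouping)
    ax.set_title(summary.filter_description or "summary")
    fig = ax.get_figure()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
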