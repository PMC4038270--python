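"""Pressure-type indices, Global Pressure Index (GPI) and pressure combinations.

Each of the four pressure groups is summarised by a non-compensatory index
(HPI, MPI, WQPI, CPI): when any contributing value reaches the impact
threshold of 3, the index is the mean of exactly the values ≥ 3, so that
sub-threshold values cannot compensate for impacted ones; otherwise it is
the plain mean of all values.  A group is *impacted* when its index ≥ 3.

The GPI adds the four group indices, counting an index only when it is
impacted; it ranges over {0} ∪ [3, 20] and is binned into five classes by
the number of pressure groups involved (0 unimpacted, 1 single … 4
quadruple).  Sites are further labelled by the combination of water-quality
(W) versus hydromorphological-plus-connectivity (HMC) impact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .harmonize import HarmonizedSite
from .schema import (
    AGGREGATED_CODE,
    GROUP_INDEX_MEMBERS,
    MORPH_INSTREAM,
    VARIABLE_ORDER,
    PressureValueError,
    load_schema,
)

IMPACT_THRESHOLD = 3.0
COMBINATIONS = ("NoP", "W", "HMC", "W+HMC")
GPI_CLASS_EDGES = (3.0, 6.0, 9.0, 12.0)
GROUP_TO_INDEX = {
    "hydrology": "HPI",
    "morphology": "MPI",
    "water_quality": "WQPI",
    "connectivity": "CPI",
}


class UndefinedIndexError(ValueError):
    """A group index was requested for an empty value set."""


def group_index(values: Iterable[float]) -> float:
    """Non-compensatory index of one pressure group.

    If any value ≥ 3, the mean of exactly the values ≥ 3 (in [3, 5]);
    otherwise the mean of all values (< 3).  The caller removes missing
    values; an empty sequence raises :class:`UndefinedIndexError`.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise UndefinedIndexError("group index undefined for an empty value set")
    for v in vals:
        if not 1.0 <= v <= 5.0:
            raise PressureValueError(f"group index input {v} outside [1, 5]")
    impacted = [v for v in vals if v >= IMPACT_THRESHOLD]
    pool = impacted if impacted else vals
    return sum(pool) / len(pool)


def gpi(indices: Iterable[float]) -> float:
    """Global Pressure Index: sum of the group indices that are ≥ 3.

    Sub-threshold and missing (NaN) indices contribute 0; if every index is
    missing the GPI is missing (NaN).
    """
    vals = list(indices)
    if all(isinstance(v, float) and math.isnan(v) for v in vals):
        return float("nan")
    return sum(float(v) for v in vals
               if not (isinstance(v, float) and math.isnan(v)) and v >= IMPACT_THRESHOLD)


def gpi_class(g: float) -> int:
    """Bin a GPI value into classes 0–4.

    0 for g < 3 (only 0 is attainable there), then half-open bins
    [3, 6), [6, 9), [9, 12) and [12, 20]; bins are half-open so fractional
    index values are always classifiable.
    """
    g = float(g)
    if math.isnan(g) or g < 0 or g > 20:
        raise PressureValueError(f"GPI {g!r} outside the attainable range [0, 20]")
    # class edges are attainable exact values (3m for m impacted groups);
    # snap away float summation jitter before binning
    return int(np.digitize(round(g, 9), GPI_CLASS_EDGES))


def combination_category(
    hpi: float, mpi: float, wqpi: float, cpi: float
) -> str:
    """W / HMC / W+HMC / NoP split of a site's impacted groups.

    Missing (NaN) indices count as not impacted.
    """
    def imp(v: float) -> bool:
        return not (isinstance(v, float) and math.isnan(v)) and v >= IMPACT_THRESHOLD

    wq = imp(wqpi)
    hmc = imp(hpi) or imp(mpi) or imp(cpi)
    if wq and hmc:
        return "W+HMC"
    if wq:
        return "W"
    if hmc:
        return "HMC"
    return "NoP"


@dataclass
class SiteScores:
    """Index values and derived classifications for one site."""

    site_id: str
    hpi: float
    mpi: float
    wqpi: float
    cpi: float
    affected_groups: int
    gpi: float
    gpi_class: int
    combination: str
    n_groups_scored: int = 4

    @property
    def complete(self) -> bool:
        return self.n_groups_scored == 4


def score_values(values: Mapping[str, float | None], site_id: str = "") -> SiteScores:
    """Score one site from its 13 harmonised quantities (12 vars + aggregate)."""
    indices: dict[str, float] = {}
    n_scored = 0
    for group, members in GROUP_INDEX_MEMBERS.items():
        present = [float(values[m]) for m in members
                   if values.get(m) is not None
                   and not (isinstance(values.get(m), float) and math.isnan(values[m]))]
        if present:
            indices[group] = group_index(present)
            n_scored += 1
        else:
            indices[group] = float("nan")
    if n_scored == 0:
        return SiteScores(site_id, *(float("nan"),) * 4, affected_groups=0,
                          gpi=float("nan"), gpi_class=-1, combination="unscorable",
                          n_groups_scored=0)
    four = [indices[g] for g in ("hydrology", "morphology", "water_quality", "connectivity")]
    affected = sum(1 for v in four if not math.isnan(v) and v >= IMPACT_THRESHOLD)
    g = gpi(four)
    return SiteScores(
        site_id=site_id,
        hpi=four[0], mpi=four[1], wqpi=four[2], cpi=four[3],
        affected_groups=affected,
        gpi=g,
        gpi_class=gpi_class(g),
        combination=combination_category(*four),
        n_groups_scored=n_scored,
    )


def score_site(h: HarmonizedSite) -> SiteScores:
    """Score one harmonised site."""
    return score_values(h.as_mapping(), site_id=h.site_id)


# ---------------------------------------------------------------------------
# Vectorised scoring of a harmonised table

def _group_index_matrix(V: np.ndarray) -> np.ndarray:
    """Row-wise non-compensatory index over a value matrix (NaN = missing)."""
    finite = np.isfinite(V)
    ge = np.where(finite, V >= IMPACT_THRESHOLD, False)
    n_ge = ge.sum(axis=1)
    n_present = finite.sum(axis=1)
    sum_ge = np.where(ge, V, 0.0).sum(axis=1)
    sum_all = np.where(finite, V, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.where(n_ge > 0,
                       sum_ge / np.maximum(n_ge, 1),
                       sum_all / np.maximum(n_present, 1))
    idx = np.where(n_present > 0, idx, np.nan)
    return idx


def score_frame(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Score every row of a harmonised table.

    Metadata columns (ecoregion, river_type, pop_density, …) are carried
    through; a ``river_type`` column is derived from ``eft_code`` and a
    ``segment_length_km`` column from ``catchment_km2`` when available.
    """
    from .typology import EFT_TO_RT  # local import to avoid cycle at module load

    out = pd.DataFrame({"site_id": harmonized["site_id"]})
    for col in ("country", "ecoregion", "eft_code", "catchment_km2",
                "pop_density", "disconnected_from_sea"):
        if col in harmonized.columns:
            out[col] = harmonized[col].to_numpy()
    if "eft_code" in harmonized.columns:
        eft = pd.to_numeric(harmonized["eft_code"], errors="coerce")
        out["river_type"] = eft.map(lambda v: EFT_TO_RT.get(int(v)) if v == v else np.nan)
    if "catchment_km2" in harmonized.columns:
        c = pd.to_numeric(harmonized["catchment_km2"], errors="coerce").to_numpy(float)
        with np.errstate(invalid="ignore"):
            seg = np.where(c < 100, 1, np.where(c <= 1000, 5, 10)).astype(float)
        seg[~np.isfinite(c) | (c <= 0)] = np.nan
        out["segment_length_km"] = seg

    idx_cols = {}
    for group, members in GROUP_INDEX_MEMBERS.items():
        V = harmonized[list(members)].to_numpy(float)
        idx_cols[GROUP_TO_INDEX[group]] = _group_index_matrix(V)
    H, M, W, C = (idx_cols["HPI"], idx_cols["MPI"], idx_cols["WQPI"], idx_cols["CPI"])
    out["HPI"], out["MPI"], out["WQPI"], out["CPI"] = H, M, W, C

    imp = np.column_stack([np.where(np.isfinite(v), v >= IMPACT_THRESHOLD, False)
                           for v in (H, M, W, C)])
    scored = np.column_stack([np.isfinite(v) for v in (H, M, W, C)])
    n_scored = scored.sum(axis=1)
    out["affected_groups"] = imp.sum(axis=1)
    contrib = np.column_stack([np.where(np.isfinite(v) & (v >= IMPACT_THRESHOLD), v, 0.0)
                               for v in (H, M, W, C)])
    g = contrib.sum(axis=1)
    g = np.where(n_scored > 0, g, np.nan)
    out["GPI"] = g
    cls = np.digitize(np.round(np.nan_to_num(g, nan=0.0), 9), GPI_CLASS_EDGES)
    out["GPI_class"] = np.where(n_scored > 0, cls, -1)

    wq = imp[:, 2]
    hmc = imp[:, 0] | imp[:, 1] | imp[:, 3]
    comb = np.select(
        [wq & hmc, wq, hmc], ["W+HMC", "W", "HMC"], default="NoP"
    ).astype(object)
    comb[n_scored == 0] = "unscorable"
    out["combination"] = comb
    out["n_groups_scored"] = n_scored
    out["complete"] = n_scored == 4
    return out


# ---------------------------------------------------------------------------
# Brute-force enumeration oracle

def enumerate_all_configurations() -> Iterator[tuple[dict[str, int], SiteScores]]:
    """Iterate the full Cartesian product of all allowed variable values.

    Yields 1 492 992 ``(configuration, SiteScores)`` pairs; used to verify
    global extremes and class coverage of the index construction.
    """
    allowed = [s.allowed_values for s in load_schema()]
    for combo in product(*allowed):
        cfg = dict(zip(VARIABLE_ORDER, combo))
        values: dict[str, float | None] = {
            c: float(v) for c, v in cfg.items() if c not in MORPH_INSTREAM
        }
        values[AGGREGATED_CODE] = sum(cfg[c] for c in MORPH_INSTREAM) / 3.0
        yield cfg, score_values(values)


def group_value_grid(group: str) -> tuple[tuple[str, ...], np.ndarray]:
    """All raw-value configurations of one pressure group.

    Returns the variable codes and an ``(n_configs, n_vars)`` float array.
    For morphology the grid is over the five raw variables (the instream
    aggregate is computed downstream).
    """
    schema = {s.code: s for s in load_schema()}
    if group == "morphology":
        codes = MORPH_INSTREAM + ("M_embankm", "M_floodpr")
    else:
        codes = GROUP_INDEX_MEMBERS[group]
    grid = np.array(list(product(*(schema[c].allowed_values for c in codes))), float)
    return tuple(codes), grid


def group_contributions(group: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-configuration group index and GPI contribution of one group.

    Returns ``(grid, index, contribution)`` where ``contribution`` is the
    index when impacted and 0 otherwise.
    """
    _, grid = group_value_grid(group)
    if group == "morphology":
        m = grid[:, :3].mean(axis=1)
        X = np.column_stack([m, grid[:, 3], grid[:, 4]])
    else:
        X = grid
    idx = _group_index_matrix(X)
    contrib = np.where(idx >= IMPACT_THRESHOLD, idx, 0.0)
    return grid, idx, contrib


@dataclass
class OracleSummary:
    """Exact statistics of the full 1 492 992-configuration enumeration."""

    n_configurations: int
    gpi_max: float
    gpi_min_positive: float
    n_gpi_zero: int
    class_counts: tuple[int, ...]      # GPI classes 0..4
    affected_counts: tuple[int, ...]   # affected_groups 0..4
    has_gap_values: bool               # any attainable GPI strictly in (0, 3)

    def describe(self) -> str:
        lines = [
            f"configurations: {self.n_configurations}",
            f"GPI max: {self.gpi_max:.4f}",
            f"GPI min positive: {self.gpi_min_positive:.4f}",
            f"GPI == 0: {self.n_gpi_zero}",
            f"attainable GPI in (0, 3): {'yes' if self.has_gap_values else 'no'}",
            "class counts (0-4): " + ", ".join(map(str, self.class_counts)),
            "affected-group counts (0-4): " + ", ".join(map(str, self.affected_counts)),
        ]
        return "\n".join(lines)


def oracle_summary() -> OracleSummary:
    """Score the full enumeration (vectorised by group decomposition).

    The GPI is additive over the four groups, so the Cartesian product of
    per-group contributions reproduces exactly the per-configuration GPIs.
    """
    groups = ("hydrology", "morphology", "connectivity", "water_quality")
    contribs = []
    impacted = []
    for gname in groups:
        _, idx, c = group_contributions(gname)
        contribs.append(c)
        impacted.append((idx >= IMPACT_THRESHOLD).astype(np.int64))
    cH, cM, cC, cW = contribs
    full = (cH[:, None, None, None] + cM[None, :, None, None]
            + cC[None, None, :, None] + cW[None, None, None, :]).ravel()
    iH, iM, iC, iW = impacted
    n_imp = (iH[:, None, None, None] + iM[None, :, None, None]
             + iC[None, None, :, None] + iW[None, None, None, :]).ravel()

    positive = full[full > 0]
    cls = np.digitize(np.round(full, 9), GPI_CLASS_EDGES)
    return OracleSummary(
        n_configurations=full.size,
        gpi_max=float(full.max()),
        gpi_min_positive=float(positive.min()),
        n_gpi_zero=int((full == 0).sum()),
        class_counts=tuple(int(v) for v in np.bincount(cls, minlength=5)),
        affected_counts=tuple(int(v) for v in np.bincount(n_imp, minlength=5)),
        has_gap_values=bool(((full > 0) & (full < IMPACT_THRESHOLD)).any()),
    )


def theoretical_gpi_max() -> float:
    """Σ over groups of the maximum attainable group index.

    Because sub-threshold values are excluded from an impacted group's
    mean, a group's index is maximised by a *single* variable at the
    group's highest allowed value (adding further, lower values dilutes
    the mean); the maximum group index therefore equals the largest
    allowed value of any variable in the group (5, 5, 5 and 4 for
    connectivity, whose strongest coding is C_B_s_do = 4).
    """
    schema = {s.code: s for s in load_schema()}
    total = 0.0
    for group, members in GROUP_INDEX_MEMBERS.items():
        maxima = []
        for code in members:
            if code == AGGREGATED_CODE:
                maxima.append(float(np.mean([schema[c].max_value for c in MORPH_INSTREAM])))
            else:
                maxima.append(float(schema[code].max_value))
        total += max(maxima)
    return total
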