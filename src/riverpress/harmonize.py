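"""Site records, validation and harmonisation to the canonical ordinal scale.

A raw site row carries identifiers, typology attributes and the 15 raw
pressure values in whatever source coding the national database used.
Harmonisation maps every present value onto the 1–5 gradient and replaces
the three instream-morphology variables (M_channel, M_instrhab, M_crosssec)
by their arithmetic mean ``M_morph_instr``.  Missing raw values propagate
as missing: absence of evidence of a pressure is not treated as absence of
the pressure, and downstream indices use only the values that are present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .schema import (
    AGGREGATED_CODE,
    MORPH_INSTREAM,
    VARIABLE_ORDER,
    PressureValueError,
    PressureVariableSpec,
    SchemaError,
    harmonize_value,
    schema_map,
)
from .typology import ECOREGIONS

#: Table 2-style environmental covariates carried through the pipeline
ENV_COVARIATES = (
    "air_temp_c",
    "strahler_order",
    "slope_permille",
    "altitude_m",
    "distance_from_source_km",
)

#: site-level metadata columns passed through harmonisation untouched
META_COLUMNS = (
    "country", "ecoregion", "eft_code", "catchment_km2",
    "pop_density", "disconnected_from_sea",
) + ENV_COVARIATES


def _is_missing(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip().upper() in ("", "NA"):
        return True
    return False


@dataclass
class SiteRecord:
    """One sampling site as read from a raw input table."""

    site_id: str
    country: str | None = None
    ecoregion: int | None = None
    eft_code: int | None = None
    catchment_km2: float | None = None
    raw_pressures: dict[str, object] = field(default_factory=dict)
    env: dict[str, float] = field(default_factory=dict)
    pop_density: float | None = None
    disconnected_from_sea: bool | None = None


@dataclass
class HarmonizedSite:
    """Validated canonical pressure values for one site.

    ``values`` holds the 12 non-aggregated variables (canonical ints, or
    None when the raw value was missing); ``m_morph_instr`` is the mean of
    the present instream-morphology values, missing only when all three are.
    """

    site_id: str
    values: dict[str, int | None]
    m_morph_instr: float | None
    missing_raw: tuple[str, ...] = ()

    def as_mapping(self) -> dict[str, float | None]:
        """All 13 harmonised quantities keyed by canonical code."""
        out: dict[str, float | None] = dict(self.values)
        out[AGGREGATED_CODE] = self.m_morph_instr
        return out


def aggregate_morphology(
    m_channel: float | None, m_instrhab: float | None, m_crosssec: float | None
) -> float | None:
    """Arithmetic mean of the present instream-morphology values.

    Each present value must be one of {1, 3, 5}; the result is missing only
    when all three inputs are missing.
    """
    present = []
    for code, v in zip(MORPH_INSTREAM, (m_channel, m_instrhab, m_crosssec)):
        if _is_missing(v):
            continue
        if float(v) not in (1.0, 3.0, 5.0):
            raise PressureValueError(f"{code}={v!r} not in allowed values {{1, 3, 5}}")
        present.append(float(v))
    if not present:
        return None
    return sum(present) / len(present)


def harmonize_site(
    record: SiteRecord, schema: Mapping[str, PressureVariableSpec] | None = None
) -> HarmonizedSite:
    """Harmonise one site's raw pressure values onto the canonical scale."""
    schema = schema_map() if schema is None else schema
    canonical: dict[str, int | None] = {}
    missing: list[str] = []
    for code in VARIABLE_ORDER:
        raw = record.raw_pressures.get(code)
        if _is_missing(raw):
            canonical[code] = None
            missing.append(code)
        else:
            canonical[code] = harmonize_value(schema[code], raw)
    m_morph = aggregate_morphology(*(canonical[c] for c in MORPH_INSTREAM))
    values = {c: canonical[c] for c in VARIABLE_ORDER if c not in MORPH_INSTREAM}
    return HarmonizedSite(
        site_id=record.site_id,
        values=values,
        m_morph_instr=m_morph,
        missing_raw=tuple(missing),
    )


@dataclass
class ValidationReport:
    """Per-site violations plus dataset-level issues; never mutates input."""

    n_sites: int
    violations: dict[str, list[str]]          # site_id -> messages
    duplicate_ids: tuple[str, ...]
    missing_counts: dict[str, int]            # variable code -> number missing

    @property
    def n_violations(self) -> int:
        return sum(len(v) for v in self.violations.values()) + len(self.duplicate_ids)

    @property
    def ok(self) -> bool:
        return self.n_violations == 0

    def summary(self) -> str:
        lines = [f"{self.n_sites} sites, {self.n_violations} violations"]
        for sid in self.duplicate_ids:
            lines.append(f"  duplicate site_id: {sid}")
        for sid, msgs in self.violations.items():
            for m in msgs:
                lines.append(f"  {sid}: {m}")
        missing = {k: v for k, v in self.missing_counts.items() if v}
        if missing:
            lines.append("missing values: " + ", ".join(f"{k}={v}" for k, v in sorted(missing.items())))
        return "\n".join(lines)


def validate_sites(
    records: Sequence[SiteRecord],
    schema: Mapping[str, PressureVariableSpec] | None = None,
) -> ValidationReport:
    """Check raw site records against the variable schema and site contract."""
    schema = schema_map() if schema is None else schema
    violations: dict[str, list[str]] = {}
    missing_counts = {c: 0 for c in VARIABLE_ORDER}
    seen: set[str] = set()
    dupes: list[str] = []

    for rec in records:
        msgs: list[str] = []
        if rec.site_id in seen:
            dupes.append(rec.site_id)
        seen.add(rec.site_id)
        if rec.ecoregion is not None and rec.ecoregion not in ECOREGIONS:
            msgs.append(f"ecoregion={rec.ecoregion} not among the analysed ecoregions "
                        f"{sorted(ECOREGIONS)}")
        if rec.eft_code is not None and rec.eft_code not in range(1, 16):
            msgs.append(f"eft_code={rec.eft_code} outside 1-15")
        if rec.catchment_km2 is not None and not rec.catchment_km2 > 0:
            msgs.append(f"catchment_km2={rec.catchment_km2} not positive")
        for code, raw in rec.raw_pressures.items():
            if code not in schema:
                msgs.append(f"unknown pressure variable {code!r}")
                continue
            if _is_missing(raw):
                missing_counts[code] += 1
                continue
            try:
                harmonize_value(schema[code], raw)
            except SchemaError as exc:
                msgs.append(str(exc))
        for code in VARIABLE_ORDER:
            if code not in rec.raw_pressures:
                missing_counts[code] += 1
        if msgs:
            violations[rec.site_id] = msgs

    return ValidationReport(
        n_sites=len(records),
        violations=violations,
        duplicate_ids=tuple(dupes),
        missing_counts=missing_counts,
    )


# ---------------------------------------------------------------------------
# DataFrame bridges

def records_from_frame(df: pd.DataFrame) -> list[SiteRecord]:
    """Build :class:`SiteRecord` objects from a raw wide-format table."""

    def _opt(row, col, cast):
        if col not in df.columns or _is_missing(row[col]):
            return None
        return cast(row[col])

    records = []
    for _, row in df.iterrows():
        env = {c: float(row[c]) for c in ENV_COVARIATES
               if c in df.columns and not _is_missing(row[c])}
        records.append(SiteRecord(
            site_id=str(row["site_id"]),
            country=_opt(row, "country", str),
            ecoregion=_opt(row, "ecoregion", lambda v: int(float(v))),
            eft_code=_opt(row, "eft_code", lambda v: int(float(v))),
            catchment_km2=_opt(row, "catchment_km2", float),
            raw_pressures={c: row[c] for c in VARIABLE_ORDER if c in df.columns},
            env=env,
            pop_density=_opt(row, "pop_density", float),
            disconnected_from_sea=_opt(
                row, "disconnected_from_sea",
                lambda v: bool(int(float(v))) if not isinstance(v, str) or v.strip() not in ("True", "False")
                else v.strip() == "True"),
        ))
    return records


def frame_from_records(records: Iterable[SiteRecord]) -> pd.DataFrame:
    """Flatten site records into the canonical wide CSV layout."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "site_id": rec.site_id,
            "country": rec.country,
            "ecoregion": rec.ecoregion,
            "eft_code": rec.eft_code,
            "catchment_km2": rec.catchment_km2,
            "pop_density": rec.pop_density,
            "disconnected_from_sea": rec.disconnected_from_sea,
        }
        row.update({c: rec.env.get(c) for c in ENV_COVARIATES})
        row.update({c: rec.raw_pressures.get(c) for c in VARIABLE_ORDER})
        rows.append(row)
    cols = (["site_id", "country", "ecoregion", "eft_code", "catchment_km2",
             "pop_density", "disconnected_from_sea"] + list(ENV_COVARIATES)
            + list(VARIABLE_ORDER))
    return pd.DataFrame(rows, columns=cols)


def harmonize_frame(
    df: pd.DataFrame, schema: Mapping[str, PressureVariableSpec] | None = None
) -> pd.DataFrame:
    """Harmonise a raw wide table; returns site_id, metadata, 12 canonical
    variables and ``M_morph_instr``.

    Each pressure column is mapped through its variable's harmonisation on
    the distinct raw values (so arbitrary source tokens and canonical
    numbers can be mixed); missing cells stay missing (NaN).
    """
    schema = schema_map() if schema is None else schema
    out = pd.DataFrame({"site_id": df["site_id"].astype(str)})
    for col in META_COLUMNS:
        if col in df.columns:
            out[col] = df[col].to_numpy()

    harmonized: dict[str, np.ndarray] = {}
    for code in VARIABLE_ORDER:
        if code not in df.columns:
            raise SchemaError(f"input is missing pressure column {code!r}")
        raw = df[code]
        mapping = {
            v: float(harmonize_value(schema[code], v))
            for v in raw.dropna().unique()
            if not _is_missing(v)
        }
        harmonized[code] = raw.map(lambda v, m=mapping: m.get(v, np.nan)).to_numpy(float)

    morph = np.column_stack([harmonized[c] for c in MORPH_INSTREAM])
    with np.errstate(invalid="ignore"):
        n_present = np.isfinite(morph).sum(axis=1)
        m_morph = np.where(n_present > 0, np.nansum(morph, axis=1) / np.maximum(n_present, 1), np.nan)

    for code in VARIABLE_ORDER:
        if code not in MORPH_INSTREAM:
            out[code] = harmonized[code]
    out[AGGREGATED_CODE] = m_morph
    out["n_missing_raw"] = sum(np.isnan(harmonized[c]).astype(int) for c in VARIABLE_ORDER)
    return out
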