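"""Pressure-variable schema and ordinal harmonisation.

Fifteen pressure variables in four groups — hydrology (H), morphology (M),
water quality (W) and connectivity (C) — describe the anthropogenic
degradation of a river sampling site.  National source data arrive in
heterogeneous codings (presence/absence flags, three- to five-level ordinal
scales); every variable is harmonised onto a common ordinal gradient from
1 (nearly undisturbed) to 5 (strongly impacted).  Not every variable can
take every level: the allowed value set of each variable is part of its
contract and is enforced throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

import yaml

GROUPS = ("hydrology", "morphology", "water_quality", "connectivity")

#: canonical column order of the 15 raw pressure variables
VARIABLE_ORDER = (
    "H_imp", "H_hydrop", "H_waterabstr", "H_resflush", "H_hydromod",
    "M_channel", "M_crosssec", "M_instrhab", "M_embankm", "M_floodpr",
    "C_B_s_up", "C_B_s_do",
    "W_acid", "W_eutroph", "W_opoll",
)

#: the three instream-morphology variables aggregated into M_morph_instr
MORPH_INSTREAM = ("M_channel", "M_instrhab", "M_crosssec")
AGGREGATED_CODE = "M_morph_instr"

#: harmonised per-site variables: the 12 non-aggregated ones plus the aggregate
HARMONIZED_VARIABLES = tuple(
    c for c in VARIABLE_ORDER if c not in MORPH_INSTREAM
) + (AGGREGATED_CODE,)

#: variables entering each group index (morphology uses the aggregate)
GROUP_INDEX_MEMBERS: dict[str, tuple[str, ...]] = {
    "hydrology": ("H_imp", "H_hydrop", "H_waterabstr", "H_resflush", "H_hydromod"),
    "morphology": (AGGREGATED_CODE, "M_embankm", "M_floodpr"),
    "water_quality": ("W_acid", "W_eutroph", "W_opoll"),
    "connectivity": ("C_B_s_up", "C_B_s_do"),
}


class SchemaError(ValueError):
    """Base class for pressure-coding problems."""


class UnknownModalityError(SchemaError):
    """A source token is not a recognised modality of the variable."""


class PressureValueError(SchemaError):
    """A numeric value lies outside the variable's allowed ordinal set."""


@dataclass(frozen=True)
class PressureVariableSpec:
    """Coding contract for one pressure variable.

    Parameters
    ----------
    code
        Short variable token, e.g. ``"H_imp"``.
    group
        One of :data:`GROUPS`.
    allowed_values
        Ordered tuple of permitted canonical ordinal values (subset of 1–5,
        always containing 1).
    class_labels
        Verbal label of each allowed ordinal value.
    source_modalities
        Mapping of lower-cased source-coding tokens to canonical values,
        monotone in severity (absence maps to 1, the most severe modality to
        ``max(allowed_values)``).
    """

    code: str
    group: str
    allowed_values: tuple[int, ...]
    class_labels: Mapping[int, str]
    source_modalities: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SchemaError(f"unknown group {self.group!r} for {self.code}")
        if not set(self.allowed_values) <= {1, 2, 3, 4, 5} or 1 not in self.allowed_values:
            raise SchemaError(f"invalid allowed_values for {self.code}: {self.allowed_values}")

    @property
    def max_value(self) -> int:
        return max(self.allowed_values)


def _spec(code: str, group: str, labels: dict[int, str], modalities: dict[str, int]) -> PressureVariableSpec:
    return PressureVariableSpec(
        code=code,
        group=group,
        allowed_values=tuple(sorted(labels)),
        class_labels=dict(labels),
        source_modalities=dict(modalities),
    )


@lru_cache(maxsize=1)
def load_schema() -> tuple[PressureVariableSpec, ...]:
    """Return the specs of the 15 pressure variables in canonical order."""
    specs = (
        _spec("H_imp", "hydrology",
              {1: "no impoundment", 3: "weak", 5: "strong"},
              {"no": 1, "weak": 3, "strong": 5}),
        _spec("H_hydrop", "hydrology",
              {1: "no hydropeaking", 3: "partial or full hydropeaking"},
              {"no": 1, "partial": 3, "yes": 3}),
        _spec("H_waterabstr", "hydrology",
              {1: "no water abstraction",
               3: "weak to medium (less than half of mean annual flow)",
               5: "strong (more than half of mean annual flow)"},
              {"no": 1, "weak": 3, "weak to medium": 3, "medium": 3, "strong": 5}),
        _spec("H_resflush", "hydrology",
              {1: "no reservoir flushing upstream", 3: "reservoir flushing upstream"},
              {"no": 1, "yes": 3}),
        _spec("H_hydromod", "hydrology",
              {1: "no seasonal hydrograph modification", 3: "seasonal hydrograph modification"},
              {"no": 1, "yes": 3}),
        _spec("M_channel", "morphology",
              {1: "natural channel plan form", 3: "intermediate", 5: "straightened"},
              {"no": 1, "intermediate": 3, "straightened": 5}),
        _spec("M_crosssec", "morphology",
              {1: "natural cross-section", 3: "intermediate", 5: "technical cross-section / U-profile"},
              {"no": 1, "intermediate": 3, "technical": 5, "u-profile": 5}),
        _spec("M_instrhab", "morphology",
              {1: "natural instream habitat", 3: "intermediate", 5: "high alteration"},
              {"no": 1, "intermediate": 3, "high": 5}),
        _spec("M_embankm", "morphology",
              {1: "no embankment (natural status)",
               2: "slight (local artificial material)",
               3: "intermediate (continuous but permeable)",
               5: "high (continuous, no permeability)"},
              {"no": 1, "slight": 2, "intermediate": 3, "high": 5}),
        _spec("M_floodpr", "morphology",
              {1: "no dykes", 3: "dykes for flood protection"},
              {"no": 1, "yes": 3}),
        _spec("C_B_s_up", "connectivity",
              {1: "no barrier on segment upstream", 3: "partial or full barrier upstream"},
              {"no": 1, "partial": 3, "yes": 3}),
        _spec("C_B_s_do", "connectivity",
              {1: "no barrier on segment downstream", 4: "partial or full barrier downstream"},
              {"no": 1, "partial": 4, "yes": 4}),
        _spec("W_acid", "water_quality",
              {1: "no acidification", 3: "acidification"},
              {"no": 1, "yes": 3}),
        _spec("W_eutroph", "water_quality",
              {1: "no artificial eutrophication", 3: "low",
               4: "intermediate (occurrence of green algae)", 5: "extreme (oxygen depletion)"},
              {"no": 1, "low": 3, "intermediate": 4, "extreme": 5}),
        _spec("W_opoll", "water_quality",
              {1: "no organic pollution", 3: "weak", 5: "strong"},
              {"no": 1, "weak": 3, "strong": 5}),
    )
    assert tuple(s.code for s in specs) == VARIABLE_ORDER
    return specs


@lru_cache(maxsize=1)
def schema_map() -> dict[str, PressureVariableSpec]:
    """Schema as a ``{code: spec}`` mapping."""
    return {s.code: s for s in load_schema()}


def get_spec(code: str) -> PressureVariableSpec:
    try:
        return schema_map()[code]
    except KeyError:
        raise SchemaError(f"unknown pressure variable code {code!r}") from None


def harmonize_value(spec: PressureVariableSpec, raw: object) -> int:
    """Map a raw source value onto the variable's canonical 1–5 ordinal value.

    ``raw`` may be a source-modality token (e.g. ``"strong"``) or a number
    that is already canonical; harmonising a canonical value is the identity.

    Raises
    ------
    UnknownModalityError
        If ``raw`` is a token that is not a modality of this variable.
    PressureValueError
        If ``raw`` is numeric but outside the allowed ordinal set.
    """
    if isinstance(raw, str):
        token = raw.strip().lower()
        try:
            num = float(token)
        except ValueError:
            if token in spec.source_modalities:
                return spec.source_modalities[token]
            raise UnknownModalityError(
                f"{spec.code}: unrecognised source modality {raw!r}"
            ) from None
    else:
        try:
            num = float(raw)  # accepts Python and numpy scalars
        except (TypeError, ValueError):
            raise UnknownModalityError(
                f"{spec.code}: cannot interpret raw value {raw!r}"
            ) from None
    if num != num:  # NaN
        raise PressureValueError(f"{spec.code}: missing value passed to harmonize_value")
    if num in spec.allowed_values and float(num).is_integer():
        return int(num)
    raise PressureValueError(
        f"{spec.code}={raw!r} not in allowed values {set(spec.allowed_values)}"
    )


def export_schema(specs: Iterable[PressureVariableSpec] | None = None) -> str:
    """Serialise the schema to YAML (group, allowed values, labels, modalities)."""
    specs = load_schema() if specs is None else tuple(specs)
    doc = {
        s.code: {
            "group": s.group,
            "allowed_values": list(s.allowed_values),
            "class_labels": {int(k): v for k, v in s.class_labels.items()},
            "source_modalities": dict(s.source_modalities),
        }
        for s in specs
    }
    return yaml.safe_dump(doc, sort_keys=False)
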