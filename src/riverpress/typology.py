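"""River typology and ecoregion lookups.

The 15 European Fish Types (EFT, predicted from environmental variables by
external software and supplied here as input) are collapsed into six river
types A–F, from *Salmo trutta fario*-dominated headwaters (A) to lowland
rivers dominated by *Gasterosteus aculeatus* and *Rutilus rutilus* (F).
Connectivity pressures are recorded on a river segment whose length depends
on catchment size (1/5/10 km for small/medium/large rivers).
"""

from __future__ import annotations

from dataclasses import dataclass


class TypologyError(ValueError):
    """Raised for EFT codes or catchment areas outside their domain."""


@dataclass(frozen=True)
class RiverType:
    code: str   # A..F
    label: str


RIVER_TYPES: dict[str, RiverType] = {
    "A": RiverType("A", "Headwater"),
    "B": RiverType("B", "Downstream"),
    "C": RiverType("C", "Greyling"),
    "D": RiverType("D", "Salmon"),
    "E": RiverType("E", "Mediterranean"),
    "F": RiverType("F", "Lowland"),
}

#: EFT code (1–15) → river type code
EFT_TO_RT: dict[int, str] = {
    1: "A", 2: "A", 3: "A", 4: "A",
    5: "B", 6: "B",
    7: "C", 9: "C",
    8: "D", 11: "D", 12: "D",
    10: "E", 13: "E",
    14: "F", 15: "F",
}

#: river type code → EFT codes
RT_TO_EFTS: dict[str, tuple[int, ...]] = {
    rt: tuple(sorted(k for k, v in EFT_TO_RT.items() if v == rt)) for rt in RIVER_TYPES
}

#: the ten analysed Illies ecoregions
ECOREGIONS: dict[int, str] = {
    1: "Ibero-Macaronesian region",
    4: "Alps",
    8: "Western highlands",
    9: "Central highlands",
    11: "Hungarian lowlands",
    13: "Western plains",
    14: "Central plains",
    16: "Eastern plains",
    18: "England",
    22: "Fenno-scandian shield",
}


def aggregate_river_type(eft_code: int) -> RiverType:
    """Collapse an EFT code (1–15) into one of the six river types A–F."""
    try:
        code = int(eft_code)
    except (TypeError, ValueError):
        raise TypologyError(f"EFT code must be an integer 1-15, got {eft_code!r}") from None
    if code != eft_code or code not in EFT_TO_RT:
        raise TypologyError(f"EFT code must be an integer 1-15, got {eft_code!r}")
    return RIVER_TYPES[EFT_TO_RT[code]]


def segment_length_km(catchment_km2: float) -> int:
    """Segment length (km) over which barrier pressures are recorded.

    1 km for small rivers (catchment < 100 km²), 5 km for medium-sized
    rivers (100–1000 km², bracket read as closed) and 10 km for large
    rivers (> 1000 km²).
    """
    c = float(catchment_km2)
    if not c > 0:
        raise TypologyError(f"catchment area must be positive, got {catchment_km2!r}")
    if c < 100:
        return 1
    if c <= 1000:
        return 5
    return 10


def ecoregion_name(number: int) -> str:
    try:
        return ECOREGIONS[int(number)]
    except (KeyError, TypeError, ValueError):
        raise TypologyError(f"unknown ecoregion number {number!r}") from None
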