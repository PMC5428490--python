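"""Fatty-acid composition ratios and the annual lipid-yield quantity.

Profiles are GC-determined percent-of-total compositions keyed by species
labels of the form ``C<chain>:<double_bonds>`` (e.g. C16:0 palmitic, C18:1
oleic).  Two breeding-relevant ratios are computed: the C18:C16 ratio
(summed 18-carbon percent over summed 16-carbon percent, all unsaturation
states included on both sides) and the desaturated:saturated ratio (>= 1
double bond over 0 double bonds).  Annual lipid yield per tree is the dry
tissue lipid content (percent) times the annual tissue yield (kg).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

from .errors import FormatError, UndefinedRatioError

_SPECIES_RE = re.compile(r"^C(\d{2}):(\d)$")


def parse_species(label: str) -> tuple[int, int]:
    """Parse 'C18:1' -> (18, 1); chain 12-24, double bonds 0-3."""
    m = _SPECIES_RE.match(label)
    if not m:
        raise FormatError(f"bad fatty-acid species label {label!r}")
    chain, bonds = int(m.group(1)), int(m.group(2))
    if not 12 <= chain <= 24:
        raise FormatError(f"{label!r}: chain length {chain} outside 12-24")
    if not 0 <= bonds <= 3:
        raise FormatError(f"{label!r}: {bonds} double bonds outside 0-3")
    return chain, bonds


@dataclass
class FattyAcidProfile:
    """Percent-of-total fatty-acid composition."""

    composition: Mapping[str, float]

    def __post_init__(self) -> None:
        self.composition = dict(self.composition)
        for label, pct in self.composition.items():
            parse_species(label)
            if pct < 0:
                raise FormatError(f"{label!r}: negative percent {pct}")
        total = sum(self.composition.values())
        if abs(total - 100.0) > 0.5:
            raise FormatError(
                f"composition percents sum to {total:.3f}, expected 100 +/- 0.5"
            )

    def percent_where(self, predicate) -> float:
        return sum(
            pct
            for label, pct in self.composition.items()
            if predicate(*parse_species(label))
        )


@dataclass(frozen=True)
class LipidTraits:
    c18_c16_ratio: float
    desat_sat_ratio: float
    lipid_content_pct: float
    annual_yield_kg: float


def c18_c16_ratio(profile: FattyAcidProfile) -> float:
    """Summed C18:x percent over summed C16:x percent."""
    c18 = profile.percent_where(lambda chain, bonds: chain == 18)
    c16 = profile.percent_where(lambda chain, bonds: chain == 16)
    if c16 == 0:
        raise UndefinedRatioError("no C16 species in profile")
    return c18 / c16


def desat_sat_ratio(profile: FattyAcidProfile) -> float:
    """Desaturated (>= 1 double bond) over saturated (0 double bonds) percent."""
    desat = profile.percent_where(lambda chain, bonds: bonds >= 1)
    sat = profile.percent_where(lambda chain, bonds: bonds == 0)
    if sat == 0:
        raise UndefinedRatioError("no saturated species in profile")
    return desat / sat


def annual_lipid_yield(lipid_content_pct: float, tissue_yield_kg: float) -> float:
    """Annual lipid mass per tree: (lipid content %)/100 x tissue yield (kg)."""
    if not 0 <= lipid_content_pct <= 100:
        raise ValueError(
            f"lipid content {lipid_content_pct} outside [0, 100] percent"
        )
    if tissue_yield_kg < 0:
        raise ValueError(f"negative tissue yield {tissue_yield_kg}")
    return lipid_content_pct / 100.0 * tissue_yield_kg


def lipid_traits(
    profile: FattyAcidProfile, lipid_content_pct: float, tissue_yield_kg: float
) -> LipidTraits:
    return LipidTraits(
        c18_c16_ratio=c18_c16_ratio(profile),
        desat_sat_ratio=desat_sat_ratio(profile),
        lipid_content_pct=lipid_content_pct,
        annual_yield_kg=annual_lipid_yield(lipid_content_pct, tissue_yield_kg),
    )
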