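"""Reactor nitrogen mass balance and nitritation-anammox stoichiometry.

Helpers for interpreting reactor performance records: hydraulic retention
time, nitrogen removal and the nitrate-to-ammonium-removal ratio, the
stoichiometric nitrate fraction expected of a combined nitritation-anammox
process, and how much of a carrier's depth a cryosection series covers.

The anammox reaction consumes 1.32 mol nitrite and produces 0.26 mol
nitrate per mol ammonium; coupled with nitritation supplying exactly that
nitrite, the process converts 0.26 / (1 + 1.32) ≈ 11% of the removed
ammonium-N to nitrate — the benchmark against which a reactor's observed
nitrate production is judged (a matching observed ratio implies aerobic
nitrite oxidation is negligible).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "ReactorRecord",
    "AnammoxStoichiometry",
    "hrt",
    "format_hrt",
    "nitrogen_balance",
    "anammox_stoichiometric_ratio",
    "depth_coverage_percent",
    "round_half_away",
]


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (so 6.25 → 6.3 at one decimal)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class ReactorRecord:
    """Influent/effluent nitrogen species (mg N L^-1) and flow for one period."""

    volume_L: float
    flow_L_per_h: float
    influent_nh4: float
    effluent_nh4: float
    effluent_no2: float
    effluent_no3: float

    def __post_init__(self) -> None:
        if not self.flow_L_per_h > 0:
            raise ValueError("flow must be > 0")
        for name in ("influent_nh4", "effluent_nh4", "effluent_no2", "effluent_no3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class AnammoxStoichiometry:
    """Molar anammox coefficients per mol ammonium oxidized."""

    nitrite_consumed_per_ammonium: float = 1.32
    nitrate_produced_per_ammonium: float = 0.26

    def __post_init__(self) -> None:
        if self.nitrite_consumed_per_ammonium <= 0:
            raise ValueError("nitrite coefficient must be > 0")
        if self.nitrate_produced_per_ammonium < 0:
            raise ValueError("nitrate coefficient must be >= 0")


def hrt(volume_L: float, flow_L_per_h: float) -> float:
    """Hydraulic retention time in hours: volume / flow."""
    if not flow_L_per_h > 0:
        raise ValueError("flow must be > 0")
    return volume_L / flow_L_per_h


def format_hrt(volume_L: float, flow_L_per_h: float) -> str:
    """HRT reported to one decimal, rounding half away from zero."""
    return f"{round_half_away(hrt(volume_L, flow_L_per_h), 1):.1f}"


def nitrogen_balance(record: ReactorRecord) -> dict[str, float]:
    """Nitrogen removal and nitrate-to-ammonium-removal percentages.

    removal% counts every effluent N species against the influent ammonium
    (so removal% plus the effluent share is exactly 100%); ratio% is
    effluent nitrate over ammonium removed.
    """
    if record.influent_nh4 <= record.effluent_nh4:
        raise ValueError("no ammonium removal; balance undefined")
    effluent_total = record.effluent_nh4 + record.effluent_no2 + record.effluent_no3
    removal = (record.influent_nh4 - effluent_total) / record.influent_nh4 * 100.0
    nh4_removed = record.influent_nh4 - record.effluent_nh4
    if nh4_removed == 0:
        raise ValueError("zero ammonium removal; ratio undefined")
    ratio = record.effluent_no3 / nh4_removed * 100.0
    return {
        "removal_percent": removal,
        "nitrate_to_ammonium_removal_percent": ratio,
    }


def anammox_stoichiometric_ratio(
    stoich: AnammoxStoichiometry | None = None,
) -> int:
    """Stoichiometric nitrate-production percentage of nitritation-anammox.

    In the coupled process AOB oxidize ammonium to exactly the nitrite the
    anammox reaction consumes: per (1 + c_no2) mol ammonium removed, c_no3
    mol nitrate is produced.  Returns the percentage rounded to the nearest
    integer (defaults give 0.26 / 2.32 → 11%).
    """
    stoich = stoich or AnammoxStoichiometry()
    ratio = (
        stoich.nitrate_produced_per_ammonium
        / (1.0 + stoich.nitrite_consumed_per_ammonium)
        * 100.0
    )
    return int(round_half_away(ratio))


def depth_coverage_percent(
    section_depth_um: float, carrier_compartment_depth_um: float
) -> int:
    """Share of the carrier's maximum biofilm depth a section series reaches.

    Sections proceed from each carrier surface toward the mid-depth "waist",
    so the maximum biofilm depth is half the carrier compartment depth; an
    800 µm series covers 80% of a 2 mm carrier and 53% of a 3 mm carrier.
    Returns an integer percent, capped at 100 (with a warning) when the
    section depth exceeds the reachable half-depth.
    """
    if not section_depth_um > 0 or not carrier_compartment_depth_um > 0:
        raise ValueError("depths must be > 0")
    half = carrier_compartment_depth_um / 2.0
    pct = section_depth_um / half * 100.0
    if pct > 100.0:
        warnings.warn(
            "section depth exceeds half the carrier depth; coverage capped at 100%",
            stacklevel=2,
        )
        pct = 100.0
    return int(round_half_away(pct))
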