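"""Stoichiometric partitioning of sediment oxygen consumption.

Upward-diffusing sulfide that never reaches the water column must be
re-oxidized (or buried as iron sulfides) within the sediment.  Complete
oxidation of sulfide to sulfate consumes two moles of O2 per mole of S:

    H2S + 2 O2 -> SO4²⁻ + 2 H⁺.

Multiplying the upward ΣH2S flux by this 2:1 stoichiometry gives the part
of the total diffusive O2 uptake attributable to sulfide oxidation; the
remainder is left to other sinks (aerobic respiration, re-oxidation of
reduced Fe/Mn, nitrification, CH4 oxidation), which this budget does not
resolve further.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fluxes import FluxResult

__all__ = [
    "OxygenBudget",
    "sulfide_o2_equivalent",
    "sulfide_fraction_of_o2",
    "build_budget",
]


@dataclass
class OxygenBudget:
    """Partition of total O2 uptake into sulfide-driven and residual parts.

    All fluxes in mmol m⁻² d⁻¹; uptake negative, upward efflux positive.
    ``sulfide_fraction`` is the percent of |j_o2| explained by sulfide
    oxidation, unrounded; ``sulfide_fraction_pct`` the integer presentation
    value.  A fraction above 100% (possible with noisy inputs) sets
    ``inconsistent`` instead of clamping.
    """

    j_o2: float
    j_h2s: float
    stoichiometry: float
    o2_for_sulfide: float
    residual_o2: float
    sulfide_fraction: float
    inconsistent: bool = False

    @property
    def sulfide_fraction_pct(self) -> int:
        return round(self.sulfide_fraction)


def sulfide_o2_equivalent(j_h2s: float, stoichiometry: float = 2.0) -> float:
    """O2 consumption (negative) implied by an upward sulfide flux.

    ``j_h2s`` must be >= 0: a downward sulfide flux is outside this
    budget's model.
    """
    if j_h2s < 0:
        raise ValueError("j_h2s must be >= 0 (upward sulfide transport)")
    if stoichiometry < 0:
        raise ValueError("stoichiometry must be >= 0")
    return -stoichiometry * j_h2s


def sulfide_fraction_of_o2(
    j_h2s: float, j_o2: float, stoichiometry: float = 2.0
) -> float:
    """Percent of total O2 uptake used to oxidize upward-diffusing sulfide.

    ``100 · stoichiometry · j_h2s / |j_o2|``, unrounded.
    """
    if j_o2 == 0:
        raise ValueError("j_o2 must be nonzero")
    if j_o2 > 0:
        raise ValueError("j_o2 must be negative (sediment O2 uptake)")
    if j_h2s < 0:
        raise ValueError("j_h2s must be >= 0")
    return 100.0 * (stoichiometry * j_h2s) / abs(j_o2)


def build_budget(
    flux_o2: FluxResult | float,
    flux_h2s: FluxResult | float,
    stoichiometry: float = 2.0,
    core_id: str | None = None,
) -> OxygenBudget:
    """Assemble the oxygen budget from O2 and ΣH2S fluxes of one core.

    Accepts :class:`~sedflux.fluxes.FluxResult` objects or bare flux values
    in mmol m⁻² d⁻¹.
    """
    j_o2 = flux_o2.flux if isinstance(flux_o2, FluxResult) else float(flux_o2)
    j_h2s = flux_h2s.flux if isinstance(flux_h2s, FluxResult) else float(flux_h2s)
    o2_for_sulfide = sulfide_o2_equivalent(j_h2s, stoichiometry)
    fraction = sulfide_fraction_of_o2(j_h2s, j_o2, stoichiometry)
    return OxygenBudget(
        j_o2=j_o2,
        j_h2s=j_h2s,
        stoichiometry=stoichiometry,
        o2_for_sulfide=o2_for_sulfide,
        residual_o2=j_o2 - o2_for_sulfide,
        sulfide_fraction=fraction,
        inconsistent=fraction > 100.0,
    )
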