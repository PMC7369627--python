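"""Acid-base speciation of dissolved sulfide in porewater.

Amperometric H2S microsensors respond only to the gaseous species H2S, while
at porewater pH a large share of dissolved sulfide is present as HS⁻.  Total
dissolved sulfide is therefore reconstructed at each depth from the paired
H2S and pH readings,

    ΣH2S = [H2S] + [HS⁻] = [H2S] · (1 + 10^(pH − pK1)),

with pK1 the first dissociation constant of H2S ⇌ H⁺ + HS⁻.  The second
dissociation (S²⁻) is negligible at porewater pH and is not modelled.

The default pK1(T, S) is the seawater fit of Millero (1988; Limnol.
Oceanogr. 33:269),

    ln K1 = 225.838 − 13275.3/T − 34.6435 ln T + 0.3449 √S − 0.0274 S

with T in kelvin and S the practical salinity, valid for 0–40 °C and
S 0–40; it reproduces the tabulated pK1 = 6.98 in fresh water and 6.51 in
S = 35 seawater at 25 °C.  pH sensors calibrated against commercial NBS
buffers are assumed; no pH-scale conversion is applied.  Any alternative
constant can be supplied through ``pk1_override``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .profiles import SoluteProfile, Solute, align_to_grid

__all__ = [
    "SpeciationParams",
    "SpeciatedProfile",
    "pk1",
    "total_sulfide",
    "speciate_profile",
]

PK1_SOURCE = "Millero (1988) seawater fit, NBS-buffer-calibrated pH assumed"

_T_RANGE = (-2.0, 40.0)
_S_RANGE = (0.0, 40.0)


def pk1(temperature_c: float, salinity: float) -> float:
    """First dissociation constant of H2S in seawater, as pK1 = −log10 K1.

    Raises ``ValueError`` outside the fit's validity range
    (−2 < T < 40 °C, 0 ≤ S ≤ 40).
    """
    if not _T_RANGE[0] < temperature_c < _T_RANGE[1]:
        raise ValueError(
            f"temperature {temperature_c} °C outside pK1 fit range "
            f"({_T_RANGE[0]}, {_T_RANGE[1]}) °C"
        )
    if not _S_RANGE[0] <= salinity <= _S_RANGE[1]:
        raise ValueError(
            f"salinity {salinity} outside pK1 fit range [{_S_RANGE[0]}, {_S_RANGE[1]}]"
        )
    t_k = temperature_c + 273.15
    ln_k = (
        225.838
        - 13275.3 / t_k
        - 34.6435 * math.log(t_k)
        + 0.3449 * math.sqrt(salinity)
        - 0.0274 * salinity
    )
    return -ln_k / math.log(10.0)


@dataclass
class SpeciationParams:
    """Temperature/salinity context for sulfide speciation.

    ``pk1_override`` bypasses the built-in formulation, e.g. to reproduce a
    calculation done with a different constant or pH scale.
    """

    temperature_c: float = 8.0
    salinity: float = 7.0
    pk1_override: float | None = None
    pk1_source: str = field(default=PK1_SOURCE)

    def pk1_value(self) -> float:
        if self.pk1_override is not None:
            return float(self.pk1_override)
        value = pk1(self.temperature_c, self.salinity)
        if not 5.5 < value < 8.5:
            raise ValueError(f"computed pK1 {value:.3f} outside plausible range (5.5, 8.5)")
        return value

    def source(self) -> str:
        if self.pk1_override is not None:
            return f"override pK1={self.pk1_override}"
        return self.pk1_source


@dataclass
class SpeciatedProfile:
    """ΣH2S profile with both sulfide species and the pH actually used."""

    depths: np.ndarray
    h2s_gas: np.ndarray
    hs_minus: np.ndarray
    total: np.ndarray
    ph_used: np.ndarray
    pk1_used: float
    n_clipped: int = 0
    core_id: str = ""
    treatment: str = ""
    timepoint_day: int = 0
    profile_replicate: int = 1

    @property
    def values(self) -> np.ndarray:
        """Alias so horizon detectors treat this like a profile of ΣH2S."""
        return self.total


def total_sulfide(h2s_gas, ph, pk1_value: float):
    """Split sensor-level [H2S] into (HS⁻, ΣH2S) at the given pH.

    ``hs_minus = h2s_gas · 10^(pH − pK1)``;
    ``total = h2s_gas · (1 + 10^(pH − pK1))``.
    Inputs may be scalars or arrays; all concentrations in μM.
    """
    h2s_gas = np.asarray(h2s_gas, dtype=float)
    ph = np.asarray(ph, dtype=float)
    if not (np.all(np.isfinite(h2s_gas)) and np.all(np.isfinite(ph)) and np.isfinite(pk1_value)):
        raise ValueError("non-finite input to total_sulfide")
    if np.any(h2s_gas < 0):
        raise ValueError("h2s_gas must be >= 0 (clip sensor noise before speciation)")
    hs_minus = h2s_gas * 10.0 ** (ph - pk1_value)
    total = h2s_gas + hs_minus
    if h2s_gas.ndim == 0:
        return float(hs_minus), float(total)
    return hs_minus, total


def speciate_profile(
    h2s_profile: SoluteProfile,
    ph_profile: SoluteProfile,
    params: SpeciationParams,
) -> SpeciatedProfile:
    """Compute the ΣH2S profile from paired H2S and pH profiles.

    pH is linearly interpolated onto the H2S depth grid; negative H2S
    readings (sensor noise) are clipped to zero before speciation and the
    number of clipped points is recorded.
    """
    if h2s_profile.solute is not Solute.H2S:
        raise ValueError(f"expected an H2S profile, got {h2s_profile.solute}")
    if ph_profile.solute is not Solute.PH:
        raise ValueError(f"expected a pH profile, got {ph_profile.solute}")
    depths, h2s_raw, ph_vals = align_to_grid(h2s_profile, ph_profile)
    n_clipped = int(np.sum(h2s_raw < 0))
    h2s = np.clip(h2s_raw, 0.0, None)
    k = params.pk1_value()
    hs_minus, total = total_sulfide(h2s, ph_vals, k)
    return SpeciatedProfile(
        depths=depths,
        h2s_gas=h2s,
        hs_minus=hs_minus,
        total=total,
        ph_used=ph_vals,
        pk1_used=k,
        n_clipped=n_clipped,
        core_id=h2s_profile.core_id,
        treatment=h2s_profile.treatment,
        timepoint_day=h2s_profile.timepoint_day,
        profile_replicate=h2s_profile.profile_replicate,
    )
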