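"""Diffusive flux estimation from near-interface concentration gradients.

Fluxes across the sediment--water interface follow Fick's first law for
sediments,

    J = −φ (Ds + Db) ∂C/∂x,

where φ is porosity, Ds the porosity-corrected sediment diffusivity,

    Ds = φ² · Dmol,

Db an additive biodiffusivity representing faunal mixing of porewater, and
∂C/∂x the concentration gradient obtained by linear regression of
concentration on depth over a near-interface window.  On this package's
depth-down axis the sign works out so that sediment O2 uptake is negative
(O2 decreases downward) and sulfide efflux toward the oxic zone is positive
(ΣH2S increases downward), matching the usual reporting convention.

Biodiffusivity is modelled as a linear function of meiofauna abundance,
calibrated by ordinary least squares on published (abundance, Db) reference
pairs; predicted Db is clipped at zero.  The reference pairs shipped as a
default are a SYNTHETIC placeholder (see ``PLACEHOLDER_DB_REFERENCE_POINTS``)
spanning transport enhancements of ~1.1--2x molecular diffusion, the range
reported for meiofauna-reworked surface sediments; any real calibration
should be supplied through configuration, or Db disabled entirely for the
pure molecular-diffusion case.

Units: depths mm, concentrations μM (= mmol m⁻³), so a raw regression
slope in μM mm⁻¹ equals 10³ mmol m⁻⁴; diffusivities m² d⁻¹ (config may
supply cm² s⁻¹; 1 cm² s⁻¹ = 8.64 m² d⁻¹); fluxes mmol m⁻² d⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .profiles import CoreContext, Solute

__all__ = [
    "DiffusivityModel",
    "BiodiffusivityFit",
    "GradientFit",
    "FluxResult",
    "molecular_diffusivity",
    "sediment_diffusivity",
    "fit_biodiffusivity",
    "db_for_abundance",
    "build_diffusivity",
    "fit_gradient",
    "diffusive_flux",
    "o2_fit_window",
    "sulfide_fit_window",
    "parabolic_window_attenuation",
    "CM2_PER_S_TO_M2_PER_D",
    "UM_PER_MM_TO_MMOL_PER_M4",
    "PLACEHOLDER_DB_REFERENCE_POINTS",
]

CM2_PER_S_TO_M2_PER_D = 8.64  # 1 cm² s⁻¹ = 1e-4 m² s⁻¹ × 86400 s d⁻¹
UM_PER_MM_TO_MMOL_PER_M4 = 1.0e3  # 1 μM mm⁻¹ = 10³ mmol m⁻⁴

# Infinite-dilution molecular diffusion coefficients as fits in T (°C),
# in 1e-6 cm² s⁻¹, from the standard compilation of tracer data for
# seawater solutes (Boudreau 1997, ch. 4).  ΣH2S transport is assigned the
# HS⁻ coefficient, the dominant species at porewater pH near or above pK1.
# No explicit salinity correction is applied (a few percent at most over
# the brackish-to-marine range; override via config when it matters).
_DMOL_FITS_CM2_S = {
    Solute.O2: lambda t: (11.70 + 0.3440 * t + 0.005050 * t * t) * 1e-6,
    Solute.H2S: lambda t: (10.40 + 0.2730 * t) * 1e-6,
}


def molecular_diffusivity(
    solute: Solute | str, temperature_c: float, salinity: float | None = None
) -> float:
    """Free-solution diffusion coefficient Dmol in m² d⁻¹ at in-situ T."""
    solute = Solute(solute)
    if solute not in _DMOL_FITS_CM2_S:
        raise ValueError(f"no Dmol fit for solute {solute}")
    if not -2.0 < temperature_c < 40.0:
        raise ValueError("temperature outside (-2, 40) °C fit range")
    return _DMOL_FITS_CM2_S[solute](temperature_c) * CM2_PER_S_TO_M2_PER_D


def sediment_diffusivity(d_mol: float, phi: float) -> float:
    """Porosity-corrected sediment diffusivity Ds = φ² · Dmol."""
    if not 0.0 < phi < 1.0:
        raise ValueError(f"porosity must be in (0, 1), got {phi}")
    if d_mol <= 0:
        raise ValueError("d_mol must be positive")
    return phi * phi * d_mol


@dataclass
class BiodiffusivityFit:
    """OLS line of biodiffusivity on meiofauna abundance."""

    reference_points: list[tuple[float, float]]
    slope: float  # m² d⁻¹ per (ind. 10 cm⁻²)
    intercept: float  # m² d⁻¹
    r_squared: float


@dataclass
class DiffusivityModel:
    """Diffusivities entering the flux law for one solute in one core."""

    solute: Solute
    d_mol: float  # m² d⁻¹
    d_s: float  # m² d⁻¹
    d_b: float  # m² d⁻¹
    phi: float
    db_clipped: bool = False

    def __post_init__(self) -> None:
        self.solute = Solute(self.solute)
        if abs(self.d_s - self.phi**2 * self.d_mol) > 1e-12 * self.d_mol:
            raise ValueError("d_s must equal phi² × d_mol")
        if self.d_b < 0:
            raise ValueError("d_b must be >= 0")


@dataclass
class GradientFit:
    """Least-squares concentration gradient over a depth window.

    ``slope`` is ∂C/∂x on the depth-down axis in mmol m⁻⁴.
    """

    slope: float
    intercept: float  # μM at depth 0
    window: tuple[float, float]  # mm
    n_points: int
    r_squared: float
    low_r2: bool = False


@dataclass
class FluxResult:
    """Diffusive flux with its gradient fit and diffusivity provenance.

    Sign convention: sediment uptake negative, efflux toward the water
    positive (depth-down gradient carries the sign).
    """

    solute: Solute
    flux: float  # mmol m⁻² d⁻¹
    gradient_fit: GradientFit
    diffusivity: DiffusivityModel
    convention: str = "as_printed"


#: SYNTHETIC placeholder (abundance ind. 10 cm⁻², Db m² d⁻¹) — NOT a
#: published calibration.  Chosen so the resulting line spans transport
#: enhancement factors (Ds+Db)/Ds of roughly 1.1 at scarce-meiofauna
#: abundances to ~2 at the high end of natural abundance gradients.
PLACEHOLDER_DB_REFERENCE_POINTS: list[tuple[float, float]] = [
    (128.0, 1.0e-5),
    (191.0, 1.6e-5),
    (828.0, 4.4e-5),
    (2030.0, 1.0e-4),
]


def fit_biodiffusivity(
    reference_points: list[tuple[float, float]] | None = None,
) -> BiodiffusivityFit:
    """OLS fit of Db (m² d⁻¹) against meiofauna abundance.

    With no argument the labelled synthetic placeholder calibration is used.
    """
    pts = PLACEHOLDER_DB_REFERENCE_POINTS if reference_points is None else list(reference_points)
    if len(pts) < 2:
        raise ValueError("need at least 2 (abundance, Db) reference points")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("reference points need at least 2 distinct abundances")
    res = stats.linregress(x, y)
    return BiodiffusivityFit(
        reference_points=[(float(a), float(b)) for a, b in pts],
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def db_for_abundance(fit: BiodiffusivityFit, abundance: float) -> tuple[float, bool]:
    """Predicted Db at an abundance; negative predictions clip to 0.

    Returns ``(d_b, clipped)``.
    """
    if abundance < 0:
        raise ValueError("abundance must be >= 0")
    raw = fit.intercept + fit.slope * abundance
    if raw < 0:
        return 0.0, True
    return float(raw), False


def build_diffusivity(
    solute: Solute | str,
    context: CoreContext,
    db_fit: BiodiffusivityFit | None = None,
    d_b: float | None = None,
    d_mol: float | None = None,
) -> DiffusivityModel:
    """Assemble the diffusivity model for one solute in one core.

    ``d_b`` overrides the abundance model; ``d_b=0`` (or ``db_fit=None``
    with ``d_b=None`` is an error — callers must state explicitly whether
    bioturbation is modelled) gives the pure molecular-diffusion case.
    """
    solute = Solute(solute)
    if d_mol is None:
        d_mol = molecular_diffusivity(solute, context.temperature_c, context.salinity)
    d_s = sediment_diffusivity(d_mol, context.porosity)
    clipped = False
    if d_b is None:
        if db_fit is None:
            raise ValueError(
                "supply a BiodiffusivityFit or an explicit d_b "
                "(use d_b=0 to disable bioturbation)"
            )
        d_b, clipped = db_for_abundance(db_fit, context.meiofauna_abundance)
    return DiffusivityModel(
        solute=solute, d_mol=d_mol, d_s=d_s, d_b=float(d_b), phi=context.porosity,
        db_clipped=clipped,
    )


def fit_gradient(
    depths_mm: np.ndarray,
    values_um: np.ndarray,
    window: tuple[float, float],
    r2_floor: float = 0.8,
) -> GradientFit:
    """OLS concentration gradient over ``window = (depth_min, depth_max)`` mm.

    A coefficient of determination below ``r2_floor`` sets a warning flag
    (``low_r2``) rather than failing; constant profiles fit slope 0 with
    r² reported as 0.
    """
    depths_mm = np.asarray(depths_mm, dtype=float)
    values_um = np.asarray(values_um, dtype=float)
    lo, hi = window
    mask = (depths_mm >= lo - 1e-9) & (depths_mm <= hi + 1e-9)
    n = int(np.sum(mask))
    if n < 2:
        raise ValueError(f"fewer than 2 points in fit window [{lo}, {hi}] mm")
    x = depths_mm[mask]
    y = values_um[mask]
    if np.ptp(y) == 0.0:
        slope_um_mm, intercept, r2 = 0.0, float(y[0]), 0.0
    else:
        res = stats.linregress(x, y)
        slope_um_mm = float(res.slope)
        intercept = float(res.intercept)
        r2 = float(res.rvalue**2)
    return GradientFit(
        slope=slope_um_mm * UM_PER_MM_TO_MMOL_PER_M4,
        intercept=intercept,
        window=(float(x[0]), float(x[-1])),
        n_points=n,
        r_squared=r2,
        low_r2=r2 < r2_floor,
    )


def diffusive_flux(
    context: CoreContext,
    diffusivity: DiffusivityModel,
    gradient: GradientFit,
    convention: str = "as_printed",
) -> FluxResult:
    """Fick's-first-law flux from a fitted gradient.

    ``as_printed``: J = φ (Ds + Db) ∂C/∂x (depth-down slope, hence O2
    uptake < 0).  ``no_outer_porosity`` drops the leading φ, the variant
    used by conventions that fold porosity into the gradient.
    """
    if convention == "as_printed":
        j = context.porosity * (diffusivity.d_s + diffusivity.d_b) * gradient.slope
    elif convention == "no_outer_porosity":
        j = (diffusivity.d_s + diffusivity.d_b) * gradient.slope
    else:
        raise ValueError(f"unknown flux convention {convention!r}")
    return FluxResult(
        solute=diffusivity.solute,
        flux=float(j),
        gradient_fit=gradient,
        diffusivity=diffusivity,
        convention=convention,
    )


def o2_fit_window(opd_mm: float, fraction: float = 0.6) -> tuple[float, float]:
    """Default O2 gradient window: interface down to ``fraction`` of the OPD.

    The upper part of the oxic zone is the quasi-linear diffusive zone;
    deeper points curve toward the zero-gradient landing at the OPD and
    would flatten the fitted slope further.
    """
    if opd_mm <= 0:
        raise ValueError("OPD must be positive to set an O2 fit window")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return (0.0, fraction * opd_mm)


def sulfide_fit_window(horizon_mm: float, width_mm: float = 1.0) -> tuple[float, float]:
    """Default ΣH2S gradient window: first ``width_mm`` below the horizon."""
    if horizon_mm < 0:
        raise ValueError("horizon must be >= 0")
    if width_mm <= 0:
        raise ValueError("window width must be positive")
    return (horizon_mm, horizon_mm + width_mm)


def parabolic_window_attenuation(window_end_mm: float, opd_mm: float) -> float:
    """Slope attenuation of a window fit on a parabolic O2 profile.

    For the constant-consumption steady state C(z) = C0 (1 − z/L)², the OLS
    slope over evenly spaced points on [0, w] equals the interface gradient
    times (1 − w/(2L)) exactly.  Used to relate a window-fitted flux to the
    true interface flux when the profile is locally parabolic.
    """
    if not 0 < window_end_mm <= opd_mm:
        raise ValueError("window end must lie in (0, OPD]")
    return 1.0 - window_end_mm / (2.0 * opd_mm)
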