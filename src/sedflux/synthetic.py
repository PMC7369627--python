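"""Steady-state synthetic porewater profiles with known ground truth.

Every analysis stage in this package can be exercised without real sensor
data by simulating the profile shapes a seasonally hypoxic, sulfidic
sediment produces:

* **O2** decays from a 280--330 μM interface value to zero at the oxygen
  penetration depth L following the constant-volumetric-consumption steady
  state, C(z) = C0·(1 − z/L)² — parabolic, with a smooth zero-gradient
  landing at L and an analytic interface gradient −2·C0/L, so the true
  diffusive O2 flux is closed-form.
* **ΣH2S** is zero above the sulfide horizon and rises linearly below it
  with a prescribed deep gradient, so the true upward sulfide flux is also
  closed-form.
* **pH** declines smoothly from ~7.6--7.9 at the interface to ~5.4--7.2 at
  depth (monotone PCHIP interpolant), optionally with a localized oxic-zone
  maximum — the diagnostic pH signature of electrogenic sulfur oxidation by
  cable bacteria (e.g. a peak of pH 8.3 at 0.75 mm), modelled as an
  additive Gaussian bump whose geometry, not mechanism, is what downstream
  code needs.

The sensor-level [H2S] profile is back-computed from the ΣH2S truth and
the noise-free pH as truth / (1 + 10^(pH − pK1)), so the speciation module
recovers the truth exactly in the noise-free case.  i.i.d. Gaussian sensor
noise is added last; there is no drift model.

``simulate_experiment`` reproduces a full incubation design — by default
4 treatments × 3 cores × 3 solutes × 3 replicate profiles × 3 weekly time
points = 324 profiles — with per-treatment parameter trajectories patterned
on a meiofauna-addition experiment (deeper O2 penetration and sulfide
horizons and strongly reduced sulfide effluxes at high meiofauna abundance
early on, convergence between treatments as a cable-bacteria population
establishes in all cores).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import PchipInterpolator

from .fluxes import (
    BiodiffusivityFit,
    build_diffusivity,
    fit_biodiffusivity,
    UM_PER_MM_TO_MMOL_PER_M4,
)
from .profiles import CoreContext, ExperimentSet, Solute, SoluteProfile, write_profile
from .speciation import SpeciationParams

__all__ = [
    "ProfileSimConfig",
    "SyntheticTruth",
    "ExperimentDesign",
    "default_design",
    "simulate_o2_profile",
    "simulate_sulfide_profiles",
    "simulate_core",
    "simulate_experiment",
    "write_experiment",
    "read_experiment",
]

_SENSOR_FLOOR_UM = -5.0  # μM clamp emulating a sensor's small-negative output


@dataclass
class ProfileSimConfig:
    """Ground-truth parameters of one simulated core at one time point."""

    surface_o2: float = 300.0  # μM at the interface
    true_opd: float = 1.6  # mm
    true_horizon: float = 3.8  # mm
    deep_sulfide_gradient: float = 60.0  # μM mm⁻¹ below the horizon
    ph_surface: float = 7.8
    ph_deep: float = 6.8
    ph_deep_depth: float = 8.0  # mm at which pH reaches ph_deep
    esox_peak: tuple[float, float] | None = None  # (peak pH, peak depth mm)
    esox_sigma: float = 0.3  # mm, width of the oxic-zone pH maximum
    noise_sd_o2: float = 0.0  # μM
    noise_sd_h2s: float = 0.0  # μM
    noise_sd_ph: float = 0.0  # pH units
    grid_o2_um: float = 100.0
    grid_chem_um: float = 250.0
    profile_bottom: float = 12.0  # mm
    overlying_mm: float = 0.5  # extent of overlying-water readings

    def __post_init__(self) -> None:
        if not 0.0 < self.true_opd < self.true_horizon < self.profile_bottom:
            raise ValueError("need 0 < true_opd < true_horizon < profile_bottom")
        if min(self.noise_sd_o2, self.noise_sd_h2s, self.noise_sd_ph) < 0:
            raise ValueError("noise sds must be >= 0")
        if self.grid_o2_um <= 0 or self.grid_chem_um <= 0:
            raise ValueError("grid steps must be positive")
        if self.deep_sulfide_gradient < 0:
            raise ValueError("deep_sulfide_gradient must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground-truth record of one simulated core at one time point.

    True fluxes are computed analytically from the generating shapes and
    the same Fick's-law convention as the fluxes module: O2 flux negative
    (uptake), sulfide flux positive (upward efflux).
    """

    core_id: str
    treatment: str
    timepoint_day: int
    config: ProfileSimConfig
    true_opd: float
    true_horizon: float
    flux_o2: float  # mmol m⁻² d⁻¹, from the interface gradient −2·C0/L
    flux_h2s: float  # mmol m⁻² d⁻¹, from the deep linear gradient
    d_b_o2: float
    d_b_h2s: float
    seed: int | None = None


def _grid(step_um: float, overlying_mm: float, bottom_mm: float) -> np.ndarray:
    """Depth grid in mm including overlying-water points, exact multiples."""
    step = step_um / 1000.0
    n_up = int(round(overlying_mm / step))
    n_down = int(round(bottom_mm / step))
    return np.arange(-n_up, n_down + 1) * step


def o2_shape(z: np.ndarray, surface_o2: float, opd: float) -> np.ndarray:
    """Noise-free O2 profile: constant-consumption parabola, zero below L."""
    z = np.asarray(z, dtype=float)
    c = np.where(
        z <= 0.0,
        surface_o2,
        surface_o2 * np.clip(1.0 - z / opd, 0.0, None) ** 2,
    )
    return c


def sulfide_shape(z: np.ndarray, horizon: float, gradient: float) -> np.ndarray:
    """Noise-free ΣH2S profile: zero above the horizon, linear below."""
    z = np.asarray(z, dtype=float)
    return gradient * np.clip(z - horizon, 0.0, None)


def ph_shape(z: np.ndarray, config: ProfileSimConfig) -> np.ndarray:
    """Noise-free pH profile: monotone decline plus optional e-SOx maximum."""
    z = np.asarray(z, dtype=float)
    x0 = -max(config.overlying_mm, 0.001)
    knots_x = [x0, 0.0, config.ph_deep_depth, max(config.profile_bottom, config.ph_deep_depth + 1e-6)]
    knots_y = [config.ph_surface, config.ph_surface, config.ph_deep, config.ph_deep]
    baseline = PchipInterpolator(knots_x, knots_y)(np.clip(z, x0, knots_x[-1]))
    if config.esox_peak is not None:
        peak_ph, peak_depth = config.esox_peak
        base_at_peak = float(PchipInterpolator(knots_x, knots_y)(peak_depth))
        amp = max(0.0, peak_ph - base_at_peak)
        baseline = baseline + amp * np.exp(
            -((z - peak_depth) ** 2) / (2.0 * config.esox_sigma**2)
        )
    return baseline


def simulate_o2_profile(
    config: ProfileSimConfig,
    context: CoreContext,
    rng: np.random.Generator | None = None,
    timepoint_day: int = 0,
    profile_replicate: int = 1,
) -> SoluteProfile:
    """One O2 microprofile (100 μm default grid) with optional noise."""
    rng = np.random.default_rng(0) if rng is None else rng
    z = _grid(config.grid_o2_um, config.overlying_mm, config.profile_bottom)
    c = o2_shape(z, config.surface_o2, config.true_opd)
    if config.noise_sd_o2 > 0:
        c = c + rng.normal(0.0, config.noise_sd_o2, size=z.size)
    c = np.clip(c, _SENSOR_FLOOR_UM, None)
    return SoluteProfile(
        solute=Solute.O2,
        depths=z,
        values=c,
        resolution_um=config.grid_o2_um,
        core_id=context.core_id,
        treatment=context.treatment,
        timepoint_day=timepoint_day,
        profile_replicate=profile_replicate,
    )


def simulate_sulfide_profiles(
    config: ProfileSimConfig,
    context: CoreContext,
    speciation_params: SpeciationParams,
    rng: np.random.Generator | None = None,
    timepoint_day: int = 0,
    profile_replicate: int = 1,
) -> tuple[SoluteProfile, SoluteProfile, np.ndarray]:
    """Paired H2S-sensor and pH profiles plus the ΣH2S truth array.

    The sensor-level [H2S] is the gas fraction of the ΣH2S truth at the
    noise-free pH, so speciating the noise-free pair returns the truth to
    machine precision.  Returns ``(h2s_profile, ph_profile, truth_total)``
    with the truth on the same (chemical, 250 μm default) grid.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    z = _grid(config.grid_chem_um, config.overlying_mm, config.profile_bottom)
    truth_total = sulfide_shape(z, config.true_horizon, config.deep_sulfide_gradient)
    ph_clean = ph_shape(z, config)
    pk1_value = speciation_params.pk1_value()
    h2s_gas = truth_total / (1.0 + 10.0 ** (ph_clean - pk1_value))

    if config.noise_sd_h2s > 0:
        h2s_gas = h2s_gas + rng.normal(0.0, config.noise_sd_h2s, size=z.size)
    h2s_gas = np.clip(h2s_gas, _SENSOR_FLOOR_UM, None)
    ph = ph_clean
    if config.noise_sd_ph > 0:
        ph = ph + rng.normal(0.0, config.noise_sd_ph, size=z.size)
    ph = np.clip(ph, 0.01, 13.99)

    meta = dict(
        core_id=context.core_id,
        treatment=context.treatment,
        timepoint_day=timepoint_day,
        profile_replicate=profile_replicate,
    )
    h2s_profile = SoluteProfile(
        solute=Solute.H2S, depths=z, values=h2s_gas,
        resolution_um=config.grid_chem_um, **meta,
    )
    ph_profile = SoluteProfile(
        solute=Solute.PH, depths=z, values=ph,
        resolution_um=config.grid_chem_um, **meta,
    )
    return h2s_profile, ph_profile, truth_total


def compute_truth(
    config: ProfileSimConfig,
    context: CoreContext,
    db_fit: BiodiffusivityFit | None,
    timepoint_day: int = 0,
    seed: int | None = None,
) -> SyntheticTruth:
    """Analytic ground-truth fluxes for a simulated core.

    O2: interface gradient of the parabola is −2·C0/L (μM mm⁻¹); ΣH2S: the
    deep linear gradient.  Both converted through J = φ(Ds+Db)·∂C/∂x.
    """
    d_o2 = build_diffusivity(Solute.O2, context, db_fit=db_fit,
                             d_b=None if db_fit is not None else 0.0)
    d_h2s = build_diffusivity(Solute.H2S, context, db_fit=db_fit,
                              d_b=None if db_fit is not None else 0.0)
    slope_o2 = -2.0 * config.surface_o2 / config.true_opd * UM_PER_MM_TO_MMOL_PER_M4
    slope_h2s = config.deep_sulfide_gradient * UM_PER_MM_TO_MMOL_PER_M4
    phi = context.porosity
    return SyntheticTruth(
        core_id=context.core_id,
        treatment=context.treatment,
        timepoint_day=timepoint_day,
        config=config,
        true_opd=config.true_opd,
        true_horizon=config.true_horizon,
        flux_o2=phi * (d_o2.d_s + d_o2.d_b) * slope_o2,
        flux_h2s=phi * (d_h2s.d_s + d_h2s.d_b) * slope_h2s,
        d_b_o2=d_o2.d_b,
        d_b_h2s=d_h2s.d_b,
        seed=seed,
    )


def simulate_core(
    config: ProfileSimConfig,
    context: CoreContext,
    speciation_params: SpeciationParams,
    rng: np.random.Generator,
    db_fit: BiodiffusivityFit | None = None,
    timepoint_day: int = 0,
    replicates: int = 3,
) -> tuple[list[SoluteProfile], SyntheticTruth]:
    """All profiles (3 solutes × replicates) of one core at one time point."""
    profiles: list[SoluteProfile] = []
    for rep in range(1, replicates + 1):
        profiles.append(
            simulate_o2_profile(config, context, rng, timepoint_day, rep)
        )
        h2s, ph, _ = simulate_sulfide_profiles(
            config, context, speciation_params, rng, timepoint_day, rep
        )
        profiles.extend([h2s, ph])
    truth = compute_truth(config, context, db_fit, timepoint_day)
    return profiles, truth


# ---------------------------------------------------------------------------
# full experimental design


@dataclass
class ExperimentDesign:
    """Factorial design of a simulated incubation experiment.

    ``treatment_params`` maps treatment → timepoint day → keyword overrides
    of :class:`ProfileSimConfig` plus the two design-level keys
    ``abundance`` (meiofauna ind. per 10 cm²) and ``sulfide_flux_target``
    (mmol m⁻² d⁻¹; converted to the deep gradient through each core's
    diffusivities).  ``between_core_cv`` applies multiplicative lognormal
    variability to OPD, horizon and flux targets between cores.
    """

    treatments: list[str] = field(default_factory=lambda: ["control", "low", "medium", "high"])
    cores_per_treatment: int = 3
    replicate_profiles: int = 3
    timepoint_days: list[int] = field(default_factory=lambda: [6, 15, 23])
    treatment_params: dict = field(default_factory=dict)
    porosity_range: tuple[float, float] = (0.85, 0.93)
    surface_o2_range: tuple[float, float] = (300.0, 330.0)
    ph_surface_range: tuple[float, float] = (7.6, 7.9)
    temperature_c: float = 8.0
    salinity: float = 7.0
    noise_sd_o2: float = 2.0
    noise_sd_h2s: float = 2.0
    noise_sd_ph: float = 0.02
    between_core_cv: float = 0.05
    db_reference_points: list[tuple[float, float]] | None = None
    db_disabled: bool = False

    def __post_init__(self) -> None:
        if min(self.cores_per_treatment, self.replicate_profiles, len(self.timepoint_days),
               len(self.treatments)) < 1:
            raise ValueError("design counts must all be >= 1")


#: Per-treatment, per-week parameter trajectories patterned on a
#: meiofauna-addition incubation: OPD and sulfide-horizon means and sulfide
#: efflux targets per treatment and time point, with the e-SOx pH maximum
#: appearing early in the high-meiofauna cores and later in control cores.
_DEFAULT_TREATMENT_PARAMS: dict[str, dict[int, dict]] = {
    "control": {
        6: dict(abundance=128, true_opd=0.8, true_horizon=3.8, sulfide_flux_target=8.8,
                ph_deep=7.0),
        15: dict(abundance=128, true_opd=1.4, true_horizon=3.2, sulfide_flux_target=4.5,
                 ph_deep=5.9, esox_peak=(7.7, 0.75)),
        23: dict(abundance=128, true_opd=1.4, true_horizon=4.0, sulfide_flux_target=2.0,
                 ph_deep=5.4, esox_peak=(8.0, 0.75)),
    },
    "low": {
        6: dict(abundance=191, true_opd=1.6, true_horizon=3.9, sulfide_flux_target=2.9,
                ph_deep=7.0),
        15: dict(abundance=191, true_opd=1.6, true_horizon=4.8, sulfide_flux_target=2.0,
                 ph_deep=6.0),
        23: dict(abundance=191, true_opd=1.8, true_horizon=4.4, sulfide_flux_target=2.2,
                 ph_deep=5.4, esox_peak=(8.0, 0.75)),
    },
    "medium": {
        6: dict(abundance=828, true_opd=2.2, true_horizon=3.8, sulfide_flux_target=4.4,
                ph_deep=6.9),
        15: dict(abundance=828, true_opd=1.7, true_horizon=4.5, sulfide_flux_target=2.2,
                 ph_deep=6.1),
        23: dict(abundance=828, true_opd=1.7, true_horizon=4.7, sulfide_flux_target=2.1,
                 ph_deep=5.4),
    },
    "high": {
        6: dict(abundance=2030, true_opd=1.6, true_horizon=6.4, sulfide_flux_target=0.4,
                ph_deep=6.4, esox_peak=(8.3, 0.75)),
        15: dict(abundance=2030, true_opd=2.3, true_horizon=4.8, sulfide_flux_target=1.8,
                 ph_deep=5.4),
        23: dict(abundance=2030, true_opd=2.3, true_horizon=5.4, sulfide_flux_target=1.9,
                 ph_deep=5.4),
    },
}


def default_design(**overrides) -> ExperimentDesign:
    """The default 4 × 3 × 3 × 3 design (→ 324 profiles over 3 solutes)."""
    params = copy.deepcopy(_DEFAULT_TREATMENT_PARAMS)
    return ExperimentDesign(treatment_params=params, **overrides)


def simulate_experiment(
    design: ExperimentDesign | None = None,
    seed: int = 0,
) -> tuple[ExperimentSet, list[SyntheticTruth]]:
    """Simulate a full factorial profile set with per-core ground truths.

    The default design emits one profile per (core × solute × replicate ×
    time point): 4 treatments × 3 cores × 3 solutes × 3 replicates × 3
    weeks = 324 profiles.  Byte-identical output for identical seeds.
    """
    if design is None:
        design = default_design()
    if not design.treatment_params:
        design = ExperimentDesign(**{**asdict(design), "treatment_params":
                                     copy.deepcopy(_DEFAULT_TREATMENT_PARAMS)})
    rng = np.random.default_rng(seed)
    db_fit = None if design.db_disabled else fit_biodiffusivity(design.db_reference_points)

    profiles: list[SoluteProfile] = []
    truths: list[SyntheticTruth] = []
    contexts: dict[str, CoreContext] = {}
    for treatment in design.treatments:
        per_tp = design.treatment_params.get(treatment)
        if per_tp is None:
            raise ValueError(f"no treatment_params for treatment {treatment!r}")
        for core_idx in range(1, design.cores_per_treatment + 1):
            core_id = f"{treatment}-{core_idx}"
            base = per_tp[min(per_tp, key=lambda d: abs(d - design.timepoint_days[0]))]
            abundance = float(base.get("abundance", 0.0))
            context = CoreContext(
                core_id=core_id,
                treatment=treatment,
                porosity=float(rng.uniform(*design.porosity_range)),
                temperature_c=design.temperature_c,
                salinity=design.salinity,
                meiofauna_abundance=abundance
                * float(np.exp(rng.normal(0.0, design.between_core_cv))),
                overlying_o2=float(rng.uniform(*design.surface_o2_range)),
            )
            contexts[core_id] = context
            spec_params = SpeciationParams(design.temperature_c, design.salinity)
            for day in design.timepoint_days:
                if day not in per_tp:
                    raise ValueError(f"treatment {treatment!r} lacks params for day {day}")
                p = dict(per_tp[day])
                p.pop("abundance", None)
                flux_target = p.pop("sulfide_flux_target", None)
                jitter = lambda: float(np.exp(rng.normal(0.0, design.between_core_cv)))
                cfg_kwargs = dict(
                    surface_o2=context.overlying_o2,
                    ph_surface=float(rng.uniform(*design.ph_surface_range)),
                    noise_sd_o2=design.noise_sd_o2,
                    noise_sd_h2s=design.noise_sd_h2s,
                    noise_sd_ph=design.noise_sd_ph,
                )
                cfg_kwargs.update(p)
                cfg_kwargs["true_opd"] = cfg_kwargs["true_opd"] * jitter()
                cfg_kwargs["true_horizon"] = max(
                    cfg_kwargs["true_horizon"] * jitter(), cfg_kwargs["true_opd"] + 0.5
                )
                config = ProfileSimConfig(**cfg_kwargs)
                if flux_target is not None:
                    config.deep_sulfide_gradient = _gradient_for_flux(
                        flux_target * jitter(), context, db_fit
                    )
                core_profiles, truth = simulate_core(
                    config, context, spec_params, rng, db_fit,
                    timepoint_day=day, replicates=design.replicate_profiles,
                )
                profiles.extend(core_profiles)
                truths.append(truth)

    experiment = ExperimentSet(
        profiles=profiles,
        contexts=contexts,
        design=dict(
            treatments=list(design.treatments),
            cores_per_treatment=design.cores_per_treatment,
            replicate_profiles=design.replicate_profiles,
            timepoint_days=list(design.timepoint_days),
            seed=seed,
        ),
    )
    return experiment, truths


def _gradient_for_flux(
    flux_target: float, context: CoreContext, db_fit: BiodiffusivityFit | None
) -> float:
    """Deep ΣH2S gradient (μM mm⁻¹) producing a target upward flux."""
    d = build_diffusivity(Solute.H2S, context, db_fit=db_fit,
                          d_b=None if db_fit is not None else 0.0)
    denom = context.porosity * (d.d_s + d.d_b) * UM_PER_MM_TO_MMOL_PER_M4
    return flux_target / denom


# ---------------------------------------------------------------------------
# fixture-set round trip


def write_experiment(
    experiment: ExperimentSet,
    truths: list[SyntheticTruth],
    outdir: str | Path,
) -> Path:
    """Write a complete self-contained fixture set.

    Emits one profile file per profile (in the dialect ``read_profile``
    reads), a manifest mapping files to metadata, the core contexts, the
    ground-truth table and a design echo.
    """
    outdir = Path(outdir)
    (outdir / "profiles").mkdir(parents=True, exist_ok=True)
    manifest = []
    for p in experiment.profiles:
        name = (
            f"{p.core_id}_{p.solute.value.replace('pH', 'pH')}"
            f"_d{p.timepoint_day}_r{p.profile_replicate}.tsv"
        )
        write_profile(p, outdir / "profiles" / name)
        manifest.append(dict(
            path=f"profiles/{name}", solute=p.solute.value, core_id=p.core_id,
            treatment=p.treatment, timepoint_day=p.timepoint_day,
            profile_replicate=p.profile_replicate, resolution_um=p.resolution_um,
        ))
    pd.DataFrame(manifest).to_csv(outdir / "manifest.csv", index=False)
    pd.DataFrame([vars(c) for c in experiment.contexts.values()]).to_csv(
        outdir / "contexts.csv", index=False
    )
    truth_rows = []
    for t in truths:
        row = dict(
            core_id=t.core_id, treatment=t.treatment, timepoint_day=t.timepoint_day,
            true_opd=t.true_opd, true_horizon=t.true_horizon,
            flux_o2=t.flux_o2, flux_h2s=t.flux_h2s,
            d_b_o2=t.d_b_o2, d_b_h2s=t.d_b_h2s,
        )
        truth_rows.append(row)
    pd.DataFrame(truth_rows).to_csv(outdir / "truth.csv", index=False)
    with open(outdir / "design.yaml", "w") as fh:
        yaml.safe_dump(experiment.design, fh)
    return outdir


def read_experiment(indir: str | Path) -> ExperimentSet:
    """Read a fixture set written by :func:`write_experiment`."""
    from .profiles import read_profile

    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    contexts_df = pd.read_csv(indir / "contexts.csv")
    contexts = {
        row["core_id"]: CoreContext(**row) for row in contexts_df.to_dict("records")
    }
    profiles = [
        read_profile(
            indir / row["path"],
            solute=row["solute"],
            core_id=row["core_id"],
            treatment=row["treatment"],
            timepoint_day=int(row["timepoint_day"]),
            profile_replicate=int(row["profile_replicate"]),
            resolution_um=float(row["resolution_um"]),
        )
        for row in manifest.to_dict("records")
    ]
    design = {}
    design_path = indir / "design.yaml"
    if design_path.exists():
        with open(design_path) as fh:
            design = yaml.safe_load(fh) or {}
    return ExperimentSet(profiles=profiles, contexts=contexts, design=design)
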