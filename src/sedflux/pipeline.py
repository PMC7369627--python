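"""Config-driven end-to-end analysis of a microprofile experiment.

Chains the analysis stages over every core and time point of an
experiment: sulfide speciation from paired H2S/pH profiles, horizon
detection on O2 and ΣH2S, near-interface gradient fits, Fick's-law fluxes
with porosity- and bioturbation-corrected diffusivities, and the
stoichiometric oxygen budget.  Statistics stop at descriptive aggregates
(mean ± standard error across replicate profiles, then across cores);
treatment-level inference is left to general-purpose tools.

Fluxes are computed per profile, then averaged per core, then per
treatment, so a treatment mean summarises cores × replicates individual
profile fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .budget import build_budget
from .fluxes import (
    BiodiffusivityFit,
    build_diffusivity,
    diffusive_flux,
    fit_biodiffusivity,
    fit_gradient,
    o2_fit_window,
    sulfide_fit_window,
)
from .horizons import oxygen_penetration_depth, sulfide_horizon, suboxic_width
from .profiles import ExperimentSet, Solute, write_summary
from .speciation import SpeciationParams, speciate_profile
from .synthetic import ExperimentDesign, default_design, read_experiment, simulate_experiment

__all__ = ["RunConfig", "PipelineResult", "aggregate", "analyze_experiment", "run"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs, loadable from a YAML file.

    ``mode`` is ``"simulate"`` (generate the experiment from ``design``)
    or ``"read"`` (load a profile set from ``input_dir``).  ``min_run`` is
    the persistence rule for horizon detection: None applies the strict
    terminal-run rule (noise-free data); an integer k requires k
    consecutive qualifying points, the robust choice for noisy sensors.
    """

    mode: str = "simulate"
    input_dir: str | None = None
    design: ExperimentDesign | None = None
    temperature_c: float = 8.0
    salinity: float = 7.0
    pk1_override: float | None = None
    db_reference_points: list[tuple[float, float]] | None = None
    db_disabled: bool = False
    o2_window_fraction: float = 0.6
    h2s_window_width: float = 1.0
    o2_threshold: float = 1.0
    h2s_threshold: float = 1.0
    min_run: int | None = 3
    smooth_points: int | None = 5
    h2s_anchor_threshold: float | None = 5.0
    horizon_basis: str = "h2s_sensor"
    flux_convention: str = "as_printed"
    stoichiometry: float = 2.0
    out_dir: str | None = None
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "read"):
            raise ValueError(f"mode must be 'simulate' or 'read', got {self.mode!r}")
        if self.mode == "read" and not self.input_dir:
            raise ValueError("read mode needs input_dir")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        design_raw = raw.pop("design", None)
        cfg = cls(**raw)
        if design_raw is not None:
            tp = design_raw.pop("treatment_params", None)
            if tp is not None:
                # YAML gives string day keys; normalise to int
                design_raw["treatment_params"] = {
                    t: {int(d): v for d, v in days.items()} for t, days in tp.items()
                }
                cfg.design = ExperimentDesign(**design_raw)
            else:
                cfg.design = default_design(**design_raw)
        return cfg

    def speciation_params(self) -> SpeciationParams:
        return SpeciationParams(self.temperature_c, self.salinity, self.pk1_override)

    def db_fit(self) -> BiodiffusivityFit | None:
        if self.db_disabled:
            return None
        return fit_biodiffusivity(self.db_reference_points)


@dataclass
class PipelineResult:
    """Per-profile, per-core and per-treatment result tables plus the log."""

    per_profile: pd.DataFrame
    per_core: pd.DataFrame
    per_treatment: pd.DataFrame
    log: str


def aggregate(values) -> tuple[float | None, float | None, int]:
    """Mean, standard error (sample sd / √n) and n of the finite values.

    Returns ``(None, None, 0)`` for an empty set and ``(mean, None, 1)``
    for a single value (the SE of one observation is undefined, reported
    as absent rather than zero).
    """
    vals = [v for v in values if v is not None and np.isfinite(v)]
    n = len(vals)
    if n == 0:
        return None, None, 0
    mean = float(np.mean(vals))
    if n == 1:
        return mean, None, 1
    se = float(np.std(vals, ddof=1) / math.sqrt(n))
    return mean, se, n


def _analyze_core_timepoint(
    experiment: ExperimentSet,
    core_id: str,
    day: int,
    config: RunConfig,
    db_fit: BiodiffusivityFit | None,
    params: SpeciationParams,
) -> tuple[list[dict], dict]:
    """Per-replicate rows and the core×timepoint aggregate row."""
    ctx = experiment.contexts[core_id]
    o2_reps = {p.profile_replicate: p for p in experiment.select(Solute.O2, core_id, day)}
    h2s_reps = {p.profile_replicate: p for p in experiment.select(Solute.H2S, core_id, day)}
    ph_reps = {p.profile_replicate: p for p in experiment.select(Solute.PH, core_id, day)}

    explicit_db = 0.0 if db_fit is None else None
    d_o2 = build_diffusivity(Solute.O2, ctx, db_fit=db_fit, d_b=explicit_db)
    d_h2s = build_diffusivity(Solute.H2S, ctx, db_fit=db_fit, d_b=explicit_db)

    rows: list[dict] = []
    opds, horizons, fluxes_o2, fluxes_h2s, fractions, widths = [], [], [], [], [], []
    for rep in sorted(set(o2_reps) | set(h2s_reps) | set(ph_reps)):
        row = dict(
            core_id=core_id, treatment=ctx.treatment, timepoint_day=day, replicate=rep,
            opd_mm=np.nan, sulfide_horizon_mm=np.nan, suboxic_width_mm=np.nan,
            flux_o2=np.nan, flux_h2s=np.nan, o2_window="", h2s_window="",
            o2_r2=np.nan, h2s_r2=np.nan, sulfide_fraction_pct=np.nan,
            n_h2s_clipped=0, flags="",
        )
        flags: list[str] = []
        opd = horizon = None
        j_o2 = j_h2s = None

        o2 = o2_reps.get(rep)
        if o2 is None:
            flags.append("missing O2 profile")
        else:
            opd = oxygen_penetration_depth(o2, config.o2_threshold, config.min_run,
                                           config.smooth_points)
            if opd is None:
                flags.append("no O2 penetration limit reached")
            elif opd <= 0:
                flags.append("anoxic surface")
            else:
                row["opd_mm"] = round(opd, 4)
                try:
                    window = o2_fit_window(opd, config.o2_window_fraction)
                    grad = fit_gradient(o2.depths, o2.values, window)
                    fx = diffusive_flux(ctx, d_o2, grad, config.flux_convention)
                    j_o2 = fx.flux
                    row["flux_o2"] = j_o2
                    row["o2_window"] = f"{grad.window[0]:.3f}..{grad.window[1]:.3f}"
                    row["o2_r2"] = grad.r_squared
                    if grad.low_r2:
                        flags.append("low O2 fit r2")
                except ValueError as exc:
                    flags.append(f"O2 gradient fit failed: {exc}")

        h2s, ph = h2s_reps.get(rep), ph_reps.get(rep)
        if h2s is None or ph is None:
            flags.append("missing H2S/pH pair")
        else:
            spec = speciate_profile(h2s, ph, params)
            row["n_h2s_clipped"] = spec.n_clipped
            horizon_profile = h2s if config.horizon_basis == "h2s_sensor" else spec
            horizon = sulfide_horizon(horizon_profile, config.h2s_threshold,
                                      config.min_run, config.smooth_points,
                                      config.h2s_anchor_threshold)
            if horizon is None:
                flags.append("no sulfide detected")
            else:
                row["sulfide_horizon_mm"] = round(horizon, 4)
                if horizon == 0:
                    flags.append("euxinic surface")
                try:
                    window = sulfide_fit_window(horizon, config.h2s_window_width)
                    grad = fit_gradient(spec.depths, spec.total, window)
                    fx = diffusive_flux(ctx, d_h2s, grad, config.flux_convention)
                    j_h2s = fx.flux
                    row["flux_h2s"] = j_h2s
                    row["h2s_window"] = f"{grad.window[0]:.3f}..{grad.window[1]:.3f}"
                    row["h2s_r2"] = grad.r_squared
                    if grad.low_r2:
                        flags.append("low H2S fit r2")
                except ValueError as exc:
                    flags.append(f"H2S gradient fit failed: {exc}")

        width = suboxic_width(opd, horizon)
        if width is not None:
            row["suboxic_width_mm"] = round(width, 4)
            if width < 0:
                flags.append("overlapping oxic and sulfidic zones")

        if j_o2 is not None and j_h2s is not None and j_o2 < 0 and j_h2s >= 0:
            b = build_budget(j_o2, j_h2s, config.stoichiometry)
            row["sulfide_fraction_pct"] = b.sulfide_fraction
            if b.inconsistent:
                flags.append("sulfide fraction > 100%")
            fractions.append(b.sulfide_fraction)
        elif j_o2 is not None and j_h2s is not None:
            flags.append("budget skipped: flux signs outside model")

        row["flags"] = "; ".join(flags)
        rows.append(row)
        opds.append(opd)
        horizons.append(horizon)
        widths.append(width)
        fluxes_o2.append(j_o2)
        fluxes_h2s.append(j_h2s)

    core_row = dict(core_id=core_id, treatment=ctx.treatment, timepoint_day=day,
                    porosity=ctx.porosity, meiofauna_abundance=ctx.meiofauna_abundance,
                    d_b_o2=d_o2.d_b, d_b_h2s=d_h2s.d_b)
    for name, series in [
        ("opd_mm", opds), ("sulfide_horizon_mm", horizons),
        ("suboxic_width_mm", widths), ("flux_o2", fluxes_o2),
        ("flux_h2s", fluxes_h2s), ("sulfide_fraction_pct", fractions),
    ]:
        mean, se, n = aggregate(series)
        core_row[f"{name}_mean"] = np.nan if mean is None else mean
        core_row[f"{name}_se"] = np.nan if se is None else se
        core_row[f"{name}_n"] = n
    return rows, core_row


def analyze_experiment(
    experiment: ExperimentSet, config: RunConfig | None = None
) -> PipelineResult:
    """Run the full analysis chain on an in-memory experiment."""
    config = config or RunConfig()
    params = config.speciation_params()
    db_fit = config.db_fit()

    profile_rows: list[dict] = []
    core_rows: list[dict] = []
    pairs = sorted({(p.core_id, p.timepoint_day) for p in experiment.profiles})
    for core_id, day in pairs:
        rows, core_row = _analyze_core_timepoint(
            experiment, core_id, day, config, db_fit, params
        )
        profile_rows.extend(rows)
        core_rows.append(core_row)

    per_profile = pd.DataFrame(profile_rows)
    per_core = pd.DataFrame(core_rows)

    treat_rows: list[dict] = []
    for (treatment, day), grp in per_core.groupby(["treatment", "timepoint_day"], sort=True):
        row = dict(treatment=treatment, timepoint_day=day, n_cores=len(grp))
        for name in ["opd_mm", "sulfide_horizon_mm", "suboxic_width_mm",
                     "flux_o2", "flux_h2s", "sulfide_fraction_pct"]:
            mean, se, n = aggregate(grp[f"{name}_mean"].tolist())
            row[f"{name}_mean"] = np.nan if mean is None else mean
            row[f"{name}_se"] = np.nan if se is None else se
            row[f"{name}_n"] = n
        treat_rows.append(row)
    per_treatment = pd.DataFrame(treat_rows)

    log = _provenance_log(config, params, db_fit, experiment)
    return PipelineResult(per_profile, per_core, per_treatment, log)


def _provenance_log(config, params, db_fit, experiment) -> str:
    lines = [
        f"sedflux {_version} pipeline run",
        f"profiles analysed: {len(experiment)}",
        f"speciation: pK1 = {params.pk1_value():.4f} ({params.source()}) "
        f"at T = {params.temperature_c} °C, S = {params.salinity}",
        f"horizon detection: thresholds O2 < {config.o2_threshold} μM, "
        f"sulfide > {config.h2s_threshold} μM on "
        + ("the raw [H2S] sensor signal" if config.horizon_basis == "h2s_sensor"
           else "the speciated ΣH2S profile")
        + ", persistence = "
        + ("terminal run" if config.min_run is None else f"{config.min_run} consecutive points")
        + ("" if not config.smooth_points or config.smooth_points <= 1
           else f", {config.smooth_points}-point moving average"),
        f"fit windows: O2 interface..{config.o2_window_fraction:.0%} of OPD; "
        f"ΣH2S horizon..horizon+{config.h2s_window_width} mm",
        f"flux convention: {config.flux_convention} (J = phi (Ds+Db) dC/dx)",
        f"stoichiometry: {config.stoichiometry} mol O2 per mol S",
    ]
    if db_fit is None:
        lines.append("biodiffusivity: disabled (Db = 0, pure molecular diffusion)")
    else:
        lines.append(
            f"biodiffusivity: Db = {db_fit.intercept:.3e} + {db_fit.slope:.3e} × abundance "
            f"(r² = {db_fit.r_squared:.3f}) from {len(db_fit.reference_points)} reference points"
        )
    return "\n".join(lines)


def run(config: RunConfig) -> PipelineResult:
    """Read or simulate an experiment, analyse it, and write outputs.

    In simulate mode the generated experiment (and its ground truth) is
    also written into ``out_dir`` so the run is fully reproducible from
    the file set alone.
    """
    if config.mode == "simulate":
        design = config.design or default_design()
        experiment, truths = simulate_experiment(design, seed=config.seed)
    else:
        experiment = read_experiment(config.input_dir)
        truths = None

    result = analyze_experiment(experiment, config)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_summary(result.per_profile, out / "profiles.csv")
        write_summary(result.per_core, out / "cores.csv")
        write_summary(result.per_treatment, out / "treatments.csv")
        (out / "run_log.txt").write_text(result.log + "\n")
        if config.mode == "simulate" and truths is not None:
            from .synthetic import write_experiment

            write_experiment(experiment, truths, out / "simulated_input")
    return result
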