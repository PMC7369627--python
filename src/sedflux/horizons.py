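"""Detection of redox horizons in porewater microprofiles.

Two depths partition a profile into the classic three-layer geometry of a
sulfidic sediment:

* the **oxygen penetration depth** (OPD): the shallowest depth below which
  O2 stays steadily under a detection threshold (1 μM by default);
* the **sulfide horizon**: the shallowest depth below which dissolved
  sulfide is steadily detectable (> 1 μM).

"Steadily" is operationalised as the *terminal-run* rule: every measured
point at or below the detected depth must be on the sub-(supra-)threshold
side, so a single noisy dip followed by recovery does not set the horizon.
A minimum-run-length alternative (``min_run=k``: the first run of at least
k consecutive qualifying points) is provided for noisy profiles, where the
terminal-run rule becomes overly strict.  The crossing is refined below
grid resolution by linear interpolation between the last point on the wrong
side and the first point of the qualifying run.

The sediment volume free of sulfide per unit area equals the sulfide
horizon depth, so relative changes in "oxidized sediment volume" between
treatments reduce to relative changes of the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np

__all__ = [
    "HorizonResult",
    "moving_average",
    "oxygen_penetration_depth",
    "sulfide_horizon",
    "oxidized_volume_increase",
    "suboxic_width",
    "detect_horizons",
]


class _ProfileLike(Protocol):
    depths: np.ndarray
    values: np.ndarray


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges.

    Standard pre-filter for threshold detection on noisy microsensor
    traces; ``window`` is the full width in points (use odd values).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return np.asarray(values, dtype=float)
    v = np.asarray(values, dtype=float)
    half = window // 2
    c = np.concatenate([[0.0], np.cumsum(v)])
    n = v.size
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    return (c[hi] - c[lo]) / (hi - lo)


def _first_qualifying_depth(
    depths: np.ndarray,
    values: np.ndarray,
    threshold: float,
    below: bool,
    min_run: int | None,
    smooth_points: int | None = None,
) -> float | None:
    """Shallowest depth from which readings stay on the qualifying side.

    ``below=True`` detects a terminal run of values < threshold (OPD);
    ``below=False`` one of values > threshold (sulfide horizon).  Only
    depths >= 0 (in the sediment) are considered.  Returns None when no
    qualifying run reaches the bottom of the profile (or, with ``min_run``,
    when no run of the required length exists).
    """
    mask = depths >= 0.0
    if not np.any(mask):
        raise ValueError("profile has no points at or below the interface")
    d = depths[mask]
    v = values[mask]
    if smooth_points is not None and smooth_points > 1:
        v = moving_average(v, smooth_points)
    ok = (v < threshold) if below else (v > threshold)

    if min_run is None:
        if not ok[-1]:
            return None  # profile bottom is on the wrong side: never settles
        # start of the terminal qualifying run
        bad = np.nonzero(~ok)[0]
        start = 0 if bad.size == 0 else int(bad[-1]) + 1
    else:
        if min_run < 1:
            raise ValueError("min_run must be >= 1")
        start = None
        run = 0
        for i, flag in enumerate(ok):
            run = run + 1 if flag else 0
            if run == min_run:
                start = i - min_run + 1
                break
        if start is None:
            return None

    if start == 0:
        return 0.0
    # linear interpolation at the threshold crossing
    d0, v0 = d[start - 1], v[start - 1]
    d1, v1 = d[start], v[start]
    if v1 == v0:
        return float(d1)
    x = d0 + (threshold - v0) * (d1 - d0) / (v1 - v0)
    return float(np.clip(x, d0, d1))


def oxygen_penetration_depth(
    o2_profile: _ProfileLike,
    threshold: float = 1.0,
    min_run: int | None = None,
    smooth_points: int | None = None,
) -> float | None:
    """Depth (mm) where O2 becomes steadily < ``threshold`` μM, or None.

    None means oxygen persists above the threshold to the bottom of the
    profile ("no penetration limit reached").  An entirely sub-threshold
    profile gives OPD = 0 (anoxic surface).
    """
    return _first_qualifying_depth(
        np.asarray(o2_profile.depths, dtype=float),
        np.asarray(o2_profile.values, dtype=float),
        threshold,
        below=True,
        min_run=min_run,
        smooth_points=smooth_points,
    )


def sulfide_horizon(
    sulfide_profile: _ProfileLike,
    threshold: float = 1.0,
    min_run: int | None = None,
    smooth_points: int | None = None,
    anchor_threshold: float | None = None,
) -> float | None:
    """Depth (mm) where sulfide becomes steadily > ``threshold`` μM, or None.

    Accepts a raw [H2S] sensor profile or a speciated ΣH2S profile (the
    latter is the default basis for reported horizons, since downstream
    zone geometry is discussed on total sulfide).  Horizon 0 means free
    sulfide already at the interface (euxinic surface).

    ``anchor_threshold`` switches to the two-stage detector for noisy
    sensors: first locate an unambiguous strong-signal depth (readings
    steadily above ``anchor_threshold``), then report the shallow end of
    the contiguous super-``threshold`` run containing it.  Isolated noise
    excursions above ``threshold`` that are not connected to the strong
    signal can then no longer fake a horizon.
    """
    depths = np.asarray(sulfide_profile.depths, dtype=float)
    values = np.asarray(sulfide_profile.values, dtype=float)
    if anchor_threshold is None:
        return _first_qualifying_depth(
            depths, values, threshold, below=False,
            min_run=min_run, smooth_points=smooth_points,
        )
    if anchor_threshold <= threshold:
        raise ValueError("anchor_threshold must exceed threshold")

    mask = depths >= 0.0
    if not np.any(mask):
        raise ValueError("profile has no points at or below the interface")
    d = depths[mask]
    v = values[mask]
    # smoothing is used only to place the anchor robustly; the walk-up and
    # crossing interpolation stay on the unsmoothed readings, since a moving
    # average smears the onset ramp upward by half the filter width
    v_sm = moving_average(v, smooth_points) if smooth_points and smooth_points > 1 else v
    anchor = _first_qualifying_depth(d, v_sm, anchor_threshold, below=False, min_run=min_run)
    if anchor is None:
        return None
    i = int(np.searchsorted(d, anchor))
    start = i
    while start > 0 and v[start - 1] > threshold:
        start -= 1
    if start == 0:
        return 0.0
    d0, v0, d1, v1 = d[start - 1], v[start - 1], d[start], v[start]
    if v1 == v0:
        return float(d1)
    return float(np.clip(d0 + (threshold - v0) * (d1 - d0) / (v1 - v0), d0, d1))


def oxidized_volume_increase(horizon_treatment: float, horizon_control: float) -> float:
    """Percent change in oxidized (sulfide-free) sediment volume.

    The oxidized volume per unit area equals the sulfide horizon depth, so
    this is ``100 · (treatment − control) / control``.
    """
    if horizon_control <= 0:
        raise ValueError("control horizon must be > 0 for a relative change")
    if horizon_treatment <= 0:
        raise ValueError("treatment horizon must be > 0")
    return 100.0 * (horizon_treatment - horizon_control) / horizon_control


def suboxic_width(opd: float | None, horizon: float | None) -> float | None:
    """Width (mm) of the suboxic separation zone between OPD and horizon.

    Negative widths (overlapping oxic and sulfidic zones) are returned
    as-is; callers flag them.  Absent inputs give None.
    """
    if opd is None or horizon is None:
        return None
    return horizon - opd


@dataclass
class HorizonResult:
    """Zone geometry of one core profile pair."""

    opd: float | None
    sulfide_horizon: float | None
    suboxic_width: float | None
    threshold_o2: float = 1.0
    threshold_h2s: float = 1.0
    persistence_rule: str = "terminal run"
    overlapping_zones: bool = False
    euxinic_surface: bool = False
    no_penetration_limit: bool = False


def detect_horizons(
    o2_profile: _ProfileLike | None,
    sulfide_profile: _ProfileLike | None,
    threshold_o2: float = 1.0,
    threshold_h2s: float = 1.0,
    min_run: int | None = None,
    smooth_points: int | None = None,
) -> HorizonResult:
    """Detect OPD and sulfide horizon and assemble the zone geometry."""
    opd = (
        oxygen_penetration_depth(o2_profile, threshold_o2, min_run, smooth_points)
        if o2_profile is not None
        else None
    )
    hor = (
        sulfide_horizon(sulfide_profile, threshold_h2s, min_run, smooth_points)
        if sulfide_profile is not None
        else None
    )
    width = suboxic_width(opd, hor)
    return HorizonResult(
        opd=opd,
        sulfide_horizon=hor,
        suboxic_width=width,
        threshold_o2=threshold_o2,
        threshold_h2s=threshold_h2s,
        persistence_rule="terminal run" if min_run is None else f"min run {min_run}",
        overlapping_zones=width is not None and width < 0,
        euxinic_surface=hor == 0.0,
        no_penetration_limit=o2_profile is not None and opd is None,
    )
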