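"""Data model and I/O for depth-resolved microsensor profiles.

Depth convention used throughout the package: millimetres, zero at the
sediment--water interface, positive downward.  Negative depths are readings
taken in the overlying water.  The interface position is taken from the
operator's recorded zero, never re-detected from profile shape.

Profile files are two-column delimited text (depth, reading) with optional
comment and header lines -- the dialect vendor sensor-suite exports reduce
to once dumped as text.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Solute",
    "SoluteProfile",
    "CoreContext",
    "ExperimentSet",
    "ProfileParseError",
    "read_profile",
    "write_profile",
    "align_to_grid",
    "write_summary",
    "read_summary",
    "load_taxon_table",
    "check_taxon_totals",
]

#: μM tolerance for small negative O2/H2S readings (sensor noise around zero).
NEGATIVE_READING_TOLERANCE = 5.0


class Solute(str, enum.Enum):
    """Solutes measured by the microsensor array."""

    O2 = "O2"
    H2S = "H2S"
    PH = "pH"


class ProfileParseError(ValueError):
    """Raised when a profile file cannot be parsed into a valid profile."""


@dataclass
class SoluteProfile:
    """One depth-ordered series of sensor readings for one solute.

    Parameters
    ----------
    solute
        Which sensor the readings come from.
    depths
        Depth coordinates in mm (0 at the interface, positive downward,
        strictly increasing; negative = overlying water).
    values
        Readings: μM for O2 and H2S, pH units for pH.
    resolution_um
        Nominal vertical step of the sensor in μm (100 for O2, 250 for
        pH/H2S in the motivating experimental design).
    """

    solute: Solute
    depths: np.ndarray
    values: np.ndarray
    resolution_um: float
    core_id: str = ""
    treatment: str = ""
    timepoint_day: int = 0
    profile_replicate: int = 1

    def __post_init__(self) -> None:
        self.solute = Solute(self.solute)
        self.depths = np.asarray(self.depths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.depths.ndim != 1 or self.values.ndim != 1:
            raise ValueError("depths and values must be one-dimensional")
        if self.depths.size != self.values.size:
            raise ValueError("depths and values must have equal length")
        if self.depths.size < 3:
            raise ValueError("a profile needs at least 3 points")
        if not np.all(np.isfinite(self.depths)) or not np.all(np.isfinite(self.values)):
            raise ValueError("depths and values must be finite")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")
        if self.solute is Solute.PH:
            if np.any((self.values <= 0) | (self.values >= 14)):
                raise ValueError("pH readings must lie in (0, 14)")
        else:
            if np.any(self.values < -NEGATIVE_READING_TOLERANCE):
                raise ValueError(
                    f"{self.solute.value} readings below "
                    f"-{NEGATIVE_READING_TOLERANCE} μM: not plausible sensor noise"
                )
        if self.resolution_um <= 0:
            raise ValueError("resolution_um must be positive")

    @property
    def n_points(self) -> int:
        return int(self.depths.size)

    def key(self) -> tuple:
        """Grouping key (core, solute, timepoint, replicate)."""
        return (self.core_id, self.solute.value, self.timepoint_day, self.profile_replicate)


@dataclass
class CoreContext:
    """Per-core environmental metadata entering the flux calculation.

    ``meiofauna_abundance`` is in individuals per 10 cm² (ind. 10⁻³ m⁻²),
    the unit used for benthic meiofauna counts.
    """

    core_id: str
    treatment: str
    porosity: float
    temperature_c: float
    salinity: float
    meiofauna_abundance: float
    overlying_o2: float = 280.0

    def __post_init__(self) -> None:
        if not 0.0 < self.porosity < 1.0:
            raise ValueError(f"porosity must be in (0, 1), got {self.porosity}")
        if self.meiofauna_abundance < 0:
            raise ValueError("meiofauna abundance must be >= 0")
        if not -2.0 < self.temperature_c < 40.0:
            raise ValueError("temperature outside (-2, 40) °C")


@dataclass
class ExperimentSet:
    """A collection of profiles plus the per-core contexts they belong to."""

    profiles: list[SoluteProfile]
    contexts: dict[str, CoreContext]
    design: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in self.profiles:
            if p.core_id not in self.contexts:
                raise ValueError(f"profile core {p.core_id!r} has no CoreContext")
        # replicate profiles of one (core, solute, timepoint) share a resolution
        res: dict[tuple, float] = {}
        for p in self.profiles:
            k = (p.core_id, p.solute.value, p.timepoint_day)
            if k in res and res[k] != p.resolution_um:
                raise ValueError(f"replicate profiles of {k} mix resolutions")
            res[k] = p.resolution_um

    def __len__(self) -> int:
        return len(self.profiles)

    def select(
        self,
        solute: Solute | str | None = None,
        core_id: str | None = None,
        timepoint_day: int | None = None,
        profile_replicate: int | None = None,
    ) -> list[SoluteProfile]:
        out = self.profiles
        if solute is not None:
            solute = Solute(solute)
            out = [p for p in out if p.solute is solute]
        if core_id is not None:
            out = [p for p in out if p.core_id == core_id]
        if timepoint_day is not None:
            out = [p for p in out if p.timepoint_day == timepoint_day]
        if profile_replicate is not None:
            out = [p for p in out if p.profile_replicate == profile_replicate]
        return out

    def timepoints(self) -> list[int]:
        return sorted({p.timepoint_day for p in self.profiles})


def read_profile(
    path: str | Path,
    *,
    solute: Solute | str,
    core_id: str = "",
    treatment: str = "",
    timepoint_day: int = 0,
    profile_replicate: int = 1,
    resolution_um: float | None = None,
    depth_unit: str = "mm",
    delimiter: str | None = None,
    comment_prefix: str = "#",
) -> SoluteProfile:
    """Read a two-column (depth, reading) text file into a profile.

    ``depth_unit`` declares the unit of the file's depth column ('mm' or
    'um'); depths are normalised to mm.  Rows are sorted by depth and exact
    duplicate depths are collapsed by averaging their readings (repeated
    readings at one position are common in sensor logs).  A single header
    line of non-numeric tokens is tolerated; any other unparseable row is a
    hard error naming the line.
    """
    if depth_unit not in ("mm", "um", "µm", "μm"):
        raise ValueError(f"depth_unit must be 'mm' or 'um', got {depth_unit!r}")
    scale = 1.0 if depth_unit == "mm" else 1e-3

    path = Path(path)
    depths: list[float] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(comment_prefix):
                continue
            tokens = line.split(delimiter) if delimiter else line.split()
            tokens = [t for t in tokens if t]
            if len(tokens) < 2:
                raise ProfileParseError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                d, v = float(tokens[0]), float(tokens[1])
            except ValueError:
                if lineno == 1 or (not depths and lineno <= 2):
                    continue  # header line
                raise ProfileParseError(f"{path}:{lineno}: unparseable row {line!r}") from None
            depths.append(d * scale)
            values.append(v)

    if len(depths) < 3:
        raise ProfileParseError(f"{path}: fewer than 3 usable data points")

    d = np.asarray(depths)
    v = np.asarray(values)
    order = np.argsort(d, kind="stable")
    d, v = d[order], v[order]
    uniq, inverse, counts = np.unique(d, return_inverse=True, return_counts=True)
    if np.any(counts > 1):
        sums = np.zeros_like(uniq)
        np.add.at(sums, inverse, v)
        v = sums / counts
        d = uniq
    if np.any(np.diff(d) <= 0):  # pragma: no cover - unique() guarantees this
        raise ProfileParseError(f"{path}: non-monotonic depths after sorting")

    if resolution_um is None:
        resolution_um = float(np.median(np.diff(d)) * 1000)
    return SoluteProfile(
        solute=Solute(solute),
        depths=d,
        values=v,
        resolution_um=resolution_um,
        core_id=core_id,
        treatment=treatment,
        timepoint_day=timepoint_day,
        profile_replicate=profile_replicate,
    )


def write_profile(profile: SoluteProfile, path: str | Path, depth_unit: str = "mm") -> None:
    """Write a profile in the exact dialect :func:`read_profile` reads."""
    scale = 1.0 if depth_unit == "mm" else 1e3
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# solute={profile.solute.value} core={profile.core_id} "
                 f"treatment={profile.treatment} day={profile.timepoint_day} "
                 f"replicate={profile.profile_replicate}\n")
        fh.write(f"# depth_unit={depth_unit}\n")
        for d, v in zip(profile.depths, profile.values):
            # shortest round-trip representation: reading back is lossless
            fh.write(f"{float(d * scale)!r}\t{float(v)!r}\n")


def align_to_grid(
    profile_a: SoluteProfile, profile_b: SoluteProfile
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolate ``profile_b`` onto ``profile_a``'s depth grid.

    Needed because pH/H2S share a 250 μm grid while O2 uses 100 μm, and
    real grids may be offset.  Linear interpolation; depths of ``a`` outside
    ``b``'s range are dropped from the pairing.

    Returns ``(depths, a_values, b_values)`` on the common sub-grid.
    """
    lo = max(profile_a.depths[0], profile_b.depths[0])
    hi = min(profile_a.depths[-1], profile_b.depths[-1])
    if lo > hi:
        raise ValueError(
            f"profiles do not overlap in depth "
            f"([{profile_a.depths[0]}, {profile_a.depths[-1]}] vs "
            f"[{profile_b.depths[0]}, {profile_b.depths[-1]}] mm)"
        )
    mask = (profile_a.depths >= lo) & (profile_a.depths <= hi)
    depths = profile_a.depths[mask]
    b_interp = np.interp(depths, profile_b.depths, profile_b.values)
    return depths, profile_a.values[mask], b_interp


def write_summary(results: pd.DataFrame | Iterable[Mapping], path: str | Path) -> None:
    """Write a result table (one row per core × timepoint) as CSV."""
    df = results if isinstance(results, pd.DataFrame) else pd.DataFrame(list(results))
    df.to_csv(path, index=False)


def read_summary(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# experiment metadata tables

_TAXON_TABLE = Path(__file__).parent / "data" / "meiofauna_taxa.csv"


def load_taxon_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the per-taxon meiofauna abundance table (ind. per 10 cm²).

    The packaged default holds the treatment-average abundances of the six
    meiofaunal taxa plus the printed per-treatment totals of the motivating
    experiment (control, low, medium, high meiofauna additions).
    """
    df = pd.read_csv(_TAXON_TABLE if path is None else path)
    return df.set_index("taxon")


def check_taxon_totals(
    table: pd.DataFrame, total_row: str = "Total"
) -> dict[str, dict[str, float]]:
    """Check that per-taxon abundances sum to the table's printed totals.

    For each treatment column returns the recomputed sum of the taxon rows,
    the printed total, and their difference -- a consistency audit of a
    metadata table whose totals were typed alongside rounded per-taxon
    means.
    """
    if total_row not in table.index:
        raise ValueError(f"no {total_row!r} row in table")
    taxa = table.drop(index=total_row)
    out: dict[str, dict[str, float]] = {}
    for col in table.columns:
        s = float(taxa[col].sum())
        printed = float(table.loc[total_row, col])
        out[col] = {"sum": s, "printed": printed, "difference": s - printed}
    return out
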