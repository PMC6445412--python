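"""Domain types, coordinate conventions, map algebra and file I/O.

Coordinate frame
----------------
All analysis maps live in the RETINAL frame of a right eye (OD):

* ``+x`` = nasal retina, ``+y`` = superior retina;
* a map is a 400 x 400 matrix sampled at 0.1 deg/pixel over a 40 x 40 deg
  patch centred on the fovea;
* the centre of pixel ``(row r, col c)`` is at
  ``(x, y) = ((c - 199.5) * 0.1, (199.5 - r) * 0.1)`` degrees, so row 0 is
  the superior edge and column 399 the nasal edge.

Scene (environment) maps are recorded in VISUAL_FIELD coordinates and must
be flipped (upside down and left-right) into the retinal frame before any
map algebra, mirroring the optical inversion of the retinal image.

Sign convention: positive combined-defocus values denote relatively myopic
defocus (focal plane in front of the retina).  This convention is written
into every map sidecar.

Meridian scans
--------------
Peripheral refraction is sampled along 5 horizontal parallels (elevations
-20, -10, 0, +10, +20 deg) with 81 azimuth samples spanning +/-40 deg, a
nominal 4 repeated scans per point, and only the spherical equivalent M
(dioptres) carried per sample.  Scan *tables on disk* use the instrument's
visual-field convention (azimuth positive toward the nasal visual field,
elevation positive upward in the visual field); the reader negates both
angles so that in-memory grids are retinal (nasal retina / superior retina
positive).  Both grids are symmetric, so the conversion is a relabelling.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MAP_SHAPE",
    "PIXEL_PITCH_DEG",
    "EXTENT_DEG",
    "ELEVATIONS_DEG",
    "AZIMUTHS_DEG",
    "Frame",
    "Semantics",
    "Condition",
    "ProfileLabel",
    "Ring",
    "Quadrant",
    "RegionKey",
    "Scene",
    "Optic",
    "ConditionKey",
    "FieldMap",
    "MeridianScanSet",
    "AveragedMeridianSet",
    "ProfileClass",
    "FrameError",
    "MapFormatError",
    "GridMismatchError",
    "pixel_coordinates",
    "flip_to_retinal",
    "add_maps",
    "blank_map",
    "read_map",
    "write_map",
    "read_scan_table",
    "write_scan_table",
]

MAP_SHAPE = (400, 400)
PIXEL_PITCH_DEG = 0.1
EXTENT_DEG = 20.0

ELEVATIONS_DEG = np.array([-20.0, -10.0, 0.0, 10.0, 20.0])
AZIMUTHS_DEG = np.linspace(-40.0, 40.0, 81)


class Frame(str, enum.Enum):
    VISUAL_FIELD = "VISUAL_FIELD"
    RETINAL = "RETINAL"


class Semantics(str, enum.Enum):
    ENV_DEFOCUS = "ENV_DEFOCUS"
    EYE_POWER = "EYE_POWER"
    LENS_POWER = "LENS_POWER"
    COMBINED_DEFOCUS = "COMBINED_DEFOCUS"
    BLANK = "BLANK"


class Condition(str, enum.Enum):
    """Measurement condition of a meridian scan set."""

    NAKED = "NAKED"
    ON_LENS_NEAR_CENTRE = "ON_LENS_NEAR_CENTRE"
    ON_LENS_DISTANCE_CENTRE = "ON_LENS_DISTANCE_CENTRE"


class ProfileLabel(str, enum.Enum):
    """Peripheral-refraction profile type of the equatorial meridian.

    NPS / TPS: the nasal / temporal edge of the profile is relatively more
    hyperopic (positive) than both the centre and the opposite edge.
    RPM / RPH: both edges are more myopic / more hyperopic than the centre.
    """

    NPS = "NPS"
    RPM = "RPM"
    RPH = "RPH"
    TPS = "TPS"
    INDETERMINATE = "INDETERMINATE"


class Ring(str, enum.Enum):
    R0_5 = "R0_5"
    R5_10 = "R5_10"
    R10_15 = "R10_15"
    R15_20 = "R15_20"

    @property
    def bounds(self) -> tuple[float, float]:
        lo = 5.0 * list(Ring).index(self)
        return lo, lo + 5.0


class Quadrant(str, enum.Enum):
    SUPERIOR = "SUPERIOR"
    INFERIOR = "INFERIOR"
    NASAL = "NASAL"
    TEMPORAL = "TEMPORAL"


class RegionKey(NamedTuple):
    ring: Ring
    quadrant: Quadrant


class Scene(str, enum.Enum):
    OFFICE = "OFFICE"
    CORRIDOR = "CORRIDOR"
    LIVING_ROOM = "LIVING_ROOM"


class Optic(str, enum.Enum):
    NAKED = "NAKED"
    NEAR_CENTRE = "NEAR_CENTRE"
    DISTANCE_CENTRE = "DISTANCE_CENTRE"


class ConditionKey(NamedTuple):
    """One of the 3 scenes x 3 optics x 4 profile classes = 36 conditions."""

    scene: Scene
    optic: Optic
    profile: ProfileLabel


class FrameError(ValueError):
    """Raised when a map is in the wrong coordinate frame for an operation."""


class MapFormatError(ValueError):
    """Raised on malformed map files or metadata."""


class GridMismatchError(ValueError):
    """Raised when two gridded objects do not share the same sampling."""


def pixel_coordinates() -> tuple[np.ndarray, np.ndarray]:
    """Return ``(X, Y)`` pixel-centre coordinate grids in degrees.

    ``X[r, c]`` / ``Y[r, c]`` are the retinal coordinates of pixel
    ``(r, c)``; x increases with column (nasal), y decreases with row
    (superior at the top).
    """
    c = np.arange(MAP_SHAPE[1])
    r = np.arange(MAP_SHAPE[0])
    x = (c - 199.5) * PIXEL_PITCH_DEG
    y = (199.5 - r) * PIXEL_PITCH_DEG
    return np.meshgrid(x, y)


@dataclass(frozen=True)
class FieldMap:
    """A 400 x 400 dioptric map over the central 40 x 40 deg.

    Attributes
    ----------
    values : ndarray, shape (400, 400)
        Dioptres at every 0.1 deg.
    frame : Frame
        VISUAL_FIELD (as recorded by a scene camera) or RETINAL.
    semantics : Semantics
        What the dioptres mean (scene defocus, eye power, lens power, ...).
    """

    values: np.ndarray
    frame: Frame
    semantics: Semantics
    eye: str = "OD"
    pixel_pitch: float = PIXEL_PITCH_DEG
    extent: float = EXTENT_DEG

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != MAP_SHAPE:
            raise MapFormatError(
                f"map must be {MAP_SHAPE[0]}x{MAP_SHAPE[1]}, got {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise MapFormatError("map contains non-finite values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "frame", Frame(self.frame))
        object.__setattr__(self, "semantics", Semantics(self.semantics))

    def with_values(self, values: np.ndarray, semantics: Semantics | None = None) -> "FieldMap":
        return replace(
            self, values=values, semantics=self.semantics if semantics is None else semantics
        )


def flip_values(values: np.ndarray) -> np.ndarray:
    """Flip a matrix upside down and left-right (an involution)."""
    return np.asarray(values)[::-1, ::-1].copy()


def flip_to_retinal(fmap: FieldMap) -> FieldMap:
    """Flip a visual-field map into the retinal frame.

    The retinal image is inverted: the upper visual field lands on the
    inferior retina and the nasal visual field on the temporal retina, so
    the matrix is flipped upside down and left-right.  Maps already in the
    retinal frame are rejected to guard against double flips.
    """
    if fmap.frame is not Frame.VISUAL_FIELD:
        raise FrameError("map is already in the RETINAL frame; refusing to flip twice")
    return replace(fmap, values=flip_values(fmap.values), frame=Frame.RETINAL)


def add_maps(maps: Sequence[FieldMap], semantics: Semantics = Semantics.COMBINED_DEFOCUS) -> FieldMap:
    """Element-wise sum of maps sharing frame, pitch and extent."""
    maps = list(maps)
    if not maps:
        raise ValueError("add_maps requires at least one map")
    first = maps[0]
    for m in maps[1:]:
        if m.frame is not first.frame:
            raise FrameError(f"frame mismatch: {m.frame} vs {first.frame}")
        if m.values.shape != first.values.shape:
            raise GridMismatchError("shape mismatch between maps")
        if (m.pixel_pitch, m.extent) != (first.pixel_pitch, first.extent):
            raise GridMismatchError("pixel pitch / extent mismatch between maps")
    total = np.sum([m.values for m in maps], axis=0)
    return replace(first, values=total, semantics=semantics)


def blank_map() -> FieldMap:
    """All-zero retinal map, standing in for 'no lens' in the naked-eye case."""
    return FieldMap(np.zeros(MAP_SHAPE), Frame.RETINAL, Semantics.BLANK)


# ---------------------------------------------------------------------------
# Map file format: plain-text CSV matrix + JSON sidecar (<path>.meta.json)

_SIGN_NOTE = "positive = relatively myopic defocus (focal plane in front of the retina)"


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_map(fmap: FieldMap, path: str | Path) -> None:
    """Write a map as a CSV matrix plus a ``<name>.meta.json`` sidecar."""
    path = Path(path)
    np.savetxt(path, fmap.values, delimiter=",", fmt="%.17g")
    meta = {
        "frame": fmap.frame.value,
        "semantics": fmap.semantics.value,
        "eye": fmap.eye,
        "pixel_pitch_deg": fmap.pixel_pitch,
        "extent_deg": fmap.extent,
        "sign_convention": _SIGN_NOTE,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_map(path: str | Path) -> FieldMap:
    """Read a map written by :func:`write_map`; round-trips to < 1e-9 D."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MapFormatError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("frame", "semantics", "pixel_pitch_deg", "extent_deg"):
        if key not in meta:
            raise MapFormatError(f"metadata sidecar missing '{key}'")
    values = np.loadtxt(path, delimiter=",", ndmin=2)
    if values.shape != MAP_SHAPE:
        raise MapFormatError(
            f"expected a {MAP_SHAPE[0]}x{MAP_SHAPE[1]} matrix, got {values.shape}"
        )
    return FieldMap(
        values,
        Frame(meta["frame"]),
        Semantics(meta["semantics"]),
        eye=meta.get("eye", "OD"),
        pixel_pitch=float(meta["pixel_pitch_deg"]),
        extent=float(meta["extent_deg"]),
    )


# ---------------------------------------------------------------------------
# Meridian scan containers

def _check_grid(elevations: np.ndarray, azimuths: np.ndarray) -> None:
    if elevations.shape != ELEVATIONS_DEG.shape or not np.allclose(elevations, ELEVATIONS_DEG):
        raise GridMismatchError(
            "expected the 5 standard parallels at -20, -10, 0, +10, +20 deg"
        )
    if azimuths.shape != AZIMUTHS_DEG.shape or not np.allclose(azimuths, AZIMUTHS_DEG):
        raise GridMismatchError("expected 81 azimuth samples spanning -40..+40 deg")


@dataclass(frozen=True)
class MeridianScanSet:
    """Repeated spherical-equivalent scans along the 5 standard parallels.

    ``scans[i, j, s]`` is the M value (dioptres) of repeat ``s`` at
    elevation ``elevations[i]`` and azimuth ``azimuths[j]``, in retinal
    coordinates (nasal retina / superior retina positive).
    """

    scans: np.ndarray  # (5, 81, n_scans)
    condition: Condition
    elevations: np.ndarray = field(default_factory=lambda: ELEVATIONS_DEG.copy())
    azimuths: np.ndarray = field(default_factory=lambda: AZIMUTHS_DEG.copy())

    def __post_init__(self) -> None:
        scans = np.asarray(self.scans, dtype=float)
        elevations = np.asarray(self.elevations, dtype=float)
        azimuths = np.asarray(self.azimuths, dtype=float)
        _check_grid(elevations, azimuths)
        if scans.ndim != 3 or scans.shape[:2] != (len(elevations), len(azimuths)):
            raise GridMismatchError(
                f"scans must have shape (5, 81, n_scans), got {scans.shape}"
            )
        if scans.shape[2] < 2:
            raise ValueError("at least 2 repeated scans are required per point")
        object.__setattr__(self, "scans", scans)
        object.__setattr__(self, "elevations", elevations)
        object.__setattr__(self, "azimuths", azimuths)
        object.__setattr__(self, "condition", Condition(self.condition))

    @property
    def n_scans(self) -> int:
        return self.scans.shape[2]


@dataclass(frozen=True)
class AveragedMeridianSet:
    """Per-point mean/SD of repeated scans; unreliable points are NaN.

    ``mean_M`` is NaN wherever the repeat SD exceeded the acceptance
    threshold (the point is MISSING, never silently zero); ``n_used`` is 0
    there.
    """

    mean_M: np.ndarray  # (5, 81), NaN = MISSING
    sd_M: np.ndarray
    n_used: np.ndarray
    condition: Condition
    elevations: np.ndarray = field(default_factory=lambda: ELEVATIONS_DEG.copy())
    azimuths: np.ndarray = field(default_factory=lambda: AZIMUTHS_DEG.copy())

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean_M, dtype=float)
        sd = np.asarray(self.sd_M, dtype=float)
        n = np.asarray(self.n_used, dtype=int)
        elevations = np.asarray(self.elevations, dtype=float)
        azimuths = np.asarray(self.azimuths, dtype=float)
        _check_grid(elevations, azimuths)
        shape = (len(elevations), len(azimuths))
        if mean.shape != shape or sd.shape != shape or n.shape != shape:
            raise GridMismatchError("mean_M, sd_M and n_used must be (5, 81)")
        object.__setattr__(self, "mean_M", mean)
        object.__setattr__(self, "sd_M", sd)
        object.__setattr__(self, "n_used", n)
        object.__setattr__(self, "elevations", elevations)
        object.__setattr__(self, "azimuths", azimuths)
        object.__setattr__(self, "condition", Condition(self.condition))

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.mean_M)

    def equator(self) -> np.ndarray:
        """Mean M along the 0-deg parallel (NaN where MISSING)."""
        i = int(np.argwhere(self.elevations == 0.0)[0, 0])
        return self.mean_M[i]


@dataclass(frozen=True)
class ProfileClass:
    """Peripheral-refraction classification of an equatorial profile."""

    label: ProfileLabel
    nasal_edge_mean: float
    temporal_edge_mean: float
    central_mean: float


# ---------------------------------------------------------------------------
# Scan-table CSV I/O
#
# On disk the instrument/visual-field convention is used (azimuth positive
# toward the nasal visual field, elevation positive upward); in memory all
# grids are retinal.  Reading negates both angles; writing restores them.

_SCAN_COLUMNS = ["condition", "elevation_deg", "azimuth_deg", "scan_index", "M_diopters"]


def write_scan_table(scans: MeridianScanSet, path: str | Path) -> None:
    """Write a tidy scan-table CSV in the visual-field sign convention."""
    rows = []
    for i, el in enumerate(scans.elevations):
        for j, az in enumerate(scans.azimuths):
            for s in range(scans.n_scans):
                rows.append((scans.condition.value, -el, -az, s, scans.scans[i, j, s]))
    df = pd.DataFrame(rows, columns=_SCAN_COLUMNS)
    df.to_csv(path, index=False)


def read_scan_table(path: str | Path, condition: Condition | None = None) -> MeridianScanSet:
    """Read a tidy scan-table CSV into retinal-frame coordinates.

    Parameters
    ----------
    condition
        Select one condition if the file holds several; may be omitted for
        single-condition files.
    """
    df = pd.read_csv(path)
    missing = set(_SCAN_COLUMNS) - set(df.columns)
    if missing:
        raise MapFormatError(f"scan table missing columns {sorted(missing)}")
    if condition is not None:
        df = df[df["condition"] == Condition(condition).value]
        if df.empty:
            raise ValueError(f"no rows for condition {condition}")
    conditions = df["condition"].unique()
    if len(conditions) != 1:
        raise ValueError(
            f"scan table holds conditions {sorted(conditions)}; pass `condition=`"
        )
    cond = Condition(conditions[0])
    # visual-field -> retinal sign convention
    df = df.assign(elevation_deg=-df["elevation_deg"], azimuth_deg=-df["azimuth_deg"])
    n_scans = int(df["scan_index"].max()) + 1
    scans = np.full((len(ELEVATIONS_DEG), len(AZIMUTHS_DEG), n_scans), np.nan)
    ei = {e: i for i, e in enumerate(ELEVATIONS_DEG)}
    aj = {round(a, 6): j for j, a in enumerate(AZIMUTHS_DEG)}
    for el, az, s, m in df[["elevation_deg", "azimuth_deg", "scan_index", "M_diopters"]].itertuples(
        index=False
    ):
        try:
            scans[ei[float(el)], aj[round(float(az), 6)], int(s)] = m
        except KeyError as exc:
            raise GridMismatchError(f"unexpected grid angle {exc} in scan table") from exc
    if np.isnan(scans).any():
        raise MapFormatError("scan table does not cover the full 5x81xN grid")
    return MeridianScanSet(scans, cond)
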