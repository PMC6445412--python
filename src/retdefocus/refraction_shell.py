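"""Filtering, averaging, classification and surface-fitting of the
peripheral-refraction shell.

The shell is sampled along 5 horizontal parallels.  Repeated scans are
averaged per point; points whose repeat standard deviation exceeds the
acceptance threshold (1 D by default) are removed as unreliable.  The
equatorial (0 deg) parallel classifies the eye's peripheral-refraction
profile by comparing the mean refraction of the outer 20-deg nasal and
temporal edges with the mean of the central 20 deg.  The central +/-20 deg
of the averaged parallels are interpolated into a 400x400 retinal map;
scan azimuths reach +/-40 deg, but only the central span feeds the map —
the outer zones serve the classifier alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RectBivariateSpline

from .core_io import (
    EXTENT_DEG,
    MAP_SHAPE,
    PIXEL_PITCH_DEG,
    AveragedMeridianSet,
    FieldMap,
    Frame,
    MeridianScanSet,
    ProfileClass,
    ProfileLabel,
    Semantics,
)

__all__ = [
    "ShellParams",
    "ShellQualityError",
    "average_scans",
    "classify_profile",
    "fill_missing_along_meridians",
    "fit_surface",
    "invert_to_power",
]


@dataclass(frozen=True)
class ShellParams:
    """Tunable parameters of the shell pipeline.

    sd_threshold : D
        Repeat-SD acceptance threshold; points above it are removed (1.0).
    tau : D
        Classification threshold — the minimum zone-mean difference that
        counts as "more positive" (0.25 D, one clinical refraction step).
    central_zone : deg
        Half-width of the central comparison zone (+/-10 deg).
    edge_zone : (deg, deg)
        Absolute-azimuth span of the nasal/temporal edge zones (20..40).
    """

    sd_threshold: float = 1.0
    tau: float = 0.25
    central_zone: float = 10.0
    edge_zone: tuple[float, float] = (20.0, 40.0)

    def __post_init__(self) -> None:
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not (0 < self.central_zone <= 40 and 0 <= self.edge_zone[0] < self.edge_zone[1] <= 40):
            raise ValueError("comparison zones must lie within the +/-40 deg scan range")


class ShellQualityError(ValueError):
    """Raised when too many points on a parallel fail the SD filter."""


def average_scans(scans: MeridianScanSet, params: ShellParams | None = None) -> AveragedMeridianSet:
    """Average repeated scans per point, removing unreliable points.

    Per point the mean and sample SD (ddof=1) over repeats are computed;
    points with SD above ``params.sd_threshold`` become MISSING (NaN).  A
    parallel with more than 50% missing points raises
    :class:`ShellQualityError`.
    """
    params = params or ShellParams()
    mean = scans.scans.mean(axis=2)
    sd = scans.scans.std(axis=2, ddof=1)
    bad = sd > params.sd_threshold
    mean = np.where(bad, np.nan, mean)
    n_used = np.where(bad, 0, scans.n_scans)
    frac_missing = bad.mean(axis=1)
    if np.any(frac_missing > 0.5):
        worst = int(np.argmax(frac_missing))
        raise ShellQualityError(
            f"parallel at {scans.elevations[worst]:+.0f} deg has "
            f"{100 * frac_missing[worst]:.0f}% unreliable points"
        )
    return AveragedMeridianSet(mean, sd, n_used, scans.condition,
                               scans.elevations, scans.azimuths)


def _zone_mean(values: np.ndarray, azimuths: np.ndarray, lo: float, hi: float) -> float:
    sel = (azimuths >= lo) & (azimuths <= hi)
    vals = values[sel]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ShellQualityError(f"no reliable points in zone [{lo}, {hi}] deg")
    return float(vals.mean())


def classify_profile(averaged: AveragedMeridianSet, params: ShellParams | None = None) -> ProfileClass:
    """Classify the equatorial peripheral-refraction profile.

    With N, T the mean M over the nasal and temporal outer edge zones and
    C the mean over the central zone, and threshold tau:

    * RPH — both edges more hyperopic: ``N - C >= tau`` and ``T - C >= tau``;
    * RPM — both edges more myopic: ``C - N >= tau`` and ``C - T >= tau``;
    * NPS — nasal edge more positive than centre and temporal edge;
    * TPS — temporal edge more positive than centre and nasal edge;
    * INDETERMINATE otherwise.

    Rules are evaluated in the order RPH, RPM, NPS, TPS, so the symmetric
    classes take precedence over the skewed ones.
    """
    params = params or ShellParams()
    eq = averaged.equator()
    az = averaged.azimuths
    lo, hi = params.edge_zone
    N = _zone_mean(eq, az, lo, hi)
    T = _zone_mean(eq, az, -hi, -lo)
    C = _zone_mean(eq, az, -params.central_zone, params.central_zone)
    tau = params.tau
    if N - C >= tau and T - C >= tau:
        label = ProfileLabel.RPH
    elif C - N >= tau and C - T >= tau:
        label = ProfileLabel.RPM
    elif N - C >= tau and N - T >= tau:
        label = ProfileLabel.NPS
    elif T - C >= tau and T - N >= tau:
        label = ProfileLabel.TPS
    else:
        label = ProfileLabel.INDETERMINATE
    return ProfileClass(label, nasal_edge_mean=N, temporal_edge_mean=T, central_mean=C)


def fill_missing_along_meridians(averaged: AveragedMeridianSet) -> AveragedMeridianSet:
    """Fill MISSING points by 1-D linear interpolation along each parallel.

    Interpolation never crosses parallels.  Missing points at a parallel's
    ends take the nearest reliable value (constant extrapolation).  A
    parallel with no reliable point at all is an error.
    """
    mean = averaged.mean_M.copy()
    for i in range(mean.shape[0]):
        row = mean[i]
        good = ~np.isnan(row)
        if not good.any():
            raise ShellQualityError(
                f"parallel at {averaged.elevations[i]:+.0f} deg has no reliable points"
            )
        if not good.all():
            mean[i] = np.interp(averaged.azimuths, averaged.azimuths[good], row[good])
    return AveragedMeridianSet(mean, averaged.sd_M, averaged.n_used, averaged.condition,
                               averaged.elevations, averaged.azimuths)


def fit_surface(
    averaged: AveragedMeridianSet, semantics: Semantics = Semantics.EYE_POWER
) -> FieldMap:
    """Interpolate the 5 averaged parallels into a 400x400 retinal map.

    A tensor-product interpolating cubic spline (no smoothing) is fitted to
    the central +/-20 deg nodes of the 5 parallels and evaluated at every
    pixel centre, so each reliable node value is reproduced exactly at its
    grid location.  MISSING nodes are first filled along their own parallel.
    """
    filled = fill_missing_along_meridians(averaged)
    central = np.abs(filled.azimuths) <= EXTENT_DEG + 1e-9
    az = filled.azimuths[central]
    nodes = filled.mean_M[:, central]
    spline = RectBivariateSpline(filled.elevations, az, nodes, kx=3, ky=3, s=0)
    x = (np.arange(MAP_SHAPE[1]) - 199.5) * PIXEL_PITCH_DEG       # azimuth, ascending
    y_desc = (199.5 - np.arange(MAP_SHAPE[0])) * PIXEL_PITCH_DEG  # elevation, by row
    values = spline(y_desc[::-1], x)[::-1]                        # spline wants ascending axes
    return FieldMap(values, Frame.RETINAL, semantics)


def invert_to_power(fmap: FieldMap) -> FieldMap:
    """Negate a refraction map so values reflect power rather than refraction."""
    return fmap.with_values(-fmap.values, Semantics.EYE_POWER)
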