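"""Contact-lens power profiles by over-refraction subtraction.

The effective on-eye power profile of a multifocal contact lens is
obtained by subtracting the naked-eye peripheral refraction from the
refraction measured while the lens is worn ("over-refraction"), per
meridian point.  The per-parallel profiles are interpolated into a
400x400 lens power map with the same surface-fit contract as the eye
maps.  Theoretical symmetric designs are derived by mirror-averaging each
parallel about azimuth zero.

Lens metadata (Dk, diameter, base curve, material) is provenance only and
enters no computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import (
    AveragedMeridianSet,
    Condition,
    FieldMap,
    GridMismatchError,
    Semantics,
)
from .refraction_shell import fit_surface
from .synthetic_data import LensDesign

__all__ = [
    "LensDesignProfile",
    "over_refraction",
    "symmetrize",
    "lens_power_map",
]


@dataclass(frozen=True)
class LensDesignProfile:
    """Per-meridian lens power differences on the scan grid.

    ``differences[i, j]`` is on-eye minus naked M (dioptres) at elevation
    ``elevations[i]``, azimuth ``azimuths[j]``; NaN where either input was
    MISSING.
    """

    design: LensDesign
    differences: np.ndarray  # (5, 81), NaN = MISSING
    elevations: np.ndarray
    azimuths: np.ndarray
    symmetric: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "design", LensDesign(self.design))
        diffs = np.asarray(self.differences, dtype=float)
        if diffs.shape != (len(self.elevations), len(self.azimuths)):
            raise GridMismatchError("differences grid does not match the meridian grid")
        object.__setattr__(self, "differences", diffs)


_DESIGN_BY_CONDITION = {
    Condition.ON_LENS_NEAR_CENTRE: LensDesign.NEAR_CENTRE,
    Condition.ON_LENS_DISTANCE_CENTRE: LensDesign.DISTANCE_CENTRE,
}


def over_refraction(
    on_eye: AveragedMeridianSet,
    naked: AveragedMeridianSet,
    design: LensDesign | None = None,
) -> LensDesignProfile:
    """Subtract the naked-eye refraction from the on-wear measurement.

    A point contributes only if reliable in both sets; MISSING propagates.
    The design is inferred from the on-eye condition unless given.
    """
    if not (
        np.array_equal(on_eye.elevations, naked.elevations)
        and np.array_equal(on_eye.azimuths, naked.azimuths)
    ):
        raise GridMismatchError("on-eye and naked-eye sets are on different grids")
    if design is None:
        try:
            design = _DESIGN_BY_CONDITION[on_eye.condition]
        except KeyError:
            raise ValueError(
                "on_eye condition is NAKED; pass `design=` explicitly"
            ) from None
    return LensDesignProfile(
        design,
        on_eye.mean_M - naked.mean_M,  # NaN propagates
        on_eye.elevations.copy(),
        on_eye.azimuths.copy(),
    )


def symmetrize(profile: LensDesignProfile) -> LensDesignProfile:
    """Mirror-average each parallel about azimuth zero.

    ``s(theta) = (f(theta) + f(-theta)) / 2`` — the theoretical symmetric
    design implied by a measured (asymmetric) profile.  Idempotent, and
    preserves each parallel's mean.  Requires a symmetric azimuth grid.
    """
    az = profile.azimuths
    if not np.allclose(az, -az[::-1]):
        raise GridMismatchError("azimuth grid is not symmetric about zero")
    sym = 0.5 * (profile.differences + profile.differences[:, ::-1])
    return replace(profile, differences=sym, symmetric=True)


def lens_power_map(profile: LensDesignProfile) -> FieldMap:
    """Interpolate the per-parallel profile into a 400x400 lens power map."""
    as_set = AveragedMeridianSet(
        profile.differences,
        np.zeros_like(profile.differences),
        np.where(np.isnan(profile.differences), 0, 1),
        _condition_for(profile.design),
        profile.elevations,
        profile.azimuths,
    )
    return fit_surface(as_set, semantics=Semantics.LENS_POWER)


def _condition_for(design: LensDesign) -> Condition:
    return (
        Condition.ON_LENS_NEAR_CENTRE
        if design is LensDesign.NEAR_CENTRE
        else Condition.ON_LENS_DISTANCE_CENTRE
    )
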