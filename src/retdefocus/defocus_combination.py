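"""Combined retinal defocus maps and their ring x quadrant segmentation.

A combined condition map is the element-wise sum of three retinal-frame
maps: the scene dioptric-defocus map (flipped from the visual field), the
eye power map (inverted refraction surface), and the lens power map (a
blank matrix for the naked eye).  The full design is 3 scenes x 3 optics
x 4 peripheral-refraction profile classes = 36 maps.

Segmentation convention (frozen)
--------------------------------
Pixel-centre eccentricity ``d`` partitions the central 20-deg disc into
four 5-deg rings, half-open at the inner edge (``5(k-1) < d <= 5k``).
Quadrants are the four 90-deg sectors centred on the retinal axes and
bounded by the +/-45-deg diagonals (the corneal-topography convention for
superior / inferior / nasal / temporal segments).  On the half-offset
pixel grid some pixel centres fall exactly on a diagonal; each of the
four diagonal rays is assigned to one adjacent sector (NE -> superior,
SE -> nasal, SW -> inferior, NW -> temporal), which keeps the 16 region
masks an exact partition of the disc with identical quadrant counts per
ring.  Pixels beyond 20 deg (the map corners) are excluded from all
statistics.  All membership tests use exact integer arithmetic in
half-pixel units, so the masks are reproducible to the pixel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import (
    MAP_SHAPE,
    ConditionKey,
    FieldMap,
    Frame,
    FrameError,
    Optic,
    ProfileLabel,
    Quadrant,
    RegionKey,
    Ring,
    Scene,
    Semantics,
    add_maps,
)

__all__ = [
    "RegionMaskSet",
    "ConditionMapSet",
    "make_region_masks",
    "combine_condition",
    "build_all_conditions",
    "extract_regions",
    "region_table",
]

ANALYSIS_PROFILES = tuple(p for p in ProfileLabel if p is not ProfileLabel.INDETERMINATE)


@dataclass(frozen=True)
class RegionMaskSet:
    """Boolean masks for the 16 ring x quadrant regions plus the excluded set."""

    masks: Mapping[RegionKey, np.ndarray]
    excluded: np.ndarray

    def counts(self) -> dict[RegionKey, int]:
        return {k: int(m.sum()) for k, m in self.masks.items()}


@dataclass(frozen=True)
class ConditionMapSet:
    """The 36 combined condition maps keyed by (scene, optic, profile)."""

    maps: Mapping[ConditionKey, FieldMap]
    provenance: dict

    def __post_init__(self) -> None:
        expected = {
            ConditionKey(s, o, p)
            for s in Scene for o in Optic for p in ANALYSIS_PROFILES
        }
        got = set(self.maps)
        if got != expected:
            raise ValueError(
                f"expected the full 36-condition design, got {len(got)} keys "
                f"(missing {len(expected - got)}, unexpected {len(got - expected)})"
            )


def make_region_masks() -> RegionMaskSet:
    """Build the frozen ring x quadrant segmentation masks."""
    # pixel-centre coordinates in half-pixel units: odd integers in -399..399
    u = 2 * np.arange(MAP_SHAPE[1]) - 399          # x (nasal positive), by column
    w = 399 - 2 * np.arange(MAP_SHAPE[0])          # y (superior positive), by row
    U, W = np.meshgrid(u, w)
    D2 = U * U + W * W                              # squared eccentricity, (0.05 deg)^2
    absU, absW = np.abs(U), np.abs(W)

    quadrant_of = {
        Quadrant.SUPERIOR: (W > absU) | ((W == U) & (U > 0)),    # + NE diagonal ray
        Quadrant.NASAL: (U > absW) | ((U == -W) & (W < 0)),      # + SE diagonal ray
        Quadrant.INFERIOR: (-W > absU) | ((W == U) & (U < 0)),   # + SW diagonal ray
        Quadrant.TEMPORAL: (-U > absW) | ((U == -W) & (W > 0)),  # + NW diagonal ray
    }
    masks: dict[RegionKey, np.ndarray] = {}
    for k, ring in enumerate(Ring, start=1):
        lo, hi = (100 * (k - 1)) ** 2, (100 * k) ** 2  # 5 deg = 100 half-pixel units
        in_ring = (D2 > lo) & (D2 <= hi)
        for quadrant, in_quad in quadrant_of.items():
            masks[RegionKey(ring, quadrant)] = in_ring & in_quad
    excluded = D2 > (100 * 4) ** 2  # beyond the 20-deg disc
    return RegionMaskSet(masks, excluded)


def combine_condition(env: FieldMap, eye: FieldMap, lens: FieldMap) -> FieldMap:
    """Sum scene defocus, eye power and lens power into one retinal map."""
    for m, name in ((env, "environment"), (eye, "eye power"), (lens, "lens power")):
        if m.frame is not Frame.RETINAL:
            raise FrameError(
                f"{name} map is still in the VISUAL_FIELD frame; flip it first"
            )
    return add_maps([env, eye, lens], semantics=Semantics.COMBINED_DEFOCUS)


def build_all_conditions(
    scene_maps: Mapping[Scene, FieldMap],
    eye_maps: Mapping[ProfileLabel, FieldMap],
    lens_maps: Mapping[Optic, FieldMap],
    provenance: dict | None = None,
) -> ConditionMapSet:
    """Combine every scene x optic x profile into the 36-map design.

    ``lens_maps[Optic.NAKED]`` should be the blank map.  Inputs are one
    representative map per class; missing classes are an error.
    """
    for enum_type, mapping, name in (
        (Scene, scene_maps, "scene"),
        (ANALYSIS_PROFILES, eye_maps, "profile"),
        (Optic, lens_maps, "optic"),
    ):
        missing = [e for e in enum_type if e not in mapping]
        if missing:
            raise ValueError(f"missing {name} maps: {[m.value for m in missing]}")
    maps = {}
    for scene in Scene:
        for optic in Optic:
            for profile in ANALYSIS_PROFILES:
                key = ConditionKey(scene, optic, profile)
                maps[key] = combine_condition(
                    scene_maps[scene], eye_maps[profile], lens_maps[optic]
                )
    return ConditionMapSet(maps, provenance or {})


def extract_regions(fmap: FieldMap, masks: RegionMaskSet) -> dict[RegionKey, np.ndarray]:
    """Per-region vectors of map values at the mask pixels."""
    if fmap.frame is not Frame.RETINAL:
        raise FrameError("regions are defined on retinal-frame maps")
    return {key: fmap.values[mask] for key, mask in masks.masks.items()}


def region_table(conditions: ConditionMapSet, masks: RegionMaskSet) -> pd.DataFrame:
    """Tidy long table: scene, optic, profile, ring, quadrant, value (D)."""
    frames = []
    for key, fmap in conditions.maps.items():
        values = extract_regions(fmap, masks)
        for region, vec in values.items():
            frames.append(
                pd.DataFrame(
                    {
                        "scene": key.scene.value,
                        "optic": key.optic.value,
                        "profile": key.profile.value,
                        "ring": region.ring.value,
                        "quadrant": region.quadrant.value,
                        "value": vec,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
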