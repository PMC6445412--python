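"""Synthetic generators for the three input classes of the pipeline.

No public dataset exists for any of the inputs: the scene dioptric-defocus
maps come from a prior recording study and the refraction scans are
unpublished.  This module emulates their statistical structure —

* **scenes**: per-direction dioptric mismatch between the gaze
  (accommodative) distance and the object distance, ``1/d_gaze - 1/d_obj``,
  over the central +/-20 deg of the visual field, built from archetype
  object layouts (office / corridor / living room), smoothed and noised;
* **shells**: repeated meridian scans of spherical equivalent M with a
  controllable profile shape (central level, symmetric quadratic
  curvature, one-sided skew ramp, elevation curvature) and i.i.d. Gaussian
  per-scan noise;
* **lens scans**: on-eye over-refraction scans equal to the naked-eye scans
  plus an analytic radial multifocal power profile (near-centre or
  distance-centre), optionally decentred and with a nasal-temporal
  asymmetry tilt.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .core_io import (
    AZIMUTHS_DEG,
    ELEVATIONS_DEG,
    MAP_SHAPE,
    PIXEL_PITCH_DEG,
    Condition,
    FieldMap,
    Frame,
    MeridianScanSet,
    ProfileLabel,
    Scene,
    Semantics,
    pixel_coordinates,
)

__all__ = [
    "SkewSide",
    "ScenePatch",
    "SceneSpec",
    "ShellSpec",
    "LensDesign",
    "LensSpec",
    "scene_preset",
    "shell_preset",
    "lens_preset",
    "make_scene",
    "make_shell",
    "make_lens_scans",
    "lens_profile",
]


class SkewSide(str, enum.Enum):
    NASAL = "NASAL"
    TEMPORAL = "TEMPORAL"
    NONE = "NONE"


class LensDesign(str, enum.Enum):
    NEAR_CENTRE = "NEAR_CENTRE"
    DISTANCE_CENTRE = "DISTANCE_CENTRE"


@dataclass(frozen=True)
class ScenePatch:
    """A disc of scene content at a given distance.

    centre_x / centre_y are visual-field degrees, radius degrees,
    distance metres.
    """

    centre_x: float
    centre_y: float
    radius: float
    distance: float


@dataclass(frozen=True)
class SceneSpec:
    archetype: Scene
    gaze_distance: float          # metres — the accommodative plane
    background_distance: float    # metres — everywhere not covered by a patch
    object_patches: tuple[ScenePatch, ...] = ()
    smoothness: float = 1.0       # deg — Gaussian blur scale of the layout
    noise_sd: float = 0.1         # D  — i.i.d. pixel noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaze_distance <= 0 or self.background_distance <= 0:
            raise ValueError("distances must be positive")
        for p in self.object_patches:
            if p.distance <= 0:
                raise ValueError("patch distances must be positive")
            if abs(p.centre_x) > 20 or abs(p.centre_y) > 20:
                raise ValueError("patches must lie within the +/-20 deg field")


@dataclass(frozen=True)
class ShellSpec:
    """Generator parameters for one eye's peripheral-refraction shell.

    The noiseless mean at azimuth theta, elevation phi (retinal degrees) is

        central_M + symmetric_curvature * theta**2 + skew(theta)
                  + elevation_curvature * phi**2

    where ``skew`` is a half-cosine ramp over the outer 20 deg of the
    skewed side, reaching ``skew_amplitude`` at |theta| = 40 deg.  The
    default per-scan noise SD matches the pooled post-filter repeat SD of
    the measurements this emulates (0.26 D).
    """

    target_class: ProfileLabel
    central_M: float = -3.25
    symmetric_curvature: float = 0.0     # D / deg^2
    skew_amplitude: float = 0.0          # D at the 40-deg edge
    skew_side: SkewSide = SkewSide.NONE
    elevation_curvature: float = 0.0005  # D / deg^2
    scan_noise_sd: float = 0.26          # D
    n_scans: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_class", ProfileLabel(self.target_class))
        object.__setattr__(self, "skew_side", SkewSide(self.skew_side))
        if self.scan_noise_sd < 0:
            raise ValueError("scan_noise_sd must be non-negative")
        if self.n_scans < 2:
            raise ValueError("n_scans must be at least 2")
        required = {
            ProfileLabel.NPS: SkewSide.NASAL,
            ProfileLabel.TPS: SkewSide.TEMPORAL,
            ProfileLabel.RPM: SkewSide.NONE,
            ProfileLabel.RPH: SkewSide.NONE,
        }
        want = required.get(self.target_class)
        if want is not None and self.skew_side is not want:
            raise ValueError(
                f"target class {self.target_class.value} requires skew_side="
                f"{want.value}, got {self.skew_side.value}"
            )


@dataclass(frozen=True)
class LensSpec:
    """Analytic multifocal contact-lens profile.

    Radial power at retinal field radius r (deg from the lens centre):

    * NEAR_CENTRE:     centre_power + add_power * exp(-r^2 / tr^2)
    * DISTANCE_CENTRE: centre_power + add_power * (1 - exp(-r^2 / tr^2))

    with ``tr = transition_radius``.  ``decentration`` shifts the lens
    centre in field degrees; ``asymmetry_amplitude`` adds a linear
    nasal-temporal power tilt reaching the stated amplitude at the nasal
    40-deg scan edge, emulating the asymmetric on-eye profiles that
    decentration and lens flexure produce.
    """

    design: LensDesign
    centre_power: float = -0.25
    add_power: float | None = None       # default by design: 2.25 / 2.50 D
    transition_radius: float = 12.0      # deg
    decentration: tuple[float, float] = (0.0, 0.0)
    asymmetry_amplitude: float = 0.0     # D at theta = +40 deg
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "design", LensDesign(self.design))
        if self.add_power is None:
            add = 2.25 if self.design is LensDesign.NEAR_CENTRE else 2.50
            object.__setattr__(self, "add_power", add)
        if self.add_power < 0:
            raise ValueError("add_power must be non-negative")
        if self.transition_radius <= 0:
            raise ValueError("transition_radius must be positive")


# ---------------------------------------------------------------------------
# Presets

def scene_preset(archetype: Scene | str, seed: int = 0) -> SceneSpec:
    """Archetype scene layouts.

    OFFICE: near desk work — gaze on the desk plane at 0.5 m, a large desk
    patch filling the inferior field slightly nearer than gaze, room walls
    a few metres away.  CORRIDOR: far gaze down a hallway (3 m) with walls
    converging at similar distances — a low-variance, near-emmetropic
    field.  LIVING_ROOM: mixed — gaze on a screen at 2 m with a near table
    below and a far window aside.
    """
    archetype = Scene(archetype)
    if archetype is Scene.OFFICE:
        return SceneSpec(
            archetype, gaze_distance=0.5, background_distance=3.0,
            object_patches=(
                ScenePatch(0.0, -13.0, 12.0, 0.55),   # desk / documents below gaze
                ScenePatch(10.0, 6.0, 6.0, 2.0),      # shelf
            ),
            smoothness=1.0, noise_sd=0.15, seed=seed,
        )
    if archetype is Scene.CORRIDOR:
        return SceneSpec(
            archetype, gaze_distance=3.0, background_distance=4.0,
            object_patches=(
                ScenePatch(-15.0, 0.0, 6.0, 2.2),     # near wall edges
                ScenePatch(15.0, 0.0, 6.0, 2.2),
            ),
            smoothness=1.5, noise_sd=0.1, seed=seed,
        )
    return SceneSpec(
        archetype, gaze_distance=2.0, background_distance=4.0,
        object_patches=(
            ScenePatch(0.0, -14.0, 9.0, 1.0),         # coffee table
            ScenePatch(12.0, 7.0, 5.0, 1.5),          # lamp
            ScenePatch(-12.0, 8.0, 6.0, 6.0),         # window / far corner
        ),
        smoothness=1.0, noise_sd=0.15, seed=seed,
    )


def shell_preset(target_class: ProfileLabel | str, seed: int = 0, **overrides) -> ShellSpec:
    """Default shell parameters producing each profile class with a clear
    margin over the 0.25 D classification threshold."""
    target_class = ProfileLabel(target_class)
    base: dict = dict(central_M=-3.25, elevation_curvature=0.0005, seed=seed)
    if target_class is ProfileLabel.NPS:
        base.update(skew_amplitude=1.5, skew_side=SkewSide.NASAL)
    elif target_class is ProfileLabel.TPS:
        base.update(skew_amplitude=1.5, skew_side=SkewSide.TEMPORAL)
    elif target_class is ProfileLabel.RPM:
        base.update(symmetric_curvature=-0.00125)
    elif target_class is ProfileLabel.RPH:
        base.update(symmetric_curvature=0.00125)
    else:
        raise ValueError("no preset for INDETERMINATE")
    base.update(overrides)
    return ShellSpec(target_class, **base)


def lens_preset(design: LensDesign | str, seed: int = 0, **overrides) -> LensSpec:
    return LensSpec(LensDesign(design), seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Generators

def make_scene(spec: SceneSpec) -> FieldMap:
    """Render a scene's dioptric-defocus map in the visual-field frame.

    Per pixel the defocus is ``1/gaze_distance - 1/object_distance`` —
    positive where the scene content sits beyond the accommodative plane.
    The layout is blurred at ``spec.smoothness`` and i.i.d. Gaussian noise
    of ``spec.noise_sd`` is added.  Deterministic given ``spec.seed``.
    """
    X, Y = pixel_coordinates()
    distance = np.full(MAP_SHAPE, spec.background_distance)
    for p in spec.object_patches:
        inside = (X - p.centre_x) ** 2 + (Y - p.centre_y) ** 2 <= p.radius**2
        distance[inside] = p.distance
    defocus = 1.0 / spec.gaze_distance - 1.0 / distance
    if spec.smoothness > 0:
        defocus = gaussian_filter(defocus, sigma=spec.smoothness / PIXEL_PITCH_DEG)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        defocus = defocus + rng.normal(0.0, spec.noise_sd, MAP_SHAPE)
    return FieldMap(defocus, Frame.VISUAL_FIELD, Semantics.ENV_DEFOCUS)


def _skew_ramp(theta: np.ndarray, amplitude: float, side: SkewSide) -> np.ndarray:
    """Half-cosine ramp over the outer 20 deg of the skewed side."""
    if side is SkewSide.NONE or amplitude == 0.0:
        return np.zeros_like(theta)
    t = theta if side is SkewSide.NASAL else -theta
    ramp = np.where(t > 20.0, 0.5 * (1.0 - np.cos(np.pi * (t - 20.0) / 20.0)), 0.0)
    return amplitude * ramp


def shell_mean_surface(spec: ShellSpec) -> np.ndarray:
    """Noiseless mean M on the (5 elevations x 81 azimuths) scan grid."""
    theta = AZIMUTHS_DEG[np.newaxis, :]
    phi = ELEVATIONS_DEG[:, np.newaxis]
    return (
        spec.central_M
        + spec.symmetric_curvature * theta**2
        + _skew_ramp(theta, spec.skew_amplitude, spec.skew_side)
        + spec.elevation_curvature * phi**2
    )


def make_shell(spec: ShellSpec) -> MeridianScanSet:
    """Generate repeated meridian scans for one synthetic eye."""
    mean = shell_mean_surface(spec)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.scan_noise_sd, mean.shape + (spec.n_scans,)) \
        if spec.scan_noise_sd > 0 else np.zeros(mean.shape + (spec.n_scans,))
    return MeridianScanSet(mean[:, :, np.newaxis] + noise, Condition.NAKED)


def lens_profile(spec: LensSpec, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Analytic lens power (D) at retinal field angles (theta, phi) deg."""
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    dx, dy = spec.decentration
    r2 = (theta - dx) ** 2 + (phi - dy) ** 2
    g = np.exp(-r2 / spec.transition_radius**2)
    radial = g if spec.design is LensDesign.NEAR_CENTRE else 1.0 - g
    return spec.centre_power + spec.add_power * radial + spec.asymmetry_amplitude * theta / 40.0


def make_lens_scans(spec: LensSpec, naked: MeridianScanSet) -> MeridianScanSet:
    """Generate on-eye scans: the naked-eye scans plus the lens profile.

    Each repeat inherits the naked scan's measurement noise, so the
    noiseless over-refraction subtraction recovers the analytic profile
    exactly.
    """
    theta = naked.azimuths[np.newaxis, :]
    phi = naked.elevations[:, np.newaxis]
    profile = lens_profile(spec, theta, phi)
    condition = (
        Condition.ON_LENS_NEAR_CENTRE
        if spec.design is LensDesign.NEAR_CENTRE
        else Condition.ON_LENS_DISTANCE_CENTRE
    )
    return MeridianScanSet(
        naked.scans + profile[:, :, np.newaxis], condition,
        naked.elevations, naked.azimuths,
    )
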