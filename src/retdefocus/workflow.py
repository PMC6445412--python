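"""End-to-end convenience pipeline over synthetic study inputs.

Builds the full 36-condition design (3 scenes x 3 optics x 4 profile
classes) from the synthetic generators: one representative
peripheral-refraction shell per profile class, one over-refraction-derived
power map per lens design, and one dioptric-defocus map per scene
archetype, all combined into retinal defocus maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core_io import (
    Condition,
    FieldMap,
    MeridianScanSet,
    Optic,
    ProfileClass,
    ProfileLabel,
    Scene,
    blank_map,
    flip_to_retinal,
)
from .defocus_combination import ANALYSIS_PROFILES, ConditionMapSet, build_all_conditions
from .lens_profiles import lens_power_map, over_refraction, symmetrize
from .refraction_shell import (
    ShellParams,
    average_scans,
    classify_profile,
    fit_surface,
    invert_to_power,
)
from .synthetic_data import (
    LensDesign,
    LensSpec,
    SceneSpec,
    ShellSpec,
    lens_preset,
    make_lens_scans,
    make_scene,
    make_shell,
    scene_preset,
    shell_preset,
)

__all__ = ["StudyInputs", "synthesize_study", "build_condition_maps"]

_OPTIC_DESIGN = {
    Optic.NEAR_CENTRE: LensDesign.NEAR_CENTRE,
    Optic.DISTANCE_CENTRE: LensDesign.DISTANCE_CENTRE,
}


@dataclass(frozen=True)
class StudyInputs:
    """The 10 baseline inputs of the design: 3 scenes + 4 eyes + 2 lenses
    (+ the blank naked-eye matrix)."""

    scene_maps: Mapping[Scene, FieldMap]           # retinal frame
    eye_maps: Mapping[ProfileLabel, FieldMap]      # power maps
    lens_maps: Mapping[Optic, FieldMap]            # power maps; NAKED -> blank
    classifications: Mapping[ProfileLabel, ProfileClass]
    seed: int


def _subseed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


def synthesize_study(
    seed: int = 0,
    params: ShellParams | None = None,
    scene_specs: Mapping[Scene, SceneSpec] | None = None,
    shell_specs: Mapping[ProfileLabel, ShellSpec] | None = None,
    lens_specs: Mapping[Optic, LensSpec] | None = None,
    symmetric_lenses: bool = False,
) -> StudyInputs:
    """Generate and process all baseline inputs deterministically.

    Any of the spec mappings may be overridden; defaults are the archetype
    presets.  With ``symmetric_lenses`` the theoretical mirror-averaged
    lens designs replace the measured (possibly asymmetric) profiles.
    """
    params = params or ShellParams()
    rng = np.random.default_rng(seed)

    scene_specs = scene_specs or {s: scene_preset(s, seed=_subseed(rng)) for s in Scene}
    scene_maps = {s: flip_to_retinal(make_scene(spec)) for s, spec in scene_specs.items()}

    shell_specs = shell_specs or {
        p: shell_preset(p, seed=_subseed(rng)) for p in ANALYSIS_PROFILES
    }
    eye_maps, classifications = {}, {}
    for profile, spec in shell_specs.items():
        averaged = average_scans(make_shell(spec), params)
        classifications[profile] = classify_profile(averaged, params)
        eye_maps[profile] = invert_to_power(fit_surface(averaged))

    # lens power maps from over-refraction on a reference naked eye
    reference_naked = make_shell(
        shell_preset(ProfileLabel.RPM, seed=_subseed(rng))
    )
    naked_avg = average_scans(reference_naked, params)
    lens_specs = lens_specs or {
        o: lens_preset(d, seed=_subseed(rng)) for o, d in _OPTIC_DESIGN.items()
    }
    lens_maps: dict[Optic, FieldMap] = {Optic.NAKED: blank_map()}
    for optic, spec in lens_specs.items():
        on_eye = average_scans(make_lens_scans(spec, reference_naked), params)
        profile = over_refraction(on_eye, naked_avg)
        if symmetric_lenses:
            profile = symmetrize(profile)
        lens_maps[optic] = lens_power_map(profile)

    return StudyInputs(scene_maps, eye_maps, lens_maps, classifications, seed)


def build_condition_maps(inputs: StudyInputs) -> ConditionMapSet:
    """Combine the study inputs into the 36 condition maps."""
    return build_all_conditions(
        inputs.scene_maps,
        inputs.eye_maps,
        inputs.lens_maps,
        provenance={"seed": inputs.seed},
    )
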