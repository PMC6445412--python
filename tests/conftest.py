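import numpy as np
import pytest
from hypothesis import settings

import retdefocus as rd

settings.register_profile("suite", max_examples=50, deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def masks() -> rd.RegionMaskSet:
    return rd.make_region_masks()


@pytest.fixture(scope="session")
def shell_params() -> rd.ShellParams:
    return rd.ShellParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def constant_map(value: float, frame=rd.Frame.RETINAL,
                 semantics=rd.Semantics.COMBINED_DEFOCUS) -> rd.FieldMap:
    return rd.FieldMap(np.full((400, 400), float(value)), frame, semantics)


def constant_scan_set(value: float, n_scans: int = 4,
                      condition=rd.Condition.NAKED) -> rd.MeridianScanSet:
    return rd.MeridianScanSet(np.full((5, 81, n_scans), float(value)), condition)
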