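"""Shared fixtures: phantoms and expensive pipeline products are built once
per session and reused across test modules."""

import numpy as np
import pytest

from cbctsct import (
    AnatomyChangeSpec,
    CbctDegradationSpec,
    GridSpec,
    PhantomSpec,
    apply_anatomy_change,
    generate_phantom,
    make_corrcbct,
    retract_fov,
    simulate_cbct,
)
from cbctsct.phantoms import GRID_PRESETS


@pytest.fixture(scope="session")
def phantom():
    """Default head-and-neck phantom (96x96x60 @ 3 mm test preset)."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(PhantomSpec(grid=GRID_PRESETS["test_small"], seed=11))


@pytest.fixture(scope="session")
def changed_case(phantom):
    """Phantom with the default anatomical change (16.4 % target shrinkage,
    superior shoulder shift, partial cavity fill) and its true deformation."""
    pct, structures = phantom
    change = AnatomyChangeSpec(
        target_shrink_fraction=0.164,
        shoulder_shift_mm=(0.0, 0.0, 6.0),
        cavity_fill_fraction=0.3,
        seed=3,
    )
    vfct, vf_structs, field = apply_anatomy_change(pct, structures, change)
    return pct, structures, vfct, vf_structs, field, change


@pytest.fixture(scope="session")
def degraded_cbct(changed_case):
    """CBCT with the criterion degradation: gain 0.8, offset 40, 80-HU
    shading, no noise."""
    _, _, vfct, _, _, _ = changed_case
    deg = CbctDegradationSpec(noise_sd=0.0, seed=5)
    cbct, fov, inverse = simulate_cbct(vfct, deg)
    return cbct, fov, inverse, deg


@pytest.fixture(scope="session")
def corrcbct_result(changed_case, degraded_cbct):
    """corrCBCT pipeline product on the degraded phantom (expensive; shared)."""
    pct, _, _, _, _, _ = changed_case
    cbct, fov, _, _ = degraded_cbct
    return make_corrcbct(pct, cbct, fov)


@pytest.fixture(scope="session")
def focus_mask(degraded_cbct):
    cbct, fov, _, _ = degraded_cbct
    return retract_fov(fov, cbct.spacing, 20.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
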