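"""Shared fixtures: phantoms are generated programmatically at test time.

``fast_kwargs`` builds a half-resolution phantom (128 px at 0.8 mm, same
102.4 mm field of view) so registration-heavy unit tests stay quick; the
acceptance suite uses the full 256 px / 0.4 mm conditions.
"""
import numpy as np
import pytest

from radpath import (
    PhantomSpec,
    make_phantom_case,
    register_case,
)

FAST = dict(in_plane_size=128, mri_spacing=(0.8, 0.8, 4.0))


@pytest.fixture(scope="session")
def fast_kwargs():
    return dict(FAST)


@pytest.fixture(scope="session")
def registered_r15(fast_kwargs):
    """One rotated phantom case (r=15) with its registration chains."""
    spec = PhantomSpec(max_rotation_deg=15.0, seed=42, **fast_kwargs)
    case = make_phantom_case(spec)
    chains = register_case(case.mri, case.stack)
    return case, chains


@pytest.fixture(scope="session")
def identity_case(fast_kwargs):
    """Zero-artifact phantom: registration should be the identity."""
    spec = PhantomSpec(seed=7, **fast_kwargs)
    case = make_phantom_case(spec)
    chains = register_case(case.mri, case.stack)
    return case, chains


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
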