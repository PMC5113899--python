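"""Shared fixtures: every structure and contact list is generated in-process."""

from __future__ import annotations

import numpy as np
import pytest

from tmbundle import (BundleSpec, bundle_axis, assign_caps, make_bundle,
                      oracle_contacts, pseudo_centroids)


@pytest.fixture(scope="session")
def bundle4():
    """Default 4-helix up-down bundle with truth metadata."""
    trace, segments, truth = make_bundle(BundleSpec(seed=0))
    return trace, segments, truth


@pytest.fixture(scope="session")
def bundle4_centroids(bundle4):
    trace, segments, truth = bundle4
    return pseudo_centroids(trace), segments, truth


@pytest.fixture(scope="session")
def oracle4(bundle4):
    """Noise-free oracle contacts of the default bundle."""
    trace, _, _ = bundle4
    return oracle_contacts(trace, cutoff=8.0, rank_noise=0.0)


@pytest.fixture(scope="session")
def caps4(bundle4):
    trace, segments, _ = bundle4
    return assign_caps(segments, max(trace.residue_ids))


@pytest.fixture(scope="session")
def axis4(bundle4, caps4):
    trace, _, _ = bundle4
    return bundle_axis(trace, caps4)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
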