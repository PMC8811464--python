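"""Shared fixtures: small networks built once per session."""

import warnings

import numpy as np
import pytest

from procsnn.connectivity import build_procedural_network, materialize
from procsnn.engine import partition
from procsnn.microcircuit import (
    brunel_fixture,
    build_reference_network,
    default_microcircuit,
    scale,
)


@pytest.fixture(scope="session")
def brunel400():
    """Small balanced random network with fitted procedural tables."""
    spec = brunel_fixture(N=400, p=0.1, g=5.0)
    ref = build_reference_network(spec, seed=42)
    clusters = partition(spec.sizes, cap=256)
    pn = build_procedural_network(ref, clusters, spec.pop_of(),
                                  spec.pop_is_exc, master_seed=7)
    mat = materialize(pn)
    return {"spec": spec, "ref": ref, "clusters": clusters, "pn": pn, "mat": mat}


@pytest.fixture(scope="session")
def microcircuit_10pct():
    """10%-scaled microcircuit with procedural tables and its
    materialized explicit twin."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spec = scale(default_microcircuit(), 0.1)
    ref = build_reference_network(spec, seed=1234)
    clusters = partition(spec.sizes, cap=256)
    pn = build_procedural_network(ref, clusters, spec.pop_of(),
                                  spec.pop_is_exc, master_seed=99)
    mat = materialize(pn)
    return {"spec": spec, "ref": ref, "clusters": clusters, "pn": pn, "mat": mat}


@pytest.fixture(scope="session")
def full_spec():
    return default_microcircuit()
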