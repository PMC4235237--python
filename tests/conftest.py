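"""Shared fixtures.

Heavy objects (the default-resolution proxy, its harmonic fields and the full
three-variant comparison) are session-scoped and computed once.
"""

import numpy as np
import pytest

import orthobone as ob
from orthobone.geometry import centerline_tangent


@pytest.fixture(scope="session")
def box():
    return ob.generate_box(2, 2, 2)


@pytest.fixture(scope="session")
def proxy_params():
    return ob.ProxyParams()


@pytest.fixture(scope="session")
def proxy(proxy_params):
    return ob.generate_proxy(proxy_params)


@pytest.fixture(scope="session")
def small_proxy_params():
    # coarse, short-arc proxy for fast unit tests
    return ob.ProxyParams(arc_angle_deg=90.0, edge_length=2.0)


@pytest.fixture(scope="session")
def small_proxy(small_proxy_params):
    return ob.generate_proxy(small_proxy_params)


@pytest.fixture(scope="session")
def reference(proxy_params):
    return lambda pts: centerline_tangent(proxy_params, pts)


@pytest.fixture(scope="session")
def fields_with_and_without_fill(proxy):
    """(phi_long, phi_rad) pairs for use_virtual False / True on the proxy."""
    out = {}
    for uv in (False, True):
        out[uv] = ob.solve_field_pair(proxy, use_virtual=uv)
    return out


@pytest.fixture(scope="session")
def frames_with_and_without_fill(proxy, fields_with_and_without_fill, reference):
    out = {}
    for uv, (pl, pr) in fields_with_and_without_fill.items():
        regs = ["cortical", "cancellous"] + (["virtual"] if uv else [])
        gl = ob.element_gradients(proxy, pl, regs)
        gr = ob.element_gradients(proxy, pr, ["cortical", "cancellous"])
        out[uv] = ob.build_frames(gl, gr, proxy, reference=reference)
    return out


@pytest.fixture(scope="session")
def comparison_run():
    """Full default three-variant comparison on the proxy (the expensive one)."""
    cfg = ob.RunConfig()
    return cfg, ob.run_comparison(cfg)
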