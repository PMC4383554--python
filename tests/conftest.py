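import numpy as np
import pytest

from airemboli.acoustics import AcousticContext
from airemboli.tree import VesselTree, build_tree


@pytest.fixture(scope="session")
def ctx() -> AcousticContext:
    """Default acoustic context (3.0 mm MCA); warms the sizing-curve cache."""
    return AcousticContext(vessel_diameter=3.0)


@pytest.fixture(scope="session")
def small_tree() -> VesselTree:
    return build_tree(3.0, 6)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def dense_pressure_solve(tree: VesselTree, blocked: frozenset) -> dict:
    """Independent oracle: assemble and solve the full nodal linear system.

    Unknowns are the pressures at the downstream node of every vessel;
    terminal downstream nodes sit at the outlet pressure, the root upstream
    node at the input pressure, and blocked vessels have zero conductance.
    """
    G = tree.generations
    vessels = [(g, i) for g in range(G + 1) for i in range(2**g)]
    idx = {v: k for k, v in enumerate(vessels)}
    n = len(vessels)
    A = np.zeros((n, n))
    b = np.zeros(n)
    p_in, p_out = tree.input_pressure_pa, tree.outlet_pressure_pa

    def conductance(v):
        return 0.0 if v in blocked else 1.0 / tree.resistance(v[0])

    for v in vessels:
        g, i = v
        k = idx[v]
        if g == G:
            A[k, k] = 1.0
            b[k] = p_out
            continue
        c_self = conductance(v)
        A[k, k] += c_self
        if g == 0:
            b[k] += c_self * p_in
        else:
            A[k, idx[(g - 1, i >> 1)]] -= c_self
        for child in ((g + 1, 2 * i), (g + 1, 2 * i + 1)):
            cc = conductance(child)
            A[k, k] += cc
            A[k, idx[child]] -= cc
    # nodes with no conductance at all (fully isolated) float at outlet pressure
    for k in range(n):
        if A[k, k] == 0.0:
            A[k, k] = 1.0
            b[k] = p_out
    p = np.linalg.solve(A, b)
    return {v: p[idx[v]] for v in vessels}
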