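"""Canonical small networks at representative phase-diagram points.

One frozen parameter point per dynamical region, used throughout the test
suite and the examples.  ``fixture_suite`` realizes them at a requested
size with couplings drawn deterministically from the given seed, and
records a checksum per matrix so that test infrastructure can detect
generator drift.
"""

from __future__ import annotations

import hashlib
from typing import Dict, Optional

from .network import GatedNetwork, make_network
from .params import NetworkParams

__all__ = ["FIXTURE_POINTS", "fixture_suite", "coupling_checksum"]

# (g_h, alpha_r, alpha_z); the "marginal" point uses the documented smooth
# surrogate alpha_z = 100 for a switchlike update gate
FIXTURE_POINTS = {
    "region1": {"g_h": 1.2, "alpha_r": 1.0, "alpha_z": 0.0},
    "region2": {"g_h": 1.9, "alpha_r": 7.0, "alpha_z": 0.0},
    "region3": {"g_h": 1.9, "alpha_r": 14.0, "alpha_z": 0.0},
    "region4": {"g_h": 3.0, "alpha_r": 0.0, "alpha_z": 0.0},
    "marginal": {"g_h": 3.0, "alpha_r": 2.5, "alpha_z": 100.0},
}


def coupling_checksum(net: GatedNetwork) -> str:
    """SHA-256 over the three coupling matrices (row-major float64 bytes)."""
    digest = hashlib.sha256()
    for mat in (net.J_h, net.J_z, net.J_r):
        digest.update(mat.tobytes())
    return digest.hexdigest()


def fixture_params(name: str, n_units: int = 100, seed: int = 0) -> NetworkParams:
    if name not in FIXTURE_POINTS:
        raise KeyError(f"unknown fixture {name!r}; have {sorted(FIXTURE_POINTS)}")
    return NetworkParams(n_units=n_units, seed=seed, **FIXTURE_POINTS[name])


def fixture_suite(seed: int = 0, n_units: int = 100,
                  names: Optional[list] = None) -> Dict[str, GatedNetwork]:
    """Realize the canonical networks; deterministic for a fixed seed.

    Returns ``{name: GatedNetwork}``; each network's checksum is stored in
    ``net.gate_override``-free metadata via :func:`coupling_checksum` on
    demand.  A checksum mismatch against a previously recorded value
    signals test-infrastructure drift, not a model property.
    """
    out = {}
    for name in names or FIXTURE_POINTS:
        out[name] = make_network(fixture_params(name, n_units, seed))
    return out
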