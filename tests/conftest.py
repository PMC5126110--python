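"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive quantities with naive loops (per-segment
polynomial fits, flood-fill connected components) so the fast implementations
are checked against independent code paths.
"""

from __future__ import annotations

import numpy as np
import pytest

from envlrtc.bands import DEFAULT_BANDS, get_band
from envlrtc.synthetic import SensorMontage, generate_montage


@pytest.fixture(scope="session")
def alpha_band():
    return get_band("alpha")


@pytest.fixture(scope="session")
def theta_band():
    return get_band("theta")


@pytest.fixture(scope="session")
def all_bands():
    return list(DEFAULT_BANDS)


@pytest.fixture(scope="session")
def grid9() -> SensorMontage:
    """A 3x3 unit grid with rook adjacency."""
    return generate_montage(9, "grid")


def naive_dfa_fluctuation(profile: np.ndarray, scale: int, order: int = 3) -> float:
    """Brute-force DFA fluctuation: explicit per-segment polyfit loop."""
    n_seg = len(profile) // scale
    x = np.arange(scale, dtype=float)
    rms = []
    for i in range(n_seg):
        seg = profile[i * scale : (i + 1) * scale]
        coeffs = np.polyfit(x, seg, order)
        resid = seg - np.polyval(coeffs, x)
        rms.append(np.sqrt(np.mean(resid**2)))
    return float(np.mean(rms))


def brute_force_tfce(t_map, adj, params):
    """Brute-force TFCE: explicit threshold loop with flood-fill components."""
    t_flat = np.asarray(t_map, dtype=float).ravel()
    t_abs = np.abs(t_flat)
    t_max = t_abs.max()
    if t_max == 0:
        return np.zeros_like(np.asarray(t_map, dtype=float))
    dh = t_max / params.n_steps
    thresholds = (np.arange(1, params.n_steps + 1) - 0.5) * dh
    neighbours = [[] for _ in range(adj.n_bins)]
    for a, b in adj.edges:
        neighbours[a].append(b)
        neighbours[b].append(a)
    extents = np.zeros((params.n_steps, adj.n_bins), dtype=np.int64)
    for k, h in enumerate(thresholds):
        active = t_abs >= h
        seen = np.zeros(adj.n_bins, dtype=bool)
        for start in range(adj.n_bins):
            if active[start] and not seen[start]:
                component = [start]
                seen[start] = True
                stack = [start]
                while stack:
                    u = stack.pop()
                    for v in neighbours[u]:
                        if active[v] and not seen[v]:
                            seen[v] = True
                            component.append(v)
                            stack.append(v)
                for u in component:
                    extents[k, u] = len(component)
    contrib = (
        extents.astype(np.float64) ** params.e_exponent
        * thresholds[:, None] ** params.h_exponent
        * dh
    )
    enhanced = np.sign(t_flat) * contrib.sum(axis=0)
    return enhanced.reshape(np.asarray(t_map).shape)
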