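"""Fixed diffusion gradient direction sets.

Two antipodally-symmetric, approximately uniform unit-vector sets are
shipped as frozen constants: 10 directions for the multi-frequency
ADC protocol and 30 directions for the tensor protocol. Both were produced
once by electrostatic-repulsion optimisation on the sphere (antipodal
charge pairs) and are normalised to unit length on access. At b = 1 ms/µm²
the direction-averaged ADC is insensitive to the particular uniform scheme.
"""

from __future__ import annotations

import numpy as np

__all__ = ["DIRECTIONS_10", "DIRECTIONS_30", "get_directions"]

_DIRECTIONS_10 = np.array([
    [-0.753364, -0.033627, 0.656744],
    [-0.663468, 0.670803, 0.331412],
    [-0.596134, -0.741605, 0.307646],
    [-0.128240, -0.439830, 0.888878],
    [-0.060435, 0.423536, 0.903861],
    [0.052709, 0.969156, 0.240747],
    [0.394419, -0.821693, 0.411405],
    [0.588075, -0.142437, 0.796166],
    [0.677833, 0.562955, 0.472888],
    [0.991523, -0.078874, 0.103256],
])

_DIRECTIONS_30 = np.array([
    [-0.978398, 0.193571, 0.072583],
    [-0.892196, -0.235362, 0.385476],
    [-0.831827, 0.208158, 0.514523],
    [-0.762684, -0.638435, 0.103507],
    [-0.750418, 0.604631, 0.267011],
    [-0.612796, -0.550937, 0.566525],
    [-0.607112, -0.108457, 0.787180],
    [-0.519998, 0.432707, 0.736456],
    [-0.381028, -0.900420, 0.209909],
    [-0.366694, 0.810526, 0.456710],
    [-0.225838, 0.109631, 0.967976],
    [-0.222749, -0.361226, 0.905483],
    [-0.219222, -0.746337, 0.628428],
    [-0.090675, 0.574934, 0.813160],
    [-0.000152, 0.995920, 0.090240],
    [0.103179, 0.859964, 0.499815],
    [0.106750, -0.930244, 0.351070],
    [0.201960, -0.605910, 0.769471],
    [0.224498, 0.256278, 0.940171],
    [0.237588, -0.187088, 0.953179],
    [0.431648, 0.586603, 0.685257],
    [0.472459, -0.881352, 0.000913],
    [0.501648, 0.829925, 0.244076],
    [0.515894, -0.729914, 0.448418],
    [0.630742, -0.342158, 0.696485],
    [0.642502, 0.129030, 0.755343],
    [0.782584, 0.461808, 0.417488],
    [0.827767, -0.518753, 0.213769],
    [0.905992, -0.074653, 0.416661],
    [0.965823, 0.248319, 0.074326],
])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=1, keepdims=True)


DIRECTIONS_10 = _unit(_DIRECTIONS_10)
DIRECTIONS_30 = _unit(_DIRECTIONS_30)


def get_directions(n: int) -> np.ndarray:
    """Return the shipped ``n``-direction set (n ∈ {10, 30}) as (n, 3)."""
    if n == 10:
        return DIRECTIONS_10.copy()
    if n == 30:
        return DIRECTIONS_30.copy()
    raise ValueError(f"no shipped direction set of size {n}")
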