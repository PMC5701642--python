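"""Small numeric helpers shared across modules."""
from __future__ import annotations

import numpy as np

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def fibonacci_sphere(n: int, zmin: float = -1.0, zmax: float = 1.0) -> np.ndarray:
    """Quasi-uniform unit vectors on the spherical zone zmin <= z <= zmax.

    The classic golden-angle spiral; with the default bounds it covers the full
    sphere. Returns an (n, 3) array of unit vectors.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n, dtype=float)
    # midpoints of n equal-area z-slices of the zone
    z = zmax - (zmax - zmin) * (i + 0.5) / n
    phi = GOLDEN_ANGLE * i
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniformly random 3x3 rotation matrix (QR of a Gaussian matrix)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Normalize vectors along an axis; raises on zero vectors."""
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    if np.any(n == 0):
        raise ValueError("cannot normalize a zero vector")
    return v / n


def fix_sign(v: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude component positive."""
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def derive_seed(*parts: int) -> np.random.SeedSequence:
    """Stable per-row seed derivation: a SeedSequence keyed on integer parts."""
    return np.random.SeedSequence([int(p) & 0x7FFFFFFF for p in parts])
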