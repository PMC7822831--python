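"""Smooth scalp topographies built from low-order spherical harmonics.

These serve two roles: as planted microstate templates for the synthetic
study, and as a synthetic stand-in reference set for sorting fitted classes
into the conventional A–F letters (left-right diagonal, right-left diagonal,
anterior-posterior, fronto-central, symmetric posterior, anterior-posterior
variant). They are parametric constructions over the electrode positions,
not empirical grand averages.
"""

from __future__ import annotations

import numpy as np

from .montage import Montage

__all__ = ["harmonic_basis", "canonical_topographies", "average_reference_maps", "unit_norm_maps"]


def average_reference_maps(maps: np.ndarray) -> np.ndarray:
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    return maps - maps.mean(axis=1, keepdims=True)


def unit_norm_maps(maps: np.ndarray) -> np.ndarray:
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("cannot normalize an all-zero map")
    return maps / norms


def harmonic_basis(montage: Montage) -> np.ndarray:
    """(8, n_channels) orthonormal average-referenced basis.

    Degree-1 and degree-2 real spherical harmonics evaluated at the
    electrode positions, average-referenced then Gram–Schmidt
    orthonormalized. Head coordinates: +x right, +y anterior, +z superior.
    """
    x, y, z = montage.positions.T
    raw = np.stack(
        [
            x,
            y,
            z,
            x * y,
            x * z,
            y * z,
            x**2 - y**2,
            2 * z**2 - x**2 - y**2,
        ]
    )
    raw = average_reference_maps(raw)
    # Gram-Schmidt keeps maps average-referenced (constant map is orthogonal
    # to average-referenced maps already).
    basis = []
    for v in raw:
        for b in basis:
            v = v - (v @ b) * b
        n = np.linalg.norm(v)
        if n < 1e-10:
            raise ValueError("degenerate harmonic basis for this montage")
        basis.append(v / n)
    return np.stack(basis)


# rows: classes A..F, columns: harmonic basis coefficients
_CANONICAL_COEF = np.array(
    [
        # x     y     z     xy    xz    yz   x2-y2  z2
        [0.8, 0.5, 0.0, 0.0, 0.0, 0.3, 0.0, 0.0],  # A: left-right diagonal
        [-0.8, 0.5, 0.0, 0.0, 0.0, 0.3, 0.0, 0.0],  # B: right-left diagonal
        [0.0, 0.9, 0.1, 0.0, 0.0, 0.0, 0.0, -0.3],  # C: anterior-posterior
        [0.0, 0.3, 0.7, 0.0, 0.0, 0.0, 0.0, 0.6],  # D: fronto-central maximum
        [0.0, 0.0, 0.8, 0.0, 0.0, -0.5, 0.0, -0.2],  # E: symmetric posterior
        [0.0, 0.6, -0.4, 0.0, 0.0, 0.0, 0.5, 0.4],  # F: anterior-posterior variant
    ]
)


def canonical_topographies(montage: Montage, k: int = 6) -> np.ndarray:
    """(k, n_channels) unit-norm average-referenced reference maps A.. ."""
    if not 1 <= k <= _CANONICAL_COEF.shape[0]:
        raise ValueError(f"k must be in 1..{_CANONICAL_COEF.shape[0]}")
    maps = _CANONICAL_COEF[:k] @ harmonic_basis(montage)
    return unit_norm_maps(average_reference_maps(maps))


def orthogonal_topographies(montage: Montage, k: int = 6) -> np.ndarray:
    """Mutually orthogonal variants of the canonical maps.

    Löwdin (symmetric) orthogonalization of :func:`canonical_topographies`;
    each map keeps correlation ≈ 0.85–0.94 with its parent but boundary
    mixtures of two classes no longer resemble a third — the property that
    makes planted class coverages identifiable from a segmentation.
    """
    raw = canonical_topographies(montage, k)
    u, _, vt = np.linalg.svd(raw, full_matrices=False)
    return unit_norm_maps(average_reference_maps(u @ vt))
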