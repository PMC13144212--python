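"""Colorized fuzzy-ratio comparison of two registered chromatograms.

The comparison is a signed, bounded, pixel-wise field: positive where the
analyzed chromatogram carries more signal than the reference, negative where
the reference dominates.  "Fuzzy" means each pixel is compared against the
best-matching value within a small neighborhood of the other image, which
absorbs residual sub-pixel misalignment after registration instead of
producing dipole artifacts around every peak.

The raw one-directional fuzzy difference is not exactly antisymmetric under
swapping the inputs, so the reported field is its antisymmetrization
``s = (f(A,B) − f(B,A)) / 2``, which makes ``compare(A,B) = −compare(B,A)``
hold exactly while preserving the zero-on-identity and added-peak behavior.
Rendering maps positive values to the green channel and negative to red.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .chromatogram import ChromatogramGrid

__all__ = ["ComparisonImage", "fuzzy_ratio", "render_rgb"]


@dataclass
class ComparisonImage:
    """Signed comparison field in [-1, 1]; positive = analyzed > reference."""

    signed: np.ndarray
    radius: int
    rel_tol: float
    floor: float
    analyzed_id: str = ""
    reference_id: str = ""

    def __post_init__(self) -> None:
        if np.abs(self.signed).max(initial=0.0) > 1 + 1e-12:
            raise ValueError("signed field must lie in [-1, 1]")


def _directional(a: np.ndarray, b: np.ndarray, radius: int, rel_tol: float, floor: float) -> np.ndarray:
    """Signed normalized difference of ``a`` against its best match in ``b``.

    For each pixel the reference value r* minimizes |a − r| over the
    (2·radius+1)² neighborhood of ``b``; s = (a − r*) / max(a, r*, floor),
    zeroed where both values sit below the floor or within the relative
    tolerance of each other.
    """
    size = 2 * radius + 1
    if radius > 0:
        bmin = ndimage.minimum_filter(b, size=size, mode="nearest")
        bmax = ndimage.maximum_filter(b, size=size, mode="nearest")
        # best match: clamp a into the neighborhood's value range
        r_star = np.clip(a, bmin, bmax)
    else:
        r_star = b
    denom = np.maximum.reduce([a, r_star, np.full_like(a, floor)])
    s = (a - r_star) / denom
    s[(a < floor) & (r_star < floor)] = 0.0
    s[np.abs(a - r_star) <= rel_tol * np.maximum(a, r_star)] = 0.0
    return s


def fuzzy_ratio(
    analyzed: ChromatogramGrid | np.ndarray,
    reference: ChromatogramGrid | np.ndarray,
    radius: int = 1,
    rel_tol: float = 0.2,
    floor: float | None = None,
) -> ComparisonImage:
    """Pixel-wise fuzzy comparison of two registered chromatograms.

    ``radius`` sets the fuzzy neighborhood half-width in pixels; ``rel_tol``
    the relative difference below which pixels count as equal; ``floor`` the
    intensity below which both images are considered background (default:
    1% of the global maximum, which keeps the field invariant when both
    grids are rescaled together).
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    a = analyzed.intensities if isinstance(analyzed, ChromatogramGrid) else np.asarray(analyzed, dtype=float)
    b = reference.intensities if isinstance(reference, ChromatogramGrid) else np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"grid dimensions differ: {a.shape} vs {b.shape}")
    if floor is None:
        top = max(a.max(initial=0.0), b.max(initial=0.0))
        floor = 0.01 * top if top > 0 else 1.0
    fwd = _directional(a, b, radius, rel_tol, floor)
    bwd = _directional(b, a, radius, rel_tol, floor)
    signed = (fwd - bwd) / 2.0
    return ComparisonImage(
        signed=signed, radius=radius, rel_tol=rel_tol, floor=float(floor),
        analyzed_id=getattr(analyzed, "sample_id", ""),
        reference_id=getattr(reference, "sample_id", ""),
    )


def render_rgb(
    comparison: ComparisonImage,
    path=None,
    *,
    background: int = 0,
):
    """Render the signed field as an RGB image (green = analyzed higher,
    red = reference higher); optionally write a PNG.

    Returns the (H, W, 3) uint8 array.  Swapping the comparison's inputs
    exactly swaps the red and green channels.
    """
    s = comparison.signed
    img = np.full((*s.shape, 3), background, dtype=np.uint8)
    pos = np.clip(s, 0, 1)
    neg = np.clip(-s, 0, 1)
    img[..., 1] = np.maximum(img[..., 1], np.round(pos * 255).astype(np.uint8))
    img[..., 0] = np.maximum(img[..., 0], np.round(neg * 255).astype(np.uint8))
    if path is not None:
        from PIL import Image

        Image.fromarray(img, mode="RGB").save(path)
    return img
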