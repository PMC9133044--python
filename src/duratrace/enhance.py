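"""Axon enhancement: MIP, multiscale vesselness, normalization and complement.

The enhancement chain turns a 3D confocal stack of Tubb3-stained meninges into
a 2D map ``P`` in [0, 1] in which tubular (axon-like) structures are bright,
together with its complement ``1 - P`` used as the path-cost image by the
centerline tracer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import frangi as _frangi

__all__ = [
    "ImageStack3D",
    "EnhancedImage",
    "max_intensity_projection",
    "frangi_vesselness",
    "normalize_and_complement",
    "enhance_stack",
]


@dataclass
class ImageStack3D:
    """A calibrated 3D fluorescence stack.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Intensity grid, z first. Finite and non-negative.
    spacing : tuple of float
        ``(dx, dy, dz)`` voxel spacing in µm.
    bit_depth : int
        8 or 16; fixes the nominal dynamic range ``[0, 2**bit_depth - 1]``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.14, 1.14, 1.0)
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("stack must be a non-empty 3D array (nz, ny, nx)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if not np.all(np.isfinite(self.voxels)) or self.voxels.min() < 0:
            raise ValueError("intensities must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class EnhancedImage:
    """Vesselness map ``P`` in [0, 1] and its complement used as path cost."""

    P: np.ndarray
    spacing: tuple[float, float] = (1.14, 1.14)
    scales_used: list[float] = field(default_factory=list)

    @property
    def cost(self) -> np.ndarray:
        """Path-cost image ``1 - P`` (axons darker than background)."""
        return 1.0 - self.P


def max_intensity_projection(stack: ImageStack3D) -> np.ndarray:
    """Project a stack along z: ``out(y, x) = max_z stack(z, y, x)``."""
    if not isinstance(stack, ImageStack3D):
        stack = ImageStack3D(np.asarray(stack))
    return stack.voxels.max(axis=0)


def frangi_vesselness(
    img: np.ndarray,
    scales: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0),
    beta: float = 0.5,
    c: float | str = "auto",
    bright_ridges: bool = True,
) -> np.ndarray:
    """Multiscale Hessian vesselness (Frangi) of a 2D image.

    For each scale sigma the image is smoothed with a Gaussian of that width
    (scale-normalized derivatives) and the Hessian eigenvalues
    ``|l1| <= |l2|`` scored with the classic bright-ridge measure
    ``exp(-R_B^2 / 2 beta^2) * (1 - exp(-S^2 / 2 c^2))`` where
    ``R_B = l1 / l2`` (blobness) and ``S = sqrt(l1^2 + l2^2)``
    (structureness); the response is zero where ``l2 > 0`` (dark ridge).
    The output is the maximum over scales.

    Parameters
    ----------
    scales : sequence of float
        Gaussian scales in pixels; all must be positive.
    beta : float
        Ridge-asymmetry sensitivity.
    c : float or "auto"
        Structureness sensitivity; "auto" uses half the maximum Hessian norm
        per scale.
    bright_ridges : bool
        True for fluorescence (bright axons on dark background).
    """
    scales = tuple(float(s) for s in scales)
    if len(scales) == 0 or any(s <= 0 for s in scales):
        raise ValueError("scales must be non-empty and positive")
    img = np.asarray(img, dtype=float)
    gamma = None if c == "auto" else float(c)
    return _frangi(
        img,
        sigmas=scales,
        beta=beta,
        gamma=gamma,
        black_ridges=not bright_ridges,
    )


def normalize_and_complement(
    img: np.ndarray,
    spacing: tuple[float, float] = (1.14, 1.14),
    scales_used: tuple[float, ...] = (),
) -> EnhancedImage:
    """Rescale an image to [0, 1] and pair it with its intensity complement.

    ``P = (img - min) / (max - min)``; a constant input maps to ``P = 0``
    everywhere so that the cost image is 1 (no preferred path).
    """
    img = np.asarray(img, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains NaN or Inf")
    lo, hi = img.min(), img.max()
    if hi > lo:
        P = (img - lo) / (hi - lo)
    else:
        P = np.zeros_like(img)
    return EnhancedImage(P=P, spacing=tuple(spacing), scales_used=list(scales_used))


def enhance_stack(
    stack: ImageStack3D,
    scales: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0),
    beta: float = 0.5,
    c: float | str = "auto",
) -> EnhancedImage:
    """Full enhancement chain: MIP -> vesselness -> normalize + complement."""
    mip = max_intensity_projection(stack)
    v = frangi_vesselness(mip, scales=scales, beta=beta, c=c)
    return normalize_and_complement(
        v, spacing=stack.spacing[:2], scales_used=scales
    )
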