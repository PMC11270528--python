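"""HR -> LR degradation: Gaussian blur followed by x2 areal down-sampling.

The low-resolution counterpart of a simulated high-resolution spectrum is
produced by convolving with a small normalized Gaussian kernel — default
dimensions (5, 7) in (F1, F2) — and then down-sampling by areal
interpolation, which for an integer factor on divisible grids is exact
block averaging.  At the default factor 2 this halves the resolution along
both axes (256 x 16384 -> 128 x 8192).

Kernel standard deviations default to (kernel_size - 1)/4 pixels per axis,
placing ±2 sigma at the kernel edge (a standard truncation).  Boundary
handling is reflect padding so crowded spectral margins are not darkened;
both choices are configurable and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import Spectrum2D

__all__ = ["DegradeConfig", "gaussian_kernel", "gaussian_blur", "areal_downsample", "degrade"]


@dataclass(frozen=True)
class DegradeConfig:
    kernel_rows: int = 5
    kernel_cols: int = 7
    sigma_rows: float | None = None   # None -> (kernel_rows - 1) / 4
    sigma_cols: float | None = None   # None -> (kernel_cols - 1) / 4
    factor: int = 2
    boundary: str = "reflect"

    def __post_init__(self) -> None:
        for k in (self.kernel_rows, self.kernel_cols):
            if k < 1 or k % 2 == 0:
                raise ValueError(f"kernel dimensions must be odd and positive, got {k}")
        if self.factor < 1:
            raise ValueError("down-sampling factor must be >= 1")

    @property
    def sigmas(self) -> tuple[float, float]:
        sr = self.sigma_rows if self.sigma_rows is not None else (self.kernel_rows - 1) / 4.0
        sc = self.sigma_cols if self.sigma_cols is not None else (self.kernel_cols - 1) / 4.0
        return (sr, sc)


def gaussian_kernel(n_rows: int, n_cols: int, sigma_rows: float, sigma_cols: float) -> np.ndarray:
    """Separable truncated Gaussian kernel, normalized to sum to 1."""

    def axis_kernel(n: int, sigma: float) -> np.ndarray:
        x = np.arange(n, dtype=np.float64) - (n - 1) / 2.0
        if sigma <= 0:
            k = (x == 0).astype(np.float64)
        else:
            k = np.exp(-0.5 * (x / sigma) ** 2)
        return k / k.sum()

    return np.outer(axis_kernel(n_rows, sigma_rows), axis_kernel(n_cols, sigma_cols))


def gaussian_blur(s: Spectrum2D, cfg: DegradeConfig = DegradeConfig()) -> Spectrum2D:
    """Convolve the grid with the normalized Gaussian kernel (dims unchanged)."""
    if s.shape[0] < cfg.kernel_rows or s.shape[1] < cfg.kernel_cols:
        raise ValueError("grid smaller than the blur kernel")
    sr, sc = cfg.sigmas
    kernel = gaussian_kernel(cfg.kernel_rows, cfg.kernel_cols, sr, sc)
    blurred = ndimage.correlate(s.grid.astype(np.float64), kernel, mode=cfg.boundary)
    out = s.copy()
    out.grid = blurred.astype(np.float32)
    return out


def areal_downsample(s: Spectrum2D, factor: int = 2) -> Spectrum2D:
    """Block-mean down-sampling: each output pixel is the mean of its
    factor x factor source block.  Axis ranges are unchanged; point counts
    divide by ``factor``."""
    if factor == 1:
        return s.copy()
    n1, n2 = s.shape
    if n1 % factor or n2 % factor:
        raise ValueError(f"factor {factor} does not divide grid dims {s.shape}")
    g = s.grid.astype(np.float64)
    small = g.reshape(n1 // factor, factor, n2 // factor, factor).mean(axis=(1, 3))
    return Spectrum2D(
        small.astype(np.float32),
        s.f1_axis.with_points(n1 // factor),
        s.f2_axis.with_points(n2 // factor),
        s.observe_frequency,
        s.label,
        dict(s.meta),
    )


def degrade(s: Spectrum2D, cfg: DegradeConfig = DegradeConfig()) -> Spectrum2D:
    """Full degradation: blur then areal down-sampling (the LR counterpart)."""
    return areal_downsample(gaussian_blur(s, cfg), cfg.factor)
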