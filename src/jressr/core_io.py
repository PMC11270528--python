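"""Spectrum container, axis conventions, unit conversions and file I/O.

Coordinate conventions
----------------------
A 2D J-resolved spectrum is stored as a ``(n_f1, n_f2)`` float32 grid.
Rows are indexed by the indirect (F1, J-coupling, Hz) axis and columns by
the direct (F2, chemical shift, ppm) axis.  Row index 0 corresponds to the
start of the F1 axis and column index 0 to the start of the F2 axis; all
pixel coordinates are 0-based ``(row, col)``.

Pixel *i* of an axis covers the physical interval
``[start + i*w, start + (i+1)*w)`` with ``w = (end - start)/n_points``; its
centre coordinate is ``start + (i + 0.5)*w``.  For an even number of F1 rows
spanning a symmetric range ``[-J, J]`` the J = 0 line therefore falls on the
boundary between rows ``n/2 - 1`` and ``n/2``, which makes the "upper half"
rows ``0 .. n/2-1`` and the "lower half" rows ``n/2 .. n-1``.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "Axis",
    "Spectrum2D",
    "UnitMismatchError",
    "SpectrumParseError",
    "pixels_to_ppm",
    "ppm_to_hz",
    "round_away",
    "flip_f1",
    "read_spectrum",
    "write_spectrum",
    "default_f1_axis",
    "default_f2_axis",
]

#: F1 (J-coupling) range in Hz of the reference 600 MHz J-Res grid.
F1_RANGE_HZ = (-39.1542, 39.1542)
#: F2 (chemical shift) range in ppm of the reference grid.
F2_RANGE_PPM = (-3.560, 13.129)


class UnitMismatchError(ValueError):
    """An operation received an axis with the wrong physical unit."""


class SpectrumParseError(ValueError):
    """A spectrum file is malformed or violates container invariants."""


@dataclass(frozen=True)
class Axis:
    """One spectral dimension: a uniform grid of ``n_points`` pixels.

    Parameters
    ----------
    n_points : int
        Number of pixels, at least 2.
    start, end : float
        Physical coordinates of the axis edges (Hz for F1, ppm for F2).
    unit : str
        Either ``"Hz"`` or ``"ppm"``.
    """

    n_points: int
    start: float
    end: float
    unit: str

    def __post_init__(self) -> None:
        # n_points == 1 is permitted so that down-sampling a 2x2 grid by 2
        # remains well defined (the pixel width is still (end-start)/n).
        if self.n_points < 1:
            raise ValueError(f"axis needs >= 1 point, got {self.n_points}")
        if self.start == self.end:
            raise ValueError("axis start and end must differ")
        if self.unit not in ("Hz", "ppm"):
            raise ValueError(f"unknown axis unit {self.unit!r}")

    @property
    def pixel_width(self) -> float:
        """Signed physical width of one pixel."""
        return (self.end - self.start) / self.n_points

    def centers(self) -> np.ndarray:
        """Physical coordinates of the pixel centres."""
        w = self.pixel_width
        return self.start + (np.arange(self.n_points) + 0.5) * w

    def with_points(self, n_points: int) -> "Axis":
        """Same physical range re-gridded to ``n_points`` pixels."""
        return dataclasses.replace(self, n_points=n_points)


def default_f1_axis(n_points: int = 256) -> Axis:
    return Axis(n_points, F1_RANGE_HZ[0], F1_RANGE_HZ[1], "Hz")


def default_f2_axis(n_points: int = 16384) -> Axis:
    return Axis(n_points, F2_RANGE_PPM[0], F2_RANGE_PPM[1], "ppm")


@dataclass
class Spectrum2D:
    """A processed 2D J-Res spectrum: intensity grid plus physical axes.

    ``grid`` is coerced to float32 (spectral data have a high dynamic range
    and 8-bit image conventions are inadequate, but float64 storage would
    double file sizes for no analytical gain).
    """

    grid: np.ndarray
    f1_axis: Axis
    f2_axis: Axis
    observe_frequency: float = 600.0
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-dimensional")
        if self.grid.shape != (self.f1_axis.n_points, self.f2_axis.n_points):
            raise ValueError(
                f"grid shape {self.grid.shape} does not match axes "
                f"({self.f1_axis.n_points}, {self.f2_axis.n_points})"
            )
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite intensities")
        if self.observe_frequency <= 0:
            raise ValueError("observe_frequency must be positive (MHz)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def copy(self) -> "Spectrum2D":
        return Spectrum2D(
            self.grid.copy(), self.f1_axis, self.f2_axis,
            self.observe_frequency, self.label, dict(self.meta),
        )


def pixels_to_ppm(d_pixels: float, axis: Axis) -> float:
    """Convert a pixel distance along a ppm axis to a ppm distance.

    Raises
    ------
    UnitMismatchError
        If ``axis`` is not a ppm axis.
    """
    if axis.unit != "ppm":
        raise UnitMismatchError(f"expected a ppm axis, got unit {axis.unit!r}")
    if d_pixels < 0:
        raise ValueError("pixel distance must be non-negative")
    return d_pixels * abs(axis.pixel_width)


def ppm_to_hz(d_ppm: float, observe_frequency: float = 600.0) -> float:
    """Convert a ppm distance to Hz at the given observe frequency (MHz).

    By definition of the ppm scale, 1 ppm corresponds to the observe
    frequency expressed in Hz (600 Hz at 600 MHz).
    """
    if observe_frequency <= 0:
        raise ValueError("observe_frequency must be positive (MHz)")
    return d_ppm * observe_frequency


def round_away(x: float, ndigits: int) -> float:
    """Round half away from zero to ``ndigits`` decimals.

    Python's builtin ``round`` rounds half to even; printed spectroscopy
    distances conventionally round half away from zero.
    """
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def flip_f1(spectrum: Spectrum2D) -> Spectrum2D:
    """Mirror a spectrum about the J = 0 line (reverse the F1 rows).

    An involution: applying it twice returns the original grid exactly.
    """
    out = spectrum.copy()
    out.grid = spectrum.grid[::-1].copy()
    return out


# ---------------------------------------------------------------------------
# Native container: single-file HDF5 with the grid and axis metadata.
# ---------------------------------------------------------------------------

_AXIS_KEYS = ("n_points", "start", "end", "unit")


def write_spectrum(spectrum: Spectrum2D, path: str | os.PathLike) -> None:
    """Write a spectrum to the native HDF5 container (bit-exact round trip)."""
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("grid", data=spectrum.grid, dtype="float32")
        for prefix, axis in (("f1", spectrum.f1_axis), ("f2", spectrum.f2_axis)):
            for key in _AXIS_KEYS:
                dset.attrs[f"{prefix}_{key}"] = getattr(axis, key)
        dset.attrs["observe_frequency"] = spectrum.observe_frequency
        dset.attrs["label"] = spectrum.label
        for k, v in spectrum.meta.items():
            f.attrs[k] = v


def read_spectrum(path: str | os.PathLike, format: str = "native") -> Spectrum2D:
    """Read a spectrum from disk.

    Only the native HDF5 container is supported; ``format`` other than
    ``"native"`` raises.  Readers for vendor processed-data formats can be
    registered downstream but are not shipped here.
    """
    if format != "native":
        raise SpectrumParseError(f"unknown spectrum format {format!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        with h5py.File(path, "r") as f:
            dset = f["grid"]
            grid = dset[...]
            axes = []
            for prefix in ("f1", "f2"):
                kwargs = {}
                for key in _AXIS_KEYS:
                    attr = f"{prefix}_{key}"
                    if attr not in dset.attrs:
                        raise SpectrumParseError(f"missing axis metadata {attr!r}")
                    kwargs[key] = dset.attrs[attr]
                axes.append(
                    Axis(int(kwargs["n_points"]), float(kwargs["start"]),
                         float(kwargs["end"]), str(kwargs["unit"]))
                )
            freq = float(dset.attrs.get("observe_frequency", 600.0))
            label = str(dset.attrs.get("label", ""))
            meta = {k: f.attrs[k] for k in f.attrs}
    except (KeyError, OSError) as exc:
        raise SpectrumParseError(f"cannot parse spectrum file {path}: {exc}") from exc
    try:
        return Spectrum2D(grid, axes[0], axes[1], freq, label, meta)
    except ValueError as exc:
        raise SpectrumParseError(str(exc)) from exc
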