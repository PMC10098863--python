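"""Cube preprocessing: crop, spectral smoothing, reflectance correction.

Raw comb cubes go through three steps before unmixing: cropping to the
region of interest around the bird, polynomial (Savitzky–Golay)
smoothing along the spectral axis to suppress band-to-band sensor
noise, and two-reference reflectance correction

    R = (raw - dark) / (white - dark)

which converts sensor counts to relative reflectance and removes the
spatially varying illumination and shadow terms. White and dark
references may be full cubes (per-pixel calibration) or single spectra
broadcast to every pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .envi_io import HyperCube

__all__ = ["ROI", "crop_roi", "smooth_spectra", "reflectance_correct", "DegenerateReferenceError"]


class DegenerateReferenceError(ValueError):
    """White and dark references coincide in at least one band."""


@dataclass(frozen=True)
class ROI:
    """Half-open pixel window [y0, y1) x [x0, x1)."""

    y0: int
    y1: int
    x0: int
    x1: int

    def __post_init__(self) -> None:
        if not (0 <= self.y0 < self.y1 and 0 <= self.x0 < self.x1):
            raise ValueError(f"ROI bounds must satisfy 0 <= y0 < y1 and 0 <= x0 < x1, got {self}")


def crop_roi(cube: HyperCube, roi: ROI) -> HyperCube:
    """Crop the cube spatially; the wavelength axis is untouched."""
    y, x, _ = cube.shape
    if roi.y1 > y or roi.x1 > x:
        raise ValueError(f"ROI {roi} exceeds cube extent {y}x{x}")
    return HyperCube(
        values=cube.values[roi.y0 : roi.y1, roi.x0 : roi.x1, :].copy(),
        wavelengths=cube.wavelengths,
    )


def smooth_spectra(cube: HyperCube, window: int = 7, order: int = 2) -> HyperCube:
    """Savitzky–Golay smoothing of every pixel spectrum.

    Each spectrum is replaced by the local least-squares polynomial fit
    of the given odd ``window`` and polynomial ``order`` along the band
    axis. Edge samples are handled by fitting the edge windows with the
    same polynomial order and evaluating the fit there, which preserves
    the filter's polynomial-reproduction property (constants and, for
    ``order >= 1``, straight lines pass through unchanged everywhere,
    edges included).
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if order >= window:
        raise ValueError(f"order ({order}) must be smaller than window ({window})")
    if window > cube.n_bands:
        raise ValueError(f"window ({window}) exceeds band count ({cube.n_bands})")
    smoothed = savgol_filter(
        cube.values.astype(float), window_length=window, polyorder=order, axis=2, mode="interp"
    )
    return HyperCube(values=smoothed, wavelengths=cube.wavelengths)


def _as_reference(ref: HyperCube | np.ndarray, cube: HyperCube, name: str) -> np.ndarray:
    """Coerce a reference to an array broadcastable against the cube."""
    arr = ref.values if isinstance(ref, HyperCube) else np.asarray(ref, dtype=float)
    if arr.ndim == 1:
        if arr.shape[0] != cube.n_bands:
            raise ValueError(f"{name} spectrum length {arr.shape[0]} != bands {cube.n_bands}")
        return arr[np.newaxis, np.newaxis, :]
    if arr.shape != cube.shape:
        raise ValueError(f"{name} reference shape {arr.shape} incompatible with cube {cube.shape}")
    return arr


def reflectance_correct(
    cube: HyperCube,
    white: HyperCube | np.ndarray,
    dark: HyperCube | np.ndarray,
    clip_max: float = 1.5,
) -> HyperCube:
    """Two-reference reflectance correction, clipped to [0, ``clip_max``].

    ``white`` and ``dark`` are either cubes of the same shape or single
    spectra broadcast over all pixels. The result is invariant under a
    common affine rescaling of (raw, white, dark); the clip ceiling
    tolerates specular pixels without hiding reference errors.

    Raises
    ------
    DegenerateReferenceError
        If white equals dark in any band (zero dynamic range).
    """
    w = _as_reference(white, cube, "white")
    d = _as_reference(dark, cube, "dark")
    denom = w - d
    degenerate = np.any(np.isclose(denom, 0.0), axis=(0, 1))
    if np.any(degenerate):
        bands = np.nonzero(degenerate)[0]
        raise DegenerateReferenceError(
            f"white and dark references coincide in band(s) {bands.tolist()}"
        )
    corrected = (cube.values.astype(float) - d) / denom
    return HyperCube(values=np.clip(corrected, 0.0, clip_max), wavelengths=cube.wavelengths)
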