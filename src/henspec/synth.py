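"""Seeded generators for comb-like spectra and linearly mixed cubes.

The farm-acquired comb dataset is not distributable, so the pipeline is
exercised on synthetic data that emulate its two documented features:

1. **Class contrast of comb reflectance.** Both classes share the
   qualitative comb shape — low reflectance in the blue/green, a
   sigmoidal rise through the red edge, a near-infrared plateau — but
   the abnormal (low-egg-production) class has higher reflectance over
   400–600 nm and a steeper mean slope over the 450–600 nm rise,
   consistent with the pale, lusterless combs of low-laying hens.

2. **Linear mixing with pure pixels.** Mixed-cube pixels follow
   r = gamma * M @ alpha + n with abundances alpha drawn from the flat
   simplex (Dirichlet(1,...,1)), illumination scale gamma uniform on
   [0.8, 1.2], and at least one planted pure pixel (one-hot alpha,
   gamma = 1) per end member, so vertex-recovery claims can be checked
   against ground truth.

Defaults mirror the study conditions: 300 bands over 400–1000 nm, a
flock of 300 hens at a 7:3 normal:abnormal ratio. The reflectance
noise level (sd 0.005) and the smooth per-bird perturbation are chosen
as realistic for calibrated reflectance at this band count; the
abnormal slope gain (1.5) is a free parameter setting class
separability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .envi_io import HyperCube

__all__ = ["SynthConfig", "LabeledSpectrum", "make_comb_endmembers", "make_flock_spectra", "make_mixed_cube", "largest_remainder_counts"]

CLASS_NORMAL = "normal"
CLASS_ABNORMAL = "abnormal"


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults are the study conditions."""

    L: int = 300
    wl_min: float = 400.0
    wl_max: float = 1000.0
    n_hens: int = 300
    class_ratio: tuple[int, int] = (7, 3)  # normal : abnormal
    noise_sd: float = 0.005
    slope_gain_abnormal: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 8:
            raise ValueError(f"need at least 8 bands, got L={self.L}")
        if not self.wl_min < self.wl_max:
            raise ValueError("wavelength range must be increasing")
        if min(self.class_ratio) <= 0:
            raise ValueError("class ratio parts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 1.0 <= self.slope_gain_abnormal <= 1.9:
            raise ValueError("slope_gain_abnormal must lie in [1.0, 1.9] to keep reflectance in [0, 1]")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wl_min, self.wl_max, self.L)


@dataclass
class LabeledSpectrum:
    """One comb reflectance curve with its laying-status label."""

    spectrum: np.ndarray
    wavelengths: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.spectrum = np.asarray(self.spectrum, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.spectrum.shape != self.wavelengths.shape:
            raise ValueError("spectrum and wavelength lengths differ")
        if self.label not in (CLASS_NORMAL, CLASS_ABNORMAL):
            raise ValueError(f"label must be {CLASS_NORMAL!r} or {CLASS_ABNORMAL!r}")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def make_comb_endmembers(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Class template spectra ``(normal, abnormal)`` on the wavelength grid.

    Both are logistic rises from a low blue/green floor to a
    near-infrared plateau. The abnormal template has a higher floor, an
    earlier and steeper rise, and an amplitude scaled by
    ``slope_gain_abnormal``, which makes it strictly brighter over
    400–600 nm and strictly steeper (mean derivative) over 450–600 nm.
    """
    wl = cfg.wavelengths
    g = cfg.slope_gain_abnormal
    normal = 0.08 + 0.45 * _sigmoid((wl - 580.0) / 40.0)
    abnormal = 0.12 + 0.45 * g * _sigmoid((wl - 560.0) / 35.0)
    return normal, abnormal


def largest_remainder_counts(total: int, ratio: Sequence[float]) -> list[int]:
    """Integer class counts summing to ``total``, proportional to ``ratio``.

    Largest-remainder rounding; ties resolve to the earlier class.
    """
    ratio = np.asarray(ratio, dtype=float)
    quotas = total * ratio / ratio.sum()
    counts = np.floor(quotas).astype(int)
    remainder = int(total - counts.sum())
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    return counts.tolist()


def _smooth_perturbation(rng: np.random.Generator, wl: np.ndarray, amplitude: float) -> np.ndarray:
    """Smooth random curve: cubic spline through ~8 jittered control points."""
    knots = np.linspace(wl[0], wl[-1], 8)
    return CubicSpline(knots, rng.normal(0.0, amplitude, size=knots.size))(wl)


def make_flock_spectra(
    cfg: SynthConfig,
    class_counts: Optional[tuple[int, int]] = None,
) -> list[LabeledSpectrum]:
    """Generate labeled comb spectra for a flock.

    Class counts default to largest-remainder rounding of
    ``cfg.class_ratio`` over ``cfg.n_hens``; pass ``class_counts``
    (normal, abnormal) to fix them exactly. Each bird's spectrum is its
    class template, scaled by a mild per-bird amplitude factor, plus a
    smooth spline perturbation and white noise of sd ``cfg.noise_sd``,
    clipped to [0, 1.2]. Fully reproducible from ``cfg.seed``.
    """
    if class_counts is None:
        if cfg.n_hens < 2:
            raise ValueError(f"need at least 2 hens, got {cfg.n_hens}")
        n_normal, n_abnormal = largest_remainder_counts(cfg.n_hens, cfg.class_ratio)
    else:
        n_normal, n_abnormal = class_counts
        if n_normal < 0 or n_abnormal < 0 or n_normal + n_abnormal < 2:
            raise ValueError("class counts must be nonnegative and sum to >= 2")
    rng = np.random.default_rng(cfg.seed)
    wl = cfg.wavelengths
    templates = dict(zip((CLASS_NORMAL, CLASS_ABNORMAL), make_comb_endmembers(cfg)))

    spectra: list[LabeledSpectrum] = []
    for label, count in ((CLASS_NORMAL, n_normal), (CLASS_ABNORMAL, n_abnormal)):
        template = templates[label]
        for _ in range(count):
            amp = 1.0 + 0.03 * rng.standard_normal()
            curve = (
                template * amp
                + _smooth_perturbation(rng, wl, 0.01)
                + rng.normal(0.0, cfg.noise_sd, size=cfg.L)
            )
            spectra.append(
                LabeledSpectrum(np.clip(curve, 0.0, 1.2), wl.copy(), label)
            )
    return spectra


def make_mixed_cube(
    cfg: SynthConfig,
    endmembers: np.ndarray,
    shape: tuple[int, int] = (32, 32),
    pure_pixels: int = 1,
    snr_db: Optional[float] = None,
    gamma_range: tuple[float, float] = (0.8, 1.2),
) -> tuple[HyperCube, np.ndarray, np.ndarray]:
    """Linearly mixed cube with planted pure pixels and ground truth.

    Parameters
    ----------
    endmembers
        L x p matrix of end-member spectra (columns).
    shape
        Spatial extent (Y, X).
    pure_pixels
        Planted pure pixels per end member (one-hot abundance, gamma=1).
    snr_db
        Additive white Gaussian noise level; ``None`` means noiseless.
        The noise sd is set from the mean pixel power so that
        10*log10(P_signal / P_noise) equals ``snr_db``.
    gamma_range
        Uniform range of the per-pixel illumination scale factor.

    Returns
    -------
    (cube, abundances, pure_indices)
        ``abundances`` has shape (Y, X, p); ``pure_indices`` is the
        (p * pure_pixels,) array of flat raster indices of the planted
        pure pixels, grouped by end member.
    """
    M = np.asarray(endmembers, dtype=float)
    if M.ndim != 2:
        raise ValueError("endmembers must be an L x p matrix")
    L, p = M.shape
    if p < 1 or p > L:
        raise ValueError(f"need 1 <= p <= L, got p={p}, L={L}")
    if pure_pixels < 1:
        raise ValueError("pure_pixels must be >= 1")
    Y, X = shape
    N = Y * X
    if N < p * pure_pixels:
        raise ValueError("cube too small for the requested pure pixels")
    rng = np.random.default_rng(cfg.seed)

    alpha = rng.dirichlet(np.ones(p), size=N)  # flat simplex
    gamma = rng.uniform(*gamma_range, size=N)
    pure_idx = rng.choice(N, size=p * pure_pixels, replace=False)
    for j in range(p):
        for i in pure_idx[j * pure_pixels : (j + 1) * pure_pixels]:
            alpha[i] = np.eye(p)[j]
            gamma[i] = 1.0

    pixels = (gamma[:, None] * (alpha @ M.T))  # N x L
    if snr_db is not None:
        p_signal = float(np.mean(pixels**2))
        noise_sd = np.sqrt(p_signal / (10.0 ** (snr_db / 10.0)))
        pixels = pixels + rng.normal(0.0, noise_sd, size=pixels.shape)

    wl = cfg.wavelengths if cfg.L == L else np.linspace(cfg.wl_min, cfg.wl_max, L)
    cube = HyperCube(values=pixels.reshape(Y, X, L), wavelengths=wl)
    return cube, alpha.reshape(Y, X, p), pure_idx
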