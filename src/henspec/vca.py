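"""Vertex Component Analysis (VCA) end-member extraction.

Under the linear mixing model each pixel spectrum is

    r = gamma * M @ alpha + n

with ``M`` the L x p matrix of pure-material (end-member) spectra,
``alpha`` a nonnegative abundance vector summing to one, ``gamma`` an
illumination scale factor and ``n`` additive noise. The pixel cloud
then lies in a convex cone whose extreme rays are the end members; the
projective projection y = r / (r^T u) collapses illumination scale and
maps the cone onto a simplex whose vertices are the end members.

VCA finds those vertices by repeatedly projecting the data onto a
random direction orthogonal to the span of the vertices found so far
and taking the pixel with the largest absolute projection. Two
subspace-identification branches are used depending on the estimated
SNR: a projective projection in the signal subspace at high SNR, and an
orthogonal projection of the mean-removed data augmented with a
constant coordinate at low SNR.

For the comb application the cube typically contains two materials
(comb tissue and background); :func:`select_comb_endmember` picks the
comb column as the end member with the highest mean reflectance over
the red/near-infrared window, where comb tissue is bright.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional
import warnings

import numpy as np

__all__ = [
    "SpectralMatrix",
    "EndmemberSet",
    "estimate_snr",
    "vca_extract",
    "spectral_angle",
    "cube_to_matrix",
    "select_comb_endmember",
    "SNR_CAP_DB",
]

# Sentinel for a numerically zero residual (noiseless data).
SNR_CAP_DB = 300.0


@dataclass
class SpectralMatrix:
    """L x N matrix of pixel spectra, one column per pixel."""

    R: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.R.ndim != 2:
            raise ValueError(f"spectral matrix must be 2-D (L, N), got {self.R.shape}")
        if not np.all(np.isfinite(self.R)):
            raise ValueError("spectral matrix contains non-finite entries")

    @property
    def n_bands(self) -> int:
        return self.R.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.R.shape[1]


@dataclass
class EndmemberSet:
    """Extracted end members: L x p matrix plus the source pixel columns."""

    M: np.ndarray
    indices: np.ndarray
    p: int

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.indices = np.asarray(self.indices, dtype=int)
        if self.M.shape[1] != self.p or self.indices.shape != (self.p,):
            raise ValueError("end-member matrix / index bookkeeping inconsistent")
        if len(set(self.indices.tolist())) != self.p:
            raise ValueError("end-member pixel indices must be distinct")


def cube_to_matrix(cube) -> SpectralMatrix:
    """Unfold a (Y, X, L) cube into the L x N pixel matrix (N = Y*X).

    Pixel n corresponds to (y, x) = divmod(n, X) — row-major raster order.
    """
    vals = np.asarray(cube.values, dtype=float)
    y, x, l = vals.shape
    return SpectralMatrix(vals.reshape(y * x, l).T)


def spectral_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle arccos(<a,b>/(|a||b|)) between two spectra, in [0, pi].

    Scale-invariant: multiplying either spectrum by a positive constant
    (the illumination factor gamma) leaves the angle unchanged.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("spectra must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("spectral angle undefined for a zero spectrum")
    cos = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.arccos(cos))


def estimate_snr(R: SpectralMatrix | np.ndarray, p: int) -> float:
    """SNR (dB) of the data relative to its p-dimensional signal subspace.

    The signal power is taken as the power of the mean-removed data
    projected onto its first p principal directions plus the power of
    the mean itself; the noise power is the residual, with the
    correction term (p/L) * P_total discounting the noise that leaks
    into the signal subspace. Returns ``SNR_CAP_DB`` when the residual
    is numerically zero and ``-SNR_CAP_DB`` when the corrected signal
    power is non-positive (pure noise).
    """
    R = R.R if isinstance(R, SpectralMatrix) else np.asarray(R, float)
    L, N = R.shape
    if not 0 < p < min(L, N):
        raise ValueError(f"need 0 < p < min(L, N) = {min(L, N)}, got p={p}")
    r_m = R.mean(axis=1, keepdims=True)
    R0 = R - r_m
    U, _, _ = np.linalg.svd(R0, full_matrices=False)
    x_p = U[:, :p].T @ R0
    P_tot = float(np.sum(R**2)) / N
    P_sig = float(np.sum(x_p**2)) / N + float(np.sum(r_m**2))
    num = P_sig - (p / L) * P_tot
    den = P_tot - P_sig
    # Residual at or below numerical roundoff: treat as noiseless.
    if den <= 1e-12 * P_tot:
        return SNR_CAP_DB
    if num <= 0:
        return -SNR_CAP_DB
    snr = 10.0 * np.log10(num / den)
    return float(np.clip(snr, -SNR_CAP_DB, SNR_CAP_DB))


def _snr_threshold(p: int) -> float:
    return 15.0 + 10.0 * np.log10(p)


def vca_extract(
    R: SpectralMatrix | np.ndarray,
    p: int,
    seed: int = 0,
    snr_db: Optional[float] = None,
) -> EndmemberSet:
    """Extract ``p`` end members as vertices of the projected pixel simplex.

    Parameters
    ----------
    R
        L x N pixel matrix (or :class:`SpectralMatrix`).
    p
        Number of end members to extract (p >= 1, p <= N).
    seed
        Seed for the random search directions; a fixed seed gives a
        deterministic vertex set, and ties in |projection| resolve to
        the lowest pixel index.
    snr_db
        Optional externally supplied SNR; estimated from the data when
        omitted. The projective (high-SNR) branch is taken above
        15 + 10*log10(p) dB.

    Returns
    -------
    EndmemberSet
        The p selected pixel columns of ``R`` (original spectra, not the
        projected ones) and their column indices.
    """
    Rm = R.R if isinstance(R, SpectralMatrix) else np.asarray(R, dtype=float)
    L, N = Rm.shape
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    if p > N:
        raise ValueError(f"p={p} exceeds the number of pixels N={N}")
    rng = np.random.default_rng(seed)

    if p == 1:
        # Degenerate simplex: the single vertex is the longest pixel vector.
        idx = int(np.argmax(np.linalg.norm(Rm, axis=0)))
        return EndmemberSet(M=Rm[:, [idx]].copy(), indices=np.array([idx]), p=1)

    if snr_db is None:
        snr_db = estimate_snr(Rm, p) if p < min(L, N) else SNR_CAP_DB

    if snr_db > _snr_threshold(p):
        # High SNR: project onto the p-dim principal subspace of the raw
        # data, then the projective projection y = x / (x^T u).
        d = p
        U, ev, _ = np.linalg.svd(Rm @ Rm.T / N, hermitian=True)
        rank = int(np.sum(ev > ev[0] * 1e-12)) if ev.size and ev[0] > 0 else 0
        x = U[:, :d].T @ Rm  # d x N
        u = x.mean(axis=1)
        denom = x.T @ u
        # Guard near-zero projective denominators (pathological pixels).
        tiny = np.finfo(float).eps * np.max(np.abs(denom)) if denom.size else 0.0
        denom = np.where(np.abs(denom) < tiny, tiny if tiny > 0 else 1.0, denom)
        y = x / denom
    else:
        # Low SNR: mean-removed orthogonal projection onto p-1 dims,
        # augmented with a constant max-norm coordinate.
        d = p - 1
        r_m = Rm.mean(axis=1, keepdims=True)
        R0 = Rm - r_m
        U, ev, _ = np.linalg.svd(R0 @ R0.T / N, hermitian=True)
        # Affine rank: mean-removed rank plus one for the affine offset.
        rank = (int(np.sum(ev > ev[0] * 1e-12)) if ev.size and ev[0] > 0 else 0) + 1
        x = U[:, :d].T @ R0
        c = float(np.max(np.linalg.norm(x, axis=0))) if d > 0 else 1.0
        y = np.vstack([x, c * np.ones((1, N))])

    if p > rank + 1:
        warnings.warn(
            f"data are rank-deficient for p={p} (rank {rank}); "
            "returned vertices may be degenerate",
            RuntimeWarning,
        )

    dim = y.shape[0]

    A = np.zeros((dim, p))
    A[-1, 0] = 1.0
    indices = np.empty(p, dtype=int)
    for i in range(p):
        # Random direction orthogonal to the span of the vertices found so far.
        for _ in range(100):
            w = rng.standard_normal(dim)
            f = w - A @ (np.linalg.pinv(A) @ w)
            norm = np.linalg.norm(f)
            if norm > 1e-12:
                f /= norm
                break
        else:  # pragma: no cover - requires pathological rank collapse
            f = rng.standard_normal(dim)
            f /= np.linalg.norm(f)
        v = np.abs(f @ y)
        v[indices[:i]] = -np.inf  # indices must be distinct even when degenerate
        indices[i] = int(np.argmax(v))  # argmax -> lowest index on ties
        A[:, i] = y[:, indices[i]]

    return EndmemberSet(M=Rm[:, indices].copy(), indices=indices, p=p)


def select_comb_endmember(
    M: np.ndarray,
    wavelengths: np.ndarray,
    band: tuple[float, float] = (600.0, 1000.0),
) -> int:
    """Index of the end-member column brightest over ``band`` (nm).

    Comb tissue reflects strongly in the red/near-infrared plateau, so
    among the recovered end members the comb is the column with the
    highest mean reflectance in the 600-1000 nm window by default.
    """
    wl = np.asarray(wavelengths, float)
    mask = (wl >= band[0]) & (wl <= band[1])
    if not np.any(mask):
        raise ValueError(f"no wavelengths inside selection band {band}")
    return int(np.argmax(np.asarray(M, float)[mask, :].mean(axis=0)))
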