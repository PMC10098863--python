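"""Fast continuous wavelet transform with the analytic Morlet wavelet.

A reflectance curve of length L is expanded into an n x L complex
coefficient matrix W by frequency-domain filtering: the signal is
zero-padded and FFT'd once, each scale's daughter wavelet is applied as
a multiplicative Gaussian window in frequency, and an inverse FFT
yields that scale's coefficient row. The mother wavelet is

    psi(t) = exp(i*w0*t) * exp(-t^2/2)

whose Fourier transform is the Gaussian

    psi_hat(w) = sqrt(2*pi) * exp(-(w - w0)^2 / 2),

an analytic (one-sided) window centered at the dimensionless frequency
``w0``. The daughter at scale ``a`` is psi_hat(a*w), centered at
w0/a with RMS width (1/sqrt(2))/a, so only a narrow frequency window
per scale carries non-negligible weight — evaluating the product only
there is what makes the transform fast. Scales are log2-uniform over
[2^a_exp, 2^b_exp]; the defaults (200 scales over [2^5, 2^6], w0 = 8)
map a 300-band spectrum to the 200 x 300 scalogram the classifier
consumes.

:func:`naive_cwt` recomputes the identical contract by direct O(n*L^2)
DFT summation with no FFT, no frequency windowing — it exists as an
independent correctness oracle, not for production use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SQRT_2PI",
    "MorletConfig",
    "ScaleSequence",
    "CWTCoefficients",
    "FeatureMap",
    "morlet_hat",
    "freq_window",
    "make_scales",
    "fcwt_transform",
    "naive_cwt",
    "to_feature_map",
]

SQRT_2PI = float(np.sqrt(2.0 * np.pi))

#: Defaults for the comb pipeline: 200 log2-spaced scales over [2^5, 2^6].
DEFAULT_N_SCALES = 200
DEFAULT_A_EXP = 5.0
DEFAULT_B_EXP = 6.0
DEFAULT_OMEGA0 = 8.0


@dataclass(frozen=True)
class MorletConfig:
    """Morlet parameters: center frequency and frequency-domain amplitude.

    ``omega0 >= 5`` keeps the admissibility correction term (the zero-mean
    fix-up, of order exp(-omega0^2/2) ~ 4e-6 at omega0=5) negligible, so
    the plain Gaussian window is used. ``amplitude`` is the peak value of
    psi_hat; sqrt(2*pi) is the Fourier pair of the time-domain mother,
    and changing it rescales every coefficient by a global constant.
    """

    omega0: float = DEFAULT_OMEGA0
    amplitude: float = SQRT_2PI

    def __post_init__(self) -> None:
        if self.omega0 < 5.0:
            raise ValueError(f"omega0 must be >= 5 (admissibility), got {self.omega0}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class ScaleSequence:
    """n wavelet scales, log2-uniform over [2^a_exp, 2^b_exp] inclusive."""

    scales: np.ndarray
    a_exp: float
    b_exp: float
    n: int

    def __len__(self) -> int:
        return self.n


@dataclass
class CWTCoefficients:
    """Complex n x L wavelet coefficients; row k belongs to scale alpha_k."""

    W: np.ndarray
    scales: ScaleSequence
    omega0: float


@dataclass
class FeatureMap:
    """Nonnegative n x L scalogram |W| — the CNN's input image."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature map must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def morlet_hat(omega, omega0: float = DEFAULT_OMEGA0, amplitude: float = SQRT_2PI):
    """Frequency-domain Morlet window amplitude * exp(-(w-w0)^2/2).

    Real, positive, maximized (= ``amplitude``) at ``omega == omega0``.
    Accepts scalars or arrays.
    """
    omega = np.asarray(omega, dtype=float)
    out = amplitude * np.exp(-0.5 * (omega - omega0) ** 2)
    return float(out) if out.ndim == 0 else out


def freq_window(omega0: float = DEFAULT_OMEGA0) -> float:
    """RMS frequency window width of psi_hat about omega0.

    For the Gaussian window |psi_hat(w)|^2 ∝ exp(-(w-w0)^2) the
    second moment about w0 is 1/2, so the width is 1/sqrt(2)
    independently of omega0. The daughter at scale alpha has width
    freq_window() / alpha about its center omega0 / alpha.
    """
    return 1.0 / float(np.sqrt(2.0))


def make_scales(a_exp: float, b_exp: float, n: int) -> ScaleSequence:
    """n scales log2-uniform over [2^a_exp, 2^b_exp], endpoints included."""
    if n < 2:
        raise ValueError(f"need at least 2 scales, got n={n}")
    if not a_exp < b_exp:
        raise ValueError(f"need a_exp < b_exp, got ({a_exp}, {b_exp})")
    scales = np.exp2(np.linspace(float(a_exp), float(b_exp), int(n)))
    return ScaleSequence(scales=scales, a_exp=float(a_exp), b_exp=float(b_exp), n=int(n))


def default_scales() -> ScaleSequence:
    """The pipeline default: 200 scales over [2^5, 2^6]."""
    return make_scales(DEFAULT_A_EXP, DEFAULT_B_EXP, DEFAULT_N_SCALES)


def _padded_length(L: int) -> int:
    """Twice the next power of two >= L (suppresses circular wrap-around)."""
    return 2 * int(2 ** np.ceil(np.log2(L)))


def _freq_grid(nfft: int) -> np.ndarray:
    """Angular frequencies 2*pi*k/nfft for the retained one-sided bins."""
    return 2.0 * np.pi * np.arange(nfft // 2 + 1) / nfft


def fcwt_transform(
    signal: np.ndarray,
    scales: ScaleSequence | None = None,
    omega0: float = DEFAULT_OMEGA0,
    amplitude: float = SQRT_2PI,
    window_eps: float = 1e-8,
) -> CWTCoefficients:
    """FFT-based continuous Morlet transform of a 1-D signal.

    The signal is zero-padded to twice the next power of two, FFT'd
    once, multiplied per scale by the daughter window psi_hat(alpha*w)
    on the one-sided frequency grid (entries below ``window_eps`` of
    the window peak are skipped — the nonzero-frequency-window
    speedup), and inverse-FFT'd; the first L samples of each row are
    kept. Rows are stacked in scale order.
    """
    x = np.asarray(signal, dtype=float).ravel()
    L = x.size
    if L < 8:
        raise ValueError(f"signal too short for the transform (L={L} < 8)")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if scales is None:
        scales = default_scales()

    nfft = _padded_length(L)
    X = np.fft.fft(x, nfft)
    xi = _freq_grid(nfft)  # one-sided grid; the analytic window ignores the rest
    # (n, nfft//2+1) daughter windows, thresholded to realize the window skip.
    psi = morlet_hat(np.outer(scales.scales, xi), omega0, amplitude)
    psi[psi < window_eps * amplitude] = 0.0
    H = np.zeros((scales.n, nfft), dtype=complex)
    H[:, : xi.size] = psi * X[: xi.size]
    W = np.fft.ifft(H, axis=1)[:, :L]
    return CWTCoefficients(W=W, scales=scales, omega0=float(omega0))


def naive_cwt(
    signal: np.ndarray,
    scales: ScaleSequence | None = None,
    omega0: float = DEFAULT_OMEGA0,
    amplitude: float = SQRT_2PI,
) -> CWTCoefficients:
    """Direct-summation oracle for :func:`fcwt_transform`.

    Same contract and padding convention, but the forward and inverse
    transforms are explicit DFT sums (O(n * L^2)) and the daughter
    window is evaluated everywhere with no thresholding. Intended for
    signals of a few hundred samples at most.
    """
    x = np.asarray(signal, dtype=float).ravel()
    L = x.size
    if L < 8:
        raise ValueError(f"signal too short for the transform (L={L} < 8)")
    if L > 512:
        raise ValueError("naive oracle is O(L^2); use signals of length <= 512")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if scales is None:
        scales = default_scales()

    nfft = _padded_length(L)
    xp = np.zeros(nfft)
    xp[:L] = x
    k = np.arange(nfft // 2 + 1)
    t = np.arange(nfft)
    # Forward DFT on the retained one-sided bins, by explicit summation.
    F = np.exp(-2j * np.pi * np.outer(k, t) / nfft)  # (half+1, nfft)
    X = F @ xp
    xi = _freq_grid(nfft)
    W = np.empty((scales.n, L), dtype=complex)
    for row, a in enumerate(scales.scales):
        H = morlet_hat(a * xi, omega0, amplitude) * X
        # Inverse DFT restricted to the one-sided support of H.
        W[row] = (np.conj(F[:, :L]).T @ H) / nfft
    return CWTCoefficients(W=W, scales=scales, omega0=float(omega0))


def to_feature_map(coeffs: CWTCoefficients) -> FeatureMap:
    """Element-wise magnitude |W|; no rescaling is applied."""
    return FeatureMap(values=np.abs(coeffs.W))
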