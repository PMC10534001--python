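"""Percent-energy CWT scalograms and fixed-size RGB images.

Each 30-s window is transformed with an analytic generalized Morse
wavelet CWT (symmetry gamma = 3, time-bandwidth P^2 = beta*gamma = 60 —
the common analytic default — at 12 voices per octave). The scalogram is
the squared coefficient magnitude expressed as percent of total energy,

    S = |coef|^2,   Scalogram = 100 * S / sum(S),

so every non-degenerate scalogram sums to exactly 100 and is invariant
to positive rescaling of the input signal. For rendering, rows are
cropped to 0-20 Hz, min-max scaled per image, passed through a fixed
monotone colormap and bicubically resized to 224 x 224 x 3.

The CWT is computed as an FFT-domain filter bank: the Morse wavelet is
defined directly in the frequency domain, H(w) ~ w^beta * exp(-w^gamma)
for w > 0, peak-normalised to 2, with log-spaced scales. The filter bank
is cached per (length, fs, parameters), so batches of equally sized
windows reuse it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from PIL import Image
from scipy import fft as sfft

from .preprocess import SignalWindow

MORSE_GAMMA = 3.0
MORSE_P2 = 60.0  # time-bandwidth product beta*gamma


class DegenerateWindowError(ValueError):
    """Raised for identically-zero windows, which have no scalogram."""


@dataclass(frozen=True)
class WindowKey:
    participant_id: str
    channel: str
    window_index: int
    label: str


@dataclass
class ScalogramMatrix:
    """Percent-energy matrix (frequency x time), frequencies descending."""

    values: np.ndarray
    frequencies: np.ndarray
    times: np.ndarray
    provenance: WindowKey

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("scalogram values must be non-negative")


@dataclass
class ScalogramImage:
    pixels: np.ndarray  # uint8, 224 x 224 x 3
    provenance: WindowKey

    def __post_init__(self) -> None:
        if self.pixels.shape != (224, 224, 3):
            raise ValueError(f"image must be 224x224x3; got {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            raise ValueError("image must be uint8 RGB")


@lru_cache(maxsize=8)
def _filter_bank(
    n: int,
    fs: float,
    voices_per_octave: int,
    gamma: float,
    p2: float,
    fmin: float,
    fmax: float,
):
    """Morse filter bank H (n_scales x nfft, real) and frequency vector."""
    beta = p2 / gamma
    n_octaves = np.log2(fmax / fmin)
    n_scales = int(np.ceil(n_octaves * voices_per_octave)) + 1
    freqs = fmax * 2.0 ** (-np.arange(n_scales) / voices_per_octave)  # descending
    # pad past the support of the slowest wavelet (time SD ~ sqrt(p2)/(2 pi f))
    pad = int(np.ceil(4.0 * np.sqrt(p2) / (2 * np.pi * fmin) * fs))
    nfft = sfft.next_fast_len(n + pad)
    w = 2 * np.pi * np.arange(nfft) / nfft  # rad/sample on [0, 2pi)
    w_peak = (beta / gamma) ** (1.0 / gamma)
    H = np.zeros((n_scales, nfft))
    pos = (w > 0) & (w <= np.pi)
    for k, f in enumerate(freqs):
        s = w_peak / (2 * np.pi * f / fs)  # scale mapping peak -> f
        sw = s * w[pos]
        # log-domain for stability; peak value 2 at sw = w_peak (analytic convention)
        lnH = beta * np.log(sw) - sw**gamma - (beta * np.log(w_peak) - w_peak**gamma)
        H[k, pos] = 2.0 * np.exp(lnH)
    return H, freqs, nfft


def cwt_morse(
    window: SignalWindow | np.ndarray,
    fs: float | None = None,
    voices_per_octave: int = 12,
    gamma: float = MORSE_GAMMA,
    p2: float = MORSE_P2,
    freq_limits: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic Morse CWT of one window.

    Returns (coefficients, frequencies): a complex (n_scales, n_samples)
    matrix with frequency rows descending. Scales are log-spaced at
    ``voices_per_octave`` per doubling, spanning at least 0.5-20 Hz.
    """
    if isinstance(window, SignalWindow):
        x, fs = window.samples, window.fs
    else:
        if fs is None:
            raise ValueError("fs is required when passing a bare array")
        x = np.asarray(window, dtype=np.float64)
    n = len(x)
    if n < 2 * fs:
        raise ValueError(f"window must be at least 2 s ({int(2 * fs)} samples); got {n}")
    if freq_limits is None:
        fmax = min(24.0, 0.98 * fs / 2)
        freq_limits = (0.3, fmax)
    fmin, fmax = freq_limits
    if fmax < 20.0:
        raise ValueError(f"fs = {fs} Hz too low for the 20 Hz band edge (max usable {fmax:.1f} Hz)")
    H, freqs, nfft = _filter_bank(n, float(fs), voices_per_octave, gamma, p2, fmin, fmax)
    X = sfft.fft(x, nfft)
    coefs = sfft.ifft(X[None, :] * H, axis=1, workers=1)[:, :n]
    return coefs, freqs.copy()


def to_scalogram(
    coefs: np.ndarray,
    frequencies: np.ndarray,
    fs: float,
    provenance: WindowKey | None = None,
) -> ScalogramMatrix:
    """Squared-magnitude scalogram normalised to a grand total of 100."""
    S = np.abs(coefs) ** 2
    total = S.sum()
    if total == 0:
        raise DegenerateWindowError("identically zero window has no percent-energy scalogram")
    values = 100.0 * S / total
    times = np.arange(S.shape[1]) / fs
    if provenance is None:
        provenance = WindowKey("", "", -1, "")
    return ScalogramMatrix(values=values, frequencies=np.asarray(frequencies), times=times,
                           provenance=provenance)


@lru_cache(maxsize=4)
def _colormap_lut(name: str) -> np.ndarray:
    import matplotlib

    cm = matplotlib.colormaps[name]
    return (cm(np.linspace(0.0, 1.0, 256))[:, :3] * 255.0 + 0.5).astype(np.uint8)


def render_image(
    sm: ScalogramMatrix,
    colormap: str = "viridis",
    freq_range: tuple[float, float] = (0.0, 20.0),
) -> ScalogramImage:
    """Crop to ``freq_range``, colour-map with per-image min-max scaling,
    and bicubically resize to 224 x 224 RGB (no axes or colorbar)."""
    mask = (sm.frequencies >= freq_range[0]) & (sm.frequencies <= freq_range[1])
    if not np.any(mask):
        raise ValueError(f"no scalogram rows inside freq_range {freq_range}")
    v = sm.values[mask]
    vmin, vmax = float(v.min()), float(v.max())
    if vmax > vmin:
        norm = (v - vmin) / (vmax - vmin)
    else:
        norm = np.zeros_like(v)
    idx = np.minimum((norm * 256.0).astype(np.intp), 255)
    rgb = _colormap_lut(colormap)[idx]
    img = Image.fromarray(rgb, mode="RGB").resize((224, 224), Image.BICUBIC)
    return ScalogramImage(pixels=np.asarray(img, dtype=np.uint8), provenance=sm.provenance)


def window_to_image(
    window: SignalWindow,
    voices_per_octave: int = 12,
    colormap: str = "viridis",
    freq_range: tuple[float, float] = (0.0, 20.0),
) -> ScalogramImage | None:
    """Full window -> image path; returns None (with a warning) for a
    degenerate all-zero window."""
    coefs, freqs = cwt_morse(window, voices_per_octave=voices_per_octave)
    key = WindowKey(window.participant_id, window.channel, window.window_index, window.class_label)
    try:
        sm = to_scalogram(coefs, freqs, window.fs, provenance=key)
    except DegenerateWindowError:
        warnings.warn(f"excluding degenerate all-zero window {key}", stacklevel=2)
        return None
    return render_image(sm, colormap=colormap, freq_range=freq_range)
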