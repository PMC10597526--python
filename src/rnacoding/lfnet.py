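"""Local filter layer: windowed Fourier analysis with learned complex filters.

The layer applies a short-time Fourier transform (Hann window, hop equal to
half the window) along the sequence axis of an ``L x D`` hidden
representation, multiplies every frame elementwise by a learned complex
filter bank, sparsifies with a soft-shrink nonlinearity, inverts the
transform by overlap-add, and adds the input back as a residual.

The periodic Hann window at half-window hop satisfies the constant
overlap-add (COLA) condition exactly, so analysis followed by plain
overlap-add synthesis is a perfect reconstruction: with an identity filter
and zero shrink threshold the layer computes ``2x``.

Everything here is written with :mod:`autograd.numpy` so the whole layer is
differentiable end to end — required both for training and for the
gradient-based mutation-effect approximations.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np


@dataclass(frozen=True)
class LfnetConfig:
    """Shape and sparsity parameters of a local-filter stack.

    ``window_length`` must be even; a default of 54 (divisible by 6) puts
    the 3-nt period on an exact frequency bin (bin 18) with an integral
    hop. ``softshrink_threshold`` is the L1 sparsity parameter of the
    soft-shrink activation applied after the filter multiplication.
    """

    window_length: int = 54
    hidden_dim: int = 32
    softshrink_threshold: float = 0.0
    n_layers: int = 1

    def __post_init__(self) -> None:
        if self.window_length % 2 != 0:
            raise ValueError("window_length must be even")
        if self.softshrink_threshold < 0:
            raise ValueError("softshrink_threshold must be nonnegative")

    @property
    def hop(self) -> int:
        return self.window_length // 2

    @property
    def n_bins(self) -> int:
        return self.window_length // 2 + 1


def hann_window(window_length: int) -> np.ndarray:
    """Periodic Hann window (COLA-exact at half-window hop)."""
    n = np.arange(window_length)
    return 0.5 - 0.5 * np.cos(2 * np.pi * n / window_length)


def init_filterbank(config: LfnetConfig, rng: np.random.RandomState, scale: float = 0.02):
    """Random complex filter bank as a (real, imag) pair, near zero.

    Near-zero initialisation makes an untrained residual layer approximate
    the identity, which keeps deep stacks trainable.
    """
    shape = (config.n_bins, config.hidden_dim)
    w_re = scale * rng.randn(*shape)
    w_im = scale * rng.randn(*shape)
    return w_re, w_im


def _frame_count(length: int, window: int, hop: int) -> int:
    # hop zeros are prepended so position 0 sits under a full COLA sum;
    # enough zeros are appended for the last original position likewise,
    # and the count is made even so the even/odd overlap-add tiling works.
    nf = int(np.ceil((length + hop) / hop)) + 1
    if nf % 2:
        nf += 1
    return nf


def stft(hidden, config: LfnetConfig):
    """Hann-windowed, half-overlapping real-to-complex transform.

    Parameters
    ----------
    hidden : array, shape (..., L, D)
        Real hidden representation; leading batch axes allowed.

    Returns
    -------
    frames : complex array, shape (..., F, B, D)
        ``B = window_length/2 + 1`` frequency bins per frame. The final
        frame is zero-padded. Inputs shorter than the window produce a
        small number of zero-padded frames.
    """
    w, hop = config.window_length, config.hop
    L = hidden.shape[-2]
    nf = _frame_count(L, w, hop)
    total = (nf - 1) * hop + w
    pad_front = anp.zeros(hidden.shape[:-2] + (hop, hidden.shape[-1]))
    pad_back = anp.zeros(hidden.shape[:-2] + (total - L - hop, hidden.shape[-1]))
    hp = anp.concatenate([pad_front, hidden, pad_back], axis=-2)
    windows = anp.stack([hp[..., k * hop : k * hop + w, :] for k in range(nf)], axis=-3)
    hann = hann_window(w)
    windows = windows * hann[:, None]
    return anp.fft.rfft(windows, axis=-2)


def softshrink(v, threshold: float):
    """Soft thresholding: shrink toward zero by ``threshold``, clip at zero."""
    return anp.sign(v) * anp.maximum(anp.abs(v) - threshold, 0.0)


def apply_filter(frames, w_re, w_im, threshold: float = 0.0):
    """Elementwise complex filter, then soft-shrink on real and imaginary parts.

    ``frames`` has shape (..., F, B, D); the filter is (B, D) broadcast over
    frames and batch.
    """
    if frames.shape[-2] != w_re.shape[0] or frames.shape[-1] != w_re.shape[1]:
        raise ValueError(
            f"filter shape {w_re.shape} does not match frames {frames.shape[-2:]}"
        )
    out = frames * (w_re + 1j * w_im)
    if threshold > 0:
        out = softshrink(anp.real(out), threshold) + 1j * softshrink(anp.imag(out), threshold)
    return out


def istft(frames, config: LfnetConfig, original_length: int):
    """Inverse transform with overlap-add; crops to ``original_length``.

    With frames produced by :func:`stft` (and no filtering) this is an exact
    inverse, because the periodic Hann window at hop = window/2 sums to one
    across overlapping frames.
    """
    w, hop = config.window_length, config.hop
    yt = anp.fft.irfft(frames, w, axis=-2)  # (..., F, w, D)
    even = yt[..., 0::2, :, :]
    odd = yt[..., 1::2, :, :]
    # consecutive even (resp. odd) frames are adjacent (offset w), so each
    # parity tiles the padded axis contiguously
    def _flatten(z):
        shp = z.shape
        return anp.reshape(z, shp[:-3] + (shp[-3] * shp[-2], shp[-1]))

    even_t = _flatten(even)           # covers [0, ...)
    odd_t = _flatten(odd)             # covers [hop, ...)
    rec = even_t[..., hop : hop + original_length, :] + odd_t[..., :original_length, :]
    return rec


def lfnet_forward(x, w_re, w_im, config: LfnetConfig):
    """One local-filter layer: istft(filter(stft(x))) + x."""
    L = x.shape[-2]
    frames = stft(x, config)
    frames = apply_filter(frames, w_re, w_im, config.softshrink_threshold)
    return istft(frames, config, L) + x


def filter_spectra(w_re: np.ndarray, w_im: np.ndarray, config: LfnetConfig):
    """Magnitude, phase and per-bin nucleotide-period annotations of a filter bank.

    Bin ``k`` of a length-``w`` window corresponds to a period of ``w/k``
    positions (infinite at DC).
    """
    z = np.asarray(w_re) + 1j * np.asarray(w_im)
    magnitude = np.abs(z)
    phase = np.arctan2(np.asarray(w_im), np.asarray(w_re))
    bins = np.arange(config.n_bins, dtype=float)
    with np.errstate(divide="ignore"):
        periods = np.where(bins > 0, config.window_length / np.maximum(bins, 1), np.inf)
    return magnitude, phase, periods


def spectra_table(w_re: np.ndarray, w_im: np.ndarray, config: LfnetConfig, layer: int = 0):
    """Tabular (layer, bin, dim, magnitude, phase, period) export for plotting."""
    import pandas as pd

    mag, phase, periods = filter_spectra(w_re, w_im, config)
    rows = []
    for b in range(mag.shape[0]):
        for d in range(mag.shape[1]):
            rows.append((layer, b, d, mag[b, d], phase[b, d], periods[b]))
    return pd.DataFrame(rows, columns=["layer", "bin", "dim", "magnitude", "phase", "period_nt"])
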