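"""Spectral-subband-centroid (SSC) front end for swallow sounds.

The chain mirrors a conventional automatic-speaker-recognition front end:

1. pre-emphasis, ``y[n] = x[n] - 0.97 x[n-1]`` — flattens spectral tilt so
   high-frequency structure (where the aspiration signature lives) is not
   swamped by the low-frequency flushing sound;
2. 20 ms frames with a 10 ms update, Hamming windowed;
3. magnitude-squared FFT per frame (zero-padded to the next power of two);
4. a Mel-warped triangular filterbank of M = 26 overlapping subbands
   spanning 0 Hz to Nyquist;
5. per frame and subband, the power-weighted mean frequency — the spectral
   subband centroid, in Hz;
6. per clip, the mean and standard deviation of each centroid over frames,
   concatenated into a single 2M = 52-dimensional feature vector.

Unlike cepstral features, SSCs are frequency *locations*: they track where
the formant-like spectral peaks sit within each subband and are therefore
naturally bounded by the subband's support and comparatively robust to
broadband noise. Because each centroid is a ratio of weighted sums over one
subband, any global power-spectrum scaling cancels; the power spectrum is
consequently left unscaled (no density normalisation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from sscswallow.audio_io import AudioClip, ValidationError

PREEMPHASIS_COEFF = 0.97


@dataclass(frozen=True)
class FeatureConfig:
    """Front-end configuration.

    Defaults follow the study conditions: 26 Mel subbands over the full band
    up to Nyquist, 20 ms / 10 ms framing, pre-emphasis 0.97, population
    standard deviation in the pooled block. ``nfft`` of ``None`` means the
    smallest power of two at least the frame length.
    """

    n_filters: int = 26
    frame_ms: float = 20.0
    hop_ms: float = 10.0
    preemphasis: float = PREEMPHASIS_COEFF
    nfft: int | None = None
    f_min: float = 0.0
    f_max: float | None = None  # None -> Nyquist of the clip
    std_ddof: int = 0  # population convention

    @property
    def n_features(self) -> int:
        return 2 * self.n_filters


@dataclass(frozen=True)
class FrameMatrix:
    """Hamming-windowed overlapping frames of one clip."""

    frames: np.ndarray  # (T, L)
    sampling_rate: int
    frame_length: int
    hop: int


@dataclass(frozen=True)
class PowerSpectrum:
    """Per-frame one-sided magnitude-squared spectra on a common bin grid."""

    psd: np.ndarray        # (T, K), K = nfft//2 + 1
    bin_freqs: np.ndarray  # (K,) Hz, bin k at k * fs / nfft
    nfft: int
    sampling_rate: int


@dataclass(frozen=True)
class MelFilterbank:
    """M triangular filters on the FFT bin grid with Mel-spaced edges.

    ``supports[m] = (f_lo, f_center, f_hi)`` in Hz after snapping the edge
    frequencies to FFT bins; filter m rises linearly from 0 at ``f_lo`` to 1
    at ``f_center`` and falls back to 0 at ``f_hi``. Under the standard
    50 %-overlap construction, filter m's upper edge is filter m+1's center.
    """

    weights: np.ndarray   # (M, K)
    supports: np.ndarray  # (M, 3) Hz
    bin_freqs: np.ndarray
    nfft: int
    sampling_rate: int

    @property
    def n_filters(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class SscMatrix:
    """Per-frame subband centroid frequencies, (T, M), in Hz."""

    centroids: np.ndarray
    supports: np.ndarray


@dataclass(frozen=True)
class FeatureVector:
    """Pooled per-clip feature vector: [means (M), standard deviations (M)]."""

    values: np.ndarray
    clip_id: str = ""
    label: int | None = None


def hz_to_mel(f):
    """Mel scale, mel(f) = 2595 log10(1 + f/700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def preemphasize(samples: np.ndarray, coeff: float = PREEMPHASIS_COEFF) -> np.ndarray:
    """First-order high-pass pre-emphasis, y[n] = x[n] - coeff * x[n-1].

    x[-1] is taken as 0, so the first output sample equals the first input
    sample and the output length matches the input length.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        raise ValidationError("preemphasize: empty input")
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - coeff * x[:-1]
    return y


def frame_signal(samples: np.ndarray, sampling_rate: int,
                 frame_ms: float = 20.0, hop_ms: float = 10.0,
                 clip_id: str = "") -> FrameMatrix:
    """Slice a signal into Hamming-windowed overlapping frames.

    Frame t covers samples ``[t*hop, t*hop + L)`` with
    ``L = round(frame_ms/1000 * fs)`` and ``hop = round(hop_ms/1000 * fs)``;
    trailing samples that do not fill a frame are dropped.
    """
    x = np.asarray(samples, dtype=np.float64)
    L = int(round(frame_ms / 1000.0 * sampling_rate))
    hop = int(round(hop_ms / 1000.0 * sampling_rate))
    if x.size < L:
        raise ValidationError(
            f"clip too short for framing: {x.size} samples < frame length {L}"
            + (f" (clip {clip_id})" if clip_id else ""))
    T = (x.size - L) // hop + 1
    idx = np.arange(L)[None, :] + hop * np.arange(T)[:, None]
    window = np.hamming(L)
    return FrameMatrix(frames=x[idx] * window[None, :],
                       sampling_rate=int(sampling_rate), frame_length=L, hop=hop)


def power_spectrum(frames: FrameMatrix, nfft: int | None = None) -> PowerSpectrum:
    """One-sided magnitude-squared spectrum of each (zero-padded) frame.

    No density scaling is applied: SSCs are ratios of power-weighted sums,
    so any global scale factor cancels.
    """
    L = frames.frame_length
    if nfft is None:
        nfft = 1 << (L - 1).bit_length()
    if nfft < L:
        raise ValidationError(f"nfft ({nfft}) must be >= frame length ({L})")
    if nfft & (nfft - 1):
        raise ValidationError(f"nfft must be a power of two, got {nfft}")
    spec = np.fft.rfft(frames.frames, n=nfft, axis=1)
    psd = (spec.real ** 2 + spec.imag ** 2)
    bin_freqs = np.arange(nfft // 2 + 1) * (frames.sampling_rate / nfft)
    return PowerSpectrum(psd=psd, bin_freqs=bin_freqs, nfft=nfft,
                         sampling_rate=frames.sampling_rate)


def build_mel_filterbank(n_filters: int, sampling_rate: int, nfft: int,
                         f_min: float = 0.0, f_max: float | None = None) -> MelFilterbank:
    """Construct M triangular filters with edges equally spaced in Mel.

    M+2 edge frequencies are placed uniformly on the Mel scale between
    mel(f_min) and mel(f_max), converted back to Hz and snapped to the
    nearest FFT bin; filter m spans edges (m-1, m, m+1) with peak 1 at the
    centre edge.
    """
    if n_filters < 1:
        raise ValidationError("n_filters must be >= 1")
    nyquist = sampling_rate / 2.0
    if f_max is None:
        f_max = nyquist
    if not (0.0 <= f_min < f_max <= nyquist):
        raise ValidationError(
            f"need 0 <= f_min < f_max <= Nyquist; got f_min={f_min}, "
            f"f_max={f_max}, Nyquist={nyquist}")
    mel_edges = np.linspace(hz_to_mel(f_min), hz_to_mel(f_max), n_filters + 2)
    hz_edges = mel_to_hz(mel_edges)
    bin_edges = np.rint(hz_edges / (sampling_rate / nfft)).astype(int)
    if np.any(np.diff(bin_edges) < 1):
        raise ValidationError(
            f"adjacent filter edges coincide after snapping to {nfft}-point "
            "FFT bins; increase nfft or reduce the filter count")
    K = nfft // 2 + 1
    bin_freqs = np.arange(K) * (sampling_rate / nfft)
    weights = np.zeros((n_filters, K))
    supports = np.empty((n_filters, 3))
    for m in range(n_filters):
        lo, center, hi = bin_edges[m], bin_edges[m + 1], bin_edges[m + 2]
        k = np.arange(lo, hi + 1)
        rising = (k - lo) / (center - lo)
        falling = (hi - k) / (hi - center)
        weights[m, lo:hi + 1] = np.where(k <= center, rising, falling)
        supports[m] = bin_freqs[[lo, center, hi]]
    return MelFilterbank(weights=weights, supports=supports, bin_freqs=bin_freqs,
                         nfft=nfft, sampling_rate=int(sampling_rate))


def compute_sscs(psd: PowerSpectrum, fb: MelFilterbank,
                 warn_on_disorder: bool = False) -> SscMatrix:
    """Spectral subband centroids for every frame and subband.

    ``C[t, m] = sum_k f_k w_m[k] P_t[k] / sum_k w_m[k] P_t[k]``. A subband
    with zero weighted power in a frame falls back to its centre frequency,
    which keeps the cross-band ascending order on silent frames.
    """
    if psd.nfft != fb.nfft or psd.sampling_rate != fb.sampling_rate:
        raise ValidationError(
            f"power spectrum (nfft={psd.nfft}, fs={psd.sampling_rate}) and "
            f"filterbank (nfft={fb.nfft}, fs={fb.sampling_rate}) use different grids")
    band_power = psd.psd @ fb.weights.T                     # (T, M)
    band_moment = psd.psd @ (fb.weights * fb.bin_freqs).T   # (T, M)
    centers = fb.supports[:, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        centroids = np.where(band_power > 0.0, band_moment / band_power,
                             centers[None, :])
    if warn_on_disorder and np.any(np.diff(centroids, axis=1) < 0):
        warnings.warn("SSC ascending order across subbands violated in at "
                      "least one frame", RuntimeWarning, stacklevel=2)
    return SscMatrix(centroids=centroids, supports=fb.supports)


def pool_features(sscs: SscMatrix, ddof: int = 0,
                  clip_id: str = "", label: int | None = None) -> FeatureVector:
    """Pool per-frame centroids into one per-clip vector of means then stds.

    The standard deviation uses the population convention (divisor T) by
    default; a single-frame clip yields an all-zero std block.
    """
    c = sscs.centroids
    if c.size == 0:
        raise ValidationError("pool_features: empty SSC matrix")
    means = c.mean(axis=0)
    stds = c.std(axis=0, ddof=ddof) if c.shape[0] > ddof else np.zeros(c.shape[1])
    return FeatureVector(values=np.concatenate([means, stds]),
                         clip_id=clip_id, label=label)


def extract_features(clip: AudioClip, config: FeatureConfig = FeatureConfig(),
                     fb: MelFilterbank | None = None) -> FeatureVector:
    """Full front end: clip in, 2M-dimensional feature vector out.

    Deterministic for fixed (samples, sampling_rate, config). A prebuilt
    filterbank may be passed to amortise construction over a dataset; it
    must match the clip's rate and the config's FFT size.
    """
    try:
        y = preemphasize(clip.samples, config.preemphasis)
        frames = frame_signal(y, clip.sampling_rate, config.frame_ms,
                              config.hop_ms, clip_id=clip.clip_id)
        psd = power_spectrum(frames, config.nfft)
        if fb is None:
            fb = build_mel_filterbank(config.n_filters, clip.sampling_rate,
                                      psd.nfft, config.f_min, config.f_max)
        sscs = compute_sscs(psd, fb)
    except ValidationError as exc:
        raise ValidationError(f"clip {clip.clip_id!r}: {exc}") from exc
    return pool_features(sscs, ddof=config.std_ddof,
                         clip_id=clip.clip_id, label=clip.label)


def feature_names(n_filters: int = 26) -> list[str]:
    """Column names for the exported feature matrix."""
    return ([f"ssc_mean_{m:02d}" for m in range(1, n_filters + 1)]
            + [f"ssc_std_{m:02d}" for m in range(1, n_filters + 1)])
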