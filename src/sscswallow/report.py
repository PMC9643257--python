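"""Diagnostic figures: waveform, per-frame PSD with SSC markers, band plot.

These are artifacts for human inspection of the front end; automated tests
assert the numbers behind them, not pixels. All functions return the numeric
data they plotted so callers can do exactly that.
"""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from sscswallow.audio_io import AudioClip, ValidationError
from sscswallow.dsp import (FeatureConfig, build_mel_filterbank, compute_sscs,
                            frame_signal, power_spectrum, preemphasize)


def plot_waveform(clip: AudioClip, path: str | os.PathLike) -> np.ndarray:
    """Time-domain plot of one clip; returns the time axis in seconds."""
    t = np.arange(clip.samples.size) / clip.sampling_rate
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(t, clip.samples, lw=0.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("amplitude")
    ax.set_title(f"clip {clip.clip_id}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return t


def frame_psd_with_sscs(clip: AudioClip, frame_index: int,
                        config: FeatureConfig = FeatureConfig()):
    """PSD (after pre-emphasis) of one frame and its M subband centroids."""
    y = preemphasize(clip.samples, config.preemphasis)
    frames = frame_signal(y, clip.sampling_rate, config.frame_ms, config.hop_ms,
                          clip_id=clip.clip_id)
    psd = power_spectrum(frames, config.nfft)
    if not (0 <= frame_index < psd.psd.shape[0]):
        raise ValidationError(
            f"frame index {frame_index} out of range (clip has {psd.psd.shape[0]} frames)")
    fb = build_mel_filterbank(config.n_filters, clip.sampling_rate, psd.nfft,
                              config.f_min, config.f_max)
    sscs = compute_sscs(psd, fb)
    return psd.bin_freqs, psd.psd[frame_index], sscs.centroids[frame_index]


def plot_frame_psd(clip: AudioClip, frame_index: int, path: str | os.PathLike,
                   config: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Plot one frame's PSD with its SSC frequencies as dashed markers.

    Returns the M centroid frequencies drawn.
    """
    freqs, psd, centroids = frame_psd_with_sscs(clip, frame_index, config)
    fig, ax = plt.subplots(figsize=(8, 4))
    with np.errstate(divide="ignore"):
        ax.plot(freqs, 10 * np.log10(np.maximum(psd, 1e-20)), lw=0.7,
                label="PSD after pre-emphasis")
    for i, c in enumerate(centroids):
        ax.axvline(c, color="r", ls="--", lw=0.6,
                   label="SSC" if i == 0 else None)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("power (dB)")
    ax.set_title(f"clip {clip.clip_id}, frame {frame_index}")
    ax.legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return centroids


def band_ssc_data(features: pd.DataFrame) -> dict[int, np.ndarray]:
    """Per-class matrix of per-clip mean SSCs (rows = clips, cols = bands)."""
    mean_cols = [c for c in features.columns if c.startswith("ssc_mean_")]
    if not mean_cols or "label" not in features.columns or len(features) == 0:
        raise ValidationError("feature table empty or missing ssc_mean_*/label columns")
    return {int(c): features.loc[features["label"] == c, mean_cols].to_numpy(float)
            for c in sorted(features["label"].unique())}


def plot_band_sscs(features: pd.DataFrame, path: str | os.PathLike) -> dict[int, np.ndarray]:
    """Band plot: per-clip mean SSCs as vertical ticks within each subband.

    One panel per class; within each of the M bands a vertical line marks
    one clip's mean centroid, so class-specific high-frequency centroids
    stand out as lines present in one panel only.
    """
    data = band_ssc_data(features)
    n_bands = next(iter(data.values())).shape[1]
    fig, axes = plt.subplots(len(data), 1, figsize=(9, 3 * len(data)),
                             sharex=True, squeeze=False)
    names = {0: "normal", 1: "aspirating"}
    for ax, (cls, mat) in zip(axes.ravel(), data.items()):
        for row in mat:
            ax.vlines(row, 0, 1, lw=0.5)
        ax.set_yticks([])
        ax.set_ylabel(f"{names.get(cls, cls)} (n={mat.shape[0]})")
        ax.set_title(f"per-clip mean SSCs across {n_bands} bands")
    axes.ravel()[-1].set_xlabel("frequency (Hz)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return data
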