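"""Synthetic swallow-sound generator.

Emulates the spectral structure reported for cervical-auscultation swallow
recordings well enough to exercise the full pipeline without clinical data:

- a *normal* swallow is a short burst of low-frequency-emphasised noise (the
  fluid "flushing" sound) shaped by an attack/decay amplitude envelope, with
  power concentrated below a few hundred Hz and rolling off at a fixed
  dB/octave tilt;
- an *aspirating* swallow is the same burst plus a narrowband noise
  component near 19.5 kHz — band-limited noise, not a pure tone, reflecting
  the broad high-frequency spectral peak that distinguishes aspirating
  clips — which pulls the top Mel subband's spectral centroid upward;
- a weak broadband noise floor stands in for electronic/room noise.

Every clip is reproducible from (config.seed, clip index, label); datasets
default to the study composition of 106 normal + 18 aspirating swallows so
the class-imbalance machinery downstream is exercised realistically.

This is a signal-level emulation, not a physiological model: it makes no
attempt at vocal-tract acoustics, bolus dynamics, or breath/cough
contaminants.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from sscswallow.audio_io import ASPIRATING, NORMAL, AudioClip, Manifest, \
    ValidationError, read_manifest, write_clip


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthesis parameters.

    The aspiration signature strength is ``peak_rms_ratio``: the RMS of the
    narrowband component relative to the base burst RMS before enveloping.
    At the default it concentrates enough power in ~600 Hz of bandwidth to
    dominate the top Mel subband and shift its centroid measurably; at 0 the
    two classes are statistically identical.
    """

    sampling_rate: int = 44100
    duration_range_s: tuple[float, float] = (0.3, 1.0)
    tilt_db_per_octave: float = -12.0   # base-noise power roll-off above cutoff
    tilt_cutoff_hz: float = 300.0       # below this the base spectrum is flat
    attack_ms: float = 40.0
    decay_ms: float = 150.0
    aspiration_peak_hz: float = 19500.0
    aspiration_bandwidth_hz: float = 600.0
    peak_rms_ratio: float = 0.3
    snr_db: float = 60.0                # base power over broadband floor power
    peak_amplitude: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        nyq = self.sampling_rate / 2.0
        if self.aspiration_peak_hz + self.aspiration_bandwidth_hz / 2.0 >= nyq:
            raise ValidationError(
                "aspiration peak band must lie below Nyquist "
                f"({self.aspiration_peak_hz} + {self.aspiration_bandwidth_hz}/2 "
                f">= {nyq})")
        lo, hi = self.duration_range_s
        if not (0.1 <= lo <= hi <= 2.0):
            raise ValidationError(
                f"duration range must satisfy 0.1 <= lo <= hi <= 2.0 s, got {lo}, {hi}")
        if self.peak_rms_ratio < 0:
            raise ValidationError("peak_rms_ratio must be >= 0")
        if not (0 < self.peak_amplitude <= 1.0):
            raise ValidationError("peak_amplitude must be in (0, 1]")


def _shaped_noise(rng: np.random.Generator, n: int, gain: np.ndarray) -> np.ndarray:
    """White Gaussian noise spectrally shaped by a one-sided amplitude gain."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white) * gain
    return np.fft.irfft(spec, n=n)


def _base_gain(freqs: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    """Amplitude gain: flat to the cutoff, then tilt_db_per_octave roll-off."""
    with np.errstate(divide="ignore"):
        octaves = np.log2(np.maximum(freqs, 1e-9) / cfg.tilt_cutoff_hz)
    gain_db = np.minimum(octaves, 0.0) * 0.0 + np.maximum(octaves, 0.0) * cfg.tilt_db_per_octave
    return 10.0 ** (gain_db / 20.0)


def _band_gain(freqs: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    """Gaussian-shaped amplitude gain centred on the aspiration peak."""
    sigma = cfg.aspiration_bandwidth_hz / 2.0
    return np.exp(-0.5 * ((freqs - cfg.aspiration_peak_hz) / sigma) ** 2)


def _envelope(n: int, sr: int, cfg: GeneratorConfig) -> np.ndarray:
    """Linear attack, sustained body, linear decay."""
    attack = min(int(round(cfg.attack_ms / 1000.0 * sr)), n // 2)
    decay = min(int(round(cfg.decay_ms / 1000.0 * sr)), n - attack)
    env = np.ones(n)
    if attack > 0:
        env[:attack] = np.linspace(0.0, 1.0, attack, endpoint=False)
    if decay > 0:
        env[n - decay:] = np.linspace(1.0, 0.0, decay)
    return env


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(x ** 2)))


def generate_clip(label: int, cfg: GeneratorConfig = GeneratorConfig(),
                  index: int = 0) -> AudioClip:
    """Synthesise one swallow clip, deterministic in (cfg.seed, index, label)."""
    cfg.validate()
    if label not in (NORMAL, ASPIRATING):
        raise ValidationError(f"label must be 0 or 1, got {label!r}")
    rng = np.random.default_rng([cfg.seed, label, index])
    lo, hi = cfg.duration_range_s
    duration = rng.uniform(lo, hi)
    n = int(round(duration * cfg.sampling_rate))
    freqs = np.fft.rfftfreq(n, d=1.0 / cfg.sampling_rate)

    base = _shaped_noise(rng, n, _base_gain(freqs, cfg))
    base /= _rms(base)
    signal = base
    if label == ASPIRATING and cfg.peak_rms_ratio > 0:
        band = _shaped_noise(rng, n, _band_gain(freqs, cfg))
        band *= cfg.peak_rms_ratio / _rms(band)
        signal = signal + band
    floor = rng.standard_normal(n) * 10.0 ** (-cfg.snr_db / 20.0)
    x = signal * _envelope(n, cfg.sampling_rate, cfg) + floor
    x *= cfg.peak_amplitude / np.max(np.abs(x))
    return AudioClip(samples=x, sampling_rate=cfg.sampling_rate, label=label,
                     subject_id=f"synth{index:03d}",
                     clip_id=f"{'asp' if label else 'norm'}_{index:03d}")


@dataclass
class SyntheticDataset:
    clips: list[AudioClip]
    manifest: Manifest
    config: GeneratorConfig


def generate_dataset(n_normal: int = 106, n_aspirating: int = 18,
                     cfg: GeneratorConfig = GeneratorConfig(),
                     out_dir: str | os.PathLike | None = None) -> SyntheticDataset:
    """Generate a labelled dataset, optionally writing WAVs and a manifest CSV.

    The default composition (106 normal, 18 aspirating) matches the clinical
    study this generator stands in for. With ``out_dir`` set, clips are
    written as ``<clip_id>.wav`` plus a ``manifest.csv``; regeneration under
    the same config reproduces the files byte for byte.
    """
    if n_normal < 0 or n_aspirating < 0:
        raise ValidationError("clip counts must be non-negative")
    clips = [generate_clip(NORMAL, cfg, i) for i in range(n_normal)]
    clips += [generate_clip(ASPIRATING, cfg, i) for i in range(n_aspirating)]
    rows = pd.DataFrame({
        "path": [f"{c.clip_id}.wav" for c in clips],
        "label": ["aspirating" if c.label else "normal" for c in clips],
        "subject_id": [c.subject_id for c in clips],
    })
    manifest = Manifest(rows=rows)
    if out_dir is not None:
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        for clip in clips:
            write_clip(clip, os.path.join(out_dir, f"{clip.clip_id}.wav"))
        rows.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
        manifest = read_manifest(os.path.join(out_dir, "manifest.csv"))
    return SyntheticDataset(clips=clips, manifest=manifest, config=cfg)


def with_peak_ratio(cfg: GeneratorConfig, ratio: float) -> GeneratorConfig:
    """Copy of the config with a different aspiration-signature strength."""
    return replace(cfg, peak_rms_ratio=ratio)
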