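"""Reading and writing swallow-sound clips and dataset manifests.

Clips are mono PCM WAV files, one per pre-segmented swallow. A dataset is
described by a CSV manifest with header ``path,label,subject_id``; labels are
drawn from the closed two-class vocabulary ``normal`` / ``aspirating``
(encoded 0 / 1 downstream).

I/O is deliberately dumb: no resampling, no filtering, no duration policing —
clips too short for feature extraction are rejected by the DSP layer, not
here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile

NORMAL = 0
ASPIRATING = 1

LABEL_NAMES = {"normal": NORMAL, "aspirating": ASPIRATING}
LABEL_STRINGS = {NORMAL: "normal", ASPIRATING: "aspirating"}

#: Samples of integer PCM with B bits are scaled by 1 / 2**(B-1), so the
#: most positive 16-bit sample maps to 32767/32768 and full negative scale
#: to exactly -1.0.
_PCM16_SCALE = 1.0 / 32768.0


class AudioIOError(IOError):
    """Unreadable, unwritable or corrupt audio file."""


class ValidationError(ValueError):
    """Input violates a structural contract (empty audio, bad label, ...)."""


@dataclass
class AudioClip:
    """One labelled, pre-segmented swallow recording.

    Parameters
    ----------
    samples : ndarray of float
        Mono amplitude sequence, nominally in [-1, 1].
    sampling_rate : int
        Sampling rate in Hz; must be positive.
    label : int or None
        0 = normal, 1 = aspirating, None = unlabelled.
    subject_id, clip_id : str
        Opaque identifiers carried through the pipeline for provenance.
    """

    samples: np.ndarray
    sampling_rate: int
    label: int | None = None
    subject_id: str = ""
    clip_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValidationError("AudioClip requires a non-empty 1-D sample array")
        if int(self.sampling_rate) <= 0:
            raise ValidationError(f"sampling_rate must be positive, got {self.sampling_rate}")
        self.sampling_rate = int(self.sampling_rate)
        if self.label is not None and self.label not in (NORMAL, ASPIRATING):
            raise ValidationError(f"label must be 0, 1 or None, got {self.label!r}")

    @property
    def duration(self) -> float:
        """Clip duration in seconds."""
        return self.samples.size / self.sampling_rate


@dataclass
class Manifest:
    """Parsed dataset manifest: rows of (path, label string, subject_id)."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.rows)


def read_clip(path: str | os.PathLike,
              label: int | None = None,
              subject_id: str = "",
              clip_id: str | None = None) -> AudioClip:
    """Read a PCM WAV file into an :class:`AudioClip`.

    Integer PCM is scaled to float by ``1 / 2**(bits-1)``; multi-channel
    input is reduced to mono by averaging channels. The sampling rate is
    preserved exactly (no resampling).
    """
    try:
        rate, data = wavfile.read(os.fspath(path))
    except FileNotFoundError:
        raise AudioIOError(f"audio file not found: {path}") from None
    except Exception as exc:  # corrupt/unparseable RIFF
        raise AudioIOError(f"cannot read audio file {path}: {exc}") from exc
    if data.size == 0:
        raise ValidationError(f"zero-length audio in {path}")
    if np.issubdtype(data.dtype, np.integer):
        bits = data.dtype.itemsize * 8
        if data.dtype == np.uint8:  # 8-bit WAV is unsigned, offset binary
            samples = (data.astype(np.float64) - 128.0) / 128.0
        else:
            samples = data.astype(np.float64) / float(2 ** (bits - 1))
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    if clip_id is None:
        clip_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return AudioClip(samples=samples, sampling_rate=int(rate), label=label,
                     subject_id=subject_id, clip_id=clip_id)


def write_clip(clip: AudioClip, path: str | os.PathLike, clip_range: bool = True) -> None:
    """Write a clip as 16-bit PCM WAV.

    Samples are quantised by rounding ``x / _PCM16_SCALE`` and clamping to
    the int16 range, so a read-after-write round-trip reproduces samples
    within one quantisation step (2**-15) and the rate exactly.
    """
    x = np.asarray(clip.samples, dtype=np.float64)
    if x.size == 0:
        raise ValidationError("cannot write empty clip")
    if not clip_range and (np.any(x > 1.0) or np.any(x < -1.0)):
        raise ValidationError("samples outside [-1, 1] and clipping disabled")
    q = np.clip(np.rint(x / _PCM16_SCALE), -32768, 32767).astype(np.int16)
    try:
        wavfile.write(os.fspath(path), clip.sampling_rate, q)
    except Exception as exc:
        raise AudioIOError(f"cannot write audio file {path}: {exc}") from exc


def read_manifest(path: str | os.PathLike) -> Manifest:
    """Parse a ``path,label,subject_id`` CSV manifest.

    Labels must come from the two-class vocabulary; unknown strings are
    rejected with the offending row number.
    """
    try:
        df = pd.read_csv(path, dtype=str).fillna("")
    except FileNotFoundError:
        raise AudioIOError(f"manifest not found: {path}") from None
    except pd.errors.EmptyDataError:
        raise ValidationError(f"manifest {path} is empty (no header)") from None
    required = ["path", "label", "subject_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest {path} missing column(s): {', '.join(missing)}")
    bad = df.index[~df["label"].isin(LABEL_NAMES)]
    if len(bad) > 0:
        row = int(bad[0])
        raise ValidationError(
            f"manifest {path} row {row}: unknown label {df.loc[row, 'label']!r} "
            f"(expected one of {sorted(LABEL_NAMES)})")
    return Manifest(rows=df[required].reset_index(drop=True))


def load_clips(manifest: Manifest, root: str | os.PathLike = ".") -> list[AudioClip]:
    """Read every clip referenced by a manifest (paths resolved against root)."""
    clips = []
    for _, row in manifest.rows.iterrows():
        p = row["path"]
        if not os.path.isabs(p):
            p = os.path.join(os.fspath(root), p)
        clips.append(read_clip(p, label=LABEL_NAMES[row["label"]],
                               subject_id=row["subject_id"]))
    return clips
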