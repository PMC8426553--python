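"""Waveform container and WAV file handling.

Audio enters the package as mono RIFF WAV (16-bit PCM or float).  The
reference sampling rate is 16 kHz; files at other rates are resampled with
a polyphase filter.  Multi-channel audio is rejected rather than silently
downmixed, since channel mixing changes amplitude-based descriptors
(shimmer, loudness, HNR).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

TARGET_RATE = 16_000

__all__ = ["Waveform", "read_wav", "write_wav", "TARGET_RATE"]


@dataclass(frozen=True)
class Waveform:
    """Mono audio samples in [-1, 1] with their sampling rate in Hz."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(
                f"Waveform must be mono (1-D); got shape {samples.shape}. "
                "Downmix or split channels before loading."
            )
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if samples.size == 0:
            raise ValueError("Waveform must contain at least one sample")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.rate

    def resampled(self, rate: int) -> "Waveform":
        if rate == self.rate:
            return self
        g = np.gcd(int(rate), int(self.rate))
        out = resample_poly(self.samples, int(rate) // g, int(self.rate) // g)
        return Waveform(out, rate)


def read_wav(path: str | Path, rate: int = TARGET_RATE) -> Waveform:
    """Read a mono WAV file, normalizing integer PCM to [-1, 1].

    Resamples to ``rate`` when the file's rate differs.  Raises on
    multi-channel input.
    """
    file_rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(
            f"{path}: expected mono audio, found {data.shape[1]} channels"
        )
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float32/float64 WAV
        samples = data.astype(np.float64)
    return Waveform(samples, int(file_rate)).resampled(rate)


def write_wav(path: str | Path, w: Waveform) -> None:
    """Write a waveform as 16-bit PCM WAV."""
    clipped = np.clip(w.samples, -1.0, 1.0)
    wavfile.write(str(path), w.rate, np.round(clipped * 32767).astype(np.int16))
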