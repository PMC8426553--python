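"""Frame-level acoustic feature extraction.

Produces the descriptor set used for depression detection from speech:
pitch (F0), cycle-level perturbation measures (jitter, shimmer), loudness
and its delta regression, MFCC and delta-MFCC, Mel-band spectra, LPC
coefficients and their line-spectral-pair (LSP) frequencies, voicing
probability, harmonic/noise RMS energies and the harmonics-to-noise ratio
(HNR).  All features are computed per short analysis frame so the output
preserves the temporal structure of the utterance — the input contract of
the sequence model.

Defaults follow the ComParE/openSMILE low-level-descriptor family: 25 ms
Hamming frames at a 10 ms hop, 13 MFCC, 26 Mel bands, LPC order 8.  The
exact feature dimensionality of the original study is not fixed anywhere;
the schema here is an explicit, configurable stand-in (77 descriptors,
zero-padded to 80 so the width divides evenly for 1/2/4/8 attention
heads).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft
from scipy.linalg import solve_toeplitz

from .audio import Waveform

logger = logging.getLogger(__name__)

__all__ = [
    "FrameParams",
    "FeatureConfig",
    "FeatureSchema",
    "FeatureMatrix",
    "PitchMarks",
    "frame_signal",
    "extract_f0",
    "mark_pitch_periods",
    "extract_jitter",
    "extract_shimmer",
    "extract_spectral",
    "extract_voicing_harmonicity",
    "extract_all",
    "delta_regression",
]


# ---------------------------------------------------------------------------
# framing


@dataclass(frozen=True)
class FrameParams:
    """Short-time analysis grid: frame length and hop in seconds."""

    frame_len: float = 0.025
    hop: float = 0.010
    window: str = "hamming"

    def __post_init__(self) -> None:
        if not (0 < self.hop <= self.frame_len):
            raise ValueError(
                f"need 0 < hop <= frame_len, got hop={self.hop}, frame_len={self.frame_len}"
            )

    def frame_samples(self, rate: int) -> int:
        return int(round(self.frame_len * rate))

    def hop_samples(self, rate: int) -> int:
        return int(round(self.hop * rate))

    def n_frames(self, n_samples: int, rate: int) -> int:
        length = self.frame_samples(rate)
        hop = self.hop_samples(rate)
        if n_samples < length:
            return 0
        return 1 + (n_samples - length) // hop

    def frame_times(self, n_frames: int, rate: int) -> np.ndarray:
        """Centre time (seconds) of each frame."""
        length = self.frame_samples(rate)
        hop = self.hop_samples(rate)
        return (np.arange(n_frames) * hop + length / 2.0) / rate


def _taper(name: str, length: int) -> np.ndarray:
    name = name.lower()
    if name in ("hamming",):
        return np.hamming(length)
    if name in ("hann", "hanning"):
        return np.hanning(length)
    if name in ("rect", "rectangular", "boxcar", "none"):
        return np.ones(length)
    raise ValueError(f"unknown window taper {name!r}")


def _frames_raw(w: Waveform, p: FrameParams) -> np.ndarray:
    length = p.frame_samples(w.rate)
    hop = p.hop_samples(w.rate)
    n = w.samples.size
    if n < length:
        raise ValueError(
            f"signal of {n / w.rate * 1000:.1f} ms is shorter than one analysis "
            f"frame; at least {p.frame_len * 1000:.0f} ms of audio is required"
        )
    t = 1 + (n - length) // hop
    idx = np.arange(length)[None, :] + hop * np.arange(t)[:, None]
    return w.samples[idx]


def frame_signal(w: Waveform, p: FrameParams) -> np.ndarray:
    """Slice a waveform into overlapping tapered frames (T x frame_samples).

    Frame t covers samples [t*hop, t*hop + frame_len); the configured taper
    is applied.  Raises when the signal is shorter than one frame.
    """
    return _frames_raw(w, p) * _taper(p.window, p.frame_samples(w.rate))


# ---------------------------------------------------------------------------
# pitch and voicing

_SILENCE_RMS = 1e-6


def _norm_autocorr(x: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Lag-normalized autocorrelation of one zero-mean frame at integer lags."""
    n = x.size
    out = np.zeros(lags.size)
    for j, lag in enumerate(lags):
        if lag >= n - 1:
            continue
        a, b = x[: n - lag], x[lag:]
        denom = np.sqrt(np.dot(a, a) * np.dot(b, b))
        out[j] = np.dot(a, b) / denom if denom > 0 else 0.0
    return out


def _parabolic(y_m1: float, y_0: float, y_p1: float) -> tuple[float, float]:
    """Vertex offset (in samples) and value of the parabola through 3 points."""
    denom = y_m1 - 2 * y_0 + y_p1
    if abs(denom) < 1e-12:
        return 0.0, y_0
    delta = 0.5 * (y_m1 - y_p1) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    value = y_0 - 0.25 * (y_m1 - y_p1) * delta
    return delta, value


def _frame_pitch(
    x: np.ndarray, rate: int, fmin: float, fmax: float
) -> tuple[float, float]:
    """Best F0 candidate (Hz) and its autocorrelation peak height for one frame."""
    x = x - x.mean()
    if np.sqrt(np.mean(x**2)) < _SILENCE_RMS:
        return 0.0, 0.0
    lag_min = max(int(np.floor(rate / fmax)), 2)
    lag_max = min(int(np.ceil(rate / fmin)), x.size - 2)
    if lag_max <= lag_min:
        return 0.0, 0.0
    lags = np.arange(lag_min, lag_max + 1)
    r = _norm_autocorr(x, lags)
    best = float(r.max())
    if best <= 0:
        return 0.0, 0.0
    # All integer multiples of the true period have near-equal peaks; pick
    # the shortest lag whose local maximum is close to the global one to
    # avoid octave-down errors.
    is_peak = np.ones(r.size, dtype=bool)
    is_peak[1:] &= r[1:] >= r[:-1]
    is_peak[:-1] &= r[:-1] >= r[1:]
    candidates = np.flatnonzero(is_peak & (r >= best - 0.08))
    j = int(candidates[0]) if candidates.size else int(np.argmax(r))
    peak = r[j]
    if 0 < j < r.size - 1:
        delta, peak = _parabolic(r[j - 1], r[j], r[j + 1])
    else:
        delta = 0.0
    lag = lags[j] + delta
    return rate / lag, float(min(max(peak, 0.0), 1.0))


def extract_f0(
    frames: np.ndarray,
    rate: int,
    fmin: float = 55.0,
    fmax: float = 500.0,
    voicing_threshold: float = 0.45,
) -> np.ndarray:
    """Per-frame fundamental frequency via normalized autocorrelation.

    Voiced frames carry F0 in [fmin, fmax]; frames whose autocorrelation
    peak falls below ``voicing_threshold`` (and silent frames) carry 0.
    """
    if not (0 < fmin < fmax < rate / 2):
        raise ValueError(f"need 0 < fmin < fmax < rate/2, got fmin={fmin}, fmax={fmax}")
    f0 = np.zeros(frames.shape[0])
    for t, frame in enumerate(frames):
        cand, peak = _frame_pitch(frame, rate, fmin, fmax)
        if peak >= voicing_threshold and fmin <= cand <= fmax:
            f0[t] = cand
    return f0


@dataclass(frozen=True)
class PitchMarks:
    """Sub-sample glottal cycle peak times (s) and interpolated amplitudes."""

    times: np.ndarray
    amplitudes: np.ndarray


def mark_pitch_periods(w: Waveform, f0_track: np.ndarray, p: FrameParams) -> PitchMarks:
    """Locate one amplitude peak per pitch period in the voiced regions.

    Walks each voiced run guided by the local F0: from the strongest peak
    outward, the next cycle peak is searched within 0.7-1.3 expected
    periods.  Peak positions and amplitudes are refined by parabolic
    interpolation, giving sub-sample resolution — a necessity for jitter
    measurement, where period perturbations of a few percent are a fraction
    of a sample per cycle.
    """
    x = w.samples
    rate = w.rate
    hop = p.hop_samples(rate)
    centers = (np.arange(f0_track.size) * hop + p.frame_samples(rate) // 2).astype(int)

    def local_period(i_sample: int) -> float:
        t = int(np.clip(round((i_sample - centers[0]) / hop), 0, f0_track.size - 1))
        f = f0_track[t]
        if f <= 0:
            voiced = f0_track[f0_track > 0]
            f = voiced.mean() if voiced.size else 0.0
        return rate / f if f > 0 else 0.0

    voiced_mask = f0_track > 0
    times: list[float] = []
    amps: list[float] = []
    t = 0
    while t < f0_track.size:
        if not voiced_mask[t]:
            t += 1
            continue
        run_start = t
        while t < f0_track.size and voiced_mask[t]:
            t += 1
        s0 = max(centers[run_start] - hop, 0)
        s1 = min(centers[t - 1] + hop, x.size - 1)
        if s1 - s0 < 4:
            continue
        seg = x[s0:s1]
        sign = 1.0 if seg.max() >= -seg.min() else -1.0
        anchor = s0 + int(np.argmax(sign * seg))
        run_marks: list[tuple[float, float]] = []

        def refine(i: int) -> tuple[float, float]:
            if 0 < i < x.size - 1:
                d, v = _parabolic(sign * x[i - 1], sign * x[i], sign * x[i + 1])
                return (i + d) / rate, v
            return i / rate, sign * x[i]

        run_marks.append(refine(anchor))
        # forward pass
        pos = anchor
        while True:
            period = local_period(pos)
            if period <= 0:
                break
            lo = pos + int(0.7 * period)
            hi = pos + int(1.3 * period) + 1
            if lo >= s1 or hi - lo < 3:
                break
            hi = min(hi, x.size)
            nxt = lo + int(np.argmax(sign * x[lo:hi]))
            run_marks.append(refine(nxt))
            pos = nxt
        # backward pass
        pos = anchor
        while True:
            period = local_period(pos)
            if period <= 0:
                break
            hi = pos - int(0.7 * period) + 1
            lo = pos - int(1.3 * period)
            if hi <= s0 or hi - lo < 3:
                break
            lo = max(lo, 0)
            prv = lo + int(np.argmax(sign * x[lo:hi]))
            run_marks.insert(0, refine(prv))
            pos = prv
        times.extend(m[0] for m in run_marks)
        amps.extend(m[1] for m in run_marks)

    order = np.argsort(times)
    return PitchMarks(np.asarray(times)[order], np.asarray(amps)[order])


def _local_perturbation(
    values: np.ndarray,
    mark_times: np.ndarray,
    frame_times: np.ndarray,
    window_s: float,
) -> np.ndarray:
    """Mean |consecutive difference| / mean, over marks near each frame.

    ``values`` has one entry per inter-mark interval (periods) or per mark
    (amplitudes); entry k is attributed to time mark_times[k].  Frames with
    fewer than 3 usable values get 0.
    """
    out = np.zeros(frame_times.size)
    if values.size < 3:
        return out
    half = window_s / 2.0
    for i, tc in enumerate(frame_times):
        sel = (mark_times >= tc - half) & (mark_times <= tc + half)
        v = values[sel]
        if v.size < 3:
            continue
        mean = np.mean(v)
        if mean <= 0:
            continue
        out[i] = float(np.mean(np.abs(np.diff(v))) / mean)
    return out


def extract_jitter(
    marks: PitchMarks,
    frame_times: np.ndarray,
    window_s: float = 0.1,
    max_rel_gap: float = 0.5,
) -> np.ndarray:
    """Per-frame local jitter: mean |T_k - T_{k+1}| / mean period.

    Periods are the intervals between consecutive cycle marks inside a
    ``window_s`` window centred on the frame; intervals that jump by more
    than ``max_rel_gap`` relative to the local median (voicing breaks) are
    discarded.  Frames without at least three valid periods get 0.
    """
    periods = np.diff(marks.times)
    if periods.size == 0:
        return np.zeros(frame_times.size)
    med = np.median(periods)
    good = np.abs(periods - med) <= max_rel_gap * med
    centers = 0.5 * (marks.times[:-1] + marks.times[1:])
    return _local_perturbation(periods[good], centers[good], frame_times, window_s)


def extract_shimmer(
    marks: PitchMarks,
    frame_times: np.ndarray,
    window_s: float = 0.1,
) -> np.ndarray:
    """Per-frame local shimmer: mean |A_k - A_{k+1}| / mean peak amplitude."""
    amps = np.abs(marks.amplitudes)
    good = amps > 0
    return _local_perturbation(amps[good], marks.times[good], frame_times, window_s)


# ---------------------------------------------------------------------------
# spectral descriptors


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(rate: int, n_fft: int, n_mel: int, fmin: float = 20.0, fmax: float | None = None) -> np.ndarray:
    """Triangular Mel filterbank (n_mel x n_fft//2+1), HTK mel scale."""
    fmax = fmax or rate / 2.0
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mel + 2)
    hz_pts = np.asarray(_mel_to_hz(mel_pts))
    bins = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    fb = np.zeros((n_mel, bins.size))
    for m in range(n_mel):
        left, center, right = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (bins - left) / max(center - left, 1e-9)
        down = (right - bins) / max(right - center, 1e-9)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def delta_regression(x: np.ndarray, width: int = 2) -> np.ndarray:
    """Delta (first-order regression) coefficients over +/- ``width`` frames.

    Edges are padded by replication, so a time-constant track has zero
    delta everywhere.
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    padded = np.concatenate([np.repeat(x[:1], width, axis=0), x, np.repeat(x[-1:], width, axis=0)], axis=0)
    norm = 2.0 * sum(k * k for k in range(1, width + 1))
    out = np.zeros_like(x)
    for k in range(1, width + 1):
        out += k * (padded[width + k: width + k + x.shape[0]] - padded[width - k: width - k + x.shape[0]])
    out /= norm
    return out[:, 0] if squeeze else out


def _lpc_frame(frame: np.ndarray, order: int) -> np.ndarray:
    """LPC by the autocorrelation method; zeros on degenerate frames."""
    n = frame.size
    if n < 2 * order:
        raise ValueError(f"frame of {n} samples too short for LPC order {order}")
    r = np.correlate(frame, frame, mode="full")[n - 1: n + order]
    if r[0] <= 0:
        return np.zeros(order)
    r = r / r[0]
    r[0] += 1e-9
    try:
        a = solve_toeplitz((r[:order], r[:order]), r[1: order + 1])
    except np.linalg.LinAlgError:
        logger.warning("LPC solve failed on a degenerate frame; using zero coefficients")
        return np.zeros(order)
    if not np.all(np.isfinite(a)):
        logger.warning("non-finite LPC coefficients on a degenerate frame; using zeros")
        return np.zeros(order)
    # autocorrelation-method LPC is stable up to round-off; guard anyway
    roots = np.roots(np.concatenate([[1.0], -a]))
    if roots.size and np.max(np.abs(roots)) >= 1.0 + 1e-6:
        logger.warning("unstable LPC polynomial on a degenerate frame; using zeros")
        return np.zeros(order)
    return a


def _lsp_from_lpc(a: np.ndarray) -> np.ndarray:
    """Line spectral pair frequencies (radians, ascending in (0, pi))."""
    order = a.size
    c = np.concatenate([[1.0], -a])  # A(z) coefficients
    ext = np.concatenate([c, [0.0]])
    p_poly = ext + ext[::-1]
    q_poly = ext - ext[::-1]
    freqs = []
    for poly in (p_poly, q_poly):
        nz = np.trim_zeros(poly, trim="f")
        if nz.size < 2:
            continue
        ang = np.angle(np.roots(nz))
        freqs.extend(a_ for a_ in ang if 1e-4 < a_ < np.pi - 1e-4)
    freqs = np.sort(np.asarray(freqs))
    if freqs.size != order:
        # degenerate spectrum: fall back to the flat-spectrum LSP grid
        freqs = np.pi * np.arange(1, order + 1) / (order + 1)
    return freqs


def extract_spectral(
    frames: np.ndarray,
    rate: int,
    n_mfcc: int = 13,
    n_mel: int = 26,
    lpc_order: int = 8,
    delta_width: int = 2,
) -> dict[str, np.ndarray]:
    """MFCC, delta-MFCC, log-Mel spectra, loudness (+delta), LPC, LSP.

    Expects tapered frames.  MFCC are the first ``n_mfcc`` DCT-II
    coefficients of the log Mel-band energies; loudness is the sum of
    Mel-band energies compressed with a 0.3 power law.  LSP frequencies are
    strictly ascending in (0, pi) for every stable LPC frame.
    """
    t, length = frames.shape
    n_fft = int(2 ** np.ceil(np.log2(length)))
    spec = np.abs(rfft(frames, n=n_fft, axis=1)) ** 2
    fb = mel_filterbank(rate, n_fft, n_mel)
    mel_energy = spec @ fb.T
    log_mel = np.log(mel_energy + 1e-10)
    mfcc = dct(log_mel, type=2, norm="ortho", axis=1)[:, :n_mfcc]
    loudness = np.sum(mel_energy**0.3, axis=1)
    lpc = np.zeros((t, lpc_order))
    lsp = np.zeros((t, lpc_order))
    for i in range(t):
        lpc[i] = _lpc_frame(frames[i], lpc_order)
        lsp[i] = _lsp_from_lpc(lpc[i])
    return {
        "mfcc": mfcc,
        "dmfcc": delta_regression(mfcc, delta_width),
        "mel": log_mel,
        "loudness": loudness,
        "dloudness": delta_regression(loudness[:, None], delta_width)[:, 0],
        "lpc": lpc,
        "lsp": lsp,
    }


def extract_voicing_harmonicity(
    frames: np.ndarray,
    rate: int,
    f0_track: np.ndarray,
    fmin: float = 55.0,
    fmax: float = 500.0,
    hnr_clip: tuple[float, float] = (-40.0, 40.0),
) -> dict[str, np.ndarray]:
    """voiceProb, harmonic/noise RMS energies and HNR per frame.

    The harmonic fraction r of each frame's power is estimated as the
    normalized autocorrelation at the pitch-period lag (for voiced frames)
    or at the best candidate lag (unvoiced), parabolic-interpolated.  Then
    harmonicERMS = rms*sqrt(r), noiseERMS = rms*sqrt(1-r) and
    HNR = 10*log10(r/(1-r)) clipped to ``hnr_clip`` — the clip keeps pure
    tones (r -> 1) and silence finite.
    """
    t = frames.shape[0]
    voice_prob = np.zeros(t)
    harm = np.zeros(t)
    noise = np.zeros(t)
    hnr = np.full(t, hnr_clip[0])
    for i, frame in enumerate(frames):
        x = frame - frame.mean()
        rms = float(np.sqrt(np.mean(x**2)))
        if rms < _SILENCE_RMS:
            continue
        if f0_track[i] > 0:
            lag = rate / f0_track[i]
            j = int(round(lag))
            if 2 <= j <= x.size - 3:
                r3 = _norm_autocorr(x, np.array([j - 1, j, j + 1]))
                _, r = _parabolic(*r3)
            else:
                r = 0.0
            r = float(np.clip(r, 0.0, 1.0 - 1e-6))
            voice_prob[i] = r
            harm[i] = rms * np.sqrt(r)
            noise[i] = rms * np.sqrt(1.0 - r)
            hnr[i] = float(
                np.clip(10.0 * np.log10(r / (1.0 - r)) if r > 0 else hnr_clip[0], *hnr_clip)
            )
        else:
            # no detected periodicity: the frame is all noise component
            _, r = _frame_pitch(frame, rate, fmin, fmax)
            voice_prob[i] = float(np.clip(r, 0.0, 1.0))
            noise[i] = rms
            hnr[i] = hnr_clip[0]
    return {"voiceProb": voice_prob, "harmonicERMS": harm, "noiseERMS": noise, "HNR": hnr}


# ---------------------------------------------------------------------------
# schema and the full extractor


_GROUP_ORDER = (
    "f0", "jitter", "shimmer", "loudness", "dloudness",
    "mfcc", "dmfcc", "mel", "lpc", "lsp",
    "voiceProb", "harmonicERMS", "noiseERMS", "HNR",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Which descriptor groups to extract and at what sizes."""

    groups: tuple[str, ...] = _GROUP_ORDER
    n_mfcc: int = 13
    n_mel: int = 26
    lpc_order: int = 8
    delta_width: int = 2
    fmin: float = 55.0
    fmax: float = 500.0
    voicing_threshold: float = 0.45
    hnr_clip: tuple[float, float] = (-40.0, 40.0)
    pad_to_multiple: int = 8

    def __post_init__(self) -> None:
        unknown = set(self.groups) - set(_GROUP_ORDER)
        if unknown:
            raise ValueError(f"unknown feature groups: {sorted(unknown)}")

    def group_names(self, group: str) -> list[str]:
        sizes = {"mfcc": self.n_mfcc, "dmfcc": self.n_mfcc, "mel": self.n_mel,
                 "lpc": self.lpc_order, "lsp": self.lpc_order}
        if group in sizes:
            return [f"{group}_{i}" for i in range(sizes[group])]
        return [group]


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature-column labels; the model's fixed-Z contract."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    @property
    def z(self) -> int:
        return len(self.names)

    @classmethod
    def from_config(cls, cfg: FeatureConfig) -> "FeatureSchema":
        names: list[str] = []
        for group in _GROUP_ORDER:
            if group in cfg.groups:
                names.extend(cfg.group_names(group))
        if cfg.pad_to_multiple > 1:
            k = 0
            while len(names) % cfg.pad_to_multiple:
                names.append(f"pad_{k}")
                k += 1
        return cls(tuple(names))


@dataclass(frozen=True)
class FeatureMatrix:
    """T x Z frame-feature array for one segment."""

    values: np.ndarray
    schema: FeatureSchema
    source_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError(f"feature matrix must be 2-D, got shape {values.shape}")
        if values.shape[1] != self.schema.z:
            raise ValueError(
                f"{self.source_id}: {values.shape[1]} columns but schema has {self.schema.z}"
            )
        if values.shape[0] < 1:
            raise ValueError(f"{self.source_id}: empty feature matrix")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"{self.source_id}: non-finite feature values")
        object.__setattr__(self, "values", values)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def extract_all(
    w: Waveform,
    p: FrameParams = FrameParams(),
    cfg: FeatureConfig = FeatureConfig(),
    source_id: str = "",
) -> FeatureMatrix:
    """Run the full frame-level extractor on one waveform.

    Deterministic: identical input and parameters give a bit-identical
    matrix.  Pitch-dependent descriptors share one F0 track; pad columns
    (when the schema is padded for head divisibility) are zero.
    """
    try:
        raw = _frames_raw(w, p)
        tapered = raw * _taper(p.window, raw.shape[1])
        t = raw.shape[0]
        columns: dict[str, np.ndarray] = {}
        need = set(cfg.groups)

        f0 = None
        if need & {"f0", "jitter", "shimmer", "voiceProb", "harmonicERMS", "noiseERMS", "HNR"}:
            f0 = extract_f0(raw, w.rate, cfg.fmin, cfg.fmax, cfg.voicing_threshold)
            columns["f0"] = f0[:, None]
        if need & {"jitter", "shimmer"}:
            marks = mark_pitch_periods(w, f0, p)
            frame_times = p.frame_times(t, w.rate)
            columns["jitter"] = extract_jitter(marks, frame_times)[:, None]
            columns["shimmer"] = extract_shimmer(marks, frame_times)[:, None]
        if need & {"loudness", "dloudness", "mfcc", "dmfcc", "mel", "lpc", "lsp"}:
            sp = extract_spectral(tapered, w.rate, cfg.n_mfcc, cfg.n_mel, cfg.lpc_order, cfg.delta_width)
            for key in ("mfcc", "dmfcc", "mel", "lpc", "lsp"):
                columns[key] = sp[key]
            columns["loudness"] = sp["loudness"][:, None]
            columns["dloudness"] = sp["dloudness"][:, None]
        if need & {"voiceProb", "harmonicERMS", "noiseERMS", "HNR"}:
            vh = extract_voicing_harmonicity(raw, w.rate, f0, cfg.fmin, cfg.fmax, cfg.hnr_clip)
            for key in ("voiceProb", "harmonicERMS", "noiseERMS", "HNR"):
                columns[key] = vh[key][:, None]

        schema = FeatureSchema.from_config(cfg)
        blocks = []
        for group in _GROUP_ORDER:
            if group in cfg.groups:
                blocks.append(np.atleast_2d(columns[group].reshape(t, -1)))
        values = np.concatenate(blocks, axis=1) if blocks else np.zeros((t, 0))
        if values.shape[1] < schema.z:  # pad columns
            pad = np.zeros((t, schema.z - values.shape[1]))
            values = np.concatenate([values, pad], axis=1)
        return FeatureMatrix(values, schema, source_id)
    except ValueError as exc:
        raise ValueError(f"feature extraction failed for segment {source_id!r}: {exc}") from exc
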