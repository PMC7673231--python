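"""F0 extraction, octave-error repair, and per-subject semitone landmarks.

The acoustic front end of the tone-production assessment: each recorded
monosyllable is reduced to an F0 contour by short-time autocorrelation,
doubling/halving tracker errors are repaired against a running median, and
the contour is summarized by three landmarks (onset, midpoint, offset of the
voiced span).  Landmarks are normalized per subject to semitones relative to
``M``, the mean F0 of that subject's tone-1 (high-flat) tokens::

    semitone = 12 * log2(F0 / M)

so that subjects with different vocal pitch occupy a common tone space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PitchParams",
    "F0Contour",
    "LandmarkTriple",
    "SubjectNormalization",
    "ToneToken",
    "UnanalyzableToken",
    "extract_f0",
    "correct_octave_errors",
    "sample_landmarks",
    "compute_reference",
    "semitone_normalize",
]


class UnanalyzableToken(ValueError):
    """Raised when a contour has too few voiced frames for landmarking."""


@dataclass(frozen=True)
class PitchParams:
    """Configuration of the autocorrelation pitch tracker.

    Defaults target child voices: the search range 75-800 Hz spans the F0 of
    both young children and adolescent boys; the 40 ms frame holds at least
    three periods of the lowest searchable pitch.
    """

    f0_min: float = 75.0
    f0_max: float = 800.0
    frame_length: float = 0.040  # seconds
    hop: float = 0.010  # seconds
    voicing_threshold: float = 0.45  # normalized autocorrelation peak
    octave_jump_threshold: float = 7.0  # semitones vs running median
    median_window: int = 5  # voiced frames in the running-median window

    def __post_init__(self) -> None:
        if not 0 < self.f0_min < self.f0_max:
            raise ValueError("need 0 < f0_min < f0_max")
        if self.frame_length < 2.0 / self.f0_min:
            raise ValueError("frame_length must cover >= 2 periods of f0_min")
        if self.hop > self.frame_length:
            raise ValueError("hop must not exceed frame_length")


@dataclass
class F0Contour:
    """Per-frame pitch track.  ``f0_hz`` is NaN wherever unvoiced."""

    frame_times: np.ndarray
    f0_hz: np.ndarray
    voiced_flags: np.ndarray
    corrected_frames: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.f0_hz = np.asarray(self.f0_hz, dtype=float)
        self.voiced_flags = np.asarray(self.voiced_flags, dtype=bool)
        if not (
            len(self.frame_times) == len(self.f0_hz) == len(self.voiced_flags)
        ):
            raise ValueError("frame arrays must have equal length")
        if len(self.frame_times) > 1 and not np.all(
            np.diff(self.frame_times) > 0
        ):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_voiced(self) -> int:
        return int(self.voiced_flags.sum())

    def voiced_f0(self) -> np.ndarray:
        return self.f0_hz[self.voiced_flags]


@dataclass(frozen=True)
class LandmarkTriple:
    """Onset / midpoint / offset F0 of one token, in Hz or semitones."""

    onset: float
    mid: float
    offset: float
    unit: str = "hz"  # "hz" or "semitone"

    def __post_init__(self) -> None:
        for v in (self.onset, self.mid, self.offset):
            if not math.isfinite(v):
                raise ValueError("landmark values must be finite")
        if self.unit not in ("hz", "semitone"):
            raise ValueError(f"unknown unit {self.unit!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.onset, self.mid, self.offset], dtype=float)


@dataclass(frozen=True)
class SubjectNormalization:
    """The subject's pitch anchor M: mean F0 of their tone-1 tokens."""

    reference_m: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.reference_m) and self.reference_m > 0):
            raise ValueError("reference_m must be positive and finite")


@dataclass
class ToneToken:
    """One produced word: who said it, which tone was targeted, what came out."""

    subject_id: str
    group: str  # "NH" or "CI"
    word_id: str
    target_tone: int  # 1..4
    contour: F0Contour | None = None
    landmarks_hz: LandmarkTriple | None = None
    landmarks_st: LandmarkTriple | None = None

    def __post_init__(self) -> None:
        if self.target_tone not in (1, 2, 3, 4):
            raise ValueError(f"target_tone must be 1..4, got {self.target_tone}")
        if self.group not in ("NH", "CI"):
            raise ValueError(f"group must be NH or CI, got {self.group!r}")


# ---------------------------------------------------------------------------
# pitch tracking
# ---------------------------------------------------------------------------


def extract_f0(
    samples: np.ndarray, sample_rate: float, params: PitchParams | None = None
) -> F0Contour:
    """Track F0 by the short-time autocorrelation peak.

    Each frame is mean-removed and its biased autocorrelation is computed via
    FFT; the candidate pitch is the highest normalized peak whose lag lies in
    ``[1/f0_max, 1/f0_min]``, refined by parabolic interpolation.  Frames whose
    peak falls below ``voicing_threshold`` are flagged unvoiced.

    Silent or aperiodic input yields a contour with zero voiced frames rather
    than an error; an inadequate sample rate raises ``ValueError``.
    """
    params = params or PitchParams()
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("samples must be non-empty")
    if sample_rate < 2.0 * params.f0_max * 4.0:
        raise ValueError(
            f"sample_rate {sample_rate} too low for f0_max {params.f0_max} "
            "(need >= 8 * f0_max)"
        )

    frame_n = int(round(params.frame_length * sample_rate))
    hop_n = max(1, int(round(params.hop * sample_rate)))
    lag_min = max(2, int(math.floor(sample_rate / params.f0_max)))
    lag_max = int(math.ceil(sample_rate / params.f0_min))

    if samples.size < frame_n:
        samples = np.pad(samples, (0, frame_n - samples.size))
    n_frames = 1 + (samples.size - frame_n) // hop_n

    starts = np.arange(n_frames) * hop_n
    frames = np.lib.stride_tricks.sliding_window_view(samples, frame_n)[starts]
    frames = frames - frames.mean(axis=1, keepdims=True)

    # biased autocorrelation of every frame at once
    nfft = 1 << int(np.ceil(np.log2(2 * frame_n)))
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    acf = np.fft.irfft(spec * np.conj(spec), n=nfft, axis=1)[:, : lag_max + 2]
    r0 = acf[:, 0].copy()
    silent = r0 <= 0
    r0[silent] = 1.0
    acf_norm = acf / r0[:, None]

    times = (starts + frame_n / 2) / sample_rate
    f0 = np.full(n_frames, np.nan)
    voiced = np.zeros(n_frames, dtype=bool)

    search = acf_norm[:, lag_min : lag_max + 1]
    peak_rel = np.argmax(search, axis=1)
    peak_lag = peak_rel + lag_min
    peak_val = search[np.arange(n_frames), peak_rel]

    for i in range(n_frames):
        if silent[i] or peak_val[i] < params.voicing_threshold:
            continue
        lag = int(peak_lag[i])
        # parabolic refinement around the integer-lag peak
        if 1 <= lag < acf_norm.shape[1] - 1:
            ym1, y0, yp1 = acf_norm[i, lag - 1 : lag + 2]
            denom = ym1 - 2 * y0 + yp1
            if denom < 0:
                lag_f = lag + 0.5 * (ym1 - yp1) / denom
            else:
                lag_f = float(lag)
        else:
            lag_f = float(lag)
        cand = sample_rate / lag_f
        if params.f0_min <= cand <= params.f0_max:
            f0[i] = cand
            voiced[i] = True

    return F0Contour(frame_times=times, f0_hz=f0, voiced_flags=voiced)


def correct_octave_errors(
    contour: F0Contour, params: PitchParams | None = None
) -> F0Contour:
    """Repair doubling/halving tracker failures against a running median.

    A voiced frame deviating from the running median of its voiced
    neighborhood by at least ``octave_jump_threshold`` semitones is replaced
    by the octave transposition (repeated x2 or x1/2) that brings it within
    the threshold, or flagged unvoiced when no transposition does.  Indices of
    altered frames are recorded on the returned contour for the audit trail.
    """
    params = params or PitchParams()
    if contour.n_voiced < 3:
        logger.warning(
            "octave correction skipped: only %d voiced frames", contour.n_voiced
        )
        return contour

    f0 = contour.f0_hz.copy()
    voiced = contour.voiced_flags.copy()
    vidx = np.flatnonzero(voiced)
    vals = f0[vidx]
    half = params.median_window // 2
    corrected: list[int] = []

    for k, idx in enumerate(vidx):
        lo, hi = max(0, k - half), min(len(vals), k + half + 1)
        neigh = np.delete(vals[lo:hi], k - lo)
        if neigh.size == 0:
            continue
        med = float(np.median(neigh))
        dev = abs(12.0 * math.log2(vals[k] / med))
        if dev < params.octave_jump_threshold:
            continue
        # try octave transpositions of the raw value
        best = None
        for shift in (-3, -2, -1, 1, 2, 3):
            cand = vals[k] * 2.0**shift
            if not (params.f0_min <= cand <= params.f0_max):
                continue
            cdev = abs(12.0 * math.log2(cand / med))
            if cdev < params.octave_jump_threshold and (
                best is None or cdev < best[1]
            ):
                best = (cand, cdev)
        if best is not None:
            f0[idx] = best[0]
        else:
            f0[idx] = np.nan
            voiced[idx] = False
        corrected.append(int(idx))

    return F0Contour(
        frame_times=contour.frame_times,
        f0_hz=f0,
        voiced_flags=voiced,
        corrected_frames=sorted(set(contour.corrected_frames) | set(corrected)),
    )


def sample_landmarks(contour: F0Contour) -> LandmarkTriple:
    """Onset, midpoint and offset F0 of the voiced span, in Hz.

    Onset/offset are the first/last voiced frames; the midpoint is the voiced
    frame nearest the temporal midpoint of the voiced span (later frame on an
    exact tie).
    """
    vidx = np.flatnonzero(contour.voiced_flags)
    if vidx.size < 3:
        raise UnanalyzableToken(
            f"need >= 3 voiced frames, found {vidx.size}"
        )
    t = contour.frame_times[vidx]
    t_mid = 0.5 * (t[0] + t[-1])
    dist = np.abs(t - t_mid)
    # later frame wins an exact tie; tolerance absorbs float rounding
    tol = 1e-9 * max(t[-1] - t[0], 1.0)
    mid_k = int(np.flatnonzero(dist <= dist.min() + tol)[-1])
    return LandmarkTriple(
        onset=float(contour.f0_hz[vidx[0]]),
        mid=float(contour.f0_hz[vidx[mid_k]]),
        offset=float(contour.f0_hz[vidx[-1]]),
        unit="hz",
    )


def compute_reference(tokens: list[ToneToken]) -> SubjectNormalization:
    """M = equal-weight mean over tone-1 tokens of each token's mean voiced F0.

    Token-level means are averaged with equal weight so long and short
    productions contribute equally to the anchor.
    """
    token_means = []
    for tok in tokens:
        if tok.target_tone != 1:
            continue
        if tok.contour is not None and tok.contour.n_voiced > 0:
            token_means.append(float(tok.contour.voiced_f0().mean()))
        elif tok.landmarks_hz is not None:
            token_means.append(float(tok.landmarks_hz.as_array().mean()))
    if not token_means:
        raise UnanalyzableToken("subject has no analyzable tone-1 tokens")
    return SubjectNormalization(reference_m=float(np.mean(token_means)))


def semitone_normalize(
    landmarks: LandmarkTriple, norm: SubjectNormalization
) -> LandmarkTriple:
    """Convert Hz landmarks to semitones re the subject anchor M."""
    vals = landmarks.as_array()
    if np.any(vals <= 0):
        raise ValueError("landmark F0 values must be positive")
    st = 12.0 * np.log2(vals / norm.reference_m)
    return LandmarkTriple(
        onset=float(st[0]), mid=float(st[1]), offset=float(st[2]),
        unit="semitone",
    )
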