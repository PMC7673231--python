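"""Synthetic tone-production cohorts.

Generates landmark-level (and optionally audio-level) productions of the 36
monosyllabic test words for simulated normal-hearing (NH) and cochlear-implant
(CI) child speakers, so every downstream stage can be exercised without
recordings.  A subject is a :class:`SubjectProfile`: a vocal-pitch anchor,
per-tone landmark templates encoding the canonical Mandarin contour shapes
(1 high-flat, 2 rising, 3 dipping, 4 falling), a flattening parameter
``lambda`` in [0, 1] pulling every contour toward its own time-mean — the CI
group's characteristic deficit — and a per-landmark Gaussian production noise.

The word list is balanced by construction: 18 syllables, each carrying the
two tones of one contrast, giving 3 word pairs per contrast and 9 words per
tone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contour_features import LandmarkTriple, ToneToken
from .cohort_stats import DemographicRecord

__all__ = [
    "SYLLABLES",
    "WORD_LIST",
    "SubjectProfile",
    "CohortSpec",
    "Cohort",
    "default_templates",
    "generate_token_landmarks",
    "synthesize_waveform",
    "generate_subject_tokens",
    "generate_cohort",
]

# 18 child-vocabulary monosyllables; consecutive triples carry one tone
# contrast each, so each tone ends up on exactly 9 words.
SYLLABLES = (
    "bei", "bi", "chi", "chuang", "deng", "hu", "jian", "mao", "mi",
    "qiang", "san", "shu", "tang", "tu", "wa", "wu", "ye", "yu",
)
_CONTRAST_ORDER = ((1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4))

#: (word_id, syllable, tone) for the full 36-word balanced list.
WORD_LIST: tuple[tuple[str, str, int], ...] = tuple(
    (f"{syl}{tone}", syl, tone)
    for k, pair in enumerate(_CONTRAST_ORDER)
    for syl in SYLLABLES[3 * k : 3 * k + 3]
    for tone in pair
)


def default_templates() -> dict[int, np.ndarray]:
    """Per-tone (onset, mid, offset) templates in semitones re the anchor.

    Tone 1 is flat at the anchor; tone 2 starts low and rises; tone 3 sits
    lowest with a mid dip; tone 4 starts highest and falls.  Values place the
    tones in the four quadrants of the onset-offset plane with 2 vs 3 the
    closest pair — the contrast real speakers separate worst — and keep the
    four per-tone template means mutually distinct so that flattening toward
    the time-mean degrades 2 vs 3 first rather than colliding other pairs.
    """
    return {
        1: np.array([0.0, 0.0, 0.0]),
        2: np.array([-4.0, -4.5, -1.0]),
        3: np.array([-5.0, -7.0, -3.0]),
        4: np.array([4.5, 2.0, -0.5]),
    }


@dataclass
class SubjectProfile:
    subject_id: str
    group: str  # NH or CI
    reference_f0: float  # Hz
    tone_templates: dict[int, np.ndarray] = field(default_factory=default_templates)
    flattening_lambda: float = 0.0
    token_noise_sd: float = 1.0  # semitones
    tokens_per_tone: int = 9
    demographics: DemographicRecord | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.flattening_lambda <= 1.0:
            raise ValueError("flattening_lambda must lie in [0, 1]")
        if self.token_noise_sd < 0:
            raise ValueError("token_noise_sd must be >= 0")
        if self.tokens_per_tone < 1:
            raise ValueError("tokens_per_tone must be >= 1")


@dataclass
class CohortSpec:
    """Study-condition parameters for one simulated cohort.

    NH subjects produce near-template contours (small lambda, 1 st noise);
    CI subjects produce flattened, noisier contours, with lambda decreasing
    slightly with duration of device use so longer users score better.
    """

    n_nh: int = 50
    n_ci: int = 50
    seed: int = 0
    nh_lambda_range: tuple[float, float] = (0.0, 0.1)
    ci_lambda_range: tuple[float, float] = (0.5, 0.9)
    nh_noise_sd: float = 1.0
    ci_noise_sd: float = 2.0
    reference_f0_range: tuple[float, float] = (220.0, 320.0)
    nh_age_range: tuple[float, float] = (2.3, 12.5)
    implantation_age_range: tuple[float, float] = (0.5, 8.0)
    duration_range: tuple[float, float] = (0.5, 9.0)
    lambda_duration_slope: float = 0.02  # lambda units per year of use

    def __post_init__(self) -> None:
        if self.n_nh < 0 or self.n_ci < 0:
            raise ValueError("cohort sizes must be >= 0")


@dataclass
class Cohort:
    spec: CohortSpec
    profiles: list[SubjectProfile]
    subjects: dict[str, list[ToneToken]]  # tokens carry true landmarks (Hz)
    manifest: pd.DataFrame
    features: pd.DataFrame  # landmark-level feature table (Hz)

    @property
    def demographics(self) -> list[DemographicRecord]:
        return [p.demographics for p in self.profiles if p.demographics]


def generate_token_landmarks(
    profile: SubjectProfile, tone: int, rng: np.random.Generator
) -> tuple[LandmarkTriple, LandmarkTriple]:
    """Draw one token's landmarks; returns (semitone truth, Hz equivalent).

    landmark = (1 - lambda) * template + lambda * mean(template) + N(0, sd)
    per coordinate, in semitones re the subject anchor; Hz values are
    ``reference_f0 * 2^(st/12)``.
    """
    tmpl = profile.tone_templates[tone]
    lam = profile.flattening_lambda
    st = (1.0 - lam) * tmpl + lam * tmpl.mean()
    st = st + rng.normal(0.0, profile.token_noise_sd, size=3)
    hz = profile.reference_f0 * np.power(2.0, st / 12.0)
    return (
        LandmarkTriple(*map(float, st), unit="semitone"),
        LandmarkTriple(*map(float, hz), unit="hz"),
    )


def synthesize_waveform(
    landmarks_hz: LandmarkTriple,
    duration: float = 0.4,
    sample_rate: float = 44_100.0,
    n_harmonics: int = 10,
    edge_hold: float = 0.02,
) -> np.ndarray:
    """Harmonic-rich signal whose F0 follows the landmark contour.

    The instantaneous F0 is the piecewise-linear path through onset (t=0),
    mid (t=T/2) and offset (t=T), with the endpoint values held for
    ``edge_hold`` seconds (half a default analysis frame) so that a
    frame-centered pitch tracker observes the true onset/offset rather than
    a mid-glide value.  The signal is a 1/k-weighted harmonic sum (a
    lowpassed pulse-train approximation) with 10 ms cosine onset/offset
    ramps.  Deterministic given its inputs.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if landmarks_hz.unit != "hz":
        raise ValueError("landmarks must be in Hz")
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    hold = min(edge_hold, duration / 5.0)
    f0 = np.interp(
        t,
        [0.0, hold, duration / 2.0, duration - hold, duration],
        [
            landmarks_hz.onset, landmarks_hz.onset, landmarks_hz.mid,
            landmarks_hz.offset, landmarks_hz.offset,
        ],
    )
    if np.any(f0 <= 0):
        raise ValueError("F0 path must stay positive")
    phase = 2.0 * math.pi * np.cumsum(f0) / sample_rate
    kmax = max(1, min(n_harmonics, int(0.45 * sample_rate / f0.max())))
    sig = np.zeros(n)
    for k in range(1, kmax + 1):
        sig += np.sin(k * phase) / k
    sig /= np.abs(sig).max()
    ramp_n = min(n // 2, int(0.010 * sample_rate))
    if ramp_n > 0:
        ramp = 0.5 * (1 - np.cos(np.linspace(0, math.pi, ramp_n)))
        sig[:ramp_n] *= ramp
        sig[-ramp_n:] *= ramp[::-1]
    return sig


def generate_subject_tokens(
    profile: SubjectProfile, rng: np.random.Generator
) -> list[ToneToken]:
    """All 36 word tokens (9 per tone) for one subject, true landmarks in Hz."""
    per_tone_count = {t: 0 for t in (1, 2, 3, 4)}
    tokens = []
    for word_id, _syl, tone in WORD_LIST:
        if per_tone_count[tone] >= profile.tokens_per_tone:
            continue
        per_tone_count[tone] += 1
        _st, hz = generate_token_landmarks(profile, tone, rng)
        tokens.append(
            ToneToken(
                subject_id=profile.subject_id,
                group=profile.group,
                word_id=word_id,
                target_tone=tone,
                landmarks_hz=hz,
            )
        )
    return tokens


def _sample_profile(
    spec: CohortSpec, group: str, index: int, rng: np.random.Generator
) -> SubjectProfile:
    sid = f"{group}{index + 1:03d}"
    ref = rng.uniform(*spec.reference_f0_range)
    if group == "NH":
        lam = rng.uniform(*spec.nh_lambda_range)
        demo = DemographicRecord(
            subject_id=sid, group="NH",
            chronological_age=float(rng.uniform(*spec.nh_age_range)),
        )
        noise = spec.nh_noise_sd
    else:
        implant = float(rng.uniform(*spec.implantation_age_range))
        duration = float(rng.uniform(*spec.duration_range))
        base = rng.uniform(*spec.ci_lambda_range)
        mid_dur = sum(spec.duration_range) / 2.0
        lam = float(
            np.clip(base - spec.lambda_duration_slope * (duration - mid_dur), 0, 1)
        )
        demo = DemographicRecord(
            subject_id=sid, group="CI",
            chronological_age=implant + duration,
            age_at_implantation=implant, duration_of_use=duration,
        )
        noise = spec.ci_noise_sd
    return SubjectProfile(
        subject_id=sid, group=group, reference_f0=float(ref),
        flattening_lambda=float(lam), token_noise_sd=noise,
        demographics=demo,
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Full deterministic cohort: profiles, tokens, manifest and feature table."""
    rng = np.random.default_rng(spec.seed)
    profiles = [_sample_profile(spec, "NH", i, rng) for i in range(spec.n_nh)]
    profiles += [_sample_profile(spec, "CI", i, rng) for i in range(spec.n_ci)]

    subjects: dict[str, list[ToneToken]] = {}
    manifest_rows, feature_rows = [], []
    for prof in profiles:
        tokens = generate_subject_tokens(prof, rng)
        subjects[prof.subject_id] = tokens
        demo = prof.demographics
        for tok in tokens:
            manifest_rows.append(
                dict(
                    subject_id=tok.subject_id,
                    group=tok.group,
                    chronological_age=round(demo.chronological_age, 3),
                    age_at_implantation=(
                        round(demo.age_at_implantation, 3)
                        if demo.age_at_implantation is not None else ""
                    ),
                    duration_of_use=(
                        round(demo.duration_of_use, 3)
                        if demo.duration_of_use is not None else ""
                    ),
                    word_id=tok.word_id,
                    target_tone=tok.target_tone,
                    wav_path="",
                )
            )
            lm = tok.landmarks_hz
            feature_rows.append(
                dict(
                    subject_id=tok.subject_id, group=tok.group,
                    word_id=tok.word_id, target_tone=tok.target_tone,
                    onset_hz=lm.onset, mid_hz=lm.mid, offset_hz=lm.offset,
                )
            )
    return Cohort(
        spec=spec,
        profiles=profiles,
        subjects=subjects,
        manifest=pd.DataFrame(manifest_rows),
        features=pd.DataFrame(feature_rows),
    )


def write_wav_corpus(
    cohort: Cohort, out_dir, duration: float = 0.4, sample_rate: float = 44_100.0
) -> pd.DataFrame:
    """Render every token to a mono 16-bit WAV; returns the updated manifest."""
    from pathlib import Path
    from scipy.io import wavfile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest.copy()
    paths = []
    for tokens in cohort.subjects.values():
        for tok in tokens:
            sig = synthesize_waveform(tok.landmarks_hz, duration, sample_rate)
            path = out / f"{tok.subject_id}_{tok.word_id}.wav"
            wavfile.write(
                path, int(sample_rate), (sig * 32000).astype(np.int16)
            )
            paths.append(str(path))
    manifest["wav_path"] = paths
    return manifest
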