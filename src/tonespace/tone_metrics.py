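"""Per-subject tone differentiability and hit-rate confusion matrices.

Two acoustic measures summarize how well a speaker separates the four
Mandarin tones in F0 landmark space:

* **Differentiability** of a tone contrast (i, j) is
  ``[(1 - Ai/A_i) + (1 - Ai/A_j)] / 2`` where ``Ai`` is the overlap measure of
  the two tone regions and ``A_i, A_j`` their areas/volumes — 0 for identical
  regions, 1 for disjoint ones.  The subject score averages the six contrasts.
* **Hit rate**: cell (i, j) of the 4x4 confusion matrix is the proportion of
  target-tone-i tokens among all tokens falling inside tone region j; the
  diagonal average is the subject's hit-rate score.

Both are computed under the 2D method (onset, offset) and the 3D method
(onset, mid, offset); regions are fitted per subject.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contour_features import ToneToken
from .tone_geometry import (
    GeometryParams,
    InsufficientDataError,
    DegenerateRegionError,
    OverlapResult,
    ToneRegion,
    contains_many,
    fit_region,
    overlap_measure,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CONTRASTS",
    "DifferentiabilityResult",
    "HitRateMatrix",
    "pairwise_differentiability",
    "landmark_matrix",
    "fit_tone_regions",
    "subject_differentiability",
    "hit_rate_matrix",
    "cohort_scores",
]

TONES = (1, 2, 3, 4)
CONTRASTS = tuple(itertools.combinations(TONES, 2))  # six unordered pairs


def contrast_key(pair: tuple[int, int]) -> str:
    return f"{pair[0]}v{pair[1]}"


@dataclass
class DifferentiabilityResult:
    subject_id: str
    method: str  # "2D" or "3D"
    contrast_scores: dict[str, float]  # NaN where undefined
    average: float

    def defined_scores(self) -> dict[str, float]:
        return {k: v for k, v in self.contrast_scores.items() if np.isfinite(v)}


@dataclass
class HitRateMatrix:
    subject_id: str
    method: str
    cells: np.ndarray  # 4x4, row=target tone, col=region; NaN columns undefined
    diagonal_average: float
    undefined_columns: list[int] = field(default_factory=list)  # tone labels


def pairwise_differentiability(
    r1: ToneRegion, r2: ToneRegion, overlap: OverlapResult
) -> float:
    """Score of one tone contrast from its regions and their overlap.

    Clipped to [0, 1]: Monte-Carlo noise can push Ai marginally above the
    smaller measure, which would otherwise give a slightly negative term.
    """
    a1, a2 = r1.measure, r2.measure
    if a1 <= 0 or a2 <= 0:
        raise DegenerateRegionError("zero-measure region in contrast")
    score = ((1.0 - overlap.ai / a1) + (1.0 - overlap.ai / a2)) / 2.0
    return float(np.clip(score, 0.0, 1.0))


def landmark_matrix(tokens: list[ToneToken], method: str) -> dict[int, np.ndarray]:
    """Per-tone arrays of normalized landmark vectors for the given method.

    2D uses (onset, offset); 3D uses (onset, mid, offset), all in semitones.
    Tokens without normalized landmarks are skipped.
    """
    if method not in ("2D", "3D"):
        raise ValueError(f"method must be '2D' or '3D', got {method!r}")
    cols = [0, 2] if method == "2D" else [0, 1, 2]
    by_tone: dict[int, list[np.ndarray]] = {t: [] for t in TONES}
    for tok in tokens:
        if tok.landmarks_st is None:
            continue
        by_tone[tok.target_tone].append(tok.landmarks_st.as_array()[cols])
    return {
        t: (np.array(v) if v else np.empty((0, len(cols))))
        for t, v in by_tone.items()
    }


def fit_tone_regions(
    tokens: list[ToneToken],
    method: str,
    params: GeometryParams | None = None,
) -> dict[int, ToneRegion]:
    """Fit one region per tone; tones with too few tokens are omitted."""
    params = params or GeometryParams()
    dim = 2 if method == "2D" else 3
    pts = landmark_matrix(tokens, method)
    regions: dict[int, ToneRegion] = {}
    for tone in TONES:
        try:
            regions[tone] = fit_region(pts[tone], dim, tone=tone, params=params)
        except (InsufficientDataError, DegenerateRegionError) as exc:
            logger.info("tone %d region not fitted: %s", tone, exc)
    return regions


def subject_differentiability(
    tokens: list[ToneToken],
    method: str,
    params: GeometryParams | None = None,
    seed: int = 0,
) -> DifferentiabilityResult:
    """Six contrast scores and their mean for one subject.

    Contrasts involving a tone whose region could not be fitted are NaN and
    excluded from the average; with fewer than two fitted regions the
    subject-level result is entirely undefined.
    """
    params = params or GeometryParams()
    subject_id = tokens[0].subject_id if tokens else ""
    regions = fit_tone_regions(tokens, method, params)
    if len(regions) < 2:
        logger.warning("subject %s: < 2 valid tone regions (%s)", subject_id, method)
        return DifferentiabilityResult(
            subject_id=subject_id,
            method=method,
            contrast_scores={contrast_key(c): float("nan") for c in CONTRASTS},
            average=float("nan"),
        )
    rng = np.random.default_rng(seed)
    scores: dict[str, float] = {}
    for pair in CONTRASTS:
        if pair[0] in regions and pair[1] in regions:
            r1, r2 = regions[pair[0]], regions[pair[1]]
            ov = overlap_measure(r1, r2, n_samples=params.n_samples, seed=rng)
            scores[contrast_key(pair)] = pairwise_differentiability(r1, r2, ov)
        else:
            scores[contrast_key(pair)] = float("nan")
    defined = [v for v in scores.values() if np.isfinite(v)]
    return DifferentiabilityResult(
        subject_id=subject_id,
        method=method,
        contrast_scores=scores,
        average=float(np.mean(defined)) if defined else float("nan"),
    )


def hit_rate_matrix(
    tokens: list[ToneToken],
    method: str,
    params: GeometryParams | None = None,
) -> HitRateMatrix:
    """4x4 target-by-region confusion matrix of containment proportions.

    cell(i, j) = (# target-i tokens inside region j) / (# tokens of any tone
    inside region j).  A token inside several regions contributes to every
    such column.  Columns whose region is unfitted or empty are NaN and
    excluded from the diagonal average.
    """
    params = params or GeometryParams()
    subject_id = tokens[0].subject_id if tokens else ""
    regions = fit_tone_regions(tokens, method, params)
    pts_by_tone = landmark_matrix(tokens, method)

    cells = np.full((4, 4), np.nan)
    undefined: list[int] = []
    for j, tone_j in enumerate(TONES):
        if tone_j not in regions:
            undefined.append(tone_j)
            continue
        counts = np.zeros(4)
        for i, tone_i in enumerate(TONES):
            pts = pts_by_tone[tone_i]
            if len(pts):
                counts[i] = int(contains_many(regions[tone_j], pts).sum())
        total = counts.sum()
        if total == 0:
            undefined.append(tone_j)
            continue
        cells[:, j] = counts / total

    diag = np.diag(cells)
    defined_diag = diag[np.isfinite(diag)]
    return HitRateMatrix(
        subject_id=subject_id,
        method=method,
        cells=cells,
        diagonal_average=(
            float(defined_diag.mean()) if defined_diag.size else float("nan")
        ),
        undefined_columns=undefined,
    )


def cohort_scores(
    subjects: dict[str, list[ToneToken]],
    methods: tuple[str, ...] = ("2D", "3D"),
    params: GeometryParams | None = None,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Long-form score tables for a cohort of subjects.

    Returns ``summary`` (one row per subject x method x measure),
    ``contrasts`` (per-contrast differentiability detail) and ``cells``
    (confusion-matrix detail).  Undefined scores are carried as NaN.
    """
    params = params or GeometryParams()
    rng = np.random.default_rng(seed)
    summary, contrasts, cells = [], [], []
    for sid, tokens in subjects.items():
        group = tokens[0].group if tokens else ""
        for method in methods:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            diff = subject_differentiability(tokens, method, params, seed=sub_seed)
            hits = hit_rate_matrix(tokens, method, params)
            summary.append(
                dict(subject_id=sid, group=group, method=method,
                     measure="differentiability", value=diff.average)
            )
            summary.append(
                dict(subject_id=sid, group=group, method=method,
                     measure="hit_rate", value=hits.diagonal_average)
            )
            for key, val in diff.contrast_scores.items():
                contrasts.append(
                    dict(subject_id=sid, group=group, method=method,
                         contrast=key, value=val)
                )
            for i, ti in enumerate(TONES):
                for j, tj in enumerate(TONES):
                    cells.append(
                        dict(subject_id=sid, group=group, method=method,
                             target_tone=ti, region_tone=tj,
                             value=hits.cells[i, j])
                    )
    return {
        "summary": pd.DataFrame(summary),
        "contrasts": pd.DataFrame(contrasts),
        "cells": pd.DataFrame(cells),
    }
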