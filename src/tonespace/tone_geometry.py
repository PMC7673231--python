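"""Tone ellipses and ellipsoids: fitting, containment, overlap.

A tone's token scatter in landmark space — (onset, offset) semitones for the
2D method, (onset, mid, offset) for 3D — is summarized by an ellipse or
ellipsoid centered on the scatter mean whose principal semiaxes lie along the
covariance eigenvectors with length ``sd_multiplier`` (default 2) sample SDs.
Pairwise region overlap, the ingredient of the differentiability score, is
estimated by seeded Monte-Carlo rejection sampling inside the smaller region,
validated elsewhere against the closed-form circle-lens area.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ToneRegion",
    "OverlapResult",
    "GeometryParams",
    "fit_region",
    "contains",
    "overlap_measure",
    "region_from_summary",
]

RIDGE = 1e-6  # semitone^2 added to covariance diagonal for stability

_UNIT_BALL = {2: math.pi, 3: 4.0 * math.pi / 3.0}


class InsufficientDataError(ValueError):
    pass


class DegenerateRegionError(ValueError):
    pass


@dataclass(frozen=True)
class GeometryParams:
    """Region-fitting and overlap-estimation configuration."""

    sd_multiplier: float = 2.0
    orientation: str = "covariance"  # or "axis_aligned"
    n_samples: int = 200_000
    ridge: float = RIDGE

    def __post_init__(self) -> None:
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be positive")
        if self.orientation not in ("covariance", "axis_aligned"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass
class ToneRegion:
    """An ellipse (dim 2) or ellipsoid (dim 3) for one tone category."""

    dim: int
    tone: int
    center: np.ndarray
    axes: np.ndarray  # rows are orthonormal direction vectors
    semiaxes: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        self.semiaxes = np.asarray(self.semiaxes, dtype=float)
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        if self.center.shape != (self.dim,):
            raise ValueError("center has wrong shape")
        if self.axes.shape != (self.dim, self.dim):
            raise ValueError("axes has wrong shape")
        if self.semiaxes.shape != (self.dim,):
            raise ValueError("semiaxes has wrong shape")
        if np.any(self.semiaxes <= 0):
            raise DegenerateRegionError("semiaxes must all be positive")
        if not np.allclose(self.axes @ self.axes.T, np.eye(self.dim), atol=1e-8):
            raise ValueError("axes must be orthonormal")

    @property
    def measure(self) -> float:
        """Area (dim 2) or volume (dim 3)."""
        return _UNIT_BALL[self.dim] * float(np.prod(self.semiaxes))

    @property
    def bounding_radius(self) -> float:
        return float(self.semiaxes.max())

    def to_dict(self) -> dict:
        return {
            "dim": self.dim,
            "tone": self.tone,
            "center": self.center.tolist(),
            "axes": self.axes.tolist(),
            "semiaxes": self.semiaxes.tolist(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "ToneRegion":
        return cls(
            dim=int(d["dim"]),
            tone=int(d["tone"]),
            center=np.array(d["center"], dtype=float),
            axes=np.array(d["axes"], dtype=float),
            semiaxes=np.array(d["semiaxes"], dtype=float),
        )

    @classmethod
    def from_json(cls, s: str) -> "ToneRegion":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class OverlapResult:
    """Monte-Carlo intersection measure of two same-dimension regions."""

    ai: float
    rel_1: float  # ai / measure of region 1
    rel_2: float
    estimator_sd: float
    n_samples: int


def fit_region(
    points: np.ndarray,
    dim: int,
    tone: int = 0,
    params: GeometryParams | None = None,
) -> ToneRegion:
    """Fit the 2-SD covariance region to a tone's landmark scatter.

    Center is the coordinate-wise mean; axes are covariance eigenvectors
    (or coordinate axes under ``orientation="axis_aligned"``); each semiaxis
    is ``sd_multiplier`` times the SD along its axis.  A small ridge keeps
    near-degenerate scatters (e.g. perfectly flat productions) invertible.
    """
    params = params or GeometryParams()
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != dim:
        raise ValueError(f"points must be (n, {dim})")
    if pts.shape[0] < dim + 1:
        raise InsufficientDataError(
            f"need >= {dim + 1} points for dim {dim}, got {pts.shape[0]}"
        )
    if np.allclose(pts, pts[0], atol=1e-12):
        raise DegenerateRegionError("all points identical")

    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1) + params.ridge * np.eye(dim)
    if params.orientation == "axis_aligned":
        variances = np.diag(cov)
        axes = np.eye(dim)
        semiaxes = params.sd_multiplier * np.sqrt(variances)
    else:
        eigvals, eigvecs = np.linalg.eigh(cov)
        axes = eigvecs.T  # rows = directions
        semiaxes = params.sd_multiplier * np.sqrt(np.maximum(eigvals, 0.0))
    return ToneRegion(
        dim=dim, tone=tone, center=center, axes=axes, semiaxes=semiaxes
    )


def contains(region: ToneRegion, point: np.ndarray) -> bool:
    """Mahalanobis membership test; the boundary counts as inside."""
    p = np.asarray(point, dtype=float)
    if p.shape != (region.dim,):
        raise ValueError(f"point must have dimension {region.dim}")
    z = region.axes @ (p - region.center) / region.semiaxes
    return bool(z @ z <= 1.0)


def contains_many(region: ToneRegion, points: np.ndarray) -> np.ndarray:
    """Vectorized membership test for an (n, dim) array of points."""
    pts = np.asarray(points, dtype=float)
    z = (pts - region.center) @ region.axes.T / region.semiaxes
    return np.einsum("ij,ij->i", z, z) <= 1.0


def _sample_uniform(region: ToneRegion, n: int, rng: np.random.Generator):
    """Uniform samples inside the region (unit-ball draw mapped affinely)."""
    d = region.dim
    g = rng.standard_normal((n, d))
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    r = rng.random(n) ** (1.0 / d)
    ball = g * r[:, None]
    return ball * region.semiaxes @ region.axes + region.center


def overlap_measure(
    r1: ToneRegion,
    r2: ToneRegion,
    n_samples: int = 200_000,
    seed: int | np.random.Generator = 0,
) -> OverlapResult:
    """Estimate the intersection measure Ai of two tone regions.

    Uniform points are drawn inside the smaller-measure region; the fraction
    also inside the other, scaled by the smaller measure, estimates Ai.
    Disjoint bounding spheres short-circuit to an exact zero.  The result is
    deterministic given the seed; ``estimator_sd`` is the binomial standard
    error of the estimate.
    """
    if r1.dim != r2.dim:
        raise ValueError("regions must share dimension")
    if n_samples < 10_000:
        raise ValueError("n_samples must be >= 10000")

    gap = float(np.linalg.norm(r1.center - r2.center))
    if gap > r1.bounding_radius + r2.bounding_radius:
        return OverlapResult(
            ai=0.0, rel_1=0.0, rel_2=0.0, estimator_sd=0.0, n_samples=0
        )

    small, other = (r1, r2) if r1.measure <= r2.measure else (r2, r1)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pts = _sample_uniform(small, n_samples, rng)
    frac = float(contains_many(other, pts).mean())
    ai = frac * small.measure
    sd = small.measure * math.sqrt(max(frac * (1 - frac), 0.0) / n_samples)
    return OverlapResult(
        ai=ai,
        rel_1=ai / r1.measure,
        rel_2=ai / r2.measure,
        estimator_sd=sd,
        n_samples=n_samples,
    )


def region_from_summary(
    center: np.ndarray,
    axes: np.ndarray,
    semiaxes: np.ndarray,
    tone: int = 0,
) -> ToneRegion:
    """Construct a region directly from its parameters (tests, plots, I/O)."""
    center = np.asarray(center, dtype=float)
    return ToneRegion(
        dim=center.shape[0],
        tone=tone,
        center=center,
        axes=np.asarray(axes, dtype=float),
        semiaxes=np.asarray(semiaxes, dtype=float),
    )
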