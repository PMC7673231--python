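"""Differentiability scores and hit-rate confusion matrices."""

import math

import numpy as np
import pytest

from tonespace.tone_geometry import GeometryParams, overlap_measure, region_from_summary
from tonespace.tone_metrics import (
    CONTRASTS,
    TONES,
    cohort_scores,
    contrast_key,
    fit_tone_regions,
    hit_rate_matrix,
    landmark_matrix,
    pairwise_differentiability,
    subject_differentiability,
)
from tonespace.synthetic_data import default_templates

from conftest import make_cluster_tokens

FAST = GeometryParams(n_samples=20_000)


def circle(center, radius, tone=0):
    return region_from_summary(
        np.asarray(center, float), np.eye(2), np.full(2, float(radius)),
        tone=tone,
    )


class TestPairwiseDifferentiability:
    def test_identical_regions_zero(self):
        r = circle([0, 0], 1)
        ov = overlap_measure(r, r, seed=0)
        assert pairwise_differentiability(r, r, ov) <= 0.01

    def test_disjoint_regions_one(self):
        r1, r2 = circle([0, 0], 1), circle([10, 0], 1)
        ov = overlap_measure(r1, r2, seed=0)
        assert pairwise_differentiability(r1, r2, ov) == 1.0

    def test_unit_circles_lens_oracle(self):
        # Ai/A = (2 arccos(1/2) - sqrt(3)/2) / pi, so score ~= 0.609
        r1, r2 = circle([0, 0], 1), circle([1, 0], 1)
        ov = overlap_measure(r1, r2, n_samples=200_000, seed=1)
        expected = 1.0 - (2 * math.acos(0.5) - math.sqrt(3) / 2) / math.pi
        assert pairwise_differentiability(r1, r2, ov) == pytest.approx(
            expected, abs=0.01
        )

    def test_symmetric_in_regions(self):
        r1 = circle([0, 0], 1.0)
        r2 = circle([0.8, 0.3], 0.6)
        ov = overlap_measure(r1, r2, seed=4)
        assert pairwise_differentiability(
            r1, r2, ov
        ) == pytest.approx(pairwise_differentiability(r2, r1, ov))


class TestSubjectDifferentiability:
    def test_well_separated_clusters_near_one(self):
        rng = np.random.default_rng(0)
        centers = {1: [0, 0, 0], 2: [12, 4, 0], 3: [0, 8, 12], 4: [12, 12, 12]}
        toks = make_cluster_tokens(centers, 9, 0.5, rng)
        for method in ("2D", "3D"):
            res = subject_differentiability(toks, method, FAST, seed=0)
            assert all(v > 0.99 for v in res.contrast_scores.values())

    def test_identical_token_sets_score_zero(self):
        # the same 9 points relabeled as each tone give identical regions
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(9, 3))
        from tonespace.contour_features import LandmarkTriple, ToneToken

        toks = []
        for tone in TONES:
            for k, p in enumerate(pts):
                toks.append(
                    ToneToken(
                        subject_id="S", group="NH", word_id=f"w{tone}{k}",
                        target_tone=tone,
                        landmarks_st=LandmarkTriple(*map(float, p),
                                                    unit="semitone"),
                    )
                )
        res = subject_differentiability(toks, "3D", FAST, seed=2)
        assert all(v <= 0.01 for v in res.contrast_scores.values())

    def test_null_scores_shrink_with_sample_size(self):
        # same population for all tones: finite-sample bias decays with n
        def null_mean(n, seed):
            rng = np.random.default_rng(seed)
            toks = make_cluster_tokens(
                {t: [0, 0, 0] for t in TONES}, n, 1.0, rng
            )
            res = subject_differentiability(toks, "2D", FAST, seed=seed)
            return res.average

        small = np.mean([null_mean(9, s) for s in range(8)])
        large = np.mean([null_mean(200, s) for s in range(8)])
        assert large < small
        assert large < 0.15

    def test_score_monotone_in_separation(self):
        # ramp the cluster separation; scores rise from ~0 toward 1
        means = []
        for sep in (0.0, 2.0, 4.0, 8.0, 16.0):
            vals = []
            for seed in range(5):
                rng = np.random.default_rng(100 + seed)
                centers = {
                    1: [0, 0, 0], 2: [sep, 0, 0],
                    3: [0, 0, sep], 4: [sep, 0, sep],
                }
                toks = make_cluster_tokens(centers, 12, 1.0, rng)
                vals.append(
                    subject_differentiability(toks, "2D", FAST, seed=seed).average
                )
            means.append(np.mean(vals))
        jitter = 0.05
        assert all(b >= a - jitter for a, b in zip(means, means[1:]))
        assert means[-1] > 0.99

    def test_nh_template_subject_weakest_contrast_is_2v3(self):
        tmpl = default_templates()
        per_contrast = {contrast_key(c): [] for c in CONTRASTS}
        for seed in range(25):
            rng = np.random.default_rng(seed)
            toks = make_cluster_tokens({t: tmpl[t] for t in TONES}, 9, 1.0, rng)
            res = subject_differentiability(toks, "2D", FAST, seed=seed)
            for k, v in res.contrast_scores.items():
                per_contrast[k].append(v)
        means = {k: np.mean(v) for k, v in per_contrast.items()}
        assert min(means, key=means.get) == "2v3"

    def test_sparse_tone_yields_undefined_contrasts(self):
        rng = np.random.default_rng(5)
        centers = {1: [0, 0, 0], 2: [5, 0, 0], 3: [0, 5, 0]}
        toks = make_cluster_tokens(centers, 9, 0.5, rng)
        res = subject_differentiability(toks, "2D", FAST, seed=0)
        assert np.isnan(res.contrast_scores["1v4"])
        assert np.isfinite(res.contrast_scores["1v2"])
        assert np.isfinite(res.average)


class TestHitRateMatrix:
    def test_separated_clusters_identity_matrix(self):
        rng = np.random.default_rng(0)
        centers = {1: [0, 0, 0], 2: [20, 6, 0], 3: [0, 14, 20], 4: [20, 20, 20]}
        toks = make_cluster_tokens(centers, 9, 0.5, rng)
        hrm = hit_rate_matrix(toks, "2D", FAST)
        np.testing.assert_allclose(hrm.cells, np.eye(4))
        assert hrm.diagonal_average == 1.0

    def test_defined_columns_sum_to_one(self):
        rng = np.random.default_rng(7)
        toks = make_cluster_tokens(
            {t: [0, 0, 0] for t in TONES}, 9, 2.0, rng
        )
        hrm = hit_rate_matrix(toks, "3D", FAST)
        sums = np.nansum(hrm.cells, axis=0)
        for j in range(4):
            if np.isfinite(hrm.cells[0, j]):
                assert sums[j] == pytest.approx(1.0, abs=1e-12)

    def test_toy_fixture_matches_enumeration(self, toy12_tokens):
        # oracle: Mahalanobis containment computed directly from each tone's
        # 3-point covariance, enumerated over all 12 points
        hrm = hit_rate_matrix(toy12_tokens, "2D", FAST)
        pts = landmark_matrix(toy12_tokens, "2D")
        expected = np.full((4, 4), np.nan)
        for j, tone_j in enumerate(TONES):
            cloud = pts[tone_j]
            mu = cloud.mean(axis=0)
            cov = np.cov(cloud, rowvar=False, ddof=1) + 1e-6 * np.eye(2)
            inv = np.linalg.inv(cov)
            counts = np.zeros(4)
            for i, tone_i in enumerate(TONES):
                for p in pts[tone_i]:
                    d = p - mu
                    if d @ inv @ d <= 4.0:  # Mahalanobis radius 2
                        counts[i] += 1
            if counts.sum():
                expected[:, j] = counts / counts.sum()
        np.testing.assert_allclose(hrm.cells, expected, atol=1e-9)

    def test_shared_points_count_in_every_containing_column(self):
        # all tones identical: every region contains everything, so each
        # column is the marginal target distribution (uniform here)
        from tonespace.contour_features import LandmarkTriple, ToneToken

        rng = np.random.default_rng(3)
        pts = rng.normal(size=(9, 3))
        toks = [
            ToneToken(
                subject_id="S", group="NH", word_id=f"w{t}{k}", target_tone=t,
                landmarks_st=LandmarkTriple(*map(float, p), unit="semitone"),
            )
            for t in TONES
            for k, p in enumerate(pts)
        ]
        hrm = hit_rate_matrix(toks, "2D", FAST)
        np.testing.assert_allclose(hrm.cells, 0.25, atol=1e-12)


class TestCohortScores:
    def test_summary_shape(self):
        rng = np.random.default_rng(0)
        centers = {1: [0, 0, 0], 2: [6, 0, 0], 3: [0, 6, 0], 4: [6, 6, 0]}
        subjects = {
            sid: make_cluster_tokens(centers, 5, 1.0, rng, subject_id=sid)
            for sid in ("A", "B")
        }
        scores = cohort_scores(subjects, params=FAST, seed=0)
        assert len(scores["summary"]) == 2 * 2 * 2  # subjects x methods x measures
        assert len(scores["contrasts"]) == 2 * 2 * 6
        assert len(scores["cells"]) == 2 * 2 * 16

    def test_identical_subjects_zero_group_sd(self):
        rng = np.random.default_rng(1)
        centers = {1: [0, 0, 0], 2: [6, 0, 0], 3: [0, 6, 0], 4: [6, 6, 0]}
        toks = make_cluster_tokens(centers, 5, 1.0, rng, subject_id="A")
        clones = {}
        for sid in ("A", "B", "C"):
            clones[sid] = [
                type(t)(
                    subject_id=sid, group=t.group, word_id=t.word_id,
                    target_tone=t.target_tone, landmarks_st=t.landmarks_st,
                )
                for t in toks
            ]
        scores = cohort_scores(clones, methods=("2D",), params=FAST, seed=0)
        hit = scores["summary"].query("measure == 'hit_rate'")["value"]
        assert hit.std() == pytest.approx(0.0, abs=1e-12)
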