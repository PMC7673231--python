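import csv
from pathlib import Path

import numpy as np
import pytest

from tonespace.contour_features import LandmarkTriple, ToneToken

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy12_tokens():
    """Twelve grid-placed tokens (3 per tone) for containment enumeration."""
    tokens = []
    with open(DATA_DIR / "toy12_landmarks.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            tokens.append(
                ToneToken(
                    subject_id=row["subject_id"],
                    group=row["group"],
                    word_id=row["word_id"],
                    target_tone=int(row["target_tone"]),
                    landmarks_st=LandmarkTriple(
                        float(row["onset_st"]),
                        float(row["mid_st"]),
                        float(row["offset_st"]),
                        unit="semitone",
                    ),
                )
            )
    return tokens


def make_cluster_tokens(centers, n_per_tone, sd, rng, subject_id="S1", group="NH"):
    """Tokens with 3D landmark clusters at the given per-tone centers."""
    tokens = []
    for tone, center in centers.items():
        pts = rng.normal(np.asarray(center, float), sd, size=(n_per_tone, 3))
        for k, p in enumerate(pts):
            tokens.append(
                ToneToken(
                    subject_id=subject_id,
                    group=group,
                    word_id=f"w{tone}_{k}",
                    target_tone=tone,
                    landmarks_st=LandmarkTriple(*map(float, p), unit="semitone"),
                )
            )
    return tokens
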