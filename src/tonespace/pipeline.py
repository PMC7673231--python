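"""Pipeline plumbing: manifests, feature tables, configuration, orchestration.

Stages: (audio or synthetic landmarks) -> per-token landmark features with
per-subject semitone normalization -> per-subject scores -> group statistics
-> figures.  Each stage reads and writes plain CSV/JSON so any step can be
inspected or re-entered, and a completed stage is skipped when its output is
newer than its input.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_stats, contour_features, tone_metrics
from .cohort_stats import DemographicRecord
from .contour_features import (
    LandmarkTriple,
    PitchParams,
    ToneToken,
    UnanalyzableToken,
)
from .tone_geometry import GeometryParams

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = [
    "subject_id", "group", "chronological_age", "age_at_implantation",
    "duration_of_use", "word_id", "target_tone", "wav_path",
]
FEATURE_COLUMNS = [
    "subject_id", "group", "word_id", "target_tone",
    "onset_hz", "mid_hz", "offset_hz",
    "onset_st", "mid_st", "offset_st", "n_corrected_frames",
]

EXIT_OK, EXIT_VALIDATION, EXIT_RUNTIME = 0, 1, 2


class ManifestError(ValueError):
    """Aggregated manifest validation failures."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


@dataclass
class PipelineConfig:
    pitch: PitchParams = field(default_factory=PitchParams)
    geometry: GeometryParams = field(default_factory=GeometryParams)
    seed: int = 0
    ss_type: int = 2
    posthoc_correction: str = "bonf"
    manifest_path: str = ""
    features_path: str = ""
    out_dir: str = "tonespace_out"

    def to_dict(self) -> dict:
        return {
            "pitch": dataclasses.asdict(self.pitch),
            "geometry": dataclasses.asdict(self.geometry),
            "seed": self.seed,
            "ss_type": self.ss_type,
            "posthoc_correction": self.posthoc_correction,
            "manifest_path": self.manifest_path,
            "features_path": self.features_path,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        pitch = PitchParams(**d.pop("pitch", {}))
        geometry = GeometryParams(**d.pop("geometry", {}))
        return cls(pitch=pitch, geometry=geometry, **d)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# manifest / demographics
# ---------------------------------------------------------------------------


def read_manifest(path) -> tuple[pd.DataFrame, list[DemographicRecord]]:
    """Load and validate a token manifest CSV.

    Validates the header, tone labels, and for CI rows the identity
    chronological age = age at implantation + duration (within 0.1 y).  All
    problems are collected into one :class:`ManifestError`.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "word_id": str})
    problems = [
        f"missing column {c!r}" for c in MANIFEST_COLUMNS if c not in df.columns
    ]
    if problems:
        raise ManifestError(problems)

    for idx, row in df.iterrows():
        tone = row["target_tone"]
        try:
            tone = int(tone)
        except (TypeError, ValueError):
            tone = -1
        if tone not in (1, 2, 3, 4):
            problems.append(f"row {idx}: bad tone label {row['target_tone']!r}")
        if row["group"] not in ("NH", "CI"):
            problems.append(f"row {idx}: bad group {row['group']!r}")

    demographics: list[DemographicRecord] = []
    for sid, sub in df.groupby("subject_id", sort=False):
        row = sub.iloc[0]
        group = row["group"]
        try:
            if group == "CI":
                demographics.append(
                    DemographicRecord(
                        subject_id=str(sid), group="CI",
                        chronological_age=float(row["chronological_age"]),
                        age_at_implantation=float(row["age_at_implantation"]),
                        duration_of_use=float(row["duration_of_use"]),
                    )
                )
            elif group == "NH":
                demographics.append(
                    DemographicRecord(
                        subject_id=str(sid), group="NH",
                        chronological_age=float(row["chronological_age"]),
                    )
                )
        except (ValueError, TypeError) as exc:
            problems.append(f"subject {sid}: {exc}")
    if problems:
        raise ManifestError(problems)
    df["target_tone"] = df["target_tone"].astype(int)
    return df, demographics


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=MANIFEST_COLUMNS)


# ---------------------------------------------------------------------------
# feature stage
# ---------------------------------------------------------------------------


def _token_from_wav(row, pitch: PitchParams) -> tuple[ToneToken, int]:
    from scipy.io import wavfile

    rate, data = wavfile.read(row["wav_path"])
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        logger.warning("%s: stereo input downmixed to mono", row["wav_path"])
        data = data.mean(axis=1)
    contour = contour_features.extract_f0(data, rate, pitch)
    contour = contour_features.correct_octave_errors(contour, pitch)
    lm = contour_features.sample_landmarks(contour)
    tok = ToneToken(
        subject_id=str(row["subject_id"]), group=row["group"],
        word_id=str(row["word_id"]), target_tone=int(row["target_tone"]),
        contour=contour, landmarks_hz=lm,
    )
    return tok, len(contour.corrected_frames)


def compute_features(
    manifest: pd.DataFrame,
    pitch: PitchParams | None = None,
    precomputed: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Token manifest -> landmark feature table with semitone normalization.

    Landmarks come from the WAV files named in the manifest, or from a
    precomputed Hz landmark table (columns onset_hz/mid_hz/offset_hz keyed by
    subject_id+word_id) when audio is bypassed.  Tokens with fewer than three
    voiced frames are excluded and counted; subjects without analyzable
    tone-1 tokens are excluded from normalized output entirely.
    """
    pitch = pitch or PitchParams()
    if precomputed is not None:
        precomputed = precomputed.set_index(["subject_id", "word_id"])

    by_subject: dict[str, list[tuple[ToneToken, int]]] = {}
    n_excluded: dict[str, int] = {}
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        try:
            if precomputed is not None:
                lm_row = precomputed.loc[(sid, str(row["word_id"]))]
                tok = ToneToken(
                    subject_id=sid, group=row["group"],
                    word_id=str(row["word_id"]),
                    target_tone=int(row["target_tone"]),
                    landmarks_hz=LandmarkTriple(
                        float(lm_row["onset_hz"]), float(lm_row["mid_hz"]),
                        float(lm_row["offset_hz"]), unit="hz",
                    ),
                )
                ncorr = 0
            else:
                tok, ncorr = _token_from_wav(row, pitch)
        except UnanalyzableToken as exc:
            logger.warning("excluding %s/%s: %s", sid, row["word_id"], exc)
            n_excluded[sid] = n_excluded.get(sid, 0) + 1
            continue
        by_subject.setdefault(sid, []).append((tok, ncorr))

    rows = []
    for sid, toks in by_subject.items():
        try:
            norm = contour_features.compute_reference([t for t, _ in toks])
        except UnanalyzableToken:
            logger.warning("subject %s: no tone-1 tokens; excluded", sid)
            continue
        for tok, ncorr in toks:
            st = contour_features.semitone_normalize(tok.landmarks_hz, norm)
            rows.append(
                dict(
                    subject_id=sid, group=tok.group, word_id=tok.word_id,
                    target_tone=tok.target_tone,
                    onset_hz=tok.landmarks_hz.onset,
                    mid_hz=tok.landmarks_hz.mid,
                    offset_hz=tok.landmarks_hz.offset,
                    onset_st=st.onset, mid_st=st.mid, offset_st=st.offset,
                    n_corrected_frames=ncorr,
                )
            )
    if n_excluded:
        logger.info("excluded unanalyzable tokens per subject: %s", n_excluded)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def tokens_from_features(features: pd.DataFrame) -> dict[str, list[ToneToken]]:
    """Rehydrate normalized tokens from a feature table for the metric stage."""
    subjects: dict[str, list[ToneToken]] = {}
    for _, row in features.iterrows():
        tok = ToneToken(
            subject_id=str(row["subject_id"]), group=row["group"],
            word_id=str(row["word_id"]), target_tone=int(row["target_tone"]),
            landmarks_hz=LandmarkTriple(
                row["onset_hz"], row["mid_hz"], row["offset_hz"], unit="hz"
            ),
            landmarks_st=LandmarkTriple(
                row["onset_st"], row["mid_st"], row["offset_st"],
                unit="semitone",
            ),
        )
        subjects.setdefault(tok.subject_id, []).append(tok)
    return subjects


# ---------------------------------------------------------------------------
# statistics stage
# ---------------------------------------------------------------------------


def compute_stats(
    scores: dict[str, pd.DataFrame],
    demographics: list[DemographicRecord],
    ss_type: int = 2,
    posthoc_correction: str = "bonf",
) -> dict:
    """Run the full statistical battery on cohort score tables.

    Returns a JSON-serializable report: two-way ANOVAs for both measures,
    repeated-measures ANOVAs over contrasts (differentiability) and tone
    types (hit-rate diagonal), measure/method Pearson correlations, the
    demographic correlation grid and the demographic OLS models for CI
    subjects.
    """
    summary = scores["summary"]
    report: dict = {"anova": {}, "rm_anova": {}, "correlations": {}, "glm": {}}

    for measure in ("differentiability", "hit_rate"):
        sub = summary[summary["measure"] == measure]
        try:
            res = cohort_stats.two_way_anova(sub, ss_type=ss_type)
            report["anova"][measure] = {
                "F": res.F, "p": res.p,
                "df": {k: list(v) for k, v in res.df.items()},
            }
        except ValueError as exc:
            report["anova"][measure] = {"error": str(exc)}

    contrasts = scores["contrasts"]
    for method in sorted(contrasts["method"].unique()):
        sub = contrasts[contrasts["method"] == method].rename(
            columns={"contrast": "condition"}
        )
        try:
            res = cohort_stats.rm_anova_oneway(
                sub, posthoc_correction=posthoc_correction
            )
            name = res.effects[0]
            report["rm_anova"][f"contrasts_{method}"] = {
                "F": res.F[name], "p": res.p[name], "p_gg": res.p_gg[name],
            }
        except ValueError as exc:
            report["rm_anova"][f"contrasts_{method}"] = {"error": str(exc)}

    diag = scores["cells"]
    diag = diag[diag["target_tone"] == diag["region_tone"]].copy()
    diag["condition"] = "tone" + diag["target_tone"].astype(str)
    for method in sorted(diag["method"].unique()):
        sub = diag[diag["method"] == method]
        try:
            res = cohort_stats.rm_anova_oneway(
                sub, posthoc_correction=posthoc_correction
            )
            name = res.effects[0]
            report["rm_anova"][f"tones_{method}"] = {
                "F": res.F[name], "p": res.p[name], "p_gg": res.p_gg[name],
            }
        except ValueError as exc:
            report["rm_anova"][f"tones_{method}"] = {"error": str(exc)}

    wide = summary.pivot_table(
        index=["subject_id", "group"], columns=["measure", "method"],
        values="value",
    )
    wide.columns = [f"{m}_{meth}" for m, meth in wide.columns]
    wide = wide.reset_index()

    pairs = [
        ("differentiability_2D", "hit_rate_2D"),
        ("differentiability_3D", "hit_rate_3D"),
        ("differentiability_2D", "differentiability_3D"),
        ("hit_rate_2D", "hit_rate_3D"),
    ]
    for grp in sorted(wide["group"].unique()):
        gw = wide[wide["group"] == grp]
        for a, b in pairs:
            if a in gw.columns and b in gw.columns:
                try:
                    r, p, p_adj = cohort_stats.pearson(gw[a], gw[b])
                    report["correlations"][f"{grp}:{a}~{b}"] = {
                        "r": r, "p": p, "p_bonferroni": p_adj,
                    }
                except ValueError:
                    pass

    demo_df = pd.DataFrame(
        [
            dict(subject_id=d.subject_id,
                 age_at_implantation=d.age_at_implantation,
                 duration_of_use=d.duration_of_use)
            for d in demographics if d.group == "CI"
        ]
    )
    if len(demo_df):
        ci = wide[wide["group"] == "CI"].merge(demo_df, on="subject_id")
        ci_demo = [d for d in demographics if d.group == "CI"]
        sid_order = {d.subject_id: d for d in ci_demo}
        for col in [c for a, b in pairs[:2] for c in (a, b)]:
            if col not in ci.columns:
                continue
            y = cohort_stats.arcsine_transform(
                np.clip(ci[col].to_numpy(float), 0, 1)
            )
            recs = [sid_order[s] for s in ci["subject_id"]]
            for pred in ("age_at_implantation", "duration_of_use"):
                try:
                    r, p, _ = cohort_stats.pearson(ci[pred], ci[col])
                    report["correlations"][f"CI:{pred}~{col}"] = {"r": r, "p": p}
                except ValueError:
                    pass
            try:
                glm = cohort_stats.glm_fit(y, recs)
                report["glm"][col] = {
                    "beta": glm.coefficients, "t": glm.t, "p": glm.p,
                    "r_squared": glm.r_squared,
                }
            except ValueError as exc:
                report["glm"][col] = {"error": str(exc)}
    return report


def format_stats_report(report: dict) -> str:
    """Human-readable text rendering of the stats JSON."""
    lines = []
    for measure, res in report.get("anova", {}).items():
        lines.append(f"Two-way ANOVA ({measure}):")
        if "error" in res:
            lines.append(f"  error: {res['error']}")
        else:
            for eff in res["F"]:
                lines.append(
                    f"  {eff}: F = {res['F'][eff]:.2f}, p = {res['p'][eff]:.3g}"
                )
    lines.append("Correlations:")
    for key, val in report.get("correlations", {}).items():
        lines.append(f"  {key}: r = {val['r']:.3f}, p = {val['p']:.3g}")
    for resp, res in report.get("glm", {}).items():
        lines.append(f"GLM ({resp}):")
        if "error" in res:
            lines.append(f"  error: {res['error']}")
            continue
        for term, beta in res["beta"].items():
            lines.append(
                f"  {term}: beta = {beta:.4f}, t = {res['t'][term]:.2f},"
                f" p = {res['p'][term]:.3g}"
            )
        lines.append(f"  R^2 = {res['r_squared']:.3f}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _stale(output: Path, *inputs: Path) -> bool:
    if not output.exists():
        return True
    return any(p.exists() and p.stat().st_mtime > output.stat().st_mtime
               for p in inputs)


def run_pipeline(config: PipelineConfig) -> int:
    """Run features -> scores -> stats -> figures, skipping current stages."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    logger.info("resolved config: %s", config.to_dict())

    try:
        manifest_path = Path(config.manifest_path)
        manifest, demographics = read_manifest(manifest_path)
    except ManifestError as exc:
        for p in exc.problems:
            logger.error("manifest: %s", p)
        return EXIT_VALIDATION

    features_path = out / "features.csv"
    try:
        if _stale(features_path, manifest_path):
            precomputed = (
                pd.read_csv(
                    config.features_path,
                    dtype={"subject_id": str, "word_id": str},
                )
                if config.features_path else None
            )
            features = compute_features(manifest, config.pitch, precomputed)
            features.to_csv(features_path, index=False)
        else:
            logger.info("features current; skipping")
            features = pd.read_csv(
                features_path, dtype={"subject_id": str, "word_id": str}
            )

        scores_path = out / "scores.csv"
        if _stale(scores_path, features_path):
            subjects = tokens_from_features(features)
            scores = tone_metrics.cohort_scores(
                subjects, params=config.geometry, seed=config.seed
            )
            scores["summary"].to_csv(scores_path, index=False)
            scores["contrasts"].to_csv(out / "scores_contrasts.csv", index=False)
            scores["cells"].to_csv(out / "scores_cells.csv", index=False)
        else:
            logger.info("scores current; skipping")
            scores = {
                "summary": pd.read_csv(scores_path),
                "contrasts": pd.read_csv(out / "scores_contrasts.csv"),
                "cells": pd.read_csv(out / "scores_cells.csv"),
            }

        stats_path = out / "stats.json"
        if _stale(stats_path, scores_path):
            report = compute_stats(
                scores, demographics,
                ss_type=config.ss_type,
                posthoc_correction=config.posthoc_correction,
            )
            stats_path.write_text(json.dumps(report, indent=2))
            (out / "stats.txt").write_text(format_stats_report(report))
        else:
            logger.info("stats current; skipping")

        from . import figures

        figures.render_figures(
            scores, tokens_from_features(features), out / "figures",
            params=config.geometry,
        )
    except Exception:  # noqa: BLE001 - stage failures must not lose outputs
        logger.exception("pipeline stage failed; partial outputs kept in %s", out)
        return EXIT_RUNTIME
    return EXIT_OK
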