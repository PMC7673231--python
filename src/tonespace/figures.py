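"""Figure rendering: tone ellipses, contrast bars, confusion heatmaps, fits."""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .tone_geometry import GeometryParams
from .tone_metrics import CONTRASTS, TONES, contrast_key, fit_tone_regions, landmark_matrix

logger = logging.getLogger(__name__)

TONE_COLORS = {1: "tab:blue", 2: "tab:orange", 3: "tab:green", 4: "tab:red"}


def _ellipse_path(region, n: int = 200) -> np.ndarray:
    theta = np.linspace(0, 2 * np.pi, n)
    circ = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    return circ * region.semiaxes @ region.axes + region.center


def plot_subject_ellipses(tokens, ax=None, params: GeometryParams | None = None):
    """Onset-offset scatter with 2-SD tone ellipses for one subject."""
    params = params or GeometryParams()
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    pts = landmark_matrix(tokens, "2D")
    regions = fit_tone_regions(tokens, "2D", params)
    for tone in TONES:
        p = pts[tone]
        if len(p):
            ax.scatter(p[:, 0], p[:, 1], s=12, color=TONE_COLORS[tone],
                       label=f"tone {tone}")
        if tone in regions:
            path = _ellipse_path(regions[tone])
            ax.plot(path[:, 0], path[:, 1], color=TONE_COLORS[tone], lw=1.2)
    if not regions:
        ax.annotate("undefined", (0.5, 0.5), xycoords="axes fraction",
                    ha="center")
    ax.set_xlabel("F0 onset (semitones)")
    ax.set_ylabel("F0 offset (semitones)")
    ax.legend(fontsize=7)
    return ax


def plot_contrast_bars(contrasts_df, method: str, ax=None):
    """Mean differentiability per contrast (+ average) with SD bars per group."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    keys = [contrast_key(c) for c in CONTRASTS]
    groups = sorted(contrasts_df["group"].unique())
    width = 0.8 / max(len(groups), 1)
    sub = contrasts_df[contrasts_df["method"] == method]
    for gi, grp in enumerate(groups):
        g = sub[sub["group"] == grp]
        means, sds = [], []
        for key in keys:
            vals = g[g["contrast"] == key]["value"].dropna()
            means.append(vals.mean())
            sds.append(vals.std())
        avg = g.groupby("subject_id")["value"].mean().dropna()
        means.append(avg.mean())
        sds.append(avg.std())
        x = np.arange(len(keys) + 1) + gi * width
        color = "black" if grp == "NH" else "gray"
        ax.bar(x, means, width=width, yerr=sds, capsize=2, color=color,
               label=grp)
    ax.set_xticks(np.arange(len(keys) + 1) + width / 2)
    ax.set_xticklabels(keys + ["avg"])
    ax.set_ylabel(f"differentiability ({method})")
    ax.set_ylim(0, 1.1)
    ax.legend()
    return ax


def plot_confusion(cells_df, method: str, group: str, ax=None):
    """Group-mean 4x4 hit-rate confusion matrix heatmap."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3.5, 3.5))
    sub = cells_df[(cells_df["method"] == method) & (cells_df["group"] == group)]
    mat = np.full((4, 4), np.nan)
    for i, ti in enumerate(TONES):
        for j, tj in enumerate(TONES):
            vals = sub[(sub["target_tone"] == ti) & (sub["region_tone"] == tj)][
                "value"].dropna()
            if len(vals):
                mat[i, j] = vals.mean()
    ax.imshow(mat, vmin=0, vmax=1, cmap="Greys")
    for i in range(4):
        for j in range(4):
            if np.isfinite(mat[i, j]):
                ax.text(j, i, f"{mat[i, j]:.2f}", ha="center", va="center",
                        color="tab:red", fontsize=8)
    ax.set_xticks(range(4), [f"E{t}" for t in TONES])
    ax.set_yticks(range(4), [f"T{t}" for t in TONES])
    ax.set_title(f"{group} {method}", fontsize=9)
    return ax


def plot_measure_correlation(summary_df, xcol, ycol, ax=None):
    """Per-subject scatter of two scores with per-group linear fits."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    wide = summary_df.pivot_table(
        index=["subject_id", "group"], columns=["measure", "method"],
        values="value")
    wide.columns = [f"{m}_{meth}" for m, meth in wide.columns]
    wide = wide.reset_index()
    styles = {"NH": dict(color="tab:blue"),
              "CI": dict(color="tab:red", facecolors="none")}
    for grp, style in styles.items():
        g = wide[wide["group"] == grp].dropna(subset=[xcol, ycol])
        if len(g) < 2:
            continue
        ax.scatter(g[xcol], g[ycol], s=15, edgecolors=style["color"],
                   facecolors=style.get("facecolors", style["color"]),
                   label=grp)
        b, a = np.polyfit(g[xcol], g[ycol], 1)
        xs = np.linspace(g[xcol].min(), g[xcol].max(), 10)
        ax.plot(xs, b * xs + a, color=style["color"], lw=1)
    ax.set_xlabel(xcol)
    ax.set_ylabel(ycol)
    ax.legend(fontsize=7)
    return ax


def render_figures(scores, subjects, out_dir, params: GeometryParams | None = None):
    """Write the standard figure set as PNGs; no-op with a warning if empty."""
    params = params or GeometryParams()
    out = Path(out_dir)
    if not scores or not len(scores.get("summary", [])):
        logger.warning("render_figures: empty scores, nothing to draw")
        return []
    out.mkdir(parents=True, exist_ok=True)
    written = []

    for sid, tokens in subjects.items():
        fig, ax = plt.subplots(figsize=(4, 4))
        plot_subject_ellipses(tokens, ax=ax, params=params)
        ax.set_title(sid, fontsize=9)
        path = out / f"ellipses_{sid}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)

    for method in ("2D", "3D"):
        fig, ax = plt.subplots(figsize=(6, 3.5))
        plot_contrast_bars(scores["contrasts"], method, ax=ax)
        path = out / f"contrast_bars_{method}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
        for grp in sorted(scores["cells"]["group"].unique()):
            fig, ax = plt.subplots(figsize=(3.5, 3.5))
            plot_confusion(scores["cells"], method, grp, ax=ax)
            path = out / f"confusion_{grp}_{method}.png"
            fig.tight_layout()
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written.append(path)

    for xcol, ycol in [
        ("differentiability_2D", "hit_rate_2D"),
        ("differentiability_3D", "hit_rate_3D"),
        ("differentiability_2D", "differentiability_3D"),
        ("hit_rate_2D", "hit_rate_3D"),
    ]:
        fig, ax = plt.subplots(figsize=(4, 4))
        plot_measure_correlation(scores["summary"], xcol, ycol, ax=ax)
        path = out / f"correlation_{xcol}__{ycol}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
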