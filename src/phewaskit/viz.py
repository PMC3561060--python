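"""Sun plots and track plots for multi-study PheWAS results.

*Sun plots* show everything one SNP does: one ray per association, ray length
−log10(p), rays sorted by significance and laid out clockwise starting at
twelve o'clock with the smallest p-value.  Rays at p < 0.01 are drawn in the
significant color (red), those at p < 0.05 in the suggestive color (grey).
Labels carry the study phenotype ("LN1 …" marks the log(1+y)-transformed
row), study, stratum and effect direction.

*Track plots* show a set of flagged (SNP, phenotype, stratum) rows across
sites as aligned tracks: chromosome location, per-site presence boxes,
−log10(p) with a direction glyph (triangle up = positive beta, down =
negative), beta, coded-allele frequency and sample size.

Spec construction (`build_sun_plot`, `build_track_plot`) is pure; rendering
(`render`) is a separate matplotlib step so specs are unit-testable without a
canvas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .core import ClassGroup, SnpRecord

__all__ = [
    "SunPlotSpec",
    "SunRay",
    "TrackPlotSpec",
    "build_sun_plot",
    "build_track_plot",
    "render",
]

#: −log10 p ceiling applied to ray radii for legibility (configurable).
DEFAULT_RADIUS_CLIP = 30.0

SIGNIFICANT_COLOR = "#cc0000"   # p < significance threshold
SUGGESTIVE_COLOR = "#8a8a8a"    # p < suggestive threshold


@dataclass(frozen=True)
class SunRay:
    label: str
    radius: float               # -log10 p (clipped)
    tier: str                   # "significant" | "suggestive"


@dataclass(frozen=True)
class SunPlotSpec:
    """Rays sorted by descending radius; first ray at top, then clockwise."""

    snp_id: str
    rays: tuple[SunRay, ...]
    significant_threshold: float = 0.01
    suggestive_threshold: float = 0.05

    def __post_init__(self):
        radii = [r.radius for r in self.rays]
        if any(a < b for a, b in zip(radii, radii[1:])):
            raise ValueError("rays must be sorted by descending radius")


@dataclass(frozen=True)
class TrackPlotSpec:
    """Aligned row set for a multi-SNP track display.

    ``rows`` is one record per (snp, phenotype, stratum) ordered by
    chromosome/position then class; ``sites`` fixes the site order of the
    presence track.  All tracks index the same rows.
    """

    rows: pd.DataFrame          # snp_id, chrom, pos, class_id, phenotype...,
    sites: tuple[str, ...]      # presence/presence-ordering
    presence: np.ndarray        # rows x sites boolean
    p_clip: float = DEFAULT_RADIUS_CLIP
    reference_p: float = 0.01


def _direction_symbol(beta: float) -> str:
    return "+" if beta > 0 else ("-" if beta < 0 else "0")


def build_sun_plot(results_for_snp: pd.DataFrame,
                   significant_threshold: float = 0.01,
                   suggestive_threshold: float = 0.05,
                   radius_clip: float = DEFAULT_RADIUS_CLIP) -> SunPlotSpec:
    """Build the radial spec for one SNP's associations.

    Includes every result below the suggestive threshold; tier is
    ``significant`` iff p is below the significant threshold.  Raises when no
    result qualifies (an empty sun plot is always a caller error).
    """
    snps = results_for_snp["snp_id"].unique()
    if len(snps) != 1:
        raise ValueError(f"expected results for exactly one SNP, got "
                         f"{sorted(snps)}")
    qualifying = results_for_snp[
        results_for_snp["p"] < suggestive_threshold].copy()
    if qualifying.empty:
        raise ValueError(
            f"no association below the suggestive threshold "
            f"{suggestive_threshold} for {snps[0]}; nothing to plot")
    qualifying = qualifying.sort_values(
        ["p", "study_id", "phenotype_name"]).reset_index(drop=True)
    rays = []
    for row in qualifying.itertuples(index=False):
        tier = ("significant" if row.p < significant_threshold
                else "suggestive")
        label = (f"{row.phenotype_name}, {row.study_id}, {row.stratum}, "
                 f"{_direction_symbol(row.beta)}")
        radius = min(-np.log10(row.p) if row.p > 0 else radius_clip,
                     radius_clip)
        rays.append(SunRay(label=label, radius=radius, tier=tier))
    return SunPlotSpec(snp_id=str(snps[0]), rays=tuple(rays),
                       significant_threshold=significant_threshold,
                       suggestive_threshold=suggestive_threshold)


def build_track_plot(groups: Sequence[ClassGroup],
                     master_registry: Mapping[str, SnpRecord],
                     sites: Sequence[str] | None = None,
                     p_clip: float = DEFAULT_RADIUS_CLIP,
                     reference_p: float = 0.01) -> TrackPlotSpec:
    """Build the aligned track spec for a set of groups.

    One row per member result of each group, ordered by chromosome and
    position then class; SNPs without a registry position are dropped with a
    warning.  Presence boxes mark which sites contributed any result for the
    row's SNP/class/stratum.
    """
    import warnings as _warnings

    if not groups:
        raise ValueError("no groups to plot")
    rows = []
    for g in groups:
        rec = master_registry.get(g.snp_id)
        if rec is None:
            _warnings.warn(f"SNP {g.snp_id} has no registry position; "
                           f"dropping its rows", RuntimeWarning, stacklevel=2)
            continue
        group_sites = sorted({r.study_id for r in g.results})
        for r in g.results:
            rows.append({
                "snp_id": g.snp_id,
                "chrom": rec.chrom, "pos": rec.pos,
                "class_id": g.class_id, "stratum": g.stratum,
                "phenotype_name": r.phenotype_name,
                "transform": r.transform,
                "study_id": r.study_id,
                "neglog10p": min(-np.log10(r.p) if r.p > 0 else p_clip,
                                 p_clip),
                "direction": _direction_symbol(r.beta),
                "beta": r.beta, "caf": r.caf, "n": r.n,
                "group_sites": tuple(group_sites),
            })
    if not rows:
        raise ValueError("no plottable rows (all SNPs lacked positions)")
    frame = pd.DataFrame(rows)

    def chrom_key(c):
        try:
            return (0, int(c))
        except ValueError:
            return (1, str(c))

    frame["_ck"] = [chrom_key(c) for c in frame["chrom"]]
    frame = frame.sort_values(["_ck", "pos", "class_id", "stratum",
                               "phenotype_name", "study_id"]
                              ).drop(columns="_ck").reset_index(drop=True)
    if sites is None:
        sites = sorted(frame["study_id"].unique())
    presence = np.zeros((len(frame), len(sites)), dtype=bool)
    for i, gs in enumerate(frame["group_sites"]):
        for j, s in enumerate(sites):
            presence[i, j] = s in gs
    return TrackPlotSpec(rows=frame.drop(columns="group_sites"),
                         sites=tuple(sites), presence=presence,
                         p_clip=p_clip, reference_p=reference_p)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _render_sun(spec: SunPlotSpec, fig):
    ax = fig.add_subplot(111, projection="polar")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)      # clockwise
    n = len(spec.rays)
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    for angle, ray in zip(angles, spec.rays):
        color = (SIGNIFICANT_COLOR if ray.tier == "significant"
                 else SUGGESTIVE_COLOR)
        ax.plot([angle, angle], [0, ray.radius], color=color, lw=1.2)
        ax.text(angle, ray.radius * 1.02, ray.label, fontsize=4,
                ha="left" if 0 <= angle < np.pi else "right",
                va="center", rotation_mode="anchor")
    ax.set_rlim(0, max(r.radius for r in spec.rays) * 1.35)
    ax.set_xticks([])
    ax.tick_params(axis="y", labelsize=5)
    ax.set_title(f"{spec.snp_id}: -log10(p) by association", fontsize=9)


_SITE_COLORS = ["#2166ac", "#b2182b", "#ef8a62", "#762a83", "#1b7837",
                "#e08214"]


def _render_tracks(spec: TrackPlotSpec, fig):
    rows = spec.rows
    x = np.arange(len(rows))
    axes = fig.subplots(5, 1, sharex=True,
                        height_ratios=[1.2, 1, 1, 1, 1])
    ax_presence, ax_p, ax_beta, ax_caf, ax_n = axes

    for j, site in enumerate(spec.sites):
        color = _SITE_COLORS[j % len(_SITE_COLORS)]
        ys = np.where(spec.presence[:, j])[0]
        ax_presence.scatter(ys, np.full(len(ys), j), marker="s", s=18,
                            color=color, label=site)
    ax_presence.set_yticks(range(len(spec.sites)), spec.sites, fontsize=5)
    ax_presence.set_ylabel("site", fontsize=6)

    up = rows["direction"] == "+"
    ax_p.scatter(x[up], rows.loc[up.values, "neglog10p"], marker="^", s=14,
                 color="k")
    ax_p.scatter(x[~up], rows.loc[(~up).values, "neglog10p"], marker="v",
                 s=14, color="k")
    ax_p.axhline(-np.log10(spec.reference_p), color=SIGNIFICANT_COLOR, lw=1)
    ax_p.set_ylabel("-log10 p", fontsize=6)

    ax_beta.scatter(x, rows["beta"], s=10, color="k")
    ax_beta.axhline(0, color="grey", ls=":", lw=1)
    ax_beta.set_ylabel("beta", fontsize=6)

    ax_caf.scatter(x, rows["caf"], s=10, color="k")
    ax_caf.set_ylim(0, 1)
    ax_caf.set_ylabel("CAF", fontsize=6)

    ax_n.scatter(x, rows["n"], s=10, color="k")
    ax_n.set_ylabel("n", fontsize=6)

    labels = [f"{r.snp_id} {r.phenotype_name[:28]} {r.stratum}"
              for r in rows.itertuples(index=False)]
    ax_n.set_xticks(x, labels, rotation=90, fontsize=4)
    fig.suptitle("Cross-site association tracks", fontsize=9)


def render(spec: SunPlotSpec | TrackPlotSpec, path: str | Path,
           format: str | None = None) -> Path:
    """Render a spec to SVG or PNG deterministically.

    The format comes from ``format`` or the path suffix; anything other than
    svg/png is an error.  SVG output is byte-stable across runs on one
    platform (fixed hash salt, no embedded date).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("svg", "png"):
        raise ValueError(f"unknown format {fmt!r} (svg or png)")
    if not path.parent.exists():
        raise FileNotFoundError(f"output directory {path.parent} does not "
                                f"exist")
    with plt.rc_context({"svg.hashsalt": "phewaskit",
                         "figure.max_open_warning": 0}):
        if isinstance(spec, SunPlotSpec):
            fig = plt.figure(figsize=(7, 7))
            _render_sun(spec, fig)
        elif isinstance(spec, TrackPlotSpec):
            fig = plt.figure(figsize=(9, 7))
            _render_tracks(spec, fig)
        else:
            raise TypeError(f"cannot render {type(spec).__name__}")
        try:
            fig.savefig(path, format=fmt, metadata=(
                {"Date": None} if fmt == "svg" else None))
        finally:
            plt.close(fig)
    return path
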