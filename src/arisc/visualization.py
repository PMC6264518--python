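"""Pair-matrix risk heatmaps and per-reference homology profile plots.

Heatmap cells are colored by A-RISC value on a red (high risk) to dark
green (low risk) scale anchored at the four category boundaries. Profile
plots compare every family member to one reference sequence, with dashed
guide lines at 75%/50%/25% (identity, similarity) or 0.75/0.50/0.25
(A-RISC).

Both renderers expose data-export hooks (:func:`heatmap_data`,
:func:`profile_data`) returning exactly the numeric grid/series plotted, so
tests and the ``--export-data`` CLI flag work on data rather than pixels.
Rendering is deterministic given matrix and options.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "arisc"  # reproducible SVG ids

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
from matplotlib import colors as mcolors  # noqa: E402
from matplotlib.colors import LinearSegmentedColormap  # noqa: E402
from matplotlib.patches import Patch  # noqa: E402

from .arisc_core import FamilyMatrix  # noqa: E402

__all__ = [
    "HeatmapOptions",
    "ProfileOptions",
    "heatmap_data",
    "profile_data",
    "risk_colormap",
    "render_pair_heatmap",
    "render_reference_profile",
]

#: default color anchors: category boundaries, red (high) to dark green (low)
DEFAULT_ANCHORS: tuple[tuple[float, str], ...] = (
    (1.00, "#d73027"),  # red
    (0.75, "#fc8d59"),  # orange
    (0.50, "#fee08b"),  # yellow
    (0.25, "#a6d96a"),  # yellow-green
    (0.00, "#1a6f38"),  # dark green
)


@dataclass(frozen=True)
class HeatmapOptions:
    color_anchors: tuple[tuple[float, str], ...] = DEFAULT_ANCHORS
    layout: Literal["full", "lower-triangle"] = "lower-triangle"
    label_rotation: float = 90.0
    output_format: Literal["png", "svg", "pdf"] = "png"

    def __post_init__(self) -> None:
        values = [v for v, _ in self.color_anchors]
        if any(b >= a for a, b in zip(values, values[1:])):
            raise ValueError("color anchor values must be strictly "
                             "descending")
        for _, c in self.color_anchors:
            mcolors.to_rgb(c)  # raises on invalid color


@dataclass(frozen=True)
class ProfileOptions:
    panels: tuple[str, ...] = ("identity", "similarity", "arisc")
    thresholds: tuple[float, float, float] = (0.75, 0.50, 0.25)
    sort: Literal["descending", "input-order"] = "descending"
    highlight_groups: Mapping[str, str] | None = None
    output_format: Literal["png", "svg", "pdf"] = "png"

    def __post_init__(self) -> None:
        for p in self.panels:
            if p not in ("identity", "similarity", "arisc"):
                raise ValueError(f"unknown profile panel: {p!r}")


def risk_colormap(anchors: Sequence[tuple[float, str]] = DEFAULT_ANCHORS,
                  ) -> LinearSegmentedColormap:
    """Linear colormap over [0, 1] interpolating between the anchors."""
    stops = sorted(anchors)  # ascending for matplotlib
    return LinearSegmentedColormap.from_list(
        "arisc_risk", [(v, c) for v, c in stops]
    )


def heatmap_data(matrix: FamilyMatrix) -> tuple[list[str], np.ndarray]:
    """The (ids, A-RISC grid) a heatmap renders; diagonal is 1.0."""
    ids = list(matrix.ids)
    n = len(ids)
    grid = np.ones((n, n))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i != j:
                grid[i, j] = matrix.get(a, b).arisc
    return ids, grid


def _sorted_members(values: dict[str, float], sort: str,
                    input_order: Sequence[str]) -> list[str]:
    if sort == "input-order":
        return [m for m in input_order if m in values]
    return sorted(values, key=lambda m: (-values[m], m))


def profile_data(matrix: FamilyMatrix, reference_id: str,
                 options: ProfileOptions | None = None,
                 ) -> dict[str, tuple[list[str], list[float]]]:
    """Per-panel (member ids, values) series a profile plot renders.

    Identity and similarity are on the percent scale, A-RISC on [0, 1].
    Members are sorted descending by value (ties alphabetical) unless
    input order is requested; the reference itself is excluded.
    """
    if options is None:
        options = ProfileOptions()
    if reference_id not in matrix.ids:
        raise KeyError(f"reference id not found in matrix: {reference_id!r}")
    others = [m for m in matrix.ids if m != reference_id]
    out: dict[str, tuple[list[str], list[float]]] = {}
    for panel in options.panels:
        values = {}
        for m in others:
            score = matrix.get(reference_id, m)
            raw = {"identity": score.I, "similarity": score.S,
                   "arisc": score.arisc}[panel]
            values[m] = 100 * raw if panel != "arisc" else raw
        order = _sorted_members(values, options.sort, others)
        out[panel] = (order, [values[m] for m in order])
    return out


def render_pair_heatmap(matrix: FamilyMatrix, path: str | Path,
                        options: HeatmapOptions | None = None) -> Path:
    """Render the triangular (or full) A-RISC pair-matrix heatmap.

    Red cells flag a high risk of cross-reactivity between the pair, dark
    green a low risk; a legend maps the four risk categories. Diagonal
    self-comparison cells are hatched to de-emphasize them.
    """
    if options is None:
        options = HeatmapOptions()
    ids, grid = heatmap_data(matrix)
    n = len(ids)
    cmap = risk_colormap(options.color_anchors)
    norm = mcolors.Normalize(vmin=0.0, vmax=1.0)

    data = grid.copy()
    if options.layout == "lower-triangle":
        mask = np.triu(np.ones((n, n), dtype=bool), k=1)
        data = np.ma.array(data, mask=mask)

    fig_size = max(4.0, 0.4 * n + 2.0)
    fig, ax = plt.subplots(figsize=(fig_size * 1.25, fig_size))
    ax.imshow(data, cmap=cmap, norm=norm, interpolation="nearest")
    for i in range(n):  # hatch the self-comparison diagonal
        ax.add_patch(plt.Rectangle((i - 0.5, i - 0.5), 1, 1, fill=False,
                                   hatch="///", edgecolor="white",
                                   linewidth=0))
    ax.set_xticks(range(n))
    ax.set_xticklabels(ids, rotation=options.label_rotation, fontsize=8)
    ax.set_yticks(range(n))
    ax.set_yticklabels(ids, fontsize=8)
    boundaries = [
        ("high (≥ 0.75)", 0.875),
        ("medium-high (0.50–0.75)", 0.625),
        ("medium-low (0.25–0.50)", 0.375),
        ("low (< 0.25)", 0.125),
    ]
    handles = [Patch(facecolor=cmap(norm(v)), label=lab)
               for lab, v in boundaries]
    ax.legend(handles=handles, title="cross-reactivity risk",
              loc="upper left", bbox_to_anchor=(1.02, 1.0), fontsize=8)
    ax.set_title("A-RISC index per sequence pair")
    fig.tight_layout()
    path = Path(path)
    _save(fig, path, options.output_format)
    plt.close(fig)
    return path


def _save(fig, path: Path, fmt: str) -> None:
    kwargs = {}
    if fmt == "svg":
        kwargs["metadata"] = {"Date": None}  # no timestamp: byte-stable
    fig.savefig(path, format=fmt, dpi=150, **kwargs)


def render_reference_profile(matrix: FamilyMatrix, reference_id: str,
                             path: str | Path,
                             options: ProfileOptions | None = None) -> Path:
    """Render per-member identity/similarity/A-RISC against one reference.

    One panel per requested quantity; dashed guide lines mark the 75%/50%/
    25% (or 0.75/0.50/0.25) thresholds in red, gray and dark green. Member
    bars can be colored by group (e.g. plant- vs animal-origin allergens)
    via ``options.highlight_groups``.
    """
    if options is None:
        options = ProfileOptions()
    series = profile_data(matrix, reference_id, options)
    npanels = len(options.panels)
    nmembers = matrix.n - 1
    fig, axes = plt.subplots(
        npanels, 1, squeeze=False,
        figsize=(max(4.0, 0.35 * nmembers + 2.0), 2.8 * npanels),
    )
    guide_colors = ("#d73027", "#888888", "#1a6f38")
    for ax, panel in zip(axes[:, 0], options.panels):
        members, values = series[panel]
        scale = 1.0 if panel == "arisc" else 100.0
        colors = ["#4477aa"] * len(members)
        if options.highlight_groups:
            colors = [options.highlight_groups.get(m, "#4477aa")
                      for m in members]
        ax.bar(range(len(members)), values, color=colors)
        for thr, gc in zip(options.thresholds, guide_colors):
            ax.axhline(thr * scale, linestyle="--", color=gc, linewidth=1)
        ax.set_xticks(range(len(members)))
        ax.set_xticklabels(members, rotation=90, fontsize=8)
        ax.set_ylim(0, 1.0 * scale)
        label = {"identity": "sequence identity (%)",
                 "similarity": "sequence similarity (%)",
                 "arisc": "A-RISC index"}[panel]
        ax.set_ylabel(label, fontsize=9)
    axes[0, 0].set_title(f"Homology to {reference_id}")
    fig.tight_layout()
    path = Path(path)
    _save(fig, path, options.output_format)
    plt.close(fig)
    return path
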