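"""Isobologram-ray plots and polygonograms.

For a fixed-ratio (1:1:1) three-drug mixture the faithful two-dimensional
reduction of the isobologram is the fixed-ratio ray itself: the additive
point A (ED50_add +/- SEM) and the experimental point M (ED50_exp +/- SEM)
plotted on the total-mixture-dose axis, with significance stars when the
two differ.  The polygonogram summarises many combinations at once: drugs
as vertices of a regular polygon, each classified triple drawn as a
translucent triangle coloured by interaction type and labelled with its
interaction index.

All rendering is deterministic: identical inputs yield byte-identical SVG.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib as mpl
import numpy as np
from matplotlib.figure import Figure
from matplotlib.lines import Line2D
from matplotlib.patches import Polygon

from .data import ValidationError
from .interaction import ADDITIVITY, ANTAGONISM, SYNERGY, InteractionResult

__all__ = ["PolygonogramSpec", "render_isobologram", "render_polygonogram",
           "CLASSIFICATION_COLORS"]

# colourblind-safe (Okabe-Ito) hues per interaction type
CLASSIFICATION_COLORS = {
    SYNERGY: "#0072B2",
    ADDITIVITY: "#999999",
    ANTAGONISM: "#D55E00",
}

_DETERMINISTIC_RC = {
    "svg.hashsalt": "isoquantal",
    "svg.fonttype": "none",
    "font.family": "DejaVu Sans",
}


def _significance_stars(p: float, alpha: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < alpha:
        return "*"
    return ""


def _save(fig: Figure, path, formats: Sequence[str]) -> dict[str, Path]:
    stem = Path(path)
    out = {}
    with mpl.rc_context(_DETERMINISTIC_RC):
        for fmt in formats:
            target = stem.with_suffix(f".{fmt}")
            fig.savefig(target, format=fmt, metadata=(
                {"Date": None} if fmt == "svg" else None), dpi=150)
            out[fmt] = target
    return out


def render_isobologram(result: InteractionResult, path,
                       formats: Sequence[str] = ("svg", "png")) -> dict[str, Path]:
    """Fixed-ratio-ray plot: additive point A vs experimental point M.

    Both points carry SEM error bars on the total mixture dose axis
    (mg/kg); significance stars annotate M when the comparison rejects
    additivity.  Writes ``<path>.svg`` and ``<path>.png`` by default.
    """
    fig = Figure(figsize=(4.0, 4.4))
    ax = fig.add_subplot(111)
    ax.errorbar([0], [result.ed50_add], yerr=[result.sem_add], fmt="o",
                color="#000000", mfc="white", capsize=5, ms=9, label="A (additive)")
    color = CLASSIFICATION_COLORS[result.classification]
    ax.errorbar([1], [result.ed50_exp], yerr=[result.sem_exp], fmt="s",
                color=color, capsize=5, ms=9, label="M (experimental)")
    stars = _significance_stars(result.p, result.alpha)
    if stars:
        ax.annotate(stars, (1, result.ed50_exp + result.sem_exp),
                    textcoords="offset points", xytext=(0, 8),
                    ha="center", fontsize=14)
    ax.set_xlim(-0.6, 1.6)
    ax.set_xticks([0, 1])
    ax.set_xticklabels(["A\n(additive)", "M\n(experimental)"])
    ax.set_ylabel("total mixture dose (mg/kg)")
    top = max(result.ed50_add + result.sem_add,
              result.ed50_exp + result.sem_exp)
    ax.set_ylim(0, 1.25 * top)
    ax.set_title(f"{result.combination_label}\n{result.classification}, "
                 f"index = {result.interaction_index:.2f}", fontsize=10)
    fig.tight_layout()
    return _save(fig, path, formats)


@dataclass(frozen=True)
class PolygonogramSpec:
    """Drugs as nodes plus classified triples/pairs as coloured hyperedges."""

    nodes: tuple[str, ...]
    hyperedges: tuple[tuple[tuple[str, ...], str, float], ...]
    colors: dict = field(default_factory=lambda: dict(CLASSIFICATION_COLORS))

    def __post_init__(self) -> None:
        if len(self.nodes) != len(set(self.nodes)):
            raise ValidationError("duplicate node labels")
        seen = set()
        for members, classification, _ in self.hyperedges:
            for m in members:
                if m not in self.nodes:
                    raise ValidationError(
                        f"hyperedge references undeclared node {m!r}")
            if classification not in self.colors:
                raise ValidationError(
                    f"unknown classification {classification!r}")
            key = frozenset(members)
            if key in seen:
                raise ValidationError(f"duplicate hyperedge {sorted(key)}")
            seen.add(key)

    @classmethod
    def from_results(cls, results: Sequence[InteractionResult],
                     extra: Sequence[tuple[str, str, float]] = (),
                     separator: str = " + ") -> "PolygonogramSpec":
        """Build a spec from interaction results (labels split on ``+``),
        optionally merged with (label, classification, index) literature
        triples."""
        edges = []
        names: set[str] = set()
        for r in results:
            members = tuple(s.strip() for s in
                            r.combination_label.split(separator))
            names.update(members)
            edges.append((members, r.classification, r.interaction_index))
        for label, classification, index in extra:
            members = tuple(s.strip() for s in label.split(separator))
            names.update(members)
            edges.append((members, classification, float(index)))
        return cls(tuple(sorted(names)), tuple(edges))


def _node_positions(nodes: Sequence[str]) -> dict[str, np.ndarray]:
    # alphabetical order around a regular polygon, first node at the top
    ordered = sorted(nodes)
    k = len(ordered)
    angles = np.pi / 2 - 2 * np.pi * np.arange(k) / k
    return {n: np.array([np.cos(a), np.sin(a)])
            for n, a in zip(ordered, angles)}


def render_polygonogram(spec: PolygonogramSpec, path,
                        formats: Sequence[str] = ("svg", "png")) -> dict[str, Path]:
    """Regular-polygon interaction overview.

    Triples are translucent triangles, pairs are straight edges, both
    coloured by classification and labelled with the interaction index at
    the centroid/midpoint.  Layout and draw order are canonical (sorted),
    so any input ordering of the hyperedges renders identically.
    """
    if len(spec.nodes) < 3:
        raise ValidationError("a polygonogram needs at least 3 nodes")
    pos = _node_positions(spec.nodes)
    fig = Figure(figsize=(6.0, 6.0))
    ax = fig.add_subplot(111)
    edges = sorted(spec.hyperedges, key=lambda e: tuple(sorted(e[0])))
    for members, classification, index in edges:
        pts = np.array([pos[m] for m in sorted(members)])
        color = spec.colors[classification]
        center = pts.mean(axis=0)
        if len(members) >= 3:
            ax.add_patch(Polygon(pts, closed=True, facecolor=color,
                                 edgecolor=color, alpha=0.30, lw=1.5))
        else:
            ax.plot(pts[:, 0], pts[:, 1], color=color, lw=2.5, alpha=0.7)
        ax.annotate(f"{index:.2f}", center, ha="center", va="center",
                    fontsize=8, color="#222222")
    for name, xy in sorted(pos.items()):
        ax.scatter(*xy, s=420, zorder=3, facecolor="white",
                   edgecolor="#222222")
        ax.annotate(name, xy, ha="center", va="center", fontsize=9, zorder=4)
    handles = [Line2D([], [], color=c, lw=4, label=k)
               for k, c in sorted(spec.colors.items())]
    ax.legend(handles=handles, loc="upper left", bbox_to_anchor=(0.0, -0.02),
              ncol=3, frameon=False, fontsize=8)
    ax.set_xlim(-1.45, 1.45)
    ax.set_ylim(-1.45, 1.45)
    ax.set_aspect("equal")
    ax.axis("off")
    return _save(fig, path, formats)
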