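"""Radial stacked-bar ("stoplight") charts of maturity assessments.

One wedge per scored question (20 wedges), grouped contiguously by domain
in the fixed clockwise order Access -> Consultation -> Technology ->
Evidence starting at 12 o'clock. Each wedge stacks five unit segments,
one per maturity level, filled bottom-up to the attained points and colored
along a red-to-green five-class palette; fractional points fill the top
segment partially. Missing answers render as an empty, hatched wedge.

Rendering is a pure function of (assessments, options, palette): the SVG
backend is pinned to a fixed hash salt and dateless metadata so re-rendering
the same input is byte-identical.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .errors import ActeMtbError
from .rubric import DOMAINS, Rubric, list_scored_questions
from .scoring import MaturityAssessment
from .stats import round_half_up


@dataclass(frozen=True)
class StoplightScale:
    """Ordered five-color palette, red (level 1) to green (level 5)."""

    colors: tuple[str, str, str, str, str]
    name: str = "custom"


#: ColorBrewer 5-class RdYlGn: perceptually ordered red -> yellow -> green.
DEFAULT_SCALE = StoplightScale(
    ("#d7191c", "#fdae61", "#ffffbf", "#a6d96a", "#1a9641"), name="rdylgn"
)

#: ColorBrewer 5-class RdYlBu: colorblind-safe ordered alternative.
COLORBLIND_SAFE_SCALE = StoplightScale(
    ("#d7191c", "#fdae61", "#ffffbf", "#abd9e9", "#2c7bb6"), name="rdylbu"
)

UNFILLED = "#ececec"


def stoplight_color(level: int, scale: StoplightScale = DEFAULT_SCALE) -> str:
    """Palette color of a maturity level (1 = red end, 5 = green end)."""
    if level not in (1, 2, 3, 4, 5):
        raise ActeMtbError(f"level {level!r} outside 1-5")
    return scale.colors[level - 1]


@dataclass(frozen=True)
class WedgeSpec:
    question_id: str
    short_label: str
    domain: str
    points: Optional[float]  # None when unanswered
    segments: tuple[float, float, float, float, float]  # fill fraction per level

    @property
    def missing(self) -> bool:
        return self.points is None

    @property
    def filled_segments(self) -> int:
        """Number of (at least partially) filled unit segments = ceil(points)."""
        return sum(1 for f in self.segments if f > 0)


def _segments(points: Optional[float]) -> tuple[float, ...]:
    if points is None:
        return (0.0,) * 5
    return tuple(float(np.clip(points - k, 0.0, 1.0)) for k in range(5))


def layout_wedges(
    assessment: MaturityAssessment,
    rubric: Rubric,
    domain_order: Sequence[str] = DOMAINS,
) -> list[WedgeSpec]:
    """Deterministic angular layout: 20 wedges, contiguous within domains."""
    wedges: list[WedgeSpec] = []
    for domain in domain_order:
        for qid in list_scored_questions(rubric, domain):
            q = rubric.question(qid)
            pts = assessment.question_points.get(qid)
            wedges.append(
                WedgeSpec(
                    question_id=qid,
                    short_label=q.short_label or qid,
                    domain=domain,
                    points=pts,
                    segments=_segments(pts),
                )
            )
    return wedges


def _draw_panel(ax, assessment, rubric, scale, domain_order):
    wedges = layout_wedges(assessment, rubric, domain_order)
    n = len(wedges)
    width = 2 * math.pi / n
    gap = 0.12 * width
    r0 = 1.2  # inner hole radius, keeps the center free for the overall score

    for i, w in enumerate(wedges):
        # clockwise from 12 o'clock
        theta = math.pi / 2 - (i + 0.5) * width
        for k in range(5):
            fill = w.segments[k]
            ax.bar(theta, 1.0, width=width - gap, bottom=r0 + k,
                   color=UNFILLED, edgecolor="white", linewidth=0.4, zorder=1)
            if fill > 0:
                ax.bar(theta, fill, width=width - gap, bottom=r0 + k,
                       color=scale.colors[k], edgecolor="white",
                       linewidth=0.4, zorder=2)
        if w.missing:
            ax.bar(theta, 5.0, width=width - gap, bottom=r0,
                   color="none", edgecolor="#bbbbbb", hatch="///",
                   linewidth=0.6, zorder=3)
        rot = math.degrees(theta)
        if rot < -90 or rot > 90:
            rot += 180
        ax.text(theta, r0 + 5.55, w.short_label, rotation=rot,
                rotation_mode="anchor", ha="center", va="center", fontsize=5.5)

    # domain arcs
    per_domain = n // len(domain_order)
    for d_idx, domain in enumerate(domain_order):
        mid = d_idx * per_domain + per_domain / 2
        theta = math.pi / 2 - mid * width
        score = assessment.domain_scores[domain].score
        label = f"{domain}\n{round_half_up(score):.1f}" if not math.isnan(score) else domain
        ax.text(theta, r0 + 7.3, label, ha="center", va="center",
                fontsize=7, fontweight="bold")

    ax.text(0.0, 0.0, f"{round_half_up(assessment.overall):.1f}",
            ha="center", va="center", fontsize=13, fontweight="bold")
    ax.set_ylim(0, r0 + 8)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.spines.clear()
    ax.set_title(f"{assessment.respondent_id} — overall "
                 f"{round_half_up(assessment.overall):.1f}", fontsize=9, pad=18)


def render_radial_chart(
    assessments: Sequence[MaturityAssessment] | MaturityAssessment,
    rubric: Rubric,
    *,
    path: Optional[str | Path] = None,
    scale: StoplightScale = DEFAULT_SCALE,
    domain_order: Sequence[str] = DOMAINS,
    fmt: str = "svg",
) -> bytes:
    """Render one assessment, or two side by side, as a deterministic SVG/PNG.

    Returns the document bytes and optionally writes them to ``path``.
    Re-rendering identical input yields byte-identical output.
    """
    if isinstance(assessments, MaturityAssessment):
        assessments = [assessments]
    if not 1 <= len(assessments) <= 2:
        raise ActeMtbError(
            f"render_radial_chart takes 1 or 2 assessments, got {len(assessments)}"
        )
    if fmt not in ("svg", "png"):
        raise ActeMtbError(f"unsupported format {fmt!r}")

    with plt.rc_context({"svg.hashsalt": "acte-mtb", "svg.fonttype": "path"}):
        fig, axes = plt.subplots(
            1, len(assessments),
            figsize=(6.4 * len(assessments), 7.2),
            subplot_kw={"projection": "polar"},
        )
        if len(assessments) == 1:
            axes = [axes]
        for ax, a in zip(axes, assessments):
            _draw_panel(ax, a, rubric, scale, domain_order)
        buf = io.BytesIO()
        fig.savefig(buf, format=fmt, metadata={"Date": None} if fmt == "svg" else None)
        plt.close(fig)
    data = buf.getvalue()
    if path is not None:
        Path(path).write_bytes(data)
    return data
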