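"""Classification of a new candidate onto the Regulatory/Executive/Supply triangle.

A candidate's load-phase slope coefficient (``New``) is placed inside the
one-sigma variation interval ``[L, R]`` of the two study cohorts and mapped
to the interpolation coefficient

    C = −1                       if New ≤ L
    C = +1                       if New ≥ R
    C = 2·(New − L)/(R − L) − 1  otherwise,

so C = −1 corresponds to the average high-ABP response (blood-pressure
dominant) and C = +1 to the average normal-ABP response (heart-rate
dominant).  C sets the stroke widths of the two triangle branches: the left
branch (Regulatory–Executive, the blood-pressure pathway) gets
``round(10 − 9·(C+1)/2)`` pixels and the right branch (Regulatory–Supply,
the heart-rate pathway) ``round(9·(C+1)/2 + 1)`` pixels, each in [1, 10].
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

from .cohort_model import VariationInterval, round_half_away
from .exceptions import ClassifierError, ValidationError

#: fixed triangle vertices: Executive, Regulatory, Supply
VERTICES = {"E": (-1.0, 0.0), "R": (0.0, 1.0), "S": (1.0, 0.0)}

MAX_THICKNESS = 10
MIN_THICKNESS = 1

LEFT_BRANCH_LABEL = "ABP (sys), ABP (sys-dis)"
RIGHT_BRANCH_LABEL = "RR, JT"

__all__ = [
    "VERTICES",
    "ClassificationResult",
    "TriangleLayout",
    "interpolation_coefficient",
    "branch_thickness",
    "classify",
    "triangle_layout",
    "render_triangle",
]


@dataclass(frozen=True)
class ClassificationResult:
    """Placement of one candidate slope in the cohort variation interval."""

    new_slope: float
    c: float
    left_thickness: int
    right_thickness: int
    tendency: str
    outside_interval: bool
    interval: VariationInterval

    def to_dict(self) -> dict:
        d = asdict(self)
        d["c_rounded"] = round_half_away(self.c, 4)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass(frozen=True)
class TriangleLayout:
    """Renderable description of the triangle diagram for one candidate."""

    vertices: dict
    left_width: int
    right_width: int
    left_label: str = LEFT_BRANCH_LABEL
    right_label: str = RIGHT_BRANCH_LABEL


def interpolation_coefficient(new_slope: float, interval: VariationInterval) -> float:
    """Linearly map a candidate slope into [−1, 1] with cut outliers."""
    if not interval.left < interval.right:
        raise ValidationError(
            f"degenerate variation interval [{interval.left}, {interval.right}]"
        )
    if new_slope <= interval.left:
        return -1.0
    if new_slope >= interval.right:
        return 1.0
    return 2.0 * (new_slope - interval.left) / interval.width - 1.0


def branch_thickness(c: float) -> tuple[int, int]:
    """Branch stroke widths in pixels for an interpolation coefficient.

    Before rounding the two widths sum to 11 exactly; rounding is half away
    from zero and results are clamped to [1, 10].
    """
    if not -1.0 <= c <= 1.0:
        raise ValidationError(f"interpolation coefficient must be in [-1, 1], got {c}")
    left = round_half_away(MAX_THICKNESS - 9.0 * (c + 1.0) / 2.0, 0)
    right = round_half_away(9.0 * (c + 1.0) / 2.0 + 1.0, 0)
    clamp = lambda v: int(min(max(v, MIN_THICKNESS), MAX_THICKNESS))  # noqa: E731
    return clamp(left), clamp(right)


def classify(
    new_slope: float,
    interval: VariationInterval,
    allow_recovery: bool = False,
) -> ClassificationResult:
    """Classify a candidate's load slope against a cohort variation interval.

    Recovery-phase intervals are refused unless ``allow_recovery`` is set,
    because the cohort separation condition fails during recovery and the
    resulting interval carries no discriminating power.
    """
    if interval.phase == "recovery" and not allow_recovery:
        raise ClassifierError(
            "refusing to classify against a recovery-phase interval: the "
            "cohort separation condition |mu2 - mu1| >= min(sigma1, sigma2) "
            "is not satisfied during recovery; pass allow_recovery=True to "
            "override"
        )
    c = interpolation_coefficient(new_slope, interval)
    left, right = branch_thickness(c)
    if left == right:
        tendency = "balanced"
    elif c < 0:
        tendency = "pressure_dominant"
    else:
        tendency = "heart_rate_dominant"
    outside = new_slope < interval.left or new_slope > interval.right
    return ClassificationResult(
        new_slope=float(new_slope),
        c=float(c),
        left_thickness=left,
        right_thickness=right,
        tendency=tendency,
        outside_interval=bool(outside),
        interval=interval,
    )


def triangle_layout(result: ClassificationResult) -> TriangleLayout:
    """Vertex coordinates and branch widths for rendering one result."""
    return TriangleLayout(
        vertices=dict(VERTICES),
        left_width=result.left_thickness,
        right_width=result.right_thickness,
    )


def render_triangle(result: ClassificationResult, path) -> None:
    """Draw the triangle diagram to ``path`` (format from the extension).

    Left branch R–E and right branch R–S are drawn with stroke widths equal
    to the pixel thicknesses; the unexamined Executive–Supply base is a
    dashed line.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    layout = triangle_layout(result)
    ex, ey = layout.vertices["E"]
    rx, ry = layout.vertices["R"]
    sx, sy = layout.vertices["S"]
    fig, ax = plt.subplots(figsize=(5, 4.5))
    ax.plot([rx, ex], [ry, ey], color="black", lw=layout.left_width, solid_capstyle="round")
    ax.plot([rx, sx], [ry, sy], color="black", lw=layout.right_width, solid_capstyle="round")
    ax.plot([ex, sx], [ey, sy], color="black", lw=1, ls="--")
    for label, (vx, vy) in layout.vertices.items():
        ax.annotate(
            label,
            (vx, vy),
            textcoords="offset points",
            xytext=(0, 8 if label == "R" else -14),
            ha="center",
            fontsize=12,
        )
    ax.annotate(layout.left_label, (-0.62, 0.58), ha="center", fontsize=8, rotation=45)
    ax.annotate(layout.right_label, (0.62, 0.58), ha="center", fontsize=8, rotation=-45)
    ax.set_title(
        f"New = {result.new_slope:.4f},  C = {round_half_away(result.c, 4):.4f}  "
        f"({result.tendency})"
    )
    ax.set_xlim(-1.4, 1.4)
    ax.set_ylim(-0.35, 1.25)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
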