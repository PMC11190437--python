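"""Flagellum-length morphometrics, ROI intensity and rank statistics.

Lengths are measured from manually traced axoneme polylines, either as the
segmented-line chord sum or as the arc length of an interpolating natural
cubic spline (chord-length parameterised), emulating the segmented-line +
fit-spline tracing workflow.  Group comparisons use the Mann-Whitney U
test: exact when feasible and tie-free, otherwise the normal approximation
with tie and continuity corrections.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.stats import mannwhitneyu

SPLINE_SUBDIVISIONS = 100  # per traced segment; keeps arc-length error << 0.01 um


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangle in pixel coordinates: origin (x, y), size (w, h)."""

    x: int
    y: int
    width: int
    height: int

    @property
    def area_px(self) -> int:
        return self.width * self.height


@dataclass
class ComparisonResult:
    """Two-group Mann-Whitney comparison (U for group1, two-group summaries)."""

    u_statistic: float
    p_value: float
    n1: int
    n2: int
    median1: float
    median2: float
    iqr1: tuple[float, float]
    iqr2: tuple[float, float]
    method: str = ""


def measure_trace_length(
    points: np.ndarray, mode: Literal["segmented", "spline"] = "spline"
) -> float:
    """Length (same units as the points, conventionally um) of a traced polyline.

    ``segmented`` sums the chords; ``spline`` measures the arc length of a
    natural cubic through the points with chord-length parameterisation,
    by fine subdivision.  Consecutive duplicate points are collapsed with
    a warning.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) >= 2:
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 0
        if not keep.all():
            warnings.warn("collapsed duplicate consecutive trace points", stacklevel=2)
            pts = pts[keep]
    if len(pts) < 2:
        raise ValueError("a trace needs at least two distinct points")

    chords = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if mode == "segmented":
        return float(chords.sum())
    if mode != "spline":
        raise ValueError(f"unknown mode {mode!r}")
    if len(pts) == 2:
        return float(chords.sum())
    t = np.concatenate([[0.0], np.cumsum(chords)])
    spline = CubicSpline(t, pts, axis=0, bc_type="natural")
    fine_t = np.concatenate(
        [
            np.linspace(t[i], t[i + 1], SPLINE_SUBDIVISIONS, endpoint=False)
            for i in range(len(t) - 1)
        ]
        + [t[-1:]]
    )
    fine = spline(fine_t)
    return float(np.linalg.norm(np.diff(fine, axis=0), axis=1).sum())


def roi_integrated_density(image: np.ndarray, roi: RectROI) -> float:
    """Sum of pixel values inside the ROI; the ROI must lie within the image."""
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    if roi.width <= 0 or roi.height <= 0:
        raise ValueError("ROI must have positive size")
    if roi.x < 0 or roi.y < 0 or roi.x + roi.width > w or roi.y + roi.height > h:
        raise ValueError(f"ROI {roi} extends outside the {h}x{w} image")
    return float(img[roi.y : roi.y + roi.height, roi.x : roi.x + roi.width].sum())


def subtract_background(
    site_density: float, background_density: float, site_area: int, background_area: int
) -> float:
    """Net integrated density; site and background ROIs must have equal area."""
    if site_area != background_area:
        raise ValueError(
            f"site ({site_area} px) and background ({background_area} px) ROI areas differ; "
            "integrated densities are not comparable"
        )
    return site_density - background_density


def net_roi_density(image: np.ndarray, site: RectROI, background: RectROI) -> float:
    """Background-subtracted integrated density of ``site``."""
    return subtract_background(
        roi_integrated_density(image, site),
        roi_integrated_density(image, background),
        site.area_px,
        background.area_px,
    )


def _iqr(values: np.ndarray) -> tuple[float, float]:
    q1, q3 = np.percentile(values, [25, 75])
    return (float(q1), float(q3))


def mann_whitney_u(
    group1,
    group2,
    alternative: Literal["two-sided", "less", "greater"] = "two-sided",
) -> ComparisonResult:
    """Mann-Whitney U comparison of two independent samples.

    U is the rank-sum statistic for group1 (midranks for ties).  The
    p-value is exact when n1*n2 <= 400 and there are no ties, otherwise a
    normal approximation with tie correction and continuity correction.
    """
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative=alternative, method=method, use_continuity=True)
    return ComparisonResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=int(a.size),
        n2=int(b.size),
        median1=float(np.median(a)),
        median2=float(np.median(b)),
        iqr1=_iqr(a),
        iqr2=_iqr(b),
        method=method,
    )


def classify_flagellum_bias(
    new_flagellum, old_flagellum, alpha: float = 0.05
) -> tuple[str, ComparisonResult]:
    """Classify per-cell paired base intensities as old/new-enriched or equal.

    Input arrays are per-cell net densities at the new- and old-flagellum
    bases; rows with a missing value in either are dropped (count reported
    via warning).  'old_enriched' needs a higher old-flagellum median and a
    two-sided Mann-Whitney p below ``alpha``; 'new_enriched' the reverse;
    anything else is 'equal'.
    """
    nf = np.asarray(new_flagellum, dtype=float)
    of = np.asarray(old_flagellum, dtype=float)
    if nf.shape != of.shape:
        raise ValueError("new/old flagellum arrays must be paired (same length)")
    ok = np.isfinite(nf) & np.isfinite(of)
    dropped = int((~ok).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} unpaired/missing rows", stacklevel=2)
    nf, of = nf[ok], of[ok]
    if nf.size < 20:
        raise ValueError(f"need >= 20 paired cells, got {nf.size}")
    cmp = mann_whitney_u(of, nf, alternative="two-sided")
    if cmp.p_value < alpha and cmp.median1 > cmp.median2:
        return "old_enriched", cmp
    if cmp.p_value < alpha and cmp.median2 > cmp.median1:
        return "new_enriched", cmp
    return "equal", cmp


def compare_lengths(
    lengths: pd.DataFrame,
    group_col: str = "condition",
    value_col: str = "length_um",
) -> dict[str, ComparisonResult]:
    """Pairwise Mann-Whitney comparisons between the two groups of a length table."""
    groups = list(lengths[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    g1 = lengths.loc[lengths[group_col] == groups[0], value_col]
    g2 = lengths.loc[lengths[group_col] == groups[1], value_col]
    return {f"{groups[0]}_vs_{groups[1]}": mann_whitney_u(g1, g2)}


def comparison_to_dict(c: ComparisonResult) -> dict:
    return {
        "U": c.u_statistic,
        "p": c.p_value,
        "n1": c.n1,
        "n2": c.n2,
        "median1": c.median1,
        "median2": c.median2,
        "iqr1": list(c.iqr1),
        "iqr2": list(c.iqr2),
        "method": c.method,
    }
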