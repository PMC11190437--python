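"""Detection of fluorescence puncta and sub-pixel centre refinement.

Candidate maxima are found by topographic prominence (the height of a peak
above the highest saddle connecting it to higher ground; the global maximum
is measured above the image background).  Centres are then refined by
fitting 1D Gaussians to the column-summed x-profile and row-summed
y-profile of a window around each peak, which is robust for both
point-like foci and symmetric annular structures.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class PeakCandidate:
    """An integer-pixel local maximum with its topographic prominence."""

    pixel: tuple[int, int]  # (y, x)
    prominence: float
    intensity: float
    channel: str = "green"


@dataclass
class Focus:
    """A sub-pixel localised punctum (all lengths in nm)."""

    centre_nm: tuple[float, float]  # (x, y)
    amplitude: float
    sigma_x_nm: float
    sigma_y_nm: float
    offset: float
    fit_rmse: float
    channel: str = "green"
    valid: bool = True
    reason: str = ""


def _neighbours(y: int, x: int, h: int, w: int):
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w:
                yield ny, nx


def detect_maxima(
    image: np.ndarray, channel: str = "green", prominence_threshold: float = 50.0
) -> list[PeakCandidate]:
    """Local maxima whose prominence exceeds ``prominence_threshold``.

    Prominence is computed by the standard persistence sweep: pixels are
    activated in descending intensity order with 8-connectivity union-find;
    when a component merges into one with a higher peak, the lower peak's
    prominence is its height above the merge level.  The surviving global
    maximum gets its height above the image minimum (the background).
    Equal-height ties are processed in ascending (y, x) order.  Returns
    candidates sorted by descending intensity.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("image is empty")
    if prominence_threshold <= 0:
        raise ValueError("prominence_threshold must be positive")
    h, w = img.shape
    flat = img.ravel()
    ys, xs = np.unravel_index(np.arange(flat.size), img.shape)
    order = np.lexsort((xs, ys, -flat))

    parent = np.full(flat.size, -1, dtype=np.int64)  # -1 = not yet activated
    peak_of = np.empty(flat.size, dtype=np.int64)  # root -> index of its peak pixel

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:  # path compression
            parent[i], i = root, parent[i]
        return root

    prominences: dict[int, float] = {}
    for idx in order:
        y, x = int(ys[idx]), int(xs[idx])
        level = flat[idx]
        roots = []
        for ny, nx in _neighbours(y, x, h, w):
            nidx = ny * w + nx
            if parent[nidx] != -1:
                r = find(nidx)
                if r not in roots:
                    roots.append(r)
        parent[idx] = idx
        peak_of[idx] = idx
        if not roots:
            continue  # idx is a new peak
        # order components by (peak height desc, peak (y,x) asc) -> survivor first
        roots.sort(key=lambda r: (-flat[peak_of[r]], int(ys[peak_of[r]]), int(xs[peak_of[r]])))
        survivor = roots[0]
        parent[idx] = survivor
        for r in roots[1:]:
            p = peak_of[r]
            prominences[int(p)] = float(flat[p] - level)
            parent[r] = survivor
    # the last surviving component's peak: prominence above background
    root = find(int(order[0]))
    gp = int(peak_of[root])
    prominences[gp] = float(flat[gp] - flat.min())

    out = [
        PeakCandidate(
            pixel=(int(ys[p]), int(xs[p])),
            prominence=prom,
            intensity=float(flat[p]),
            channel=channel,
        )
        for p, prom in prominences.items()
        if prom > prominence_threshold
    ]
    out.sort(key=lambda c: (-c.intensity, c.pixel))
    return out


def _gauss1d(x, amplitude, mu, sigma, offset):
    return amplitude * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + offset


def _fit_profile(profile: np.ndarray) -> tuple[np.ndarray, float]:
    """Fit (amplitude, mu, sigma, offset) to a 1D profile; returns (params, rmse)."""
    x = np.arange(profile.size, dtype=float)
    base = float(profile.min())
    weights = np.clip(profile - base, 0.0, None)
    total = weights.sum()
    if total <= 0:
        raise RuntimeError("flat profile")
    mu0 = float((x * weights).sum() / total)
    var0 = float(((x - mu0) ** 2 * weights).sum() / total)
    sigma0 = max(math.sqrt(max(var0, 1e-6)), 0.5)
    p0 = [float(profile.max() - base), mu0, sigma0, base]
    popt, _ = curve_fit(
        _gauss1d, x, profile, p0=p0, maxfev=2000, xtol=1e-8, ftol=1e-8
    )
    if popt[0] <= 0 or not np.isfinite(popt).all():
        raise RuntimeError("degenerate Gaussian fit")
    popt[2] = abs(popt[2])
    rmse = float(np.sqrt(np.mean((_gauss1d(x, *popt) - profile) ** 2)))
    return popt, rmse


def fit_centre(
    image: np.ndarray,
    peak: PeakCandidate,
    window_px: int = 15,
    pixel_size_nm: float = 65.0,
) -> Focus:
    """Refine a peak to a sub-pixel centre by marginal 1D Gaussian fits.

    The window is clamped to the image; the x-profile is the column sum and
    the y-profile the row sum over the window.  A non-converging fit yields
    ``valid=False`` with the reason recorded, never an exception.
    """
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be an odd integer >= 3")
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    half = window_px // 2
    py, px = peak.pixel
    y0 = min(max(py - half, 0), max(h - window_px, 0))
    x0 = min(max(px - half, 0), max(w - window_px, 0))
    win = img[y0 : y0 + window_px, x0 : x0 + window_px]

    try:
        (ax, mx, sx, ox), rmse_x = _fit_profile(win.sum(axis=0))
        (ay, my, sy, oy), rmse_y = _fit_profile(win.sum(axis=1))
    except RuntimeError as exc:
        return Focus(
            centre_nm=(px * pixel_size_nm, py * pixel_size_nm),
            amplitude=float("nan"),
            sigma_x_nm=float("nan"),
            sigma_y_nm=float("nan"),
            offset=float("nan"),
            fit_rmse=float("nan"),
            channel=peak.channel,
            valid=False,
            reason=f"fit failed: {exc}",
        )

    n = win.shape[0]
    if not (0 <= mx <= n - 1 and 0 <= my <= n - 1):
        return Focus(
            centre_nm=((x0 + mx) * pixel_size_nm, (y0 + my) * pixel_size_nm),
            amplitude=float("nan"),
            sigma_x_nm=sx * pixel_size_nm,
            sigma_y_nm=sy * pixel_size_nm,
            offset=float("nan"),
            fit_rmse=float("nan"),
            channel=peak.channel,
            valid=False,
            reason="fitted centre escaped the window",
        )

    # profile sums carry window_px * per-pixel values; report per-pixel scale
    amplitude = float(peak.intensity)
    return Focus(
        centre_nm=((x0 + mx) * pixel_size_nm, (y0 + my) * pixel_size_nm),
        amplitude=amplitude,
        sigma_x_nm=float(sx * pixel_size_nm),
        sigma_y_nm=float(sy * pixel_size_nm),
        offset=float((ox + oy) / (2 * n)),
        fit_rmse=float(math.hypot(rmse_x, rmse_y) / n),
        channel=peak.channel,
        valid=True,
    )


def localise(
    image: np.ndarray,
    channel: str = "green",
    prominence_threshold: float = 50.0,
    window_px: int = 15,
    pixel_size_nm: float = 65.0,
    seed_pixels: Sequence[tuple[int, int]] | None = None,
) -> list[Focus]:
    """Detect-and-fit convenience wrapper.

    ``seed_pixels`` (a list of (y, x) integer pixels) substitutes for
    automatic detection, mirroring manual point selection.
    """
    if seed_pixels is not None:
        img = np.asarray(image, dtype=float)
        peaks = [
            PeakCandidate(
                pixel=(int(y), int(x)),
                prominence=float("inf"),
                intensity=float(img[int(y), int(x)]),
                channel=channel,
            )
            for y, x in seed_pixels
        ]
    else:
        peaks = detect_maxima(image, channel, prominence_threshold)
    return [fit_centre(image, p, window_px, pixel_size_nm) for p in peaks]
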