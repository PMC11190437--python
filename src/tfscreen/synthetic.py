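"""Synthetic dual-channel fluorescence scenes with exact ground truth.

Every downstream measurement (localisation, pairing, pseudo-diameter) is
validated against scenes generated here, where the geometry is known to
machine precision.  The renderer integrates the Gaussian PSF analytically
over pixel areas, so sub-pixel positions are meaningful and photons are
conserved; noise is Poisson shot noise on the expectation plus additive
Gaussian camera noise.

Coordinate convention: the origin sits at the centre of pixel (0, 0),
x runs rightward (columns), y downward (rows), all positions in nm.
Images are float arrays indexed ``[y, x]``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .config import SceneConfig

Channel = Literal["green", "red"]

CHANNELS: tuple[Channel, Channel] = ("green", "red")

# quadrature for annular structures: a ring is discretised into point
# sources much more finely than any PSF used here (sub-5 nm spacing on a
# 400 nm ring with 256 points)
_RING_POINTS = 256
_DISC_RADII = 16
_DISC_POINTS = 64


@dataclass(frozen=True)
class Emitter:
    """A point source: expected ``amplitude`` photons at ``centre_nm`` (x, y)."""

    centre_nm: tuple[float, float]
    amplitude: float
    channel: Channel = "red"

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class AnnularStructure:
    """An annulus/disc standing for a transition-fibre-like structure.

    ``ring_weight`` interpolates between a filled disc (0) and a pure ring
    (1) of ``true_diameter_nm``; total expected photons are ``amplitude``.
    """

    centre_nm: tuple[float, float]
    true_diameter_nm: float
    amplitude: float
    ring_weight: float = 1.0
    channel: Channel = "green"

    def __post_init__(self) -> None:
        if not (0 < self.true_diameter_nm < 1000):
            raise ValueError("true_diameter_nm must lie in (0, 1000) nm")
        if not (0 <= self.ring_weight <= 1):
            raise ValueError("ring_weight must lie in [0, 1]")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass
class GroundTruth:
    """Exact scene description plus structure-to-nearest-red-emitter distances."""

    emitters: list[Emitter]
    structures: list[AnnularStructure]
    # (structure index, red emitter index, centre-to-centre distance in nm)
    pair_distances_nm: list[tuple[int, int, float]] = field(default_factory=list)


def _bounds_nm(config: SceneConfig) -> tuple[float, float, float, float]:
    """(xmin, xmax, ymin, ymax) of the image footprint in nm."""
    h, w = config.image_size_px
    p = config.pixel_size_nm
    return (-0.5 * p, (w - 0.5) * p, -0.5 * p, (h - 0.5) * p)


def _check_bounds(config: SceneConfig, emitters, structures) -> None:
    xmin, xmax, ymin, ymax = _bounds_nm(config)
    for i, e in enumerate(emitters):
        x, y = e.centre_nm
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            raise ValueError(
                f"emitter {i} at ({x:.1f}, {y:.1f}) nm lies outside the "
                f"image footprint x:[{xmin:.1f}, {xmax:.1f}] y:[{ymin:.1f}, {ymax:.1f}]"
            )
    for i, s in enumerate(structures):
        x, y = s.centre_nm
        r = 0.5 * s.true_diameter_nm
        if not (xmin <= x - r and x + r <= xmax and ymin <= y - r and y + r <= ymax):
            raise ValueError(
                f"structure {i} (centre ({x:.1f}, {y:.1f}) nm, radius {r:.1f} nm) "
                "extends outside the image footprint"
            )


def _pixel_profiles(n: int, centres_px: np.ndarray, sigma_px: float) -> np.ndarray:
    """Row k = integral of a unit 1D Gaussian at centres_px[k] over each pixel.

    Pixel i covers [i-0.5, i+0.5] in pixel units.
    """
    edges = np.arange(n + 1, dtype=float) - 0.5
    z = (edges[None, :] - np.asarray(centres_px, dtype=float)[:, None]) / (
        sigma_px * math.sqrt(2.0)
    )
    c = erf(z)
    return 0.5 * (c[:, 1:] - c[:, :-1])


def _point_cloud(structure: AnnularStructure) -> tuple[np.ndarray, np.ndarray]:
    """Discretise a structure into weighted point sources (positions nm, weights)."""
    cx, cy = structure.centre_nm
    radius = 0.5 * structure.true_diameter_nm
    xs: list[np.ndarray] = []
    ws: list[np.ndarray] = []
    if structure.ring_weight > 0:
        theta = np.linspace(0.0, 2 * math.pi, _RING_POINTS, endpoint=False)
        pts = np.column_stack(
            [cx + radius * np.cos(theta), cy + radius * np.sin(theta)]
        )
        xs.append(pts)
        ws.append(
            np.full(_RING_POINTS, structure.ring_weight * structure.amplitude / _RING_POINTS)
        )
    if structure.ring_weight < 1:
        # filled disc as concentric rings weighted by annulus area
        k = np.arange(_DISC_RADII)
        radii = (k + 0.5) / _DISC_RADII * radius
        area_w = (2 * k + 1).astype(float)
        area_w /= area_w.sum()
        disc_amp = (1 - structure.ring_weight) * structure.amplitude
        theta = np.linspace(0.0, 2 * math.pi, _DISC_POINTS, endpoint=False)
        for r_k, w_k in zip(radii, area_w):
            pts = np.column_stack([cx + r_k * np.cos(theta), cy + r_k * np.sin(theta)])
            xs.append(pts)
            ws.append(np.full(_DISC_POINTS, disc_amp * w_k / _DISC_POINTS))
    return np.concatenate(xs, axis=0), np.concatenate(ws)


def _render_channel(
    config: SceneConfig, emitters: Sequence[Emitter], structures: Sequence[AnnularStructure]
) -> np.ndarray:
    h, w = config.image_size_px
    p = config.pixel_size_nm
    sigma_px = config.psf_sigma_nm / p
    image = np.full((h, w), float(config.background_level))

    points: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    for e in emitters:
        points.append(np.asarray(e.centre_nm, dtype=float)[None, :])
        weights.append(np.array([e.amplitude]))
    for s in structures:
        pts, ws = _point_cloud(s)
        points.append(pts)
        weights.append(ws)
    if not points:
        return image

    pts = np.concatenate(points, axis=0)
    ws = np.concatenate(weights)
    px = _pixel_profiles(w, pts[:, 0] / p, sigma_px)  # (n_pts, w)
    py = _pixel_profiles(h, pts[:, 1] / p, sigma_px)  # (n_pts, h)
    image += (py * ws[:, None]).T @ px
    return image


def scene_rng(config: SceneConfig, scene_index: int = 0) -> np.random.Generator:
    """One independent, reproducible RNG stream per (seed, scene index)."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, scene_index]))


def render_scene(
    config: SceneConfig,
    emitters: Sequence[Emitter] = (),
    structures: Sequence[AnnularStructure] = (),
    *,
    noise: bool = True,
    scene_index: int = 0,
) -> tuple[dict[Channel, np.ndarray], GroundTruth]:
    """Render both channels and return (images, ground truth).

    Noiseless expectation = background + objects convolved with the Gaussian
    PSF; with ``noise=True`` each pixel is Poisson(expectation) plus
    Normal(0, read_noise_sd).  Identical (config, objects, scene_index)
    produce bit-identical images.
    """
    _check_bounds(config, emitters, structures)
    images: dict[Channel, np.ndarray] = {}
    rng = scene_rng(config, scene_index)
    for channel in CHANNELS:
        expectation = _render_channel(
            config,
            [e for e in emitters if e.channel == channel],
            [s for s in structures if s.channel == channel],
        )
        if noise:
            img = rng.poisson(expectation).astype(float)
            if config.read_noise_sd > 0:
                img += rng.normal(0.0, config.read_noise_sd, size=expectation.shape)
            images[channel] = img
        else:
            images[channel] = expectation

    truth = GroundTruth(emitters=list(emitters), structures=list(structures))
    reds = [(i, e) for i, e in enumerate(emitters) if e.channel == "red"]
    for si, s in enumerate(structures):
        if not reds:
            continue
        dists = [
            (math.hypot(s.centre_nm[0] - e.centre_nm[0], s.centre_nm[1] - e.centre_nm[1]), ei)
            for ei, e in reds
        ]
        d, ei = min(dists)
        truth.pair_distances_nm.append((si, ei, d))
    return images, truth


# ---------------------------------------------------------------------------
# cell-cycle fixtures
# ---------------------------------------------------------------------------

Stage = Literal["G1", "G1S", "S"]
Timing = Literal["early", "late", "probasal"]


def _stage_counts(n_cells: int, stage_mix: dict[str, float]) -> list[Stage]:
    """Deterministic largest-remainder allocation of cells to stages."""
    stages: tuple[Stage, ...] = ("G1", "G1S", "S")
    total = sum(stage_mix.get(s, 0.0) for s in stages)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"stage_mix proportions must sum to 1 (got {total:g})")
    raw = {s: n_cells * stage_mix.get(s, 0.0) for s in stages}
    counts = {s: int(math.floor(raw[s])) for s in stages}
    rem = n_cells - sum(counts.values())
    for s in sorted(stages, key=lambda s: raw[s] - counts[s], reverse=True)[:rem]:
        counts[s] += 1
    out: list[Stage] = []
    for s in stages:
        out.extend([s] * counts[s])
    return out


def _cell_geometry(
    stage: Stage, timing: Timing, centre: tuple[float, float], rng: np.random.Generator
) -> tuple[list[Emitter], list[AnnularStructure], int, int, bool]:
    """Basal-body layout for one cell.

    SAS-6 (red) marks the proximal end of every basal body: a G1 cell has a
    mature basal body (MBB) plus its probasal body (2 red foci); at the G1-S
    transition the probasal body has matured into a second MBB (still 2 red
    foci); in S phase two new probasal bodies have formed (4 red foci).
    Green transition-fibre structures sit ~300 nm distal to SAS-6 on each
    basal body that carries the tagged protein at that stage.
    """
    cx, cy = centre
    jitter = rng.uniform(-150.0, 150.0, size=2)
    old_mbb = (cx + jitter[0], cy + jitter[1])
    axis = rng.uniform(0.0, 2 * math.pi)  # old->new basal body axis

    def offset(p, d, ang):
        return (p[0] + d * math.cos(ang), p[1] + d * math.sin(ang))

    # distal direction (towards the flagellum) roughly perpendicular to the axis
    distal = axis + math.pi / 2

    bodies: list[tuple[tuple[float, float], str]] = [(old_mbb, "mature")]
    if stage == "G1":
        bodies.append((offset(old_mbb, 300.0, axis), "probasal"))
    elif stage == "G1S":
        bodies.append((offset(old_mbb, 800.0, axis), "maturing"))
    else:  # S phase: two mature bodies, each with a new probasal body
        new_mbb = offset(old_mbb, 800.0, axis)
        bodies.append((new_mbb, "maturing"))
        bodies.append((offset(old_mbb, 300.0, axis + math.pi / 3), "probasal"))
        bodies.append((offset(new_mbb, 300.0, axis - math.pi / 3), "probasal"))

    emitters = [
        Emitter(centre_nm=p, amplitude=2000.0, channel="red") for p, _ in bodies
    ]

    # which bodies carry the tagged green protein
    green_on: list[tuple[float, float]] = []
    green_on_probasal = False
    for p, kind in bodies:
        if timing == "probasal":
            green_on.append(p)
            if kind == "probasal":
                green_on_probasal = True
        elif timing == "early":
            if kind == "mature" or kind == "maturing":
                green_on.append(p)
        else:  # late: the maturing body acquires signal only once 4 red foci exist
            if kind == "mature" or (kind == "maturing" and stage == "S"):
                green_on.append(p)

    structures = [
        AnnularStructure(
            centre_nm=offset(p, 300.0, distal),
            true_diameter_nm=340.0,
            amplitude=2000.0,
            ring_weight=1.0,
            channel="green",
        )
        for p in green_on
    ]
    red_count = len(emitters)
    return emitters, structures, red_count, len(structures), green_on_probasal


def make_cell_cycle_fixture(
    config: SceneConfig,
    n_cells: int,
    stage_mix: dict[str, float],
    tfp_timing: Timing,
    *,
    noise: bool = True,
) -> tuple[list[tuple[dict[Channel, np.ndarray], GroundTruth]], pd.DataFrame]:
    """Scenes for a cell-cycle recruitment experiment plus per-cell truth.

    ``tfp_timing`` controls when the tagged protein appears: 'early' puts
    2 green structures on cells at the G1-S transition (recruited before
    basal-body duplication), 'late' leaves a single green structure until
    4 red foci are present, 'probasal' co-locates green with every red
    focus.  Returns the rendered scenes and a truth table with columns
    cell_id, stage, red_focus_count, green_structure_count, green_on_probasal.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if tfp_timing not in ("early", "late", "probasal"):
        raise ValueError(f"unknown tfp_timing {tfp_timing!r}")
    stages = _stage_counts(n_cells, stage_mix)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 987654321]))
    shuffle_rng.shuffle(stages)

    h, w = config.image_size_px
    centre = ((w - 1) / 2 * config.pixel_size_nm, (h - 1) / 2 * config.pixel_size_nm)

    scenes = []
    rows = []
    for cell_id, stage in enumerate(stages):
        # geometry uses its own stream so pixel noise and layout stay decoupled
        geom_rng = np.random.default_rng(np.random.SeedSequence([config.seed, cell_id, 1]))
        emitters, structures, n_red, n_green, on_probasal = _cell_geometry(
            stage, tfp_timing, centre, geom_rng
        )
        scenes.append(
            render_scene(config, emitters, structures, noise=noise, scene_index=cell_id)
        )
        rows.append(
            {
                "cell_id": cell_id,
                "stage": stage,
                "red_focus_count": n_red,
                "green_structure_count": n_green,
                "green_on_probasal": on_probasal,
            }
        )
    return scenes, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def write_scene(path: str | Path, images: dict[Channel, np.ndarray]) -> None:
    """Write one scene as a 2-page TIFF, channel order (green, red)."""
    import tifffile

    stack = np.stack([images["green"], images["red"]]).astype(np.float32)
    tifffile.imwrite(str(path), stack)


def read_scene(path: str | Path) -> dict[Channel, np.ndarray]:
    import tifffile

    stack = tifffile.imread(str(path)).astype(float)
    return {"green": stack[0], "red": stack[1]}


def truth_table(truths: Iterable[GroundTruth]) -> pd.DataFrame:
    """Flatten ground truths into a CSV-ready table."""
    rows = []
    for scene_id, t in enumerate(truths):
        for oid, e in enumerate(t.emitters):
            rows.append(
                {
                    "scene_id": scene_id,
                    "object_id": oid,
                    "type": "emitter",
                    "x_nm": e.centre_nm[0],
                    "y_nm": e.centre_nm[1],
                    "diameter_nm": 0.0,
                    "channel": e.channel,
                }
            )
        base = len(t.emitters)
        for oid, s in enumerate(t.structures):
            rows.append(
                {
                    "scene_id": scene_id,
                    "object_id": base + oid,
                    "type": "structure",
                    "x_nm": s.centre_nm[0],
                    "y_nm": s.centre_nm[1],
                    "diameter_nm": s.true_diameter_nm,
                    "channel": s.channel,
                }
            )
    return pd.DataFrame(rows)
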