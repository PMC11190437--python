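"""Synthetic-recovery experiments used for validation and reproducibility.

Each function runs a self-contained seeded experiment on synthetic scenes
and returns plain numbers: localisation/pairing recovery, pseudo-diameter
isotropy and monotonicity, rotation robustness, and the type-I error
calibration of the Mann-Whitney test.  Problem sizes default to what the
validation suite uses (200 scenes, 2000 null simulations).
"""
from __future__ import annotations

import math

import numpy as np

from .config import GeometryConfig, SceneConfig
from .geometry import pair_to_nearest, pseudo_diameter
from .localise import localise
from .morpho import mann_whitney_u
from .synthetic import AnnularStructure, Emitter, render_scene


def localisation_recovery(
    n_scenes: int = 200,
    seed: int = 1,
    offset_range_nm: tuple[float, float] = (150.0, 450.0),
    amplitude: float = 5000.0,
) -> dict:
    """Centre-fitting and pairing recovery on seeded two-focus scenes.

    Each scene holds one red point emitter and one green ring (250 nm) at a
    uniformly drawn offset; both are localised, paired with the 500 nm
    cutoff, and compared to ground truth.  Returns the median centre error
    (px), the mean absolute pairing-distance error (nm), the number of
    pairs and the number of pairs beyond the cutoff (should be 0).
    """
    cfg = SceneConfig(
        image_size_px=(32, 32), background_level=20.0, read_noise_sd=2.0, seed=seed
    )
    p = cfg.pixel_size_nm
    centre = ((32 - 1) / 2 * p, (32 - 1) / 2 * p)
    centre_errors_px: list[float] = []
    distance_errors_nm: list[float] = []
    n_pairs = 0
    n_beyond = 0
    for i in range(n_scenes):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i, 7]))
        jitter = rng.uniform(-100.0, 100.0, size=2)
        red = (centre[0] + jitter[0], centre[1] + jitter[1])
        offset = rng.uniform(*offset_range_nm)
        theta = rng.uniform(0.0, 2 * math.pi)
        green = (red[0] + offset * math.cos(theta), red[1] + offset * math.sin(theta))
        images, _ = render_scene(
            cfg,
            [Emitter(red, amplitude, "red")],
            [AnnularStructure(green, 250.0, amplitude, channel="green")],
            scene_index=i,
        )
        greens = [f for f in localise(images["green"], "green", 50.0, 15, p) if f.valid]
        reds = [f for f in localise(images["red"], "red", 50.0, 15, p) if f.valid]
        g = max(greens, key=lambda f: f.amplitude)
        r = max(reds, key=lambda f: f.amplitude)
        centre_errors_px.append(
            math.hypot(g.centre_nm[0] - green[0], g.centre_nm[1] - green[1]) / p
        )
        centre_errors_px.append(
            math.hypot(r.centre_nm[0] - red[0], r.centre_nm[1] - red[1]) / p
        )
        pairs, _ = pair_to_nearest([g], [r], 500.0)
        for q in pairs:
            n_pairs += 1
            if q.distance_nm > 500.0:
                n_beyond += 1
            distance_errors_nm.append(abs(q.distance_nm - offset))
    return {
        "median_centre_error_px": float(np.median(centre_errors_px)),
        "pairing_mae_nm": float(np.mean(distance_errors_nm)),
        "n_pairs": n_pairs,
        "n_beyond_cutoff": n_beyond,
        "n_scenes": n_scenes,
    }


def _centred_scene_config(size: int = 48) -> tuple[SceneConfig, tuple[float, float]]:
    cfg = SceneConfig(
        image_size_px=(size, size), background_level=0.0, read_noise_sd=0.0
    )
    c = (size - 1) / 2 * cfg.pixel_size_nm
    return cfg, (c, c)


def isotropy_spread(amplitude: float = 10000.0) -> dict:
    """Spread of the 45 effective diameters on a noiseless isotropic spot (%)."""
    cfg, centre = _centred_scene_config()
    images, _ = render_scene(
        cfg, [Emitter(centre, amplitude, "green")], noise=False
    )
    res = pseudo_diameter(images["green"], centre, cfg, GeometryConfig())
    eff = np.array([q.effective_diameter_nm for q in res.profiles if q.valid])
    return {
        "n_valid": int(eff.size),
        "spread_pct": float((eff.max() - eff.min()) / eff.mean() * 100.0),
        "mean_effective_diameter_nm": float(eff.mean()),
    }


def ring_diameter_sweep(
    true_diameters_nm: tuple[float, ...] = (220.0, 280.0, 340.0, 400.0),
) -> dict:
    """Measured pseudo-diameter per noiseless ring diameter; checks monotonicity."""
    cfg, centre = _centred_scene_config()
    geometry = GeometryConfig()
    measured = []
    for d in true_diameters_nm:
        images, _ = render_scene(
            cfg,
            [],
            [AnnularStructure(centre, float(d), 10000.0, channel="green")],
            noise=False,
        )
        res = pseudo_diameter(images["green"], centre, cfg, geometry)
        measured.append(res.pseudo_diameter_nm)
    diffs = np.diff(measured)
    return {
        "true_diameters_nm": list(true_diameters_nm),
        "measured_pseudo_diameters_nm": [float(m) for m in measured],
        "strictly_increasing": bool((diffs > 0).all()),
    }


def rotation_robustness(diameter_nm: float = 340.0) -> dict:
    """Pseudo-diameter change (%) when an anisotropic scene is rotated by 90 deg.

    The structure is a two-emitter dumbbell (300 nm separation at 30 deg)
    so the measurement has a preferred axis; the scene is re-rendered with
    the geometry rotated a quarter turn about the structure centre.
    """
    cfg, centre = _centred_scene_config()
    sep, base_angle = 300.0, math.radians(30.0)
    results = []
    for extra in (0.0, math.pi / 2):
        ang = base_angle + extra
        dx, dy = 0.5 * sep * math.cos(ang), 0.5 * sep * math.sin(ang)
        emitters = [
            Emitter((centre[0] - dx, centre[1] - dy), 5000.0, "green"),
            Emitter((centre[0] + dx, centre[1] + dy), 5000.0, "green"),
        ]
        images, _ = render_scene(cfg, emitters, noise=False)
        res = pseudo_diameter(images["green"], centre, cfg, GeometryConfig())
        results.append(res.pseudo_diameter_nm)
    change = abs(results[1] - results[0]) / results[0] * 100.0
    return {
        "pseudo_diameter_nm": float(results[0]),
        "rotated_pseudo_diameter_nm": float(results[1]),
        "change_pct": float(change),
    }


def mwu_type1_calibration(
    n_simulations: int = 2000, n_per_group: int = 20, alpha: float = 0.05, seed: int = 5
) -> dict:
    """Empirical type-I error of the Mann-Whitney test under the null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_simulations):
        a = rng.normal(size=n_per_group)
        b = rng.normal(size=n_per_group)
        if mann_whitney_u(a, b).p_value < alpha:
            rejections += 1
    return {
        "type1_error": rejections / n_simulations,
        "n_simulations": n_simulations,
        "n_per_group": n_per_group,
        "alpha": alpha,
    }
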