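"""End-to-end screen pipeline: simulate -> detect -> measure -> gate -> stats.

``run_screen`` renders a synthetic cohort (controls plus candidates),
localises foci in both channels, measures distance-to-SAS-6 and
pseudo-diameter per cell, derives gate baselines from the control
proteins, applies the inclusion gate, and compares candidate vs control
pseudo-diameters.  Everything is driven by one seed and writes
deterministic CSV/JSON outputs plus a run manifest.
"""
from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, ProteinSpec
from .geometry import aggregate_metrology, pair_to_nearest, pseudo_diameter
from .localise import localise
from .morpho import comparison_to_dict, mann_whitney_u
from .screen import ControlBaselines, apply_inclusion_gate
from .synthetic import AnnularStructure, Emitter, render_scene

log = logging.getLogger("tfscreen")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def simulate_protein_scenes(
    config: PipelineConfig, protein: ProteinSpec, protein_index: int
):
    """Render ``n_cells`` scenes for one tagged protein.

    Each cell carries a SAS-6 (red) point emitter near the image centre and
    the protein's green object at its characteristic offset in a random
    direction.  Scene RNG streams derive from (seed, protein, cell) so every
    cell is independently reproducible.
    """
    scene_cfg = config.scene.model_copy(
        update={"seed": config.seed + 1000 * (protein_index + 1)}
    )
    h, w = scene_cfg.image_size_px
    p = scene_cfg.pixel_size_nm
    centre = ((w - 1) / 2 * p, (h - 1) / 2 * p)
    out = []
    for cell in range(config.n_cells):
        geom_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, protein_index, cell])
        )
        jitter = geom_rng.uniform(-100.0, 100.0, size=2)
        red_pos = (centre[0] + jitter[0], centre[1] + jitter[1])
        theta = geom_rng.uniform(0.0, 2 * math.pi)
        green_pos = (
            red_pos[0] + protein.offset_nm * math.cos(theta),
            red_pos[1] + protein.offset_nm * math.sin(theta),
        )
        emitters = [Emitter(centre_nm=red_pos, amplitude=protein.amplitude, channel="red")]
        structures = []
        if protein.shape == "ring":
            structures.append(
                AnnularStructure(
                    centre_nm=green_pos,
                    true_diameter_nm=protein.diameter_nm,
                    amplitude=protein.amplitude,
                    channel="green",
                )
            )
        else:
            emitters.append(
                Emitter(centre_nm=green_pos, amplitude=protein.amplitude, channel="green")
            )
        images, truth = render_scene(
            scene_cfg, emitters, structures, scene_index=cell
        )
        out.append((cell, images, truth))
    return out


def measure_cohort(config: PipelineConfig) -> pd.DataFrame:
    """Per-cell distance and pseudo-diameter measurements for every protein."""
    rows = []
    for pi, protein in enumerate(config.proteins):
        for cell, images, _truth in simulate_protein_scenes(config, protein, pi):
            green = localise(
                images["green"],
                "green",
                config.detection.prominence_green,
                config.detection.window_px,
                config.scene.pixel_size_nm,
            )
            red = localise(
                images["red"],
                "red",
                config.detection.prominence_red,
                config.detection.window_px,
                config.scene.pixel_size_nm,
            )
            pairs, _ = pair_to_nearest(green, red, config.geometry.cutoff_nm)
            if not pairs:
                log.warning("protein %s cell %d: no focus pair", protein.name, cell)
                continue
            pair = max(pairs, key=lambda q: q.green_focus.amplitude)
            pd_res = pseudo_diameter(
                images["green"], pair.green_focus.centre_nm, config.scene, config.geometry
            )
            rows.append(
                {
                    "protein_id": protein.name,
                    "role": protein.role,
                    "cell_id": cell,
                    "distance_nm": pair.distance_nm,
                    "pseudo_diameter_nm": pd_res.pseudo_diameter_nm,
                    "argmax_angle_deg": pd_res.argmax_angle_deg,
                    "n_valid_profiles": pd_res.n_valid_profiles,
                }
            )
    return pd.DataFrame(rows)


def run_screen(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline and write outputs under ``out_dir``.

    Writes measurements.csv, summary.csv, candidates.csv, comparisons.json,
    class_counts.json and manifest.json.  Rerunning with the same config
    and seed reproduces the CSV outputs byte-for-byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "run_id": _config_hash(config),
        "seed": config.seed,
        "tfscreen_version": __version__,
        "stages": {},
    }

    try:
        measurements = measure_cohort(config)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("simulate/detect/measure", exc) from exc
    manifest["stages"]["measure"] = {"rows": int(len(measurements))}

    try:
        summary = aggregate_metrology(measurements)
    except Exception as exc:
        raise StageError("aggregate", exc) from exc

    roles = {p.name: p.role for p in config.proteins}
    by_id = {m.protein_id: m for m in summary}

    def _control(role: str):
        for name, r in roles.items():
            if r == role and name in by_id:
                return by_id[name]
        raise ValueError(f"no measured control with role {role}")

    try:
        baselines = ControlBaselines(
            poc5_mean_distance_nm=_control("poc5_control").mean_distance_nm,
            tzp150_mean_distance_nm=_control("tzp150_control").mean_distance_nm,
            bbp136_mean_pseudo_diameter_nm=_control("bbp136_control").mean_pseudo_diameter_nm,
        )
        verdicts = apply_inclusion_gate(summary, baselines)
    except Exception as exc:
        raise StageError("gate", exc) from exc
    manifest["stages"]["gate"] = {"candidates": len(verdicts)}

    try:
        candidates = [n for n, r in roles.items() if r == "candidate" and n in by_id]
        control = _control("bbp136_control").protein_id
        comparisons = {}
        for name in candidates:
            g1 = measurements.loc[
                measurements["protein_id"] == name, "pseudo_diameter_nm"
            ]
            g2 = measurements.loc[
                measurements["protein_id"] == control, "pseudo_diameter_nm"
            ]
            comparisons[f"{name}_vs_{control}_pseudo_diameter"] = comparison_to_dict(
                mann_whitney_u(g1, g2)
            )
    except Exception as exc:
        raise StageError("stats", exc) from exc
    manifest["stages"]["stats"] = {"comparisons": len(comparisons)}

    run_id = manifest["run_id"]
    measurements.insert(0, "run_id", run_id)
    measurements.to_csv(out / "measurements.csv", index=False)

    summary_df = pd.DataFrame(
        [
            {
                "run_id": run_id,
                "protein_id": m.protein_id,
                "role": roles.get(m.protein_id, "candidate"),
                "n_cells": m.n_cells,
                "mean_distance_nm": m.mean_distance_nm,
                "sem_distance_nm": m.sem_distance_nm,
                "mean_pseudo_diameter_nm": m.mean_pseudo_diameter_nm,
                "sem_pseudo_diameter_nm": m.sem_pseudo_diameter_nm,
            }
            for m in summary
        ]
    )
    summary_df.to_csv(out / "summary.csv", index=False)

    candidates_df = summary_df[["run_id", "protein_id", "role"]].copy()
    candidates_df["gate_verdict"] = [verdicts[p] for p in candidates_df["protein_id"]]
    candidates_df.to_csv(out / "candidates.csv", index=False)

    verdict_counts: dict[str, int] = {}
    for v in verdicts.values():
        verdict_counts[v] = verdict_counts.get(v, 0) + 1
    class_counts = {"run_id": run_id, "gate_verdict": verdict_counts}

    baselines_dict = {
        "poc5_mean_distance_nm": baselines.poc5_mean_distance_nm,
        "tzp150_mean_distance_nm": baselines.tzp150_mean_distance_nm,
        "bbp136_mean_pseudo_diameter_nm": baselines.bbp136_mean_pseudo_diameter_nm,
    }
    (out / "comparisons.json").write_text(json.dumps(comparisons, indent=2, sort_keys=True))
    (out / "class_counts.json").write_text(json.dumps(class_counts, indent=2, sort_keys=True))
    manifest["baselines"] = baselines_dict
    manifest["gate_verdicts"] = verdicts
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
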