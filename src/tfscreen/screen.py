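"""Decision logic of the transition-fibre protein screen.

Covers the inclusion gate (distal to POC5, proximal to TZP150, wider than
BBP136), recruitment-timing classification from cell-cycle focus counts,
reciprocal-best-hit orthology over precomputed alignment tables, class
bookkeeping across the screen's annotation axes, and the back-of-envelope
alpha-helix length estimate.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import math

import pandas as pd

from .geometry import ProteinMetrology

GATE_VERDICTS = ("included", "excluded_proximal", "excluded_distal", "excluded_narrow")
RECRUITMENT_CLASSES = (
    "before_duplication",
    "after_duplication",
    "probasal",
    "unclassified",
)
FLAGELLUM_BIAS = ("old_enriched", "new_enriched", "equal", "untested")
CONSERVATION = ("beyond_kinetoplastids", "kinetoplastid_only", "unknown")
RNAI_PHENOTYPES = (
    "assembly_defect",
    "length_defect",
    "growth_defect_only",
    "none",
    "untested",
)


@dataclass(frozen=True)
class ControlBaselines:
    """Gate thresholds measured on the three control proteins (nm)."""

    poc5_mean_distance_nm: float
    tzp150_mean_distance_nm: float
    bbp136_mean_pseudo_diameter_nm: float

    def __post_init__(self) -> None:
        if not (0 < self.poc5_mean_distance_nm < self.tzp150_mean_distance_nm):
            raise ValueError(
                "POC5 mean distance must be positive and below the TZP150 mean"
            )
        if self.bbp136_mean_pseudo_diameter_nm <= 0:
            raise ValueError("BBP136 mean pseudo-diameter must be positive")


@dataclass
class CandidateRecord:
    """One protein's aggregated annotations across the screen."""

    protein_id: str
    name: str
    metrology: ProteinMetrology | None = None
    gate_verdict: str = "included"
    recruitment_class: str = "unclassified"
    flagellum_bias: str = "untested"
    conservation: str = "unknown"
    rnai_phenotype: str = "untested"
    orthologue_family: str = ""


@dataclass(frozen=True)
class CellObservation:
    cell_id: int
    red_focus_count: int
    green_focus_count: int
    green_on_probasal: bool = False

    def __post_init__(self) -> None:
        if self.red_focus_count not in (2, 4):
            raise ValueError("red_focus_count must be 2 (G1 / G1-S) or 4 (S phase)")
        if self.green_focus_count < 0:
            raise ValueError("green_focus_count must be non-negative")


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    e_value: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")


def apply_inclusion_gate(
    candidates: Iterable[ProteinMetrology], baselines: ControlBaselines
) -> dict[str, str]:
    """Gate verdict per protein id.

    A candidate is excluded_proximal if its mean distance is <= the POC5
    mean, excluded_distal if >= the TZP150 mean, excluded_narrow if its
    mean pseudo-diameter is <= the BBP136 mean; otherwise included.
    Comparisons use protein-level means with strict inequalities required
    to pass, so a candidate exactly at a boundary is excluded.  Missing
    metrology yields 'unclassified' with a warning.
    """
    verdicts: dict[str, str] = {}
    for m in candidates:
        if (
            m is None
            or not math.isfinite(m.mean_distance_nm)
            or not math.isfinite(m.mean_pseudo_diameter_nm)
        ):
            warnings.warn(
                f"candidate {getattr(m, 'protein_id', '?')} has missing metrology",
                stacklevel=2,
            )
            verdicts[getattr(m, "protein_id", "?")] = "unclassified"
            continue
        if m.mean_distance_nm <= baselines.poc5_mean_distance_nm:
            verdicts[m.protein_id] = "excluded_proximal"
        elif m.mean_distance_nm >= baselines.tzp150_mean_distance_nm:
            verdicts[m.protein_id] = "excluded_distal"
        elif m.mean_pseudo_diameter_nm <= baselines.bbp136_mean_pseudo_diameter_nm:
            verdicts[m.protein_id] = "excluded_narrow"
        else:
            verdicts[m.protein_id] = "included"
    return verdicts


def classify_recruitment(
    observations: list[CellObservation], min_fraction: float = 0.25
) -> str:
    """Recruitment-timing class from per-cell focus counts.

    * probasal: at least ``min_fraction`` of S-phase cells (4 red foci)
      show signal on a probasal body;
    * before_duplication: at least ``min_fraction`` of 2-red-foci cells
      already show a second green focus;
    * after_duplication: a second green focus appears only once 4 red
      foci are present;
    * otherwise unclassified.

    Needs >= 10 observations spanning both red-focus counts; order-free.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must lie in (0, 1]")
    if len(observations) < 10:
        return "unclassified"
    two = [o for o in observations if o.red_focus_count == 2]
    four = [o for o in observations if o.red_focus_count == 4]
    if not two or not four:
        return "unclassified"
    frac_probasal = sum(o.green_on_probasal for o in four) / len(four)
    if frac_probasal >= min_fraction:
        return "probasal"
    frac_early_second = sum(o.green_focus_count >= 2 for o in two) / len(two)
    if frac_early_second >= min_fraction:
        return "before_duplication"
    if all(o.green_focus_count <= 1 for o in two) and any(
        o.green_focus_count >= 2 for o in four
    ):
        return "after_duplication"
    return "unclassified"


# ---------------------------------------------------------------------------
# reciprocal best hits
# ---------------------------------------------------------------------------


def read_hit_table(path: str | Path) -> tuple[list[HitRecord], int]:
    """Parse a 12-column tabular alignment file (query, subject, ..., E, bitscore).

    Malformed rows are skipped; their count is returned alongside the hits.
    """
    hits: list[HitRecord] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                skipped += 1
                continue
            try:
                hits.append(
                    HitRecord(
                        query_id=parts[0],
                        subject_id=parts[1],
                        e_value=float(parts[10]),
                        bitscore=float(parts[11]),
                    )
                )
            except ValueError:
                skipped += 1
    if skipped:
        warnings.warn(f"skipped {skipped} malformed alignment rows", stacklevel=2)
    return hits, skipped


def _best_hits(hits: Iterable[HitRecord]) -> dict[str, HitRecord]:
    """Best hit per query: lowest E-value, ties by higher bitscore then subject id."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (h.e_value, -h.bitscore, h.subject_id) < (
            cur.e_value,
            -cur.bitscore,
            cur.subject_id,
        ):
            best[h.query_id] = h
    return best


def reciprocal_best_hits(
    hits_ab: Iterable[HitRecord],
    hits_ba: Iterable[HitRecord],
    e_threshold: float = 1e-5,
) -> list[tuple[str, str]]:
    """Orthologue pairs (a, b): mutual best hits with both E-values <= threshold."""
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs: list[tuple[str, str]] = []
    for a, hit in sorted(best_ab.items()):
        b = hit.subject_id
        back = best_ba.get(b)
        if (
            back is not None
            and back.subject_id == a
            and hit.e_value <= e_threshold
            and back.e_value <= e_threshold
        ):
            pairs.append((a, b))
    return pairs


# ---------------------------------------------------------------------------
# class bookkeeping
# ---------------------------------------------------------------------------


def summarize_classes(records: list[CandidateRecord]) -> dict:
    """Exact counts per label on every classification axis.

    ``conserved_family_count`` additionally collapses conserved proteins by
    orthologue family (e.g. the three CEP164 paralogues count once), the
    way conserved components are usually tallied.
    """
    axes = {
        "gate_verdict": GATE_VERDICTS + ("unclassified",),
        "recruitment_class": RECRUITMENT_CLASSES,
        "flagellum_bias": FLAGELLUM_BIAS,
        "conservation": CONSERVATION,
        "rnai_phenotype": RNAI_PHENOTYPES,
    }
    summary: dict = {"total": len(records)}
    for axis, labels in axes.items():
        counts = {label: 0 for label in labels}
        for r in records:
            value = getattr(r, axis)
            if value not in counts:
                raise ValueError(f"record {r.protein_id}: unknown {axis} {value!r}")
            counts[value] += 1
        summary[axis] = counts
    conserved_families = {
        (r.orthologue_family or r.name)
        for r in records
        if r.conservation == "beyond_kinetoplastids"
    }
    summary["conserved_family_count"] = len(conserved_families)
    summary["flagellum_differential_count"] = sum(
        r.flagellum_bias in ("old_enriched", "new_enriched") for r in records
    )
    return summary


def helix_length(
    n_residues: int, pitch_angstrom: float = 5.4, residues_per_turn: float = 3.6
) -> float:
    """Length in nm of an ideal alpha-helix of ``n_residues`` amino acids.

    n / residues_per_turn turns, each rising one pitch: 1000 residues make
    a ~150 nm helical arm.
    """
    if n_residues < 0:
        raise ValueError("n_residues must be non-negative")
    if pitch_angstrom <= 0 or residues_per_turn <= 0:
        raise ValueError("pitch and residues per turn must be positive")
    return n_residues / residues_per_turn * pitch_angstrom / 10.0


# ---------------------------------------------------------------------------
# printed screen assignments
# ---------------------------------------------------------------------------


def load_screen_assignments() -> list[CandidateRecord]:
    """The 30 screened proteins with their published class assignments."""
    with resources.files("tfscreen.data").joinpath("tfp_assignments.csv").open() as fh:
        df = pd.read_csv(fh)
    records = []
    for _, row in df.iterrows():
        records.append(
            CandidateRecord(
                protein_id=row["protein_id"],
                name=row["name"],
                gate_verdict="included",
                recruitment_class=row["recruitment_class"],
                flagellum_bias=row["flagellum_bias"],
                conservation=row["conservation"],
                rnai_phenotype=row["rnai_phenotype"],
                orthologue_family=row["orthologue_family"] if pd.notna(row["orthologue_family"]) else "",
            )
        )
    return records
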