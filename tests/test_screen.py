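"""Screen decision logic: gate, recruitment, RBH orthology, class counts, helix arithmetic."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfscreen import (
    CellObservation,
    ControlBaselines,
    HitRecord,
    apply_inclusion_gate,
    classify_recruitment,
    helix_length,
    load_screen_assignments,
    reciprocal_best_hits,
    summarize_classes,
)
from tfscreen.geometry import ProteinMetrology
from tfscreen.screen import read_hit_table


def metrology(pid, distance, diameter, n=10):
    return ProteinMetrology(
        protein_id=pid,
        n_cells=n,
        mean_distance_nm=distance,
        sem_distance_nm=5.0,
        mean_pseudo_diameter_nm=diameter,
        sem_pseudo_diameter_nm=5.0,
    )


BASELINES = ControlBaselines(
    poc5_mean_distance_nm=250.0,
    tzp150_mean_distance_nm=450.0,
    bbp136_mean_pseudo_diameter_nm=100.0,
)


class TestInclusionGate:
    def test_one_proximal_candidate_removed_from_31(self):
        """A cohort of 31 candidates with exactly one inside the POC5 bound
        gates down to 30 included proteins; the width criterion removes none."""
        cands = [metrology(f"TFP{i}", 300.0 + i, 250.0) for i in range(30)]
        cands.append(metrology("proximal_one", 200.0, 250.0))
        verdicts = apply_inclusion_gate(cands, BASELINES)
        counts = {v: sum(x == v for x in verdicts.values()) for v in set(verdicts.values())}
        assert counts == {"included": 30, "excluded_proximal": 1}

    def test_each_exclusion_branch(self):
        verdicts = apply_inclusion_gate(
            [
                metrology("prox", 200.0, 250.0),
                metrology("dist", 500.0, 250.0),
                metrology("narrow", 300.0, 80.0),
                metrology("ok", 300.0, 250.0),
            ],
            BASELINES,
        )
        assert verdicts == {
            "prox": "excluded_proximal",
            "dist": "excluded_distal",
            "narrow": "excluded_narrow",
            "ok": "included",
        }

    def test_boundary_values_are_excluded(self):
        verdicts = apply_inclusion_gate(
            [metrology("at_poc5", 250.0, 250.0), metrology("at_bbp", 300.0, 100.0)],
            BASELINES,
        )
        assert verdicts["at_poc5"] == "excluded_proximal"
        assert verdicts["at_bbp"] == "excluded_narrow"

    def test_missing_metrology_unclassified(self):
        with pytest.warns(UserWarning):
            verdicts = apply_inclusion_gate(
                [metrology("nan", float("nan"), 250.0)], BASELINES
            )
        assert verdicts["nan"] == "unclassified"

    def test_partition_covers_all_candidates(self):
        rng = np.random.default_rng(0)
        cands = [
            metrology(f"P{i}", rng.uniform(100, 600), rng.uniform(50, 400))
            for i in range(40)
        ]
        verdicts = apply_inclusion_gate(cands, BASELINES)
        assert len(verdicts) == 40
        assert set(verdicts.values()) <= {
            "included",
            "excluded_proximal",
            "excluded_distal",
            "excluded_narrow",
        }

    def test_baseline_ordering_enforced(self):
        with pytest.raises(ValueError):
            ControlBaselines(500.0, 400.0, 100.0)


def obs(red, green, probasal=False):
    obs.counter = getattr(obs, "counter", 0) + 1
    return CellObservation(obs.counter, red, green, probasal)


class TestRecruitment:
    def test_second_focus_before_duplication(self):
        observations = [obs(2, 2) for _ in range(10)] + [obs(4, 2) for _ in range(5)]
        assert classify_recruitment(observations) == "before_duplication"

    def test_second_focus_only_after_duplication(self):
        observations = [obs(2, 1) for _ in range(10)] + [obs(4, 2) for _ in range(5)]
        assert classify_recruitment(observations) == "after_duplication"

    def test_probasal_at_one_third_fraction(self):
        s_cells = [obs(4, 4, probasal=(i % 3 == 0)) for i in range(9)]
        observations = [obs(2, 2) for _ in range(6)] + s_cells
        assert classify_recruitment(observations, min_fraction=0.25) == "probasal"

    def test_single_stage_unclassified(self):
        assert classify_recruitment([obs(2, 1) for _ in range(12)]) == "unclassified"

    def test_too_few_observations_unclassified(self):
        assert classify_recruitment([obs(2, 2), obs(4, 2)]) == "unclassified"

    def test_order_free(self):
        observations = [obs(2, 2) for _ in range(10)] + [obs(4, 2) for _ in range(5)]
        rng = np.random.default_rng(1)
        for _ in range(5):
            shuffled = list(observations)
            rng.shuffle(shuffled)
            assert classify_recruitment(shuffled) == classify_recruitment(observations)


def brute_force_rbh(hits_ab, hits_ba, e_threshold=1e-5):
    """Independent oracle: test every (a, b) pair for mutual-best status."""

    def is_best(hits, query, subject):
        mine = [h for h in hits if h.query_id == query]
        if not mine:
            return False
        best = sorted(mine, key=lambda h: (h.e_value, -h.bitscore, h.subject_id))[0]
        return best.subject_id == subject

    pairs = set()
    queries = {h.query_id for h in hits_ab}
    subjects = {h.subject_id for h in hits_ab}
    for a in queries:
        for b in subjects:
            ab = [h for h in hits_ab if h.query_id == a and h.subject_id == b]
            ba = [h for h in hits_ba if h.query_id == b and h.subject_id == a]
            if not ab or not ba:
                continue
            e_ab = min(h.e_value for h in ab)
            e_ba = min(h.e_value for h in ba)
            if is_best(hits_ab, a, b) and is_best(hits_ba, b, a):
                if e_ab <= e_threshold and e_ba <= e_threshold:
                    pairs.add((a, b))
    return sorted(pairs)


class TestReciprocalBestHits:
    def test_empty_tables(self):
        assert reciprocal_best_hits([], []) == []

    def test_toy_four_gene_tables(self):
        ab = [
            HitRecord("a1", "b1", 1e-30, 200.0),
            HitRecord("a1", "b2", 1e-8, 80.0),
            HitRecord("a2", "b1", 1e-9, 90.0),
        ]
        ba = [
            HitRecord("b1", "a1", 1e-28, 190.0),
            HitRecord("b2", "a2", 1e-7, 70.0),
        ]
        pairs = reciprocal_best_hits(ab, ba)
        assert pairs == [("a1", "b1")]
        assert pairs == brute_force_rbh(ab, ba)

    def test_threshold_rejects_weak_reciprocal_pair(self):
        ab = [HitRecord("a1", "b1", 1e-4, 50.0)]
        ba = [HitRecord("b1", "a1", 1e-30, 200.0)]
        assert reciprocal_best_hits(ab, ba) == []

    def test_matches_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            na, nb = rng.integers(2, 21, size=2)
            ab, ba = [], []
            for i in range(na):
                for j in rng.choice(nb, size=rng.integers(1, nb + 1), replace=False):
                    ab.append(
                        HitRecord(f"a{i}", f"b{j}", 10.0 ** rng.uniform(-40, 0), float(rng.integers(40, 300)))
                    )
            for j in range(nb):
                for i in rng.choice(na, size=rng.integers(1, na + 1), replace=False):
                    ba.append(
                        HitRecord(f"b{j}", f"a{i}", 10.0 ** rng.uniform(-40, 0), float(rng.integers(40, 300)))
                    )
            assert reciprocal_best_hits(ab, ba) == brute_force_rbh(ab, ba)

    def test_each_id_in_at_most_one_pair(self):
        ab = [HitRecord("a1", "b1", 1e-20, 100.0), HitRecord("a2", "b1", 1e-25, 120.0)]
        ba = [HitRecord("b1", "a2", 1e-22, 110.0)]
        pairs = reciprocal_best_hits(ab, ba)
        flat = [x for pair in pairs for x in pair]
        assert len(flat) == len(set(flat))

    def test_malformed_rows_skipped_with_count(self, tmp_path):
        path = tmp_path / "hits.tsv"
        good = "a1\tb1\t90.0\t100\t5\t0\t1\t100\t1\t100\t1e-30\t200\n"
        path.write_text(good + "broken row\n" + "a2\tb2\tx\t.\t.\t.\t.\t.\t.\t.\tnot_a_number\t50\n")
        with pytest.warns(UserWarning, match="skipped 2"):
            hits, skipped = read_hit_table(path)
        assert skipped == 2 and len(hits) == 1 and hits[0].query_id == "a1"


class TestClassCounts:
    def test_published_assignment_counts(self):
        """The screen's published per-protein assignments: 30 proteins, 15
        recruited before and 13 after duplication (2 to probasal bodies), six
        needed for flagellum assembly, three for normal length, five with a
        new/old-flagellum intensity differential and nine conserved families
        beyond the kinetoplastids."""
        records = load_screen_assignments()
        summary = summarize_classes(records)
        assert summary["total"] == 30
        assert summary["recruitment_class"]["before_duplication"] == 15
        assert summary["recruitment_class"]["after_duplication"] == 13
        assert summary["recruitment_class"]["probasal"] == 2
        assert summary["rnai_phenotype"]["assembly_defect"] == 6
        assert summary["rnai_phenotype"]["length_defect"] == 3
        assert summary["flagellum_differential_count"] == 5
        assert summary["conserved_family_count"] == 9
        # totals conserved on every axis
        for axis in ("recruitment_class", "flagellum_bias", "conservation", "rnai_phenotype"):
            assert sum(summary[axis].values()) == 30

    def test_empty_input_all_zero(self):
        summary = summarize_classes([])
        assert summary["total"] == 0
        assert all(v == 0 for v in summary["recruitment_class"].values())

    def test_one_record_per_class(self):
        from tfscreen import CandidateRecord

        records = [
            CandidateRecord("p1", "p1", recruitment_class="before_duplication"),
            CandidateRecord("p2", "p2", recruitment_class="after_duplication"),
            CandidateRecord("p3", "p3", recruitment_class="probasal"),
        ]
        summary = summarize_classes(records)
        for label in ("before_duplication", "after_duplication", "probasal"):
            assert summary["recruitment_class"][label] == 1


class TestHelixLength:
    @pytest.mark.parametrize(
        "n, expected",
        [(1000, 150.0), (0, 0.0), (360, 54.0)],
    )
    def test_known_values(self, n, expected):
        assert helix_length(n) == pytest.approx(expected, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(a=st.integers(0, 5000), b=st.integers(0, 5000))
    def test_linear_in_residues(self, a, b):
        assert helix_length(a + b) == pytest.approx(helix_length(a) + helix_length(b))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            helix_length(-1)
        with pytest.raises(ValueError):
            helix_length(100, pitch_angstrom=0.0)
        with pytest.raises(ValueError):
            helix_length(100, residues_per_turn=-3.6)
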