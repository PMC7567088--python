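"""Synthetic paired-cohort generator and simulated detector.

The checks here validate the generator against its own closed forms:
marginal detection frequency equals the configured sensitivity, the pair
copula reproduces the independence limits PPA -> 100*s and
CPPA -> 100*s/(2-s), perfect correlation removes discordance, and the
recorded ground-truth pair outcomes are exactly what the matching
pipeline recomputes from the emitted boxes.
"""

import filecmp

import numpy as np
import pytest

from paircad import (
    SimulationConfig,
    end_to_end_fixture,
    evaluate_reproducibility,
    generate_cohort,
    simulate_detector,
)
from paircad import io_formats as iof


def small_config(**kw):
    base = dict(
        pair_counts={"N": 30, "C": 10},
        sensitivity={"N": 0.8, "C": 0.7},
        extra_lesions_mean={"N": 0.2, "C": 0.3},
        n_normal_exams=15,
        seed=11,
    )
    base.update(kw)
    return SimulationConfig(**base)


def agreement_at_zero_cutoff(cohort, label="N"):
    res = evaluate_reproducibility(
        [p for p in cohort.pairs if p.class_label == label],
        cohort.lesions_by_exam(), cohort.detections_by_exam(), cutoff=0.0)
    return res[label]


class TestGenerateCohort:
    def test_default_design_has_248_pairs(self):
        cohort = generate_cohort(SimulationConfig(seed=3))
        tally = {}
        for p in cohort.pairs:
            tally[p.class_label] = tally.get(p.class_label, 0) + 1
        assert tally == {"N": 121, "C": 28, "IO": 12, "PLE": 67, "PN": 20}
        assert len(cohort.pairs) == 248

    def test_same_seed_reproduces_exactly(self):
        a = generate_cohort(small_config())
        b = generate_cohort(small_config())
        assert a.exams == b.exams and a.lesions == b.lesions and a.pairs == b.pairs

    def test_zero_jitter_copies_boxes_to_followup(self):
        cohort = generate_cohort(small_config(jitter_px=0.0))
        by_exam = cohort.lesions_by_exam()
        for pair in cohort.pairs:
            init = {l.lesion_id: l.box for l in by_exam[pair.initial_exam_id]}
            fu = {l.lesion_id: l.box for l in by_exam[pair.followup_exam_id]}
            assert init == fu

    def test_boxes_lie_within_image(self):
        cfg = small_config(jitter_px=40.0)
        cohort = generate_cohort(cfg)
        for l in cohort.lesions:
            assert l.box.x_min >= 0 and l.box.y_min >= 0
            assert l.box.x_max <= cfg.image_width
            assert l.box.y_max <= cfg.image_height

    def test_oversized_boxes_rejected(self):
        with pytest.raises(ValueError, match="cannot fit"):
            SimulationConfig(box_size_range=(50.0, 1200.0)).validate()


class TestSimulateDetector:
    def test_perfect_detector_gives_full_agreement(self):
        cfg = small_config(sensitivity={"N": 1.0, "C": 1.0}, fp_rate=0.0)
        cohort = simulate_detector(generate_cohort(cfg), cfg)
        assert all(a and b for a, b in cohort.pair_outcomes.values())
        res = agreement_at_zero_cutoff(cohort)
        assert res.ppa == res.cppa == 100.0

    def test_perfect_correlation_removes_discordance(self):
        """rho = 1 shares the latent detectability exactly, so a lesion is
        found on both exams or neither: the b and c cells are empty."""
        cfg = small_config(pair_counts={"N": 200}, sensitivity={"N": 0.7},
                          extra_lesions_mean={"N": 0.0},
                          pair_correlation=1.0, fp_rate=0.0)
        cohort = simulate_detector(generate_cohort(cfg), cfg)
        res = agreement_at_zero_cutoff(cohort)
        assert res.counts.b == 0 and res.counts.c == 0
        assert res.counts.a > 0
        assert res.ppa == res.cppa == 100.0

    def test_independent_exams_recover_closed_forms(self):
        """At rho=0 each exam detects a lesion independently with s=0.8, so
        PPA -> 100*s = 80 and CPPA -> 100*s/(2-s) = 66.67 as pairs grow."""
        cfg = SimulationConfig(
            pair_counts={"N": 2000}, sensitivity={"N": 0.8},
            extra_lesions_mean={"N": 0.0}, n_normal_exams=0,
            pair_correlation=0.0, fp_rate=0.0, seed=5)
        cohort = simulate_detector(generate_cohort(cfg), cfg)
        res = agreement_at_zero_cutoff(cohort)
        assert res.ppa == pytest.approx(80.0, abs=2.0)
        assert res.cppa == pytest.approx(100 * 0.8 / 1.2, abs=2.0)

    def test_marginal_detection_frequency_matches_sensitivity(self):
        """Per-lesion, per-exam detection frequency converges to s
        (binomial check at 2000 lesions per exam side)."""
        cfg = SimulationConfig(
            pair_counts={"N": 2000}, sensitivity={"N": 0.65},
            extra_lesions_mean={"N": 0.0}, n_normal_exams=0,
            pair_correlation=0.4, fp_rate=0.0, seed=9)
        cohort = simulate_detector(generate_cohort(cfg), cfg)
        n = len(cohort.pairs)
        freq_init = sum(a for a, _ in cohort.pair_outcomes.values()) / n
        freq_fu = sum(b for _, b in cohort.pair_outcomes.values()) / n
        # 3-sigma binomial band: sqrt(.65*.35/2000) ~ 0.0107
        assert freq_init == pytest.approx(0.65, abs=0.033)
        assert freq_fu == pytest.approx(0.65, abs=0.033)

    def test_agreement_monotone_in_pair_correlation(self):
        ppas = []
        for rho in (0.0, 0.5, 1.0):
            cfg = SimulationConfig(
                pair_counts={"N": 600}, sensitivity={"N": 0.8},
                extra_lesions_mean={"N": 0.0}, n_normal_exams=0,
                pair_correlation=rho, fp_rate=0.0, seed=21)
            cohort = simulate_detector(generate_cohort(cfg), cfg)
            ppas.append(agreement_at_zero_cutoff(cohort).ppa)
        assert ppas[0] <= ppas[1] <= ppas[2]

    def test_false_alarm_rate_matches_poisson_mean(self):
        """With sensitivity 0 every detection is a false alarm; the per-exam
        count averages the configured Poisson rate."""
        cfg = SimulationConfig(
            pair_counts={"N": 100}, sensitivity={"N": 0.0},
            extra_lesions_mean={"N": 0.0}, n_normal_exams=100,
            fp_rate=5.0, seed=13)
        cohort = simulate_detector(generate_cohort(cfg), cfg)
        n_exams = len(cohort.exams)
        n_dets = len(cohort.detections_initial) + len(cohort.detections_followup)
        assert n_dets / n_exams == pytest.approx(5.0, abs=0.5)

    def test_recorded_outcomes_equal_pipeline_recomputation(self):
        """The generator's ground-truth pair outcomes are exactly what
        matching at cutoff 0 recomputes from the emitted boxes."""
        cfg = small_config(fp_rate=2.0)
        cohort = simulate_detector(generate_cohort(cfg), cfg)
        les_by, det_by = cohort.lesions_by_exam(), cohort.detections_by_exam()
        from paircad import exam_outcome, match_exam

        for pair in cohort.pairs:
            recomputed = []
            for exam_id in (pair.initial_exam_id, pair.followup_exam_id):
                ms = match_exam(
                    [d for d in det_by.get(exam_id, [])
                     if d.class_label == pair.class_label],
                    [l for l in les_by.get(exam_id, [])
                     if l.class_label == pair.class_label],
                    cutoff=0.0)
                recomputed.append(exam_outcome(ms) == "detected")
            assert tuple(recomputed) == cohort.pair_outcomes[pair.pair_id]

    def test_tp_boxes_overlap_their_lesion_above_threshold(self):
        from paircad.matching import iou

        cfg = small_config(fp_rate=0.0)
        cohort = simulate_detector(generate_cohort(cfg), cfg)
        les_by = cohort.lesions_by_exam()
        for d in cohort.detections_initial + cohort.detections_followup:
            best = max(iou(d.box, l.box) for l in les_by[d.exam_id])
            assert 0.5 < best <= 0.96


class TestEndToEndFixture:
    def test_fixture_is_complete_and_self_consistent(self, tmp_path):
        cfg = small_config(fp_rate=1.0)
        paths = end_to_end_fixture(cfg, tmp_path / "fix")
        exams = iof.read_exams(paths["exams"])
        pairs = iof.read_pair_manifest(paths["pairs"], exams)
        lesions = iof.read_lesions(paths["lesions"])
        dets = (iof.read_detections(paths["detections_initial"])
                + iof.read_detections(paths["detections_followup"]))
        les_by, det_by = {}, {}
        for l in lesions:
            les_by.setdefault(l.exam_id, []).append(l)
        for d in dets:
            det_by.setdefault(d.exam_id, []).append(d)
        res = evaluate_reproducibility(pairs, les_by, det_by, cutoff=0.0)

        # the recorded outcome table reproduces the recomputed a/b/c/d
        recorded = {}
        for line in paths["outcomes"].read_text().splitlines()[1:]:
            pid, a, b = line.split(",")
            recorded[pid] = (a == "1", b == "1")
        for label in ("N", "C"):
            cell = {"a": 0, "b": 0, "c": 0, "d": 0}
            for p in pairs:
                if p.class_label != label:
                    continue
                i, f = recorded[p.pair_id]
                cell[{(1, 1): "a", (1, 0): "b", (0, 1): "c", (0, 0): "d"}
                     [(int(i), int(f))]] += 1
            counts = res[label].counts
            assert (counts.a, counts.b, counts.c, counts.d) == (
                cell["a"], cell["b"], cell["c"], cell["d"])

    def test_same_seed_writes_identical_files(self, tmp_path):
        a = end_to_end_fixture(small_config(), tmp_path / "a")
        b = end_to_end_fixture(small_config(), tmp_path / "b")
        for key in a:
            assert filecmp.cmp(a[key], b[key], shallow=False), key
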