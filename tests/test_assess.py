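"""Session assessment: sequence integrity, grading, progress tracking."""

import itertools

import numpy as np
import pytest

from baduanjin import synth
from baduanjin.assess import SessionReport, assess_session, detect_sequence_errors, track_progress
from baduanjin.classify import AccuracyGrade, MotionClassifier


class TestDetectSequenceErrors:
    def test_identical_sequences_clean(self):
        missing, order = detect_sequence_errors([1, 2, 3, 4], [1, 2, 3, 4])
        assert missing == set() and order == []

    def test_missing_motion_three(self):
        missing, order = detect_sequence_errors([1, 2, 4, 5, 6, 7, 8], list(range(1, 9)))
        assert missing == {3}
        assert order == []

    def test_adjacent_transposition(self):
        missing, order = detect_sequence_errors([2, 1, 3], [1, 2, 3])
        assert missing == set()
        assert order == [(1, 2)]

    def test_transposition_later_in_sequence(self):
        missing, order = detect_sequence_errors([1, 2, 4, 3], [1, 2, 3, 4])
        assert missing == set()
        assert order == [(3, 4)]

    def test_empty_recognized_all_missing(self):
        missing, order = detect_sequence_errors([], [1, 2, 3])
        assert missing == {1, 2, 3} and order == []

    def test_unexpected_classes_ignored_for_order(self):
        missing, order = detect_sequence_errors([1, 7, 2, 3], [1, 2, 3])
        assert missing == set() and order == []

    def test_duplicate_expected_rejected(self):
        with pytest.raises(ValueError):
            detect_sequence_errors([1, 2], [1, 1, 2])

    def test_matches_brute_force_edit_oracle(self):
        """Dropping any class subset and applying any disjoint adjacent swaps
        to an expected sequence of length <= 5 must be recovered exactly."""
        for L in (2, 3, 4, 5):
            expected = list(range(1, L + 1))
            for r in range(L):
                for dels in itertools.combinations(expected, r):
                    seq = [c for c in expected if c not in dels]
                    adj = list(zip(seq, seq[1:]))
                    for k in range(len(adj) + 1):
                        for swaps in itertools.combinations(adj, k):
                            if any(
                                s1[1] == s2[0] for s1 in swaps for s2 in swaps if s1 != s2
                            ):
                                continue  # overlapping swaps are ambiguous
                            rec = list(seq)
                            for a, b in swaps:
                                i, j = rec.index(a), rec.index(b)
                                rec[i], rec[j] = rec[j], rec[i]
                            missing, order = detect_sequence_errors(rec, expected)
                            assert missing == set(dels), (expected, rec)
                            assert sorted(order) == sorted(swaps), (expected, rec)

    def test_locality_removing_one_class(self):
        expected = list(range(1, 9))
        clean_missing, _ = detect_sequence_errors(expected, expected)
        for c in expected:
            rec = [x for x in expected if x != c]
            missing, order = detect_sequence_errors(rec, expected)
            assert missing == clean_missing | {c}
            assert order == []


@pytest.fixture(scope="module")
def fitted_models():
    """Recognizer (classes 1-4) and grader trained on a small synthetic set."""
    samples = synth.make_labeled_dataset(2, classes=(1, 2, 3, 4), frames=40, seed=5)
    motions = [s.motion for s in samples]
    recognizer = MotionClassifier(method="knn", seed=0).fit(
        motions, [s.motion_class for s in samples]
    )
    grader = MotionClassifier(method="knn", seed=0).fit(
        motions, [int(s.grade) for s in samples]
    )
    return recognizer, grader


@pytest.fixture(scope="module")
def templates():
    return {c: synth.make_template(c, frames=40, seed=5) for c in (1, 2, 3, 4)}


class TestAssessSession:
    def test_complete_session_clean(self, fitted_models, templates):
        recognizer, grader = fitted_models
        captured = synth.make_session([1, 2, 3, 4], profile=synth.EXPERIENCED, frames=40, seed=5)
        report = assess_session(captured, recognizer, grader, templates, [1, 2, 3, 4])
        assert report.missing == set()
        assert report.order_errors == []
        assert len(report.grades) == 4
        assert len(report.distances) == 4
        assert all(np.isfinite(report.distances))

    def test_dropped_class_reported_missing(self, fitted_models, templates):
        recognizer, grader = fitted_models
        captured = synth.make_session(
            [1, 2, 3, 4], dropouts={3}, profile=synth.EXPERIENCED, frames=40, seed=6, template_seed=5
        )
        report = assess_session(captured, recognizer, grader, templates, [1, 2, 3, 4])
        assert report.missing == {3}

    def test_swapped_pair_reported(self, fitted_models, templates):
        recognizer, grader = fitted_models
        captured = synth.make_session(
            [1, 2, 3, 4], swaps=[(3, 4)], profile=synth.EXPERIENCED, frames=40, seed=7, template_seed=5
        )
        report = assess_session(captured, recognizer, grader, templates, [1, 2, 3, 4])
        assert report.missing == set()
        assert report.order_errors == [(3, 4)]

    def test_unfitted_models_rejected(self, templates):
        with pytest.raises(RuntimeError):
            assess_session([], MotionClassifier(), MotionClassifier(), templates, [1, 2])

    def test_report_serializes(self, fitted_models, templates):
        import json

        recognizer, grader = fitted_models
        captured = synth.make_session([1, 2], profile=synth.EXPERIENCED, frames=40, seed=8, template_seed=5)
        report = assess_session(captured, recognizer, grader, templates, [1, 2])
        blob = json.dumps(report.to_dict())
        assert "recognized_sequence" in blob


def _dummy_report(lesson, expected, recognized):
    grades = [AccuracyGrade.PASS] * len(recognized)
    missing, order = detect_sequence_errors(recognized, expected)
    return SessionReport(
        subject_id="s1",
        lesson=lesson,
        recognized_sequence=recognized,
        expected_sequence=expected,
        grades=grades,
        missing=missing,
        order_errors=order,
        distances=[1.0] * len(recognized),
    )


#: The eight-week course schedule: motions 1-3 every lesson, 4-6 from
#: lesson 4, 7-8 from lesson 6 — 45 performed motions for a complete student.
COURSE = {
    1: [1, 2, 3], 2: [1, 2, 3], 3: [1, 2, 3],
    4: [1, 2, 3, 4, 5, 6], 5: [1, 2, 3, 4, 5, 6],
    6: list(range(1, 9)), 7: list(range(1, 9)), 8: list(range(1, 9)),
}


class TestTrackProgress:
    def test_complete_course_45_rows(self):
        reports = [_dummy_report(l, exp, list(exp)) for l, exp in COURSE.items()]
        table = track_progress(reports)
        assert len(table) == 45
        assert table["performed"].all()
        assert set(table.columns) == {"subject", "lesson", "motion", "performed", "grade", "distance"}

    def test_one_missing_motion_flagged(self):
        reports = []
        for l, exp in COURSE.items():
            rec = [c for c in exp if not (l == 4 and c == 3)]  # forgot motion 3 in lesson 4
            reports.append(_dummy_report(l, exp, rec))
        table = track_progress(reports)
        assert len(table) == 45
        assert table["performed"].sum() == 44
        flagged = table[~table["performed"]]
        assert flagged.iloc[0]["lesson"] == 4 and flagged.iloc[0]["motion"] == 3
        assert flagged.iloc[0]["grade"] is None

    def test_empty_reports_empty_table(self):
        assert len(track_progress([])) == 0
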