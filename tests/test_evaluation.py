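"""Event scoring, workload scoring, macro-averaging, TSCV planning,
and recursive feature elimination."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from weareeg.core_io import Event, EventList, Recording
from weareeg.evaluation import (ConfusionCounts, EventScore,
                                aggregate_subjects, f1_score, gmean_percent,
                                rfecv_select, score_cwm, score_events,
                                tscv_split)

# Published per-subject two-channel (frontotemporal wearable montage)
# benchmark rows on the CHB-MIT corpus, used as *inputs* to the
# macro-average arithmetic.
CHBMIT_2CH_SENS = [1.00, 0.50, 1.00, 0.33, 1.00, 0.00, 0.50, 1.00, 1.00,
                   1.00, 1.00, 0.94, 0.27, 0.25, 0.68, 0.00, 0.00, 0.40,
                   1.00, 0.43, 0.00, 1.00, 1.00, 1.00]
CHBMIT_2CH_FAR = [5.41, 0.00, 0.73, 0.17, 2.91, 0.00, 0.00, 4.80, 0.00,
                  0.00, 0.00, 14.4, 0.00, 0.00, 2.83, 0.00, 6.00, 0.00,
                  0.00, 2.73, 1.74, 1.72, 1.15, 11.8]


class TestScoreEvents:
    def test_f1_from_published_per_subject_metrics(self):
        assert f1_score(1.00, 0.75) == pytest.approx(0.86, abs=0.005)
        assert f1_score(1.00, 0.38) == pytest.approx(0.56, abs=0.01)

    def test_far_direct(self):
        ref = EventList()
        hyp = EventList([Event(10, 20, "alarm"), Event(100, 110, "alarm")])
        s = score_events(ref, hyp, total_time_h=24.0)
        assert s.far_per_day == pytest.approx(2.0)
        assert s.sens is None  # no reference events: not applicable

    def test_any_overlap_matching(self):
        ref = EventList([Event(100, 160), Event(400, 460)])
        hyp = EventList([Event(150, 170, "alarm"), Event(600, 610, "alarm")])
        s = score_events(ref, hyp, total_time_h=1.0)
        assert (s.tp, s.fn, s.fp) == (1, 1, 1)
        assert s.sens == pytest.approx(0.5)
        assert s.prec == pytest.approx(0.5)

    def test_nonpositive_total_time_rejected(self):
        with pytest.raises(ValueError):
            score_events(EventList([Event(0, 1)]), EventList(),
                         total_time_h=0.0)

    @given(st.lists(st.tuples(st.floats(0, 10000), st.floats(1, 100)),
                    min_size=1, max_size=10))
    def test_self_match_is_perfect(self, raw):
        ref = EventList(Event(on, on + d) for on, d in raw)
        s = score_events(ref, ref, total_time_h=10.0)
        assert s.sens == 1.0
        assert s.prec == 1.0
        assert s.far_per_day == 0.0

    @given(st.floats(0.05, 1.0), st.floats(0.05, 1.0))
    def test_f1_symmetric_and_bounded(self, a, b):
        assert f1_score(a, b) == pytest.approx(f1_score(b, a))
        assert f1_score(a, b) <= max(a, b) + 1e-12


class TestAggregate:
    def test_published_sensitivity_row_macro_average(self):
        scores = [EventScore(s, None, None, None) for s in CHBMIT_2CH_SENS]
        assert aggregate_subjects(scores).sens == pytest.approx(0.64,
                                                                abs=0.005)

    def test_published_far_row_macro_average(self):
        scores = [EventScore(None, None, None, f) for f in CHBMIT_2CH_FAR]
        assert aggregate_subjects(scores).far_per_day == pytest.approx(
            2.35, abs=0.01)

    def test_single_subject_identity(self):
        s = EventScore(0.5, 0.7, 0.58, 1.2)
        agg = aggregate_subjects([s])
        assert (agg.sens, agg.prec, agg.f1, agg.far_per_day) == (
            0.5, 0.7, 0.58, 1.2)

    def test_identical_subjects_average_to_themselves(self):
        s = EventScore(0.8, 0.6, 0.69, 2.0)
        agg = aggregate_subjects([s] * 5)
        assert agg.sens == pytest.approx(0.8)

    def test_not_applicable_excluded_not_zeroed(self):
        scores = [EventScore(1.0, 1.0, 1.0, 0.0),
                  EventScore(None, 1.0, None, 0.0)]
        assert aggregate_subjects(scores).sens == 1.0


class TestCWMScore:
    def test_gmean_of_published_testing_rows(self):
        assert gmean_percent(82.9, 66.1) == pytest.approx(74.0, abs=0.05)
        assert gmean_percent(73.3, 87.7) == pytest.approx(80.2, abs=0.05)

    def test_perfect_classifier(self):
        s = score_cwm(ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
        assert s.acc == s.spec == s.gmean == 100.0

    def test_counts_to_scores(self):
        s = score_cwm(ConfusionCounts(tp=40, tn=30, fp=20, fn=10))
        assert s.acc == pytest.approx(70.0)
        assert s.sens == pytest.approx(80.0)
        assert s.spec == pytest.approx(60.0)
        assert s.gmean == pytest.approx(np.sqrt(80 * 60))

    def test_zero_denominator_not_applicable(self):
        s = score_cwm(ConfusionCounts(tp=0, tn=10, fp=0, fn=0))
        assert s.sens is None
        assert s.gmean is None


def _record(duration_s, events=(), fs=32.0):
    n = int(duration_s * fs)
    ev = EventList(Event(on, off, "seizure") for on, off in events)
    return Recording(np.zeros((1, n)), fs, ["F7T7"], montage="bipolar",
                     events=ev)


class TestTSCV:
    def test_boundary_and_fold_count_on_continuous_record(self):
        rec = _record(10 * 3600, events=[(2 * 3600, 2 * 3600 + 60)])
        plan = tscv_split([rec], slice_h=1.0)
        assert plan.folds[0].train_span == (0.0, 5 * 3600.0)
        assert len(plan.folds) == 5

    def test_late_seizure_pushes_warmup_boundary(self):
        rec = _record(10 * 3600, events=[(8.2 * 3600, 8.2 * 3600 + 60)])
        plan = tscv_split([rec], slice_h=1.0)
        assert plan.folds[0].train_span[1] == pytest.approx(9 * 3600.0)
        assert len(plan.folds) == 1

    def test_insufficient_data_skipped_with_report(self):
        plan = tscv_split([_record(4 * 3600, events=[(100, 160)])])
        assert not plan
        assert "insufficient warm-up" in plan.skipped_reason

    def test_no_seizure_anywhere_skipped(self):
        plan = tscv_split([_record(3600) for _ in range(10)])
        assert not plan
        assert "seizure" in plan.skipped_reason

    def test_per_record_slices_cover_post_warmup_exactly_once(self):
        recs = [_record(3600, events=[(100, 160)] if k == 0 else ())
                for k in range(8)]
        plan = tscv_split(recs)
        spans = [f.test_span for f in plan.folds]
        assert spans[0][0] == pytest.approx(5 * 3600.0)
        assert spans[-1][1] == pytest.approx(8 * 3600.0)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert a1 == pytest.approx(b0)

    def test_causality_every_fold(self):
        recs = [_record(2 * 3600, events=[(100, 160)]) for _ in range(5)]
        plan = tscv_split(recs)
        for fold in plan.folds:
            assert fold.test_span[0] >= fold.train_span[1]


class TestRFECV:
    def _planted(self, rng, n=240, informative=10, noise=20):
        y = (np.arange(n) % 2).astype(int)
        X = rng.normal(size=(n, informative + noise))
        X[y == 1, :informative] += 1.5
        return X, y

    def test_planted_signal_recovery(self, rng):
        X, y = self._planted(rng)
        sel = rfecv_select(X, y, folds=10, n_trees=25, seed=0)
        assert np.intersect1d(sel, np.arange(10)).size >= 8

    def test_target_size_elimination(self, rng):
        X, y = self._planted(rng, n=120, informative=10, noise=46)
        sel = rfecv_select(X, y, folds=10, target_size=18, seed=0)
        assert len(sel) == 18

    def test_all_noise_features_near_chance(self, rng):
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.model_selection import cross_val_score

        n = 120
        y = (np.arange(n) % 2).astype(int)
        X = np.random.default_rng(11).normal(size=(n, 12))
        sel = rfecv_select(X, y, folds=6, n_trees=25, seed=0)
        clf = RandomForestClassifier(25, random_state=0)
        acc = cross_val_score(clf, X[:, sel], y, cv=6).mean()
        assert 0.3 <= acc <= 0.7  # chance-level band

    def test_too_many_folds_rejected(self, rng):
        with pytest.raises(ValueError):
            rfecv_select(rng.normal(size=(10, 3)), np.arange(10) % 2,
                         folds=30)

    def test_deterministic_given_seed(self, rng):
        X, y = self._planted(rng, n=120, informative=5, noise=10)
        a = rfecv_select(X, y, folds=5, seed=3)
        b = rfecv_select(X, y, folds=5, seed=3)
        assert np.array_equal(a, b)
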