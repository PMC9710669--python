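"""FDD-ES core: drift events, model spawning, best-k selection, soft voting,
the online loop and the final union biomarker model."""

import numpy as np
import pytest

import biodrift as bd
from biodrift.ensemble import (BatchRandomForestLearner, DriftEvent,
                               FDDEnsemble, detect_feature_drift, soft_vote)
from biodrift.prequential import ConfusionMatrix

from conftest import make_names


def fs(*names, origin=""):
    return bd.FeatureSet(names, origin=origin)


class TestDetectFeatureDrift:
    def test_selection_within_known_panel_is_silent(self):
        assert detect_feature_drift(fs("a", "b"), fs("a", "b", "c"),
                                    fs()) is None

    def test_single_novel_gene_fires(self):
        sel = fs(*[f"g{i}" for i in range(1, 11)])
        known = fs(*[f"g{i}" for i in range(1, 10)])
        ev = detect_feature_drift(sel, known, fs())
        assert ev is not None
        assert list(ev.novel) == ["g10"]

    def test_cumulative_memory_suppresses_reselection(self):
        """A second chunk re-selecting only first-chunk genes fires nothing."""
        known = fs("k1", "k2")
        first = fs("k1", "n1", "n2")
        ev1 = detect_feature_drift(first, known, fs())
        assert list(ev1.novel) == ["n1", "n2"]
        union = fs().union(ev1.novel)
        ev2 = detect_feature_drift(fs("n2", "k2", "n1"), known, union)
        assert ev2 is None

    def test_event_invariants(self):
        with pytest.raises(ValueError):
            DriftEvent(0, fs("a"), fs())
        with pytest.raises(ValueError):
            DriftEvent(0, fs("a"), fs("b"))

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            detect_feature_drift(fs(), fs("a"), fs())


class TestSoftVote:
    class _Stub:
        def __init__(self, dist):
            self.dist = np.asarray(dist, dtype=float)

        def predict_proba(self, x):
            return self.dist

    def test_single_model_identity(self):
        m = self._Stub([0.7, 0.3])
        np.testing.assert_allclose(soft_vote([m], np.zeros(1)), [0.7, 0.3])

    def test_opposed_votes_tie_to_lowest_class(self):
        dist = soft_vote([self._Stub([1, 0]), self._Stub([0, 1])], np.zeros(1))
        np.testing.assert_allclose(dist, [0.5, 0.5])
        assert int(np.argmax(dist)) == 0

    def test_three_model_average(self):
        models = [self._Stub([0.6, 0.4]), self._Stub([0.6, 0.4]),
                  self._Stub([0.0, 1.0])]
        dist = soft_vote(models, np.zeros(1))
        np.testing.assert_allclose(dist, [0.4, 0.6])
        assert int(np.argmax(dist)) == 1

    def test_empty_model_list_rejected(self):
        with pytest.raises(ValueError):
            soft_vote([], np.zeros(1))


def small_ensemble(panel=None, window=50, n_features=30, best_k=2):
    return FDDEnsemble(make_names(n_features), n_classes=3,
                       known_panel=panel, window=window, best_k=best_k,
                       n_select=5, seed=0)


def scripted_stream(n, n_features, informative, rng, effect=3.0, k=3):
    """Labels 0..k-1 uniform; `informative` columns carry a strong signal."""
    y = rng.integers(0, k, n)
    X = rng.normal(size=(n, n_features))
    for j in informative:
        X[:, j] += effect * (y - 1)
    return X, y


class TestSelectBestModels:
    def _model_with(self, ens, features, born_at, recalls):
        m = ens._build_model(bd.FeatureSet(features), born_at, "discovered")
        for y_true, y_pred in recalls:
            m.confusion.update(y_true, y_pred)
        return m

    def test_clamped_to_model_count(self):
        ens = small_ensemble(panel=fs("g0000"))
        ens.models.append(self._model_with(ens, ["g0001"], 5, [(0, 0)]))
        assert len(ens.select_best_models(10)) == 1

    def test_higher_balanced_accuracy_wins(self):
        ens = small_ensemble(panel=fs("g0000"))
        good = self._model_with(ens, ["g0001"], 5, [(0, 0), (1, 1)])
        poor = self._model_with(ens, ["g0002"], 6, [(0, 0), (1, 0)])
        ens.models += [poor, good]
        assert ens.select_best_models(1) == [good]

    def test_tie_broken_by_recency(self):
        ens = small_ensemble(panel=fs("g0000"))
        old = self._model_with(ens, ["g0001"], 5, [(0, 0), (1, 0)])
        new = self._model_with(ens, ["g0002"], 9, [(0, 0), (1, 0)])
        ens.models += [old, new]
        assert ens.select_best_models(1) == [new]

    def test_unevaluated_models_rank_last(self):
        ens = small_ensemble(panel=fs("g0000"))
        fresh = self._model_with(ens, ["g0001"], 9, [])
        poor = self._model_with(ens, ["g0002"], 5, [(0, 1), (1, 0)])
        ens.models += [fresh, poor]
        assert ens.select_best_models(1) == [poor]

    def test_no_discovered_models_gives_empty_list(self):
        ens = small_ensemble(panel=fs("g0000"))
        assert ens.select_best_models(3) == []


class TestOnlineLoop:
    def test_no_selection_before_first_full_window(self):
        rng = np.random.default_rng(0)
        ens = small_ensemble(panel=fs("g0000", "g0001"), window=50)
        X, y = scripted_stream(49, 30, [2, 3], rng)
        for xi, yi in zip(X, y):
            ens.process_instance(xi, yi)
        assert ens.chunk_index == 0
        assert len(ens.models) == 1
        assert ens.drift_log == []

    def test_forced_novel_chunk_fires_one_event(self):
        """A chunk dominated by non-panel markers logs exactly one event
        at the window boundary and spawns a model over the full selection."""
        rng = np.random.default_rng(1)
        ens = small_ensemble(panel=fs("g0000"), window=50)
        X, y = scripted_stream(50, 30, [5, 6, 7], rng)
        for xi, yi in zip(X, y):
            ens.process_instance(xi, yi)
        assert len(ens.drift_log) == 1
        ev = ens.drift_log[0]
        assert {"g0005", "g0006", "g0007"} <= set(ev.selected)
        assert len(ens.models) == 2
        spawned = ens.models[-1]
        assert spawned.features == ev.selected  # full selection, not novel
        assert len(spawned.features) == 5

    def test_single_class_chunk_skipped_and_logged(self):
        rng = np.random.default_rng(2)
        ens = small_ensemble(panel=fs("g0000"), window=30)
        X = rng.normal(size=(30, 30))
        for xi in X:
            ens.process_instance(xi, 1)
        assert ens.skipped_chunks == [0]
        assert len(ens.models) == 1

    def test_no_forgetting_model_count_monotone(self):
        rng = np.random.default_rng(3)
        ens = small_ensemble(panel=fs("g0000"), window=40)
        counts, unions = [], []
        segs = [[3, 4], [10, 11], [15, 16]]
        for seg in segs:
            X, y = scripted_stream(120, 30, seg, rng)
            for xi, yi in zip(X, y):
                ens.process_instance(xi, yi)
                counts.append(len(ens.models))
                unions.append(len(ens.discovered_union))
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert all(b >= a for a, b in zip(unions, unions[1:]))
        assert len(ens.final_biomarker_model()) <= 1 + 5 * len(ens.drift_log)

    def test_de_novo_uniform_before_any_model(self):
        ens = small_ensemble(panel=None, window=50)
        pred, dist = ens.process_instance(np.zeros(30), 0)
        np.testing.assert_allclose(dist, np.full(3, 1 / 3))
        assert pred == 0

    def test_de_novo_first_model_takes_ckb_seat(self):
        rng = np.random.default_rng(4)
        ens = small_ensemble(panel=None, window=50)
        X, y = scripted_stream(100, 30, [5, 6], rng)
        for xi, yi in zip(X, y):
            ens.process_instance(xi, yi)
        assert ens.c_kb is not None
        assert ens.c_kb.role == "knowledge_based"
        assert len(ens.known_panel) == 0

    def test_prequential_ordering_audit(self):
        """Replaying logged predictions reproduces each model's confusion:
        predictions never depend on the instance being scored."""
        rng = np.random.default_rng(5)
        ens = small_ensemble(panel=fs("g0000", "g0003"), window=40)
        X, y = scripted_stream(160, 30, [3, 8], rng)
        trace = bd.PrequentialTrace(3)
        for xi, yi in zip(X, y):
            pred, _ = ens.process_instance(xi, yi)
            trace.evaluate_then_update(yi, pred)
        assert trace.replay() == trace.values


class TestWarmStart:
    def test_spawned_model_beats_unwarmed_clone(self):
        """Warm-starting on the spawning chunk helps on an immediately
        following chunk from the same distribution."""
        rng = np.random.default_rng(6)
        ens = small_ensemble(panel=fs("g0000"), window=80)
        X, y = scripted_stream(80, 30, [5, 6, 7], rng)
        for xi, yi in zip(X, y):
            ens.process_instance(xi, yi)
        assert len(ens.models) == 2
        warm = ens.models[-1]
        cold = ens._build_model(warm.features, born_at=warm.born_at,
                                role="discovered")
        X2, y2 = scripted_stream(120, 30, [5, 6, 7], rng)
        res = {}
        for name, model in [("warm", warm), ("cold", cold)]:
            cm = ConfusionMatrix(3)
            for xi, yi in zip(X2, y2):
                cm.update(yi, model.predict(xi))
                model.learn(xi, yi)
            res[name] = cm.balanced_accuracy()
        assert res["warm"] > res["cold"]

    def test_distinct_born_at_across_events(self):
        rng = np.random.default_rng(7)
        ens = small_ensemble(panel=fs("g0000"), window=40)
        for seg in [[3, 4], [10, 11], [15, 16]]:
            X, y = scripted_stream(40, 30, seg, rng, effect=4.0)
            for xi, yi in zip(X, y):
                ens.process_instance(xi, yi)
        assert len(ens.drift_log) == 3
        borns = [m.born_at for m in ens.discovered_models]
        assert len(set(borns)) == len(borns) == 3
        assert len(ens.models) == 4  # C_KB plus one model per event


class TestFinalBiomarkerModel:
    def test_no_events_identity(self):
        ens = small_ensemble(panel=fs("g0001", "g0002"))
        assert list(ens.final_biomarker_model()) == ["g0001", "g0002"]

    def test_union_order_known_first(self):
        ens = small_ensemble(panel=fs("g0001", "g0002"))
        ens.discovered_union = fs("g0002", "g0003")
        assert list(ens.final_biomarker_model()) == ["g0001", "g0002", "g0003"]

    def test_panel_retention_on_synthetic_run(self, retention_report):
        """Union rule: the final model always contains the full initial
        panel — intersection size equals panel size."""
        panel, rep = retention_report
        final = rep.final_panel
        assert len(final.intersection(panel)) == len(panel) == 50
        assert len(final) >= 50


class TestBatchForestLearner:
    def test_fits_after_one_chunk_then_static(self):
        rng = np.random.default_rng(8)
        rf = BatchRandomForestLearner(2, ["a", "b"], seed=0,
                                      n_estimators=20, fit_size=40)
        X = rng.normal(size=(40, 2))
        y = (X[:, 0] > 0).astype(int)
        p0 = rf.predict_proba_one(X[0])
        np.testing.assert_allclose(p0, [0.5, 0.5])  # uniform before fit
        for xi, yi in zip(X, y):
            rf.learn_one(xi, yi)
        assert rf.fitted
        acc = np.mean([np.argmax(rf.predict_proba_one(xi)) == yi
                       for xi, yi in zip(X, y)])
        assert acc > 0.9

    def test_rf_base_learner_runs_in_ensemble(self):
        rng = np.random.default_rng(9)
        ens = FDDEnsemble(make_names(20), 3, known_panel=fs("g0000", "g0001"),
                          window=40, best_k=1, n_select=3,
                          base_learner="rf", seed=0)
        X, y = scripted_stream(80, 20, [4, 5], rng)
        for xi, yi in zip(X, y):
            ens.process_instance(xi, yi)
        assert len(ens.models) >= 2
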