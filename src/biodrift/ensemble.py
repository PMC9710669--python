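"""The feature-drift-detecting online ensemble (FDD-ES).

The stream is cut into landmark windows of ``W`` instances. Each completed
window is ranked with mRMR; if the top ``n_select`` genes contain any gene
that is neither in the known biomarker panel nor in any previous window's
selection, a *feature-drift event* fires and a new base classifier is
trained on the window over the full selected gene set. Base models are
never discarded (no catastrophic forgetting): prediction soft-votes the
knowledge-based model C_KB (built on the known panel) together with the
``R`` discovered models whose prequential balanced accuracy — measured
before each model sees the instance — is currently highest. The final
biomarker model is the union of the known panel with every gene discovered
along the stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureSet
from .hoeffding import (HoeffdingAdaptiveTreeClassifier,
                        HoeffdingTreeClassifier)
from .mrmr import Chunk, SingleClassChunkError, mrmr_rank
from .prequential import ConfusionMatrix


class BatchRandomForestLearner:
    """Chunk-trained random forest with the online-learner interface.

    A forest cannot learn incrementally: it is fitted once on the chunk that
    spawned it (500 trees, sqrt max-features) and is a static classifier
    afterwards; before fitting it accumulates instances until it has seen a
    full chunk. Provided for fidelity to the batch-learner variant; the
    adaptive Hoeffding tree is the default base learner.
    """

    def __init__(self, n_classes: int, feature_names, seed: int = 0,
                 n_estimators: int = 500, fit_size: int = 200) -> None:
        from sklearn.ensemble import RandomForestClassifier
        self.n_classes = n_classes
        self.feature_names = list(feature_names)
        self.fit_size = fit_size
        self._buf_x: list[np.ndarray] = []
        self._buf_y: list[int] = []
        self.model = RandomForestClassifier(
            n_estimators=n_estimators, max_features="sqrt", random_state=seed)
        self.fitted = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BatchRandomForestLearner":
        self.model.fit(X, y)
        self.fitted = True
        self._buf_x, self._buf_y = [], []
        return self

    def learn_one(self, x: np.ndarray, y: int) -> "BatchRandomForestLearner":
        if not self.fitted:
            self._buf_x.append(np.asarray(x, dtype=float))
            self._buf_y.append(int(y))
            if len(self._buf_y) >= self.fit_size and len(set(self._buf_y)) >= 2:
                self.fit(np.vstack(self._buf_x), np.array(self._buf_y))
        return self

    def predict_proba_one(self, x: np.ndarray) -> np.ndarray:
        if not self.fitted:
            return np.full(self.n_classes, 1.0 / self.n_classes)
        probs = self.model.predict_proba(np.asarray(x, dtype=float)[None, :])[0]
        full = np.zeros(self.n_classes)
        full[self.model.classes_] = probs
        return full


def make_learner(kind: str, n_classes: int, feature_names, seed: int = 0,
                 fit_size: int = 200, **kwargs):
    if kind == "hat":
        return HoeffdingAdaptiveTreeClassifier(n_classes, feature_names, **kwargs)
    if kind == "vfdt":
        return HoeffdingTreeClassifier(n_classes, feature_names, **kwargs)
    if kind == "rf":
        return BatchRandomForestLearner(n_classes, feature_names, seed=seed,
                                        fit_size=fit_size)
    raise ValueError(f"unknown base learner: {kind}")


@dataclass
class DriftEvent:
    """One feature-drift detection: which genes the chunk selected and which
    of them were novel (never seen in the panel or any earlier chunk)."""

    chunk_index: int
    selected: FeatureSet
    novel: FeatureSet

    def __post_init__(self) -> None:
        if len(self.novel) == 0:
            raise ValueError("a drift event requires novel features")
        if any(f not in self.selected for f in self.novel):
            raise ValueError("novel features must be a subset of selected")


def detect_feature_drift(selected: FeatureSet, known_panel: FeatureSet,
                         discovered_union: FeatureSet,
                         chunk_index: int = 0) -> DriftEvent | None:
    """Fire an event iff the selection contains genes outside both the known
    panel and everything selected in previous chunks."""
    if len(selected) == 0:
        raise ValueError("selected feature set is empty")
    novel = selected.difference(known_panel).difference(discovered_union)
    if len(novel) == 0:
        return None
    return DriftEvent(chunk_index=chunk_index, selected=selected, novel=novel)


@dataclass
class BaseModel:
    """A classifier bound to one gene set, with its prequential confusion."""

    features: FeatureSet
    indices: np.ndarray
    learner: object
    confusion: ConfusionMatrix
    born_at: int
    role: str  # "knowledge_based" or "discovered"

    def predict_proba(self, x_full: np.ndarray) -> np.ndarray:
        return self.learner.predict_proba_one(x_full[self.indices])

    def predict(self, x_full: np.ndarray) -> int:
        return int(np.argmax(self.predict_proba(x_full)))

    def learn(self, x_full: np.ndarray, y: int) -> None:
        self.learner.learn_one(x_full[self.indices], y)

    def balanced_accuracy(self) -> float | None:
        if self.confusion.total == 0:
            return None
        return self.confusion.balanced_accuracy()


def soft_vote(models: list[BaseModel], x_full: np.ndarray) -> np.ndarray:
    """Unweighted mean of member class distributions; argmax (lowest class
    index on ties) is the ensemble prediction."""
    if not models:
        raise ValueError("soft_vote needs at least one model")
    dists = np.stack([m.predict_proba(x_full) for m in models])
    return dists.mean(axis=0)


class FDDEnsemble:
    """Online ensemble state and processing loop.

    Parameters
    ----------
    feature_names:
        The stream's gene identifiers, in input-vector order.
    n_classes:
        Size of the fixed label set.
    known_panel:
        The initial biomarker panel for C_KB; empty means de-novo discovery
        (no classifier exists until the first drift event).
    window / best_k / n_select:
        Landmark-window size W, number R of discovered models that join
        C_KB in the vote, and genes selected per chunk.
    base_learner:
        "hat" (default), "vfdt", or "rf" (chunk-trained batch forest).
    chunk_feature_cap:
        Optional cap on how many features mRMR scans per chunk (the
        highest-variance ones within the chunk); None scans all.
    """

    def __init__(self, feature_names, n_classes: int,
                 known_panel: FeatureSet | None = None, window: int = 200,
                 best_k: int = 2, n_select: int = 10,
                 base_learner: str = "hat", seed: int = 0,
                 chunk_feature_cap: int | None = None,
                 learner_kwargs: dict | None = None) -> None:
        if window < 2:
            raise ValueError("window must be >= 2")
        if best_k < 1:
            raise ValueError("best_k must be >= 1")
        self.feature_names = list(feature_names)
        self._col = {f: i for i, f in enumerate(self.feature_names)}
        self.n_classes = int(n_classes)
        self.known_panel = known_panel or FeatureSet(origin="known_panel")
        self.window = int(window)
        self.best_k = int(best_k)
        self.n_select = int(n_select)
        self.base_learner = base_learner
        self.seed = int(seed)
        self.chunk_feature_cap = chunk_feature_cap
        self.learner_kwargs = dict(learner_kwargs or {})

        self.models: list[BaseModel] = []
        self.drift_log: list[DriftEvent] = []
        self.skipped_chunks: list[int] = []
        self.discovered_union = FeatureSet(origin="discovered")
        self._buf_x: list[np.ndarray] = []
        self._buf_y: list[int] = []
        self.n_seen = 0
        self.chunk_index = 0

        if len(self.known_panel) > 0:
            self.models.append(self._build_model(self.known_panel, born_at=0,
                                                 role="knowledge_based"))

    # -- model plumbing ---------------------------------------------------

    def _build_model(self, features: FeatureSet, born_at: int,
                     role: str) -> BaseModel:
        missing = [f for f in features if f not in self._col]
        if missing:
            raise KeyError(f"panel genes not in stream: {missing}")
        idx = np.array([self._col[f] for f in features], dtype=int)
        learner = make_learner(self.base_learner, self.n_classes,
                               list(features), seed=self.seed + born_at,
                               fit_size=self.window, **self.learner_kwargs)
        return BaseModel(features=features, indices=idx, learner=learner,
                         confusion=ConfusionMatrix(self.n_classes),
                         born_at=born_at, role=role)

    @property
    def c_kb(self) -> BaseModel | None:
        for m in self.models:
            if m.role == "knowledge_based":
                return m
        return None

    @property
    def discovered_models(self) -> list[BaseModel]:
        return [m for m in self.models if m.role == "discovered"]

    def select_best_models(self, k: int) -> list[BaseModel]:
        """The k discovered models with highest prequential balanced
        accuracy; unevaluated models rank last; ties go to the newer model.
        C_KB is not part of this ranking — it always votes."""
        if k < 1:
            raise ValueError("k must be >= 1")
        ranked = sorted(
            self.discovered_models,
            key=lambda m: (m.balanced_accuracy() is not None,
                           m.balanced_accuracy() or -1.0, m.born_at),
            reverse=True)
        return ranked[:k]

    # -- the online loop --------------------------------------------------

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        voters = ([self.c_kb] if self.c_kb is not None else []) \
            + self.select_best_models(self.best_k)
        if not voters:
            return np.full(self.n_classes, 1.0 / self.n_classes)
        return soft_vote(voters, x)

    def process_instance(self, x: np.ndarray, y: int
                         ) -> tuple[int, np.ndarray]:
        """Test-then-train on one instance.

        Prediction (and every model's own prequential bookkeeping) happens
        strictly before any model sees the label. Returns the ensemble's
        predicted label and class distribution.
        """
        x = np.asarray(x, dtype=float)
        y = int(y)
        dist = self.predict_proba(x)
        pred = int(np.argmax(dist))
        for m in self.models:
            m.confusion.update(y, m.predict(x))
        for m in self.models:
            m.learn(x, y)
        self.n_seen += 1
        self._buf_x.append(x)
        self._buf_y.append(y)
        if len(self._buf_y) >= self.window:
            self._complete_chunk()
        return pred, dist

    def _complete_chunk(self) -> None:
        X = np.vstack(self._buf_x)
        yv = np.array(self._buf_y, dtype=int)
        names = self.feature_names
        if (self.chunk_feature_cap is not None
                and len(names) > self.chunk_feature_cap):
            var = X.var(axis=0)
            keep = np.sort(np.argsort(-var, kind="stable")[:self.chunk_feature_cap])
            X = X[:, keep]
            names = [names[i] for i in keep]
        try:
            selected = mrmr_rank(Chunk(X, yv, names), self.n_select)
        except SingleClassChunkError:
            self.skipped_chunks.append(self.chunk_index)
        else:
            event = detect_feature_drift(selected, self.known_panel,
                                         self.discovered_union,
                                         chunk_index=self.chunk_index)
            if event is not None:
                self.drift_log.append(event)
                self.discovered_union = self.discovered_union.union(event.novel)
                self._spawn_base_model(event)
        self.chunk_index += 1
        self._buf_x, self._buf_y = [], []

    def _spawn_base_model(self, event: DriftEvent) -> None:
        """Train a new base model on the chunk over the event's full selected
        gene set (all n_select genes, not only the novel ones) and append it;
        existing models are never replaced."""
        # de-novo mode: the first spawned model takes the C_KB seat
        role = "knowledge_based" if not self.models else "discovered"
        model = self._build_model(event.selected, born_at=self.n_seen,
                                  role=role)
        for xb, yb in zip(self._buf_x, self._buf_y):  # warm start on chunk
            model.learn(xb, yb)
        self.models.append(model)

    # -- outputs ----------------------------------------------------------

    def final_biomarker_model(self) -> FeatureSet:
        """Known panel united with every discovered gene: panel members
        first, discovered genes in first-selection order."""
        return self.known_panel.union(self.discovered_union, origin="final")
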