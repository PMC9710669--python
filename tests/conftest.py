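import numpy as np
import pytest
from hypothesis import settings

import biodrift as bd

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_names(p: int) -> list[str]:
    return [f"g{i:04d}" for i in range(p)]


@pytest.fixture(scope="session")
def two_segment_stream() -> bd.ExpressionStream:
    """Canonical drifting stream: disjoint informative blocks, cohort switch."""
    cfg = bd.two_segment_config(n_instances=2000, n_features=200, seed=1)
    return bd.generate_drifting_stream(cfg)


@pytest.fixture(scope="session")
def planted_chunk() -> tuple[bd.Chunk, bd.FeatureSet]:
    """One W=500 chunk with 10 planted informative genes, effect size 2."""
    planted = bd.FeatureSet(make_names(60)[20:30])
    cfg = bd.StreamConfig(n_instances=500, n_features=60,
                          segments=[bd.DriftSegment(0, planted, 2.0)], seed=7)
    s = bd.generate_drifting_stream(cfg)
    return bd.Chunk(s.X, s.y, s.feature_names), planted


@pytest.fixture(scope="session")
def retention_report(two_segment_stream):
    """Full online run initialized with an arbitrary 50-gene panel."""
    panel = bd.FeatureSet(make_names(200)[100:150], origin="known_panel")
    report = bd.run_experiment(
        two_segment_stream,
        bd.ExperimentConfig(window=200, best_k=2, panel=panel, seed=1))
    return panel, report


def single_hat_prequential(stream, feature_subset=None, seed=0):
    """Drive one adaptive tree test-then-train over a stream; returns the
    prediction list (used to cross-check baseline equivalences)."""
    names = feature_subset or stream.feature_names
    idx = stream.feature_indices(names)
    tree = bd.HoeffdingAdaptiveTreeClassifier(stream.n_classes, names)
    preds = []
    for inst in stream:
        preds.append(int(np.argmax(tree.predict_proba_one(inst.x[idx]))))
        tree.learn_one(inst.x[idx], inst.y)
    return preds
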