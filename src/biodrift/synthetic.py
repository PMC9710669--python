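"""Synthetic drifting expression streams and survival fixtures.

Real transcriptomic streams concatenate cohorts profiled years apart on
different platforms: the genes that separate tumour subtypes change as the
stream progresses (feature drift) and a cohort switch shifts and rescales
every feature at once (batch effect). This module generates streams with
exactly those two pathologies under full control, plus proportional-hazards
survival data, so the online learner and the downstream survival analysis
can be exercised and validated without any external download.

The generative model, per stream segment: each class is assigned one of
``n_classes`` equispaced points on [-effect_size/2, +effect_size/2] for every
informative feature (the assignment permuted per feature), and expression is
that class mean plus Normal(0, noise_sd) noise; non-informative features are
pure noise. Labels are drawn i.i.d. from ``class_probs`` — imbalanced by
default, as tumour subtype frequencies are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .features import FeatureSet
from .stream import ExpressionStream

#: Default subtype frequencies; deliberately imbalanced so that balanced
#: accuracy and raw accuracy disagree.
DEFAULT_CLASS_PROBS = (0.45, 0.25, 0.15, 0.10, 0.05)


class ConfigurationError(ValueError):
    """Raised when a stream configuration violates its invariants."""


@dataclass
class DriftSegment:
    """A maximal run of the stream over which the informative genes are fixed.

    ``start`` is the index of the first instance of the segment;
    ``informative_features`` the genes that carry class signal there;
    ``effect_size`` the class-mean separation in Z-units.
    """

    start: int
    informative_features: FeatureSet
    effect_size: float = 2.0

    def __post_init__(self) -> None:
        if len(self.informative_features) == 0:
            raise ConfigurationError("informative_features must be non-empty")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")


@dataclass
class StreamConfig:
    """Full recipe for a synthetic drifting stream."""

    n_instances: int = 2000
    n_features: int = 200
    n_classes: int = 5
    class_probs: tuple = DEFAULT_CLASS_PROBS
    segments: list[DriftSegment] = field(default_factory=list)
    source_switch_at: int | None = None
    shift_magnitude: float = 1.0
    scale_factor: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_instances <= 0 or self.n_features <= 0:
            raise ConfigurationError("n_instances and n_features must be positive")
        probs = np.asarray(self.class_probs, dtype=float)
        if len(probs) != self.n_classes:
            raise ConfigurationError("class_probs length must equal n_classes")
        if abs(probs.sum() - 1.0) > 1e-12 or (probs < 0).any():
            raise ConfigurationError("class_probs must be a probability vector")
        if not self.segments:
            self.segments = [DriftSegment(
                0, default_informative(self.n_features, 0))]
        starts = [s.start for s in self.segments]
        if starts[0] != 0 or any(b <= a for a, b in zip(starts, starts[1:])):
            raise ConfigurationError(
                "segment starts must begin at 0 and be strictly increasing")
        if starts[-1] >= self.n_instances:
            raise ConfigurationError("segment start beyond stream end")
        biggest = max(len(s.informative_features) for s in self.segments)
        if self.n_features < biggest:
            raise ConfigurationError("n_features smaller than an informative set")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.source_switch_at is not None and not (
                0 < self.source_switch_at < self.n_instances):
            raise ConfigurationError("source_switch_at out of range")


def feature_names(n_features: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n_features)]


def default_informative(n_features: int, segment: int, size: int = 10) -> FeatureSet:
    """Disjoint 10-gene informative blocks, one per segment index."""
    names = feature_names(n_features)
    lo = segment * size
    if lo + size > n_features:
        raise ConfigurationError("not enough features for informative block")
    return FeatureSet(names[lo:lo + size], origin=f"segment:{segment}")


def two_segment_config(n_instances: int = 2000, n_features: int = 200,
                       effect_size: float = 2.0, source_switch: bool = True,
                       seed: int = 0, **kw) -> StreamConfig:
    """The canonical test-bench stream: two disjoint informative blocks with
    a drift at the midpoint and (optionally) a cohort switch at 3/4."""
    segs = [DriftSegment(0, default_informative(n_features, 0), effect_size),
            DriftSegment(n_instances // 2, default_informative(n_features, 1),
                         effect_size)]
    return StreamConfig(
        n_instances=n_instances, n_features=n_features, segments=segs,
        source_switch_at=(3 * n_instances // 4) if source_switch else None,
        seed=seed, **kw)


def generate_drifting_stream(config: StreamConfig) -> ExpressionStream:
    """Generate a labeled stream per the segment model above.

    Fully reproducible: identical configs (including seed) give bit-identical
    streams. The class-mean pattern of each informative feature is drawn once
    per segment.
    """
    rng = np.random.default_rng(config.seed)
    n, p, k = config.n_instances, config.n_features, config.n_classes
    names = feature_names(p)
    col = {f: i for i, f in enumerate(names)}

    y = rng.choice(k, size=n, p=np.asarray(config.class_probs, dtype=float))
    X = rng.normal(0.0, config.noise_sd, size=(n, p))

    bounds = [s.start for s in config.segments] + [n]
    for seg, lo, hi in zip(config.segments, bounds, bounds[1:]):
        levels = np.linspace(-seg.effect_size / 2, seg.effect_size / 2, k)
        for f in seg.informative_features:
            class_means = levels[rng.permutation(k)]
            X[lo:hi, col[f]] += class_means[y[lo:hi]]

    stream = ExpressionStream(
        feature_names=names, X=X, y=y,
        sources=np.array(["source_a"] * n, dtype=object),
        class_names=[f"class{c}" for c in range(k)])
    if config.source_switch_at is not None:
        stream = apply_source_shift(stream, config.source_switch_at,
                                    config.shift_magnitude, config.scale_factor)
    return stream


def apply_source_shift(stream: ExpressionStream, at: int, shift: float,
                       scale: float = 1.0,
                       new_source: str = "source_b") -> ExpressionStream:
    """Emulate a cohort/platform switch: from instance ``at`` on, every
    feature x becomes scale*x + shift and the source tag changes. Labels are
    untouched — only the measurement process shifts, not the biology."""
    if not 0 < at < len(stream):
        raise ConfigurationError(f"switch index {at} out of range (0, {len(stream)})")
    X = stream.X.copy()
    X[at:] = scale * X[at:] + shift
    sources = stream.sources.copy()
    sources[at:] = new_source
    return ExpressionStream(
        feature_names=list(stream.feature_names), X=X, y=stream.y.copy(),
        sources=sources, class_names=list(stream.class_names),
        sample_ids=list(stream.sample_ids))


@dataclass
class SurvivalTable:
    """Follow-up data: observed time, event indicator, per-gene expression."""

    time: np.ndarray
    event: np.ndarray
    expression: "np.ndarray"
    gene_names: list[str]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.expression = np.atleast_2d(np.asarray(self.expression, dtype=float))
        if not (len(self.time) == len(self.event) == self.expression.shape[0]):
            raise ValueError("column lengths differ")
        if (self.time <= 0).any():
            raise ValueError("times must be positive")


def generate_survival_data(n: int, betas, censor_rate: float = 0.2,
                           seed: int = 0,
                           baseline_hazard: float = 0.1) -> SurvivalTable:
    """Exponential proportional-hazards survival data.

    Covariates are standard normal; event time for subject i is exponential
    with rate ``baseline_hazard * exp(x_i . betas)``. Censoring is an
    independent exponential whose rate is solved numerically so the expected
    censored fraction equals ``censor_rate``.
    """
    if n <= 0:
        raise ConfigurationError("n must be positive")
    if not 0 <= censor_rate < 1:
        raise ConfigurationError("censor_rate must be in [0, 1)")
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(betas)))
    hazard = baseline_hazard * np.exp(X @ betas)
    t_event = rng.exponential(1.0 / hazard)

    if censor_rate == 0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        # P(censored | hazard h) = c/(c+h) for independent Exp(c) censoring
        def mean_censored(c: float) -> float:
            return float(np.mean(c / (c + hazard))) - censor_rate
        c = brentq(mean_censored, 1e-12, 1e6)
        t_cens = rng.exponential(1.0 / c, size=n)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)

    genes = [f"g{i:04d}" for i in range(len(betas))]
    return SurvivalTable(time=time, event=event, expression=X, gene_names=genes)
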