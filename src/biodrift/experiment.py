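"""Experiment harness: drive the ensemble and a matched baseline over a
stream, producing paired prequential traces.

The baseline ("NoEns") is a single online learner over the known panel —
with an empty panel, over the whole feature space — with no feature-drift
detection and no spawned models: exactly the static-panel practice the
ensemble is meant to improve on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ensemble import DriftEvent, FDDEnsemble, make_learner
from .features import FeatureSet
from .prequential import PrequentialTrace
from .stream import ExpressionStream


@dataclass
class ExperimentConfig:
    window: int = 200
    best_k: int = 2
    n_select: int = 10
    base_learner: str = "hat"
    panel: FeatureSet | None = None
    seed: int = 0
    chunk_feature_cap: int | None = None
    learner_kwargs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()
             if k not in ("panel", "learner_kwargs")}
        d["panel"] = list(self.panel) if self.panel is not None else []
        return d


@dataclass
class ExperimentReport:
    """Everything one run produces: paired traces, drift events, the final
    biomarker model, and enough config echo to rerun it."""

    config: dict
    ens_trace: PrequentialTrace | None
    noens_trace: PrequentialTrace | None
    n_models: list[int]
    active_model_ids: list[list[int]]
    drift_events: list[DriftEvent]
    final_panel: FeatureSet
    source_switch_index: int | None

    @property
    def n_instances(self) -> int:
        return 0 if self.ens_trace is None else len(self.ens_trace.values)

    def write_trace_csv(self, path: str | Path) -> None:
        lines = ["instance_index,ens_balacc,noens_balacc,n_models,active_model_ids"]
        for i in range(self.n_instances):
            ids = ";".join(str(m) for m in self.active_model_ids[i])
            lines.append(f"{i},{self.ens_trace.values[i]:.10f},"
                         f"{self.noens_trace.values[i]:.10f},"
                         f"{self.n_models[i]},{ids}")
        Path(path).write_text("\n".join(lines) + "\n")

    def write_drift_log(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for ev in self.drift_events:
                fh.write(json.dumps({"chunk_index": ev.chunk_index,
                                     "selected": list(ev.selected),
                                     "novel": list(ev.novel)}) + "\n")

    def write_final_panel(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.final_panel) + "\n")


def run_experiment(stream: ExpressionStream,
                   config: ExperimentConfig) -> ExperimentReport:
    """Test-then-train the ensemble and the NoEns baseline over the stream.

    Deterministic given the stream and config seed. An empty stream yields
    an empty report.
    """
    n = len(stream)
    ens = FDDEnsemble(stream.feature_names, stream.n_classes,
                      known_panel=config.panel, window=config.window,
                      best_k=config.best_k, n_select=config.n_select,
                      base_learner=config.base_learner, seed=config.seed,
                      chunk_feature_cap=config.chunk_feature_cap,
                      learner_kwargs=config.learner_kwargs)
    baseline_feats = (list(config.panel) if config.panel and len(config.panel)
                      else list(stream.feature_names))
    baseline = make_learner(
        config.base_learner if config.base_learner != "rf" else "hat",
        stream.n_classes, baseline_feats, seed=config.seed,
        **config.learner_kwargs)
    base_idx = stream.feature_indices(baseline_feats)

    switch = _source_switch_index(stream)
    if n == 0:
        return ExperimentReport(config.to_dict(), None, None, [], [], [],
                                ens.final_biomarker_model(), switch)

    ens_trace = PrequentialTrace(stream.n_classes)
    noens_trace = PrequentialTrace(stream.n_classes)
    n_models: list[int] = []
    active_ids: list[list[int]] = []
    for inst in stream:
        voters = ([ens.c_kb] if ens.c_kb is not None else []) \
            + ens.select_best_models(ens.best_k)
        active_ids.append([ens.models.index(m) for m in voters])
        pred, _ = ens.process_instance(inst.x, inst.y)
        ens_trace.evaluate_then_update(inst.y, pred)
        n_models.append(len(ens.models))

        xb = inst.x[base_idx]
        bpred = int(np.argmax(baseline.predict_proba_one(xb)))
        noens_trace.evaluate_then_update(inst.y, bpred)
        baseline.learn_one(xb, inst.y)

    return ExperimentReport(config.to_dict(), ens_trace, noens_trace,
                            n_models, active_ids, list(ens.drift_log),
                            ens.final_biomarker_model(), switch)


def _source_switch_index(stream: ExpressionStream) -> int | None:
    s = stream.sources
    for i in range(1, len(s)):
        if s[i] != s[i - 1]:
            return i
    return None


def windowed_accuracy(trace: PrequentialTrace, half_window: int = 50) -> np.ndarray:
    """Per-instance correctness smoothed with a centred moving mean."""
    correct = np.array([t == p for t, p in trace.predictions], dtype=float)
    kernel = np.ones(2 * half_window + 1)
    # normalize by actual in-range window sizes so edges are unbiased
    sums = np.convolve(correct, kernel, mode="same")
    counts = np.convolve(np.ones_like(correct), kernel, mode="same")
    return sums / counts


def largest_drop_index(trace: PrequentialTrace, half_window: int = 50) -> int:
    """Index where the smoothed accuracy falls most steeply — the recorded
    dip location of a run (e.g. at a cohort switch)."""
    acc = windowed_accuracy(trace, half_window)
    n, w = len(acc), half_window
    if n <= 2 * w:
        return int(np.argmin(acc))
    drop = acc[:n - 2 * w] - acc[2 * w:]  # fall from i to i+2w, centred i+w
    return int(np.argmax(drop) + w)


def plot_traces(report: ExperimentReport, path: str | Path) -> None:
    """Paired-trace figure: solid = ensemble, dotted = baseline, dashed
    vertical line at the source switch."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(report.n_instances)
    ax.plot(x, report.ens_trace.values, "-", label="FDD-ES")
    ax.plot(x, report.noens_trace.values, ":", label="NoEns")
    if report.source_switch_index is not None:
        ax.axvline(report.source_switch_index, ls="--", color="grey")
    ax.set_xlabel("online instances")
    ax.set_ylabel("cumulative balanced accuracy")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
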