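"""Incremental decision trees: VFDT and its drift-adaptive extension (HAT).

The Very Fast Decision Tree grows from a single root as instances stream
in. Each leaf accumulates per-class Gaussian sufficient statistics for every
feature; every ``grace_period`` instances it evaluates candidate binary
splits by information gain and splits when the Hoeffding bound

    eps = sqrt( R^2 ln(1/delta) / (2 n) ),   R = log2(n_classes)

certifies that the observed best split beats the runner-up with confidence
1 - delta (or when the two are within the tie threshold tau). Leaves that
have seen at least ``nb_threshold`` instances predict with a Gaussian
naive-Bayes posterior; younger leaves fall back to normalized class counts.

The adaptive variant attaches an ADWIN change detector to every node,
monitoring the 0/1 error of the subtree's prediction on instances passing
through. A detection starts an alternate subtree trained in parallel on the
same traffic; periodically the alternate's ADWIN error estimate is compared
with the original's and, when lower by more than a Hoeffding bound, the
alternate replaces the original subtree. On a stationary stream where no
detector fires, the adaptive tree is behaviourally identical to the VFDT.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .adwin import ADWINDetector

_VAR_FLOOR = 1e-3  # variance smoothing, in squared Z-units


def hoeffding_bound(value_range: float, delta: float, n: int) -> float:
    """One-sided Hoeffding deviation bound for a mean of n values in a range.

    eps = sqrt(R^2 * ln(1/delta) / (2 n)).
    """
    if value_range <= 0:
        raise ValueError("value_range must be positive")
    if not 0 < delta <= 1:
        raise ValueError("delta must be in (0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return math.sqrt(value_range ** 2 * math.log(1.0 / delta) / (2.0 * n))


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total <= 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


@dataclass
class _Node:
    """A tree node; a leaf until it splits.

    Leaves hold per-(feature, class) Welford accumulators (count is the
    class count; ``mean``/``m2`` are feature x class arrays). Internal nodes
    keep only the split and their children. Adaptive trees add an ADWIN
    detector and possibly an alternate subtree.
    """

    n_classes: int
    n_features: int
    class_counts: np.ndarray = None
    mean: np.ndarray = None
    m2: np.ndarray = None
    is_leaf: bool = True
    split_feature: int = -1
    threshold: float = 0.0
    children: list = None
    n_since_attempt: int = 0
    adwin: ADWINDetector | None = None
    alternate: "_Node | None" = None
    alt_traffic: int = 0

    def __post_init__(self) -> None:
        if self.class_counts is None:
            self.class_counts = np.zeros(self.n_classes)
            self.mean = np.zeros((self.n_features, self.n_classes))
            self.m2 = np.zeros((self.n_features, self.n_classes))

    def update_stats(self, x: np.ndarray, y: int) -> None:
        self.class_counts[y] += 1
        n = self.class_counts[y]
        delta = x - self.mean[:, y]
        self.mean[:, y] += delta / n
        self.m2[:, y] += delta * (x - self.mean[:, y])

    def leaf_distribution(self, x: np.ndarray, nb_threshold: int) -> np.ndarray:
        counts = self.class_counts
        total = counts.sum()
        k = self.n_classes
        if total == 0:
            return np.full(k, 1.0 / k)
        if total < nb_threshold:
            return counts / total
        # Gaussian naive Bayes from the leaf's sufficient statistics
        log_joint = np.full(k, -np.inf)
        log_prior = np.log((counts + 1.0) / (total + k))  # Laplace-smoothed
        for c in range(k):
            if counts[c] == 0:
                log_joint[c] = log_prior[c] + self.n_features * math.log(1e-9)
                continue
            n = counts[c]
            var = np.where(n >= 2, self.m2[:, c] / max(n - 1, 1), 0.0) + _VAR_FLOOR
            ll = -0.5 * (np.log(2 * np.pi * var)
                         + (x - self.mean[:, c]) ** 2 / var)
            log_joint[c] = log_prior[c] + ll.sum()
        log_joint -= log_joint.max()
        p = np.exp(log_joint)
        return p / p.sum()

    def route(self, x: np.ndarray) -> "_Node":
        return self.children[0 if x[self.split_feature] <= self.threshold else 1]


@dataclass
class SplitAttempt:
    """Instrumentation record of one split evaluation at a leaf."""

    n_seen: int
    best_gain: float
    second_gain: float
    epsilon: float
    did_split: bool
    feature: int = -1
    threshold: float = float("nan")


class HoeffdingTreeClassifier:
    """VFDT over a fixed feature space.

    Parameters
    ----------
    n_classes:
        Size of the (fixed) label set; unseen labels raise.
    feature_names:
        The gene identifiers this tree may consult, in input-vector order.
    delta_split:
        Split-confidence complement; 1e-5 corresponds to requiring the best
        split to be truly best with probability 0.99999.
    grace_period:
        Instances a leaf observes between split attempts.
    nb_threshold:
        Leaf size at which prediction switches from majority counts to the
        naive-Bayes posterior.
    tau:
        Tie threshold: split anyway once the bound is this tight.
    """

    adaptive = False

    def __init__(self, n_classes: int, feature_names,
                 delta_split: float = 1e-5, grace_period: int = 100,
                 nb_threshold: int = 10, tau: float = 0.05,
                 n_split_points: int = 10, adwin_delta: float = 0.002,
                 alt_check_interval: int = 100) -> None:
        self.n_classes = int(n_classes)
        self.feature_names = list(feature_names)
        self.n_features = len(self.feature_names)
        self.delta_split = float(delta_split)
        self.grace_period = int(grace_period)
        self.nb_threshold = int(nb_threshold)
        self.tau = float(tau)
        self.n_split_points = int(n_split_points)
        self.adwin_delta = float(adwin_delta)
        self.alt_check_interval = int(alt_check_interval)
        self.root = self._new_leaf()
        self.n_seen = 0
        self.frozen = False
        self.split_log: list[SplitAttempt] = []

    # -- construction helpers --------------------------------------------

    def _new_leaf(self) -> _Node:
        node = _Node(self.n_classes, self.n_features)
        if self.adaptive:
            node.adwin = ADWINDetector(delta=self.adwin_delta)
        return node

    # -- prediction -------------------------------------------------------

    def _leaf_for(self, node: _Node, x: np.ndarray) -> _Node:
        while not node.is_leaf:
            node = node.route(x)
        return node

    def predict_proba_one(self, x: np.ndarray) -> np.ndarray:
        """Class distribution at the leaf x routes to; sums to 1."""
        x = np.asarray(x, dtype=float)
        leaf = self._leaf_for(self.root, x)
        return leaf.leaf_distribution(x, self.nb_threshold)

    def predict_one(self, x) -> int:
        return int(np.argmax(self.predict_proba_one(x)))

    # -- learning ---------------------------------------------------------

    def learn_one(self, x: np.ndarray, y: int) -> "HoeffdingTreeClassifier":
        if not 0 <= y < self.n_classes:
            raise ValueError(f"unknown class label {y}")
        if self.frozen:
            return self
        x = np.asarray(x, dtype=float)
        self.n_seen += 1
        self.root = self._learn_node(self.root, x, int(y))
        return self

    def freeze(self) -> "HoeffdingTreeClassifier":
        """Stop all learning; the tree becomes a static classifier."""
        self.frozen = True
        return self

    def _learn_node(self, node: _Node, x: np.ndarray, y: int) -> _Node:
        if self.adaptive:
            pred = self._leaf_for(node, x).leaf_distribution(x, self.nb_threshold)
            err = 0.0 if int(np.argmax(pred)) == y else 1.0
            change, _ = node.adwin.update(err)
            if change and node.alternate is None:
                node.alternate = self._new_leaf()
            if node.alternate is not None:
                node.alternate = self._learn_node(node.alternate, x, y)
                node.alt_traffic += 1
                if node.alt_traffic % self.alt_check_interval == 0:
                    promoted = self._compare_alternate(node)
                    if promoted is not None:
                        return promoted
        if node.is_leaf:
            node.update_stats(x, y)
            node.n_since_attempt += 1
            if node.n_since_attempt >= self.grace_period:
                node.n_since_attempt = 0
                self._attempt_split(node)
        else:
            child = 0 if x[node.split_feature] <= node.threshold else 1
            node.children[child] = self._learn_node(node.children[child], x, y)
        return node

    def _compare_alternate(self, node: _Node) -> _Node | None:
        alt = node.alternate
        n = min(node.adwin.width, alt.adwin.width)
        if n < 1:
            return None
        eps = hoeffding_bound(1.0, self.delta_split, n)
        err_node = node.adwin.estimate()
        err_alt = alt.adwin.estimate()
        if err_alt < err_node - eps:
            node.alternate = None
            return alt  # alternate takes over the subtree
        if err_node < err_alt - eps:
            node.alternate = None  # alternate abandoned
        return None

    # -- split machinery --------------------------------------------------

    def _attempt_split(self, node: _Node) -> None:
        counts = node.class_counts
        present = counts > 0
        total = counts.sum()
        if present.sum() < 2:
            return
        parent_h = _entropy(counts)
        gains = np.empty(self.n_features)
        thrs = np.empty(self.n_features)
        for f in range(self.n_features):
            gains[f], thrs[f] = self._best_threshold(node, f, parent_h)
        f = int(np.argmax(gains))  # argmax keeps the lowest index on ties
        gain, thr = float(gains[f]), float(thrs[f])
        if not np.isfinite(gain):
            return
        others = np.delete(gains, f)
        # the null split (gain 0) is always a competing alternative
        second_gain = max(float(others.max(initial=-np.inf)), 0.0)
        eps = hoeffding_bound(math.log2(self.n_classes), self.delta_split,
                              int(total))
        do_split = gain > 0 and (gain - second_gain > eps or eps < self.tau)
        self.split_log.append(SplitAttempt(int(total), gain, second_gain,
                                           eps, do_split, f, thr))
        if do_split:
            node.is_leaf = False
            node.split_feature = f
            node.threshold = float(thr)
            node.children = [self._new_leaf(), self._new_leaf()]
            node.mean = node.m2 = None  # leaf stats no longer needed

    def _best_threshold(self, node: _Node, f: int, parent_h: float):
        counts = node.class_counts
        present = np.where(counts > 0)[0]
        mu = node.mean[f, present]
        n = counts[present]
        var = np.where(n >= 2, node.m2[f, present] / np.maximum(n - 1, 1), 0.0)
        sd = np.sqrt(var + _VAR_FLOOR)
        lo = float((mu - 3 * sd).min())
        hi = float((mu + 3 * sd).max())
        if hi <= lo:
            return -np.inf, np.nan
        thresholds = np.linspace(lo, hi, self.n_split_points + 2)[1:-1]
        # expected left-class counts under the per-class Gaussian model
        z = (thresholds[:, None] - mu[None, :]) / sd[None, :]
        left = ndtr(z) * n[None, :]
        right = n[None, :] - left
        total = counts.sum()
        best_gain, best_thr = -np.inf, np.nan
        for i, t in enumerate(thresholds):
            l, r = left[i], right[i]
            wl, wr = l.sum() / total, r.sum() / total
            if wl <= 0 or wr <= 0:
                continue
            gain = parent_h - wl * _entropy(l) - wr * _entropy(r)
            if gain > best_gain:
                best_gain, best_thr = gain, float(t)
        return best_gain, best_thr

    # -- introspection ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        def count(node: _Node) -> int:
            if node.is_leaf:
                return 1
            return 1 + sum(count(c) for c in node.children)
        return count(self.root)

    def split_features_used(self) -> set[str]:
        used: set[str] = set()

        def walk(node: _Node) -> None:
            if not node.is_leaf:
                used.add(self.feature_names[node.split_feature])
                for c in node.children:
                    walk(c)
            if node.alternate is not None:
                walk(node.alternate)
        walk(self.root)
        return used

    def to_dict(self) -> dict:
        """JSON-serializable dump of the tree structure and leaf counts."""
        def conv(node: _Node) -> dict:
            d: dict = {"leaf": node.is_leaf,
                       "class_counts": node.class_counts.tolist()}
            if not node.is_leaf:
                d["feature"] = self.feature_names[node.split_feature]
                d["threshold"] = node.threshold
                d["children"] = [conv(c) for c in node.children]
            return d
        return {"n_classes": self.n_classes, "n_seen": self.n_seen,
                "root": conv(self.root)}

    def dumps(self) -> str:
        return json.dumps(self.to_dict())


class HoeffdingAdaptiveTreeClassifier(HoeffdingTreeClassifier):
    """HAT: the VFDT above with per-node ADWIN monitoring and alternate
    subtrees. See the module docstring for the adaptation protocol."""

    adaptive = True
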