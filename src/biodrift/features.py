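"""Ordered gene sets.

Biomarker panels and per-chunk selections are *ordered* collections of gene
identifiers without duplicates; selection order is meaningful (mRMR returns
features in greedy order, and the final learned panel lists known-panel
members before discovered ones, in first-selection order).
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator


class FeatureSet:
    """An ordered, duplicate-free collection of gene identifiers.

    Parameters
    ----------
    features
        Gene identifiers in order. Duplicates raise ``ValueError``.
    origin
        Free-form provenance tag, e.g. ``"known_panel"`` or ``"chunk:3"``.
    """

    __slots__ = ("_features", "_index", "origin")

    def __init__(self, features: Iterable[str] = (), origin: str = "") -> None:
        feats = list(features)
        index = {f: i for i, f in enumerate(feats)}
        if len(index) != len(feats):
            seen: set[str] = set()
            dups = sorted({f for f in feats if f in seen or seen.add(f)})
            raise ValueError(f"duplicate feature identifiers: {dups}")
        self._features: tuple[str, ...] = tuple(feats)
        self._index = index
        self.origin = origin

    @property
    def features(self) -> tuple[str, ...]:
        return self._features

    def __len__(self) -> int:
        return len(self._features)

    def __iter__(self) -> Iterator[str]:
        return iter(self._features)

    def __contains__(self, item: object) -> bool:
        return item in self._index

    def __getitem__(self, i: int) -> str:
        return self._features[i]

    def __eq__(self, other: object) -> bool:
        if isinstance(other, FeatureSet):
            return self._features == other._features
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self._features)

    def __repr__(self) -> str:
        head = ", ".join(self._features[:4])
        tail = ", ..." if len(self) > 4 else ""
        return f"FeatureSet([{head}{tail}], n={len(self)}, origin={self.origin!r})"

    def union(self, other: Iterable[str], origin: str = "") -> "FeatureSet":
        """Order-preserving union: self first, then unseen members of other."""
        merged = list(self._features)
        for f in other:
            if f not in self._index and f not in merged[len(self._features):]:
                merged.append(f)
        return FeatureSet(merged, origin=origin or self.origin)

    def difference(self, other: Iterable[str]) -> "FeatureSet":
        """Members of self not in other, order preserved."""
        drop = set(other)
        return FeatureSet([f for f in self._features if f not in drop],
                          origin=self.origin)

    def intersection(self, other: Iterable[str]) -> "FeatureSet":
        keep = set(other)
        return FeatureSet([f for f in self._features if f in keep],
                          origin=self.origin)
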