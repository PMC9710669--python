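"""ADWIN: adaptive-windowing change detection with logarithmic memory.

Maintains a variable-length window of a bounded signal in an exponential
histogram (rows of buckets holding 1, 2, 4, ... observations). After every
update each admissible split of the window into old|recent halves is tested:
if the two sub-window means differ by more than

    eps_cut = sqrt( (1 / (2 m)) * ln(4 / delta') )

where m is the harmonic mean of the two sub-window sizes and
delta' = delta / (number of tested cut points), the oldest bucket is dropped
and a change is flagged. The window therefore grows while the mean is
stable and shrinks automatically when it shifts, using O(log W) memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass
class _Bucket:
    total: float
    count: int


@dataclass
class ADWINDetector:
    """Adaptive-window mean estimator and change detector.

    Parameters
    ----------
    delta:
        Detection confidence; smaller means fewer false alarms and slower
        detection. 0.002 is the conventional default.
    max_buckets_per_row:
        Capacity M of each histogram row; a row holding more than M+1
        buckets compresses its two oldest into the next row.
    """

    delta: float = 0.002
    max_buckets_per_row: int = 5
    rows: list[list[_Bucket]] = field(default_factory=list)  # rows[i]: size 2^i
    total_count: int = 0
    total_sum: float = 0.0
    n_detections: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.delta < 1:
            raise ValueError("delta must be in (0, 1)")

    # -- bookkeeping ------------------------------------------------------

    def _insert(self, value: float) -> None:
        if not self.rows:
            self.rows.append([])
        self.rows[0].append(_Bucket(value, 1))
        self.total_sum += value
        self.total_count += 1
        # compress: merging the two oldest buckets of an over-full row
        i = 0
        while i < len(self.rows) and len(self.rows[i]) > self.max_buckets_per_row:
            old0 = self.rows[i].pop(0)
            old1 = self.rows[i].pop(0)
            if i + 1 == len(self.rows):
                self.rows.append([])
            self.rows[i + 1].append(_Bucket(old0.total + old1.total,
                                            old0.count + old1.count))
            i += 1

    def _drop_oldest_bucket(self) -> int:
        for row in reversed(self.rows):  # largest row holds the oldest data
            if row:
                b = row.pop(0)
                self.total_sum -= b.total
                self.total_count -= b.count
                return b.count
        return 0

    def _buckets_old_to_new(self):
        for row in reversed(self.rows):
            yield from row

    @property
    def n_buckets(self) -> int:
        return sum(len(r) for r in self.rows)

    # -- public API -------------------------------------------------------

    def update(self, value: float) -> tuple[bool, int]:
        """Add one observation in [0, 1].

        Returns ``(change_detected, n_dropped)`` where ``n_dropped`` counts
        observations discarded from the old end of the window.
        """
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"value {value} outside [0, 1]")
        self._insert(value)
        n_dropped = 0
        change = True
        detected = False
        while change:
            change = False
            buckets = list(self._buckets_old_to_new())
            n_cuts = len(buckets) - 1
            if n_cuts < 1:
                break
            delta_prime = self.delta / n_cuts
            ln_term = math.log(4.0 / delta_prime)
            sum0 = cnt0 = 0.0
            for b in buckets[:-1]:  # the newest bucket is never the old half
                sum0 += b.total
                cnt0 += b.count
                cnt1 = self.total_count - cnt0
                if cnt0 < 1 or cnt1 < 1:
                    continue
                mean0 = sum0 / cnt0
                mean1 = (self.total_sum - sum0) / cnt1
                m = 1.0 / (1.0 / cnt0 + 1.0 / cnt1)  # harmonic-mean size
                eps_cut = math.sqrt(ln_term / (2.0 * m))
                if abs(mean0 - mean1) >= eps_cut:
                    n_dropped += self._drop_oldest_bucket()
                    detected = True
                    change = True
                    break
        if detected:
            self.n_detections += 1
        return detected, n_dropped

    def estimate(self) -> float:
        """Mean of the current (post-drop) window."""
        if self.total_count < 1:
            raise ValueError("empty detector has no estimate")
        return self.total_sum / self.total_count

    @property
    def width(self) -> int:
        return self.total_count

    def dump(self) -> list[list[dict]]:
        """Debug dump of bucket rows (row 0 = newest, size-1 buckets)."""
        return [[{"sum": b.total, "count": b.count} for b in row]
                for row in self.rows]
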