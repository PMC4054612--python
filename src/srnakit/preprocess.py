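"""Read preprocessing: 3' adapter clipping, two-sided quality trimming and
minimum-length filtering.

The adapter search follows cutadapt's 3'-adapter semantics: every
occurrence of the adapter, full-length or as a prefix overhanging the read
end, is scored by Hamming distance; matches with an error rate above
``error_rate`` of the aligned length or an overlap below ``min_overlap``
are rejected; among valid matches the one with the most matching bases
wins (ties: fewer mismatches, then leftmost).  Quality trimming is the
BWA-style partial-sum rule applied first at the 3' end, then at the 5'
end: the cut maximising the sum of (cutoff - q) over the trailing
(leading) segment is removed when that sum is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .config import RunConfig
from .io import ReadRecord

_ENCODE = {"A": 1, "C": 2, "G": 3, "T": 4, "N": 5}


def _encode(seq: str) -> np.ndarray:
    # 'N' encodes to a value that never equals a genome/adapter base code,
    # so it always counts as a mismatch.
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class AdapterClipper:
    """Finds the best 3'-anchored adapter occurrence; caches per sequence.

    The cache is safe because the cut position depends only on the read
    sequence, and small RNA libraries are highly redundant.
    """

    def __init__(self, adapter: str, error_rate: float = 0.1, min_overlap: int = 3):
        if not adapter:
            raise ValueError("adapter must be non-empty")
        self.adapter = adapter.upper()
        self.error_rate = error_rate
        self.min_overlap = min_overlap
        self._arr = _encode(self.adapter)
        self._cache: dict[str, int] = {}

    def find_cut(self, sequence: str) -> int:
        """Return the cut index (read kept as ``sequence[:cut]``); ``len``
        if no valid adapter occurrence exists."""
        cut = self._cache.get(sequence)
        if cut is None:
            cut = self._scan(sequence)
            self._cache[sequence] = cut
        return cut

    def _scan(self, sequence: str) -> int:
        n, m = len(sequence), len(self.adapter)
        if n < self.min_overlap:
            return n
        # Fast path: an exact full-length occurrence has the maximum
        # possible number of matches and zero mismatches; leftmost wins.
        pos = sequence.find(self.adapter)
        if pos != -1:
            return pos
        seq = _encode(sequence)
        best_key = (-1, 0)  # (matches, -mismatches); leftmost wins ties
        best_cut = n
        for p in range(0, n - self.min_overlap + 1):
            aligned = min(m, n - p)
            mism = int(np.count_nonzero(seq[p : p + aligned] != self._arr[:aligned]))
            if mism > self.error_rate * aligned:
                continue
            matches = aligned - mism
            key = (matches, -mism)
            if key > best_key:
                best_key = key
                best_cut = p
        return best_cut


def clip_adapter(
    read: ReadRecord,
    adapter: str | AdapterClipper,
    error_rate: float = 0.1,
    min_overlap: int = 3,
) -> ReadRecord:
    """Remove the best-scoring 3' adapter occurrence from a read.

    Returns the read unchanged when no valid occurrence is found; an
    adapter match at position 0 yields an empty read (discarded later by
    the length filter).
    """
    clipper = (
        adapter
        if isinstance(adapter, AdapterClipper)
        else AdapterClipper(adapter, error_rate, min_overlap)
    )
    cut = clipper.find_cut(read.sequence)
    if cut >= len(read.sequence):
        return read
    return ReadRecord(read.read_id, read.sequence[:cut], read.quality[:cut])


def quality_trim(read: ReadRecord, cutoff: int) -> ReadRecord:
    """BWA-style partial-sum quality trimming at the 3' then the 5' end."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    q = read.quality
    n = len(q)
    if n == 0:
        return read
    x = cutoff - q.astype(np.int64)
    # 3' end: choose the suffix [k, n) with maximal positive sum(x).
    suffix = np.concatenate([np.cumsum(x[::-1])[::-1], [0]])  # suffix[k] = sum x[k:]
    k3 = int(np.argmax(suffix))
    if suffix[k3] <= 0:
        k3 = n
    # 5' end: prefix [0, k) with maximal positive sum over the remainder.
    x5 = x[:k3]
    prefix = np.concatenate([[0], np.cumsum(x5)])  # prefix[k] = sum x[:k]
    k5 = int(np.argmax(prefix))
    if prefix[k5] <= 0:
        k5 = 0
    if k5 == 0 and k3 == n:
        return read
    return ReadRecord(read.read_id, read.sequence[k5:k3], q[k5:k3])


@dataclass
class PreprocessReport:
    """Per-library read accounting and post-clip length histogram."""

    library: str = ""
    raw_reads: int = 0
    kept_reads: int = 0
    length_histogram: dict[int, int] = field(default_factory=dict)

    @property
    def discarded_reads(self) -> int:
        return self.raw_reads - self.kept_reads

    @property
    def discarded_pct(self) -> float:
        return 100.0 * self.discarded_reads / self.raw_reads if self.raw_reads else 0.0

    @property
    def length_mode(self) -> int | None:
        if not self.length_histogram:
            return None
        return max(self.length_histogram, key=lambda k: (self.length_histogram[k], -k))


def length_filter(
    reads: Iterable[ReadRecord], min_length: int, library: str = ""
) -> tuple[list[ReadRecord], PreprocessReport]:
    """Drop reads shorter than ``min_length`` (inclusive threshold)."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    report = PreprocessReport(library=library)
    kept: list[ReadRecord] = []
    for read in reads:
        report.raw_reads += 1
        if len(read) >= min_length:
            kept.append(read)
            report.kept_reads += 1
            L = len(read)
            report.length_histogram[L] = report.length_histogram.get(L, 0) + 1
    return kept, report


def preprocess_reads(
    reads: Iterable[ReadRecord],
    config: RunConfig,
    library: str = "",
    clipper: AdapterClipper | None = None,
) -> tuple[list[ReadRecord], PreprocessReport]:
    """Full preprocessing of one library: clip, trim, length-filter.

    The operation order follows the published protocol (adapter removal,
    then quality trimming); set ``config.trim_quality_first`` to invert it.
    """
    clipper = clipper or AdapterClipper(
        config.adapter, config.adapter_error_rate, config.adapter_min_overlap
    )

    def _stream() -> Iterator[ReadRecord]:
        for read in reads:
            if config.trim_quality_first:
                read = quality_trim(read, config.quality_cutoff)
                read = clip_adapter(read, clipper)
            else:
                read = clip_adapter(read, clipper)
                read = quality_trim(read, config.quality_cutoff)
            yield read

    return length_filter(_stream(), config.min_length, library=library)
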