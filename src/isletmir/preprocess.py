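"""3' adaptor clipping and read filtering.

Raw small RNA reads run through the insert into the 3' adaptor, so the
adaptor (or a prefix of it, at the read end) must be located and everything
from its leftmost occurrence removed. Reads shorter than 16 nt after clipping
cannot be mapped confidently, and reads that are mostly N carry no sequence
information; both are discarded, with removals counted by cause.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

DEFAULT_MIN_LENGTH = 16
DEFAULT_MAX_N_FRACTION = 0.5
DEFAULT_MIN_OVERLAP = 6


@dataclass
class CleanReadSet:
    """Retained reads plus an accounting of what was removed.

    Invariant: ``n_input == len(reads) + n_removed_short + n_removed_n``.
    """

    reads: list[tuple[str, str]]
    n_input: int
    n_removed_short: int
    n_removed_n: int
    n_clipped: int

    def length_histogram(self) -> dict[int, int]:
        return length_histogram(self.reads)


def clip_adaptor(
    sequence: str, adaptor: str, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> str:
    """Return the read prefix preceding the leftmost adaptor match.

    A match is an exact occurrence of an adaptor *prefix* of length >=
    ``min_overlap``; at the read end the remaining bases are compared against
    the corresponding adaptor prefix, so read-through into a truncated adaptor
    is still clipped. The read is returned unchanged when no match exists.
    """
    if not adaptor:
        raise ValueError("adaptor must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    n, la = len(sequence), len(adaptor)
    for i in range(0, n - min_overlap + 1):
        k = min(la, n - i)
        if sequence[i : i + k] == adaptor[:k]:
            return sequence[:i]
    return sequence


def filter_reads(
    reads: Iterable[tuple[str, str]],
    min_length: int = DEFAULT_MIN_LENGTH,
    max_n_fraction: float = DEFAULT_MAX_N_FRACTION,
) -> CleanReadSet:
    """Drop too-short and N-dominated reads (assumes clipping already done).

    Length is checked first: a read failing both criteria is counted once,
    as short.
    """
    kept: list[tuple[str, str]] = []
    n_short = n_n = n_input = 0
    for name, seq in reads:
        n_input += 1
        if len(seq) < min_length:
            n_short += 1
        elif seq.count("N") > max_n_fraction * len(seq):
            n_n += 1
        else:
            kept.append((name, seq))
    return CleanReadSet(
        reads=kept,
        n_input=n_input,
        n_removed_short=n_short,
        n_removed_n=n_n,
        n_clipped=0,
    )


def preprocess_reads(
    reads: Sequence[tuple[str, str]],
    adaptor: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_n_fraction: float = DEFAULT_MAX_N_FRACTION,
) -> CleanReadSet:
    """Clip the 3' adaptor from every read, then filter; the usual entry
    point for a raw library."""
    clipped = []
    n_clipped = 0
    for name, seq in reads:
        c = clip_adaptor(seq, adaptor, min_overlap)
        if len(c) < len(seq):
            n_clipped += 1
        clipped.append((name, c))
    out = filter_reads(clipped, min_length=min_length, max_n_fraction=max_n_fraction)
    out.n_clipped = n_clipped
    return out


def length_histogram(reads: Iterable[tuple[str, str]]) -> dict[int, int]:
    """Histogram of read lengths; sums to the number of reads. A peak near
    22 nt is the signature of a mature-miRNA-dominated library."""
    return dict(sorted(Counter(len(seq) for _, seq in reads).items()))
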