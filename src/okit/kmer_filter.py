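"""Canonical k-mer counting and the median-count read filter.

Reads of nuclear origin (including NUPT/NUMT chimeras) carry k-mers that
are rare relative to the deeply covered organellar genome; reads from
high-copy nuclear repeats carry k-mers that are far too frequent. Both are
removed by comparing each read's per-k-mer counts against thresholds
derived from the cohort median:

* ``rmkc`` — the read's median k-mer count, one number per read;
* ``mkc``  — the median of ``rmkc`` over all reads of one class;
* ``lkc = 0.3 x mkc`` and ``hkc = 5 x mkc`` — low/high count thresholds;
* a read is removed when more than one-fifth of its k-mer counts fall
  strictly below ``lkc`` or strictly above ``hkc``.

Counting is canonical (strand-collapsed): each k-length window is keyed by
the lexicographic minimum of the word and its reverse complement; windows
containing N are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from okit.io_formats import Read

__all__ = [
    "KmerCountTable",
    "ReadKmerProfile",
    "FilterThresholds",
    "canonical_kmers",
    "build_count_table",
    "read_profile",
    "compute_thresholds",
    "filter_reads",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"
_COMP_CODE = (3, 2, 1, 0)


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_CODE_BASE[code & 3])
        code >>= 2
    return "".join(reversed(out))


def _encoded_canonical(seq: str, k: int) -> List[int]:
    """Rolling 2-bit encoding of min(word, revcomp(word)) per window.

    Maintains forward and reverse-complement codes incrementally; windows
    containing a non-ACGT base are skipped. Integer comparison of the 2-bit
    codes equals lexicographic comparison of the words because A<C<G<T maps
    to 0<1<2<3.
    """
    n = len(seq)
    if k < 1 or n < k:
        return []
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    out: List[int] = []
    fwd = rev = 0
    valid = 0  # consecutive valid bases ending at current position
    for i, base in enumerate(seq):
        code = _BASE_CODE.get(base)
        if code is None:
            valid = 0
            fwd = rev = 0
            continue
        fwd = ((fwd << 2) | code) & mask
        rev = (rev >> 2) | (_COMP_CODE[code] << shift)
        valid += 1
        if valid >= k:
            out.append(fwd if fwd <= rev else rev)
    return out


def canonical_kmers(seq: str, k: int) -> List[str]:
    """All canonical k-mers of ``seq`` in window order.

    Each window of length k containing only ACGT contributes the
    lexicographic minimum of the word and its reverse complement; windows
    with N (or any other character) are skipped. A sequence shorter than k
    yields an empty list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return [_decode(c, k) for c in _encoded_canonical(seq.upper(), k)]


@dataclass
class KmerCountTable:
    """Counts of canonical k-mers across a read set (keys are 2-bit codes)."""

    k: int
    counts: Dict[int, int] = field(default_factory=dict)

    def count(self, canonical_code: int) -> int:
        return self.counts.get(canonical_code, 0)

    def count_word(self, word: str) -> int:
        """Count for a k-mer given as a string (canonicalized here)."""
        codes = _encoded_canonical(word.upper(), self.k)
        if len(codes) != 1:
            raise ValueError("word length must equal k and contain only ACGT")
        return self.count(codes[0])

    def items_as_words(self) -> Iterable[Tuple[str, int]]:
        for code, n in self.counts.items():
            yield _decode(code, self.k), n

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class ReadKmerProfile:
    read_id: str
    n_kmers: int
    rmkc: float
    frac_low: float
    frac_high: float

    @property
    def usable(self) -> bool:
        return self.n_kmers > 0


@dataclass
class FilterThresholds:
    """Cohort-level thresholds; lkc/hkc are fixed multiples of mkc."""

    mkc: float
    low_mult: float = 0.3
    high_mult: float = 5.0
    max_outlier_frac: float = 1.0 / 5.0

    @property
    def lkc(self) -> float:
        return self.low_mult * self.mkc

    @property
    def hkc(self) -> float:
        return self.high_mult * self.mkc


def build_count_table(reads: Sequence[Read], k: int = 31) -> KmerCountTable:
    """Tally canonical k-mers over a read set.

    Equivalent to a brute-force dictionary tally of :func:`canonical_kmers`
    over all reads; the sum of counts equals the number of valid windows.
    """
    if not reads:
        raise ValueError("no reads for counting")
    counts: Dict[int, int] = {}
    for r in reads:
        for code in _encoded_canonical(r.seq, k):
            counts[code] = counts.get(code, 0) + 1
    return KmerCountTable(k=k, counts=counts)


def _median(values: Sequence[float]) -> float:
    # statistics.median: mean of the two middle values for even n
    return float(median(values))


def read_profile(
    read: Read, table: KmerCountTable, thresholds: Optional[FilterThresholds] = None
) -> ReadKmerProfile:
    """Per-read k-mer count profile against a count table.

    ``rmkc`` is the median of the read's per-window counts (mean of the two
    middle values for even n). ``frac_low``/``frac_high`` are the fractions
    of counts strictly below ``lkc`` / strictly above ``hkc``; both are 0
    when no thresholds are supplied. A read with no valid k-mers yields an
    unusable profile (``n_kmers == 0``).
    """
    codes = _encoded_canonical(read.seq, table.k)
    if not codes:
        return ReadKmerProfile(read.id, 0, 0.0, 0.0, 0.0)
    counts = [table.count(c) for c in codes]
    rmkc = _median(counts)
    frac_low = frac_high = 0.0
    if thresholds is not None:
        n = len(counts)
        frac_low = sum(1 for c in counts if c < thresholds.lkc) / n
        frac_high = sum(1 for c in counts if c > thresholds.hkc) / n
    return ReadKmerProfile(read.id, len(counts), rmkc, frac_low, frac_high)


def compute_thresholds(
    profiles: Sequence[ReadKmerProfile],
    low_mult: float = 0.3,
    high_mult: float = 5.0,
    max_outlier_frac: float = 1.0 / 5.0,
) -> FilterThresholds:
    """Cohort thresholds from read profiles: mkc = median of rmkc."""
    rmkcs = [p.rmkc for p in profiles if p.usable]
    if not rmkcs:
        raise ValueError("no usable profiles to compute thresholds from")
    return FilterThresholds(
        mkc=_median(rmkcs),
        low_mult=low_mult,
        high_mult=high_mult,
        max_outlier_frac=max_outlier_frac,
    )


def filter_reads(
    reads: Sequence[Read],
    table: KmerCountTable,
    thresholds: FilterThresholds,
) -> Tuple[List[Read], List[Tuple[Read, str]]]:
    """Partition reads into (kept, removed-with-reason).

    A read is removed iff strictly more than ``max_outlier_frac`` of its
    k-mer counts are outliers (below lkc or above hkc); the reason is
    ``low_kmer`` when low outliers dominate (ties included), else
    ``high_kmer``. Reads with zero valid k-mers are removed as
    ``too_short``. Input order is preserved in both outputs.
    """
    kept: List[Read] = []
    removed: List[Tuple[Read, str]] = []
    for r in reads:
        prof = read_profile(r, table, thresholds)
        if not prof.usable:
            removed.append((r, "too_short"))
        elif prof.frac_low + prof.frac_high > thresholds.max_outlier_frac:
            reason = "low_kmer" if prof.frac_low >= prof.frac_high else "high_kmer"
            removed.append((r, reason))
        else:
            kept.append(r)
    return kept, removed
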