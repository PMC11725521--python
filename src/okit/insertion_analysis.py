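"""NUPT/NUMT identification, substitution spectra and siRNA enrichment.

Organellar DNA fragments inserted into the nuclear genome (NUPTs from the
plastid, NUMTs from the mitochondrion) decay roughly neutrally after
insertion, so their percent identity to the extant organellar genome
proxies insertion age. The workflow:

1. BLASTN HSPs of organelle-vs-nuclear alignments are filtered
   (identity > 80%, length > 100 bp, both strict), HSPs completely
   embedded in strictly longer HSPs are removed, and overlapping or
   book-ended intervals are merged; the merged interval's identity is the
   unweighted mean of its members.
2. Substitutions between nuclear copies and the organellar source are read
   from minimap2-style ``cs`` difference strings, collapsed onto the six
   strand-symmetric classes, and cytosine substitutions are resolved into
   the plant methylation contexts CG / CHG / CHH (H = A, C or T) using the
   organellar (ancestral) sequence.
3. siRNA-locus overlap with insertions is tested against a permutation
   null in which each feature is re-placed uniformly within its own
   chromosome.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from okit.io_formats import Hsp, PafRecord, revcomp

__all__ = [
    "MergedInsertion",
    "SubstitutionRecord",
    "SpectrumTable",
    "EnrichmentResult",
    "filter_hsps",
    "remove_embedded",
    "merge_insertions",
    "call_substitutions",
    "spectrum",
    "enrichment_test",
    "summarize",
]

SUBSTITUTION_CLASSES = (
    "C:G>T:A", "C:G>A:T", "C:G>G:C",
    "T:A>C:G", "T:A>A:T", "T:A>G:C",
)

CONTEXTS = ("CG", "CHG", "CHH")
_H = frozenset("ACT")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class MergedInsertion:
    """A nuclear interval of organellar origin (0-based half-open)."""

    chrom: str
    start: int
    end: int
    mean_identity: float
    n_hsps: int
    source: str  # NUPT | NUMT

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("insertion interval must satisfy end > start")
        if self.source not in ("NUPT", "NUMT"):
            raise ValueError("source must be NUPT or NUMT")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SubstitutionRecord:
    organelle_pos: int
    ref: str
    alt: str
    context: str = "NA"  # CG | CHG | CHH | NA

    def __post_init__(self):
        if self.ref == self.alt or self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError(f"bad substitution {self.ref}>{self.alt}")


@dataclass
class SpectrumTable:
    """Strand-collapsed substitution class counts with cytosine contexts."""

    class_counts: Dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in SUBSTITUTION_CLASSES}
    )
    context_counts: Dict[str, int] = field(default_factory=lambda: {c: 0 for c in CONTEXTS})
    denominators: Dict[str, int] = field(default_factory=lambda: {c: 0 for c in CONTEXTS})

    @property
    def total(self) -> int:
        return sum(self.class_counts.values())

    def class_fractions(self) -> Dict[str, float]:
        t = self.total
        return {c: (n / t if t else 0.0) for c, n in self.class_counts.items()}

    def context_rates(self) -> Dict[str, float]:
        """Cytosine substitutions per context site (needs denominators)."""
        return {
            c: (self.context_counts[c] / self.denominators[c] if self.denominators[c] else 0.0)
            for c in CONTEXTS
        }


@dataclass
class EnrichmentResult:
    observed_overlap: int
    null_mean: float
    fold: float
    p_empirical: float
    ci_low: float
    ci_high: float
    n_samples: int


# ---------------------------------------------------------------------------
# HSP filtering / merging

def filter_hsps(
    hsps: Sequence[Hsp], min_identity: float = 80.0, min_length: int = 100
) -> List[Hsp]:
    """Retain HSPs with pident > 80 and length > 100 bp (both strict)."""
    return [h for h in hsps if h.pident > min_identity and h.length > min_length]


def remove_embedded(hsps: Sequence[Hsp]) -> List[Hsp]:
    """Drop HSPs whose nuclear interval is contained (shared endpoints
    allowed) in a strictly longer HSP's interval on the same sequence.

    Exact-duplicate intervals keep one copy: highest bitscore, then input
    order. Output preserves input order of the survivors.
    """
    survivors: List[Optional[Hsp]] = list(hsps)
    by_chrom: Dict[str, List[int]] = {}
    for i, h in enumerate(hsps):
        by_chrom.setdefault(h.sseqid, []).append(i)
    for idxs in by_chrom.values():
        for i in idxs:
            hi = hsps[i]
            li = hi.send - hi.sstart
            for j in idxs:
                if i == j or survivors[i] is None:
                    continue
                hj = hsps[j]
                lj = hj.send - hj.sstart
                if hj.sstart <= hi.sstart and hi.send <= hj.send:
                    if lj > li:
                        survivors[i] = None
                        break
                    if lj == li and hi.sstart == hj.sstart:
                        # exact duplicate: keep highest bitscore, then first
                        if (hj.bitscore, -j) > (hi.bitscore, -i):
                            survivors[i] = None
                            break
    return [h for h in survivors if h is not None]


def merge_insertions(hsps: Sequence[Hsp], source: str) -> List[MergedInsertion]:
    """Merge overlapping or book-ended HSP intervals per nuclear sequence.

    Matches the interval-merge default of distance 0 (book-ended intervals
    merge). The merged identity is the unweighted mean of member pident.
    Output is sorted by (chrom, start) and the intervals per chromosome are
    disjoint.
    """
    by_chrom: Dict[str, List[Hsp]] = {}
    for h in hsps:
        by_chrom.setdefault(h.sseqid, []).append(h)
    out: List[MergedInsertion] = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda h: (h.sstart, h.send))
        cur: List[Hsp] = []
        cur_end = None
        for h in group:
            if cur and h.sstart > cur_end:
                out.append(_emit(chrom, cur, source))
                cur = []
            cur.append(h)
            cur_end = h.send if cur_end is None or h.send > cur_end else cur_end
        if cur:
            out.append(_emit(chrom, cur, source))
    return out


def _emit(chrom: str, members: List[Hsp], source: str) -> MergedInsertion:
    return MergedInsertion(
        chrom=chrom,
        start=min(h.sstart for h in members),
        end=max(h.send for h in members),
        mean_identity=float(np.mean([h.pident for h in members])),
        n_hsps=len(members),
        source=source,
    )


# ---------------------------------------------------------------------------
# Substitution calling from cs tags

_CS_TOKEN = re.compile(r"(:\d+|\*[a-z]{2}|[+\-][a-z]+|=[A-Za-z]+)")


def cytosine_context(seq: str, pos: int, ref: str) -> str:
    """Methylation context of a C:G site on the organellar sequence.

    For a pyrimidine-strand C at ``pos``: CG iff the next base is G; CHG
    iff next is H (A/C/T) and the base after is G; CHH iff both downstream
    bases are H. A reference G is resolved on the reverse complement
    (upstream bases, complemented). NA within 2 bases of a sequence end or
    when any inspected base is ambiguous.
    """
    n = len(seq)
    if ref == "C":
        if pos + 2 >= n:
            return "NA"
        b1, b2 = seq[pos + 1], seq[pos + 2]
    elif ref == "G":
        if pos - 2 < 0:
            return "NA"
        b1 = _COMP.get(seq[pos - 1], "N")
        b2 = _COMP.get(seq[pos - 2], "N")
    else:
        return "NA"
    if b1 == "G":
        return "CG"
    if b1 in _H:
        if b2 == "G":
            return "CHG"
        if b2 in _H:
            return "CHH"
    return "NA"


def _cs_substitutions(cs: str, rec: PafRecord, organelle_seq: str) -> Iterable[Tuple[int, str, str]]:
    """Yield (target_pos, ref, alt) for each substitution in a cs string.

    For '+' strand records the target cursor starts at tstart and advances;
    for '-' strand the cs string walks the reverse-complemented target, so
    positions map to tend-1 backwards and bases are complemented.
    """
    offset = 0  # bases of target consumed
    for tok in _CS_TOKEN.findall(cs):
        op = tok[0]
        if op == ":":
            offset += int(tok[1:])
        elif op == "=":
            offset += len(tok) - 1
        elif op == "*":
            ref, alt = tok[1].upper(), tok[2].upper()
            if rec.strand == "+":
                pos = rec.tstart + offset
            else:
                pos = rec.tend - 1 - offset
                ref, alt = _COMP.get(ref, "N"), _COMP.get(alt, "N")
            if ref in "ACGT" and alt in "ACGT" and ref != alt:
                yield pos, ref, alt
            offset += 1
        elif op == "-":
            offset += len(tok) - 1  # deletion from target consumed
        # '+' (insertion into query) consumes no target


def call_substitutions(
    paf_records: Sequence[PafRecord], organelle_seq: str
) -> List[SubstitutionRecord]:
    """Extract single-base substitutions from cs-tagged alignments of
    nuclear insertion copies (query) against the organellar genome (target).

    Indels and multi-base blocks are ignored; context is assigned from the
    organellar sequence (the pre-insertion state).
    """
    organelle_seq = organelle_seq.upper()
    out: List[SubstitutionRecord] = []
    for rec in paf_records:
        if rec.cs is None:
            raise ValueError(f"PAF record {rec.qname}: cs tag absent")
        for pos, ref, alt in _cs_substitutions(rec.cs, rec, organelle_seq):
            out.append(
                SubstitutionRecord(
                    organelle_pos=pos,
                    ref=ref,
                    alt=alt,
                    context=cytosine_context(organelle_seq, pos, ref),
                )
            )
    return out


def _collapse_class(ref: str, alt: str) -> str:
    """Map a substitution to its strand-collapsed class (pyrimidine ref)."""
    if ref in "GA":  # purine reference: complement both
        ref, alt = _COMP[ref], _COMP[alt]
    pair = "C:G" if ref == "C" else "T:A"
    alt_pair = {"T": "T:A", "A": "A:T", "G": "G:C", "C": "C:G"}[alt]
    return f"{pair}>{alt_pair}"


def spectrum(
    substitutions: Sequence[SubstitutionRecord],
    organelle_seq: Optional[str] = None,
    aligned_intervals: Optional[Sequence[Tuple[int, int]]] = None,
) -> SpectrumTable:
    """Tabulate the six strand-collapsed substitution classes.

    ``context_counts`` accumulates cytosine-class substitutions with a
    defined CG/CHG/CHH context. When the organellar sequence and the
    aligned target intervals are given, per-context site counts over those
    intervals are stored as denominators for rate normalization.
    """
    table = SpectrumTable()
    for s in substitutions:
        table.class_counts[_collapse_class(s.ref, s.alt)] += 1
        if s.ref in "CG" and s.context in CONTEXTS:
            table.context_counts[s.context] += 1
    if organelle_seq is not None and aligned_intervals is not None:
        seq = organelle_seq.upper()
        seen = set()
        for start, end in aligned_intervals:
            for i in range(max(start, 0), min(end, len(seq))):
                if i in seen:
                    continue
                seen.add(i)
                if seq[i] in "CG":
                    ctx = cytosine_context(seq, i, seq[i])
                    if ctx in CONTEXTS:
                        table.denominators[ctx] += 1
    return table


# ---------------------------------------------------------------------------
# Permutation enrichment test

def _prefix_coverage(
    intervals: List[Tuple[int, int]]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge intervals; return (starts, ends, cumulative length before each)."""
    merged: List[Tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    starts = np.array([s for s, _ in merged], dtype=np.int64)
    ends = np.array([e for _, e in merged], dtype=np.int64)
    cumlen = np.concatenate(([0], np.cumsum(ends - starts)))
    return starts, ends, cumlen


def _covered_below(prefix, x: np.ndarray) -> np.ndarray:
    """Annotation bases covered in [0, x) for each x (vectorized)."""
    starts, ends, cumlen = prefix
    j = np.searchsorted(starts, x, side="right") - 1
    jc = np.maximum(j, 0)
    partial = np.clip(np.minimum(x, ends[jc]) - starts[jc], 0, None)
    return np.where(j < 0, 0, cumlen[jc] + partial)


def enrichment_test(
    features: Sequence[Tuple[str, int, int]],
    annotations: Sequence[MergedInsertion],
    genome: Dict[str, int],
    n_samples: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation test of feature/annotation base overlap.

    ``observed_overlap`` is the total intersection in bases. The null
    re-places every feature uniformly within its own chromosome (length
    preserved; features may overlap each other) ``n_samples`` times.
    ``p_empirical = (1 + #{null >= observed}) / (1 + n_samples)``. The 95%
    CI is on the observed fold: ``observed / null_97.5`` to
    ``observed / null_2.5``, so under the null it covers fold = 1 at the
    nominal rate.
    """
    ann_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for a in annotations:
        ann_by_chrom.setdefault(a.chrom, []).append((a.start, a.end))
    prefix = {c: _prefix_coverage(ivs) for c, ivs in ann_by_chrom.items()}

    rng = np.random.default_rng(seed)
    observed = 0
    null = np.zeros(n_samples, dtype=np.int64)
    for chrom, start, end in features:
        if chrom not in genome:
            raise ValueError(f"feature chromosome {chrom!r} missing from genome sizes")
        length = end - start
        if length > genome[chrom]:
            raise ValueError(f"feature on {chrom} longer than its chromosome")
        if chrom in prefix:
            pfx = prefix[chrom]
            obs = _covered_below(pfx, np.array([end])) - _covered_below(pfx, np.array([start]))
            observed += int(obs[0])
            starts = rng.integers(0, genome[chrom] - length + 1, size=n_samples)
            null += _covered_below(pfx, starts + length) - _covered_below(pfx, starts)
        else:
            # chromosome without annotations contributes nothing but the
            # RNG stream stays aligned across inputs
            rng.integers(0, genome[chrom] - length + 1, size=n_samples)

    null_mean = float(null.mean()) if n_samples else 0.0
    fold = observed / null_mean if null_mean > 0 else 0.0
    p = (1 + int((null >= observed).sum())) / (1 + n_samples)
    if null_mean > 0:
        lo_q, hi_q = np.percentile(null, [2.5, 97.5])
        ci_low = observed / hi_q if hi_q > 0 else (np.inf if observed > 0 else 0.0)
        ci_high = observed / lo_q if lo_q > 0 else np.inf
    else:
        ci_low = ci_high = 0.0
    return EnrichmentResult(
        observed_overlap=observed,
        null_mean=null_mean,
        fold=fold,
        p_empirical=p,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_samples=n_samples,
    )


# ---------------------------------------------------------------------------
# Cross-species summaries

def summarize(species_table: pd.DataFrame) -> Dict[str, object]:
    """Cross-species summary of insertion content.

    ``species_table`` needs one row per species with columns
    ``nuclear_genome_size``, ``nupt_total_len``, ``numt_total_len`` and
    optionally ``nupt_mean_identity`` / ``numt_mean_identity``. Pearson
    correlations are reported on both raw and log10-scaled cumulative
    lengths; with fewer than 3 rows correlations are undefined (NaN).
    """
    out: Dict[str, object] = {"table": species_table.copy()}

    def _pearson(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            return float("nan")
        return float(stats.pearsonr(x, y)[0])

    pairs = {
        "r_nupt_vs_genome": ("nupt_total_len", "nuclear_genome_size"),
        "r_numt_vs_genome": ("numt_total_len", "nuclear_genome_size"),
        "r_nupt_vs_numt": ("nupt_total_len", "numt_total_len"),
    }
    for name, (a, b) in pairs.items():
        out[name] = _pearson(species_table[a], species_table[b])
        out[name + "_log"] = _pearson(
            np.log10(np.maximum(species_table[a], 1)),
            np.log10(np.maximum(species_table[b], 1)),
        )
    if {"nupt_mean_identity", "numt_mean_identity"} <= set(species_table.columns):
        out["r_identity_nupt_vs_numt"] = _pearson(
            species_table["nupt_mean_identity"], species_table["numt_mean_identity"]
        )
    return out


def identity_histogram(
    insertions: Sequence[MergedInsertion], bin_width: float = 1.0
) -> pd.DataFrame:
    """Cumulative insertion length per identity bin over (80, 100]."""
    edges = np.arange(80.0, 100.0 + bin_width, bin_width)
    lengths = np.zeros(len(edges) - 1, dtype=np.int64)
    for ins in insertions:
        b = int(np.clip(np.searchsorted(edges, ins.mean_identity, side="left") - 1, 0, len(lengths) - 1))
        lengths[b] += ins.length
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "cumulative_length": lengths}
    )
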