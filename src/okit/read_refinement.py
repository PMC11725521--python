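"""Graph-alignment refinement of the mitochondrion-labeled read pool.

Chloroplast reads misclassified as mitochondrial align nearly end-to-end
to the chloroplast assembly graph; aligning against the graph (rather than
a linearized sequence) avoids the clipped alignments that circular DNA and
heteroplasmy would otherwise cause. A read is discarded when any of its
alignments has left and right query clips of at most ``max_clip`` bases
and identity strictly above ``min_identity``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

from okit.io_formats import GafRecord, Read

__all__ = ["RefinementThresholds", "is_chloroplast_like", "remove_chloroplast_reads"]


@dataclass
class RefinementThresholds:
    max_clip: int = 100
    min_identity: float = 0.95

    def __post_init__(self):
        if self.max_clip < 0:
            raise ValueError("max_clip must be >= 0")
        if not (0.0 < self.min_identity < 1.0):
            raise ValueError("min_identity must be in (0, 1)")


def is_chloroplast_like(rec: GafRecord, t: RefinementThresholds) -> bool:
    """True iff the alignment is almost end-to-end at high identity:
    qstart <= max_clip, (qlen - qend) <= max_clip (both inclusive) and
    matches/blocklen > min_identity (strict)."""
    if rec.blocklen == 0:
        raise ValueError(f"GAF record {rec.qname}: zero block length")
    left_clip = rec.qstart
    right_clip = rec.qlen - rec.qend
    return (
        left_clip <= t.max_clip
        and right_clip <= t.max_clip
        and rec.matches / rec.blocklen > t.min_identity
    )


def remove_chloroplast_reads(
    reads: Sequence[Read],
    gaf: Sequence[GafRecord],
    t: RefinementThresholds = RefinementThresholds(),
) -> Tuple[List[Read], Set[str]]:
    """Drop reads with any chloroplast-like alignment; unaligned reads kept.

    Returns (retained mitochondrial reads, ids of removed reads); input
    order is preserved.
    """
    flagged: Dict[str, bool] = {}
    for rec in gaf:
        if is_chloroplast_like(rec, t):
            flagged[rec.qname] = True
    removed_ids = {r.id for r in reads if flagged.get(r.id, False)}
    kept = [r for r in reads if r.id not in removed_ids]
    return kept, removed_ids
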