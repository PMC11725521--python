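"""Assembly-graph topology classification and isomer extraction.

A complete chloroplast assembly graph from a typical land plant collapses
to three segments — the large single copy (LSC), the small single copy
(SSC) and one inverted repeat (IR) — connected by four links so that two
circular walks exist: LSC·IR·SSC·rc(IR) and LSC·IR·rc(SSC)·rc(IR). These
are the two heteroplasmic isomers that coexist equimolarly in vivo,
differing only in the relative orientation of SSC and LSC. Species that
have lost the IR assemble to a single self-circularizing segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

from okit.io_formats import AssemblyGraph, Link, PafRecord, Segment, revcomp

__all__ = [
    "TopologyCall",
    "IsomerPair",
    "canonicalize_links",
    "classify_structure",
    "extract_isomers",
    "label_chloroplast_contigs",
]

logger = logging.getLogger(__name__)

MIN_SEGMENT_LEN = 50  # isolated segments shorter than this are assembler debris


def _flip(orient: str) -> str:
    return "-" if orient == "+" else "+"


def _link_key(l: Link) -> tuple:
    return (l.from_id, l.from_orient, l.to_id, l.to_orient)


def canonicalize_links(links: Sequence[Link]) -> List[Link]:
    """Replace each link by the lexicographically smaller of itself and its
    orientation-flipped complement; collapse duplicates (input order kept)."""
    seen = set()
    out: List[Link] = []
    for l in links:
        comp = Link(l.to_id, _flip(l.to_orient), l.from_id, _flip(l.from_orient), l.overlap)
        canon = l if _link_key(l) <= _link_key(comp) else comp
        key = _link_key(canon)
        if key not in seen:
            seen.add(key)
            out.append(canon)
    return out


@dataclass
class TopologyCall:
    """Result of structural classification of an assembly graph."""

    klass: str  # quadripartite | circular | incomplete | other
    lsc_id: Optional[str] = None
    ssc_id: Optional[str] = None
    ir_id: Optional[str] = None
    circle_id: Optional[str] = None
    # oriented walk (segment_id, orient) realizing isomer A, quadripartite only
    walk: Optional[List[Tuple[str, str]]] = None


@dataclass
class IsomerPair:
    """The two heteroplasmic chloroplast configurations."""

    isomer_a: str
    isomer_b: str
    note: str = ""


def _prepare(graph: AssemblyGraph) -> Tuple[List[Segment], List[Link]]:
    if not graph.segments:
        raise ValueError("empty assembly graph")
    links = canonicalize_links(graph.links)
    # degree per (segment, end); end "s"=start, "e"=end
    degree: Dict[Tuple[str, str], int] = {}
    for l in links:
        degree[(l.from_id, "e" if l.from_orient == "+" else "s")] = (
            degree.get((l.from_id, "e" if l.from_orient == "+" else "s"), 0) + 1
        )
        degree[(l.to_id, "s" if l.to_orient == "+" else "e")] = (
            degree.get((l.to_id, "s" if l.to_orient == "+" else "e"), 0) + 1
        )
    # prune short isolated debris
    kept_segments = []
    for s in graph.segments:
        deg = degree.get((s.id, "s"), 0) + degree.get((s.id, "e"), 0)
        slen = s.length if s.length is not None else (len(s.seq) if s.seq else 0)
        if deg == 0 and slen < MIN_SEGMENT_LEN:
            logger.warning("pruning short isolated segment %s (%d bp)", s.id, slen)
            continue
        kept_segments.append(s)
    kept_ids = {s.id for s in kept_segments}
    links = [l for l in links if l.from_id in kept_ids and l.to_id in kept_ids]
    return kept_segments, links


def _seg_len(s: Segment) -> int:
    return s.length if s.length is not None else len(s.seq or "")


def _find_quadripartite_walk(
    singles: List[Segment], ir: Segment, linkset: set
) -> Optional[List[Tuple[str, str]]]:
    """Search for the alternating circuit A→IR→B→rc(IR)→A.

    Tries both orderings of the single-copy segments and all orientation
    combinations; returns the oriented walk for the first circuit whose four
    links are all present in the canonical link set.
    """
    r = ir.id
    for a, b in ((singles[0], singles[1]), (singles[1], singles[0])):
        for oa, orr, ob in product("+-", repeat=3):
            walk_links = [
                Link(a.id, oa, r, orr),
                Link(r, orr, b.id, ob),
                Link(b.id, ob, r, _flip(orr)),
                Link(r, _flip(orr), a.id, oa),
            ]
            if all(_link_key(canonicalize_links([wl])[0]) in linkset for wl in walk_links):
                return [(a.id, oa), (r, orr), (b.id, ob), (r, _flip(orr))]
    return None


def classify_structure(graph: AssemblyGraph) -> TopologyCall:
    """Classify a (canonicalized) assembly graph.

    quadripartite: exactly 3 segments and 4 canonical links, one segment
    (the IR) incident to all four, the two single-copy segments incident to
    two each, and the alternating circuit LSC→IR→SSC→rc(IR) present.
    circular: a single segment whose only link joins its end to its start.
    incomplete: some segment end has degree 0. Anything else: other.
    """
    segments, links = _prepare(graph)
    if not segments:
        raise ValueError("empty assembly graph after pruning")

    # self-loops on a candidate IR segment are assembler artifacts; drop for
    # the quadripartite check but keep them for the single-circle check
    if len(segments) == 1:
        s = segments[0]
        self_circ = Link(s.id, "+", s.id, "+")
        if len(links) == 1 and _link_key(links[0]) == _link_key(self_circ):
            return TopologyCall(klass="circular", circle_id=s.id)

    if len(segments) == 3:
        incidence: Dict[str, int] = {s.id: 0 for s in segments}
        nonloop = []
        for l in links:
            if l.from_id == l.to_id:
                logger.warning("dropping self-loop on segment %s before classification", l.from_id)
                continue
            nonloop.append(l)
            incidence[l.from_id] += 1
            incidence[l.to_id] += 1
        if len(nonloop) == 4:
            by_inc = sorted(segments, key=lambda s: incidence[s.id])
            if incidence[by_inc[2].id] == 4 and all(incidence[s.id] == 2 for s in by_inc[:2]):
                ir = by_inc[2]
                singles = sorted(by_inc[:2], key=lambda s: (-_seg_len(s), s.id))
                linkset = {_link_key(l) for l in nonloop}
                walk = _find_quadripartite_walk(singles, ir, linkset)
                if walk is not None:
                    # LSC = longer single copy; ties broken lexicographically
                    lsc, ssc = singles[0], singles[1]
                    if walk[0][0] != lsc.id:
                        # rotate the walk so it starts at the LSC
                        walk = walk[2:] + walk[:2]
                    return TopologyCall(
                        klass="quadripartite",
                        lsc_id=lsc.id,
                        ssc_id=ssc.id,
                        ir_id=ir.id,
                        walk=walk,
                    )

    # dangling ends?
    occupied = set()
    for l in links:
        occupied.add((l.from_id, "e" if l.from_orient == "+" else "s"))
        occupied.add((l.to_id, "s" if l.to_orient == "+" else "e"))
    for s in segments:
        if (s.id, "s") not in occupied or (s.id, "e") not in occupied:
            return TopologyCall(klass="incomplete")
    return TopologyCall(klass="other")


def _oriented_seq(seg: Segment, orient: str) -> str:
    if seg.seq is None:
        raise ValueError(f"segment {seg.id} has no sequence")
    return seg.seq if orient == "+" else revcomp(seg.seq)


def _walk_overlaps(graph: AssemblyGraph, walk: List[Tuple[str, str]]) -> List[int]:
    """Overlap consumed at each of the circular walk's junctions."""
    canon = canonicalize_links(graph.links)
    by_key = {_link_key(l): l.overlap for l in canon}
    overlaps = []
    n = len(walk)
    for i in range(n):
        a_id, a_o = walk[i]
        b_id, b_o = walk[(i + 1) % n]
        key = _link_key(canonicalize_links([Link(a_id, a_o, b_id, b_o)])[0])
        overlaps.append(by_key.get(key, 0))
    return overlaps


def extract_isomers(graph: AssemblyGraph, call: TopologyCall):
    """Emit the heteroplasmic isomer pair (quadripartite) or the single
    circular sequence.

    Isomer A follows the classified walk LSC·IR·SSC·rc(IR), trimming each
    link's overlap from the successor segment; isomer B is identical except
    the SSC contribution is reverse-complemented.
    """
    if call.klass == "circular":
        return graph.segment(call.circle_id).seq
    if call.klass != "quadripartite" or call.walk is None:
        raise ValueError("no walkable structure (call is %s)" % call.klass)
    overlaps = _walk_overlaps(graph, call.walk)

    def build(flip_ssc: bool) -> str:
        parts = []
        for i, (sid, orient) in enumerate(call.walk):
            o = orient
            if flip_ssc and sid == call.ssc_id:
                o = _flip(orient)
            seq = _oriented_seq(graph.segment(sid), o)
            trim = overlaps[i - 1] if i > 0 else overlaps[-1]
            # overlap of the incoming link is trimmed from this successor;
            # for i == 0 the incoming link is the closing one (index -1)
            parts.append(seq[trim:] if trim else seq)
        return "".join(parts)

    return IsomerPair(
        isomer_a=build(False),
        isomer_b=build(True),
        note=f"lsc={call.lsc_id} ir={call.ir_id} ssc={call.ssc_id}",
    )


def label_chloroplast_contigs(
    contigs: Sequence[Segment],
    paf: Sequence[PafRecord],
    min_coverage: float = 0.90,
    min_similarity: float = 0.95,
) -> Dict[str, str]:
    """Label contigs as chloroplast when alignments to the chloroplast
    genome cover >90% of the contig at >95% similarity (both strict).

    Coverage is the union of query intervals over the contig length;
    similarity is total matches over total block length.
    """
    by_id = {c.id: c for c in contigs}
    cov_ivs: Dict[str, List[Tuple[int, int]]] = {c.id: [] for c in contigs}
    matches: Dict[str, int] = {c.id: 0 for c in contigs}
    blocks: Dict[str, int] = {c.id: 0 for c in contigs}
    for rec in paf:
        if rec.qname not in by_id:
            raise ValueError(f"alignment references unknown contig {rec.qname!r}")
        cov_ivs[rec.qname].append((rec.qstart, rec.qend))
        matches[rec.qname] += rec.matches
        blocks[rec.qname] += rec.blocklen

    labels: Dict[str, str] = {}
    for cid, c in by_id.items():
        ivs = sorted(cov_ivs[cid])
        covered = 0
        cur_s = cur_e = None
        for s, e in ivs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            covered += cur_e - cur_s
        clen = _seg_len(c)
        coverage = covered / clen if clen else 0.0
        similarity = matches[cid] / blocks[cid] if blocks[cid] else 0.0
        labels[cid] = (
            "chloroplast" if coverage > min_coverage and similarity > min_similarity else "other"
        )
    return labels
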