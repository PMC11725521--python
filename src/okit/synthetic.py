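"""Seeded synthetic fixtures for every pipeline input.

Generates, with full ground truth: a quadripartite chloroplast genome
(LSC + IR + SSC + inverted IR) and its truth assembly graph and isomer
pair; circular/linear mitochondrial sequences (optionally with a small
extra circle); a nuclear genome carrying NUPT/NUMT insertions of
programmable age and substitution bias; HiFi-like reads with
organelle/nuclear copy-number asymmetry; classifier-style labels with
programmable confusion; and oracle stand-ins for the assembler and graph
aligner so the iterative pipeline is testable without external binaries.

Every generator is bit-reproducible under a fixed seed. The read model is
substitution-only (no homopolymer indels) with lognormal lengths; defaults
emulate HiFi at ~0.1% error. Copy-ratio defaults echo the coverage
asymmetry of real whole-plant DNA extractions: chloroplast 50x,
mitochondrion 20x, nuclear 1x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from okit.graph_topology import IsomerPair
from okit.insertion_analysis import SubstitutionRecord, cytosine_context
from okit.io_formats import (
    AssemblyGraph,
    GafRecord,
    Link,
    PafRecord,
    Read,
    Segment,
    revcomp,
)

__all__ = [
    "ChloroplastTruth",
    "InsertionTruth",
    "FixtureTruth",
    "random_sequence",
    "make_quadripartite_genome",
    "make_mitochondrion",
    "plant_insertions",
    "simulate_reads",
    "class_labels_from_origins",
    "stub_classifier",
    "oracle_assembler",
    "oracle_graph_aligner",
    "downsample_reads",
    "default_fixture",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


@dataclass
class ChloroplastTruth:
    genome: str  # LSC + IR + SSC + revcomp(IR)
    lsc: Tuple[int, int]
    ira: Tuple[int, int]
    ssc: Tuple[int, int]
    irb: Tuple[int, int]
    graph: AssemblyGraph
    isomers: IsomerPair


@dataclass
class InsertionTruth:
    """One planted insertion with its recorded decay events."""

    chrom: str
    start: int
    end: int
    source: str  # NUPT | NUMT
    organelle_start: int
    organelle_end: int
    identity: float  # planted target identity (percent)
    substitutions: List[SubstitutionRecord] = field(default_factory=list)


@dataclass
class FixtureTruth:
    chloroplast: Optional[ChloroplastTruth] = None
    mito_sequences: Dict[str, str] = field(default_factory=dict)
    mito_circular: Dict[str, bool] = field(default_factory=dict)
    mito_genes: List[str] = field(default_factory=list)
    nuclear_seq: Optional[str] = None
    insertions: List[InsertionTruth] = field(default_factory=list)
    read_labels: Dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Genomes

def make_quadripartite_genome(
    lsc_len: int = 12000, ssc_len: int = 5000, ir_len: int = 3000, seed: int = 0, k: int = 31
) -> ChloroplastTruth:
    """Chloroplast genome LSC·IRa·SSC·IRb with IRb = revcomp(IRa), plus the
    truth 3-segment assembly graph and both heteroplasmic isomers."""
    if min(lsc_len, ssc_len, ir_len) < 4 * k:
        raise ValueError(f"all region lengths must be >= 4*k = {4 * k}")
    rng = np.random.default_rng(seed)
    lsc = random_sequence(lsc_len, rng)
    ir = random_sequence(ir_len, rng)
    ssc = random_sequence(ssc_len, rng)
    genome = lsc + ir + ssc + revcomp(ir)
    graph = AssemblyGraph(
        segments=[Segment("LSC", lsc), Segment("IR", ir), Segment("SSC", ssc)],
        links=[
            Link("LSC", "+", "IR", "+"),
            Link("IR", "+", "SSC", "+"),
            Link("SSC", "+", "IR", "-"),
            Link("IR", "-", "LSC", "+"),
        ],
    )
    isomers = IsomerPair(
        isomer_a=genome,
        isomer_b=lsc + ir + revcomp(ssc) + revcomp(ir),
        note="synthetic truth",
    )
    return ChloroplastTruth(
        genome=genome,
        lsc=(0, lsc_len),
        ira=(lsc_len, lsc_len + ir_len),
        ssc=(lsc_len + ir_len, lsc_len + ir_len + ssc_len),
        irb=(lsc_len + ir_len + ssc_len, len(genome)),
        graph=graph,
        isomers=isomers,
    )


def make_mitochondrion(
    main_len: int = 30000,
    small_circle_len: int = 0,
    n_genes: int = 38,
    seed: int = 1,
) -> Tuple[Dict[str, str], Dict[str, bool], List[str]]:
    """Mitochondrial sequences (a main circle, optionally a small circle)
    and the list of conserved genes deemed present in the assembly.

    Gene content is carried as truth metadata for the stub gene-search
    adapter rather than as embedded coding sequence; completeness scoring
    consumes hit tables, not sequence.
    """
    from okit.completeness import DEFAULT_PANEL_GENES

    rng = np.random.default_rng(seed)
    seqs = {"mito_main": random_sequence(main_len, rng)}
    circ = {"mito_main": True}
    if small_circle_len:
        seqs["mito_small"] = random_sequence(small_circle_len, rng)
        circ["mito_small"] = True
    genes = list(DEFAULT_PANEL_GENES[:n_genes])
    return seqs, circ, genes


# ---------------------------------------------------------------------------
# Insertions

DEFAULT_CTX_BIAS = {
    # class probabilities for planted substitutions; C:G>T:A dominates
    "C:G>T:A": 0.60,
    "C:G>A:T": 0.08,
    "C:G>G:C": 0.07,
    "T:A>C:G": 0.10,
    "T:A>A:T": 0.08,
    "T:A>G:C": 0.07,
}
# among C:G>T:A events, the fraction placed at CG / CHG / CHH context sites
DEFAULT_CT_CONTEXT_WEIGHTS = {"CG": 0.6, "CHG": 0.3, "CHH": 0.1}


def _site_contexts(seq: str) -> Dict[str, List[int]]:
    """Positions of C/G bases per methylation context in a sequence."""
    out: Dict[str, List[int]] = {"CG": [], "CHG": [], "CHH": []}
    for i, b in enumerate(seq):
        if b in "CG":
            ctx = cytosine_context(seq, i, b)
            if ctx in out:
                out[ctx].append(i)
    return out


def _mutate_fragment(
    fragment: str,
    org_start: int,
    organelle_seq: str,
    n_subs: int,
    ctx_bias: Dict[str, float],
    ct_context_weights: Dict[str, float],
    rng: np.random.Generator,
) -> Tuple[str, List[SubstitutionRecord]]:
    """Apply n_subs substitutions to a fragment under class/context bias.

    Returns the mutated fragment and truth records positioned on the
    organellar genome. Context is taken from the full organellar sequence
    so boundary sites resolve exactly as the caller will see them.
    """
    classes = list(ctx_bias)
    probs = np.array([ctx_bias[c] for c in classes], dtype=float)
    probs = probs / probs.sum()

    by_ref: Dict[str, List[int]] = {"C": [], "G": [], "T": [], "A": []}
    for i, b in enumerate(fragment):
        if b in by_ref:
            by_ref[b].append(i)
    ctx_sites = {
        ctx: [i for i in _site_contexts(fragment)[ctx]]
        for ctx in ("CG", "CHG", "CHH")
    }
    used: set = set()
    frag = list(fragment)
    records: List[SubstitutionRecord] = []

    def pick(pool: List[int]) -> Optional[int]:
        pool = [i for i in pool if i not in used]
        if not pool:
            return None
        return int(pool[rng.integers(0, len(pool))])

    ctx_names = list(ct_context_weights)
    ctx_probs = np.array([ct_context_weights[c] for c in ctx_names], dtype=float)
    ctx_probs = ctx_probs / ctx_probs.sum()

    drawn = rng.choice(len(classes), size=n_subs, p=probs)
    for ci in drawn:
        klass = classes[ci]
        pyr_ref, pyr_alt = klass[0], klass[4]  # e.g. "C:G>T:A" -> C, T
        if klass.startswith("C:G"):
            ctx = ctx_names[int(rng.choice(len(ctx_names), p=ctx_probs))]
            pos = pick(ctx_sites[ctx])
            if pos is None:
                pos = pick(by_ref["C"] + by_ref["G"])
        else:
            pos = pick(by_ref["T"] + by_ref["A"])
        if pos is None:
            continue  # fragment exhausted for this class; planted count may undershoot
        used.add(pos)
        ref = fragment[pos]
        if ref in ("C", "T"):
            alt = pyr_alt
        else:  # purine strand: complement the class alt
            alt = {"A": "T", "C": "G", "G": "C", "T": "A"}[pyr_alt]
        frag[pos] = alt
        org_pos = org_start + pos
        records.append(
            SubstitutionRecord(
                organelle_pos=org_pos,
                ref=ref,
                alt=alt,
                context=cytosine_context(organelle_seq, org_pos, ref),
            )
        )
    records.sort(key=lambda r: r.organelle_pos)
    return "".join(frag), records


def plant_insertions(
    nuclear_len: int,
    organelle_seq: str,
    n: int,
    identity_targets: Sequence[float],
    ctx_bias: Optional[Dict[str, float]] = None,
    ct_context_weights: Optional[Dict[str, float]] = None,
    fragment_len: int = 1000,
    source: str = "NUPT",
    seed: int = 0,
    chrom: str = "nuc1",
) -> Tuple[str, List[InsertionTruth]]:
    """Plant n mutated organelle fragments into a random nuclear background.

    Each fragment of ``fragment_len`` bases is copied from a random
    position of the organellar genome, mutated down to its target identity
    (round((1 - identity/100) * len) substitutions) under the class/context
    bias, and inserted at non-overlapping uniform positions with at least
    200 bp of nuclear spacer between insertions and from the ends.
    """
    if ctx_bias is None:
        ctx_bias = DEFAULT_CTX_BIAS
    if ct_context_weights is None:
        ct_context_weights = DEFAULT_CT_CONTEXT_WEIGHTS
    rng = np.random.default_rng(seed)
    organelle_seq = organelle_seq.upper()
    if any(not (80.0 < t <= 100.0) for t in identity_targets):
        raise ValueError("identity targets must lie in (80, 100]")

    pad = 200
    if n * (fragment_len + pad) + pad > nuclear_len:
        raise ValueError("insertions cannot fit disjointly in the nuclear sequence")
    background = random_sequence(nuclear_len, rng)

    # choose non-overlapping slots left-to-right
    free = nuclear_len - n * fragment_len - (n + 1) * pad
    gaps = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1)))
    positions = []
    cursor = 0
    for i in range(n):
        cursor += pad + int(gaps[i])
        positions.append(cursor)
        cursor += fragment_len

    truths: List[InsertionTruth] = []
    pieces: List[str] = []
    prev = 0
    for i, pos in enumerate(positions):
        target = float(identity_targets[i % len(identity_targets)])
        org_start = int(rng.integers(0, len(organelle_seq) - fragment_len + 1))
        fragment = organelle_seq[org_start : org_start + fragment_len]
        n_subs = int(round((1.0 - target / 100.0) * fragment_len))
        mutated, records = _mutate_fragment(
            fragment, org_start, organelle_seq, n_subs, ctx_bias, ct_context_weights, rng
        )
        pieces.append(background[prev:pos])
        pieces.append(mutated)
        prev = pos + fragment_len
        truths.append(
            InsertionTruth(
                chrom=chrom,
                start=pos,
                end=pos + fragment_len,
                source=source,
                organelle_start=org_start,
                organelle_end=org_start + fragment_len,
                identity=target,
                substitutions=records,
            )
        )
    pieces.append(background[prev:])
    return "".join(pieces), truths


def insertion_paf_records(
    nuclear_seq: str, truths: Sequence[InsertionTruth], organelle_seq: str
) -> List[PafRecord]:
    """Truth cs-tagged PAF of each planted insertion vs its organelle source
    (gap-free by construction, so the cs string is matches + substitutions)."""
    organelle_seq = organelle_seq.upper()
    out = []
    for i, t in enumerate(truths):
        q = nuclear_seq[t.start : t.end]
        ref = organelle_seq[t.organelle_start : t.organelle_end]
        cs_parts: List[str] = []
        run = 0
        mm = 0
        for a, b in zip(ref, q):
            if a == b:
                run += 1
            else:
                if run:
                    cs_parts.append(f":{run}")
                    run = 0
                cs_parts.append(f"*{a.lower()}{b.lower()}")
                mm += 1
        if run:
            cs_parts.append(f":{run}")
        L = len(q)
        out.append(
            PafRecord(
                qname=f"{t.chrom}:{t.start}-{t.end}",
                qlen=L, qstart=0, qend=L, strand="+",
                tname="organelle", tlen=len(organelle_seq),
                tstart=t.organelle_start, tend=t.organelle_end,
                matches=L - mm, blocklen=L, mapq=60, cs="".join(cs_parts),
            )
        )
    return out


def insertion_blast6_lines(truths: Sequence[InsertionTruth], qseqid: str = "organelle") -> List[str]:
    """Truth BLAST outfmt-6 rows (1-based inclusive subject coordinates)."""
    rows = []
    for t in truths:
        L = t.end - t.start
        mism = int(round((1.0 - t.identity / 100.0) * L))
        pident = 100.0 * (L - mism) / L
        rows.append(
            "\t".join(
                str(x)
                for x in (
                    qseqid, t.chrom, f"{pident:.2f}", L, mism, 0,
                    t.organelle_start + 1, t.organelle_end,
                    t.start + 1, t.end,
                    "1e-50", 2 * L,
                )
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Reads

def simulate_reads(
    genomes: Dict[str, Tuple[str, bool, float]],
    coverage: float = 30.0,
    mean_len: float = 2000.0,
    len_sd: float = 300.0,
    error_rate: float = 0.001,
    seed: int = 0,
    label_of: Optional[Dict[str, str]] = None,
) -> Tuple[List[Read], Dict[str, str]]:
    """HiFi-like reads from a set of genomes.

    ``genomes`` maps name -> (sequence, circular, copy_ratio); the read
    count per genome is coverage * copy_ratio * len(genome) / mean_len.
    Lengths are lognormal with the requested mean and SD; errors are
    uniform substitutions at ``error_rate``. Circular genomes are sampled
    across the origin. Returns reads plus a read_id -> true-origin map
    (the genome name, or the value from ``label_of``).
    """
    rng = np.random.default_rng(seed)
    # lognormal parameterized by desired arithmetic mean/sd
    sigma2 = math.log(1.0 + (len_sd / mean_len) ** 2)
    mu = math.log(mean_len) - sigma2 / 2.0
    reads: List[Read] = []
    labels: Dict[str, str] = {}
    for name in sorted(genomes):
        seq, circular, ratio = genomes[name]
        glen = len(seq)
        n_reads = int(round(coverage * ratio * glen / mean_len))
        doubled = seq + seq if circular else seq
        for i in range(n_reads):
            rlen = int(np.clip(rng.lognormal(mu, math.sqrt(sigma2)), 100, None))
            rlen = min(rlen, glen)
            max_start = glen - 1 if circular else glen - rlen
            start = int(rng.integers(0, max_start + 1))
            rseq = doubled[start : start + rlen]
            if error_rate > 0:
                arr = np.frombuffer(rseq.encode(), dtype=np.uint8).copy()
                errs = np.flatnonzero(rng.random(rlen) < error_rate)
                for p in errs:
                    choices = [b for b in b"ACGT" if b != arr[p]]
                    arr[p] = choices[rng.integers(0, 3)]
                rseq = arr.tobytes().decode()
            rid = f"{name}_read{i}"
            reads.append(Read(id=rid, seq=rseq))
            labels[rid] = label_of[name] if label_of else name
    return reads, labels


def class_labels_from_origins(read_labels: Dict[str, str]) -> Dict[str, str]:
    """Collapse genome-of-origin names to classifier classes: 'chloroplast'
    -> plastid, 'mito_*' -> mitochondrion, 'nuclear' -> nuclear."""
    out = {}
    for rid, origin in read_labels.items():
        if origin == "chloroplast":
            out[rid] = "plastid"
        elif origin.startswith("mito"):
            out[rid] = "mitochondrion"
        elif origin == "nuclear":
            out[rid] = "nuclear"
        else:
            out[rid] = "unknown"
    return out


def stub_classifier(
    reads: Sequence[Read],
    truth_labels: Dict[str, str],
    confusion: Optional[Dict[str, Dict[str, float]]] = None,
    seed: int = 0,
    force_organelle_ids: Optional[Dict[str, str]] = None,
) -> List[Read]:
    """Assign classifier-style labels by sampling each read's confusion row.

    ``confusion`` maps true label -> {predicted label: probability} (rows
    must sum to 1); identity confusion by default. ``force_organelle_ids``
    maps specific read ids to a forced label, emulating the documented
    failure mode where reads covering nuclear insertions of organellar DNA
    are labeled as organellar.
    """
    rng = np.random.default_rng(seed)
    out: List[Read] = []
    for r in reads:
        truth = truth_labels[r.id]
        if force_organelle_ids and r.id in force_organelle_ids:
            label = force_organelle_ids[r.id]
        elif confusion is None or truth not in confusion:
            label = truth
        else:
            row = confusion[truth]
            names = sorted(row)
            probs = np.array([row[n] for n in names], dtype=float)
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(f"confusion row for {truth!r} does not sum to 1")
            label = names[int(rng.choice(len(names), p=probs))]
        out.append(Read(id=r.id, seq=r.seq, qual=r.qual, label=label))
    return out


# ---------------------------------------------------------------------------
# Oracle adapters

def _broken_graph(seed_tag: str = "x") -> AssemblyGraph:
    return AssemblyGraph(
        segments=[Segment(f"frag{seed_tag}1", "ACGT" * 200), Segment(f"frag{seed_tag}2", "TTGC" * 150)],
        links=[Link(f"frag{seed_tag}1", "+", f"frag{seed_tag}2", "+")],
    )


def oracle_assembler(
    reads: Sequence[Read],
    truth: FixtureTruth,
    target: str = "chloroplast",
    min_purity: float = 0.90,
    min_coverage: Optional[float] = None,
) -> AssemblyGraph:
    """Assembler stand-in with a fixed contract.

    Emits the truth graph when at least ``min_purity`` of the supplied
    reads originate from the target genome and their coverage of it is at
    least ``min_coverage`` (default 20x for the chloroplast, 10x for the
    lower-coverage mitochondrion); otherwise emits a deliberately broken
    graph with dangling segments, so retry logic can be exercised.
    """
    if not reads:
        raise ValueError("no reads supplied to assembler")
    if min_coverage is None:
        min_coverage = 20.0 if target == "chloroplast" else 10.0
    if target == "chloroplast":
        if truth.chloroplast is None:
            raise ValueError("fixture has no chloroplast truth")
        origin_names = {"chloroplast"}
        glen = len(truth.chloroplast.genome)
    else:
        origin_names = set(truth.mito_sequences)
        glen = sum(len(s) for s in truth.mito_sequences.values())

    def origin(read_id: str) -> str:
        lab = truth.read_labels.get(read_id, "unknown")
        return lab

    n_target = sum(1 for r in reads if origin(r.id) in origin_names)
    target_bases = sum(len(r) for r in reads if origin(r.id) in origin_names)
    purity = n_target / len(reads)
    cov = target_bases / glen if glen else 0.0
    if purity >= min_purity and cov >= min_coverage:
        if target == "chloroplast":
            return truth.chloroplast.graph
        segs = [Segment(name, seq) for name, seq in sorted(truth.mito_sequences.items())]
        links = [
            Link(name, "+", name, "+")
            for name in sorted(truth.mito_sequences)
            if truth.mito_circular.get(name, False)
        ]
        return AssemblyGraph(segments=segs, links=links)
    return _broken_graph()


def oracle_graph_aligner(
    reads: Sequence[Read], graph: AssemblyGraph, truth: FixtureTruth
) -> List[GafRecord]:
    """Graph-aligner stand-in: reads whose true origin is the chloroplast
    align end-to-end at ~99.9% identity; other reads get no alignment."""
    seg0 = graph.segments[0].id if graph.segments else "s1"
    out: List[GafRecord] = []
    for r in reads:
        if truth.read_labels.get(r.id) == "chloroplast":
            L = len(r)
            matches = max(1, int(round(L * 0.999)))
            out.append(
                GafRecord(
                    qname=r.id, qlen=L, qstart=0, qend=L, strand="+",
                    path=[(seg0, "+")], matches=matches, blocklen=L,
                )
            )
    return out


def downsample_reads(
    reads: Sequence[Read], genome_size: int, target_coverage: float, seed: int = 0
) -> List[Read]:
    """Sample reads without replacement until total bases reach
    target_coverage * genome_size (the crossing read is included).

    If the input has fewer bases than the target, all reads are returned.
    """
    if target_coverage <= 0:
        raise ValueError("target_coverage must be > 0")
    target_bases = target_coverage * genome_size
    total = sum(len(r) for r in reads)
    if total < target_bases:
        import warnings

        warnings.warn("fewer input bases than the downsampling target; returning all reads")
        return list(reads)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    out: List[Read] = []
    acc = 0
    for idx in order:
        out.append(reads[idx])
        acc += len(reads[idx])
        if acc >= target_bases:
            break
    return out


# ---------------------------------------------------------------------------
# Bundled default fixture

def default_fixture(
    seed: int = 42,
    coverage_chloro: float = 50.0,
    coverage_mito: float = 20.0,
    coverage_nuclear: float = 1.0,
    nuclear_len: int = 120_000,
    n_insertions: int = 8,
    small_circle: bool = True,
) -> Tuple[List[Read], FixtureTruth]:
    """The study-condition fixture: quadripartite chloroplast, mitochondrion
    with an optional small circle, a nuclear genome with planted NUPTs, and
    HiFi-like reads at 50x/20x/1x chloroplast/mitochondrion/nuclear
    coverage."""
    truth = FixtureTruth()
    truth.chloroplast = make_quadripartite_genome(seed=seed)
    truth.mito_sequences, truth.mito_circular, truth.mito_genes = make_mitochondrion(
        main_len=30000, small_circle_len=5000 if small_circle else 0, seed=seed + 1
    )
    nuclear_seq, insertions = plant_insertions(
        nuclear_len=nuclear_len,
        organelle_seq=truth.chloroplast.genome,
        n=n_insertions,
        identity_targets=[99.0, 97.0, 95.0, 92.0],
        seed=seed + 2,
    )
    truth.nuclear_seq = nuclear_seq
    truth.insertions = insertions

    genomes: Dict[str, Tuple[str, bool, float]] = {
        "chloroplast": (truth.chloroplast.genome, True, coverage_chloro),
        "nuclear": (nuclear_seq, False, coverage_nuclear),
    }
    for name, seq in truth.mito_sequences.items():
        genomes[name] = (seq, truth.mito_circular[name], coverage_mito)
    label_of = {"chloroplast": "chloroplast", "nuclear": "nuclear"}
    for name in truth.mito_sequences:
        label_of[name] = name
    reads, labels = simulate_reads(
        genomes, coverage=1.0, mean_len=2000.0, seed=seed + 3, label_of=label_of
    )
    truth.read_labels = labels
    return reads, truth
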