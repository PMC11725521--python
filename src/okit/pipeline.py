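"""Pipeline orchestration: classify -> k-mer filter -> iterative chloroplast
assembly with structure check -> mitochondrial refinement -> mitochondrial
assembly.

External tools (read classifier, assembler, graph aligner) are consumed
through pluggable adapters: either subprocess command templates or in-
process callables (the synthetic module's oracle stand-ins). The
chloroplast branch runs first; the mitochondrial k-mer thresholds are
computed only after chloroplast-like reads have been removed, and the
final mitochondrial assembly uses all remaining reads without
subsampling, since mitochondrial coverage is lower and genomes larger.
"""

from __future__ import annotations

import json
import logging
import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from okit import graph_topology, kmer_filter, read_refinement
from okit.completeness import DEFAULT_PANEL, CompletenessReport, assess_completeness
from okit.graph_topology import IsomerPair, TopologyCall, classify_structure, extract_isomers
from okit.io_formats import AssemblyGraph, GafRecord, Read, parse_gaf, parse_gfa, write_fasta, write_fastq, write_gfa
from okit.read_refinement import RefinementThresholds, remove_chloroplast_reads

__all__ = [
    "PipelineConfig",
    "Adapters",
    "StageResult",
    "assemble_chloroplast",
    "assemble_mitochondrion",
    "run_all",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every pipeline-level constant, with the published defaults."""

    k: int = 31
    low_mult: float = 0.3
    high_mult: float = 5.0
    max_outlier_frac: float = 1.0 / 5.0
    reads_per_round: int = 800
    max_rounds: int = 10
    max_clip: int = 100
    min_identity: float = 0.95
    evalue_threshold: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        for name in ("k", "reads_per_round", "max_rounds", "max_clip"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Adapters:
    """In-process adapter callables.

    classifier(reads) -> labeled reads;
    assembler(reads, target) -> AssemblyGraph;
    graph_aligner(reads, graph) -> list of GafRecord;
    gene_search(graph) -> list of (gene, evalue) hits.
    """

    classifier: Callable[[Sequence[Read]], List[Read]]
    assembler: Callable[[Sequence[Read], str], AssemblyGraph]
    graph_aligner: Callable[[Sequence[Read], AssemblyGraph], List[GafRecord]]
    gene_search: Optional[Callable[[AssemblyGraph], List[Tuple[str, float]]]] = None


@dataclass
class StageResult:
    stage: str
    n_in: int = 0
    n_kept: int = 0
    n_removed: int = 0
    rounds: List[Dict] = field(default_factory=list)
    topology: Optional[str] = None
    notes: List[str] = field(default_factory=list)

    def check_conservation(self):
        assert self.n_in == self.n_kept + self.n_removed, "read conservation violated"


def _kmer_filter_class(
    reads: Sequence[Read], config: PipelineConfig
) -> Tuple[List[Read], List[Tuple[Read, str]], kmer_filter.FilterThresholds]:
    """Build a per-class count table and apply the rmkc/mkc filter."""
    table = kmer_filter.build_count_table(reads, k=config.k)
    profiles = [kmer_filter.read_profile(r, table) for r in reads]
    thresholds = kmer_filter.compute_thresholds(
        profiles,
        low_mult=config.low_mult,
        high_mult=config.high_mult,
        max_outlier_frac=config.max_outlier_frac,
    )
    kept, removed = kmer_filter.filter_reads(reads, table, thresholds)
    return kept, removed, thresholds


def assemble_chloroplast(
    reads: Sequence[Read],
    config: PipelineConfig,
    adapters: Adapters,
):
    """Iterative chloroplast assembly from k-mer-filtered plastid reads.

    Each round samples ``reads_per_round`` reads without replacement
    (seeded with config.seed + round), runs the assembler adapter and
    classifies the graph; the loop stops at a quadripartite or circular
    call and emits the isomer pair (or single circle). After
    ``max_rounds`` the best-seen graph is returned with its
    (incomplete/other) classification recorded.
    """
    result = StageResult(stage="chloroplast_assembly", n_in=len(reads))
    if not reads:
        raise ValueError("no plastid reads supplied")
    best: Tuple[Optional[AssemblyGraph], Optional[TopologyCall]] = (None, None)
    for rnd in range(config.max_rounds):
        if len(reads) <= config.reads_per_round:
            sample = list(reads)
            if rnd == 0 and len(reads) < config.reads_per_round:
                logger.warning(
                    "only %d reads available (< reads_per_round=%d); using all",
                    len(reads), config.reads_per_round,
                )
                result.notes.append("fewer reads than reads_per_round; single draw uses all")
        else:
            rng = np.random.default_rng(config.seed + rnd)
            idx = rng.choice(len(reads), size=config.reads_per_round, replace=False)
            sample = [reads[i] for i in sorted(idx)]
        try:
            graph = adapters.assembler(sample, "chloroplast")
        except Exception as e:  # one retry per the stage contract
            logger.warning("assembler failed in round %d (%s); retrying once", rnd, e)
            graph = adapters.assembler(sample, "chloroplast")
        call = classify_structure(graph)
        result.rounds.append({"round": rnd, "n_reads": len(sample), "klass": call.klass})
        best = (graph, call)
        if call.klass in ("quadripartite", "circular"):
            isomers = extract_isomers(graph, call)
            result.topology = call.klass
            result.n_kept = len(reads)
            result.check_conservation()
            return isomers, graph, call, result
        if len(reads) <= config.reads_per_round:
            break  # identical draw every round; no point iterating
    graph, call = best
    result.topology = call.klass if call else "other"
    result.n_kept = len(reads)
    result.check_conservation()
    return None, graph, call, result


def assemble_mitochondrion(
    reads: Sequence[Read],
    chloro_graph: AssemblyGraph,
    config: PipelineConfig,
    adapters: Adapters,
):
    """Mitochondrial branch: graph-alignment refinement against the
    chloroplast graph, then per-class k-mer filtering, then a single
    assembler run on all remaining reads (no subsampling)."""
    result = StageResult(stage="mitochondrial_assembly", n_in=len(reads))
    if not reads:
        raise ValueError("no mitochondrial signal: zero mitochondrion-labeled reads")
    gaf = adapters.graph_aligner(reads, chloro_graph)
    refined, removed_ids = remove_chloroplast_reads(
        reads, gaf, RefinementThresholds(config.max_clip, config.min_identity)
    )
    result.notes.append(f"chloroplast-like reads removed: {len(removed_ids)}")
    if not refined:
        raise ValueError("no mitochondrial signal: all reads removed as chloroplast-like")
    kept, removed, _ = _kmer_filter_class(refined, config)
    result.n_kept = len(kept)
    result.n_removed = len(removed_ids) + len(removed)
    result.check_conservation()
    if not kept:
        raise ValueError("no mitochondrial signal: k-mer filter removed all reads")
    graph = adapters.assembler(kept, "mitochondrion")
    report: Optional[CompletenessReport] = None
    if adapters.gene_search is not None:
        hits = adapters.gene_search(graph)
        report = assess_completeness(hits, DEFAULT_PANEL, config.evalue_threshold)
    result.topology = classify_structure(graph).klass if graph.segments else None
    return graph, report, result


def run_all(
    reads: Sequence[Read],
    config: PipelineConfig,
    adapters: Adapters,
    outdir: Optional[Path] = None,
) -> Dict:
    """Full pipeline: classify, filter per class, assemble chloroplast
    iteratively, refine and assemble the mitochondrion; optionally write
    isomers.fasta / chloroplast.gfa / mitochondrion.gfa / completeness.tsv
    and per-stage JSON logs to ``outdir``. Returns a result dictionary with
    every stage object. Exit status convention: 0 complete, 1 incomplete
    chloroplast, 2 hard failure (raised)."""
    labeled = adapters.classifier(list(reads))
    plastid = [r for r in labeled if r.label == "plastid"]
    mito = [r for r in labeled if r.label == "mitochondrion"]
    n_unknown = sum(1 for r in labeled if r.label in (None, "unknown", "nuclear"))
    logger.info(
        "classified: %d plastid, %d mitochondrion, %d nuclear/unknown (discarded)",
        len(plastid), len(mito), n_unknown,
    )
    if not plastid:
        raise ValueError("classifier produced no plastid-labeled reads")

    cp_kept, cp_removed, cp_thresholds = _kmer_filter_class(plastid, config)
    filter_stage = StageResult(
        stage="kmer_filter_plastid",
        n_in=len(plastid),
        n_kept=len(cp_kept),
        n_removed=len(cp_removed),
    )
    filter_stage.check_conservation()

    isomers, cp_graph, cp_call, cp_stage = assemble_chloroplast(cp_kept, config, adapters)
    mt_graph = mt_report = mt_stage = None
    if mito:
        mt_graph, mt_report, mt_stage = assemble_mitochondrion(mito, cp_graph, config, adapters)

    status = 0 if cp_call and cp_call.klass in ("quadripartite", "circular") else 1

    results = {
        "status": status,
        "config": asdict(config),
        "stages": [filter_stage, cp_stage] + ([mt_stage] if mt_stage else []),
        "chloroplast": {"graph": cp_graph, "call": cp_call, "isomers": isomers},
        "mitochondrion": {"graph": mt_graph, "completeness": mt_report},
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if isinstance(isomers, IsomerPair):
            write_fasta([("isomer_A", isomers.isomer_a), ("isomer_B", isomers.isomer_b)],
                        outdir / "isomers.fasta")
        elif isinstance(isomers, str):
            write_fasta([("circular", isomers)], outdir / "isomers.fasta")
        if cp_graph is not None:
            write_gfa(cp_graph, outdir / "chloroplast.gfa")
        if mt_graph is not None:
            write_gfa(mt_graph, outdir / "mitochondrion.gfa")
        if mt_report is not None:
            with open(outdir / "completeness.tsv", "w") as fh:
                fh.write("gene\tstatus\n")
                for g in DEFAULT_PANEL.genes:
                    fh.write(f"{g}\t{'present' if g in mt_report.present else 'absent'}\n")
        with open(outdir / "stages.json", "w") as fh:
            for st in results["stages"]:
                fh.write(json.dumps({
                    "stage": st.stage, "n_in": st.n_in, "n_kept": st.n_kept,
                    "n_removed": st.n_removed, "topology": st.topology,
                    "rounds": st.rounds, "notes": st.notes,
                }) + "\n")
    return results


# ---------------------------------------------------------------------------
# Subprocess adapters for real external tools

@dataclass
class CommandAdapters:
    """Build :class:`Adapters` from shell command templates.

    Templates use ``{reads}``, ``{graph}``, ``{out}`` placeholders; each
    adapter writes its inputs to a temp directory, substitutes paths, runs
    the command and parses the expected output file (classifier: TSV of
    read_id<TAB>label; assembler: GFA; graph aligner: GAF).
    """

    classifier_cmd: Optional[str] = None
    assembler_cmd: Optional[str] = None
    graph_aligner_cmd: Optional[str] = None

    def missing(self) -> List[str]:
        out = []
        for name, cmd in (
            ("classifier", self.classifier_cmd),
            ("assembler", self.assembler_cmd),
            ("graph_aligner", self.graph_aligner_cmd),
        ):
            if cmd is None:
                out.append(name)
        return out

    def build(self) -> Adapters:
        miss = self.missing()
        if miss:
            raise RuntimeError("missing adapter commands: " + ", ".join(miss))
        return Adapters(
            classifier=self._classifier,
            assembler=self._assembler,
            graph_aligner=self._graph_aligner,
        )

    def _run(self, template: str, **paths) -> None:
        cmd = template.format(**{k: shlex.quote(str(v)) for k, v in paths.items()})
        subprocess.run(cmd, shell=True, check=True)

    def _classifier(self, reads: Sequence[Read]) -> List[Read]:
        with tempfile.TemporaryDirectory() as td:
            rp, op = Path(td) / "reads.fq", Path(td) / "labels.tsv"
            write_fastq(reads, rp)
            self._run(self.classifier_cmd, reads=rp, out=op)
            labels = {}
            for line in op.read_text().splitlines():
                rid, label = line.split("\t")[:2]
                labels[rid] = label
        return [Read(r.id, r.seq, r.qual, labels.get(r.id, "unknown")) for r in reads]

    def _assembler(self, reads: Sequence[Read], target: str) -> AssemblyGraph:
        with tempfile.TemporaryDirectory() as td:
            rp, op = Path(td) / "reads.fq", Path(td) / "assembly.gfa"
            write_fastq(reads, rp)
            self._run(self.assembler_cmd, reads=rp, out=op)
            return parse_gfa(op)

    def _graph_aligner(self, reads: Sequence[Read], graph: AssemblyGraph) -> List[GafRecord]:
        with tempfile.TemporaryDirectory() as td:
            rp, gp, op = Path(td) / "reads.fq", Path(td) / "graph.gfa", Path(td) / "aln.gaf"
            write_fastq(reads, rp)
            write_gfa(graph, gp)
            self._run(self.graph_aligner_cmd, reads=rp, graph=gp, out=op)
            return parse_gaf(op)
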