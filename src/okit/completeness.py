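"""BUSCO-style completeness scoring of mitochondrial assemblies.

Plant mitochondrial genomes are too structurally diverse for a
graph-topology completeness check, so completeness is scored as the
presence or absence of a panel of conserved mitochondrial protein-coding
genes (41 by default) in translated-search hits against the assembly.
Copy number and orientation are deliberately ignored: assembly graphs
collapse long repeats into single nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Set, Tuple

__all__ = ["GenePanel", "CompletenessReport", "DEFAULT_PANEL", "assess_completeness"]

logger = logging.getLogger(__name__)

# Conserved mitochondrial protein-coding genes: ATP synthase, cytochrome c
# maturation/biogenesis, respiratory complexes III/IV/I, maturase, membrane
# transporter, ribosomal proteins and succinate dehydrogenase subunits.
DEFAULT_PANEL_GENES: Tuple[str, ...] = (
    "atp1", "atp4", "atp6", "atp8", "atp9",
    "ccmB", "ccmC", "ccmFC", "ccmFN",
    "cob",
    "cox1", "cox2", "cox3",
    "matR",
    "mttB",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "nad7", "nad9",
    "rpl2", "rpl5", "rpl10", "rpl16",
    "rps1", "rps2", "rps3", "rps4", "rps7", "rps10", "rps11", "rps12",
    "rps13", "rps14", "rps19",
    "sdh3", "sdh4",
)


@dataclass
class GenePanel:
    genes: Tuple[str, ...] = DEFAULT_PANEL_GENES

    def __post_init__(self):
        self.genes = tuple(self.genes)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("panel gene names must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


DEFAULT_PANEL = GenePanel()
assert len(DEFAULT_PANEL) == 41


@dataclass
class CompletenessReport:
    present: Set[str] = field(default_factory=set)
    absent: Set[str] = field(default_factory=set)

    @property
    def n_present(self) -> int:
        return len(self.present)

    @property
    def panel_size(self) -> int:
        return len(self.present) + len(self.absent)


def assess_completeness(
    hits: Iterable[Tuple[str, float]],
    panel: GenePanel = DEFAULT_PANEL,
    evalue_threshold: float = 1e-3,
) -> CompletenessReport:
    """Score gene presence from (gene, evalue) hits.

    A gene is present iff it has at least one hit with evalue <= threshold
    (inclusive, matching aligner-side -evalue semantics). Hits naming genes
    outside the panel are skipped with a warning.
    """
    if len(panel) == 0:
        raise ValueError("empty gene panel")
    present: Set[str] = set()
    for gene, evalue in hits:
        if gene not in panel:
            logger.warning("hit for gene %r not in panel; skipped", gene)
            continue
        if evalue <= evalue_threshold:
            present.add(gene)
    return CompletenessReport(present=present, absent=set(panel.genes) - present)


def parse_hits_table(path) -> List[Tuple[str, float]]:
    """Read a hits table: 2 columns (gene, evalue) or BLAST-6 with the gene
    in the subject (2nd) column and evalue in column 11."""
    hits: List[Tuple[str, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) == 2:
                hits.append((f[0], float(f[1])))
            elif len(f) >= 12:
                hits.append((f[1], float(f[10])))
            else:
                raise ValueError("hits table must have 2 or >=12 columns")
    return hits
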