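"""Short mechanistic paths from drugs to disease genes.

Paths have the form drug ->1 target ->2 mediator ->3 disease gene, where the
drug->target link counts as the first edge.  A 1-edge path exists when a
target is itself a disease gene; a 2-edge path when a target is adjacent to
one; a 3-edge path routes through a mediator gene that is neither a disease
gene nor the path's target.  Mediator summaries count, per gene set, the
distinct disease genes adjacent to each mediator, as a count and as a
fraction of the set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import pandas as pd

from .networks import DrugTargetNetwork, GeneSet


@dataclass(frozen=True)
class MechanisticPath:
    drug: str
    nodes: tuple[str, ...]  # target [, mediator], disease gene

    @property
    def n_edges(self) -> int:
        return len(self.nodes)  # drug->target contributes one edge

    @property
    def target(self) -> str:
        return self.nodes[0]

    @property
    def mediator(self) -> str | None:
        return self.nodes[1] if len(self.nodes) == 3 else None

    @property
    def disease_gene(self) -> str:
        return self.nodes[-1]


def enumerate_paths(
    drug: str,
    dtn: DrugTargetNetwork,
    net: nx.Graph,
    disease: GeneSet,
    max_edges: int = 3,
    *,
    allow_disease_mediators: bool = False,
) -> list[MechanisticPath]:
    """All simple drug -> target [-> mediator] -> disease-gene paths with at
    most ``max_edges`` edges (the drug->target link included).

    Mediators that are themselves disease genes are excluded by default:
    those routes already appear as shorter paths.
    """
    if max_edges not in (1, 2, 3):
        raise ValueError("max_edges must be 1, 2 or 3")
    if drug not in dtn:
        raise KeyError(f"drug {drug!r} absent from the drug-target network")

    targets = sorted(dtn.targets_of(drug))
    disease_genes = disease.genes
    paths: list[MechanisticPath] = []
    for t in targets:
        if t in disease_genes:
            paths.append(MechanisticPath(drug=drug, nodes=(t,)))
        if max_edges < 2 or t not in net:
            continue
        for g in sorted(net.neighbors(t)):
            if g in disease_genes and g != t:
                paths.append(MechanisticPath(drug=drug, nodes=(t, g)))
        if max_edges < 3:
            continue
        for m in sorted(net.neighbors(t)):
            if m == t or (m in disease_genes and not allow_disease_mediators):
                continue
            for g in sorted(net.neighbors(m)):
                if g in disease_genes and g not in (t, m):
                    paths.append(MechanisticPath(drug=drug, nodes=(t, m, g)))
    return paths


def mediator_summary(
    paths: Sequence[MechanisticPath],
    gene_sets: Sequence[GeneSet],
    net: nx.Graph,
) -> pd.DataFrame:
    """Per (target, mediator) of every 3-edge path, the number of distinct
    genes of each gene set adjacent to the mediator, and that count as a
    fraction of the set's size.

    Counts are over distinct genes, so path multiplicity does not matter.
    """
    if not paths:
        raise ValueError("no paths to summarize")
    pairs = sorted(
        {(p.target, p.mediator) for p in paths if p.mediator is not None}
    )
    rows = []
    for target, mediator in pairs:
        neigh = set(net.neighbors(mediator)) if mediator in net else set()
        row: dict[str, object] = {"target": target, "mediator": mediator}
        for gs in gene_sets:
            count = len(neigh & gs.genes)
            row[f"{gs.name}_count"] = count
            row[f"{gs.name}_fraction"] = count / len(gs.genes)
        rows.append(row)
    return pd.DataFrame(rows)


def paths_frame(paths: Sequence[MechanisticPath], gene_set_name: str = "") -> pd.DataFrame:
    """Tabular path listing (drug, target, mediator-or-blank, disease gene)."""
    return pd.DataFrame(
        {
            "drug": [p.drug for p in paths],
            "target": [p.target for p in paths],
            "mediator": [p.mediator or "" for p in paths],
            "disease_gene": [p.disease_gene for p in paths],
            "n_edges": [p.n_edges for p in paths],
            "gene_set": gene_set_name,
        }
    )
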