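"""Gene-gene interactome and drug-target network handling.

The interactome is an undirected simple graph over gene symbols (a
:class:`networkx.Graph`).  The drug-target network is the bipartite relation
drug -> gene retained from raw bioactivity records whose mean pActivity
(negative base-10 log of molar activity) clears a potency threshold:
pActivity >= 5 corresponds to activity at <= 10 uM.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: multiply log10(value) offsets per declared concentration unit so that
#: pActivity = UNIT_OFFSET[unit] - log10(value_in_unit) equals -log10(molar)
UNIT_OFFSET = {"nM": 9.0, "uM": 6.0, "M": 0.0}


class MalformedEdgeError(ValueError):
    """An edge-list line could not be parsed as two gene symbols."""


class EmptyGeneSetError(ValueError):
    """A gene set has no genes left after restriction to the interactome."""


@dataclass(frozen=True)
class GeneSet:
    """A named disease gene set (e.g. one row of a GMT file)."""

    name: str
    genes: frozenset[str]
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise EmptyGeneSetError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class ActivityRecord:
    """All standard-value measurements for one (drug, gene) pair.

    ``activity_values`` are raw concentrations in the declared ``unit``;
    non-positive values cannot be log-transformed and are rejected upstream.
    """

    drug_id: str
    gene: str
    activity_values: tuple[float, ...]
    unit: str = "nM"

    @property
    def n(self) -> int:
        return len(self.activity_values)


@dataclass
class DrugTargetNetwork:
    """Drug -> target-gene relation with mean-pActivity provenance."""

    pairs: set[tuple[str, str]] = field(default_factory=set)
    mean_pactivity: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def drugs(self) -> list[str]:
        return sorted({d for d, _ in self.pairs})

    def targets_of(self, drug_id: str) -> set[str]:
        return {g for d, g in self.pairs if d == drug_id}

    def __contains__(self, drug_id: str) -> bool:
        return any(d == drug_id for d, _ in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.pairs)
        return pd.DataFrame(
            {
                "drug_id": [d for d, _ in rows],
                "gene": [g for _, g in rows],
                "mean_pactivity": [self.mean_pactivity[p] for p in rows],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DrugTargetNetwork":
        df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "gene": str})
        net = cls()
        for row in df.itertuples(index=False):
            pair = (row.drug_id, row.gene)
            net.pairs.add(pair)
            net.mean_pactivity[pair] = float(row.mean_pactivity)
        return net


def load_interactome(
    source: str | Path | Iterable[str],
    *,
    skip_header: bool = False,
    sif: bool = False,
) -> nx.Graph:
    """Load an undirected simple interactome from a two-column edge list.

    Self-loops and duplicate edges are dropped (counts are logged).  SIF input
    (``node  relation  node``) is accepted with ``sif=True`` or a ``.sif``
    suffix.

    Raises
    ------
    ValueError
        If the input is empty.
    MalformedEdgeError
        Naming the 1-based line number of the first unparseable line.
    """
    if isinstance(source, (str, Path)):
        p = Path(source)
        sif = sif or p.suffix.lower() == ".sif"
        lines: Iterable[str] = p.read_text().splitlines()
    else:
        lines = list(source)

    graph = nx.Graph()
    n_self, n_dup, n_edges_seen = 0, 0, 0
    for lineno, line in enumerate(lines, start=1):
        if skip_header and lineno == 1:
            continue
        if not line.strip():
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if sif and len(fields) == 3:
            a, b = fields[0].strip(), fields[2].strip()
        elif len(fields) >= 2:
            a, b = fields[0].strip(), fields[1].strip()
        else:
            raise MalformedEdgeError(
                f"line {lineno}: expected two gene symbols, got {line!r}"
            )
        if not a or not b:
            raise MalformedEdgeError(f"line {lineno}: empty gene symbol")
        n_edges_seen += 1
        if a == b:
            n_self += 1
            graph.add_node(a)
            continue
        if graph.has_edge(a, b):
            n_dup += 1
            continue
        graph.add_edge(a, b)

    if n_edges_seen == 0:
        raise ValueError("empty edge list: no edges found")
    if n_self or n_dup:
        logger.info(
            "interactome cleanup: dropped %d self-loops, %d duplicate edges",
            n_self,
            n_dup,
        )
    return graph


def write_interactome(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


def pactivity(value: float, unit: str = "nM") -> float:
    """-log10 molar activity of a raw standard value in the given unit."""
    if unit not in UNIT_OFFSET:
        raise ValueError(f"unknown unit {unit!r}; expected one of {sorted(UNIT_OFFSET)}")
    if value <= 0:
        raise ValueError(f"non-positive activity value {value}")
    return UNIT_OFFSET[unit] - math.log10(value)


def filter_drug_targets(
    records: Sequence[ActivityRecord],
    threshold_pactivity: float = 5.0,
) -> DrugTargetNetwork:
    """Retain (drug, gene) pairs whose mean pActivity clears the threshold.

    The mean is the arithmetic average of per-measurement -log10 molar
    activities over all n measurements of the pair; duplicates are all kept.
    Records containing a non-positive activity value are rejected with a
    warning rather than aborting the build.
    """
    net = DrugTargetNetwork()
    for rec in records:
        try:
            values = [pactivity(v, rec.unit) for v in rec.activity_values]
        except ValueError as exc:
            logger.warning(
                "rejecting record (%s, %s): %s", rec.drug_id, rec.gene, exc
            )
            continue
        if not values:
            continue
        mean_p = sum(values) / len(values)
        if mean_p >= threshold_pactivity:
            pair = (rec.drug_id, rec.gene)
            net.pairs.add(pair)
            net.mean_pactivity[pair] = mean_p
    return net


def read_activity_csv(path: str | Path) -> list[ActivityRecord]:
    """Read raw activity records (columns drug_id, gene, standard_value, unit)
    and group measurements by (drug, gene) pair."""
    df = pd.read_csv(path, dtype={"drug_id": str, "gene": str, "unit": str})
    records = []
    for (drug, gene, unit), grp in df.groupby(
        ["drug_id", "gene", "unit"], sort=True
    ):
        records.append(
            ActivityRecord(
                drug_id=drug,
                gene=gene,
                activity_values=tuple(float(v) for v in grp["standard_value"]),
                unit=unit,
            )
        )
    return records


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one gene set per line, ``name  description  genes...``."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno}: need name, description, >=1 gene")
        name, desc, genes = fields[0], fields[1], fields[2:]
        sets.append(GeneSet(name=name, genes=frozenset(g for g in genes if g), source_label=desc))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.source_label, *sorted(gs.genes)]) + "\n")


def restrict_gene_set(gs: GeneSet, net: nx.Graph) -> GeneSet:
    """Intersect a gene set with the interactome's node set.

    Genes outside the network are dropped with a logged warning; an empty
    intersection raises (proximity is undefined without in-network genes).
    """
    kept = frozenset(g for g in gs.genes if g in net)
    dropped = gs.genes - kept
    if dropped:
        logger.warning(
            "gene set %s: dropped %d genes absent from interactome",
            gs.name,
            len(dropped),
        )
    if not kept:
        raise EmptyGeneSetError(
            f"gene set {gs.name!r} has no genes in the interactome"
        )
    return GeneSet(name=gs.name, genes=kept, source_label=gs.source_label)
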