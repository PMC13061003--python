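"""Closest-distance network proximity of drug targets to disease modules.

For a drug with target set T and a disease gene set S, the proximity is

    d(S, T) = (1/|T|) * sum_{t in T} min_{s in S} d(s, t)

where d(s, t) is the unweighted shortest-path length in the interactome.
Targets unreachable from every disease gene contribute +inf, which makes the
drug's proximity +inf (an alternative mode drops unreachable targets from the
average).  Per gene set, drugs are ranked ascending in d; ties are broken
lexicographically by drug id so each ranking is a strict permutation, which
downstream Markov-chain rank aggregation requires.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .networks import DrugTargetNetwork, GeneSet, restrict_gene_set

logger = logging.getLogger(__name__)


class NoTargetsInNetworkError(ValueError):
    """No drug target is present in the interactome (distinct from +inf)."""


def closest_proximity(
    targets: set[str],
    disease_genes: set[str],
    net: nx.Graph,
    *,
    drop_unreachable: bool = False,
) -> float:
    """Average over in-network targets of the hop distance to the nearest
    in-network disease gene.

    Raises :class:`NoTargetsInNetworkError` when no target is an interactome
    node -- a different condition from a finite target set with no path to
    the module, which yields ``inf`` (or, with ``drop_unreachable=True``,
    averages over the reachable targets only).
    """
    t_in = {t for t in targets if t in net}
    s_in = {s for s in disease_genes if s in net}
    if not t_in:
        raise NoTargetsInNetworkError("no drug target present in the interactome")
    if not s_in:
        raise ValueError("no disease gene present in the interactome")

    # one multi-source BFS from the module instead of |S| single-source runs
    dist = nx.multi_source_dijkstra_path_length(net, s_in)
    per_target = [dist.get(t, math.inf) for t in t_in]
    if drop_unreachable:
        finite = [d for d in per_target if math.isfinite(d)]
        if not finite:
            return math.inf
        return sum(finite) / len(finite)
    return sum(per_target) / len(per_target)


@dataclass
class ProximityMatrix:
    """Drugs x gene-sets proximities with per-column strict rankings."""

    distances: pd.DataFrame  # rows: drug_id, cols: gene-set name, values d(S,T)
    ranks: pd.DataFrame  # same shape; 1 = most proximal
    excluded_drugs: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def drugs(self) -> list[str]:
        return list(self.distances.index)

    @property
    def gene_sets(self) -> list[str]:
        return list(self.distances.columns)

    def ranked_list(self, gene_set: str) -> list[str]:
        """Drug ids of one column ordered best (rank 1) to worst."""
        col = self.ranks[gene_set].sort_values()
        return list(col.index)

    def write(self, outdir: str | Path, stem: str = "proximity") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.distances.to_csv(outdir / f"{stem}_distances.tsv", sep="\t")
        self.ranks.to_csv(outdir / f"{stem}_ranks.tsv", sep="\t")
        import json

        (outdir / f"{stem}_metadata.json").write_text(
            json.dumps(self.metadata | {"excluded_drugs": self.excluded_drugs}, indent=2)
        )


def _strict_ranks(d: pd.Series) -> pd.Series:
    """Ascending ranks with lexicographic drug-id tie-break (strict permutation).

    +inf distances sort after every finite distance, so unreachable drugs are
    ranked last.
    """
    order = sorted(d.index, key=lambda drug: (d[drug], drug))
    return pd.Series(
        {drug: i + 1 for i, drug in enumerate(order)}, name=d.name
    ).reindex(d.index)


def proximity_screen(
    dtn: DrugTargetNetwork,
    gene_sets: Sequence[GeneSet],
    net: nx.Graph,
    *,
    drop_unreachable: bool = False,
) -> ProximityMatrix:
    """Proximity of every drug to every gene set, with per-column rankings.

    Drugs with zero in-network targets are excluded from the matrix (their
    ids are logged and recorded in ``excluded_drugs``); gene sets are
    restricted to the interactome before scoring.
    """
    restricted = [restrict_gene_set(gs, net) for gs in gene_sets]
    if not restricted:
        raise ValueError("no gene set survives restriction to the interactome")

    drugs, excluded = [], []
    for drug in dtn.drugs:
        if any(t in net for t in dtn.targets_of(drug)):
            drugs.append(drug)
        else:
            excluded.append(drug)
    if excluded:
        logger.warning("excluded %d drugs with no in-network targets: %s",
                       len(excluded), excluded)
    if not drugs:
        raise ValueError("no drug has any target in the interactome")

    # one BFS per gene set, reused across all drugs
    d = pd.DataFrame(index=drugs, columns=[gs.name for gs in restricted], dtype=float)
    for gs in restricted:
        dist = nx.multi_source_dijkstra_path_length(net, set(gs.genes))
        for drug in drugs:
            t_in = [t for t in dtn.targets_of(drug) if t in net]
            per_target = [dist.get(t, math.inf) for t in t_in]
            if drop_unreachable:
                finite = [v for v in per_target if math.isfinite(v)]
                d.loc[drug, gs.name] = (
                    sum(finite) / len(finite) if finite else math.inf
                )
            else:
                d.loc[drug, gs.name] = sum(per_target) / len(per_target)

    ranks = d.apply(_strict_ranks, axis=0).astype(int)
    meta = {
        "tie_rule": "lexicographic by drug_id",
        "infinity_policy": "drop_unreachable" if drop_unreachable else "propagate",
        "n_drugs": len(drugs),
        "n_gene_sets": len(restricted),
    }
    return ProximityMatrix(distances=d, ranks=ranks, excluded_drugs=excluded, metadata=meta)


def rank_correlation(matrix: ProximityMatrix, min_common: int = 3) -> pd.DataFrame:
    """Pairwise Spearman correlation of proximity columns.

    Each pair is computed over the drugs with finite proximity in both
    columns; pairs with fewer than ``min_common`` such drugs are reported as
    missing (NaN).  The table is symmetric with a unit diagonal.
    """
    cols = matrix.gene_sets
    if len(cols) < 2:
        raise ValueError("rank correlation needs at least two gene-set columns")
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            da, db = matrix.distances[a], matrix.distances[b]
            mask = np.isfinite(da) & np.isfinite(db)
            if mask.sum() < min_common:
                rho = np.nan
            else:
                rho = stats.spearmanr(da[mask], db[mask]).statistic
            out.loc[a, b] = out.loc[b, a] = rho
    return out
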