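"""Synthetic study generator with known ground truth.

Emulates the inputs of a network-pharmacology repurposing screen at desk
scale: a scale-free interactome (preferential attachment, so the degree
heterogeneity that proximity methods are sensitive to is present), a planted
connected disease module, drugs whose targets are placed either inside or
near the module (proximal) or uniformly (distal) under a controllable
coupling strength, clinical phases correlated with the planted proximity,
and dose-response observations drawn from the sigmoid model's own generative
process with known fold changes.

Every generator is deterministic under the scenario seed, and ground-truth
labels are written to a sidecar JSON next to the data files so downstream
checks never reach into the generator's internals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .dose_response import DoseResponseDataset, simulate_dataset
from .networks import (
    DrugTargetNetwork,
    GeneSet,
    write_gmt,
    write_interactome,
)
from .rediscovery import PhaseTable


@dataclass(frozen=True)
class DoseResponseTruth:
    drug: str
    assay: str
    fc_true: float
    y0_true: float = 30.0
    k_true: float = 2.0
    ec50_true: float = 0.5  # on the log10-micromolar axis
    sigma_true: float = 0.05
    direction: str = "decrease"
    doses_uM: tuple[float, ...] = (1.0, 3.0, 10.0)
    n_replicates: int = 5


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study.

    ``proximity_signal`` is the probability that a drug's targets are placed
    within one interaction of the disease module; ``phase_signal`` the
    probability that a drug's clinical phase is tied to its planted
    proximity label (proximal -> phase 4, distal -> phase 1) rather than
    drawn uniformly from {0..4}.
    """

    seed: int = 0
    n_genes: int = 800
    attachment: int = 3  # preferential-attachment edges per new node
    n_drugs: int = 120
    n_disease_genes: int = 40
    targets_per_drug: int = 3
    proximity_signal: float = 0.5
    phase_signal: float = 0.5
    indication: str = "planted_indication"
    dose_response_truth: tuple[DoseResponseTruth, ...] = ()

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_drugs, self.n_disease_genes,
               self.targets_per_drug, self.attachment) < 1:
            raise ValueError("all counts must be positive")
        if not (0 <= self.proximity_signal <= 1 and 0 <= self.phase_signal <= 1):
            raise ValueError("signals must lie in [0, 1]")
        if self.n_disease_genes >= self.n_genes:
            raise ValueError("disease module must be smaller than the gene universe")

    def rng(self, stream: int) -> np.random.Generator:
        # independent substreams per generator stage
        return np.random.default_rng([self.seed, stream])


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def make_interactome(scenario: SyntheticScenario) -> nx.Graph:
    """Connected scale-free-ish interactome via preferential attachment."""
    if scenario.n_genes < 10:
        raise ValueError("need at least 10 genes")
    if scenario.attachment >= scenario.n_genes:
        raise ValueError("attachment parameter must be below n_genes")
    seed = int(scenario.rng(1).integers(0, 2**31 - 1))
    g = nx.barabasi_albert_graph(scenario.n_genes, scenario.attachment, seed=seed)
    return nx.relabel_nodes(g, {i: _gene_name(i) for i in g.nodes()})


def plant_disease_module(net: nx.Graph, scenario: SyntheticScenario) -> GeneSet:
    """Snowball-sample a connected subgraph of the requested size as the
    disease gene set."""
    rng = scenario.rng(2)
    nodes = sorted(net.nodes())
    if scenario.n_disease_genes > len(nodes):
        raise ValueError("module larger than the network")
    start = nodes[int(rng.integers(len(nodes)))]
    module = {start}
    frontier = sorted(net.neighbors(start))
    while len(module) < scenario.n_disease_genes:
        if not frontier:
            raise RuntimeError("could not grow a connected disease module")
        pick = frontier[int(rng.integers(len(frontier)))]
        module.add(pick)
        frontier = sorted(
            {n for m in module for n in net.neighbors(m)} - module
        )
    return GeneSet(
        name="planted_module", genes=frozenset(module), source_label="synthetic"
    )


def make_drugs(
    net: nx.Graph, disease: GeneSet, scenario: SyntheticScenario
) -> tuple[DrugTargetNetwork, dict[str, bool]]:
    """Drug-target network plus per-drug planted-proximal labels.

    With probability ``proximity_signal`` a drug samples its targets from
    the disease module and its first neighborhood (so its closest proximity
    is at most 1); otherwise targets are uniform over all genes.  Retained
    mean pActivities are drawn above the conventional potency threshold.
    """
    rng = scenario.rng(3)
    nodes = sorted(net.nodes())
    near_module = sorted(
        set(disease.genes) | {n for g in disease.genes for n in net.neighbors(g)}
    )
    dtn = DrugTargetNetwork()
    labels: dict[str, bool] = {}
    for i in range(scenario.n_drugs):
        drug = f"D{i:04d}"
        proximal = bool(rng.random() < scenario.proximity_signal)
        pool = near_module if proximal else nodes
        targets = rng.choice(pool, size=min(scenario.targets_per_drug, len(pool)),
                             replace=False)
        labels[drug] = proximal
        for t in targets:
            pair = (drug, str(t))
            dtn.pairs.add(pair)
            dtn.mean_pactivity[pair] = float(5.0 + 4.0 * rng.random())
    return dtn, labels


def make_phase_table(
    drug_labels: dict[str, bool], scenario: SyntheticScenario
) -> PhaseTable:
    """Clinical phases for the planted indication.

    With probability ``phase_signal`` a drug's phase is determined by its
    proximity label (proximal -> 4, distal -> 1; the distal floor of 1
    keeps the bottom mean positive so rediscovery rates stay defined);
    otherwise the phase is uniform on {0..4}.  ``phase_signal = 0``
    therefore gives i.i.d. phases and expected rediscovery rate 1.
    """
    rng = scenario.rng(4)
    phase = {}
    for drug in sorted(drug_labels):
        if rng.random() < scenario.phase_signal:
            ph = 4 if drug_labels[drug] else 1
        else:
            ph = int(rng.integers(0, 5))
        phase[(drug, scenario.indication)] = ph
    return PhaseTable(phase=phase)


def make_dose_response(
    scenario: SyntheticScenario,
) -> list[DoseResponseDataset]:
    """Dose-response observations drawn from the sigmoid model itself at the
    scenario's planted parameter values (three concentrations per drug by
    default, replicated)."""
    rng = scenario.rng(5)
    datasets = []
    for truth in scenario.dose_response_truth:
        datasets.append(
            simulate_dataset(
                drug=truth.drug,
                assay=truth.assay,
                direction_of_benefit=truth.direction,
                doses_uM=truth.doses_uM,
                n_replicates=truth.n_replicates,
                y0=truth.y0_true,
                fc=truth.fc_true,
                k=truth.k_true,
                ec50=truth.ec50_true,
                sigma=truth.sigma_true,
                rng=rng,
            )
        )
    return datasets


@dataclass
class ScenarioArtifacts:
    interactome: nx.Graph
    disease_module: GeneSet
    drug_targets: DrugTargetNetwork
    proximal_labels: dict[str, bool]
    phase_table: PhaseTable
    dose_response: list[DoseResponseDataset]


def generate(scenario: SyntheticScenario) -> ScenarioArtifacts:
    """Run every generator stage of a scenario."""
    net = make_interactome(scenario)
    disease = plant_disease_module(net, scenario)
    dtn, labels = make_drugs(net, disease, scenario)
    phases = make_phase_table(labels, scenario)
    dr = make_dose_response(scenario)
    return ScenarioArtifacts(
        interactome=net,
        disease_module=disease,
        drug_targets=dtn,
        proximal_labels=labels,
        phase_table=phases,
        dose_response=dr,
    )


def write_scenario(scenario: SyntheticScenario, outdir: str | Path) -> ScenarioArtifacts:
    """Generate a scenario and write every input file the pipeline consumes,
    plus a ground-truth sidecar JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    art = generate(scenario)

    write_interactome(art.interactome, outdir / "interactome.tsv")
    write_gmt([art.disease_module], outdir / "gene_sets.gmt")
    art.drug_targets.write_tsv(outdir / "drug_targets.tsv")
    art.phase_table.write_csv(outdir / "phases.csv")

    rows = []
    for ds in art.dose_response:
        for c, y in zip(ds.concentrations_uM, ds.bioactivity):
            rows.append(
                {
                    "drug": ds.drug,
                    "assay": ds.assay,
                    "direction_of_benefit": ds.direction_of_benefit,
                    "control_type": ds.control_type,
                    "concentration_uM": c,
                    "bioactivity": y,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "drug", "assay", "direction_of_benefit", "control_type",
            "concentration_uM", "bioactivity",
        ],
    ).to_csv(outdir / "dose_response.csv", index=False)

    truth = {
        "seed": scenario.seed,
        "indication": scenario.indication,
        "n_edges": art.interactome.number_of_edges(),
        "disease_genes": sorted(art.disease_module.genes),
        "proximal_labels": {d: bool(v) for d, v in art.proximal_labels.items()},
        "dose_response_truth": [asdict(t) for t in scenario.dose_response_truth],
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return art
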