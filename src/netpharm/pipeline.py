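"""Pipeline orchestration: config, manifests and stage runners.

Each runner reads the input files named in a :class:`RunConfig`, executes
one stage of the screen (proximity screen + aggregation, rediscovery
validation, dose-response testing, path enumeration) and writes TSV/JSON
outputs together with a manifest recording input checksums and settings so
runs can be reproduced bit-for-bit (draw-for-draw for the MCMC stage).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import __version__
from .dose_response import (
    SamplerConfig,
    SigmoidDoseResponseModel,
    hypothesis_partition,
    standardize,
)
from .networks import DrugTargetNetwork, load_interactome, read_gmt
from .path_analysis import enumerate_paths, mediator_summary, paths_frame
from .proximity import proximity_screen, rank_correlation
from .rank_aggregation import ALGORITHMS, RankedList, select_and_aggregate
from .rediscovery import PhaseTable, curve_frame, rediscovery_curve

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for one pipeline run; mirrors the YAML config layout."""

    interactome: str = "interactome.tsv"
    gene_sets: str = "gene_sets.gmt"
    drug_targets: str = "drug_targets.tsv"
    phases: str = "phases.csv"
    dose_response: str = "dose_response.csv"
    outdir: str = "results"

    pactivity_threshold: float = 5.0
    drop_unreachable: bool = False

    aggregation_algorithms: tuple[str, ...] = ALGORITHMS
    teleport: float = 0.05
    penalty_p: float = 0.5
    top_k: int | None = None

    k_values: tuple[int, ...] = (10, 25, 50)
    bottom_l: int | None = None
    eligibility_min_drugs: int = 100

    x_scale: str = "log10"
    seed: int = 0
    chains_walkers: int = 32
    draws: int = 6000
    warmup: int = 6000
    rhat_max: float = 1.01
    ess_min: float = 400.0
    mcse_ratio_max: float = 0.1

    max_path_edges: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("aggregation_algorithms", "k_values"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(config: RunConfig, inputs: Sequence[str | Path], outdir: Path) -> dict:
    manifest = {
        "netpharm_version": __version__,
        "settings": asdict(config),
        "inputs": {
            str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def run_screen(config: RunConfig):
    """networks -> proximity -> rank aggregation; writes proximity matrices,
    the consensus ranking and the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    net = load_interactome(config.interactome)
    gene_sets = read_gmt(config.gene_sets)
    dtn = DrugTargetNetwork.read_tsv(config.drug_targets)

    matrix = proximity_screen(
        dtn, gene_sets, net, drop_unreachable=config.drop_unreachable
    )
    matrix.write(outdir)
    if len(matrix.gene_sets) >= 2:
        rank_correlation(matrix).to_csv(outdir / "rank_correlation.tsv", sep="\t")

    lists = [
        RankedList(name=gs, items=tuple(matrix.ranked_list(gs)))
        for gs in matrix.gene_sets
    ]
    if len(lists) >= 2:
        agg = select_and_aggregate(
            lists,
            candidates=config.aggregation_algorithms,
            penalty_p=config.penalty_p,
            top_k=config.top_k,
            teleport=config.teleport,
        )
        consensus_items = agg.consensus.items
        stationary = [agg.stationary[d] for d in consensus_items]
        report = {
            "selected_algorithm": agg.algorithm,
            "mean_kendall": agg.mean_kendall,
            "per_algorithm_kendall": agg.per_algorithm_kendall,
        }
    else:
        # one gene set: its proximity ranking is the consensus as-is
        agg = None
        consensus_items = lists[0].items
        stationary = [float("nan")] * len(consensus_items)
        report = {"selected_algorithm": "single-list passthrough"}

    pd.DataFrame(
        {
            "rank": range(1, len(consensus_items) + 1),
            "drug_id": consensus_items,
            "stationary": stationary,
        }
    ).to_csv(outdir / "consensus.tsv", sep="\t", index=False)
    (outdir / "aggregation_report.json").write_text(
        json.dumps(
            report | {"teleport": config.teleport, "penalty_p": config.penalty_p},
            indent=2,
        )
    )
    write_manifest(
        config, [config.interactome, config.gene_sets, config.drug_targets], outdir
    )
    return matrix, agg


def load_consensus(outdir: str | Path) -> RankedList:
    df = pd.read_csv(Path(outdir) / "consensus.tsv", sep="\t", dtype={"drug_id": str})
    return RankedList(name="consensus", items=tuple(df["drug_id"]))


def run_validation(config: RunConfig):
    """Rediscovery curves over eligible indications (plus every indication
    actually present when none meets the eligibility bar)."""
    outdir = Path(config.outdir)
    consensus = load_consensus(outdir)
    table = PhaseTable.read_csv(config.phases)

    eligible = table.eligible_indications(min_drugs=config.eligibility_min_drugs)
    indications = eligible or table.indications
    results = []
    for ind in indications:
        results.extend(
            rediscovery_curve(consensus, table, ind, config.k_values, config.bottom_l)
        )
    frame = curve_frame(results)
    frame.to_csv(outdir / "rediscovery.tsv", sep="\t", index=False)
    write_manifest(config, [config.phases], outdir)
    return frame


def run_doseresponse(config: RunConfig):
    """Fit every drug-assay dataset, apply the convergence gate, test the
    protective hypothesis, and write the per-pair summary grid."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(config.dose_response)

    sampler = SamplerConfig(
        draws=config.draws,
        warmup=config.warmup,
        walkers=config.chains_walkers,
        seed=config.seed,
    )
    rows = []
    for (drug, assay), _ in df.groupby(["drug", "assay"], sort=True):
        try:
            model = SigmoidDoseResponseModel.from_dataframe(
                df, drug, assay, x_scale=config.x_scale
            )
            res = model.fit(sampler)
            check = res.check_fit(
                rhat_max=config.rhat_max,
                ess_min=config.ess_min,
                mcse_ratio_max=config.mcse_ratio_max,
            )
            ht = res.hypothesis_test()
            ht.excluded = not check.passed
            ht.exclusion_reason = "; ".join(check.reasons)
            record = {
                "drug": drug,
                "assay": assay,
                "p_protective": ht.p_protective,
                "p_neutral": ht.p_neutral,
                "p_adverse": ht.p_adverse,
                "bf": ht.bf,
                "two_log_bf": ht.two_log_bf,
                "prior_corrected_bf": ht.prior_corrected_bf,
                "evidence_grade": ht.evidence_grade,
                "excluded": ht.excluded,
                "reason": ht.exclusion_reason,
            }
            (outdir / f"doseresponse_{drug}_{assay}.json").write_text(
                json.dumps(
                    record | {"posterior_summary": res.summary().to_dict()},
                    indent=2,
                    default=str,
                )
            )
        except Exception as exc:  # keep the batch alive on per-dataset failure
            logger.error("dose-response fit failed for (%s, %s): %s", drug, assay, exc)
            record = {
                "drug": drug,
                "assay": assay,
                "excluded": True,
                "reason": f"fit error: {exc}",
            }
        rows.append(record)
    grid = pd.DataFrame(rows)
    grid.to_csv(outdir / "doseresponse_summary.tsv", sep="\t", index=False)
    write_manifest(config, [config.dose_response], outdir)
    return grid


def run_paths(config: RunConfig):
    """Enumerate mechanistic paths for every drug against every gene set and
    write the path table and mediator summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = load_interactome(config.interactome)
    gene_sets = read_gmt(config.gene_sets)
    dtn = DrugTargetNetwork.read_tsv(config.drug_targets)

    frames, all_paths = [], []
    for gs in gene_sets:
        for drug in dtn.drugs:
            paths = enumerate_paths(
                drug, dtn, net, gs, max_edges=config.max_path_edges
            )
            if paths:
                frames.append(paths_frame(paths, gene_set_name=gs.name))
                all_paths.extend(paths)
    paths_df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else paths_frame([], gene_set_name="")
    )
    paths_df.to_csv(outdir / "paths.tsv", sep="\t", index=False)
    if any(p.mediator for p in all_paths):
        mediator_summary(all_paths, gene_sets, net).to_csv(
            outdir / "mediator_summary.tsv", sep="\t", index=False
        )
    write_manifest(
        config, [config.interactome, config.gene_sets, config.drug_targets], outdir
    )
    return paths_df
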