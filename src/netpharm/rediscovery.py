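"""Rediscovery-rate validation of a consensus drug ranking.

For an indication i with per-drug maximum clinical phase phi(d, i) in
{0, ..., 4} (0 = never investigated, 4 = approved), the rediscovery rate of
the top-k drugs relative to the bottom-l drugs of a ranking is

    r_l(k, i) = mean phase of top-k / mean phase of bottom-l.

Rates above 1 indicate that highly ranked drugs are enriched in compounds
already investigated clinically for the indication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .rank_aggregation import RankedList

PHASES = (0, 1, 2, 3, 4)

#: bottom-list size used by default on long rankings
DEFAULT_L = 1808


@dataclass
class PhaseTable:
    """Map (drug_id, indication) -> max clinical phase; absent pairs are 0."""

    phase: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        bad = {p for p in self.phase.values() if p not in PHASES}
        if bad:
            raise ValueError(f"phases outside 0-4: {sorted(bad)}")

    def get(self, drug_id: str, indication: str) -> int:
        return self.phase.get((drug_id, indication), 0)

    @property
    def indications(self) -> list[str]:
        return sorted({i for _, i in self.phase})

    def eligible_indications(self, min_drugs: int = 100, min_phase: int = 1) -> list[str]:
        """Indications with enough clinical activity for a multi-indication
        report: at least ``min_drugs`` drugs at phase >= ``min_phase``."""
        counts: dict[str, int] = {}
        for (_, ind), ph in self.phase.items():
            if ph >= min_phase:
                counts[ind] = counts.get(ind, 0) + 1
        return sorted(i for i, c in counts.items() if c >= min_drugs)

    @classmethod
    def read_csv(cls, path: str | Path) -> "PhaseTable":
        df = pd.read_csv(path, dtype={"drug_id": str, "indication": str})
        return cls(
            phase={
                (r.drug_id, r.indication): int(r.max_phase)
                for r in df.itertuples(index=False)
            }
        )

    def write_csv(self, path: str | Path) -> None:
        rows = sorted(self.phase.items())
        pd.DataFrame(
            {
                "drug_id": [d for (d, _), _ in rows],
                "indication": [i for (_, i), _ in rows],
                "max_phase": [p for _, p in rows],
            }
        ).to_csv(path, index=False)


@dataclass
class RediscoveryResult:
    indication: str
    k: int
    l: int
    phi_top: float
    phi_bottom: float
    rate: float  # NaN when undefined (phi_bottom == 0)

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rate)


def mean_phase(
    drugs: Sequence[str] | set[str], indication: str, table: PhaseTable
) -> float:
    """Arithmetic mean clinical phase over a drug set; absent pairs count 0."""
    drugs = list(drugs)
    if not drugs:
        raise ValueError("empty drug set")
    return sum(table.get(d, indication) for d in drugs) / len(drugs)


def default_l(n: int) -> int:
    """The standard bottom-list size when the ranking is long enough,
    otherwise a third of the list."""
    return DEFAULT_L if n >= 2 * DEFAULT_L else n // 3


def rediscovery_rate(
    consensus: RankedList,
    table: PhaseTable,
    indication: str,
    k: int,
    l: int | None = None,
) -> RediscoveryResult:
    """Ratio of mean phases between the first k and last l drugs of the
    consensus; undefined (NaN rate) when the bottom mean is zero."""
    n = len(consensus)
    if l is None:
        l = default_l(n)
    if k < 1 or l < 1:
        raise ValueError("k and l must be positive")
    if k + l > n:
        raise ValueError(f"k + l = {k + l} exceeds list length {n} (sets must be disjoint)")
    top = consensus.items[:k]
    bottom = consensus.items[-l:]
    phi_top = mean_phase(top, indication, table)
    phi_bottom = mean_phase(bottom, indication, table)
    rate = phi_top / phi_bottom if phi_bottom > 0 else math.nan
    return RediscoveryResult(
        indication=indication, k=k, l=l, phi_top=phi_top, phi_bottom=phi_bottom, rate=rate
    )


def rediscovery_curve(
    consensus: RankedList,
    table: PhaseTable,
    indication: str,
    k_values: Sequence[int],
    l: int | None = None,
) -> list[RediscoveryResult]:
    """One rediscovery rate per k at fixed l."""
    return [rediscovery_rate(consensus, table, indication, k, l) for k in k_values]


def curve_frame(results: Sequence[RediscoveryResult]) -> pd.DataFrame:
    """Long-format table of rediscovery results for TSV export."""
    return pd.DataFrame(
        {
            "indication": [r.indication for r in results],
            "k": [r.k for r in results],
            "l": [r.l for r in results],
            "phi_top": [r.phi_top for r in results],
            "phi_bottom": [r.phi_bottom for r in results],
            "rate": [r.rate for r in results],
            "defined": [r.defined for r in results],
        }
    )
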