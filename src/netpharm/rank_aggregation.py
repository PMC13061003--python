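"""Markov-chain rank aggregation of multiple drug rankings.

Consensus rankings are built from the stationary distribution of a Markov
chain over the items: from the current item u a candidate v is proposed
uniformly, and the chain moves according to how the input lists order u and
v.  The three classical chains differ in the move rule:

* MC1 -- move if at least one list ranking both items puts v above u;
* MC2 -- move if a strict majority of such lists puts v above u;
* MC3 -- move with probability equal to the fraction of such lists putting
  v above u.

A small teleportation mass mixed into the transition matrix guarantees
irreducibility.  Borda (mean-rank) aggregation is included as a
deterministic baseline.  Algorithm selection minimizes the mean modified
Kendall distance between the consensus and the input lists, a top-k distance
with a penalty parameter for item pairs whose relative order a truncated
list leaves undetermined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

ALGORITHMS = ("MC3", "MC2", "MC1", "Borda")  # tie precedence, best first


@dataclass(frozen=True)
class RankedList:
    """An ordered list of items, position 1 = best; no duplicates."""

    name: str
    items: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.items)) != len(self.items):
            raise ValueError(f"ranked list {self.name!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.items)

    def position(self) -> dict[str, int]:
        return {item: i for i, item in enumerate(self.items)}


@dataclass
class AggregationResult:
    algorithm: str
    consensus: RankedList
    stationary: dict[str, float]
    mean_kendall: float
    per_algorithm_kendall: dict[str, float] = field(default_factory=dict)


def _universe(lists: Sequence[RankedList]) -> list[str]:
    seen: dict[str, None] = {}
    for rl in lists:
        for item in rl.items:
            seen.setdefault(item)
    return sorted(seen)


def mc_transition_matrix(
    lists: Sequence[RankedList],
    variant: str = "MC3",
    teleport: float = 0.05,
) -> tuple[np.ndarray, list[str]]:
    """Row-stochastic transition matrix of the chosen chain over the union
    of items, with uniform teleportation mixed in for ergodicity.

    Returns the matrix and the item order of its rows/columns.
    """
    if variant not in ("MC1", "MC2", "MC3"):
        raise ValueError(f"unknown MC variant {variant!r}")
    if not 0 < teleport < 1:
        raise ValueError("teleport must be in (0, 1)")
    if len(lists) < 2:
        raise ValueError("need at least two ranked lists")

    items = _universe(lists)
    n = len(items)
    idx = {it: i for i, it in enumerate(items)}
    positions = [rl.position() for rl in lists]

    # above[i, j] = number of lists ranking both that put j above i
    above = np.zeros((n, n))
    both = np.zeros((n, n))
    for pos in positions:
        ranked = [idx[i] for i in pos]
        sub = np.array(ranked)
        r = np.array([pos[items[i]] for i in sub])
        # pairwise comparisons within this list
        cmp = r[None, :] < r[:, None]  # cmp[a,b]: b ranked above a
        above[np.ix_(sub, sub)] += cmp
        both[np.ix_(sub, sub)] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(both > 0, above / np.maximum(both, 1), 0.0)

    if variant == "MC1":
        move = (above >= 1).astype(float)
    elif variant == "MC2":
        move = (above > both / 2).astype(float)
    else:  # MC3
        move = frac
    np.fill_diagonal(move, 0.0)

    P = move / n
    np.fill_diagonal(P, 1.0 - P.sum(axis=1))
    P = (1.0 - teleport) * P + teleport / n
    return P, items


def stationary_distribution(
    P: np.ndarray, tol: float = 1e-10, max_iter: int = 100_000
) -> np.ndarray:
    """Stationary probability vector of a row-stochastic irreducible matrix,
    by power iteration to an L-inf tolerance."""
    n = P.shape[0]
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("matrix is not row-stochastic")
    pi = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = pi @ P
        nxt /= nxt.sum()
        if np.max(np.abs(nxt - pi)) < tol:
            return nxt
        pi = nxt
    residual = float(np.max(np.abs(pi @ P - pi)))
    raise RuntimeError(
        f"power iteration did not converge in {max_iter} steps (residual {residual:.3e})"
    )


def borda(lists: Sequence[RankedList]) -> tuple[RankedList, dict[str, float]]:
    """Mean-rank (Borda) consensus; items absent from a list take rank
    len(list) + 1 in that list."""
    items = _universe(lists)
    scores = {}
    for it in items:
        rs = []
        for rl in lists:
            pos = rl.position()
            rs.append(pos[it] + 1 if it in pos else len(rl) + 1)
        scores[it] = float(np.mean(rs))
    order = sorted(items, key=lambda it: (scores[it], it))
    return RankedList(name="Borda", items=tuple(order)), scores


def mc_consensus(
    lists: Sequence[RankedList], variant: str, teleport: float = 0.05
) -> tuple[RankedList, dict[str, float]]:
    """Consensus ranking of one MC variant: items by descending stationary
    probability, ties broken lexicographically."""
    P, items = mc_transition_matrix(lists, variant, teleport)
    pi = stationary_distribution(P)
    stat = dict(zip(items, pi))
    order = sorted(items, key=lambda it: (-stat[it], it))
    return RankedList(name=variant, items=tuple(order)), stat


def modified_kendall(
    list_a: RankedList,
    list_b: RankedList,
    penalty_p: float = 0.5,
    top_k: int | None = None,
) -> float:
    """Top-k Kendall distance with penalty parameter, normalized to [0, 1].

    Only the top-k prefixes of the two lists are compared.  For every
    unordered pair of items appearing in either prefix:

    * both pairs ordered by both prefixes (an item absent from a prefix is
      implicitly below every present item): contribute 1 if discordant;
    * relative order undetermined in one list (both items missing from that
      prefix): contribute ``penalty_p``.

    The sum is divided by the number of evaluated pairs.
    """
    if top_k is None:
        top_k = min(len(list_a), len(list_b))
    if top_k < 2:
        raise ValueError("top_k must be at least 2")
    if not 0 <= penalty_p <= 1:
        raise ValueError("penalty_p must be in [0, 1]")

    a = list_a.items[:top_k]
    b = list_b.items[:top_k]
    pos_a = {it: i for i, it in enumerate(a)}
    pos_b = {it: i for i, it in enumerate(b)}
    union = sorted(set(a) | set(b))

    total, n_pairs = 0.0, 0
    for i, x in enumerate(union):
        for y in union[i + 1 :]:
            n_pairs += 1
            in_a = (x in pos_a) + (y in pos_a)
            in_b = (x in pos_b) + (y in pos_b)
            if in_a == 0 or in_b == 0:
                # pair order undetermined in one list entirely
                total += penalty_p
                continue

            def order(pos: Mapping[str, int]) -> int | None:
                # +1 if x above y, -1 if y above x, None if undetermined
                if x in pos and y in pos:
                    return 1 if pos[x] < pos[y] else -1
                if x in pos:
                    return 1  # y absent -> below x
                if y in pos:
                    return -1
                return None

            oa, ob = order(pos_a), order(pos_b)
            if oa is None or ob is None:
                total += penalty_p
            elif oa != ob:
                total += 1.0
    return total / n_pairs if n_pairs else 0.0


def mean_kendall_to_inputs(
    consensus: RankedList,
    lists: Sequence[RankedList],
    penalty_p: float,
    top_k: int | None,
) -> float:
    return float(
        np.mean([modified_kendall(consensus, rl, penalty_p, top_k) for rl in lists])
    )


def select_and_aggregate(
    lists: Sequence[RankedList],
    candidates: Sequence[str] = ALGORITHMS,
    penalty_p: float = 0.5,
    top_k: int | None = None,
    teleport: float = 0.05,
) -> AggregationResult:
    """Run every candidate algorithm with uniform list weights and return the
    one whose consensus minimizes the mean modified Kendall distance to the
    inputs (ties resolved by the fixed precedence MC3 > MC2 > MC1 > Borda)."""
    if len(lists) < 2:
        raise ValueError("need at least two ranked lists")
    unknown = set(candidates) - set(ALGORITHMS)
    if unknown:
        raise ValueError(f"unknown algorithms: {sorted(unknown)}")

    results: dict[str, tuple[RankedList, dict[str, float], float]] = {}
    for algo in ALGORITHMS:
        if algo not in candidates:
            continue
        if algo == "Borda":
            consensus, scores = borda(lists)
            # invert mean ranks into a pseudo-stationary mass for reporting
            inv = {it: 1.0 / s for it, s in scores.items()}
            z = sum(inv.values())
            stat = {it: v / z for it, v in inv.items()}
        else:
            consensus, stat = mc_consensus(lists, algo, teleport)
        mk = mean_kendall_to_inputs(consensus, lists, penalty_p, top_k)
        results[algo] = (consensus, stat, mk)

    winner = min(results, key=lambda a: (results[a][2], ALGORITHMS.index(a)))
    consensus, stat, mk = results[winner]
    return AggregationResult(
        algorithm=winner,
        consensus=RankedList(name=f"consensus[{winner}]", items=consensus.items),
        stationary=stat,
        mean_kendall=mk,
        per_algorithm_kendall={a: r[2] for a, r in results.items()},
    )
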