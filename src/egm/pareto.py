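"""Pareto-front filtering of mined subgroups and top-k reporting.

The t-based quality trades off three things a grower cares about separately:
how far the subgroup mean is shifted (in the search direction), how tight the
subgroup is around that mean, and how many fields the description covers.
Rather than committing to one scalarization, the report keeps every subgroup
not dominated simultaneously in (directional mean, sd, size) — higher mean,
lower sd, larger size are better — and then presents the top-k by quality
after size filtering and redundancy clean-up.

The filtering is asymmetric: it discards subgroups dominated by another
*found* subgroup, but cannot certify the survivors as globally optimal,
since the search does not enumerate every possible description.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

from .emm_search import Subgroup


@dataclasses.dataclass(frozen=True)
class ObjectiveTriple:
    """One subgroup's coordinates in the Pareto space.

    ``dmean`` is the directional mean (mean for high-direction searches,
    -mean for low), so larger is always better; ``sd`` smaller is better;
    ``n`` larger is better.
    """

    dmean: float
    sd: float
    n: int


def dominates(x: ObjectiveTriple, y: ObjectiveTriple) -> bool:
    """True iff x is at least as good as y in all three objectives and
    strictly better in at least one."""
    ge = x.dmean >= y.dmean and x.sd <= y.sd and x.n >= y.n
    strict = x.dmean > y.dmean or x.sd < y.sd or x.n > y.n
    return ge and strict


def _triple(sg: Subgroup, direction: str) -> ObjectiveTriple:
    mean = sg.stats.mean
    return ObjectiveTriple(
        dmean=mean if direction == "high" else -mean,
        sd=sg.stats.sd,
        n=sg.stats.n,
    )


def pareto_front_triples(triples: Sequence[ObjectiveTriple]) -> list[int]:
    """Indices of the non-dominated triples, input order preserved."""
    keep = []
    for i, x in enumerate(triples):
        if not any(dominates(y, x) for j, y in enumerate(triples) if j != i):
            keep.append(i)
    return keep


def pareto_front(
    subgroups: Sequence[Subgroup], direction: str = "high"
) -> list[Subgroup]:
    """Subgroups not dominated by any other in (directional mean, sd, n).

    Subgroups with undefined stats (quality -inf) are dropped first; equal
    triples are mutually non-dominating and all kept.  Idempotent.
    """
    valid = [sg for sg in subgroups if sg.stats.quality != float("-inf")]
    triples = [_triple(sg, direction) for sg in valid]
    keep = set(pareto_front_triples(triples))
    return [sg for i, sg in enumerate(valid) if i in keep]


def _attr_kind_sets(sg: Subgroup) -> set[tuple[str, str]]:
    return {(c.attribute, c.kind) for c in sg.description.conditions}


def top_k_report(
    front: Iterable[Subgroup],
    k: int = 5,
    min_size: int = 15,
) -> tuple[list[Subgroup], list[str]]:
    """Paper-style top-k presentation of a Pareto front.

    Keeps subgroups with n > ``min_size``; collapses redundant same-attribute
    same-direction threshold conditions inside a description to the tightest
    (e.g. K_soil ≤ 200 ∧ K_soil ≤ 100 becomes K_soil ≤ 100 — already the
    canonical form of the search); when two survivors' member sets are nested
    and their descriptions differ only in thresholds on the same attributes,
    only the larger subgroup is presented.  Returns the k highest-quality
    survivors and a list of notices.

    Note the collapse applies at reporting only; the search and the front
    keep all distinct subgroups.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    notices: list[str] = []
    survivors = [sg for sg in front if sg.stats.n > min_size]
    # canonical form already keeps only the tightest same-direction threshold
    survivors = [
        dataclasses.replace(sg, description=sg.description.canonical())
        for sg in survivors
    ]
    drop: set[int] = set()
    for i, small in enumerate(survivors):
        for j, big in enumerate(survivors):
            if i == j or j in drop:
                continue
            if not (
                small.members <= big.members
                and _attr_kind_sets(small) == _attr_kind_sets(big)
            ):
                continue
            if small.members < big.members:
                reason = "nested inside"
            elif (len(small.description), str(small.description)) > (
                len(big.description),
                str(big.description),
            ):
                # identical member sets under cosmetically different
                # thresholds: keep one, deterministically
                reason = "same member set as"
            else:
                continue
            drop.add(i)
            notices.append(
                f"dropped {small.description} (n={small.stats.n}): {reason} "
                f"{big.description} (n={big.stats.n})"
            )
            break
    kept = [sg for i, sg in enumerate(survivors) if i not in drop]
    kept.sort(
        key=lambda sg: (
            -sg.stats.quality,
            len(sg.description),
            str(sg.description),
        )
    )
    if len(kept) < k:
        notices.append(f"only {len(kept)} subgroup(s) survive the filters (k={k})")
    return kept[:k], notices
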