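"""Beam-search subgroup discovery over the growth-curve random effects.

After the mixed-model fit, each field is one record whose target is an
empirical-Bayes random effect (a, b or c), marginally standard normal for
the population.  A subgroup is the set of fields satisfying a conjunction of
conditions on soil/management descriptors; it is exceptional when its target
sample pulls away from mean zero, which the one-sample t statistic

    t_G = mean(u_G) * sqrt(n) / sd(u_G)

captures.  The quality measure is t_G when searching for high values and
-t_G when searching for low values.  The search is level-wise beam search:
numeric descriptors are split at equal-frequency quantiles recomputed within
the current subgroup, categorical descriptors contribute equality and
inequality conditions.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_data import CATEGORICAL_DESCRIPTORS, NUMERIC_DESCRIPTORS


class SearchError(ValueError):
    """Raised for invalid search configurations or undefined statistics."""


# ---------------------------------------------------------------------------
# description language
# ---------------------------------------------------------------------------

_KINDS = ("numeric_le", "numeric_gt", "cat_eq", "cat_neq")
_SYMBOL = {"numeric_le": "≤", "numeric_gt": ">", "cat_eq": "=", "cat_neq": "≠"}


@dataclasses.dataclass(frozen=True)
class Condition:
    """One atomic condition on a descriptor.

    ``kind`` is ``numeric_le`` / ``numeric_gt`` for thresholds on numeric
    descriptors and ``cat_eq`` / ``cat_neq`` for category (in)equality.
    Records with a missing value on the attribute never satisfy a condition.
    """

    attribute: str
    kind: str
    value: float | str

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise SearchError(f"unknown condition kind {self.kind!r}")

    def mask(self, fields: pd.DataFrame) -> np.ndarray:
        col = fields[self.attribute]
        if self.kind == "numeric_le":
            out = col.to_numpy(float) <= float(self.value)
        elif self.kind == "numeric_gt":
            out = col.to_numpy(float) > float(self.value)
        elif self.kind == "cat_eq":
            out = col.astype(object).to_numpy() == self.value
        else:
            out = (col.astype(object).to_numpy() != self.value) & col.notna().to_numpy()
        return np.where(col.isna().to_numpy(), False, out)

    def __str__(self) -> str:
        v = self.value
        if isinstance(v, float):
            v = f"{v:g}"
        return f"{self.attribute} {_SYMBOL[self.kind]} {v}"


@dataclasses.dataclass(frozen=True)
class Description:
    """A conjunction of conditions; the empty conjunction is the whole dataset."""

    conditions: tuple[Condition, ...] = ()

    def canonical(self) -> "Description":
        """Tightest-kept canonical form, sorted for deterministic display.

        Per numeric attribute at most one <=-condition (smallest threshold)
        and one >-condition (largest) survive; duplicate categorical
        conditions collapse.
        """
        le: dict[str, Condition] = {}
        gt: dict[str, Condition] = {}
        cats: dict[tuple, Condition] = {}
        for c in self.conditions:
            if c.kind == "numeric_le":
                if c.attribute not in le or c.value < le[c.attribute].value:
                    le[c.attribute] = c
            elif c.kind == "numeric_gt":
                if c.attribute not in gt or c.value > gt[c.attribute].value:
                    gt[c.attribute] = c
            else:
                cats.setdefault((c.attribute, c.kind, c.value), c)
        conds = list(le.values()) + list(gt.values()) + list(cats.values())
        conds.sort(key=lambda c: (c.attribute, c.kind, str(c.value)))
        return Description(tuple(conds))

    def mask(self, fields: pd.DataFrame) -> np.ndarray:
        out = np.ones(len(fields), dtype=bool)
        for c in self.conditions:
            out &= c.mask(fields)
        return out

    def __len__(self) -> int:
        return len(self.conditions)

    def __str__(self) -> str:
        if not self.conditions:
            return "(all)"
        return " ∧ ".join(str(c) for c in self.conditions)


# ---------------------------------------------------------------------------
# quality measure
# ---------------------------------------------------------------------------


def t_statistic(values: Sequence[float]) -> float:
    """One-sample t statistic against mean zero: mean * sqrt(n) / sd (ddof=1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise SearchError("t statistic needs at least 2 values")
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        raise SearchError("t statistic undefined for zero spread")
    return float(np.mean(v) * math.sqrt(v.size) / sd)


def quality(values: Sequence[float], direction: str) -> float:
    """Directional quality: t for ``high``, -t for ``low``."""
    if direction not in ("high", "low"):
        raise SearchError(f"direction must be 'high' or 'low', got {direction!r}")
    t = t_statistic(values)
    return t if direction == "high" else -t


# ---------------------------------------------------------------------------
# subgroups
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SubgroupStats:
    n: int
    mean: float
    sd: float
    t: float
    quality: float


@dataclasses.dataclass(frozen=True)
class Subgroup:
    description: Description
    members: frozenset
    stats: SubgroupStats

    def __str__(self) -> str:
        s = self.stats
        return (
            f"{self.description}  (n={s.n}, mean={s.mean:.3f}, "
            f"sd={s.sd:.3f}, t={s.t:.2f})"
        )


@dataclasses.dataclass
class BeamConfig:
    """Search hyper-parameters.

    ``target`` selects the random-effect component mined; ``direction``
    orients the quality; ``beam_width`` may be ``None`` for an exhaustive
    (infinite-beam) run; ``n_bins`` equal-frequency bins give ``n_bins - 1``
    numeric thresholds, recomputed within the current subgroup at each level.
    ``min_size`` guards the t statistic during search (reporting applies its
    own, larger size filter).
    """

    target: str = "a"
    direction: str = "high"
    beam_width: int | None = 25
    depth: int = 2
    n_bins: int = 6
    min_size: int = 2
    numeric_attributes: tuple[str, ...] = NUMERIC_DESCRIPTORS
    categorical_attributes: tuple[str, ...] = CATEGORICAL_DESCRIPTORS

    def validate(self, fields: pd.DataFrame) -> None:
        if self.target not in ("a", "b", "c"):
            raise SearchError("target must be one of 'a', 'b', 'c'")
        if self.direction not in ("high", "low"):
            raise SearchError("direction must be 'high' or 'low'")
        if self.beam_width is not None and self.beam_width < 1:
            raise SearchError("beam_width must be >= 1 (or None for exhaustive)")
        if self.depth < 1 or self.n_bins < 2 or self.min_size < 2:
            raise SearchError("depth >= 1, n_bins >= 2, min_size >= 2 required")


def evaluate(
    desc: Description,
    fields: pd.DataFrame,
    targets: pd.Series,
    config: BeamConfig,
) -> Subgroup:
    """Materialize a description: members, target stats, directional quality.

    Subgroups smaller than ``config.min_size`` (or with zero target spread)
    get quality -inf so they never enter the beam.
    """
    desc = desc.canonical()
    mask = desc.mask(fields)
    members = frozenset(fields.index[mask])
    vals = targets.loc[list(members)].to_numpy(float) if members else np.array([])
    n = len(vals)
    if n < max(2, config.min_size) or (n > 0 and np.std(vals, ddof=0) == 0.0):
        stats = SubgroupStats(
            n=n,
            mean=float(np.mean(vals)) if n else float("nan"),
            sd=float("nan"),
            t=float("nan"),
            quality=float("-inf"),
        )
    else:
        t = t_statistic(vals)
        stats = SubgroupStats(
            n=n,
            mean=float(np.mean(vals)),
            sd=float(np.std(vals, ddof=1)),
            t=t,
            quality=t if config.direction == "high" else -t,
        )
    return Subgroup(description=desc, members=members, stats=stats)


def refine(
    desc: Description, fields: pd.DataFrame, config: BeamConfig
) -> list[Description]:
    """All one-condition refinements of a description.

    Numeric thresholds are the ``n_bins - 1`` equal-frequency quantiles of
    the attribute among the current members (non-missing values only), each
    contributing a <=- and a >-condition; every category observed among the
    members contributes an =- and a !=-condition.  Results are canonical and
    de-duplicated; refinements that collapse into the parent are dropped.
    """
    mask = desc.canonical().mask(fields)
    members = fields.loc[mask]
    out: list[Description] = []
    seen: set[tuple] = set()
    parent = desc.canonical().conditions

    def push(cond: Condition) -> None:
        cand = Description(parent + (cond,)).canonical()
        key = cand.conditions
        if key == parent or key in seen:
            return
        seen.add(key)
        out.append(cand)

    qs = np.arange(1, config.n_bins) / config.n_bins
    for attr in config.numeric_attributes:
        if attr not in fields.columns:
            continue
        vals = members[attr].dropna().to_numpy(float)
        if vals.size == 0:
            continue
        thresholds = np.unique(np.quantile(vals, qs))
        for thr in thresholds:
            push(Condition(attr, "numeric_le", float(thr)))
            push(Condition(attr, "numeric_gt", float(thr)))
    for attr in config.categorical_attributes:
        if attr not in fields.columns:
            continue
        for cat in sorted(members[attr].dropna().unique().tolist()):
            push(Condition(attr, "cat_eq", cat))
            push(Condition(attr, "cat_neq", cat))
    return out


def _beam_key(sg: Subgroup):
    """Sort key: quality desc, then shorter description, then lexicographic."""
    return (-sg.stats.quality, len(sg.description), str(sg.description))


def beam_search(
    fields: pd.DataFrame,
    targets: pd.Series,
    config: BeamConfig,
) -> list[Subgroup]:
    """Level-wise beam search; returns every distinct evaluated subgroup.

    At each level the top ``beam_width`` candidates by quality seed the next
    level; ``beam_width=None`` keeps all (exhaustive over the description
    language to the given depth).  Deterministic: ties are broken by shorter
    description, then the lexicographic canonical string.  The result is
    sorted by quality descending and de-duplicated on (canonical
    description, member set).
    """
    config.validate(fields)
    missing = [u for u in fields.index if u not in targets.index]
    if missing:
        raise SearchError(f"no target value for unit(s) {missing[:5]}")

    all_seen: dict[tuple, Subgroup] = {}
    beam: list[Subgroup] = [
        evaluate(Description(), fields, targets, config)
    ]
    for _level in range(config.depth):
        candidates: dict[tuple, Subgroup] = {}
        for sg in beam:
            if len(sg.description) >= config.depth:
                continue
            for cand_desc in refine(sg.description, fields, config):
                sg_new = evaluate(cand_desc, fields, targets, config)
                key = (sg_new.description.conditions, sg_new.members)
                if key not in candidates:
                    candidates[key] = sg_new
        for key, sg_new in candidates.items():
            if key not in all_seen:
                all_seen[key] = sg_new
        ranked = sorted(candidates.values(), key=_beam_key)
        if config.beam_width is not None:
            ranked = ranked[: config.beam_width]
        beam = [sg for sg in ranked if np.isfinite(sg.stats.quality)]
        if not beam:
            break
    return sorted(all_seen.values(), key=_beam_key)


def subgroups_frame(subgroups: Iterable[Subgroup]) -> pd.DataFrame:
    """Tabular view of a subgroup list (one row per subgroup)."""
    rows = []
    for sg in subgroups:
        s = sg.stats
        rows.append(
            {
                "description": str(sg.description),
                "n": s.n,
                "mean": s.mean,
                "sd": s.sd,
                "t": s.t,
                "quality": s.quality,
                "members": ";".join(sorted(map(str, sg.members))),
            }
        )
    return pd.DataFrame(rows)
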