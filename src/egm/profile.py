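"""Confounder profiles of subgroups: years, yield, irrigation, planting time.

A mined description mentions only soil and management descriptors; before
interpreting a subgroup agronomically one checks whether it is secretly a
year effect (the year distribution), whether it tracks final yield, and
whether irrigation or planting moment could explain it.  Planting moment is
summarized per year by splitting the planting period into early / middle /
late thirds (equal-frequency; earlier thirds take the extra fields when the
count is not divisible by three).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .emm_search import Subgroup

TERTILE_LABELS = ("early", "middle", "late")


@dataclasses.dataclass(frozen=True)
class SubgroupProfile:
    """Descriptive annotations of one subgroup (no statistical test applied)."""

    year_counts: dict[int, int]
    mean_yield: float
    irrigation: tuple[int, int]  # (not irrigated, irrigated)
    planting: tuple[int, int, int]  # (early, middle, late)
    n_unknown_planting: int = 0


def planting_tertiles(fields: pd.DataFrame) -> pd.Series:
    """Label every field-year early / middle / late within its year.

    Fields are ordered by planting date with a stable sort (date ties keep
    input order) and split into three equal-frequency groups per year; when
    n mod 3 != 0 the earlier groups take the extra fields.  Fields with a
    missing planting date are labelled ``"unknown"``.
    """
    out = pd.Series("unknown", index=fields.index, dtype=object)
    for _year, grp in fields.groupby("year", sort=True):
        dated = grp[grp["planting_date"].notna()]
        order = dated["planting_date"].sort_values(kind="stable").index
        n = len(order)
        if n == 0:
            continue
        base, extra = divmod(n, 3)
        sizes = [base + (1 if i < extra else 0) for i in range(3)]
        start = 0
        for label, size in zip(TERTILE_LABELS, sizes):
            out.loc[order[start : start + size]] = label
            start += size
    return out


def subgroup_profile(sg: Subgroup, fields: pd.DataFrame) -> SubgroupProfile:
    """Year counts, mean yield, irrigation and planting-tertile counts."""
    members = fields.loc[sorted(sg.members)]
    year_counts = members["year"].value_counts().sort_index()
    yields = members["yield_ton_ha"].dropna() if "yield_ton_ha" in members else pd.Series(dtype=float)
    mean_yield = float(yields.mean()) if len(yields) else float("nan")
    if "irrigated" in members:
        irr = members["irrigated"].fillna(False).astype(bool)
        irrigation = (int((~irr).sum()), int(irr.sum()))
    else:
        irrigation = (0, 0)
    if "planting_date" in fields.columns:
        tert_all = planting_tertiles(fields)
        tert = tert_all.loc[members.index]
        planting = tuple(int((tert == lab).sum()) for lab in TERTILE_LABELS)
        unknown = int((tert == "unknown").sum())
    else:
        planting = (0, 0, 0)
        unknown = len(members)
    return SubgroupProfile(
        year_counts={int(y): int(c) for y, c in year_counts.items()},
        mean_yield=mean_yield,
        irrigation=irrigation,
        planting=planting,  # type: ignore[arg-type]
        n_unknown_planting=unknown,
    )


def profile_columns(sg: Subgroup, fields: pd.DataFrame) -> dict:
    """Profile flattened to report-CSV columns."""
    p = subgroup_profile(sg, fields)
    row: dict = {"mean_yield": np.round(p.mean_yield, 2)}
    for year in sorted(fields["year"].unique().tolist()):
        row[f"n_{year}"] = p.year_counts.get(int(year), 0)
    row["n_not_irrigated"], row["n_irrigated"] = p.irrigation
    for lab, cnt in zip(TERTILE_LABELS, p.planting):
        row[f"n_planted_{lab}"] = cnt
    return row
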