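"""Univariate linear QSPR screening and prediction.

The model is ``property = intercept + slope * index`` (ordinary least
squares), screened by the Pearson correlation's two-sided p-value (t
distribution with n-2 degrees of freedom).  The published coefficient tables
put the property on the left and the index on the right, and that orientation
is used throughout, even though the running text of the source nominally
describes the regression the other way around.

Fits are performed within a pharmacological group; the hypouricemic group has
only three members, so its p-values rest on a single degree of freedom and
every such model carries a ``low_n`` flag.  No multiple-testing adjustment is
applied -- the screen is the raw ``p < alpha`` filter the study reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fixtures import published_equations


@dataclass
class LinearModel:
    property: str
    index: str
    slope: float
    intercept: float
    r: float
    p: float
    n: int
    group: str = ""
    low_n: bool = False

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def as_dict(self) -> dict:
        return {
            "group": self.group, "property": self.property, "index": self.index,
            "intercept": self.intercept, "slope": self.slope, "r": self.r,
            "p": self.p, "n": self.n, "low_n": self.low_n,
        }


def fit_linear(x, y, property: str = "y", index: str = "x",
               group: str = "") -> LinearModel:
    """OLS fit of y on x with pairwise deletion of missing values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 paired values, got {n}")
    if np.ptp(x) == 0:
        raise ValueError(f"constant predictor {index!r}")
    res = stats.linregress(x, y)
    return LinearModel(
        property=property, index=index, group=group,
        slope=float(res.slope), intercept=float(res.intercept),
        r=float(res.rvalue), p=float(res.pvalue), n=n, low_n=n <= 3,
    )


def correlation_screen(indices: pd.DataFrame, props: pd.DataFrame,
                       alpha: float = 0.05,
                       groups: dict[str, str] | None = None) -> list[LinearModel]:
    """Fit every (index, property) pair and keep models with p < alpha.

    Both tables are indexed by compound name; only shared compounds are used.
    If ``groups`` maps compounds to group labels, fits run within each group
    (the study never pools across pharmacological groups).  Within each
    (group, property) the surviving models are ranked by |r| descending, ties
    broken by index column order.
    """
    shared = indices.index.intersection(props.index)
    if len(shared) == 0:
        raise ValueError("no shared compound rows between the two tables")
    ind, prp = indices.loc[shared], props.loc[shared]
    if groups is None:
        membership = {"": list(shared)}
    else:
        membership = {}
        for c in shared:
            membership.setdefault(groups[c], []).append(c)
    out: list[LinearModel] = []
    for gname, members in membership.items():
        gi, gp = ind.loc[members], prp.loc[members]
        for prop in gp.columns:
            fits = []
            for rank, col in enumerate(gi.columns):
                x, y = gi[col].values, gp[prop].values
                keep = np.isfinite(x.astype(float)) & np.isfinite(y.astype(float))
                if keep.sum() < 3 or np.ptp(x[keep].astype(float)) == 0:
                    continue
                m = fit_linear(x, y, property=prop, index=col, group=gname)
                if m.p < alpha:
                    fits.append((rank, m))
            fits.sort(key=lambda rm: (-abs(rm[1].r), rm[0]))
            out.extend(m for _, m in fits)
    return out


def screen_table(models: list[LinearModel]) -> pd.DataFrame:
    return pd.DataFrame([m.as_dict() for m in models])


class PublishedEquationSet:
    """The 82 published linear equations, addressable by equation number."""

    def __init__(self, table: pd.DataFrame | None = None):
        self.table = published_equations() if table is None else table
        self._by_no = {int(r.eq_no): r for r in self.table.itertuples()}

    def __len__(self) -> int:
        return len(self.table)

    def equation(self, eq_no: int):
        try:
            return self._by_no[int(eq_no)]
        except KeyError:
            raise KeyError(f"no published equation number {eq_no}") from None

    def predict(self, eq_no: int, x: float) -> float:
        """intercept + slope * x for one equation."""
        if not math.isfinite(x):
            raise ValueError(f"non-finite index value {x!r}")
        eq = self.equation(eq_no)
        return float(eq.intercept + eq.slope * x)

    def predict_all(self, index_table: pd.DataFrame,
                    groups: dict[str, str] | None = None) -> pd.DataFrame:
        """Apply every equation to its index column for every compound.

        When ``groups`` is given, an equation is only applied to compounds of
        its own pharmacological group.
        """
        rows = []
        for eq in self.table.itertuples():
            for compound in index_table.index:
                if groups is not None and groups.get(compound) != eq.group:
                    continue
                rows.append({
                    "eq_no": int(eq.eq_no), "group": eq.group,
                    "property": eq.property, "index": eq.index,
                    "compound": compound,
                    "predicted": float(eq.intercept
                                       + eq.slope * index_table.loc[compound, eq.index]),
                })
        return pd.DataFrame(rows)
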