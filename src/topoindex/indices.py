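"""The eleven topological indices of the study, in published column order.

Adjacency-matrix indices (from the degree vectors):

* Gutman ``M = sum(delta_i^2)`` and valence variant ``Mv = sum(delta_v_i^2)``
* Randić connectivity ``chi0 = sum(delta_i^-1/2)`` over vertices,
  ``chi1 = sum((delta_i*delta_j)^-1/2)`` over edges, and the valence variants
  ``chi0v``/``chi1v`` built from delta_v.

Distance-matrix indices (from the Barysz matrix, S_i the distance degrees):

* Wiener ``W = trace + upper-triangle sum``
* Rouvray–Crafford ``R = sum of all matrix elements`` (= 2W - trace)
* Pyka ``A = sum(S_i^2)``, ``B0 = sum(S_i^-1/2)`` over vertices and
  ``B1 = sum((S_i*S_j)^-1/2)`` over bonded pairs.

A caveat on ``A``: the defining formula ``sum(S_i^2)`` is implemented
literally, but its output is far larger than the values the source table
prints (those violate the Cauchy–Schwarz bound ``sum(S_i^2) >= (sum S_i)^2/n``
implied by the same table's R column), so the published A column cannot come
from this formula.  :data:`PYKA_A_CAVEAT` travels with every result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .barysz import AtomDescriptors, BaryszMatrix, barysz_matrix, degrees
from .fixtures import INDEX_COLUMNS
from .structures import MolecularGraph

PYKA_A_CAVEAT = (
    "pyka_A implements the defining formula sum(S_i^2) literally; the "
    "published study's printed A values are inconsistent with that formula "
    "(they violate its Cauchy-Schwarz lower bound) and cannot be reproduced."
)


@dataclass
class IndexVector:
    """The eleven indices of one compound, published column order."""

    name: str
    M: float
    Mv: float
    chi0: float
    chi1: float
    chi0v: float
    chi1v: float
    W: float
    R: float
    A: float
    B0: float
    B1: float
    a_caveat: str = field(default=PYKA_A_CAVEAT, repr=False)

    def as_series(self) -> pd.Series:
        return pd.Series({c: getattr(self, c) for c in INDEX_COLUMNS}, name=self.name)


def gutman_M(desc: AtomDescriptors, valence: bool = False) -> float:
    """Sum of squared (valence) degrees."""
    d = desc.delta_v if valence else desc.delta
    return float(np.sum(d**2))


def randic_chi(g: MolecularGraph, desc: AtomDescriptors, m: int,
               valence: bool = False) -> float:
    """Connectivity index of order m (0: vertices, 1: edges).

    Each bond contributes one edge term regardless of its order; bond
    multiplicity enters only through the degrees themselves.
    """
    if m not in (0, 1):
        raise ValueError(f"order m must be 0 or 1, got {m}")
    d = desc.delta_v if valence else desc.delta
    if np.any(d <= 0):
        raise ValueError("zero degree encountered (isolated vertex?)")
    if m == 0:
        return float(np.sum(d**-0.5))
    return float(sum((d[b.i] * d[b.j]) ** -0.5 for b in g.bonds))


def wiener_W(dm: BaryszMatrix) -> float:
    """Trace plus strict upper triangle of the distance matrix."""
    return float(dm.trace + np.triu(dm.d, 1).sum())


def rouvray_R(dm: BaryszMatrix) -> float:
    """Sum of every matrix element (both triangles plus the diagonal)."""
    return float(dm.d.sum())


def pyka_A(dm: BaryszMatrix) -> float:
    """Literal sum of squared distance degrees; see PYKA_A_CAVEAT."""
    return float(np.sum(dm.s**2))


def pyka_B(dm: BaryszMatrix, g: MolecularGraph, order: int) -> float:
    """Distance-degree connectivity: order 0 over vertices, 1 over bonds."""
    if order not in (0, 1):
        raise ValueError(f"order must be 0 or 1, got {order}")
    s = dm.s
    if np.any(s <= 0):
        raise ValueError("non-positive distance degree (single-atom graph?)")
    if order == 0:
        return float(np.sum(s**-0.5))
    return float(sum((s[b.i] * s[b.j]) ** -0.5 for b in g.bonds))


def compute_all(g: MolecularGraph, kcc_dialect: str = "eq85",
                degree_dialect: str = "bond-order") -> IndexVector:
    """All eleven indices of one compound."""
    desc = degrees(g, dialect=degree_dialect)
    dm = barysz_matrix(g, kcc_dialect=kcc_dialect)
    return IndexVector(
        name=g.name,
        M=gutman_M(desc),
        Mv=gutman_M(desc, valence=True),
        chi0=randic_chi(g, desc, 0),
        chi1=randic_chi(g, desc, 1),
        chi0v=randic_chi(g, desc, 0, valence=True),
        chi1v=randic_chi(g, desc, 1, valence=True),
        W=wiener_W(dm),
        R=rouvray_R(dm),
        A=pyka_A(dm),
        B0=pyka_B(dm, g, 0),
        B1=pyka_B(dm, g, 1),
    )


def compute_table(graphs: list[MolecularGraph], **kwargs) -> pd.DataFrame:
    """Index table (compounds x eleven indices) in published column order."""
    rows = [compute_all(g, **kwargs).as_series() for g in graphs]
    return pd.DataFrame(rows)
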