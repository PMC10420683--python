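"""Embedded study data: compound structures, the published index table and
the published regression equations.

The ten study compounds -- three hypouricemic (blood uric acid-lowering)
agents and seven anti-androgens -- are stored as Kekulé SMILES in
``data/compounds.smi`` so the tautomer/nitro drawing conventions are
auditable (see docs/methods.md for how the drawings were selected).
"""

from __future__ import annotations

import importlib.resources
from functools import lru_cache

import pandas as pd

from .structures import MolecularGraph, parse_smiles

#: published-table column order for the eleven indices
INDEX_COLUMNS = ["M", "Mv", "chi0", "chi1", "chi0v", "chi1v", "W", "R", "A", "B0", "B1"]

HYPOURICEMIC = ("Allopurinol", "Oxypurinol", "Febuxostat")
ANTI_ANDROGENS = (
    "Abiraterone",
    "Bicalutamide",
    "Flutamide",
    "Nilutamide",
    "Leflunomide",
    "Teriflunomide",
    "Ailanthone",
)


def _data(name: str):
    return importlib.resources.files("topoindex").joinpath("data", name)


@lru_cache(maxsize=1)
def fixture_smiles() -> list[tuple[str, str, str]]:
    """(smiles, name, group) triples in published-table row order."""
    rows = []
    for line in _data("compounds.smi").read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smiles, name, group = line.split("\t")
        rows.append((smiles, name, group))
    return rows


def fixture_compounds() -> list[MolecularGraph]:
    """The ten study compounds, parsed fresh, in published-table row order."""
    return [parse_smiles(smiles, name) for smiles, name, _ in fixture_smiles()]


def compound_groups() -> dict[str, str]:
    """Compound name -> pharmacological group label."""
    return {name: group for _, name, group in fixture_smiles()}


def table1() -> pd.DataFrame:
    """The published table of eleven indices for the ten compounds.

    Indexed by compound name, with a ``group`` column followed by the eleven
    index columns in published order.  These are the printed values (used for
    the chemometric analyses, which the source carried out on this table),
    not the values this package computes.
    """
    df = pd.read_csv(_data("table1_indices.csv"))
    return df.set_index("compound")


def published_equations() -> pd.DataFrame:
    """The 82 published univariate linear equations (property = b + a*index).

    Columns: eq_no, group, property, index, intercept, slope, r.
    """
    return pd.read_csv(_data("published_equations.csv"))
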