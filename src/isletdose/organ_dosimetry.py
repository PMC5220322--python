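"""Organ-level S-values: pancreas <- kidneys and pancreas <- pancreas.

Reference anthropomorphic-phantom S-values for the two source-target
pairs of the model (adult male and female, In-111 and Ga-68) are
packaged as a CSV.  The packaged values are back-derived from published
whole-organ dose examples via S = D / (tau * A0), with the derivation
recorded per row in a provenance column; a user-supplied table in the
same format (e.g. genuine phantom Monte Carlo output) can be substituted
anywhere a table is accepted.

The kidneys-to-islet cross-dose reuses the kidneys-to-pancreas S-value:
at inter-organ distances only photons matter and they are absorbed
equally by islet and exocrine tissue, while kidney-emitted electrons do
not reach the pancreas.  That assumption is model structure (see
``dose_model``), not data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from io import StringIO

import pandas as pd

__all__ = [
    "OrganSValue",
    "derive_svalue_from_example",
    "load_svalue_table",
    "lookup_svalue",
]


@dataclass(frozen=True)
class OrganSValue:
    source: str
    target: str
    sex: str
    nuclide_id: str
    value_mgy_per_mbqh: float
    provenance: str

    def __post_init__(self) -> None:
        if self.value_mgy_per_mbqh <= 0:
            raise ValueError("S-value must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")


def derive_svalue_from_example(dose_mgy: float, tau_mbqh_per_mbq: float, a0_mbq: float) -> float:
    """Invert one dose example: S = D / (tau * A0), in mGy/(MBq.h)."""
    if dose_mgy <= 0 or tau_mbqh_per_mbq <= 0 or a0_mbq <= 0:
        raise ValueError("dose, tau and administered activity must all be positive")
    return dose_mgy / (tau_mbqh_per_mbq * a0_mbq)


def load_svalue_table(path=None) -> pd.DataFrame:
    """Load the packaged organ S-value table (or a user CSV of the same schema).

    Columns: source, target, sex, nuclide, value_mGy_per_MBqh, provenance.
    """
    if path is None:
        text = resources.files("isletdose.data").joinpath("organ_svalues.csv").read_text()
        df = pd.read_csv(StringIO(text))
    else:
        df = pd.read_csv(path)
    required = {"source", "target", "sex", "nuclide", "value_mGy_per_MBqh", "provenance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"organ S-value table missing columns {sorted(missing)}")
    keys = df[["source", "target", "sex", "nuclide"]]
    if keys.duplicated().any():
        raise ValueError("duplicate (source, target, sex, nuclide) rows in S-value table")
    if (df["value_mGy_per_MBqh"] <= 0).any():
        raise ValueError("organ S-values must be positive")
    return df


def lookup_svalue(
    source: str,
    target: str,
    sex: str,
    nuclide_id: str,
    table: pd.DataFrame | None = None,
) -> OrganSValue:
    """Look up one organ S-value; raises ``KeyError`` listing available tuples."""
    df = load_svalue_table() if table is None else table
    hit = df[
        (df["source"] == source)
        & (df["target"] == target)
        & (df["sex"] == sex)
        & (df["nuclide"] == nuclide_id)
    ]
    if hit.empty:
        available = [
            tuple(row)
            for row in df[["source", "target", "sex", "nuclide"]].itertuples(index=False)
        ]
        raise KeyError(
            f"no S-value for ({source}, {target}, {sex}, {nuclide_id}); "
            f"available tuples: {available}"
        )
    row = hit.iloc[0]
    return OrganSValue(
        source=row["source"],
        target=row["target"],
        sex=row["sex"],
        nuclide_id=row["nuclide"],
        value_mgy_per_mbqh=float(row["value_mGy_per_MBqh"]),
        provenance=str(row["provenance"]),
    )
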