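"""Tumor-evolution (traceability) analysis on paired normal/tumor cohorts.

Each patient contributes one adjacent-normal and one tumor sample; the
subtype of each member of the pair yields a 3x3 normal-to-tumor transition
table, from which conversion rates (e.g. the fraction of normal-EPC tissue
that becomes HPC or MPC in the tumor) and Sankey-diagram exports follow.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io import SampleTable
from .stats import SUBTYPE_ORDER, round_to_print

__all__ = [
    "PairedCohort",
    "build_pairs",
    "transition_table",
    "conversion_rate",
    "export_sankey",
    "read_sankey",
]


@dataclass
class PairedCohort:
    """Patient-matched (normal, tumor) sample pairs plus leftovers."""

    pairs: list  # list of (patient_id, normal_sample_id, tumor_sample_id)
    unpaired: list = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def build_pairs(meta: SampleTable) -> PairedCohort:
    """Pair samples by patient: exactly one normal + one tumor per patient.

    Patients with any other configuration (tumor only, two normals, ...) are
    reported unpaired; ambiguous patients additionally raise a warning.
    """
    df = meta.data
    for col in ("patient_id", "tissue"):
        if col not in df.columns:
            raise ValueError(f"metadata must contain a {col} column for pairing")
    pairs, unpaired = [], []
    for patient, grp in df.groupby("patient_id", sort=True):
        normals = grp.loc[grp["tissue"] == "normal", "sample_id"].tolist()
        tumors = grp.loc[grp["tissue"] == "tumor", "sample_id"].tolist()
        if len(normals) == 1 and len(tumors) == 1:
            pairs.append((patient, normals[0], tumors[0]))
        else:
            unpaired.extend(grp["sample_id"].tolist())
            if len(normals) > 1 or len(tumors) > 1:
                warnings.warn(
                    f"patient {patient!r} has {len(normals)} normal / "
                    f"{len(tumors)} tumor samples; excluded as ambiguous",
                    stacklevel=2,
                )
    return PairedCohort(pairs=pairs, unpaired=unpaired)


def transition_table(pairs: PairedCohort, assignments: pd.DataFrame) -> pd.DataFrame:
    """3x3 counts of normal-subtype (rows) to tumor-subtype (columns).

    Row/column order is fixed (EPC, HPC, MPC); the grand total equals the
    number of pairs.
    """
    subtype = assignments.set_index("sample_id")["subtype"]
    table = pd.DataFrame(0, index=list(SUBTYPE_ORDER), columns=list(SUBTYPE_ORDER))
    for patient, normal_id, tumor_id in pairs.pairs:
        for sid in (normal_id, tumor_id):
            if sid not in subtype.index:
                raise ValueError(
                    f"paired sample {sid!r} (patient {patient!r}) has no subtype assignment"
                )
        table.loc[subtype[normal_id], subtype[tumor_id]] += 1
    table.index.name = "normal"
    table.columns.name = "tumor"
    return table


def conversion_rate(table: pd.DataFrame, from_subtype: str, to_subtypes) -> float:
    """Percentage of ``from_subtype`` normal tissue converting into any of
    ``to_subtypes`` in the tumor, rounded to 1 dp (half-to-even)."""
    to_subtypes = set(to_subtypes)
    unknown = ({from_subtype} | to_subtypes) - set(SUBTYPE_ORDER)
    if unknown:
        raise ValueError(f"unknown subtypes: {sorted(unknown)}")
    row = table.loc[from_subtype]
    total = int(row.sum())
    if total == 0:
        raise ValueError(f"no pairs with normal subtype {from_subtype}")
    converted = int(row[list(to_subtypes)].sum())
    return round_to_print(100.0 * converted / total)


def export_sankey(table: pd.DataFrame, path) -> dict:
    """Write a renderer-agnostic Sankey JSON (nodes + nonzero links)."""
    nodes = [f"normal:{s}" for s in table.index] + [f"tumor:{s}" for s in table.columns]
    links = [
        {"source": f"normal:{i}", "target": f"tumor:{j}", "value": int(table.loc[i, j])}
        for i in table.index
        for j in table.columns
        if table.loc[i, j] > 0
    ]
    doc = {"nodes": nodes, "links": links, "total_pairs": int(table.to_numpy().sum())}
    Path(path).write_text(json.dumps(doc, indent=2))
    return doc


def read_sankey(path) -> pd.DataFrame:
    """Reconstruct the transition table from a Sankey JSON export."""
    doc = json.loads(Path(path).read_text())
    table = pd.DataFrame(0, index=list(SUBTYPE_ORDER), columns=list(SUBTYPE_ORDER))
    for link in doc["links"]:
        i = link["source"].split(":", 1)[1]
        j = link["target"].split(":", 1)[1]
        table.loc[i, j] = int(link["value"])
    table.index.name = "normal"
    table.columns.name = "tumor"
    return table
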