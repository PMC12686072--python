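"""The EMT marker panel: built-in default and user-supplied overrides.

The default panel is the classic epithelial/mesenchymal biomarker set used
for the typing: 22 epithelial genes (keratins, cadherin, claudins, ESRP
splicing factors, ovo-like TFs, ...) and 16 mesenchymal genes (ZEB/SNAI/TWIST
families, vimentin, TGF-beta ligands, collagens, ...). One published symbol,
"EARP1", matches no human gene; it is read as ESRP1 and the substitution is
recorded in run metadata whenever the default panel is used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .io import canonicalize_gene

__all__ = ["GenePanel", "default_panel", "load_panel"]

_EPITHELIAL = (
    "KRT18", "KRT19", "CDH1", "EPCAM", "F11R", "ESRP1", "ESRP2",
    "CLDN1", "CLDN4", "CLDN7", "S100A14", "PRSS8", "PRSS22", "ST14",
    "ZNF165", "C1ORF116", "KDF1", "CRB3", "ELF3", "HNF4A", "OVOL1", "OVOL2",
)
_MESENCHYMAL = (
    "ZEB1", "ZEB2", "SNAI1", "SNAI2", "TWIST1", "TWIST2", "VIM",
    "TGFB1", "TGFB2", "TGFB3", "FN1", "SPARC", "COL1A1", "COL1A2",
    "MMP2", "TCF4",
)


@dataclass(frozen=True)
class GenePanel:
    """Two disjoint, non-empty gene lists defining the EMT signature axes."""

    epithelial: tuple
    mesenchymal: tuple
    name: str = "custom"
    version: str = "0"
    notes: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        epi = tuple(canonicalize_gene(g) for g in self.epithelial)
        mes = tuple(canonicalize_gene(g) for g in self.mesenchymal)
        object.__setattr__(self, "epithelial", epi)
        object.__setattr__(self, "mesenchymal", mes)
        if not epi or not mes:
            raise ValueError("panel lists must be non-empty")
        if len(set(epi)) != len(epi) or len(set(mes)) != len(mes):
            raise ValueError("panel lists contain duplicate symbols")
        overlap = set(epi) & set(mes)
        if overlap:
            raise ValueError(f"genes in both panel lists: {sorted(overlap)}")

    @property
    def all_genes(self) -> tuple:
        return self.epithelial + self.mesenchymal


def default_panel() -> GenePanel:
    """The built-in 22-epithelial / 16-mesenchymal marker panel."""
    return GenePanel(
        epithelial=_EPITHELIAL,
        mesenchymal=_MESENCHYMAL,
        name="emt-default",
        version="1.0",
        notes={"symbol_substitutions": {"EARP1": "ESRP1"}},
    )


def load_panel(path) -> GenePanel:
    """Load a panel from JSON or YAML with keys 'epithelial', 'mesenchymal'."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "epithelial" not in raw or "mesenchymal" not in raw:
        raise ValueError(f"{path}: panel file must define 'epithelial' and 'mesenchymal'")
    return GenePanel(
        epithelial=tuple(raw["epithelial"]),
        mesenchymal=tuple(raw["mesenchymal"]),
        name=str(raw.get("name", path.stem)),
        version=str(raw.get("version", "0")),
    )
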