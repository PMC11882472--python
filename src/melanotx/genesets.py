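"""Gene-set registry: GMT parsing and the packaged melanoma panels.

Two collections ship with the package. ``panels_printed.gmt`` holds the
panels whose full membership is printed in the study this pipeline models
(the 10-gene MAPK transcriptional-output panel of Wagle et al., quiescence,
pro-apoptotic, ferroptosis, intrinsic-resistance and ABC-transporter panels,
and the differentiation marker panel). ``synthetic_reconstructions.gmt``
holds stand-in reconstructions of externally defined sets (PI3K/AKT/mTOR,
the 157-marker proliferation list, cyclebase-style cell-cycle phase markers
and the Tsoi differentiation-subtype signatures): these are synthetic,
plausible-membership placeholders meant to exercise the scoring machinery,
and users should override them with the published lists for real analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = ["GeneSet", "load_gmt", "load_gene_sets", "packaged_gene_sets"]


@dataclass(frozen=True)
class GeneSet:
    """A named gene panel with an optional category tag.

    Categories follow ``mapk_targets``, ``pi3k_akt``, ``proliferation``,
    ``quiescence``, ``cell_cycle_phase:<G1|S|G2|M>``, ``apoptosis``,
    ``ferroptosis``, ``resistance_panel``, ``abc_transporters``,
    ``marker_panel``, ``subtype:<name>`` or ``custom``.
    """

    name: str
    genes: tuple[str, ...]
    category: str = "custom"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        upper = tuple(g.strip().upper() for g in self.genes)
        if len(set(upper)) != len(upper):
            raise ValueError(f"gene set {self.name!r} has duplicate symbols")
        object.__setattr__(self, "genes", upper)
        if self.category.startswith("cell_cycle_phase:"):
            phase = self.category.split(":", 1)[1]
            if phase not in {"G1", "S", "G2", "M"}:
                raise ValueError(f"unknown cell-cycle phase {phase!r}")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def phase(self) -> str | None:
        if self.category.startswith("cell_cycle_phase:"):
            return self.category.split(":", 1)[1]
        return None

    @property
    def subtype(self) -> str | None:
        if self.category.startswith("subtype:"):
            return self.category.split(":", 1)[1]
        return None


def load_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Parse a GMT file (name, description, genes...; tab separated).

    The description field is used as the category tag when it matches a known
    category, otherwise the set is tagged ``custom``.
    """
    registry: dict[str, GeneSet] = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}: line {lineno}: GMT lines need >= 3 tab-separated fields"
            )
        name, desc = fields[0].strip(), fields[1].strip()
        genes = [g for g in fields[2:] if g.strip()]
        category = desc if desc else "custom"
        gs = GeneSet(name=name, genes=tuple(genes), category=category)
        if name in registry:
            raise ValueError(f"{path}: duplicate gene-set name {name!r}")
        registry[name] = gs
    return registry


def packaged_gene_sets(include_reconstructed: bool = True) -> dict[str, GeneSet]:
    """Registry of the packaged panels.

    ``include_reconstructed=False`` restricts the registry to panels whose
    membership is printed verbatim in the study.
    """
    files = ["panels_printed.gmt"]
    if include_reconstructed:
        files.append("synthetic_reconstructions.gmt")
    registry: dict[str, GeneSet] = {}
    for fname in files:
        ref = resources.files("melanotx.data").joinpath(fname)
        with resources.as_file(ref) as path:
            part = load_gmt(path)
        overlap = set(part) & set(registry)
        if overlap:
            raise ValueError(f"duplicate gene-set names across files: {sorted(overlap)}")
        registry.update(part)
    return registry


def load_gene_sets(
    paths: Iterable[str | Path] = (), packaged: bool = True
) -> dict[str, GeneSet]:
    """Merge user GMT files with (optionally) the packaged panels.

    Duplicate names across sources raise, so a user file cannot silently
    shadow a packaged panel.
    """
    registry: dict[str, GeneSet] = packaged_gene_sets() if packaged else {}
    for p in paths:
        part = load_gmt(p)
        overlap = set(part) & set(registry)
        if overlap:
            raise ValueError(f"duplicate gene-set names: {sorted(overlap)}")
        registry.update(part)
    return registry
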