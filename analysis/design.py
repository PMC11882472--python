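"""Shared study design for the analysis scripts.

One synthetic dataset emulates the five-arm melanoma treatment experiment:
MAPK output strongly suppressed by the degrader, less so by the two kinase
inhibitors and barely by the degradation-incompetent analogue; proliferation
down and quiescence/apoptosis/ferroptosis programs up under effective
treatment; an undifferentiated signature in untreated cells, a
neural-crest-like shift under the inhibitors and a melanocytic shift under
the degrader; plus eight validation genes planted at the fold changes later
read back by qPCR.
"""

from pathlib import Path

from melanotx.genesets import GeneSet, packaged_gene_sets
from melanotx.simulate import SimulationConfig

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "results" / "analysis" / "dataset"
OUT_DIR = ROOT / "results" / "analysis"

#: log2 fold changes of the eight qPCR validation genes (degrader arm)
VALIDATION_LFCS = {
    "VALGENE01": -3.0,
    "VALGENE02": -1.03,
    "VALGENE03": -1.07,
    "VALGENE04": 3.30,
    "VALGENE05": 2.87,
    "VALGENE06": 2.87,
    "VALGENE07": 1.28,
    "VALGENE08": 2.03,
}

QPCR_REFERENCE = "REFGENE01"


def registry():
    reg = packaged_gene_sets()
    for gene in list(VALIDATION_LFCS) + [QPCR_REFERENCE]:
        reg[f"SET_{gene}"] = GeneSet(f"SET_{gene}", (gene,))
    return reg


def study_config(seed: int = 1, n_genes: int = 2000) -> SimulationConfig:
    effects = [
        ("MAPK_TARGETS_WAGLE", "PROTAC", -2.5),
        ("MAPK_TARGETS_WAGLE", "VEMURAFENIB", -1.5),
        ("MAPK_TARGETS_WAGLE", "BI882370", -1.5),
        ("MAPK_TARGETS_WAGLE", "ME_PROTAC", -0.5),
        ("PROLIFERATION", "PROTAC", -1.8),
        ("PROLIFERATION", "VEMURAFENIB", -1.6),
        ("PROLIFERATION", "BI882370", -1.6),
        ("QUIESCENCE_G0", "PROTAC", 1.5),
        ("APOPTOSIS", "PROTAC", 0.8),
        ("APOPTOSIS", "VEMURAFENIB", 0.3),
        ("APOPTOSIS", "BI882370", 0.3),
        ("FERROPTOSIS", "PROTAC", 0.8),
        ("FERROPTOSIS", "VEMURAFENIB", 0.6),
        ("FERROPTOSIS", "BI882370", 0.6),
        ("TSOI_UNDIFFERENTIATED", "NEGATIVE", 1.5),
        ("TSOI_NEURAL_CREST_LIKE", "VEMURAFENIB", 1.5),
        ("TSOI_NEURAL_CREST_LIKE", "BI882370", 1.5),
        ("TSOI_MELANOCYTIC", "PROTAC", 1.2),
    ]
    effects += [(f"SET_{g}", "PROTAC", lfc) for g, lfc in VALIDATION_LFCS.items()]
    return SimulationConfig(
        seed=seed, n_genes=n_genes, planted_effects=tuple(effects)
    )
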