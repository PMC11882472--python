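"""End-to-end orchestration: counts (synthetic or supplied) -> preprocessing ->
differential expression -> pathway activity -> differentiation state -> qPCR.

A single :class:`PipelineConfig` (YAML/JSON round-trippable) drives every
stage with the study's default thresholds (low-count filter 10 in 80% of
samples; DEG at FDR < 0.05 and |log2FC| >= 1.5). Outputs are TSV tables per
stage plus a machine-readable ``summary.json``; runs are deterministic under
a fixed seed.
"""

from __future__ import annotations

import itertools
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import (
    cell_cycle_phase_profile,
    class_summary,
    combined_zscore_activity,
    compare_groups,
)
from .de import ContrastSpec, overlap_analysis, run_contrast
from .diffstate import marker_panel_report, mitf_axl_ratio, position_states, resistance_score
from .genesets import GeneSet, load_gene_sets
from .preprocess import (
    CountMatrix,
    estimate_size_factors,
    filter_low_expression,
    gene_zscores,
    read_counts,
    read_sample_sheet,
)
from .qpcr import concordance, delta_delta_ct, read_qpcr_table
from .simulate import SimulationConfig, generate_counts, generate_qpcr

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Either ``counts_path``/``samples_path`` point at real data or ``synth``
    holds a :class:`SimulationConfig` (as a mapping when serialized).
    """

    outdir: str = "results/pipeline"
    seed: int = 0
    counts_path: str | None = None
    samples_path: str | None = None
    synth: dict | None = None
    qpcr_path: str | None = None
    contrasts: list[list[str]] = field(default_factory=list)
    control_class: str = "NEGATIVE"
    alpha: float = 0.05
    lfc: float = 1.5
    min_count: int = 10
    sample_fraction: float = 0.8
    gene_set_paths: list[str] = field(default_factory=list)
    axes: list[str] = field(default_factory=lambda: ["neural_crest_like", "melanocytic_transitory"])
    zgamma_denominator: str = "sqrt"
    engine: str = "native"

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.lfc <= 0 or self.min_count <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")
        if self.counts_path is None and self.synth is None:
            raise ValueError("config needs counts_path or a synth block")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _load_counts(config: PipelineConfig) -> tuple[CountMatrix, pd.DataFrame | None]:
    """Returns (counts, truth-or-None)."""
    if config.synth is not None:
        sim = dict(config.synth)
        sim.setdefault("seed", config.seed)
        sim["classes"] = tuple(sim.get("classes", ()) or ())
        if not sim["classes"]:
            del sim["classes"]
        if "planted_effects" in sim:
            sim["planted_effects"] = tuple(
                (str(a), str(b), float(c)) for a, b, c in sim["planted_effects"]
            )
        dataset = generate_counts(SimulationConfig(**sim))
        return dataset.counts, dataset.truth
    counts = read_counts(config.counts_path)
    if config.samples_path is None:
        raise ValueError("real counts need a samples_path sample sheet")
    samples = read_sample_sheet(config.samples_path)
    return CountMatrix(counts, samples), None


def _round(obj, ndigits: int = 10):
    """Recursively round floats so summary JSON is byte-stable."""
    if isinstance(obj, float):
        if np.isnan(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, ndigits) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _round(float(obj), ndigits)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write tables + summary JSON under ``config.outdir``.

    Returns the summary dictionary. Any stage failure aborts with an error
    naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "thresholds": {
            "alpha": config.alpha,
            "lfc": config.lfc,
            "min_count": config.min_count,
            "sample_fraction": config.sample_fraction,
        },
        "engine": config.engine,
        "zgamma_denominator": config.zgamma_denominator,
    }
    registry = load_gene_sets(config.gene_set_paths, packaged=True)

    stage = "load_counts"
    try:
        counts, truth = _load_counts(config)
        summary["n_genes_input"] = int(counts.counts.shape[0])
        summary["n_samples"] = int(counts.counts.shape[1])
        summary["classes"] = sorted(counts.samples["class"].unique().tolist())

        stage = "preprocess"
        filtered = filter_low_expression(counts, config.min_count, config.sample_fraction)
        norm = estimate_size_factors(filtered)
        norm = gene_zscores(norm)
        summary["n_genes_filtered"] = int(filtered.counts.shape[0])
        norm.normalized.to_csv(outdir / "normalized.tsv", sep="\t")
        norm.zscores.to_csv(outdir / "zscores.tsv", sep="\t")
        norm.size_factors.to_csv(outdir / "size_factors.tsv", sep="\t")

        stage = "differential_expression"
        contrasts = [ContrastSpec(a, b) for a, b in config.contrasts]
        if not contrasts:
            others = [c for c in summary["classes"] if c != config.control_class]
            contrasts = [ContrastSpec(c, config.control_class) for c in others]
        deg_sets: dict[str, set[str]] = {}
        deg_counts: dict[str, dict[str, int]] = {}
        de_tables: dict[str, pd.DataFrame] = {}
        for spec in contrasts:
            table = run_contrast(
                filtered,
                spec,
                size_factors=norm.size_factors,
                alpha=config.alpha,
                lfc_threshold=config.lfc,
                engine=config.engine,
            )
            de_tables[str(spec)] = table
            table.to_csv(outdir / f"de_{spec}.tsv", sep="\t")
            up = set(table.index[table["call"] == "up"])
            down = set(table.index[table["call"] == "down"])
            deg_sets[str(spec)] = up | down
            deg_counts[str(spec)] = {
                "up": len(up), "down": len(down), "total": len(up) + len(down)
            }
        summary["deg_counts"] = deg_counts
        if len(deg_sets) >= 2:
            overlap = overlap_analysis(deg_sets)
            summary["overlap"] = {
                "region_counts": overlap["region_counts"],
                "shared_fraction": overlap["shared_fraction"],
                "jaccard": overlap["jaccard"],
            }
            (outdir / "overlap.json").write_text(
                json.dumps(_round(overlap), indent=2, sort_keys=True)
            )

        stage = "signature_activity"
        score_sets = [
            "MAPK_TARGETS_WAGLE", "PI3K_AKT_MTOR", "PROLIFERATION", "QUIESCENCE_G0",
            "APOPTOSIS", "FERROPTOSIS",
        ]
        activity_summary: dict[str, dict] = {}
        score_frames = []
        for name in score_sets:
            scores = combined_zscore_activity(
                norm, registry[name], denominator=config.zgamma_denominator
            )
            cs = class_summary(scores)
            activity_summary[name] = {
                "class_means": cs["mean"].to_dict(),
                "class_se": cs["se"].to_dict(),
            }
            comps = {}
            for cls in cs.index:
                if cls != config.control_class and config.control_class in cs.index:
                    comps[f"{cls}_vs_{config.control_class}"] = compare_groups(
                        scores, cls, config.control_class
                    )
            activity_summary[name]["comparisons"] = comps
            sf = scores.reset_index(names="sample_id")
            sf.insert(0, "set", name)
            score_frames.append(sf)
        pd.concat(score_frames).to_csv(outdir / "activity_scores.tsv", sep="\t", index=False)
        summary["activity"] = activity_summary

        phase_sets = {k: v for k, v in registry.items() if v.phase is not None}
        if phase_sets:
            pairs = [
                (c, config.control_class)
                for c in summary["classes"]
                if c != config.control_class
            ]
            phases = cell_cycle_phase_profile(norm, phase_sets, compare=pairs)
            phases["phase_means"].to_csv(outdir / "cell_cycle_phase_means.tsv", sep="\t")
            summary["cell_cycle"] = {
                k: {"difference": v["difference"], "p": v["p"]}
                for k, v in phases["comparisons"].items()
            }

        stage = "differentiation_state"
        subtype_sets = {k: v for k, v in registry.items() if v.subtype is not None}
        sub_scores = {
            gs.subtype: combined_zscore_activity(norm, gs) for gs in subtype_sets.values()
        }
        if {"melanocytic", "transitory"} <= set(sub_scores):
            mel = registry["TSOI_MELANOCYTIC"].genes
            tra = registry["TSOI_TRANSITORY"].genes
            union = GeneSet(
                name="MELANOCYTIC_TRANSITORY",
                genes=tuple(dict.fromkeys(mel + tra)),
                category="subtype:melanocytic_transitory",
            )
            sub_scores["melanocytic_transitory"] = combined_zscore_activity(norm, union)
        summary["subtype_scores"] = {
            k: class_summary(v)["mean"].to_dict() for k, v in sub_scores.items()
        }
        positions = position_states(sub_scores, config.axes[0], config.axes[1])
        positions.to_csv(outdir / "positions.tsv", sep="\t")
        summary["positions"] = positions["region"].to_dict()

        ratio = mitf_axl_ratio(norm)
        summary["mitf_axl"] = {
            "class_means": ratio["summary"]["mean"].to_dict(),
            "comparisons": {
                k: {"difference": v["difference"], "p": v["p"]}
                for k, v in ratio["comparisons"].items()
            },
        }
        res = resistance_score(norm, registry["INTRINSIC_RESISTANCE"])
        summary["resistance"] = {
            "class_means": res["summary"]["mean"].to_dict(),
            "comparisons": {
                k: {"difference": v["difference"], "p": v["p"]}
                for k, v in res["comparisons"].items()
            },
        }
        panel_report = marker_panel_report(norm, registry["DIFF_MARKER_PANEL"])
        panel_report["correlation"].to_csv(outdir / "marker_correlation.tsv", sep="\t")

        stage = "qpcr"
        if config.qpcr_path is not None:
            qtable = read_qpcr_table(config.qpcr_path)
            qres = delta_delta_ct(qtable)
            qres.to_csv(outdir / "qpcr_log2fc.tsv", sep="\t")
            first = de_tables[str(contrasts[0])]
            conc = concordance(qres["log2fc"], first["log2fc"].dropna())
            summary["qpcr_concordance"] = {k: conc[k] for k in ("r", "p", "n_genes")}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary_clean = _round(summary)
    (outdir / "summary.json").write_text(
        json.dumps(summary_clean, indent=2, sort_keys=True) + "\n"
    )
    (outdir / "run_log.txt").write_text(
        f"melanotx {__version__}\npython {sys.version.split()[0]}\n"
        f"seed {config.seed}\nalpha {config.alpha}\nlfc {config.lfc}\n"
        f"min_count {config.min_count}\nsample_fraction {config.sample_fraction}\n"
        f"engine {config.engine}\n"
    )
    return summary_clean
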