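"""Synthetic bulk RNA-seq counts with planted gene-set effects, plus matched qPCR tables.

The generator emulates the design of the study this pipeline models: one
melanoma cell line under five treatment classes (a BRAF-V600E degrader, its
degradation-incompetent methylated analogue, two kinase inhibitors and a
vehicle control) with a small number of biological replicates per class.
Counts are negative-binomial with a log-normal baseline-mean distribution, a
mean-dispersion trend alpha(mu) = a0 + a1/mu, log-normal per-sample size
factors, and per-gene-set log2 fold-change effects planted in chosen classes.
A companion qPCR simulator emits Ct tables whose expected 2^-ddCt recovers
the planted fold changes against an unperturbed reference gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genesets import GeneSet, packaged_gene_sets
from .preprocess import CountMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "default_classes",
    "build_gene_universe",
    "generate_counts",
    "generate_qpcr",
    "write_dataset",
]

#: treatment classes of the emulated design
DEFAULT_CLASSES = ("PROTAC", "ME_PROTAC", "VEMURAFENIB", "BI882370", "NEGATIVE")


def default_classes() -> tuple[str, ...]:
    return DEFAULT_CLASSES


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the count simulator.

    ``planted_effects`` is a list of (gene_set_name, class_label,
    log2_fold_change) triples; the named sets must exist in the gene-set
    registry the generator is given (packaged panels by default). Baseline
    per-gene means are log-normal: log mu ~ N(baseline_mean_log_mu,
    baseline_mean_log_sigma) on the natural-log scale. Per-gene dispersion
    follows alpha(mu) = dispersion_a0 + dispersion_a1 / mu. Size factors are
    log-normal(0, size_factor_log_sd) so normalization is exercised.
    """

    seed: int = 0
    n_genes: int = 2000
    classes: tuple[str, ...] = DEFAULT_CLASSES
    replicates_per_class: int = 3
    baseline_mean_log_mu: float = 5.0
    baseline_mean_log_sigma: float = 1.5
    dispersion_a0: float = 0.01
    dispersion_a1: float = 1.0
    size_factor_log_sd: float = 0.1
    planted_effects: tuple[tuple[str, str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.replicates_per_class < 2:
            raise ValueError("replicates_per_class must be >= 2")
        if self.dispersion_a0 <= 0 or self.dispersion_a1 < 0:
            raise ValueError("dispersion trend must be strictly positive")
        for _, label, _ in self.planted_effects:
            if label not in self.classes:
                raise ValueError(f"planted effect targets unknown class {label!r}")


@dataclass
class SyntheticDataset:
    """Counts plus the planted truth and (optionally) a qPCR table."""

    counts: CountMatrix
    truth: pd.DataFrame  # columns: gene, class, log2fc (0 for unplanted pairs)
    config: SimulationConfig
    gene_means: pd.Series  # baseline mu_g, internal ground truth
    qpcr: pd.DataFrame | None = None

    def planted_genes(self, class_label: str) -> pd.DataFrame:
        t = self.truth
        return t[(t["class"] == class_label) & (t["log2fc"] != 0)]

    def true_log2fc(self, gene: str, class_label: str) -> float:
        t = self.truth
        row = t[(t["gene"] == gene) & (t["class"] == class_label)]
        return float(row["log2fc"].iloc[0]) if len(row) else 0.0


def build_gene_universe(
    n_genes: int, registry: dict[str, GeneSet] | None = None
) -> list[str]:
    """Panel symbols first (so every packaged panel can be scored), then
    filler genes GENE0001... up to ``n_genes``."""
    if registry is None:
        registry = packaged_gene_sets()
    panel_genes: list[str] = []
    seen: set[str] = set()
    for gs in registry.values():
        for g in gs.genes:
            if g not in seen:
                seen.add(g)
                panel_genes.append(g)
    if n_genes < len(panel_genes):
        raise ValueError(
            f"n_genes={n_genes} smaller than the {len(panel_genes)} panel symbols"
        )
    fillers: list[str] = []
    i = 1
    while len(panel_genes) + len(fillers) < n_genes:
        name = f"GENE{i:04d}"
        if name not in seen:
            fillers.append(name)
        i += 1
    return panel_genes + fillers


def generate_counts(
    config: SimulationConfig, registry: dict[str, GeneSet] | None = None
) -> SyntheticDataset:
    """Draw a count matrix under the configured design.

    Counts for gene g in sample j of class c are NB with mean
    s_j * mu_g * 2^lfc(g, c) and dispersion alpha(mu_g); identical config and
    seed give bit-identical output.
    """
    if registry is None:
        registry = packaged_gene_sets()
    for set_name, _, _ in config.planted_effects:
        if set_name not in registry:
            raise ValueError(f"planted effect names unknown gene set {set_name!r}")

    genes = build_gene_universe(config.n_genes, registry)
    rng = np.random.default_rng(config.seed)

    log_mu = rng.normal(
        config.baseline_mean_log_mu, config.baseline_mean_log_sigma, size=config.n_genes
    )
    mu = np.exp(log_mu)
    alpha = config.dispersion_a0 + config.dispersion_a1 / mu

    gene_index = {g: i for i, g in enumerate(genes)}
    lfc = np.zeros((config.n_genes, len(config.classes)))
    class_index = {c: k for k, c in enumerate(config.classes)}
    for set_name, label, effect in config.planted_effects:
        rows = [gene_index[g] for g in registry[set_name].genes if g in gene_index]
        lfc[rows, class_index[label]] += effect

    n_samples = len(config.classes) * config.replicates_per_class
    size_factors = np.exp(rng.normal(0.0, config.size_factor_log_sd, size=n_samples))

    sample_ids, sample_class, sample_rep = [], [], []
    for c in config.classes:
        for r in range(1, config.replicates_per_class + 1):
            sample_ids.append(f"{c}_{r}")
            sample_class.append(c)
            sample_rep.append(r)

    counts = np.empty((config.n_genes, n_samples), dtype=np.int64)
    for j, (sid, c) in enumerate(zip(sample_ids, sample_class)):
        mean_j = size_factors[j] * mu * np.exp2(lfc[:, class_index[c]])
        # NB(mean m, dispersion a): n = 1/a successes, p = n / (n + m)
        n_param = 1.0 / alpha
        p_param = n_param / (n_param + mean_j)
        counts[:, j] = rng.negative_binomial(n_param, p_param)

    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)
    samples = pd.DataFrame(
        {"class": sample_class, "replicate": sample_rep},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = pd.DataFrame(
        {
            "gene": np.repeat(genes, len(config.classes)),
            "class": np.tile(list(config.classes), config.n_genes),
            "log2fc": lfc.ravel(),
        }
    )
    return SyntheticDataset(
        counts=CountMatrix(counts_df, samples),
        truth=truth,
        config=config,
        gene_means=pd.Series(mu, index=genes, name="baseline_mean"),
    )


def generate_qpcr(
    dataset: SyntheticDataset,
    target_genes: list[str],
    reference_gene: str,
    noise_sd: float,
    treated_class: str,
    control_class: str,
    n_replicates: int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a comparative-Ct qPCR table for the planted effects.

    Ct values are built so the expected ddCt of a target equals minus its
    planted log2 fold change (treated vs control), with independent Gaussian
    noise of sd ``noise_sd`` on every Ct measurement. The reference gene must
    be unperturbed in both classes (the internal-control assumption).
    """
    genes = set(dataset.counts.genes)
    for g in list(target_genes) + [reference_gene]:
        if g.upper() not in genes:
            raise ValueError(f"gene {g!r} absent from the count matrix")
    reference_gene = reference_gene.upper()
    for cls in (treated_class, control_class):
        if dataset.true_log2fc(reference_gene, cls) != 0.0:
            raise ValueError(
                f"reference gene {reference_gene} carries a planted effect in "
                f"{cls}; it cannot serve as internal control"
            )
    rng = np.random.default_rng(dataset.config.seed + 10_007 if seed is None else seed)

    ct_ref_base = 20.0
    rows = []
    for gene in target_genes:
        gene = gene.upper()
        mu = float(dataset.gene_means.get(gene, 100.0))
        ct_base = max(30.0 - np.log2(mu + 1.0), 5.0)
        lfc = dataset.true_log2fc(gene, treated_class) - dataset.true_log2fc(
            gene, control_class
        )
        for group, cls, shift in (
            ("treated", treated_class, -lfc),
            ("control", control_class, 0.0),
        ):
            for r in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{cls}_qpcr_{r}",
                        "group": group,
                        "gene": gene,
                        "ct_target": ct_base + shift + rng.normal(0.0, noise_sd),
                        "ct_reference": ct_ref_base + rng.normal(0.0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write counts TSV, sample sheet CSV, truth TSV and (if present) qPCR CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.csv",
        "truth": outdir / "truth.tsv",
    }
    dataset.counts.counts.to_csv(paths["counts"], sep="\t")
    dataset.counts.samples.to_csv(paths["samples"])
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False)
    if dataset.qpcr is not None:
        paths["qpcr"] = outdir / "qpcr.csv"
        dataset.qpcr.to_csv(paths["qpcr"], index=False)
    return paths
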