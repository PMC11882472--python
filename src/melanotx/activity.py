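"""Combined z-score gene-set activity and companion statistics.

The central statistic is the combined z-score: for a gene set with n member
genes present in the matrix, a sample's activity is

    Z_gamma = (sum_i z_i) / sqrt(n)

where z_i is the gene's expression z-score in that sample. Under independent
standard-normal gene z-scores the statistic is itself standard normal, which
is why the denominator uses the number of genes actually found (dropout
keeps the null variance at 1). A configuration switch substitutes the plain
mean (sum/n) for sensitivity analyses. Group comparisons use Welch's
two-sided t-test on replicate scores; the test identity is recorded in the
returned metadata because the study never names its test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .de import bh_adjust
from .genesets import GeneSet
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "combined_zscore_activity",
    "class_summary",
    "compare_groups",
    "pearson_correlation",
    "pca_explained_variance",
    "ora_enrichment",
    "cell_cycle_phase_profile",
]


def combined_zscore_activity(
    z: NormalizedMatrix, gene_set: GeneSet, denominator: str = "sqrt"
) -> pd.DataFrame:
    """Per-sample combined z-score for one gene set.

    Returns a DataFrame indexed by sample with columns ``score``, ``n_used``
    and ``class``. Set genes missing from the matrix are dropped with a
    warning and reflected in ``n_used``.
    """
    if z.zscores is None:
        raise ValueError("z-scores not computed; run gene_zscores first")
    present = [g for g in gene_set.genes if g in z.zscores.index]
    missing = sorted(set(gene_set.genes) - set(present))
    if not present:
        raise ValueError(f"no genes of set {gene_set.name!r} present in the matrix")
    if missing:
        logger.warning(
            "set %s: %d/%d genes absent (%s)",
            gene_set.name, len(missing), len(gene_set), ", ".join(missing[:5]),
        )
    n = len(present)
    sums = z.zscores.loc[present].sum(axis=0)
    if denominator == "sqrt":
        score = sums / np.sqrt(n)
    elif denominator == "n":
        score = sums / n
    else:
        raise ValueError("denominator must be 'sqrt' or 'n'")
    return pd.DataFrame(
        {"score": score, "n_used": n, "class": z.classes().loc[score.index]}
    )


def class_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of the per-sample scores within each class."""
    g = scores.groupby("class")["score"]
    return pd.DataFrame(
        {"mean": g.mean(), "se": g.sem(ddof=1), "n": g.size()}
    )


def compare_groups(
    scores: pd.DataFrame, class_a: str, class_b: str
) -> dict:
    """Welch t comparison of per-replicate scores between two classes.

    Returns mean_a - mean_b with the two-sided Welch p-value; the test name
    travels in the result for report transparency.
    """
    a = scores.loc[scores["class"] == class_a, "score"].to_numpy()
    b = scores.loc[scores["class"] == class_b, "score"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Welch comparison needs >= 2 replicates per class")
    if np.allclose(a, b) and len(a) == len(b):
        p = 1.0  # identical replicate vectors: no evidence of a difference
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return {
        "class_a": class_a,
        "class_b": class_b,
        "difference": float(a.mean() - b.mean()),
        "p": p,
        "test": "welch_t_two_sided",
    }


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r with its two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with >= 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance in an input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def pca_explained_variance(
    z: NormalizedMatrix, gene_set: GeneSet
) -> dict:
    """PCA of samples in the space of one gene set's z-scores.

    Centers the samples x genes submatrix and returns per-component variance
    fractions (summing to 1), the PC1+PC2 fraction, and PC1/PC2 sample
    projections.
    """
    if z.zscores is None:
        raise ValueError("z-scores not computed")
    present = [g for g in gene_set.genes if g in z.zscores.index]
    if not present:
        raise ValueError(f"no genes of set {gene_set.name!r} present")
    X = z.zscores.loc[present].T.to_numpy()  # samples x genes
    if X.shape[0] < 2:
        raise ValueError("PCA needs >= 2 samples")
    n_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp)
    proj = pca.fit_transform(X - X.mean(axis=0))
    frac = pca.explained_variance_ratio_
    frac = frac / frac.sum()  # guard fp drift; components span total variance
    projections = pd.DataFrame(
        proj[:, : min(2, n_comp)],
        index=z.zscores.columns,
        columns=[f"PC{i+1}" for i in range(min(2, n_comp))],
    )
    return {
        "variance_fractions": frac,
        "pc1_pc2_fraction": float(frac[: min(2, n_comp)].sum()),
        "projections": projections,
    }


def ora_enrichment(
    query: set[str], registry: dict[str, GeneSet], universe: set[str]
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per registry set.

    The population is the universe, successes are the set's genes within the
    universe, draws are the query; the p-value is the upper tail
    P(X >= observed overlap), BH-adjusted across sets.
    """
    universe = {g.upper() for g in universe}
    query = {g.upper() for g in query}
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N, n_draw = len(universe), len(query)
    rows = []
    for name, gs in registry.items():
        members = set(gs.genes) & universe
        k = len(query & members)
        # P(X >= k) for X ~ Hypergeom(N, |members|, n_draw)
        p = float(stats.hypergeom.sf(k - 1, N, len(members), n_draw)) if members else 1.0
        rows.append({"set": name, "set_in_universe": len(members), "overlap": k, "p": p})
    table = pd.DataFrame(rows).set_index("set")
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    return table.sort_values("p")


def cell_cycle_phase_profile(
    z: NormalizedMatrix,
    phase_sets: dict[str, GeneSet],
    compare: list[tuple[str, str]] | None = None,
) -> dict:
    """Mean marker z-score per cell-cycle phase per sample, with optional
    per-phase Welch comparisons between classes.

    Phases with no marker genes present are skipped with a warning.
    """
    if z.zscores is None:
        raise ValueError("z-scores not computed")
    per_phase = {}
    for name, gs in phase_sets.items():
        phase = gs.phase or name
        present = [g for g in gs.genes if g in z.zscores.index]
        if not present:
            logger.warning("phase %s: no marker genes present; skipped", phase)
            continue
        per_phase[phase] = z.zscores.loc[present].mean(axis=0)
    if not per_phase:
        raise ValueError("no phase markers present in the matrix")
    means = pd.DataFrame(per_phase)
    means["class"] = z.classes().loc[means.index]
    comparisons = {}
    for a, b in compare or []:
        for phase in [c for c in means.columns if c != "class"]:
            sc = means[[phase, "class"]].rename(columns={phase: "score"})
            comparisons[f"{phase}:{a}_vs_{b}"] = compare_groups(sc, a, b)
    return {"phase_means": means, "comparisons": comparisons}
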