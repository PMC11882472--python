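"""Negative-binomial Wald differential expression and DEG set algebra.

Per contrast (numerator class vs denominator class) the stage mirrors the
standard bulk RNA-seq workflow: median-of-ratios size factors, per-gene
method-of-moments dispersion estimates shrunk toward a fitted mean-dispersion
trend alpha(mu) = a0 + a1/mu, a per-gene NB GLM with log link and log
size-factor offsets, a two-sided Wald test on the class coefficient, and
Benjamini-Hochberg adjustment. No fold-change shrinkage is applied: DEG
calls act on the plain maximum-likelihood log2 fold change, with the study's
thresholds FDR < 0.05 and |log2FC| >= 1.5. An optional engine delegates the
per-contrast fit to pyDESeq2 for accession-level reproduction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .preprocess import CountMatrix, estimate_size_factors

__all__ = [
    "ContrastSpec",
    "bh_adjust",
    "fit_nb_dispersion",
    "wald_de_test",
    "run_contrast",
    "call_degs",
    "overlap_analysis",
]

LN2 = float(np.log(2.0))
MIN_DISPERSION = 1e-8

#: DEG thresholds of the study design
DEFAULT_ALPHA = 0.05
DEFAULT_LFC = 1.5


@dataclass(frozen=True)
class ContrastSpec:
    """Two-class contrast: log2 fold changes are numerator over denominator."""

    numerator: str
    denominator: str

    def __str__(self) -> str:  # used in file names / report keys
        return f"{self.numerator}_vs_{self.denominator}"


def bh_adjust(p: np.ndarray | list[float] | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are preserved and excluded from the number of tests m.
    Monotonicity is enforced by a cumulative minimum from the largest p.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def _check_contrast(m: CountMatrix, design: ContrastSpec) -> tuple[list[str], list[str]]:
    num = m.samples_in_class(design.numerator)
    den = m.samples_in_class(design.denominator)
    for label, group in ((design.numerator, num), (design.denominator, den)):
        if len(group) == 0:
            raise ValueError(f"class {label!r} absent from the sample sheet")
        if len(group) < 2:
            raise ValueError(
                f"class {label!r} has a single replicate; no within-group variance"
            )
    return num, den


def fit_nb_dispersion(
    m: CountMatrix,
    design: ContrastSpec,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene NB dispersions for a two-class contrast.

    Gene-wise estimates come from the method of moments on size-factor
    normalized counts, pooling within-class variances:
    alpha_raw = (v - xi * mu) / mu^2 with xi = mean(1/s_j), the Poisson
    sampling correction. A trend alpha(mu) = a0 + a1/mu is fitted across
    genes by non-negative least squares, and gene-wise estimates are shrunk
    toward it by precision-weighted averaging in log space. Genes with no
    usable gene-wise estimate (zero or negative raw moment) take the trend
    value at their mean.

    Returns a DataFrame with columns ``mean``, ``alpha_raw``, ``alpha_trend``,
    ``alpha`` indexed by gene.
    """
    num, den = _check_contrast(m, design)
    cols = num + den
    sub = m.counts[cols]
    if size_factors is None:
        size_factors = estimate_size_factors(m).size_factors
    s = size_factors.loc[cols].to_numpy()
    q = sub.to_numpy(dtype=float) / s

    groups = [np.arange(len(num)), np.arange(len(num), len(cols))]
    n_tot = len(cols)
    xi = float(np.mean(1.0 / s))

    # pooled within-class variance and balanced mean
    ss = np.zeros(q.shape[0])
    df = 0
    class_means = []
    for idx in groups:
        block = q[:, idx]
        mu_c = block.mean(axis=1)
        class_means.append(mu_c)
        ss += ((block - mu_c[:, None]) ** 2).sum(axis=1)
        df += len(idx) - 1
    v = ss / df
    mu = np.mean(class_means, axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = np.where(mu > 0, (v - xi * mu) / np.maximum(mu, 1e-12) ** 2, np.nan)

    fit_mask = np.isfinite(alpha_raw) & (mu > 0)
    if fit_mask.sum() >= 10:
        X = np.column_stack([np.ones(fit_mask.sum()), 1.0 / mu[fit_mask]])
        coef, _ = optimize.nnls(X, np.clip(alpha_raw[fit_mask], 0.0, None))
        a0, a1 = coef
    else:  # tiny matrices: flat fallback at the positive median
        pos = alpha_raw[fit_mask & (alpha_raw > 0)]
        a0, a1 = (float(np.median(pos)) if pos.size else MIN_DISPERSION), 0.0
    alpha_trend = np.maximum(a0 + a1 / np.maximum(mu, 1e-12), MIN_DISPERSION)

    # precision weights: gene-wise ~ half the residual d.o.f., trend a fixed prior
    w_gene = max((n_tot - 2) / 2.0, 0.5)
    w_trend = 2.0
    usable = np.isfinite(alpha_raw) & (alpha_raw > 0)
    log_alpha = np.log(alpha_trend)
    log_alpha[usable] = (
        w_gene * np.log(alpha_raw[usable]) + w_trend * np.log(alpha_trend[usable])
    ) / (w_gene + w_trend)
    alpha = np.maximum(np.exp(log_alpha), MIN_DISPERSION)

    return pd.DataFrame(
        {"mean": mu, "alpha_raw": alpha_raw, "alpha_trend": alpha_trend, "alpha": alpha},
        index=sub.index,
    )


def _fit_gene_glm(
    y: np.ndarray, x: np.ndarray, offset: np.ndarray, alpha: float
) -> tuple[float, float] | None:
    """NB GLM log-link fit of one gene; returns (coef, se) in natural log."""
    X = np.column_stack([np.ones_like(x), x])
    fam = sm.families.NegativeBinomial(alpha=max(alpha, MIN_DISPERSION))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=100, tol=1e-8)
        coef = float(res.params[1])
        se = float(res.bse[1])
        if not (np.isfinite(coef) and np.isfinite(se)):
            return None
        return coef, se
    except Exception:
        return None


def wald_de_test(
    m: CountMatrix,
    design: ContrastSpec,
    dispersions: pd.DataFrame | pd.Series,
    size_factors: pd.Series | None = None,
    alpha: float = DEFAULT_ALPHA,
    lfc_threshold: float = DEFAULT_LFC,
) -> pd.DataFrame:
    """Per-gene NB Wald test for one contrast.

    Returns a DataFrame indexed by gene with columns ``base_mean``,
    ``log2fc`` (MLE, numerator vs denominator), ``se``, ``p``, ``fdr`` and
    ``call`` in {up, down, ns}. Genes with all-zero counts in both classes
    get p = NaN and are excluded from the BH m.
    """
    num, den = _check_contrast(m, design)
    cols = num + den
    sub = m.counts[cols]
    if size_factors is None:
        size_factors = estimate_size_factors(m).size_factors
    s = size_factors.loc[cols].to_numpy()
    offset = np.log(s)
    x = np.array([1.0] * len(num) + [0.0] * len(den))

    disp = dispersions["alpha"] if isinstance(dispersions, pd.DataFrame) else dispersions
    disp = disp.reindex(sub.index)

    q = sub.to_numpy(dtype=float) / s
    base_mean = q.mean(axis=1)

    n_genes = sub.shape[0]
    log2fc = np.full(n_genes, np.nan)
    se_arr = np.full(n_genes, np.nan)
    pvals = np.full(n_genes, np.nan)
    counts_arr = sub.to_numpy()

    for i in range(n_genes):
        y = counts_arr[i]
        if y.sum() == 0:
            continue  # all-zero in both classes: untestable
        fit = _fit_gene_glm(y, x, offset, float(disp.iloc[i]))
        if fit is None:
            # moment fallback (one class all-zero or IRLS failure)
            mu_n = q[i, : len(num)].mean() + 0.5
            mu_d = q[i, len(num):].mean() + 0.5
            log2fc[i] = np.log2(mu_n / mu_d)
            continue
        coef, se = fit
        log2fc[i] = coef / LN2
        se_arr[i] = se / LN2
        if se > 0:
            z = coef / se
            pvals[i] = 2.0 * stats.norm.sf(abs(z))

    fdr = bh_adjust(pvals)
    result = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se_arr,
            "p": pvals,
            "fdr": fdr,
        },
        index=sub.index,
    )
    result["call"] = call_degs(result, alpha=alpha, lfc_threshold=lfc_threshold)
    return result


def call_degs(
    table: pd.DataFrame, alpha: float = DEFAULT_ALPHA, lfc_threshold: float = DEFAULT_LFC
) -> pd.Series:
    """DEG labels: up iff fdr < alpha and log2fc >= lfc_threshold, down iff
    fdr < alpha and log2fc <= -lfc_threshold, else ns. Thresholds inclusive
    on |log2FC|, strict on FDR."""
    sig = table["fdr"] < alpha
    call = pd.Series("ns", index=table.index)
    call[sig & (table["log2fc"] >= lfc_threshold)] = "up"
    call[sig & (table["log2fc"] <= -lfc_threshold)] = "down"
    return call


def run_contrast(
    m: CountMatrix,
    design: ContrastSpec,
    size_factors: pd.Series | None = None,
    alpha: float = DEFAULT_ALPHA,
    lfc_threshold: float = DEFAULT_LFC,
    engine: str = "native",
) -> pd.DataFrame:
    """Dispersion fit + Wald test for one contrast.

    ``engine="pydeseq2"`` delegates the whole stage to pyDESeq2 (same output
    columns), intended for reproducing accession-level results with the
    reference tool; the native engine is the package's own implementation.
    """
    if engine == "pydeseq2":
        return _run_pydeseq2(m, design, alpha=alpha, lfc_threshold=lfc_threshold)
    if engine != "native":
        raise ValueError(f"unknown DE engine {engine!r}")
    disp = fit_nb_dispersion(m, design, size_factors=size_factors)
    return wald_de_test(
        m, design, disp, size_factors=size_factors, alpha=alpha, lfc_threshold=lfc_threshold
    )


def _run_pydeseq2(
    m: CountMatrix, design: ContrastSpec, alpha: float, lfc_threshold: float
) -> pd.DataFrame:
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    sub = m.subset_classes([design.numerator, design.denominator])
    meta = sub.samples.rename(columns={"class": "condition"})[["condition"]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dds = DeseqDataSet(
            counts=sub.counts.T, metadata=meta, design="~condition", quiet=True
        )
        dds.deseq2()
        ds = DeseqStats(
            dds,
            contrast=["condition", design.numerator, design.denominator],
            quiet=True,
        )
        ds.summary()
    res = ds.results_df
    out = pd.DataFrame(
        {
            "base_mean": res["baseMean"],
            "log2fc": res["log2FoldChange"],
            "se": res["lfcSE"],
            "p": res["pvalue"],
            "fdr": res["padj"],
        }
    )
    out.index = sub.counts.index
    out["call"] = call_degs(out, alpha=alpha, lfc_threshold=lfc_threshold)
    return out


def overlap_analysis(deg_sets: dict[str, set[str]]) -> dict:
    """Venn partition of named DEG sets.

    Returns region cardinalities for every non-empty membership pattern,
    pairwise Jaccard indices, the genes unique to each set, and each set's
    shared fraction (members found in at least one other set).
    """
    if len(deg_sets) < 2:
        raise ValueError("overlap analysis needs at least two named sets")
    names = list(deg_sets)
    sets = {k: set(v) for k, v in deg_sets.items()}
    universe = set().union(*sets.values())

    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo)) if combo else set()
            outside = set().union(*(sets[n] for n in names if n not in combo), set())
            regions["&".join(combo)] = len(inside - outside)

    jaccard = {}
    for a, b in itertools.combinations(names, 2):
        union = sets[a] | sets[b]
        jaccard[f"{a}|{b}"] = len(sets[a] & sets[b]) / len(union) if union else np.nan

    unique = {n: sorted(sets[n] - set().union(*(sets[k] for k in names if k != n)))
              for n in names}
    shared_fraction = {}
    for n in names:
        others = set().union(*(sets[k] for k in names if k != n))
        shared_fraction[n] = len(sets[n] & others) / len(sets[n]) if sets[n] else np.nan

    return {
        "region_counts": regions,
        "jaccard": jaccard,
        "unique": unique,
        "shared_fraction": shared_fraction,
        "set_sizes": {n: len(sets[n]) for n in names},
        "universe_size": len(universe),
    }
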