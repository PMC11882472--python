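"""Count-matrix containers, low-count filtering, RLE normalization and per-gene z-scores.

The pipeline operates on bulk RNA-seq counts of cells under several treatment
classes (degrader, degradation-incompetent analogue, two kinase inhibitors,
vehicle control). Normalization uses the relative-log-expression /
median-of-ratios method: each sample's size factor is the median, over
reference genes, of the ratio of its count to the gene's geometric mean.
Per-gene z-scores are computed across all samples on the normalized values and
feed the combined z-score activity statistic downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "read_counts",
    "read_sample_sheet",
    "filter_low_expression",
    "estimate_size_factors",
    "gene_zscores",
]


@dataclass
class CountMatrix:
    """Gene x sample non-negative integer counts with per-sample annotation.

    Parameters
    ----------
    counts
        DataFrame indexed by unique gene symbols, columns are sample ids.
    samples
        DataFrame indexed by sample id with columns ``class`` (treatment
        class label) and ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.counts.index = pd.Index(
            [str(g).strip().upper() for g in self.counts.index], name="gene"
        )
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups[:5]}")
        if "class" not in self.samples.columns:
            raise ValueError("sample sheet must carry a 'class' column")
        missing = [s for s in self.counts.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"samples without annotation: {missing}")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integral")
        self.counts = self.counts.astype(np.int64)
        # keep annotation aligned and restricted to present samples
        self.samples = self.samples.loc[self.counts.columns]
        self.samples.index.name = "sample_id"

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def classes(self) -> pd.Series:
        """Sample id -> treatment class label."""
        return self.samples["class"]

    def samples_in_class(self, label: str) -> list[str]:
        return list(self.samples.index[self.samples["class"] == label])

    def subset_classes(self, labels: list[str]) -> "CountMatrix":
        keep = [s for s in self.counts.columns if self.samples.loc[s, "class"] in labels]
        if not keep:
            raise ValueError(f"no samples in classes {labels}")
        return CountMatrix(self.counts[keep], self.samples.loc[keep])


@dataclass
class NormalizedMatrix:
    """Size-factor-normalized counts and (optionally) per-gene z-scores."""

    size_factors: pd.Series
    normalized: pd.DataFrame
    samples: pd.DataFrame
    zscores: pd.DataFrame | None = field(default=None)

    def classes(self) -> pd.Series:
        return self.samples["class"]

    def samples_in_class(self, label: str) -> list[str]:
        return list(self.samples.index[self.samples["class"] == label])


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a count table (genes in the first column), sniffing TSV vs CSV."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else None
    df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
    df.index = pd.Index([str(g).strip().upper() for g in df.index], name="gene")
    return df


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet CSV with columns sample_id, class, replicate."""
    df = pd.read_csv(path)
    if "sample_id" in df.columns:
        return df.set_index("sample_id")
    first = df.columns[0]
    if first.startswith("Unnamed") or first == "":
        df = df.rename(columns={first: "sample_id"})
        return df.set_index("sample_id")
    raise ValueError("sample sheet requires a 'sample_id' column")


def filter_low_expression(
    m: CountMatrix, min_count: int = 10, sample_fraction: float = 0.8
) -> CountMatrix:
    """Drop genes whose count falls below ``min_count`` in at least
    ``sample_fraction`` of samples.

    The boundary is inclusive: a gene below threshold in exactly 80% of
    samples is removed under the defaults.
    """
    if not 0 < sample_fraction <= 1:
        raise ValueError("sample_fraction must be in (0, 1]")
    below = (m.counts < min_count).mean(axis=1)
    keep = below < sample_fraction
    if not keep.any():
        raise ValueError(
            f"no genes survive filtering at min_count={min_count}, "
            f"sample_fraction={sample_fraction}"
        )
    return CountMatrix(m.counts.loc[keep], m.samples)


def estimate_size_factors(
    m: CountMatrix, pseudo_reference: bool = False
) -> NormalizedMatrix:
    """Median-of-ratios size factors and normalized counts.

    The reference set is the genes with strictly positive counts in every
    sample; for each sample the size factor is the median over reference genes
    of count / per-gene geometric mean. ``pseudo_reference=True`` falls back to
    geometric means over positive entries only, for matrices where no gene is
    positive everywhere.
    """
    counts = m.counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if all_positive.any():
        ref = counts[all_positive]
        log_geomean = np.log(ref).mean(axis=1)
        log_ratios = np.log(ref) - log_geomean[:, None]
    elif pseudo_reference:
        with np.errstate(divide="ignore"):
            logc = np.where(counts > 0, np.log(counts), np.nan)
        log_geomean = np.nanmean(logc, axis=1)
        log_ratios = logc - log_geomean[:, None]
        if np.all(np.isnan(log_ratios)):
            raise ValueError("no usable genes for pseudo-reference size factors")
    else:
        raise ValueError(
            "no gene has strictly positive counts in all samples; "
            "re-run with pseudo_reference=True to use a positive-entry fallback"
        )
    s = np.exp(np.nanmedian(log_ratios, axis=0))
    size_factors = pd.Series(s, index=m.counts.columns, name="size_factor")
    normalized = m.counts.div(size_factors, axis=1)
    return NormalizedMatrix(size_factors=size_factors, normalized=normalized, samples=m.samples)


def gene_zscores(m: NormalizedMatrix, within_class: bool = False) -> NormalizedMatrix:
    """Standardize each gene across samples: z = (x - mean) / sd, sd with the
    n-1 denominator. Zero-variance genes get z = 0 (logged). ``within_class``
    standardizes inside each treatment class instead of jointly."""
    x = m.normalized
    if x.shape[1] < 2:
        raise ValueError("z-scores need at least 2 samples")

    def _z(block: pd.DataFrame) -> pd.DataFrame:
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        flat = sd == 0
        if flat.any():
            logger.warning("%d zero-variance genes set to z = 0", int(flat.sum()))
        sd = sd.replace(0, np.nan)
        z = block.sub(mu, axis=0).div(sd, axis=0)
        return z.fillna(0.0)

    if within_class:
        parts = []
        for label in m.samples["class"].unique():
            cols = m.samples_in_class(label)
            parts.append(_z(x[cols]))
        z = pd.concat(parts, axis=1)[x.columns]
    else:
        z = _z(x)
    return NormalizedMatrix(
        size_factors=m.size_factors, normalized=m.normalized, samples=m.samples, zscores=z
    )
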