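"""Filter low-count genes, normalize by median-of-ratios and z-score per gene.

Reads the dataset written by 01_simulate_dataset.py; writes normalized.tsv,
zscores.tsv and size_factors.tsv under results/analysis/.
"""

from design import DATA_DIR, OUT_DIR
from melanotx.preprocess import (
    CountMatrix,
    estimate_size_factors,
    filter_low_expression,
    gene_zscores,
    read_counts,
    read_sample_sheet,
)


def load_dataset() -> CountMatrix:
    counts = DATA_DIR / "counts.tsv"
    if not counts.exists():
        raise SystemExit("dataset missing; run 01_simulate_dataset.py first")
    return CountMatrix(read_counts(counts), read_sample_sheet(DATA_DIR / "samples.csv"))


def preprocess(m: CountMatrix):
    filtered = filter_low_expression(m, min_count=10, sample_fraction=0.8)
    norm = gene_zscores(estimate_size_factors(filtered))
    return filtered, norm


def main() -> None:
    m = load_dataset()
    filtered, norm = preprocess(m)
    print(f"low-count filter (<10 in 80% of samples): "
          f"{m.counts.shape[0]} -> {filtered.counts.shape[0]} genes")
    sf = norm.size_factors
    print(f"size factors: min {sf.min():.3f}, max {sf.max():.3f} "
          f"(geometric spread exercises the normalization)")
    norm.normalized.to_csv(OUT_DIR / "normalized.tsv", sep="\t")
    norm.zscores.to_csv(OUT_DIR / "zscores.tsv", sep="\t")
    sf.to_csv(OUT_DIR / "size_factors.tsv", sep="\t")
    print(f"wrote normalized/zscore matrices under {OUT_DIR}")


if __name__ == "__main__":
    main()
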