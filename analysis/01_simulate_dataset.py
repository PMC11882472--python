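"""Simulate the five-arm treatment dataset and write it to disk.

Writes counts.tsv, samples.csv and truth.tsv under results/analysis/dataset/.
"""

import argparse

from design import DATA_DIR, registry, study_config
from melanotx.simulate import generate_counts, write_dataset


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    cfg = study_config(seed=args.seed)
    ds = generate_counts(cfg, registry())
    paths = write_dataset(ds, DATA_DIR)

    planted = ds.truth[ds.truth["log2fc"] != 0]
    print(f"simulated {ds.counts.counts.shape[0]} genes x "
          f"{ds.counts.counts.shape[1]} samples "
          f"({len(cfg.classes)} classes x {cfg.replicates_per_class} replicates)")
    print(f"planted effects: {len(planted)} gene/class pairs across "
          f"{planted['class'].nunique()} classes")
    for name, p in paths.items():
        print(f"  wrote {name}: {p.relative_to(DATA_DIR.parents[2])}")


if __name__ == "__main__":
    main()
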