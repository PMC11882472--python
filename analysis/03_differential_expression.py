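"""Differential expression of every treatment arm against the vehicle control.

NB Wald tests at FDR < 0.05 and |log2FC| >= 1.5, then DEG set overlap across
arms. Writes per-contrast tables and overlap.json under results/analysis/.
"""

import importlib
import json

from design import OUT_DIR
from melanotx.de import ContrastSpec, overlap_analysis, run_contrast

prep = importlib.import_module("02_preprocess")


def main() -> None:
    filtered, norm = prep.preprocess(prep.load_dataset())
    arms = [c for c in sorted(filtered.samples["class"].unique()) if c != "NEGATIVE"]
    deg_sets = {}
    for arm in arms:
        spec = ContrastSpec(arm, "NEGATIVE")
        table = run_contrast(filtered, spec, size_factors=norm.size_factors)
        table.to_csv(OUT_DIR / f"de_{spec}.tsv", sep="\t")
        up = int((table["call"] == "up").sum())
        down = int((table["call"] == "down").sum())
        deg_sets[arm] = set(table.index[table["call"] != "ns"])
        print(f"{spec}: {up} up, {down} down")

    overlap = overlap_analysis(deg_sets)
    (OUT_DIR / "overlap.json").write_text(json.dumps(
        {k: overlap[k] for k in ("region_counts", "shared_fraction", "jaccard", "set_sizes")},
        indent=2, sort_keys=True, default=list,
    ))
    shared = overlap["shared_fraction"]
    print("fraction of each arm's DEGs shared with another arm:")
    for arm, frac in sorted(shared.items()):
        print(f"  {arm}: {100 * frac:.1f}%")


if __name__ == "__main__":
    main()
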