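"""Differentiation-state positioning and early-resistance readouts.

Scores the Tsoi-style subtype signatures per treatment arm, places arms in
the (neural-crest-like, melanocytic-transitory) plane with median cutoffs,
and reports MITF/AXL ratios, the intrinsic-resistance panel and the ABC
transporter panel. Writes positions.tsv and diffstate_summary.json.
"""

import importlib
import json

from design import OUT_DIR, registry
from melanotx.activity import class_summary, combined_zscore_activity
from melanotx.diffstate import (
    marker_panel_report,
    mitf_axl_ratio,
    position_states,
    resistance_score,
    subtype_scores,
)
from melanotx.genesets import GeneSet

prep = importlib.import_module("02_preprocess")


def main() -> None:
    _, norm = prep.preprocess(prep.load_dataset())
    reg = registry()

    sigs = {k: v for k, v in reg.items() if v.subtype is not None}
    scores = subtype_scores(norm, sigs)
    union = GeneSet(
        "MELANOCYTIC_TRANSITORY",
        tuple(dict.fromkeys(reg["TSOI_MELANOCYTIC"].genes + reg["TSOI_TRANSITORY"].genes)),
        category="subtype:melanocytic_transitory",
    )
    scores["melanocytic_transitory"] = combined_zscore_activity(norm, union)
    for subtype, table in scores.items():
        means = class_summary(table)["mean"]
        print(f"{subtype}: top arm {means.idxmax()} ({means.max():+.2f})")

    positions = position_states(scores, "neural_crest_like", "melanocytic_transitory")
    positions.to_csv(OUT_DIR / "positions.tsv", sep="\t")
    print("\ninferred state per arm:")
    for arm, row in positions.iterrows():
        print(f"  {arm}: {row['region']}")

    ratio = mitf_axl_ratio(norm)
    print("\nMITF/AXL log2 ratio per arm (low = early-resistance-prone):")
    for arm, row in ratio["summary"].iterrows():
        print(f"  {arm}: {row['mean']:+.2f} +- {row['se']:.2f}")

    res = resistance_score(norm, reg["INTRINSIC_RESISTANCE"])
    comp = res["comparisons"].get("NEGATIVE_vs_PROTAC") or res["comparisons"].get(
        "PROTAC_vs_NEGATIVE"
    )
    print(f"\nintrinsic-resistance panel, degrader vs control: p = {comp['p']:.2f}")

    abc = marker_panel_report(norm, reg["ABC_TRANSPORTERS"],
                              compare=[("PROTAC", "NEGATIVE"), ("PROTAC", "BI882370")])
    markers = marker_panel_report(norm, reg["DIFF_MARKER_PANEL"])
    markers["correlation"].to_csv(OUT_DIR / "marker_correlation.tsv", sep="\t")

    summary = {
        "positions": positions["region"].to_dict(),
        "mitf_axl_class_means": ratio["summary"]["mean"].round(3).to_dict(),
        "resistance_p_degrader_vs_control": comp["p"],
        "abc_comparisons": {
            k: {"difference": v["difference"], "p": v["p"]}
            for k, v in abc["comparisons"].items()
        },
    }
    (OUT_DIR / "diffstate_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float)
    )


if __name__ == "__main__":
    main()
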