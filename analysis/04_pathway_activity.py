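"""Pathway activity: combined z-scores for the MAPK output panel and the
survival/proliferation programs, MAPK PCA variance, and the MAPK ~
proliferation correlation.

Writes activity_scores.tsv and activity_summary.json under results/analysis/.
"""

import importlib
import json

from design import OUT_DIR, registry
from melanotx.activity import (
    cell_cycle_phase_profile,
    class_summary,
    combined_zscore_activity,
    compare_groups,
    pca_explained_variance,
    pearson_correlation,
)

prep = importlib.import_module("02_preprocess")

PANELS = ["MAPK_TARGETS_WAGLE", "PI3K_AKT_MTOR", "PROLIFERATION",
          "QUIESCENCE_G0", "APOPTOSIS", "FERROPTOSIS"]


def main() -> None:
    _, norm = prep.preprocess(prep.load_dataset())
    reg = registry()

    summary, frames = {}, []
    for name in PANELS:
        scores = combined_zscore_activity(norm, reg[name])
        cs = class_summary(scores)
        comp = compare_groups(scores, "PROTAC", "NEGATIVE")
        summary[name] = {
            "class_means": cs["mean"].round(3).to_dict(),
            "degrader_vs_control_p": comp["p"],
        }
        frames.append(scores.assign(set=name))
        print(f"{name}: degrader mean {cs.loc['PROTAC', 'mean']:+.2f}, "
              f"control mean {cs.loc['NEGATIVE', 'mean']:+.2f}, "
              f"Welch p = {comp['p']:.2e}")

    mapk = combined_zscore_activity(norm, reg["MAPK_TARGETS_WAGLE"])
    prolif = combined_zscore_activity(norm, reg["PROLIFERATION"])
    r, p = pearson_correlation(mapk["score"], prolif["score"])
    print(f"MAPK activity ~ proliferation across samples: r = {r:.2f}, p = {p:.1e}")
    summary["mapk_proliferation_correlation"] = {"r": r, "p": p}

    pca = pca_explained_variance(norm, reg["MAPK_TARGETS_WAGLE"])
    print(f"PC1+PC2 of the 10 MAPK panel genes explain "
          f"{100 * pca['pc1_pc2_fraction']:.2f}% of sample variance")
    summary["mapk_pca_pc1_pc2_pct"] = 100 * pca["pc1_pc2_fraction"]

    phase_sets = {k: v for k, v in reg.items() if v.phase is not None}
    phases = cell_cycle_phase_profile(
        norm, phase_sets, compare=[("PROTAC", "NEGATIVE")]
    )
    for key, comp in phases["comparisons"].items():
        print(f"cell cycle {key}: diff {comp['difference']:+.2f}, p = {comp['p']:.2e}")

    import pandas as pd
    pd.concat(frames).to_csv(OUT_DIR / "activity_scores.tsv", sep="\t")
    (OUT_DIR / "activity_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float)
    )


if __name__ == "__main__":
    main()
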