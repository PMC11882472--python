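"""Comparative-Ct qPCR readback of the planted validation genes and its
concordance with the RNA-seq fold changes.

Regenerates the study dataset, simulates a triplicate qPCR assay (Ct noise
sd 0.3) for the eight validation genes, quantifies with 2^-ddCt and
correlates against the RNA-seq log2 fold changes of the degrader contrast.
Writes qpcr_log2fc.tsv and qpcr_summary.json.
"""

import argparse
import json

import pandas as pd

from design import DATA_DIR, OUT_DIR, QPCR_REFERENCE, VALIDATION_LFCS, registry, study_config
from melanotx.qpcr import concordance, delta_delta_ct
from melanotx.simulate import generate_counts, generate_qpcr


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--noise-sd", type=float, default=0.3)
    args = parser.parse_args()

    ds = generate_counts(study_config(seed=args.seed), registry())
    table = generate_qpcr(
        ds, list(VALIDATION_LFCS), QPCR_REFERENCE, args.noise_sd,
        treated_class="PROTAC", control_class="NEGATIVE",
    )
    qres = delta_delta_ct(table)
    qres.to_csv(OUT_DIR / "qpcr_log2fc.tsv", sep="\t")

    print("gene      planted   qPCR log2FC (2^-ddCt)")
    for gene, lfc in VALIDATION_LFCS.items():
        print(f"{gene}  {lfc:+6.2f}   {qres.loc[gene, 'log2fc']:+6.2f} "
              f"+- {qres.loc[gene, 'se']:.2f}")

    de_path = OUT_DIR / "de_PROTAC_vs_NEGATIVE.tsv"
    if not de_path.exists():
        raise SystemExit("DE table missing; run 03_differential_expression.py first")
    de = pd.read_csv(de_path, sep="\t", index_col=0)
    conc = concordance(qres["log2fc"], de["log2fc"].dropna())
    print(f"\nqPCR ~ RNA-seq concordance over {conc['n_genes']} genes: "
          f"r = {conc['r']:.2f}, p = {conc['p']:.1e}")
    (OUT_DIR / "qpcr_summary.json").write_text(
        json.dumps({"concordance": {k: conc[k] for k in ('r', 'p', 'n_genes')}},
                   indent=2, default=float)
    )


if __name__ == "__main__":
    main()
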