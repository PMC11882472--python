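"""Comparative-Ct (2^-ddCt) quantification and qPCR / RNA-seq concordance.

For each target gene, dCt = Ct_target - Ct_reference per sample; ddCt is the
mean treated dCt minus the mean control dCt; the relative expression is
2^-ddCt, so log2 fold change = -ddCt. The replicate standard error is
propagated from the two group dCt variances. No amplification-efficiency
correction is applied (the plain comparative-Ct model).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .activity import pearson_correlation

__all__ = ["read_qpcr_table", "validate_qpcr_table", "delta_delta_ct", "concordance"]

REQUIRED_COLUMNS = ("sample_id", "group", "gene", "ct_target", "ct_reference")


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_qpcr_table(table)
    return table


def validate_qpcr_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"qPCR table missing columns: {missing}")
    bad_group = set(table["group"]) - {"treated", "control"}
    if bad_group:
        raise ValueError(f"group must be treated/control, found {sorted(bad_group)}")
    ct = table[["ct_target", "ct_reference"]].to_numpy(dtype=float)
    if not np.isfinite(ct).all() or (ct <= 0).any():
        raise ValueError("Ct values must be finite and > 0")


def delta_delta_ct(table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene ddCt, fold change 2^-ddCt, log2FC and replicate SE.

    Aggregation happens at the dCt level: group means of per-sample dCt are
    differenced, and the SE is sqrt(var_t/n_t + var_c/n_c) of the group dCt
    values (identical on the ddCt and log2FC scales).
    """
    validate_qpcr_table(table)
    t = table.copy()
    t["dct"] = t["ct_target"] - t["ct_reference"]
    rows = []
    for gene, block in t.groupby("gene", sort=True):
        treated = block.loc[block["group"] == "treated", "dct"]
        control = block.loc[block["group"] == "control", "dct"]
        if control.empty:
            raise ValueError(f"gene {gene!r} has no control measurements")
        if treated.empty:
            raise ValueError(f"gene {gene!r} has no treated measurements")
        ddct = float(treated.mean() - control.mean())
        var_t = float(treated.var(ddof=1)) if len(treated) > 1 else 0.0
        var_c = float(control.var(ddof=1)) if len(control) > 1 else 0.0
        se = float(np.sqrt(var_t / len(treated) + var_c / len(control)))
        rows.append(
            {
                "gene": gene,
                "ddct": ddct,
                "fold_change": float(2.0 ** (-ddct)),
                "log2fc": -ddct,
                "se": se,
                "n_treated": len(treated),
                "n_control": len(control),
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def concordance(
    qpcr_lfc: pd.Series, rnaseq_lfc: pd.Series
) -> dict:
    """Pearson correlation between qPCR and RNA-seq log2 fold changes on the
    genes shared by both tables."""
    shared = qpcr_lfc.index.intersection(rnaseq_lfc.index)
    if len(shared) < 3:
        raise ValueError(f"concordance needs >= 3 shared genes, found {len(shared)}")
    r, p = pearson_correlation(
        qpcr_lfc.loc[shared].to_numpy(), rnaseq_lfc.loc[shared].to_numpy()
    )
    return {"r": r, "p": p, "n_genes": int(len(shared)), "genes": list(shared)}
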