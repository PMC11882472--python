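"""Melanoma differentiation-state positioning and early-resistance readouts.

Melanoma cells move along a differentiation trajectory (undifferentiated ->
neural-crest-like -> transitory -> melanocytic); drug pressure can push cells
toward dedifferentiated, drug-tolerant states. This module scores each
treatment class on subtype signatures with the combined z-score statistic,
places classes in a two-axis plane with median cutoffs (the quadrant a class
lands in names its inferred state), computes the MITF/AXL ratio whose low
values mark early resistance to targeted therapy, and scores an
intrinsic-resistance panel.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .activity import class_summary, combined_zscore_activity, compare_groups
from .genesets import GeneSet
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "subtype_scores",
    "position_states",
    "mitf_axl_ratio",
    "resistance_score",
    "marker_panel_report",
]


def subtype_scores(
    z: NormalizedMatrix, signatures: dict[str, GeneSet]
) -> dict[str, pd.DataFrame]:
    """Per-sample combined z-scores for each differentiation-subtype signature.

    Returns {subtype: per-sample score table}; class means and SE come from
    :func:`melanotx.activity.class_summary`.
    """
    out = {}
    for name, gs in signatures.items():
        subtype = gs.subtype or name
        out[subtype] = combined_zscore_activity(z, gs)
    return out


def position_states(
    scores: dict[str, pd.DataFrame],
    axis_x: str,
    axis_y: str,
    tol: float = 1e-12,
) -> pd.DataFrame:
    """Quadrant assignment of treatment classes in a two-axis score plane.

    Each class's axis value is its mean replicate score; the cutoffs are the
    medians of those class means across all classes present. A class within
    ``tol`` of a cutoff is flagged on-boundary.
    """
    for axis in (axis_x, axis_y):
        if axis not in scores:
            raise ValueError(f"axis {axis!r} has no score table")
    sx = class_summary(scores[axis_x])["mean"]
    sy = class_summary(scores[axis_y])["mean"]
    classes = sx.index.intersection(sy.index)
    if len(classes) < 2:
        raise ValueError("median cutoffs need >= 2 classes")
    mx, my = float(sx.loc[classes].median()), float(sy.loc[classes].median())

    rows = []
    for c in classes:
        dx, dy = sx[c] - mx, sy[c] - my
        on_boundary = abs(dx) <= tol or abs(dy) <= tol
        if on_boundary:
            logger.info("class %s lies on a median cutoff", c)
        label = (
            f"{'high' if dx > 0 else 'low'}_{axis_x}/"
            f"{'high' if dy > 0 else 'low'}_{axis_y}"
        )
        rows.append(
            {
                "class": c,
                axis_x: float(sx[c]),
                axis_y: float(sy[c]),
                "region": "on-boundary" if on_boundary else label,
                "on_boundary": on_boundary,
            }
        )
    out = pd.DataFrame(rows).set_index("class")
    out.attrs["cutoffs"] = {axis_x: mx, axis_y: my}
    return out


def mitf_axl_ratio(
    norm: NormalizedMatrix, pseudocount: float = 1.0
) -> dict:
    """Per-class log2 MITF/AXL ratio of normalized expression.

    ratio_j = log2((MITF_j + c) / (AXL_j + c)) per replicate with
    pseudocount c; low values mark early resistance. Returns per-sample
    ratios, class mean +- SE and all pairwise Welch comparisons.
    """
    for gene in ("MITF", "AXL"):
        if gene not in norm.normalized.index:
            raise ValueError(f"{gene} absent from the matrix")
    mitf = norm.normalized.loc["MITF"]
    axl = norm.normalized.loc["AXL"]
    ratio = np.log2((mitf + pseudocount) / (axl + pseudocount))
    table = pd.DataFrame({"score": ratio, "class": norm.classes().loc[ratio.index]})
    summary = class_summary(table)
    comparisons = {
        f"{a}_vs_{b}": compare_groups(table, a, b)
        for a, b in itertools.combinations(summary.index, 2)
    }
    return {"per_sample": table, "summary": summary, "comparisons": comparisons}


def resistance_score(z: NormalizedMatrix, panel: GeneSet) -> dict:
    """Combined z-score of the intrinsic-resistance panel per class, with
    pairwise Welch p-values."""
    scores = combined_zscore_activity(z, panel)
    summary = class_summary(scores)
    comparisons = {
        f"{a}_vs_{b}": compare_groups(scores, a, b)
        for a, b in itertools.combinations(summary.index, 2)
    }
    return {"per_sample": scores, "summary": summary, "comparisons": comparisons}


def marker_panel_report(
    norm: NormalizedMatrix,
    panel: GeneSet,
    compare: list[tuple[str, str]] | None = None,
) -> dict:
    """Per-gene class summaries and the gene-gene Pearson matrix for a panel.

    Expression summaries use normalized counts; correlations are computed
    across all samples. Panel genes absent from the matrix are reported, not
    fatal.
    """
    present = [g for g in panel.genes if g in norm.normalized.index]
    missing = sorted(set(panel.genes) - set(present))
    if missing:
        logger.warning("marker panel: %d genes absent (%s)", len(missing), missing[:5])
    expr = norm.normalized.loc[present]
    classes = norm.classes()

    summaries = {}
    for g in present:
        table = pd.DataFrame({"score": expr.loc[g], "class": classes.loc[expr.columns]})
        summaries[g] = class_summary(table)

    comparisons = {}
    for a, b in compare or []:
        for g in present:
            table = pd.DataFrame({"score": expr.loc[g], "class": classes})
            try:
                comparisons[f"{g}:{a}_vs_{b}"] = compare_groups(table, a, b)
            except ValueError:
                continue

    # correlation across samples; constant genes yield NaN rows by convention
    corr = expr.T.corr(method="pearson")
    return {
        "expression": expr,
        "class_summaries": summaries,
        "comparisons": comparisons,
        "correlation": corr,
        "missing": missing,
    }
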