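"""Relative qPCR expression via the comparative ΔCq method.

Per sample, ΔCq = mean replicate Cq(target) − mean replicate Cq(reference);
relative expression is 2^(−ΔCq), and fold change divides by the mean
relative expression of the control group, so the control mean is 1 by
construction. Amplification efficiency is fixed at 2 (no efficiency
correction).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def relative_expression(
    records: pd.DataFrame,
    reference_gene: str = "GAPDH",
    control_group: str = "control",
) -> pd.DataFrame:
    """Per-sample, per-gene relative expression and fold change vs control.

    ``records`` is a tidy Cq table with columns sample, group, gene, cq
    (replicate rows allowed). Samples lacking the reference gene are
    excluded with a warning. Returns a tidy frame with columns sample,
    group, gene, delta_cq, rel_expr (2^−ΔCq) and fold_change.
    """
    required = {"sample", "group", "gene", "cq"}
    if not required.issubset(records.columns):
        raise ValueError(f"Cq table needs columns {sorted(required)}")
    if (records["cq"] <= 0).any():
        raise ValueError("Cq values must be positive")

    mean_cq = (
        records.groupby(["sample", "group", "gene"], sort=False)["cq"].mean().reset_index()
    )
    ref = mean_cq[mean_cq["gene"] == reference_gene].set_index("sample")["cq"]
    missing = sorted(set(mean_cq["sample"]) - set(ref.index))
    if missing:
        warnings.warn(f"samples without reference gene '{reference_gene}' excluded: {missing}")
    targets = mean_cq[
        (mean_cq["gene"] != reference_gene) & mean_cq["sample"].isin(ref.index)
    ].copy()
    if targets.empty:
        raise ValueError("no target-gene measurements with a reference Cq")
    targets["delta_cq"] = targets["cq"] - targets["sample"].map(ref)
    targets["rel_expr"] = 2.0 ** (-targets["delta_cq"])

    out = []
    for gene, sub in targets.groupby("gene", sort=False):
        ctrl = sub.loc[sub["group"] == control_group, "rel_expr"]
        if ctrl.empty:
            raise ValueError(f"gene '{gene}' has no samples in group '{control_group}'")
        sub = sub.copy()
        sub["fold_change"] = sub["rel_expr"] / ctrl.mean()
        out.append(sub)
    result = pd.concat(out, ignore_index=True)
    return result[["sample", "group", "gene", "delta_cq", "rel_expr", "fold_change"]]


def group_fold_summary(folds: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SEM fold change per gene and group, tidy for plotting/stats."""
    g = folds.groupby(["gene", "group"])["fold_change"]
    return g.agg(mean="mean", sem=lambda x: np.std(x, ddof=1) / np.sqrt(len(x)), n="size").reset_index()
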