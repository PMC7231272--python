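"""Relative expression from qPCR Ct tables and nonparametric group comparison.

Relative expression follows the 2^dCt convention against a panel of reference
genes: for each sample the reference Ct is the arithmetic mean of the
reference genes' Cts (equivalently, the geometric mean of their expressions),
and a target's relative expression is ``2 ** (ref_ct - ct)``.  Group contrasts
use the two-sided Mann-Whitney U test on biological-replicate values, exact
for small groups, normal-approximated with tie correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["gene", "sample", "group", "replicate", "ct"]


def _validate_ct(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if not np.isfinite(ct["ct"]).all() or (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be finite and positive")
    return ct


def relative_expression(ct: pd.DataFrame, targets: Sequence[str],
                        references: Sequence[str]) -> pd.DataFrame:
    """2^dCt relative expression of each target gene against the reference panel.

    Every sample must carry one measurement of every reference gene; a missing
    reference is an error naming the sample.
    """
    ct = _validate_ct(ct)
    ref_rows = ct[ct["gene"].isin(references)]
    ref_ct = ref_rows.groupby("sample")["ct"].agg(["mean", "size"])
    for sample in ct["sample"].unique():
        if sample not in ref_ct.index or ref_ct.loc[sample, "size"] != len(references):
            raise ValueError(f"sample {sample!r} lacks a complete reference-gene panel")
    wanted = ct[ct["gene"].isin(list(targets))].copy()
    wanted["rel_expr"] = 2.0 ** (ref_ct["mean"].reindex(wanted["sample"]).to_numpy()
                                 - wanted["ct"].to_numpy())
    out = wanted[["gene", "sample", "group", "replicate", "rel_expr"]].reset_index(drop=True)
    out.attrs["normalization"] = ("2^dCt vs arithmetic-mean Ct of references: "
                                  + ",".join(references))
    return out


@dataclass(frozen=True)
class GroupComparison:
    gene: str
    group_a: str
    group_b: str
    u_statistic: float
    p_value: float
    method: str
    significant: bool


def compare_groups(rel: pd.DataFrame, gene: str, group_a: str, group_b: str,
                   alpha: float = 0.01) -> GroupComparison:
    """Two-sided Mann-Whitney U between two groups of replicate expressions.

    Uses the exact null distribution when both groups have at most 8
    replicates and the data are tie-free, otherwise the normal approximation
    with tie correction.  Requires at least 3 replicates per group.
    """
    sub = rel[rel["gene"] == gene]
    xa = sub.loc[sub["group"] == group_a, "rel_expr"].to_numpy(dtype=float)
    xb = sub.loc[sub["group"] == group_b, "rel_expr"].to_numpy(dtype=float)
    if len(xa) < 3 or len(xb) < 3:
        raise ValueError(f"{gene}: need >=3 replicates per group "
                         f"({len(xa)} vs {len(xb)})")
    pooled = np.concatenate([xa, xb])
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (max(len(xa), len(xb)) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
    return GroupComparison(gene=gene, group_a=group_a, group_b=group_b,
                           u_statistic=float(res.statistic), p_value=float(res.pvalue),
                           method=method, significant=bool(res.pvalue < alpha))


def comparison_table(rel: pd.DataFrame, genes: Sequence[str], group_a: str,
                     group_b: str, alpha: float = 0.01) -> pd.DataFrame:
    rows = [compare_groups(rel, g, group_a, group_b, alpha) for g in genes]
    return pd.DataFrame([r.__dict__ for r in rows])
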