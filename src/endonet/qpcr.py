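"""2^-ΔΔCT relative quantification and the validation correlation network.

Target CT values are normalized to the arithmetic mean CT of two
endogenous control genes (equivalent to the geometric mean of their
abundances), then calibrated against the mean ΔCT of the baseline-stage
samples, so the geometric mean of baseline relative expression is exactly
1. The validated genes are then screened pairwise with the Pearson
correlation test and the edge list is Benjamini–Hochberg filtered at an
FDR of 0.05, each retained edge carrying the correlation sign.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = ["delta_delta_ct", "relative_expression_table", "correlation_network"]


def delta_delta_ct(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_genes: list[str],
    stage_of_sample: dict[str, str],
    baseline_stage: str,
) -> pd.Series:
    """Per-sample 2^-ΔΔCT relative expression of one target gene.

    ΔCT_s = CT_target,s − mean(CT of the reference genes in s);
    ΔΔCT_s = ΔCT_s − mean over baseline-stage samples of ΔCT;
    result = 2^(−ΔΔCT).
    """
    for g in [target_gene, *reference_genes]:
        if g not in ct_table.index:
            raise ValueError(f"CT values missing for gene {g!r}")
        row = ct_table.loc[g]
        if row.isna().any():
            missing = list(row.index[row.isna()])
            raise ValueError(f"missing CT for gene {g!r} in sample(s) {missing[:5]}")
    samples = list(ct_table.columns)
    unknown = [s for s in samples if s not in stage_of_sample]
    if unknown:
        raise ValueError(f"samples without a stage: {unknown[:5]}")
    base_samples = [s for s in samples if stage_of_sample[s] == baseline_stage]
    if not base_samples:
        raise ValueError(f"no samples for baseline stage {baseline_stage!r}")
    ref_ct = ct_table.loc[list(reference_genes)].mean(axis=0)
    delta = ct_table.loc[target_gene] - ref_ct
    ddct = delta - delta[base_samples].mean()
    rel = np.power(2.0, -ddct)
    rel.name = target_gene
    return rel


def relative_expression_table(
    ct_table: pd.DataFrame,
    reference_genes: list[str],
    stage_of_sample: dict[str, str],
    baseline_stage: str,
) -> pd.DataFrame:
    """2^-ΔΔCT for every non-reference gene in the CT table."""
    targets = [g for g in ct_table.index if g not in set(reference_genes)]
    rows = [
        delta_delta_ct(ct_table, g, reference_genes, stage_of_sample, baseline_stage)
        for g in targets
    ]
    return pd.DataFrame(rows)


def correlation_network(
    relative_expression: pd.DataFrame,
    alpha: float = 0.05,
    log_scale: bool = True,
    per_stage: bool = False,
    stage_of_sample: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Signed, FDR-filtered all-pairs Pearson correlation edge list.

    Correlations are computed across samples (or across stage means when
    ``per_stage``), by default on log2 of the relative expression; p-values
    use the t transform ``t = r·sqrt((n−2)/(1−r²))`` and are BH-adjusted
    jointly over all pairs. Edges with adjusted p < ``alpha`` are kept,
    each unordered pair once, with a positive/negative sign attribute.
    """
    data = relative_expression.copy()
    if log_scale:
        if (data.to_numpy() <= 0).any():
            raise ValueError("relative expression must be positive for log scale")
        data = np.log2(data)
    if per_stage:
        if stage_of_sample is None:
            raise ValueError("per_stage correlation needs stage_of_sample")
        stages = pd.Series({s: stage_of_sample[s] for s in data.columns})
        data = data.T.groupby(stages).mean().T
    values = data.to_numpy(dtype=float)
    n = values.shape[1]
    if n < 3:
        raise ValueError("need at least 3 observations per gene")
    sd = values.std(axis=1)
    if (sd == 0).any():
        dropped = list(data.index[sd == 0])
        warnings.warn(
            f"excluding {len(dropped)} constant gene(s): {dropped[:5]}", stacklevel=2
        )
        data = data.loc[sd > 0]
        values = values[sd > 0]
    genes = list(data.index)
    columns = ["gene_a", "gene_b", "r", "p_value", "fdr_adjusted_p", "sign"]
    if len(genes) < 2:
        return pd.DataFrame(columns=columns)
    r = np.clip(np.corrcoef(values), -1.0, 1.0)
    iu = np.triu_indices(len(genes), k=1)
    rv = r[iu]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rv * np.sqrt((n - 2) / (1.0 - rv**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(rv) >= 1.0, 0.0, p)
    padj = bh_adjust(p)
    keep = padj < alpha
    return pd.DataFrame(
        {
            "gene_a": np.asarray(genes)[iu[0][keep]],
            "gene_b": np.asarray(genes)[iu[1][keep]],
            "r": rv[keep],
            "p_value": p[keep],
            "fdr_adjusted_p": padj[keep],
            "sign": np.where(rv[keep] > 0, "positive", "negative"),
        }
    )
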