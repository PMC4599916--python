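"""qPCR Ct normalization by double median-centering.

Raw Ct values (PCR cycles to threshold; lower = more template) are centred
by subtracting each sample's median, then each gene's median of the
sample-centred values. The negation of the result is reported, so higher
values correspond to increased expression (a −ΔΔCt scale). Undetectable
genes are encoded as missing and ignored by the medians.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import InputError

__all__ = ["CtNormalizer", "double_median_center", "anova_tukey", "long_to_wide"]


def long_to_wide(long_df: pd.DataFrame, gene_col="gene", sample_col="sample", ct_col="ct"):
    """Pivot a (gene, sample, ct) long table into a genes x samples matrix."""
    return long_df.pivot_table(index=gene_col, columns=sample_col, values=ct_col, aggfunc="mean")


def double_median_center(ct: pd.DataFrame) -> pd.DataFrame:
    """−ΔΔCt matrix: center within samples, then within genes, then negate.

    ``ct`` is a genes x samples DataFrame of raw Ct values; missing entries
    are ignored by the medians. Genes or samples that are entirely missing
    are dropped with a warning. After the transform (pre-negation) every
    gene's row median is exactly zero, and the output is invariant to adding
    a constant to any single sample's raw Ct column.
    """
    if not isinstance(ct, pd.DataFrame):
        ct = pd.DataFrame(ct)
    ct = ct.astype(float)
    dead_genes = ct.index[ct.isna().all(axis=1)]
    dead_samples = ct.columns[ct.isna().all(axis=0)]
    if len(dead_genes) or len(dead_samples):
        warnings.warn(
            f"dropping entirely-missing genes {list(dead_genes)} and "
            f"samples {list(dead_samples)}",
            stacklevel=2,
        )
        ct = ct.drop(index=dead_genes, columns=dead_samples)
    if ct.shape[0] < 2 or ct.shape[1] < 2:
        raise InputError("double centering needs at least 2 genes and 2 samples")
    step1 = ct - ct.median(axis=0, skipna=True)
    step2 = step1.sub(step1.median(axis=1, skipna=True), axis=0)
    return -step2


class CtNormalizer(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper around :func:`double_median_center` (stateless)."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return double_median_center(X)


def anova_tukey(values: pd.DataFrame, value_col: str = "value", group_col: str = "group"):
    """One-way ANOVA plus Tukey HSD contrasts on normalized expression values.

    Thin pass-through to scipy/statsmodels for the routine group comparison;
    returns ``(anova_p, tukey_table)``.
    """
    from scipy.stats import f_oneway
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = [g[value_col].dropna().to_numpy() for _, g in values.groupby(group_col)]
    if len(groups) < 2:
        raise InputError("need at least two groups for ANOVA")
    anova_p = float(f_oneway(*groups).pvalue)
    sub = values.dropna(subset=[value_col])
    tk = pairwise_tukeyhsd(sub[value_col].to_numpy(), sub[group_col].to_numpy())
    table = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return anova_p, table
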