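"""Relative transcript quantification from qPCR Ct tables.

Implements the delta–delta Ct method against a multi-gene reference index:
for each sample, ΔCt = Ct(gene) − index, where the index is the arithmetic
mean of the technical-replicate-averaged Cts of the five reference genes
(EF-1α, UP1, UP2, TIP41, UBC by default). ΔΔCt is the mean ΔCt difference
between treated and control samples and the relative normalized abundance
is QRN = 2^(−ΔΔCt), with amplification efficiency fixed at 2 (one cycle =
one doubling). Significance of treated-vs-control differences in ΔCt uses
an exact two-sided Mann–Whitney test for small groups.
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

log = logging.getLogger(__name__)

REFERENCE_GENES = ("EF-1a", "UP1", "UP2", "TIP41", "UBC")


class InputError(ValueError):
    pass


def _mean_ct(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Technical-replicate-averaged Ct per (gene, sample)."""
    if (ct_table["ct"] <= 0).any():
        raise InputError("Ct values must be positive")
    return (ct_table.groupby(["gene_id", "sample_id"])["ct"]
            .mean().unstack("sample_id"))


def reference_index(ct_table: pd.DataFrame,
                    reference_genes=REFERENCE_GENES) -> pd.Series:
    """Per-sample reference index: mean Ct of the reference genes (cycles)."""
    mean_ct = _mean_ct(ct_table)
    for gene in reference_genes:
        if gene not in mean_ct.index:
            raise InputError(f"reference gene {gene!r} absent from the table")
        missing = mean_ct.columns[mean_ct.loc[gene].isna()]
        if len(missing):
            raise InputError(
                f"reference gene {gene!r} missing in sample(s) {list(missing)}")
    return mean_ct.loc[list(reference_genes)].mean(axis=0)


def delta_ct(ct_table: pd.DataFrame, gene: str, samples,
             reference_genes=REFERENCE_GENES) -> np.ndarray:
    """Index-normalized ΔCt of one gene over the named samples."""
    mean_ct = _mean_ct(ct_table)
    index = reference_index(ct_table, reference_genes)
    if gene not in mean_ct.index:
        raise InputError(f"gene {gene!r} absent from the table")
    vals = mean_ct.loc[gene, list(samples)]
    if vals.isna().any():
        raise InputError(f"gene {gene!r} unmeasured in some requested samples")
    return (vals - index[list(samples)]).to_numpy()


def qrn(ct_table: pd.DataFrame, gene: str, bent_samples, control_samples,
        reference_genes=REFERENCE_GENES) -> float:
    """Quantitative relative normalized abundance, bent vs. control."""
    if not list(control_samples):
        raise InputError("no control samples given")
    d_bent = delta_ct(ct_table, gene, bent_samples, reference_genes)
    d_ctrl = delta_ct(ct_table, gene, control_samples, reference_genes)
    ddct = d_bent.mean() - d_ctrl.mean()
    return float(2.0 ** (-ddct))


def mw_test(group_a, group_b, exact_max_n: int = 8) -> float:
    """Two-sided Mann–Whitney p; exact by enumeration for small groups.

    The exact p is P(|U − nm/2| >= |u_obs − nm/2|) over all C(n+m, n)
    equally likely assignments of the pooled mid-ranks to group A (so ties
    are handled by mid-ranks, with a logged note). Groups larger than
    ``exact_max_n`` fall back to the normal approximation.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("each group needs >= 2 values")
    n, m = len(a), len(b)
    if n > exact_max_n or m > exact_max_n:
        return float(mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic").pvalue)
    pooled = np.concatenate([a, b])
    if len(np.unique(pooled)) < len(pooled):
        log.info("ties present; using mid-ranks in the exact Mann-Whitney test")
    ranks = rankdata(pooled)
    mu = n * m / 2.0
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
    dev = abs(u_obs - mu)
    total = comb(n + m, n)
    hits = 0
    for idx in combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2.0
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def quantify_genes(ct_table: pd.DataFrame, genes, bent_samples,
                   control_samples,
                   reference_genes=REFERENCE_GENES) -> pd.DataFrame:
    """QRN fold-change and Mann–Whitney p for each gene of interest."""
    rows = []
    for gene in genes:
        fold = qrn(ct_table, gene, bent_samples, control_samples,
                   reference_genes)
        d_bent = delta_ct(ct_table, gene, bent_samples, reference_genes)
        d_ctrl = delta_ct(ct_table, gene, control_samples, reference_genes)
        rows.append((gene, fold, mw_test(d_bent, d_ctrl)))
    return pd.DataFrame(rows, columns=["gene_id", "qrn", "p_mw"])
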