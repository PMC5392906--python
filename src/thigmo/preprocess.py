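"""Per-comparison probeset pre-filters and probeset→gene collapsing.

Filters are applied separately for each two-group comparison: a probeset
excluded from one comparison (e.g. unexpressed in both groups at 0.5 h) may
still be tested in another, matching the per-comparison wording of the
microarray protocol this pipeline reimplements.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

UNEXPRESSED_THRESHOLD = 4.0


class InputError(ValueError):
    pass


def _check_samples(matrix: pd.DataFrame, samples) -> None:
    missing = [s for s in samples if s not in matrix.columns]
    if missing:
        raise InputError(f"unknown sample ids: {missing}")


def filter_unexpressed(matrix: pd.DataFrame, group_a, group_b,
                       threshold: float = UNEXPRESSED_THRESHOLD) -> set:
    """Probesets unexpressed in a comparison: every intensity of BOTH groups
    below ``threshold``. Returns the set of excluded probeset ids."""
    group_a, group_b = list(group_a), list(group_b)
    _check_samples(matrix, group_a + group_b)
    if matrix.empty:
        return set()
    sub = matrix[group_a + group_b].to_numpy()
    excluded = (sub < threshold).all(axis=1)
    return set(matrix.index[excluded])


def pooled_within_group_variance(matrix: pd.DataFrame, group_a, group_b) -> pd.Series:
    """Pooled (equal-variance) within-group variance per probeset."""
    a = matrix[list(group_a)].to_numpy(float)
    b = matrix[list(group_b)].to_numpy(float)
    na, nb = a.shape[1], b.shape[1]
    ssa = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssb = ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return pd.Series((ssa + ssb) / (na + nb - 2), index=matrix.index)


def filter_extreme_variance(matrix: pd.DataFrame, group_a, group_b,
                            low_q: float = 0.001, high_q: float = 0.999) -> set:
    """Exclude probesets with extreme pooled within-group variance.

    A probeset is excluded when its variance falls strictly below the
    ``low_q`` or strictly above the ``high_q`` empirical quantile of the
    variance distribution across probesets, so the equal-variance t-test
    downstream is not dominated by near-constant or wildly noisy probes.
    """
    group_a, group_b = list(group_a), list(group_b)
    _check_samples(matrix, group_a + group_b)
    if len(matrix) < 10:
        raise InputError("need >= 10 probesets for meaningful variance quantiles")
    var = pooled_within_group_variance(matrix, group_a, group_b)
    if var.nunique() == 1:
        log.warning("all pooled variances equal; variance filter excludes nothing")
        return set()
    lo, hi = np.quantile(var.to_numpy(), [low_q, high_q])
    excluded = (var < lo) | (var > hi)
    return set(var.index[excluded])


def collapse_probesets(results: pd.DataFrame, gene_map: pd.DataFrame,
                       policy: str = "min_q") -> pd.DataFrame:
    """Collapse probeset-level test results to one representative per gene.

    With the default ``min_q`` policy the representative probeset is the one
    with the smallest BH q in the comparison; ties break toward the larger
    |log2fc|, then the lexicographically smaller probeset id. Probesets
    missing from the map are retained under their own id with
    ``unmapped=True``.

    ``results`` must carry columns probeset_id, log2fc, q_bh.
    """
    if policy != "min_q":
        raise ValueError(f"unknown collapse policy: {policy}")
    mapping = gene_map.set_index("probeset_id")["gene_id"]
    df = results.copy()
    df["gene_id"] = df["probeset_id"].map(mapping)
    df["unmapped"] = df["gene_id"].isna()
    df.loc[df["unmapped"], "gene_id"] = df.loc[df["unmapped"], "probeset_id"]
    df = df.sort_values(
        by=["q_bh", "log2fc", "probeset_id"],
        ascending=[True, True, True],
        key=lambda s: -s.abs() if s.name == "log2fc" else s,
    )
    out = df.drop_duplicates("gene_id", keep="first").reset_index(drop=True)
    cols = ["gene_id"] + [c for c in out.columns if c != "gene_id"]
    return out[cols]
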