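"""Two-group equal-variance t-tests with BH adjustment for the six defined
comparisons, emitting ternary up/down/ns statuses per probeset.

Comparisons
-----------
C0.5, C2, C24, C72
    bent-once vs. control at each harvest time; log2 fold-change is
    bent − control.
2Bvs1B24
    bent-twice (0.5 h after the second bending) vs. bent-once at 24 h —
    the second-bending response against its immediate pre-bending baseline.
2Bvs1B0.5
    bent-twice vs. bent-once at 0.5 h — whether the amplitude of the second
    response differs from the first.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import preprocess

log = logging.getLogger(__name__)

ALPHA = 0.05

#: comparison_id -> ((treatment, time_h) of group A, of group B); the
#: reported log2 fold-change is mean(B) − mean(A)
COMPARISONS = {
    "C0.5": (("control", 0.5), ("bent_once", 0.5)),
    "C2": (("control", 2.0), ("bent_once", 2.0)),
    "C24": (("control", 24.0), ("bent_once", 24.0)),
    "C72": (("control", 72.0), ("bent_once", 72.0)),
    "2Bvs1B24": (("bent_once", 24.0), ("bent_twice", 0.5)),
    "2Bvs1B0.5": (("bent_once", 0.5), ("bent_twice", 0.5)),
}

TIME_COMPARISONS = ("C0.5", "C2", "C24", "C72")


class InputError(ValueError):
    pass


def ttest_rows(a: np.ndarray, b: np.ndarray):
    """Vectorized pooled-variance two-sided t-test over matrix rows.

    Returns (delta, t, df, p) with delta = rowmean(b) − rowmean(a).
    Degenerate rows (pooled variance 0): equal means give t = 0, p = 1;
    unequal means give p = 0 (perfect separation, flagged by the caller).
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise InputError("each group needs >= 2 values")
    df = na + nb - 2
    delta = b.mean(axis=1) - a.mean(axis=1)
    ssa = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssb = ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled = (ssa + ssb) / df
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_se = se == 0.0
    if np.any(zero_se):
        same = zero_se & (delta == 0.0)
        sep = zero_se & (delta != 0.0)
        t[same], p[same] = 0.0, 1.0
        t[sep] = np.sign(delta[sep]) * np.inf
        p[sep] = 0.0
        if np.any(sep):
            log.warning("%d probeset(s) with zero pooled variance and unequal "
                        "means: p set to 0", int(sep.sum()))
    return delta, t, df, p


def two_group_ttest(group_a, group_b):
    """Scalar convenience wrapper: (log2fc, t, df, p) for two value vectors."""
    delta, t, df, p = ttest_rows(np.asarray(group_a)[None, :],
                                 np.asarray(group_b)[None, :])
    return float(delta[0]), float(t[0]), int(df), float(p[0])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ComparisonSet:
    """Per-comparison probeset statistics plus the filter bookkeeping."""

    results: dict = field(default_factory=dict)     # comparison_id -> DataFrame
    filter_reports: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)
    alpha: float = ALPHA

    def deg_ids(self, comparison_id: str) -> set:
        df = self.results[comparison_id]
        return set(df.loc[df["status"] != 0, "probeset_id"])


def comparison_groups(design: pd.DataFrame, comparison_id: str):
    """Sample-id lists (group A, group B) for a named comparison."""
    if comparison_id not in COMPARISONS:
        raise InputError(f"unknown comparison: {comparison_id}")
    (ta, ha), (tb, hb) = COMPARISONS[comparison_id]
    sel_a = design.loc[(design.treatment == ta) & (design.time_h == ha), "sample_id"]
    sel_b = design.loc[(design.treatment == tb) & (design.time_h == hb), "sample_id"]
    return sel_a.tolist(), sel_b.tolist()


def run_comparisons(matrix: pd.DataFrame, design: pd.DataFrame,
                    alpha: float = ALPHA,
                    variance_quantiles: tuple = (0.001, 0.999),
                    apply_variance_filter: bool = True) -> ComparisonSet:
    """Run all six comparisons with per-comparison filtering and BH.

    For each comparison: drop probesets unexpressed in both groups (all
    intensities < 4), drop extreme-variance probesets, test the rest with the
    pooled-variance t-test, adjust within the comparison by BH, and call
    status +1/−1/0 at the given alpha.
    """
    out = ComparisonSet(alpha=alpha)
    for cid in COMPARISONS:
        ga, gb = comparison_groups(design, cid)
        if len(ga) < 2 or len(gb) < 2:
            out.errors[cid] = (f"comparison {cid} needs >= 2 replicates per "
                               f"group (got {len(ga)} vs {len(gb)})")
            continue
        unexpressed = preprocess.filter_unexpressed(matrix, ga, gb)
        kept = matrix.drop(index=unexpressed)
        removed_var: set = set()
        if apply_variance_filter and len(kept) >= 10:
            removed_var = preprocess.filter_extreme_variance(
                kept, ga, gb, *variance_quantiles)
            kept = kept.drop(index=removed_var)
        out.filter_reports[cid] = {
            "removed_unexpressed": unexpressed,
            "removed_variance": removed_var,
        }
        delta, t, df, p = ttest_rows(kept[ga].to_numpy(), kept[gb].to_numpy())
        q = bh_adjust(p)
        status = np.where(q < alpha, np.sign(delta).astype(int), 0)
        out.results[cid] = pd.DataFrame({
            "probeset_id": kept.index,
            "log2fc": delta,
            "t": t,
            "df": df,
            "p_raw": p,
            "q_bh": q,
            "status": status,
        }).reset_index(drop=True)
    return out


def collapse_comparison_set(cset: ComparisonSet,
                            gene_map: pd.DataFrame) -> ComparisonSet:
    """Gene-level view of a probeset-level ComparisonSet (min-q policy)."""
    out = ComparisonSet(alpha=cset.alpha, errors=dict(cset.errors),
                        filter_reports=dict(cset.filter_reports))
    for cid, df in cset.results.items():
        out.results[cid] = preprocess.collapse_probesets(df, gene_map)
    return out


def deg_union(cset: ComparisonSet) -> pd.DataFrame:
    """Genes (or probesets) significant in at least one comparison, with one
    log2fc/status column pair per comparison."""
    key = "gene_id" if all("gene_id" in df.columns
                           for df in cset.results.values()) else "probeset_id"
    pieces = []
    for cid, df in cset.results.items():
        sub = df.set_index(key)[["log2fc", "status"]]
        sub.columns = [f"log2fc_{cid}", f"status_{cid}"]
        pieces.append(sub)
    wide = pd.concat(pieces, axis=1).fillna({c: 0 for p in pieces for c in p.columns})
    status_cols = [c for c in wide.columns if c.startswith("status_")]
    wide[status_cols] = wide[status_cols].astype(int)
    return wide[(wide[status_cols] != 0).any(axis=1)].reset_index(names=key)
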