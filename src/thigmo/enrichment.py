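"""Per-cluster term enrichment via a one-sided hypergeometric test.

Given a flat gene→term annotation map and a background universe, the
probability of observing at least k annotated genes in a cluster of size n,
when K of the N background genes carry the term, is the hypergeometric
upper tail P(X >= k). No ontology-graph propagation is performed: the
annotation map is taken as-is (term hierarchy resolution, if wanted, must
happen upstream).
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust


class InputError(ValueError):
    pass


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K successes, n draws)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def load_annotation(gene_term_pairs) -> dict:
    """gene→set-of-terms from an iterable of (gene_id, term_id) pairs or a
    two-column DataFrame."""
    if isinstance(gene_term_pairs, pd.DataFrame):
        gene_term_pairs = gene_term_pairs.iloc[:, :2].itertuples(index=False)
    ann: dict = {}
    for gene, term in gene_term_pairs:
        ann.setdefault(gene, set()).add(term)
    return ann


def enrich_cluster(cluster_genes, annotation: dict, background=None,
                   p_max: float = 0.05, cluster_id=None) -> pd.DataFrame:
    """Terms over-represented in a cluster against the background universe.

    ``annotation`` maps gene_id → set of term ids; ``background`` defaults
    to every annotated gene. Terms present in the cluster (k >= 1) are
    tested one-sided; rows with p < ``p_max`` are returned sorted by p
    ascending, with BH q computed over all tested terms alongside.
    """
    if background is None:
        background = set(annotation)
    background = set(background)
    cluster_genes = list(dict.fromkeys(cluster_genes))
    strays = [g for g in cluster_genes if g not in background]
    if strays:
        raise InputError(f"genes absent from background: {sorted(strays)}")
    if not cluster_genes:
        return pd.DataFrame(columns=["cluster_id", "term_id", "k", "n", "K",
                                     "N", "p_hyper", "q_bh"])
    N, n = len(background), len(cluster_genes)
    term_in_cluster: dict = {}
    for g in cluster_genes:
        for t in annotation.get(g, ()):
            term_in_cluster[t] = term_in_cluster.get(t, 0) + 1
    term_in_bg = {t: 0 for t in term_in_cluster}
    for g in background:
        for t in annotation.get(g, ()):
            if t in term_in_bg:
                term_in_bg[t] += 1
    rows = []
    for t in sorted(term_in_cluster):
        k, K = term_in_cluster[t], term_in_bg[t]
        rows.append((cluster_id, t, k, n, K, N,
                     hypergeom_upper_tail(k, N, K, n)))
    df = pd.DataFrame(rows, columns=["cluster_id", "term_id", "k", "n",
                                     "K", "N", "p_hyper"])
    df["q_bh"] = bh_adjust(df["p_hyper"].to_numpy()) if len(df) else []
    df = df[df["p_hyper"] < p_max]
    return df.sort_values(["p_hyper", "term_id"]).reset_index(drop=True)


def enrich_all_clusters(assignment: pd.DataFrame, annotation: dict,
                        background=None, p_max: float = 0.05) -> pd.DataFrame:
    """Run enrich_cluster for every cluster in an assignment table; genes
    without annotation are ignored (they cannot contribute a term)."""
    if background is None:
        background = set(annotation)
    out = []
    for cl, sub in assignment.groupby("cluster"):
        genes = [g for g in sub.index if g in background]
        out.append(enrich_cluster(genes, annotation, background,
                                  p_max=p_max, cluster_id=cl))
    if not out:
        return pd.DataFrame(columns=["cluster_id", "term_id", "k", "n", "K",
                                     "N", "p_hyper", "q_bh"])
    return pd.concat(out, ignore_index=True)
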