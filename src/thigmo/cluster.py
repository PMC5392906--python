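"""Three-block feature encoding of expression trajectories and Euclidean
k-means partitioning of differentially expressed genes.

Each gene's feature vector concatenates, unweighted:

* 5 velocities — per-interval rates of change of the log2 fold-change
  profile over the padded time grid {0, 0.5, 2, 24, 72, 120} h (the 0 h and
  120 h endpoints carry fold-change 0), in log2FC·h⁻¹;
* 4 sign grades — the ternary significance status (−1/0/+1) at the four
  measured time-points;
* 1 accommodation delta — second-bending log2 ratio minus first-bending
  log2 ratio, grouping genes by their behaviour toward a repeated stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

PADDED_TIMES = (0.0, 0.5, 2.0, 24.0, 72.0, 120.0)
MEASURED_TIMES = (0.5, 2.0, 24.0, 72.0)


class InputError(ValueError):
    pass


@dataclass
class GeneProfile:
    """Gene-level summary feeding the feature encoder.

    ``a_t``: log2 fold-change bent vs. control per measured time;
    ``s_t``: ternary significance status per measured time;
    ``r_1b``: log2 ratio 0.5 h after one bending;
    ``r_2b``: log2 ratio 0.5 h after the second bending vs. 24 h after the
    first. Untested comparisons contribute 0.
    """

    gene_id: str
    a_t: dict = field(default_factory=dict)
    s_t: dict = field(default_factory=dict)
    r_1b: float = 0.0
    r_2b: float = 0.0


def velocity_features(profile: GeneProfile, form: str = "difference") -> np.ndarray:
    """Rates of change over consecutive padded intervals.

    ``difference`` is the physical difference quotient (a_{t+1} − a_t)/Δt;
    ``sum_printed`` preserves the historically printed (a_{t+1} + a_t)/Δt
    variant for faithfulness comparisons.
    """
    if form not in ("difference", "sum_printed"):
        raise InputError(f"unknown velocity form: {form}")
    a = [0.0] + [float(profile.a_t.get(t, 0.0)) for t in MEASURED_TIMES] + [0.0]
    v = []
    for i in range(len(PADDED_TIMES) - 1):
        dt = PADDED_TIMES[i + 1] - PADDED_TIMES[i]
        if dt == 0:
            raise InputError("zero-length interval")
        num = a[i + 1] - a[i] if form == "difference" else a[i + 1] + a[i]
        v.append(num / dt)
    return np.array(v)


def sign_grade_features(profile: GeneProfile) -> np.ndarray:
    """Ternary significance grades at 0.5, 2, 24 and 72 h."""
    missing = [t for t in MEASURED_TIMES if t not in profile.s_t]
    if missing:
        raise InputError(f"missing status for time(s): {missing}")
    return np.array([float(profile.s_t[t]) for t in MEASURED_TIMES])


def accommodation_delta(profile: GeneProfile) -> float:
    """Second-bending ratio minus first-bending ratio (log2 units)."""
    return float(profile.r_2b) - float(profile.r_1b)


def feature_vector(profile: GeneProfile, velocity_form: str = "difference") -> np.ndarray:
    return np.concatenate([
        velocity_features(profile, velocity_form),
        sign_grade_features(profile),
        [accommodation_delta(profile)],
    ])


def profiles_from_comparisons(cset, gene_ids=None,
                              key: str = "gene_id") -> list[GeneProfile]:
    """Build GeneProfiles from a gene-level ComparisonSet.

    Genes filtered out of (untested in) a comparison contribute fold-change
    and status 0 there, consistent with the zero-padded endpoints.
    """
    time_map = {"C0.5": 0.5, "C2": 2.0, "C24": 24.0, "C72": 72.0}
    tables = {cid: df.set_index(key) for cid, df in cset.results.items()}
    if gene_ids is None:
        gene_ids = sorted(set().union(*(t.index for t in tables.values())))
    profiles = []
    for g in gene_ids:
        a_t, s_t = {}, {}
        for cid, t in time_map.items():
            if cid in tables and g in tables[cid].index:
                a_t[t] = float(tables[cid].at[g, "log2fc"])
                s_t[t] = int(tables[cid].at[g, "status"])
            else:
                a_t[t], s_t[t] = 0.0, 0
        r_2b = 0.0
        if "2Bvs1B24" in tables and g in tables["2Bvs1B24"].index:
            r_2b = float(tables["2Bvs1B24"].at[g, "log2fc"])
        profiles.append(GeneProfile(gene_id=g, a_t=a_t, s_t=s_t,
                                    r_1b=a_t[0.5], r_2b=r_2b))
    return profiles


def feature_matrix(profiles, velocity_form: str = "difference") -> pd.DataFrame:
    cols = ([f"v{i}" for i in range(1, 6)]
            + [f"s{t:g}h" for t in MEASURED_TIMES] + ["d_acc"])
    rows = [feature_vector(p, velocity_form) for p in profiles]
    return pd.DataFrame(rows, index=[p.gene_id for p in profiles], columns=cols)


def euclidean_distance(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise InputError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.sqrt(((x - y) ** 2).sum()))


def _wcss(points: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    return float(((points - centers[labels]) ** 2).sum())


def _lloyd(points: np.ndarray, centers: np.ndarray, max_iter: int = 300):
    """Lloyd iterations; asserts the WCSS objective never increases."""
    n, k = len(points), len(centers)
    prev = np.inf
    for _ in range(max_iter):
        d2 = cdist(points, centers, "sqeuclidean")
        labels = d2.argmin(axis=1)
        for j in range(k):
            mask = labels == j
            if not mask.any():
                # re-seed an empty cluster from the farthest point
                far = d2.min(axis=1).argmax()
                centers[j] = points[far]
                labels[far] = j
                mask = labels == j
            centers[j] = points[mask].mean(axis=0)
        cur = _wcss(points, labels, centers)
        assert cur <= prev + 1e-9, "k-means objective increased"
        if prev - cur <= 1e-12:
            break
        prev = cur
    return labels, centers, cur


def kmeans_cluster(features, k: int = 35, restarts: int = 25,
                   seed: int | None = None, max_iter: int = 300):
    """Euclidean k-means, best of ``restarts`` random initializations.

    Initialization draws k distinct data points uniformly. Input order does
    not affect the result for a fixed seed: rows are canonically ordered by
    index label before initialization. Returns a DataFrame (index as input)
    with a ``cluster`` column, plus the winning centers and WCSS.
    """
    if isinstance(features, pd.DataFrame):
        order = np.argsort(features.index.to_numpy(), kind="stable")
        index = features.index.to_numpy()[order]
        points = features.to_numpy(float)[order]
    else:
        points = np.asarray(features, float)
        index = np.arange(len(points))
    if not np.isfinite(points).all():
        raise InputError("non-finite feature values")
    n = len(points)
    if n < k:
        raise InputError(f"cannot form {k} clusters from {n} points")
    rng = np.random.default_rng(seed)
    if comb(n, k) <= restarts:
        # tiny problem: enumerate every distinct data-point initialization
        inits = (np.array(c) for c in combinations(range(n), k))
    else:
        inits = (rng.choice(n, size=k, replace=False) for _ in range(restarts))
    best = None
    for idx in inits:
        labels, centers, wcss = _lloyd(points, points[idx].copy(), max_iter)
        if best is None or wcss < best[2]:
            best = (labels, centers, wcss)
    labels, centers, wcss = best
    assignment = pd.DataFrame({"cluster": labels}, index=index).sort_index()
    return assignment, centers, wcss


def select_representative(cluster_genes, features: pd.DataFrame,
                          keep_only=None) -> str:
    """Gene closest (Euclidean) to the per-coordinate median of its cluster.

    ``keep_only`` optionally restricts candidates (e.g. to genes whose
    annotation matches the cluster's enriched function); the distance
    criterion is unchanged.
    """
    genes = list(cluster_genes)
    if not genes:
        raise InputError("empty cluster")
    sub = features.loc[genes]
    median = sub.median(axis=0).to_numpy()
    candidates = [g for g in genes if keep_only is None or g in set(keep_only)]
    if not candidates:
        candidates = genes
    dists = {g: euclidean_distance(sub.loc[g].to_numpy(), median)
             for g in candidates}
    return min(sorted(dists), key=dists.get)


def cluster_summaries(assignment: pd.DataFrame, profiles) -> pd.DataFrame:
    """Per-cluster, per-time quartiles of log2 fold-change (boxplot data)."""
    prof = {p.gene_id: p for p in profiles}
    rows = []
    for cl, sub in assignment.groupby("cluster"):
        for t in MEASURED_TIMES:
            vals = np.array([prof[g].a_t[t] for g in sub.index if g in prof])
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append((cl, t, len(vals), vals.min(), q1, med, q3, vals.max()))
    return pd.DataFrame(rows, columns=["cluster", "time_h", "n", "min",
                                       "q1", "median", "q3", "max"])
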