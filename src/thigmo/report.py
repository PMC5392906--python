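"""Pipeline orchestration, Venn-style overlap counts and serialization."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import accommodation, cluster, diffexpr, enrichment, simulate

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "diffexpr", "features_clustering",
          "accommodation", "enrichment")


class InputError(ValueError):
    pass


def venn_counts(cset: diffexpr.ComparisonSet) -> pd.DataFrame:
    """Exclusive-region counts for the four time-point DEG sets.

    One row per non-empty combination of {C0.5, C2, C24, C72} (15 regions),
    counting genes significant in exactly that combination, plus per-time
    up/down tallies appended as single-comparison summary rows.
    """
    missing = [c for c in diffexpr.TIME_COMPARISONS if c not in cset.results]
    if missing:
        raise InputError(f"missing comparison(s): {missing}")
    sets = {c: cset.deg_ids(c) for c in diffexpr.TIME_COMPARISONS}
    rows = []
    for r in range(1, 5):
        for combo in combinations(diffexpr.TIME_COMPARISONS, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(*(sets[c] for c in diffexpr.TIME_COMPARISONS
                                  if c not in combo)) if r < 4 else set()
            rows.append(("+".join(combo), len(inside - outside)))
    venn = pd.DataFrame(rows, columns=["region", "count"])
    tallies = []
    for c in diffexpr.TIME_COMPARISONS:
        df = cset.results[c]
        tallies.append((c, int((df["status"] == 1).sum()),
                        int((df["status"] == -1).sum())))
    updown = pd.DataFrame(tallies, columns=["comparison", "n_up", "n_down"])
    return venn, updown


@dataclass
class PipelineConfig:
    """End-to-end run settings; one master seed drives every stage."""

    outdir: str = "thigmo_run"
    seed: int = 0
    alpha: float = diffexpr.ALPHA
    k: int = 35
    restarts: int = 25
    velocity_form: str = "difference"
    variance_quantiles: tuple = (0.001, 0.999)
    enrichment_p_max: float = 0.05
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    # paths for user-supplied data; None means simulate
    expression_path: str | None = None
    design_path: str | None = None
    gene_map_path: str | None = None
    annotation_path: str | None = None


def _stage_seed(master: int, stage: str) -> int:
    """Stable per-stage seed derived from the master seed (< 2^31)."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def run_pipeline(config: PipelineConfig) -> Path:
    """Simulate (or load) → filter/test → cluster → classify → enrich.

    Writes all result tables as TSV plus a JSON manifest into
    ``config.outdir``; identical config + seed gives byte-identical tables.
    On stage failure, partial outputs are kept next to a FAILED marker file
    naming the stage, and the exception propagates.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages_done = []
    stage = "simulate"
    try:
        if config.expression_path is None:
            simcfg = simulate.SimConfig(**{
                **asdict(config.sim),
                "seed": _stage_seed(config.seed, "simulate"),
            })
            matrix, design, truth, gene_map = simulate.simulate_dataset(simcfg)
            simulate.write_dataset(out, matrix, design, truth, gene_map)
        else:
            for name, path in (("expression", config.expression_path),
                               ("design", config.design_path),
                               ("gene map", config.gene_map_path)):
                if path is None or not Path(path).exists():
                    raise InputError(f"{name} table not found: {path}")
            matrix = pd.read_csv(config.expression_path, sep="\t", index_col=0)
            design = pd.read_csv(config.design_path, sep="\t")
            gene_map = pd.read_csv(config.gene_map_path, sep="\t")
        stages_done.append(stage)

        stage = "preprocess"   # filters run inside run_comparisons
        stage = "diffexpr"
        cset = diffexpr.run_comparisons(
            matrix, design, alpha=config.alpha,
            variance_quantiles=config.variance_quantiles)
        gset = diffexpr.collapse_comparison_set(cset, gene_map)
        for cid, df in gset.results.items():
            df.to_csv(out / f"comparison_{cid.replace('.', '_')}.tsv",
                      sep="\t", index=False)
        union = diffexpr.deg_union(gset)
        union.to_csv(out / "deg_union.tsv", sep="\t", index=False)
        venn, updown = venn_counts(gset)
        venn.to_csv(out / "venn_regions.tsv", sep="\t", index=False)
        updown.to_csv(out / "deg_updown.tsv", sep="\t", index=False)
        stages_done.extend(["preprocess", "diffexpr"])

        stage = "features_clustering"
        deg_genes = union["gene_id"].tolist()
        profiles = cluster.profiles_from_comparisons(gset, deg_genes)
        feats = cluster.feature_matrix(profiles, config.velocity_form)
        k = min(config.k, max(1, len(feats)))
        assignment, centers, wcss = cluster.kmeans_cluster(
            feats, k=k, restarts=config.restarts,
            seed=_stage_seed(config.seed, "kmeans"))
        assignment.to_csv(out / "clusters.tsv", sep="\t",
                          index_label="gene_id")
        cluster.cluster_summaries(assignment, profiles).to_csv(
            out / "cluster_boxplot_data.tsv", sep="\t", index=False)
        medians = feats.groupby(assignment["cluster"]).median()
        medians.to_csv(out / "cluster_median_features.tsv", sep="\t")
        reps = pd.DataFrame(
            [(cl, cluster.select_representative(sub.index, feats))
             for cl, sub in assignment.groupby("cluster")],
            columns=["cluster", "representative_gene"])
        reps.to_csv(out / "cluster_representatives.tsv", sep="\t", index=False)
        stages_done.append(stage)

        stage = "accommodation"
        calls = accommodation.classify_all(gset)
        calls.to_csv(out / "accommodation_calls.tsv", sep="\t", index=False)
        summary = accommodation.summarize_accommodation(calls)
        (out / "accommodation_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
        stages_done.append(stage)

        stage = "enrichment"
        if config.annotation_path is not None:
            if not Path(config.annotation_path).exists():
                raise InputError(
                    f"annotation table not found: {config.annotation_path}")
            ann = enrichment.load_annotation(
                pd.read_csv(config.annotation_path, sep="\t"))
            enrichment.enrich_all_clusters(
                assignment, ann, p_max=config.enrichment_p_max).to_csv(
                out / "enrichment.tsv", sep="\t", index=False)
        stages_done.append(stage)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise

    cfg = asdict(config)
    cfg.pop("outdir")  # run location must not affect the manifest hash
    cfg["variance_quantiles"] = list(config.variance_quantiles)
    manifest = {
        "stages": stages_done,
        "seed": config.seed,
        "stage_seeds": {s: _stage_seed(config.seed, s)
                        for s in ("simulate", "kmeans")},
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "kmeans_wcss": float(wcss),
        "n_deg_union": int(len(union)),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return out
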