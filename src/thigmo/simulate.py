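"""Synthetic stem-bending transcriptome generator with planted ground truth.

Emulates the structure of a two-treatment bending experiment on young poplar
stems: normalized log2 intensities for bent vs. control plants harvested 0.5,
2, 24 and 72 h after a transient bending, plus a twice-bent condition
harvested 0.5 h after a second bending applied 24 h after the first. Every
gene carries a planted response archetype (its log2 fold-change trajectory)
and an accommodation class (how its response to the second bending compares
with its response to the first), so downstream statistics, clustering and
classification can be scored against known truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

TIME_POINTS = (0.5, 2.0, 24.0, 72.0)

ARCHETYPES = (
    "early_transient_up",
    "early_up_sustained",
    "early_down",
    "late_up_72h",
    "down_then_up",
    "flat",
)

ACCOMMODATION_CLASSES = (
    "accommodated_null",
    "accommodated_reduced",
    "non_accommodated",
    "newly_regulated",
    "not_applicable",
)

# log2 fold-change trajectory per archetype, as multiples of the per-gene
# effect magnitude E > 0, at 0.5 / 2 / 24 / 72 h post-bending.
_ARCHETYPE_SHAPES = {
    "early_transient_up": (1.0, 0.5, 0.0, 0.0),
    "early_up_sustained": (1.0, 1.0, 0.75, 0.0),
    "early_down": (-1.0, -0.5, 0.0, 0.0),
    "late_up_72h": (0.0, 0.0, 0.0, 1.0),
    "down_then_up": (-1.0, 0.0, 0.0, 1.0),
    "flat": (0.0, 0.0, 0.0, 0.0),
}


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimConfig:
    """Stated world for the generator.

    Fractions mirror the proportions the source experiment reported: most
    first-bending responders are fully accommodated, a minority keep a
    reduced response, and a few percent respond identically to both
    bendings. Effect magnitudes are drawn uniformly from
    [effect_min, effect_max] log2 units per responsive gene.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    archetype_fractions: dict = field(default_factory=lambda: {
        "early_transient_up": 0.30,
        "early_up_sustained": 0.05,
        "early_down": 0.15,
        "late_up_72h": 0.10,
        "down_then_up": 0.05,
        "flat": 0.35,
    })
    # conditional on the gene responding 0.5 h after the first bending
    accommodation_fractions: dict = field(default_factory=lambda: {
        "accommodated_null": 0.86,
        "accommodated_reduced": 0.10,
        "non_accommodated": 0.04,
    })
    # probability that a gene with no 0.5 h response is newly regulated
    newly_regulated_fraction: float = 0.05
    effect_min: float = 2.0
    effect_max: float = 4.0
    reduced_factor: float = 0.4    # second/first response ratio when reduced
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    noise_sd: float = 0.2          # log2 units, per replicate measurement
    noise_df: float | None = None  # Student-t df for heavier tails; None = Gaussian
    low_intensity_fraction: float = 0.10
    low_intensity_mean: float = 2.5
    low_intensity_sd: float = 0.3
    multi_probeset_fraction: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise ConfigError(f"n_replicates must be >= 2, got {self.n_replicates}")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        for name, fracs, keys in (
            ("archetype_fractions", self.archetype_fractions, ARCHETYPES),
            ("accommodation_fractions", self.accommodation_fractions,
             ("accommodated_null", "accommodated_reduced", "non_accommodated")),
        ):
            if set(fracs) - set(keys):
                raise ConfigError(f"unknown keys in {name}: {set(fracs) - set(keys)}")
            total = sum(fracs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1, got {total}")
        for p in (self.newly_regulated_fraction, self.low_intensity_fraction,
                  self.multi_probeset_fraction):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("fractions must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def generate_design(config: SimConfig) -> pd.DataFrame:
    """Sample sheet: control + bent-once at all four times, bent-twice at 0.5 h.

    `time_h` is hours after the most recent bending. Deterministic.
    """
    config.validate()
    rows = []
    for treatment in ("control", "bent_once"):
        for t in TIME_POINTS:
            for rep in range(1, config.n_replicates + 1):
                rows.append((f"{treatment}_{t:g}h_r{rep}", treatment, t, rep))
    for rep in range(1, config.n_replicates + 1):
        rows.append((f"bent_twice_0.5h_r{rep}", "bent_twice", 0.5, rep))
    return pd.DataFrame(rows, columns=["sample_id", "treatment", "time_h", "replicate"])


def _plant_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(n)])

    arch_names = list(config.archetype_fractions)
    archetypes = rng.choice(arch_names, size=n,
                            p=[config.archetype_fractions[a] for a in arch_names])

    low = rng.random(n) < config.low_intensity_fraction
    # low-intensity genes are the unexpressed subpopulation: no planted signal
    archetypes[low] = "flat"

    magnitude = rng.uniform(config.effect_min, config.effect_max, size=n)
    shapes = np.array([_ARCHETYPE_SHAPES[a] for a in archetypes])
    effects = shapes * magnitude[:, None]  # n x 4, log2 units

    responds_first = effects[:, 0] != 0.0
    classes = np.full(n, "not_applicable", dtype=object)
    acc_names = list(config.accommodation_fractions)
    acc_probs = [config.accommodation_fractions[a] for a in acc_names]
    idx_resp = np.flatnonzero(responds_first)
    classes[idx_resp] = rng.choice(acc_names, size=idx_resp.size, p=acc_probs)
    # genes still responding at 24 h carry a shifted baseline when the second
    # bending is applied; plant them only as fully accommodated or
    # non-accommodated so the planted class is recoverable from the tests
    sustained = responds_first & (effects[:, 2] != 0.0)
    reclass = sustained & (classes == "accommodated_reduced")
    classes[reclass] = "accommodated_null"

    idx_quiet = np.flatnonzero(~responds_first & ~low)
    newly = idx_quiet[rng.random(idx_quiet.size) < config.newly_regulated_fraction]
    classes[newly] = "newly_regulated"

    second = np.zeros(n)
    second[classes == "non_accommodated"] = effects[classes == "non_accommodated", 0]
    mask = classes == "accommodated_reduced"
    second[mask] = config.reduced_factor * effects[mask, 0]
    mask = classes == "newly_regulated"
    second[mask] = rng.uniform(config.effect_min, config.effect_max, size=mask.sum())

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    baseline[low] = rng.normal(config.low_intensity_mean, config.low_intensity_sd,
                               size=low.sum())

    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "archetype": archetypes,
        "accommodation_class": classes,
        "baseline_log2": baseline,
        "low_intensity": low,
        "second_bending_effect": second,
    })
    for j, t in enumerate(TIME_POINTS):
        truth[f"effect_{t:g}h"] = effects[:, j]
    return truth


def simulate_dataset(config: SimConfig):
    """Generate (expression matrix, design, truth table, probeset→gene map).

    Matrix entries are baseline + planted treatment effect + replicate noise
    on the log2 scale. A fraction of genes receives a second probeset with an
    independent noise draw to exercise probeset collapsing. Bit-identical for
    equal configs (all randomness flows from ``config.seed``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = generate_design(config)
    truth = _plant_truth(config, rng)
    n = config.n_genes

    effects = truth[[f"effect_{t:g}h" for t in TIME_POINTS]].to_numpy()
    t_index = {t: j for j, t in enumerate(TIME_POINTS)}

    # true mean log2 intensity per gene per sample
    mean = np.empty((n, len(design)))
    for s, row in enumerate(design.itertuples(index=False)):
        if row.treatment == "control":
            mean[:, s] = truth["baseline_log2"]
        elif row.treatment == "bent_once":
            mean[:, s] = truth["baseline_log2"] + effects[:, t_index[row.time_h]]
        else:  # bent_twice, harvested 0.5 h after the 2nd bending = 24.5 h
            # after the first: baseline is the 24 h post-first-bending state
            mean[:, s] = (truth["baseline_log2"] + effects[:, t_index[24.0]]
                          + truth["second_bending_effect"].to_numpy())

    # second probesets for a fraction of genes (independent noise, same truth)
    extra = np.flatnonzero(rng.random(n) < config.multi_probeset_fraction)
    probeset_ids = [f"{g}_ps1" for g in truth["gene_id"]]
    probeset_ids += [f"{truth['gene_id'].iloc[i]}_ps2" for i in extra]
    true_rows = np.vstack([mean, mean[extra]])

    if config.noise_df is not None:
        noise = rng.standard_t(config.noise_df, size=true_rows.shape) * config.noise_sd
    else:
        noise = rng.normal(0.0, config.noise_sd, size=true_rows.shape) \
            if config.noise_sd > 0 else 0.0
    values = true_rows + noise

    # keep the unexpressed subpopulation strictly under the intensity filter
    low_rows = np.concatenate([truth["low_intensity"].to_numpy(),
                               truth["low_intensity"].to_numpy()[extra]])
    values[low_rows] = np.minimum(values[low_rows], 3.95)

    matrix = pd.DataFrame(values, index=pd.Index(probeset_ids, name="probeset_id"),
                          columns=design["sample_id"].tolist())
    gene_map = pd.DataFrame({
        "probeset_id": probeset_ids,
        "gene_id": [p.rsplit("_ps", 1)[0] for p in probeset_ids],
    })
    truth = truth.drop(columns=["baseline_log2"])
    return matrix, design, truth, gene_map


def write_dataset(outdir, matrix, design, truth, gene_map) -> None:
    """Serialize all four tables as TSV under ``outdir``."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(out / "expression_matrix.tsv", sep="\t")
    design.to_csv(out / "design.tsv", sep="\t", index=False)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    gene_map.to_csv(out / "probeset_gene_map.tsv", sep="\t", index=False)
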