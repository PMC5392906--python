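import pytest

from thigmo import diffexpr, simulate


@pytest.fixture(scope="session")
def small_dataset():
    """2,000-gene dataset at the default stated world (noise_sd 0.2)."""
    cfg = simulate.SimConfig(n_genes=2000, seed=0)
    matrix, design, truth, gene_map = simulate.simulate_dataset(cfg)
    return cfg, matrix, design, truth, gene_map


@pytest.fixture(scope="session")
def zero_noise_dataset():
    """Noise-free dataset: planted effects are exactly recoverable."""
    cfg = simulate.SimConfig(n_genes=400, seed=7, noise_sd=0.0)
    matrix, design, truth, gene_map = simulate.simulate_dataset(cfg)
    return cfg, matrix, design, truth, gene_map


@pytest.fixture(scope="session")
def small_comparisons(small_dataset):
    """Gene-level comparison set for the 2,000-gene dataset."""
    _, matrix, design, _, gene_map = small_dataset
    cset = diffexpr.run_comparisons(matrix, design)
    return diffexpr.collapse_comparison_set(cset, gene_map)
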