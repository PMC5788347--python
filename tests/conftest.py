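import numpy as np
import pytest

from scqpcr import AssayPanel, ChipConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_config():
    """A small chip (2 subarrays x 8 units) for fast end-to-end runs."""
    return ChipConfig(n_subarrays=2, units_per_subarray=8, seed=7)


@pytest.fixture
def mrna_config():
    """One-step mRNA workflow settings: 12 pre-amplification cycles."""
    return ChipConfig(n_subarrays=2, units_per_subarray=8, preamp_cycles=12, seed=11)


@pytest.fixture
def two_gene_panel():
    return AssayPanel(
        gene_names=["gene_a", "gene_b"],
        mean_copies=[200.0, 50.0],
        lognormal_cv=0.5,
    )


def two_population_matrix(
    n_per_pop=60,
    n_genes=10,
    n_shifted=5,
    fold=4.0,
    cv=0.5,
    seed=0,
    correlation=None,
):
    """Cells x genes copy matrix with two populations and known shifts.

    Base abundances span ~2.5 decades (as real panels do); the first
    ``n_shifted`` genes differ between the populations, reciprocally: some
    up by ``fold``, the rest strongly down, emulating the mutually biased
    marker expression of two distinct cell types.
    """
    from scqpcr import ExpressionMatrix, simulate_cell_population
    import pandas as pd

    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    base = np.logspace(1.0, 3.5, n_genes)
    shifted = base.copy()
    n_up = (n_shifted + 1) // 2
    shifted[:n_up] *= fold
    shifted[n_up:n_shifted] /= 2 * fold
    pa = AssayPanel(genes, mean_copies=base, lognormal_cv=cv, correlation=correlation)
    pb = AssayPanel(genes, mean_copies=shifted, lognormal_cv=cv, correlation=correlation)
    ta = simulate_cell_population(pa, n_per_pop, population="A", rng=rng)
    tb = simulate_cell_population(pb, n_per_pop, population="B", rng=rng)
    copies = np.vstack([ta.counts, tb.counts]).astype(float)
    labels = ["A"] * n_per_pop + ["B"] * n_per_pop
    df = pd.DataFrame(copies, columns=genes,
                      index=[f"c{i}" for i in range(2 * n_per_pop)])
    return ExpressionMatrix(df, pd.Series(labels, index=df.index))
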