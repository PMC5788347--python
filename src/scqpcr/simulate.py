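"""Stochastic simulator of a multiplexed single-cell RT-qPCR chip run.

Every stage of the chip's data-generating process is modelled explicitly so
that the downstream analysis can be validated against known ground truth:

1. Template capture — molecules partition into cell-processing units
   following a Poisson law (purified-RNA dilutions), or per-cell counts are
   drawn around lognormal, copula-correlated per-cell rates (cell runs).
2. Reverse transcription — binomial thinning of the per-unit molecule count.
3. Pre-amplification — a Galton–Watson branching process: each molecule
   independently duplicates per cycle with the per-cycle efficiency, for
   7 (two-step miRNA) or 12 (one-step mRNA) cycles.
4. Sample splitting — every post-amplification molecule lands in detection
   chamber j with probability ``split_fraction_per_chamber`` (the remainder
   stays behind in the pre-amplification chamber and is discarded).
5. Detection qPCR — each chamber produces a 40-cycle sigmoidal fluorescence
   trace whose midpoint shifts by −1 cycle per template doubling (at 100%
   per-cycle detection efficiency), with multiplicative Gaussian noise.

Randomness is organised as one root seed with per-unit child streams: a
``numpy.random.SeedSequence(seed)`` is spawned into ``n_units + 1`` children;
child 0 drives truth generation, child ``i + 1`` drives unit *i*'s RT,
pre-amplification, splitting and trace noise, in that order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import OCCUPANCY_STATES, AssayPanel, ChipConfig

__all__ = [
    "TrueState",
    "ChipRun",
    "simulate_molecule_capture",
    "simulate_cell_population",
    "simulate_downstream",
    "simulate_trace",
    "simulate_chip_run",
]


@dataclass
class TrueState:
    """Ground truth for one chip run: per-unit occupancy and molecule counts."""

    gene_names: list[str]
    counts: np.ndarray  # (n_units, n_genes) non-negative ints
    occupancy: np.ndarray  # (n_units,) strings from OCCUPANCY_STATES
    population: np.ndarray  # (n_units,) population labels

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(self.gene_names):
            raise ValueError("counts must be (n_units, n_genes)")
        if np.any(self.counts < 0):
            raise ValueError("molecule counts must be non-negative")
        self.occupancy = np.asarray(self.occupancy, dtype=object)
        self.population = np.asarray(self.population, dtype=object)
        if len(self.occupancy) != self.n_units or len(self.population) != self.n_units:
            raise ValueError("occupancy/population length mismatch")
        bad = set(self.occupancy) - set(OCCUPANCY_STATES)
        if bad:
            raise ValueError(f"unknown occupancy states: {sorted(bad)}")

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class ChipRun:
    """A simulated device run: config, retained truth, and raw traces.

    ``traces`` has shape (n_units, chambers_per_unit, n_qpcr_cycles); cycle
    index is 1-based in all exported tables.  ``chamber_assays`` maps each
    detection chamber to the gene it assays (shared across units).
    """

    config: ChipConfig
    truth: TrueState
    traces: np.ndarray
    chamber_assays: list[str]

    def __post_init__(self) -> None:
        expected = (
            self.truth.n_units,
            self.config.chambers_per_unit,
            self.config.n_qpcr_cycles,
        )
        if self.traces.shape != expected:
            raise ValueError(f"traces must have shape {expected}, got {self.traces.shape}")
        if len(self.chamber_assays) != self.config.chambers_per_unit:
            raise ValueError("one assay label per detection chamber required")

    @property
    def addresses(self) -> np.ndarray:
        """(n_units, 2) array of 1-based (subarray, unit-within-subarray)."""
        idx = np.arange(self.truth.n_units)
        return np.column_stack(
            (idx // self.config.units_per_subarray + 1,
             idx % self.config.units_per_subarray + 1)
        )


def _resolve_rng(rng, seed=None):
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def simulate_molecule_capture(
    config: ChipConfig,
    concentration: float | np.ndarray | None = None,
    molecules_per_unit_mean: float | np.ndarray | None = None,
    molecules_per_pg: float | None = None,
    gene: str = "target",
    rng: np.random.Generator | None = None,
) -> TrueState:
    """Partition purified template into units by Poisson shot noise.

    Exactly one of ``concentration`` (pg per unit, requiring a
    ``molecules_per_pg`` conversion factor) or ``molecules_per_unit_mean``
    must be given; either may be a scalar or one value per subarray, which
    mimics loading a dilution series with one concentration per linear array.
    Units are labelled "empty" because no cell is present in these runs.
    """
    if (concentration is None) == (molecules_per_unit_mean is None):
        raise ValueError(
            "supply exactly one of concentration / molecules_per_unit_mean"
        )
    if concentration is not None:
        if molecules_per_pg is None:
            raise ValueError("molecules_per_pg is required with concentration")
        mean = np.asarray(concentration, dtype=float) * molecules_per_pg
    else:
        mean = np.asarray(molecules_per_unit_mean, dtype=float)
    if np.any(mean < 0):
        raise ValueError("mean molecules per unit must be non-negative")
    if mean.ndim == 0:
        per_unit = np.full(config.n_units, float(mean))
    elif mean.shape == (config.n_subarrays,):
        per_unit = np.repeat(mean, config.units_per_subarray)
    else:
        raise ValueError("mean must be scalar or one value per subarray")

    rng = _resolve_rng(rng, config.seed)
    counts = rng.poisson(per_unit)[:, None]
    return TrueState(
        gene_names=[gene],
        counts=counts,
        occupancy=np.full(config.n_units, "empty", dtype=object),
        population=np.full(config.n_units, "rna", dtype=object),
    )


def simulate_cell_population(
    panel: AssayPanel,
    n_cells: int,
    population: str = "pop1",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    occupancy: Sequence[str] | None = None,
) -> TrueState:
    """Draw per-cell molecule counts for one population.

    Per-cell rates are lognormal (matching the panel's per-gene CV), made
    dependent across genes through a Gaussian copula with the panel's
    correlation matrix; bimodal genes are silenced per cell by a Bernoulli
    indicator with success probability ``detect_fraction``.  Counts are
    Poisson around the resulting rate.  Units whose occupancy is not
    "single" or "multiple" carry zero molecules.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = _resolve_rng(rng, seed)
    g = panel.n_genes

    # Gaussian copula: correlated standard normals -> per-gene lognormal rates
    try:
        chol = np.linalg.cholesky(panel.correlation + 1e-12 * np.eye(g))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - panel validates PSD
        raise ValueError("correlation matrix is not positive semi-definite") from exc
    z = rng.standard_normal((n_cells, g)) @ chol.T
    sigma = np.sqrt(np.log1p(np.square(panel.lognormal_cv)))
    mu = np.log(panel.mean_copies) - 0.5 * sigma**2
    rates = np.exp(mu + sigma * z)

    on = rng.random((n_cells, g)) < panel.detect_fraction
    rates = rates * on

    if occupancy is None:
        occupancy = np.full(n_cells, "single", dtype=object)
    else:
        occupancy = np.asarray(list(occupancy), dtype=object)
        if len(occupancy) != n_cells:
            raise ValueError("occupancy must have one entry per unit")
    has_cell = np.isin(occupancy, ("single", "multiple"))
    rates[~has_cell] = 0.0

    counts = rng.poisson(rates)
    return TrueState(
        gene_names=list(panel.gene_names),
        counts=counts,
        occupancy=occupancy,
        population=np.full(n_cells, population, dtype=object),
    )


def concat_truth(parts: Sequence[TrueState]) -> TrueState:
    """Stack populations loaded onto different sections of the same chip."""
    genes = parts[0].gene_names
    for p in parts[1:]:
        if p.gene_names != genes:
            raise ValueError("all parts must share the same gene panel")
    return TrueState(
        gene_names=genes,
        counts=np.concatenate([p.counts for p in parts]),
        occupancy=np.concatenate([p.occupancy for p in parts]),
        population=np.concatenate([p.population for p in parts]),
    )


def _preamplify(counts: np.ndarray, p: float, cycles: int,
                rng: np.random.Generator, deterministic: bool) -> np.ndarray:
    """Galton–Watson growth: each molecule duplicates w.p. p per cycle."""
    if deterministic:
        return np.rint(counts * (1.0 + p) ** cycles).astype(np.int64)
    out = counts.astype(np.int64)
    for _ in range(cycles):
        out = out + rng.binomial(out, p)
    return out


def _split_chambers(post: np.ndarray, f: float, n_chambers: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Multinomial metering of molecules into chambers; remainder discarded.

    ``post`` is (..., ) molecule counts; returns (..., n_chambers).
    Implemented as sequential conditional binomials.
    """
    remaining = post.astype(np.int64)
    out = np.empty(post.shape + (n_chambers,), dtype=np.int64)
    prob_left = 1.0
    for j in range(n_chambers):
        pj = min(f / prob_left, 1.0)
        taken = rng.binomial(remaining, pj)
        out[..., j] = taken
        remaining = remaining - taken
        prob_left -= f
    return out


def default_assay_map(truth: TrueState, config: ChipConfig) -> np.ndarray:
    """Gene index assayed by each chamber: simplex if one gene, else round-robin."""
    g = truth.n_genes
    return np.arange(config.chambers_per_unit) % g


def simulate_downstream(
    truth: TrueState,
    config: ChipConfig,
    rng: np.random.Generator | None = None,
    assay_map: np.ndarray | None = None,
    deterministic_preamp: bool = False,
    _unit_rngs: Sequence[np.random.Generator] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """RT → pre-amplification → chamber splitting for every unit.

    Returns ``(templates, assay_map)`` where ``templates[u, j]`` is the
    number of molecules of chamber *j*'s assayed gene delivered to that
    chamber, and ``assay_map[j]`` indexes ``truth.gene_names``.
    """
    if truth.n_units < 1:
        raise ValueError("truth must contain at least one unit")
    if assay_map is None:
        assay_map = default_assay_map(truth, config)
    assay_map = np.asarray(assay_map, dtype=int)
    if assay_map.shape != (config.chambers_per_unit,):
        raise ValueError("assay_map must give one gene index per chamber")
    if np.any((assay_map < 0) | (assay_map >= truth.n_genes)):
        raise ValueError("assay_map indexes outside the gene panel")

    rng = _resolve_rng(rng, config.seed)
    f = config.split_fraction_per_chamber
    templates = np.empty((truth.n_units, config.chambers_per_unit), dtype=np.int64)
    for u in range(truth.n_units):
        r = _unit_rngs[u] if _unit_rngs is not None else rng
        cdna = r.binomial(truth.counts[u], config.rt_efficiency)
        post = _preamplify(cdna, config.preamp_per_cycle_efficiency,
                           config.preamp_cycles, r, deterministic_preamp)
        split = _split_chambers(post, f, config.chambers_per_unit, r)
        templates[u] = split[assay_map, np.arange(config.chambers_per_unit)]
    return templates, assay_map


# Trace-shape defaults: arbitrary fluorescence units; only the induced CT
# values matter downstream.
TRACE_BASELINE = 100.0
TRACE_PLATEAU = 1000.0
TRACE_C_REF = 21.5  # CT of a chamber holding exactly one template molecule
TRACE_WIDTH = 1.2


def trace_midpoint(template_count: int, config: ChipConfig,
                   c_ref: float = TRACE_C_REF) -> float:
    """Sigmoid midpoint cycle for a given chamber template count.

    At per-cycle detection efficiency *e* the midpoint advances by one cycle
    per factor (1+e) of template, i.e. −1 cycle per doubling when e = 1.
    """
    if template_count < 1:
        raise ValueError("midpoint undefined for empty chambers")
    e = config.qpcr_per_cycle_efficiency
    if e <= 0:
        raise ValueError("qpcr_per_cycle_efficiency must be positive")
    return c_ref - np.log(template_count) / np.log(1.0 + e)


def simulate_trace(
    template_count: int,
    config: ChipConfig,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    baseline: float = TRACE_BASELINE,
    plateau: float = TRACE_PLATEAU,
    c_ref: float = TRACE_C_REF,
    width: float = TRACE_WIDTH,
) -> np.ndarray:
    """One 40-cycle qPCR fluorescence trace for a chamber.

    ``trace(c) = (baseline + plateau * sigmoid((c - c_mid)/width)) * (1 + ε_c)``
    with ε_c ~ Normal(0, noise_sd²) per cycle.  An empty chamber
    (``template_count == 0``) yields a flat baseline.  The half-plateau level
    above baseline is crossed exactly at ``c_mid``, so the true CT is
    recoverable from the noiseless trace.
    """
    if template_count < 0:
        raise ValueError("template_count must be non-negative")
    cycles = np.arange(1, config.n_qpcr_cycles + 1, dtype=float)
    if template_count == 0:
        signal = np.full_like(cycles, baseline)
    else:
        c_mid = trace_midpoint(template_count, config, c_ref)
        signal = baseline + plateau / (1.0 + np.exp(-(cycles - c_mid) / width))
    if noise_sd > 0:
        rng = _resolve_rng(rng, config.seed)
        signal = signal * (1.0 + noise_sd * rng.standard_normal(signal.shape))
    return np.maximum(signal, 0.0)


def simulate_chip_run(
    config: ChipConfig,
    truth: TrueState | None = None,
    panel: AssayPanel | None = None,
    assay_map: np.ndarray | None = None,
    noise_sd: float = 0.02,
    deterministic_preamp: bool = False,
    molecules_per_unit_mean: float | np.ndarray | None = None,
    **trace_kwargs,
) -> ChipRun:
    """Simulate a complete device run from truth to fluorescence traces.

    If ``truth`` is omitted it is generated from ``panel`` (cells fill the
    chip) or from ``molecules_per_unit_mean`` (purified-RNA run).  RNG
    streams: SeedSequence(config.seed) spawned into n_units + 1 children;
    child 0 for truth, child i+1 for unit i (RT, pre-amp, split, then the
    trace noise of its chambers in chamber order).
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_units + 1)
    root = np.random.default_rng(children[0])

    if truth is None:
        if panel is not None:
            truth = simulate_cell_population(panel, config.n_units, rng=root)
        elif molecules_per_unit_mean is not None:
            truth = simulate_molecule_capture(
                config, molecules_per_unit_mean=molecules_per_unit_mean, rng=root
            )
        else:
            raise ValueError("supply truth, panel, or molecules_per_unit_mean")
    if truth.n_units != config.n_units:
        raise ValueError(
            f"truth has {truth.n_units} units but config expects {config.n_units}"
        )

    unit_rngs = [np.random.default_rng(c) for c in children[1:]]
    templates, assay_map = simulate_downstream(
        truth, config, assay_map=assay_map,
        deterministic_preamp=deterministic_preamp, _unit_rngs=unit_rngs,
    )
    traces = np.empty(
        (truth.n_units, config.chambers_per_unit, config.n_qpcr_cycles)
    )
    for u in range(truth.n_units):
        for j in range(config.chambers_per_unit):
            traces[u, j] = simulate_trace(
                int(templates[u, j]), config, noise_sd=noise_sd,
                rng=unit_rngs[u], **trace_kwargs,
            )
    chamber_assays = [truth.gene_names[i] for i in assay_map]
    return ChipRun(config=config, truth=truth, traces=traces,
                   chamber_assays=chamber_assays)
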