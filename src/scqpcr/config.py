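"""Chip geometry, reaction parameters, and assay-panel descriptions.

The device modelled here processes single cells in four linear subarrays of
cell-processing units.  Each unit carries a cell through capture (0.3 nL),
reverse transcription (10 nL), low-cycle multiplexed pre-amplification
(50 nL), metering into twenty 0.15-nL splitting chambers, and finally twenty
independent 6.4-nL qPCR detection chambers read out over 40 thermal cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

#: Recorded occupancy states of a cell trap after visual inspection.
OCCUPANCY_STATES = ("single", "multiple", "debris", "empty")

#: Sentinel used in delimited tables for chambers that never crossed threshold.
UNDETECTED = "UNDETECTED"


@dataclass(frozen=True)
class ChipConfig:
    """Physical and protocol parameters of one device run.

    Volumes are in nanolitres and come from the device geometry.  The split
    fraction per detection chamber defaults to the volumetric ratio
    0.15 nL / 50 nL = 0.003; a variant where ~20% of pre-amplification
    product is metered (1% per chamber) can be selected by setting
    ``split_fraction_per_chamber=0.01``.

    ``preamp_cycles`` is 7 for the two-step miRNA workflow and 12 for the
    one-step mRNA workflow.  ``rt_efficiency`` and
    ``preamp_per_cycle_efficiency`` are not instrument-calibrated values;
    they are plausible defaults for simulation.  ``qpcr_per_cycle_efficiency``
    controls the detection-PCR trace spacing: at 1.0 the trace midpoint
    shifts by exactly −1 cycle per template doubling.
    """

    n_subarrays: int = 4
    units_per_subarray: int = 50
    chambers_per_unit: int = 20
    capture_volume_nl: float = 0.3
    rt_volume_nl: float = 10.0
    preamp_volume_nl: float = 50.0
    split_volume_nl: float = 0.15
    detection_volume_nl: float = 6.4
    split_fraction_per_chamber: float = 0.003
    preamp_cycles: int = 7
    rt_efficiency: float = 0.5
    preamp_per_cycle_efficiency: float = 0.9
    qpcr_per_cycle_efficiency: float = 1.0
    n_qpcr_cycles: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subarrays, self.units_per_subarray, self.chambers_per_unit) < 1:
            raise ValueError("chip dimensions must be positive")
        for name in (
            "capture_volume_nl",
            "rt_volume_nl",
            "preamp_volume_nl",
            "split_volume_nl",
            "detection_volume_nl",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.split_fraction_per_chamber <= 1 / self.chambers_per_unit:
            raise ValueError(
                "split_fraction_per_chamber must lie in (0, 1/chambers_per_unit]"
            )
        for name in (
            "rt_efficiency",
            "preamp_per_cycle_efficiency",
            "qpcr_per_cycle_efficiency",
        ):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.preamp_cycles < 0 or self.n_qpcr_cycles < 2:
            raise ValueError("cycle counts out of range")

    @property
    def n_units(self) -> int:
        return self.n_subarrays * self.units_per_subarray

    @classmethod
    def prototype(cls, **overrides) -> "ChipConfig":
        """The early 52-units-per-subarray prototype (208 units total)."""
        overrides.setdefault("units_per_subarray", 52)
        return cls(**overrides)

    def to_dict(self) -> dict:
        return asdict(self)


def _as_float_array(x, n: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (n,)).copy()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass
class AssayPanel:
    """A panel of targets with population-level expression parameters.

    Per-gene cell-to-cell heterogeneity is lognormal with coefficient of
    variation ``lognormal_cv``; ``detect_fraction`` below 1 makes a gene
    bimodal (a per-cell Bernoulli switches the gene off entirely, as seen
    for e.g. miR-221-3p in K562 cells).  ``correlation`` is the gene–gene
    Gaussian-copula correlation of the per-cell rates within a population.
    """

    gene_names: Sequence[str]
    mean_copies: np.ndarray | float = 100.0
    lognormal_cv: np.ndarray | float = 0.6
    detect_fraction: np.ndarray | float = 1.0
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_names = list(self.gene_names)
        n = len(self.gene_names)
        if n < 1:
            raise ValueError("panel must contain at least one gene")
        if len(set(self.gene_names)) != n:
            raise ValueError("gene names must be unique")
        self.mean_copies = _as_float_array(self.mean_copies, n, "mean_copies")
        if np.any(self.mean_copies <= 0):
            raise ValueError("mean_copies must be positive")
        self.lognormal_cv = _as_float_array(self.lognormal_cv, n, "lognormal_cv")
        if np.any(self.lognormal_cv < 0):
            raise ValueError("lognormal_cv must be non-negative")
        self.detect_fraction = _as_float_array(self.detect_fraction, n, "detect_fraction")
        if np.any((self.detect_fraction < 0) | (self.detect_fraction > 1)):
            raise ValueError("detect_fraction must lie in [0, 1]")
        if self.correlation is None:
            self.correlation = np.eye(n)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.correlation.shape != (n, n):
            raise ValueError(f"correlation must be {n}x{n}")
        if not np.allclose(self.correlation, self.correlation.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        eigmin = float(np.linalg.eigvalsh(self.correlation).min())
        if eigmin < -1e-8:
            raise ValueError(
                f"correlation matrix is not positive semi-definite "
                f"(smallest eigenvalue {eigmin:.3g})"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)
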