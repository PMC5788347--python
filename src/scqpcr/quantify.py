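"""Single-molecule cutoffs, digital estimates, copy numbers, and curves.

This is the quantitative core of the pipeline:

* a single-molecule CT cutoff, mean + z·SD of the CTs from units that
  amplified in all twenty detection chambers (z = 2.5758 captures 99% of a
  normal distribution two-sidedly);
* the digital response-curve estimator, converting the fraction of positive
  units on an array into a Poisson mean λ = −ln(1 − k/N) and a molecule
  count N·λ with a binomial confidence interval mapped through the same
  transform;
* CT → copy-number conversion, copies = 2^(CT_single_molecule − CT);
* weighted standard-curve fits with the qPCR efficiency
  100 × (10^(−1/slope) − 1);
* the coefficient-of-variation precision metric and the within- versus
  between-unit variance comparison used to attribute low-concentration
  scatter to Poisson sampling of templates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint
import statsmodels.api as sm

__all__ = [
    "CTMatrix",
    "SingleMoleculeCutoff",
    "DigitalEstimate",
    "StandardCurveFit",
    "VariancePartition",
    "single_molecule_cutoff",
    "classify_units",
    "digital_estimate",
    "ct_to_copies",
    "fit_standard_curve",
    "precision_metric",
    "variance_partition",
]

#: Two-sided 99% standard-normal quantile used by the cutoff construction.
DEFAULT_Z = 2.5758


@dataclass
class CTMatrix:
    """Units × detection-chambers table of called CTs (NaN = undetected)."""

    ct: np.ndarray
    subarray: np.ndarray
    unit: np.ndarray
    assays: list[str]
    occupancy: np.ndarray | None = None
    population: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ct = np.asarray(self.ct, dtype=float)
        if self.ct.ndim != 2:
            raise ValueError("ct must be 2-D (units x chambers)")
        if len(self.assays) != self.ct.shape[1]:
            raise ValueError("one assay label per chamber column required")
        if len(self.subarray) != self.ct.shape[0] or len(self.unit) != self.ct.shape[0]:
            raise ValueError("one (subarray, unit) address per row required")

    @property
    def n_units(self) -> int:
        return self.ct.shape[0]

    @property
    def n_chambers(self) -> int:
        return self.ct.shape[1]

    @property
    def detected(self) -> np.ndarray:
        return ~np.isnan(self.ct)

    def fully_detected_cts(self) -> np.ndarray:
        """CTs from units that generated signal in every chamber (flattened).

        These are the inputs to the single-molecule cutoff estimate.
        """
        full = self.detected.all(axis=1)
        return self.ct[full].ravel()

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "CTMatrix":
        """Build from a long CT table (subarray, unit, chamber, assay, ct)."""
        required = {"subarray", "unit", "chamber", "assay", "ct"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"CT table is missing columns: {sorted(missing)}")
        wide = df.pivot_table(index=["subarray", "unit"], columns="chamber",
                              values="ct", dropna=False, aggfunc="first")
        wide = wide.sort_index()
        chambers = sorted(wide.columns)
        assays = (
            df.drop_duplicates("chamber").set_index("chamber")["assay"]
            .reindex(chambers).tolist()
        )
        meta = {}
        for col in ("occupancy", "population"):
            if col in df.columns:
                meta[col] = (
                    df.drop_duplicates(["subarray", "unit"])
                    .set_index(["subarray", "unit"])[col]
                    .reindex(wide.index)
                    .to_numpy()
                )
        idx = wide.index.to_frame(index=False)
        return cls(
            ct=wide[chambers].to_numpy(dtype=float),
            subarray=idx["subarray"].to_numpy(),
            unit=idx["unit"].to_numpy(),
            assays=[str(a) for a in assays],
            **meta,
        )


@dataclass(frozen=True)
class SingleMoleculeCutoff:
    """Mean/SD of single-molecule CTs and the derived detection cutoff.

    ``cutoff_ct = mean_ct + z * sd_ct`` captures 99% of the fitted normal at
    the default z.  ``preamp_cycle_offset`` shifts the cutoff for assays run
    with fewer pre-amplification cycles (e.g. +5 cycles when applying a
    12-cycle mRNA-derived cutoff to a 7-cycle miRNA workflow).
    """

    mean_ct: float
    sd_ct: float
    z: float = DEFAULT_Z
    preamp_cycle_offset: int = 0
    n: int | None = None

    def __post_init__(self) -> None:
        if self.sd_ct < 0:
            raise ValueError("sd_ct must be non-negative")
        if self.z <= 0:
            raise ValueError("z must be positive")

    @property
    def cutoff_ct(self) -> float:
        return self.mean_ct + self.z * self.sd_ct

    @property
    def offset_cutoff_ct(self) -> float:
        return self.cutoff_ct + self.preamp_cycle_offset

    def reference_ct(self, reference: str = "mean") -> float:
        """The CT anchored at one template molecule, offset-adjusted.

        ``reference="mean"`` (default) uses the mean single-molecule CT — the
        expected CT of one molecule; ``"cutoff"`` uses the 99% tail bound.
        """
        if reference == "mean":
            return self.mean_ct + self.preamp_cycle_offset
        if reference == "cutoff":
            return self.offset_cutoff_ct
        raise ValueError("reference must be 'mean' or 'cutoff'")


def single_molecule_cutoff(
    ct_values, z: float = DEFAULT_Z, preamp_offset: int = 0
) -> SingleMoleculeCutoff:
    """Estimate the single-molecule CT cutoff from fully-detected units.

    ``ct_values`` must be CTs restricted to cell-processing units that
    generated a signal in all detection chambers.  Sample SD uses the n−1
    denominator.
    """
    vals = np.asarray(ct_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise ValueError("need at least 2 CT values to estimate a cutoff")
    return SingleMoleculeCutoff(
        mean_ct=float(vals.mean()),
        sd_ct=float(vals.std(ddof=1)),
        z=z,
        preamp_cycle_offset=preamp_offset,
        n=int(vals.size),
    )


def _cutoff_value(cutoff) -> float:
    if isinstance(cutoff, SingleMoleculeCutoff):
        return cutoff.offset_cutoff_ct
    return float(cutoff)


def classify_units(
    ctm: CTMatrix | np.ndarray,
    cutoff: SingleMoleculeCutoff | float,
    min_fraction: float = 0.75,
) -> np.ndarray:
    """Per-unit positivity: strictly more than ``min_fraction`` of chambers
    must have CT strictly below the cutoff (with 20 chambers: ≥ 16 of 20).
    """
    ct = ctm.ct if isinstance(ctm, CTMatrix) else np.asarray(ctm, dtype=float)
    if not 0 < min_fraction < 1:
        raise ValueError("min_fraction must lie in (0, 1)")
    c = _cutoff_value(cutoff)
    with np.errstate(invalid="ignore"):
        below = np.nansum(ct < c, axis=1)
    return below > min_fraction * ct.shape[1]


@dataclass(frozen=True)
class DigitalEstimate:
    """Digital response-curve estimate from k positive units out of N."""

    k: int
    n: int
    lambda_hat: float
    total_molecules: float
    ci95: tuple[float, float]
    saturated: bool
    ci_method: str


def digital_estimate(
    k: int, n: int, ci_method: str = "wilson"
) -> DigitalEstimate:
    """Convert positive-unit counts to molecule numbers via Poisson statistics.

    λ̂ = −ln(1 − k/N) per unit, total = N·λ̂; the 95% CI is a binomial CI on
    the positive fraction (Wilson score by default, Clopper–Pearson via
    ``ci_method="clopper-pearson"``) mapped through p ↦ −N·ln(1 − p).  A
    fully positive array (k = N) has no finite point estimate: the lower CI
    bound is then a lower bound on the molecule count and the result is
    flagged saturated.
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError("require 0 <= k <= N with N >= 1")
    methods = {"wilson": "wilson", "clopper-pearson": "beta"}
    if ci_method not in methods:
        raise ValueError(f"ci_method must be one of {sorted(methods)}")
    p_lo, p_hi = proportion_confint(k, n, alpha=0.05, method=methods[ci_method])
    to_total = lambda p: np.inf if p >= 1 else -n * np.log1p(-p)
    saturated = k == n
    lam = np.inf if saturated else -np.log1p(-k / n)
    return DigitalEstimate(
        k=int(k),
        n=int(n),
        lambda_hat=float(lam),
        total_molecules=float(n * lam) if not saturated else np.inf,
        ci95=(float(to_total(p_lo)), float(to_total(p_hi))),
        saturated=saturated,
        ci_method=ci_method,
    )


def ct_to_copies(
    ct, cutoff: SingleMoleculeCutoff | float, reference: str = "mean"
):
    """Convert CT values to copy numbers: copies = 2^(CT_ref − CT).

    ``cutoff`` may be a :class:`SingleMoleculeCutoff` (whose offset-adjusted
    mean or cutoff CT anchors one molecule, per ``reference``) or a bare
    reference CT.  Undetected entries (NaN) map to 0 copies.
    """
    if isinstance(cutoff, SingleMoleculeCutoff):
        ref = cutoff.reference_ct(reference)
    else:
        ref = float(cutoff)
    ct = np.asarray(ct, dtype=float)
    copies = np.power(2.0, ref - ct)
    copies = np.where(np.isnan(ct), 0.0, copies)
    return copies if copies.ndim else float(copies)


@dataclass
class StandardCurveFit:
    """Weighted least-squares standard curve: CT on log10(concentration)."""

    slope: float
    intercept: float
    slope_se: float
    efficiency_pct: float
    efficiency_se_range: tuple[float, float]
    r_squared: float
    weights: np.ndarray
    concentrations: np.ndarray
    n_obs: int

    def summary(self) -> str:
        lo, hi = self.efficiency_se_range
        lines = [
            "Standard curve (WLS: CT ~ log10 concentration)",
            f"  n obs                {self.n_obs}",
            f"  slope                {self.slope:8.4f} cycles/log10 (SE {self.slope_se:.4f})",
            f"  intercept            {self.intercept:8.4f} cycles",
            f"  efficiency           {self.efficiency_pct:7.1f} %  (SE range {lo:.0f} to {hi:.0f} %)",
            f"  weighted R^2         {self.r_squared:8.4f}",
        ]
        return "\n".join(lines)


def slope_to_efficiency(slope: float) -> float:
    """qPCR efficiency in percent from a standard-curve slope.

    100 × (10^(−1/slope) − 1); a perfect-doubling slope of −1/log10(2)
    ≈ −3.3219 gives exactly 100%.
    """
    if slope == 0:
        raise ValueError("slope must be non-zero")
    return 100.0 * (10.0 ** (-1.0 / slope) - 1.0)


def fit_standard_curve(
    ct_groups, concentrations, weight_cap: float | None = None
) -> StandardCurveFit:
    """Fit a weighted standard curve from replicate CTs per concentration.

    ``ct_groups`` is a sequence of CT collections, one per concentration;
    each concentration's weight is the inverse of the SD of its CTs.  Groups
    with zero SD (e.g. noiseless simulations) get their weight capped at
    ``weight_cap`` (default: 10 × the largest finite weight, or 1.0 when
    every group is degenerate).  Requires ≥ 3 distinct concentrations and
    ≥ 2 replicates per concentration.
    """
    concentrations = np.asarray(concentrations, dtype=float)
    if len(ct_groups) != concentrations.size:
        raise ValueError("one CT group per concentration required")
    if np.unique(concentrations).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.any(concentrations <= 0):
        raise ValueError("concentrations must be positive")

    groups = [np.asarray(g, dtype=float) for g in ct_groups]
    groups = [g[~np.isnan(g)] for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 replicate CTs per concentration")

    sds = np.array([g.std(ddof=1) for g in groups])
    with np.errstate(divide="ignore"):
        weights = 1.0 / sds
    finite = np.isfinite(weights)
    if weight_cap is None:
        weight_cap = 10.0 * weights[finite].max() if finite.any() else 1.0
    weights = np.minimum(weights, weight_cap)

    y = np.concatenate(groups)
    x = np.concatenate(
        [np.full(g.size, np.log10(c)) for g, c in zip(groups, concentrations)]
    )
    w = np.concatenate([np.full(g.size, wt) for g, wt in zip(groups, weights)])
    model = sm.WLS(y, sm.add_constant(x), weights=w)
    res = model.fit()
    slope, intercept = float(res.params[1]), float(res.params[0])
    slope_se = float(res.bse[1])
    effs = sorted(
        slope_to_efficiency(s) for s in (slope - slope_se, slope + slope_se)
    )
    return StandardCurveFit(
        slope=slope,
        intercept=intercept,
        slope_se=slope_se,
        efficiency_pct=slope_to_efficiency(slope),
        efficiency_se_range=(effs[0], effs[1]),
        r_squared=float(min(max(res.rsquared, 0.0), 1.0)),
        weights=weights,
        concentrations=concentrations,
        n_obs=int(y.size),
    )


def precision_metric(copies) -> float:
    """Measurement precision as a coefficient of variation, 100 × SD/mean."""
    vals = np.asarray(copies, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise ValueError("need at least 2 values")
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("mean must be positive")
    return float(100.0 * vals.std(ddof=1) / mean)


@dataclass
class VariancePartition:
    """Within-unit vs between-unit CT variability on one or more arrays."""

    unit_sds: np.ndarray
    array_sds: np.ndarray
    statistic: float
    pvalue: float

    @property
    def mean_unit_sd(self) -> float:
        return float(self.unit_sds.mean())

    @property
    def mean_array_sd(self) -> float:
        return float(self.array_sds.mean())


def variance_partition(ctm: CTMatrix | np.ndarray, array_ids=None) -> VariancePartition:
    """Compare per-unit CT scatter with whole-array CT scatter.

    At limiting dilution, template numbers vary between units by Poisson
    sampling while the 20 chambers of one unit share the same template, so
    the within-unit SDs sit well below the array-wide SD.  Per-unit SDs are
    computed over each unit's detected chambers (≥ 2 required); array SDs
    pool all detected CTs per array (grouped by ``array_ids``, default: all
    units form one array).  The two SD samples are compared with a Wilcoxon
    rank-sum test.
    """
    ct = ctm.ct if isinstance(ctm, CTMatrix) else np.asarray(ctm, dtype=float)
    if array_ids is None:
        if isinstance(ctm, CTMatrix):
            array_ids = ctm.subarray
        else:
            array_ids = np.zeros(ct.shape[0], dtype=int)
    array_ids = np.asarray(array_ids)
    if ct.shape[0] < 2 or ct.shape[1] < 2:
        raise ValueError("need at least 2 units with at least 2 chambers")

    unit_sds = []
    for row in ct:
        vals = row[~np.isnan(row)]
        if vals.size >= 2:
            unit_sds.append(vals.std(ddof=1))
    unit_sds = np.asarray(unit_sds)
    if unit_sds.size < 2:
        raise ValueError("fewer than 2 units have >= 2 detected chambers")

    array_sds = []
    for a in np.unique(array_ids):
        vals = ct[array_ids == a].ravel()
        vals = vals[~np.isnan(vals)]
        if vals.size >= 2:
            array_sds.append(vals.std(ddof=1))
    array_sds = np.asarray(array_sds)
    if array_sds.size < 1:
        raise ValueError("no array has >= 2 detected chambers")

    stat, p = stats.ranksums(unit_sds, array_sds)
    return VariancePartition(
        unit_sds=unit_sds, array_sds=array_sds,
        statistic=float(stat), pvalue=float(p),
    )
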