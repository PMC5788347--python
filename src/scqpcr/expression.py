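"""Population-level analysis of single-cell copy-number matrices.

Detection calls (all replicate chambers below the cutoff), rank-sum
differential expression with Benjamini–Hochberg control, hierarchical
clustering on a correlation distance with Ward linkage, and
permutation-calibrated Spearman co-expression — including the pooled
versus per-population comparison that exposes Simpson's paradox when
heterogeneous cell types are analysed as one sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .quantify import SingleMoleculeCutoff, _cutoff_value

__all__ = [
    "ExpressionMatrix",
    "detection_call",
    "differential_expression",
    "hierarchical_cluster",
    "ClusteringResult",
    "coexpression",
    "pooled_vs_grouped",
    "PooledVsGrouped",
]


class ExpressionMatrix:
    """Cells × genes copy numbers with per-cell population labels.

    ``copies`` is a DataFrame indexed by cell id; ``population`` a Series
    aligned to it.  ``replicate_cts`` optionally maps gene → DataFrame of
    replicate chamber CTs (cells × replicates) for panels that repeat an
    assay across chambers.
    """

    def __init__(self, copies: pd.DataFrame, population,
                 replicate_cts: dict[str, pd.DataFrame] | None = None):
        copies = pd.DataFrame(copies)
        if (copies.to_numpy() < 0).any():
            raise ValueError("copy numbers must be non-negative")
        population = pd.Series(population, index=copies.index)
        if population.isna().any() or (population.astype(str) == "").any():
            raise ValueError("every cell needs a population label")
        self.copies = copies
        self.population = population
        self.replicate_cts = replicate_cts or {}

    @property
    def genes(self) -> list[str]:
        return list(self.copies.columns)

    @property
    def populations(self) -> list:
        return sorted(self.population.unique())

    @property
    def n_cells(self) -> int:
        return len(self.copies)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a long table (cell_id, population, gene, copies)."""
        required = {"cell_id", "population", "gene", "copies"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"expression table is missing columns: {sorted(missing)}")
        wide = df.pivot_table(index="cell_id", columns="gene", values="copies",
                              aggfunc="first")
        pop = df.drop_duplicates("cell_id").set_index("cell_id")["population"]
        return cls(wide, pop.reindex(wide.index))

    def to_long(self) -> pd.DataFrame:
        long = self.copies.reset_index(names="cell_id").melt(
            id_vars="cell_id", var_name="gene", value_name="copies"
        )
        long["population"] = self.population.reindex(long["cell_id"]).to_numpy()
        return long[["cell_id", "population", "gene", "copies"]]


def detection_call(replicate_cts, cutoff: SingleMoleculeCutoff | float):
    """A gene is detected in a cell iff *every* replicate CT is below cutoff.

    ``replicate_cts`` is an array-like (cells × replicates) of CTs, NaN for
    undetected chambers.  Requiring all replicates suppresses sporadic
    background amplification at the cost of sensitivity for one-copy genes.
    """
    cts = np.asarray(replicate_cts, dtype=float)
    if cts.ndim == 1:
        cts = cts[:, None]
    if cts.shape[1] < 1:
        raise ValueError("need at least one replicate per gene")
    c = _cutoff_value(cutoff)
    with np.errstate(invalid="ignore"):
        below = (cts < c) & ~np.isnan(cts)
    return below.all(axis=1)


def _ranksum_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) with tie correction."""
    if np.all(x == x[0]) and np.all(y == x[0]):
        # Every observation tied: no evidence either way.
        return float(len(x) * len(y) / 2.0), 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def differential_expression(em: ExpressionMatrix, fdr: float = 0.01) -> pd.DataFrame:
    """Per-gene rank-sum test between the two populations, BH-adjusted.

    Returns one row per gene with group medians/means, the Mann–Whitney U
    statistic, raw and BH-adjusted p-values, and a significance flag at the
    requested FDR (default 0.01).
    """
    pops = em.populations
    if len(pops) != 2:
        raise ValueError(f"exactly 2 populations required, found {len(pops)}")
    a, b = pops
    mask_a = (em.population == a).to_numpy()
    mask_b = (em.population == b).to_numpy()
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError("each population needs at least 3 cells")

    rows = []
    for gene in em.genes:
        x = em.copies[gene].to_numpy()[mask_a]
        y = em.copies[gene].to_numpy()[mask_b]
        stat, p = _ranksum_pvalue(x, y)
        rows.append({
            "gene": gene,
            f"median_{a}": float(np.median(x)),
            f"median_{b}": float(np.median(y)),
            f"mean_{a}": float(np.mean(x)),
            f"mean_{b}": float(np.mean(y)),
            "statistic": stat,
            "pvalue": p,
        })
    out = pd.DataFrame(rows)
    reject, qvals, _, _ = multipletests(out["pvalue"], alpha=fdr, method="fdr_bh")
    out["qvalue"] = qvals
    out["significant"] = reject
    return out


@dataclass
class ClusteringResult:
    linkage: np.ndarray
    leaf_order: np.ndarray
    labels_k2: np.ndarray
    distance: np.ndarray
    cell_ids: list

    def ordered_matrix(self, em: "ExpressionMatrix") -> pd.DataFrame:
        """Log-scaled expression reordered by the dendrogram, heatmap-ready."""
        logx = np.log10(em.copies + 1.0)
        return logx.iloc[self.leaf_order]


def hierarchical_cluster(em: ExpressionMatrix) -> ClusteringResult:
    """Cluster cells on log-scaled expression with a correlation distance.

    Distance between cells i, j is (1 − Pearson r of their log10(x+1)
    profiles over genes) / 2; agglomeration uses Ward linkage on these
    dissimilarities (the ward.D2 construction).  A cell with zero variance
    across genes has undefined correlations; its distances are set to the
    maximum 1 with a warning.  Returns the merge tree, the dendrogram leaf
    order, and the two-group cut labels.
    """
    if em.n_cells < 2:
        raise ValueError("need at least 2 cells to cluster")
    logx = np.log10(em.copies.to_numpy(dtype=float) + 1.0)
    sd = logx.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} cell(s) have zero variance across genes; "
            "their correlation distances are set to 1",
            RuntimeWarning,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(logx)
    d = (1.0 - r) / 2.0
    d[flat, :] = 1.0
    d[:, flat] = 1.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    z = linkage(squareform(d, checks=False), method="ward")
    return ClusteringResult(
        linkage=z,
        leaf_order=np.asarray(leaves_list(z)),
        labels_k2=np.asarray(fcluster(z, t=2, criterion="maxclust")),
        distance=d,
        cell_ids=list(em.copies.index),
    )


def _spearman_perm_p(
    x: np.ndarray, y: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Observed Spearman rho and a two-sided permutation p with +1 smoothing.

    One gene's values are permuted across cells, breaking the pairing while
    preserving both marginals; ties get average ranks.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    nx = np.linalg.norm(rx)
    ny = np.linalg.norm(ry)
    if nx == 0 or ny == 0:
        return np.nan, np.nan
    rx /= nx
    ry /= ny
    rho = float(rx @ ry)
    perms = rng.permuted(np.tile(ry, (n_perm, 1)), axis=1)
    rho_perm = perms @ rx
    exceed = int(np.sum(np.abs(rho_perm) >= abs(rho) - 1e-12))
    return rho, (1.0 + exceed) / (1.0 + n_perm)


def coexpression(
    em: ExpressionMatrix,
    n_perm: int = 10_000,
    fdr: float = 0.01,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Permutation-calibrated Spearman co-expression within each population.

    For every gene pair and population: Spearman rho over cells, a two-sided
    permutation p-value (one gene permuted across cells, +1 smoothing), and
    BH adjustment across all assessable pairs of the whole analysis.  Pairs
    where either gene is undetected in every cell of a population are not
    assessable (rho is NA).  The pooled rho (populations merged) is reported
    alongside for comparison.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives too coarse a p-value resolution")
    rng = rng if rng is not None else np.random.default_rng(seed)
    genes = em.genes
    rows = []
    for pop in em.populations:
        sub = em.copies[(em.population == pop).to_numpy()]
        n_cells = len(sub)
        for ga, gb in combinations(genes, 2):
            x = sub[ga].to_numpy(dtype=float)
            y = sub[gb].to_numpy(dtype=float)
            assessable = bool(np.any(x > 0) and np.any(y > 0))
            if assessable:
                rho, p = _spearman_perm_p(x, y, n_perm, rng)
                assessable = not np.isnan(rho)
            if not assessable:
                rho, p = np.nan, np.nan
            rows.append({
                "population": pop, "gene_a": ga, "gene_b": gb,
                "n_cells": n_cells, "rho": rho, "pvalue": p,
                "assessable": assessable,
            })
    out = pd.DataFrame(rows)

    pooled = {}
    for ga, gb in combinations(genes, 2):
        x = em.copies[ga].to_numpy(dtype=float)
        y = em.copies[gb].to_numpy(dtype=float)
        if np.any(x > 0) and np.any(y > 0) and np.std(x) > 0 and np.std(y) > 0:
            pooled[(ga, gb)] = float(stats.spearmanr(x, y).statistic)
        else:
            pooled[(ga, gb)] = np.nan
    out["pooled_rho"] = [pooled[(a, b)] for a, b in zip(out["gene_a"], out["gene_b"])]

    out["qvalue"] = np.nan
    out["significant"] = False
    mask = out["assessable"].to_numpy()
    if mask.any():
        reject, qvals, _, _ = multipletests(
            out.loc[mask, "pvalue"], alpha=fdr, method="fdr_bh"
        )
        out.loc[mask, "qvalue"] = qvals
        out.loc[mask, "significant"] = reject
    return out


@dataclass
class PooledVsGrouped:
    """Pooled and per-population rank correlation of one gene pair."""

    gene_a: str
    gene_b: str
    pooled_rho: float
    pooled_p: float
    group_rho: dict
    group_p: dict
    sign_reversal: bool

    def summary(self) -> str:
        lines = [
            f"Spearman correlation, {self.gene_a} vs {self.gene_b}",
            f"  pooled      rho = {self.pooled_rho:+.3f}  (perm p = {self.pooled_p:.4g})",
        ]
        for pop in self.group_rho:
            lines.append(
                f"  {pop:<11} rho = {self.group_rho[pop]:+.3f}  "
                f"(perm p = {self.group_p[pop]:.4g})"
            )
        lines.append(f"  sign reversal (Simpson's paradox): {self.sign_reversal}")
        return "\n".join(lines)


def pooled_vs_grouped(
    em: ExpressionMatrix,
    gene_a: str,
    gene_b: str,
    n_perm: int = 10_000,
    scheme: str = "pooled",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PooledVsGrouped:
    """Contrast the pooled rank correlation with per-population correlations.

    ``scheme`` controls the null for the pooled p-value: "pooled" permutes
    across all cells; "within" permutes within each population (preserving
    between-population structure).  The sign-reversal flag is set when the
    pooled rho and both within-population rhos are non-zero with the two
    group rhos sharing a sign opposite to the pooled one — the hallmark of
    Simpson's paradox in pooled co-expression estimates.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives too coarse a p-value resolution")
    if len(em.populations) != 2:
        raise ValueError("exactly 2 populations required")
    if scheme not in ("pooled", "within"):
        raise ValueError("scheme must be 'pooled' or 'within'")
    rng = rng if rng is not None else np.random.default_rng(seed)

    x = em.copies[gene_a].to_numpy(dtype=float)
    y = em.copies[gene_b].to_numpy(dtype=float)

    if scheme == "pooled":
        pooled_rho, pooled_p = _spearman_perm_p(x, y, n_perm, rng)
    else:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rx = (rx - rx.mean()) / np.linalg.norm(rx - rx.mean())
        ryc = (ry - ry.mean()) / np.linalg.norm(ry - ry.mean())
        pooled_rho = float(rx @ ryc)
        masks = [(em.population == p).to_numpy() for p in em.populations]
        perms = np.tile(ry, (n_perm, 1))
        for m in masks:
            perms[:, m] = rng.permuted(perms[:, m], axis=1)
        pc = perms - perms.mean(axis=1, keepdims=True)
        pc /= np.linalg.norm(pc, axis=1, keepdims=True)
        rho_perm = pc @ rx
        exceed = int(np.sum(np.abs(rho_perm) >= abs(pooled_rho) - 1e-12))
        pooled_p = (1.0 + exceed) / (1.0 + n_perm)

    group_rho, group_p = {}, {}
    for pop in em.populations:
        m = (em.population == pop).to_numpy()
        group_rho[pop], group_p[pop] = _spearman_perm_p(x[m], y[m], n_perm, rng)

    rhos = list(group_rho.values())
    reversal = (
        not np.isnan(pooled_rho)
        and all(not np.isnan(r) and r != 0 for r in rhos)
        and pooled_rho != 0
        and np.sign(rhos[0]) == np.sign(rhos[1])
        and np.sign(rhos[0]) != np.sign(pooled_rho)
    )
    return PooledVsGrouped(
        gene_a=gene_a, gene_b=gene_b,
        pooled_rho=pooled_rho, pooled_p=pooled_p,
        group_rho=group_rho, group_p=group_p,
        sign_reversal=bool(reversal),
    )
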