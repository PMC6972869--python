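"""Trait genetic-correlation networks: soft-threshold adjacency, scale-free
model selection, topological overlap, and module extraction.

The network follows the weighted-correlation-network recipe: adjacency
a_ij = |r_g ij|^beta for valid pairs whose r_g P-value passes the threshold
(else 0), scale-free fit of the degree distribution for selecting
(beta, threshold), TOM similarity w_ij = (l_ij + a_ij)/(min{k_i,k_j}+1-a_ij)
with dissimilarity d = 1 - w, and average-linkage clustering of d cut at a
fraction of the maximum merge height.

Two connectivity notions coexist on purpose: the scale-free fit uses the COUNT
of direct connections (degree), while TOM's k_i is the weighted sum of
adjacencies. Both are computed and reported; the count drives model selection.
A consequence worth knowing: the nonzero pattern of |r_g|^beta does not depend
on beta, so the count-based fit — and hence the selected cell's R^2 — varies
only with the P-value threshold, and the documented tie-break (smaller beta
first) resolves the resulting ties.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .ldsc import GeneticCorrelationMatrix

logger = logging.getLogger(__name__)

DEFAULT_BETA_GRID = (2, 4, 6, 8)
DEFAULT_THRESHOLD_GRID = (0.5, 0.3, 0.2, 0.1)


class DegenerateFitError(ValueError):
    """Degree distribution too uniform for a log-log power-law fit."""


@dataclass
class NetworkConfig:
    beta: float
    p_threshold: float
    selected: bool = False


@dataclass
class AdjacencyMatrix:
    traits: list
    a: np.ndarray
    config: NetworkConfig

    @property
    def count_degree(self) -> np.ndarray:
        """Number of direct connections per node (nonzero adjacencies)."""
        return (self.a > 0).sum(axis=1)

    @property
    def weighted_degree(self) -> np.ndarray:
        return self.a.sum(axis=1)


@dataclass
class ScaleFreeFit:
    r2: float
    slope: float
    n_zero_degree: int
    bins: pd.DataFrame


@dataclass
class TOMMatrix:
    traits: list
    w: np.ndarray
    l: np.ndarray
    k: np.ndarray
    d: np.ndarray


@dataclass
class ModulePartition:
    """Trait -> module labels; label 0 = isolated or unassigned."""

    traits: list
    labels: np.ndarray
    min_size: int = 3

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def modules(self) -> dict:
        out = {}
        for lab in sorted(set(self.labels) - {0}):
            out[int(lab)] = [t for t, l in zip(self.traits, self.labels) if l == lab]
        return out

    @property
    def n_modules(self) -> int:
        return len(set(self.labels) - {0})


def power_adjacency(
    rg: GeneticCorrelationMatrix, beta: float, p_threshold: float
) -> AdjacencyMatrix:
    """a_ij = |r_g ij|^beta where the pair is valid and P <= threshold, else 0."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must lie in (0, 1]")
    with np.errstate(invalid="ignore"):
        a = np.abs(rg.rg) ** beta
        passing = rg.valid & (np.nan_to_num(rg.p, nan=np.inf) <= p_threshold)
    a = np.where(passing, a, 0.0)
    a = np.nan_to_num(a, nan=0.0)
    np.fill_diagonal(a, 0.0)
    a = (a + a.T) / 2.0
    return AdjacencyMatrix(list(rg.traits), a, NetworkConfig(beta, p_threshold))


def fit_power_law(degrees: np.ndarray, n_bins: int = 10) -> ScaleFreeFit:
    """Scale-free fit on a degree vector.

    Nodes with k=0 are excluded; the remaining degrees go into ``n_bins``
    equal-width bins; log10 bin frequency is regressed on log10 mean bin
    degree over the nonempty bins. Fewer than two nonempty bins (e.g. all
    nodes share one degree) is a :class:`DegenerateFitError`.
    """
    degrees = np.asarray(degrees, dtype=float)
    n_zero = int((degrees == 0).sum())
    k = degrees[degrees > 0]
    if k.size == 0 or k.min() == k.max():
        raise DegenerateFitError("all connected nodes share a single degree value")
    counts, edges = np.histogram(k, bins=n_bins)
    rows = []
    for b in range(n_bins):
        if counts[b] == 0:
            continue
        lo, hi = edges[b], edges[b + 1]
        sel = (k >= lo) & (k <= hi if b == n_bins - 1 else k < hi)
        rows.append({"bin_mean_k": k[sel].mean(), "freq": counts[b] / k.size})
    bins = pd.DataFrame(rows)
    if len(bins) < 2:
        raise DegenerateFitError("fewer than two nonempty degree bins")
    x = np.log10(bins["bin_mean_k"].to_numpy())
    y = np.log10(bins["freq"].to_numpy())
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 else 1.0 - (resid ** 2).sum() / ss_tot
    return ScaleFreeFit(float(r2), float(slope), n_zero, bins)


def scale_free_fit(adj: AdjacencyMatrix, n_bins: int = 10) -> ScaleFreeFit:
    return fit_power_law(adj.count_degree, n_bins=n_bins)


def select_network_config(
    rg: GeneticCorrelationMatrix,
    beta_grid: Sequence[float] = DEFAULT_BETA_GRID,
    threshold_grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    n_bins: int = 10,
) -> Tuple[NetworkConfig, pd.DataFrame]:
    """Grid search over (beta, P threshold), selecting the largest scale-free R^2.

    Cells with a rising degree distribution (positive slope) are not
    scale-free and are disqualified; ties within 1e-12 resolve to the smaller
    beta, then the larger threshold. Raises if every cell is degenerate or
    disqualified.
    """
    if not len(beta_grid) or not len(threshold_grid):
        raise ValueError("grids must be non-empty")
    rows = []
    best = None
    best_r2 = -np.inf
    for beta in sorted(beta_grid):
        for thr in sorted(threshold_grid, reverse=True):
            row = {"beta": beta, "threshold": thr, "r2": np.nan, "slope": np.nan,
                   "n_zero_degree": np.nan, "status": "ok"}
            try:
                fit = scale_free_fit(power_adjacency(rg, beta, thr), n_bins=n_bins)
                row.update(r2=fit.r2, slope=fit.slope, n_zero_degree=fit.n_zero_degree)
                if fit.slope >= 0:
                    row["status"] = "positive_slope"
                elif fit.r2 > best_r2 + 1e-12:
                    best_r2 = fit.r2
                    best = NetworkConfig(beta, thr, selected=True)
            except DegenerateFitError:
                row["status"] = "degenerate"
            rows.append(row)
    table = pd.DataFrame(rows)
    if best is None:
        raise DegenerateFitError(
            "no grid cell yields a usable scale-free fit; configure beta and "
            "the P-value threshold manually"
        )
    return best, table


def tom_dissimilarity(adj: AdjacencyMatrix) -> TOMMatrix:
    """Topological overlap w and dissimilarity d = 1 - w.

    l_ij sums shared-neighbour products over u != i, j (the zero diagonal
    makes the plain matrix product equivalent); k_i is the weighted
    connectivity. w_ii is fixed at 1.
    """
    a = adj.a
    L = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = (L + a) / (kmin + 1.0 - a)
    w = np.nan_to_num(w, nan=0.0)
    np.fill_diagonal(w, 1.0)
    w = (w + w.T) / 2.0
    return TOMMatrix(adj.traits, w, L, k, 1.0 - w)


def detect_modules(
    tom: TOMMatrix,
    min_size: int = 3,
    cut_height_fraction: float = 0.9,
) -> ModulePartition:
    """Average-linkage clustering of the TOM dissimilarity.

    The dendrogram is cut at ``cut_height_fraction`` x the maximum merge
    height; clusters smaller than ``min_size`` fall back to label 0; labels
    are assigned in decreasing cluster-size order.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    n = len(tom.traits)
    if n < min_size:
        warnings.warn("fewer clustered nodes than min_size: single label-0 partition", stacklevel=2)
        return ModulePartition(tom.traits, np.zeros(n, dtype=int), min_size)
    d = tom.d.copy()
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    heights = Z[:, 2]
    if heights.max() - heights.min() <= 1e-12 * max(1.0, heights.max()):
        # every merge at one height (uniform network): a single branch
        raw = np.ones(n, dtype=int)
    else:
        cut = cut_height_fraction * heights.max()
        raw = fcluster(Z, t=cut, criterion="distance")
    labels = np.zeros(n, dtype=int)
    sizes = pd.Series(raw).value_counts()
    next_label = 1
    for lab in sizes.index:  # value_counts sorts by decreasing size (stable)
        if sizes[lab] >= min_size:
            labels[raw == lab] = next_label
            next_label += 1
    return ModulePartition(tom.traits, labels, min_size)


def modules_from_adjacency(
    adj: AdjacencyMatrix, min_size: int = 3, cut_height_fraction: float = 0.9
) -> Tuple[ModulePartition, Optional[TOMMatrix]]:
    """Full module extraction: isolated nodes (count degree 0) get label 0 and
    TOM/clustering run on the connected subgraph only."""
    k = adj.count_degree
    connected = k > 0
    traits = list(adj.traits)
    labels = np.zeros(len(traits), dtype=int)
    if connected.sum() == 0:
        return ModulePartition(traits, labels, min_size), None
    sub = AdjacencyMatrix(
        [t for t, c in zip(traits, connected) if c],
        adj.a[np.ix_(connected, connected)],
        adj.config,
    )
    tom = tom_dissimilarity(sub)
    part = detect_modules(tom, min_size=min_size, cut_height_fraction=cut_height_fraction)
    labels[np.flatnonzero(connected)] = part.labels
    return ModulePartition(traits, labels, min_size), tom


class ModuleDetector(ClusterMixin, BaseEstimator):
    """Clusterer over traits: r_g matrix in, module labels out.

    With ``beta``/``p_threshold`` unset, the (beta, threshold) pair is chosen
    by the scale-free grid search. Fitted attributes: ``config_``, ``grid_``,
    ``adjacency_``, ``tom_``, ``partition_``, ``labels_``.
    """

    def __init__(
        self,
        beta: Optional[float] = None,
        p_threshold: Optional[float] = None,
        beta_grid: Sequence[float] = DEFAULT_BETA_GRID,
        threshold_grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
        n_bins: int = 10,
        min_size: int = 3,
        cut_height_fraction: float = 0.9,
    ):
        self.beta = beta
        self.p_threshold = p_threshold
        self.beta_grid = beta_grid
        self.threshold_grid = threshold_grid
        self.n_bins = n_bins
        self.min_size = min_size
        self.cut_height_fraction = cut_height_fraction

    def fit(self, rg: GeneticCorrelationMatrix, y=None):
        if self.beta is not None and self.p_threshold is not None:
            self.config_ = NetworkConfig(self.beta, self.p_threshold, selected=False)
            self.grid_ = None
        else:
            self.config_, self.grid_ = select_network_config(
                rg, self.beta_grid, self.threshold_grid, self.n_bins
            )
        self.adjacency_ = power_adjacency(rg, self.config_.beta, self.config_.p_threshold)
        self.partition_, self.tom_ = modules_from_adjacency(
            self.adjacency_, self.min_size, self.cut_height_fraction
        )
        self.labels_ = self.partition_.labels
        return self
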