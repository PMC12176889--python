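"""Binary functional networks from pairwise Pearson correlation.

Each region is a node; links are placed between the K most strongly
correlated region pairs (default K = 400 among 84 regions, i.e. 11.5%
density).  Retaining a fixed link count rather than a correlation
cutoff keeps density — and hence every density-dependent network
measure — comparable across subjects.  The thresholded network is
binary and undirected: no weights survive filtering.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PipelineConfig",
    "CorrelationMatrix",
    "FunctionalNetwork",
    "correlation_matrix",
    "threshold_topk",
    "write_edgelist",
    "write_adjacency",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of the network/dynamics pipeline.

    k_links:
        Links retained per network (default 400, giving 11.5% density on
        84 nodes).
    window_length, window_step:
        Sliding-window extent and stride in volumes (defaults 40 and 1).
    ranking:
        ``"signed"`` ranks pairs by correlation value (strongest positive
        coactivation first, the default); ``"absolute"`` ranks by |r|.
    include_final_window:
        The default window count is ``floor((T - W) / step)``, which for
        216 volumes / window 40 / step 1 yields 176 snapshots; setting
        this flag appends the final admissible start (the inclusive
        convention, 177).
    fine_tune:
        Kernighan–Lin style node-swapping refinement after each
        modularity bisection.
    """

    k_links: int = 400
    window_length: int = 40
    window_step: int = 1
    ranking: str = "signed"
    include_final_window: bool = False
    fine_tune: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_links < 1:
            raise ValueError("k_links must be positive")
        if self.window_length < 3:
            raise ValueError("window_length must be at least 3 volumes")
        if self.window_step < 1:
            raise ValueError("window_step must be >= 1")
        if self.ranking not in ("signed", "absolute"):
            raise ValueError(f"ranking must be 'signed' or 'absolute', got {self.ranking!r}")


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with region labels.

    Zero-variance regions produce undefined correlations; those entries
    are set to 0 and the offending labels recorded in
    ``zero_variance_regions``.
    """

    values: np.ndarray
    region_labels: list
    zero_variance_regions: list = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FunctionalNetwork:
    """Binary undirected graph on ``n_nodes`` nodes.

    Edges are unordered pairs of 0-based node indices stored as sorted
    tuples; node ``i`` corresponds to ``region_labels[i]``.
    """

    n_nodes: int
    edges: frozenset
    region_labels: tuple = ()

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def density(self) -> float:
        return 2.0 * len(self.edges) / (self.n_nodes * (self.n_nodes - 1))

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=float)
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            d[i] += 1
            d[j] += 1
        return d


def correlation_matrix(
    ts,
    volume_range: tuple[int, int] | None = None,
) -> CorrelationMatrix:
    """Pearson correlation between all region pairs.

    Parameters
    ----------
    ts:
        A :class:`~netflex.io.RegionTimeSeries`.
    volume_range:
        Optional 1-based inclusive ``(start, stop)`` interval restricting
        the computation to a window of volumes; must contain at least 3
        volumes.
    """
    signals = ts.signals
    if volume_range is not None:
        start, stop = volume_range
        if not (1 <= start <= stop <= ts.n_volumes):
            raise ValueError(
                f"volume_range {volume_range} outside [1, {ts.n_volumes}]"
            )
        if stop - start + 1 < 3:
            raise ValueError("volume_range must span at least 3 volumes")
        signals = signals[:, start - 1 : stop]
    sd = signals.std(axis=1)
    zero_var = np.flatnonzero(sd == 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(signals)
    if zero_var.size:
        r[zero_var, :] = 0.0
        r[:, zero_var] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationMatrix(
        values=r,
        region_labels=list(ts.region_labels),
        zero_variance_regions=[ts.region_labels[i] for i in zero_var],
    )


def threshold_topk(
    corr: CorrelationMatrix,
    k: int = 400,
    ranking: str = "signed",
) -> FunctionalNetwork:
    """Keep the K strongest links; binarize.

    Pairs are ranked by correlation value (``signed``, descending) or by
    absolute value (``absolute``); exact ties are broken by lexicographic
    node-pair order so the edge set is fully deterministic.
    """
    n = corr.n_regions
    n_pairs = n * (n - 1) // 2
    if k > n_pairs:
        raise ValueError(f"k={k} exceeds the {n_pairs} node pairs of a {n}-node network")
    if ranking not in ("signed", "absolute"):
        raise ValueError(f"unknown ranking mode {ranking!r}")
    iu, ju = np.triu_indices(n, k=1)
    vals = corr.values[iu, ju]
    key = np.abs(vals) if ranking == "absolute" else vals
    # stable sort on (-key, i, j): lexsort uses the last key as primary
    order = np.lexsort((ju, iu, -key))[:k]
    edges = frozenset((int(iu[o]), int(ju[o])) for o in order)
    return FunctionalNetwork(
        n_nodes=n, edges=edges, region_labels=tuple(corr.region_labels)
    )


def _sorted_edges(net: FunctionalNetwork) -> list[tuple[int, int]]:
    return sorted(net.edges)


def write_edgelist(net: FunctionalNetwork, path: str | Path) -> None:
    """Edge list as two-column TSV of region labels (``node_a<TAB>node_b``)."""
    labels = net.region_labels or tuple(range(net.n_nodes))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for i, j in _sorted_edges(net):
            w.writerow([labels[i], labels[j]])


def write_adjacency(net: FunctionalNetwork, path: str | Path) -> None:
    """Square 0/1 adjacency matrix as CSV (row per node, no header)."""
    a = net.adjacency().astype(int)
    np.savetxt(path, a, fmt="%d", delimiter=",")
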