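"""Sliding-window network dynamics and the flexibility statistic.

A network snapshot is built from each 40-volume window of the signal
matrix (top-K thresholding plus modularity maximization, exactly as for
the static network), the window sliding one volume at a time.  Because
the module detector assigns arbitrary labels independently per window,
modules are first matched across consecutive windows by node overlap;
only after this relabeling does a label change mean a genuine
reorganization.  Flexibility is then the rate at which regions change
module membership between consecutive windows, scaled to [0, 1].

Window-count convention: with T volumes, window length W and step s the
pipeline takes ``floor((T - W) / s)`` windows starting at volumes
1, 1+s, ... — for 216 volumes, W=40, s=1 that is 176 snapshots.  The
arithmetic admits one further start; ``include_final_window`` in
:class:`~netflex.network.PipelineConfig` restores that inclusive
convention (177).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from .community import detect_modules
from .io import RegionTimeSeries
from .network import PipelineConfig, correlation_matrix, threshold_topk

__all__ = [
    "WindowPartitionSequence",
    "FlexibilityResult",
    "window_sequence",
    "relabel_sequence",
    "flexibility",
    "subject_indices",
    "write_indices",
]


@dataclass(frozen=True)
class WindowPartitionSequence:
    """Ordered per-window partitions of a sliding-window analysis.

    ``intervals`` are 1-based inclusive volume ranges of equal length;
    ``memberships`` holds one label array per window (labels comparable
    across windows only when ``relabeled``); ``q_values`` the per-window
    modularity scores.
    """

    intervals: tuple
    memberships: tuple
    q_values: tuple
    region_labels: tuple
    relabeled: bool = False

    def __post_init__(self) -> None:
        lengths = {stop - start for start, stop in self.intervals}
        if len(lengths) > 1:
            raise ValueError("windows must share a single length")
        steps = {
            self.intervals[i + 1][0] - self.intervals[i][0]
            for i in range(len(self.intervals) - 1)
        }
        if len(steps) > 1:
            raise ValueError("window starts must be equally spaced")

    @property
    def n_windows(self) -> int:
        return len(self.intervals)

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)


@dataclass(frozen=True)
class FlexibilityResult:
    """Per-region and overall module-switching rates, both in [0, 1].

    Each region's rate is (# membership changes) / (n_windows - 1); the
    overall value is the mean across regions.

    A region that keeps its module through windows 1-2 of a three-window
    sequence and switches in window 3 has one change over two
    transitions:

    >>> 1 / (3 - 1)
    0.5
    """

    per_region: dict
    overall: float


def window_sequence(ts: RegionTimeSeries, cfg: PipelineConfig) -> WindowPartitionSequence:
    """Build, threshold and partition the network of every sliding window."""
    w, step = cfg.window_length, cfg.window_step
    if w > ts.n_volumes:
        raise ValueError(
            f"window_length {w} exceeds the {ts.n_volumes} available volumes"
        )
    n_windows = (ts.n_volumes - w) // step
    if cfg.include_final_window:
        n_windows += 1
    if n_windows < 2:
        raise ValueError(
            "flexibility undefined: fewer than 2 windows "
            f"({ts.n_volumes} volumes, window {w}, step {step})"
        )
    intervals = []
    memberships = []
    qs = []
    for idx in range(n_windows):
        start = 1 + idx * step
        stop = start + w - 1
        corr = correlation_matrix(ts, volume_range=(start, stop))
        net = threshold_topk(corr, k=cfg.k_links, ranking=cfg.ranking)
        res = detect_modules(net, fine_tune=cfg.fine_tune)
        intervals.append((start, stop))
        memberships.append(np.array(res.partition.membership, dtype=int))
        qs.append(res.q)
    return WindowPartitionSequence(
        intervals=tuple(intervals),
        memberships=tuple(tuple(int(x) for x in mem) for mem in memberships),
        q_values=tuple(qs),
        region_labels=tuple(ts.region_labels),
        relabeled=False,
    )


def _match_labels(
    prev: np.ndarray, cur: np.ndarray, next_fresh: int
) -> tuple[np.ndarray, int]:
    """Relabel `cur` so modules inherit the label of their best match in `prev`.

    Matching maximizes total node overlap with an exact one-to-one
    assignment; among co-optimal assignments ties go to the larger
    current module, then to the module earlier in canonical order
    (ascending smallest member node — the order in which the detector
    assigns labels, so equivalently the lower label) — encoded as
    integer lexicographic terms inside the assignment weights.  Working
    in canonical module order keeps the whole matching invariant to any
    relabeling of the incoming window.  Modules left unmatched (or
    matched with zero overlap) get fresh labels never used before.
    """
    n = len(cur)
    # canonical ordering on both sides: by smallest member node.  This
    # makes the whole matching a function of module CONTENT only, so
    # relabeling either window never changes which memberships end up
    # flagged as changed.
    prev_labels = np.array(
        sorted(np.unique(prev), key=lambda pl: int(np.flatnonzero(prev == pl)[0]))
    )
    cur_labels = np.array(
        sorted(np.unique(cur), key=lambda cl: int(np.flatnonzero(cur == cl)[0]))
    )
    overlap = np.zeros((prev_labels.size, cur_labels.size), dtype=np.int64)
    cur_sizes = np.zeros(cur_labels.size, dtype=np.int64)
    for ci, cl in enumerate(cur_labels):
        in_c = cur == cl
        cur_sizes[ci] = in_c.sum()
        for pi, pl in enumerate(prev_labels):
            overlap[pi, ci] = np.sum(in_c & (prev == pl))
    # weight = overlap (primary), current-module size (secondary),
    # lower current label (tertiary); integer scaling keeps each level
    # strictly dominant over the sum of all lower-level terms.
    n_c = cur_labels.size
    w3 = n_c - np.arange(n_c)  # lower label -> larger term
    scale3 = int(w3.sum()) + 1
    w2 = cur_sizes * scale3
    scale2 = int(w2.sum()) + scale3
    weights = overlap * scale2 + (w2 + w3)[np.newaxis, :]
    weights[overlap == 0] = 0  # zero overlap never counts as a match
    rows, cols = linear_sum_assignment(weights, maximize=True)
    new = np.empty_like(cur)
    assigned = {}
    for pi, ci in zip(rows, cols):
        if overlap[pi, ci] > 0:
            assigned[cur_labels[ci]] = prev_labels[pi]
    for cl in cur_labels:
        if cl not in assigned:
            assigned[cl] = next_fresh
            next_fresh += 1
    for i in range(n):
        new[i] = assigned[cur[i]]
    return new, next_fresh


def relabel_sequence(seq: WindowPartitionSequence) -> WindowPartitionSequence:
    """Chain-match module labels across consecutive windows.

    Window 1 keeps its labels; every later window inherits labels from
    its predecessor by maximum node overlap, so a label change between
    consecutive windows reflects true membership reorganization rather
    than the detector's arbitrary labeling.  Membership sets are
    untouched; only labels move.
    """
    if seq.relabeled:
        raise ValueError("sequence is already relabeled")
    mems = [np.array(m, dtype=int) for m in seq.memberships]
    out = [mems[0]]
    next_fresh = int(mems[0].max()) + 1
    for cur in mems[1:]:
        new, next_fresh = _match_labels(out[-1], cur, next_fresh)
        next_fresh = max(next_fresh, int(new.max()) + 1)
        out.append(new)
    return replace(
        seq,
        memberships=tuple(tuple(int(x) for x in m) for m in out),
        relabeled=True,
    )


def flexibility(seq: WindowPartitionSequence) -> FlexibilityResult:
    """Rate of module-membership change per region, averaged network-wide."""
    if not seq.relabeled:
        raise ValueError(
            "flexibility requires a relabeled sequence: labels of raw "
            "window partitions are not comparable"
        )
    if seq.n_windows < 2:
        raise ValueError("flexibility undefined: need at least 2 windows")
    mems = np.array(seq.memberships, dtype=int)  # windows x regions
    changes = (mems[1:] != mems[:-1]).sum(axis=0)
    rates = changes / (seq.n_windows - 1)
    per_region = {
        lab: float(r) for lab, r in zip(seq.region_labels, rates)
    }
    return FlexibilityResult(per_region=per_region, overall=float(rates.mean()))


def subject_indices(ts: RegionTimeSeries, cfg: PipelineConfig | None = None) -> dict:
    """Static modularity plus sliding-window flexibility for one subject.

    Returns a flat record suitable for one row of ``indices.csv``.
    """
    cfg = cfg or PipelineConfig()
    corr = correlation_matrix(ts)
    net = threshold_topk(corr, k=cfg.k_links, ranking=cfg.ranking)
    static = detect_modules(net, fine_tune=cfg.fine_tune)
    seq = relabel_sequence(window_sequence(ts, cfg))
    flex = flexibility(seq)
    return {
        "subject": ts.subject_id,
        "modularity_q": static.q,
        "flexibility": flex.overall,
        "n_windows": seq.n_windows,
        "k_links": cfg.k_links,
        "window_length": cfg.window_length,
    }


def write_indices(records: list[dict], path: str | Path) -> None:
    """Write per-subject network indices as CSV."""
    cols = ["subject", "modularity_q", "flexibility", "n_windows", "k_links", "window_length"]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols)
        w.writeheader()
        for rec in records:
            w.writerow({c: rec[c] for c in cols})
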