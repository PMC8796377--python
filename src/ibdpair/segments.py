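"""IBD tract extraction and path-comparison metrics.

Decoded per-site IBD states are turned into contiguous segments, either
directly from the Viterbi path or from posterior probabilities with a
confidence cutoff (sites whose maximum posterior falls below the cutoff are
left unassigned and break runs).  Output coordinates follow the BED
convention: 0-based half-open, spanning the first to the last member site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ibd_model import SiteTable

__all__ = [
    "IBDSegment",
    "call_segments_viterbi",
    "call_segments_posterior",
    "compare_assignments",
]

UNASSIGNED = -1


@dataclass(frozen=True)
class IBDSegment:
    """A maximal run of one IBD state.

    ``start``/``end`` are BED-style 0-based half-open physical coordinates;
    ``mean_posterior`` averages the posterior of the assigned state over the
    member sites (1.0 for Viterbi calls without posteriors).
    """

    chrom: str
    start: int
    end: int
    state: int
    n_sites: int
    mean_posterior: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("segment start must precede end")
        if self.n_sites < 1:
            raise ValueError("segment must contain at least one site")


def _runs_to_segments(
    assigned: np.ndarray, sites: SiteTable, posteriors: np.ndarray | None
) -> list[IBDSegment]:
    """Group consecutive same-state assigned sites into segments.

    Runs break at chromosome boundaries, at state changes and at
    unassigned sites.
    """
    n = len(assigned)
    if n != len(sites):
        raise ValueError("assignment vector and site table lengths differ")
    breaks = np.ones(n, dtype=bool)
    if n > 1:
        breaks[1:] = (assigned[1:] != assigned[:-1]) | sites.new_chrom[1:]
    segments: list[IBDSegment] = []
    starts = np.nonzero(breaks)[0]
    ends = np.append(starts[1:], n)
    for s, t in zip(starts, ends):
        state = int(assigned[s])
        if state == UNASSIGNED:
            continue
        if posteriors is not None:
            mean_post = float(posteriors[s:t, state].mean())
        else:
            mean_post = 1.0
        segments.append(
            IBDSegment(
                chrom=str(sites.chrom[s]),
                start=int(sites.pos[s]) - 1,
                end=int(sites.pos[t - 1]),
                state=state,
                n_sites=int(t - s),
                mean_posterior=mean_post,
            )
        )
    return segments


def call_segments_viterbi(
    path: np.ndarray, sites: SiteTable, posteriors: np.ndarray | None = None
) -> list[IBDSegment]:
    """Run-length encode a Viterbi path into IBD segments.

    Every site belongs to exactly one segment, so the segments partition
    each chromosome's sites.
    """
    path = np.asarray(path)
    if path.shape != (len(sites),):
        raise ValueError("path and site table lengths differ")
    if not np.isin(path, (0, 1, 2)).all():
        raise ValueError("path states must be 0, 1 or 2")
    return _runs_to_segments(path.astype(np.int64), sites, posteriors)


def call_segments_posterior(
    posteriors: np.ndarray, sites: SiteTable, cutoff: float = 0.95
) -> list[IBDSegment]:
    """Call segments from posterior probabilities with a confidence cutoff.

    A site is assigned its argmax state only if that posterior is at least
    ``cutoff`` (which must exceed 1/3, the uninformative level); unassigned
    sites break runs and belong to no segment.
    """
    if not (1.0 / 3.0 < cutoff <= 1.0):
        raise ValueError(f"cutoff must lie in (1/3, 1], got {cutoff!r}")
    posteriors = np.asarray(posteriors, dtype=float)
    if posteriors.shape != (len(sites), 3):
        raise ValueError("posteriors must be L x 3, aligned to the site table")
    assigned = posteriors.argmax(axis=1).astype(np.int64)
    assigned[posteriors.max(axis=1) < cutoff] = UNASSIGNED
    return _runs_to_segments(assigned, sites, posteriors)


def compare_assignments(test_path: np.ndarray, truth_path: np.ndarray) -> dict:
    """Site-wise comparison of a decoded path against a reference path.

    Returns overall accuracy plus one-vs-rest false positive and false
    negative rates per IBD state, all derived from the 3x3 confusion
    matrix (rows = truth, columns = test).  Rates with an empty denominator
    are reported as NaN.
    """
    test = np.asarray(test_path)
    truth = np.asarray(truth_path)
    if test.shape != truth.shape:
        raise ValueError("paths must have equal length")
    n = test.size
    confusion = np.zeros((3, 3), dtype=np.int64)
    np.add.at(confusion, (truth.astype(int), test.astype(int)), 1)
    accuracy = float(np.trace(confusion)) / n
    fpr = np.full(3, np.nan)
    fnr = np.full(3, np.nan)
    for s in range(3):
        tp = confusion[s, s]
        fn = confusion[s].sum() - tp
        fp = confusion[:, s].sum() - tp
        tn = n - tp - fn - fp
        if fp + tn > 0:
            fpr[s] = fp / (fp + tn)
        if fn + tp > 0:
            fnr[s] = fn / (fn + tp)
    return {
        "accuracy": accuracy,
        "confusion": confusion,
        "fpr": fpr,
        "fnr": fnr,
        "n_sites": int(n),
    }
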