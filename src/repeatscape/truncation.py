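"""5' truncation (3':5' normalized depth ratio) and element age (pairwise pi)
from reads mapped to a LINE consensus.

The consensus is stored 5'->3' of the element, so "5' half" means the first
half of the reference. All depth summaries are divided by the total number of
reads aligned to the full-length reference, making profiles comparable
across species with different sequencing depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .consensus import ReadAlignment, pileup_counts

logger = logging.getLogger(__name__)

WINDOW = 10  # bp; tiling windows (step = window)
MIN_COMPARABLE_SITES = 30


@dataclass
class CoverageProfile:
    element_family: str
    window_depth: np.ndarray  # normalized mean depth per 10 bp tile
    half_depth: tuple  # (5' half, 3' half)
    third_depth: tuple  # (5', middle, 3')
    ratio_3p_5p: Optional[float]
    n_reads_total: int


@dataclass
class DivergenceProfile:
    element_family: str
    per_read_pi: np.ndarray
    median_pi: float
    excluded_sites: np.ndarray
    bin_width: float
    n_reads_used: int
    n_reads_dropped: int


def position_depth(alignments: Sequence[ReadAlignment], length: int) -> np.ndarray:
    depth = np.zeros(length, dtype=np.int64)
    for aln in alignments:
        depth[aln.ref_start : aln.ref_end] += 1
    return depth


def coverage_profile(
    alignments: Sequence[ReadAlignment],
    consensus_length: int,
    element_family: str = "",
) -> CoverageProfile:
    """Depth per 10 bp tile, per half and per third, each normalized by the
    total aligned-read count; ratio_3p_5p = mean 3' half depth / mean 5' half
    depth (None when the 5' half has zero depth)."""
    if not alignments:
        raise ValueError("need at least one alignment")
    depth = position_depth(alignments, consensus_length).astype(float)
    n_total = len(alignments)

    n_windows = (consensus_length + WINDOW - 1) // WINDOW
    window_depth = np.array(
        [depth[i * WINDOW : (i + 1) * WINDOW].mean() for i in range(n_windows)]
    ) / n_total

    mid = consensus_length // 2
    half5 = depth[:mid].mean() / n_total
    half3 = depth[mid:].mean() / n_total

    t1, t2 = consensus_length // 3, 2 * consensus_length // 3
    thirds = (
        depth[:t1].mean() / n_total,
        depth[t1:t2].mean() / n_total,
        depth[t2:].mean() / n_total,
    )

    ratio = None if half5 == 0 else half3 / half5
    if ratio is None:
        logger.warning("5' half has zero depth; 3':5' ratio undefined")
    return CoverageProfile(
        element_family=element_family,
        window_depth=window_depth,
        half_depth=(half5, half3),
        third_depth=thirds,
        ratio_3p_5p=ratio,
        n_reads_total=n_total,
    )


def column_frequencies(
    alignments: Sequence[ReadAlignment], consensus_length: int
) -> np.ndarray:
    """Per consensus position: frequency of the most frequent base among
    covering reads (NaN for uncovered columns)."""
    counts = pileup_counts(alignments, consensus_length)
    depth = counts.sum(axis=0)
    freqs = np.full(consensus_length, np.nan)
    covered = depth > 0
    freqs[covered] = counts[:, covered].max(axis=0) / depth[covered]
    return freqs


def subfamily_site_filter(
    freqs: np.ndarray,
    bin_width: float = 0.01,
    max_bin_distance: int = 3,
) -> np.ndarray:
    """Positions whose top-base frequency falls in a histogram bin more than
    ``max_bin_distance`` bins from the modal bin; these are treated as
    defining a separate subfamily and excluded from divergence estimates.

    Empty (NaN) columns are skipped with a warning and never excluded.
    """
    valid = ~np.isnan(freqs)
    if not valid.any():
        raise ValueError("no columns with observations")
    if (~valid).any():
        logger.warning("%d empty columns skipped", int((~valid).sum()))
    bins = np.full(len(freqs), -1, dtype=int)
    bins[valid] = np.floor(freqs[valid] / bin_width + 1e-9).astype(int)
    observed = bins[valid]
    counts = np.bincount(observed)
    top = counts.max()
    # modal bin; ties resolved toward the higher-frequency bin
    mode_bin = int(np.flatnonzero(counts == top)[-1])
    excluded = valid & (np.abs(bins - mode_bin) > max_bin_distance)
    return np.flatnonzero(excluded)


def pairwise_pi(
    alignments: Sequence[ReadAlignment],
    consensus: str,
    excluded_sites: Sequence[int] = (),
    min_sites: int = MIN_COMPARABLE_SITES,
    element_family: str = "",
) -> DivergenceProfile:
    """Per-read divergence from the consensus over comparable sites.

    Comparable sites are aligned, non-N on both sequences, and not in
    ``excluded_sites``; reads with fewer than ``min_sites`` comparable sites
    are dropped. The summary statistic is the median over reads.
    """
    cons = np.frombuffer(consensus.encode("ascii"), dtype=np.uint8)
    ex_mask = np.zeros(len(consensus), dtype=bool)
    ex = np.asarray(list(excluded_sites), dtype=int)
    if ex.size:
        ex_mask[ex] = True
    pis = []
    dropped = 0
    for aln in alignments:
        arr = np.frombuffer(aln.seq_aligned.encode("ascii"), dtype=np.uint8)
        span = slice(aln.ref_start, aln.ref_end)
        cons_sub = cons[span]
        usable = (
            (arr != ord("N"))
            & (cons_sub != ord("N"))
            & ~ex_mask[span]
        )
        n = int(usable.sum())
        if n < min_sites:
            dropped += 1
            continue
        mism = int(np.count_nonzero((arr != cons_sub) & usable))
        pis.append(mism / n)
    if not pis:
        raise ValueError("all reads dropped (too few comparable sites)")
    pis = np.array(pis)
    return DivergenceProfile(
        element_family=element_family,
        per_read_pi=pis,
        median_pi=float(np.median(pis)),
        excluded_sites=np.asarray(sorted(excluded_sites), dtype=int),
        bin_width=0.01,
        n_reads_used=len(pis),
        n_reads_dropped=dropped,
    )
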