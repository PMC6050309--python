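"""TE-family enrichment adjacent to a target SSR motif.

Flanks (default 400 bp each side of a locus) are compared against replicate
random genomic backgrounds with a matching length multiset; enrichment is a
one-tailed exact test on region-level presence/absence. Region-level counts
(not base counts) are used because bases within a region are not independent
trials.
"""

from __future__ import annotations

import logging
import math
import re
from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass
from statistics import median

import numpy as np
from scipy import stats

from .ssr import _merge_intervals
from .types import GenomeSequence, Region, SsrLocus, TeAnnotation

logger = logging.getLogger(__name__)

DEFAULT_FLANK_WIDTH = 400
DEFAULT_N_REPLICATES = 5
DEFAULT_ALPHA = 0.01


@dataclass
class FlankSet:
    target_motif: str
    flank_width: int
    regions: list  # list[Region]

    @property
    def total_bases(self) -> int:
        return sum(r.length for r in self.regions)


@dataclass
class EnrichmentResult:
    te_family: str
    adjacent_content: float
    background_content: float
    ratio: float
    p_value: float
    n_flanks: int
    n_background_regions: int
    flank_hits: int
    background_hits: int
    significant: bool
    # side-resolved hit counts (5p = flank upstream of the locus), reported
    # alongside the side-agnostic test
    flank_hits_5p: int = 0
    flank_hits_3p: int = 0


@dataclass
class CoOccurrence:
    te_family: str
    joint_prob: float
    conditional_prob: float


def extract_flanks(
    loci: list[SsrLocus],
    genome: list[GenomeSequence],
    width: int = DEFAULT_FLANK_WIDTH,
    target_motif: str | None = None,
) -> FlankSet:
    """Up to two regions per locus, [start-width, start) and [end, end+width),
    clipped at contig bounds; zero-length regions are dropped."""
    if width <= 0:
        raise ValueError("flank width must be positive")
    lengths = {c.name: c.length for c in genome}
    regions = []
    motifs = set()
    for i, locus in enumerate(loci):
        if locus.contig not in lengths:
            raise ValueError(f"locus contig {locus.contig!r} not in assembly")
        clen = lengths[locus.contig]
        if locus.end > clen:
            raise ValueError(f"locus [{locus.start},{locus.end}) exceeds {locus.contig}")
        motifs.add(locus.canonical_motif)
        up = Region(locus.contig, max(0, locus.start - width), locus.start, "5p", i)
        down = Region(locus.contig, locus.end, min(clen, locus.end + width), "3p", i)
        for r in (up, down):
            if r.length > 0:
                regions.append(r)
    if target_motif is None:
        target_motif = motifs.pop() if len(motifs) == 1 else "mixed"
    return FlankSet(target_motif=target_motif, flank_width=width, regions=regions)


_GAP_RE = re.compile("N{10,}")


def _gap_intervals(genome: list[GenomeSequence]) -> dict:
    gaps = {}
    for c in genome:
        gaps[c.name] = [(m.start(), m.end()) for m in _GAP_RE.finditer(c.residues)]
    return gaps


def sample_background(
    genome: list[GenomeSequence],
    flanks: FlankSet,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
    max_tries_factor: int = 100,
) -> list[list[Region]]:
    """Replicate random region sets matching the flank length multiset.

    Placement is uniform over contigs weighted by length; regions that would
    extend past a contig end or overlap an assembly gap (>=10 consecutive N)
    are rejected and redrawn. Overlaps between background regions are
    allowed. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    contigs = [c for c in genome if c.length > 0]
    names = [c.name for c in contigs]
    lengths = np.array([c.length for c in contigs], dtype=float)
    weights = lengths / lengths.sum()
    gaps = _gap_intervals(genome)
    target_lengths = [r.length for r in flanks.regions]
    max_len = max(target_lengths, default=0)
    if max_len and all(c.length < max_len for c in contigs):
        raise ValueError("no contig long enough to place the largest region")

    replicates = []
    for _ in range(n_replicates):
        regions = []
        for rlen in target_lengths:
            budget = max_tries_factor * max(1, len(target_lengths))
            placed = False
            for _ in range(budget):
                ci = rng.choice(len(contigs), p=weights)
                clen = int(lengths[ci])
                if clen < rlen:
                    continue
                start = int(rng.integers(0, clen - rlen + 1))
                end = start + rlen
                if any(s < end and start < e for s, e in gaps[names[ci]]):
                    continue
                regions.append(Region(names[ci], start, end))
                placed = True
                break
            if not placed:
                raise RuntimeError("could not place background region within budget")
        replicates.append(regions)
    return replicates


def _family_index(annotations: list[TeAnnotation]) -> dict:
    """family -> contig -> (starts array, ends array) of merged intervals."""
    by_family = defaultdict(lambda: defaultdict(list))
    for a in annotations:
        by_family[a.family][a.contig].append((a.start, a.end))
    index = {}
    for fam, by_contig in by_family.items():
        index[fam] = {}
        for contig, ivs in by_contig.items():
            merged = _merge_intervals(ivs)
            index[fam][contig] = (
                np.array([s for s, _ in merged]),
                np.array([e for _, e in merged]),
            )
    return index


def _overlap_bases(index_entry, region: Region) -> int:
    """Total overlap between a region and merged sorted intervals."""
    if index_entry is None:
        return 0
    starts, ends = index_entry
    # first interval whose end > region.start
    i = int(np.searchsorted(ends, region.start, side="right"))
    total = 0
    while i < len(starts) and starts[i] < region.end:
        total += min(int(ends[i]), region.end) - max(int(starts[i]), region.start)
        i += 1
    return total


def region_te_content(
    regions: list[Region], annotations: list[TeAnnotation]
) -> tuple[dict, dict]:
    """Per family: fraction of region bases annotated, and the number of
    regions containing at least one overlap of that family."""
    total_bases = sum(r.length for r in regions)
    index = _family_index(annotations)
    content = {}
    hits = {}
    for fam, by_contig in index.items():
        bases = 0
        n_hit = 0
        for r in regions:
            ov = _overlap_bases(by_contig.get(r.contig), r)
            bases += ov
            if ov > 0:
                n_hit += 1
        content[fam] = bases / total_bases if total_bases else 0.0
        hits[fam] = n_hit
    return content, hits


def fisher_greater_p(table) -> float:
    """One-tailed (greater) Fisher exact p for a 2x2 table
    [[a, b], [c, d]] with 'a' the flank-hit cell."""
    return float(stats.fisher_exact(table, alternative="greater")[1])


def enrichment_test(
    flanks: FlankSet,
    backgrounds: list[list[Region]],
    annotations: list[TeAnnotation],
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentResult]:
    """Per-family enrichment of TE content in flanks vs pooled backgrounds.

    ratio = flank base-fraction / mean background base-fraction (0/0 -> 1,
    logged). The exact test is on region-level presence/absence with
    alternative "greater" (enrichment in flanks).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not backgrounds:
        raise ValueError("need at least one background replicate")
    flank_content, flank_hits = region_te_content(flanks.regions, annotations)
    side_hits = {}
    for side in ("5p", "3p"):
        side_regions = [r for r in flanks.regions if r.side == side]
        if side_regions:
            _, side_hits[side] = region_te_content(side_regions, annotations)
        else:
            side_hits[side] = {}
    bg_contents = []
    bg_hits_pooled = defaultdict(int)
    n_bg_regions = 0
    for rep in backgrounds:
        c, h = region_te_content(rep, annotations)
        bg_contents.append(c)
        n_bg_regions += len(rep)
        for fam, n in h.items():
            bg_hits_pooled[fam] += n

    families = sorted(set(flank_content) | set(bg_hits_pooled))
    n_flanks = len(flanks.regions)
    results = []
    for fam in families:
        fc = flank_content.get(fam, 0.0)
        bc = float(np.mean([c.get(fam, 0.0) for c in bg_contents]))
        if fc == 0.0 and bc == 0.0:
            ratio = 1.0
            logger.info("family %s absent from flanks and background; ratio=1", fam)
        elif bc == 0.0:
            ratio = math.inf
        else:
            ratio = fc / bc
        fh = flank_hits.get(fam, 0)
        bh = bg_hits_pooled.get(fam, 0)
        p = fisher_greater_p([[fh, n_flanks - fh], [bh, n_bg_regions - bh]])
        results.append(
            EnrichmentResult(
                te_family=fam,
                adjacent_content=fc,
                background_content=bc,
                ratio=ratio,
                p_value=p,
                n_flanks=n_flanks,
                n_background_regions=n_bg_regions,
                flank_hits=fh,
                background_hits=bh,
                significant=p < alpha,
                flank_hits_5p=side_hits["5p"].get(fam, 0),
                flank_hits_3p=side_hits["3p"].get(fam, 0),
            )
        )
    return results


def co_occurrence(
    loci: list[SsrLocus],
    annotations: list[TeAnnotation],
    genome: list[GenomeSequence],
    flank_width: int = DEFAULT_FLANK_WIDTH,
    tile_width: int | None = None,
    families: list[str] | None = None,
) -> list[CoOccurrence]:
    """Joint and conditional SSR/TE co-occurrence probabilities.

    conditional = fraction of loci with >=1 family annotation within
    ``flank_width`` on either side; joint = fraction of non-overlapping
    genome tiles containing >=1 locus AND >=1 family annotation. The default
    tile width is the footprint of a flanked locus: 2 x flank_width + median
    array length.
    """
    if tile_width is None:
        med = median([l.array_length for l in loci]) if loci else 0
        tile_width = int(2 * flank_width + med)
    if tile_width <= 0:
        raise ValueError("tile_width must be positive")
    index = _family_index(annotations)
    if families is None:
        families = sorted(index)

    # tiles per contig (trailing partial tile included)
    loci_by_contig = defaultdict(list)
    for l in loci:
        loci_by_contig[l.contig].append((l.start, l.end))

    results = []
    for fam in families:
        by_contig = index.get(fam, {})
        # conditional: annotation within flank_width of the locus
        n_adj = 0
        for l in loci:
            probe = Region(l.contig, max(0, l.start - flank_width), l.end + flank_width)
            if _overlap_bases(by_contig.get(l.contig), probe) > 0:
                n_adj += 1
        conditional = n_adj / len(loci) if loci else 0.0

        n_tiles = 0
        n_joint = 0
        for contig in genome:
            starts_loci = sorted(loci_by_contig.get(contig.name, []))
            ls = [s for s, _ in starts_loci]
            le = [e for _, e in starts_loci]
            fam_entry = by_contig.get(contig.name)
            for t0 in range(0, contig.length, tile_width):
                t1 = min(t0 + tile_width, contig.length)
                n_tiles += 1
                # any locus overlapping [t0, t1)?
                i = bisect_left(le, t0 + 1)
                has_ssr = i < len(ls) and ls[i] < t1
                if not has_ssr:
                    continue
                if _overlap_bases(fam_entry, Region(contig.name, t0, t1)) > 0:
                    n_joint += 1
        joint = n_joint / n_tiles if n_tiles else 0.0
        results.append(CoOccurrence(te_family=fam, joint_prob=joint, conditional_prob=conditional))
    return results
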