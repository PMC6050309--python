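"""Perfect-microsatellite detection and repeat-landscape summaries.

A locus is a maximal run of a perfectly repeated 2-6 bp unit; whole-unit
counting applies, so reported array length is always n_units x unit length.
Minimum array lengths: 12 bp for 2-4mers and "longer than 15 bp" for 5-6mers,
giving effective whole-unit minima of 12/12/12/20/18 bp.

N bases break arrays. Scanning is forward-strand only; canonicalization
(lexicographic minimum over rotations and reverse-complement rotations)
makes the counts strand-symmetric.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .types import GenomeSequence, Read, SsrLocus, TeAnnotation, revcomp

#: minimum whole-unit array length per unit length (1-mers kept for the
#: separately-reported homopolymer channel)
MIN_ARRAY_LENGTH = {1: 12, 2: 12, 3: 12, 4: 12, 5: 20, 6: 18}

MAX_UNIT = 6


class ReducibleUnitError(ValueError):
    """The unit is itself a tandem repeat of a shorter unit."""


def is_reducible(unit: str) -> bool:
    """True if ``unit`` is a whole-number repeat of a shorter unit."""
    k = len(unit)
    for p in range(1, k):
        if k % p == 0 and unit == unit[:p] * (k // p):
            return True
    return False


def canonicalize_motif(unit: str) -> str:
    """Rotation/strand-normalized motif: the lexicographically smallest
    string among all rotations of the unit and of its reverse complement.

    Raises on non-ACGT characters and on reducible units (e.g. "ATAT").
    """
    if not 1 <= len(unit) <= MAX_UNIT:
        raise ValueError(f"unit length must be 1-{MAX_UNIT}, got {len(unit)}")
    if any(c not in "ACGT" for c in unit):
        raise ValueError(f"unit must be over ACGT: {unit!r}")
    if is_reducible(unit):
        raise ReducibleUnitError(f"unit {unit!r} is reducible")
    rc = revcomp(unit)
    k = len(unit)
    candidates = [unit[i:] + unit[:i] for i in range(k)]
    candidates += [rc[i:] + rc[:i] for i in range(k)]
    return min(candidates)


# ---------------------------------------------------------------------------
# Scanner
# ---------------------------------------------------------------------------


def _scan_contig(contig: GenomeSequence, max_unit: int) -> list[SsrLocus]:
    """Find maximal perfect tandem regions for every unit length 1..max_unit.

    For period k, positions i where s[i] == s[i+k] (both non-N) form runs; a
    run over [i, j) corresponds to a perfect region [i, j + k). Regions whose
    minimal period is < k are skipped (they are found at the smaller period).
    The region is trimmed at its right end to whole units.
    """
    seq = contig.residues
    L = len(seq)
    if L < 2:
        return []
    a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    not_n = a != ord("N")
    match = {}
    cum = {}
    for k in range(1, max_unit + 1):
        if L <= k:
            match[k] = np.zeros(0, dtype=bool)
        else:
            match[k] = (a[k:] == a[:-k]) & not_n[k:] & not_n[:-k]
        # prefix sums for O(1) "is period p over [i, j)" queries
        cum[k] = np.concatenate(([0], np.cumsum(match[k], dtype=np.int64)))

    def has_period(p: int, start: int, length: int) -> bool:
        # region [start, start+length) has period p iff match_p is all-true
        # over [start, start+length-p)
        n = length - p
        if n <= 0:
            return True
        return (cum[p][start + n] - cum[p][start]) == n

    loci = []
    for k in range(1, max_unit + 1):
        m = match[k]
        if m.size == 0:
            continue
        # run starts / ends in the boolean match array
        padded = np.concatenate(([False], m, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)  # exclusive
        for i, j in zip(starts, ends):
            region_len = (j - i) + k
            n_units = region_len // k
            if n_units * k < MIN_ARRAY_LENGTH[k]:
                continue
            # minimal-period check: skip if any smaller period covers region
            if any(has_period(p, i, region_len) for p in range(1, k)):
                continue
            unit = seq[i : i + k]
            loci.append(
                SsrLocus(
                    contig=contig.name,
                    start=int(i),
                    end=int(i + n_units * k),
                    unit=unit,
                    canonical_motif=canonicalize_motif(unit),
                    n_units=int(n_units),
                )
            )
    return loci


def resolve_overlaps(loci: list[SsrLocus]) -> list[SsrLocus]:
    """Greedy overlap resolution across unit lengths: keep the longer array;
    tie -> smaller unit; remaining tie -> leftmost."""
    kept: list[SsrLocus] = []
    occupied = defaultdict(list)  # contig -> list of kept (start, end)
    for locus in sorted(
        loci, key=lambda l: (-l.array_length, l.unit_length, l.contig, l.start)
    ):
        if all(
            locus.end <= s or locus.start >= e for s, e in occupied[locus.contig]
        ):
            kept.append(locus)
            occupied[locus.contig].append((locus.start, locus.end))
    kept.sort(key=lambda l: (l.contig, l.start))
    return kept


def scan_ssrs(
    genome: list[GenomeSequence] | GenomeSequence,
    include_homopolymers: bool = False,
    max_unit: int = MAX_UNIT,
) -> list[SsrLocus]:
    """Scan an assembly for maximal perfect microsatellite arrays.

    Returns non-overlapping loci with units of length 2..``max_unit``
    (1-mers only when ``include_homopolymers``; they are never pooled with
    the 2-6mer landscape downstream).
    """
    if isinstance(genome, GenomeSequence):
        genome = [genome]
    loci = []
    for contig in genome:
        loci.extend(_scan_contig(contig, max_unit))
    if not include_homopolymers:
        loci = [l for l in loci if l.unit_length >= 2]
    return resolve_overlaps(loci)


# ---------------------------------------------------------------------------
# Landscape summaries
# ---------------------------------------------------------------------------


@dataclass
class SsrLandscape:
    """Per-genome SSR density statistics (loci/Mbp and bp/Mbp)."""

    species: str
    genome_size: int
    per_motif: dict = field(default_factory=dict)  # motif -> (loci/Mbp, bp/Mbp)
    per_unit_length: dict = field(default_factory=dict)  # k -> (loci/Mbp, bp/Mbp)
    total_loci_per_mbp: float = 0.0
    total_bp_per_mbp: float = 0.0

    @property
    def genome_size_mbp(self) -> float:
        return self.genome_size / 1e6


def summarize_landscape(
    loci: list[SsrLocus], genome_size: int, species: str = ""
) -> SsrLandscape:
    """Densities per canonical motif and per unit-length class.

    loci/Mbp = count x 1e6 / genome_size; bp/Mbp = total array bp x 1e6 /
    genome_size. Homopolymer loci, if present, are excluded from totals.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    scale = 1e6 / genome_size
    by_motif = defaultdict(lambda: [0, 0])
    by_k = defaultdict(lambda: [0, 0])
    total = [0, 0]
    for l in loci:
        if l.unit_length < 2:
            continue
        by_motif[l.canonical_motif][0] += 1
        by_motif[l.canonical_motif][1] += l.array_length
        by_k[l.unit_length][0] += 1
        by_k[l.unit_length][1] += l.array_length
        total[0] += 1
        total[1] += l.array_length
    return SsrLandscape(
        species=species,
        genome_size=genome_size,
        per_motif={m: (c * scale, bp * scale) for m, (c, bp) in by_motif.items()},
        per_unit_length={k: (c * scale, bp * scale) for k, (c, bp) in by_k.items()},
        total_loci_per_mbp=total[0] * scale,
        total_bp_per_mbp=total[1] * scale,
    )


def fold_variation(values) -> float:
    """max/min over strictly positive per-species values."""
    values = list(values)
    if len(values) < 2:
        raise ValueError("need at least two values")
    if any(v <= 0 for v in values):
        raise ValueError("all values must be strictly positive")
    return max(values) / min(values)


def gc_content(genome: list[GenomeSequence] | GenomeSequence) -> float:
    """(G+C)/(A+C+G+T); Ns excluded from the denominator."""
    if isinstance(genome, GenomeSequence):
        genome = [genome]
    gc = 0
    acgt = 0
    for contig in genome:
        a = np.frombuffer(contig.residues.encode("ascii"), dtype=np.uint8)
        for b in b"ACGT":
            n = int(np.count_nonzero(a == b))
            acgt += n
            if b in b"GC":
                gc += n
    if acgt == 0:
        raise ValueError("no non-N bases in genome")
    return gc / acgt


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _merged_bases(annotations, key=None) -> dict:
    """Overlap-collapsed annotated bases grouped by ``key(annotation)``."""
    groups = defaultdict(lambda: defaultdict(list))
    for a in annotations:
        groups[key(a) if key else None][a.contig].append((a.start, a.end))
    out = {}
    for g, by_contig in groups.items():
        out[g] = sum(
            e - s
            for ivs in by_contig.values()
            for s, e in _merge_intervals(ivs)
        )
    return out


@dataclass
class TeLandscape:
    """Per-family / per-class genomic TE percentages (overlap-collapsed)."""

    genome_size: int
    per_family_pct: dict
    per_class_pct: dict
    total_pct: float


def te_landscape_summary(
    annotations: list[TeAnnotation],
    genome_size: int,
    contig_lengths: dict | None = None,
) -> TeLandscape:
    """Genomic % occupied per family, per te_class, and in total.

    Overlapping annotations within a grouping are counted once. When
    ``contig_lengths`` is given, out-of-bounds annotations raise.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if contig_lengths is not None:
        for a in annotations:
            if a.contig not in contig_lengths or a.end > contig_lengths[a.contig]:
                raise ValueError(
                    f"annotation [{a.start},{a.end}) out of bounds on {a.contig}"
                )
    scale = 100.0 / genome_size
    fam = _merged_bases(annotations, key=lambda a: a.family)
    cls = _merged_bases(annotations, key=lambda a: a.te_class)
    tot = _merged_bases(annotations)
    return TeLandscape(
        genome_size=genome_size,
        per_family_pct={f: bp * scale for f, bp in fam.items()},
        per_class_pct={c: bp * scale for c, bp in cls.items()},
        total_pct=tot.get(None, 0) * scale,
    )


def subsample_reads(reads: list[Read], target_mbp: float, seed: int) -> list[Read]:
    """Uniform sample without replacement until cumulative length first
    reaches ``target_mbp``; deterministic given ``seed``."""
    target_bp = target_mbp * 1e6
    total = sum(len(r) for r in reads)
    if target_bp > total:
        raise ValueError(
            f"target {target_mbp} Mbp exceeds available {total / 1e6:.3f} Mbp"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    out = []
    acc = 0
    for idx in order:
        out.append(reads[idx])
        acc += len(reads[idx])
        if acc >= target_bp:
            break
    return out
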