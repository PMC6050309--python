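"""Reference-free LINE consensus building by iterative mapping + majority rule.

The internal mapper is an ungapped seed-and-extend aligner (exact k-mer
seeds, both strands, best placement per read, ties leftmost). Coverage
thresholds follow the iterative procedure: none on the first pass, 10x from
the second mapping iteration, 20x on the final mapping. Iteration stops when
the mapped-read count no longer increases (or the consensus is unchanged).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .types import Read, revcomp

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class ReadAlignment:
    """An ungapped placement of (part of) a read on the consensus.

    ``seq_aligned`` is the oriented read subsequence covering reference
    positions [ref_start, ref_start + len(seq_aligned)); a minus-orientation
    read contributes its reverse complement.
    """

    read_id: str
    ref_start: int
    orientation: str
    seq_aligned: str
    n_mismatches: int

    @property
    def ref_end(self) -> int:
        return self.ref_start + len(self.seq_aligned)

    def aligned_pairs(self):
        for i, base in enumerate(self.seq_aligned):
            yield self.ref_start + i, base


@dataclass
class ConsensusModel:
    sequence: str  # uppercase; masked positions are whatever the pileup gave
    masked: np.ndarray  # bool per position, True = below depth threshold
    per_position_depth: np.ndarray
    iteration: int
    n_reads_mapped: int
    mapped_history: list = field(default_factory=list)

    @property
    def display_sequence(self) -> str:
        """Masked positions lowercased (soft-masked)."""
        return "".join(
            c.lower() if m else c for c, m in zip(self.sequence, self.masked)
        )

    def masked_spans(self) -> list[tuple[int, int]]:
        spans = []
        in_span = False
        for i, m in enumerate(self.masked):
            if m and not in_span:
                spans.append([i, i + 1])
                in_span = True
            elif m:
                spans[-1][1] = i + 1
            else:
                in_span = False
        return [(s, e) for s, e in spans]


def _kmer_index(reference: str, k: int) -> dict:
    index = defaultdict(list)
    for i in range(len(reference) - k + 1):
        kmer = reference[i : i + k]
        if "N" not in kmer:
            index[kmer].append(i)
    return index


def _try_place(
    read_seq: str, ref_arr: np.ndarray, offset: int, min_overlap: int
) -> tuple[int, int, int] | None:
    """Ungapped placement of the read at reference offset; returns
    (ref_start, n_match, n_mismatch) over the overlapping span or None."""
    L = len(ref_arr)
    rlen = len(read_seq)
    ref_start = max(0, offset)
    ref_end = min(L, offset + rlen)
    if ref_end - ref_start < min_overlap:
        return None
    read_arr = np.frombuffer(read_seq.encode("ascii"), dtype=np.uint8)
    sub = read_arr[ref_start - offset : ref_end - offset]
    ref_sub = ref_arr[ref_start:ref_end]
    valid = (sub != ord("N")) & (ref_sub != ord("N"))
    n_match = int(np.count_nonzero((sub == ref_sub) & valid))
    n_mismatch = int(np.count_nonzero(valid)) - n_match
    return ref_start, n_match, n_mismatch


def map_reads(
    reads: list[Read],
    reference: str,
    k: int = 17,
    max_mismatch_rate: float = 0.2,
    min_overlap: int = 30,
    seed_step: int = 1,
) -> list[ReadAlignment]:
    """Seed-and-extend ungapped mapping of reads to a single reference.

    Exact k-mer seeds are looked up on both strands; each candidate offset is
    scored over the overlapping span and the best placement (most matches
    minus mismatches; ties -> leftmost, forward strand first) is kept if its
    mismatch rate is <= ``max_mismatch_rate``. Unmapped reads are omitted.
    """
    if len(reference) < k:
        raise ValueError("reference shorter than seed length")
    index = _kmer_index(reference, k)
    ref_arr = np.frombuffer(reference.encode("ascii"), dtype=np.uint8)
    alignments = []
    for read in reads:
        best = None  # (score, orient_rank, ref_start, orientation, seq, mm)
        for orientation, seq in (("+", read.sequence), ("-", revcomp(read.sequence))):
            offsets = set()
            for j in range(0, len(seq) - k + 1, seed_step):
                kmer = seq[j : j + k]
                for pos in index.get(kmer, ()):
                    offsets.add(pos - j)
            for offset in sorted(offsets):
                placed = _try_place(seq, ref_arr, offset, min_overlap)
                if placed is None:
                    continue
                ref_start, n_match, n_mm = placed
                span = n_match + n_mm
                if span == 0 or n_mm / span > max_mismatch_rate:
                    continue
                score = n_match - n_mm
                orank = 0 if orientation == "+" else 1
                key = (-score, orank, ref_start)
                if best is None or key < best[0]:
                    a0 = ref_start - offset
                    a1 = min(len(ref_arr), offset + len(seq)) - offset
                    best = (key, ref_start, orientation, seq[a0:a1], n_mm)
        if best is not None:
            _, ref_start, orientation, seq_aligned, n_mm = best
            alignments.append(
                ReadAlignment(
                    read_id=read.id,
                    ref_start=ref_start,
                    orientation=orientation,
                    seq_aligned=seq_aligned,
                    n_mismatches=n_mm,
                )
            )
    return alignments


def pileup_counts(
    alignments: list[ReadAlignment], reference_length: int
) -> np.ndarray:
    """4 x L matrix of base counts (A, C, G, T; N ignored)."""
    counts = np.zeros((4, reference_length), dtype=np.int64)
    for aln in alignments:
        arr = np.frombuffer(aln.seq_aligned.encode("ascii"), dtype=np.uint8)
        pos = np.arange(aln.ref_start, aln.ref_end)
        for bi, base in enumerate(b"ACGT"):
            sel = arr == base
            if sel.any():
                np.add.at(counts[bi], pos[sel], 1)
    return counts


def majority_consensus(
    alignments: list[ReadAlignment],
    reference_length: int,
    depth_threshold: int,
    previous_consensus: str | None = None,
) -> ConsensusModel:
    """Per-position majority base; ties prefer the previous consensus base,
    else alphabetical; positions with depth < threshold are masked."""
    if not alignments:
        raise ValueError("no mapped reads")
    counts = pileup_counts(alignments, reference_length)
    depth = counts.sum(axis=0)
    maxc = counts.max(axis=0)
    # alphabetical winner by default (argmax returns lowest index = A first)
    winner = counts.argmax(axis=0)
    if previous_consensus is not None:
        prev = np.frombuffer(previous_consensus.encode("ascii"), dtype=np.uint8)
        for bi, base in enumerate(b"ACGT"):
            tie_prev = (prev == base) & (counts[bi] == maxc)
            winner[tie_prev] = bi
    seq = np.array(list(_BASES), dtype="U1")[winner]
    if previous_consensus is not None:
        # keep the previous base where nothing aligned at all
        nocov = depth == 0
        prev_chars = np.array(list(previous_consensus), dtype="U1")
        seq[nocov] = prev_chars[nocov]
    masked = depth < depth_threshold
    return ConsensusModel(
        sequence="".join(seq),
        masked=masked,
        per_position_depth=depth,
        iteration=0,
        n_reads_mapped=len(alignments),
    )


def build_consensus_iterative(
    reads: list[Read],
    initial_reference: str,
    k: int = 17,
    max_mismatch_rate: float = 0.2,
    min_overlap: int = 30,
    max_iterations: int = 10,
    mid_depth_threshold: int = 10,
    final_depth_threshold: int = 20,
    converge_on_read_ids: bool = False,
) -> ConsensusModel:
    """Iterate map -> majority consensus until no additional reads map.

    The first pass applies no depth mask; the 10x threshold applies from the
    second mapping iteration and 20x on the final mapping. Convergence is no
    increase in the mapped-read count (or, with ``converge_on_read_ids``, no
    new distinct read ids), or an unchanged consensus; a hard iteration cap
    returns the best model with a warning.
    """
    if not initial_reference:
        raise ValueError("initial reference must be non-empty")
    reference = initial_reference
    history = []
    seen_ids: set[str] = set()
    alignments = None
    iteration = 0
    converged = False
    while iteration < max_iterations:
        iteration += 1
        alignments = map_reads(
            reads, reference, k=k, max_mismatch_rate=max_mismatch_rate,
            min_overlap=min_overlap,
        )
        if not alignments:
            raise ValueError("no reads mapped to the initial reference")
        threshold = 0 if iteration == 1 else mid_depth_threshold
        model = majority_consensus(
            alignments, len(reference), threshold, previous_consensus=reference
        )
        n_mapped = len(alignments)
        new_ids = {a.read_id for a in alignments} - seen_ids
        seen_ids.update(a.read_id for a in alignments)
        history.append(n_mapped)
        unchanged = model.sequence == reference
        if iteration >= 2:
            no_growth = (
                (len(new_ids) == 0) if converge_on_read_ids
                else (n_mapped <= history[-2])
            )
            if no_growth or unchanged:
                converged = True
                reference = model.sequence
                break
        reference = model.sequence
    if not converged:
        logger.warning(
            "consensus did not converge within %d iterations", max_iterations
        )
    # final mapping with the 20x threshold
    final_alignments = map_reads(
        reads, reference, k=k, max_mismatch_rate=max_mismatch_rate,
        min_overlap=min_overlap,
    )
    final = majority_consensus(
        final_alignments, len(reference), final_depth_threshold,
        previous_consensus=reference,
    )
    final.iteration = iteration
    final.mapped_history = history + [len(final_alignments)]
    return final
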