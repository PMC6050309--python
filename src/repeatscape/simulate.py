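"""Synthetic genomes, reads, trees and traits with known ground truth.

The generator plants TE copies (with per-copy divergence, shared
subfamily-diagnostic substitutions, optional 5' truncation and an optional
SSR tail appended at the 3' end) and standalone SSR loci on an i.i.d.
background, all non-overlapping; a truth table records every feature.

The mutation model is substitution-only, so ungapped mapping and pairwise
divergence are exact. By default the background is scrubbed of spurious
perfect arrays so that the scanner's output matches the truth table exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import ssr as ssr_mod
from .phylo import Phylogeny, simulate_bm_matrix
from .types import GenomeSequence, Read, SsrLocus, TeAnnotation, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class TeFamilyConfig:
    name: str
    consensus_length: int
    copy_number: int
    divergence: float = 0.0
    truncation_q: float = 0.0  # fraction of copies missing a 5' prefix
    truncation_extent: tuple = (0.5, 0.5)  # (min, max) fraction of length removed
    ssr_tail: Optional[tuple] = None  # (motif, n_units) or (motif, (min, max))
    n_subfamilies: int = 1
    n_diagnostic_sites: int = 0
    te_class: str = "LINE"


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 100_000
    gc_fraction: float = 0.5
    te_families: list = field(default_factory=list)  # list[TeFamilyConfig]
    background_ssr: dict = field(default_factory=dict)  # motif -> n loci
    background_ssr_units: tuple = (4, 8)  # (min, max) units per planted locus
    read_length: int = 100
    read_depth: float = 30.0
    read_error_rate: float = 0.0
    contig_name: str = "chr1"
    suppress_spurious_ssrs: bool = True
    placement_budget_factor: int = 100


@dataclass
class PlantedTe:
    family: str
    start: int
    end: int
    strand: str
    truncated: bool
    subfamily: int
    tail_start: Optional[int]
    tail_end: Optional[int]
    copy_sequence: str  # element sequence 5'->3' of the element, pre-strand


@dataclass
class PlantedSsr:
    motif: str  # canonical
    unit: str
    start: int
    end: int
    n_units: int
    source_family: Optional[str]  # family name when the locus is a TE tail


@dataclass
class TruthTable:
    tes: list = field(default_factory=list)
    ssrs: list = field(default_factory=list)
    family_consensus: dict = field(default_factory=dict)
    subfamily_sites: dict = field(default_factory=dict)  # family -> positions
    genome_length: int = 0

    def family_bp_fraction(self) -> dict:
        out: dict = {}
        for te in self.tes:
            out[te.family] = out.get(te.family, 0) + (te.end - te.start)
        return {f: bp / self.genome_length for f, bp in out.items()}

    def te_annotations(self, contig: str) -> list:
        return [
            TeAnnotation(
                contig=contig,
                start=te.start,
                end=te.end,
                strand=te.strand,
                family=te.family,
                te_class="LINE",
                raw_class="LINE/" + te.family,
            )
            for te in self.tes
        ]

    def ssr_loci(self, contig: str) -> list:
        return [
            SsrLocus(
                contig=contig,
                start=s.start,
                end=s.end,
                unit=s.unit,
                canonical_motif=s.motif,
                n_units=s.n_units,
            )
            for s in self.ssrs
        ]


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _mutate(arr: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> None:
    """Substitute each given position with a different random base."""
    for pos in positions:
        choices = _BASES[_BASES != arr[pos]]
        arr[pos] = rng.choice(choices)


def _arr_to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def simulate_genome(config: SimulationConfig):
    """Build a genome and its truth table; deterministic given config.seed.

    Raises if the features cannot be placed without overlap within the
    placement budget.
    """
    rng = np.random.default_rng(config.seed)
    truth = TruthTable(genome_length=config.genome_length)

    # 1. build family consensus sequences and per-subfamily diagnostic alleles
    diag_alleles = {}
    for fam in config.te_families:
        cons = _random_sequence(rng, fam.consensus_length, config.gc_fraction)
        truth.family_consensus[fam.name] = _arr_to_str(cons)
        if fam.n_subfamilies > 1 and fam.n_diagnostic_sites > 0:
            sites = np.sort(
                rng.choice(fam.consensus_length, fam.n_diagnostic_sites, replace=False)
            )
            truth.subfamily_sites[fam.name] = sites
            alleles = {}
            for sub in range(fam.n_subfamilies):
                if sub == 0:
                    alleles[sub] = {int(p): _arr_to_str(cons[p : p + 1]) for p in sites}
                else:
                    sub_alleles = {}
                    for p in sites:
                        others = _BASES[_BASES != cons[p]]
                        sub_alleles[int(p)] = chr(rng.choice(others))
                    alleles[sub] = sub_alleles
            diag_alleles[fam.name] = alleles
        else:
            truth.subfamily_sites[fam.name] = np.array([], dtype=int)
            diag_alleles[fam.name] = {0: {}}

    # 2. realize every feature sequence before placement
    features = []  # (kind, payload, genome-strand sequence)
    for fam in config.te_families:
        cons = np.frombuffer(
            truth.family_consensus[fam.name].encode("ascii"), dtype=np.uint8
        )
        diag_sites = set(int(p) for p in truth.subfamily_sites[fam.name])
        n_trunc = int(round(fam.truncation_q * fam.copy_number))
        for i in range(fam.copy_number):
            copy = cons.copy()
            sub = int(rng.integers(0, max(1, fam.n_subfamilies)))
            for p, base in diag_alleles[fam.name].get(sub, {}).items():
                copy[p] = ord(base)
            if fam.divergence > 0:
                hits = rng.random(len(copy)) < fam.divergence
                for p in diag_sites:
                    hits[p] = False
                _mutate(copy, np.flatnonzero(hits), rng)
            truncated = i < n_trunc
            if truncated:
                lo, hi = fam.truncation_extent
                extent = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
                cut = int(round(extent * len(copy)))
                copy = copy[cut:]
            tail = None
            if fam.ssr_tail is not None:
                motif, units = fam.ssr_tail
                if isinstance(units, (tuple, list)):
                    n_units = int(rng.integers(units[0], units[1] + 1))
                else:
                    n_units = int(units)
                tail = (motif, n_units)
            features.append(("te", (fam, sub, truncated, tail), copy))
    for motif, n_loci in config.background_ssr.items():
        lo, hi = config.background_ssr_units
        for _ in range(int(n_loci)):
            n_units = int(rng.integers(lo, hi + 1))
            min_len = ssr_mod.MIN_ARRAY_LENGTH.get(len(motif), 12)
            n_units = max(n_units, math.ceil(min_len / len(motif)))
            seq = np.frombuffer((motif * n_units).encode("ascii"), dtype=np.uint8)
            features.append(("ssr", (motif, n_units), seq))

    total_planted = sum(
        len(seq) + (len(p[3][0]) * p[3][1] if kind == "te" and p[3] else 0)
        for kind, p, seq in features
    )
    if total_planted >= config.genome_length:
        raise ValueError(
            f"planted features ({total_planted} bp) exceed genome length"
        )

    # 3. background, with optional scrubbing of spurious perfect arrays
    genome = _random_sequence(rng, config.genome_length, config.gc_fraction)
    if config.suppress_spurious_ssrs:
        _scrub_ssrs(genome, rng, config.contig_name, protected=[])

    # 4. place features without overlap: random order, random gaps (>=1 bp
    #    guard between features so planted arrays can never merge)
    blocks = []  # (kind, payload, elem, strand, block array)
    for fi in rng.permutation(len(features)):
        kind, payload, elem = features[fi]
        tail_seq = b""
        if kind == "te" and payload[3] is not None:
            motif, n_units = payload[3]
            tail_seq = (motif * n_units).encode("ascii")
        strand = "+" if kind == "ssr" or rng.random() < 0.5 else "-"
        # element + tail inserted as one block, in element orientation,
        # then reverse-complemented as a whole for minus-strand copies
        block = np.concatenate([elem, np.frombuffer(tail_seq, dtype=np.uint8)])
        if strand == "-":
            block = np.frombuffer(
                revcomp(_arr_to_str(block)).encode("ascii"), dtype=np.uint8
            ).copy()
        blocks.append((kind, payload, elem, strand, block))

    n = len(blocks)
    free = config.genome_length - sum(len(b[4]) for b in blocks)
    if free < n + 1:
        raise RuntimeError("genome too small to separate all planted features")
    # n + 1 gaps, each >= 1, summing to the free space
    gaps = rng.multinomial(free - (n + 1), np.full(n + 1, 1.0 / (n + 1))) + 1
    cursor = 0
    for gi, (kind, payload, elem, strand, block) in enumerate(blocks):
        cursor += int(gaps[gi])
        start = cursor
        end = start + len(block)
        genome[start:end] = block
        cursor = end
        tail_len = len(block) - len(elem)

        if kind == "te":
            fam, sub, truncated, tail = payload
            elem_len = len(elem)
            if strand == "+":
                te_start, te_end = start, start + elem_len
                ts, te_ = (te_end, te_end + tail_len) if tail_len else (None, None)
            else:
                # on minus strand the tail sits genome-left of the element
                te_start, te_end = start + tail_len, end
                ts, te_ = (start, start + tail_len) if tail_len else (None, None)
            truth.tes.append(
                PlantedTe(
                    family=fam.name,
                    start=te_start,
                    end=te_end,
                    strand=strand,
                    truncated=truncated,
                    subfamily=sub,
                    tail_start=ts,
                    tail_end=te_,
                    copy_sequence=_arr_to_str(elem),
                )
            )
            if tail_len:
                motif, n_units = tail
                unit = motif if strand == "+" else revcomp(motif)
                # the observed forward-strand unit at the locus start
                obs_unit = _arr_to_str(genome[ts : ts + len(motif)])
                truth.ssrs.append(
                    PlantedSsr(
                        motif=ssr_mod.canonicalize_motif(motif),
                        unit=obs_unit,
                        start=ts,
                        end=te_,
                        n_units=n_units,
                        source_family=fam.name,
                    )
                )
        else:
            motif, n_units = payload
            truth.ssrs.append(
                PlantedSsr(
                    motif=ssr_mod.canonicalize_motif(motif),
                    unit=motif,
                    start=start,
                    end=end,
                    n_units=n_units,
                    source_family=None,
                )
            )

    # 5. break any repeat continuation at planted SSR boundaries and scrub
    #    arrays the substitution process may have created elsewhere
    if config.suppress_spurious_ssrs:
        protected = [(s.start, s.end) for s in truth.ssrs]
        _scrub_ssrs(genome, rng, config.contig_name, protected=protected)

    contig = GenomeSequence(name=config.contig_name, residues=_arr_to_str(genome))
    _check_truth(contig, truth)
    return [contig], truth


def _scrub_ssrs(
    genome: np.ndarray,
    rng: np.random.Generator,
    contig_name: str,
    protected: Sequence[tuple],
    max_rounds: int = 20,
) -> None:
    """Mutate one mid-array base of every scanner-detectable array that is
    not an exact planted locus, until none remain."""
    for _ in range(max_rounds):
        contig = GenomeSequence(name=contig_name, residues=_arr_to_str(genome))
        loci = ssr_mod.scan_ssrs([contig])
        prot = set(protected)
        spurious = [l for l in loci if (l.start, l.end) not in prot]
        # also catch near-threshold arrays that touch a protected locus
        if not spurious:
            return
        for l in spurious:
            # avoid touching protected intervals themselves
            pos = (l.start + l.end) // 2
            if any(s <= pos < e for s, e in protected):
                candidates = [p for p in range(l.start, l.end)
                              if not any(s <= p < e for s, e in protected)]
                if not candidates:
                    continue
                pos = candidates[len(candidates) // 2]
            _mutate(genome, np.array([pos]), rng)
    raise RuntimeError("could not scrub spurious arrays within round budget")


def _check_truth(contig: GenomeSequence, truth: TruthTable) -> None:
    for s in truth.ssrs:
        arr = contig.residues[s.start : s.end]
        unit = arr[: len(s.unit)]
        assert arr == unit * s.n_units, "planted SSR not a perfect array"


def simulate_reads(
    genome: Sequence[GenomeSequence],
    depth: float,
    read_length: int,
    error_rate: float,
    seed: int,
) -> list[Read]:
    """Uniform shotgun reads over both strands with i.i.d. substitution
    errors; expected coverage equals ``depth``."""
    rng = np.random.default_rng(seed)
    total = sum(c.length for c in genome)
    if read_length > max(c.length for c in genome):
        raise ValueError("read length exceeds every contig length")
    n_reads = int(round(depth * total / read_length))
    eligible = [c for c in genome if c.length >= read_length]
    weights = np.array([c.length - read_length + 1 for c in eligible], dtype=float)
    weights /= weights.sum()
    reads = []
    for i in range(n_reads):
        ci = int(rng.choice(len(eligible), p=weights))
        contig = eligible[ci]
        start = int(rng.integers(0, contig.length - read_length + 1))
        seq = contig.residues[start : start + read_length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = revcomp(seq)
        if error_rate > 0:
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
            hits = np.flatnonzero(rng.random(read_length) < error_rate)
            _mutate(arr, hits, rng)
            seq = _arr_to_str(arr)
        reads.append(
            Read(
                id=f"read_{i}",
                sequence=seq,
                contig=contig.name,
                start=start,
                strand=strand,
            )
        )
    return reads


def simulate_bm_traits(
    tree: Phylogeny,
    sigma2,
    seed: int,
    tip_regimes: Optional[Mapping[str, str]] = None,
    trait_name: str = "trait",
) -> pd.DataFrame:
    """One BM trait realization on the tree (root value 0).

    ``sigma2`` may be a scalar rate or a per-regime map (requires
    ``tip_regimes``); branch increments are Normal(0, sigma2 x length).
    """
    rng = np.random.default_rng(seed)
    if isinstance(sigma2, Mapping):
        tips = simulate_bm_matrix(
            tree, np.nan, 1, rng, tip_regimes=tip_regimes, branch_sigma2=sigma2
        )
    else:
        tips = simulate_bm_matrix(tree, float(sigma2), 1, rng)
    return pd.DataFrame({trait_name: tips[:, 0]}, index=pd.Index(tree.tip_labels, name="species"))
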