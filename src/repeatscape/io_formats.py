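"""Readers and writers for the external formats the pipeline touches.

Internally everything is 0-based half-open; the RepeatMasker ``.out``
dialect (1-based inclusive, "C" for complement strand) and BED (already
half-open) are converted at this boundary only.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Optional, Union

import dendropy
import pandas as pd
from Bio import SeqIO

from .types import GenomeSequence, NeSeries, Read, SsrLocus, TeAnnotation

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

_NON_ACGTN = re.compile(r"[^ACGTN]")


def parse_fasta(path: PathLike) -> list[GenomeSequence]:
    """Read a FASTA file into :class:`GenomeSequence` records.

    Residues are uppercased; characters outside {A,C,G,T,N} are mapped to N
    with a logged count. Duplicate names and empty files are format errors.
    """
    records = []
    seen = set()
    n_subs = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence name: {rec.id}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        cleaned, n = _NON_ACGTN.subn("N", residues)
        n_subs += n
        records.append(GenomeSequence(name=rec.id, residues=cleaned))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    if n_subs:
        logger.info("mapped %d non-ACGTN characters to N in %s", n_subs, path)
    return records


def write_fasta(records: Iterable[GenomeSequence], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            seq = rec.residues
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def parse_reads(path: PathLike, fmt: Optional[str] = None) -> list[Read]:
    """Read sequencing reads from FASTA or FASTQ (qualities discarded)."""
    if fmt is None:
        fmt = _sniff_read_format(path)
    reads = []
    for rec in SeqIO.parse(str(path), fmt):
        seq = _NON_ACGTN.sub("N", str(rec.seq).upper())
        reads.append(Read(id=rec.id, sequence=seq))
    if not reads:
        raise FormatError(f"no reads in {path}")
    return reads


def _sniff_read_format(path: PathLike) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fastq" if line.startswith("@") else "fasta"
    raise FormatError(f"empty read file: {path}")


def write_reads_fasta(reads: Iterable[Read], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.sequence}\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

_CLASS_MAP = {
    "LINE": "LINE",
    "SINE": "SINE",
    "LTR": "LTR",
    "DNA": "DNA",
    "RC": "DNA",  # rolling-circle elements grouped with DNA transposons
}

# Tokens that refine a family label within a class (checked in order).
_FAMILY_TOKENS = ("BovB", "Rex", "L3", "L2", "L1", "CR1", "Tc1", "Mariner")


def _derive_family(name: str, rm_class: str) -> str:
    """Collapse a repeat name + class/family column to a family label.

    e.g. class "LINE/CR1" with a name containing "L3" -> "CR1-L3".
    Falls back to the subclass after "/" or the raw name.
    """
    sub = rm_class.split("/", 1)[1] if "/" in rm_class else ""
    if sub.startswith("CR1") or "CR1" in name:
        if "L3" in name or "L3" in sub:
            return "CR1-L3"
        if "L2" in name or "L2" in sub:
            return "CR1-L2"
        return "CR1"
    for token in ("BovB", "Rex"):
        if token in name or token in sub:
            return token
    if sub.startswith("Tc1") or "Tc1" in name or "Mariner" in name:
        return "Tc1-Mariner"
    if sub:
        return sub
    return name


def _classify(rm_class: str) -> str:
    head = rm_class.split("/", 1)[0]
    return _CLASS_MAP.get(head, "other")


def parse_repeatmasker_out(path: PathLike) -> list[TeAnnotation]:
    """Parse the modern fixed-column RepeatMasker ``.out`` dialect.

    Expects 3 header lines (or none), whitespace-separated columns, 1-based
    inclusive query coordinates, and strand "C" for complement. Coordinates
    are converted to 0-based half-open; "C" maps to "-". Rows whose class
    cannot be mapped keep their family with te_class "other".
    """
    annotations = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            fields = stripped.split()
            # header lines start with "SW"/"score" or "bit"
            if fields[0].lower() in ("sw", "score", "bit"):
                continue
            if len(fields) < 11:
                raise FormatError(f"{path}:{lineno}: expected >=11 columns, got {len(fields)}")
            try:
                contig = fields[4]
                begin = int(fields[5])
                end = int(fields[6])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinates: {exc}") from None
            strand_field = fields[8]
            if strand_field == "C":
                strand = "-"
            elif strand_field in ("+", ""):
                strand = "+"
            else:
                raise FormatError(f"{path}:{lineno}: bad strand {strand_field!r}")
            name = fields[9]
            rm_class = fields[10]
            if begin < 1 or end < begin:
                raise FormatError(f"{path}:{lineno}: bad interval {begin}..{end}")
            annotations.append(
                TeAnnotation(
                    contig=contig,
                    start=begin - 1,
                    end=end,
                    strand=strand,
                    family=_derive_family(name, rm_class),
                    te_class=_classify(rm_class),
                    raw_class=rm_class,
                )
            )
    return annotations


_OUT_HEADER = (
    "   SW   perc perc perc  query     position in query   "
    "          matching  repeat       position in repeat\n"
    "score   div. del. ins.  sequence  begin end    (left) "
    "          repeat    class/family begin end    (left) ID\n"
    "\n"
)


def write_repeatmasker_out(annotations: Iterable[TeAnnotation], path: PathLike) -> None:
    """Emit annotations in the ``.out`` dialect (1-based inclusive, C strand)."""
    with open(path, "w") as fh:
        fh.write(_OUT_HEADER)
        for i, a in enumerate(annotations, start=1):
            strand = "C" if a.strand == "-" else "+"
            rm_class = a.raw_class or a.te_class
            fh.write(
                f"  250   0.0  0.0  0.0  {a.contig}  {a.start + 1} {a.end} (0) "
                f"{strand}  {a.family}  {rm_class}  1 {a.end - a.start} (0) {i}\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def parse_bed(path: PathLike) -> list[TeAnnotation]:
    """Read BED6 with the family label in the name field.

    The name field may be "family" or "family|class"; score is ignored.
    """
    annotations = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: BED needs >=4 columns")
            name = fields[3]
            family, _, te_class = name.partition("|")
            strand = fields[5] if len(fields) > 5 else "+"
            annotations.append(
                TeAnnotation(
                    contig=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=strand if strand in ("+", "-") else "+",
                    family=family,
                    te_class=te_class or "other",
                )
            )
    return annotations


def write_bed(annotations: Iterable[TeAnnotation], path: PathLike) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            name = f"{a.family}|{a.te_class}" if a.te_class else a.family
            fh.write(f"{a.contig}\t{a.start}\t{a.end}\t{name}\t0\t{a.strand}\n")


def write_ssr_bed(loci: Iterable[SsrLocus], path: PathLike) -> None:
    """BED6 for SSR loci: name = canonical motif, score = n_units."""
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l.contig}\t{l.start}\t{l.end}\t{l.canonical_motif}\t{l.n_units}\t+\n")


def parse_ssr_bed(path: PathLike) -> list[SsrLocus]:
    loci = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            contig, start, end, motif, score = fields[:5]
            start, end, n_units = int(start), int(end), int(score)
            unit_len = (end - start) // n_units
            loci.append(
                SsrLocus(
                    contig=contig,
                    start=start,
                    end=end,
                    unit=motif if len(motif) == unit_len else motif[:unit_len],
                    canonical_motif=motif,
                    n_units=n_units,
                )
            )
    return loci


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------


def parse_newick(path_or_string: PathLike) -> "dendropy.Tree":
    """Parse a single rooted Newick tree with branch lengths.

    Missing branch lengths on non-root edges are an error; polytomies are
    allowed here and resolved downstream. Accepts a path or a literal
    Newick string.
    """
    text = str(path_or_string)
    if not text.lstrip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    tree = dendropy.Tree.get(data=text, schema="newick")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise FormatError("duplicate tip labels in tree")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise FormatError("tree has edges without branch lengths")
        if node.edge.length < 0:
            raise FormatError("negative branch length")
    n_polytomies = sum(
        1 for nd in tree.preorder_internal_node_iter() if len(nd.child_nodes()) > 2
    )
    if n_polytomies:
        logger.warning("tree contains %d polytomies (will be resolved)", n_polytomies)
    return tree


def write_newick(tree: "dendropy.Tree", path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(
            tree.as_string(
                schema="newick",
                suppress_rooting=True,
                real_value_format_specifier=".12g",
            )
        )


# ---------------------------------------------------------------------------
# Ne series and trait tables
# ---------------------------------------------------------------------------


def read_ne_series(
    path: PathLike,
    species: str = "",
    generation_time: float = 3.0,
    mutation_rate: Optional[float] = None,
) -> NeSeries:
    """Read a two-column (time, Ne) numeric table; '#' lines are comments.

    Points are sorted by time; duplicated times and fewer than 3 points are
    errors (endpoint trimming plus a median needs at least 3 points).
    """
    points = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            try:
                t, ne = float(fields[0]), float(fields[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric cell") from None
            points.append((t, ne))
    if len(points) < 3:
        raise FormatError(f"{path}: need >=3 points, got {len(points)}")
    points.sort(key=lambda p: p[0])
    times = [t for t, _ in points]
    if len(set(times)) != len(times):
        raise FormatError(f"{path}: duplicated time points")
    return NeSeries(
        species=species or Path(path).stem,
        points=points,
        generation_time=generation_time,
        mutation_rate=mutation_rate,
    )


def read_trait_table(path: PathLike) -> pd.DataFrame:
    """TSV with a 'species' column; returns a species-indexed numeric frame."""
    df = pd.read_csv(path, sep="\t")
    if "species" not in df.columns:
        raise FormatError("trait table must have a 'species' column")
    if df["species"].duplicated().any():
        raise FormatError("duplicate species in trait table")
    return df.set_index("species")


def write_trait_table(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index_label="species")
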