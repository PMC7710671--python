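"""Nucleotide alignments, gene maps, and the flat-file formats they travel in.

An :class:`Alignment` is a rectangular matrix of uppercase nucleotide
characters over the DNA alphabet plus IUPAC ambiguity codes, ``N``, the
alignment gap ``-`` and the missing-marker placeholder ``?``.  A
:class:`GeneMap` assigns every column of a concatenated supermatrix to a named
marker using 1-based inclusive coordinates (the RAxML partition-file
convention, kept throughout all APIs to avoid off-by-one drift).

Readers accept FASTA and relaxed sequential PHYLIP; writers emit files that
the readers parse back bit-identically.  The module also implements the two
supermatrix-assembly steps of the analysis: the length-based
sequence-inclusion filter and union-of-taxa concatenation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import numpy as np
from Bio import AlignIO, SeqIO

from .errors import AlignmentError, FilterError, PartitionError

#: IUPAC one-letter codes mapped to the set of compatible nucleotides.
#: ``N``, ``-`` and ``?`` are compatible with everything (treated as missing
#: data downstream, though the three characters are preserved in files).
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT",
}

#: Characters that carry no state information at all.
MISSING_CHARS = frozenset("N-?")

ALPHABET = frozenset(IUPAC_CODES)

PathLike = Union[str, Path]


def _as_text_handle(source: Union[PathLike, TextIO], mode: str = "r"):
    """Return (handle, needs_close) for a path or an already-open stream."""
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


class Alignment:
    """Immutable rectangular nucleotide alignment with named taxa.

    Parameters
    ----------
    records
        Iterable of ``(taxon_name, sequence)`` pairs.  Names are stripped of
        surrounding whitespace and must be unique and non-empty; sequences are
        uppercased, ``U`` is mapped to ``T``, and every character must be a
        nucleotide, an IUPAC ambiguity code, ``N``, ``-`` or ``?``.
    """

    __slots__ = ("taxa", "matrix", "_index")

    def __init__(self, records: Iterable[tuple[str, str]]):
        taxa: list[str] = []
        rows: list[str] = []
        for name, seq in records:
            name = str(name).strip()
            if not name:
                raise AlignmentError("empty taxon name")
            if name in taxa:
                raise AlignmentError(f"duplicate taxon {name!r}")
            taxa.append(name)
            rows.append(str(seq).upper().replace("U", "T"))
        if not taxa:
            raise AlignmentError("alignment has no sequences")
        length = len(rows[0])
        if length == 0:
            raise AlignmentError("alignment has zero sites")
        for name, row in zip(taxa, rows):
            if len(row) != length:
                raise AlignmentError(
                    f"ragged alignment: taxon {name!r} has length {len(row)}, "
                    f"expected {length}"
                )
            for pos, ch in enumerate(row, start=1):
                if ch not in ALPHABET:
                    raise AlignmentError(
                        f"illegal character {ch!r} at site {pos} of taxon {name!r}"
                    )
        self.taxa: list[str] = taxa
        self.matrix: np.ndarray = np.array(
            [list(r) for r in rows], dtype="<U1"
        )
        self.matrix.setflags(write=False)
        self._index = {t: i for i, t in enumerate(taxa)}

    # -- basic introspection -------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        """Number of sites (columns)."""
        return self.matrix.shape[1]

    def row(self, taxon: str) -> str:
        """Sequence of one taxon as a string."""
        try:
            i = self._index[taxon]
        except KeyError:
            raise AlignmentError(f"unknown taxon {taxon!r}") from None
        return "".join(self.matrix[i])

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._index

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.taxa == other.taxa
            and bool(np.array_equal(self.matrix, other.matrix))
        )

    def __repr__(self) -> str:
        return f"<Alignment {self.n_taxa} taxa x {self.length} sites>"

    # -- derived alignments --------------------------------------------------

    def subset_taxa(self, taxa: Sequence[str]) -> "Alignment":
        """Alignment restricted to ``taxa`` (given order)."""
        return Alignment((t, self.row(t)) for t in taxa)

    def site_slice(self, start: int, end: int) -> "Alignment":
        """Columns ``start..end`` (1-based inclusive)."""
        if not (1 <= start <= end <= self.length):
            raise AlignmentError(
                f"site range {start}-{end} outside 1-{self.length}"
            )
        sub = self.matrix[:, start - 1 : end]
        return Alignment(
            (t, "".join(sub[i])) for i, t in enumerate(self.taxa)
        )

    def ungapped_lengths(self) -> np.ndarray:
        """Per-taxon count of characters outside ``{-, ?, N}``."""
        missing = np.isin(self.matrix, list(MISSING_CHARS))
        return (~missing).sum(axis=1)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_alignment(source: Union[PathLike, TextIO], format: str = "fasta") -> Alignment:
    """Read an alignment from FASTA or relaxed sequential PHYLIP.

    ``format`` is ``"fasta"`` or ``"phylip_relaxed"``.  Lowercase input is
    uppercased and ``U`` becomes ``T``.  Ragged rows, duplicate taxa and
    characters outside the alphabet raise :class:`AlignmentError`.
    """
    handle, close = _as_text_handle(source)
    try:
        if format == "fasta":
            records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
        elif format == "phylip_relaxed":
            try:
                msa = AlignIO.read(handle, "phylip-relaxed")
            except ValueError as exc:
                raise AlignmentError(f"malformed relaxed PHYLIP: {exc}") from exc
            records = [(rec.id, str(rec.seq)) for rec in msa]
        else:
            raise AlignmentError(f"unknown alignment format {format!r}")
    finally:
        if close:
            handle.close()
    return Alignment(records)


def write_alignment(
    aln: Alignment, dest: Union[PathLike, TextIO], format: str = "fasta"
) -> None:
    """Write ``aln`` so that :func:`read_alignment` parses it back identically."""
    handle, close = _as_text_handle(dest, "w")
    try:
        if format == "fasta":
            for taxon in aln.taxa:
                handle.write(f">{taxon}\n{aln.row(taxon)}\n")
        elif format == "phylip_relaxed":
            handle.write(f" {aln.n_taxa} {aln.length}\n")
            for taxon in aln.taxa:
                handle.write(f"{taxon}  {aln.row(taxon)}\n")
        else:
            raise AlignmentError(f"unknown alignment format {format!r}")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Gene map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneMap:
    """Ordered, non-overlapping 1-based inclusive site ranges, one per marker."""

    entries: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        if not self.entries:
            raise PartitionError("empty gene map")
        names = [e[0] for e in self.entries]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise PartitionError(f"duplicate gene names: {dup}")
        prev_end = 0
        for name, start, end in self.entries:
            if start > end:
                raise PartitionError(f"gene {name!r}: start {start} > end {end}")
            if start < 1:
                raise PartitionError(f"gene {name!r}: start {start} < 1")
            if start <= prev_end:
                raise PartitionError(
                    f"gene {name!r} range {start}-{end} overlaps previous range "
                    f"ending at {prev_end}"
                )
            prev_end = end

    @classmethod
    def from_lengths(cls, named_lengths: Iterable[tuple[str, int]]) -> "GeneMap":
        """Consecutive ranges from ``(name, length)`` pairs starting at site 1."""
        entries = []
        pos = 1
        for name, length in named_lengths:
            entries.append((name, pos, pos + length - 1))
            pos += length
        return cls(tuple(entries))

    @property
    def names(self) -> list[str]:
        return [e[0] for e in self.entries]

    @property
    def total_span(self) -> int:
        return self.entries[-1][2]

    def range_of(self, gene: str) -> tuple[int, int]:
        for name, start, end in self.entries:
            if name == gene:
                return start, end
        raise PartitionError(f"unknown gene {gene!r}")

    def lengths(self) -> dict[str, int]:
        return {n: e - s + 1 for n, s, e in self.entries}

    def validate_coverage(self, alignment_length: int) -> None:
        """Require the ranges to tile ``1..alignment_length`` with no gaps."""
        pos = 1
        gaps: list[str] = []
        for name, start, end in self.entries:
            if start > pos:
                gaps.append(f"{pos}-{start - 1}")
            pos = end + 1
        if pos <= alignment_length:
            gaps.append(f"{pos}-{alignment_length}")
        if self.total_span > alignment_length:
            raise PartitionError(
                f"gene map spans {self.total_span} sites but alignment has "
                f"{alignment_length}"
            )
        if gaps:
            raise PartitionError(
                "gene map does not cover alignment; uncovered sites: "
                + ", ".join(gaps)
            )

    def site_gene_indices(self) -> np.ndarray:
        """Gene index (0-based, GeneMap order) for every site ``1..total_span``."""
        out = np.empty(self.total_span, dtype=int)
        for gi, (_, start, end) in enumerate(self.entries):
            out[start - 1 : end] = gi
        return out

    def slice_gene(self, aln: Alignment, gene: str) -> Alignment:
        start, end = self.range_of(gene)
        return aln.site_slice(start, end)


def read_partitions(source: Union[PathLike, TextIO]) -> GeneMap:
    """Parse a RAxML-style partition file: lines ``DNA, name = start-end``."""
    handle, close = _as_text_handle(source)
    try:
        entries = []
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                left, right = line.split("=")
                _, name = left.split(",", 1)
                start_s, end_s = right.strip().split("-")
                entries.append((name.strip(), int(start_s), int(end_s)))
            except ValueError as exc:
                raise PartitionError(
                    f"cannot parse partition line {lineno}: {line!r}"
                ) from exc
    finally:
        if close:
            handle.close()
    return GeneMap(tuple(entries))


def write_partitions(genes: GeneMap, dest: Union[PathLike, TextIO]) -> None:
    handle, close = _as_text_handle(dest, "w")
    try:
        for name, start, end in genes.entries:
            handle.write(f"DNA, {name} = {start}-{end}\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Supermatrix assembly
# ---------------------------------------------------------------------------

def filter_sequences(
    aln: Alignment,
    min_fraction: float = 0.45,
    min_length: int = 250,
    combine: str = "or",
    strict_greater: bool = False,
) -> Alignment:
    """Apply the length-based sequence-inclusion filter.

    A sequence's ungapped length ``L`` (characters outside ``{-, ?, N}``)
    passes the fraction criterion when ``L >= min_fraction * alignment_length``
    and the absolute criterion when ``L >= min_length`` (``>`` when
    ``strict_greater``).  ``combine`` chooses the connective between the two
    criteria: ``"or"`` (default, the permissive reading that maximises taxon
    count) or ``"and"``.

    Raises :class:`FilterError` when nothing survives.
    """
    if combine not in ("or", "and"):
        raise FilterError(f"combine must be 'or' or 'and', got {combine!r}")
    lengths = aln.ungapped_lengths()
    frac_ok = lengths >= min_fraction * aln.length
    abs_ok = lengths > min_length if strict_greater else lengths >= min_length
    keep = (frac_ok | abs_ok) if combine == "or" else (frac_ok & abs_ok)
    if not keep.any():
        raise FilterError("no sequences pass filter")
    kept_taxa = [t for t, k in zip(aln.taxa, keep) if k]
    return aln.subset_taxa(kept_taxa)


def concatenate(
    alignments: Sequence[tuple[str, Alignment]]
) -> tuple[Alignment, GeneMap]:
    """Concatenate per-marker alignments into a supermatrix.

    Output taxa are the union of input taxa in first-seen order; a taxon
    absent from a marker receives a run of ``?`` of that marker's length.
    The returned :class:`GeneMap` has consecutive ranges in input order.
    """
    if not alignments:
        raise AlignmentError("nothing to concatenate")
    taxa: list[str] = []
    for _, aln in alignments:
        for t in aln.taxa:
            if t not in taxa:
                taxa.append(t)
    # warn when some pair of markers shares no taxon at all
    for i in range(len(alignments)):
        for j in range(i + 1, len(alignments)):
            a, b = alignments[i][1], alignments[j][1]
            if not set(a.taxa) & set(b.taxa):
                warnings.warn(
                    f"markers {alignments[i][0]!r} and {alignments[j][0]!r} "
                    "share no taxa",
                    stacklevel=2,
                )
    rows = {t: [] for t in taxa}
    for name, aln in alignments:
        blank = "?" * aln.length
        for t in taxa:
            rows[t].append(aln.row(t) if t in aln else blank)
    genes = GeneMap.from_lengths((name, aln.length) for name, aln in alignments)
    supermatrix = Alignment((t, "".join(rows[t])) for t in taxa)
    return supermatrix, genes
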