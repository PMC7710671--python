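"""Summary statistics of a (super)matrix: variable sites, parsimony-informative
sites, and per-marker missingness.

The default counting rule treats every non-``{A,C,G,T}`` character — gaps,
``?``, ``N`` and partial IUPAC ambiguity codes alike — as missing data, which
makes the printed counts reproducible under one stated rule.  An alternative
``ambiguity="strict"`` mode scores a column as variable only when no single
nucleotide is compatible with every observed character (so ``A`` and ``R``
still count as potentially constant); it exists because published counts from
different programs differ in exactly this respect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignments import Alignment, GeneMap, IUPAC_CODES, MISSING_CHARS
from .errors import PartitionError

_BASES = "ACGT"
_BASE_BIT = {b: 1 << i for i, b in enumerate(_BASES)}
#: char -> 4-bit mask of compatible nucleotides
_CHAR_MASK = {
    ch: sum(_BASE_BIT[b] for b in states) for ch, states in IUPAC_CODES.items()
}


@dataclass
class AlignmentSummary:
    """Counts reported for a supermatrix plus per-marker missingness."""

    n_taxa: int
    n_sites: int
    n_variable: int
    n_parsimony_informative: int
    per_gene_missingness: pd.DataFrame | None = None
    per_taxon_presence: pd.DataFrame | None = None

    def __post_init__(self):
        if not (
            0 <= self.n_parsimony_informative <= self.n_variable <= self.n_sites
        ):
            raise ValueError(
                "expected 0 <= informative <= variable <= sites, got "
                f"{self.n_parsimony_informative}/{self.n_variable}/{self.n_sites}"
            )

    def to_tsv(self) -> str:
        lines = [
            "statistic\tvalue",
            f"n_taxa\t{self.n_taxa}",
            f"n_sites\t{self.n_sites}",
            f"n_variable\t{self.n_variable}",
            f"n_parsimony_informative\t{self.n_parsimony_informative}",
        ]
        if self.per_gene_missingness is not None:
            for _, r in self.per_gene_missingness.iterrows():
                lines.append(f"missingness_{r['gene']}\t{r['missing_fraction']:.6f}")
        return "\n".join(lines) + "\n"


def _base_counts(aln: Alignment) -> np.ndarray:
    """(4, n_sites) matrix of unambiguous base counts per column."""
    return np.stack([(aln.matrix == b).sum(axis=0) for b in _BASES])


def count_variable_sites(aln: Alignment, ambiguity: str = "missing") -> int:
    """Number of columns with >= 2 distinct states among unambiguous bases.

    ``ambiguity="missing"`` (default) discards every non-ACGT character before
    counting states.  ``ambiguity="strict"`` scores a column as variable when
    the IUPAC compatibility sets of its non-gap characters have an empty
    intersection (no single nucleotide explains the column).
    """
    if ambiguity == "missing":
        counts = _base_counts(aln)
        return int(((counts > 0).sum(axis=0) >= 2).sum())
    if ambiguity == "strict":
        masks = np.vectorize(_CHAR_MASK.__getitem__)(aln.matrix).astype(np.uint8)
        # gaps and ? are pure missing even in strict mode; N intersects as 1111
        hard_missing = np.isin(aln.matrix, ["-", "?"])
        masks[hard_missing] = 0b1111
        inter = np.bitwise_and.reduce(masks, axis=0)
        observed = (~np.isin(aln.matrix, list(MISSING_CHARS))).sum(axis=0)
        return int(((inter == 0) & (observed >= 2)).sum())
    raise ValueError(f"unknown ambiguity mode {ambiguity!r}")


def count_parsimony_informative(aln: Alignment) -> int:
    """Columns where >= 2 unambiguous states each occur in >= 2 taxa."""
    counts = _base_counts(aln)
    return int(((counts >= 2).sum(axis=0) >= 2).sum())


def missingness_report(aln: Alignment, genes: GeneMap) -> pd.DataFrame:
    """Per-gene fraction of taxon x site cells in ``{-, ?, N}``.

    Returns a frame with columns ``gene``, ``missing_fraction`` and
    ``n_taxa_present`` (a gene is present for a taxon when at least one of its
    cells is non-missing).
    """
    if genes.total_span != aln.length:
        raise PartitionError(
            f"gene map covers {genes.total_span} sites but alignment has "
            f"{aln.length}"
        )
    genes.validate_coverage(aln.length)
    missing = np.isin(aln.matrix, list(MISSING_CHARS))
    rows = []
    for name, start, end in genes.entries:
        block = missing[:, start - 1 : end]
        present = (~block).any(axis=1)
        rows.append(
            {
                "gene": name,
                "missing_fraction": float(block.mean()),
                "n_taxa_present": int(present.sum()),
            }
        )
    return pd.DataFrame(rows)


def taxon_gene_presence(aln: Alignment, genes: GeneMap) -> pd.DataFrame:
    """Boolean taxon x gene presence table (True = marker sampled)."""
    genes.validate_coverage(aln.length)
    missing = np.isin(aln.matrix, list(MISSING_CHARS))
    data = {
        name: (~missing[:, start - 1 : end]).any(axis=1)
        for name, start, end in genes.entries
    }
    return pd.DataFrame(data, index=aln.taxa)


def summarize(
    aln: Alignment, genes: GeneMap | None = None, ambiguity: str = "missing"
) -> AlignmentSummary:
    """Full summary: taxa, sites, variable, informative, missingness."""
    return AlignmentSummary(
        n_taxa=aln.n_taxa,
        n_sites=aln.length,
        n_variable=count_variable_sites(aln, ambiguity=ambiguity),
        n_parsimony_informative=count_parsimony_informative(aln),
        per_gene_missingness=None if genes is None else missingness_report(aln, genes),
        per_taxon_presence=None if genes is None else taxon_gene_presence(aln, genes),
    )
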