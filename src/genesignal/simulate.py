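"""Synthetic multi-marker datasets with topological conflict.

The generator emulates the data regime the signal analysis is built for:
several markers of unequal length evolved under GTR+Γ along one of two
topologies that differ by a single contested internal branch (clade A sister
to B, or A sister to C), with block-structured missingness — whole
taxon-by-marker sequences absent, the way markers are actually missing from
sparse supermatrices, rather than scattered gaps.

One global seed expands into independent per-gene streams through numpy's
``SeedSequence(entropy=seed, spawn_key=(gene_index,))``, so adding a gene to
a configuration never perturbs the data of earlier genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .alignments import Alignment, GeneMap, concatenate
from .errors import GenesignalError
from .models import EigenSystem, SubstitutionModel, build_rate_matrix, discretize_gamma
from .trees import PhyloTree

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]

#: Default inner branch length (substitutions/site) for all uncontested edges.
DEFAULT_EDGE_LENGTH = 0.05


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GeneSpec:
    """One simulated marker: length, which topology it evolved on, and how
    strongly the contested internode is resolved."""

    name: str
    length: int
    true_topology: str  # "AB" or "AC"
    internode_length: float = 0.1
    scale: float = 1.0

    def __post_init__(self):
        if self.length < 1:
            raise GenesignalError(f"gene {self.name!r}: length must be >= 1")
        if self.true_topology not in ("AB", "AC"):
            raise GenesignalError(
                f"gene {self.name!r}: true_topology must be 'AB' or 'AC'"
            )
        if self.internode_length < 0 or self.scale <= 0:
            raise GenesignalError(
                f"gene {self.name!r}: internode_length >= 0 and scale > 0 required"
            )


@dataclass
class SimulationConfig:
    """Taxon sets, per-gene specifications, model, missingness and seed."""

    clade_a: tuple[str, ...]
    clade_b: tuple[str, ...]
    clade_c: tuple[str, ...]
    outgroup: tuple[str, ...]
    gene_specs: tuple[GeneSpec, ...]
    model: SubstitutionModel = field(default_factory=SubstitutionModel.jc)
    missingness: float = 0.0
    seed: int = 0

    def __post_init__(self):
        groups = [self.clade_a, self.clade_b, self.clade_c, self.outgroup]
        all_taxa = [t for g in groups for t in g]
        if len(set(all_taxa)) != len(all_taxa):
            raise GenesignalError("clades overlap")
        if len(all_taxa) < 4:
            raise GenesignalError("need at least 4 taxa")
        if any(len(g) < 1 for g in groups):
            raise GenesignalError("every clade and the outgroup need >= 1 taxon")
        if not self.gene_specs:
            raise GenesignalError("need at least one gene")
        if not (0.0 <= self.missingness <= 1.0):
            raise GenesignalError("missingness must be in [0, 1]")

    @property
    def taxa(self) -> list[str]:
        return list(self.clade_a + self.clade_b + self.clade_c + self.outgroup)


def _clade_newick(taxa: Sequence[str], bl: float) -> str:
    """Pectinate subtree over ``taxa`` with every edge of length ``bl``."""
    if len(taxa) == 1:
        return f"{taxa[0]}:{bl:g}"
    inner = f"{taxa[0]}:{bl:g}"
    for t in taxa[1:]:
        inner = f"({inner},{t}:{bl:g}):{bl:g}"
    return inner


def build_topology_pair(
    cfg_or_groups,
    internode_length: float = 0.1,
    scale: float = 1.0,
) -> tuple[PhyloTree, PhyloTree]:
    """The two skeleton topologies: (A,B) sisters and (A,C) sisters.

    Accepts a :class:`SimulationConfig` or a 4-tuple of taxon sequences
    ``(clade_a, clade_b, clade_c, outgroup)``.  Every uncontested edge has
    length ``DEFAULT_EDGE_LENGTH * scale``; the contested internode gets
    ``internode_length`` as given.
    """
    if isinstance(cfg_or_groups, SimulationConfig):
        a, b, c, og = (
            cfg_or_groups.clade_a,
            cfg_or_groups.clade_b,
            cfg_or_groups.clade_c,
            cfg_or_groups.outgroup,
        )
    else:
        a, b, c, og = cfg_or_groups
    bl = DEFAULT_EDGE_LENGTH * scale
    sub = {k: _clade_newick(v, bl) for k, v in
           (("A", a), ("B", b), ("C", c), ("O", og))}
    ab = (
        f"(({sub['A']},{sub['B']}):{internode_length:g},"
        f"{sub['C']},{sub['O']});"
    )
    ac = (
        f"(({sub['A']},{sub['C']}):{internode_length:g},"
        f"{sub['B']},{sub['O']});"
    )
    return PhyloTree.from_newick(ab), PhyloTree.from_newick(ac)


def simulate_alignment(
    tree: PhyloTree,
    model: SubstitutionModel,
    n_sites: int,
    seed: SeedLike = 0,
) -> Alignment:
    """Forward simulation of ``n_sites`` columns along ``tree`` under GTR+Γ.

    Root states are drawn from the stationary frequencies; each site is
    assigned one discrete-gamma rate category; states propagate edge by edge
    via the transition matrices.  Deterministic given the seed.
    """
    if n_sites < 1:
        raise GenesignalError("n_sites must be >= 1")
    rng = _rng(seed)
    pi = model.pi
    rates = discretize_gamma(model.gamma_shape, model.n_categories)
    eig = EigenSystem(build_rate_matrix(model), pi)
    nodes = list(tree.dtree.preorder_node_iter())
    for node in nodes:
        if node.parent_node is not None and node.edge.length is None:
            raise GenesignalError("tree has branches without lengths")
    cats = rng.integers(0, model.n_categories, size=n_sites)
    states: dict[int, np.ndarray] = {}
    root = nodes[0]
    states[id(root)] = rng.choice(4, size=n_sites, p=pi)
    for node in nodes[1:]:
        parent_states = states[id(node.parent_node)]
        t = float(node.edge.length)
        pmats = eig.p_matrices(rates * t)  # (ncat, 4, 4)
        probs = pmats[cats, parent_states]  # (n_sites, 4)
        cum = probs.cumsum(axis=1)
        cum /= cum[:, -1:]
        u = rng.random(n_sites)
        states[id(node)] = (u[:, None] > cum).sum(axis=1)
    bases = np.array(list("ACGT"))
    records = []
    for leaf in tree.dtree.leaf_node_iter():
        records.append((leaf.taxon.label, "".join(bases[states[id(leaf)]])))
    return Alignment(records)


def apply_missingness(
    aln: Alignment,
    genes: GeneMap,
    p: float,
    seed: SeedLike = 0,
    max_resample: int = 100,
) -> Alignment:
    """Mask whole taxon-by-gene blocks with ``?`` independently at rate ``p``.

    A gene is never left with all taxa masked: offending genes are resampled
    (up to ``max_resample`` times, then an error is raised, which is the
    certain outcome at ``p = 1``).
    """
    if not (0.0 <= p <= 1.0):
        raise GenesignalError("missingness probability must be in [0, 1]")
    if p == 0.0:
        return aln
    genes.validate_coverage(aln.length)
    rng = _rng(seed)
    n_taxa = aln.n_taxa
    mask = np.zeros((n_taxa, len(genes.entries)), dtype=bool)
    for gi in range(len(genes.entries)):
        col = rng.random(n_taxa) < p
        tries = 0
        while col.all():
            tries += 1
            if tries > max_resample:
                raise GenesignalError(
                    f"gene {genes.entries[gi][0]!r}: could not avoid masking "
                    f"all taxa after {max_resample} resamples (p={p})"
                )
            col = rng.random(n_taxa) < p
        mask[:, gi] = col
    rows = []
    for ti, taxon in enumerate(aln.taxa):
        row = list(aln.row(taxon))
        for gi, (_, start, end) in enumerate(genes.entries):
            if mask[ti, gi]:
                row[start - 1 : end] = "?" * (end - start + 1)
        rows.append((taxon, "".join(row)))
    return Alignment(rows)


@dataclass
class ConflictDataset:
    """Everything :func:`generate_conflict_dataset` produces."""

    gene_alignments: list  # [(name, Alignment)]
    supermatrix: Alignment
    genes: GeneMap
    tree_ab: PhyloTree  # T1 skeleton: clades A and B sisters
    tree_ac: PhyloTree  # T2 skeleton: clades A and C sisters
    true_trees: dict  # gene name -> PhyloTree it evolved on
    truth_table: pd.DataFrame  # gene, true_topology, internode_length, expected_sign


def generate_conflict_dataset(cfg: SimulationConfig) -> ConflictDataset:
    """Simulate every gene on its true topology and assemble the supermatrix.

    The truth table records, per gene, the expected sign of ΔGLS when T1 is
    the AB topology: +1 for genes simulated under AB, −1 under AC, 0 when the
    contested internode has length zero (no signal either way).
    """
    ss = np.random.SeedSequence(entropy=cfg.seed)
    gene_alns: list[tuple[str, Alignment]] = []
    true_trees: dict[str, PhyloTree] = {}
    rows = []
    for gi, spec in enumerate(cfg.gene_specs):
        ab, ac = build_topology_pair(
            cfg, internode_length=spec.internode_length, scale=spec.scale
        )
        true_tree = ab if spec.true_topology == "AB" else ac
        gene_seed = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(gi,))
        aln = simulate_alignment(
            true_tree, cfg.model, spec.length, seed=np.random.default_rng(gene_seed)
        )
        if cfg.missingness > 0:
            gmap = GeneMap.from_lengths([(spec.name, spec.length)])
            mask_seed = np.random.SeedSequence(
                entropy=cfg.seed, spawn_key=(gi, 1)
            )
            aln = apply_missingness(
                aln, gmap, cfg.missingness, seed=np.random.default_rng(mask_seed)
            )
        gene_alns.append((spec.name, aln))
        true_trees[spec.name] = true_tree
        expected = 0 if spec.internode_length == 0 else (
            1 if spec.true_topology == "AB" else -1
        )
        rows.append(
            {
                "gene": spec.name,
                "true_topology": spec.true_topology,
                "internode_length": spec.internode_length,
                "length": spec.length,
                "expected_sign": expected,
            }
        )
    supermatrix, genes = concatenate(gene_alns)
    tree_ab, tree_ac = build_topology_pair(cfg, internode_length=0.05, scale=1.0)
    return ConflictDataset(
        gene_alignments=gene_alns,
        supermatrix=supermatrix,
        genes=genes,
        tree_ab=tree_ab,
        tree_ac=tree_ac,
        true_trees=true_trees,
        truth_table=pd.DataFrame(rows),
    )


def default_config(
    seed: int = 0,
    missingness: float = 0.0,
    model: SubstitutionModel | None = None,
) -> SimulationConfig:
    """The reference study conditions: 12 taxa in three clades plus an
    outgroup pair, and five markers — one long, strongly AB-resolving gene
    (the "rpb2-like" marker) against four weaker genes that favour AC.
    """
    if model is None:
        model = SubstitutionModel(
            exchangeabilities=(1.5, 4.0, 1.2, 1.1, 5.0, 1.0),
            base_frequencies=(0.26, 0.22, 0.24, 0.28),
            gamma_shape=0.5,
            n_categories=4,
        )
    return SimulationConfig(
        clade_a=("A1", "A2", "A3", "A4"),
        clade_b=("B1", "B2", "B3"),
        clade_c=("C1", "C2", "C3"),
        outgroup=("O1", "O2"),
        gene_specs=(
            GeneSpec("rpb2_like", 1000, "AB", internode_length=0.1),
            GeneSpec("weak1", 400, "AC", internode_length=0.01),
            GeneSpec("weak2", 550, "AC", internode_length=0.01),
            GeneSpec("weak3", 650, "AC", internode_length=0.01),
            GeneSpec("weak4", 800, "AC", internode_length=0.01),
        ),
        model=model,
        missingness=missingness,
        seed=seed,
    )
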