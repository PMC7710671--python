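"""Felsenstein-pruning likelihood engine for GTR+Γ on a fixed topology.

Per-site log-likelihoods are computed by the pruning algorithm over unique
site patterns (compressed columns weighted by multiplicity, expanded back to
site order on output), with the discrete-gamma mixture averaged per site and
numerical underflow handled by per-node scaling factors accumulated in log
space.  Missing and ambiguous leaf characters contribute a partial-likelihood
vector with ones at every compatible state (IUPAC-aware; ``-``, ``?`` and
``N`` are identical).

Branch lengths are optimised one edge at a time with a bounded scalar search.
For a reversible model the likelihood as a function of a single edge length
factorises as ``L(t) = (pi ⊙ F) · P(t) · D`` where ``D`` is the post-order
partial below the edge and ``F`` collects everything else via a pre-order
("above") pass, so each trial length costs one 4x4 product per category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar, Bounds

from .alignments import Alignment, IUPAC_CODES
from .errors import GenesignalError
from .models import (
    EigenSystem,
    SubstitutionModel,
    build_rate_matrix,
    discretize_gamma,
    empirical_frequencies,
)
from .trees import PhyloTree

BL_MIN = 1e-8
BL_MAX = 50.0

_STATE_INDEX = {b: i for i, b in enumerate("ACGT")}
#: char -> length-4 0/1 compatibility vector
_CHAR_PARTIAL = {
    ch: np.array(
        [1.0 if b in states else 0.0 for b in "ACGT"]
    )
    for ch, states in IUPAC_CODES.items()
}


@dataclass
class SiteLikelihoodTable:
    """Per-site log-likelihoods of one alignment under one topology."""

    topology_id: str
    per_site_lnL: np.ndarray

    def __post_init__(self):
        self.per_site_lnL = np.asarray(self.per_site_lnL, dtype=float)
        if self.per_site_lnL.ndim != 1 or self.per_site_lnL.size == 0:
            raise GenesignalError("per-site table must be a non-empty vector")
        if np.any(self.per_site_lnL > 1e-9):
            raise GenesignalError("site log-likelihoods must be <= 0")

    @property
    def n_sites(self) -> int:
        return self.per_site_lnL.size

    @property
    def total_lnL(self) -> float:
        return float(self.per_site_lnL.sum())


class CompressedAlignment:
    """Unique site patterns of an alignment, with multiplicities.

    Reusable across engines so that repeated likelihood evaluations on the
    same data (e.g. during an NNI search) pay the compression cost once.
    """

    def __init__(self, aln: Alignment):
        self.taxa = list(aln.taxa)
        self.n_sites = aln.length
        patterns, inverse, counts = np.unique(
            aln.matrix, axis=1, return_inverse=True, return_counts=True
        )
        self.site_to_pattern = inverse.ravel()
        self.weights = counts.astype(float)
        self.n_patterns = patterns.shape[1]
        lut = np.vectorize(lambda c: _STATE_INDEX.get(c, -1))(patterns)
        # tip partials: (n_taxa, n_patterns, 4)
        tips = np.empty((len(self.taxa), self.n_patterns, 4))
        for ti in range(len(self.taxa)):
            for pi_ in range(self.n_patterns):
                tips[ti, pi_] = _CHAR_PARTIAL[patterns[ti, pi_]]
        self.tip_partials = tips
        self._taxon_index = {t: i for i, t in enumerate(self.taxa)}

    def tip_partial(self, taxon: str) -> np.ndarray:
        return self.tip_partials[self._taxon_index[taxon]]


@dataclass
class OptResult:
    lnL: float
    n_passes: int
    converged: bool
    warning: str | None = None


class PruningEngine:
    """Likelihood calculator bound to one alignment, tree and model.

    The tree is referenced, not copied: ``optimize_edges`` mutates the branch
    lengths of the :class:`~genesignal.trees.PhyloTree` it was given.  Callers
    that need to preserve the input tree pass a copy.
    """

    def __init__(
        self,
        aln: Alignment | CompressedAlignment,
        tree: PhyloTree,
        model: SubstitutionModel,
    ):
        comp = aln if isinstance(aln, CompressedAlignment) else CompressedAlignment(aln)
        leaf_labels = set(tree.leaf_labels())
        aln_taxa = set(comp.taxa)
        missing = sorted(leaf_labels - aln_taxa)
        if missing:
            raise GenesignalError(
                f"tree leaves absent from alignment: {', '.join(missing)}"
            )
        extra = sorted(aln_taxa - leaf_labels)
        if extra:
            raise GenesignalError(
                f"alignment taxa absent from tree: {', '.join(extra)}"
            )
        self.data = comp
        self.tree = tree
        # node arrays in postorder; root is the last entry
        self._nodes = list(tree.dtree.postorder_node_iter())
        self._id = {id(n): i for i, n in enumerate(self._nodes)}
        self.n_nodes = len(self._nodes)
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        self.blen = np.zeros(self.n_nodes)
        self.is_leaf = np.zeros(self.n_nodes, dtype=bool)
        self._tip_idx = np.full(self.n_nodes, -1, dtype=int)
        for i, node in enumerate(self._nodes):
            if node.parent_node is not None:
                p = self._id[id(node.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                length = node.edge.length if node.edge.length is not None else 0.0
                self.blen[i] = max(float(length), 0.0)
            if not node.child_nodes():
                self.is_leaf[i] = True
                self._tip_idx[i] = comp._taxon_index[node.taxon.label]
            elif node.taxon is not None and node.taxon.label in comp._taxon_index:
                # data-bearing internal node (e.g. a tree rooted at a taxon)
                self.is_leaf[i] = True
                self._tip_idx[i] = comp._taxon_index[node.taxon.label]
        self.root = self.n_nodes - 1
        self.set_model(model)

    # -- model / branch management ------------------------------------------

    def set_model(self, model: SubstitutionModel) -> None:
        self.model = model
        self.pi = model.pi
        self.rates = discretize_gamma(model.gamma_shape, model.n_categories)
        self.ncat = model.n_categories
        self.eig = EigenSystem(build_rate_matrix(model), self.pi)
        self.P = np.empty((self.n_nodes, self.ncat, 4, 4))
        for i in range(self.n_nodes):
            if self.parent[i] >= 0:
                self.P[i] = self.eig.p_matrices(self.blen[i] * self.rates)
        self._fresh = False

    def set_branch_length(self, i: int, t: float) -> None:
        self.blen[i] = t
        self.P[i] = self.eig.p_matrices(t * self.rates)
        self._nodes[i].edge.length = float(t)
        self._fresh = False

    # -- pruning passes ------------------------------------------------------

    def _down_pass(self) -> None:
        npat, ncat = self.data.n_patterns, self.ncat
        self.down = [None] * self.n_nodes
        self.dscale = [None] * self.n_nodes
        for i in range(self.n_nodes):  # postorder by construction
            if self.is_leaf[i] and not self.children[i]:
                tip = self.data.tip_partials[self._tip_idx[i]]
                self.down[i] = np.broadcast_to(tip, (ncat, npat, 4)).copy()
                self.dscale[i] = np.zeros(npat)
                continue
            part = np.ones((ncat, npat, 4))
            scale = np.zeros(npat)
            if self.is_leaf[i]:  # leaf-rooted tree: root carries data too
                part *= self.data.tip_partials[self._tip_idx[i]]
            for c in self.children[i]:
                part *= np.einsum("kpj,kij->kpi", self.down[c], self.P[c])
                scale += self.dscale[c]
            smax = part.max(axis=(0, 2))
            smax = np.where(smax > 0, smax, 1.0)
            part /= smax[None, :, None]
            scale += np.log(smax)
            self.down[i] = part
            self.dscale[i] = scale

    def _above_pass(self) -> None:
        npat, ncat = self.data.n_patterns, self.ncat
        self.above = [None] * self.n_nodes
        self.ascale = [None] * self.n_nodes
        self.above[self.root] = np.ones((ncat, npat, 4))
        self.ascale[self.root] = np.zeros(npat)
        for i in reversed(range(self.n_nodes)):  # preorder
            for c in self.children[i]:
                f, fscale = self._flank(i, exclude=c)
                # above[c](j) = sum_i P_c[j, i] f(i)  (reversible model)
                a = np.einsum("kpi,kji->kpj", f, self.P[c])
                smax = a.max(axis=(0, 2))
                smax = np.where(smax > 0, smax, 1.0)
                a /= smax[None, :, None]
                self.above[c] = a
                self.ascale[c] = fscale + np.log(smax)

    def _flank(self, p: int, exclude: int) -> tuple[np.ndarray, np.ndarray]:
        """above[p] times p's own tip partial and all child subtrees but one."""
        f = self.above[p].copy()
        fscale = self.ascale[p].copy()
        if self.is_leaf[p]:
            f *= self.data.tip_partials[self._tip_idx[p]]
        for s in self.children[p]:
            if s != exclude:
                f *= np.einsum("kpj,kij->kpi", self.down[s], self.P[s])
                fscale += self.dscale[s]
        return f, fscale

    def _refresh(self, above: bool = False) -> None:
        if not self._fresh:
            self._down_pass()
            self._above = False
            self._fresh = True
        if above and not getattr(self, "_above", False):
            self._above_pass()
            self._above = True

    # -- likelihood ----------------------------------------------------------

    def pattern_log_likelihoods(self) -> np.ndarray:
        self._refresh()
        w = 1.0 / self.ncat
        like = w * np.einsum("kpi,i->p", self.down[self.root], self.pi)
        with np.errstate(divide="ignore"):
            return np.log(like) + self.dscale[self.root]

    def site_log_likelihoods(self, topology_id: str = "T") -> SiteLikelihoodTable:
        lnl = self.pattern_log_likelihoods()[self.data.site_to_pattern]
        return SiteLikelihoodTable(topology_id, np.minimum(lnl, 0.0))

    def total_log_likelihood(self) -> float:
        return float(self.pattern_log_likelihoods() @ self.data.weights)

    # -- branch-length optimisation ------------------------------------------

    def _edge_objective(self, i: int):
        """Return f(t) -> total lnL as a function of edge i's length only."""
        p = self.parent[i]
        f, fscale = self._flank(p, exclude=i)
        pif = self.pi[None, None, :] * f
        d = self.down[i]
        base_scale = fscale + self.dscale[i]
        w = 1.0 / self.ncat

        def lnl(t: float) -> float:
            pk = self.eig.p_matrices(t * self.rates)
            a = np.einsum("kpi,kij->kpj", pif, pk)
            like = w * (a * d).sum(axis=(0, 2))
            with np.errstate(divide="ignore"):
                lp = np.log(like) + base_scale
            return float(lp @ self.data.weights)

        return lnl

    def optimize_edge(self, i: int, xatol: float = 1e-9) -> float:
        """Optimise one edge length in place; returns the new total lnL."""
        self._refresh(above=True)
        f = self._edge_objective(i)
        current = f(self.blen[i])
        res = minimize_scalar(
            lambda t: -f(t), bounds=(BL_MIN, BL_MAX), method="bounded",
            options={"xatol": xatol},
        )
        if -res.fun > current:
            self.set_branch_length(i, float(res.x))
            return float(-res.fun)
        return current

    def optimize_edges(
        self,
        edge_ids: list[int] | None = None,
        tol: float = 1e-4,
        max_passes: int = 100,
    ) -> OptResult:
        """Sweep bounded 1-D searches over edges until joint convergence.

        ``edge_ids`` restricts the sweep (engine node indices); default is
        every edge, in postorder.
        """
        ids = [
            i for i in (edge_ids if edge_ids is not None else range(self.n_nodes))
            if self.parent[i] >= 0
        ]
        last = current = self.total_log_likelihood()
        for n_pass in range(1, max_passes + 1):
            for i in ids:
                current = self.optimize_edge(i)
            if current - last < tol:
                return OptResult(current, n_pass, True)
            last = current
        return OptResult(
            last, max_passes, False,
            warning=f"branch optimisation stopped after {max_passes} passes",
        )

    def node_id_of(self, node) -> int:
        return self._id[id(node)]


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def site_log_likelihoods(
    aln: Alignment | CompressedAlignment,
    tree: PhyloTree,
    model: SubstitutionModel,
    topology_id: str = "T",
) -> SiteLikelihoodTable:
    """Per-site log-likelihoods of ``aln`` on ``tree`` under ``model``."""
    return PruningEngine(aln, tree, model).site_log_likelihoods(topology_id)


def optimize_branch_lengths(
    aln: Alignment | CompressedAlignment,
    tree: PhyloTree,
    model: SubstitutionModel,
    tol: float = 1e-4,
    max_passes: int = 100,
) -> tuple[PhyloTree, OptResult]:
    """Maximum-likelihood branch lengths on a fixed topology.

    Returns a new tree (same topology) and the optimisation record; lengths
    are clamped to ``[1e-8, 50]`` substitutions/site.
    """
    out = tree.copy()
    if out.root_degree() == 2:
        out.deroot()
    engine = PruningEngine(aln, out, model)
    info = engine.optimize_edges(tol=tol, max_passes=max_passes)
    return out, info


@dataclass
class FitResult:
    lnL: float
    n_cycles: int
    converged: bool


def fit_model(
    aln: Alignment | CompressedAlignment,
    tree: PhyloTree,
    gamma_shape: float = 1.0,
    n_categories: int = 4,
    tol: float = 1e-2,
    max_cycles: int = 8,
    optimize_branches: bool = True,
    branch_tol: float = 1e-3,
) -> tuple[SubstitutionModel, PhyloTree, FitResult]:
    """Joint GTR+Γ fit: exchangeabilities and gamma shape by bounded
    derivative-free search, alternating with branch-length sweeps.

    Base frequencies are empirical (counted from the alignment with missing
    characters excluded), matching the convention of standard GTRGAMMA runs.
    All starting points are deterministic: equal exchangeabilities, the given
    ``gamma_shape``, and the tree's input branch lengths.
    """
    comp = aln if isinstance(aln, CompressedAlignment) else CompressedAlignment(aln)
    if isinstance(aln, CompressedAlignment):
        freqs = _frequencies_from_compressed(comp)
    else:
        freqs = empirical_frequencies(aln)
    out = tree.copy()
    if out.root_degree() == 2:
        out.deroot()
    model = SubstitutionModel(
        base_frequencies=tuple(freqs),
        gamma_shape=gamma_shape,
        n_categories=n_categories,
    )
    engine = PruningEngine(comp, out, model)

    log_bounds = Bounds(
        lb=[np.log(1e-3)] * 5 + [np.log(0.02)],
        ub=[np.log(1e3)] * 5 + [np.log(100.0)],
    )

    def unpack(x: np.ndarray) -> SubstitutionModel:
        ex = np.exp(x[:5])
        return model.replace(
            exchangeabilities=(*ex, 1.0), gamma_shape=float(np.exp(x[5]))
        )

    def objective(x: np.ndarray) -> float:
        engine.set_model(unpack(x))
        return -engine.total_log_likelihood()

    x = np.concatenate([np.log(np.asarray(model.exchangeabilities[:5])),
                        [np.log(model.gamma_shape)]])
    last = -objective(x)
    converged = False
    n_cycles = 0
    for n_cycles in range(1, max_cycles + 1):
        res = minimize(
            objective, x, method="Powell", bounds=log_bounds,
            options={"xtol": 1e-3, "ftol": 1e-6, "maxiter": 3},
        )
        x = res.x
        engine.set_model(unpack(x))
        if optimize_branches:
            engine.optimize_edges(tol=branch_tol, max_passes=5)
        current = engine.total_log_likelihood()
        if current - last < tol:
            converged = True
            last = current
            break
        last = current
    return engine.model, out, FitResult(last, n_cycles, converged)


def _frequencies_from_compressed(comp: CompressedAlignment) -> np.ndarray:
    # tip partials with exactly one compatible state are unambiguous bases
    tp = comp.tip_partials  # (ntaxa, npat, 4)
    unambiguous = tp.sum(axis=2) == 1
    counts = (tp * unambiguous[:, :, None] * comp.weights[None, :, None]).sum(
        axis=(0, 1)
    )
    if counts.sum() == 0:
        raise GenesignalError("alignment contains no unambiguous bases")
    freqs = np.maximum(counts / counts.sum(), 1e-6)
    return freqs / freqs.sum()
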