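"""Independent reference implementations used to check the package.

Everything here is deliberately naive and self-contained: likelihoods by
exhaustive enumeration of interior-node states with scipy's generic matrix
exponential, discrete-gamma rates by numerical quadrature, topologies and
splits from nested-tuple structures.  None of it shares code paths with the
implementations it is used to verify.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

#: independent IUPAC table (deliberately re-stated, not imported)
CHAR_STATES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT",
}
BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def gtr_q(exchangeabilities, freqs):
    """Normalised GTR generator, written out longhand."""
    s = list(exchangeabilities)
    pi = np.asarray(freqs, dtype=float)
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    q = np.zeros((4, 4))
    for rate, (i, j) in zip(s, pairs):
        q[i, j] = rate * pi[j]
        q[j, i] = rate * pi[i]
    for i in range(4):
        q[i, i] = -q[i].sum()
    return q / -(pi * np.diag(q)).sum()


def gamma_rates_quadrature(alpha, k):
    """Mean of the mean-one gamma density over each inter-quantile bin."""
    edges = [0.0] + list(
        gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    ) + [np.inf]
    rates = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        val, _ = quad(
            lambda x: x * gamma_dist.pdf(x, a=alpha, scale=1.0 / alpha),
            lo, min(hi, 400.0),
        )
        rates.append(val * k)
    return np.array(rates)


def jc_p_same(t):
    return 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)


def jc_p_diff(t):
    return 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)


def brute_force_site_lnl(aln, tree, model):
    """Site log-likelihoods by summation over all interior-state assignments
    and gamma categories; P(t) via scipy expm.  Exponential in tree size."""
    from genesignal.models import discretize_gamma  # rates contract is shared

    q = gtr_q(model.exchangeabilities, model.base_frequencies)
    pi = np.asarray(model.base_frequencies)
    rates = discretize_gamma(model.gamma_shape, model.n_categories)
    nodes = list(tree.dtree.preorder_node_iter())
    internals = [n for n in nodes if n.child_nodes()]
    out = []
    for site in range(aln.length):
        total = 0.0
        for rate in rates:
            pmat = {
                id(n): expm(q * rate * (n.edge.length or 0.0)) for n in nodes[1:]
            }
            acc = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                states = {id(n): a for n, a in zip(internals, assign)}
                prob = pi[states[id(nodes[0])]]
                for n in nodes[1:]:
                    parent_state = states[id(n.parent_node)]
                    if n.child_nodes():
                        prob *= pmat[id(n)][parent_state, states[id(n)]]
                    else:
                        ch = aln.row(n.taxon.label)[site]
                        compat = [BASE_INDEX[b] for b in CHAR_STATES[ch]]
                        prob *= pmat[id(n)][parent_state, compat].sum()
                acc += prob
            total += acc / len(rates)
        out.append(np.log(total))
    return np.array(out)


# ---------------------------------------------------------------------------
# Exhaustive topology enumeration (nested tuples)
# ---------------------------------------------------------------------------

def rooted_trees(labels):
    """All rooted binary tree shapes over ``labels`` as nested tuples."""
    labels = sorted(labels)
    if len(labels) == 1:
        return [labels[0]]
    first, rest = labels[0], labels[1:]
    out = []
    for r in range(len(rest)):
        for combo in itertools.combinations(rest, r):
            left_labels = [first, *combo]
            right_labels = [l for l in rest if l not in combo]
            if not right_labels:
                continue
            for lt in rooted_trees(left_labels):
                for rt in rooted_trees(right_labels):
                    out.append((lt, rt))
    return out


def unrooted_topologies(labels):
    """All unrooted binary topologies: ``(labels[0], T)`` with T rooted over
    the rest.  Returns nested tuples; 5 labels give 15 topologies."""
    labels = sorted(labels)
    return [(labels[0], t) for t in rooted_trees(labels[1:])]


def tuple_leaves(t):
    if isinstance(t, str):
        return frozenset([t])
    return tuple_leaves(t[0]) | tuple_leaves(t[1])


def tuple_clades(t, acc=None):
    """Leaf sets of every subtree of a nested tuple."""
    if acc is None:
        acc = []
    acc.append(tuple_leaves(t))
    if not isinstance(t, str):
        tuple_clades(t[0], acc)
        tuple_clades(t[1], acc)
    return acc


def tuple_splits(t):
    """Non-trivial unrooted splits of a nested-tuple tree, normalised to the
    side not containing the smallest label."""
    all_leaves = tuple_leaves(t)
    ref = min(all_leaves)
    n = len(all_leaves)
    out = set()
    for clade in tuple_clades(t):
        side = all_leaves - clade if ref in clade else clade
        if 2 <= len(side) <= n - 2:
            out.add(frozenset(side))
    return out


def tuple_to_newick(t, brlen=0.1):
    """Newick with uniform branch lengths; the nested-tuple root becomes a
    degree-2 root node (harmless under unrooted semantics)."""

    def rec(node):
        if isinstance(node, str):
            return f"{node}:{brlen}"
        return f"({rec(node[0])},{rec(node[1])}):{brlen}"

    return f"({rec(t[0])},{rec(t[1])});"
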