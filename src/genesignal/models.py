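"""The GTR+Γ nucleotide substitution model.

A general time-reversible rate matrix is parameterised by six symmetric
exchangeabilities (order AC, AG, AT, CG, CT, GT; GT is fixed to 1) and four
stationary base frequencies, and is normalised so the expected substitution
rate at stationarity is one — branch lengths are then in expected
substitutions per site.  Among-site rate variation uses Yang's discrete
approximation of the mean-one gamma distribution: ``k`` equal-weight
categories whose rates are the means of the inter-quantile bins.

Transition probabilities are computed through a symmetrised
eigendecomposition of the generator (exact for reversible models, and the
eigensystem is computed once and reused across branches and rate categories).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import gamma as _gamma_dist

from .alignments import Alignment
from .errors import GenesignalError

BASES = "ACGT"
#: Index pairs for the exchangeability vector, order AC, AG, AT, CG, CT, GT.
PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
PAIR_NAMES = ("AC", "AG", "AT", "CG", "CT", "GT")


@dataclass(frozen=True)
class SubstitutionModel:
    """GTR+Γ parameters.

    ``exchangeabilities`` are rescaled on construction so GT == 1;
    ``base_frequencies`` are renormalised to sum exactly to one.
    """

    exchangeabilities: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_frequencies: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float = 1.0
    n_categories: int = 4

    def __post_init__(self):
        ex = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.base_frequencies, dtype=float)
        if ex.shape != (6,) or np.any(ex <= 0) or not np.all(np.isfinite(ex)):
            raise GenesignalError("exchangeabilities must be 6 positive reals")
        if pi.shape != (4,) or np.any(pi <= 0) or not np.all(np.isfinite(pi)):
            raise GenesignalError("base frequencies must be 4 positive reals")
        if abs(pi.sum() - 1.0) > 1e-6:
            raise GenesignalError(
                f"base frequencies sum to {pi.sum():.8f}, expected 1"
            )
        if self.gamma_shape <= 0:
            raise GenesignalError("gamma shape must be positive")
        if self.n_categories < 1:
            raise GenesignalError("need at least one rate category")
        object.__setattr__(
            self, "exchangeabilities", tuple(ex / ex[5])
        )
        object.__setattr__(
            self, "base_frequencies", tuple(pi / pi.sum())
        )

    # -- constructors --------------------------------------------------------

    @classmethod
    def jc(cls, gamma_shape: float = 1.0, n_categories: int = 1) -> "SubstitutionModel":
        """Jukes–Cantor: equal exchangeabilities and frequencies."""
        return cls(gamma_shape=gamma_shape, n_categories=n_categories)

    @classmethod
    def with_empirical_frequencies(
        cls, aln: Alignment, **kwargs
    ) -> "SubstitutionModel":
        return cls(base_frequencies=tuple(empirical_frequencies(aln)), **kwargs)

    def replace(self, **kwargs) -> "SubstitutionModel":
        return replace(self, **kwargs)

    # -- derived quantities --------------------------------------------------

    @property
    def pi(self) -> np.ndarray:
        return np.asarray(self.base_frequencies)

    def rate_matrix(self) -> np.ndarray:
        return build_rate_matrix(self)

    def category_rates(self) -> np.ndarray:
        return discretize_gamma(self.gamma_shape, self.n_categories)

    # -- plain-text serialization -------------------------------------------

    def to_text(self) -> str:
        lines = [
            "model = GTR+G",
            "exchangeabilities = "
            + " ".join(f"{x:.10g}" for x in self.exchangeabilities),
            "base_frequencies = "
            + " ".join(f"{x:.10g}" for x in self.base_frequencies),
            f"gamma_shape = {self.gamma_shape:.10g}",
            f"n_categories = {self.n_categories}",
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SubstitutionModel":
        fields: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or "=" not in line:
                continue
            key, val = line.split("=", 1)
            fields[key.strip()] = val.strip()
        try:
            return cls(
                exchangeabilities=tuple(
                    float(x) for x in fields["exchangeabilities"].split()
                ),
                base_frequencies=tuple(
                    float(x) for x in fields["base_frequencies"].split()
                ),
                gamma_shape=float(fields["gamma_shape"]),
                n_categories=int(fields["n_categories"]),
            )
        except KeyError as exc:
            raise GenesignalError(f"model text missing field {exc}") from exc


def empirical_frequencies(aln: Alignment, floor: float = 1e-6) -> np.ndarray:
    """Base frequencies counted from the alignment, missing characters excluded.

    A small ``floor`` keeps every frequency strictly positive even when a base
    never occurs.
    """
    counts = np.array([(aln.matrix == b).sum() for b in BASES], dtype=float)
    total = counts.sum()
    if total == 0:
        raise GenesignalError("alignment contains no unambiguous bases")
    freqs = counts / total
    freqs = np.maximum(freqs, floor)
    return freqs / freqs.sum()


def build_rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """Normalised GTR generator Q (rows sum to 0, mean rate 1)."""
    ex = np.asarray(model.exchangeabilities)
    pi = model.pi
    q = np.zeros((4, 4))
    for s, (i, j) in zip(ex, PAIRS):
        q[i, j] = s * pi[j]
        q[j, i] = s * pi[i]
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -(pi * np.diag(q)).sum()
    return q / mu


def discretize_gamma(alpha: float, k: int) -> np.ndarray:
    """Mean-of-quantile-bin rates for a k-category discrete gamma.

    The underlying distribution is Gamma(alpha, rate=alpha) (mean one); bin
    boundaries are its ``i/k`` quantiles and each category rate is the mean of
    the density over its bin, computed via the incomplete-gamma identity
    ``E[X; a<X<b] = F_{alpha+1}(b) - F_{alpha+1}(a)`` for the mean-one
    parameterisation.  Rates are strictly increasing with weighted mean one.
    """
    if alpha <= 0:
        raise GenesignalError("gamma shape must be positive")
    if k < 1:
        raise GenesignalError("need at least one rate category")
    if k == 1:
        return np.ones(1)
    bounds = _gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    cdf_up = _gamma_dist.cdf(bounds, a=alpha + 1, scale=1.0 / alpha)
    cdf_up = np.concatenate([[0.0], cdf_up, [1.0]])
    rates = k * np.diff(cdf_up)
    return rates / (rates.mean())


class EigenSystem:
    """Cached symmetrised eigendecomposition of a reversible generator.

    For reversible Q, ``S = diag(sqrt(pi)) Q diag(1/sqrt(pi))`` is symmetric;
    with ``S = V diag(lam) V'``, the transition matrix is
    ``P(t) = diag(1/sqrt(pi)) V diag(exp(lam t)) V' diag(sqrt(pi))``.
    """

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        self.pi = np.asarray(pi, dtype=float)
        sqrt_pi = np.sqrt(self.pi)
        s = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        s = (s + s.T) / 2.0  # symmetrise away roundoff
        lam, v = np.linalg.eigh(s)
        self.lam = lam
        self.left = v / sqrt_pi[:, None]       # diag(1/sqrt(pi)) V
        self.right = (v * sqrt_pi[:, None]).T  # V' diag(sqrt(pi))

    def p_matrix(self, vt: float) -> np.ndarray:
        """P(vt) for a single rate x time product."""
        p = (self.left * np.exp(self.lam * vt)) @ self.right
        return np.clip(p, 0.0, None)

    def p_matrices(self, vts: np.ndarray) -> np.ndarray:
        """Stack of P matrices for an array of rate x time products."""
        vts = np.asarray(vts, dtype=float)
        e = np.exp(np.multiply.outer(vts, self.lam))  # (..., 4)
        p = np.einsum("ik,...k,kj->...ij", self.left, e, self.right)
        return np.clip(p, 0.0, None)


def stationary_frequencies(q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a generator (left null vector of Q)."""
    w, vl = np.linalg.eig(q.T)
    i = int(np.argmin(np.abs(w)))
    pi = np.real(vl[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def transition_probabilities(
    q: np.ndarray, t: float, rate: float = 1.0
) -> np.ndarray:
    """Stochastic matrix P = exp(Q * rate * t) for one branch and category."""
    if t < 0 or rate < 0 or not np.isfinite(t) or not np.isfinite(rate):
        raise GenesignalError("branch length and rate must be finite and >= 0")
    pi = stationary_frequencies(q)
    return EigenSystem(q, pi).p_matrix(rate * t)
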