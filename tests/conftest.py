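import numpy as np
import pytest

from genesignal import Alignment, SubstitutionModel, read_newick


@pytest.fixture
def jc1():
    """Jukes-Cantor, one rate category."""
    return SubstitutionModel.jc(n_categories=1)


@pytest.fixture
def gtr_model():
    return SubstitutionModel(
        exchangeabilities=(1.5, 4.0, 1.2, 1.1, 5.0, 1.0),
        base_frequencies=(0.26, 0.22, 0.24, 0.28),
        gamma_shape=0.5,
        n_categories=4,
    )


@pytest.fixture
def quartet_tree():
    return read_newick("((A:0.1,B:0.3):0.2,(C:0.15,D:0.4):0.1);")


@pytest.fixture
def quartet_alignment():
    return Alignment(
        [("A", "ACG-TA"), ("B", "AAGTTA"), ("C", "ACRTTC"), ("D", "TCGTNA")]
    )


def random_model(rng: np.random.Generator, n_categories: int = 2) -> SubstitutionModel:
    """Random but valid GTR+Γ parameterisation for property tests."""
    freqs = rng.dirichlet(np.full(4, 5.0))
    freqs = np.maximum(freqs, 0.05)
    freqs = freqs / freqs.sum()
    return SubstitutionModel(
        exchangeabilities=tuple(rng.uniform(0.3, 4.0, 6)),
        base_frequencies=tuple(freqs),
        gamma_shape=float(rng.uniform(0.3, 2.0)),
        n_categories=n_categories,
    )


def random_alignment(
    rng: np.random.Generator, taxa, n_sites: int, missing_frac: float = 0.1
) -> Alignment:
    chars = np.array(list("ACGT-?NRY"))
    probs = np.array([0.2, 0.2, 0.2, 0.2] + [missing_frac / 5] * 5)
    probs[:4] += (1 - probs.sum()) / 4
    rows = []
    for t in taxa:
        rows.append((t, "".join(rng.choice(chars, size=n_sites, p=probs))))
    return Alignment(rows)
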