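import numpy as np
import pytest

from epiqtl.core_map import ChromosomeMap, GenotypeMatrix, LinkageMap
from epiqtl.simulator import SimDesign, simulate_f2


# ---------------------------------------------------------------------------
# independent enumeration oracle for the two-locus gametic-selection model


def oracle_two_locus(u, v, x, r):
    """Brute-force 9-class frequencies by enumerating the 4x4 gamete pairs.

    Written independently of the package's vectorized implementation:
    gametes are represented as allele strings and every (female, male)
    combination is accumulated into its genotype class.
    """
    gametes = ["AB", "Ab", "aB", "ab"]
    base = {"AB": (1 - r) / 2, "Ab": r / 2, "aB": r / 2, "ab": (1 - r) / 2}
    viab = {"AB": 1.0, "Ab": v, "aB": u, "ab": x}
    lam = sum(base[g] * viab[g] for g in gametes)
    male = {g: base[g] * viab[g] / lam for g in gametes}

    def genotype_class(fg, mg):
        ga = (fg[0] + mg[0]).count("a")   # copies of allele a at locus A
        gb = (fg[1] + mg[1]).count("b")   # copies of allele b at locus B
        return 3 * ga + gb

    freq = np.zeros(9)
    for fg in gametes:
        for mg in gametes:
            freq[genotype_class(fg, mg)] += base[fg] * male[mg]
    return freq


def oracle_multinomial_negll(counts):
    """Factory: negative log-likelihood of (u, v, x) at fixed r, built on
    the enumeration oracle (independent of the package's likelihood)."""

    def negll(params, r):
        u, v, x = params
        if min(u, v, x) < 0:
            return np.inf
        pi = oracle_two_locus(u, v, x, r)
        with np.errstate(divide="ignore"):
            terms = np.where(counts > 0, counts * np.log(pi), 0.0)
        return -float(np.sum(terms))

    return negll


@pytest.fixture(scope="session")
def small_map():
    return LinkageMap([ChromosomeMap("1", [f"m{i}" for i in range(1, 6)],
                                     np.array([0.0, 10, 20, 30, 40]))])


@pytest.fixture(scope="session")
def mendelian_dataset():
    """n=200 F2 without selection, QTL h2 = 0.10 at 25 cM."""
    design = SimDesign(n=200, sdl_pos=None, sdl_h2=None)
    return simulate_f2(design, seed=7)


@pytest.fixture(scope="session")
def distorted_dataset():
    """n=300 F2 with the reference design (SDL h2 = 0.10)."""
    return simulate_f2(SimDesign(), seed=13)


@pytest.fixture
def rng():
    return np.random.default_rng(20130709)
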