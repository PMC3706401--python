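"""Two-locus gametic-selection model for linked epistatic SDL in F2.

The model: an F1 (AB/ab) produces gametes AB, Ab, aB, ab with Mendelian
frequencies (1-r)/2, r/2, r/2, (1-r)/2 where r is the recombination
fraction between the two loci.  Female gametes are transmitted unchanged.
Male gametes survive with relative viabilities 1, v, u, x for AB, Ab, aB,
ab respectively; the surviving male gamete pool is renormalized by

    lambda = (1-r)/2 + v*r/2 + u*r/2 + x*(1-r)/2.

F2 genotype frequencies are the outer product of the (unselected) female
gamete distribution and the post-selection male gamete distribution.  The
16 ordered states (female gamete x male gamete) collapse to 9 observable
genotype classes.

Epistasis between the two SDL means the double-recombinant viability x
deviates from the product u*v of the single-locus viabilities.

Gamete index convention: 0=AB, 1=Ab, 2=aB, 3=ab (bit 1 = P2 allele at the
first locus, bit 0 = P2 allele at the second locus).  Ordered one-locus
classes: 0=AA, 1=Aa (female A, male a), 2=aA, 3=aa.  Collapsed 9-class
order: AABB, AABb, AAbb, AaBB, AaBb, Aabb, aaBB, aaBb, aabb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ViabilityParams",
    "GameteTable",
    "TwoLocusFreqTable",
    "FitnessTriple",
    "GAMETES",
    "CLASS_NAMES",
    "ORDERED_TO_CLASS",
    "male_gamete_frequencies",
    "genotype_frequencies",
    "marginal_fitness",
]

GAMETES = ("AB", "Ab", "aB", "ab")

CLASS_NAMES = (
    "AABB", "AABb", "AAbb",
    "AaBB", "AaBb", "Aabb",
    "aaBB", "aaBb", "aabb",
)

# ordered state (f, m) -> collapsed class 3*classA + classB, where
# classA = (f >> 1) + (m >> 1) and classB = (f & 1) + (m & 1)
ORDERED_TO_CLASS = np.array(
    [[3 * ((f >> 1) + (m >> 1)) + ((f & 1) + (m & 1)) for m in range(4)]
     for f in range(4)]
)


class DegenerateModelError(ValueError):
    """All surviving male gamete classes have zero mass (lambda = 0)."""


@dataclass(frozen=True)
class ViabilityParams:
    """Male gamete viabilities relative to AB, plus the SDL recombination
    fraction.

    Attributes
    ----------
    u : float
        Viability of gamete aB relative to AB.
    v : float
        Viability of gamete Ab relative to AB.
    x : float
        Viability of gamete ab relative to AB.
    r : float
        Recombination fraction between the two SDL, in [0, 0.5].
    """

    u: float
    v: float
    x: float
    r: float

    def __post_init__(self):
        for name in ("u", "v", "x"):
            val = getattr(self, name)
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"viability {name} must be finite and >= 0, got {val}")
        if not 0.0 <= self.r <= 0.5:
            raise ValueError(f"recombination fraction r must be in [0, 0.5], got {self.r}")

    @property
    def weights(self) -> np.ndarray:
        """Viability weights in gamete order (AB, Ab, aB, ab)."""
        return np.array([1.0, self.v, self.u, self.x])

    @property
    def is_mendelian(self) -> bool:
        return self.u == self.v == self.x == 1.0

    def swapped_loci(self) -> "ViabilityParams":
        """Parameters after relabelling locus A <-> B (swaps u and v)."""
        return ViabilityParams(u=self.v, v=self.u, x=self.x, r=self.r)


@dataclass(frozen=True)
class GameteTable:
    """Post-selection male gamete frequencies and the normalizer lambda."""

    q: np.ndarray  # (q_AB, q_Ab, q_aB, q_ab)
    lam: float

    @property
    def q_AB(self) -> float:
        return float(self.q[0])

    @property
    def q_Ab(self) -> float:
        return float(self.q[1])

    @property
    def q_aB(self) -> float:
        return float(self.q[2])

    @property
    def q_ab(self) -> float:
        return float(self.q[3])


@dataclass(frozen=True)
class TwoLocusFreqTable:
    """Ordered (4x4) and collapsed (9) F2 genotype frequencies."""

    ordered: np.ndarray   # shape (4, 4): female gamete x male gamete
    collapsed: np.ndarray  # shape (9,), CLASS_NAMES order

    def as_dict(self) -> dict[str, float]:
        return dict(zip(CLASS_NAMES, self.collapsed))


@dataclass(frozen=True)
class FitnessTriple:
    """Relative fitnesses of ordered one-locus genotypes, AA as reference.

    f2 is the fitness of Aa (female A, male a), f3 of aA, f4 of aa.  Under
    male-only gametic selection f3 = 1 and f2 = f4 (the female allele is
    never selected), but the triple is kept general.
    """

    f2: float
    f3: float
    f4: float

    @property
    def is_neutral(self) -> bool:
        return self.f2 == self.f3 == self.f4 == 1.0

    def het_weight(self) -> float:
        """Weight applied to the heterozygote class, (f2 + f3) / 2."""
        return 0.5 * (self.f2 + self.f3)


def mendelian_gamete_freqs(r: float) -> np.ndarray:
    """F1 gamete frequencies (AB, Ab, aB, ab) without selection."""
    return np.array([(1 - r) / 2, r / 2, r / 2, (1 - r) / 2])


def male_gamete_frequencies(params: ViabilityParams) -> GameteTable:
    """Post-selection male gamete distribution.

    q_AB = (1-r)/(2*lambda), q_Ab = v*r/(2*lambda), q_aB = u*r/(2*lambda),
    q_ab = x*(1-r)/(2*lambda).
    """
    base = mendelian_gamete_freqs(params.r)
    weighted = base * params.weights
    lam = float(weighted.sum())
    if lam <= 0.0:
        raise DegenerateModelError(
            "all male gamete classes have zero post-selection mass"
        )
    return GameteTable(q=weighted / lam, lam=lam)


def genotype_frequencies(params: ViabilityParams) -> TwoLocusFreqTable:
    """F2 genotype frequencies after male gametic selection.

    Ordered frequency (female gamete f, male gamete m) is the product of
    the Mendelian female frequency and the post-selection male frequency;
    the 16 ordered states are pooled into the 9 observable classes.
    """
    female = mendelian_gamete_freqs(params.r)
    male = male_gamete_frequencies(params).q
    ordered = np.outer(female, male)
    collapsed = np.zeros(9)
    np.add.at(collapsed, ORDERED_TO_CLASS.ravel(), ordered.ravel())
    return TwoLocusFreqTable(ordered=ordered, collapsed=collapsed)


def marginal_fitness(params: ViabilityParams, locus: str = "A") -> FitnessTriple:
    """Single-locus relative fitnesses induced by the two-locus selection.

    Marginalizing the post-selection table over the other locus gives the
    four ordered one-locus genotype frequencies; dividing by the Mendelian
    1/4 and scaling so that fitness(AA) = 1 yields (1, f2, f3, f4).
    Because only male gametes are selected, f3 = 1 and
    f2 = f4 = q_a / q_A, the ratio of post-selection male allele
    frequencies at the locus.

    Parameters
    ----------
    params : ViabilityParams
    locus : {"A", "B"}
        Which SDL to marginalize onto.
    """
    if locus not in ("A", "B"):
        raise ValueError(f"locus must be 'A' or 'B', got {locus!r}")
    q = male_gamete_frequencies(params).q
    if locus == "A":
        q_P1, q_P2 = q[0] + q[1], q[2] + q[3]  # male gametes carrying A / a
    else:
        q_P1, q_P2 = q[0] + q[2], q[1] + q[3]  # carrying B / b
    if q_P1 <= 0.0:
        raise ZeroDivisionError(
            f"reference class at locus {locus} has zero post-selection male "
            f"allele frequency; fitnesses relative to AA are undefined"
        )
    ratio = float(q_P2 / q_P1)
    return FitnessTriple(f2=ratio, f3=1.0, f4=ratio)
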