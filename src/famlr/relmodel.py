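"""Relationship definitions and joint two-individual genotype probabilities.

Pairwise relationships between non-inbred individuals are summarised by the
IBD-sharing coefficients (k0, k1, k2): the probabilities that the pair shares
0, 1 or 2 alleles identical by descent at an autosomal locus.  Background
relatedness within a population is modelled with the coancestry coefficient
theta through the sequential Dirichlet ("urn") construction: the probability
of the next allele drawn from the population depends on the alleles already
drawn,

    P(next = A_i | counts m) = (m_i * theta + (1 - theta) * p_i)
                               / (1 + (m - 1) * theta),

where m_i is the number of copies of A_i among the m founder alleles drawn so
far and p_i is the population frequency.  Joint genotype probabilities for a
pair follow by mixing over the latent IBD state j: draw 4 - j founder alleles
sequentially and copy the j shared alleles to both individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

__all__ = [
    "IBDCoefficients",
    "RELATIONSHIPS",
    "ibd_for_relationship",
    "relationship_names",
    "kinship_coefficient",
    "urn_next_allele_prob",
    "pair_genotype_prob",
    "enumerate_pair_states",
    "UNRELATED",
]

Genotype = tuple  # unordered pair of allele labels, stored sorted


@dataclass(frozen=True)
class IBDCoefficients:
    """Probabilities of a pair sharing 0, 1 or 2 alleles IBD at a locus."""

    k0: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        for v in (self.k0, self.k1, self.k2):
            if v < 0:
                raise ValueError("IBD coefficients must be non-negative")
        if abs(self.k0 + self.k1 + self.k2 - 1.0) > 1e-12:
            raise ValueError("IBD coefficients must sum to 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.k0, self.k1, self.k2)


_REL_TABLE = {
    "parent-offspring": (Fraction(0), Fraction(1), Fraction(0)),
    "sibling": (Fraction(1, 4), Fraction(1, 2), Fraction(1, 4)),
    "half-sibling": (Fraction(1, 2), Fraction(1, 2), Fraction(0)),
    "first-cousin": (Fraction(3, 4), Fraction(1, 4), Fraction(0)),
    "second-cousin": (Fraction(15, 16), Fraction(1, 16), Fraction(0)),
    "unrelated": (Fraction(1), Fraction(0), Fraction(0)),
}

RELATIONSHIPS: dict[str, IBDCoefficients] = {
    name: IBDCoefficients(*(float(v) for v in ks)) for name, ks in _REL_TABLE.items()
}

UNRELATED = RELATIONSHIPS["unrelated"]


def relationship_names() -> list[str]:
    """Canonical relationship names, from closest to most distant."""
    return list(RELATIONSHIPS)


def _canon_name(name: str) -> str:
    key = name.strip().lower().replace("_", "-").replace(" ", "-")
    aliases = {
        "po": "parent-offspring",
        "parent-child": "parent-offspring",
        "full-sibling": "sibling",
        "sib": "sibling",
        "half-sib": "half-sibling",
        "cousin": "first-cousin",
    }
    return aliases.get(key, key)


def ibd_for_relationship(name: str) -> IBDCoefficients:
    """IBD-sharing coefficients for a named relationship.

    Accepted names (case-insensitive, hyphen/underscore/space variants):
    parent-offspring, sibling, half-sibling, first-cousin, second-cousin,
    unrelated.
    """
    key = _canon_name(name)
    try:
        return RELATIONSHIPS[key]
    except KeyError:
        raise ValueError(
            f"unknown relationship {name!r}; expected one of {', '.join(RELATIONSHIPS)}"
        ) from None


def kinship_coefficient(k: IBDCoefficients) -> float:
    """Kinship coefficient psi = k1/4 + k2/2.

    The probability that one allele drawn at random from each individual of
    the pair is IBD.
    """
    return k.k1 / 4.0 + k.k2 / 2.0


def urn_next_allele_prob(counts: dict, p: dict, theta: float) -> dict:
    """Distribution of the next founder allele given previous draw counts.

    Parameters
    ----------
    counts
        Allele label -> number of founder copies already drawn (sum = m).
    p
        Allele label -> population frequency (sums to 1).
    theta
        Coancestry coefficient in [0, 1).

    Returns
    -------
    dict
        Allele label -> probability; sums to 1.
    """
    if not 0.0 <= theta < 1.0:
        raise ValueError("theta must be in [0, 1)")
    m = sum(counts.values())
    den = 1.0 + (m - 1) * theta
    # m = 0 gives den = 1 - theta and numerator (1-theta) p_i, i.e. p itself.
    return {a: (counts.get(a, 0) * theta + (1.0 - theta) * pa) / den for a, pa in p.items()}


def _seq_prob(seq: tuple, p: dict, theta: float) -> float:
    """Probability of an ordered sequence of founder-allele draws under the urn."""
    prob = 1.0
    counts: dict = {}
    m = 0
    for a in seq:
        den = 1.0 + (m - 1) * theta
        prob *= (counts.get(a, 0) * theta + (1.0 - theta) * p[a]) / den
        counts[a] = counts.get(a, 0) + 1
        m += 1
    return prob


def _orderings(g: Genotype):
    a, b = g
    if a == b:
        return ((a, b),)
    return ((a, b), (b, a))


def _minus(g: Genotype, s):
    """Remove one copy of s from the genotype multiset."""
    a, b = g
    return b if a == s else a


def _p_given_ibd0(g1: Genotype, g2: Genotype, p: dict, theta: float) -> float:
    # four founder draws: both alleles of each individual
    return sum(
        _seq_prob(o1 + o2, p, theta) for o1 in _orderings(g1) for o2 in _orderings(g2)
    )


def _p_given_ibd1(g1: Genotype, g2: Genotype, p: dict, theta: float) -> float:
    # three founder draws: the shared allele, then each individual's other allele
    total = 0.0
    for s in set(g1) & set(g2):
        total += _seq_prob((s, _minus(g1, s), _minus(g2, s)), p, theta)
    return total


def _p_given_ibd2(g1: Genotype, g2: Genotype, p: dict, theta: float) -> float:
    if g1 != g2:
        return 0.0
    return sum(_seq_prob(o, p, theta) for o in _orderings(g1))


def pair_genotype_prob(
    g1, g2, k: IBDCoefficients, theta: float, p: dict
) -> float:
    """Joint probability of an unordered genotype pair at one locus.

    ``P(G1, G2 | k, theta, p) = k0 P0 + k1 P1 + k2 P2`` where ``Pj`` is the
    probability of observing the pair given exactly j shared IBD lineages,
    obtained by summing sequential urn-draw probabilities over every ordered
    founder-draw sequence and IBD-allele assignment consistent with the pair.
    Summing over all unordered pair states yields 1 for any (k, theta, p).

    ``g1`` and ``g2`` are 2-tuples of allele labels (order within a genotype
    and the order of the two individuals are both irrelevant).

    Raises
    ------
    ValueError
        If ``p`` is not normalised, or an observed allele has zero or missing
        frequency (a sign that frequency flooring was skipped).
    """
    if abs(sum(p.values()) - 1.0) > 1e-6:
        raise ValueError("frequency vector must sum to 1")
    g1 = tuple(sorted(g1))
    g2 = tuple(sorted(g2))
    for a in (*g1, *g2):
        if p.get(a, 0.0) <= 0.0:
            raise ValueError(
                f"allele {a!r} has zero/undefined frequency; floor frequencies first"
            )
    prob = 0.0
    if k.k0:
        prob += k.k0 * _p_given_ibd0(g1, g2, p, theta)
    if k.k1:
        prob += k.k1 * _p_given_ibd1(g1, g2, p, theta)
    if k.k2:
        prob += k.k2 * _p_given_ibd2(g1, g2, p, theta)
    return prob


def enumerate_pair_states(alleles) -> list[tuple[Genotype, Genotype]]:
    """All unordered genotype-pair states over an allele universe.

    A state is an unordered pair of unordered genotypes; the two individuals
    are exchangeable, so ``((a,b),(c,d))`` and ``((c,d),(a,b))`` are one
    state.  Used by the enumeration oracles and for exact pair-probability
    tables.
    """
    alleles = list(alleles)
    genotypes = [
        tuple(sorted((alleles[i], alleles[j])))
        for i in range(len(alleles))
        for j in range(i, len(alleles))
    ]
    states = []
    for i, ga in enumerate(genotypes):
        for gb in genotypes[i:]:
            states.append((ga, gb))
    return states


def pair_state_probability(
    state: tuple[Genotype, Genotype], k: IBDCoefficients, theta: float, p: dict
) -> float:
    """Probability of an exchangeable pair state (sums to 1 over states).

    For a state with two distinct genotypes this is the sum of the two ordered
    assignments; :func:`pair_genotype_prob` is symmetric so that is twice the
    ordered probability.
    """
    g1, g2 = state
    prob = pair_genotype_prob(g1, g2, k, theta, p)
    if g1 != g2:
        prob *= 2.0
    return prob
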