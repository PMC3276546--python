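"""Simulation of genotype pairs for named relationships.

Two samplers are provided, matching the two regimes studied:

* ``theta_true = 0``: founders' alleles are drawn independently from the
  population frequencies and dropped through a pedigree (one random allele
  from each parent) to realise the target relationship.  Total independence
  between founder draws makes the simulated population's coancestry exactly
  zero.
* ``theta_true > 0``: per locus, a latent IBD state j is drawn from
  (k0, k1, k2) and 4 - j founder alleles are drawn sequentially with the urn
  rule, the j shared alleles being copied to both individuals, so empirical
  pair-state frequencies converge to the model's pair probabilities.

The theta-0 simulator additionally records the latent IBD state realised at
each locus (from founder-lineage bookkeeping); this is used only by tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .popdata import FrequencyPanel
from .relmodel import IBDCoefficients, ibd_for_relationship

__all__ = [
    "GenotypePair",
    "SimConfig",
    "simulate_pair_theta0",
    "simulate_pair_theta",
    "simulate_pairs",
    "pairs_to_frame",
]


@dataclass
class GenotypePair:
    """Two unordered diploid genotypes over a shared locus list.

    ``genotypes[locus] = (genotype1, genotype2)`` with each genotype a sorted
    2-tuple of allele labels.  ``ibd_states`` (theta-0 simulator only) holds
    the realised number of alleles shared IBD per locus, for diagnostics.
    """

    genotypes: dict[str, tuple[tuple, tuple]]
    ibd_states: dict[str, int] | None = field(default=None, repr=False)

    def items(self):
        return self.genotypes.items()

    def __getitem__(self, locus):
        return self.genotypes[locus]

    @property
    def loci(self) -> list[str]:
        return list(self.genotypes)

    def shared_allele_count(self, locus: str) -> int:
        """Size of the multiset intersection of the two genotypes at a locus."""
        g1, g2 = self.genotypes[locus]
        g2 = list(g2)
        shared = 0
        for a in g1:
            if a in g2:
                g2.remove(a)
                shared += 1
        return shared


@dataclass
class SimConfig:
    """A reproducible simulation request for one cell of the study grid."""

    relationship: str
    pop: str
    theta_true: float
    n_pairs: int
    seed: int

    def __post_init__(self) -> None:
        ibd_for_relationship(self.relationship)  # validates the name
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if not 0.0 <= self.theta_true < 1.0:
            raise ValueError("theta_true must be in [0, 1)")


# Pedigrees as (n_founders, [(child, parent_a, parent_b), ...], (target1, target2)).
# Founders are ids 0..n_founders-1; children get consecutive ids.
_PEDIGREES = {
    "unrelated": (2, [], (0, 1)),
    "parent-offspring": (2, [(2, 0, 1)], (0, 2)),
    "sibling": (2, [(2, 0, 1), (3, 0, 1)], (2, 3)),
    # founders: shared parent 0, other parents 1 and 2
    "half-sibling": (3, [(3, 0, 1), (4, 0, 2)], (3, 4)),
    # founders: grandparents 0,1; spouses 2,3 -> sib parents 4,5 -> cousins 6,7
    "first-cousin": (4, [(4, 0, 1), (5, 0, 1), (6, 4, 2), (7, 5, 3)], (6, 7)),
    # one more generation: great-grandparents 0,1; founders 2..5 marry in
    "second-cousin": (
        6,
        [(6, 0, 1), (7, 0, 1), (8, 6, 2), (9, 7, 3), (10, 8, 4), (11, 9, 5)],
        (10, 11),
    ),
}


def simulate_pair_theta0(
    relationship: str,
    panel: FrequencyPanel,
    pop: str,
    rng: np.random.Generator,
) -> GenotypePair:
    """Simulate one pair by i.i.d. founder draws plus pedigree gene dropping.

    Every founder allele carries a unique lineage tag; the realised IBD state
    per locus (0, 1 or 2 shared lineages between the target pair) is recorded
    in ``GenotypePair.ibd_states`` for diagnostic use only.
    """
    ibd_for_relationship(relationship)  # validates the name
    name = _canon(relationship)
    n_founders, drops, (t1, t2) = _PEDIGREES[name]
    genotypes: dict[str, tuple[tuple, tuple]] = {}
    ibd_states: dict[str, int] = {}
    for locus in panel.loci:
        labels = panel.alleles[locus]
        p = panel.freq(pop, locus)
        # founder alleles: (lineage_id, allele_label)
        draws = rng.choice(len(labels), size=2 * n_founders, p=p)
        members: list[tuple] = [
            ((2 * i, labels[draws[2 * i]]), (2 * i + 1, labels[draws[2 * i + 1]]))
            for i in range(n_founders)
        ]
        for _child, pa, pb in drops:
            ga = members[pa][rng.integers(2)]
            gb = members[pb][rng.integers(2)]
            members.append((ga, gb))
        a1, a2 = members[t1]
        b1, b2 = members[t2]
        # shared lineage count = realised IBD state (pedigree members are outbred)
        lineages2 = [b1[0], b2[0]]
        shared = 0
        for lin, _ in (a1, a2):
            if lin in lineages2:
                lineages2.remove(lin)
                shared += 1
        ibd_states[locus] = shared
        genotypes[locus] = (
            tuple(sorted((a1[1], a2[1]))),
            tuple(sorted((b1[1], b2[1]))),
        )
    return GenotypePair(genotypes, ibd_states)


def _canon(relationship: str) -> str:
    from .relmodel import _canon_name

    return _canon_name(relationship)


def simulate_pair_theta(
    relationship: str | IBDCoefficients,
    panel: FrequencyPanel,
    pop: str,
    theta_true: float,
    rng: np.random.Generator,
) -> GenotypePair:
    """Simulate one pair from a population with coancestry ``theta_true``.

    Per locus: draw the IBD state j from (k0, k1, k2), then draw ``4 - j``
    founder alleles sequentially with the urn rule and copy the j shared
    alleles to both individuals.  At ``theta_true = 0`` this is
    distributionally identical to :func:`simulate_pair_theta0`.
    """
    k = (
        relationship
        if isinstance(relationship, IBDCoefficients)
        else ibd_for_relationship(relationship)
    )
    kvec = np.array(k.as_tuple())
    genotypes: dict[str, tuple[tuple, tuple]] = {}
    for locus in panel.loci:
        labels = panel.alleles[locus]
        p = panel.freq(pop, locus)
        j = int(rng.choice(3, p=kvec))
        founders = _urn_draws(4 - j, p, theta_true, rng)
        if j == 0:
            g1 = (founders[0], founders[1])
            g2 = (founders[2], founders[3])
        elif j == 1:
            g1 = (founders[0], founders[1])
            g2 = (founders[0], founders[2])
        else:
            g1 = (founders[0], founders[1])
            g2 = g1
        genotypes[locus] = (
            tuple(sorted(labels[i] for i in g1)),
            tuple(sorted(labels[i] for i in g2)),
        )
    return GenotypePair(genotypes)


def _urn_draws(m: int, p: np.ndarray, theta: float, rng: np.random.Generator) -> list[int]:
    """m sequential founder-allele draws (as indices) under the urn rule."""
    counts = np.zeros(len(p))
    out = []
    for drawn in range(m):
        den = 1.0 + (drawn - 1) * theta
        probs = (counts * theta + (1.0 - theta) * p) / den
        i = int(rng.choice(len(p), p=probs / probs.sum()))
        counts[i] += 1
        out.append(i)
    return out


def simulate_pairs(config: SimConfig, panel: FrequencyPanel) -> list[GenotypePair]:
    """Simulate ``config.n_pairs`` pairs, bit-reproducibly.

    One child seed per pair is spawned deterministically from ``config.seed``
    (numpy ``SeedSequence``), so the stream for pair i does not depend on how
    many pairs precede it and parallel execution reproduces serial output.
    Uses the gene-dropping sampler when ``theta_true == 0`` and the urn
    sampler otherwise.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_pairs)
    out = []
    for child in children:
        rng = np.random.default_rng(child)
        if config.theta_true == 0.0:
            out.append(simulate_pair_theta0(config.relationship, panel, config.pop, rng))
        else:
            out.append(
                simulate_pair_theta(
                    config.relationship, panel, config.pop, config.theta_true, rng
                )
            )
    return out


def pairs_to_frame(pairs: list[GenotypePair]):
    """Wide genotype dump: pair_id, locus, ind1/ind2 allele columns."""
    import pandas as pd

    rows = []
    for i, pair in enumerate(pairs):
        for locus, (g1, g2) in pair.items():
            rows.append((i, locus, g1[0], g1[1], g2[0], g2[1]))
    return pd.DataFrame(
        rows,
        columns=["pair_id", "locus", "ind1_allele1", "ind1_allele2",
                 "ind2_allele1", "ind2_allele2"],
    )
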