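import pytest

from famlr.relmodel import (
    IBDCoefficients,
    RELATIONSHIPS,
    enumerate_pair_states,
    ibd_for_relationship,
    kinship_coefficient,
    pair_genotype_prob,
    pair_state_probability,
    urn_next_allele_prob,
)

THETAS = (0.0, 0.01, 0.03, 0.1)


class TestIBDCoefficients:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("parent-offspring", (0.0, 1.0, 0.0)),
            ("sibling", (0.25, 0.5, 0.25)),
            ("half-sibling", (0.5, 0.5, 0.0)),
            ("first-cousin", (0.75, 0.25, 0.0)),
            ("second-cousin", (15 / 16, 1 / 16, 0.0)),
            ("unrelated", (1.0, 0.0, 0.0)),
        ],
    )
    def test_standard_pedigree_values(self, name, expected):
        assert ibd_for_relationship(name).as_tuple() == pytest.approx(expected)

    def test_name_variants_accepted(self):
        assert ibd_for_relationship("Parent Offspring") == RELATIONSHIPS["parent-offspring"]
        assert ibd_for_relationship("first_cousin") == RELATIONSHIPS["first-cousin"]

    def test_unknown_name_raises(self):
        with pytest.raises(ValueError, match="unknown relationship"):
            ibd_for_relationship("twin")

    def test_invalid_coefficients_rejected(self):
        with pytest.raises(ValueError):
            IBDCoefficients(0.5, 0.6, 0.0)
        with pytest.raises(ValueError):
            IBDCoefficients(-0.1, 1.1, 0.0)

    @pytest.mark.parametrize(
        "name, psi",
        [("sibling", 0.25), ("second-cousin", 0.015625), ("unrelated", 0.0),
         ("parent-offspring", 0.25), ("half-sibling", 0.125), ("first-cousin", 0.0625)],
    )
    def test_kinship_coefficient(self, name, psi):
        assert kinship_coefficient(ibd_for_relationship(name)) == pytest.approx(psi)


class TestUrnRule:
    def test_first_draw_returns_population_frequencies(self):
        p = {"a": 0.1, "b": 0.9}
        assert urn_next_allele_prob({}, p, 0.03) == pytest.approx(p)

    def test_single_prior_copy(self):
        p = {"a": 0.1, "b": 0.9}
        out = urn_next_allele_prob({"a": 1}, p, 0.03)
        assert out["a"] == pytest.approx(0.03 + 0.97 * 0.1)  # 0.127

    @pytest.mark.parametrize("theta", THETAS)
    def test_output_sums_to_one(self, theta):
        p = {"a": 0.2, "b": 0.3, "c": 0.5}
        for counts in ({}, {"a": 1}, {"a": 2, "c": 1}, {"b": 3}):
            out = urn_next_allele_prob(counts, p, theta)
            assert sum(out.values()) == pytest.approx(1.0, abs=1e-12)

    def test_theta_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            urn_next_allele_prob({}, {"a": 1.0}, 1.0)


P3 = {"a": 0.1, "b": 0.3, "c": 0.6}


class TestPairGenotypeProb:
    def test_unrelated_theta0_is_independent_product(self):
        p = {"a": 0.1, "b": 0.9}
        k = RELATIONSHIPS["unrelated"]
        assert pair_genotype_prob(("a", "a"), ("a", "a"), k, 0.0, p) == pytest.approx(1e-4)

    def test_sibling_homozygote_pair_closed_form(self):
        p = {"a": 0.1, "b": 0.9}
        k = RELATIONSHIPS["sibling"]
        pa = 0.1
        expected = 0.25 * pa**4 + 0.5 * pa**3 + 0.25 * pa**2
        assert pair_genotype_prob(("a", "a"), ("a", "a"), k, 0.0, p) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "g1, g2, expected",
        [
            # classical theta=0 two-individual probabilities for sibling k
            (("a", "a"), ("a", "b"), 0.25 * 2 * 0.1**3 * 0.3 + 0.5 * 0.1**2 * 0.3),
            (("a", "b"), ("a", "b"),
             0.25 * (2 * 0.1 * 0.3) ** 2
             + 0.5 * (0.1 * 0.3 * (0.1 + 0.3))
             + 0.25 * 2 * 0.1 * 0.3),
            (("a", "b"), ("a", "c"), 0.25 * 4 * 0.1**2 * 0.3 * 0.6 + 0.5 * 0.1 * 0.3 * 0.6),
            (("a", "b"), ("c", "c"), 0.25 * 2 * 0.1 * 0.3 * 0.6**2),
        ],
    )
    def test_sibling_textbook_patterns(self, g1, g2, expected):
        k = RELATIONSHIPS["sibling"]
        assert pair_genotype_prob(g1, g2, k, 0.0, P3) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("rel", list(RELATIONSHIPS))
    @pytest.mark.parametrize("theta", THETAS)
    def test_normalizes_over_pair_states(self, rel, theta):
        k = RELATIONSHIPS[rel]
        total = sum(
            pair_state_probability(s, k, theta, P3) for s in enumerate_pair_states(P3)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("theta", THETAS)
    def test_exchangeable_in_individuals(self, theta):
        k = RELATIONSHIPS["sibling"]
        for g1, g2 in [(("a", "b"), ("a", "c")), (("a", "a"), ("b", "c")),
                       (("a", "b"), ("b", "c"))]:
            assert pair_genotype_prob(g1, g2, k, theta, P3) == pytest.approx(
                pair_genotype_prob(g2, g1, k, theta, P3), rel=1e-12
            )

    @pytest.mark.parametrize("theta", THETAS)
    def test_marginalizes_to_single_genotype_urn_probability(self, theta):
        # summing over individual 2's genotypes leaves individual 1's marginal
        k = RELATIONSHIPS["sibling"]
        alleles = list(P3)
        genotypes = [
            tuple(sorted((alleles[i], alleles[j])))
            for i in range(len(alleles))
            for j in range(i, len(alleles))
        ]
        for g1 in genotypes:
            marg = sum(pair_genotype_prob(g1, g2, k, theta, P3) for g2 in genotypes)
            a, b = g1
            if a == b:
                single = P3[a] * (theta + (1 - theta) * P3[a])
            else:
                single = 2 * P3[a] * (1 - theta) * P3[b]
            assert marg == pytest.approx(single, rel=1e-10)

    def test_zero_frequency_observed_allele_rejected(self):
        p = {"a": 0.0, "b": 1.0}
        with pytest.raises(ValueError, match="floor"):
            pair_genotype_prob(("a", "a"), ("b", "b"), RELATIONSHIPS["sibling"], 0.0, p)

    def test_unnormalized_frequencies_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            pair_genotype_prob(("a", "a"), ("a", "a"), RELATIONSHIPS["sibling"], 0.0,
                               {"a": 0.5, "b": 0.6})


def _brute_force_pair_prob(g1, g2, k, theta, p):
    """Exhaustive enumeration over ordered founder-draw sequences and IBD
    assignments; independent of the production enumeration (which collapses
    orderings analytically per IBD state)."""
    def seq_prob(seq):
        prob, counts, m = 1.0, {}, 0
        for a in seq:
            prob *= (counts.get(a, 0) * theta + (1 - theta) * p[a]) / (1 + (m - 1) * theta)
            counts[a] = counts.get(a, 0) + 1
            m += 1
        return prob

    g1, g2 = tuple(sorted(g1)), tuple(sorted(g2))
    alleles = list(p)
    total = 0.0
    # j=0: all ordered draws of 4 founders
    from itertools import product

    for seq in product(alleles, repeat=4):
        if tuple(sorted(seq[:2])) == g1 and tuple(sorted(seq[2:])) == g2:
            total += k.k0 * seq_prob(seq)
    for seq in product(alleles, repeat=3):
        s, x, y = seq
        if tuple(sorted((s, x))) == g1 and tuple(sorted((s, y))) == g2:
            total += k.k1 * seq_prob(seq)
    for seq in product(alleles, repeat=2):
        if tuple(sorted(seq)) == g1 and tuple(sorted(seq)) == g2:
            total += k.k2 * seq_prob(seq)
    return total


@pytest.mark.parametrize("rel", ["sibling", "half-sibling", "parent-offspring"])
@pytest.mark.parametrize("theta", [0.0, 0.03])
def test_matches_exhaustive_enumeration_oracle(rel, theta):
    k = RELATIONSHIPS[rel]
    for g1, g2 in enumerate_pair_states(P3):
        assert pair_genotype_prob(g1, g2, k, theta, P3) == pytest.approx(
            _brute_force_pair_prob(g1, g2, k, theta, P3), rel=1e-12
        )
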