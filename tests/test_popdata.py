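import math

import numpy as np
import pytest

from famlr.popdata import (
    FrequencyPanel,
    PanelFormatError,
    PanelValidationError,
    fst_weir_cockerham,
    gene_diversity,
    profile_entropy,
    read_panel,
    write_panel,
)

from conftest import make_single_locus_panel


def _write(tmp_path, text, name="panel.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


HEADER = "population,locus,allele,frequency,sample_size\n"


class TestReadPanel:
    def test_roundtrip_identity(self, tmp_path):
        path = _write(tmp_path, HEADER + "P,L,a,0.6,50\nP,L,b,0.4,50\n")
        panel = read_panel(path)
        assert panel.populations == ["P"] and panel.loci == ["L"]
        assert panel.freq_map("P", "L") == pytest.approx({"a": 0.6, "b": 0.4})
        assert panel.n("P") == 50

    def test_rounded_sum_is_renormalized(self, tmp_path):
        path = _write(tmp_path, HEADER + "P,L,a,0.598,50\nP,L,b,0.399,50\n")
        panel = read_panel(path)
        p = panel.freq("P", "L")
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert p[0] == pytest.approx(0.598 / 0.997)

    def test_sum_outside_tolerance_rejected(self, tmp_path):
        path = _write(tmp_path, HEADER + "P,L,a,0.6,50\nP,L,b,0.6,50\n")
        with pytest.raises(PanelValidationError, match="L"):
            read_panel(path)

    def test_missing_column_is_format_error(self, tmp_path):
        path = _write(tmp_path, "population,locus,allele,frequency\nP,L,a,1.0\n")
        with pytest.raises(PanelFormatError, match="sample_size"):
            read_panel(path)

    def test_negative_frequency_rejected(self, tmp_path):
        path = _write(tmp_path, HEADER + "P,L,a,-0.1,50\nP,L,b,1.1,50\n")
        with pytest.raises(PanelValidationError):
            read_panel(path)

    def test_allele_universe_is_union_with_zero_fill(self, tmp_path):
        text = HEADER + (
            "P1,L,a,0.5,50\nP1,L,b,0.5,50\n"
            "P2,L,a,0.4,60\nP2,L,c,0.6,60\n"
        )
        panel = read_panel(_write(tmp_path, text))
        assert panel.alleles["L"] == ["a", "b", "c"]
        assert panel.freq_map("P2", "L")["b"] == 0.0
        assert panel.freq_map("P1", "L")["c"] == 0.0

    def test_write_read_roundtrip(self, tmp_path, fixture_panel):
        path = tmp_path / "fix.csv"
        write_panel(fixture_panel, path)
        back = read_panel(path)
        for pop in fixture_panel.populations:
            for locus in fixture_panel.loci:
                np.testing.assert_allclose(
                    back.freq(pop, locus), fixture_panel.freq(pop, locus), atol=1e-12
                )


class TestGeneDiversityEntropy:
    def test_monomorphic_locus_has_no_diversity_and_no_entropy(self):
        panel = make_single_locus_panel({"a": 1.0})
        h, hbar = gene_diversity(panel, "X")
        s, tot, dip = profile_entropy(panel, "X")
        assert hbar == 0.0 and tot == 0.0 and dip == 0.0

    def test_equifrequent_values(self, str_panel):
        h, hbar = gene_diversity(str_panel, "POP")
        assert hbar == pytest.approx(0.9)
        s, tot, dip = profile_entropy(str_panel, "POP")
        assert tot == pytest.approx(13 * math.log2(10))
        assert dip == pytest.approx(2 * tot)

    def test_two_allele_equifrequent_is_one_bit(self):
        panel = make_single_locus_panel({"a": 0.5, "b": 0.5})
        s, tot, _ = profile_entropy(panel, "X")
        assert tot == pytest.approx(1.0)

    def test_unknown_population_raises(self, str_panel):
        with pytest.raises(KeyError):
            gene_diversity(str_panel, "NOPE")
        with pytest.raises(KeyError):
            profile_entropy(str_panel, "NOPE")

    def test_invariant_to_relabeling_and_zero_alleles(self):
        base = make_single_locus_panel({"a": 0.7, "b": 0.3})
        padded = make_single_locus_panel({"z9": 0.3, "q": 0.7, "ghost": 0.0})
        assert gene_diversity(base, "X")[1] == pytest.approx(
            gene_diversity(padded, "X")[1]
        )
        assert profile_entropy(base, "X")[1] == pytest.approx(
            profile_entropy(padded, "X")[1]
        )

    def test_entropy_zero_iff_diversity_zero(self):
        for freq in ({"a": 1.0}, {"a": 0.9, "b": 0.1}, {"a": 0.5, "b": 0.5}):
            panel = make_single_locus_panel(freq)
            _, hbar = gene_diversity(panel, "X")
            _, tot, _ = profile_entropy(panel, "X")
            assert (tot == 0.0) == (hbar == 0.0)
            assert tot >= 0.0


def _ms_oracle(p1, p2, n1, n2):
    """Weir-Cockerham 1984 via ANOVA mean squares with HWE genotype proportions.

    Independent of the closed-form a/b/c components used by the package.
    """
    r = 2
    nsum = n1 + n2
    nc = (nsum - (n1 * n1 + n2 * n2) / nsum) / (r - 1)
    num = den = 0.0
    for f1, f2 in zip(p1, p2):
        pbar = (n1 * f1 + n2 * f2) / nsum
        msp = 2 * (n1 * (f1 - pbar) ** 2 + n2 * (f2 - pbar) ** 2) / (r - 1)

        def ssi(n, p):
            return n * (
                p * p * (1 - p) ** 2
                + 2 * p * (1 - p) * (0.5 - p) ** 2
                + (1 - p) ** 2 * p * p
            )

        msi = 2 * (ssi(n1, f1) + ssi(n2, f2)) / ((n1 - 1) + (n2 - 1))
        msg = (n1 * 2 * f1 * (1 - f1) + n2 * 2 * f2 * (1 - f2)) / (2 * nsum)
        num += msp - msi
        den += msp + (nc - 1) * msi + nc * msg
    return num / den


class TestWeirCockerhamFst:
    def test_identical_populations_report_zero(self, str_panel):
        panel = FrequencyPanel(
            populations=["A", "B"],
            loci=list(str_panel.loci),
            alleles={l: list(str_panel.alleles[l]) for l in str_panel.loci},
            freqs={
                (pop, l): str_panel.freq("POP", l).copy()
                for pop in ("A", "B")
                for l in str_panel.loci
            },
            sizes={"A": 200, "B": 200},
        )
        res = fst_weir_cockerham(panel, "A", "B")
        assert res.raw <= 0.0
        assert res.reported == 0.0

    def test_biallelic_matches_mean_squares_oracle(self, two_pop_biallelic):
        res = fst_weir_cockerham(two_pop_biallelic, "A", "B")
        oracle = _ms_oracle([0.2, 0.8], [0.8, 0.2], 100, 100)
        assert res.raw == pytest.approx(oracle, rel=1e-12)

    def test_multiallelic_unequal_n_matches_oracle(self):
        rng = np.random.default_rng(3)
        q1, q2 = rng.dirichlet(np.ones(5)), rng.dirichlet(np.ones(5))
        panel = FrequencyPanel(
            ["A", "B"], ["L"], {"L": list("abcde")},
            {("A", "L"): q1, ("B", "L"): q2}, {"A": 120, "B": 75},
        )
        assert fst_weir_cockerham(panel, "A", "B").raw == pytest.approx(
            _ms_oracle(q1, q2, 120, 75), rel=1e-12
        )

    def test_symmetry_exact(self, fixture_panel):
        for a, b in [("POP1", "POP5"), ("POP2", "POP4")]:
            assert (
                fst_weir_cockerham(fixture_panel, a, b).raw
                == fst_weir_cockerham(fixture_panel, b, a).raw
            )

    def test_monotone_in_frequency_difference(self):
        vals = []
        for pb in (0.25, 0.35, 0.5, 0.7):
            panel = FrequencyPanel(
                ["A", "B"], ["L"], {"L": ["x", "y"]},
                {("A", "L"): np.array([0.2, 0.8]), ("B", "L"): np.array([pb, 1 - pb])},
                {"A": 5000, "B": 5000},
            )
            vals.append(fst_weir_cockerham(panel, "A", "B").raw)
        assert vals == sorted(vals)

    def test_shared_monomorphic_locus_not_estimable(self):
        panel = FrequencyPanel(
            ["A", "B"], ["L"], {"L": ["x"]},
            {("A", "L"): np.array([1.0]), ("B", "L"): np.array([1.0])},
            {"A": 50, "B": 50},
        )
        assert not fst_weir_cockerham(panel, "A", "B").estimable

    def test_unknown_population_raises(self, two_pop_biallelic):
        with pytest.raises(KeyError):
            fst_weir_cockerham(two_pop_biallelic, "A", "Z")
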