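"""Allele-frequency panels and panel-level summaries.

A :class:`FrequencyPanel` holds per-population, per-locus allele-frequency
distributions together with the diploid sample sizes used to estimate them.
Panel summaries implemented here are the standard informativeness measures
for forensic marker sets: observed gene diversity (expected heterozygosity),
Shannon entropy of the profile, and the Weir–Cockerham (1984)
variance-components estimator of FST between population pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FrequencyPanel",
    "PanelFormatError",
    "PanelValidationError",
    "read_panel",
    "write_panel",
    "gene_diversity",
    "profile_entropy",
    "fst_weir_cockerham",
    "FstResult",
]

#: Maximum tolerated deviation of a raw per-(population, locus) frequency sum
#: from 1 before the file is rejected (published tables are rounded).
RENORM_TOLERANCE = 0.01

REQUIRED_COLUMNS = ("population", "locus", "allele", "frequency", "sample_size")


class PanelFormatError(ValueError):
    """A panel file is structurally malformed (missing columns etc.)."""


class PanelValidationError(ValueError):
    """A panel file parses but violates the frequency-panel invariants."""


@dataclass
class FrequencyPanel:
    """Per-population allele-frequency distributions over a shared locus set.

    Parameters
    ----------
    populations
        Population labels, in first-encountered order.
    loci
        Locus labels, in first-encountered order.
    alleles
        Per-locus allele universe: the union of alleles observed in any
        population, ordered as first encountered.
    freqs
        ``(population, locus) -> frequency vector`` aligned with
        ``alleles[locus]``.  Each vector is non-negative and sums to 1.
    sizes
        ``population -> diploid sample size`` (number of individuals).
    """

    populations: list[str]
    loci: list[str]
    alleles: dict[str, list[str]]
    freqs: dict[tuple[str, str], np.ndarray]
    sizes: dict[str, int]
    _allele_index: dict[str, dict[str, int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._allele_index = {
            locus: {a: i for i, a in enumerate(labels)}
            for locus, labels in self.alleles.items()
        }

    def freq(self, pop: str, locus: str) -> np.ndarray:
        """Frequency vector for ``(pop, locus)``, aligned with the allele universe."""
        self._check_pop(pop)
        if locus not in self.alleles:
            raise KeyError(f"unknown locus {locus!r}")
        return self.freqs[(pop, locus)]

    def freq_map(self, pop: str, locus: str) -> dict[str, float]:
        """Allele label -> frequency mapping for ``(pop, locus)``."""
        return dict(zip(self.alleles[locus], self.freq(pop, locus)))

    def n(self, pop: str) -> int:
        self._check_pop(pop)
        return self.sizes[pop]

    def _check_pop(self, pop: str) -> None:
        if pop not in self.sizes:
            raise KeyError(f"unknown population {pop!r}")

    def validate(self) -> None:
        """Raise :class:`PanelValidationError` if any invariant is broken."""
        for pop in self.populations:
            if self.sizes.get(pop, 0) < 1:
                raise PanelValidationError(f"sample size for {pop!r} must be >= 1")
            for locus in self.loci:
                p = self.freqs.get((pop, locus))
                if p is None:
                    raise PanelValidationError(f"missing ({pop!r}, {locus!r})")
                if len(p) != len(self.alleles[locus]):
                    raise PanelValidationError(
                        f"frequency vector length mismatch at ({pop!r}, {locus!r})"
                    )
                if np.any(p < 0):
                    raise PanelValidationError(
                        f"negative frequency at ({pop!r}, {locus!r})"
                    )
                if abs(float(p.sum()) - 1.0) > 1e-9:
                    raise PanelValidationError(
                        f"frequencies at ({pop!r}, {locus!r}) sum to {p.sum():.12f}"
                    )

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame (zero-frequency alleles included)."""
        rows = []
        for pop in self.populations:
            for locus in self.loci:
                p = self.freqs[(pop, locus)]
                for allele, f in zip(self.alleles[locus], p):
                    rows.append((pop, locus, allele, float(f), self.sizes[pop]))
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def read_panel(path, dialect: str | None = None) -> FrequencyPanel:
    """Read a long-format allele-frequency table into a :class:`FrequencyPanel`.

    The file must have a header with columns ``population, locus, allele,
    frequency, sample_size``.  Frequencies for each (population, locus) are
    renormalized to sum exactly to 1 provided the raw sum is within
    ``RENORM_TOLERANCE`` of 1; larger deviations raise
    :class:`PanelValidationError`.  Alleles absent in a population (but seen in
    another) carry frequency 0.  Loci and alleles keep first-encountered order.

    Parameters
    ----------
    path
        File path.
    dialect
        Field delimiter; ``None`` sniffs ``\\t`` vs ``,`` from the header line.
    """
    if dialect is None:
        with open(path) as fh:
            header = fh.readline()
        dialect = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=dialect, dtype={"allele": str, "population": str, "locus": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PanelFormatError(f"missing required column(s): {', '.join(missing)}")
    return panel_from_frame(df)


def panel_from_frame(df: pd.DataFrame) -> FrequencyPanel:
    """Build a validated panel from a long-format DataFrame (see :func:`read_panel`)."""
    populations: list[str] = list(dict.fromkeys(df["population"].astype(str)))
    loci: list[str] = list(dict.fromkeys(df["locus"].astype(str)))
    alleles: dict[str, list[str]] = {}
    for locus, sub in df.groupby("locus", sort=False):
        alleles[str(locus)] = list(dict.fromkeys(sub["allele"].astype(str)))

    sizes: dict[str, int] = {}
    for pop, sub in df.groupby("population", sort=False):
        n_vals = set(int(v) for v in sub["sample_size"])
        if len(n_vals) != 1:
            raise PanelValidationError(f"inconsistent sample_size for {pop!r}")
        n = n_vals.pop()
        if n < 1:
            raise PanelValidationError(f"sample size for {pop!r} must be >= 1")
        sizes[str(pop)] = n

    freqs: dict[tuple[str, str], np.ndarray] = {}
    grouped = {
        (str(p), str(l)): sub
        for (p, l), sub in df.groupby(["population", "locus"], sort=False)
    }
    for pop in populations:
        for locus in loci:
            labels = alleles[locus]
            p = np.zeros(len(labels))
            sub = grouped.get((pop, locus))
            if sub is not None:
                idx = {a: i for i, a in enumerate(labels)}
                for allele, f in zip(sub["allele"].astype(str), sub["frequency"]):
                    f = float(f)
                    if f < 0:
                        raise PanelValidationError(
                            f"negative frequency at ({pop!r}, {locus!r}, {allele!r})"
                        )
                    p[idx[allele]] += f
            raw_sum = float(p.sum())
            if abs(raw_sum - 1.0) > RENORM_TOLERANCE:
                raise PanelValidationError(
                    f"frequencies at ({pop!r}, {locus!r}) sum to {raw_sum:.4f}, "
                    f"outside 1 +/- {RENORM_TOLERANCE}"
                )
            freqs[(pop, locus)] = p / raw_sum

    panel = FrequencyPanel(populations, loci, alleles, freqs, sizes)
    panel.validate()
    return panel


def write_panel(panel: FrequencyPanel, path, dialect: str = ",") -> None:
    """Write a panel in the long format accepted by :func:`read_panel`."""
    panel.to_frame().to_csv(path, sep=dialect, index=False)


def gene_diversity(panel: FrequencyPanel, pop: str) -> tuple[pd.Series, float]:
    """Observed gene diversity (expected heterozygosity) per locus and its mean.

    Per locus ``h_l = 1 - sum_i p_i**2`` (plug-in, no small-sample correction);
    the panel summary ``H_bar`` is the unweighted mean over loci.

    Returns
    -------
    (per_locus, mean)
        ``per_locus`` is a Series indexed by locus; ``mean`` is H̄.
    """
    panel._check_pop(pop)
    h = pd.Series(
        {locus: 1.0 - float(np.sum(panel.freq(pop, locus) ** 2)) for locus in panel.loci},
        name="h",
    )
    return h, float(h.mean())


def profile_entropy(panel: FrequencyPanel, pop: str) -> tuple[pd.Series, float, float]:
    """Shannon entropy (bits) per locus, per haplotype, and per diploid profile.

    ``S_l = -sum_i p_i log2 p_i`` with ``0 log 0 = 0``.  The haplotype total is
    ``sum_l S_l``; the diploid-profile total is twice that (loci and the two
    allele draws per locus are independent under the model).
    """
    panel._check_pop(pop)
    out = {}
    for locus in panel.loci:
        p = panel.freq(pop, locus)
        nz = p[p > 0]
        out[locus] = float(-np.sum(nz * np.log2(nz)))
    s = pd.Series(out, name="entropy_bits")
    total = float(s.sum())
    return s, total, 2.0 * total


@dataclass(frozen=True)
class FstResult:
    """Weir–Cockerham FST estimate for one population pair.

    ``raw`` may be negative; ``reported`` clips at 0 (the convention used when
    tabulating).  ``estimable`` is False when the denominator vanishes (e.g. a
    single locus monomorphic for the same allele in both populations).
    """

    raw: float
    reported: float
    estimable: bool = True


def fst_weir_cockerham(panel: FrequencyPanel, pop_a: str, pop_b: str) -> FstResult:
    """Multi-allele, multi-locus Weir–Cockerham (1984) FST between two populations.

    Variance components a (among populations), b (among individuals within
    populations) and c (within individuals) are accumulated over every allele
    at every locus and combined as a ratio of sums: ``theta_hat = sum a /
    sum (a + b + c)``.  With only frequency data available, the observed
    heterozygosity entering the components is taken at its Hardy–Weinberg
    expectation ``2 p (1 - p)`` per population.

    The estimator is exactly symmetric in the two populations.  Negative raw
    estimates are possible (and expected when the populations are identical);
    the reported value clips at zero.
    """
    panel._check_pop(pop_a)
    panel._check_pop(pop_b)
    n1, n2 = float(panel.n(pop_a)), float(panel.n(pop_b))
    r = 2.0
    n_bar = (n1 + n2) / r
    n_c = (n1 + n2 - (n1 * n1 + n2 * n2) / (n1 + n2)) / (r - 1.0)

    num = 0.0
    den = 0.0
    for locus in panel.loci:
        p1 = panel.freq(pop_a, locus)
        p2 = panel.freq(pop_b, locus)
        for f1, f2 in zip(p1, p2):
            p_bar = (n1 * f1 + n2 * f2) / (n1 + n2)
            s2 = (n1 * (f1 - p_bar) ** 2 + n2 * (f2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
            # HWE expectation of observed heterozygosity for this allele
            h1 = 2.0 * f1 * (1.0 - f1)
            h2 = 2.0 * f2 * (1.0 - f2)
            h_bar = (n1 * h1 + n2 * h2) / (n1 + n2)
            if n_bar <= 1.0:
                raise PanelValidationError("Weir-Cockerham requires mean sample size > 1")
            a = (n_bar / n_c) * (
                s2
                - (p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0) / (n_bar - 1.0)
            )
            b = (n_bar / (n_bar - 1.0)) * (
                p_bar * (1.0 - p_bar)
                - ((r - 1.0) / r) * s2
                - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
            )
            c = h_bar / 2.0
            num += a
            den += a + b + c

    if den == 0.0:
        return FstResult(raw=float("nan"), reported=float("nan"), estimable=False)
    raw = num / den
    return FstResult(raw=raw, reported=max(raw, 0.0), estimable=True)


def summary_table(panel: FrequencyPanel) -> pd.DataFrame:
    """Per-(population, locus) gene diversity and entropy, long format."""
    rows = []
    for pop in panel.populations:
        h, _ = gene_diversity(panel, pop)
        s, _, _ = profile_entropy(panel, pop)
        for locus in panel.loci:
            rows.append((pop, locus, h[locus], s[locus]))
    return pd.DataFrame(rows, columns=["population", "locus", "h", "entropy_bits"])


def fst_matrix(panel: FrequencyPanel) -> pd.DataFrame:
    """Pairwise reported-FST matrix over all panel populations."""
    pops = panel.populations
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            res = fst_weir_cockerham(panel, a, b)
            val = res.reported if res.estimable else float("nan")
            mat.loc[a, b] = val
            mat.loc[b, a] = val
    return mat
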