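"""Synthetic allele-frequency panels with the structure the analysis assumes.

Panels emulate published forensic frequency tables: multi-allelic unlinked
loci, several population samples diverged from a common ancestral base, and
finite estimation sample sizes.  Divergence follows the same Dirichlet
parameterisation as the confidence-interval variance model: a population at
divergence F from the base has locus frequencies drawn from
``Dirichlet(p_base * (1 - F) / F)``, whose mean is the base vector and whose
per-allele variance is ``F p (1 - p)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .popdata import FrequencyPanel

__all__ = [
    "PanelSpec",
    "generate_equifrequent_panel",
    "generate_diverged_panels",
    "codis_like_fixture",
]


@dataclass
class PanelSpec:
    """Recipe for a synthetic base panel.

    ``concentration`` controls the base distribution: ``None`` means
    equi-frequent alleles; a float c draws each locus's base frequencies from
    a symmetric Dirichlet(c) (smaller c -> more skewed, lower diversity).
    """

    n_loci: int
    alleles_per_locus: int
    n: int = 200
    concentration: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.alleles_per_locus < 2 or self.n < 1:
            raise ValueError("n_loci >= 1, alleles_per_locus >= 2, n >= 1 required")


def _locus_names(n_loci: int) -> list[str]:
    return [f"L{i + 1:02d}" for i in range(n_loci)]


def _allele_names(n_alleles: int) -> list[str]:
    return [f"A{i + 1}" for i in range(n_alleles)]


def generate_equifrequent_panel(
    n_loci: int, alleles_per_locus: int, n: int = 200, population: str = "POP"
) -> FrequencyPanel:
    """Single-population panel with every allele at frequency 1/k.

    The two marker types studied are k = 10 (STR-like) and k = 2 (SNP-like).
    """
    spec = PanelSpec(n_loci, alleles_per_locus, n)
    loci = _locus_names(spec.n_loci)
    labels = _allele_names(spec.alleles_per_locus)
    p = np.full(spec.alleles_per_locus, 1.0 / spec.alleles_per_locus)
    panel = FrequencyPanel(
        populations=[population],
        loci=loci,
        alleles={locus: list(labels) for locus in loci},
        freqs={(population, locus): p.copy() for locus in loci},
        sizes={population: spec.n},
    )
    panel.validate()
    return panel


def generate_base_panel(spec: PanelSpec, population: str = "BASE") -> FrequencyPanel:
    """Base panel per ``spec``; Dirichlet-sampled loci when a concentration is set."""
    if spec.concentration is None:
        return generate_equifrequent_panel(
            spec.n_loci, spec.alleles_per_locus, spec.n, population
        )
    rng = np.random.default_rng(spec.seed)
    loci = _locus_names(spec.n_loci)
    labels = _allele_names(spec.alleles_per_locus)
    freqs = {
        (population, locus): rng.dirichlet(
            np.full(spec.alleles_per_locus, spec.concentration)
        )
        for locus in loci
    }
    panel = FrequencyPanel(
        populations=[population],
        loci=loci,
        alleles={locus: list(labels) for locus in loci},
        freqs={k: v / v.sum() for k, v in freqs.items()},
        sizes={population: spec.n},
    )
    panel.validate()
    return panel


def generate_diverged_panels(
    base: FrequencyPanel,
    f_values,
    seed: int,
    base_pop: str | None = None,
    sizes=None,
    names=None,
) -> FrequencyPanel:
    """Derive one population per divergence value F from a base panel.

    For F > 0, each derived population's frequencies at each locus are an
    independent draw from ``Dirichlet(p_base (1 - F) / F)``; F = 0 returns an
    exact copy of the base.  The expected derived frequencies equal the base
    frequencies with per-allele variance ``F p (1 - p)``, so the expected
    Weir–Cockerham FST between two populations independently derived at F is
    approximately F (and approximately F/2 against the undrifted base).

    Parameters
    ----------
    base
        Panel supplying the ancestral frequencies (its first population is
        used unless ``base_pop`` names another).
    f_values
        One divergence per derived population, each in [0, 1).
    seed
        Seeds the Dirichlet draws.
    sizes, names
        Optional per-population diploid sample sizes and labels.
    """
    f_values = list(f_values)
    for f in f_values:
        if not 0.0 <= f < 1.0:
            raise ValueError("each F must be in [0, 1)")
    base_pop = base_pop or base.populations[0]
    names = list(names) if names is not None else [
        f"POP{i + 1}" for i in range(len(f_values))
    ]
    sizes = list(sizes) if sizes is not None else [base.n(base_pop)] * len(f_values)
    rng = np.random.default_rng(seed)

    freqs: dict[tuple[str, str], np.ndarray] = {}
    for name, f in zip(names, f_values):
        for locus in base.loci:
            p = base.freq(base_pop, locus)
            if f == 0.0:
                q = p.copy()
            else:
                alpha = np.maximum(p, 1e-12) * (1.0 - f) / f
                q = rng.dirichlet(alpha)
                q = q / q.sum()
            freqs[(name, locus)] = q
    panel = FrequencyPanel(
        populations=names,
        loci=list(base.loci),
        alleles={locus: list(base.alleles[locus]) for locus in base.loci},
        freqs=freqs,
        sizes=dict(zip(names, sizes)),
    )
    panel.validate()
    return panel


#: Fixture geometry: five populations diverged from a 13-locus, 10-allele
#: base.  POP5 is both the most diverged (F = 0.07) and, by construction,
#: the lowest-diversity population (its base is re-skewed before divergence),
#: mirroring the real panel where the same sample plays both roles.
_FIXTURE_F = (0.0, 0.015, 0.02, 0.04, 0.07)
_FIXTURE_SIZES = (200, 210, 200, 200, 180)
_FIXTURE_NAMES = ("POP1", "POP2", "POP3", "POP4", "POP5")
_FIXTURE_SEED = 20120209


def codis_like_fixture() -> FrequencyPanel:
    """Deterministic built-in 5-population, 13-locus, 10-allele panel.

    Base frequencies are a seeded symmetric-Dirichlet draw (moderately even,
    like STR ladders); the five populations diverge from it by
    F in {0.0001, 0.015, 0.02, 0.04, 0.07}.  The most-diverged population's
    frequencies are drawn around a low-diversity (concentrated) base, so it is
    the designated low-diversity population.  Output is identical on every
    call.
    """
    spec = PanelSpec(n_loci=13, alleles_per_locus=10, n=200,
                     concentration=8.0, seed=_FIXTURE_SEED)
    base = generate_base_panel(spec)
    panel = generate_diverged_panels(
        base, _FIXTURE_F[:4], seed=_FIXTURE_SEED + 1,
        sizes=_FIXTURE_SIZES[:4], names=_FIXTURE_NAMES[:4],
    )
    # low-diversity base: mass concentrated on few alleles per locus
    low_spec = PanelSpec(n_loci=13, alleles_per_locus=10, n=180,
                         concentration=0.45, seed=_FIXTURE_SEED + 2)
    low_base = generate_base_panel(low_spec)
    low = generate_diverged_panels(
        low_base, [_FIXTURE_F[4]], seed=_FIXTURE_SEED + 3,
        sizes=[_FIXTURE_SIZES[4]], names=[_FIXTURE_NAMES[4]],
    )
    freqs = dict(panel.freqs)
    for locus in panel.loci:
        freqs[("POP5", locus)] = low.freq("POP5", locus)
    out = FrequencyPanel(
        populations=list(_FIXTURE_NAMES),
        loci=list(panel.loci),
        alleles={locus: list(panel.alleles[locus]) for locus in panel.loci},
        freqs=freqs,
        sizes=dict(zip(_FIXTURE_NAMES, _FIXTURE_SIZES)),
    )
    out.validate()
    return out
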