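"""Likelihood ratios for relationships with confidence intervals on ln LR.

The likelihood ratio compares the probability of an observed genotype pair
under a specified relationship against the unrelated hypothesis,

    LR = P(G | k_rel, theta) / P(G | unrelated, theta),

multiplied across unlinked loci (so ln LR sums).  The observed allele
frequencies entering both probabilities are estimates; their uncertainty is
modelled with a Dirichlet (evolutionary, governed by theta_ci) plus binomial
(sampling, governed by the diploid sample size n) covariance

    Cov(p_i, p_j) = c (p_i d_ij - p_i p_j),   c = theta_ci + (1 - theta_ci)/(2n),

and propagated to ln LR by the delta method, locus by locus.  Because 13 or
more unlinked loci contribute additively, ln LR is approximately normal and
symmetric confidence bounds loglr -/+ z sqrt(Var) apply; bootstrapping over
genotypes is not meaningful here because the uncertainty lives in the
frequency estimates, not in resampled genotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .popdata import FrequencyPanel
from .relmodel import IBDCoefficients, UNRELATED, pair_genotype_prob

__all__ = [
    "LRInterval",
    "floor_frequencies",
    "locus_lr",
    "profile_loglr",
    "lnlr_variance",
    "lr_confidence_interval",
    "ProfileLRCalculator",
    "default_floor",
]

_GRAD_STEP = 1e-6  # central-difference step on allele frequencies


@dataclass(frozen=True)
class LRInterval:
    """Point estimate, variance and confidence bounds for ln LR.

    ``degenerate`` marks a ln LR of -inf (zero numerator, e.g. a
    parent-offspring hypothesis with no shared allele at some locus); the
    bounds are then -inf as well and the variance is undefined (nan).
    """

    loglr: float
    variance: float
    lcl: float
    ucl: float
    alpha: float
    z: float
    degenerate: bool = False


def default_floor(n: int) -> float:
    """Default allele-frequency floor 1/(2n + 1) for a sample of n individuals."""
    return 1.0 / (2 * n + 1)


def floor_frequencies(
    p: dict, observed, floor: float
) -> tuple[dict, int]:
    """Raise observed alleles to at least ``floor`` and renormalise.

    Cross-population evaluation routinely meets alleles unseen in the assumed
    population sample; a zero frequency would zero both likelihoods.  Every
    observed allele below the floor is set to the floor and the remaining
    alleles are scaled down proportionally so the vector sums to 1.

    Returns
    -------
    (adjusted, n_floored)
        The adjusted frequency map and the number of alleles floored.
    """
    if not 0.0 < floor <= 0.05:
        raise ValueError("floor must be in (0, 0.05]")
    observed = set(observed)
    universe = set(p) | observed
    if floor >= 1.0 / len(universe):
        raise ValueError(f"floor {floor} >= 1/{len(universe)} alleles; lower it")
    low = {a for a in observed if p.get(a, 0.0) < floor}
    if not low:
        return dict(p), 0
    floored_mass = floor * len(low)
    rest = {a: p.get(a, 0.0) for a in universe if a not in low}
    rest_sum = sum(rest.values())
    scale = (1.0 - floored_mass) / rest_sum
    adjusted = {a: f * scale for a, f in rest.items()}
    adjusted.update({a: floor for a in low})
    return adjusted, len(low)


def locus_lr(g1, g2, k: IBDCoefficients, theta_assumed: float, p: dict) -> float:
    """Single-locus LR for relationship ``k`` versus unrelated.

    ``p`` must already be floored/normalised.  The denominator is strictly
    positive after flooring; the numerator (and hence the LR) may be 0, e.g.
    a parent-offspring hypothesis when the pair shares no allele.
    """
    den = pair_genotype_prob(g1, g2, UNRELATED, theta_assumed, p)
    if den <= 0.0:
        raise ArithmeticError("unrelated-pair probability is zero after flooring")
    if k == UNRELATED:
        return 1.0
    num = pair_genotype_prob(g1, g2, k, theta_assumed, p)
    return num / den


def profile_loglr(
    pair, k: IBDCoefficients, theta_assumed: float, panel: FrequencyPanel, pop: str,
    floor: float | None = None,
) -> float:
    """Natural-log LR summed over the profile's loci; -inf if any locus LR is 0."""
    calc = ProfileLRCalculator(panel, pop, k, theta_assumed, theta_ci=0.0, floor=floor)
    total = 0.0
    for locus, (g1, g2) in pair.items():
        lr, _ = calc.locus_result(locus, g1, g2)
        if lr == 0.0:
            return float("-inf")
        total += math.log(lr)
    return total


def lnlr_variance(
    pair, k: IBDCoefficients, theta_assumed: float, theta_ci: float,
    panel: FrequencyPanel, pop: str, floor: float | None = None,
) -> float:
    """Delta-method variance of ln LR under the Dirichlet frequency model.

    Per locus, the gradient of ln LR with respect to the allele-frequency
    vector is taken by component-wise central differences (no simplex
    renormalisation: the covariance annihilates the all-ones direction) and
    contracted with ``c (diag(p) - p p^T)``.  Only alleles appearing in the
    genotype pair have non-zero gradient.

    Raises
    ------
    ArithmeticError
        If ln LR is -inf (variance undefined).
    """
    calc = ProfileLRCalculator(panel, pop, k, theta_assumed, theta_ci, floor=floor)
    total = 0.0
    for locus, (g1, g2) in pair.items():
        lr, var = calc.locus_result(locus, g1, g2)
        if lr == 0.0:
            raise ArithmeticError("ln LR is -inf; variance undefined")
        total += var
    return total


def lr_confidence_interval(
    pair, k: IBDCoefficients, theta_assumed: float, theta_ci: float,
    panel: FrequencyPanel, pop: str, alpha: float = 0.05,
    one_sided: bool = False, floor: float | None = None,
) -> LRInterval:
    """Confidence interval on ln LR at level alpha (two-sided by default).

    ``lcl/ucl = loglr -/+ z sqrt(Var)`` with ``z = z_{1-alpha/2}`` (or
    ``z_{1-alpha}`` in one-sided mode).  A -inf ln LR yields a degenerate
    (-inf, -inf) interval.  Exponentiating the bounds gives the interval on
    the LR scale.
    """
    calc = ProfileLRCalculator(panel, pop, k, theta_assumed, theta_ci, floor=floor)
    return calc.interval(pair, alpha=alpha, one_sided=one_sided)


class ProfileLRCalculator:
    """Profile ln LR and CI evaluator with per-locus genotype-pair caching.

    In a simulation study the same (locus, genotype pair) recurs across
    thousands of simulated pairs; results are cached per canonicalised pair so
    grid runs cost one enumeration per distinct pair, not per replicate.
    """

    def __init__(
        self,
        panel: FrequencyPanel,
        pop: str,
        k: IBDCoefficients,
        theta_assumed: float,
        theta_ci: float,
        floor: float | None = None,
        alpha: float = 0.05,
        one_sided: bool = False,
    ) -> None:
        panel._check_pop(pop)
        if not 0.0 <= theta_assumed < 1.0 or not 0.0 <= theta_ci < 1.0:
            raise ValueError("theta values must be in [0, 1)")
        self.panel = panel
        self.pop = pop
        self.k = k
        self.theta_assumed = theta_assumed
        self.theta_ci = theta_ci
        self.alpha = alpha
        self.one_sided = one_sided
        self.floor = default_floor(panel.n(pop)) if floor is None else floor
        n = panel.n(pop)
        self._c = theta_ci + (1.0 - theta_ci) / (2.0 * n)
        self._freq_maps = {locus: panel.freq_map(pop, locus) for locus in panel.loci}
        self._cache: dict[tuple, tuple[float, float]] = {}
        self.floored_events = 0

    def locus_result(self, locus: str, g1, g2) -> tuple[float, float]:
        """(LR, delta-method variance contribution) for one locus.

        The variance contribution is reported as 0 when the LR is 0 (the
        caller must treat the profile as degenerate).
        """
        g1 = tuple(sorted(g1))
        g2 = tuple(sorted(g2))
        if g2 < g1:
            g1, g2 = g2, g1
        key = (locus, g1, g2)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        base = self._freq_maps[locus]
        p, n_floored = floor_frequencies(base, (*g1, *g2), self.floor)
        self.floored_events += n_floored
        lr = locus_lr(g1, g2, self.k, self.theta_assumed, p)
        var = 0.0
        if lr > 0.0 and self._c > 0.0:
            var = self._locus_variance(g1, g2, p)
        self._cache[key] = (lr, var)
        return lr, var

    def _locus_variance(self, g1, g2, p: dict) -> float:
        # gradient of ln LR w.r.t. the frequencies of observed alleles only;
        # the pair probability does not depend on unobserved components.
        observed = sorted(set((*g1, *g2)))
        grads = {}
        for a in observed:
            up = dict(p)
            up[a] = p[a] + _GRAD_STEP
            dn = dict(p)
            dn[a] = p[a] - _GRAD_STEP
            lr_up = self._raw_lr(g1, g2, up)
            lr_dn = self._raw_lr(g1, g2, dn)
            grads[a] = (math.log(lr_up) - math.log(lr_dn)) / (2.0 * _GRAD_STEP)
        s1 = sum(grads[a] ** 2 * p[a] for a in observed)
        s2 = sum(grads[a] * p[a] for a in observed)
        return max(self._c * (s1 - s2 * s2), 0.0)

    def _raw_lr(self, g1, g2, p: dict) -> float:
        # perturbed vectors are off the simplex; skip the normalisation check
        num = self._raw_prob(g1, g2, self.k, p)
        den = self._raw_prob(g1, g2, UNRELATED, p)
        return num / den

    def _raw_prob(self, g1, g2, k, p):
        from .relmodel import _p_given_ibd0, _p_given_ibd1, _p_given_ibd2

        prob = 0.0
        if k.k0:
            prob += k.k0 * _p_given_ibd0(g1, g2, p, self.theta_assumed)
        if k.k1:
            prob += k.k1 * _p_given_ibd1(g1, g2, p, self.theta_assumed)
        if k.k2:
            prob += k.k2 * _p_given_ibd2(g1, g2, p, self.theta_assumed)
        return prob

    def loglr_and_variance(self, pair) -> tuple[float, float]:
        """(ln LR, Var) over a profile; (-inf, nan) when degenerate."""
        total = 0.0
        var = 0.0
        for locus, (g1, g2) in pair.items():
            lr, v = self.locus_result(locus, g1, g2)
            if lr == 0.0:
                return float("-inf"), float("nan")
            total += math.log(lr)
            var += v
        return total, var

    def interval(self, pair, alpha: float | None = None, one_sided: bool | None = None) -> LRInterval:
        alpha = self.alpha if alpha is None else alpha
        one_sided = self.one_sided if one_sided is None else one_sided
        if not 0.0 < alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        z = float(norm.ppf(1.0 - alpha) if one_sided else norm.ppf(1.0 - alpha / 2.0))
        loglr, var = self.loglr_and_variance(pair)
        if loglr == float("-inf"):
            return LRInterval(loglr, float("nan"), float("-inf"), float("-inf"),
                              alpha, z, degenerate=True)
        half = z * math.sqrt(var)
        return LRInterval(loglr, var, loglr - half, loglr + half, alpha, z)
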