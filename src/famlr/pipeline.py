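"""Orchestration of the two study grids and report writing.

``run_population_grid`` reproduces the population-structure experiment: for
every (true population, assumed population) pair, simulate related and
unrelated pairs at theta_true = 0 from the true population, evaluate the
ln LR lower confidence limit (LCL) under the assumed population's
frequencies, and summarise each cell with distinguishability D and
power/false-positive-rate curves.

``run_parameter_sweep`` reproduces the parameter experiment on equi-frequent
panels: D as a function of marker count and type (10-allele STR-like vs
2-allele SNP-like), relationship, and the true and assumed coancestry
coefficients.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics, popdata
from .lr_engine import ProfileLRCalculator
from .metrics import LCLSample, NotEstimable
from .pairsim import SimConfig, simulate_pairs
from .popdata import FrequencyPanel
from .relmodel import ibd_for_relationship
from .synthetic_data import generate_equifrequent_panel

__all__ = ["GridResult", "run_population_grid", "run_parameter_sweep", "report"]

logger = logging.getLogger(__name__)

#: Default replicate count per grid cell (the full study size; tests and the
#: worked examples use fewer).
DEFAULT_REPS = 10_000

#: Default sweep grid for the true coancestry coefficient.
DEFAULT_THETA_TRUE_GRID = (0.0, 0.001, 0.01, 0.05, 0.1)


@dataclass
class GridResult:
    """Output of :func:`run_population_grid`.

    ``d_matrix`` is assumed population (rows) by true population (columns);
    ``lcl`` maps ``(true_pop, assumed_pop, 'related'|'unrelated')`` to an
    :class:`LCLSample`; ``curves`` maps ``(true_pop, assumed_pop)`` to a
    power/FPR DataFrame.  ``metadata`` captures everything needed to
    reproduce the run byte-identically.
    """

    d_matrix: pd.DataFrame
    lcl: dict = field(default_factory=dict)
    curves: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def _cell_seed(base_seed: int, *indices: int) -> int:
    # deterministic per-cell seed, independent of iteration order
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=tuple(indices))
    return int(ss.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF


def compute_lcls(pairs, calculator: ProfileLRCalculator) -> LCLSample:
    """Evaluate the LCL of every simulated pair under one calculator."""
    values = [calculator.interval(pair).lcl for pair in pairs]
    return LCLSample.from_values(values)


def run_population_grid(
    panel: FrequencyPanel,
    relationship: str = "sibling",
    reps: int = DEFAULT_REPS,
    theta_assumed: float = 0.01,
    theta_ci: float = 0.01,
    alpha: float = 0.05,
    seed: int = 0,
    floor: float | None = None,
) -> GridResult:
    """Simulate and score every (true population, assumed population) cell.

    For each cell, ``reps`` related and ``reps`` unrelated pairs are simulated
    from the true population at theta_true = 0 (gene dropping); the same
    simulated pairs are re-scored under every assumed population so that
    across-column differences reflect frequency misspecification only.
    """
    if len(panel.populations) < 2:
        raise ValueError("panel must contain at least 2 populations")
    if reps < 100:
        raise ValueError("reps must be >= 100")
    k = ibd_for_relationship(relationship)
    pops = panel.populations
    d_matrix = pd.DataFrame(np.nan, index=pops, columns=pops)
    result = GridResult(d_matrix=d_matrix)
    # one calculator per assumed population: the per-(locus, genotype-pair)
    # cache is then shared across all true populations
    calcs = {
        pop: ProfileLRCalculator(
            panel, pop, k, theta_assumed, theta_ci, floor=floor, alpha=alpha
        )
        for pop in pops
    }
    for ti, true_pop in enumerate(pops):
        related = simulate_pairs(
            SimConfig(relationship, true_pop, 0.0, reps, _cell_seed(seed, ti, 0)), panel
        )
        unrelated = simulate_pairs(
            SimConfig("unrelated", true_pop, 0.0, reps, _cell_seed(seed, ti, 1)), panel
        )
        for assumed_pop in pops:
            calc = calcs[assumed_pop]
            rel_lcl = compute_lcls(related, calc)
            unr_lcl = compute_lcls(unrelated, calc)
            result.lcl[(true_pop, assumed_pop, "related")] = rel_lcl
            result.lcl[(true_pop, assumed_pop, "unrelated")] = unr_lcl
            try:
                d = metrics.distinguishability(rel_lcl, unr_lcl)
            except NotEstimable:
                d = np.nan
            d_matrix.loc[assumed_pop, true_pop] = d
            grid = metrics.default_threshold_grid(rel_lcl, unr_lcl)
            curve = metrics.power_fpr_curve(rel_lcl, unr_lcl, grid)
            result.curves[(true_pop, assumed_pop)] = pd.DataFrame(
                [(c.threshold, c.power, c.fpr) for c in curve],
                columns=["threshold", "power", "fpr"],
            )
            logger.info(
                "cell true=%s assumed=%s D=%.3f floored=%d degenerate=%d/%d",
                true_pop, assumed_pop, d, calc.floored_events,
                rel_lcl.n_degenerate, unr_lcl.n_degenerate,
            )
    result.metadata = {
        "relationship": relationship,
        "reps": reps,
        "theta_assumed": theta_assumed,
        "theta_ci": theta_ci,
        "alpha": alpha,
        "seed": seed,
        "floor": floor,
        "populations": list(pops),
        "loci": list(panel.loci),
        "panel_checksum": panel_checksum(panel),
    }
    return result


def run_parameter_sweep(
    marker_counts=(10, 20, 30, 40, 50, 60),
    marker_type: str = "STR",
    relationships=("sibling", "half-sibling", "first-cousin", "second-cousin"),
    theta_true_grid=(0.0,),
    theta_assumed_grid=(0.01,),
    reps: int = 2_000,
    n: int = 200,
    theta_ci: float = 0.01,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """D over marker count/type, relationship and coancestry settings.

    ``marker_type`` 'STR' uses 10-allele equi-frequent loci, 'SNP' 2-allele.
    Simulation uses the urn sampler so theta_true > 0 is honoured.  A
    parent-offspring request yields a not-estimable (NaN) D row: unrelated
    pairs then have -inf ln LR at almost every profile, so the LCL
    distribution is undefined.
    """
    alleles = {"STR": 10, "SNP": 2}[marker_type.upper()]
    rows = []
    for mi, n_markers in enumerate(marker_counts):
        panel = generate_equifrequent_panel(n_markers, alleles, n)
        pop = panel.populations[0]
        calcs: dict[tuple, ProfileLRCalculator] = {}
        for ri, rel in enumerate(relationships):
            k = ibd_for_relationship(rel)
            for tti, theta_true in enumerate(theta_true_grid):
                related = simulate_pairs(
                    SimConfig(rel, pop, theta_true, reps, _cell_seed(seed, mi, ri, tti, 0)),
                    panel,
                )
                unrelated = simulate_pairs(
                    SimConfig("unrelated", pop, theta_true, reps,
                              _cell_seed(seed, mi, ri, tti, 1)),
                    panel,
                )
                for theta_assumed in theta_assumed_grid:
                    key = (rel, theta_assumed)
                    if key not in calcs:
                        calcs[key] = ProfileLRCalculator(
                            panel, pop, k, theta_assumed, theta_ci, alpha=alpha
                        )
                    calc = calcs[key]
                    rel_lcl = compute_lcls(related, calc)
                    unr_lcl = compute_lcls(unrelated, calc)
                    try:
                        d = metrics.distinguishability(rel_lcl, unr_lcl)
                    except NotEstimable:
                        d = np.nan
                    rows.append(
                        (marker_type.upper(), n_markers, rel, theta_true,
                         theta_assumed, d, len(rel_lcl.values), len(unr_lcl.values))
                    )
    return pd.DataFrame(
        rows,
        columns=["marker_type", "n_markers", "relationship", "theta_true",
                 "theta_assumed", "D", "n_finite_related", "n_finite_unrelated"],
    )


def panel_checksum(panel: FrequencyPanel) -> str:
    """Hex digest of the panel contents (reproducibility metadata)."""
    import hashlib

    h = hashlib.sha256()
    h.update(panel.to_frame().to_csv(index=False).encode())
    return h.hexdigest()[:16]


def _atomic_write(path: str, text: str) -> None:
    d = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def report(grid: GridResult, outdir, panel: FrequencyPanel | None = None) -> list[str]:
    """Write a grid run's numeric content as TSVs (plus JSON metadata).

    Emits the D matrix, per-cell LCL histograms and power/FPR curves, and —
    when the panel is supplied — the pairwise FST matrix and per-locus gene
    diversity/entropy table.  All writes are atomic (write-then-rename).
    """
    os.makedirs(outdir, exist_ok=True)
    written = []

    def emit(name: str, text: str) -> None:
        path = os.path.join(outdir, name)
        _atomic_write(path, text)
        written.append(path)

    emit("d_matrix.tsv", grid.d_matrix.to_csv(sep="\t", index_label="assumed_pop"))
    emit("metadata.json", json.dumps(grid.metadata, indent=2, sort_keys=True) + "\n")

    hist_rows = []
    for (true_pop, assumed_pop, status), sample in grid.lcl.items():
        if len(sample.values):
            counts, edges = np.histogram(sample.values, bins=40)
            for lo, hi, c in zip(edges[:-1], edges[1:], counts):
                hist_rows.append((true_pop, assumed_pop, status, lo, hi, int(c)))
        hist_rows.append((true_pop, assumed_pop, status, float("-inf"),
                          float("-inf"), sample.n_degenerate))
    emit(
        "lcl_histograms.tsv",
        pd.DataFrame(
            hist_rows,
            columns=["true_pop", "assumed_pop", "status", "bin_lo", "bin_hi", "count"],
        ).to_csv(sep="\t", index=False),
    )

    curve_rows = []
    for (true_pop, assumed_pop), df in grid.curves.items():
        df = df.assign(true_pop=true_pop, assumed_pop=assumed_pop)
        curve_rows.append(df)
    if curve_rows:
        emit(
            "power_fpr_curves.tsv",
            pd.concat(curve_rows, ignore_index=True).to_csv(sep="\t", index=False),
        )

    if panel is not None:
        emit("fst_matrix.tsv", popdata.fst_matrix(panel).to_csv(sep="\t", index_label="population"))
        emit("diversity.tsv", popdata.summary_table(panel).to_csv(sep="\t", index=False))
    return written
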