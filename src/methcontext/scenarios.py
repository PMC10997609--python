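"""Canonical simulation scenarios used for validation.

Each function plants a known signal with the generator, runs the
corresponding analysis end to end, and returns the measured statistics.
These are the package's calibration experiments: footprint recovery,
depletion monotonicity, DMR null behaviour and planted-coupling
recovery.  Problem sizes are chosen to give comfortable statistical
resolution at interactive runtimes (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cgi import CgiHistoneModel
from .context import build_observed_profile, preference_correlation
from .dmr import TileDMRModel, call_dmrs
from .formats_io import GenomeSequence
from .simulate import (
    SimConfig,
    simulate_chip,
    simulate_genome,
    simulate_methylome,
    simulate_preference_profile,
)


def footprint_recovery(seed: int = 0, genome_length: int = 1_200_000) -> dict:
    """Plant one enzyme's footprint noiselessly and recover it.

    Conditions: single enzyme at weight 2 on the logit scale, zero
    baseline, zero site noise, 100x coverage, ~50k CpGs.  Returns the
    correlation against the planted profile and against an independent
    random control profile.
    """
    config = SimConfig(
        seed=seed, genome_length=genome_length, n_contigs=2, cgi_count=0,
        enzyme_weights={"E": 2.0}, baseline=0.0, site_noise_sd=0.0,
        coverage_mean=100.0, depletion_factors={"t0": {}}, coupled_timepoints=(),
    )
    genome, cgis = simulate_genome(config)
    planted = simulate_preference_profile(seed + 10_000, name="E")
    control = simulate_preference_profile(seed + 20_000, name="control")
    methylome = simulate_methylome(genome, cgis, {"E": planted}, config, "t0")
    observed = build_observed_profile(methylome, genome)
    return {
        "n_cpg": len(methylome) // 2,
        "r_planted": preference_correlation(observed, planted).r,
        "r_control": preference_correlation(observed, control).r,
    }


def depletion_series(
    seed: int,
    deltas: tuple[float, ...] = (1.0, 0.75, 0.5, 0.25, 0.0),
    genome_length: int = 100_000,
) -> list[float]:
    """Correlation against the planted profile as residual enzyme
    activity delta decreases -- the in-silico analogue of a degron
    depletion time course.

    The weight keeps the logit within the logistic's near-linear range
    (saturation would otherwise depress the value-scale Pearson at full
    activity) and the site noise is strong enough that the signal-to-
    noise ratio, hence r, falls as delta does.
    """
    timepoints = {f"d{i}": {"E": d} for i, d in enumerate(deltas)}
    config = SimConfig(
        seed=seed, genome_length=genome_length, n_contigs=1, cgi_count=0,
        enzyme_weights={"E": 0.75}, baseline=0.0, site_noise_sd=1.0,
        coverage_mean=30.0, depletion_factors=timepoints, coupled_timepoints=(),
    )
    genome, cgis = simulate_genome(config)
    planted = simulate_preference_profile(seed + 10_000, name="E")
    out = []
    for tp in timepoints:
        methylome = simulate_methylome(genome, cgis, {"E": planted}, config, tp)
        observed = build_observed_profile(methylome, genome)
        out.append(preference_correlation(observed, planted).r)
    return out


def mean_depletion_series(n_seeds: int = 10, base_seed: int = 0,
                          deltas: tuple[float, ...] = (1.0, 0.75, 0.5, 0.25, 0.0)) -> np.ndarray:
    rs = np.array([depletion_series(base_seed + i, deltas) for i in range(n_seeds)])
    return rs.mean(axis=0)


def planted_dmr_fixture() -> pd.DataFrame:
    """A 10-tile toy: 3 tiles losing 40 points at deep coverage, 7 null."""
    rows = []
    for i in range(10):
        planted = i < 3
        ma, ua = (350, 150) if planted else (250, 250)   # 70% vs 50%
        mb, ub = (150, 350) if planted else (250, 250)   # 30% vs 50%
        rows.append({
            "contig": "chr1", "start": i * 1000, "end": (i + 1) * 1000,
            "name": f"chr1:{i * 1000}-{(i + 1) * 1000}",
            "n_cpg_a": 10, "n_cpg_b": 10,
            "meth_a": ma, "unmeth_a": ua, "meth_b": mb, "unmeth_b": ub,
            "diff": 100 * mb / (mb + ub) - 100 * ma / (ma + ua),
        })
    return pd.DataFrame(rows)


def null_dmr_fraction(seed: int = 0, genome_length: int = 500_000) -> dict:
    """Fraction of significant DMR calls when both conditions share the
    same true methylome (read sampling is the only difference)."""
    config = SimConfig(
        seed=seed, genome_length=genome_length, n_contigs=1, cgi_count=50,
        cgi_length=800, baseline=1.0, site_noise_sd=0.0, coverage_mean=30.0,
        depletion_factors={"condA": {}, "condB": {}}, coupled_timepoints=(),
    )
    genome, cgis = simulate_genome(config)
    profiles = {e: simulate_preference_profile(seed + 10_000 + i, name=e)
                for i, e in enumerate(config.enzyme_weights)}
    a = simulate_methylome(genome, cgis, profiles, config, "condA")
    b = simulate_methylome(genome, cgis, profiles, config, "condB")
    results = TileDMRModel([a], [b], genome).fit()
    n = len(results.table)
    return {
        "n_tiles": n,
        "n_significant": results.n_hypo + results.n_hyper,
        "fraction_significant": (results.n_hypo + results.n_hyper) / n if n else 0.0,
    }


def cgi_coupling(seed: int = 0, beta: float = 0.4, n_cgis: int = 500) -> dict:
    """Plant histone-coupled extra demethylation in the cofactor
    depletion and measure the Spearman trend across CGIs.

    The enzyme depletion removes only the maintenance enzyme; the
    cofactor depletion scales every enzyme down and, when beta > 0,
    additionally demethylates CGIs in proportion to their normalized
    histone score (the generative claim the analysis is built to
    detect).
    """
    config = SimConfig(
        seed=seed, genome_length=1_200_000, n_contigs=2, cgi_count=n_cgis,
        cgi_length=800, cgi_cpg_density=0.10, histone_coupling=beta,
        baseline=1.39, site_noise_sd=0.5, coverage_mean=30.0,
    )
    genome, cgis = simulate_genome(config)
    profiles = {e: simulate_preference_profile(seed + 10_000 + i, name=e)
                for i, e in enumerate(sorted(config.enzyme_weights))}
    chip = simulate_chip(cgis, config, coupled=beta > 0)
    day0 = simulate_methylome(genome, cgis, profiles, config, "day0")
    day4_enzyme = simulate_methylome(genome, cgis, profiles, config, "day4_enzyme")
    day4_cofactor = simulate_methylome(
        genome, cgis, profiles, config, "day4_cofactor",
        histone_norm=chip["histone_norm"],
    )
    model = CgiHistoneModel(
        cgis, chip["chip_counts"], chip["input_counts"],
        chip["chip_total"], chip["input_total"],
        u0=[day0], u4=[day4_cofactor], d0=[day0], d4=[day4_enzyme],
    )
    results = model.fit()
    return {"rho": results.rho, "p": results.p_value, "n": results.n}
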