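"""Shared experiment harnesses for the acceptance suite.

Scaled-down but statistically honest versions of the pipeline's
calibration / power experiments, all deterministic under fixed seeds.
"""

from __future__ import annotations

import numpy as np

from sweepscan.calibration import SENTINEL, rank_value
from sweepscan.config import PipelineConfig
from sweepscan.pipeline import (
    build_calibrations,
    classify_targets,
    define_region,
    scan_gene,
)
from sweepscan.stats import dind, fay_wu_dh, tajimas_d
from sweepscan.synthetic import (
    DemographyModel,
    SimulationParams,
    SweepModel,
    generate_control_set,
    simulate_neutral,
    simulate_sweep,
)

NE = 10_000
DEM = DemographyModel.constant_size(NE)
PARAMS = SimulationParams(
    n_haplotypes_per_pop=30,
    region_length=30_000,
    mutation_rate=5e-8,
    recombination_rate=1e-8,
)
CONFIG = PipelineConfig(populations=("pop0",), min_bin_count=20)


def neutral_replicates(n_reps: int, seed: int, params=None):
    params = params or SimulationParams(
        n_haplotypes_per_pop=30, region_length=20_000,
        mutation_rate=5e-8, recombination_rate=1e-8,
    )
    out = []
    for i in range(n_reps):
        out.append(simulate_neutral(params, DEM, seed=seed + i))
    return out


def neutral_means(n_reps: int, seed: int) -> tuple[float, float]:
    """Mean Tajima's D and mean DH over constant-size neutral replicates."""
    ds, dhs = [], []
    for m in neutral_replicates(n_reps, seed):
        d = tajimas_d(m)
        h = fay_wu_dh(m)
        if not np.isnan(d):
            ds.append(d)
        if not np.isnan(h):
            dhs.append(h)
    return float(np.mean(ds)), float(np.mean(dhs))


def build_control_calibration(n_genes: int, seed: int):
    control = generate_control_set(n_genes, PARAMS, DEM, seed=seed)
    return control, build_calibrations(control, CONFIG)


def dind_type1_fraction(
    calibrations, n_focal_genes: int, seed: int
) -> tuple[int, int]:
    """(outliers, tested): one randomly chosen testable SNP per neutral gene
    ranked against the control calibration."""
    rng = np.random.default_rng(seed)
    dist = calibrations.dind["pop0"]
    testable = calibrations.dind_testable["pop0"]
    n_out = 0
    n_tested = 0
    for i in range(n_focal_genes):
        m = simulate_neutral(PARAMS, DEM, seed=int(seed + 7_000 + i))
        candidates = []
        for j in np.nonzero(m.segregating())[0]:
            daf = m.derived_frequency()[j]
            if testable[dist.bin_index(float(daf))]:
                candidates.append(int(j))
        if not candidates:
            continue
        j = int(rng.choice(candidates))
        r = dind(m, j, flank_total=CONFIG.dind_flank_total)
        if not r.computed:
            continue
        rank = rank_value(
            dist, r.daf, SENTINEL if r.sentinel_flag else r.dind,
            testable=testable,
        )
        if rank is None:
            continue
        n_tested += 1
        if rank >= CONFIG.rank_outlier:
            n_out += 1
    return n_out, n_tested


def sweep_focal_outlier_rate(
    calibrations, n_reps: int, seed: int, target_daf: float = 0.8,
    s: float = 1.0,
) -> float:
    """Fraction of sweep replicates whose focal-SNP DIND exceeds the
    neutral 95th percentile of the matched DAF bin."""
    dist = calibrations.dind["pop0"]
    testable = calibrations.dind_testable["pop0"]
    sweep = SweepModel(
        position=PARAMS.region_length // 2,
        selection_coefficient=s,
        target_daf=target_daf,
    )
    n_hit = 0
    n_eval = 0
    for i in range(n_reps):
        res = simulate_sweep(PARAMS, DEM, sweep, seed=seed + i)
        r = dind(res.matrix, res.focal_index,
                 flank_total=CONFIG.dind_flank_total)
        if not r.computed:
            continue
        rank = rank_value(
            dist, r.daf, SENTINEL if r.sentinel_flag else r.dind,
            testable=testable,
        )
        if rank is None:
            continue
        n_eval += 1
        if rank >= CONFIG.rank_outlier:
            n_hit += 1
    if n_eval == 0:
        return 0.0
    return n_hit / n_eval


def gene_flag_rates(
    calibrations, n_genes: int, seed: int, target_daf: float = 0.8,
    s: float = 1.0,
) -> tuple[float, float]:
    """(neutral flag rate, sweep flag rate) under the full decision rules."""
    region = define_region(
        "g", "1", 1, PARAMS.region_length, flank=0
    )
    sweep = SweepModel(
        position=PARAMS.region_length // 2,
        selection_coefficient=s,
        target_daf=target_daf,
    )
    flags_neutral = []
    flags_sweep = []
    for i in range(n_genes):
        m = simulate_neutral(PARAMS, DEM, seed=seed + 50_000 + i)
        res = scan_gene(m, region, calibrations, CONFIG)
        flags_neutral.append(classify_targets(res, CONFIG).flagged)
        sw = simulate_sweep(PARAMS, DEM, sweep, seed=seed + 90_000 + i)
        res = scan_gene(sw.matrix, region, calibrations, CONFIG)
        flags_sweep.append(classify_targets(res, CONFIG).flagged)
    return float(np.mean(flags_neutral)), float(np.mean(flags_sweep))
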