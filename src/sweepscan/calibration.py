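"""Empirical null calibration: frequency-binned percentile distributions
built from a control gene set, plus coalescent-simulation P values for the
DIND test.

Sentinel DIND values (iπ_D = 0, assigned dataset-max + offset downstream)
are represented internally as +inf so they rank above every finite value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .stats import DindResult, dind
from .synthetic import DemographyModel, SimulationParams, simulate_neutral

__all__ = [
    "EmpiricalDistribution",
    "build_binned_calibration",
    "rank_value",
    "dind_testable_bins",
    "dh_window_threshold",
    "dind_sim_pvalue",
    "SimPValue",
    "SENTINEL",
]

SENTINEL = float("inf")

_DOMAIN = {"maf": (0.0, 0.5), "daf": (0.0, 1.0), "none": (0.0, 1.0)}


@dataclass
class EmpiricalDistribution:
    """Equal-width-binned empirical percentile structure.

    ``bin_values[k]`` holds the sorted control statistics whose bin
    variable fell into bin k; +inf entries are sentinel-tagged values.
    """

    bin_variable: str  # 'maf', 'daf' or 'none'
    n_bins: int
    bin_edges: np.ndarray
    bin_values: list[np.ndarray]

    def bin_index(self, bin_value: float) -> int:
        lo, hi = _DOMAIN[self.bin_variable]
        if self.bin_variable == "none":
            return 0
        if not (lo <= bin_value <= hi):
            raise ValueError(
                f"bin value {bin_value} outside [{lo}, {hi}] for "
                f"{self.bin_variable!r} binning"
            )
        k = int((bin_value - lo) / (hi - lo) * self.n_bins)
        return min(k, self.n_bins - 1)

    def default_testable(self) -> np.ndarray:
        """A bin is usable at all only if it holds control values."""
        return np.array([v.size > 0 for v in self.bin_values])

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "bin_variable": self.bin_variable,
            "n_bins": self.n_bins,
            "bin_edges": [float(e) for e in self.bin_edges],
            "bin_values": [
                {
                    "finite": [float(x) for x in v[np.isfinite(v)]],
                    "n_sentinel": int(np.sum(np.isinf(v))),
                }
                for v in self.bin_values
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EmpiricalDistribution":
        values = []
        for b in d["bin_values"]:
            v = np.array(b["finite"] + [SENTINEL] * b["n_sentinel"])
            values.append(np.sort(v))
        return cls(
            bin_variable=d["bin_variable"],
            n_bins=int(d["n_bins"]),
            bin_edges=np.asarray(d["bin_edges"], dtype=float),
            bin_values=values,
        )


def build_binned_calibration(
    control_values: Iterable[tuple[float, float]],
    bin_variable: str = "daf",
    n_bins: int = 100,
) -> EmpiricalDistribution:
    """Bin (bin_value, statistic) control pairs into equal-width classes.

    Defaults follow the pipeline conventions: MAF over [0, 0.5] in 50
    classes for FST, DAF over [0, 1] in 100 classes for DIND; pass
    ``bin_variable='none'`` for an unbinned (single class) distribution.
    Statistics may be finite or +inf (sentinel-tagged).
    """
    if bin_variable not in _DOMAIN:
        raise ValueError(f"unknown bin variable {bin_variable!r}")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if bin_variable == "none":
        n_bins = 1
    lo, hi = _DOMAIN[bin_variable]
    edges = np.linspace(lo, hi, n_bins + 1)
    bins: list[list[float]] = [[] for _ in range(n_bins)]
    n_in = 0
    for bin_value, stat in control_values:
        if not (np.isfinite(stat) or np.isinf(stat)):
            continue  # NaN: undefined statistic, not part of the null
        n_in += 1
        if bin_variable == "none":
            k = 0
        else:
            k = min(int((bin_value - lo) / (hi - lo) * n_bins), n_bins - 1)
            k = max(k, 0)
        bins[k].append(float(stat))
    if n_in == 0:
        raise ValueError("no usable control values")
    return EmpiricalDistribution(
        bin_variable=bin_variable,
        n_bins=n_bins,
        bin_edges=edges,
        bin_values=[np.sort(np.array(b)) for b in bins],
    )


def rank_value(
    dist: EmpiricalDistribution,
    bin_value: float,
    statistic: float,
    testable: np.ndarray | None = None,
) -> float | None:
    """Empirical rank of ``statistic`` within its frequency bin.

    rank = (count below + half the tied count) / bin size, i.e. the
    fraction of control values <= the statistic with midpoint tie
    correction.  Sentinel statistics (+inf) rank above all finite values.
    Returns None when the bin is untestable.
    """
    if testable is None:
        testable = dist.default_testable()
    k = dist.bin_index(bin_value)
    if not testable[k]:
        return None
    vals = dist.bin_values[k]
    lo = int(np.searchsorted(vals, statistic, side="left"))
    hi = int(np.searchsorted(vals, statistic, side="right"))
    return float((lo + 0.5 * (hi - lo)) / vals.size)


def dind_testable_bins(
    dist: EmpiricalDistribution,
    max_sentinel_fraction: float = 0.05,
    min_count: int = 1,
) -> np.ndarray:
    """Per-bin testability for the DIND calibration.

    A bin is testable iff its 95th percentile is a finite value — i.e.
    strictly fewer than ``max_sentinel_fraction`` of its control values
    are sentinels — and it holds at least ``min_count`` values.
    """
    flags = np.zeros(dist.n_bins, dtype=bool)
    for k, vals in enumerate(dist.bin_values):
        if vals.size < max(min_count, 1):
            continue
        frac_sent = float(np.sum(np.isinf(vals))) / vals.size
        flags[k] = frac_sent < max_sentinel_fraction
    return flags


def dh_window_threshold(
    control_window_values: Sequence[float],
    percentile: float = 5.0,
    min_values: int = 20,
) -> float:
    """Empirical low percentile (default 5th) of control-window DH values.

    Uses the sorted-index definition: the value at rank
    ``ceil(p/100 * N)`` (1-based) of the sorted sample.
    """
    vals = np.sort(np.asarray(control_window_values, dtype=float))
    vals = vals[np.isfinite(vals)]
    if vals.size < min_values:
        raise ValueError(
            f"need >= {min_values} control window values, got {vals.size}"
        )
    k = max(int(math.ceil(percentile / 100.0 * vals.size)) - 1, 0)
    return float(vals[k])


# ----------------------------------------------------------------------
@dataclass
class SimPValue:
    """Simulation-based significance for one observed DIND value."""

    p: float
    p_corrected: float  # (k + 1) / (n + 1)
    n_in_bin: int
    defined: bool


def dind_sim_pvalue(
    observed: DindResult,
    demography: DemographyModel,
    params: SimulationParams,
    population: str | None = None,
    n_iter: int = 2000,
    seed: int | None = None,
    n_bins: int = 100,
    flank_total: int = 40,
) -> SimPValue:
    """Coalescent-simulation P value for an observed DIND result.

    Runs ``n_iter`` neutral simulations of ``params.region_length`` bp
    (default pipeline: 20,000 bp, 2,000 iterations), computes DIND-DAF
    pairs for every SNP with the same operation used on real data, bins
    them in DAF classes and reports the proportion of simulated values in
    the observed DAF's bin that are >= the observed DIND.  Sentinels on
    either side are treated as above every finite value, exactly as in the
    empirical ranking.
    """
    if not np.isfinite(observed.daf):
        raise ValueError("observed result has no defined DAF")
    from .synthetic import _child_seeds  # shared splitting rule

    seeds = _child_seeds(seed, n_iter)
    sim_daf: list[float] = []
    sim_val: list[float] = []
    for s in seeds:
        m = simulate_neutral(params, demography, seed=s)
        for j in range(m.n_sites):
            r = dind(m, j, flank_total=flank_total, population=population)
            if not r.computed:
                continue
            sim_daf.append(r.daf)
            sim_val.append(SENTINEL if r.sentinel_flag else r.dind)
    if not sim_val:
        warnings.warn("no simulated DIND values produced", stacklevel=2)
        return SimPValue(float("nan"), float("nan"), 0, False)
    daf_arr = np.asarray(sim_daf)
    val_arr = np.asarray(sim_val)
    k_obs = min(int(observed.daf * n_bins), n_bins - 1)
    k_sim = np.minimum((daf_arr * n_bins).astype(int), n_bins - 1)
    in_bin = val_arr[k_sim == k_obs]
    if in_bin.size == 0:
        warnings.warn(
            f"no simulated DIND values in DAF bin {k_obs}", stacklevel=2
        )
        return SimPValue(float("nan"), float("nan"), 0, False)
    obs_val = SENTINEL if observed.sentinel_flag else observed.dind
    k_ge = int(np.sum(in_bin >= obs_val))
    p = k_ge / in_bin.size
    p_corr = (k_ge + 1) / (in_bin.size + 1)
    return SimPValue(float(p), float(p_corr), int(in_bin.size), True)
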