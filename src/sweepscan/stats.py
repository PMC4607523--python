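"""Population-genetic statistics on phased haplotype matrices.

Implements nucleotide diversity (pi), Watterson's theta, Tajima's D, the
normalized Fay-Wu H statistic (DH) with sliding windows, the per-SNP
two-population Weir-Cockerham FST estimator, the derived intra-allelic
nucleotide diversity (DIND) test with its dataset-level sentinel rule, and
linkage-disequilibrium r^2.

Conventions: allele 1 is derived at polarized sites, -1 is missing.  All
"total" statistics (pi, theta_W, theta_L) are sums over the analyzed sites,
not per-bp densities, so that e.g. two haplotypes differing at three sites
give pi = 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .matrix import MISSING, HaplotypeMatrix

__all__ = [
    "WindowStat",
    "DindResult",
    "PopSiteCounts",
    "nucleotide_diversity",
    "watterson_theta",
    "tajimas_d",
    "fay_wu_dh",
    "sliding_dh",
    "weir_cockerham_fst",
    "site_counts",
    "dind",
    "finalize_dind_sentinels",
    "ld_r2",
]


# ----------------------------------------------------------------------
# helpers
def _harmonic(n: int, power: int = 1) -> float:
    """sum_{i=1}^{n} 1/i**power."""
    i = np.arange(1, n + 1, dtype=float)
    return float(np.sum(1.0 / i**power))


def _rows(haps: HaplotypeMatrix, population: str | None) -> np.ndarray:
    return haps.haplotype_indices(population)


def _pairwise_diff_total(sub: np.ndarray) -> float:
    """Mean pairwise difference over all haplotype pairs of ``sub``.

    Missing entries are handled by comparing each pair only at mutually
    non-missing sites and rescaling the raw difference count by the
    fraction of sites compared.  Pairs with nothing to compare are dropped
    from the average.
    """
    n, n_sites = sub.shape
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    if n_sites == 0:
        return 0.0
    if not np.any(sub == MISSING):
        # fast path via per-site allele counts
        c = (sub == 1).sum(axis=0).astype(float)
        return float(np.sum(2.0 * c * (n - c)) / (n * (n - 1)))
    total = 0.0
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            ok = (sub[i] != MISSING) & (sub[j] != MISSING)
            m = int(ok.sum())
            if m == 0:
                continue
            diff = int(np.sum(sub[i][ok] != sub[j][ok]))
            total += diff * (n_sites / m)
            n_pairs += 1
    if n_pairs == 0:
        return float("nan")
    return total / n_pairs


# ----------------------------------------------------------------------
# diversity / SFS statistics
def nucleotide_diversity(
    haps: HaplotypeMatrix,
    site_subset: Sequence[int] | np.ndarray | None = None,
    population: str | None = None,
) -> float:
    """Mean number of pairwise differences (pi) over the selected sites."""
    rows = _rows(haps, population)
    if rows.size < 2:
        raise ValueError("nucleotide diversity requires >= 2 haplotypes")
    sub = haps.alleles[rows]
    if site_subset is not None:
        sub = sub[:, np.asarray(site_subset, dtype=np.int64)]
    return _pairwise_diff_total(sub)


def watterson_theta(
    haps: HaplotypeMatrix, population: str | None = None
) -> float:
    """theta_W = S / a_n with a_n = sum_{i=1}^{n-1} 1/i."""
    rows = _rows(haps, population)
    n = rows.size
    if n < 2:
        raise ValueError("Watterson's theta requires >= 2 haplotypes")
    s = int(haps.segregating(rows).sum())
    return s / _harmonic(n - 1)


def tajimas_d(
    haps: HaplotypeMatrix, population: str | None = None
) -> float:
    """Tajima's D; NaN when S = 0 (undefined, not an error)."""
    rows = _rows(haps, population)
    n = rows.size
    if n < 2:
        raise ValueError("Tajima's D requires >= 2 haplotypes")
    seg = haps.segregating(rows)
    s = int(seg.sum())
    if s == 0:
        return float("nan")
    pi = _pairwise_diff_total(haps.alleles[rows][:, seg])
    a1 = _harmonic(n - 1)
    a2 = _harmonic(n - 1, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:
        # n = 2 degenerates: pi == theta_W exactly, D -> 0 by symmetry
        return 0.0 if abs(pi - s / a1) < 1e-12 else float("nan")
    return float((pi - s / a1) / np.sqrt(var))


def fay_wu_dh(
    haps: HaplotypeMatrix,
    population: str | None = None,
    site_subset: Sequence[int] | np.ndarray | None = None,
) -> float:
    """Normalized Fay-Wu H (DH): (pi - theta_L) / sqrt(Var).

    Only polarized sites are counted; unpolarized sites in the subset are
    excluded with a warning.  Sites with missing data are skipped (the
    unfolded spectrum is undefined for partial columns).  Returns NaN when
    no segregating polarized site remains.
    """
    rows = _rows(haps, population)
    n = rows.size
    if n < 2:
        raise ValueError("DH requires >= 2 haplotypes")
    if site_subset is None:
        idx = np.arange(haps.n_sites)
    else:
        idx = np.asarray(site_subset, dtype=np.int64)
    pol = haps.polarized[idx]
    if not np.all(pol):
        warnings.warn(
            f"excluding {int((~pol).sum())} unpolarized site(s) from DH",
            stacklevel=2,
        )
        idx = idx[pol]
    sub = haps.alleles[rows][:, idx]
    called = (sub != MISSING).all(axis=0)
    sub = sub[:, called]
    c = (sub == 1).sum(axis=0)
    seg = (c > 0) & (c < n)
    c = c[seg].astype(float)
    s = c.size
    if s == 0:
        return float("nan")
    an = _harmonic(n - 1)
    bn = _harmonic(n - 1, 2)
    bn1 = _harmonic(n, 2)
    pi = float(np.sum(2.0 * c * (n - c)) / (n * (n - 1)))
    theta_l = float(np.sum(c) / (n - 1))
    theta_w = s / an
    theta_sq = s * (s - 1) / (an**2 + bn)
    var = (n - 2) / (6.0 * (n - 1)) * theta_w + (
        18.0 * n**2 * (3.0 * n + 2.0) * bn1
        - (88.0 * n**3 + 9.0 * n**2 - 13.0 * n + 6.0)
    ) / (9.0 * n * (n - 1) ** 2) * theta_sq
    return float((pi - theta_l) / np.sqrt(var))


# ----------------------------------------------------------------------
# sliding windows
@dataclass
class WindowStat:
    """One sliding-window value over a 1-based, fully closed interval."""

    start: int
    end: int
    n_snps: int
    value: float | None
    defined: bool


def sliding_dh(
    haps: HaplotypeMatrix,
    region_start: int,
    region_end: int,
    window: int = 5000,
    step: int = 500,
    min_snps: int = 3,
    population: str | None = None,
) -> list[WindowStat]:
    """DH in sliding windows tiling [region_start, region_end].

    A window with fewer than ``min_snps`` polarized segregating SNPs is
    reported as undefined.  When the window exceeds the region length a
    single whole-region window is used.
    """
    if not (window >= step > 0):
        raise ValueError("require window >= step > 0")
    length = region_end - region_start + 1
    if length <= 0:
        raise ValueError("empty region")
    if window >= length:
        starts = [region_start]
        window = length
    else:
        last = region_end - window + 1
        starts = list(range(region_start, last + 1, step))
        if starts[-1] != last and starts[-1] + window - 1 < region_end:
            starts.append(last)  # trailing window flush with the region edge
    rows = _rows(haps, population)
    out: list[WindowStat] = []
    for s0 in starts:
        e0 = min(s0 + window - 1, region_end)
        in_win = np.nonzero(
            (haps.positions >= s0) & (haps.positions <= e0) & haps.polarized
        )[0]
        seg = haps.segregating(rows)[in_win]
        n_snps = int(seg.sum())
        if n_snps < min_snps:
            out.append(WindowStat(s0, e0, n_snps, None, False))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            val = fay_wu_dh(haps, population=population, site_subset=in_win)
        if np.isnan(val):
            out.append(WindowStat(s0, e0, n_snps, None, False))
        else:
            out.append(WindowStat(s0, e0, n_snps, float(val), True))
    return out


# ----------------------------------------------------------------------
# Weir-Cockerham FST (two populations, one SNP)
@dataclass(frozen=True)
class PopSiteCounts:
    """Per-population summary of one biallelic site.

    n: genotyped diploid individuals; p: frequency of the focal allele;
    het: observed heterozygote frequency.
    """

    n: int
    p: float
    het: float


def site_counts(
    haps: HaplotypeMatrix, site: int, population: str
) -> PopSiteCounts:
    """Summarize one site for one population, pairing haplotypes 2i/2i+1."""
    rows = haps.haplotype_indices(population)
    a = haps.alleles[rows, site].reshape(-1, 2)
    ok = (a != MISSING).all(axis=1)
    a = a[ok]
    n = a.shape[0]
    if n == 0:
        return PopSiteCounts(0, float("nan"), float("nan"))
    p = float(a.mean())
    het = float((a[:, 0] != a[:, 1]).mean())
    return PopSiteCounts(n, p, het)


def weir_cockerham_fst(
    counts_a: PopSiteCounts, counts_b: PopSiteCounts
) -> float:
    """Per-SNP two-population Weir-Cockerham estimator a/(a+b+c).

    Returns NaN when the site is monomorphic across both populations
    (a + b + c = 0).
    """
    if counts_a.n < 1 or counts_b.n < 1:
        raise ValueError("both populations need >= 1 genotyped sample")
    r = 2
    ns = np.array([counts_a.n, counts_b.n], dtype=float)
    ps = np.array([counts_a.p, counts_b.p], dtype=float)
    hs = np.array([counts_a.het, counts_b.het], dtype=float)
    nbar = ns.mean()
    if nbar <= 1:
        return float("nan")
    nc = (r * nbar - np.sum(ns**2) / (r * nbar)) / (r - 1)
    pbar = float(np.sum(ns * ps) / (r * nbar))
    s2 = float(np.sum(ns * (ps - pbar) ** 2) / ((r - 1) * nbar))
    hbar = float(np.sum(ns * hs) / (r * nbar))
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - (r - 1) / r * s2
        - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    denom = a + b + c
    if denom == 0:
        return float("nan")
    return float(a / denom)


# ----------------------------------------------------------------------
# DIND
@dataclass
class DindResult:
    """DIND at one focal SNP: iπ_A / iπ_D over a fixed flank window."""

    focal_index: int
    focal_id: str
    position: int
    daf: float
    i_pi_a: float
    i_pi_d: float
    dind: float
    sentinel_flag: bool
    n_flank_used: int
    computed: bool

    @classmethod
    def not_computed(cls, focal_index: int, focal_id: str, position: int,
                     daf: float) -> "DindResult":
        return cls(focal_index, focal_id, position, daf, float("nan"),
                   float("nan"), float("nan"), False, 0, False)


def _select_flanks(
    candidates_below: np.ndarray,
    candidates_above: np.ndarray,
    flank_total: int,
) -> np.ndarray | None:
    """Nearest ``flank_total`` flanking sites, balanced when possible.

    Takes up to flank_total//2 from each side and borrows from the longer
    side otherwise; None when fewer than flank_total exist overall.
    """
    half = flank_total // 2
    n_below, n_above = candidates_below.size, candidates_above.size
    if n_below + n_above < flank_total:
        return None
    take_below = min(half, n_below)
    take_above = min(flank_total - take_below, n_above)
    take_below = flank_total - take_above
    below = candidates_below[-take_below:] if take_below else candidates_below[:0]
    above = candidates_above[:take_above]
    return np.concatenate([below, above])


def dind(
    haps: HaplotypeMatrix,
    focal_index: int,
    flank_total: int = 40,
    population: str | None = None,
    max_missing: float = 0.1,
) -> DindResult:
    """DIND test at ``focal_index`` using a constant flank window.

    The flank consists of the nearest ``flank_total`` polymorphic sites
    (balanced up-/downstream when possible), the focal site excluded; sites
    with more than ``max_missing`` missing haplotypes are not eligible.
    Results are flagged sentinel when iπ_D = 0 and must be finalized at the
    dataset level with :func:`finalize_dind_sentinels`.  Results are marked
    not-computed when the flank cannot be filled or an allele class has
    fewer than 2 haplotypes.
    """
    if not haps.polarized[focal_index]:
        raise ValueError("focal site must be polarized")
    rows = _rows(haps, population)
    focal_id = f"snp_{haps.positions[focal_index]}"
    pos = int(haps.positions[focal_index])
    focal = haps.alleles[rows, focal_index]
    keep = focal != MISSING
    rows = rows[keep]
    focal = focal[keep]
    n = focal.size
    daf = float((focal == 1).mean()) if n else float("nan")
    der = rows[focal == 1]
    anc = rows[focal == 0]
    if der.size < 2 or anc.size < 2:
        return DindResult.not_computed(focal_index, focal_id, pos, daf)
    seg = haps.segregating(rows)
    miss_frac = 1.0 - haps.called_counts(rows) / rows.size
    eligible = seg & (miss_frac <= max_missing)
    eligible[focal_index] = False
    cand = np.nonzero(eligible)[0]
    flanks = _select_flanks(
        cand[cand < focal_index], cand[cand > focal_index], flank_total
    )
    if flanks is None:
        return DindResult.not_computed(focal_index, focal_id, pos, daf)
    i_pi_a = _pairwise_diff_total(haps.alleles[np.ix_(anc, flanks)])
    i_pi_d = _pairwise_diff_total(haps.alleles[np.ix_(der, flanks)])
    if i_pi_d == 0.0:
        return DindResult(focal_index, focal_id, pos, daf, i_pi_a, i_pi_d,
                          float("nan"), True, flanks.size, True)
    return DindResult(focal_index, focal_id, pos, daf, i_pi_a, i_pi_d,
                      float(i_pi_a / i_pi_d), False, flanks.size, True)


def finalize_dind_sentinels(
    results: Sequence[DindResult], offset: float = 20.0
) -> list[DindResult]:
    """Assign dataset max finite DIND + ``offset`` to sentinel results.

    The maximum is taken once over the whole dataset, after all finite
    values are known.  Raises if every computed result is a sentinel.
    """
    finite = [
        r.dind for r in results if r.computed and not r.sentinel_flag
        and np.isfinite(r.dind)
    ]
    sentinels = [r for r in results if r.computed and r.sentinel_flag]
    if sentinels and not finite:
        raise ValueError("all DIND results are sentinels; no finite maximum")
    if not sentinels:
        return list(results)
    value = max(finite) + offset
    return [
        replace(r, dind=value) if (r.computed and r.sentinel_flag) else r
        for r in results
    ]


# ----------------------------------------------------------------------
# linkage disequilibrium
def ld_r2(col_i: np.ndarray, col_j: np.ndarray) -> float:
    """r^2 between two haplotype columns over non-missing haplotypes.

    NaN when either site is monomorphic in the jointly called set.
    """
    x = np.asarray(col_i)
    y = np.asarray(col_j)
    ok = (x != MISSING) & (y != MISSING)
    x = x[ok].astype(float)
    y = y[ok].astype(float)
    if x.size == 0:
        return float("nan")
    pa = x.mean()
    pb = y.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    pab = float(np.mean(x * y))
    d = pab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))
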