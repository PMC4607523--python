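"""Independent brute-force reference implementations used only by tests.

Everything here is written from the definitions (double loops, explicit
spectra, formula-by-formula evaluation) and deliberately shares no code
with the package.
"""

from __future__ import annotations

import math

import numpy as np


def pi_bruteforce(mat: np.ndarray) -> float:
    """Mean pairwise difference via an explicit double loop (no missing)."""
    n = mat.shape[0]
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int(np.sum(mat[i] != mat[j]))
    return 2.0 * total / (n * (n - 1))


def watterson_bruteforce(mat: np.ndarray) -> float:
    n = mat.shape[0]
    s = 0
    for col in mat.T:
        if 0 < col.sum() < n:
            s += 1
    a_n = sum(1.0 / i for i in range(1, n))
    return s / a_n


def tajimas_d_bruteforce(mat: np.ndarray) -> float:
    """Constant-by-constant evaluation of Tajima's D."""
    n = mat.shape[0]
    s = sum(1 for col in mat.T if 0 < col.sum() < n)
    if s == 0:
        return float("nan")
    pi = pi_bruteforce(mat)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def sfs_spectrum(mat: np.ndarray) -> dict[int, int]:
    """xi_i: number of sites with derived allele in i copies (segregating)."""
    n = mat.shape[0]
    xi: dict[int, int] = {}
    for col in mat.T:
        c = int(col.sum())
        if 0 < c < n:
            xi[c] = xi.get(c, 0) + 1
    return xi


def dh_numerator_bruteforce(mat: np.ndarray) -> float:
    """pi - theta_L computed from the explicit frequency spectrum."""
    n = mat.shape[0]
    xi = sfs_spectrum(mat)
    pi = sum(
        2.0 * i * (n - i) / (n * (n - 1)) * cnt for i, cnt in xi.items()
    )
    theta_l = sum(i * cnt for i, cnt in xi.items()) / (n - 1)
    return pi - theta_l


def dh_bruteforce(mat: np.ndarray) -> float:
    """Full normalized Fay-Wu H from the spectrum and variance constants."""
    n = mat.shape[0]
    xi = sfs_spectrum(mat)
    s = sum(xi.values())
    if s == 0:
        return float("nan")
    an = sum(1.0 / i for i in range(1, n))
    bn = sum(1.0 / i**2 for i in range(1, n))
    bn1 = bn + 1.0 / n**2
    theta_w = s / an
    theta_sq = s * (s - 1) / (an * an + bn)
    var = (n - 2) / (6 * (n - 1)) * theta_w + (
        18 * n * n * (3 * n + 2) * bn1
        - (88 * n**3 + 9 * n * n - 13 * n + 6)
    ) / (9 * n * (n - 1) ** 2) * theta_sq
    return dh_numerator_bruteforce(mat) / math.sqrt(var)


def wc_fst_bruteforce(
    n_a: int, p_a: float, h_a: float, n_b: int, p_b: float, h_b: float
) -> float:
    """Two-population Weir-Cockerham a, b, c written out term by term."""
    r = 2
    nbar = (n_a + n_b) / 2
    nc = (r * nbar - (n_a**2 + n_b**2) / (r * nbar)) / (r - 1)
    pbar = (n_a * p_a + n_b * p_b) / (r * nbar)
    s2 = (
        n_a * (p_a - pbar) ** 2 + n_b * (p_b - pbar) ** 2
    ) / ((r - 1) * nbar)
    hbar = (n_a * h_a + n_b * h_b) / (r * nbar)
    a = (nbar / nc) * (
        s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - (r - 1) / r * s2
        - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    if a + b + c == 0:
        return float("nan")
    return a / (a + b + c)


def dind_bruteforce(
    mat: np.ndarray, focal: int, flank_cols: list[int]
) -> tuple[float, float]:
    """(i_pi_A, i_pi_D) via within-class pairwise double loops."""

    def mean_pairwise(rows: list[int]) -> float:
        total = 0
        npairs = 0
        for x in range(len(rows)):
            for y in range(x + 1, len(rows)):
                for c in flank_cols:
                    if mat[rows[x], c] != mat[rows[y], c]:
                        total += 1
                npairs += 1
        return total / npairs

    anc = [i for i in range(mat.shape[0]) if mat[i, focal] == 0]
    der = [i for i in range(mat.shape[0]) if mat[i, focal] == 1]
    return mean_pairwise(anc), mean_pairwise(der)


def r2_bruteforce(x: np.ndarray, y: np.ndarray) -> float:
    """r^2 by direct haplotype-count enumeration."""
    n = len(x)
    n_ab = sum(1 for i in range(n) if x[i] == 1 and y[i] == 1)
    p_a = sum(x) / n
    p_b = sum(y) / n
    d = n_ab / n - p_a * p_b
    return d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))


def percentile_bruteforce(values, q: float) -> float:
    """Sorted-index percentile: value at 1-based rank ceil(q/100 * N)."""
    vals = sorted(values)
    k = max(int(math.ceil(q / 100 * len(vals))) - 1, 0)
    return vals[k]


def rank_bruteforce(values, stat: float) -> float:
    """Midpoint-corrected fraction of values <= stat."""
    less = sum(1 for v in values if v < stat)
    eq = sum(1 for v in values if v == stat)
    return (less + 0.5 * eq) / len(values)
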