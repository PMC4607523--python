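"""Phased haplotype matrix: the substrate of every statistic in the scan.

Alleles are coded 0 (ancestral, when the site is polarized; otherwise
reference), 1 (derived/alternate) and -1 (missing).  Each diploid sample
contributes exactly two consecutive haplotype rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

MISSING = -1


@dataclass
class HaplotypeMatrix:
    """Phased binary allele matrix (haplotypes x sites).

    Parameters
    ----------
    alleles:
        int8 array of shape ``(n_haplotypes, n_sites)`` over {0, 1, -1}.
    positions:
        strictly increasing 1-based physical positions, one per column.
    samples:
        diploid sample labels; ``len(samples) * 2 == n_haplotypes``.
        Haplotypes ``2*i`` and ``2*i + 1`` belong to ``samples[i]``.
    populations:
        population label per sample (parallel to ``samples``).
    polarized:
        per-site flag, True when allele 0 is a confirmed ancestral state.
    ref, alt:
        optional per-site nucleotide labels for allele 0 / allele 1.
    """

    alleles: np.ndarray
    positions: np.ndarray
    samples: list[str]
    populations: list[str]
    polarized: np.ndarray | None = None
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape[1] != self.positions.shape[0]:
            raise ValueError("column count must equal number of positions")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.positions.size and self.positions[0] < 1:
            raise ValueError("positions are 1-based (must be >= 1)")
        if len(self.samples) * 2 != self.alleles.shape[0]:
            raise ValueError(
                "each diploid sample contributes exactly 2 haplotypes"
            )
        if len(self.populations) != len(self.samples):
            raise ValueError("populations must be given per sample")
        if self.polarized is None:
            self.polarized = np.zeros(self.n_sites, dtype=bool)
        else:
            self.polarized = np.asarray(self.polarized, dtype=bool)
            if self.polarized.shape[0] != self.n_sites:
                raise ValueError("polarized flags must be per site")
        if self.ref is None:
            self.ref = np.full(self.n_sites, "A", dtype="U1")
        else:
            self.ref = np.asarray(self.ref, dtype="U1")
        if self.alt is None:
            self.alt = np.full(self.n_sites, "G", dtype="U1")
        else:
            self.alt = np.asarray(self.alt, dtype="U1")

    # ------------------------------------------------------------------
    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def sample_map(self) -> list[tuple[str, str]]:
        """(sample, population) for every haplotype row."""
        out = []
        for s, p in zip(self.samples, self.populations):
            out.append((s, p))
            out.append((s, p))
        return out

    @property
    def population_labels(self) -> list[str]:
        """Distinct population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    # ------------------------------------------------------------------
    def haplotype_indices(self, population: str | None = None) -> np.ndarray:
        """Row indices of haplotypes belonging to ``population`` (or all)."""
        if population is None:
            return np.arange(self.n_haplotypes)
        idx = [
            j
            for i, p in enumerate(self.populations)
            if p == population
            for j in (2 * i, 2 * i + 1)
        ]
        if not idx:
            raise KeyError(f"no samples in population {population!r}")
        return np.asarray(idx)

    def for_population(self, population: str) -> "HaplotypeMatrix":
        """Sub-matrix restricted to one population's haplotypes."""
        keep = [i for i, p in enumerate(self.populations) if p == population]
        if not keep:
            raise KeyError(f"no samples in population {population!r}")
        rows = self.haplotype_indices(population)
        return replace(
            self,
            alleles=self.alleles[rows],
            samples=[self.samples[i] for i in keep],
            populations=[self.populations[i] for i in keep],
        )

    def take_sites(self, index: Sequence[int] | np.ndarray) -> "HaplotypeMatrix":
        index = np.asarray(index, dtype=np.int64)
        return replace(
            self,
            alleles=self.alleles[:, index],
            positions=self.positions[index],
            polarized=self.polarized[index],
            ref=self.ref[index],
            alt=self.alt[index],
        )

    # ------------------------------------------------------------------
    def derived_counts(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Per-site count of allele 1 among non-missing entries of ``rows``."""
        sub = self.alleles if rows is None else self.alleles[rows]
        return (sub == 1).sum(axis=0)

    def called_counts(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Per-site count of non-missing entries of ``rows``."""
        sub = self.alleles if rows is None else self.alleles[rows]
        return (sub != MISSING).sum(axis=0)

    def segregating(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Boolean per-site flag: polymorphic among the selected haplotypes."""
        d = self.derived_counts(rows)
        c = self.called_counts(rows)
        return (d > 0) & (d < c)

    def derived_frequency(self, rows: np.ndarray | None = None) -> np.ndarray:
        d = self.derived_counts(rows).astype(float)
        c = self.called_counts(rows).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(c > 0, d / c, np.nan)


def concatenate_samples(matrices: Iterable[HaplotypeMatrix]) -> HaplotypeMatrix:
    """Stack matrices that share positions (e.g. per-population splits)."""
    mats = list(matrices)
    first = mats[0]
    for m in mats[1:]:
        if not np.array_equal(m.positions, first.positions):
            raise ValueError("matrices must share identical positions")
    return replace(
        first,
        alleles=np.vstack([m.alleles for m in mats]),
        samples=[s for m in mats for s in m.samples],
        populations=[p for m in mats for p in m.populations],
    )
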