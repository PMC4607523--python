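"""Per-gene scan orchestration, selection-target classification and the
gene-set resampling significance test.

The classifier applies three rules to a gene's evidence bundle:

R1  in one population, significant signals in at least two distinct
    feature families — A: gene-level diversity/SFS statistics at or below
    the low control percentile; B: a per-SNP FST rank at or above the
    outlier threshold in a comparison involving that population; C: a
    per-SNP DIND rank at or above the outlier threshold in that
    population;
R2  one SNP whose DIND rank is significant in every analyzed population
    (requires at least three populations);
R3  one SNP with a DIND rank above the extreme single-variant threshold.

DH below its control fifth percentile is recorded as confirmatory only and
never triggers a flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import (
    SENTINEL,
    EmpiricalDistribution,
    build_binned_calibration,
    dh_window_threshold,
    dind_testable_bins,
    rank_value,
)
from .config import PipelineConfig
from .matrix import HaplotypeMatrix
from .stats import (
    DindResult,
    WindowStat,
    dind,
    finalize_dind_sentinels,
    nucleotide_diversity,
    site_counts,
    sliding_dh,
    tajimas_d,
    watterson_theta,
    weir_cockerham_fst,
)
from .synthetic import ControlSet

__all__ = [
    "GeneRegion",
    "define_region",
    "SnpEvidence",
    "GeneScanResult",
    "Classification",
    "Calibrations",
    "build_calibrations",
    "scan_gene",
    "classify_targets",
    "gene_positive_for_resampling",
    "resampling_pvalue",
    "export_candidate_table",
]

GENE_STATS = ("pi", "theta_w", "tajimas_d")


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class GeneRegion:
    """Gene coordinates plus the scanned flanked interval (1-based closed)."""

    label: str
    chrom: str
    gene_start: int
    gene_end: int
    scan_start: int
    scan_end: int


def define_region(
    label: str,
    chrom: str,
    gene_start: int,
    gene_end: int,
    flank: int = 25_000,
) -> GeneRegion:
    """Gene region with a symmetric flank, clipped at position 1."""
    if gene_end < gene_start:
        raise ValueError("gene_end must be >= gene_start")
    return GeneRegion(
        label=label,
        chrom=chrom,
        gene_start=gene_start,
        gene_end=gene_end,
        scan_start=max(1, gene_start - flank),
        scan_end=gene_end + flank,
    )


# ----------------------------------------------------------------------
@dataclass
class SnpEvidence:
    """Per-SNP ranks and annotations feeding the classifier."""

    snp_id: str
    position: int = 0
    derived_allele: str = ""
    daf: dict[str, float] = field(default_factory=dict)
    dind_value: dict[str, float] = field(default_factory=dict)
    dind_sentinel: dict[str, bool] = field(default_factory=dict)
    dind_rank: dict[str, float] = field(default_factory=dict)
    dind_sim_p: dict[str, float] = field(default_factory=dict)
    fst_value: dict[tuple[str, str], float] = field(default_factory=dict)
    fst_rank: dict[tuple[str, str], float] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "snp_id": self.snp_id,
            "position": self.position,
            "derived_allele": self.derived_allele,
            "daf": self.daf,
            "dind_value": self.dind_value,
            "dind_sentinel": self.dind_sentinel,
            "dind_rank": self.dind_rank,
            "dind_sim_p": self.dind_sim_p,
            "fst_value": {"|".join(k): v for k, v in self.fst_value.items()},
            "fst_rank": {"|".join(k): v for k, v in self.fst_rank.items()},
            "notes": self.notes,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SnpEvidence":
        return cls(
            snp_id=d["snp_id"],
            position=d.get("position", 0),
            derived_allele=d.get("derived_allele", ""),
            daf=dict(d.get("daf", {})),
            dind_value=dict(d.get("dind_value", {})),
            dind_sentinel=dict(d.get("dind_sentinel", {})),
            dind_rank=dict(d.get("dind_rank", {})),
            dind_sim_p=dict(d.get("dind_sim_p", {})),
            fst_value={
                tuple(k.split("|")): v
                for k, v in d.get("fst_value", {}).items()
            },
            fst_rank={
                tuple(k.split("|")): v
                for k, v in d.get("fst_rank", {}).items()
            },
            notes=list(d.get("notes", [])),
        )


@dataclass
class Classification:
    flagged: bool
    rules: list[str]
    populations: list[str]
    supporting_snps: list[str]

    def to_dict(self) -> dict:
        return {
            "flagged": self.flagged,
            "rules": self.rules,
            "populations": self.populations,
            "supporting_snps": self.supporting_snps,
        }


@dataclass
class GeneScanResult:
    """Evidence bundle for one gene: stats, ranks, windows, classification."""

    gene: str
    populations: list[str]
    gene_stats: dict[str, dict[str, float]] = field(default_factory=dict)
    gene_stat_ranks: dict[str, dict[str, float]] = field(default_factory=dict)
    snps: list[SnpEvidence] = field(default_factory=list)
    dh_windows: dict[str, list[WindowStat]] = field(default_factory=dict)
    dh_threshold: dict[str, float] = field(default_factory=dict)
    classification: Classification | None = None

    def dh_below_threshold(self, population: str) -> list[WindowStat]:
        """Confirmatory-only: defined windows under the control percentile."""
        thr = self.dh_threshold.get(population)
        if thr is None:
            return []
        return [
            w for w in self.dh_windows.get(population, [])
            if w.defined and w.value <= thr
        ]

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "populations": self.populations,
            "gene_stats": self.gene_stats,
            "gene_stat_ranks": self.gene_stat_ranks,
            "snps": [s.to_dict() for s in self.snps],
            "dh_windows": {
                p: [
                    [w.start, w.end, w.n_snps, w.value, w.defined]
                    for w in ws
                ]
                for p, ws in self.dh_windows.items()
            },
            "dh_threshold": self.dh_threshold,
            "classification": (
                self.classification.to_dict() if self.classification else None
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneScanResult":
        res = cls(
            gene=d["gene"],
            populations=list(d["populations"]),
            gene_stats=d.get("gene_stats", {}),
            gene_stat_ranks=d.get("gene_stat_ranks", {}),
            snps=[SnpEvidence.from_dict(s) for s in d.get("snps", [])],
            dh_windows={
                p: [WindowStat(*w) for w in ws]
                for p, ws in d.get("dh_windows", {}).items()
            },
            dh_threshold=d.get("dh_threshold", {}),
        )
        c = d.get("classification")
        if c:
            res.classification = Classification(
                c["flagged"], c["rules"], c["populations"],
                c["supporting_snps"],
            )
        return res


# ----------------------------------------------------------------------
@dataclass
class Calibrations:
    """All empirical nulls derived from the control set."""

    gene_level: dict[str, dict[str, EmpiricalDistribution]]
    fst: dict[tuple[str, str], EmpiricalDistribution]
    dind: dict[str, EmpiricalDistribution]
    dind_testable: dict[str, np.ndarray]
    dh_threshold: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "gene_level": {
                p: {s: d.to_dict() for s, d in stats.items()}
                for p, stats in self.gene_level.items()
            },
            "fst": {
                "|".join(k): d.to_dict() for k, d in self.fst.items()
            },
            "dind": {p: d.to_dict() for p, d in self.dind.items()},
            "dind_testable": {
                p: [bool(x) for x in f] for p, f in self.dind_testable.items()
            },
            "dh_threshold": self.dh_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Calibrations":
        return cls(
            gene_level={
                p: {
                    s: EmpiricalDistribution.from_dict(v)
                    for s, v in stats.items()
                }
                for p, stats in d["gene_level"].items()
            },
            fst={
                tuple(k.split("|")): EmpiricalDistribution.from_dict(v)
                for k, v in d["fst"].items()
            },
            dind={
                p: EmpiricalDistribution.from_dict(v)
                for p, v in d["dind"].items()
            },
            dind_testable={
                p: np.asarray(f, dtype=bool)
                for p, f in d["dind_testable"].items()
            },
            dh_threshold=dict(d["dh_threshold"]),
        )


def _gene_level_stats(
    matrix: HaplotypeMatrix, population: str, length: int
) -> dict[str, float]:
    """Per-bp pi and theta_W plus Tajima's D for one population."""
    return {
        "pi": nucleotide_diversity(matrix, population=population) / length,
        "theta_w": watterson_theta(matrix, population=population) / length,
        "tajimas_d": tajimas_d(matrix, population=population),
    }


def _pop_pairs(populations: Sequence[str]) -> list[tuple[str, str]]:
    return list(itertools.combinations(populations, 2))


def _pooled_maf(
    matrix: HaplotypeMatrix, site: int, pair: tuple[str, str]
) -> float:
    rows = np.concatenate(
        [matrix.haplotype_indices(p) for p in pair]
    )
    col = matrix.alleles[rows, site]
    col = col[col >= 0]
    if col.size == 0:
        return float("nan")
    p = float(col.mean())
    return min(p, 1.0 - p)


def _dind_all_sites(
    matrix: HaplotypeMatrix, population: str, config: PipelineConfig
) -> list[DindResult]:
    out = []
    rows = matrix.haplotype_indices(population)
    seg = matrix.segregating(rows)
    for j in np.nonzero(seg & matrix.polarized)[0]:
        out.append(
            dind(
                matrix,
                int(j),
                flank_total=config.dind_flank_total,
                population=population,
                max_missing=config.dind_max_missing,
            )
        )
    return out


def build_calibrations(
    control_set: ControlSet, config: PipelineConfig
) -> Calibrations:
    """Build every empirical null from the control gene set.

    Gene-level pi/theta_W are per-bp densities so regions of different
    length remain comparable; FST is binned by the MAF pooled over the two
    compared populations; DIND sentinels enter the calibration as +inf.
    """
    pops = [
        p for p in config.populations
        if p in control_set.genes[0].matrix.population_labels
    ]
    if not pops:
        pops = control_set.genes[0].matrix.population_labels
    pairs = _pop_pairs(pops)

    gene_level_vals: dict[str, dict[str, list]] = {
        p: {s: [] for s in GENE_STATS} for p in pops
    }
    fst_vals: dict[tuple[str, str], list] = {pr: [] for pr in pairs}
    dind_vals: dict[str, list] = {p: [] for p in pops}
    dh_vals: dict[str, list] = {p: [] for p in pops}

    for gene in control_set:
        m = gene.matrix
        length = gene.end - gene.start + 1
        for p in pops:
            stats = _gene_level_stats(m, p, length)
            for s in GENE_STATS:
                gene_level_vals[p][s].append((0.0, stats[s]))
            for r in _dind_all_sites(m, p, config):
                if not r.computed:
                    continue
                v = SENTINEL if r.sentinel_flag else r.dind
                dind_vals[p].append((r.daf, v))
            for w in sliding_dh(
                m, gene.start, gene.end,
                window=config.dh_window, step=config.dh_step,
                min_snps=config.dh_min_snps, population=p,
            ):
                if w.defined:
                    dh_vals[p].append(w.value)
        for pair in pairs:
            rows = np.concatenate(
                [m.haplotype_indices(p) for p in pair]
            )
            seg = np.nonzero(m.segregating(rows))[0]
            for j in seg:
                f = weir_cockerham_fst(
                    site_counts(m, int(j), pair[0]),
                    site_counts(m, int(j), pair[1]),
                )
                if np.isnan(f):
                    continue
                fst_vals[pair].append((_pooled_maf(m, int(j), pair), f))

    gene_level = {
        p: {
            s: build_binned_calibration(v, bin_variable="none", n_bins=1)
            for s, v in stats.items()
        }
        for p, stats in gene_level_vals.items()
    }
    fst = {
        pr: build_binned_calibration(
            v, bin_variable="maf", n_bins=config.maf_bins
        )
        for pr, v in fst_vals.items()
        if v
    }
    dind_cal = {
        p: build_binned_calibration(
            v, bin_variable="daf", n_bins=config.daf_bins
        )
        for p, v in dind_vals.items()
        if v
    }
    testable = {
        p: dind_testable_bins(d, min_count=config.min_bin_count)
        for p, d in dind_cal.items()
    }
    dh_thr = {
        p: dh_window_threshold(v, percentile=config.dh_percentile)
        for p, v in dh_vals.items()
        if len(v) >= 20
    }
    return Calibrations(
        gene_level=gene_level,
        fst=fst,
        dind=dind_cal,
        dind_testable=testable,
        dh_threshold=dh_thr,
    )


# ----------------------------------------------------------------------
def scan_gene(
    matrix: HaplotypeMatrix,
    region: GeneRegion,
    calibrations: Calibrations,
    config: PipelineConfig,
) -> GeneScanResult:
    """Compute all statistics, ranks and windows for one gene region."""
    pops = [p for p in config.populations if p in matrix.population_labels]
    if not pops:
        pops = matrix.population_labels
    if not calibrations.gene_level:
        raise ValueError("missing calibrations")
    length = region.scan_end - region.scan_start + 1
    result = GeneScanResult(gene=region.label, populations=pops)

    # gene-level statistics and low-tail ranks
    for p in pops:
        stats = _gene_level_stats(matrix, p, length)
        result.gene_stats[p] = stats
        ranks = {}
        for s in GENE_STATS:
            dist = calibrations.gene_level[p][s]
            v = stats[s]
            ranks[s] = (
                rank_value(dist, 0.0, v) if np.isfinite(v) else None
            )
        result.gene_stat_ranks[p] = ranks

    # per-SNP evidence
    evidence: dict[int, SnpEvidence] = {}

    def ev(j: int) -> SnpEvidence:
        if j not in evidence:
            pos = int(matrix.positions[j])
            evidence[j] = SnpEvidence(
                snp_id=f"{region.label}_snp_{pos}",
                position=pos,
                derived_allele=str(matrix.alt[j]),
            )
        return evidence[j]

    for p in pops:
        results = _dind_all_sites(matrix, p, config)
        computed = [r for r in results if r.computed]
        finite = [r.dind for r in computed if not r.sentinel_flag]
        for r in computed:
            e = ev(r.focal_index)
            e.daf[p] = r.daf
            e.dind_sentinel[p] = r.sentinel_flag
            if r.sentinel_flag:
                e.dind_value[p] = (
                    max(finite) + config.dind_sentinel_offset
                    if finite else float("nan")
                )
            else:
                e.dind_value[p] = r.dind
            rank = rank_value(
                calibrations.dind[p],
                r.daf,
                SENTINEL if r.sentinel_flag else r.dind,
                testable=calibrations.dind_testable[p],
            )
            if rank is not None:
                e.dind_rank[p] = rank

    for pair in _pop_pairs(pops):
        if pair not in calibrations.fst:
            continue
        rows = np.concatenate([matrix.haplotype_indices(p) for p in pair])
        for j in np.nonzero(matrix.segregating(rows))[0]:
            f = weir_cockerham_fst(
                site_counts(matrix, int(j), pair[0]),
                site_counts(matrix, int(j), pair[1]),
            )
            if np.isnan(f):
                continue
            e = ev(int(j))
            e.fst_value[pair] = f
            rank = rank_value(
                calibrations.fst[pair], _pooled_maf(matrix, int(j), pair), f
            )
            if rank is not None:
                e.fst_rank[pair] = rank

    result.snps = [evidence[j] for j in sorted(evidence)]

    # DH windows (confirmatory)
    for p in pops:
        result.dh_windows[p] = sliding_dh(
            matrix, region.scan_start, region.scan_end,
            window=config.dh_window, step=config.dh_step,
            min_snps=config.dh_min_snps, population=p,
        )
        if p in calibrations.dh_threshold:
            result.dh_threshold[p] = calibrations.dh_threshold[p]

    return result


# ----------------------------------------------------------------------
def classify_targets(
    result: GeneScanResult, config: PipelineConfig | None = None
) -> Classification:
    """Apply the R1/R2/R3 selection-target decision rules (module docstring)."""
    if config is None:
        config = PipelineConfig()
    low_pct = config.gene_level_percentile / 100.0
    outlier = config.rank_outlier
    extreme = config.rank_extreme
    pops = result.populations

    rules: list[str] = []
    hit_pops: set[str] = set()
    support: set[str] = set()

    for p in pops:
        families: set[str] = set()
        fam_snps: set[str] = set()
        ranks = result.gene_stat_ranks.get(p, {})
        if any(
            r is not None and r <= low_pct for r in ranks.values()
        ):
            families.add("A")
        for s in result.snps:
            if any(
                p in pair and r >= outlier
                for pair, r in s.fst_rank.items()
            ):
                families.add("B")
                fam_snps.add(s.snp_id)
            if s.dind_rank.get(p, -1.0) >= outlier:
                families.add("C")
                fam_snps.add(s.snp_id)
        if len(families) >= 2:
            rules.append(f"R1:{p}:{'+'.join(sorted(families))}")
            hit_pops.add(p)
            support |= fam_snps

    if len(pops) >= 3:
        for s in result.snps:
            if all(s.dind_rank.get(p, -1.0) >= outlier for p in pops):
                rules.append(f"R2:{s.snp_id}")
                hit_pops.update(pops)
                support.add(s.snp_id)

    for s in result.snps:
        for p, r in s.dind_rank.items():
            if r > extreme:
                rules.append(f"R3:{s.snp_id}:{p}")
                hit_pops.add(p)
                support.add(s.snp_id)

    cls = Classification(
        flagged=bool(rules),
        rules=sorted(set(rules)),
        populations=sorted(hit_pops),
        supporting_snps=sorted(support),
    )
    result.classification = cls
    return cls


# ----------------------------------------------------------------------
def gene_positive_for_resampling(
    result: GeneScanResult, config: PipelineConfig | None = None
) -> bool:
    """Per-sample gene criterion of the resampling test.

    A gene counts as positively selected when it carries at least one
    variant with a significant DIND test in three populations, or at least
    two variants that are outliers for both DIND and FST in the same
    population.
    """
    if config is None:
        config = PipelineConfig()
    outlier = config.rank_outlier
    pops = result.populations
    if len(pops) >= 3:
        for s in result.snps:
            if sum(s.dind_rank.get(p, -1.0) >= outlier for p in pops) >= 3:
                return True
    for p in pops:
        joint = 0
        for s in result.snps:
            if s.dind_rank.get(p, -1.0) >= outlier and any(
                p in pair and r >= outlier for pair, r in s.fst_rank.items()
            ):
                joint += 1
        if joint >= 2:
            return True
    return False


def resampling_pvalue(
    gene_flags: Sequence[bool],
    observed_count: int,
    set_size: int = 8,
    n_samples: int = 100,
    seed: int | None = None,
    exhaustive: bool = False,
) -> float:
    """Gene-set resampling significance.

    Draws ``n_samples`` sets of ``set_size`` genes without replacement from
    the control universe and returns the fraction of samples whose
    positive-gene count is >= ``observed_count``.  In exhaustive mode all
    subsets are enumerated and the exact probability is returned.
    """
    flags = np.asarray(gene_flags, dtype=bool)
    n = flags.size
    if set_size > n:
        raise ValueError("set_size exceeds number of control genes")
    if observed_count <= 0:
        return 1.0
    if exhaustive:
        hits = sum(
            1
            for subset in itertools.combinations(range(n), set_size)
            if int(flags[list(subset)].sum()) >= observed_count
        )
        return hits / comb(n, set_size)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    hits = 0
    for _ in range(n_samples):
        pick = rng.choice(n, size=set_size, replace=False)
        if int(flags[pick].sum()) >= observed_count:
            hits += 1
    return hits / n_samples


# ----------------------------------------------------------------------
def export_candidate_table(
    results: Sequence[GeneScanResult],
    populations: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One row per supporting variant of each flagged gene.

    Columns carry the gene, SNP id, derived allele, per-population DAF and
    DIND ranks / simulation P values, per-comparison FST ranks and notes;
    the frame round-trips losslessly through TSV.
    """
    if populations is None:
        pool: list[str] = []
        for r in results:
            for p in r.populations:
                if p not in pool:
                    pool.append(p)
        populations = pool
    pairs: list[tuple[str, str]] = []
    for r in results:
        for s in r.snps:
            for pr in s.fst_rank:
                if pr not in pairs:
                    pairs.append(pr)
    cols = ["gene", "snp_id", "derived_allele"]
    cols += [f"daf_{p}" for p in populations]
    cols += [f"dind_rank_{p}" for p in populations]
    cols += [f"dind_sim_p_{p}" for p in populations]
    cols += [f"fst_rank_{a}_{b}" for a, b in pairs]
    cols += ["notes"]
    rows = []
    for r in results:
        if r.classification is None or not r.classification.flagged:
            continue
        keep = set(r.classification.supporting_snps)
        for s in r.snps:
            if s.snp_id not in keep:
                continue
            row: dict = {
                "gene": r.gene,
                "snp_id": s.snp_id,
                "derived_allele": s.derived_allele,
                "notes": ";".join(s.notes),
            }
            for p in populations:
                row[f"daf_{p}"] = s.daf.get(p, np.nan)
                row[f"dind_rank_{p}"] = s.dind_rank.get(p, np.nan)
                row[f"dind_sim_p_{p}"] = s.dind_sim_p.get(p, np.nan)
            for pr in pairs:
                row[f"fst_rank_{pr[0]}_{pr[1]}"] = s.fst_rank.get(pr, np.nan)
            rows.append(row)
    return pd.DataFrame(rows, columns=cols)
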