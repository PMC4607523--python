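"""Synthetic input generation: neutral and sweep haplotype datasets,
control gene sets, outgroup alleles and low-coverage ancient genotypes.

The neutral genealogy engine is delegated to msprime behind the module
contract (infinite-sites binary mutations, allele 0 = true ancestral);
everything downstream — the sweep conditioning, control sets, outgroup
misassignment and the ancient coverage model — is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import msprime
import numpy as np
import pandas as pd

from .matrix import MISSING, HaplotypeMatrix

__all__ = [
    "ConfigurationError",
    "SimulationParams",
    "DemographyModel",
    "SweepModel",
    "SweepResult",
    "ControlGene",
    "ControlSet",
    "simulate_neutral",
    "simulate_sweep",
    "generate_control_set",
    "generate_outgroups",
    "generate_ancient",
]

_NUCS = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    """Inconsistent simulation configuration (e.g. populations never merge)."""


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one simulated region."""

    n_haplotypes_per_pop: int = 60
    region_length: int = 20_000
    mutation_rate: float = 1.2e-8
    recombination_rate: float = 1.0e-8
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_haplotypes_per_pop < 2 or self.n_haplotypes_per_pop % 2:
            raise ConfigurationError(
                "n_haplotypes_per_pop must be even and >= 2 (diploid pairing)"
            )
        if self.region_length < 1:
            raise ConfigurationError("region_length must be >= 1")
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ConfigurationError("rates must be >= 0")


@dataclass(frozen=True)
class Split:
    """Population split (backward in time: derived labels merge into ancestral)."""

    time: float
    derived: tuple[str, ...]
    ancestral: str


@dataclass
class DemographyModel:
    """Piecewise-constant multi-population demography.

    ``epochs`` maps every population label (sampled or ancestral) to a list
    of (start_time_generations_ago, effective_size) with strictly
    increasing times starting at 0.  ``splits`` must connect all sampled
    populations to a single root.
    """

    populations: list[str]
    epochs: dict[str, list[tuple[float, float]]]
    splits: list[Split] = field(default_factory=list)
    bottlenecks: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for pop, eps in self.epochs.items():
            times = [t for t, _ in eps]
            if times != sorted(set(times)):
                raise ConfigurationError(
                    f"epoch times for {pop!r} must be strictly increasing"
                )
            if not eps or eps[0][0] != 0:
                raise ConfigurationError(
                    f"first epoch of {pop!r} must start at time 0"
                )
            if any(size <= 0 for _, size in eps):
                raise ConfigurationError("population sizes must be > 0")
        for pop in self.populations:
            if pop not in self.epochs:
                raise ConfigurationError(f"no epochs for population {pop!r}")
        self._check_single_root()

    def _check_single_root(self) -> None:
        """All sampled populations must reach a common ancestor."""
        parent = {}
        for sp in self.splits:
            for d in sp.derived:
                parent[d] = sp.ancestral
        def root(p: str) -> str:
            seen = set()
            while p in parent:
                if p in seen:
                    raise ConfigurationError("cyclic split structure")
                seen.add(p)
                p = parent[p]
            return p
        roots = {root(p) for p in self.populations}
        if len(roots) > 1:
            raise ConfigurationError(
                f"populations never coalesce: multiple roots {sorted(roots)}"
            )

    # ------------------------------------------------------------------
    @classmethod
    def constant_size(cls, ne: float, label: str = "pop0") -> "DemographyModel":
        return cls(populations=[label], epochs={label: [(0.0, ne)]})

    @classmethod
    def default_three_population(cls) -> "DemographyModel":
        """African-constant + out-of-Africa bottleneck + growth defaults.

        Parameter values are editable defaults (see defaults/demography.yaml),
        not estimates.
        """
        return cls(
            populations=["YRI", "CEU", "CHBJPT"],
            epochs={
                "YRI": [(0.0, 12_000.0)],
                "CEU": [(0.0, 20_000.0), (800.0, 1_500.0)],
                "CHBJPT": [(0.0, 25_000.0), (800.0, 1_200.0)],
                "OOA": [(0.0, 1_800.0)],
                "ANC": [(0.0, 10_000.0)],
            },
            splits=[
                Split(1_600.0, ("CEU", "CHBJPT"), "OOA"),
                Split(3_500.0, ("YRI", "OOA"), "ANC"),
            ],
        )

    @classmethod
    def from_dict(cls, d: dict) -> "DemographyModel":
        return cls(
            populations=list(d["populations"]),
            epochs={
                p: [(float(t), float(s)) for t, s in eps]
                for p, eps in d["epochs"].items()
            },
            splits=[
                Split(float(s["time"]), tuple(s["derived"]), s["ancestral"])
                for s in d.get("splits", [])
            ],
            bottlenecks=[
                (b[0], float(b[1]), float(b[2]))
                for b in d.get("bottlenecks", [])
            ],
        )

    def to_msprime(self) -> msprime.Demography:
        dem = msprime.Demography()
        for pop, eps in self.epochs.items():
            dem.add_population(name=pop, initial_size=eps[0][1])
        for pop, eps in self.epochs.items():
            for t, size in eps[1:]:
                dem.add_population_parameters_change(
                    time=t, population=pop, initial_size=size, growth_rate=0
                )
        for sp in self.splits:
            dem.add_population_split(
                time=sp.time, derived=list(sp.derived), ancestral=sp.ancestral
            )
        for pop, t, strength in self.bottlenecks:
            dem.add_instantaneous_bottleneck(
                time=t, population=pop, strength=strength
            )
        dem.sort_events()
        return dem


@dataclass(frozen=True)
class SweepModel:
    """Hard-sweep conditioning for a focal variant."""

    position: int
    selection_coefficient: float
    target_daf: float
    onset_time: float = 0.0
    population: str | None = None  # None: sweep across all sampled haplotypes
    noise_scale: float = 0.005

    def __post_init__(self) -> None:
        if not (0.0 < self.target_daf <= 1.0):
            raise ConfigurationError("target_daf must be in (0, 1]")


# ----------------------------------------------------------------------
def _child_seeds(seed: int | None, n: int) -> list[int]:
    """Deterministic child-seed derivation (documented splitting rule)."""
    ss = np.random.SeedSequence(seed)
    state = ss.generate_state(n, dtype=np.uint32)
    return [int(v) if v > 0 else 1 for v in state]


def _discretize_positions(float_pos: np.ndarray) -> np.ndarray:
    """Map continuous infinite-sites positions to unique 1-based integers."""
    out = np.empty(float_pos.size, dtype=np.int64)
    prev = 0
    for i, p in enumerate(float_pos):
        v = max(prev + 1, int(np.floor(p)) + 1)
        out[i] = v
        prev = v
    return out


def _site_alleles(n_sites: int, rng: np.random.Generator):
    """Seeded (ref, alt) nucleotide labels per site, ref != alt."""
    ref = _NUCS[rng.integers(0, 4, n_sites)]
    shift = rng.integers(1, 4, n_sites)
    alt_idx = (np.searchsorted(_NUCS, ref) + shift) % 4
    return ref.astype("U1"), _NUCS[alt_idx].astype("U1")


def simulate_neutral(
    params: SimulationParams,
    demography: DemographyModel,
    seed: int | None = None,
) -> HaplotypeMatrix:
    """Neutral coalescent simulation; allele 0 is the true ancestral state.

    Returns a phased 0/1 matrix with sorted unique integer positions
    (infinite-sites, binary mutation model), deterministic under a fixed
    seed.
    """
    if seed is None:
        seed = params.seed
    s_anc, s_mut, s_lab = _child_seeds(seed, 3)
    n_ind = params.n_haplotypes_per_pop // 2
    ts = msprime.sim_ancestry(
        samples={pop: n_ind for pop in demography.populations},
        demography=demography.to_msprime(),
        sequence_length=params.region_length,
        recombination_rate=params.recombination_rate,
        ploidy=2,
        random_seed=s_anc,
    )
    mts = msprime.sim_mutations(
        ts,
        rate=params.mutation_rate,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=s_mut,
    )
    geno = mts.genotype_matrix().T.astype(np.int8)  # haplotypes x sites
    float_pos = np.array([s.position for s in mts.sites()])
    positions = _discretize_positions(float_pos)
    samples = []
    populations = []
    for pop in demography.populations:
        for k in range(n_ind):
            samples.append(f"{pop}_{k}")
            populations.append(pop)
    rng = np.random.default_rng(s_lab)
    ref, alt = _site_alleles(positions.size, rng)
    return HaplotypeMatrix(
        alleles=geno,
        positions=positions,
        samples=samples,
        populations=populations,
        polarized=np.ones(positions.size, dtype=bool),
        ref=ref,
        alt=alt,
    )


# ----------------------------------------------------------------------
@dataclass
class SweepResult:
    """Sweep dataset plus the location of the conditioned focal variant."""

    matrix: HaplotypeMatrix
    focal_index: int
    carriers: np.ndarray  # haplotype rows carrying the derived focal allele


def simulate_sweep(
    params: SimulationParams,
    demography: DemographyModel,
    sweep: SweepModel,
    seed: int | None = None,
) -> SweepResult:
    """Hard sweep via a documented star-genealogy approximation.

    A neutral background is simulated first; the derived class at the focal
    variant (size ``round(target_daf * n)``) is then forced to descend from
    a single founder haplotype: carriers copy the founder's alleles and
    each carrier independently retains its original allele at a site with
    probability ``min(0.25, noise_scale / s)``, so stronger selection
    (younger sweeps) leaves less intra-allelic diversity.
    """
    if sweep.selection_coefficient <= 0:
        raise ConfigurationError(
            "selection_coefficient must be > 0 (s = 0 is the neutral model; "
            "use simulate_neutral)"
        )
    if not (1 <= sweep.position <= params.region_length):
        raise ConfigurationError("sweep position outside the region")
    if seed is None:
        seed = params.seed
    s_neu, s_pick = _child_seeds(seed, 2)
    base = simulate_neutral(params, demography, seed=s_neu)
    rows = base.haplotype_indices(sweep.population)
    n = rows.size
    k = int(round(sweep.target_daf * n))
    if k < 2:
        raise ConfigurationError(
            f"derived class too small: target_daf * n = {sweep.target_daf * n:.2f} < 2"
        )
    k = min(k, n)
    rng = np.random.default_rng(s_pick)
    carriers = rng.choice(rows, size=k, replace=False)
    founder = carriers[0]
    alleles = base.alleles.copy()
    p_noise = min(0.25, sweep.noise_scale / sweep.selection_coefficient)
    original = alleles[carriers].copy()
    founder_row = alleles[founder].copy()
    alleles[carriers] = founder_row[None, :]
    if p_noise > 0:
        keep = rng.random(original.shape) < p_noise
        alleles[carriers] = np.where(keep, original, alleles[carriers])
    # insert (or overwrite) the focal variant itself
    pos = int(sweep.position)
    existing = np.nonzero(base.positions == pos)[0]
    carrier_mask = np.zeros(base.n_haplotypes, dtype=bool)
    carrier_mask[carriers] = True
    focal_col = carrier_mask.astype(np.int8)
    if existing.size:
        fi = int(existing[0])
        alleles[:, fi] = focal_col
        positions = base.positions
        polarized = base.polarized
        ref, alt = base.ref, base.alt
    else:
        fi = int(np.searchsorted(base.positions, pos))
        alleles = np.insert(alleles, fi, focal_col, axis=1)
        positions = np.insert(base.positions, fi, pos)
        polarized = np.insert(base.polarized, fi, True)
        ref = np.insert(base.ref, fi, "A")
        alt = np.insert(base.alt, fi, "G")
    matrix = HaplotypeMatrix(
        alleles=alleles,
        positions=positions,
        samples=base.samples,
        populations=base.populations,
        polarized=polarized,
        ref=ref,
        alt=alt,
    )
    return SweepResult(matrix=matrix, focal_index=fi, carriers=carriers)


# ----------------------------------------------------------------------
@dataclass
class ControlGene:
    label: str
    matrix: HaplotypeMatrix
    start: int
    end: int


@dataclass
class ControlSet:
    """Independent neutral regions standing in for a control gene set."""

    genes: list[ControlGene]

    def __post_init__(self) -> None:
        labels = [g.label for g in self.genes]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("control gene labels must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def generate_control_set(
    n_genes: int,
    params: SimulationParams,
    demography: DemographyModel,
    seed: int | None = None,
) -> ControlSet:
    """n_genes independent neutral regions with derived per-gene seeds."""
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    seeds = _child_seeds(seed, n_genes)
    genes = []
    for i, s in enumerate(seeds):
        m = simulate_neutral(params, demography, seed=s)
        genes.append(
            ControlGene(f"control_{i:04d}", m, 1, params.region_length)
        )
    return ControlSet(genes)


# ----------------------------------------------------------------------
def generate_outgroups(
    matrix: HaplotypeMatrix,
    n_outgroups: int,
    divergence: float | Sequence[float],
    seed: int | None = None,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-site outgroup alleles for parsimony polarization.

    Each outgroup carries the generator's true ancestral allele (ref) and
    is independently flipped to the derived allele with probability
    ``1 - exp(-divergence)``, emulating misassignment risk.  Returns a
    table with columns (chrom, pos, sample, allele).
    """
    if n_outgroups < 1:
        raise ConfigurationError("n_outgroups must be >= 1")
    if np.isscalar(divergence):
        divs = [float(divergence)] * n_outgroups
    else:
        divs = [float(d) for d in divergence]
        if len(divs) != n_outgroups:
            raise ConfigurationError("one divergence per outgroup required")
    if any(d < 0 for d in divs):
        raise ConfigurationError("divergence must be >= 0")
    if labels is None:
        labels = [f"outgroup_{i}" for i in range(n_outgroups)]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for og, d in zip(labels, divs):
        p_flip = 1.0 - np.exp(-d)
        flips = rng.random(matrix.n_sites) < p_flip
        alleles = np.where(flips, matrix.alt, matrix.ref)
        for pos, a in zip(matrix.positions, alleles):
            rows.append((matrix.chrom, int(pos), og, str(a)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "sample", "allele"])


def generate_ancient(
    matrix: HaplotypeMatrix,
    samples: Sequence[tuple[str, float]],
    seed: int | None = None,
    depth_two: int = 4,
    depth_one: int = 1,
) -> pd.DataFrame:
    """Low-coverage ancient genotype table.

    Each ancient sample's true genotype is a seeded draw of two haplotypes
    from ``matrix``.  Per-site read depth ~ Poisson(mean_coverage): depth
    >= ``depth_two`` reports both alleles, depth in [depth_one, depth_two)
    reports a single randomly chosen allele, depth 0 (below ``depth_one``)
    is missing ('.').  Columns: (chrom, pos, sample, allele1, allele2).
    """
    for _, cov in samples:
        if cov < 0:
            raise ConfigurationError("mean_coverage must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    letters = np.stack([matrix.ref, matrix.alt], axis=1)  # n_sites x 2
    rows = []
    for label, cov in samples:
        h1, h2 = rng.choice(matrix.n_haplotypes, size=2, replace=False)
        g1 = matrix.alleles[h1]
        g2 = matrix.alleles[h2]
        depth = rng.poisson(cov, size=matrix.n_sites)
        pick = rng.integers(0, 2, size=matrix.n_sites)
        for j, pos in enumerate(matrix.positions):
            if depth[j] >= depth_two and g1[j] != MISSING and g2[j] != MISSING:
                a1 = letters[j][g1[j]]
                a2 = letters[j][g2[j]]
            elif depth[j] >= depth_one and (g1[j] != MISSING or g2[j] != MISSING):
                g = g1[j] if pick[j] == 0 else g2[j]
                if g == MISSING:
                    g = g2[j] if g1[j] == MISSING else g1[j]
                a1 = letters[j][g]
                a2 = "."
            else:
                a1 = "."
                a2 = "."
            rows.append((matrix.chrom, int(pos), label, str(a1), str(a2)))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "sample", "allele1", "allele2"]
    )
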