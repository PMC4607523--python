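"""Ancestral-state assignment by outgroup parsimony, ancient-sample
annotation, and modern-human-specific site classification."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "VariantRecord",
    "infer_ancestral",
    "annotate_ancient",
    "classify_modern_specific",
]

_MISSING_ALLELES = {None, "", ".", "N", "n", "-"}


def infer_ancestral(
    human_alleles: Iterable[str],
    outgroup_alleles: Iterable[str | None],
    min_informative: int = 4,
) -> str | None:
    """Parsimony ancestral allele from outgroup states, or None (unpolarized).

    The ancestral state is assigned only when at least ``min_informative``
    outgroups carry data, they unanimously agree on one allele, and that
    allele is among the human alleles; any disagreement, missing data below
    the quorum, or an outgroup allele absent from the human sample leaves
    the site unpolarized.
    """
    human = {a.upper() for a in human_alleles}
    informative = [
        a.upper() for a in outgroup_alleles if a not in _MISSING_ALLELES
    ]
    if len(informative) < min_informative:
        return None
    states = set(informative)
    if len(states) != 1:
        return None
    allele = states.pop()
    if allele not in human:
        return None
    return allele


@dataclass
class VariantRecord:
    """One biallelic site with polarization and archaic annotations."""

    id: str
    chrom: str
    position: int
    ref: str
    alt: str
    ancestral: str | None = None  # None = unpolarized
    pop_derived: dict[str, int] = field(default_factory=dict)
    pop_called: dict[str, int] = field(default_factory=dict)
    archaic_states: dict[str, str] = field(default_factory=dict)
    modern_specific: bool | None = None

    @property
    def polarized(self) -> bool:
        return self.ancestral is not None

    @property
    def derived(self) -> str | None:
        if not self.polarized:
            return None
        return self.alt if self.ancestral == self.ref else self.ref

    def daf(self, population: str) -> float:
        """Derived allele frequency; requires polarization."""
        if not self.polarized:
            raise ValueError("DAF undefined at unpolarized site")
        called = self.pop_called[population]
        if called == 0:
            return float("nan")
        der = self.pop_derived[population]
        if self.ancestral == self.alt:
            der = called - der
        return der / called

    def maf(self, population: str) -> float:
        called = self.pop_called[population]
        if called == 0:
            return float("nan")
        p = self.pop_derived[population] / called
        return min(p, 1.0 - p)

    def pooled_daf(self) -> float:
        called = sum(self.pop_called.values())
        if called == 0:
            return float("nan")
        der = sum(self.pop_derived.values())
        if self.ancestral == self.alt:
            der = called - der
        return der / called


def annotate_ancient(
    variant: VariantRecord,
    ancient_genotypes: Mapping[str, Sequence[str]],
) -> VariantRecord:
    """Attach per-ancient-sample states to a polarized variant.

    ``ancient_genotypes`` maps sample label to (allele1, allele2); '.'
    marks an absent allele (single-allele or missing call).  States are
    'ancestral', 'derived', 'het', 'single:ancestral', 'single:derived',
    'missing'; alleles matching neither ref nor alt are flagged
    'inconsistent' and excluded from downstream classification.
    """
    if not variant.polarized:
        raise ValueError("variant must be polarized before annotation")
    anc = variant.ancestral
    der = variant.derived
    for sample, alleles in ancient_genotypes.items():
        called = [
            a.upper() for a in alleles if a not in _MISSING_ALLELES
        ]
        if not called:
            variant.archaic_states[sample] = "missing"
            continue
        if any(a not in (variant.ref, variant.alt) for a in called):
            variant.archaic_states[sample] = "inconsistent"
            continue
        if len(called) == 1:
            state = "single:ancestral" if called[0] == anc else "single:derived"
        elif called[0] != called[1]:
            state = "het"
        else:
            state = "ancestral" if called[0] == anc else "derived"
        variant.archaic_states[sample] = state
    return variant


_ANCESTRAL_STATES = {"ancestral", "single:ancestral"}
_UNINFORMATIVE_STATES = {"missing", "inconsistent"}


def classify_modern_specific(
    variant: VariantRecord, min_global_daf: float = 0.5
) -> bool | None:
    """Flag sites where archaics are ancestral but modern humans derived.

    True iff every informative archaic sample shows only the ancestral
    allele (heterozygous or derived calls break the flag) and the pooled
    modern DAF is at least ``min_global_daf``.  None (undefined) when no
    informative archaic state exists.
    """
    if not variant.polarized:
        raise ValueError("variant must be polarized")
    informative = [
        s for s in variant.archaic_states.values()
        if s not in _UNINFORMATIVE_STATES
    ]
    if not informative:
        variant.modern_specific = None
        return None
    flag = all(s in _ANCESTRAL_STATES for s in informative) and (
        variant.pooled_daf() >= min_global_daf
    )
    variant.modern_specific = bool(flag)
    return variant.modern_specific
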