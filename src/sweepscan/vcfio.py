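"""Standard-format I/O: VCF in/out, BED regions, TSV tables.

VCF reading is backed by cyvcf2.  Internally coordinates are 1-based and
fully closed; BED input (0-based half-open) is converted at the boundary.
When an ``AA`` INFO tag is present and matches REF or ALT the matrix is
recoded so allele 0 is ancestral and the site is marked polarized.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .matrix import MISSING, HaplotypeMatrix
from .pipeline import GeneRegion, define_region

log = logging.getLogger("sweepscan")

__all__ = ["read_vcf", "write_vcf", "read_regions", "read_table", "write_tsv"]


def read_vcf(
    path: str | Path,
    sample_populations: Mapping[str, str] | None = None,
    samples: Sequence[str] | None = None,
    region: GeneRegion | None = None,
    allow_unphased: bool = False,
    seed: int | None = None,
) -> HaplotypeMatrix:
    """Load phased biallelic SNPs into a HaplotypeMatrix.

    Multi-allelic and non-SNP records are skipped (counts logged).
    Unphased genotypes raise unless ``allow_unphased`` is set, in which
    case they are randomly phased with the run seed.  Missing requested
    samples raise.
    """
    vcf = VCF(str(path))
    file_samples = list(vcf.samples)
    if samples is None:
        samples = file_samples
    else:
        missing = [s for s in samples if s not in file_samples]
        if missing:
            raise ValueError(f"samples not in VCF: {missing}")
    col = {s: file_samples.index(s) for s in samples}
    if sample_populations is None:
        sample_populations = {s: "pop0" for s in samples}
    populations = [sample_populations.get(s, "pop0") for s in samples]

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows: list[np.ndarray] = []
    positions: list[int] = []
    polarized: list[bool] = []
    refs: list[str] = []
    alts: list[str] = []
    chrom = "1"
    n_skipped = 0
    for lineno, v in enumerate(vcf, start=1):
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        if region is not None and not (
            region.scan_start <= v.POS <= region.scan_end
        ):
            continue
        chrom = v.CHROM
        geno = v.genotypes  # [a0, a1, phased] per sample
        hap = np.empty(2 * len(samples), dtype=np.int8)
        for i, s in enumerate(samples):
            a0, a1, phased = geno[col[s]][:3]
            if a0 >= 0 and a1 >= 0 and not phased and a0 != a1:
                if not allow_unphased:
                    raise ValueError(
                        f"unphased heterozygote at record {lineno} "
                        f"(pos {v.POS}, sample {s}); use allow_unphased"
                    )
                if rng.random() < 0.5:
                    a0, a1 = a1, a0
            hap[2 * i] = a0 if a0 >= 0 else MISSING
            hap[2 * i + 1] = a1 if a1 >= 0 else MISSING
        ref, alt = v.REF.upper(), v.ALT[0].upper()
        aa = v.INFO.get("AA")
        pol = False
        if aa is not None:
            aa = str(aa).upper()
            if aa == alt:
                # recode so 0 = ancestral
                swap = hap >= 0
                hap[swap] = 1 - hap[swap]
                ref, alt = alt, ref
                pol = True
            elif aa == ref:
                pol = True
        rows.append(hap)
        positions.append(v.POS)
        polarized.append(pol)
        refs.append(ref)
        alts.append(alt)
    if n_skipped:
        log.info("skipped %d multi-allelic/non-SNP record(s)", n_skipped)
    if not rows:
        alleles = np.zeros((2 * len(samples), 0), dtype=np.int8)
    else:
        alleles = np.stack(rows, axis=1)
    order = np.argsort(positions, kind="stable") if positions else []
    return HaplotypeMatrix(
        alleles=alleles[:, order] if len(positions) else alleles,
        positions=np.asarray(positions, dtype=np.int64)[order]
        if positions else np.empty(0, dtype=np.int64),
        samples=list(samples),
        populations=populations,
        polarized=np.asarray(polarized)[order] if positions else None,
        ref=np.asarray(refs, dtype="U1")[order] if positions else None,
        alt=np.asarray(alts, dtype="U1")[order] if positions else None,
        chrom=chrom,
    )


def write_vcf(matrix: HaplotypeMatrix, path: str | Path) -> None:
    """Write a minimal phased VCF with an AA INFO tag at polarized sites."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n'
        )
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        fh.write(f"##contig=<ID={matrix.chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for j in range(matrix.n_sites):
            info = f"AA={matrix.ref[j]}" if matrix.polarized[j] else "."
            gts = []
            for i in range(len(matrix.samples)):
                a0 = matrix.alleles[2 * i, j]
                a1 = matrix.alleles[2 * i + 1, j]
                gts.append(
                    f"{'.' if a0 < 0 else a0}|{'.' if a1 < 0 else a1}"
                )
            fh.write(
                f"{matrix.chrom}\t{matrix.positions[j]}\t"
                f"snp_{matrix.positions[j]}\t{matrix.ref[j]}\t"
                f"{matrix.alt[j]}\t.\tPASS\t{info}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_regions(path: str | Path, flank: int = 25_000) -> list[GeneRegion]:
    """Read gene regions from BED (0-based half-open -> 1-based closed)."""
    regions: list[GeneRegion] = []
    labels: set[str] = set()
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {i + 1}: {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else f"region_{i}"
            if label in labels:
                raise ValueError(f"duplicate region label {label!r}")
            labels.add(label)
            regions.append(
                define_region(label, chrom, start + 1, end, flank=flank)
            )
    return regions


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV table (outgroup alleles, ancient genotypes, reports)."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
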