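"""Linking epivariations to candidate cis sequence causes.

Some epivariations are secondary events downstream of a regulatory sequence
mutation (e.g. a rare SNV disrupting a CTCF binding motif near the region).
This module extracts rare variants flanking each DMR, annotates which fall
inside transcription-factor motif intervals, checks co-segregation of
variant and methylation state across carriers, and tests enrichment of
motif-disrupting rare variants in DMR carriers versus non-carriers.

Coordinates are 1-based inclusive internally; BED input/output converts at
the boundary (BED is 0-based half-open).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .dmr_caller import DmrCall
from .inheritance import EnrichmentResult, fisher_exact_2x2

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "MotifInterval",
    "DmrVariantPair",
    "read_vcf_variants",
    "read_motif_bed",
    "write_motif_bed",
    "extract_rare_variants_near_dmrs",
    "annotate_motif_disruption",
    "cosegregation_check",
    "motif_disruption_enrichment",
]

GT_REF, GT_HET, GT_HOM, GT_MISSING = "ref", "het", "hom", "missing"


@dataclass(frozen=True)
class VariantRecord:
    chromosome: str
    position: int  # 1-based; indels anchored at leftmost changed base
    ref: str
    alt: str
    population_af: float
    carrier_genotypes: tuple[tuple[str, str], ...] = ()  # (sample, gt-class)

    def __post_init__(self) -> None:
        if not (0.0 <= self.population_af <= 1.0):
            raise ValueError(f"population_af out of [0,1]: {self.population_af}")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")

    def genotype_of(self, sample: str) -> str:
        for s, g in self.carrier_genotypes:
            if s == sample:
                return g
        return GT_MISSING

    def carriers(self) -> set[str]:
        return {s for s, g in self.carrier_genotypes if g in (GT_HET, GT_HOM)}


@dataclass(frozen=True)
class MotifInterval:
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    tf_name: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("motif start > end")


@dataclass
class DmrVariantPair:
    dmr: DmrCall
    variant: VariantRecord
    disrupted_motifs: tuple[MotifInterval, ...] = ()


def read_vcf_variants(path: str | Path, af_field: str = "AF") -> list[VariantRecord]:
    """Read variants from a VCF; population AF taken from INFO[``af_field``].

    Genotypes are classified as ref / het / hom / missing per sample.
    Records lacking the AF field get AF 0 (treated as maximally rare).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out = []
    for rec in vcf:
        af = rec.INFO.get(af_field)
        if af is None:
            af = 0.0
        elif isinstance(af, tuple):
            af = af[0]
        gts = []
        for s, g in zip(samples, rec.gt_types):
            # cyvcf2: 0=hom ref, 1=het, 2=unknown, 3=hom alt
            cls = {0: GT_REF, 1: GT_HET, 2: GT_MISSING, 3: GT_HOM}[int(g)]
            gts.append((s, cls))
        alt = rec.ALT[0] if rec.ALT else "."
        out.append(
            VariantRecord(
                chromosome=rec.CHROM,
                position=int(rec.POS),
                ref=rec.REF,
                alt=alt,
                population_af=float(af),
                carrier_genotypes=tuple(gts),
            )
        )
    return out


def read_motif_bed(path: str | Path) -> list[MotifInterval]:
    """Read motif intervals from BED (0-based half-open -> 1-based inclusive)."""
    t = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for row in t.itertuples(index=False):
        chrom, start0, end0 = row[0], int(row[1]), int(row[2])
        name = str(row[3]) if len(row) > 3 else "."
        strand = str(row[5]) if len(row) > 5 else "+"
        out.append(MotifInterval(chrom, start0 + 1, end0, name, strand))
    return out


def write_motif_bed(motifs: list[MotifInterval], path: str | Path) -> None:
    """Write motif intervals as BED (1-based inclusive -> 0-based half-open)."""
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f"{m.chromosome}\t{m.start - 1}\t{m.end}\t{m.tf_name}\t0\t{m.strand}\n")


def extract_rare_variants_near_dmrs(
    variants: list[VariantRecord],
    calls: list[DmrCall],
    flank_bp: int = 5000,
    maf_cut: float = 0.001,
) -> list[DmrVariantPair]:
    """Pair each DMR with rare variants in its flanks.

    A variant pairs with a DMR when its position lies within
    [dmr.start - flank_bp, dmr.end + flank_bp] and its population allele
    frequency is strictly below ``maf_cut``. Defaults match the
    population-scale screen (±5 kb, MAF < 0.1%); targeted-sequencing scale
    uses flank_bp=75000, maf_cut=0.01.
    """
    rare = [v for v in variants if v.population_af < maf_cut]
    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in rare:
        by_chrom.setdefault(v.chromosome, []).append(v)
    pairs = []
    for call in calls:
        for v in by_chrom.get(call.chromosome, []):
            if call.start - flank_bp <= v.position <= call.end + flank_bp:
                pairs.append(DmrVariantPair(dmr=call, variant=v))
    return pairs


def annotate_motif_disruption(
    pairs: list[DmrVariantPair],
    motifs: list[MotifInterval],
    tf_filter: str | None = None,
) -> list[DmrVariantPair]:
    """Attach to each pair the motifs containing the variant position.

    Containment is by the variant's anchor position (for indels, the
    leftmost changed base under VCF left-alignment). ``tf_filter`` restricts
    the annotation to one factor (e.g. "CTCF").
    """
    trees: dict[str, IntervalTree] = {}
    for m in motifs:
        if tf_filter is not None and m.tf_name != tf_filter:
            continue
        # IntervalTree is half-open; motif [start, end] -> [start, end + 1)
        trees.setdefault(m.chromosome, IntervalTree()).addi(m.start, m.end + 1, m)
    for pair in pairs:
        tree = trees.get(pair.variant.chromosome)
        hits = sorted(
            (iv.data for iv in tree.at(pair.variant.position)) if tree else [],
            key=lambda m: (m.start, m.end, m.tf_name),
        )
        pair.disrupted_motifs = tuple(hits)
    return pairs


def cosegregation_check(
    dmr_carriers: set[str],
    variant: VariantRecord,
    samples_tested: set[str],
) -> str:
    """Do variant carriers and DMR carriers coincide across tested samples?

    Returns "cosegregates" when carrier-of-variant <=> carrier-of-DMR for
    every tested sample with a non-missing genotype, "discordant" on any
    mismatch, "uninformative" with fewer than two informative samples.
    """
    informative = [
        s for s in samples_tested if variant.genotype_of(s) != GT_MISSING
    ]
    if len(informative) < 2:
        return "uninformative"
    for s in informative:
        has_variant = variant.genotype_of(s) in (GT_HET, GT_HOM)
        has_dmr = s in dmr_carriers
        if has_variant != has_dmr:
            return "discordant"
    return "cosegregates"


def motif_disruption_enrichment(
    carrier_with: int,
    carrier_without: int,
    noncarrier_with: int,
    noncarrier_without: int,
) -> EnrichmentResult:
    """Enrichment of motif-disrupting rare variants at DMRs in carriers.

    Counting unit is the sample-locus pair: each assayed sample at each DMR
    locus contributes one observation — it either harbors >= 1 rare
    motif-disrupting variant in the flank, or not. Carriers of the
    epivariation are compared to non-carrier samples at the same loci with
    a two-sided Fisher exact test.
    """
    return fisher_exact_2x2(
        [[carrier_with, carrier_without], [noncarrier_with, noncarrier_without]]
    )
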