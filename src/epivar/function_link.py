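"""Functional correlates of epivariations.

Promoter methylation is repressive, so an epivariation overlapping a gene
promoter should move that gene's expression: hypermethylation down,
hypomethylation up, often to the most extreme rank of the cohort, and — for
allelic events — silencing one allele entirely. This module links DMRs to
promoters (TSS ± 2 kb), ranks carrier expression within the cohort, tests
the direction effect (hypo vs hyper carrier z-scores, Wilcoxon rank-sum),
summarizes allelic imbalance from ref/alt read counts at heterozygous
transcribed SNVs (depth >= 7), and measures cross-tissue concordance of
outlier methylation as a Spearman correlation of signed deviation
percentiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import BetaMatrix
from .dmr_caller import HYPER, DmrCall

logger = logging.getLogger(__name__)

__all__ = [
    "GeneAnnotation",
    "AseSite",
    "link_dmr_genes",
    "expression_outlier_rank",
    "direction_test",
    "allelic_imbalance",
    "cross_tissue_concordance",
]


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chromosome: str
    tss: int  # 1-based
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError("tss must be >= 1")


@dataclass(frozen=True)
class AseSite:
    """Ref/alt read counts at one heterozygous transcribed SNV."""

    gene_id: str
    sample_id: str
    position: int
    ref_count: int
    alt_count: int

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count


def link_dmr_genes(
    calls: list[DmrCall],
    genes: list[GeneAnnotation],
    promoter_halfwidth: int = 2000,
) -> list[tuple[DmrCall, GeneAnnotation]]:
    """Pair DMRs with genes whose promoter they overlap.

    The promoter is TSS ± ``promoter_halfwidth`` regardless of strand (the
    window is symmetric); any >= 1 bp overlap with the DMR span links the
    pair, and a DMR may link several genes.
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    pairs = []
    for call in calls:
        for g in by_chrom.get(call.chromosome, []):
            lo = max(1, g.tss - promoter_halfwidth)
            hi = g.tss + promoter_halfwidth
            if call.start <= hi and lo <= call.end:
                pairs.append((call, g))
    return pairs


def expression_outlier_rank(
    expr: pd.DataFrame, gene: str, carrier_sample: str
) -> dict:
    """Rank a carrier's expression of one gene within the cohort.

    ``expr`` is genes x samples. Rank 1 is the lowest expression; ties take
    the average rank. The z-score uses the full-cohort mean and SD (carrier
    included); with constant expression z is NaN but the rank is still
    reported.
    """
    row = expr.loc[gene].dropna()
    if len(row) < 3:
        raise ValueError(f"need >= 3 samples with expression for {gene}")
    if carrier_sample not in row.index:
        raise KeyError(f"no expression for {carrier_sample} at {gene}")
    ranks = row.rank(method="average")
    n = len(row)
    sd = float(row.std(ddof=0))
    z = float("nan") if sd < 1e-15 else float((row[carrier_sample] - row.mean()) / sd)
    rank = float(ranks[carrier_sample])
    return {"rank": rank, "n": n, "percentile": rank / n, "z": z}


def direction_test(
    hypo_carrier_z: list[float], hyper_carrier_z: list[float]
) -> float:
    """Two-sided rank-sum test: hypo-carrier vs hyper-carrier expression z.

    If hypomethylation raises expression and hypermethylation represses it,
    the two groups separate in rank. Exact Wilcoxon rank-sum when both
    groups have n <= 25, normal approximation with continuity correction
    otherwise.
    """
    x, y = np.asarray(hypo_carrier_z, float), np.asarray(hyper_carrier_z, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if (x.size <= 25 and y.size <= 25) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def allelic_imbalance(
    sites: list[AseSite], min_depth: int = 7, mono_cut: float = 0.10
) -> dict[tuple[str, str], dict]:
    """Pooled allelic-expression imbalance per gene-sample.

    Sites below ``min_depth`` total reads are dropped; surviving counts are
    pooled (summed) per gene-sample before taking the minor-allele fraction
    min(ref, alt) / (ref + alt) — per-site ratios are never averaged.
    ``monoallelic`` is set when the pooled minor fraction is strictly below
    ``mono_cut``. Gene-samples without a usable site are absent.
    """
    pooled: dict[tuple[str, str], list[int]] = {}
    for s in sites:
        if s.depth < min_depth:
            continue
        key = (s.gene_id, s.sample_id)
        acc = pooled.setdefault(key, [0, 0])
        acc[0] += s.ref_count
        acc[1] += s.alt_count
    out = {}
    for key, (ref, alt) in pooled.items():
        minor = min(ref, alt) / (ref + alt)
        out[key] = {
            "ref_count": ref,
            "alt_count": alt,
            "minor_fraction": minor,
            "monoallelic": minor < mono_cut,
        }
    return out


def _signed_deviation(
    call: DmrCall, beta: BetaMatrix, carrier: str
) -> tuple[float, float] | None:
    """Carrier's (percentile, oriented deviation) at the call's probes.

    Percentile is the carrier's population rank of mean beta, oriented by
    call direction (1.0 = most extreme in the event's direction). The
    oriented deviation is the carrier's mean beta minus the cohort median,
    signed the same way; unlike the percentile it does not saturate for
    strong outliers, so it preserves an ordering among them.
    """
    pids = [p for p in call.supporting_probe_ids if p in beta.values.index]
    if not pids or carrier not in beta.values.columns:
        return None
    means = beta.values.loc[pids].mean(axis=0, skipna=True)
    if carrier not in means.index or np.isnan(means[carrier]):
        return None
    ranks = means.rank(method="average")  # 1 = lowest mean beta
    n = means.notna().sum()
    r = ranks[carrier]
    sign = 1.0
    if call.direction != HYPER:
        r = n + 1 - r
        sign = -1.0
    dev = sign * float(means[carrier] - means.median())
    return float(r / n), dev


def cross_tissue_concordance(
    calls_tissue_a: list[DmrCall],
    beta_tissue_a: BetaMatrix,
    beta_tissue_b: BetaMatrix,
) -> dict:
    """Concordance of outlier methylation across tissues of the same people.

    For each DMR called in tissue A, the carrier's oriented deviation and
    population percentile are computed in both tissues; concordant biology
    puts the carrier near percentile 1.0 in tissue B as well. Spearman rho
    is computed over the oriented deviations (percentiles saturate at 1.0
    for strong outliers, which would make their ranks degenerate); rho is
    None with < 3 usable DMRs or zero spread.
    """
    rows = []
    for call in calls_tissue_a:
        da = _signed_deviation(call, beta_tissue_a, call.sample_id)
        db = _signed_deviation(call, beta_tissue_b, call.sample_id)
        if da is None or db is None:
            continue
        rows.append(
            {
                "sample_id": call.sample_id,
                "chromosome": call.chromosome,
                "start": call.start,
                "end": call.end,
                "direction": call.direction,
                "percentile_a": da[0],
                "percentile_b": db[0],
                "deviation_a": da[1],
                "deviation_b": db[1],
            }
        )
    table = pd.DataFrame(rows)
    rho = None
    if len(table) >= 3:
        a, b = table["deviation_a"], table["deviation_b"]
        if a.nunique() > 1 and b.nunique() > 1:
            rho = float(sps.spearmanr(a, b).statistic)
    return {"pairs": table, "spearman_rho": rho}
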