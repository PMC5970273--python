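"""Trio and pedigree analysis of epivariations, plus the cohort statistics.

Given per-sample DMR calls and a pedigree, this module classifies each event
as de novo (present in the child, absent in both parents) or inherited,
counts parent-to-child transmissions over informative meioses, and runs the
enrichment and summary statistics: two-sided Fisher exact tests on 2x2
tables, the transmission-deficit test against the Mendelian expectation of
half of informative meioses transmitted, de novo rate enrichment, and
validation / cohort summary rates.

Carrier status in family members is decided by a deterministic threshold:
an individual carries an epivariation when their mean beta over the event's
supporting probes deviates from the control mean in the event's direction by
at least ``carrier_delta`` (default 0.15, mirroring the caller's
mean-deviation criterion). This replaces the original visual inspection of
family methylation plots with a reproducible rule.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import BetaMatrix, ControlStats
from .dmr_caller import HYPER, DmrCall, find_recurrent

logger = logging.getLogger(__name__)

__all__ = [
    "Pedigree",
    "TransmissionSummary",
    "EnrichmentResult",
    "read_pedigree",
    "fisher_exact_2x2",
    "classify_trio",
    "count_transmissions",
    "transmission_deficit_test",
    "de_novo_enrichment",
    "frequency_enrichment",
    "cohort_summary",
    "concordance_rate",
]

MISSING_PARENT = {"0", ".", "", None}


@dataclass
class Pedigree:
    """Family structure: individual -> (family, father, mother, sex)."""

    records: pd.DataFrame  # indexed by individual_id

    def __post_init__(self) -> None:
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        for ind in self.records.index:
            seen = set()
            stack = [ind]
            while stack:
                cur = stack.pop()
                if cur in seen:
                    raise ValueError(f"pedigree cycle involving {ind}")
                seen.add(cur)
                if cur in self.records.index:
                    for col in ("father_id", "mother_id"):
                        p = self.records.at[cur, col]
                        if p not in MISSING_PARENT and not pd.isna(p):
                            stack.append(p)

    def parents_of(self, individual_id: str) -> tuple[str | None, str | None]:
        if individual_id not in self.records.index:
            return None, None
        r = self.records.loc[individual_id]
        f = None if r["father_id"] in MISSING_PARENT else r["father_id"]
        m = None if r["mother_id"] in MISSING_PARENT else r["mother_id"]
        return f, m

    def children_of(self, parent_id: str) -> list[str]:
        r = self.records
        mask = (r["father_id"] == parent_id) | (r["mother_id"] == parent_id)
        return list(r.index[mask])

    def family_of(self) -> dict[str, str]:
        return self.records["family_id"].to_dict()


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a PED-like TSV: family_id, individual_id, father_id, mother_id, sex[, role]."""
    t = pd.read_csv(path, sep="\t", dtype=str)
    t = t.set_index("individual_id")
    return Pedigree(t)


@dataclass
class TransmissionSummary:
    """Aggregated parent-to-child transmission of epivariations."""

    n_informative_meioses: int
    n_transmitted: int
    p_value: float  # exact two-sided binomial against 0.5
    p_value_fisher: float  # Fisher variant on rounded Mendelian expectation

    @property
    def expected_transmitted(self) -> float:
        return self.n_informative_meioses / 2.0


@dataclass
class EnrichmentResult:
    """A 2x2 association: fold change of proportions, odds ratio, Fisher p."""

    table: tuple[tuple[int, int], tuple[int, int]]
    fold: float
    odds_ratio: float
    p_two_sided: float
    fold_undefined: bool = False


def fisher_exact_2x2(table) -> EnrichmentResult:
    """Two-sided Fisher's exact test on a 2x2 table of non-negative counts.

    The two-sided p sums hypergeometric probabilities of all tables with the
    observed margins whose point probability does not exceed that of the
    observed table (within relative tolerance). A zero margin makes every
    table equally likely; p = 1 by convention.
    """
    (a, b), (c, d) = [[int(x) for x in row] for row in table]
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    row1, row2, col1, col2 = a + b, c + d, a + c, b + d
    if 0 in (row1, row2, col1, col2):
        warnings.warn("fisher_exact_2x2: zero margin, p = 1.0 by convention")
        p = 1.0
    else:
        p = float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    odds = math.inf if b * c == 0 and a * d > 0 else (
        (a * d) / (b * c) if b * c else float("nan")
    )
    fold_undefined = row2 == 0 or c == 0
    if fold_undefined:
        fold = math.inf if row1 and a else float("nan")
    else:
        fold = (a / row1) / (c / row2) if row1 else float("nan")
    return EnrichmentResult(
        table=((a, b), (c, d)),
        fold=fold,
        odds_ratio=odds,
        p_two_sided=min(1.0, p),
        fold_undefined=fold_undefined,
    )


def _carrier_status(
    beta: BetaMatrix,
    individual: str,
    call: DmrCall,
    stats: ControlStats,
    carrier_delta: float,
) -> bool | None:
    """True/False carrier status, or None when the individual lacks data."""
    if individual is None or individual not in beta.values.columns:
        return None
    pids = [p for p in call.supporting_probe_ids if p in beta.values.index
            and p in stats.table.index]
    if not pids:
        return None
    vals = beta.values.loc[pids, individual].to_numpy(float)
    if np.all(np.isnan(vals)):
        return None
    dev = float(np.nanmean(vals) - stats.table.loc[pids, "mean"].mean())
    sign = 1.0 if call.direction == HYPER else -1.0
    return sign * dev >= carrier_delta


def classify_trio(
    call: DmrCall,
    beta: BetaMatrix,
    pedigree: Pedigree,
    stats: ControlStats,
    carrier_delta: float = 0.15,
) -> str:
    """Label a child's epivariation as de novo, inherited, or unknown.

    De novo requires both parents present with data and both non-carrier;
    one carrier parent gives inherited_maternal / inherited_paternal; both
    carriers give ``inherited_biparental``. Missing parental data with no
    carrier found yields ``unknown``.
    """
    father, mother = pedigree.parents_of(call.sample_id)
    f_status = _carrier_status(beta, father, call, stats, carrier_delta)
    m_status = _carrier_status(beta, mother, call, stats, carrier_delta)
    if f_status is None and m_status is None:
        label = "unknown"
    elif m_status and f_status:
        label = "inherited_biparental"
    elif m_status:
        label = "inherited_maternal"
    elif f_status:
        label = "inherited_paternal"
    elif f_status is None or m_status is None:
        label = "unknown"
    else:
        label = "de_novo"
    call.inheritance = label
    return label


def count_transmissions(
    calls: dict[str, list[DmrCall]],
    pedigree: Pedigree,
    beta: BetaMatrix,
    stats: ControlStats,
    carrier_delta: float = 0.15,
) -> TransmissionSummary:
    """Count parent-to-child transmissions of segregating epivariations.

    Distinct epivariation loci are formed by clustering calls that share
    direction and supporting probes across the cohort. For each locus and
    each carrier parent, every child of that parent with data is one
    informative meiosis; the meiosis is transmitted when the child is also a
    carrier (same threshold rule). Children-only events contribute no
    informative meioses (they are the de novo case).
    """
    all_calls = [c for lst in calls.values() for c in lst]
    loci = find_recurrent(all_calls, family_of=None, min_carriers=1)
    family_of = pedigree.family_of()
    n_informative = 0
    n_transmitted = 0
    for cluster in loci:
        rep = cluster[0]
        carriers = {c.sample_id for c in cluster}
        # parents among the cluster's carriers, or carrier-by-threshold parents
        families = {family_of.get(s) for s in carriers if s in family_of}
        for fam in families:
            members = pedigree.records.index[pedigree.records["family_id"] == fam]
            for parent in members:
                if pedigree.children_of(parent):
                    status = _carrier_status(beta, parent, rep, stats, carrier_delta)
                    if status:
                        for child in pedigree.children_of(parent):
                            cs = _carrier_status(beta, child, rep, stats, carrier_delta)
                            if cs is None:
                                continue
                            n_informative += 1
                            n_transmitted += int(cs)
    if n_informative == 0:
        return TransmissionSummary(0, 0, 1.0, 1.0)
    p_binom, p_fisher = transmission_deficit_test(n_transmitted, n_informative)
    return TransmissionSummary(n_informative, n_transmitted, p_binom, p_fisher)


def transmission_deficit_test(
    n_transmitted: int, n_informative: int
) -> tuple[float, float]:
    """Test observed transmissions against the Mendelian expectation of 1/2.

    Returns (exact two-sided binomial p at rate 0.5, Fisher variant).
    The binomial test is the headline statistic. The Fisher variant compares
    [[t, n - t], [round(n/2), n - round(n/2)]] — observed against an
    integer-rounded Mendelian table — and is reported for comparability with
    contingency-style presentations of the same deficit.
    """
    if n_informative < 1:
        raise ValueError("need at least one informative meiosis")
    if n_transmitted > n_informative:
        raise ValueError("transmitted exceeds informative")
    p_binom = float(
        sps.binomtest(n_transmitted, n_informative, 0.5, alternative="two-sided").pvalue
    )
    half = round(n_informative / 2)
    p_fisher = fisher_exact_2x2(
        [[n_transmitted, n_informative - n_transmitted],
         [half, n_informative - half]]
    ).p_two_sided
    return p_binom, p_fisher


def de_novo_enrichment(
    case_de_novo: int,
    case_resolved: int,
    control_de_novo: int,
    control_resolved: int,
) -> EnrichmentResult:
    """Compare the de novo fraction of resolved epivariations, cases vs controls.

    ``resolved`` counts events whose inheritance could be determined. Fold is
    the ratio of de novo rates; p is the two-sided Fisher exact test on
    [[case_dn, case_inherited], [control_dn, control_inherited]].
    """
    if case_de_novo > case_resolved or control_de_novo > control_resolved:
        raise ValueError("de novo count exceeds resolved count")
    return fisher_exact_2x2(
        [
            [case_de_novo, case_resolved - case_de_novo],
            [control_de_novo, control_resolved - control_de_novo],
        ]
    )


def frequency_enrichment(
    case_carriers: int, n_cases: int, control_carriers: int, n_controls: int
) -> EnrichmentResult:
    """Carrier-rate ratio of epivariations, cases vs population controls."""
    return fisher_exact_2x2(
        [
            [case_carriers, n_cases - case_carriers],
            [control_carriers, n_controls - control_carriers],
        ]
    )


def cohort_summary(calls: dict[str, list[DmrCall]], n_samples: int) -> dict:
    """Summarize curated calls: event and carrier counts plus rounded percentages."""
    if n_samples == 0:
        raise ValueError("n_samples must be positive")
    counts = {s: len([c for c in lst if c.passes_curation]) for s, lst in calls.items()}
    n_dmrs = sum(counts.values())
    carriers = [s for s, c in counts.items() if c >= 1]
    single = [s for s, c in counts.items() if c == 1]
    multi = [s for s, c in counts.items() if c >= 2]
    return {
        "n_dmrs": n_dmrs,
        "n_carriers": len(carriers),
        "pct_carriers": round(100 * len(carriers) / n_samples),
        "n_single": len(single),
        "pct_single": round(100 * len(single) / n_samples),
        "n_multi": len(multi),
        "pct_multi": round(100 * len(multi) / n_samples),
    }


def concordance_rate(n_concordant: int, n_informative: int) -> int:
    """Validation true-positive rate as an integer percentage."""
    if n_informative < 1:
        raise ValueError("need at least one informative assay")
    if n_concordant > n_informative:
        raise ValueError("concordant exceeds informative")
    return round(100 * n_concordant / n_informative)
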