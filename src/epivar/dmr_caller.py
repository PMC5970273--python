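"""Outlier DMR ("epivariation") calling.

An epivariation is a rare, locus-level methylation state in a single sample
that deviates markedly from the population. The caller scans 1-kb windows
over position-sorted probes and, per sample, requires multiple independent
outlier probes so that single-probe artifacts (underlying SNVs, poor
hybridization) cannot produce a call.

Two modes are provided:

* **reference mode** — each test sample is compared against per-probe
  summaries of a large external control cohort (:class:`ControlStats`).
  A hypermethylated window needs (i) >= 3 probes each above the 99.9th
  control percentile and >= 0.15 above the control mean, and (ii) >= 1 probe
  >= 0.10 above the control maximum. Hypomethylation mirrors this against
  the 0.1th percentile, mean and minimum.
* **leave-one-out mode** — used when no matched external controls exist:
  each sample is compared against the remaining cohort, a probe qualifying
  when its beta is >= 0.15 beyond the max (or min) of all other samples,
  with >= 3 qualifying probes per window and no extreme-probe requirement.

Same-direction qualifying windows that share supporting probes merge into a
single call spanning its supporting probes. Manual curation of the original
screen is replaced by automated flags (``noncontiguous``, ``batch_suspect``,
``deletion_overlap``); flagged calls are excluded from summaries by default
but are never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import BetaMatrix, ControlStats, ProbeManifest
from .sample_qc import DeletionFlag

logger = logging.getLogger(__name__)

__all__ = [
    "WindowParams",
    "DmrCall",
    "ImprintedCall",
    "call_dmrs_reference",
    "call_dmrs_loo",
    "apply_deletion_filter",
    "curation_flags",
    "call_imprinted",
    "find_recurrent",
    "calls_to_bed",
]

HYPER = "hyper"
HYPO = "hypo"


@dataclass(frozen=True)
class WindowParams:
    """Thresholds of the sliding-window caller.

    ``mean_delta`` is the minimum absolute beta deviation from the control
    mean for a supporting probe; ``extreme_delta`` the excess beyond the
    control max/min for the extreme probe; ``loo_delta`` the margin beyond
    the cohort max/min in leave-one-out mode.
    """

    window_bp: int = 1000
    min_outlier_probes: int = 3
    mean_delta: float = 0.15
    extreme_delta: float = 0.10
    upper_q: float = 0.999
    lower_q: float = 0.001
    loo_delta: float = 0.15

    def __post_init__(self) -> None:
        for name in ("mean_delta", "extreme_delta", "loo_delta"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.min_outlier_probes < 1 or self.window_bp < 1:
            raise ValueError("min_outlier_probes and window_bp must be >= 1")


@dataclass
class DmrCall:
    """One epivariation event in one sample.

    Span is the 1-based inclusive range of the supporting (criterion-i)
    probes. ``extreme_probe_ids`` is empty only in leave-one-out mode, where
    no extreme-probe criterion applies.
    """

    sample_id: str
    chromosome: str
    start: int
    end: int
    direction: str  # "hyper" | "hypo"
    supporting_probe_ids: tuple[str, ...]
    extreme_probe_ids: tuple[str, ...]
    max_abs_deviation: float
    flags: set = field(default_factory=set)
    inheritance: str = "untested"

    def overlaps(self, chromosome: str, start: int, end: int) -> bool:
        return (
            self.chromosome == chromosome
            and self.start <= end
            and start <= self.end
        )

    @property
    def passes_curation(self) -> bool:
        return not self.flags


@dataclass(frozen=True)
class ImprintedCall:
    """Aberrant mean methylation at an imprinted locus in one sample."""

    sample_id: str
    locus_name: str
    mean_beta: float
    control_mean: float
    control_sd: float
    rule: str  # "sd3" | "extreme_high" | "extreme_low"
    rules_triggered: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# window scan machinery


def _merge_windows(
    qualifying: list[tuple[int, int]],
    crit1_idx: np.ndarray,
) -> list[np.ndarray]:
    """Merge qualifying windows (index spans) that share criterion-(i) probes.

    ``qualifying`` holds (lo, hi) inclusive index spans into the sorted probe
    array; ``crit1_idx`` marks criterion-(i) probes. Returns, per merged
    event, the array of criterion-(i) probe indices it contains.
    """
    cur_probes: set[int] = set()
    out: list[np.ndarray] = []
    for lo, hi in qualifying:
        probes = {i for i in crit1_idx if lo <= i <= hi}
        if cur_probes and (probes & cur_probes):
            cur_probes |= probes
        else:
            if cur_probes:
                out.append(np.array(sorted(cur_probes)))
            cur_probes = set(probes)
    if cur_probes:
        out.append(np.array(sorted(cur_probes)))
    return out


def _scan_windows(
    pos: np.ndarray,
    crit1: np.ndarray,
    crit2: np.ndarray | None,
    params: WindowParams,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Enumerate probe-anchored windows and merge qualifying ones.

    For each anchor probe p, the window covers probes in
    [pos[p], pos[p] + window_bp). A window qualifies with
    >= min_outlier_probes criterion-(i) probes and (when ``crit2`` is given)
    >= 1 criterion-(ii) probe. Returns (crit1 indices, crit2 indices) per
    merged event.
    """
    n = pos.size
    qualifying: list[tuple[int, int]] = []
    for a in range(n):
        b = a
        while b + 1 < n and pos[b + 1] <= pos[a] + params.window_bp - 1:
            b += 1
        c1 = np.count_nonzero(crit1[a : b + 1])
        if c1 < params.min_outlier_probes:
            continue
        if crit2 is not None and not crit2[a : b + 1].any():
            continue
        qualifying.append((a, b))

    crit1_idx = np.where(crit1)[0]
    events = _merge_windows(qualifying, crit1_idx)
    out = []
    for ev in events:
        lo, hi = ev.min(), ev.max()
        if crit2 is None:
            ext = np.array([], dtype=int)
        else:
            # extreme probes inside any qualifying window of this event
            ext_mask = np.zeros(n, dtype=bool)
            for a, b in qualifying:
                if any(lo <= i <= hi for i in crit1_idx[(crit1_idx >= a) & (crit1_idx <= b)]):
                    ext_mask[a : b + 1] = True
            ext = np.where(crit2 & ext_mask)[0]
        out.append((ev, ext))
    return out


def call_dmrs_reference(
    sample_beta: pd.Series,
    stats: ControlStats,
    manifest: ProbeManifest,
    params: WindowParams = WindowParams(),
    sample_id: str = "sample",
) -> list[DmrCall]:
    """Call epivariations in one sample against a reference control cohort.

    Boundary semantics follow the stated criteria literally: the mean and
    extreme margins (">= 0.15", ">= 0.10") are inclusive, exceedance of the
    percentile / max / min is strict for the percentile and inclusive-margin
    for the extremes. Probes without control stats or without data in the
    sample are skipped and can never support a call.
    """
    calls: list[DmrCall] = []
    st = stats.table
    for chrom in manifest.chromosomes():
        probes = manifest.probes_on(chrom)
        avail = probes.index.intersection(st.index).intersection(sample_beta.index)
        probes = probes.loc[probes.index.isin(avail)]
        if probes.empty:
            continue
        pos = probes["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"manifest not position-sorted on {chrom}")
        beta = sample_beta.loc[probes.index].to_numpy(float)
        s = st.loc[probes.index]
        mean = s["mean"].to_numpy()
        ok = ~np.isnan(beta)

        for direction in (HYPER, HYPO):
            if direction == HYPER:
                crit1 = ok & (beta > s["q_upper"].to_numpy()) & (
                    beta >= mean + params.mean_delta
                )
                crit2 = ok & (beta >= s["max"].to_numpy() + params.extreme_delta)
            else:
                crit1 = ok & (beta < s["q_lower"].to_numpy()) & (
                    beta <= mean - params.mean_delta
                )
                crit2 = ok & (beta <= s["min"].to_numpy() - params.extreme_delta)
            for ev, ext in _scan_windows(pos, crit1, crit2, params):
                dev = np.abs(beta[ev] - mean[ev])
                calls.append(
                    DmrCall(
                        sample_id=sample_id,
                        chromosome=chrom,
                        start=int(pos[ev.min()]),
                        end=int(pos[ev.max()]),
                        direction=direction,
                        supporting_probe_ids=tuple(probes.index[ev]),
                        extreme_probe_ids=tuple(probes.index[ext]),
                        max_abs_deviation=float(dev.max()),
                    )
                )
    return calls


def call_dmrs_cohort_reference(
    cohort: BetaMatrix,
    stats: ControlStats,
    manifest: ProbeManifest,
    params: WindowParams = WindowParams(),
) -> dict[str, list[DmrCall]]:
    """Reference-mode calling for every sample of a cohort."""
    return {
        s: call_dmrs_reference(cohort.sample(s), stats, manifest, params, sample_id=s)
        for s in cohort.sample_ids
    }


def call_dmrs_loo(
    cohort: BetaMatrix,
    manifest: ProbeManifest,
    params: WindowParams = WindowParams(),
) -> dict[str, list[DmrCall]]:
    """Leave-one-out calling: each sample against the rest of its cohort.

    A probe supports hypermethylation in sample s when
    beta_s >= max(cohort minus s) + loo_delta (mirror for hypo); a window
    needs >= min_outlier_probes such probes and has no extreme-probe
    criterion. Used for cohorts without an external control set.
    """
    if len(cohort.sample_ids) < 3:
        raise ValueError("leave-one-out calling needs >= 3 samples")
    out: dict[str, list[DmrCall]] = {s: [] for s in cohort.sample_ids}
    for chrom in manifest.chromosomes():
        probes = manifest.probes_on(chrom)
        probes = probes.loc[probes.index.isin(cohort.values.index)]
        if probes.empty:
            continue
        pos = probes["pos"].to_numpy()
        v = cohort.values.loc[probes.index].to_numpy(float)  # probes x samples
        vmax = np.where(np.isnan(v), -np.inf, v)
        vmin = np.where(np.isnan(v), np.inf, v)
        # leave-one-out max/min via top-2 order statistics per probe
        ord_max = np.sort(vmax, axis=1)
        ord_min = np.sort(vmin, axis=1)
        top1, top2 = ord_max[:, -1], ord_max[:, -2]
        bot1, bot2 = ord_min[:, 0], ord_min[:, 1]
        for j, sample in enumerate(cohort.sample_ids):
            beta = v[:, j]
            ok = ~np.isnan(beta)
            loo_max = np.where(vmax[:, j] == top1, top2, top1)
            loo_min = np.where(vmin[:, j] == bot1, bot2, bot1)
            hyper1 = ok & np.isfinite(loo_max) & (beta >= loo_max + params.loo_delta)
            hypo1 = ok & np.isfinite(loo_min) & (beta <= loo_min - params.loo_delta)
            for direction, crit1 in ((HYPER, hyper1), (HYPO, hypo1)):
                for ev, _ in _scan_windows(pos, crit1, None, params):
                    margin = np.where(
                        crit1[ev],
                        np.abs(beta[ev] - np.where(direction == HYPER, loo_max[ev], loo_min[ev])),
                        0.0,
                    )
                    out[sample].append(
                        DmrCall(
                            sample_id=sample,
                            chromosome=chrom,
                            start=int(pos[ev.min()]),
                            end=int(pos[ev.max()]),
                            direction=direction,
                            supporting_probe_ids=tuple(probes.index[ev]),
                            extreme_probe_ids=(),
                            max_abs_deviation=float(margin.max()),
                        )
                    )
    return out


def apply_deletion_filter(
    calls: list[DmrCall], flags: list[DeletionFlag]
) -> tuple[list[DmrCall], list[DmrCall]]:
    """Remove calls overlapping a putative homozygous deletion in the same sample.

    Erratic beta at deleted loci mimics outlier methylation; any >= 1 bp
    overlap with a same-sample deletion flag disqualifies the call. Returns
    (kept, removed); removed calls carry the ``deletion_overlap`` flag.
    """
    by_sample: dict[str, list[DeletionFlag]] = {}
    for f in flags:
        by_sample.setdefault(f.sample_id, []).append(f)
    kept, removed = [], []
    for c in calls:
        hit = any(
            c.overlaps(f.chromosome, f.start, f.end)
            for f in by_sample.get(c.sample_id, [])
        )
        if hit:
            c.flags.add("deletion_overlap")
            removed.append(c)
        else:
            kept.append(c)
    return kept, removed


def curation_flags(
    call: DmrCall,
    sample_beta: pd.Series,
    stats: ControlStats,
    manifest: ProbeManifest,
    cohort: BetaMatrix | None = None,
    params: WindowParams = WindowParams(),
) -> DmrCall:
    """Automated stand-ins for the manual-curation heuristics.

    ``noncontiguous``: a probe with negligible deviation (signed deviation in
    the call's direction < mean_delta / 2) lies strictly between two
    supporting probes — the pattern of random groupings of individually
    artifactual probes rather than a block methylation change.

    ``batch_suspect``: restricted to the call's supporting probes, the mean
    of the carrier's processing batch deviates from the mean of the other
    batches by >= mean_delta / 2 in the call's direction at >= half the
    probes — the signature of an array-batch shift rather than one outlier
    sample. Skipped when batch labels are absent.
    """
    sign = 1.0 if call.direction == HYPER else -1.0
    probes = manifest.probes_on(call.chromosome)
    span = probes[(probes["pos"] >= call.start) & (probes["pos"] <= call.end)]
    span = span.loc[span.index.isin(stats.table.index)]
    support = set(call.supporting_probe_ids)
    if len(span) > len(support):
        dev = sign * (
            sample_beta.reindex(span.index).to_numpy(float)
            - stats.table.loc[span.index, "mean"].to_numpy()
        )
        is_support = np.array([p in support for p in span.index])
        sup_idx = np.where(is_support)[0]
        inner = (np.arange(len(span)) > sup_idx.min()) & (
            np.arange(len(span)) < sup_idx.max()
        )
        quiet = ~is_support & inner & ~np.isnan(dev) & (dev < params.mean_delta / 2)
        if quiet.any():
            call.flags.add("noncontiguous")

    if cohort is not None and cohort.batch is not None:
        batches = cohort.batch
        carrier_batch = batches.get(call.sample_id)
        if carrier_batch is not None:
            in_batch = batches.index[batches == carrier_batch]
            out_batch = batches.index[batches != carrier_batch]
            if len(in_batch) >= 2 and len(out_batch) >= 1:
                pids = [p for p in call.supporting_probe_ids if p in cohort.values.index]
                if pids:
                    bmean = cohort.values.loc[pids, in_batch].mean(axis=1)
                    omean = cohort.values.loc[pids, out_batch].mean(axis=1)
                    shifted = sign * (bmean - omean) >= params.mean_delta / 2
                    if shifted.mean() >= 0.5:
                        call.flags.add("batch_suspect")
    return call


def call_imprinted(
    sample_beta: pd.Series,
    loci: dict[str, list[str]],
    controls: BetaMatrix,
    sample_id: str = "sample",
    sd_mult: float = 3.0,
    high_cut: float = 0.8,
    low_cut: float = 0.2,
) -> list[ImprintedCall]:
    """Screen imprinted loci for gain/loss of imprinting.

    Imprinted regions carry parent-of-origin methylation, so bulk beta is
    expected to be intermediate. Per locus, the sample's mean beta over the
    locus probes is compared to the distribution of per-control locus means:
    a call is made when |difference| > 3 control SDs, or the sample mean is
    > 0.8 or < 0.2. All triggered rules are recorded; ``sd3`` takes
    precedence in the ``rule`` field.
    """
    out: list[ImprintedCall] = []
    for locus, probe_ids in loci.items():
        pids = [p for p in probe_ids if p in sample_beta.index and p in controls.values.index]
        if not pids:
            logger.warning("imprinted locus %s has no usable probes; skipped", locus)
            continue
        mb = float(np.nanmean(sample_beta.loc[pids].to_numpy(float)))
        if np.isnan(mb):
            continue
        ctl_means = np.nanmean(controls.values.loc[pids].to_numpy(float), axis=0)
        ctl_means = ctl_means[~np.isnan(ctl_means)]
        if ctl_means.size < 2:
            logger.warning("imprinted locus %s has <2 controls; skipped", locus)
            continue
        cm = float(ctl_means.mean())
        csd = float(ctl_means.std(ddof=0))
        rules = []
        if abs(mb - cm) > sd_mult * csd:
            rules.append("sd3")
        if mb > high_cut:
            rules.append("extreme_high")
        if mb < low_cut:
            rules.append("extreme_low")
        if rules:
            out.append(
                ImprintedCall(
                    sample_id=sample_id,
                    locus_name=locus,
                    mean_beta=mb,
                    control_mean=cm,
                    control_sd=csd,
                    rule=rules[0],
                    rules_triggered=tuple(rules),
                )
            )
    return out


def find_recurrent(
    calls: list[DmrCall],
    family_of: dict[str, str] | None = None,
    min_carriers: int = 2,
) -> list[list[DmrCall]]:
    """Cluster the same methylation change seen in multiple unrelated samples.

    Calls cluster (transitively) when they share direction and >= 1
    supporting probe. ``family_of`` maps sample_id -> family_id; carriers are
    counted one per family so related carriers do not inflate recurrence.
    Returns clusters with >= ``min_carriers`` unrelated carriers.
    """
    n = len(calls)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    probe_map: dict[tuple[str, str], int] = {}
    for i, c in enumerate(calls):
        for p in c.supporting_probe_ids:
            key = (c.direction, p)
            if key in probe_map:
                ri, rj = find(i), find(probe_map[key])
                parent[ri] = rj
            else:
                probe_map[key] = i

    groups: dict[int, list[DmrCall]] = {}
    for i, c in enumerate(calls):
        groups.setdefault(find(i), []).append(c)

    clusters = []
    for g in groups.values():
        if family_of:
            carriers = {family_of.get(c.sample_id, c.sample_id) for c in g}
        else:
            carriers = {c.sample_id for c in g}
        if len(carriers) >= min_carriers:
            clusters.append(g)
    return clusters


def calls_to_bed(calls: list[DmrCall]) -> pd.DataFrame:
    """Render calls as BED6+ (0-based half-open; score = deviation x 1000)."""
    return pd.DataFrame(
        [
            {
                "chrom": c.chromosome,
                "start": c.start - 1,
                "end": c.end,
                "name": c.sample_id,
                "score": int(round(c.max_abs_deviation * 1000)),
                "strand": "+" if c.direction == HYPER else "-",
                "probes": ",".join(c.supporting_probe_ids),
                "flags": ",".join(sorted(c.flags)) or ".",
                "inheritance": c.inheritance,
            }
            for c in calls
        ]
    )
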