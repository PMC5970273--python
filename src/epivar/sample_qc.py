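"""Sample-level quality control.

Four screens are applied before (and one after) DMR calling:

* sex inference from sex-chromosome signal, flagging mismatches with
  reported sex;
* detection of clustered probe hybridization failures, the signature of a
  homozygous deletion (no target DNA -> erratic beta, high detection p);
* PCA outlier screening on M values;
* post-hoc exclusion of samples yielding an excess of DMR calls, which in
  practice marks array-quality problems rather than biology.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import BetaMatrix, DetectionPMatrix, ProbeManifest, mvalue_transform

logger = logging.getLogger(__name__)

__all__ = [
    "DeletionFlag",
    "QcReport",
    "infer_sex",
    "flag_failed_probe_clusters",
    "pca_outlier_samples",
    "exclude_high_dmr_samples",
    "deletion_flags_to_bed",
]


@dataclass(frozen=True)
class DeletionFlag:
    """A putative homozygous deletion: >=3 co-failing probes within 3 kb."""

    sample_id: str
    chromosome: str
    start: int  # 1-based, position of first failing probe
    end: int  # 1-based, position of last failing probe
    failing_probe_ids: tuple[str, ...]

    @property
    def n_failing(self) -> int:
        return len(self.failing_probe_ids)


@dataclass
class QcReport:
    sample_id: str
    inferred_sex: str = "unknown"
    sex_mismatch: bool = False
    mean_chrY_detection_p: float = float("nan")
    mean_chrX_beta: float = float("nan")
    pca_outlier: bool = False
    n_dmrs: int = 0
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.excluded and not self.exclusion_reason:
            raise ValueError("excluded sample needs an exclusion_reason")


def infer_sex(
    beta: BetaMatrix,
    detp: DetectionPMatrix,
    manifest: ProbeManifest,
) -> pd.DataFrame:
    """Infer sample sex from (mean chrY detection p, mean chrX beta).

    Males have hybridizing chrY probes (low detection p) and hemizygous,
    bimodal chrX methylation; females show failed chrY probes and
    intermediate chrX beta from X inactivation. Samples are split by 2-means
    clustering on the two features (z-scaled); the cluster with lower mean
    chrY detection p is male. Returns a DataFrame indexed by sample with
    columns inferred_sex, sex_mismatch, mean_chrY_detection_p, mean_chrX_beta.
    """
    classes = manifest.chrom_class_of()
    y_probes = manifest.table.index[classes == "Y"]
    x_probes = manifest.table.index[classes == "X"]
    samples = beta.sample_ids
    out = pd.DataFrame(
        index=pd.Index(samples, name="sample_id"),
        columns=["inferred_sex", "sex_mismatch", "mean_chrY_detection_p", "mean_chrX_beta"],
    )
    out["inferred_sex"] = "unknown"
    out["sex_mismatch"] = False

    y_avail = detp.values.index.intersection(y_probes)
    x_avail = beta.values.index.intersection(x_probes)
    if len(y_avail) == 0 or len(x_avail) == 0:
        warnings.warn("infer_sex: no sex-chromosome probes; all samples 'unknown'")
        return out

    feat_y = detp.values.loc[y_avail, samples].mean(axis=0, skipna=True)
    feat_x = beta.values.loc[x_avail, samples].mean(axis=0, skipna=True)
    out["mean_chrY_detection_p"] = feat_y
    out["mean_chrX_beta"] = feat_x

    feats = np.column_stack([feat_y.to_numpy(float), feat_x.to_numpy(float)])
    spread = feats.std(axis=0)
    if np.all(spread < 1e-12) or len(samples) < 2:
        warnings.warn("infer_sex: degenerate clustering (all samples identical)")
        return out
    scaled = (feats - feats.mean(axis=0)) / np.where(spread < 1e-12, 1.0, spread)

    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(scaled)
    labels = km.labels_
    mean_y = [feat_y.to_numpy(float)[labels == k].mean() for k in (0, 1)]
    male_label = int(np.argmin(mean_y))
    out["inferred_sex"] = np.where(labels == male_label, "male", "female")

    if beta.sex_reported is not None:
        reported = beta.sex_reported.reindex(out.index)
        known = reported.isin(["male", "female"])
        out.loc[known, "sex_mismatch"] = (
            out.loc[known, "inferred_sex"] != reported[known]
        )
    return out


def flag_failed_probe_clusters(
    detp: DetectionPMatrix,
    manifest: ProbeManifest,
    window_bp: int = 3000,
    min_probes: int = 3,
    p_threshold: float = 0.01,
) -> list[DeletionFlag]:
    """Flag windows with clustered probe-detection failures per sample.

    A span qualifies when >= ``min_probes`` probes with detection
    p > ``p_threshold`` co-occur within ``window_bp``. Qualifying spans that
    share failing probes are merged; the flag interval runs from the first to
    the last failing probe of the merged set.
    """
    flags: list[DeletionFlag] = []
    for chrom in manifest.chromosomes():
        probes = manifest.probes_on(chrom)
        avail = probes.index.intersection(detp.values.index)
        if len(avail) < min_probes:
            continue
        probes = probes.loc[probes.index.isin(avail)]
        pos = probes["pos"].to_numpy()
        pvals = detp.values.loc[probes.index]
        for sample in detp.sample_ids:
            p = pvals[sample].to_numpy(float)
            failing = np.where(~np.isnan(p) & (p > p_threshold))[0]
            if failing.size < min_probes:
                continue
            fpos = pos[failing]
            # windows anchored at each failing probe: [fpos[a], fpos[a]+window_bp)
            # qualify when they hold >= min_probes failing probes; qualifying
            # windows sharing failing probes merge into one flag
            windows: list[tuple[int, int]] = []  # index spans into `failing`
            for a in range(failing.size):
                b = a
                while b + 1 < failing.size and fpos[b + 1] <= fpos[a] + window_bp - 1:
                    b += 1
                if b - a + 1 >= min_probes:
                    windows.append((a, b))
            if not windows:
                continue
            merged: list[list[int]] = []
            for a, b in windows:  # already sorted by a
                if merged and a <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], b)
                else:
                    merged.append([a, b])
            for a, b in merged:
                pids = tuple(probes.index[failing[a : b + 1]])
                flags.append(
                    DeletionFlag(
                        sample_id=sample,
                        chromosome=chrom,
                        start=int(fpos[a]),
                        end=int(fpos[b]),
                        failing_probe_ids=pids,
                    )
                )
    return flags


def pca_outlier_samples(
    m_values: pd.DataFrame,
    n_components: int = 2,
    z_cut: float = 4.0,
) -> list[str]:
    """Flag samples that are extreme on any leading principal component.

    ``m_values`` is a probes x samples matrix of M values (autosomal probes
    only; chrX is screened separately by sex stratum). Scores are computed by
    SVD of the mean-centered matrix; a sample is flagged when its score lies
    more than ``z_cut`` robust SDs (MAD x 1.4826) from the component median.
    """
    n_samples = m_values.shape[1]
    if n_samples < max(3, n_components + 1):
        raise ValueError(f"need more samples than components, got {n_samples}")
    x = m_values.to_numpy(dtype=float).T  # samples x probes
    x = np.nan_to_num(x - np.nanmean(x, axis=0, keepdims=True))
    k = min(n_components, min(x.shape) - 1)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :k] * s[:k]
    flagged: set[str] = set()
    for c in range(scores.shape[1]):
        col = scores[:, c]
        med = np.median(col)
        mad = np.median(np.abs(col - med)) * 1.4826
        if mad < 1e-12:
            # robust scale collapses when most samples coincide; fall back
            # to mean absolute deviation so a lone extreme sample still shows
            mad = np.mean(np.abs(col - med)) or 0.0
            if mad < 1e-12:
                continue
        out = np.abs(col - med) > z_cut * mad
        flagged.update(np.asarray(m_values.columns)[out])
    return sorted(flagged)


def exclude_high_dmr_samples(
    per_sample_dmr_counts: dict[str, int], max_dmrs: int = 10
) -> set[str]:
    """Samples with strictly more than ``max_dmrs`` curated calls are excluded.

    Excess calls in one sample indicate technical artifacts rather than many
    real events; the boundary count (exactly ``max_dmrs``) is retained.
    """
    return {s for s, c in per_sample_dmr_counts.items() if c > max_dmrs}


def deletion_flags_to_bed(flags: list[DeletionFlag]) -> pd.DataFrame:
    """Render deletion flags as 6-column BED (0-based half-open)."""
    return pd.DataFrame(
        [
            {
                "chrom": f.chromosome,
                "start": f.start - 1,
                "end": f.end,
                "name": f.sample_id,
                "score": f.n_failing,
                "strand": ".",
            }
            for f in flags
        ]
    )
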