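"""Data model and shared transforms for methylation-array matrices.

The pipeline operates on Infinium-style array data: a probe manifest giving
genomic placement of each CpG probe, a matrix of per-sample beta values
(fraction methylated, in [0, 1]) and a parallel matrix of detection p-values
(hybridization confidence). All genomic coordinates are 1-based on disk and
in memory; BED output converts explicitly at the boundary.

On-disk convention follows GEO series-matrix layout: probes as rows, samples
as columns, tab-separated, ``NA`` for missing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeManifest",
    "BetaMatrix",
    "DetectionPMatrix",
    "ControlStats",
    "read_manifest",
    "read_beta_matrix",
    "read_detp_matrix",
    "write_matrix",
    "quantile_normalize",
    "mvalue_transform",
    "compute_control_stats",
]

_AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}
_X_NAMES = {"chrX", "X"}
_Y_NAMES = {"chrY", "Y"}


def chrom_class(chromosome: str) -> str:
    """Classify a chromosome name as 'autosome', 'X', or 'Y'.

    Synthetic chromosomes (e.g. 'chrS') count as autosomes.
    """
    if chromosome in _X_NAMES:
        return "X"
    if chromosome in _Y_NAMES:
        return "Y"
    return "autosome"


@dataclass
class ProbeManifest:
    """Genomic placement of array probes; the coordinate backbone for windows.

    ``table`` is indexed by probe_id with columns ``chrom`` (str), ``pos``
    (1-based int), ``design_type`` ('I' or 'II').
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids in manifest: {dups[:5]}")
        if (t["pos"] < 1).any():
            raise ValueError("manifest positions must be >= 1")
        self.table = t.sort_values(["chrom", "pos"], kind="stable")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def probes_on(self, chromosome: str) -> pd.DataFrame:
        """Probes on one chromosome in position-sorted order."""
        return self.table[self.table["chrom"] == chromosome]

    def chrom_class_of(self) -> pd.Series:
        return self.table["chrom"].map(chrom_class)

    def autosomal_probes(self) -> pd.Index:
        return self.table.index[self.chrom_class_of() == "autosome"]


@dataclass
class BetaMatrix:
    """Per-probe, per-sample methylation fractions.

    ``values``: DataFrame, probes (rows) x samples (columns), entries in
    [0, 1] or NaN. ``batch`` and ``sex_reported`` are optional per-sample
    Series aligned to the columns.
    """

    values: pd.DataFrame
    batch: pd.Series | None = None
    sex_reported: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        v = self.values.to_numpy(dtype=float)
        bad = (v < 0) | (v > 1)
        if np.any(bad & ~np.isnan(v)):
            i, j = np.argwhere(bad & ~np.isnan(v))[0]
            raise ValueError(
                f"beta value out of [0,1] at probe {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}: {v[i, j]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    def sample(self, sample_id: str) -> pd.Series:
        return self.values[sample_id]


@dataclass
class DetectionPMatrix:
    """Detection p-values on the same probe x sample axes as a BetaMatrix."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        bad = (v < 0) | (v > 1)
        if np.any(bad & ~np.isnan(v)):
            raise ValueError("detection p-value out of [0,1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ControlStats:
    """Per-probe summaries of the control-cohort beta distribution.

    ``table`` is indexed by probe_id with columns n, mean, sd, q_upper,
    q_lower, max, min. Probes with fewer than two non-missing control values
    are absent (stats unavailable; callers must skip them).
    """

    table: pd.DataFrame
    upper_q: float = 0.999
    lower_q: float = 0.001

    def available(self, probe_ids) -> pd.Index:
        return pd.Index(probe_ids).intersection(self.table.index)


# ---------------------------------------------------------------------------
# Readers / writers


def read_manifest(path: str | Path) -> ProbeManifest:
    """Read a probe-manifest TSV with columns probe_id, chrom, pos, design_type."""
    t = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    t = t.set_index("probe_id")
    t["pos"] = t["pos"].astype(int)
    return ProbeManifest(t)


def _read_matrix(path: str | Path, manifest: ProbeManifest, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                probe = df.index[bad.argmax()]
                raise ValueError(
                    f"malformed numeric cell in {kind} matrix at probe {probe!r}, "
                    f"sample {col!r}: {df[col][bad].iloc[0]!r}"
                )
            df[col] = coerced
    unknown = df.index.difference(manifest.probe_ids)
    if len(unknown):
        logger.warning(
            "%s matrix: dropping %d probes absent from manifest", kind, len(unknown)
        )
        df = df.loc[df.index.intersection(manifest.probe_ids)]
    # align to manifest (sorted) order, keeping only probes present in file
    order = manifest.probe_ids[manifest.probe_ids.isin(df.index)]
    return df.loc[order]


def read_beta_matrix(path: str | Path, manifest: ProbeManifest) -> BetaMatrix:
    """Read a beta-value TSV (probes x samples) restricted to manifest probes."""
    return BetaMatrix(_read_matrix(path, manifest, "beta"))


def read_detp_matrix(path: str | Path, manifest: ProbeManifest) -> DetectionPMatrix:
    """Read a detection p-value TSV on the same layout as the beta matrix."""
    return DetectionPMatrix(_read_matrix(path, manifest, "detection-p"))


def write_matrix(values: pd.DataFrame, path: str | Path) -> None:
    """Write a probes x samples matrix as TSV with NA for missing."""
    out = values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# Transforms


def quantile_normalize(m: BetaMatrix) -> BetaMatrix:
    """Force all samples onto a common empirical distribution.

    Each sample's non-missing values are replaced by the cross-sample mean of
    order statistics at the matching within-sample rank. Samples with missing
    cells are normalized against a rank-interpolated reference; missing cells
    stay missing. With a single sample the input is returned unchanged.
    """
    v = m.values.to_numpy(dtype=float)
    n_probes, n_samples = v.shape
    if n_samples < 2:
        warnings.warn("quantile_normalize: single sample, returning unchanged")
        return m

    # Reference quantile function on a grid of n_probes points: average each
    # sample's empirical quantile function (linear interpolation between
    # order statistics).
    grid = np.linspace(0.0, 1.0, n_probes)
    ref = np.zeros(n_probes)
    n_used = 0
    for j in range(n_samples):
        col = v[:, j]
        obs = np.sort(col[~np.isnan(col)])
        if obs.size == 0:
            continue
        if obs.size == 1:
            ref += obs[0]
        else:
            q = np.linspace(0.0, 1.0, obs.size)
            ref += np.interp(grid, q, obs)
        n_used += 1
    ref /= n_used

    out = np.full_like(v, np.nan)
    for j in range(n_samples):
        col = v[:, j]
        mask = ~np.isnan(col)
        n = mask.sum()
        if n == 0:
            continue
        # average ranks for ties -> interpolate the reference between grid pts
        order = pd.Series(col[mask]).rank(method="average").to_numpy() - 1.0
        q = order / (n - 1) if n > 1 else np.zeros(1)
        out[mask, j] = np.interp(q, grid, ref)
    out = np.clip(out, 0.0, 1.0)
    return BetaMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        batch=m.batch,
        sex_reported=m.sex_reported,
    )


def mvalue_transform(beta, epsilon: float = 0.001):
    """logit2 transform: log2(b / (1 - b)) with b clipped to [eps, 1 - eps].

    Variance-stabilized scale used for PCA and density QC. Accepts scalars
    or arrays; clipping guarantees finite output at beta = 0 or 1.
    """
    b = np.clip(np.asarray(beta, dtype=float), epsilon, 1.0 - epsilon)
    out = np.log2(b / (1.0 - b))
    return float(out) if np.isscalar(beta) else out


def compute_control_stats(
    controls: BetaMatrix, upper_q: float = 0.999, lower_q: float = 0.001
) -> ControlStats:
    """Per-probe control-distribution summaries against which outliers are defined.

    Quantiles use linear interpolation between order statistics
    (index h = (n - 1) q + 1 on the sorted values); SD uses the population
    denominator n. Probes with fewer than 2 non-missing controls are omitted.
    """
    v = controls.values.to_numpy(dtype=float)
    n = (~np.isnan(v)).sum(axis=1)
    keep = n >= 2
    if not keep.all():
        logger.info("compute_control_stats: %d probes with <2 controls skipped",
                    int((~keep).sum()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(v, axis=1)
        sd = np.nanstd(v, axis=1, ddof=0)
        qup = np.nanquantile(v, upper_q, axis=1)
        qlo = np.nanquantile(v, lower_q, axis=1)
        vmax = np.nanmax(np.where(np.isnan(v), -np.inf, v), axis=1)
        vmin = np.nanmin(np.where(np.isnan(v), np.inf, v), axis=1)
    table = pd.DataFrame(
        {
            "n": n,
            "mean": mean,
            "sd": sd,
            "q_upper": qup,
            "q_lower": qlo,
            "max": vmax,
            "min": vmin,
        },
        index=controls.values.index,
    )[keep]
    return ControlStats(table, upper_q=upper_q, lower_q=lower_q)
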