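from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from epivar.core_io import BetaMatrix, ControlStats, ProbeManifest


def make_manifest(positions, chrom="chrS", prefix="cg"):
    """Manifest with one probe per position on a single chromosome."""
    t = pd.DataFrame(
        {
            "probe_id": [f"{prefix}{i:04d}" for i in range(len(positions))],
            "chrom": [chrom] * len(positions),
            "pos": list(positions),
            "design_type": ["II"] * len(positions),
        }
    ).set_index("probe_id")
    return ProbeManifest(t)


def make_stats(probe_ids, mean, q_upper=None, q_lower=None, vmax=None, vmin=None, sd=0.02):
    """Hand-built control stats with constant or per-probe values."""
    n = len(probe_ids)

    def expand(x, default):
        if x is None:
            x = default
        return np.full(n, x) if np.isscalar(x) else np.asarray(x, float)

    mean = expand(mean, None)
    table = pd.DataFrame(
        {
            "n": np.full(n, 100),
            "mean": mean,
            "sd": expand(sd, None),
            "q_upper": expand(q_upper, mean + 0.05),
            "q_lower": expand(q_lower, mean - 0.05),
            "max": expand(vmax, mean + 0.08),
            "min": expand(vmin, mean - 0.08),
        },
        index=pd.Index(probe_ids),
    )
    return ControlStats(table)


def make_beta(values, sample_ids=None, probe_ids=None, **kw):
    v = np.atleast_2d(np.asarray(values, float))
    probe_ids = probe_ids or [f"cg{i:04d}" for i in range(v.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(v.shape[1])]
    return BetaMatrix(pd.DataFrame(v, index=probe_ids, columns=sample_ids), **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
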