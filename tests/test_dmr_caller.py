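"""The sliding-window outlier caller against hand cases and a naive oracle."""

import numpy as np
import pandas as pd
import pytest

from epivar.core_io import BetaMatrix, compute_control_stats
from epivar.dmr_caller import (
    DmrCall,
    WindowParams,
    apply_deletion_filter,
    call_dmrs_loo,
    call_dmrs_reference,
    call_imprinted,
    curation_flags,
    find_recurrent,
)
from epivar.sample_qc import DeletionFlag

from conftest import make_beta, make_manifest, make_stats
from oracles import reference_caller_enumeration

PARAMS = WindowParams()


def run_reference(positions, beta_vals, stats):
    manifest = make_manifest(positions)
    sample = pd.Series(beta_vals, index=manifest.table.index, dtype=float)
    return call_dmrs_reference(sample, stats, manifest, PARAMS, sample_id="pt")


class TestReferenceCaller:
    def test_sample_at_control_mean_is_null(self):
        positions = [100, 300, 500, 700, 900]
        stats = make_stats([f"cg{i:04d}" for i in range(5)], mean=0.10,
                           q_upper=0.20, vmax=0.30)
        assert run_reference(positions, [0.10] * 5, stats) == []

    def test_three_strong_probes_one_hyper_call(self):
        # controls: mean 0.10, 99.9th pct 0.20, max 0.30 everywhere
        positions = [100, 300, 500, 700, 900]
        stats = make_stats([f"cg{i:04d}" for i in range(5)], mean=0.10,
                           q_upper=0.20, vmax=0.30)
        calls = run_reference(positions, [0.45, 0.45, 0.45, 0.10, 0.10], stats)
        assert len(calls) == 1
        c = calls[0]
        assert c.direction == "hyper"
        assert set(c.supporting_probe_ids) == {"cg0000", "cg0001", "cg0002"}
        assert len(c.extreme_probe_ids) >= 1
        assert (c.start, c.end) == (100, 500)
        assert c.max_abs_deviation == pytest.approx(0.35)

    def test_extreme_probe_may_coincide_with_supporting(self):
        # third probe passes (i) only (0.28 > 0.20, >= 0.25) but probes 1-2
        # still satisfy (ii); one call remains
        positions = [100, 300, 500, 700, 900]
        stats = make_stats([f"cg{i:04d}" for i in range(5)], mean=0.10,
                           q_upper=0.20, vmax=0.30)
        calls = run_reference(positions, [0.45, 0.45, 0.28, 0.10, 0.10], stats)
        assert len(calls) == 1
        assert set(calls[0].supporting_probe_ids) == {"cg0000", "cg0001", "cg0002"}

    def test_no_extreme_probe_no_call(self):
        # all probes pass (i) but none reaches max + 0.10
        positions = [100, 300, 500, 700, 900]
        stats = make_stats([f"cg{i:04d}" for i in range(5)], mean=0.10,
                           q_upper=0.20, vmax=0.30)
        assert run_reference(positions, [0.28, 0.28, 0.28, 0.28, 0.28], stats) == []

    def test_hypo_mirror(self):
        positions = [100, 300, 500]
        stats = make_stats([f"cg{i:04d}" for i in range(3)], mean=0.80,
                           q_lower=0.70, vmin=0.60)
        calls = run_reference(positions, [0.40, 0.40, 0.40], stats)
        assert len(calls) == 1 and calls[0].direction == "hypo"

    def test_probes_outside_window_not_grouped(self):
        # three outliers but spread over 2 kb: no single 1-kb window holds 3
        positions = [100, 1000, 2100]
        stats = make_stats([f"cg{i:04d}" for i in range(3)], mean=0.10,
                           q_upper=0.20, vmax=0.30)
        assert run_reference(positions, [0.45, 0.45, 0.45], stats) == []

    def test_missing_beta_cannot_support(self):
        positions = [100, 300, 500]
        stats = make_stats([f"cg{i:04d}" for i in range(3)], mean=0.10,
                           q_upper=0.20, vmax=0.30)
        assert run_reference(positions, [0.45, np.nan, 0.45], stats) == []

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_oracle(self, seed):
        """Random matrices: merged calls equal the naive window enumeration."""
        rng = np.random.default_rng(seed)
        n_probes = int(rng.integers(10, 200))
        n_controls = int(rng.integers(5, 50))
        positions = np.sort(
            rng.choice(np.arange(1, n_probes * 120), n_probes, replace=False)
        )
        controls = make_beta(rng.random((n_probes, n_controls)))
        stats = compute_control_stats(controls)
        # mixture of null and outlier-ish values to exercise both branches
        beta_vals = np.where(
            rng.random(n_probes) < 0.25, rng.random(n_probes), 0.5
        )
        calls = run_reference(positions, beta_vals, stats)
        st = stats.table
        oracle_events = reference_caller_enumeration(
            positions,
            beta_vals,
            {k: st[k].to_numpy() for k in ("mean", "q_upper", "q_lower", "max", "min")},
            PARAMS,
        )
        manifest_ids = [f"cg{i:04d}" for i in range(n_probes)]
        got = {
            (c.direction, frozenset(c.supporting_probe_ids), frozenset(c.extreme_probe_ids))
            for c in calls
        }
        expected = {
            (
                e["direction"],
                frozenset(manifest_ids[i] for i in e["crit1"]),
                frozenset(manifest_ids[i] for i in e["crit2"]),
            )
            for e in oracle_events
        }
        assert got == expected

    def test_monotone_in_mean_delta(self, rng):
        n = 50
        positions = np.arange(1, n + 1) * 150
        controls = make_beta(rng.random((n, 30)))
        stats = compute_control_stats(controls)
        beta_vals = rng.random(n)
        counts = []
        for delta in (0.05, 0.15, 0.30):
            params = WindowParams(mean_delta=delta)
            manifest = make_manifest(positions)
            sample = pd.Series(beta_vals, index=manifest.table.index)
            counts.append(len(call_dmrs_reference(sample, stats, manifest, params)))
        assert counts[0] >= counts[1] >= counts[2]

    def test_inlying_extra_control_never_adds_calls(self, rng):
        n = 30
        positions = np.arange(1, n + 1) * 200
        vals = rng.uniform(0.2, 0.6, size=(n, 25))
        beta_vals = rng.random(n)
        base_stats = compute_control_stats(make_beta(vals))
        extra = (vals.min(axis=1) + vals.max(axis=1)) / 2  # strictly inside range
        aug_stats = compute_control_stats(
            make_beta(np.column_stack([vals, extra]),
                      sample_ids=[f"s{j}" for j in range(26)])
        )
        manifest = make_manifest(positions)
        sample = pd.Series(beta_vals, index=manifest.table.index)
        n_base = len(call_dmrs_reference(sample, base_stats, manifest, PARAMS))
        n_aug = len(call_dmrs_reference(sample, aug_stats, manifest, PARAMS))
        assert n_aug <= n_base


class TestLooCaller:
    def test_identical_cohort_no_calls(self):
        manifest = make_manifest([100, 300, 500])
        cohort = make_beta(np.full((3, 5), 0.5))
        calls = call_dmrs_loo(cohort, manifest)
        assert all(len(v) == 0 for v in calls.values())

    def test_shifted_sample_called_once(self, rng):
        n = 10
        manifest = make_manifest(np.arange(1, n + 1) * 120)
        vals = rng.uniform(0.30, 0.35, size=(n, 21))
        vals[2:5, 0] += 0.40  # 3 adjacent probes shifted in sample 0
        cohort = make_beta(vals)
        calls = call_dmrs_loo(cohort, manifest)
        assert len(calls["s0"]) == 1
        assert calls["s0"][0].direction == "hyper"
        assert all(len(calls[f"s{j}"]) == 0 for j in range(1, 21))

    def test_shift_below_margin_not_called(self, rng):
        n = 10
        manifest = make_manifest(np.arange(1, n + 1) * 120)
        vals = rng.uniform(0.30, 0.35, size=(n, 21))
        vals[2:5, 0] += 0.10  # below loo_delta over the others' max
        cohort = make_beta(np.clip(vals, 0, 1))
        calls = call_dmrs_loo(cohort, manifest)
        assert all(len(v) == 0 for v in calls.values())

    def test_too_few_samples(self):
        manifest = make_manifest([100])
        with pytest.raises(ValueError):
            call_dmrs_loo(make_beta([[0.5, 0.5]]), manifest)


class TestDeletionFilter:
    def _call(self, sample="pt", start=1000, end=1800):
        return DmrCall(sample, "chrS", start, end, "hyper",
                       ("cg1", "cg2", "cg3"), ("cg1",), 0.4)

    def test_no_flags_unchanged(self):
        kept, removed = apply_deletion_filter([self._call()], [])
        assert len(kept) == 1 and removed == []

    def test_overlap_same_sample_removed(self):
        flag = DeletionFlag("pt", "chrS", 1700, 4000, ("cgx",))
        kept, removed = apply_deletion_filter([self._call()], [flag])
        assert kept == [] and len(removed) == 1
        assert "deletion_overlap" in removed[0].flags

    def test_other_sample_kept(self):
        flag = DeletionFlag("other", "chrS", 1700, 4000, ("cgx",))
        kept, removed = apply_deletion_filter([self._call()], [flag])
        assert len(kept) == 1 and removed == []


class TestCurationFlags:
    def _setup(self, beta_vals, support_ranks):
        positions = [100, 250, 400, 550, 700]
        manifest = make_manifest(positions)
        ids = list(manifest.table.index)
        stats = make_stats(ids, mean=0.10, q_upper=0.20, vmax=0.30)
        sample = pd.Series(beta_vals, index=ids)
        support = tuple(ids[r] for r in support_ranks)
        call = DmrCall("pt", "chrS", positions[support_ranks[0]],
                       positions[support_ranks[-1]], "hyper", support,
                       (support[0],), 0.35)
        return call, sample, stats, manifest

    def test_contiguous_block_unflagged(self):
        call, sample, stats, manifest = self._setup(
            [0.45, 0.45, 0.45, 0.10, 0.10], [0, 1, 2])
        out = curation_flags(call, sample, stats, manifest)
        assert "noncontiguous" not in out.flags

    def test_interspersed_quiet_probes_flagged(self):
        call, sample, stats, manifest = self._setup(
            [0.45, 0.10, 0.45, 0.10, 0.45], [0, 2, 4])
        out = curation_flags(call, sample, stats, manifest)
        assert "noncontiguous" in out.flags

    def test_batch_shift_flagged(self):
        from epivar.synthetic import SimulationConfig, simulate_cohort
        from epivar.core_io import compute_control_stats

        sim = simulate_cohort(
            SimulationConfig(seed=11, n_controls=60, n_cases=6, n_probes=400,
                             n_planted_epivariations=0, n_planted_deletions=0,
                             batch_shift=0.25)
        )
        batch_rec = next(r for r in sim.truth if r.type == "batch")
        carrier = next(s for s in batch_rec.sample_ids if s in sim.case_ids)
        # control stats from the unshifted batch only, so the caller sees the
        # shifted samples as outliers
        clean = [s for s in sim.control_ids if sim.beta.batch[s] != "batch0"]
        stats = compute_control_stats(BetaMatrix(sim.beta.values[clean]))
        calls = call_dmrs_reference(
            sim.beta.sample(carrier), stats, sim.manifest, sample_id=carrier
        )
        hits = [c for c in calls
                if set(c.supporting_probe_ids) & set(batch_rec.probe_ids)]
        assert hits, "planted batch shift should surface as a call"
        out = curation_flags(hits[0], sim.beta.sample(carrier), stats,
                             sim.manifest, cohort=sim.beta)
        assert "batch_suspect" in out.flags


class TestImprinted:
    def _controls(self, rng, mean, sd, n=100):
        vals = rng.normal(mean, sd, size=(4, n)).clip(0, 1)
        # per-control locus means ~ Normal(mean, sd/2); rescale to target SD
        vals = mean + (vals - vals.mean()) * (sd / max(vals.std(), 1e-9))
        return make_beta(vals.clip(0, 1))

    def test_no_call_at_control_mean(self, rng):
        controls = self._controls(rng, 0.50, 0.02)
        pids = list(controls.values.index)
        sample = pd.Series(0.50, index=pids)
        assert call_imprinted(sample, {"LOC1": pids}, controls) == []

    def test_sd3_rule(self, rng):
        controls = self._controls(rng, 0.50, 0.0)  # zero spread: SD ~ 0
        pids = list(controls.values.index)
        sample = pd.Series(0.57, index=pids)
        calls = call_imprinted(sample, {"LOC1": pids}, controls)
        assert len(calls) == 1 and calls[0].rule == "sd3"

    def test_extreme_high_only_when_within_3sd(self):
        # control locus means 0.80 +/- 0.03; sample 0.85 is inside 3 SD but
        # beyond the 0.8 absolute bound
        vals = np.array([[0.77, 0.80, 0.83, 0.80, 0.77, 0.83]] * 3)
        controls = make_beta(vals)
        pids = list(controls.values.index)
        sample = pd.Series(0.85, index=pids)
        calls = call_imprinted(sample, {"LOC1": pids}, controls)
        assert len(calls) == 1
        assert calls[0].rule == "extreme_high"
        assert calls[0].rules_triggered == ("extreme_high",)

    def test_locus_without_probes_skipped(self, rng):
        controls = self._controls(rng, 0.5, 0.02)
        sample = pd.Series(0.5, index=controls.values.index)
        assert call_imprinted(sample, {"EMPTY": ["cg_missing"]}, controls) == []


class TestRecurrence:
    def _call(self, sample, probes, direction="hyper"):
        return DmrCall(sample, "chrS", 100, 500, direction, tuple(probes),
                       (probes[0],), 0.4)

    def test_single_carrier_no_cluster(self):
        assert find_recurrent([self._call("a", ["p1", "p2", "p3"])]) == []

    def test_two_unrelated_shared_probes_cluster(self):
        calls = [self._call("a", ["p1", "p2", "p3"]),
                 self._call("b", ["p2", "p3", "p4"])]
        clusters = find_recurrent(calls)
        assert len(clusters) == 1 and len(clusters[0]) == 2

    def test_opposite_directions_never_cluster(self):
        calls = [self._call("a", ["p1", "p2", "p3"], "hyper"),
                 self._call("b", ["p1", "p2", "p3"], "hypo")]
        assert find_recurrent(calls) == []

    def test_related_carriers_count_once(self):
        calls = [self._call("child", ["p1", "p2", "p3"]),
                 self._call("mother", ["p1", "p2", "p3"])]
        family = {"child": "fam1", "mother": "fam1"}
        assert find_recurrent(calls, family_of=family) == []

    def test_transitive_closure(self):
        calls = [self._call("a", ["p1", "p2", "p3"]),
                 self._call("b", ["p3", "p4", "p5"]),
                 self._call("c", ["p5", "p6", "p7"])]
        clusters = find_recurrent(calls)
        assert len(clusters) == 1 and len(clusters[0]) == 3
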