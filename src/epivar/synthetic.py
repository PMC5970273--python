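"""Synthetic methylation cohorts with planted ground truth.

The generator emulates the statistical structure the pipeline assumes,
without any real array data:

* per-probe baseline methylation is bimodal — most CpGs are either nearly
  unmethylated (Beta(2,18)) or nearly fully methylated (Beta(18,2)), with a
  minority intermediate (Beta(10,10));
* per-sample values scatter around the probe baseline with a small,
  beta-distributed noise (default SD 0.02, typical of replicate 450k beta
  precision at non-extreme probes);
* planted epivariations are *allelic*: a diploid sample gaining full
  methylation on one allele moves bulk beta by roughly half the allele
  change, hence the default shift of 0.35 across a cluster of >= 3 probes
  within 1 kb;
* planted homozygous deletions produce the hybridization-failure signature:
  detection p well above 0.01 and erratic beta at >= 3 clustered probes;
* families transmit parental epivariations to each child independently with
  probability tau, and children can acquire private de novo events;
* expression, allelic read counts, and rare motif-disrupting variants are
  coupled to planted promoter events in the direction biology dictates.

Every draw flows from one integer seed through ``numpy.random.default_rng``;
identical configs give bit-identical outputs. The synthetic genome is a
single autosome ``chrS`` (plus optional small chrX/chrY probe sets for
sex-inference tests), coordinates 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import BetaMatrix, DetectionPMatrix, ProbeManifest
from .dmr_caller import HYPER, HYPO
from .inheritance import Pedigree
from .variant_link import GT_HET, GT_REF, MotifInterval, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "SimulatedCohort",
    "SimulatedFamilies",
    "simulate_cohort",
    "plant_epivariation",
    "plant_deletion",
    "simulate_families",
    "simulate_expression_and_variants",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped simulation conditions.

    Defaults follow the scaled recovery design: 200 reference controls, 20
    test samples, 20 planted allelic epivariations of +/-0.35 across 4
    probes, 5 planted deletions, probe noise SD 0.02.
    """

    n_controls: int = 200
    n_cases: int = 20
    n_probes: int = 2000
    probe_archetype_mix: tuple[float, float, float] = (0.45, 0.45, 0.10)
    mean_gap_bp: int = 500
    noise_sd: float = 0.02
    detection_p_baseline: float = 0.001
    n_planted_epivariations: int = 20
    planted_delta: float = 0.35
    planted_delta_spread: float = 0.10
    probes_per_event: int = 4
    event_span_bp: int = 1000
    n_planted_deletions: int = 5
    batch_shift: float = 0.0
    n_batches: int = 2
    include_sex_chroms: bool = False
    # family layer
    n_families: int = 117
    children_range: tuple[int, int] = (2, 4)
    n_parental_events: int = 47
    transmission_prob: float = 0.5
    de_novo_rate: float = 0.1
    # functional layer
    expression_effect: float = 1.5
    expression_effect_sd: float = 0.3
    ase_depth: int = 30
    motif_coupling: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_sd", "planted_delta", "transmission_prob",
                     "de_novo_rate", "motif_coupling"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if abs(sum(self.probe_archetype_mix) - 1.0) > 1e-9:
            raise ValueError("probe_archetype_mix must sum to 1")


@dataclass(frozen=True)
class TruthRecord:
    event_id: str
    type: str  # epivariation | deletion | batch | expression_effect | motif_variant
    sample_ids: tuple[str, ...]
    chromosome: str
    start: int
    end: int
    direction: str = ""
    delta: float = 0.0
    probe_ids: tuple[str, ...] = ()
    inheritance_truth: str = ""
    transmitted_children: tuple[str, ...] = ()
    gene_id: str = ""


@dataclass
class SimulatedCohort:
    manifest: ProbeManifest
    beta: BetaMatrix
    detp: DetectionPMatrix
    truth: list[TruthRecord]
    control_ids: list[str]
    case_ids: list[str]
    baselines: pd.Series  # per-probe baseline mu

    @property
    def controls(self) -> BetaMatrix:
        return BetaMatrix(self.beta.values[self.control_ids])

    @property
    def cases(self) -> BetaMatrix:
        return BetaMatrix(self.beta.values[self.case_ids])


@dataclass
class SimulatedFamilies:
    manifest: ProbeManifest
    beta: BetaMatrix  # family members
    controls: BetaMatrix
    pedigree: Pedigree
    truth: list[TruthRecord]
    baselines: pd.Series


# ---------------------------------------------------------------------------


def _beta_params(mu: np.ndarray, sd: float) -> tuple[np.ndarray, np.ndarray]:
    """Shape parameters of a Beta with mean mu and SD ~ sd (capped to validity)."""
    mu = np.clip(mu, 0.02, 0.98)
    var_cap = mu * (1 - mu) * 0.5  # keep the distribution unimodal enough
    var = np.minimum(sd**2, var_cap)
    nu = mu * (1 - mu) / var - 1.0
    return mu * nu, (1 - mu) * nu


def _draw_beta_matrix(
    rng: np.random.Generator, mu: np.ndarray, n_samples: int, sd: float
) -> np.ndarray:
    a, b = _beta_params(mu, sd)
    return rng.beta(a[:, None], b[:, None], size=(mu.size, n_samples))


def _make_manifest(rng: np.random.Generator, config: SimulationConfig) -> ProbeManifest:
    gaps = rng.geometric(1.0 / config.mean_gap_bp, size=config.n_probes)
    pos = np.cumsum(gaps) + 1000
    rows = {
        "probe_id": [f"cgS{i:06d}" for i in range(config.n_probes)],
        "chrom": ["chrS"] * config.n_probes,
        "pos": pos,
        "design_type": ["II"] * config.n_probes,
    }
    if config.include_sex_chroms:
        nx, ny = 30, 20
        rows["probe_id"] += [f"cgX{i:04d}" for i in range(nx)]
        rows["chrom"] += ["chrX"] * nx
        rows["pos"] = np.concatenate([rows["pos"], np.arange(1, nx + 1) * 5000])
        rows["design_type"] += ["II"] * nx
        rows["probe_id"] += [f"cgY{i:04d}" for i in range(ny)]
        rows["chrom"] += ["chrY"] * ny
        rows["pos"] = np.concatenate([rows["pos"], np.arange(1, ny + 1) * 5000])
        rows["design_type"] += ["II"] * ny
    t = pd.DataFrame(rows).set_index("probe_id")
    return ProbeManifest(t)


def _draw_baselines(
    rng: np.random.Generator,
    n: int,
    mix: tuple[float, float, float],
    persistence: float = 0.9,
) -> np.ndarray:
    """Per-probe baseline methylation, locus-coherent.

    Archetypes follow a Markov chain along the chromosome (stay probability
    ``persistence``, else redraw from ``mix``), mimicking the coherence of
    CpG islands and methylated domains; the stationary distribution equals
    ``mix``.
    """
    arch = np.empty(n, dtype=int)
    arch[0] = rng.choice(3, p=list(mix))
    stay = rng.random(n) < persistence
    redraw = rng.choice(3, size=n, p=list(mix))
    for i in range(1, n):
        arch[i] = arch[i - 1] if stay[i] else redraw[i]
    mu = np.empty(n)
    mu[arch == 0] = rng.beta(2, 18, size=int((arch == 0).sum()))  # unmethylated
    mu[arch == 1] = rng.beta(18, 2, size=int((arch == 1).sum()))  # methylated
    mu[arch == 2] = rng.beta(10, 10, size=int((arch == 2).sum()))  # intermediate
    return mu


def _eligible_runs(
    manifest: ProbeManifest, chrom: str, k: int, span_bp: int
) -> list[np.ndarray]:
    """Index runs of k consecutive probes whose positions fit within span_bp."""
    probes = manifest.probes_on(chrom)
    pos = probes["pos"].to_numpy()
    runs = []
    for a in range(pos.size - k + 1):
        if pos[a + k - 1] - pos[a] <= span_bp - 1:
            runs.append(np.arange(a, a + k))
    return runs


def _pick_disjoint_runs(
    rng: np.random.Generator, runs: list[np.ndarray], n: int, min_gap: int = 3
) -> list[np.ndarray]:
    """Sample n runs with non-adjacent probe sets (so events never collide)."""
    order = rng.permutation(len(runs))
    taken: set[int] = set()
    chosen = []
    for i in order:
        run = runs[i]
        lo, hi = run.min() - min_gap, run.max() + min_gap
        if any(j in taken for j in range(lo, hi + 1)):
            continue
        chosen.append(run)
        taken.update(range(lo, hi + 1))
        if len(chosen) == n:
            return chosen
    raise ValueError(
        f"could not place {n} disjoint events; only {len(chosen)} fit the genome"
    )


def plant_epivariation(
    values: pd.DataFrame,
    probe_ids: list[str],
    carriers: list[str],
    delta: float,
    direction: str,
    existing: list[TruthRecord],
    manifest: ProbeManifest,
    event_id: str = "epi",
) -> TruthRecord:
    """Shift carrier beta at a probe run by +/- delta (clipped to [0.02, 0.98]).

    Models an allelic methylation change in bulk tissue: one allele switching
    state moves the average by about half its full range. Modifies ``values``
    in place and returns the truth record; overlapping a previously planted
    event is an error.
    """
    planted = {p for r in existing for p in r.probe_ids}
    if planted & set(probe_ids):
        raise ValueError("event overlaps an existing planted event")
    sign = 1.0 if direction == HYPER else -1.0
    block = values.loc[probe_ids, carriers].to_numpy(float)
    values.loc[probe_ids, carriers] = np.clip(block + sign * delta, 0.02, 0.98)
    pos = manifest.table.loc[probe_ids, "pos"]
    rec = TruthRecord(
        event_id=event_id,
        type="epivariation",
        sample_ids=tuple(carriers),
        chromosome=str(manifest.table.loc[probe_ids[0], "chrom"]),
        start=int(pos.min()),
        end=int(pos.max()),
        direction=direction,
        delta=delta,
        probe_ids=tuple(probe_ids),
    )
    existing.append(rec)
    return rec


def plant_deletion(
    detp_values: pd.DataFrame,
    beta_values: pd.DataFrame,
    probe_ids: list[str],
    carrier: str,
    rng: np.random.Generator,
    existing: list[TruthRecord],
    manifest: ProbeManifest,
    event_id: str = "del",
) -> TruthRecord:
    """Plant a homozygous-deletion signature in one sample.

    With no target DNA the probes fail: detection p is drawn uniformly from
    (0.02, 0.5) and beta becomes uniform noise on [0, 1]. Modifies both
    matrices in place.
    """
    planted = {p for r in existing for p in r.probe_ids}
    if planted & set(probe_ids):
        raise ValueError("event overlaps an existing planted event")
    k = len(probe_ids)
    detp_values.loc[probe_ids, carrier] = rng.uniform(0.02, 0.5, size=k)
    beta_values.loc[probe_ids, carrier] = rng.uniform(0.0, 1.0, size=k)
    pos = manifest.table.loc[probe_ids, "pos"]
    rec = TruthRecord(
        event_id=event_id,
        type="deletion",
        sample_ids=(carrier,),
        chromosome=str(manifest.table.loc[probe_ids[0], "chrom"]),
        start=int(pos.min()),
        end=int(pos.max()),
        probe_ids=tuple(probe_ids),
    )
    existing.append(rec)
    return rec


def _event_direction(mu: np.ndarray) -> str:
    """Plant hyper events on low-methylation loci and vice versa, so the
    shifted value clears the control extreme rather than saturating the clip."""
    return HYPER if float(np.mean(mu)) < 0.5 else HYPO


def _feasible_direction(mu: np.ndarray, delta: float) -> str | None:
    """Direction in which every probe of the run can shift by the full delta.

    An allelic event is only expressible in bulk when the shifted value stays
    inside the measurable range; loci whose baselines straddle both extremes
    cannot host a clean event and are skipped.
    """
    hyper_ok = float(np.max(mu)) + delta <= 0.96
    hypo_ok = float(np.min(mu)) - delta >= 0.04
    if hyper_ok and hypo_ok:
        return _event_direction(mu)
    if hyper_ok:
        return HYPER
    if hypo_ok:
        return HYPO
    return None


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate manifest, beta/detection-p matrices, and the truth table.

    Controls are null draws; planted epivariations and deletions are
    assigned to case samples (round-robin so every event has exactly one
    carrier). With ``batch_shift`` > 0 one batch additionally receives a
    systematic shift at a dedicated probe run, the signature the
    ``batch_suspect`` curation flag should catch.
    """
    rng = np.random.default_rng(config.seed)
    manifest = _make_manifest(rng, config)
    chrS = manifest.probes_on("chrS")
    mu = pd.Series(
        _draw_baselines(rng, len(chrS), config.probe_archetype_mix),
        index=chrS.index,
    )

    control_ids = [f"ctl_{i:03d}" for i in range(config.n_controls)]
    case_ids = [f"case_{i:03d}" for i in range(config.n_cases)]
    samples = control_ids + case_ids
    vals = _draw_beta_matrix(rng, mu.to_numpy(), len(samples), config.noise_sd)
    beta = pd.DataFrame(vals, index=chrS.index, columns=samples)
    detp = pd.DataFrame(
        rng.uniform(0.0, 2 * config.detection_p_baseline, size=beta.shape),
        index=chrS.index,
        columns=samples,
    )

    truth: list[TruthRecord] = []
    n_events = config.n_planted_epivariations + config.n_planted_deletions
    n_events += 1 if config.batch_shift > 0 else 0
    if n_events:
        runs = _eligible_runs(manifest, "chrS", config.probes_per_event,
                              config.event_span_bp)
        delta_max = config.planted_delta + config.planted_delta_spread
        runs = [
            r for r in runs if _feasible_direction(mu.to_numpy()[r], delta_max)
        ]
        chosen = _pick_disjoint_runs(rng, runs, n_events)
        epi_runs = chosen[: config.n_planted_epivariations]
        del_runs = chosen[config.n_planted_epivariations :
                          config.n_planted_epivariations + config.n_planted_deletions]
        batch_run = chosen[-1] if config.batch_shift > 0 else None

        for i, run in enumerate(epi_runs):
            pids = list(chrS.index[run])
            carrier = case_ids[i % max(1, len(case_ids))] if case_ids else control_ids[0]
            delta = config.planted_delta + rng.uniform(
                -config.planted_delta_spread, config.planted_delta_spread
            )
            direction = _feasible_direction(mu.loc[pids].to_numpy(), delta)
            plant_epivariation(
                beta, pids, [carrier], delta, direction,
                truth, manifest, event_id=f"epi_{i:03d}",
            )
        for i, run in enumerate(del_runs):
            pids = list(chrS.index[run])
            carrier = case_ids[(config.n_planted_epivariations + i) % max(1, len(case_ids))] if case_ids else control_ids[0]
            plant_deletion(
                detp, beta, pids, carrier, rng, truth, manifest,
                event_id=f"del_{i:03d}",
            )

    batch = pd.Series(
        [f"batch{i % config.n_batches}" for i in range(len(samples))],
        index=samples,
    )
    if config.batch_shift > 0 and batch_run is not None:
        pids = list(chrS.index[batch_run])
        members = list(batch.index[batch == "batch0"])
        direction = _event_direction(mu.loc[pids].to_numpy())
        sign = 1.0 if direction == HYPER else -1.0
        block = beta.loc[pids, members].to_numpy(float)
        beta.loc[pids, members] = np.clip(
            block + sign * config.batch_shift, 0.02, 0.98
        )
        truth.append(
            TruthRecord(
                event_id="batch_000",
                type="batch",
                sample_ids=tuple(members),
                chromosome="chrS",
                start=int(chrS["pos"].to_numpy()[batch_run.min()]),
                end=int(chrS["pos"].to_numpy()[batch_run.max()]),
                direction=direction,
                delta=config.batch_shift,
                probe_ids=tuple(pids),
            )
        )

    sex_reported = None
    if config.include_sex_chroms:
        sexes = ["male" if i % 2 == 0 else "female" for i in range(len(samples))]
        sex_reported = pd.Series(sexes, index=samples)
        xb = np.empty((30, len(samples)))
        yb = np.empty((20, len(samples)))
        yp = np.empty((20, len(samples)))
        for j, sex in enumerate(sexes):
            if sex == "male":
                # hemizygous X: bimodal extremes; Y present: low detection p
                comp = rng.random(30) < 0.5
                xb[:, j] = np.where(
                    comp, rng.beta(2, 30, 30), rng.beta(30, 2, 30)
                )
                yb[:, j] = rng.beta(10, 10, 20)
                yp[:, j] = rng.uniform(0.0, 0.005, 20)
            else:
                xb[:, j] = rng.beta(25, 25, 30)  # X inactivation -> intermediate
                yb[:, j] = rng.uniform(0.0, 1.0, 20)  # no Y target: erratic
                yp[:, j] = rng.uniform(0.2, 0.8, 20)
        x_ids = [f"cgX{i:04d}" for i in range(30)]
        y_ids = [f"cgY{i:04d}" for i in range(20)]
        beta = pd.concat([
            beta,
            pd.DataFrame(xb, index=x_ids, columns=samples),
            pd.DataFrame(yb, index=y_ids, columns=samples),
        ])
        detp = pd.concat([
            detp,
            pd.DataFrame(
                rng.uniform(0.0, 2 * config.detection_p_baseline, (30, len(samples))),
                index=x_ids, columns=samples,
            ),
            pd.DataFrame(yp, index=y_ids, columns=samples),
        ])
        order = manifest.probe_ids
        beta = beta.loc[order]
        detp = detp.loc[order]

    return SimulatedCohort(
        manifest=manifest,
        beta=BetaMatrix(beta, batch=batch, sex_reported=sex_reported),
        detp=DetectionPMatrix(detp),
        truth=truth,
        control_ids=control_ids,
        case_ids=case_ids,
        baselines=mu,
    )


def simulate_families(config: SimulationConfig) -> SimulatedFamilies:
    """Simulate nuclear families plus a matched control cohort.

    Each family has a mother, father and 2-4 children. Parental
    epivariations are planted one carrier parent each and transmitted to
    each child independently with probability ``transmission_prob``;
    additional child-private (de novo) events are planted at
    ``de_novo_rate`` per child. Truth records carry the inheritance label
    and the list of children who received the event.
    """
    rng = np.random.default_rng(config.seed + 1)
    manifest = _make_manifest(rng, config)
    chrS = manifest.probes_on("chrS")
    mu = pd.Series(
        _draw_baselines(rng, len(chrS), config.probe_archetype_mix),
        index=chrS.index,
    )

    rows = []
    members: list[str] = []
    for f in range(config.n_families):
        fam = f"fam{f:03d}"
        father, mother = f"{fam}_fa", f"{fam}_mo"
        rows.append((fam, father, "0", "0", "male"))
        rows.append((fam, mother, "0", "0", "female"))
        n_children = int(rng.integers(config.children_range[0],
                                      config.children_range[1] + 1))
        for c in range(n_children):
            rows.append((fam, f"{fam}_c{c}", father, mother, "unknown"))
        members.extend(r[1] for r in rows[-(2 + n_children):])
    ped = Pedigree(
        pd.DataFrame(
            rows, columns=["family_id", "individual_id", "father_id",
                           "mother_id", "sex"]
        ).set_index("individual_id")
    )

    control_ids = [f"ctl_{i:03d}" for i in range(config.n_controls)]
    ctl_vals = _draw_beta_matrix(rng, mu.to_numpy(), len(control_ids), config.noise_sd)
    controls = BetaMatrix(pd.DataFrame(ctl_vals, index=chrS.index, columns=control_ids))

    fam_vals = _draw_beta_matrix(rng, mu.to_numpy(), len(members), config.noise_sd)
    beta = pd.DataFrame(fam_vals, index=chrS.index, columns=members)

    truth: list[TruthRecord] = []
    children = [m for m in members if ped.parents_of(m)[0] is not None]
    n_de_novo = rng.binomial(1, config.de_novo_rate, size=len(children))
    n_events = config.n_parental_events + int(n_de_novo.sum())
    runs = _eligible_runs(manifest, "chrS", config.probes_per_event,
                          config.event_span_bp)
    delta_max = config.planted_delta + config.planted_delta_spread
    runs = [
        r for r in runs if _feasible_direction(mu.to_numpy()[r], delta_max)
    ]
    chosen = _pick_disjoint_runs(rng, runs, n_events)

    families = sorted(set(ped.records["family_id"]))
    for i in range(config.n_parental_events):
        run = chosen[i]
        pids = list(chrS.index[run])
        fam = families[int(rng.integers(len(families)))]
        fam_members = ped.records.index[ped.records["family_id"] == fam]
        parents = [m for m in fam_members if ped.parents_of(m)[0] is None]
        parent = parents[int(rng.integers(2))]
        kids = ped.children_of(parent)
        transmitted = tuple(k for k in kids
                            if rng.random() < config.transmission_prob)
        carriers = [parent, *transmitted]
        delta = config.planted_delta + rng.uniform(
            -config.planted_delta_spread, config.planted_delta_spread
        )
        direction = _feasible_direction(mu.loc[pids].to_numpy(), delta)
        rec = plant_epivariation(
            beta, pids, carriers, delta, direction,
            truth, manifest, event_id=f"fam_epi_{i:03d}",
        )
        truth[-1] = replace(
            rec,
            inheritance_truth=("inherited_paternal" if parent.endswith("_fa")
                               else "inherited_maternal"),
            transmitted_children=transmitted,
        )

    j = config.n_parental_events
    for child, takes in zip(children, n_de_novo):
        if not takes:
            continue
        run = chosen[j]
        j += 1
        pids = list(chrS.index[run])
        delta = config.planted_delta + rng.uniform(
            -config.planted_delta_spread, config.planted_delta_spread
        )
        direction = _feasible_direction(mu.loc[pids].to_numpy(), delta)
        rec = plant_epivariation(
            beta, pids, [child], delta, direction,
            truth, manifest, event_id=f"denovo_epi_{j:03d}",
        )
        truth[-1] = replace(rec, inheritance_truth="de_novo")

    return SimulatedFamilies(
        manifest=manifest,
        beta=BetaMatrix(beta),
        controls=controls,
        pedigree=ped,
        truth=truth,
        baselines=mu,
    )


def simulate_expression_and_variants(
    config: SimulationConfig, cohort: SimulatedCohort
) -> dict:
    """Couple expression, allelic counts, and rare variants to planted events.

    For each planted epivariation a synthetic gene is placed with its TSS
    inside the event span. Carrier expression shifts by ``expression_effect``
    cohort SDs (down for hyper, up for hypo). Carriers of hyper promoter
    events show near-monoallelic expression in the ASE counts; all other
    gene-samples are balanced. With probability ``motif_coupling`` each
    event's carrier harbors a private rare variant (AF < 0.001) inside a
    CTCF motif placed within the event span; decoy motifs without variants
    are scattered elsewhere.
    """
    rng = np.random.default_rng(config.seed + 2)
    samples = cohort.beta.sample_ids
    events = [r for r in cohort.truth if r.type == "epivariation"]

    genes, expr_rows, truth_extra = [], [], []
    from .function_link import AseSite, GeneAnnotation

    ase_sites: list[AseSite] = []
    motifs: list[MotifInterval] = []
    variants: list[VariantRecord] = []

    for i, ev in enumerate(events):
        gid = f"gene_{ev.event_id}"
        tss = (ev.start + ev.end) // 2
        genes.append(GeneAnnotation(gid, ev.chromosome, tss, "+"))
        base = rng.normal(8.0, 1.0, size=len(samples))
        effect = rng.normal(config.expression_effect, config.expression_effect_sd)
        sign = -1.0 if ev.direction == HYPER else 1.0
        idx = [samples.index(s) for s in ev.sample_ids]
        # carriers are placed at the target z (cohort scale 1.0) with a small
        # residual, emulating the near-deterministic impact of promoter
        # methylation switches on that gene's output
        base[idx] = 8.0 + sign * effect + rng.normal(0.0, 0.3, size=len(idx))
        expr_rows.append(pd.Series(base, index=samples, name=gid))
        truth_extra.append(
            TruthRecord(
                event_id=f"expr_{ev.event_id}", type="expression_effect",
                sample_ids=ev.sample_ids, chromosome=ev.chromosome,
                start=ev.start, end=ev.end, direction=ev.direction,
                delta=sign * effect, gene_id=gid,
            )
        )

        # allelic counts at one transcribed het SNV per gene and sample
        for s in samples:
            depth = config.ase_depth
            if s in ev.sample_ids and ev.direction == HYPER:
                minor = rng.binomial(depth, 0.02)
            else:
                minor = rng.binomial(depth, 0.5)
            ase_sites.append(
                AseSite(gene_id=gid, sample_id=s, position=tss + 50,
                        ref_count=depth - minor, alt_count=minor)
            )

        # a CTCF motif inside the event span; carrier-private rare variant
        # with probability motif_coupling
        m_start = tss - 9
        motif = MotifInterval(ev.chromosome, m_start, m_start + 18, "CTCF", "+")
        motifs.append(motif)
        if rng.random() < config.motif_coupling:
            vpos = int(rng.integers(motif.start, motif.end + 1))
            gts = tuple(
                (s, GT_HET if s in ev.sample_ids else GT_REF) for s in samples
            )
            variants.append(
                VariantRecord(
                    chromosome=ev.chromosome, position=vpos, ref="C", alt="T",
                    population_af=float(rng.uniform(0.0, 0.0009)),
                    carrier_genotypes=gts,
                )
            )
            truth_extra.append(
                TruthRecord(
                    event_id=f"motif_{ev.event_id}", type="motif_variant",
                    sample_ids=ev.sample_ids, chromosome=ev.chromosome,
                    start=vpos, end=vpos, gene_id=gid,
                )
            )

    # decoy motifs away from events, plus common background variants
    genome_end = int(cohort.manifest.probes_on("chrS")["pos"].max())
    event_spans = [(r.start - 2000, r.end + 2000) for r in events]
    placed = 0
    while placed < 20:
        p = int(rng.integers(1000, genome_end))
        if any(lo <= p <= hi for lo, hi in event_spans):
            continue
        motifs.append(MotifInterval("chrS", p, p + 18, "CTCF", "+"))
        placed += 1
    for _ in range(50):
        p = int(rng.integers(1000, genome_end))
        carriers = rng.random(len(samples)) < 0.3
        gts = tuple(
            (s, GT_HET if carriers[k] else GT_REF) for k, s in enumerate(samples)
        )
        variants.append(
            VariantRecord(
                chromosome="chrS", position=p, ref="A", alt="G",
                population_af=float(rng.uniform(0.05, 0.5)),
                carrier_genotypes=gts,
            )
        )

    expr = pd.DataFrame(expr_rows)
    motifs.sort(key=lambda m: (m.chromosome, m.start))
    variants.sort(key=lambda v: (v.chromosome, v.position))
    return {
        "expression": expr,
        "genes": genes,
        "ase_sites": ase_sites,
        "motifs": motifs,
        "variants": variants,
        "truth": truth_extra,
    }
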