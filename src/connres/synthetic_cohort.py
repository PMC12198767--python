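"""Synthetic cohorts: modular connectomes, BOLD-like series, lesion library.

Real data behind this kind of study (longitudinal stroke cohort with
resting-state fMRI) are access-restricted, so every downstream stage is
exercised on synthetic material that reproduces the study's structure: a
246-region connectome organized into 17 modules, a control group and a
patient group followed over up to three timepoints, a designated hub set
whose inter-module connectivity differs between groups, and a library of
122 virtual-lesion region sets whose sizes follow a right-skewed law
calibrated to a median of 6 regions per mask (IQR 2-11).

Group difference ("hub redistribution"): hub nodes carry a built-in
inter-module weight surplus, making them the high-participation nodes of
the network. The redistribution strength kappa >= 0 moves a fraction
kappa / (1 + kappa) of that surplus onto non-hub inter-module edges,
preserving total weight. Patients default to a larger kappa than controls,
flattening the participation-coefficient distribution (hubs down, anti-hubs
up) without changing its mean - the architecture change hypothesized to
underlie post-stroke resilience.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import ModulePartition, WeightedConnectome, region_name
from .lesion_mapping import LesionRegionSet
from .preprocessing import RegionTimeSeries

__all__ = [
    "LesionSizeParams",
    "CohortSpec",
    "SubjectRecord",
    "SyntheticCohort",
    "make_partition",
    "simulate_connectome",
    "simulate_timeseries",
    "simulate_lesion_library",
    "build_cohort",
]

LESION_LOCATIONS = (
    "subcortical",
    "cortical",
    "cortico-subcortical",
    "white matter",
    "brainstem",
    "cerebellum",
)
#: cohort frequencies of primary-lesion locations (counts 13/27/15/5/9/6 of 75)
LESION_LOCATION_P = np.array([13, 27, 15, 5, 9, 6], dtype=float) / 75.0


@dataclass(frozen=True)
class LesionSizeParams:
    """Discretized log-normal law for regions-per-mask.

    ``median`` fixes exp(mu); ``sigma`` is the least-squares fit of the two
    quartiles to the target IQR [2, 11] under the median-6 constraint (a
    two-parameter law cannot match median and both quartiles exactly; the
    fit lands the continuous quartiles at about [3.2, 11.3], and rounding
    gives a discretized IQR of [3, 11]). Sizes are rounded, then truncated
    to [1, max_fraction * n_nodes].
    """

    median: float = 6.0
    sigma: float = 0.9425045109204436
    max_fraction: float = 0.2

    def sample(self, rng: np.random.Generator, n: int, n_nodes: int) -> np.ndarray:
        upper = max(1, int(np.floor(self.max_fraction * n_nodes)))
        raw = rng.lognormal(mean=np.log(self.median), sigma=self.sigma, size=n)
        sizes = np.clip(np.round(raw).astype(int), 1, upper)
        return sizes


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; identical specs (including
    seed) generate bit-identical cohorts."""

    n_patients: int = 75
    n_controls: int = 18
    timepoints_patients: tuple[str, ...] = ("TP1", "TP2", "TP3")
    timepoints_controls: tuple[str, ...] = ("TP1", "TP2")
    n_nodes: int = 246
    n_modules: int = 17
    mu_within: float = 0.55
    mu_between: float = 0.0
    noise_sd: float = 0.05
    hub_fraction: float = 0.1
    hub_redistribution_control: float = 0.0
    hub_redistribution_patient: float = 3.0
    missing_tp3_fraction: float = 0.2  # 15 of 75 patients lack TP3
    include_primary_lesions: bool = True  # False gives fully exchangeable groups
    lesion_count: int = 122
    lesion_size_params: LesionSizeParams = field(default_factory=LesionSizeParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu_between < 1.0 and 0.0 <= self.mu_within < 1.0):
            raise ValueError("mu_within and mu_between must lie in [0, 1)")
        if self.n_modules > self.n_nodes or self.n_modules < 1:
            raise ValueError("need 1 <= n_modules <= n_nodes")
        if self.hub_redistribution_control < 0 or self.hub_redistribution_patient < 0:
            raise ValueError("hub redistribution strengths must be >= 0")
        if not 0.0 <= self.hub_fraction <= 1.0:
            raise ValueError("hub_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's grouping, demographics and primary-lesion summary.

    Controls carry no lesion fields and an empty primary region set.
    """

    subject_id: str
    group: str  # "control" | "patient"
    timepoints: tuple[str, ...]
    age: float
    sex: str  # "male" | "female"
    nihss: int | None = None
    lesion_size: float | None = None  # cm^3
    lesion_type: str | None = None  # "ischaemic" | "haemorrhagic"
    lesion_location: str | None = None
    primary_removed_regions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.group not in ("control", "patient"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.group == "control":
            if self.primary_removed_regions or self.nihss is not None:
                raise ValueError("controls carry no lesion/NIHSS fields")
        else:
            if self.nihss is None or not 0 <= self.nihss <= 42:
                raise ValueError("patient NIHSS must lie in [0, 42]")


@dataclass(frozen=True)
class SyntheticCohort:
    spec: CohortSpec
    partition: ModulePartition
    hub_nodes: tuple[str, ...]
    subjects: tuple[SubjectRecord, ...]
    connectomes: dict  # (subject_id, timepoint) -> WeightedConnectome
    lesion_library: tuple[LesionRegionSet, ...]

    def subject(self, subject_id: str) -> SubjectRecord:
        for rec in self.subjects:
            if rec.subject_id == subject_id:
                return rec
        raise KeyError(subject_id)


# ---------------------------------------------------------------------------

def make_partition(n_nodes: int, n_modules: int, seed: int) -> ModulePartition:
    """Random partition of ``n_nodes`` regions into non-empty modules."""
    if not 1 <= n_modules <= n_nodes:
        raise ValueError(
            f"need 1 <= n_modules <= n_nodes, got {n_modules} > {n_nodes}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_nodes)
    chunks = np.array_split(perm, n_modules)  # every chunk non-empty
    modules = np.empty(n_nodes, dtype=int)
    for m, chunk in enumerate(chunks):
        modules[chunk] = m
    node_ids = tuple(region_name(i + 1) for i in range(n_nodes))
    return ModulePartition(node_ids=node_ids, module_ids=modules)


def simulate_connectome(
    partition: ModulePartition,
    mu_within: float,
    mu_between: float,
    hub_nodes: Sequence[str] = (),
    hub_redistribution: float = 0.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    transplant_split: int = 1,
) -> WeightedConnectome:
    """Modular correlation-like matrix with optional hub redistribution.

    Within-module weights center on ``mu_within``, between-module on
    ``mu_between``. Hub nodes act as module gateways: hub-hub pairs carry
    strong edges at ``mu_within`` (the inter-module backbone), so at low
    binarization densities a module reaches the rest of the network only
    through its hubs - the concentrated architecture whose gateways are
    single points of failure.

    ``hub_redistribution`` (kappa) de-concentrates that backbone: a
    fraction kappa/(1+kappa) of hub-hub edges loses its surplus over
    ``mu_between``, and each lost surplus is split over ``transplant_split``
    randomly chosen non-hub inter-module edges. Total weight is preserved
    (mean participation barely moves), hub PC falls and peripheral PC rises
    with kappa, and inter-module connectivity becomes redundant at the
    member level. Symmetric Gaussian noise is added last; off-diagonals are
    clipped to [-1, 1].
    """
    if partition.n_nodes == 0:
        raise ValueError("empty partition")
    if hub_redistribution < 0:
        raise ValueError("hub_redistribution must be >= 0")
    if not (0.0 <= mu_within < 1.0 and 0.0 <= mu_between < 1.0):
        raise ValueError("mu_within and mu_between must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n = partition.n_nodes
    modules = partition.module_ids
    same = modules[:, None] == modules[None, :]
    W = np.where(same, mu_within, mu_between).astype(float)

    if len(hub_nodes):
        lookup = {nid: i for i, nid in enumerate(partition.node_ids)}
        try:
            hub_pos = np.asarray([lookup[h] for h in hub_nodes], dtype=int)
        except KeyError as exc:
            raise KeyError(f"hub node {exc.args[0]!r} not in partition") from None
        is_hub = np.zeros(n, dtype=bool)
        is_hub[hub_pos] = True
        inter = ~same
        # gateway backbone: strong hub-hub inter-module edges
        hub_edge = inter & is_hub[:, None] & is_hub[None, :]
        W[hub_edge] = mu_within
        surplus = mu_within - mu_between
        if hub_redistribution > 0.0 and surplus > 0.0:
            f = hub_redistribution / (1.0 + hub_redistribution)
            hi, hj = np.where(np.triu(hub_edge, k=1))
            sink = inter & ~is_hub[:, None] & ~is_hub[None, :]
            si, sj = np.where(np.triu(sink, k=1))
            n_move = int(round(f * len(hi)))
            n_sink = min(n_move * max(1, transplant_split), len(si))
            if n_move and n_sink:
                pick_h = rng.choice(len(hi), size=n_move, replace=False)
                pick_s = rng.choice(len(si), size=n_sink, replace=False)
                W[hi[pick_h], hj[pick_h]] -= surplus
                W[hj[pick_h], hi[pick_h]] -= surplus
                deposit = n_move * surplus / n_sink
                W[si[pick_s], sj[pick_s]] += deposit
                W[sj[pick_s], si[pick_s]] += deposit

    noise = rng.normal(0.0, noise_sd, size=(n, n))
    W = W + np.triu(noise, k=1) + np.triu(noise, k=1).T
    W = np.clip(W, -1.0, 1.0)
    np.fill_diagonal(W, 1.0)
    return WeightedConnectome(partition.node_ids, W)


def _nearest_correlation(target: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped positive-definite repair, rescaled to unit diagonal."""
    vals, vecs = np.linalg.eigh(target)
    vals = np.clip(vals, floor * vals.max(), None)
    M = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(M))
    M = M / np.outer(d, d)
    np.fill_diagonal(M, 1.0)
    return (M + M.T) / 2.0


def simulate_timeseries(
    connectome: WeightedConnectome,
    n_volumes: int,
    tr_seconds: float = 2.0,
    drift_amp: float = 1.0,
    spike_rate: float = 0.01,
    seed: int = 0,
) -> RegionTimeSeries:
    """BOLD-like series whose noise-free correlation matches the connectome.

    Gaussian samples are coloured by the Cholesky factor of the (PSD-
    repaired) target correlation matrix. Slow drifts (linear plus one slow
    cosine per region) and sporadic global spikes are injected so the
    preprocessing stages have realistic work; the drift basis and the spike
    indicator are returned as nuisance regressors.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    if n_volumes < 10:
        raise ValueError("need n_volumes >= 10")
    rng = np.random.default_rng(seed)
    n = connectome.n_nodes
    target = _nearest_correlation(connectome.weights)
    L = np.linalg.cholesky(target)
    signal = L @ rng.standard_normal((n, n_volumes))

    t = np.arange(n_volumes, dtype=float)
    lin = (t - t.mean()) / n_volumes
    cos = np.cos(2.0 * np.pi * t / n_volumes)
    gains_lin = rng.normal(0.0, 1.0, size=n)
    gains_cos = rng.normal(0.0, 1.0, size=n)
    drift = drift_amp * (np.outer(gains_lin, lin) + np.outer(gains_cos, cos))

    spikes = rng.random(n_volumes) < spike_rate
    spike_amp = rng.normal(0.0, 3.0, size=n)
    spike_term = np.outer(spike_amp, spikes.astype(float))

    nuisance = np.column_stack([cos, spikes.astype(float)])
    return RegionTimeSeries(
        region_ids=connectome.node_ids,
        samples=signal + drift + spike_term,
        tr_seconds=tr_seconds,
        nuisance=nuisance,
    )


def simulate_lesion_library(
    nodes: Sequence[str],
    n_masks: int,
    size_params: LesionSizeParams | None = None,
    seed: int = 0,
    partition: ModulePartition | None = None,
    p_same_module: float = 0.75,
) -> list[LesionRegionSet]:
    """Library of virtual-lesion region sets with clustered sampling.

    Each mask picks a seed module and draws regions preferentially from it
    (probability ``p_same_module`` while regions remain), mimicking the
    territorial clustering of vascular lesions. Sizes follow the discretized
    log-normal law of ``size_params``.
    """
    if n_masks < 1:
        raise ValueError("need n_masks >= 1")
    nodes = list(nodes)
    size_params = size_params or LesionSizeParams()
    if round(size_params.median) > len(nodes):
        raise ValueError(
            f"requested mask size {size_params.median} exceeds the "
            f"{len(nodes)} available regions"
        )
    rng = np.random.default_rng(seed)
    sizes = size_params.sample(rng, n_masks, len(nodes))
    library: list[LesionRegionSet] = []
    for k, size in enumerate(sizes):
        if partition is not None:
            seed_module = int(rng.integers(partition.n_modules))
            in_module = [
                nid for nid in nodes
                if nid in partition.node_ids
                and partition.module_of(nid) == seed_module
            ]
            out_module = [nid for nid in nodes if nid not in set(in_module)]
            rng.shuffle(in_module)
            rng.shuffle(out_module)
            chosen: list[str] = []
            while len(chosen) < size:
                take_same = in_module and (
                    not out_module or rng.random() < p_same_module
                )
                chosen.append(in_module.pop() if take_same else out_module.pop())
            regions = frozenset(chosen)
        else:
            regions = frozenset(
                rng.choice(nodes, size=int(size), replace=False).tolist()
            )
        library.append(
            LesionRegionSet(
                mask_id=f"M{k + 1:03d}",
                regions=regions,
                overlap_fraction={r: 1.0 for r in regions},
                source="synthetic",
            )
        )
    return library


# ---------------------------------------------------------------------------

def _sample_patient_covariates(rng: np.random.Generator) -> dict:
    age = float(np.clip(rng.normal(53.0, 9.0), 18.0, 95.0))
    sex = "female" if rng.random() < 32.0 / 75.0 else "male"
    # NIHSS: right-skewed discretized log-normal with mean ~6, SD ~6
    sigma2 = np.log(2.0)
    nihss = int(np.clip(
        np.round(rng.lognormal(np.log(6.0) - sigma2 / 2.0, np.sqrt(sigma2))),
        0, 42,
    ))
    lesion_type = "ischaemic" if rng.random() < 64.0 / 75.0 else "haemorrhagic"
    location = str(rng.choice(LESION_LOCATIONS, p=LESION_LOCATION_P))
    return dict(age=age, sex=sex, nihss=nihss,
                lesion_type=lesion_type, lesion_location=location)


def build_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Assemble subjects, per-(subject, timepoint) connectomes and lesions.

    Controls receive the control redistribution strength, patients the
    patient one. Each patient's primary lesion is drawn from the library and
    its regions are removed from all of that patient's matrices (ledger
    reason ``primary_lesion``). All randomness derives from ``spec.seed``.
    """
    root = np.random.SeedSequence(spec.seed)
    s_part, s_hubs, s_lib, s_cov, s_conn = root.spawn(5)

    partition = make_partition(
        spec.n_nodes, spec.n_modules, seed=s_part.generate_state(1)[0]
    )
    rng_hubs = np.random.default_rng(s_hubs)
    n_hubs = int(round(spec.hub_fraction * spec.n_nodes))
    # hubs are module gateways: spread them round-robin across modules so
    # every module gets one before any module gets a second
    hubs: list[str] = []
    pools = {
        m: list(partition.members(m)) for m in range(partition.n_modules)
    }
    for pool in pools.values():
        rng_hubs.shuffle(pool)
    module_cycle = 0
    while len(hubs) < n_hubs:
        pool = pools[module_cycle % partition.n_modules]
        if pool:
            hubs.append(pool.pop())
        module_cycle += 1
    hub_nodes = tuple(sorted(hubs))
    library = simulate_lesion_library(
        partition.node_ids,
        spec.lesion_count,
        spec.lesion_size_params,
        seed=s_lib.generate_state(1)[0],
        partition=partition,
    )

    rng_cov = np.random.default_rng(s_cov)
    subjects: list[SubjectRecord] = []
    n_missing_tp3 = int(round(spec.missing_tp3_fraction * spec.n_patients))
    missing_tp3 = set(
        rng_cov.choice(spec.n_patients, size=n_missing_tp3, replace=False).tolist()
    ) if "TP3" in spec.timepoints_patients else set()

    for c in range(spec.n_controls):
        subjects.append(
            SubjectRecord(
                subject_id=f"C{c + 1:03d}",
                group="control",
                timepoints=tuple(spec.timepoints_controls),
                age=float(np.clip(rng_cov.normal(55.0, 9.0), 18.0, 95.0)),
                sex="female" if rng_cov.random() < 10.0 / 18.0 else "male",
            )
        )
    for p in range(spec.n_patients):
        cov = _sample_patient_covariates(rng_cov)
        mask = library[int(rng_cov.integers(len(library)))]
        lesion_size = float(
            mask.n_regions * rng_cov.lognormal(np.log(9.8 / 6.0), 1.0)
        )
        tps = tuple(
            tp for tp in spec.timepoints_patients
            if not (tp == "TP3" and p in missing_tp3)
        )
        primary = (
            frozenset(mask.regions) if spec.include_primary_lesions
            else frozenset()
        )
        subjects.append(
            SubjectRecord(
                subject_id=f"P{p + 1:03d}",
                group="patient",
                timepoints=tps,
                age=cov["age"],
                sex=cov["sex"],
                nihss=cov["nihss"],
                lesion_size=lesion_size,
                lesion_type=cov["lesion_type"],
                lesion_location=cov["lesion_location"],
                primary_removed_regions=primary,
            )
        )

    connectomes: dict[tuple[str, str], WeightedConnectome] = {}
    conn_children = s_conn.spawn(len(subjects))
    for rec, child in zip(subjects, conn_children):
        kappa = (
            spec.hub_redistribution_control
            if rec.group == "control"
            else spec.hub_redistribution_patient
        )
        tp_children = child.spawn(len(rec.timepoints))
        for tp, tp_child in zip(rec.timepoints, tp_children):
            conn = simulate_connectome(
                partition,
                spec.mu_within,
                spec.mu_between,
                hub_nodes=hub_nodes,
                hub_redistribution=kappa,
                noise_sd=spec.noise_sd,
                seed=tp_child.generate_state(1)[0],
            )
            if rec.primary_removed_regions:
                conn = conn.drop_nodes(
                    rec.primary_removed_regions, reason="primary_lesion"
                )
            connectomes[(rec.subject_id, tp)] = conn

    return SyntheticCohort(
        spec=spec,
        partition=partition,
        hub_nodes=hub_nodes,
        subjects=tuple(subjects),
        connectomes=connectomes,
        lesion_library=tuple(library),
    )
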