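"""Synthetic cohorts with plantable hemispheric asymmetry.

Generates everything the pipeline consumes — a covariate table for a
preterm/term cohort, per-subject connectomes, and optional streamline
summaries — with known ground truth, so the full analysis can be exercised
and calibrated without any imaging data.

Each intra-hemispheric network is a rewired ring lattice (the Watts–Strogatz
small-world family): the target edge density fixes the lattice neighbor
count, and each edge is rewired with a hemisphere-specific probability.
Asymmetry is planted through real topology, never by perturbing metric
values after the fact:

* a ``sigma`` effect delta splits the rewiring probability across
  hemispheres (left ``p - delta/2``, right ``p + delta/2``; less rewiring
  means a more lattice-like, higher-sigma hemisphere, so positive delta is a
  leftward small-worldness advantage);
* a ``density`` effect splits the intra-hemispheric edge density the same
  way;
* a fronto-limbic ROI effect in (0, 1) reroutes that fraction of the
  hemisphere's edges onto the ROI node, raising its betweenness (positive =
  left ROI boosted, negative = right).

Effects in ``asymmetry_effects`` apply to every preterm subject; effects in
``subgroup_asymmetry_effects`` apply only to preterm subjects whose simulated
Bayley social-emotional composite falls below 85.

Randomness: one master seed; subject ``i`` and stream ``s`` (0 = covariate
table, 1 = connectome, 2 = tractogram) use
``numpy.random.SeedSequence(master_seed, spawn_key=(s, i))``, so subjects are
reproducible independently of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .atlas import ROI_NAMES, default_atlas, roi_label
from .connectome import Connectome, HemisphereNetwork, StreamlineSet
from .errors import ConfigurationError, GenerationError

BAYLEY_SCALES = ("cognitive", "language", "motor", "se")
SE_CUTOFF = 85.0  # 1 SD below the standardized mean of 100 (SD 15)

_STREAM_TABLE, _STREAM_CONNECTOME, _STREAM_TRACTOGRAM = 0, 1, 2


@dataclass(frozen=True)
class GroupCovariates:
    """Distribution parameters for one group's covariates.

    Gestational age and age at MRI are in weeks, drawn from truncated
    normals; Bayley composites are normal (population mean 100, SD 15) with
    group-specific parameters; ``assessed_prop`` is the fraction with a
    completed follow-up assessment.
    """

    ga_mean: float
    ga_sd: float
    ga_range: tuple[float, float]
    age_mri_mean: float
    age_mri_sd: float
    age_mri_range: tuple[float, float]
    male_prop: float
    bpd_prev: float
    assessed_prop: float
    bayley_mean: Mapping[str, float]
    bayley_sd: Mapping[str, float]


def _preterm_defaults() -> GroupCovariates:
    return GroupCovariates(
        ga_mean=30.08, ga_sd=3.94, ga_range=(23.0, 36.9),
        age_mri_mean=37.30, age_mri_sd=1.33, age_mri_range=(36.0, 41.0),
        male_prop=0.394, bpd_prev=0.453, assessed_prop=57 / 64,
        bayley_mean={"cognitive": 95.47, "language": 89.21,
                     "motor": 95.38, "se": 97.28},
        bayley_sd={"cognitive": 14.47, "language": 15.42,
                   "motor": 16.41, "se": 17.39},
    )


def _term_defaults() -> GroupCovariates:
    return GroupCovariates(
        ga_mean=38.39, ga_sd=1.22, ga_range=(37.0, 42.0),
        age_mri_mean=38.61, age_mri_sd=0.86, age_mri_range=(36.0, 41.0),
        male_prop=0.348, bpd_prev=0.0, assessed_prop=21 / 33,
        bayley_mean={"cognitive": 102.38, "language": 93.95,
                     "motor": 105.04, "se": 108.57},
        bayley_sd={"cognitive": 8.74, "language": 6.68,
                   "motor": 11.03, "se": 11.95},
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generative parameters; defaults emulate the study
    conditions (64 preterm + 33 term, 32 nodes per hemisphere, edge density
    giving 8 lattice neighbors, moderate rewiring)."""

    n_preterm: int = 64
    n_term: int = 33
    nodes_per_hemisphere: int = 32
    intra_edge_density: float = 0.26
    lattice_rewire_prob_left: float = 0.20
    lattice_rewire_prob_right: float = 0.20
    interhemispheric_density: float = 0.05
    asymmetry_effects: Mapping[str, float] = field(default_factory=dict)
    subgroup_asymmetry_effects: Mapping[str, float] = field(default_factory=dict)
    fa_mean: float = 0.25
    fa_sd: float = 0.05
    fibers_per_edge_mean: float = 5.0
    preterm_covariates: GroupCovariates = field(default_factory=_preterm_defaults)
    term_covariates: GroupCovariates = field(default_factory=_term_defaults)
    seed: int = 0

    def validate(self) -> None:
        if self.n_preterm < 1 or self.n_term < 1:
            raise ConfigurationError(
                f"group sizes must be >= 1, got n_preterm={self.n_preterm}, "
                f"n_term={self.n_term}"
            )
        if self.nodes_per_hemisphere < 4:
            raise ConfigurationError("need at least 4 nodes per hemisphere")
        if not 0.0 < self.intra_edge_density <= 1.0:
            raise ConfigurationError(
                f"intra_edge_density must be in (0, 1], got "
                f"{self.intra_edge_density}"
            )
        for name in ("lattice_rewire_prob_left", "lattice_rewire_prob_right",
                     "interhemispheric_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.fa_mean < 1.0:
            raise ConfigurationError(f"fa_mean must be in (0, 1), got {self.fa_mean}")
        if self.fa_sd < 0 or self.fa_mean - 3 * self.fa_sd <= 0 \
                or self.fa_mean + 3 * self.fa_sd >= 1:
            raise ConfigurationError(
                "fa_mean +/- 3*fa_sd must stay inside (0, 1): "
                f"mean={self.fa_mean}, sd={self.fa_sd}"
            )
        if self.fibers_per_edge_mean <= 0:
            raise ConfigurationError("fibers_per_edge_mean must be > 0")
        known = set(GLOBAL_EFFECT_KEYS) | set(ROI_NAMES)
        for effects in (self.asymmetry_effects, self.subgroup_asymmetry_effects):
            bad = set(effects) - known
            if bad:
                raise ConfigurationError(
                    f"unknown asymmetry_effects keys {sorted(bad)}; "
                    f"expected {sorted(known)}"
                )


GLOBAL_EFFECT_KEYS = ("sigma", "density")


@dataclass
class SyntheticCohort:
    """One generated cohort: covariate table, connectomes, optional
    tractograms, and the planted ground truth."""

    cohort_table: pd.DataFrame
    connectomes: list[Connectome]
    atlas: pd.DataFrame
    truth: dict
    tractograms: list[StreamlineSet] | None = None


def _rng(master_seed: int, stream: int, subject: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(stream, subject))
    )


def _trunc_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort_table(config: SimulationConfig, seed: int | None = None
                          ) -> pd.DataFrame:
    """Draw the cohort covariate table.

    Columns: subject_id, group, sex, gestational_age, age_at_mri, bpd,
    bayley_{cognitive,language,motor,se}, assessed_flag, se_abnormal.
    Bayley scores are NaN for unassessed subjects; ``se_abnormal`` applies
    the < 85 social-emotional cutoff among assessed subjects.
    """
    config.validate()
    master = config.seed if seed is None else seed
    rng = _rng(master, _STREAM_TABLE)
    rows = []
    specs = [("preterm", config.n_preterm, config.preterm_covariates, "P"),
             ("term", config.n_term, config.term_covariates, "T")]
    for group, n, cov, prefix in specs:
        ga = _trunc_normal(rng, cov.ga_mean, cov.ga_sd, *cov.ga_range, size=n)
        age = _trunc_normal(rng, cov.age_mri_mean, cov.age_mri_sd,
                            *cov.age_mri_range, size=n)
        male = rng.random(n) < cov.male_prop
        bpd = rng.random(n) < cov.bpd_prev
        assessed = rng.random(n) < cov.assessed_prop
        bayley = {s: rng.normal(cov.bayley_mean[s], cov.bayley_sd[s], size=n)
                  for s in BAYLEY_SCALES}
        for i in range(n):
            row = {
                "subject_id": f"{prefix}{i + 1:03d}",
                "group": group,
                "sex": "male" if male[i] else "female",
                "gestational_age": round(float(ga[i]), 2),
                "age_at_mri": round(float(age[i]), 2),
                "bpd": "yes" if bpd[i] else "no",
                "assessed_flag": bool(assessed[i]),
            }
            for s in BAYLEY_SCALES:
                row[f"bayley_{s}"] = (
                    round(float(bayley[s][i]), 1) if assessed[i] else np.nan
                )
            row["se_abnormal"] = (
                bool(row["bayley_se"] < SE_CUTOFF) if assessed[i] else False
            )
            rows.append(row)
    return pd.DataFrame(rows)


def _lattice_k(n_nodes: int, density: float) -> int:
    """Even lattice neighbor count approximating the target density."""
    k = int(round(density * (n_nodes - 1) / 2.0)) * 2
    k = max(k, 2)
    if k >= n_nodes:
        raise ConfigurationError(
            f"density {density} unreachable on a ring lattice with "
            f"{n_nodes} nodes (requires k={k} < n)"
        )
    return k


def simulate_hemisphere_graph(
    n_nodes: int,
    density: float,
    rewire_prob: float,
    seed: int,
    side: str = "left",
    node_labels: list[int] | None = None,
    max_tries: int = 100,
) -> HemisphereNetwork:
    """Connected rewired ring lattice at the target density.

    Builds a ring lattice with the even neighbor count nearest to the
    density, rewires each edge with ``rewire_prob``, and retries (bounded)
    until the result is connected.
    """
    if n_nodes < 4:
        raise ConfigurationError(f"need n_nodes >= 4, got {n_nodes}")
    k = _lattice_k(n_nodes, density)
    try:
        g = nx.connected_watts_strogatz_graph(
            n_nodes, k, rewire_prob, tries=max_tries, seed=int(seed)
        )
    except nx.NetworkXError as exc:
        raise GenerationError(
            f"no connected graph in {max_tries} attempts "
            f"(n={n_nodes}, k={k}, p={rewire_prob})"
        ) from exc
    adj = nx.to_numpy_array(g, nodelist=range(n_nodes), dtype=np.uint8)
    labels = list(range(n_nodes)) if node_labels is None else list(node_labels)
    return HemisphereNetwork(side=side, node_labels=labels, adjacency=adj)


def _reroute_onto_node(adj: np.ndarray, node: int, prob: float,
                       rng: np.random.Generator) -> None:
    """Reroute a fraction of edges so one endpoint becomes ``node``,
    raising its degree and betweenness (in place)."""
    edges = np.argwhere(np.triu(adj, 1))
    for a, b in edges:
        if node in (a, b) or rng.random() >= prob:
            continue
        keep, drop = (a, b) if rng.random() < 0.5 else (b, a)
        if adj[keep, node]:
            continue
        adj[a, b] = adj[b, a] = 0
        adj[keep, node] = adj[node, keep] = 1


def _subject_params(config: SimulationConfig, row) -> dict:
    """Resolve per-subject generative parameters after planted effects."""
    effects: dict[str, float] = {}
    if row["group"] == "preterm":
        for k, v in config.asymmetry_effects.items():
            effects[k] = effects.get(k, 0.0) + v
        if bool(row.get("se_abnormal", False)):
            for k, v in config.subgroup_asymmetry_effects.items():
                effects[k] = effects.get(k, 0.0) + v
    d_sigma = effects.get("sigma", 0.0)
    d_density = effects.get("density", 0.0)
    params = {
        "rewire_left": float(np.clip(
            config.lattice_rewire_prob_left - d_sigma / 2.0, 0.0, 1.0)),
        "rewire_right": float(np.clip(
            config.lattice_rewire_prob_right + d_sigma / 2.0, 0.0, 1.0)),
        "density_left": float(np.clip(
            config.intra_edge_density + d_density / 2.0, 0.0, 1.0)),
        "density_right": float(np.clip(
            config.intra_edge_density - d_density / 2.0, 0.0, 1.0)),
        "roi_effects": {r: effects[r] for r in ROI_NAMES if r in effects},
    }
    return params


def simulate_connectome(
    config: SimulationConfig,
    subject_row,
    seed: int | None = None,
    atlas: pd.DataFrame | None = None,
    subject_index: int = 0,
) -> Connectome:
    """One subject's symmetric connectome with planted hemispheric structure.

    Left and right intra-hemispheric blocks are independent rewired
    lattices (group-shifted parameters); sparse interhemispheric edges are
    added at ``interhemispheric_density``; FA weights on existing edges are
    truncated-normal and fiber counts zero-truncated Poisson.
    """
    config.validate()
    master = config.seed if seed is None else seed
    rng = _rng(master, _STREAM_CONNECTOME, subject_index)
    if atlas is None:
        atlas = default_atlas(config.nodes_per_hemisphere)
    n = config.nodes_per_hemisphere
    params = _subject_params(config, subject_row)
    blocks = {}
    for side in ("left", "right"):
        net = simulate_hemisphere_graph(
            n,
            params[f"density_{side}"],
            params[f"rewire_{side}"],
            seed=int(rng.integers(2**31)),
            side=side,
        )
        block = net.adjacency.copy()
        for roi_name, eff in params["roi_effects"].items():
            boosted = "left" if eff > 0 else "right"
            if side == boosted and eff != 0.0:
                node = roi_label(atlas, roi_name, side) - 1 - (0 if side == "left" else n)
                _reroute_onto_node(block, node, abs(eff), rng)
        blocks[side] = block
    full = np.zeros((2 * n, 2 * n), dtype=np.uint8)
    full[:n, :n] = blocks["left"]
    full[n:, n:] = blocks["right"]
    inter = rng.random((n, n)) < config.interhemispheric_density
    full[:n, n:] = inter
    full[n:, :n] = inter.T
    np.fill_diagonal(full, 0)

    lo = (0.0 - config.fa_mean) / config.fa_sd
    hi = (1.0 - config.fa_mean) / config.fa_sd
    fa_draws = truncnorm.rvs(lo, hi, loc=config.fa_mean, scale=config.fa_sd,
                             size=(2 * n, 2 * n), random_state=rng)
    fa = np.triu(fa_draws, 1) * np.triu(full, 1)
    fa = fa + fa.T
    counts = np.zeros_like(full, dtype=int)
    iu = np.triu(full, 1).astype(bool)
    # zero-truncated Poisson fiber counts on existing edges
    n_edges = int(iu.sum())
    draws = rng.poisson(config.fibers_per_edge_mean, size=n_edges)
    while np.any(draws == 0):
        zero = draws == 0
        draws[zero] = rng.poisson(config.fibers_per_edge_mean, size=int(zero.sum()))
    counts[iu] = draws
    counts = counts + counts.T
    return Connectome(
        subject_id=str(subject_row["subject_id"]),
        labels=atlas["label_id"].tolist(),
        fa_weight=fa,
        fiber_count=counts,
        binary=full,
    )


def simulate_tractogram(
    connectome: Connectome,
    config: SimulationConfig,
    seed: int | None = None,
    subject_index: int = 0,
) -> StreamlineSet:
    """Streamline summary consistent with a connectome.

    Every existing edge gets its ``fiber_count`` fibers (zero-truncated by
    construction), each with 5-50 voxel FA samples; fiber means are centered
    so the mean-of-fiber-means reproduces the edge FA weight (within the
    [0, 1] clipping tolerance of 0.02).
    """
    config.validate()
    master = config.seed if seed is None else seed
    rng = _rng(master, _STREAM_TRACTOGRAM, subject_index)
    fibers = []
    n = len(connectome.labels)
    for i in range(n):
        for j in range(i + 1, n):
            if not connectome.binary[i, j]:
                continue
            n_fib = max(int(connectome.fiber_count[i, j]), 1)
            target = float(connectome.fa_weight[i, j])
            noise = rng.normal(0.0, 0.01, size=n_fib)
            fiber_means = np.clip(target + noise - noise.mean(), 0.0, 1.0)
            for fm in fiber_means:
                n_vox = int(rng.integers(5, 51))
                v_noise = rng.normal(0.0, 0.02, size=n_vox)
                voxels = np.clip(fm + v_noise - v_noise.mean(), 0.0, 1.0)
                fibers.append(
                    (connectome.labels[i], connectome.labels[j], voxels)
                )
    return StreamlineSet(subject_id=connectome.subject_id, fibers=fibers)


def simulate_cohort(
    config: SimulationConfig,
    seed: int | None = None,
    with_tractograms: bool = False,
) -> SyntheticCohort:
    """Full cohort: table, connectomes (one per row), truth sidecar."""
    config.validate()
    master = config.seed if seed is None else seed
    table = simulate_cohort_table(config, seed=master)
    atlas = default_atlas(config.nodes_per_hemisphere)
    connectomes = []
    tractograms = [] if with_tractograms else None
    per_subject = []
    for i, (_, row) in enumerate(table.iterrows()):
        conn = simulate_connectome(config, row, seed=master, atlas=atlas,
                                   subject_index=i)
        connectomes.append(conn)
        per_subject.append(
            {"subject_id": row["subject_id"], **_subject_params(config, row)}
        )
        if with_tractograms:
            tractograms.append(
                simulate_tractogram(conn, config, seed=master, subject_index=i)
            )
    truth = {
        "master_seed": master,
        "asymmetry_effects": dict(config.asymmetry_effects),
        "subgroup_asymmetry_effects": dict(config.subgroup_asymmetry_effects),
        "per_subject": per_subject,
    }
    return SyntheticCohort(
        cohort_table=table,
        connectomes=connectomes,
        atlas=atlas,
        truth=truth,
        tractograms=tractograms,
    )


def with_effects(config: SimulationConfig, **effects) -> SimulationConfig:
    """Copy of ``config`` with planted preterm asymmetry effects."""
    return replace(config, asymmetry_effects=dict(effects))
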