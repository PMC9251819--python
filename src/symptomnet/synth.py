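"""Synthetic cohorts from a sparse latent Gaussian graphical model.

The real item-level trial data are restricted, so every downstream stage is
exercised on cohorts drawn from a known ground truth.  The generator follows
the standard psychometric latent-variable assumption: item scores arise from
a latent multivariate normal whose precision matrix is sparse, with
community-clustered support (dense within instrument/subscale blocks, sparse
between) plus a small number of planted *bridge* nodes that carry strong
cross-community edges.  Latent values are discretized through per-item
ordered thresholds into each instrument's ordinal range.

Defaults are calibrated to the study cohort the package emulates:
n = 446 participants, age 40.0 +/- 10.9 years (truncated to [18, 65]),
70% male, and mostly positive edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .instruments import CohortTable, ItemSchema, default_schema, write_cohort
from .ggm import partial_from_precision

__all__ = [
    "SimConfig",
    "GroundTruthNetwork",
    "make_ground_truth",
    "sample_cohort",
    "simulate_cohort",
    "fixture_suite",
]

#: minimum eigenvalue enforced on the ground-truth precision matrix
MIN_EIGENVALUE = 0.05


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the emulated study conditions."""

    n: int = 446
    within_density: float = 0.3
    between_density: float = 0.02
    n_bridges: int = 4
    partial_range: tuple[float, float] = (0.2, 0.4)
    negative_edge_prob: float = 0.1
    seed: int = 0
    mean_age: float = 40.0
    sd_age: float = 10.9
    prop_male: float = 0.70
    thresholds: str = "skewed"  # skewed | uniform
    skew_power: float = 0.6  # <1 puts more mass on low (mild) categories

    def __post_init__(self) -> None:
        if not (0.0 <= self.within_density <= 1.0 and 0.0 <= self.between_density <= 1.0):
            raise ValueError("densities must lie in [0, 1]")
        lo, hi = self.partial_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("partial_range must lie within (0, 1)")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.thresholds not in ("skewed", "uniform"):
            raise ValueError("thresholds must be 'skewed' or 'uniform'")
        if not 0.0 <= self.prop_male <= 1.0:
            raise ValueError("prop_male must lie in [0, 1]")


@dataclass
class GroundTruthNetwork:
    """True precision / partial-correlation structure behind a synthetic cohort."""

    precision: np.ndarray
    partials: np.ndarray
    support: np.ndarray
    planted_bridges: list[tuple[str, tuple[str, str]]] = field(default_factory=list)

    @property
    def bridge_node_ids(self) -> list[str]:
        return sorted({node for node, _ in self.planted_bridges})

    def save(self, edge_path, sidecar_path=None, schema: ItemSchema | None = None,
             config: SimConfig | None = None) -> None:
        """Serialize as an edge list (node_i, node_j, partial) + JSON sidecar."""
        ids = schema.ids if schema is not None else [str(i) for i in range(len(self.partials))]
        with open(edge_path, "w", encoding="utf-8") as fh:
            fh.write("node_i,node_j,partial_correlation\n")
            p = len(ids)
            for i in range(p):
                for j in range(i + 1, p):
                    if self.support[i, j]:
                        fh.write(f"{ids[i]},{ids[j]},{self.partials[i, j]:.10g}\n")
        if sidecar_path is not None:
            payload = {
                "config": asdict(config) if config is not None else None,
                "planted_bridges": [[n, list(c)] for n, c in self.planted_bridges],
            }
            with open(sidecar_path, "w", encoding="utf-8") as fh:
                json.dump(payload, fh, indent=1)


def make_ground_truth(schema: ItemSchema, config: SimConfig) -> GroundTruthNetwork:
    """Draw a sparse, positive-definite ground-truth network.

    Edges appear independently with probability ``within_density`` inside a
    community and ``between_density`` across communities; ``n_bridges`` nodes
    additionally receive two strong cross-community edges each (drawn at the
    top of ``partial_range``, always positive).  Positive definiteness is
    enforced by shrinking the off-diagonal block until the smallest
    eigenvalue of the precision matrix is at least ``MIN_EIGENVALUE``; the
    zero pattern is unchanged by the shrinkage.
    """
    rng = np.random.default_rng(config.seed)
    ids = schema.ids
    p = len(ids)
    labels = schema.community_labels()

    lo, hi = config.partial_range
    target = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            dens = config.within_density if labels[i] == labels[j] else config.between_density
            if rng.random() < dens:
                mag = rng.uniform(lo, hi)
                sign = -1.0 if rng.random() < config.negative_edge_prob else 1.0
                target[i, j] = target[j, i] = sign * mag

    # plant bridge nodes: strong positive cross-community connectors
    planted: list[tuple[str, tuple[str, str]]] = []
    if config.n_bridges > 0:
        if config.n_bridges > p:
            raise ValueError("n_bridges exceeds the number of nodes")
        bridge_idx = rng.choice(p, size=config.n_bridges, replace=False)
        for bi in bridge_idx:
            others = [j for j in range(p) if labels[j] != labels[bi]]
            if not others:
                raise ValueError("cannot plant bridges with a single community")
            partners = rng.choice(others, size=min(2, len(others)), replace=False)
            for pj in partners:
                target[bi, pj] = target[pj, bi] = hi
                planted.append((ids[bi], (labels[bi], labels[pj])))

    # precision with unit diagonal and off-diagonal -target; shrink to PD
    K = np.eye(p) - target
    np.fill_diagonal(K, 1.0)
    shrink = 1.0
    for _ in range(60):
        K_try = np.eye(p) + shrink * (K - np.eye(p))
        if np.linalg.eigvalsh(K_try).min() >= MIN_EIGENVALUE:
            K = K_try
            break
        shrink *= 0.9
    else:
        raise RuntimeError("could not reach a positive-definite precision matrix")

    partials = partial_from_precision(K)
    support = np.abs(partials) > 0
    return GroundTruthNetwork(
        precision=K, partials=partials, support=support, planted_bridges=planted
    )


def _category_thresholds(item, config: SimConfig) -> np.ndarray:
    """Latent z-scale cutpoints mapping N(0,1) draws to the item's categories."""
    c = item.n_categories
    k = np.arange(1, c)
    if config.thresholds == "uniform":
        cum = k / c
    else:
        cum = (k / c) ** config.skew_power
    return stats.norm.ppf(cum)


def sample_cohort(
    truth: GroundTruthNetwork, schema: ItemSchema, config: SimConfig
) -> CohortTable:
    """Draw ``config.n`` participants from the ground-truth model.

    Latent vectors are multivariate normal with covariance equal to the
    correlation matrix implied by ``truth.precision``; each latent variable
    is then cut at item-specific thresholds into the item's integer range.
    Age is truncated-normal on [18, 65]; sex is Bernoulli(prop_male).
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed + 1)  # distinct stream from truth
    p = schema.n_items
    cov = np.linalg.inv(truth.precision)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    latent = rng.multivariate_normal(np.zeros(p), corr, size=config.n, method="cholesky")

    scores = np.empty((config.n, p), dtype=np.int64)
    for j, item in enumerate(schema.items):
        cuts = _category_thresholds(item, config)
        scores[:, j] = item.min_score + np.searchsorted(cuts, latent[:, j])

    # synthetic global PSP total (0-100, higher = better): a noisy monotone
    # inverse of the mean PSP subscore severity, not the official scoring rule
    psp_cols = [j for j, it in enumerate(schema.items) if it.instrument == "PSP"]
    psp_total = None
    if psp_cols:
        severity = scores[:, psp_cols].mean(axis=1) / 6.0  # in [0, 1]
        noise = rng.normal(0.0, 5.0, size=config.n)
        psp_total = np.clip(
            np.round(100.0 * (1.0 - severity) + noise), 0, 100
        ).astype(np.int64)

    a, b = (18 - config.mean_age) / config.sd_age, (65 - config.mean_age) / config.sd_age
    age = stats.truncnorm.rvs(
        a, b, loc=config.mean_age, scale=config.sd_age, size=config.n, random_state=rng
    )
    sex = np.where(rng.random(config.n) < config.prop_male, "male", "female")

    import pandas as pd

    demographics = pd.DataFrame({"age": np.round(age, 1), "sex": sex})
    participant_ids = [f"S{i:04d}" for i in range(config.n)]
    return CohortTable(
        schema=schema,
        scores=scores,
        participant_ids=participant_ids,
        demographics=demographics,
        psp_total=psp_total,
    )


def simulate_cohort(
    config: SimConfig | None = None, schema: ItemSchema | None = None
) -> tuple[CohortTable, GroundTruthNetwork]:
    """Convenience wrapper: ground truth + cohort in one seeded call."""
    config = config or SimConfig()
    schema = schema or default_schema()
    truth = make_ground_truth(schema, config)
    return sample_cohort(truth, schema, config), truth


def tiny_schema(n_per_community: int = 3, n_communities: int = 2) -> ItemSchema:
    """A small synthetic schema (7-point items) for fast tests and fixtures."""
    from .instruments import ItemDef

    items = []
    communities = {}
    for c in range(n_communities):
        for k in range(n_per_community):
            iid = f"T{c}{k}"
            items.append(
                ItemDef(
                    id=iid,
                    label=f"synthetic item {iid}",
                    instrument="PANSS",
                    subscale="general",
                    min_score=1,
                    max_score=7,
                )
            )
            communities[iid] = f"block-{c}"
    return ItemSchema(items=tuple(items), communities=communities)


def fixture_suite(out_dir) -> None:
    """Write a small library of seeded, named fixtures for tests and demos.

    Emits (a) a tiny 6-node cohort, (b) the default 43-node cohort, and
    (c) a block-diagonal null cohort (no cross-community edges), each with
    its ground-truth edge list and JSON sidecar.  Re-running produces
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    specs = {
        "tiny6": (tiny_schema(), SimConfig(n=120, seed=7, n_bridges=1,
                                           within_density=0.6, between_density=0.05)),
        "default43": (default_schema(), SimConfig(seed=11)),
        "null_block": (default_schema(), SimConfig(seed=13, between_density=0.0,
                                                   n_bridges=0)),
    }
    for name, (schema, cfg) in specs.items():
        truth = make_ground_truth(schema, cfg)
        table = sample_cohort(truth, schema, cfg)
        write_cohort(table, out / f"{name}_cohort.csv")
        truth.save(
            out / f"{name}_truth_edges.csv",
            out / f"{name}_truth.json",
            schema=schema,
            config=cfg,
        )
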