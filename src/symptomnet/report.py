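"""Layout, figures, descriptive tables and the end-to-end pipeline runner.

The network drawing follows the field's conventions: a weighted
Fruchterman-Reingold force-directed layout (strongly connected nodes pulled
together), one color for positive and another for negative partial
correlations, edge width proportional to |weight|, and bridge nodes visually
marked.  Every figure has a machine-readable CSV twin so nothing is
reported that cannot be checked; the pipeline writes a manifest (config,
seeds, per-file hashes) so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .ggm import NetworkModel, estimate_network
from .inference import CentralityReport, centrality_report
from .instruments import CohortTable, default_schema, read_cohort
from .stability import case_drop_bootstrap, edge_bootstrap
from .synth import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["Layout", "RunConfig", "layout_fr", "render", "descriptives", "run_pipeline"]

POSITIVE_EDGE_COLOR = "#2166ac"  # blue
NEGATIVE_EDGE_COLOR = "#b2182b"  # red
#: minimum node separation after rescaling to the unit square
MIN_NODE_SEPARATION = 1e-6


@dataclass
class Layout:
    """Node coordinates in the unit square, deterministic given the seed."""

    coordinates: dict[str, tuple[float, float]]
    iterations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, x, y) for k, (x, y) in self.coordinates.items()],
            columns=["id", "x", "y"],
        )


def layout_fr(model: NetworkModel, seed: int = 0, iterations: int = 500) -> Layout:
    """Weighted Fruchterman-Reingold layout of the estimated network.

    Attraction scales with |partial correlation| while repulsion is
    weight-blind; initial positions are seeded so the layout is a pure
    function of (model, seed, iterations).  Coordinates are rescaled to the
    unit square; a single node sits at its center.
    """
    g = model.to_graph()
    for _, _, d in g.edges(data=True):
        d["absweight"] = abs(d["weight"])
    if g.number_of_nodes() == 1:
        coords = {n: (0.5, 0.5) for n in g.nodes}
        return Layout(coordinates=coords, iterations=iterations, seed=seed)
    pos = nx.spring_layout(
        g, weight="absweight", iterations=iterations, seed=seed, dim=2
    )
    xy = np.array([pos[n] for n in g.nodes])
    span = xy.max(axis=0) - xy.min(axis=0)
    span[span == 0] = 1.0
    xy = (xy - xy.min(axis=0)) / span
    # nudge exact coincidences apart (deterministic)
    for i in range(len(xy)):
        for j in range(i + 1, len(xy)):
            if np.linalg.norm(xy[i] - xy[j]) < MIN_NODE_SEPARATION:
                xy[j] = xy[j] + MIN_NODE_SEPARATION * (j + 1)
    coords = {n: (float(x), float(y)) for n, (x, y) in zip(g.nodes, xy)}
    return Layout(coordinates=coords, iterations=iterations, seed=seed)


def render(
    model: NetworkModel,
    centrality: CentralityReport,
    layout: Layout,
    out_dir,
) -> list[Path]:
    """Write the network, centrality and bridge figures plus CSV twins.

    Emits ``network.png``/``network_edges.csv`` (per-edge style table:
    endpoints, weight, color, width), ``centrality.png``/``centrality.csv``
    (z-scored profiles) and ``bridge.png``/``bridge.csv``.  The CSV values
    are exactly the numbers drawn.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    ids = centrality.table["id"].tolist()
    if set(layout.coordinates) != set(ids):
        raise ValueError("layout and centrality report cover different node sets")

    # --- network figure + edge style table
    edges = model.edge_list()
    style = pd.DataFrame(
        [
            {
                "node_i": a,
                "node_j": b,
                "weight": w,
                "color": POSITIVE_EDGE_COLOR if w > 0 else NEGATIVE_EDGE_COLOR,
                "width": 6.0 * abs(w),
            }
            for a, b, w in edges
        ],
        columns=["node_i", "node_j", "weight", "color", "width"],
    )
    style.to_csv(out / "network_edges.csv", index=False)
    written.append(out / "network_edges.csv")

    fig, ax = plt.subplots(figsize=(8, 8))
    for _, row in style.iterrows():
        x1, y1 = layout.coordinates[row["node_i"]]
        x2, y2 = layout.coordinates[row["node_j"]]
        ax.plot([x1, x2], [y1, y2], color=row["color"], lw=row["width"], alpha=0.7,
                zorder=1)
    bridge_set = set(centrality.bridge_nodes)
    for node in ids:
        x, y = layout.coordinates[node]
        is_bridge = node in bridge_set
        ax.scatter(
            [x], [y], s=420, zorder=2,
            c="#fddbc7" if is_bridge else "#d1e5f0",
            edgecolors="black", linewidths=2.0 if is_bridge else 0.8,
        )
        ax.annotate(node, (x, y), ha="center", va="center", fontsize=6, zorder=3)
    ax.set_axis_off()
    fig.savefig(out / "network.png", dpi=150)
    plt.close(fig)
    written.append(out / "network.png")

    # --- centrality profile figure + table
    cent = centrality.table
    cent.to_csv(out / "centrality.csv", index=False)
    written.append(out / "centrality.csv")
    fig, axes = plt.subplots(1, 3, figsize=(9, 0.22 * len(ids) + 2), sharey=True)
    ypos = np.arange(len(ids))[::-1]
    for ax, col, title in zip(
        axes,
        ["strength_z", "expected_influence_z", "predictability"],
        ["Strength (z)", "Expected influence (z)", "Predictability (R²)"],
    ):
        ax.plot(cent[col], ypos, "o-", ms=3)
        ax.set_title(title, fontsize=9)
        ax.grid(alpha=0.3)
    axes[0].set_yticks(ypos)
    axes[0].set_yticklabels(cent["id"], fontsize=6)
    fig.tight_layout()
    fig.savefig(out / "centrality.png", dpi=150)
    plt.close(fig)
    written.append(out / "centrality.png")

    # --- bridge centrality figure + table
    bridge = cent[["id", "community", "bridge_strength", "bridge_betweenness",
                   "is_bridge"]]
    bridge.to_csv(out / "bridge.csv", index=False)
    written.append(out / "bridge.csv")
    fig, axes = plt.subplots(1, 2, figsize=(7, 0.22 * len(ids) + 2), sharey=True)
    for ax, col, title in zip(
        axes, ["bridge_strength", "bridge_betweenness"],
        ["Bridge strength", "Bridge betweenness"],
    ):
        colors = ["#b2182b" if b else "#4393c3" for b in cent["is_bridge"]]
        ax.barh(ypos, cent[col], color=colors)
        ax.set_title(title, fontsize=9)
        ax.grid(alpha=0.3)
    axes[0].set_yticks(ypos)
    axes[0].set_yticklabels(cent["id"], fontsize=6)
    fig.tight_layout()
    fig.savefig(out / "bridge.png", dpi=150)
    plt.close(fig)
    written.append(out / "bridge.png")
    return written


def descriptives(table: CohortTable) -> pd.DataFrame:
    """Sample descriptives: n, demographics, per-subscale totals mean (SD)."""
    rows = [{"measure": "n", "mean": float(table.n), "sd": np.nan, "pct": np.nan}]
    if table.demographics is not None:
        if "age" in table.demographics:
            age = table.demographics["age"].to_numpy(dtype=float)
            rows.append({"measure": "age_years", "mean": age.mean(),
                         "sd": age.std(ddof=1) if len(age) > 1 else 0.0, "pct": np.nan})
        if "sex" in table.demographics:
            male = (table.demographics["sex"] == "male").mean()
            rows.append({"measure": "male", "mean": np.nan, "sd": np.nan,
                         "pct": 100.0 * male})
    subscales: dict[tuple[str, str], list[int]] = {}
    for j, item in enumerate(table.schema.items):
        subscales.setdefault((item.instrument, item.subscale), []).append(j)
    for (instrument, subscale), cols in subscales.items():
        totals = table.scores[:, cols].sum(axis=1).astype(float)
        rows.append({
            "measure": f"{instrument}_{subscale}_total",
            "mean": totals.mean(),
            "sd": totals.std(ddof=1) if len(totals) > 1 else 0.0,
            "pct": np.nan,
        })
    if table.psp_total is not None:
        tot = table.psp_total.astype(float)
        rows.append({"measure": "psp_total", "mean": tot.mean(),
                     "sd": tot.std(ddof=1) if len(tot) > 1 else 0.0, "pct": np.nan})
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; serialized into the output dir."""

    input_path: str | None = None  # cohort CSV; None -> simulate
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    method: str = "pearson"
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    top_fraction: float = 0.20
    run_stability: bool = False
    edge_boot_B: int = 1000
    case_drop_B: int = 500
    seed: int = 0
    layout_iterations: int = 500
    out_dir: str = "symptomnet_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and write all artifacts plus a manifest.

    Stages: descriptives -> network estimation -> centrality/bridge
    inference -> (optional) stability -> layout -> render.  Any stage
    failure aborts with the stage name; partial outputs are preserved.
    The manifest records the config, software version and a hash of every
    table output, enabling byte-identical re-runs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.json", "w", encoding="utf-8") as fh:
        json.dump(asdict(config), fh, indent=1)

    stages_done: list[str] = []
    stage = "load"
    try:
        schema = default_schema()
        if config.input_path is not None:
            table = read_cohort(config.input_path, schema, strict=True)
        else:
            sim = SimConfig(**{"seed": config.seed, **config.simulate})
            table, truth = simulate_cohort(sim, schema)
            truth.save(out / "truth_edges.csv", out / "truth.json",
                       schema=schema, config=sim)

        stage = "descriptives"
        desc = descriptives(table)
        desc.to_csv(out / "descriptives.csv", index=False)
        stages_done.append(stage)

        stage = "estimate_network"
        model = estimate_network(
            table, method=config.method, gamma=config.gamma,
            n_lambda=config.n_lambda, lambda_min_ratio=config.lambda_min_ratio,
        )
        pd.DataFrame(model.edge_list(), columns=["source", "target", "weight"]).to_csv(
            out / "edges.csv", index=False
        )
        nx.write_graphml(model.to_graph(), out / "network.graphml")
        with open(out / "model.json", "w", encoding="utf-8") as fh:
            json.dump(
                {"lambda": model.lam, "gamma": model.gamma, "ebic": model.ebic,
                 "n_edges": model.n_edges, "method": model.method, "n": model.n,
                 "seed": config.seed},
                fh, indent=1,
            )
        stages_done.append(stage)

        stage = "inference"
        cent = centrality_report(model, fraction=config.top_fraction)
        stages_done.append(stage)

        stage = "stability"
        if config.run_stability:
            settings = {"method": config.method, "gamma": config.gamma,
                        "n_lambda": config.n_lambda,
                        "lambda_min_ratio": config.lambda_min_ratio}
            eb = edge_bootstrap(table, settings, B=config.edge_boot_B,
                                seed=config.seed)
            cd = case_drop_bootstrap(table, settings, B=config.case_drop_B,
                                     seed=config.seed)
            eb.edge_ci.to_csv(out / "edge_ci.csv", index=False)
            cd.drop_curve.to_csv(out / "drop_curve.csv", index=False)
            with open(out / "stability.json", "w", encoding="utf-8") as fh:
                json.dump({"cs_coefficient": cd.cs}, fh, indent=1)
        stages_done.append(stage)

        stage = "layout"
        layout = layout_fr(model, seed=config.seed,
                           iterations=config.layout_iterations)
        layout.to_frame().to_csv(out / "layout.csv", index=False)
        stages_done.append(stage)

        stage = "render"
        render(model, cent, layout, out)
        stages_done.append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    hashes = {
        f.name: _sha256(f)
        for f in sorted(out.iterdir())
        if f.suffix in {".csv", ".json", ".graphml"} and f.name != "manifest.json"
    }
    manifest = {
        "version": __version__,
        "stages": stages_done,
        "seed": config.seed,
        "config": asdict(config),
        "hashes": hashes,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return out
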