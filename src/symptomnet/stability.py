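"""Bootstrap accuracy and stability diagnostics for estimated networks.

Two resampling schemes, both rerunning the *full* estimation pipeline
(correlation, lasso path, EBIC selection) on each replicate:

* **edge bootstrap** — nonparametric resampling of participants with
  replacement; per-edge quantile confidence intervals describe the
  sampling variability of the regularized edge weights.
* **case-dropping bootstrap** — for each drop proportion q in a grid,
  subsamples retaining ``ceil((1 - q) n)`` participants without
  replacement; the Pearson correlation between full-sample and subsample
  centrality vectors quantifies how far the centrality ordering survives
  data loss.

The **correlation-stability (CS) coefficient** summarizes the drop curves:
the largest q at which at least ``prob`` (default 0.95) of replicates keep a
correlation of at least ``threshold`` (default 0.7) with the full-sample
centralities.

One master seed spawns independent per-replicate RNG streams, so every
resample's row indices are reproducible and independent of execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ggm import estimate_network
from . import inference

logger = logging.getLogger(__name__)

__all__ = [
    "StabilityReport",
    "edge_bootstrap",
    "case_drop_bootstrap",
    "cs_coefficient",
    "DEFAULT_DROP_GRID",
]

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.80, 0.05), 2))
CS_THRESHOLD = 0.7
CS_PROB = 0.95

_CENTRALITY_FUNS = {
    "strength": lambda m, comm: inference.strength(m),
    "expected_influence": lambda m, comm: inference.expected_influence(m),
    "bridge_strength": lambda m, comm: inference.bridge_strength(m, comm),
}


@dataclass
class StabilityReport:
    """Edge CIs, case-drop curves and CS coefficients of one cohort."""

    edge_ci: pd.DataFrame | None = None  # node_i, node_j, estimate, lower, upper
    drop_curve: pd.DataFrame | None = None  # index, q, replicate, correlation
    cs: dict[str, float] = field(default_factory=dict)
    boot_reps: int = 0
    alpha: float = 0.05
    seed: int | None = None
    n_failed: int = 0

    def save(self, out_dir) -> None:
        from pathlib import Path
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if self.edge_ci is not None:
            self.edge_ci.to_csv(out / "edge_ci.csv", index=False)
        if self.drop_curve is not None:
            self.drop_curve.to_csv(out / "drop_curve.csv", index=False)
        with open(out / "stability.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "cs_coefficient": self.cs,
                    "boot_reps": self.boot_reps,
                    "alpha": self.alpha,
                    "seed": self.seed,
                    "n_failed_replicates": self.n_failed,
                },
                fh,
                indent=1,
            )


def _replicate_rngs(seed: int, B: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(B)]


def _estimate(table, settings: dict | None):
    return estimate_network(table, **(settings or {}))


def _resampled(table, idx):
    """A shallow cohort copy restricted to the given row indices."""
    from .instruments import CohortTable

    if isinstance(table, CohortTable):
        return CohortTable(
            schema=table.schema,
            scores=table.scores[idx],
            participant_ids=[table.participant_ids[i] for i in idx],
            demographics=(
                table.demographics.iloc[idx].reset_index(drop=True)
                if table.demographics is not None
                else None
            ),
            psp_total=table.psp_total[idx] if table.psp_total is not None else None,
        )
    return np.asarray(table)[idx]


def edge_bootstrap(
    table,
    settings: dict | None = None,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    include_zero_edges: bool = False,
) -> StabilityReport:
    """Nonparametric bootstrap confidence intervals for edge weights.

    Each of the B replicates resamples participants with replacement at the
    original sample size and reruns the whole estimation.  Intervals are the
    ``[alpha/2, 1 - alpha/2]`` quantiles of each edge's replicate weights.
    By default only edges nonzero in the point estimate are reported (the
    regularized intervals of shrunk-out edges are not significance tests).
    Replicates whose estimation fails are dropped and counted; more than 10%
    failures aborts.
    """
    point = _estimate(table, settings)
    p = point.p
    ids = point.node_ids or [str(i) for i in range(p)]
    n = table.n if hasattr(table, "n") else np.asarray(table).shape[0]

    boots = np.full((B, p, p), np.nan)
    n_failed = 0
    for b, rng in enumerate(_replicate_rngs(seed, B)):
        idx = rng.integers(0, n, size=n)
        try:
            boots[b] = _estimate(_resampled(table, idx), settings).weights
        except Exception as exc:  # degenerate resample
            n_failed += 1
            logger.warning("edge bootstrap replicate %d failed: %s", b, exc)
    if n_failed > 0.10 * B:
        raise RuntimeError(f"{n_failed}/{B} bootstrap replicates failed")

    iu, ju = np.triu_indices(p, 1)
    rows = []
    for i, j in zip(iu, ju):
        est = point.weights[i, j]
        if est == 0.0 and not include_zero_edges:
            continue
        vals = boots[:, i, j]
        vals = vals[~np.isnan(vals)]
        lo, hi = np.quantile(vals, [alpha / 2.0, 1.0 - alpha / 2.0])
        rows.append(
            {
                "node_i": ids[i],
                "node_j": ids[j],
                "estimate": est,
                "lower": lo,
                "upper": hi,
            }
        )
    return StabilityReport(
        edge_ci=pd.DataFrame(rows),
        boot_reps=B - n_failed,
        alpha=alpha,
        seed=seed,
        n_failed=n_failed,
    )


def case_drop_bootstrap(
    table,
    settings: dict | None = None,
    indices: tuple[str, ...] = ("strength", "expected_influence", "bridge_strength"),
    grid=DEFAULT_DROP_GRID,
    B: int = 500,
    seed: int = 0,
    communities=None,
) -> StabilityReport:
    """Case-dropping bootstrap of centrality orderings.

    For each drop proportion q, B subsamples retain ``ceil((1-q) n)`` rows
    without replacement; the Pearson correlation between full-sample and
    subsample centrality vectors is recorded.  A replicate with an undefined
    correlation (zero variance, e.g. an empty network) is reported as
    missing with a warning.
    """
    for q in grid:
        if not 0.0 < q < 0.95:
            raise ValueError("drop proportions must lie in (0, 0.95)")
    unknown = [k for k in indices if k not in _CENTRALITY_FUNS]
    if unknown:
        raise ValueError(f"unknown centrality indices: {unknown}")

    point = _estimate(table, settings)
    comm = communities if communities is not None else point.communities
    full = {k: _CENTRALITY_FUNS[k](point, comm) for k in indices}
    n = table.n if hasattr(table, "n") else np.asarray(table).shape[0]

    rows = []
    n_failed = 0
    rngs = _replicate_rngs(seed, len(grid) * B)
    for gi, q in enumerate(grid):
        keep = int(np.ceil((1.0 - q) * n))
        for b in range(B):
            rng = rngs[gi * B + b]
            idx = rng.choice(n, size=keep, replace=False)
            try:
                sub = _estimate(_resampled(table, idx), settings)
            except Exception as exc:
                n_failed += 1
                logger.warning("case-drop replicate (q=%.2f, %d) failed: %s", q, b, exc)
                continue
            for k in indices:
                sv = _CENTRALITY_FUNS[k](sub, comm)
                fv = full[k]
                if np.std(sv) == 0 or np.std(fv) == 0:
                    logger.warning(
                        "undefined correlation for %s at q=%.2f (zero variance)", k, q
                    )
                    corr = np.nan
                else:
                    corr = float(np.corrcoef(fv, sv)[0, 1])
                rows.append({"index": k, "q": q, "replicate": b, "correlation": corr})
    total = len(grid) * B
    if n_failed > 0.10 * total:
        raise RuntimeError(f"{n_failed}/{total} case-drop replicates failed")

    curve = pd.DataFrame(rows)
    report = StabilityReport(
        drop_curve=curve, boot_reps=B, seed=seed, n_failed=n_failed
    )
    report.cs = {
        k: cs_coefficient(curve[curve["index"] == k]) for k in indices
    }
    return report


def cs_coefficient(
    drop_curve: pd.DataFrame, threshold: float = CS_THRESHOLD, prob: float = CS_PROB
) -> float:
    """Correlation-stability coefficient of one index's drop curve.

    CS = the largest drop proportion q in the grid at which the fraction of
    replicates with correlation >= ``threshold`` is >= ``prob``; 0.0 when no
    grid value qualifies.  Missing correlations count as failures.
    """
    if "correlation" not in drop_curve or "q" not in drop_curve:
        raise ValueError("drop_curve needs 'q' and 'correlation' columns")
    cs = 0.0
    for q, grp in drop_curve.groupby("q"):
        vals = grp["correlation"].to_numpy()
        ok = np.nan_to_num(vals, nan=-np.inf) >= threshold
        if ok.mean() >= prob and q > cs:
            cs = float(q)
    return cs
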