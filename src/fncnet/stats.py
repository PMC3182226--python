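"""Group-level statistics on metric curves.

At each point of the cost grid, network metrics (C_net, L_net, E_global,
E_local, gamma, lambda, sigma) are compared between the two groups with
pooled-variance two-sample two-tailed t-tests at alpha = 0.05, uncorrected
(16 grid points x 0.05 = 0.80 expected false positives, i.e. fewer than
one). Nodal metrics (K, C, L and the two efficiencies per node) get the
same tests as post-hocs, with Benjamini-Hochberg q-values reported
alongside the raw p-values for transparency. Where a network metric
differs, its relationship to symptom severity is assessed by Pearson
correlation with PANSS-like scores within the patient group, per grid
point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .graphs import CostGrid
from .metrics import NODAL_METRIC_NAMES

__all__ = [
    "ClinicalScores",
    "percost_group_test",
    "nodal_posthoc",
    "symptom_correlation",
    "false_positive_budget",
]


@dataclass(frozen=True)
class ClinicalScores:
    """PANSS-like 7-item scale scores (each scale ranges 7-49)."""

    subject_id: str
    panss_positive: int
    panss_negative: int

    def __post_init__(self) -> None:
        for name in ("panss_positive", "panss_negative"):
            v = getattr(self, name)
            if not 7 <= v <= 49:
                raise ValueError(f"{name}={v} outside the 7-item range 7-49")


def _curve_matrix(
    curves: pd.DataFrame,
    grid: CostGrid,
    metric: str,
    node: str,
    group: str,
) -> np.ndarray:
    """Subjects x grid-points value matrix for one metric/node/group."""
    sel = curves[
        (curves["metric"] == metric)
        & (curves["node"] == node)
        & (curves["group"] == group)
    ]
    if sel.empty:
        raise ValueError(
            f"no curves for metric={metric!r}, node={node!r}, group={group!r}"
        )
    wide = sel.pivot_table(
        index="subject_id", columns="edge_count", values="value", dropna=False
    )
    missing = [E for E in grid.edge_counts if E not in wide.columns]
    if missing:
        raise ValueError(f"curves missing grid points {missing}")
    return wide.loc[:, list(grid.edge_counts)].to_numpy()


def _group_labels(curves: pd.DataFrame) -> list[str]:
    labels = [g for g in curves["group"].unique() if g != ""]
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups in curves, got {labels}")
    return labels


def percost_group_test(
    curves: pd.DataFrame,
    grid: CostGrid,
    metric_name: str,
    node: str = "network",
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample two-tailed t-test at every grid point for one metric.

    Returns a tidy table (edge_count, k_cost, t, p, significant) with t
    oriented as first group minus second group (group order = appearance
    order in the curves). Significance is alpha uncorrected, flagged in a
    column, never filtered.
    """
    g1, g2 = _group_labels(curves)
    a = _curve_matrix(curves, grid, metric_name, node, g1)
    b = _curve_matrix(curves, grid, metric_name, node, g2)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    t, p = sps.ttest_ind(a, b, axis=0, equal_var=equal_var)
    return pd.DataFrame(
        {
            "metric": metric_name,
            "node": node,
            "edge_count": list(grid.edge_counts),
            "k_cost": list(grid.costs),
            "t": t,
            "p": p,
            "significant": p < alpha,
        }
    )


def nodal_posthoc(
    curves: pd.DataFrame,
    grid: CostGrid,
    metrics: tuple[str, ...] = NODAL_METRIC_NAMES,
    alpha: float = 0.05,
    fdr: bool = True,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-node per-cost post-hoc group tests over the nodal metrics.

    One row per (node, metric, grid point) with t, p, a significance flag
    at alpha uncorrected, and (by default) a Benjamini-Hochberg q-value
    column computed over all rows of the table. These tests are post-hocs:
    the pipeline runs them after the network-level comparison, and the
    uncorrected flags carry the caveat that nodal results may not survive
    FDR correction.
    """
    nodes = sorted(set(curves.loc[curves["node"] != "network", "node"]))
    frames = []
    for metric in metrics:
        for node in nodes:
            frames.append(
                percost_group_test(
                    curves, grid, metric, node=node, alpha=alpha,
                    equal_var=equal_var,
                )
            )
    table = pd.concat(frames, ignore_index=True)
    if fdr:
        finite = np.isfinite(table["p"].to_numpy())
        q = np.full(len(table), np.nan)
        if finite.any():
            q[finite] = multipletests(
                table.loc[finite, "p"], method="fdr_bh"
            )[1]
        table["q_fdr"] = q
        table["significant_fdr"] = table["q_fdr"] < alpha
    return table


def symptom_correlation(
    curves: pd.DataFrame,
    scores: pd.DataFrame,
    metric_name: str,
    node: str = "network",
    which_scale: str = "negative",
    group: str | None = None,
) -> pd.DataFrame:
    """Pearson correlation of a metric with symptom scores, per grid point.

    Restricted to the patient group (by default the group that actually
    has scores in the manifest). Returns (edge_count, k_cost, r, p, n).
    """
    col = f"score_{which_scale}"
    if col not in scores.columns:
        raise ValueError(f"scores table has no column {col!r}")
    scored = scores.dropna(subset=[col])
    if group is not None:
        scored = scored[scored["group"] == group]
    if len(scored) < 3:
        raise ValueError("need at least 3 scored patients")
    if scored[col].nunique() == 1:
        raise ValueError("symptom scores have zero variance")
    sel = curves[
        (curves["metric"] == metric_name)
        & (curves["node"] == node)
        & (curves["subject_id"].isin(scored["subject_id"]))
    ]
    if sel.empty:
        raise ValueError(f"no curves for metric={metric_name!r}, node={node!r}")
    wide = sel.pivot_table(
        index="subject_id", columns="edge_count", values="value", dropna=False
    )
    cost_of = dict(
        sel[["edge_count", "k_cost"]].drop_duplicates().to_numpy().tolist()
    )
    score_vec = scored.set_index("subject_id")[col].reindex(wide.index)
    rows = []
    for E in wide.columns:
        r, p = sps.pearsonr(wide[E].to_numpy(), score_vec.to_numpy(dtype=float))
        rows.append(
            {
                "metric": metric_name,
                "node": node,
                "scale": which_scale,
                "edge_count": int(E),
                "k_cost": float(cost_of[E]),
                "r": float(r),
                "p": float(p),
                "n": len(wide),
            }
        )
    return pd.DataFrame(rows)


def false_positive_budget(n_tests: int, alpha: float = 0.05) -> float:
    """Expected number of false positives among n uncorrected tests."""
    if n_tests < 1:
        raise ValueError("need n_tests >= 1")
    return n_tests * alpha
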