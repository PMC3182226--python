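"""End-to-end pipeline: cohort on disk -> statistics tables on disk.

Stages (each reloadable from the previous stage's outputs, so the pipeline
can be restarted anywhere):

  simulate      cohort/subjects/*.tsv + manifest.tsv + ground_truth.json
  connectivity  fnc/<subject>_z.tsv (Fisher-z FNC), fnc/strengths.tsv,
                fnc/mean_abs_z_<group>.tsv, fnc/strength_test.json
  graphs        grid.json (fixed edge-count grid or auto-selected regime)
  metrics       curves.tsv (long format, network + nodal, per grid point)
  nulls         nulls/<subject>.json (ensemble references per grid point)
                and gamma/lambda/sigma rows appended -> curves_full.tsv
  stats         stats/network_tests.tsv, stats/nodal_tests.tsv,
                stats/symptom_correlations.tsv, stats/summary.json

Seeding: one global seed is fanned out with numpy SeedSequence spawning,
keyed by stage and subject index, so per-subject streams are independent
and the whole run is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import ConnectivityMatrices, strength_group_test
from .graphs import CostGrid, build_grid, find_regime
from .metrics import NETWORK_METRIC_NAMES, metric_curves
from .nulls import random_reference
from .preprocessing import (
    SubjectTimecourses,
    bandpass,
    read_manifest,
    read_timecourses,
)
from .stats import false_positive_budget, nodal_posthoc, percost_group_test, \
    symptom_correlation
from .synthetic import CohortConfig, simulate_cohort, write_cohort

__all__ = ["PipelineConfig", "run_pipeline", "make_synthetic"]

log = logging.getLogger("fncnet")


@dataclass
class PipelineConfig:
    """Configuration for a full analysis run.

    Exactly one of ``edge_counts`` (explicit grid, as ``[e_min, e_max,
    e_step]``) or ``auto_regime=True`` must be chosen.
    """

    manifest: str = "cohort/manifest.tsv"
    subjects_dir: str | None = None  # default: <manifest dir>/subjects
    out_dir: str = "results"
    tr_seconds: float = 1.5
    f_low: float = 0.01
    f_high: float = 0.10
    # "fft" (ideal), "butterworth" (zero-phase IIR) or "none". Note that at
    # short scan lengths band-passing can leave fewer effective in-band
    # degrees of freedom than components (e.g. ~54 Fourier modes for T=194,
    # TR=1.5 s, 0.01-0.10 Hz vs N=57), which makes the partial-correlation
    # step ill-conditioned: "fft" is then singular and "butterworth" noisy.
    # Prefer "butterworth" for real scanner data (whose energy concentrates
    # in-band) and "none" for broadband simulated cohorts.
    filter_method: str = "butterworth"
    edge_counts: tuple[int, int, int] | None = (560, 665, 7)
    auto_regime: bool = False
    regime_step: int = 7
    n_ensemble: int = 100
    n_swap_attempts: int | None = None
    seed: int = 0
    alpha: float = 0.05
    equal_var: bool = True
    fdr: bool = True
    include_nodal: bool = True
    ridge: float = 0.0
    symptom_scales: tuple[str, ...] = ("negative", "positive")

    def __post_init__(self) -> None:
        if self.auto_regime and self.edge_counts is not None:
            raise ValueError("choose either an explicit edge-count grid or auto_regime")
        if not self.auto_regime and self.edge_counts is None:
            raise ValueError("need an edge-count grid when auto_regime is off")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "edge_counts" in raw and raw["edge_counts"] is not None:
            raw["edge_counts"] = tuple(raw["edge_counts"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage_seed(seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage/per-subject seed below 2**31."""
    stage_key = zlib.crc32(stage.encode()) % (2**31)
    h = np.random.SeedSequence([seed, stage_key, index])
    return int(h.generate_state(1)[0] % (2**31))


def make_synthetic(
    cohort_config: CohortConfig, out_dir: str | Path
) -> Path:
    """Simulate a cohort and write it to disk (delegates to synthetic module)."""
    subjects, manifest, truth = simulate_cohort(cohort_config)
    return write_cohort(subjects, manifest, truth, out_dir)


def _load_subjects(config: PipelineConfig) -> tuple[pd.DataFrame, list[SubjectTimecourses]]:
    manifest_path = Path(config.manifest)
    manifest = read_manifest(manifest_path)
    subjects_dir = (
        Path(config.subjects_dir)
        if config.subjects_dir
        else manifest_path.parent / "subjects"
    )
    subjects = []
    for _, row in manifest.iterrows():
        path = subjects_dir / f"{row.subject_id}.tsv"
        if not path.exists():
            raise FileNotFoundError(
                f"subject file missing for {row.subject_id!r}: {path}"
            )
        subjects.append(
            read_timecourses(
                path,
                tr_seconds=config.tr_seconds,
                subject_id=str(row.subject_id),
                group=str(row.group),
            )
        )
    return manifest, subjects


def _write_matrix(M: np.ndarray, labels: tuple[str, ...], path: Path) -> None:
    pd.DataFrame(M, columns=list(labels)).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def stage_connectivity(config: PipelineConfig) -> dict:
    manifest, subjects = _load_subjects(config)
    out = Path(config.out_dir) / "fnc"
    out.mkdir(parents=True, exist_ok=True)
    strengths, groups = [], []
    by_group: dict[str, list[np.ndarray]] = {}
    for tc in subjects:
        filtered = (
            tc
            if config.filter_method == "none"
            else bandpass(
                tc, config.f_low, config.f_high, method=config.filter_method
            )
        )
        conn = ConnectivityMatrices.from_timecourses(filtered, ridge=config.ridge)
        _write_matrix(conn.Z_fnc, conn.component_ids, out / f"{tc.subject_id}_z.tsv")
        strengths.append(conn.strength)
        groups.append(tc.group)
        by_group.setdefault(tc.group, []).append(np.abs(conn.Z_fnc))
    stab = pd.DataFrame(
        {"subject_id": [t.subject_id for t in subjects],
         "group": groups, "strength": strengths}
    )
    stab.to_csv(out / "strengths.tsv", sep="\t", index=False)
    for label, mats in by_group.items():
        _write_matrix(
            np.mean(mats, axis=0), subjects[0].component_ids,
            out / f"mean_abs_z_{label}.tsv",
        )
    result: dict = {"n_subjects": len(subjects)}
    sizes = stab.groupby("group").size()
    if len(sizes) == 2 and (sizes >= 2).all():
        t, p = strength_group_test(
            stab["strength"].to_numpy(), stab["group"].to_numpy(),
            equal_var=config.equal_var,
        )
        result["strength_test"] = {"t": t, "p": p}
    (out / "strength_test.json").write_text(json.dumps(result, indent=1))
    return result


def _load_z_matrices(config: PipelineConfig) -> tuple[pd.DataFrame, list[np.ndarray], tuple[str, ...]]:
    manifest = read_manifest(config.manifest)
    out = Path(config.out_dir) / "fnc"
    mats, labels = [], ()
    for sid in manifest["subject_id"]:
        path = out / f"{sid}_z.tsv"
        if not path.exists():
            raise FileNotFoundError(
                f"connectivity stage output missing for {sid!r}: {path}"
            )
        df = pd.read_csv(path, sep="\t")
        labels = tuple(df.columns)
        mats.append(df.to_numpy(dtype=float))
    return manifest, mats, labels


def stage_graphs(config: PipelineConfig) -> CostGrid:
    _, mats, _ = _load_z_matrices(config)
    n = mats[0].shape[0]
    if config.auto_regime:
        grid = find_regime(
            mats,
            e_step=config.regime_step,
            n_random=max(5, config.n_ensemble // 5),
            seed=_stage_seed(config.seed, "regime"),
            n_swap_attempts=config.n_swap_attempts,
        )
    else:
        e_min, e_max, e_step = config.edge_counts
        grid = build_grid(n, e_min, e_max, e_step)
    (Path(config.out_dir) / "grid.json").write_text(json.dumps(grid.to_dict()))
    return grid


def _load_grid(config: PipelineConfig) -> CostGrid:
    path = Path(config.out_dir) / "grid.json"
    if not path.exists():
        raise FileNotFoundError(f"graphs stage output missing: {path}")
    raw = json.loads(path.read_text())
    return CostGrid(n_nodes=raw["n_nodes"], edge_counts=tuple(raw["edge_counts"]))


def stage_metrics(config: PipelineConfig) -> pd.DataFrame:
    manifest, mats, labels = _load_z_matrices(config)
    grid = _load_grid(config)
    frames = []
    for (_, row), Z in zip(manifest.iterrows(), mats):
        frames.append(
            metric_curves(
                Z, grid,
                subject_id=str(row.subject_id), group=str(row.group),
                node_labels=labels, include_nodal=config.include_nodal,
            )
        )
    curves = pd.concat(frames, ignore_index=True)
    curves.to_csv(Path(config.out_dir) / "curves.tsv", sep="\t", index=False)
    return curves


def stage_nulls(config: PipelineConfig) -> pd.DataFrame:
    from .graphs import threshold_to_edges

    manifest, mats, labels = _load_z_matrices(config)
    grid = _load_grid(config)
    curves = pd.read_csv(Path(config.out_dir) / "curves.tsv", sep="\t")
    nulls_dir = Path(config.out_dir) / "nulls"
    nulls_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    n_disc = 0
    for s_idx, ((_, row), Z) in enumerate(zip(manifest.iterrows(), mats)):
        per_cost = []
        for g_idx, (E, cost) in enumerate(zip(grid.edge_counts, grid.costs)):
            g = threshold_to_edges(Z, E, node_labels=labels)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                ref = random_reference(
                    g,
                    n_ensemble=config.n_ensemble,
                    seed=_stage_seed(config.seed, "nulls", s_idx * 10_000 + g_idx),
                    n_swap_attempts=config.n_swap_attempts,
                )
            n_disc += ref.n_disconnected
            per_cost.append({"edge_count": E, "k_cost": cost, **asdict(ref)})
            for name in ("gamma", "lambda_", "sigma"):
                rows.append(
                    {
                        "subject_id": str(row.subject_id),
                        "group": str(row.group),
                        "edge_count": E,
                        "k_cost": cost,
                        "metric": name.rstrip("_"),
                        "node": "network",
                        "value": getattr(ref, name),
                    }
                )
        (nulls_dir / f"{row.subject_id}.json").write_text(
            json.dumps(per_cost, indent=1)
        )
    if n_disc:
        log.warning("%d disconnected rewired reference graphs encountered", n_disc)
    full = pd.concat([curves, pd.DataFrame(rows)], ignore_index=True)
    full.to_csv(Path(config.out_dir) / "curves_full.tsv", sep="\t", index=False)
    return full


def stage_stats(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    curves_path = out / "curves_full.tsv"
    if not curves_path.exists():
        curves_path = out / "curves.tsv"
    curves = pd.read_csv(curves_path, sep="\t")
    grid = _load_grid(config)
    manifest = read_manifest(config.manifest)
    stats_dir = out / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)

    network_metric_names = [
        m for m in ("c_net", "l_net", "e_global", "e_local", "gamma", "lambda", "sigma")
        if (curves["metric"] == m).any()
    ]
    net_tables = [
        percost_group_test(
            curves, grid, m, alpha=config.alpha, equal_var=config.equal_var
        )
        for m in network_metric_names
    ]
    network_tests = pd.concat(net_tables, ignore_index=True)
    network_tests.to_csv(stats_dir / "network_tests.tsv", sep="\t", index=False)

    nodal_tests = None
    if config.include_nodal and (curves["node"] != "network").any():
        nodal_tests = nodal_posthoc(
            curves, grid, alpha=config.alpha, fdr=config.fdr,
            equal_var=config.equal_var,
        )
        nodal_tests.to_csv(stats_dir / "nodal_tests.tsv", sep="\t", index=False)

    corr_frames = []
    has_scores = any(
        manifest[f"score_{scale}"].notna().any()
        for scale in config.symptom_scales
        if f"score_{scale}" in manifest.columns
    )
    if has_scores:
        for scale in config.symptom_scales:
            col = f"score_{scale}"
            if col not in manifest.columns or manifest[col].notna().sum() < 3:
                continue
            for m in network_metric_names:
                corr_frames.append(
                    symptom_correlation(curves, manifest, m, which_scale=scale)
                )
    if corr_frames:
        corrs = pd.concat(corr_frames, ignore_index=True)
        corrs.to_csv(stats_dir / "symptom_correlations.tsv", sep="\t", index=False)

    summary = {
        "n_grid_points": len(grid),
        "alpha": config.alpha,
        "false_positive_budget": false_positive_budget(len(grid), config.alpha),
        "network_significant": {
            m: int(network_tests.loc[network_tests["metric"] == m, "significant"].sum())
            for m in network_metric_names
        },
        "nodal_significant_uncorrected": (
            int(nodal_tests["significant"].sum()) if nodal_tests is not None else None
        ),
    }
    (stats_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


STAGES = ("connectivity", "graphs", "metrics", "nulls", "stats")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the stats summary.

    A stage failure is re-raised annotated with the stage name. A run log
    (versions, seed, stage timings, config) is written to run_log.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stage_fns = {
        "connectivity": stage_connectivity,
        "graphs": stage_graphs,
        "metrics": stage_metrics,
        "nulls": stage_nulls,
        "stats": stage_stats,
    }
    summary: dict = {}
    for name in STAGES:
        t0 = time.perf_counter()
        log.info("stage %s ...", name)
        try:
            result = stage_fns[name](config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        if name == "stats":
            summary = result
    run_log = {
        "fncnet_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "stage_seconds": timings,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=1))
    return summary
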