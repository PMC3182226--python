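"""Synthetic two-group cohorts with known partial-correlation structure.

Every downstream stage (filtering, partial correlation, cost-matched
graphs, null models, group statistics) is testable without any data
download: subjects are drawn as zero-mean Gaussian time series whose
ground-truth precision (inverse covariance) matrix has a known graph
support, so the true partial-correlation network is known exactly.

Construction: a base topology (ring lattice, Watts-Strogatz, or G(n, m)
random graph) gives the adjacency A; the precision matrix is

    P = I - s * A      (s = partial_corr_strength)

whose implied partial correlations are exactly +s on the edges of A and 0
elsewhere (off-diagonal precision entries are negative so partial
correlations come out positive). P is SPD iff s < 1 / lambda_max(A); this
is checked explicitly, and if violated the diagonal is inflated to
1.1 x row absolute sums (guaranteed SPD by diagonal dominance) at the cost
of shrinking the realized partial correlations — the construction raises
if the shrinkage would take them below half the requested strength.

Group effects modify one group's topology: ``extra_triangle_edges`` closes
open triangles (raising ground-truth clustering, the effect the group
comparison is designed to detect), and ``extra_edges`` attaches explicit
extra node pairs (e.g. to give one node a degree difference). Defaults
emulate the study conditions of the motivating design: two groups of 19
subjects, 57 components, 194 timepoints at TR = 1.5 s.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import linalg

from .preprocessing import SubjectTimecourses, write_manifest, write_timecourses

__all__ = [
    "GroupEffect",
    "TopologySpec",
    "SymptomModel",
    "CohortConfig",
    "make_precision_matrix",
    "build_topology",
    "simulate_subject",
    "simulate_cohort",
    "write_cohort",
    "default_cohort_config",
]

BASE_TOPOLOGIES = ("ring_lattice", "watts_strogatz", "random_gnm")


@dataclass(frozen=True)
class GroupEffect:
    """Per-group modification of the base topology.

    extra_triangle_edges
        Number of edges added that each close an open triangle (two
        neighbours of a common node that are not yet connected), raising
        ground-truth clustering.
    extra_edges
        Explicit extra node pairs, e.g. to alter one node's degree.
    strength_delta
        Added to partial_corr_strength for this group.
    """

    extra_triangle_edges: int = 0
    extra_edges: tuple[tuple[int, int], ...] = ()
    strength_delta: float = 0.0


@dataclass(frozen=True)
class TopologySpec:
    """Ground-truth network topology and partial-correlation strength."""

    n_nodes: int
    base_topology: str = "watts_strogatz"
    neighbors_k: int = 4
    rewire_prob: float = 0.05
    partial_corr_strength: float = 0.15
    sign_pattern: str = "negative"
    group_effect: GroupEffect = field(default_factory=GroupEffect)

    def __post_init__(self) -> None:
        if self.n_nodes < 4:
            raise ValueError("need n_nodes >= 4")
        if self.sign_pattern not in ("negative", "alternating"):
            raise ValueError("sign_pattern must be 'negative' or 'alternating'")
        if self.base_topology not in BASE_TOPOLOGIES:
            raise ValueError(
                f"base_topology must be one of {BASE_TOPOLOGIES}, "
                f"got {self.base_topology!r}"
            )
        if self.neighbors_k % 2 or self.neighbors_k <= 0:
            raise ValueError("neighbors_k must be a positive even integer")
        if self.neighbors_k >= self.n_nodes:
            raise ValueError("neighbors_k must be < n_nodes")
        if not 0 <= self.rewire_prob <= 1:
            raise ValueError("rewire_prob must lie in [0, 1]")
        if not 0 <= self.partial_corr_strength < 1:
            raise ValueError("partial_corr_strength must lie in [0, 1)")


@dataclass(frozen=True)
class SymptomModel:
    """Synthetic symptom scores linearly coupled to a ground-truth metric.

    Scores are integer-rounded Gaussians around a linear function of the
    chosen per-subject network metric (standardised within the scored
    group), truncated to the 7-item PANSS-like range 7-49. ``slope`` is in
    score points per within-group SD of the metric; the designed
    population correlation is slope / sqrt(slope^2 + noise_sd^2).
    """

    metric: str = "l_net"
    scale: str = "negative"
    slope: float = 3.0
    intercept: float = 15.0
    noise_sd: float = 4.0
    ref_cost: float = 0.39


@dataclass(frozen=True)
class CohortConfig:
    group_sizes: tuple[int, int] = (19, 19)
    group_labels: tuple[str, str] = ("HC", "SZ")
    n_timepoints: int = 194
    tr_seconds: float = 1.5
    topology_per_group: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    temporal_ar1: float = 0.3
    seed: int = 0
    symptom_model: SymptomModel | None = field(default_factory=SymptomModel)
    patient_group: str | None = None  # defaults to the second group label

    def __post_init__(self) -> None:
        if len(self.group_labels) != len(set(self.group_labels)):
            raise ValueError("group labels must be distinct")
        if any(s < 0 for s in self.group_sizes):
            raise ValueError("group sizes must be nonnegative")
        topo = dict(self.topology_per_group) or {
            label: default_topology(label == self.group_labels[1])
            for label in self.group_labels
        }
        n_nodes = {t.n_nodes for t in topo.values()}
        if len(n_nodes) != 1:
            raise ValueError("all groups must share n_nodes")
        if self.n_timepoints <= n_nodes.pop() + 2:
            raise ValueError(
                "n_timepoints must exceed n_nodes + 2 so partial correlations "
                "controlling for the other N-2 components are estimable"
            )
        if not 0 <= self.temporal_ar1 < 1:
            raise ValueError("temporal_ar1 must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        object.__setattr__(self, "topology_per_group", topo)

    @property
    def n_nodes(self) -> int:
        return next(iter(self.topology_per_group.values())).n_nodes


def default_topology(patient_like: bool, n_nodes: int = 57) -> TopologySpec:
    """Default ground-truth topology for one group.

    Both groups are Watts-Strogatz with 6 neighbours and mixed-sign
    partial correlations of magnitude 0.19 (the mixed signs keep the
    precision SPD at that strength); the designed clustering group effect
    is topological: the patient-like group is a near-lattice (2% rewiring,
    high ground-truth clustering — the direction the motivating design
    reports for patients) while the control group is fully rewired (random
    topology at the same density, low clustering).
    """
    return TopologySpec(
        n_nodes=n_nodes,
        neighbors_k=6,
        rewire_prob=0.02 if patient_like else 1.0,
        partial_corr_strength=0.19,
        sign_pattern="alternating",
    )


def default_cohort_config(seed: int = 0) -> CohortConfig:
    return CohortConfig(seed=seed)


def build_topology(spec: TopologySpec, seed: int | None = 0) -> np.ndarray:
    """Boolean adjacency of the ground-truth support, group effect applied."""
    rng = np.random.default_rng(seed)
    nx_seed = int(rng.integers(0, 2**31 - 1))
    n, k = spec.n_nodes, spec.neighbors_k
    if spec.base_topology == "ring_lattice":
        G = nx.watts_strogatz_graph(n, k, 0.0)
    elif spec.base_topology == "watts_strogatz":
        G = nx.watts_strogatz_graph(n, k, spec.rewire_prob, seed=nx_seed)
    else:
        G = nx.gnm_random_graph(n, n * k // 2, seed=nx_seed)
    eff = spec.group_effect
    for _ in range(eff.extra_triangle_edges):
        # node-first sampling keeps degrees balanced: a uniform node with an
        # open neighbour pair, then a uniform open pair within that node
        openable = {}
        for node in G.nodes:
            nbrs = list(G.neighbors(node))
            pairs = [
                (min(a, b), max(a, b))
                for i, a in enumerate(nbrs)
                for b in nbrs[i + 1 :]
                if not G.has_edge(a, b)
            ]
            if pairs:
                openable[node] = sorted(set(pairs))
        if not openable:
            break
        node = sorted(openable)[int(rng.integers(0, len(openable)))]
        pairs = openable[node]
        a, b = pairs[int(rng.integers(0, len(pairs)))]
        G.add_edge(a, b)
    for (a, b) in eff.extra_edges:
        if a == b or not (0 <= a < n and 0 <= b < n):
            raise ValueError(f"invalid extra edge ({a}, {b})")
        G.add_edge(a, b)
    A = nx.to_numpy_array(G, nodelist=range(n), dtype=bool)
    np.fill_diagonal(A, False)
    return A


def make_precision_matrix(
    spec: TopologySpec,
    seed: int | None = 0,
    return_adjacency: bool = False,
):
    """Symmetric positive-definite precision matrix with known support.

    Off-diagonal entries have magnitude ``s`` on the topology's edges and
    the diagonal is 1, so the implied partial correlations have magnitude
    exactly ``s`` on the support. With ``sign_pattern="negative"`` (the
    default) all precision entries are negative, giving all-positive
    partial correlations; ``"alternating"`` draws random signs per edge,
    which roughly halves the spectral norm of the off-diagonal block
    (from ~k to ~2*sqrt(k) for mean degree k) and therefore admits
    stronger partial correlations while staying SPD — closer to real FNC,
    where inter-network partial correlations are mixed-sign. If the matrix
    is not safely SPD (s too close to 1/lambda_max of the signed
    adjacency), the diagonal is inflated to 1.1 x row absolute sums; the
    construction raises if the resulting partial correlations would fall
    below half the requested strength.
    """
    A = build_topology(spec, seed=seed)
    s = spec.partial_corr_strength + spec.group_effect.strength_delta
    if not 0 <= s < 1:
        raise ValueError(f"effective strength {s} out of [0, 1)")
    n = spec.n_nodes
    B = A.astype(float)
    if spec.sign_pattern == "alternating":
        rng = np.random.default_rng(
            np.random.SeedSequence([0 if seed is None else seed, 1]).generate_state(1)[0]
        )
        iu = np.triu_indices(n, k=1)
        signs = np.ones((n, n))
        signs[iu] = rng.choice([-1.0, 1.0], size=len(iu[0]))
        signs = np.triu(signs, 1) + np.triu(signs, 1).T
        B = B * signs
    P = np.eye(n) - s * B
    eigmin = float(np.linalg.eigvalsh(P)[0])
    if eigmin < 0.05:
        row_sums = np.abs(P).sum(axis=1) - np.abs(np.diag(P))
        diag = np.maximum(1.0, 1.1 * row_sums)
        P = P - np.diag(np.diag(P)) + np.diag(diag)
        d = np.sqrt(np.diag(P))
        realized = s / np.outer(d, d)
        worst = float(realized[A].min()) if A.any() else s
        if s > 0 and worst < 0.5 * s:
            raise ValueError(
                "diagonal-dominance repair cannot reach SPD within strength "
                f"constraints: realized partial correlation {worst:.3f} fell "
                f"below half the requested {s:.3f}; lower the strength or the "
                "topology density"
            )
    return (P, A) if return_adjacency else P


def implied_partial_correlations(P: np.ndarray) -> np.ndarray:
    """Ground-truth partial correlations -P_ij / sqrt(P_ii P_jj), diagonal 0."""
    d = np.sqrt(np.diag(P))
    R = -P / np.outer(d, d)
    np.fill_diagonal(R, 0.0)
    return R


def simulate_subject(
    precision: np.ndarray,
    n_timepoints: int,
    ar1: float = 0.0,
    seed: int | None = 0,
    tr_seconds: float = 1.5,
    subject_id: str = "subject",
    group: str = "",
    noise_sd: float = 0.0,
) -> SubjectTimecourses:
    """Gaussian time series with covariance = inverse precision.

    Rows are i.i.d. draws from N(0, P^-1); optional AR(1) smoothing is
    applied per component afterwards (innovations scaled by
    sqrt(1 - ar1^2) so stationary variance is preserved) and columns are
    re-standardised — temporal autocorrelation is added without changing
    the cross-sectional partial-correlation target. Optional white
    measurement noise (noise_sd) is added last. Deterministic given seed.
    """
    P = np.asarray(precision, dtype=float)
    n = P.shape[0]
    if not np.allclose(P, P.T, atol=1e-10):
        raise ValueError("precision must be symmetric")
    try:
        L = np.linalg.cholesky(P)
    except np.linalg.LinAlgError as exc:
        raise ValueError("precision matrix is not positive definite") from exc
    rng = np.random.default_rng(seed)
    Zn = rng.standard_normal((n_timepoints, n))
    # x = L^-T z  has covariance (L L^T)^-1 = P^-1
    X = linalg.solve_triangular(L, Zn.T, lower=True, trans="T").T
    if ar1:
        Y = np.empty_like(X)
        Y[0] = X[0]
        scale = np.sqrt(1.0 - ar1**2)
        for t in range(1, n_timepoints):
            Y[t] = ar1 * Y[t - 1] + scale * X[t]
        X = Y
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    if noise_sd > 0:
        X = X + noise_sd * rng.standard_normal(X.shape)
    return SubjectTimecourses(
        data=X,
        tr_seconds=tr_seconds,
        subject_id=subject_id,
        group=group,
    )


def _subject_metric(tc: SubjectTimecourses, metric: str, ref_cost: float) -> float:
    """Estimated network metric of one subject at a reference cost."""
    from .connectivity import ConnectivityMatrices
    from .graphs import edges_for_cost, threshold_to_edges
    from .metrics import network_metrics

    conn = ConnectivityMatrices.from_timecourses(tc)
    E = edges_for_cost(ref_cost, tc.n_components)
    g = threshold_to_edges(conn.Z_fnc, E)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # inf handled upstream
        value = getattr(network_metrics(g), metric)
    return float(value)


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[SubjectTimecourses], pd.DataFrame, dict]:
    """Simulate the full two-group cohort.

    Returns the subjects, a manifest DataFrame (subject_id, group,
    score_positive, score_negative; scores only for the patient-like
    group), and a ground-truth dictionary (per-group precision matrices,
    topology edge lists, seed). Bit-reproducible for a fixed config.
    """
    root = np.random.SeedSequence(config.seed)
    group_seeds = root.spawn(len(config.group_labels))
    truth: dict = {"seed": config.seed, "groups": {}}
    subjects: list[SubjectTimecourses] = []
    rows: list[dict] = []
    patient_group = config.patient_group or config.group_labels[1]

    for g_idx, (label, size) in enumerate(
        zip(config.group_labels, config.group_sizes)
    ):
        spec = config.topology_per_group[label]
        topo_seed = int(group_seeds[g_idx].generate_state(1)[0] % (2**31))
        P, A = make_precision_matrix(spec, seed=topo_seed, return_adjacency=True)
        ii, jj = np.nonzero(np.triu(A, k=1))
        truth["groups"][label] = {
            "precision": P.tolist(),
            "edges": list(zip(ii.tolist(), jj.tolist())),
            "topology_seed": topo_seed,
            "spec": asdict(spec),
        }
        subj_seeds = group_seeds[g_idx].spawn(size)
        for s_idx in range(size):
            sid = f"{label}{s_idx + 1:02d}"
            seed_i = int(subj_seeds[s_idx].generate_state(1)[0] % (2**31))
            tc = simulate_subject(
                P,
                n_timepoints=config.n_timepoints,
                ar1=config.temporal_ar1,
                seed=seed_i,
                tr_seconds=config.tr_seconds,
                subject_id=sid,
                group=label,
                noise_sd=config.noise_sd,
            )
            subjects.append(tc)
            rows.append(
                {
                    "subject_id": sid,
                    "group": label,
                    "score_positive": np.nan,
                    "score_negative": np.nan,
                }
            )

    manifest = pd.DataFrame(rows)
    model = config.symptom_model
    if model is not None and (manifest["group"] == patient_group).sum() >= 3:
        score_seed = int(root.generate_state(2)[1] % (2**31))
        rng = np.random.default_rng(score_seed)
        mask = (manifest["group"] == patient_group).to_numpy()
        patients = [tc for tc in subjects if tc.group == patient_group]
        values = np.array(
            [_subject_metric(tc, model.metric, model.ref_cost) for tc in patients]
        )
        finite = np.isfinite(values)
        if not finite.all():
            # a disconnected graph makes l_net infinite; treat it as the
            # most severe finite value rather than propagating inf
            fill = values[finite].max() if finite.any() else 0.0
            values = np.where(finite, values, fill)
        sd = values.std(ddof=0)
        zvals = (values - values.mean()) / (sd if sd > 0 else 1.0)
        raw = model.intercept + model.slope * zvals + rng.normal(
            0.0, model.noise_sd, size=len(patients)
        )
        scores = np.clip(np.rint(raw), 7, 49).astype(int)
        other = np.clip(
            np.rint(rng.normal(16.0, 5.0, size=len(patients))), 7, 49
        ).astype(int)
        col = "score_negative" if model.scale == "negative" else "score_positive"
        other_col = "score_positive" if col == "score_negative" else "score_negative"
        manifest.loc[mask, col] = scores
        manifest.loc[mask, other_col] = other
    return subjects, manifest, truth


def write_cohort(
    subjects: list[SubjectTimecourses],
    manifest: pd.DataFrame,
    truth: dict,
    out_dir: str | Path,
) -> Path:
    """Write one TSV per subject plus manifest.tsv and ground_truth.json."""
    out_dir = Path(out_dir)
    (out_dir / "subjects").mkdir(parents=True, exist_ok=True)
    for tc in subjects:
        write_timecourses(tc, out_dir / "subjects" / f"{tc.subject_id}.tsv")
    write_manifest(manifest, out_dir / "manifest.tsv")
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return out_dir
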