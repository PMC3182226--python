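"""Partial-correlation functional network connectivity (FNC).

For each subject with component time-course matrix ``Y`` (timepoints x N),
the connectivity between components j and k is the partial correlation of
their time courses controlling for the remaining N-2 components. Writing
the sample covariance of ``[X, Z]`` (X the pair, Z the rest) in blocks

    S = [[S11, S12],
         [S21, S22]],

the partial covariance of X given Z is the Schur complement
``S11 - S12 S22^-1 S21``; normalising it by its own diagonal gives the
partial correlation. Equivalently, with precision matrix ``P = S^-1``,

    r_partial(j, k) = -P_jk / sqrt(P_jj * P_kk),

which is what the production route computes once in O(N^3). The per-pair
blockwise route is retained both as public API and as the independent
check of the inverse-covariance route. Partial correlations are then
Fisher r-to-z transformed, and connectivity strength is the mean absolute
z over the off-diagonal pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocessing import SubjectTimecourses

__all__ = [
    "ConnectivityMatrices",
    "sample_covariance",
    "partial_correlation_matrix",
    "partial_correlation_pair",
    "fisher_z",
    "connectivity_strength",
    "strength_group_test",
]


def sample_covariance(tc: SubjectTimecourses | np.ndarray) -> np.ndarray:
    """Sample covariance of the component time courses (unbiased, T-1).

    Partial correlations are invariant to the denominator choice; the
    unbiased estimator is used and documented for reproducibility.
    """
    data = tc.data if isinstance(tc, SubjectTimecourses) else np.asarray(tc, float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 timepoints")
    S = np.cov(data, rowvar=False, ddof=1)
    return np.atleast_2d(S)


def partial_correlation_matrix(
    S: np.ndarray, ridge: float = 0.0
) -> np.ndarray:
    """Full N x N partial-correlation matrix from a covariance matrix.

    Computed as the negated, diagonally normalised inverse covariance.
    The diagonal is set to 0 by convention (as in the group-mean FNC
    matrices, whose diagonal is intentionally zeroed for display).

    Parameters
    ----------
    ridge : float
        Optional Tikhonov term ``ridge * mean(diag(S)) * I`` added before
        inversion, as a conditioning guard when T is close to N. Default
        0 (no repair): with T ~= 194 timepoints and N = 57 components the
        covariance is comfortably full-rank.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if S.ndim != 2 or S.shape[1] != n:
        raise ValueError("covariance must be square")
    if n < 3:
        raise ValueError(
            "partial correlation needs N >= 3 (no components left to control for)"
        )
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    if ridge > 0:
        S = S + ridge * float(np.mean(np.diag(S))) * np.eye(n)
    try:
        P = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - message wrap
        raise np.linalg.LinAlgError(
            "covariance is singular; enable the ridge guard or supply more "
            "timepoints"
        ) from exc
    d = np.sqrt(np.diag(P))
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise np.linalg.LinAlgError("inverse covariance has non-positive diagonal")
    R = -P / np.outer(d, d)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 0.0)
    return R


def partial_correlation_pair(S: np.ndarray, j: int, k: int) -> float:
    """Partial correlation of components j and k controlling for the rest.

    Blockwise route: the 2x2 Schur complement ``S11 - S12 S22^-1 S21`` of
    the pair against the remaining N-2 components, normalised by its own
    diagonal. Agrees with :func:`partial_correlation_matrix` to numerical
    precision for SPD covariance; kept as the independent formulation.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if j == k:
        raise ValueError("need two distinct components")
    if n < 3:
        raise ValueError("partial correlation needs N >= 3")
    pair = [j, k]
    rest = [i for i in range(n) if i not in (j, k)]
    S11 = S[np.ix_(pair, pair)]
    S12 = S[np.ix_(pair, rest)]
    S22 = S[np.ix_(rest, rest)]
    try:
        schur = S11 - S12 @ np.linalg.solve(S22, S12.T)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"S22 singular while conditioning pair ({j}, {k}) on the rest"
        ) from exc
    denom = np.sqrt(schur[0, 0] * schur[1, 1])
    if denom <= 0 or not np.isfinite(denom):
        raise np.linalg.LinAlgError(
            f"degenerate partial covariance for pair ({j}, {k})"
        )
    return float(schur[0, 1] / denom)


def fisher_z(R: np.ndarray) -> np.ndarray:
    """Fisher r-to-z (atanh) transform, elementwise on the off-diagonal.

    The diagonal stays 0. Raises on |r| >= 1 (infinite z).
    """
    R = np.asarray(R, dtype=float)
    off = ~np.eye(R.shape[0], dtype=bool)
    if np.any(np.abs(R[off]) >= 1.0):
        raise ValueError("|r| >= 1 encountered; Fisher z is unbounded there")
    Z = np.arctanh(R)
    np.fill_diagonal(Z, 0.0)
    return Z


def connectivity_strength(Z: np.ndarray) -> float:
    """Connectivity strength: mean |z| over the N(N-1)/2 off-diagonal pairs."""
    Z = np.asarray(Z, dtype=float)
    iu = np.triu_indices(Z.shape[0], k=1)
    return float(np.mean(np.abs(Z[iu])))


def strength_group_test(
    strengths: np.ndarray,
    groups: np.ndarray,
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sample two-tailed t-test for a group difference in strength.

    Pooled-variance Student t by default (``equal_var=False`` gives Welch).
    Group order follows first appearance in ``groups``; t is computed as
    (mean of first group) - (mean of second group).
    """
    strengths = np.asarray(strengths, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    a = strengths[groups == labels[0]]
    b = strengths[groups == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


@dataclass(frozen=True)
class ConnectivityMatrices:
    """Per-subject covariance, partial-correlation, and Fisher-z matrices."""

    S: np.ndarray
    R_partial: np.ndarray
    Z_fnc: np.ndarray
    subject_id: str = "subject"
    group: str = ""
    component_ids: tuple[str, ...] = ()

    @classmethod
    def from_timecourses(
        cls, tc: SubjectTimecourses, ridge: float = 0.0
    ) -> "ConnectivityMatrices":
        S = sample_covariance(tc)
        R = partial_correlation_matrix(S, ridge=ridge)
        return cls(
            S=S,
            R_partial=R,
            Z_fnc=fisher_z(R),
            subject_id=tc.subject_id,
            group=tc.group,
            component_ids=tc.component_ids,
        )

    @property
    def strength(self) -> float:
        return connectivity_strength(self.Z_fnc)
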