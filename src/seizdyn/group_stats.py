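"""Group-level inference for cohort comparisons.

Two families of tests are provided:

* one-way ANOVA on seizure-onset times (from raw values or from published
  ``mean, SEM, n`` summaries) with step-down Sidak (Holm-Sidak) correction
  for multiple comparisons against a control group;
* a nonparametric cluster-based permutation test for time-resolved curves
  (cumulative line length, behavioral score tracks).  A pointwise
  two-sample statistic (pooled-variance t, or a rank-sum z for ordinal
  data) is thresholded at a two-sided pointwise alpha; contiguous
  supra-threshold runs of the same sign form clusters whose mass is the
  summed statistic; the null distribution of the maximum absolute cluster
  mass is built by permuting group labels, which controls the family-wise
  error over time without assuming a sampling distribution for the curves.

When the number of distinct label assignments is no larger than the
requested number of permutations, the permutation distribution is
enumerated exhaustively and the p-values are exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AlignmentError, DegenerateSignalError, ParameterError, PreconditionError

_BIG = 1e12  # stand-in for an infinite statistic (zero within-group variance)


@dataclass(frozen=True)
class GroupSummary:
    """Published per-group summary: mean +/- SEM over ``n`` subjects."""

    group: str
    n: int
    mean: float
    sem: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise PreconditionError("GroupSummary needs n >= 2")
        if self.sem <= 0:
            raise ParameterError("sem must be positive")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)


@dataclass
class Cluster:
    start_s: float
    end_s: float
    mass: float
    p: float
    start_index: int = 0
    end_index: int = 0  # inclusive


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    alpha_point: float
    n_perm: int
    seed: int
    stat: str = "t"
    exact: bool = False
    times: np.ndarray | None = None

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha]

    def to_dict(self) -> dict:
        return {
            "clusters": [
                {
                    "start_s": c.start_s,
                    "end_s": c.end_s,
                    "mass": c.mass,
                    "p": c.p,
                }
                for c in self.clusters
            ],
            "alpha_point": self.alpha_point,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "stat": self.stat,
            "exact": self.exact,
        }


# ---------------------------------------------------------------------------
# ANOVA + Holm-Sidak
# ---------------------------------------------------------------------------

def anova_oneway(groups) -> tuple[float, float]:
    """Classical one-way ANOVA.

    ``groups`` is either a list of per-group value arrays or a list of
    :class:`GroupSummary`; the summary path reconstructs the between- and
    within-group sums of squares from ``mean``, ``SD = SEM * sqrt(n)`` and
    ``n``, which recovers the F statistic the raw data would give.
    """
    if len(groups) < 2:
        raise PreconditionError("need >= 2 groups")
    if all(isinstance(g, GroupSummary) for g in groups):
        ns = np.array([g.n for g in groups], dtype=float)
        means = np.array([g.mean for g in groups])
        sds = np.array([g.sd for g in groups])
    else:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        if any(a.size < 2 for a in arrays):
            raise PreconditionError("every group needs n >= 2")
        ns = np.array([a.size for a in arrays], dtype=float)
        means = np.array([a.mean() for a in arrays])
        sds = np.array([a.std(ddof=1) for a in arrays])
    n_tot = ns.sum()
    k = len(ns)
    grand = (ns * means).sum() / n_tot
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds**2).sum()
    df_b, df_w = k - 1, n_tot - k
    if ss_within <= 0:
        raise DegenerateSignalError("zero within-group variance; F is undefined")
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), p


def holm_sidak_vs_control(pvalues, comparisons=None) -> np.ndarray:
    """Step-down Sidak adjustment of a family of versus-control p-values.

    Sorted ascending, ``p_adj(i) = max_{j<=i} 1 - (1 - p(j))^(m - j + 1)``
    clipped to 1; the result is monotone in the raw p-values and returned in
    the original order.  ``comparisons`` is an optional parallel list of
    labels, only used for validation of length.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ParameterError("pvalues must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    if comparisons is not None and len(comparisons) != p.size:
        raise ParameterError("comparisons must match pvalues in length")
    return multipletests(p, method="holm-sidak")[1]


# ---------------------------------------------------------------------------
# pointwise statistics (vectorised over permutations)
# ---------------------------------------------------------------------------

def _t_from_index(X, X2, idx, n1, n2):
    """Pooled two-sample t for group A given row-index matrix ``idx``.

    ``X`` is the stacked data (n_subjects x T), ``X2`` its square; ``idx``
    has shape (n_perm, n1) and selects group A per permutation.
    """
    tot = X.sum(axis=0)
    tot2 = X2.sum(axis=0)
    sa = X[idx].sum(axis=1)
    sa2 = X2[idx].sum(axis=1)
    sb = tot - sa
    sb2 = tot2 - sa2
    ma, mb = sa / n1, sb / n2
    ssa = sa2 - sa**2 / n1
    ssb = sb2 - sb**2 / n2
    df = n1 + n2 - 2
    sp2 = np.maximum(ssa + ssb, 0.0) / df
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = ma - mb
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / denom
    t = np.where(denom > 0, t, np.where(diff == 0, 0.0, np.sign(diff) * _BIG))
    return t


def _rank_transform(X):
    """Per-timepoint midranks and tie-corrected rank-sum scale factors."""
    n, T = X.shape
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    # tie correction per column: sum(t^3 - t) over tie groups
    tie_term = np.zeros(T)
    for j in range(T):
        _, counts = np.unique(X[:, j], return_counts=True)
        tie_term[j] = np.sum(counts**3 - counts)
    return ranks, tie_term


def _z_from_ranks(ranks, tie_term, idx, n1, n2):
    """Normal-approximation rank-sum z for group A per permutation."""
    n = n1 + n2
    W = ranks[idx].sum(axis=1)
    mu = n1 * (n + 1) / 2.0
    var = (n1 * n2 / 12.0) * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (W - mu) / np.sqrt(var)
    return np.where(var > 0, z, 0.0)


def _clusters_from_stat(s: np.ndarray, thr: float) -> list[tuple[int, int, float]]:
    """Sign-homogeneous supra-threshold runs: (start, end inclusive, mass)."""
    out = []
    for sign in (1.0, -1.0):
        above = sign * s > thr
        if not above.any():
            continue
        d = np.diff(above.astype(np.int8))
        starts = np.nonzero(d == 1)[0] + 1
        ends = np.nonzero(d == -1)[0]
        if above[0]:
            starts = np.concatenate([[0], starts])
        if above[-1]:
            ends = np.concatenate([ends, [above.size - 1]])
        for a, b in zip(starts, ends):
            out.append((int(a), int(b), float(s[a : b + 1].sum())))
    return sorted(out)


def _max_cluster_masses(stat_matrix: np.ndarray, thr: float) -> np.ndarray:
    out = np.zeros(stat_matrix.shape[0])
    for i, row in enumerate(stat_matrix):
        masses = [abs(m) for *_ab, m in _clusters_from_stat(row, thr)]
        out[i] = max(masses, default=0.0)
    return out


def cluster_permutation_test(
    groupA: np.ndarray,
    groupB: np.ndarray,
    stat: str = "t",
    alpha_point: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    times: np.ndarray | None = None,
) -> ClusterResult:
    """Cluster-based permutation test between two curve matrices.

    ``groupA`` and ``groupB`` are (subjects x timepoints) matrices on a
    common grid.  ``stat`` selects the pointwise two-sample statistic:
    ``"t"`` (pooled-variance t) or ``"ranksum"`` (tie-corrected rank-sum z,
    appropriate for ordinal scores).  Cluster p-values use the maximum
    absolute cluster mass across label permutations; with Monte Carlo
    sampling ``p = (1 + #{null >= observed}) / (n_perm + 1)``, and when all
    distinct assignments are enumerable within ``n_perm`` the distribution
    is exhausted and p is the exact proportion.
    """
    A = np.atleast_2d(np.asarray(groupA, dtype=float))
    B = np.atleast_2d(np.asarray(groupB, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise AlignmentError("group curve matrices must share one time grid")
    if times is not None and len(times) != A.shape[1]:
        raise AlignmentError("times must match the curve grid")
    n1, n2 = A.shape[0], B.shape[0]
    if min(n1, n2) < 3:
        raise PreconditionError("each group needs >= 3 subjects")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse permutation null")
    if stat not in ("t", "ranksum"):
        raise ParameterError("stat must be 't' or 'ranksum'")

    X = np.vstack([A, B])
    n = n1 + n2
    if stat == "t":
        X2 = X**2
        thr = float(stats.t.ppf(1 - alpha_point / 2, n - 2))

        def stat_fn(idx):
            return _t_from_index(X, X2, idx, n1, n2)

    else:
        ranks, tie_term = _rank_transform(X)
        thr = float(stats.norm.ppf(1 - alpha_point / 2))

        def stat_fn(idx):
            return _z_from_ranks(ranks, tie_term, idx, n1, n2)

    obs = stat_fn(np.arange(n1)[None, :])[0]
    clusters = _clusters_from_stat(obs, thr)

    exact = comb(n, n1) <= n_perm
    if exact:
        idx = np.array(list(combinations(range(n), n1)), dtype=np.intp)
    else:
        rng = np.random.default_rng(seed)
        idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n1].astype(np.intp)
    null = _max_cluster_masses(stat_fn(idx), thr)

    out = []
    for a, b, mass in clusters:
        tol = 1e-9 * max(1.0, abs(mass))
        if exact:
            p = float(np.mean(null >= abs(mass) - tol))
        else:
            p = float((1 + np.sum(null >= abs(mass) - tol)) / (len(null) + 1))
        t0 = float(times[a]) if times is not None else float(a)
        t1 = float(times[b]) if times is not None else float(b)
        out.append(Cluster(t0, t1, mass, p, start_index=a, end_index=b))
    return ClusterResult(
        clusters=out,
        alpha_point=alpha_point,
        n_perm=len(idx),
        seed=seed,
        stat=stat,
        exact=exact,
        times=times,
    )
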