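"""Comparison statistics for matched-cohort burden analyses.

Three procedures, all honouring within-match-set correlation:

* :func:`poisson_irr` — incidence rate ratio from the two-group Poisson model
  with log link and log person-time offset. The point estimate of that model
  is analytically the crude ratio (sum of events over sum of person-time,
  group 1 vs group 0); clustering enters only the variance through a one-way
  cluster sandwich (GEE with independence working correlation).
* :func:`rao_scott_test` — Pearson chi-square for a 2x2 group-by-outcome
  table deflated by a first-order design-effect estimate from cluster-level
  totals.
* :func:`cluster_robust_mean_test` — two-group mean difference with CR0
  cluster sandwich variance, small-sample factor G/(G-1), and a t reference
  distribution on G-1 degrees of freedom.

Significance in the reporting layer uses the dual rule: p < 0.05 AND the 95%
confidence interval excluding 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

Z975 = 1.959963984540054


@dataclass(frozen=True)
class IrrEstimate:
    irr: float
    ci_low: float
    ci_high: float
    se_log_irr: float
    n_clusters: int
    events: tuple[float, float] = (np.nan, np.nan)        # (group1, group0)
    person_time: tuple[float, float] = (np.nan, np.nan)

    @property
    def defined(self) -> bool:
        return math.isfinite(self.irr)

    @property
    def p_value(self) -> float:
        """Two-sided Wald p for log IRR = 0."""
        if not self.defined or not math.isfinite(self.se_log_irr) \
                or self.se_log_irr == 0:
            return np.nan
        return float(2 * stats.norm.sf(abs(math.log(self.irr))
                                       / self.se_log_irr))


@dataclass(frozen=True)
class ClusteredTestResult:
    statistic: float
    df: float
    p_value: float
    method: str
    estimate: float = np.nan


def _as_arrays(*cols):
    return [np.asarray(c) for c in cols]


def _group_mask(group) -> np.ndarray:
    g = np.asarray(group)
    if g.dtype.kind in "biuf":
        return g.astype(bool)
    return (g == "case") | (g == "1")


def poisson_irr(events, person_time, group, cluster=None,
                continuity_correction: bool = False,
                alpha: float = 0.05) -> IrrEstimate:
    """IRR with log person-time offset and cluster-robust Wald CI.

    Parameters are member-level arrays: event counts, person-time at risk
    (same units both groups), group indicator (1/'case' = exposed), and an
    optional cluster label (match set); omitted clusters mean independence.

    With zero events in either group the IRR is undefined and NaNs are
    returned, unless ``continuity_correction`` adds 0.5 to all four group
    sums (events and person-time).
    """
    y, t = _as_arrays(events, person_time)
    g = _group_mask(group)
    if y.shape != t.shape or y.shape != g.shape:
        raise ValueError("events, person_time and group must align")
    if not g.any() or g.all():
        raise ValueError("both groups must be nonempty")
    if np.any(t <= 0):
        raise ValueError("person_time must be positive for members at risk")
    cl = (np.arange(len(y)) if cluster is None else np.asarray(cluster))
    codes, _ = _factorize(cl)
    n_clusters = int(codes.max()) + 1

    e1, t1 = float(y[g].sum()), float(t[g].sum())
    e0, t0 = float(y[~g].sum()), float(t[~g].sum())
    if (e1 == 0 or e0 == 0) and continuity_correction:
        e1, t1, e0, t0 = e1 + 0.5, t1 + 0.5, e0 + 0.5, t0 + 0.5
    if e1 == 0 or e0 == 0:
        return IrrEstimate(np.nan, np.nan, np.nan, np.nan, n_clusters,
                           (e1, e0), (t1, t0))

    beta1 = math.log((e1 / t1) / (e0 / t0))
    beta0 = math.log(e0 / t0)

    # cluster sandwich on the Poisson score; bread from the fitted means
    mu = t * np.exp(beta0 + beta1 * g)
    X = np.column_stack([np.ones(len(y)), g.astype(float)])
    A = X.T @ (X * mu[:, None])
    resid = y - mu
    S = np.zeros((n_clusters, 2))
    np.add.at(S, codes, X * resid[:, None])
    B = S.T @ S
    Ainv = np.linalg.inv(A)
    V = Ainv @ B @ Ainv
    se = math.sqrt(max(V[1, 1], 0.0))

    z = stats.norm.ppf(1 - alpha / 2)
    return IrrEstimate(math.exp(beta1), math.exp(beta1 - z * se),
                       math.exp(beta1 + z * se), se, n_clusters,
                       (e1, e0), (t1, t0))


def _factorize(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, codes = np.unique(labels, return_inverse=True)
    return codes, uniq


def rao_scott_test(outcome, group, cluster=None) -> ClusteredTestResult:
    """First-order Rao-Scott adjusted chi-square for a clustered 2x2 table.

    The Pearson statistic of the group-by-outcome table is divided by a
    design effect estimated from cluster-level outcome totals within each
    group; with singleton clusters the design effect is exactly 1 and the
    statistic reduces to the classical Pearson chi-square. A degenerate table
    (everyone the same outcome) yields statistic 0, p = 1.
    """
    y = np.asarray(outcome).astype(float)
    g = _group_mask(group)
    if not g.any() or g.all():
        raise ValueError("both groups must be nonempty")
    cl = (np.arange(len(y)) if cluster is None else np.asarray(cluster))

    n1, n0 = int(g.sum()), int((~g).sum())
    s1, s0 = float(y[g].sum()), float(y[~g].sum())
    n, s = n1 + n0, s1 + s0
    if s == 0 or s == n:
        return ClusteredTestResult(0.0, 1.0, 1.0, "rao_scott")

    # Pearson chi-square of the 2x2 table
    p_pool = s / n
    exp1, exp0 = n1 * p_pool, n0 * p_pool
    x2 = ((s1 - exp1) ** 2 / exp1 + ((n1 - s1) - (n1 - exp1)) ** 2 / (n1 - exp1)
          + (s0 - exp0) ** 2 / exp0
          + ((n0 - s0) - (n0 - exp0)) ** 2 / (n0 - exp0))

    # design effect from cluster-level totals, per group
    v_clust, v_binom = 0.0, 0.0
    for mask, n_g, s_g in ((g, n1, s1), (~g, n0, s0)):
        p_g = s_g / n_g
        codes, _ = _factorize(cl[mask])
        m_gc = np.bincount(codes)
        y_gc = np.bincount(codes, weights=y[mask])
        v_clust += float(((y_gc - m_gc * p_g) ** 2).sum()) / n_g ** 2
        v_binom += p_g * (1 - p_g) / n_g
    deff = v_clust / v_binom if v_binom > 0 else 1.0
    if deff <= 0:
        deff = 1.0

    x2_rs = x2 / deff
    p = float(stats.chi2.sf(x2_rs, df=1))
    return ClusteredTestResult(float(x2_rs), 1.0, p, "rao_scott")


def cluster_robust_mean_test(values, group, cluster=None) -> ClusteredTestResult:
    """Two-group mean comparison with cluster-robust (sandwich) variance.

    OLS of the value on a group indicator; CR0 cluster sandwich scaled by
    G/(G-1); two-sided p from t with G-1 degrees of freedom. ``estimate`` is
    the group-1 minus group-0 mean difference.
    """
    v = np.asarray(values, dtype=float)
    g = _group_mask(group)
    if not g.any() or g.all():
        raise ValueError("both groups must be nonempty")
    cl = (np.arange(len(v)) if cluster is None else np.asarray(cluster))
    codes, _ = _factorize(cl)
    G = int(codes.max()) + 1
    if G < 2:
        raise ValueError("need at least 2 clusters")

    X = np.column_stack([np.ones(len(v)), g.astype(float)])
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ v)
    resid = v - X @ beta
    S = np.zeros((G, 2))
    np.add.at(S, codes, X * resid[:, None])
    B = S.T @ S
    Ainv = np.linalg.inv(XtX)
    V = (G / (G - 1)) * (Ainv @ B @ Ainv)
    se = math.sqrt(max(V[1, 1], 0.0))
    diff = float(beta[1])
    if se == 0:
        tstat, p = (0.0, 1.0) if diff == 0 else (np.inf, 0.0)
    else:
        tstat = diff / se
        p = float(2 * stats.t.sf(abs(tstat), df=G - 1))
    return ClusteredTestResult(float(tstat), float(G - 1), p,
                               "cluster_robust_t", diff)


def is_significant(p_value: float, ci_low: float, ci_high: float,
                   alpha: float = 0.05) -> bool:
    """Dual significance rule: p < alpha AND the 95% CI excludes 1."""
    if not (np.isfinite(p_value) and np.isfinite(ci_low)
            and np.isfinite(ci_high)):
        return False
    return (p_value < alpha) and not (ci_low <= 1.0 <= ci_high)
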