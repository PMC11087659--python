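"""Linear-time subset scan over traits with HC and TC score functions.

For every threshold on a geometric alpha grid, traits are ranked by a priority
function (small p* first for higher criticism; large |z*| first for truncated
chi-squared) and the score function is maximized over priority prefixes.
Under the strong LTSS property the best prefix is the best subset overall, so
the search is linear in p per grid value; an exhaustive enumerator over all
2^p - 1 subsets is provided as an independent oracle for p <= 20.

The truncated chi-squared maximization only evaluates prefixes up to the
number of threshold-exceeding traits: appending a non-exceeding trait leaves
the subset sum unchanged while the null sum grows stochastically, so the score
cannot increase (exactly so in the shared-draw tail estimator).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

from ._errors import DomainError
from .tc_tail import TCTailTable, tc_tail_neglog  # noqa: F401  (re-export)

__all__ = [
    "AlphaGrid",
    "make_alpha_grid",
    "SubsetScore",
    "hc_score",
    "ltss_maximize_hc",
    "ltss_maximize_tc",
    "hc_max_batch",
    "tc_max_batch",
    "exhaustive_scan",
    "exhaustive_max_batch",
    "phewas_minp",
    "bonferroni_level",
    "tc_tail_neglog",
    "TCTailTable",
]

EXHAUSTIVE_P_CAP = 20


@dataclass(frozen=True)
class AlphaGrid:
    """Geometric grid of p-value thresholds and paired |z| thresholds."""

    alphas: np.ndarray
    gammas: np.ndarray
    p_traits: int

    @property
    def length(self) -> int:
        return len(self.alphas)

    @property
    def grid_hash(self) -> str:
        return hashlib.sha256(np.ascontiguousarray(self.alphas).tobytes()).hexdigest()[:16]


def make_alpha_grid(
    p: int, length: int = 200, lower: float | None = None, upper: float = 0.05
) -> AlphaGrid:
    """Default grid: geometric sequence of ``length`` thresholds from the
    Bonferroni level ``upper/p`` up to ``upper``."""
    if p < 1:
        raise DomainError("p must be >= 1")
    if length < 1:
        raise DomainError("grid length must be >= 1")
    if lower is None:
        lower = upper / p
    if not (0.0 < lower <= upper < 1.0):
        raise DomainError("need 0 < lower <= upper < 1")
    alphas = np.geomspace(lower, upper, length) if length > 1 else np.array([float(lower)])
    gammas = -ndtri(alphas / 2.0)
    return AlphaGrid(alphas=alphas, gammas=gammas, p_traits=int(p))


@dataclass
class SubsetScore:
    """A maximized score: statistic value, subset and where on the grid it was found."""

    statistic: float
    subset: np.ndarray  # sorted original trait indices
    grid_index: int
    k: int
    trace: dict = field(default_factory=dict, repr=False)


def _hc_F(N, k, alpha):
    """HC score (N_alpha(S) - alpha k) / sqrt(k alpha (1 - alpha)).

    Shared by the linear scan, the batch fast path and the exhaustive oracle
    so that cross-checks are bit-exact.
    """
    N = np.asarray(N, dtype=float)
    k = np.asarray(k, dtype=float)
    return (N - alpha * k) / np.sqrt(k * alpha * (1.0 - alpha))


def hc_score(p_star: np.ndarray, alpha: float, subset) -> float:
    """HC score of one explicit subset at one threshold (strict p* < alpha)."""
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise DomainError("subset must be nonempty")
    if not (0.0 < alpha < 1.0):
        raise DomainError("alpha must lie in (0, 1)")
    p_star = np.asarray(p_star, dtype=float)
    N = int(np.sum(p_star[subset] < alpha))
    return float(_hc_F(N, subset.size, alpha))


def ltss_maximize_hc(p_star: np.ndarray, grid: AlphaGrid) -> SubsetScore:
    """Maximize the HC score over all subsets via priority prefixes.

    Traits are sorted by ascending p* (stable, ties by trait index) — this
    realizes the indicator priority for every alpha simultaneously.  All
    prefix sizes k = 1..p are scored at each alpha (reference prefix-scan
    path); ties resolve to the smallest grid index then the smallest k.
    """
    p_star = np.asarray(p_star, dtype=float)
    if p_star.ndim != 1 or p_star.size < 1:
        raise DomainError("p_star must be a nonempty vector")
    p = p_star.size
    order = np.argsort(p_star, kind="stable")
    ps = p_star[order]
    alphas = grid.alphas
    K = np.arange(1, p + 1, dtype=float)
    # N for prefix of size k at alpha = count of the k smallest p* below alpha
    ind = (ps[None, :] < alphas[:, None]).astype(np.int64)
    Nmat = np.cumsum(ind, axis=1)
    F = _hc_F(Nmat, K[None, :], alphas[:, None])
    flat = int(np.argmax(F))  # first max: smallest grid index, then smallest k
    gi, kbest = divmod(flat, p)
    stat = float(F[gi, kbest])
    kbest += 1
    trace = {"alpha": alphas.copy(), "best_F": F.max(axis=1),
             "best_k": F.argmax(axis=1) + 1}
    return SubsetScore(statistic=stat, subset=np.sort(order[:kbest]),
                       grid_index=int(gi), k=int(kbest), trace=trace)


def ltss_maximize_tc(
    z_star: np.ndarray, grid: AlphaGrid, table: TCTailTable | None = None
) -> SubsetScore:
    """Maximize the TC score over all subsets via priority prefixes.

    Traits sort by descending z*^2 (stable, ties by index).  At each gamma
    only prefixes within the exceeding set are scored (see module docstring);
    with no exceedance the singleton top trait scores F = 0.
    """
    z_star = np.asarray(z_star, dtype=float)
    if z_star.ndim != 1 or z_star.size < 1:
        raise DomainError("z_star must be a nonempty vector")
    if not np.all(np.isfinite(z_star)):
        raise DomainError("non-finite z_star")
    if table is None:
        table = TCTailTable(grid.gammas)
    z2 = z_star * z_star
    order = np.argsort(-z2, kind="stable")
    z2s = z2[order]
    csum = np.cumsum(z2s)
    best = (-np.inf, 0, 1)  # (F, grid_index, k)
    trace_F = np.zeros(grid.length)
    trace_k = np.ones(grid.length, dtype=int)
    trace_e = np.zeros(grid.length, dtype=int)
    for gi, gamma in enumerate(grid.gammas):
        e = int(np.sum(z2s > gamma * gamma))
        trace_e[gi] = e
        if e == 0:
            cand_F, cand_k = 0.0, 1
        else:
            ks = np.arange(1, e + 1)
            F = table.neglog_tail(csum[:e], ks, gi)
            jbest = int(np.argmax(F))
            cand_F, cand_k = float(F[jbest]), jbest + 1
        trace_F[gi], trace_k[gi] = cand_F, cand_k
        if cand_F > best[0]:
            best = (cand_F, gi, cand_k)
    stat, gi, k = best
    trace = {"gamma": grid.gammas.copy(), "best_F": trace_F, "best_k": trace_k,
             "n_exceed": trace_e}
    return SubsetScore(statistic=float(stat), subset=np.sort(order[:k]),
                       grid_index=int(gi), k=int(k), trace=trace)


def hc_max_batch(p_star: np.ndarray, grid: AlphaGrid) -> np.ndarray:
    """H_HC for many variants at once (statistics only).

    Uses the analytic shortcut that at fixed alpha the best subset is
    {j : p*_j < alpha} when nonempty (else any singleton); bit-identical to
    :func:`ltss_maximize_hc` (shared score helper, same dtype arithmetic).
    """
    P = np.atleast_2d(np.asarray(p_star, dtype=float))
    M = P.shape[0]
    H = np.full(M, -np.inf)
    for alpha in grid.alphas:
        N = (P < alpha).sum(axis=1)
        f = _hc_F(N, np.maximum(N, 1), alpha)
        np.maximum(H, f, out=H)
    return H


def tc_max_batch(
    z_star: np.ndarray, grid: AlphaGrid, table: TCTailTable | None = None
) -> np.ndarray:
    """H_TC for many variants at once (statistics only); matches the single scan."""
    Z = np.atleast_2d(np.asarray(z_star, dtype=float))
    if table is None:
        table = TCTailTable(grid.gammas)
    M, p = Z.shape
    z2 = np.sort(Z * Z, axis=1)[:, ::-1]
    csum = np.cumsum(z2, axis=1)
    H = np.full(M, -np.inf)
    for gi, gamma in enumerate(grid.gammas):
        e = (z2 > gamma * gamma).sum(axis=1)
        cand = np.zeros(M)
        rows = np.flatnonzero(e > 0)
        if rows.size:
            counts = e[rows]
            starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
            k_flat = np.arange(counts.sum()) - np.repeat(starts, counts) + 1
            row_rep = np.repeat(rows, counts)
            m_flat = csum[row_rep, k_flat - 1]
            F = table.neglog_tail(m_flat, k_flat, gi)
            cand[rows] = np.maximum.reduceat(F, starts)
        np.maximum(H, cand, out=H)
    return H


def _exhaustive_core(values: np.ndarray, grid: AlphaGrid, statistic: str,
                     table: TCTailTable | None):
    """Vectorized enumeration of all 2^p - 1 subsets for M instances at once.

    Enumeration happens in the priority-sorted coordinate system and subset
    sums use masked cumulative sums, so a prefix subset's sum is bit-identical
    to the linear scan's (appending zeros is exact in IEEE arithmetic); the
    enumeration itself is independent of any LTSS shortcut.

    Returns (H, grid_index, subset_row, order) with subset_row indexing the
    bitmask ``row + 1`` over sorted positions.
    """
    V = np.atleast_2d(np.asarray(values, dtype=float))
    M, p = V.shape
    if p > EXHAUSTIVE_P_CAP:
        raise DomainError(f"exhaustive scan refuses p > {EXHAUSTIVE_P_CAP} (got {p})")
    if p < 1:
        raise DomainError("need at least one trait")
    n_sub = (1 << p) - 1
    subs = np.arange(1, n_sub + 1, dtype=np.int64)
    memb = ((subs[:, None] >> np.arange(p)) & 1).astype(np.int8)
    k = memb.sum(axis=1, dtype=np.int64)
    bestF = np.full(M, -np.inf)
    bestg = np.zeros(M, dtype=np.int64)
    bestrow = np.zeros(M, dtype=np.int64)

    def _update(F, gi):
        cand = F.max(axis=1)
        rows = F.argmax(axis=1)
        upd = cand > bestF
        bestF[upd] = cand[upd]
        bestg[upd] = gi
        bestrow[upd] = rows[upd]

    if statistic == "hc":
        order = np.argsort(V, axis=1, kind="stable")
        ps = np.take_along_axis(V, order, axis=1)
        membT = memb.astype(np.int64).T
        for gi, alpha in enumerate(grid.alphas):
            N = (ps < alpha).astype(np.int64) @ membT
            F = _hc_F(N, k[None, :], alpha)
            _update(F, gi)
    elif statistic == "tc":
        if table is None:
            table = TCTailTable(grid.gammas)
        z2 = V * V
        order = np.argsort(-z2, axis=1, kind="stable")
        z2s = np.take_along_axis(z2, order, axis=1)
        # cs[i, s, j]: masked cumulative sum of instance i, subset s, through sorted pos j
        cs = np.cumsum(memb[None, :, :] * z2s[:, None, :], axis=2)
        k_flat = np.tile(k, M)
        for gi, gamma in enumerate(grid.gammas):
            e = (z2s > gamma * gamma).sum(axis=1)
            m = np.zeros((M, n_sub))
            rows = e > 0
            if rows.any():
                idx = (e[rows] - 1)[:, None, None]
                m[rows] = np.take_along_axis(cs[rows], idx, axis=2)[:, :, 0]
            F = table.neglog_tail(m.ravel(), k_flat, gi).reshape(M, n_sub)
            _update(F, gi)
    else:
        raise DomainError(f"unknown statistic {statistic!r}")
    return bestF, bestg, bestrow, order


def exhaustive_max_batch(values: np.ndarray, grid: AlphaGrid, statistic: str = "hc",
                         table: TCTailTable | None = None) -> np.ndarray:
    """True subset-scan maxima for many instances (oracle; statistics only)."""
    return _exhaustive_core(values, grid, statistic, table)[0]


def exhaustive_scan(
    values: np.ndarray,
    grid: AlphaGrid,
    statistic: str = "hc",
    table: TCTailTable | None = None,
) -> SubsetScore:
    """True maximum over all 2^p - 1 subsets per grid value (test oracle).

    ``values`` is p* for ``statistic="hc"`` and z* for ``statistic="tc"``.
    Hard cap p <= 20 (feasible in practice only up to p ~ 15).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise DomainError("exhaustive_scan takes one instance; see exhaustive_max_batch")
    H, gi, row, order = _exhaustive_core(values, grid, statistic, table)
    bits = row[0] + 1
    members_sorted = np.flatnonzero((bits >> np.arange(values.size)) & 1)
    subset = np.sort(order[0, members_sorted])
    return SubsetScore(statistic=float(H[0]), subset=subset, grid_index=int(gi[0]),
                       k=int(members_sorted.size), trace={})


def bonferroni_level(level: float, n_tests: int) -> float:
    """Per-test significance level controlling the family-wise error at ``level``."""
    if n_tests < 1:
        raise DomainError("n_tests must be >= 1")
    if not (0.0 < level < 1.0):
        raise DomainError("level must lie in (0, 1)")
    return level / n_tests


def phewas_minp(
    z: np.ndarray, n_tests: int, level: float = 0.05
) -> tuple[np.ndarray, bool, float]:
    """PheWAS baseline: per-trait two-sided tests with Bonferroni adjustment.

    Returns (selected trait indices, reject flag, per-test threshold); a trait
    is selected when its raw two-sided p-value falls below level/n_tests.
    """
    z = np.asarray(z, dtype=float)
    if n_tests < z.size:
        raise DomainError("n_tests must be at least the number of traits")
    thr = bonferroni_level(level, n_tests)
    pvals = 2.0 * ndtr(-np.abs(z))
    selected = np.flatnonzero(pvals < thr)
    return selected, bool(selected.size > 0), thr
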