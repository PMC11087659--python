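"""Null calibration of the scan statistics and assembly of scan results.

Both maximized statistics are compared against their joint Monte-Carlo null:
B draws of p iid standard-normal z-scores (already white under the null) run
through the same maximizers.  HC additionally admits an exact analytic
p-value: the maximized HC statistic is a function of the counts of p* values
under each grid threshold, so P(H_HC >= h) is a boundary-crossing probability
of uniform order statistics, computed here by an exact dynamic program with
binomial increments across the grid.

The combined statistic is min(p_HC, p_TC); its null is obtained from the same
joint draws by pooled within-sample ranking, preserving the HC/TC dependence.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from ._errors import DomainError, ValidationError
from .io_formats import ZVector
from .subset_scan import (
    AlphaGrid,
    SubsetScore,
    TCTailTable,
    _hc_F,
    hc_max_batch,
    ltss_maximize_hc,
    ltss_maximize_tc,
    make_alpha_grid,
    tc_max_batch,
)
from .trait_correlation import TraitCorrelationMatrix, repair_psd
from .whitening import zca_cor_whiten

__all__ = [
    "NullDistribution",
    "ScanResult",
    "simulate_null",
    "mc_pvalue",
    "hc_pvalue_analytic",
    "hc_pvalue_analytic_many",
    "combined_test",
    "scan_and_test",
    "get_tc_table",
]

_TC_TABLE_REGISTRY: dict[tuple, TCTailTable] = {}
_NULL_MEMO: dict[tuple, "NullDistribution"] = {}
_HC_TRANS_MEMO: dict[tuple, list] = {}


def get_tc_table(grid: AlphaGrid, n_draws: int = 100_000, seed: int | None = None) -> TCTailTable:
    """Process-wide TC tail table per (grid, draws, seed): null and observed
    statistics must share one table for their comparison to be meaningful."""
    from .tc_tail import TC_TABLE_SEED

    seed = TC_TABLE_SEED if seed is None else int(seed)
    key = (grid.grid_hash, int(n_draws), seed)
    if key not in _TC_TABLE_REGISTRY:
        _TC_TABLE_REGISTRY[key] = TCTailTable(grid.gammas, n_draws=n_draws, seed=seed)
    return _TC_TABLE_REGISTRY[key]


@dataclass
class NullDistribution:
    """B joint Monte-Carlo draws of (H_HC, H_TC) under the global null."""

    p_traits: int
    grid_hash: str
    B: int
    seed: int
    h_hc: np.ndarray  # sorted ascending
    h_tc: np.ndarray  # sorted ascending
    joint_hc: np.ndarray  # unsorted, paired
    joint_tc: np.ndarray

    def pp_tc(self) -> np.ndarray:
        """Pooled within-sample pseudo p-values of the TC null draws."""
        if not hasattr(self, "_pp_tc"):
            self._pp_tc = (self.B - np.searchsorted(self.h_tc, self.joint_tc,
                                                    side="left")) / self.B
        return self._pp_tc

    def pp_hc(self, grid: AlphaGrid | None = None, mode: str = "analytic") -> np.ndarray:
        """Pseudo p-values of the HC null draws (analytic transform or pooled ranks).

        The HC null is heavily atomic (the grid's Bonferroni lower bound
        collects every draw whose smallest p* undercuts it into one statistic
        value), so the analytic tail is used when a grid is supplied.
        """
        key = "_pp_hc_" + mode
        if not hasattr(self, key):
            if mode == "analytic":
                if grid is None or grid.grid_hash != self.grid_hash:
                    raise ValidationError("analytic HC pseudo p-values need the matching grid")
                setattr(self, key, hc_pvalue_analytic_many(self.joint_hc,
                                                           self.p_traits, grid))
            else:
                setattr(self, key, (self.B - np.searchsorted(
                    self.h_hc, self.joint_hc, side="left")) / self.B)
        return getattr(self, key)

    def to_json(self, path) -> None:
        payload = {
            "format": "traitscan-null", "version": 1,
            "p": self.p_traits, "grid_hash": self.grid_hash,
            "B": self.B, "seed": self.seed,
            "joint_hc": self.joint_hc.tolist(), "joint_tc": self.joint_tc.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "NullDistribution":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("format") != "traitscan-null":
            raise ValidationError("not a null-distribution cache file")
        jh = np.asarray(d["joint_hc"], dtype=float)
        jt = np.asarray(d["joint_tc"], dtype=float)
        return cls(int(d["p"]), str(d["grid_hash"]), int(d["B"]), int(d["seed"]),
                   np.sort(jh), np.sort(jt), jh, jt)


def simulate_null(
    p: int,
    grid: AlphaGrid,
    B: int = 10_000,
    seed: int = 0,
    table: TCTailTable | None = None,
    cache_dir=None,
) -> NullDistribution:
    """Simulate the joint null of (H_HC, H_TC) for p traits.

    Under the null the whitened scores are iid standard normal, so no
    whitening is needed.  Results are memoized in-process and optionally on
    disk, keyed by (p, grid, B, seed); identical keys reproduce identical
    draws bit-for-bit.
    """
    if B < 100:
        raise DomainError("B must be >= 100")
    table = table if table is not None else get_tc_table(grid)
    key = (p, grid.grid_hash, B, seed, table.n_draws, table.seed)
    if key in _NULL_MEMO:
        return _NULL_MEMO[key]
    path = None
    if cache_dir is not None:
        path = Path(cache_dir) / ("null_p%d_g%s_B%d_s%d_t%d_%d.npz" % key)
        if path.exists():
            d = np.load(path)
            null = NullDistribution(p, grid.grid_hash, B, seed,
                                    np.sort(d["joint_hc"]), np.sort(d["joint_tc"]),
                                    d["joint_hc"], d["joint_tc"])
            _NULL_MEMO[key] = null
            return null
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((B, p))
    P = 2.0 * stats.norm.sf(np.abs(Z))
    joint_hc = hc_max_batch(P, grid)
    joint_tc = tc_max_batch(Z, grid, table)
    null = NullDistribution(p, grid.grid_hash, B, seed,
                            np.sort(joint_hc), np.sort(joint_tc), joint_hc, joint_tc)
    _NULL_MEMO[key] = null
    if path is not None:
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, joint_hc=joint_hc, joint_tc=joint_tc)
    return null


def mc_pvalue(h_obs: float, null_draws: np.ndarray, convention: str = "conservative") -> float:
    """Empirical p-value of an observed statistic against sorted null draws.

    ``conservative`` (default): (#{h_b >= h_obs} + 1) / (B + 1).
    ``eq13``: the literal printed form, the fraction of null draws strictly
    below the observed statistic (a p-value complement; kept for reproduction).
    """
    draws = np.asarray(null_draws, dtype=float)
    B = draws.size
    if B < 1:
        raise DomainError("need at least one null draw")
    n_below = int(np.searchsorted(draws, h_obs, side="left"))
    if convention == "conservative":
        return (B - n_below + 1.0) / (B + 1.0)
    if convention == "eq13":
        return n_below / float(B)
    raise DomainError(f"unknown convention {convention!r}")


def _hc_count_thresholds(h_obs: float, p: int, alphas: np.ndarray) -> np.ndarray:
    """Smallest count b_i with max_k F_HC >= h_obs at each alpha (p+1 if unreachable).

    At fixed alpha and total count N the best-subset HC score is F(N, N) for
    N >= 1 and F(0, 1) for N = 0.  Scores are evaluated with the scan's own
    floating-point expression so ties at the atomic statistic values are kept.
    """
    b = np.empty(alphas.size, dtype=np.int64)
    for i, a in enumerate(alphas):
        if float(_hc_F(0, 1, a)) >= h_obs:
            b[i] = 0
            continue
        if h_obs <= 0:
            b[i] = 1
            continue
        n = max(int(np.ceil(h_obs * h_obs * a / (1.0 - a))), 1)
        while n > 1 and float(_hc_F(n - 1, n - 1, a)) >= h_obs:
            n -= 1
        while n <= p and float(_hc_F(n, n, a)) < h_obs:
            n += 1
        b[i] = n if n <= p else p + 1
    return b


def hc_pvalue_analytic(h_obs: float, p: int, grid: AlphaGrid) -> float:
    """Exact P(H_HC >= h_obs) under the null.

    H_HC >= h iff the count of p* values below some grid threshold reaches
    b_i(h).  The complement — every count staying below its threshold — is
    evaluated by an exact DP over the grid: counts of iid uniforms are Markov
    with binomial increments N_i | N_{i-1} ~ N_{i-1} + Bin(p - N_{i-1}, q_i),
    q_i = (a_i - a_{i-1})/(1 - a_{i-1}).
    """
    if not np.isfinite(h_obs):
        return 1.0 if h_obs < 0 else 0.0
    if p > 5000:
        warnings.warn("analytic HC p-value degenerate for p > 5000; use MC", stacklevel=2)
        raise DomainError("p too large for the analytic recursion")
    alphas = np.asarray(grid.alphas, dtype=float)
    b = _hc_count_thresholds(h_obs, p, alphas)
    if np.any(b == 0):
        return 1.0
    # collapse to the tightest constraint per distinct alpha (grids may repeat)
    m = b - 1  # survive iff N_i <= m_i for all i
    key = (p, grid.grid_hash)
    if key not in _HC_TRANS_MEMO:
        counts = np.arange(p + 1)
        n0 = counts[:, None]
        delta = counts[None, :] - n0  # transition N_{i-1}=n0 -> N_i=n0+delta
        mats = []
        a_prev = 0.0
        for a_i in alphas:
            q = (a_i - a_prev) / (1.0 - a_prev)
            if q > 0:
                trans = stats.binom.pmf(delta, p - n0, q)
                trans[delta < 0] = 0.0
            else:
                trans = None
            mats.append(trans)
            a_prev = a_i
        _HC_TRANS_MEMO[key] = mats
    mats = _HC_TRANS_MEMO[key]
    probs = np.zeros(p + 1)
    probs[0] = 1.0
    counts = np.arange(p + 1)
    for trans, m_i in zip(mats, m):
        if trans is not None:
            probs = probs @ trans
        probs[counts > m_i] = 0.0
        if not probs.any():
            return 1.0
    return float(min(max(1.0 - probs.sum(), 0.0), 1.0))


def hc_pvalue_analytic_many(h_values: np.ndarray, p: int, grid: AlphaGrid) -> np.ndarray:
    """Analytic HC tail at many observed values (deduplicated; H_HC is atomic)."""
    h_values = np.asarray(h_values, dtype=float)
    uniq, inv = np.unique(h_values, return_inverse=True)
    pv = np.array([hc_pvalue_analytic(float(h), p, grid) for h in uniq])
    return pv[inv].reshape(h_values.shape)


def combined_test(
    h_hc_obs: float,
    h_tc_obs: float,
    null: NullDistribution,
    grid: AlphaGrid | None = None,
    hc_pvalues: str = "analytic",
) -> tuple[float, float, float, float]:
    """Min-p combination of the HC and TC tests against the joint null.

    Returns (p_HC, p_TC, H_combined, p_combined).  p_HC is analytic by default
    (exact handling of the atomic HC null; falls back to MC when the recursion
    is infeasible), p_TC is Monte-Carlo.  The combined statistic's null is
    built from the same joint draws — each draw's HC value goes through the
    identical analytic transform and its TC value through pooled within-sample
    ranking — preserving the HC/TC dependence.
    """
    B = null.B
    if hc_pvalues == "analytic" and grid is not None:
        try:
            p_hc = hc_pvalue_analytic(h_hc_obs, null.p_traits, grid)
            pp_hc = null.pp_hc(grid, "analytic")
        except DomainError:
            hc_pvalues = "mc"
    if hc_pvalues != "analytic" or grid is None:
        p_hc = mc_pvalue(h_hc_obs, null.h_hc)
        pp_hc = null.pp_hc(mode="mc")
    p_tc = mc_pvalue(h_tc_obs, null.h_tc)
    h_comb_null = np.minimum(pp_hc, null.pp_tc())
    h_comb = min(p_hc, p_tc)
    p_comb = (np.sum(h_comb_null <= h_comb) + 1.0) / (B + 1.0)
    return float(p_hc), float(p_tc), float(h_comb), float(p_comb)


@dataclass
class ScanResult:
    """Full outcome of one variant's scan."""

    variant_id: str
    trait_ids: list[str]
    z: np.ndarray
    z_star: np.ndarray
    h_hc: float
    p_hc: float
    h_tc: float
    p_tc: float
    h_combined: float
    p_combined: float
    s_hc: np.ndarray
    s_tc: np.ndarray
    s_combined: np.ndarray
    winner: str  # "hc" | "tc"
    diag_cor: np.ndarray
    low_cor_traits: list[str]
    p_hc_analytic: float | None = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "variant_id": self.variant_id,
            "trait_ids": list(self.trait_ids),
            "z": self.z.tolist(),
            "z_star": self.z_star.tolist(),
            "H_HC": self.h_hc, "p_HC": self.p_hc,
            "H_TC": self.h_tc, "p_TC": self.p_tc,
            "H_combined": self.h_combined, "p_combined": self.p_combined,
            "p_HC_analytic": self.p_hc_analytic,
            "S_HC": [self.trait_ids[j] for j in self.s_hc],
            "S_TC": [self.trait_ids[j] for j in self.s_tc],
            "S_combined": [self.trait_ids[j] for j in self.s_combined],
            "winner": self.winner,
            "diag_cor": self.diag_cor.tolist(),
            "low_cor_traits": list(self.low_cor_traits),
            "provenance": dict(self.provenance),
        }


def scan_and_test(
    z: ZVector | np.ndarray,
    R: TraitCorrelationMatrix | np.ndarray,
    grid: AlphaGrid | None = None,
    B: int = 10_000,
    seed: int = 0,
    null: NullDistribution | None = None,
    table: TCTailTable | None = None,
    hc_pvalues: str = "analytic",
    eigenfloor: float = 1e-8,
    diag_cor_threshold: float = 0.7,
    cache_dir=None,
) -> ScanResult:
    """Whiten, scan with both statistics, and calibrate: the full pipeline.

    Pure function of (inputs, seed): identical arguments yield identical
    results.
    """
    if isinstance(z, ZVector):
        variant_id, trait_ids, zvec = z.variant_id, z.trait_ids, z.z
    else:
        zvec = np.asarray(z, dtype=float)
        variant_id, trait_ids = "variant", [f"T{j+1}" for j in range(zvec.size)]
    Rm = R if isinstance(R, TraitCorrelationMatrix) else repair_psd(np.asarray(R, float))
    if isinstance(R, TraitCorrelationMatrix) and list(Rm.trait_ids) != list(trait_ids):
        if set(Rm.trait_ids) >= set(trait_ids):
            idx = [Rm.trait_ids.index(t) for t in trait_ids]
            Rm = TraitCorrelationMatrix(list(trait_ids), Rm.R[np.ix_(idx, idx)], Rm.source)
        else:
            raise ValidationError("correlation matrix lacks traits present in z")
    p = zvec.size
    grid = grid if grid is not None else make_alpha_grid(p)
    table = table if table is not None else get_tc_table(grid)
    white = zca_cor_whiten(zvec, Rm.R, eigenfloor=eigenfloor)
    hc = ltss_maximize_hc(white.p_star, grid)
    tc = ltss_maximize_tc(white.z_star, grid, table)
    if null is None:
        null = simulate_null(p, grid, B=B, seed=seed, table=table, cache_dir=cache_dir)
    if null.p_traits != p or null.grid_hash != grid.grid_hash:
        raise ValidationError("null distribution does not match this p/grid")
    p_hc, p_tc, h_comb, p_comb = combined_test(
        hc.statistic, tc.statistic, null, grid=grid, hc_pvalues=hc_pvalues)
    p_hc_analytic = p_hc if hc_pvalues == "analytic" else None
    winner = "hc" if p_hc <= p_tc else "tc"
    s_comb = hc.subset if winner == "hc" else tc.subset
    low = [trait_ids[j] for j in white.low_cor_traits(diag_cor_threshold)]
    return ScanResult(
        variant_id=variant_id, trait_ids=list(trait_ids), z=zvec,
        z_star=white.z_star,
        h_hc=hc.statistic, p_hc=p_hc, h_tc=tc.statistic, p_tc=p_tc,
        h_combined=h_comb, p_combined=p_comb,
        s_hc=hc.subset, s_tc=tc.subset, s_combined=s_comb, winner=winner,
        diag_cor=white.diag_cor, low_cor_traits=low,
        p_hc_analytic=p_hc_analytic,
        provenance={
            "grid_length": grid.length,
            "alpha_lower": float(grid.alphas[0]), "alpha_upper": float(grid.alphas[-1]),
            "grid_hash": grid.grid_hash, "B": null.B, "null_seed": null.seed,
            "correlation_source": getattr(Rm, "source", "supplied"),
            "tc_draws": table.n_draws,
        },
    )
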