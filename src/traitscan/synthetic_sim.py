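"""Synthetic multi-trait GWAS generator and scenario runner.

One replicate draws a genotype x ~ Binomial(2, maf), trait errors with rows
iid MVN(0, Sigma), and Y = x beta' + errors (continuous columns centered;
binary traits thresholded from the latent Gaussian at a configurable
prevalence).  Marginal per-trait summary statistics (OLS or logistic) feed the
scan pipeline and the PheWAS baseline, and selection quality is reported as
size / precision / recall / Jaccard together with rejection power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import DomainError, ValidationError
from .io_formats import NullZPanel
from .significance import get_tc_table, scan_and_test, simulate_null
from .subset_scan import make_alpha_grid, phewas_minp
from .trait_correlation import repair_psd

__all__ = [
    "SimulationConfig",
    "MetricsReport",
    "exchangeable_sigma",
    "block_diagonal_sigma",
    "generate_dataset",
    "summarize_gwas",
    "simulate_null_panel",
    "evaluate_selection",
    "run_scenario",
]


def exchangeable_sigma(p: int, rho: float, var: float = 1.0) -> np.ndarray:
    S = np.full((p, p), rho * var)
    np.fill_diagonal(S, var)
    return S


def block_diagonal_sigma(block_sizes, rhos, var: float = 1.0) -> np.ndarray:
    blocks = [exchangeable_sigma(b, r, var) for b, r in zip(block_sizes, rhos)]
    p = sum(block_sizes)
    S = np.zeros((p, p))
    o = 0
    for B in blocks:
        b = B.shape[0]
        S[o:o + b, o:o + b] = B
        o += b
    return S


@dataclass
class SimulationConfig:
    """Knobs for one simulation scenario."""

    n: int = 1000
    p: int = 50
    maf: float = 0.3
    sigma: np.ndarray | None = None          # trait error covariance
    rho: float = 0.3                         # used when sigma is None
    structure: str = "exchangeable"          # exchangeable | block_diagonal | from_matrix
    block_sizes: tuple = ()
    block_rhos: tuple = ()
    beta: np.ndarray | None = None           # effect vector; S0 = {j: beta_j != 0}
    n_causal: int = 2                        # used when beta is None
    effect: float = 0.15                     # common effect size when beta is None
    trait_types: list[str] | None = None     # default all continuous
    prevalence: float = 0.5                  # binary-trait latent threshold
    n_reps: int = 200
    B_null: int = 2000
    level: float = 0.05
    grid_length: int = 200
    alpha_upper: float = 0.05
    seed: int = 0
    tc_draws: int = 50_000
    corr_source: str = "true"                # "true" uses cor(Sigma) for whitening

    def resolve_sigma(self) -> np.ndarray:
        if self.sigma is not None:
            S = np.asarray(self.sigma, dtype=float)
        elif self.structure == "exchangeable":
            S = exchangeable_sigma(self.p, self.rho)
        elif self.structure == "block_diagonal":
            S = block_diagonal_sigma(self.block_sizes, self.block_rhos)
        else:
            raise DomainError("structure 'from_matrix' requires an explicit sigma")
        if S.shape != (self.p, self.p):
            raise ValidationError("sigma must be p x p")
        vals = np.linalg.eigvalsh((S + S.T) / 2.0)
        if vals.min() < -1e-10:
            raise ValidationError("sigma is not positive semidefinite")
        return S

    def resolve_beta(self) -> np.ndarray:
        if self.beta is not None:
            b = np.asarray(self.beta, dtype=float)
            if b.shape != (self.p,):
                raise ValidationError("beta must have length p")
            return b
        b = np.zeros(self.p)
        b[: self.n_causal] = self.effect
        return b

    def resolve_types(self) -> list[str]:
        tt = self.trait_types if self.trait_types is not None else ["continuous"] * self.p
        if len(tt) != self.p:
            raise ValidationError("trait_types must have length p")
        return list(tt)


@dataclass
class MetricsReport:
    """Average selection metrics and power, one row per method."""

    rows: dict[str, dict] = field(default_factory=dict)
    n_reps: int = 0
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self.rows, orient="index")
        df.index.name = "method"
        df["n_reps"] = self.n_reps
        df["seed"] = self.seed
        return df.reset_index()

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def generate_dataset(config: SimulationConfig, rep_seed: int):
    """One replicate: (genotype, trait matrix, true subset S0)."""
    rng = np.random.default_rng(rep_seed)
    sigma = config.resolve_sigma()
    beta = config.resolve_beta()
    types = config.resolve_types()
    x = rng.binomial(2, config.maf, size=config.n).astype(float)
    chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(config.p))
    eps = rng.standard_normal((config.n, config.p)) @ chol.T
    Y = np.outer(x, beta) + eps
    for j, t in enumerate(types):
        if t == "binary":
            cut = np.quantile(Y[:, j], 1.0 - config.prevalence)
            Y[:, j] = (Y[:, j] > cut).astype(float)
        else:
            Y[:, j] = Y[:, j] - Y[:, j].mean()
    s0 = np.flatnonzero(beta != 0.0)
    return x, Y, s0


def _ols_summary(x: np.ndarray, Y: np.ndarray):
    """Vectorized marginal OLS (with intercept via centering) per trait column."""
    n = x.size
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValidationError("non-constant genotype required")
    Yc = Y - Y.mean(axis=0)
    beta = (xc @ Yc) / sxx
    rss = np.einsum("ij,ij->j", Yc, Yc) - beta * beta * sxx
    se = np.sqrt(np.maximum(rss, 0.0) / ((n - 2) * sxx))
    se = np.where(se == 0, np.finfo(float).tiny, se)
    z = beta / se
    return beta, se, z


def summarize_gwas(x: np.ndarray, Y: np.ndarray, trait_types=None) -> pd.DataFrame:
    """Per-trait marginal summary statistics (beta, se, z, pval, flag).

    Continuous traits use OLS; binary traits a logistic MLE (statsmodels),
    with separation or non-convergence flagged rather than raised.
    """
    x = np.asarray(x, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == x.size and Y.ndim == 2:
        pass
    else:
        raise ValidationError("Y must be n x p")
    p = Y.shape[1]
    types = list(trait_types) if trait_types is not None else ["continuous"] * p
    cont = [j for j, t in enumerate(types) if t == "continuous"]
    rows = np.empty((p, 3))
    flags = np.zeros(p, dtype=bool)
    if cont:
        b, s, z = _ols_summary(x, Y[:, cont])
        rows[cont, 0], rows[cont, 1], rows[cont, 2] = b, s, z
    for j, t in enumerate(types):
        if t == "continuous":
            continue
        import warnings

        import statsmodels.api as sm

        X = sm.add_constant(x)
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")  # separation is flagged, not raised
                fit = sm.Logit(Y[:, j], X).fit(disp=0, maxiter=100)
            bj, sj = float(fit.params[1]), float(fit.bse[1])
            if not np.isfinite(bj) or not np.isfinite(sj) or sj > 1e3:
                raise ValueError("unstable fit")
            rows[j] = (bj, sj, bj / sj)
        except Exception:
            flags[j] = True
            rows[j] = (0.0, np.inf, 0.0)
    df = pd.DataFrame({
        "trait_id": [f"T{j+1}" for j in range(p)],
        "trait_type": types,
        "beta": rows[:, 0],
        "se": rows[:, 1],
        "z": rows[:, 2],
    })
    df["pval"] = 2.0 * stats.norm.sf(np.abs(df["z"]))
    df["flagged"] = flags
    return df


def simulate_null_panel(
    n: int, sigma: np.ndarray, K: int, maf: float = 0.3, seed: int = 0,
    n_cohorts: int = 1,
) -> NullZPanel:
    """K independent null SNPs scored by marginal OLS, vectorized.

    SNPs are split across ``n_cohorts`` independent trait matrices (one cohort
    of n individuals each), mirroring null panels pooled over genomic regions
    or studies; more cohorts average out the finite-sample noise of any single
    cohort's trait correlation.
    """
    rng = np.random.default_rng(seed)
    p = sigma.shape[0]
    chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(p))
    blocks = np.array_split(np.arange(K), n_cohorts)
    Z = np.empty((K, p))
    for idx in blocks:
        Y = rng.standard_normal((n, p)) @ chol.T
        Yc = Y - Y.mean(axis=0)
        syy = np.einsum("ij,ij->j", Yc, Yc)
        X = rng.binomial(2, maf, size=(n, len(idx))).astype(float)
        Xc = X - X.mean(axis=0)
        sxx = np.einsum("ij,ij->j", Xc, Xc)
        B = (Xc.T @ Yc) / sxx[:, None]           # block x p slopes
        rss = syy[None, :] - B * B * sxx[:, None]
        se = np.sqrt(np.maximum(rss, 1e-300) / ((n - 2) * sxx[:, None]))
        Z[idx] = B / se
    return NullZPanel([f"snp{k+1}" for k in range(K)],
                      [f"T{j+1}" for j in range(p)], Z)


def evaluate_selection(S_star, S0) -> dict:
    """Exact set arithmetic for size, precision, recall and Jaccard."""
    S_star = set(np.asarray(S_star, dtype=int).tolist())
    S0 = set(np.asarray(S0, dtype=int).tolist())
    if not S_star:
        raise DomainError("selected subset must be nonempty")
    inter = len(S_star & S0)
    out = {"size": float(len(S_star)), "precision": inter / len(S_star)}
    out["recall"] = inter / len(S0) if S0 else float("nan")
    out["jaccard"] = inter / len(S_star | S0) if (S_star | S0) else float("nan")
    return out


def run_scenario(config: SimulationConfig) -> MetricsReport:
    """Run n_reps replicates and average metrics per method.

    The null distribution is simulated once per (p, grid, B) and shared across
    replicates; replicate seeds derive from the master seed by a counter.
    """
    sigma = config.resolve_sigma()
    d = np.sqrt(np.diag(sigma))
    R = repair_psd(sigma / np.outer(d, d))
    grid = make_alpha_grid(config.p, length=config.grid_length, upper=config.alpha_upper)
    table = get_tc_table(grid, n_draws=config.tc_draws)
    null = simulate_null(config.p, grid, B=config.B_null, seed=config.seed,
                         table=table)
    types = config.resolve_types()
    methods = ("traitscan_hc", "traitscan_tc", "traitscan_combined", "phewas")
    acc = {m: {"size": [], "precision": [], "recall": [], "jaccard": [], "reject": []}
           for m in methods}
    ss = np.random.SeedSequence(config.seed)
    rep_seeds = ss.generate_state(config.n_reps + 1)[1:]
    for r in range(config.n_reps):
        x, Y, s0 = generate_dataset(config, int(rep_seeds[r]))
        summ = summarize_gwas(x, Y, types)
        z = summ["z"].to_numpy()
        res = scan_and_test(z, R, grid=grid, null=null, table=table, seed=config.seed)
        sel_phewas, rej_phewas, _ = phewas_minp(z, n_tests=config.p, level=config.level)
        picks = {
            "traitscan_hc": (res.s_hc, res.p_hc <= config.level),
            "traitscan_tc": (res.s_tc, res.p_tc <= config.level),
            "traitscan_combined": (res.s_combined, res.p_combined <= config.level),
            "phewas": (sel_phewas, rej_phewas),
        }
        for m, (sel, rej) in picks.items():
            acc[m]["reject"].append(bool(rej))
            if m == "phewas" and len(sel) == 0:
                # PheWAS can select nothing; selection metrics then count as 0
                acc[m]["size"].append(0.0)
                acc[m]["precision"].append(0.0)
                acc[m]["recall"].append(0.0 if len(s0) else float("nan"))
                acc[m]["jaccard"].append(0.0 if len(s0) else float("nan"))
                continue
            met = evaluate_selection(sel, s0)
            for kk, vv in met.items():
                acc[m][kk].append(vv)
    report = MetricsReport(n_reps=config.n_reps, seed=config.seed)
    for m in methods:
        report.rows[m] = {
            "size": float(np.mean(acc[m]["size"])),
            "precision": float(np.mean(acc[m]["precision"])),
            "recall": float(np.nanmean(acc[m]["recall"])) if acc[m]["recall"] else float("nan"),
            "jaccard": float(np.nanmean(acc[m]["jaccard"])) if acc[m]["jaccard"] else float("nan"),
            "power": float(np.mean(acc[m]["reject"])),
        }
    return report
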