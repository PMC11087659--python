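"""Score-level association statistics from per-SNP summary data.

A genetic score X_gs = sum_l c_l X_l (PRS or imputed expression) is treated as
a single composite variant.  Its regression on each trait is reconstructed
from per-SNP GWAS summary statistics plus a reference panel supplying SNP
variances and LD:

    X_gs' X_gs ~ n_j * c' S c           (S = reference dosage covariance)
    (X' y_j)_l = n_j * s_l^2 * beta_jl
    y_j' y_j  ~ median_l { n_j^2 s_l^2 se_jl^2 + n_j s_l^2 beta_jl^2 }

and the Wald z follows from the usual OLS identities with n_j - q residual
degrees of freedom as printed (``dof="single"`` switches to n_j - 1).
Logistic (case-control) coefficients are first mapped to the linear scale by
the factor r/(1+r)^2, r = n_control/n_case, which leaves z invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import (
    DegenerateStatisticError,
    DomainError,
    MissingVariantError,
    ValidationError,
)
from .io_formats import TraitMeta, ZVector
from .significance import ScanResult, scan_and_test

__all__ = [
    "ScoreModel",
    "ScoreAssociation",
    "build_score_model",
    "logistic_to_linear",
    "estimate_yty",
    "score_association",
    "score_zvector",
    "score_scan",
]


@dataclass
class ScoreModel:
    """SNP weights plus the reference-panel second moments they need."""

    variant_ids: list[str]
    weights: np.ndarray
    effect_alleles: list[str]
    other_alleles: list[str]
    ld: np.ndarray       # q x q dosage covariance from the reference panel
    snp_var: np.ndarray  # diag(ld)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.ld = np.asarray(self.ld, dtype=float)
        self.snp_var = np.asarray(self.snp_var, dtype=float)
        q = len(self.variant_ids)
        if q < 1:
            raise ValidationError("score must contain at least one SNP")
        if self.weights.shape != (q,) or self.ld.shape != (q, q):
            raise ValidationError("score model shape mismatch")
        if np.any(self.snp_var <= 0):
            raise ValidationError("reference SNP variances must be positive")

    @property
    def q(self) -> int:
        return len(self.variant_ids)


@dataclass
class ScoreAssociation:
    trait_id: str
    beta_gs: float
    se_gs: float
    z_gs: float
    yty_estimate: float
    n_used: int


def build_score_model(weights: pd.DataFrame, dosages: np.ndarray) -> ScoreModel:
    """Assemble a ScoreModel from a weights table and harmonized reference dosages.

    ``dosages`` is individuals x q, columns ordered as the weights rows and
    already counted on each effect allele.  LD uses centered dosages with the
    1/(n_ref - 1) denominator.
    """
    D = np.asarray(dosages, dtype=float)
    q = len(weights)
    if D.ndim != 2 or D.shape[1] != q:
        raise ValidationError("dosage matrix must be individuals x q")
    if D.shape[0] < 2:
        raise ValidationError("reference panel needs at least 2 individuals")
    Dc = D - D.mean(axis=0)
    S = Dc.T @ Dc / (D.shape[0] - 1)
    return ScoreModel(
        variant_ids=list(weights["variant_id"]),
        weights=weights["weight"].to_numpy(dtype=float),
        effect_alleles=list(weights["effect_allele"]),
        other_alleles=list(weights["other_allele"]),
        ld=S,
        snp_var=np.diag(S).copy(),
    )


def logistic_to_linear(b: float, se_b: float, n_case: int, n_control: int) -> tuple[float, float]:
    """Map a logistic slope and SE to the linear-probability scale.

    Scale factor r/(1+r)^2 with r = n_control/n_case; b/se is invariant.
    """
    if n_case <= 0 or n_control <= 0:
        raise DomainError("n_case and n_control must be positive")
    if se_b <= 0:
        raise DomainError("se must be positive")
    r = n_control / n_case
    f = r / (1.0 + r) ** 2
    return f * b, f * se_b


def estimate_yty(per_snp, n: int) -> float:
    """Median across SNPs of n^2 s_l^2 se_l^2 + n s_l^2 beta_l^2."""
    vals = []
    for beta_l, se_l, s2_l in per_snp:
        if s2_l <= 0:
            raise DomainError("SNP variance must be positive")
        vals.append(n * n * s2_l * se_l * se_l + n * s2_l * beta_l * beta_l)
    if not vals:
        raise DomainError("need at least one SNP")
    return float(np.median(vals))


def _harmonized_effects(summary: pd.DataFrame, score: ScoreModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP (beta, se) aligned to the score's effect alleles; sign flips on swap."""
    df = summary.set_index("variant_id")
    missing = [v for v in score.variant_ids if v not in df.index]
    if missing:
        raise MissingVariantError(missing)
    betas = np.empty(score.q)
    ses = np.empty(score.q)
    for i, vid in enumerate(score.variant_ids):
        row = df.loc[vid]
        beta, se = float(row["beta"]), float(row["se"])
        ea = None
        if "effect_allele" in row.index and pd.notna(row["effect_allele"]):
            ea = str(row["effect_allele"]).upper()
        if ea is not None:
            se_eff = score.effect_alleles[i].upper()
            se_oth = score.other_alleles[i].upper()
            if ea == se_eff:
                pass
            elif ea == se_oth:
                beta = -beta
            else:
                raise ValidationError(
                    f"{vid}: summary effect allele {ea} matches neither score allele "
                    f"{se_eff}/{se_oth}"
                )
        betas[i], ses[i] = beta, se
    return betas, ses


def score_association(
    summary: pd.DataFrame,
    score: ScoreModel,
    meta: TraitMeta,
    dof: str = "paper",
) -> ScoreAssociation:
    """Reconstruct the score-on-trait Wald test from per-SNP summary statistics.

    ``summary`` holds one row per score SNP for this trait with columns
    variant_id, beta, se (linear scale; logistic inputs should pass through
    :func:`logistic_to_linear` first) and optionally effect/other alleles for
    harmonization.
    """
    n_j = meta.n
    q = score.q
    if n_j <= q:
        raise DomainError(f"trait {meta.trait_id}: n ({n_j}) must exceed q ({q})")
    betas, ses = _harmonized_effects(summary, score)
    c = score.weights
    xtx = n_j * float(c @ score.ld @ c)
    if xtx <= 0:
        raise DegenerateStatisticError("score variance is non-positive in the reference")
    xty_per_snp = n_j * score.snp_var * betas
    xty = float(c @ xty_per_snp)
    yty = estimate_yty(list(zip(betas, ses, score.snp_var)), n_j)
    beta_gs = xty / xtx
    denom = n_j - q if dof == "paper" else n_j - 1
    sigma2 = (yty - beta_gs * xty) / denom
    if sigma2 <= 0:
        raise DegenerateStatisticError(
            f"trait {meta.trait_id}: negative residual variance from summary inputs; "
            "check allele harmonization and sample sizes"
        )
    se_gs = math.sqrt(sigma2 / xtx)
    return ScoreAssociation(
        trait_id=meta.trait_id,
        beta_gs=float(beta_gs),
        se_gs=float(se_gs),
        z_gs=float(beta_gs / se_gs),
        yty_estimate=yty,
        n_used=n_j,
    )


def score_zvector(
    summaries: dict[str, pd.DataFrame],
    score: ScoreModel,
    metas: list[TraitMeta],
    score_id: str = "score",
    dof: str = "paper",
) -> ZVector:
    """z_{j,gs} across traits, assembled into a scannable ZVector."""
    zs = []
    for meta in metas:
        df = summaries[meta.trait_id].copy()
        if meta.trait_type == "binary":
            conv = [logistic_to_linear(b, s, meta.n_case, meta.n_control)
                    for b, s in zip(df["beta"], df["se"])]
            df["beta"] = [c[0] for c in conv]
            df["se"] = [c[1] for c in conv]
        zs.append(score_association(df, score, meta, dof=dof).z_gs)
    return ZVector(score_id, [m.trait_id for m in metas], np.asarray(zs))


def score_scan(
    summaries: dict[str, pd.DataFrame],
    score: ScoreModel,
    metas: list[TraitMeta],
    R,
    score_id: str = "score",
    dof: str = "paper",
    **scan_options,
) -> ScanResult:
    """Score-level scan: the score is treated as a single composite variant,
    reusing the same trait correlation matrix as single-SNP scans."""
    zvec = score_zvector(summaries, score, metas, score_id=score_id, dof=dof)
    return scan_and_test(zvec, R, **scan_options)
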