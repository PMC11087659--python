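"""Estimation of the trait-level z-score correlation matrix under the null.

The p x p correlation of per-trait z-scores is estimated either empirically
from a panel of null SNPs (Pearson correlation of z columns over
pairwise-complete SNPs), or from individual-level residuals of per-trait
regressions on the genotype.  The overlapping-sample attenuation
n12/sqrt(n1*n2) * sigma12 is provided for assembling matrices from known trait
covariances, and `repair_psd` floors eigenvalues so the matrix admits an
inverse square root for whitening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import DomainError, InsufficientDataError, ValidationError
from .io_formats import NullZPanel

__all__ = [
    "TraitCorrelationMatrix",
    "select_null_snps",
    "thin_null_panel",
    "estimate_z_correlation",
    "overlap_correlation",
    "estimate_sigma_individual",
    "repair_psd",
]


@dataclass
class TraitCorrelationMatrix:
    """Symmetric unit-diagonal correlation of z-scores under the null."""

    trait_ids: list[str]
    R: np.ndarray
    source: str  # "null_snps" | "individual" | "supplied"
    eigenfloor_applied: bool = False

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        p = len(self.trait_ids)
        if self.R.shape != (p, p):
            raise ValidationError("correlation matrix shape does not match trait_ids")
        if np.max(np.abs(self.R - self.R.T)) > 1e-10:
            raise ValidationError("correlation matrix is not symmetric")
        if np.max(np.abs(np.diag(self.R) - 1.0)) > 1e-12:
            raise ValidationError("correlation matrix diagonal must be 1")

    @property
    def p(self) -> int:
        return len(self.trait_ids)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("trait_id\t" + "\t".join(self.trait_ids) + "\n")
            for t, row in zip(self.trait_ids, self.R):
                fh.write(t + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path, source: str = "supplied") -> "TraitCorrelationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        return cls(list(df.columns), df.to_numpy(dtype=float), source)


def select_null_snps(
    pvals: np.ndarray, threshold: float = 0.05, mode: str = "all_traits"
) -> np.ndarray:
    """Indices of SNPs usable as null SNPs: p-value above threshold.

    ``all_traits`` (default) keeps SNP k only when p > threshold for every
    trait; ``per_trait`` returns a boolean K x p mask to be applied pairwise.
    """
    pvals = np.asarray(pvals, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(pvals) <= 0 or np.nanmax(pvals) > 1:
            raise DomainError("p-values must lie in (0, 1]")
    keep_mask = pvals > threshold  # NaN compares False: missing p treated as non-null
    if mode == "per_trait":
        return keep_mask
    if mode != "all_traits":
        raise DomainError(f"unknown mode {mode!r}")
    idx = np.flatnonzero(np.all(keep_mask | np.isnan(pvals), axis=1) & ~np.all(np.isnan(pvals), axis=1))
    if idx.size == 0:
        raise InsufficientDataError("no SNPs survive the null filter")
    if idx.size < 10:
        warnings.warn(
            f"only {idx.size} null SNP(s) survive the filter; correlation will be noisy",
            stacklevel=2,
        )
    return idx


def thin_null_panel(panel: NullZPanel, step: int) -> NullZPanel:
    """Keep every ``step``-th SNP (crude stand-in for LD pruning)."""
    if step < 1:
        raise DomainError("step must be >= 1")
    return NullZPanel(panel.snp_ids[::step], list(panel.trait_ids), panel.z[::step])


def estimate_z_correlation(panel: NullZPanel) -> TraitCorrelationMatrix:
    """Empirical z-score correlation over null SNPs (pairwise-complete Pearson)."""
    df = pd.DataFrame(panel.z, columns=panel.trait_ids)
    nonmiss = df.notna()
    sd = df.std(ddof=1)
    constant = [t for t in panel.trait_ids if not np.isfinite(sd[t]) or sd[t] == 0.0]
    if constant:
        raise ValidationError(
            f"undefined correlation: constant z column for trait(s) {', '.join(constant)}"
        )
    joint = nonmiss.to_numpy(dtype=float).T @ nonmiss.to_numpy(dtype=float)
    if np.min(joint) < 2:
        j1, j2 = np.unravel_index(np.argmin(joint), joint.shape)
        raise InsufficientDataError(
            f"traits {panel.trait_ids[j1]}, {panel.trait_ids[j2]} share <2 null SNPs"
        )
    R = df.corr(method="pearson", min_periods=2).to_numpy(dtype=float)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return TraitCorrelationMatrix(list(panel.trait_ids), R, source="null_snps")


def overlap_correlation(n1: int, n2: int, n12: int, sigma12: float) -> float:
    """z-score correlation for two traits measured on overlapping samples."""
    if n1 <= 0 or n2 <= 0 or n12 < 0:
        raise DomainError("sample sizes must be positive (overlap nonnegative)")
    if n12 > min(n1, n2):
        raise DomainError("overlap n12 cannot exceed min(n1, n2)")
    if abs(sigma12) > 1:
        raise DomainError("|sigma12| must be <= 1")
    return (n12 / np.sqrt(n1 * n2)) * sigma12


def estimate_sigma_individual(
    traits: np.ndarray, genotype: np.ndarray, trait_ids: list[str] | None = None
) -> TraitCorrelationMatrix:
    """Residual trait correlation from individual-level data.

    Fits a separate no-intercept OLS of each (centered) trait on the genotype
    and returns the correlation of the residual covariance
    (Y - x beta_hat)' (Y - x beta_hat) / (n - 1).
    """
    Y = np.asarray(traits, dtype=float)
    x = np.asarray(genotype, dtype=float)
    if Y.ndim != 2 or x.ndim != 1 or Y.shape[0] != x.shape[0]:
        raise ValidationError("traits must be n x p and genotype length n")
    n, p = Y.shape
    if n < 3:
        raise InsufficientDataError("need at least 3 individuals")
    if np.var(x) == 0:
        raise ValidationError("zero-variance genotype")
    beta = (x @ Y) / (x @ x)
    resid = Y - np.outer(x, beta)
    sigma = resid.T @ resid / (n - 1)
    d = np.sqrt(np.diag(sigma))
    if np.any(d == 0):
        raise ValidationError("zero-variance residual trait")
    R = sigma / np.outer(d, d)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    ids = trait_ids if trait_ids is not None else [f"T{j+1}" for j in range(p)]
    return TraitCorrelationMatrix(ids, R, source="individual")


def repair_psd(
    R: np.ndarray,
    eigenfloor: float = 1e-8,
    trait_ids: list[str] | None = None,
    source: str = "supplied",
) -> TraitCorrelationMatrix:
    """Clip eigenvalues at ``eigenfloor`` and renormalize to a correlation matrix.

    A no-op (input returned unchanged, flag unset) when all eigenvalues already
    reach the floor.
    """
    R = np.asarray(R, dtype=float)
    if np.max(np.abs(R - R.T)) > 1e-10:
        raise ValidationError("repair_psd: input not symmetric within 1e-10")
    ids = trait_ids if trait_ids is not None else [f"T{j+1}" for j in range(R.shape[0])]
    vals, vecs = np.linalg.eigh((R + R.T) / 2.0)
    if vals.min() >= eigenfloor:
        out = R.copy()
        np.fill_diagonal(out, 1.0)
        return TraitCorrelationMatrix(ids, (out + out.T) / 2.0, source, eigenfloor_applied=False)
    vals = np.clip(vals, eigenfloor, None)
    A = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d)
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 1.0)
    return TraitCorrelationMatrix(ids, A, source, eigenfloor_applied=True)
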