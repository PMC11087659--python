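"""ZCA-cor whitening of z-score vectors.

On a correlation matrix R the ZCA-cor whitener is the unique symmetric
inverse square root W = R^(-1/2): whitened scores are uncorrelated under the
null and each z*_j stays maximally correlated with its original z_j among all
whitening rotations.  cor(z*_j, z_j) = (R^(1/2))_jj is reported (``diag_cor``)
so low-interpretability traits (conventionally < 0.7) can be flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from ._errors import DomainError, ValidationError
from .trait_correlation import TraitCorrelationMatrix

__all__ = ["WhitenedZ", "zca_cor_whiten", "whitened_pvalues", "prune_correlated_traits"]

#: p* values are clipped below at the smallest positive normal double
P_FLOOR = float(np.finfo(float).tiny)


@dataclass
class WhitenedZ:
    z_star: np.ndarray
    p_star: np.ndarray
    whitener: np.ndarray
    diag_cor: np.ndarray

    def low_cor_traits(self, threshold: float = 0.7) -> np.ndarray:
        """Indices whose whitened score correlates with the original below ``threshold``."""
        return np.flatnonzero(self.diag_cor < threshold)


def whitened_pvalues(z_star: np.ndarray) -> np.ndarray:
    """Two-sided normal tails 2(1 - Phi(|z*|)), floored at the tiniest normal double."""
    z_star = np.asarray(z_star, dtype=float)
    if not np.all(np.isfinite(z_star)):
        raise DomainError("non-finite whitened z")
    return np.maximum(2.0 * ndtr(-np.abs(z_star)), P_FLOOR)


def zca_cor_whiten(
    z: np.ndarray, R: TraitCorrelationMatrix | np.ndarray, eigenfloor: float = 1e-8
) -> WhitenedZ:
    """Whiten z with the symmetric inverse square root of the correlation matrix.

    Deterministic: eigendecomposition with eigenvalues clipped at
    ``eigenfloor``.  Raises when z is non-finite or R is singular beyond
    repair.
    """
    Rm = R.R if isinstance(R, TraitCorrelationMatrix) else np.asarray(R, dtype=float)
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or z.shape[0] != Rm.shape[0]:
        raise ValidationError("z length must match correlation dimension")
    if not np.all(np.isfinite(z)):
        raise DomainError("non-finite z")
    vals, vecs = np.linalg.eigh((Rm + Rm.T) / 2.0)
    if vals.min() < -1e-6:
        raise np.linalg.LinAlgError(
            "correlation matrix is indefinite; run repair_psd first"
        )
    if vals.max() < eigenfloor:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular after repair; prune redundant traits"
        )
    vals = np.clip(vals, eigenfloor, None)
    W = (vecs / np.sqrt(vals)) @ vecs.T  # R^(-1/2), symmetric
    sqrtR = (vecs * np.sqrt(vals)) @ vecs.T
    # identity whitener short-circuit keeps z* bitwise equal to z when R = I
    if np.array_equal(Rm, np.eye(Rm.shape[0])):
        z_star = z.copy()
        W = np.eye(Rm.shape[0])
        diag_cor = np.ones(Rm.shape[0])
    else:
        z_star = W @ z
        diag_cor = np.diag(sqrtR).copy()
    return WhitenedZ(z_star=z_star, p_star=whitened_pvalues(z_star), whitener=W,
                     diag_cor=diag_cor)


def prune_correlated_traits(R: np.ndarray, max_abs_cor: float) -> np.ndarray:
    """Greedy pruning: indices of a trait subset with all |cor| <= max_abs_cor.

    Optional pre-scan step (off by default); earlier traits win ties.
    """
    R = np.asarray(R, dtype=float)
    keep: list[int] = []
    for j in range(R.shape[0]):
        if all(abs(R[j, k]) <= max_abs_cor for k in keep):
            keep.append(j)
    return np.asarray(keep, dtype=int)
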