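"""Weighted genomic relationship matrix G, blending, and the H inverse.

G = Z D Z' / sum_i 2 p_i (1 - p_i), with Z the centered gene contents
and D a diagonal matrix of per-SNP variance weights (D = I gives the
standard VanRaden matrix).  When centering frequencies are estimated
from the same animals that enter G, the raw matrix is singular (its
rows sum to zero); blending (1 - alpha) G + alpha A22 restores
invertibility, as in single-step GBLUP practice.

H combines pedigree and genomic information; its inverse is A_inverse
with the genotyped block incremented by (G_inverse - A22_inverse).
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .pedigree import RelationshipMatrix


def lambda_scaling(freqs: np.ndarray) -> float:
    """lambda = 1 / sum_i 2 p_i (1 - p_i), the SNP-variance scaling constant."""
    s = float(np.sum(2.0 * freqs * (1.0 - freqs)))
    if s <= 0:
        raise ValueError("all SNPs monomorphic: sum 2p(1-p) is zero")
    return 1.0 / s


def build_G(
    Z_centered: np.ndarray,
    weights: np.ndarray | None,
    lam: float,
    ids: list[str],
) -> RelationshipMatrix:
    """Raw (unblended) weighted genomic relationship matrix Z D Z' * lambda."""
    Z = np.asarray(Z_centered, dtype=np.float64)
    if weights is None:
        G = (Z @ Z.T) * lam
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (Z.shape[1],):
            raise ValueError("weight vector length must equal SNP count")
        if np.any(w < 0):
            raise ValueError("SNP weights must be non-negative")
        G = (Z * w) @ Z.T * lam
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(G, list(ids), "G")


def blend_G(
    G_raw: RelationshipMatrix, A22: RelationshipMatrix, blend_alpha: float
) -> RelationshipMatrix:
    """(1 - alpha) G + alpha A22; alpha = 0 returns G unchanged."""
    if not (0.0 <= blend_alpha < 1.0):
        raise ValueError("blend_alpha must lie in [0, 1)")
    if blend_alpha == 0.0:
        return G_raw
    if G_raw.ids != A22.ids:
        raise ValueError("G and A22 id orderings differ")
    return RelationshipMatrix(
        (1.0 - blend_alpha) * G_raw.values + blend_alpha * A22.values,
        list(G_raw.ids),
        "G",
    )


def checked_cho_factor(values: np.ndarray, context: str):
    """Cholesky factor with an explicit near-singularity guard.

    LAPACK's potrf can return a tiny positive last pivot for an exactly
    singular matrix instead of failing, which would silently corrupt the
    solve; the pivot-ratio check catches that.
    """
    try:
        c, low = scipy.linalg.cho_factor(values)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(context) from exc
    d = np.abs(np.diag(c))
    if d.size and d.min() <= 1e-7 * d.max():
        raise np.linalg.LinAlgError(context)
    return c, low


def invert_relationship(mat: RelationshipMatrix, role: str) -> RelationshipMatrix:
    """Dense symmetric inverse; raises (never pseudo-inverts) when singular."""
    cf = checked_cho_factor(
        mat.values,
        f"{mat.role} matrix is singular or not positive definite; "
        "blend with A22 (blend_alpha > 0) or prune duplicate animals/SNPs",
    )
    inv = scipy.linalg.cho_solve(cf, np.eye(mat.n))
    inv = 0.5 * (inv + inv.T)
    return RelationshipMatrix(inv, list(mat.ids), role)


def build_H_inverse(
    A_inv: RelationshipMatrix,
    A22_inv: RelationshipMatrix,
    G_inv: RelationshipMatrix,
    genotyped_ids: list[str],
) -> RelationshipMatrix:
    """A_inverse with the genotyped block incremented by G_inv - A22_inv."""
    if list(G_inv.ids) != list(genotyped_ids) or list(A22_inv.ids) != list(genotyped_ids):
        raise ValueError("G inverse / A22 inverse orderings do not match genotyped ids")
    pos = {a: i for i, a in enumerate(A_inv.ids)}
    missing = [g for g in genotyped_ids if g not in pos]
    if missing:
        raise ValueError(f"genotyped ids missing from pedigree matrix: {missing}")
    H = A_inv.values.copy()
    take = np.array([pos[g] for g in genotyped_ids], dtype=np.int64)
    if len(take):
        H[np.ix_(take, take)] += G_inv.values - A22_inv.values
    return RelationshipMatrix(H, list(A_inv.ids), "H_inverse")
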