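"""Genomic and combined relationship matrices.

Implements the weighted genomic relationship matrix
``G = Z D Z' / sum_i 2 p_i (1 - p_i)`` (VanRaden method 1 when D = I, with
Z the gene content centered by twice the allele frequency), blending of G
toward the pedigree submatrix A22 for invertibility, and the single-step
inverse ``H^-1 = A^-1 + [[0,0],[0, G*^-1 - A22^-1]]`` scattered over the
genotyped block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .genotypes import GenotypeMatrix

__all__ = [
    "RelationshipMatrix",
    "build_G",
    "blend_tune_G",
    "build_H_inverse",
    "inv_psd",
    "scaling_constant",
    "save_matrix",
    "load_matrix",
]


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix with its id ordering and a kind tag."""

    values: np.ndarray
    ids: np.ndarray
    kind: str  # one of A, A22, G, G_star
    meta: dict | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relationship matrix must be square")
        if v.shape[0] != len(self.ids):
            raise ValueError("dimension does not match id list")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("relationship matrix not symmetric")
        self.values = v
        self.ids = np.asarray(self.ids)


def save_matrix(matrix: RelationshipMatrix, path: str) -> None:
    """Persist as indexed triplets (i, j, value; lower triangle, 0-based)
    with an id sidecar at ``<path>.ids``."""
    v = matrix.values
    il, jl = np.tril_indices(v.shape[0])
    with open(path, "w") as fh:
        fh.write(f"# kind={matrix.kind}\n")
        for i, j in zip(il, jl):
            if v[i, j] != 0.0:
                fh.write(f"{i}\t{j}\t{float(v[i, j])!r}\n")
    np.savetxt(f"{path}.ids", matrix.ids, fmt="%s")


def load_matrix(path: str) -> RelationshipMatrix:
    """Read a triplet-text relationship matrix written by :func:`save_matrix`."""
    ids = np.loadtxt(f"{path}.ids", dtype=np.int64, ndmin=1)
    n = len(ids)
    v = np.zeros((n, n))
    kind = "A"
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "kind=" in line:
                    kind = line.strip().split("kind=")[1]
                continue
            i, j, x = line.split("\t")
            v[int(i), int(j)] = v[int(j), int(i)] = float(x)
    return RelationshipMatrix(values=v, ids=ids, kind=kind)


def scaling_constant(freqs: np.ndarray) -> float:
    """k = sum_i 2 p_i (1 - p_i), the genomic variance scaling denominator."""
    p = np.asarray(freqs, dtype=float)
    return float(np.sum(2.0 * p * (1.0 - p)))


def build_G(
    geno: GenotypeMatrix,
    weights: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
) -> RelationshipMatrix:
    """Weighted genomic relationship matrix G = Z D Z' / k.

    ``weights`` is the diagonal of D (defaults to ones, the unweighted
    VanRaden matrix); ``freqs`` defaults to the frequencies observed in the
    genotyped set. Fixed (p = 0 or 1) SNPs must have been removed by QC.
    """
    p = geno.allele_freq() if freqs is None else np.asarray(freqs, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("allele frequency 0 or 1 encountered; run QC first")
    Z = geno.centered(p)
    k = scaling_constant(p)
    if weights is not None:
        d = np.asarray(weights, dtype=float)
        if d.shape != (geno.n_snps,) or np.any(d <= 0):
            raise ValueError("weights must be positive, one per SNP")
        if np.all(d == 1.0):
            weights = None  # identity fast path: bitwise-equal to unweighted
    if weights is None:
        G = (Z @ Z.T) / k
    else:
        G = ((Z * d) @ Z.T) / k
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(values=G, ids=geno.ids, kind="G", meta={"k": k})


def blend_tune_G(
    G: RelationshipMatrix, A22: RelationshipMatrix | np.ndarray, blend_alpha: float = 0.05
) -> RelationshipMatrix:
    """G* = (1 - alpha) G + alpha A22, with a condition-number diagnostic."""
    if not (0.0 <= blend_alpha < 1.0):
        raise ValueError("blend_alpha must be in [0, 1)")
    A22v = A22.values if isinstance(A22, RelationshipMatrix) else np.asarray(A22, float)
    if isinstance(A22, RelationshipMatrix) and not np.array_equal(A22.ids, G.ids):
        raise ValueError("G and A22 id orderings differ")
    if A22v.shape != G.values.shape:
        raise ValueError("G and A22 dimensions differ")
    if blend_alpha == 0.0:
        Gs = G.values
    else:
        Gs = (1.0 - blend_alpha) * G.values + blend_alpha * A22v
    cond = float(np.linalg.cond(Gs))
    return RelationshipMatrix(
        values=Gs, ids=G.ids, kind="G_star",
        meta={**(G.meta or {}), "blend_alpha": blend_alpha, "condition_number": cond},
    )


def inv_psd(M: np.ndarray, label: str = "matrix") -> np.ndarray:
    """Inverse of a symmetric positive-definite matrix via Cholesky."""
    try:
        c, low = scipy.linalg.cho_factor(M, check_finite=False)
    except scipy.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            f"{label} is not positive definite; blend toward A22 (blend_alpha > 0)"
        ) from e
    inv = scipy.linalg.cho_solve((c, low), np.eye(M.shape[0]), check_finite=False)
    return 0.5 * (inv + inv.T)


def build_H_inverse(
    A_inv: sp.spmatrix,
    A22_inv: np.ndarray,
    G_star_inv: np.ndarray,
    genotyped_index: np.ndarray,
) -> sp.csc_matrix:
    """H^-1 = A^-1 with (G*^-1 - A22^-1) added into the genotyped block.

    ``genotyped_index`` gives the row positions of genotyped animals inside
    A's (pedigree) ordering, matching the row order of G* and A22.
    """
    idx = np.asarray(genotyped_index, dtype=np.int64)
    ng = len(idx)
    if G_star_inv.shape != (ng, ng) or A22_inv.shape != (ng, ng):
        raise ValueError("genotyped-block dimensions inconsistent with index")
    A = A_inv.tocoo()
    if ng == 0:
        return A.tocsc()
    corr = G_star_inv - A22_inv
    rows = np.concatenate([A.row, np.repeat(idx, ng)])
    cols = np.concatenate([A.col, np.tile(idx, ng)])
    vals = np.concatenate([A.data, corr.ravel()])
    # coo -> csc sums duplicate entries, adding the correction into A^-1
    return sp.coo_matrix((vals, (rows, cols)), shape=A.shape).tocsc()
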