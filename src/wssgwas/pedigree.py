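"""Pedigree container and pedigree-based relationship matrices.

The :class:`Pedigree` holds animal/sire/dam triplets in topological order
(parents before offspring) and provides the numerator relationship matrix A
(tabular method), inbreeding coefficients (Meuwissen & Luo ancestor tracing),
and the sparse inverse of A assembled directly by Henderson's rules — A is
never inverted densely on the main path, so the pipeline scales beyond toy
pedigrees.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["Pedigree", "PedigreeError"]


class PedigreeError(ValueError):
    """Raised for malformed pedigrees (cycles, unknown parents, bad ids)."""


def _toposort(animal: np.ndarray, sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Kahn topological sort of animals so parents precede offspring.

    Returns the permutation of row indices; raises PedigreeError on a cycle
    (an animal that is its own ancestor) or on a parent id absent from the
    animal column.
    """
    index = {a: i for i, a in enumerate(animal)}
    n = len(animal)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=int)
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p == 0:
                continue
            if p not in index:
                raise PedigreeError(f"parent id {p} of animal {animal[i]} not in pedigree")
            children[index[p]].append(i)
            indeg[i] += 1
    order: list[int] = [i for i in range(n) if indeg[i] == 0]
    head = 0
    while head < len(order):
        i = order[head]
        head += 1
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                order.append(c)
    if len(order) != n:
        raise PedigreeError("pedigree contains a cycle (an animal is its own ancestor)")
    return np.asarray(order)


class Pedigree:
    """Ordered pedigree: integer animal ids >= 1, parent id 0 = unknown.

    Parameters
    ----------
    table : DataFrame with columns ``animal``, ``sire``, ``dam`` and
        optionally ``generation`` and ``genotyped``. Rows are re-ordered
        topologically if necessary.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"animal", "sire", "dam"}
        missing = required - set(table.columns)
        if missing:
            raise PedigreeError(f"pedigree table missing columns: {sorted(missing)}")
        t = table.copy()
        t["animal"] = t["animal"].astype(np.int64)
        t["sire"] = t["sire"].astype(np.int64)
        t["dam"] = t["dam"].astype(np.int64)
        if (t["animal"] < 1).any():
            raise PedigreeError("animal ids must be >= 1")
        if t["animal"].duplicated().any():
            raise PedigreeError("duplicate animal ids")
        animal = t["animal"].to_numpy()
        order = _toposort(animal, t["sire"].to_numpy(), t["dam"].to_numpy())
        # keep original order when already topological (stable for fixtures)
        if not np.array_equal(np.sort(order), order):
            t = t.iloc[order]
        if "generation" not in t.columns:
            t["generation"] = 0
        if "genotyped" not in t.columns:
            t["genotyped"] = False
        self.table = t.reset_index(drop=True)
        self._index = {a: i for i, a in enumerate(self.table["animal"].to_numpy())}
        ai = self.table["animal"].to_numpy()
        self.sire_idx = np.array(
            [self._index[s] if s != 0 else -1 for s in self.table["sire"]], dtype=np.int64
        )
        self.dam_idx = np.array(
            [self._index[d] if d != 0 else -1 for d in self.table["dam"]], dtype=np.int64
        )
        # ordering invariant: parents precede offspring in row order
        rows = np.arange(len(ai))
        for p_idx in (self.sire_idx, self.dam_idx):
            known = p_idx >= 0
            if np.any(p_idx[known] >= rows[known]):
                raise PedigreeError("internal ordering failure: parent after offspring")
        self._inbreeding: np.ndarray | None = None

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["animal"].to_numpy()

    @property
    def genotyped_mask(self) -> np.ndarray:
        return self.table["genotyped"].to_numpy(dtype=bool)

    @property
    def genotyped_index(self) -> np.ndarray:
        """Row positions of genotyped animals, in pedigree order."""
        return np.flatnonzero(self.genotyped_mask)

    def indices_of(self, ids) -> np.ndarray:
        try:
            return np.array([self._index[int(a)] for a in np.atleast_1d(ids)], dtype=np.int64)
        except KeyError as e:  # pragma: no cover - message formatting
            raise PedigreeError(f"animal id {e.args[0]} not in pedigree") from None

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    # ------------------------------------------------------------------
    def _mendelian_variance(self, F: np.ndarray) -> np.ndarray:
        """Within-family (Mendelian sampling) variance d_i given parental F.

        d = 1 if both parents unknown; 0.75 - 0.25 F_known with one known
        parent; 0.5 - 0.25 (F_s + F_d) with both known.
        """
        s, d = self.sire_idx, self.dam_idx
        out = np.ones(self.n)
        one = (s >= 0) ^ (d >= 0)
        known = np.where(s >= 0, s, d)
        out[one] = 0.75 - 0.25 * F[known[one]]
        both = (s >= 0) & (d >= 0)
        out[both] = 0.5 - 0.25 * (F[s[both]] + F[d[both]])
        return out

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients by Meuwissen & Luo ancestor tracing.

        For each animal the diagonal a_ii = sum_j L_ij^2 d_j is accumulated
        over its ancestors, where L is the lower-triangular factor of
        A = L D L' and d_j the Mendelian sampling variance; F_i = a_ii - 1.
        """
        if self._inbreeding is not None:
            return self._inbreeding
        n = self.n
        s, d = self.sire_idx, self.dam_idx
        F = np.zeros(n)
        dvec = np.empty(n)
        for i in range(n):
            si, di = s[i], d[i]
            if si < 0 and di < 0:
                dvec[i] = 1.0
            elif si < 0 or di < 0:
                dvec[i] = 0.75 - 0.25 * F[max(si, di)]
            else:
                dvec[i] = 0.5 - 0.25 * (F[si] + F[di])
            if si < 0 and di < 0:
                F[i] = 0.0
                continue
            L: dict[int, float] = {i: 1.0}
            a_ii = 0.0
            for j in range(i, -1, -1):
                lj = L.pop(j, 0.0)
                if lj == 0.0:
                    continue
                a_ii += lj * lj * dvec[j]
                sj, dj = s[j], d[j]
                if sj >= 0:
                    L[sj] = L.get(sj, 0.0) + 0.5 * lj
                if dj >= 0:
                    L[dj] = L.get(dj, 0.0) + 0.5 * lj
            F[i] = a_ii - 1.0
        self._inbreeding = F
        return F

    def relationship_matrix(self) -> np.ndarray:
        """Dense numerator relationship matrix A by the tabular method."""
        n = self.n
        if n > 20000:
            raise MemoryError("tabular A is dense; refusing n > 20000")
        A = np.zeros((n, n))
        s, d = self.sire_idx, self.dam_idx
        for i in range(n):
            si, di = s[i], d[i]
            row = np.zeros(i)
            if si >= 0:
                row += A[:i, si]
            if di >= 0:
                row += A[:i, di]
            A[i, :i] = A[:i, i] = 0.5 * row
            A[i, i] = 1.0 + (0.5 * A[si, di] if (si >= 0 and di >= 0) else 0.0)
        return A

    def a_inverse(self) -> sp.csr_matrix:
        """Sparse inverse of A by Henderson's rules with inbreeding."""
        F = self.inbreeding()
        alpha = 1.0 / self._mendelian_variance(F)
        s, d = self.sire_idx, self.dam_idx
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []
        i = np.arange(self.n)

        def add(r, c, v):
            rows.append(np.asarray(r))
            cols.append(np.asarray(c))
            vals.append(np.asarray(v, dtype=float))

        add(i, i, alpha)
        for p in (s, d):
            m = p >= 0
            add(p[m], i[m], -0.5 * alpha[m])
            add(i[m], p[m], -0.5 * alpha[m])
            add(p[m], p[m], 0.25 * alpha[m])
        both = (s >= 0) & (d >= 0)
        add(s[both], d[both], 0.25 * alpha[both])
        add(d[both], s[both], 0.25 * alpha[both])
        Ainv = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n),
        ).tocsr()
        return Ainv

    def a_submatrix(self, rows: np.ndarray) -> np.ndarray:
        """A restricted to the given row positions (e.g. A22 for genotyped)."""
        A = self.relationship_matrix()
        rows = np.asarray(rows)
        return A[np.ix_(rows, rows)]
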