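"""Orthogonal two-component-signaling subset selection.

Given a crosstalk matrix of median output levels (histidine kinases on
rows, response regulators on columns), a greedy pass assigns one
reference cell per row and column by repeatedly taking the largest
unblocked value and blocking its row and column.  Each reference is
divided by every other value in its row and column and the quotients are
multiplied; the per-reference scores multiply into one matrix score, so
strongly diagonal (orthogonal) matrices score high.  The best k-pair
subset (k = 4..7 in the original screen) is found by exhaustive
enumeration of submatrices.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CrosstalkMatrix",
    "SubsetScore",
    "assign_references",
    "score_matrix",
    "best_subset",
]


@dataclass(frozen=True)
class CrosstalkMatrix:
    """HK x RR matrix of median output levels (strictly positive MEFL)."""

    values: np.ndarray = field(repr=False)
    hk_labels: tuple[str, ...] = ()
    rr_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("crosstalk matrix must be 2-D")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("all crosstalk values must be finite and > 0")
        object.__setattr__(self, "values", v)
        if not self.hk_labels:
            object.__setattr__(self, "hk_labels", tuple(f"HK{i+1}" for i in range(v.shape[0])))
        if not self.rr_labels:
            object.__setattr__(self, "rr_labels", tuple(f"RR{j+1}" for j in range(v.shape[1])))
        if len(self.hk_labels) != v.shape[0] or len(self.rr_labels) != v.shape[1]:
            raise ValueError("label lengths must match the matrix shape")

    @classmethod
    def from_csv(cls, path) -> "CrosstalkMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(values=df.to_numpy(dtype=float),
                   hk_labels=tuple(map(str, df.index)),
                   rr_labels=tuple(map(str, df.columns)))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=list(self.hk_labels),
                     columns=list(self.rr_labels)).to_csv(path)


@dataclass(frozen=True)
class SubsetScore:
    hk_indices: tuple[int, ...]
    rr_indices: tuple[int, ...]
    references: tuple[tuple[int, int], ...]  # within the submatrix
    score: float
    log10_score: float
    hk_labels: tuple[str, ...] = ()
    rr_labels: tuple[str, ...] = ()


def _as_square_array(M) -> np.ndarray:
    v = M.values if isinstance(M, CrosstalkMatrix) else np.asarray(M, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError(f"need a square matrix, got shape {v.shape}")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValueError("matrix entries must be finite and > 0")
    return v


def assign_references(M) -> list[tuple[int, int]]:
    """Greedy reference assignment: one cell per row and column.

    Repeatedly takes the maximum among unblocked cells (first occurrence
    in row-major order on ties), records it, and blocks its row and
    column.  Returns (row, col) pairs in selection order.
    """
    v = _as_square_array(M)
    k = v.shape[0]
    work = v.copy()
    refs: list[tuple[int, int]] = []
    for _ in range(k):
        flat = int(np.nanargmax(work))  # row-major first occurrence on ties
        i, j = divmod(flat, k)
        refs.append((i, j))
        work[i, :] = np.nan
        work[:, j] = np.nan
    return refs


def score_matrix(M) -> float:
    """Orthogonality score of a square all-positive crosstalk matrix.

    Product over the greedy references of (reference / other) over the
    2(k-1) other cells in that reference's row and column; quotients and
    the final score are strictly positive.
    """
    v = _as_square_array(M)
    k = v.shape[0]
    score = 1.0
    for i, j in assign_references(v):
        ref = v[i, j]
        for jj in range(k):
            if jj != j:
                score *= ref / v[i, jj]
        for ii in range(k):
            if ii != i:
                score *= ref / v[ii, j]
    return score


def _log10_score(v: np.ndarray) -> float:
    """log10 of score_matrix, overflow-safe for large subset searches."""
    k = v.shape[0]
    lv = np.log10(v)
    total = 0.0
    for i, j in assign_references(v):
        total += 2 * (k - 1) * lv[i, j] - (lv[i, :].sum() - lv[i, j]) - (lv[:, j].sum() - lv[i, j])
    return total


def best_subset(M, k: int, mode: str = "cognate_pairs") -> SubsetScore:
    """Exhaustive search for the best-scoring k x k submatrix.

    ``cognate_pairs``: one index set selects matched HK-RR pairs (the
    same indices on rows and columns).  ``independent``: all row-subset x
    column-subset combinations.  Ties break by lexicographic index
    order (the enumeration order of itertools.combinations).
    """
    if mode not in ("cognate_pairs", "independent"):
        raise ValueError(f"mode must be cognate_pairs|independent, got {mode!r}")
    v = M.values if isinstance(M, CrosstalkMatrix) else np.asarray(M, dtype=float)
    if v.ndim != 2:
        raise ValueError("need a 2-D matrix")
    n_hk, n_rr = v.shape
    if k > min(n_hk, n_rr) or k < 1:
        raise ValueError(f"k={k} exceeds matrix dimensions {v.shape}")
    if mode == "cognate_pairs" and n_hk != n_rr:
        raise ValueError("cognate_pairs mode needs a square matrix")

    if mode == "cognate_pairs":
        candidates = ((idx, idx) for idx in itertools.combinations(range(n_hk), k))
    else:
        candidates = itertools.product(
            itertools.combinations(range(n_hk), k),
            itertools.combinations(range(n_rr), k),
        )

    best_log = -math.inf
    best_rows = best_cols = None
    for rows, cols in candidates:
        sub = v[np.ix_(rows, cols)]
        ls = _log10_score(sub)
        if ls > best_log:
            best_log, best_rows, best_cols = ls, rows, cols

    sub = v[np.ix_(best_rows, best_cols)]
    refs = tuple(assign_references(sub))
    hk_lab = (tuple(M.hk_labels[i] for i in best_rows)
              if isinstance(M, CrosstalkMatrix) else ())
    rr_lab = (tuple(M.rr_labels[j] for j in best_cols)
              if isinstance(M, CrosstalkMatrix) else ())
    return SubsetScore(
        hk_indices=tuple(best_rows),
        rr_indices=tuple(best_cols),
        references=refs,
        score=score_matrix(sub),
        log10_score=best_log,
        hk_labels=hk_lab,
        rr_labels=rr_lab,
    )
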