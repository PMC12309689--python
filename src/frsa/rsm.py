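"""Representational similarity matrices (RSMs) and their vectorization.

An RSM is a symmetric condition-by-condition matrix of response
similarities.  Three kinds occur here: Pearson correlations of feature
vectors or time courses, ``1 - |difference|`` of scalar summaries, and
binary categorical model matrices.  Downstream statistics operate on the
strictly-lower-triangular entries in a fixed column-major order so that
permutation shuffles are reproducible across modules.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "RSM",
    "rsm_from_features",
    "rsm_from_scalars",
    "rsm_from_timecourses",
    "lower_triangle",
    "from_lower_triangle",
    "lower_triangle_indices",
]

_SYM_TOL = 1e-9


class RSM:
    """Condition-pair similarity matrix.

    Parameters
    ----------
    matrix : (n, n) array
        Symmetric similarity values; NaN marks undefined entries.
    kind : {"correlation", "one-minus-absdiff", "binary"}
    labels : sequence, optional
        Condition labels (defaults to 1..n).
    """

    KINDS = ("correlation", "one-minus-absdiff", "binary")

    def __init__(self, matrix, kind: str = "correlation", labels=None):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValueError(f"RSM matrix must be square, got shape {matrix.shape}")
        if kind not in self.KINDS:
            raise ValueError(f"unknown RSM kind {kind!r}")
        finite = np.isfinite(matrix)
        asym = np.abs(matrix - matrix.T)
        if np.any(asym[finite & finite.T] > _SYM_TOL):
            raise ValueError("RSM matrix is not symmetric within 1e-9")
        self.matrix = matrix
        self.kind = kind
        self.labels = list(labels) if labels is not None else list(
            range(1, matrix.shape[0] + 1)
        )
        if len(self.labels) != matrix.shape[0]:
            raise ValueError("label count must equal matrix dimension")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_undefined(self) -> int:
        """Number of undefined (NaN) entries in the lower triangle."""
        return int(np.sum(np.isnan(self.lower_triangle())))

    def lower_triangle(self) -> np.ndarray:
        return lower_triangle(self)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path, kind: str = "correlation") -> "RSM":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), kind=kind, labels=list(df.columns))

    def __repr__(self) -> str:  # pragma: no cover
        return f"RSM(n={self.n}, kind={self.kind!r})"


def lower_triangle_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strict lower triangle in column-major
    order: column 0 top-to-bottom, then column 1, ...  Fixed project-wide."""
    cols, rows = [], []
    for j in range(n):
        for i in range(j + 1, n):
            rows.append(i)
            cols.append(j)
    return np.asarray(rows), np.asarray(cols)


def lower_triangle(rsm) -> np.ndarray:
    """Strictly-below-diagonal entries, column-major; length n(n-1)/2."""
    matrix = rsm.matrix if isinstance(rsm, RSM) else np.asarray(rsm, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("lower_triangle expects a square matrix")
    finite = np.isfinite(matrix)
    if np.any(np.abs(matrix - matrix.T)[finite & finite.T] > _SYM_TOL):
        raise ValueError("matrix asymmetric beyond 1e-9")
    rows, cols = lower_triangle_indices(matrix.shape[0])
    return matrix[rows, cols]


def from_lower_triangle(values, diagonal: float = 1.0) -> np.ndarray:
    """Rebuild the symmetric matrix from a column-major triangle vector;
    exact inverse of :func:`lower_triangle` for the off-diagonal part."""
    values = np.asarray(values, dtype=float)
    m = values.size
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if n < 2 or n * (n - 1) // 2 != m:
        raise ValueError(f"vector length {m} is not a triangular number")
    out = np.full((n, n), diagonal)
    rows, cols = lower_triangle_indices(n)
    out[rows, cols] = values
    out[cols, rows] = values
    return out


def _pearson_matrix(vectors: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations of row vectors; rows with zero
    variance yield NaN entries instead of raising."""
    v = vectors - vectors.mean(axis=1, keepdims=True)
    sd = np.sqrt(np.sum(v**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (v @ v.T) / np.outer(sd, sd)
    c[(sd == 0)[:, None] | (sd == 0)[None, :]] = np.nan
    np.fill_diagonal(c, 1.0)
    c = np.clip(c, -1.0, 1.0)
    return c


def rsm_from_features(features, labels=None) -> RSM:
    """Pearson-correlation RSM over per-condition feature vectors.

    ``features`` is a sequence of equal-length 1-D vectors (or an
    (n_conditions, n_features) array).  Zero-variance vectors produce
    undefined (NaN) entries, excluded pairwise downstream.
    """
    arr = np.atleast_2d(np.asarray([np.ravel(f) for f in features], dtype=float))
    if arr.shape[0] < 2:
        raise ValueError("need >= 2 conditions")
    return RSM(_pearson_matrix(arr), kind="correlation", labels=labels)


def rsm_from_scalars(values, labels=None) -> RSM:
    """``1 - |v_i - v_j|`` similarity from one scalar summary per condition
    (e.g. the mean produced ITI ratio)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values")
    return RSM(
        1.0 - np.abs(v[:, None] - v[None, :]), kind="one-minus-absdiff", labels=labels
    )


def rsm_from_timecourses(avg_epochs, labels=None) -> RSM:
    """Pearson-correlation RSM of per-condition average response cycles
    (channel-pooled, demeaned implicitly by the correlation)."""
    arr = np.atleast_2d(np.asarray([np.ravel(e) for e in avg_epochs], dtype=float))
    if arr.shape[0] < 2:
        raise ValueError("need >= 2 conditions")
    return RSM(_pearson_matrix(arr), kind="correlation", labels=labels)
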