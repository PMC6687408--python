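"""Signed linkage-disequilibrium matrices.

LD is carried as the signed dosage correlation ``r`` between variants:
clumping thresholds are on ``r**2`` (unsigned) while the correlated
inverse-variance-weighted estimator needs the sign, so a single signed
matrix serves both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LdMatrix"]


@dataclass
class LdMatrix:
    """Symmetric signed correlation matrix over an ordered set of variants.

    Parameters
    ----------
    ids
        Variant identifiers, in matrix order.
    r
        Square symmetric matrix of signed correlations; unit diagonal.
    """

    ids: list[str]
    r: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.ids)
        if self.r.shape != (n, n):
            raise ValueError(f"LD matrix shape {self.r.shape} does not match {n} ids")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise ValueError("LD correlations must lie in [-1, 1]")
        self._index = {v: i for i, v in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def submatrix(self, ids: list[str]) -> "LdMatrix":
        """Restrict to ``ids`` (in the given order)."""
        missing = [v for v in ids if v not in self._index]
        if missing:
            raise KeyError(f"variants missing from LD matrix: {missing}")
        idx = np.array([self._index[v] for v in ids], dtype=int)
        return LdMatrix(list(ids), self.r[np.ix_(idx, idx)])

    def r_between(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def r2(self) -> np.ndarray:
        """Unsigned squared correlations (used by clumping)."""
        return self.r**2

    def stabilized(self, eps: float = 1e-8) -> "LdMatrix":
        """Return a positive-semi-definite copy via eigenvalue clipping.

        Sample LD from finite reference panels is frequently indefinite;
        eigenvalues below ``eps`` are clipped up before any linear solve.
        The diagonal is renormalized to 1 afterwards.
        """
        w, v = np.linalg.eigh(self.r)
        if w.min() >= eps:
            return self
        w = np.clip(w, eps, None)
        m = (v * w) @ v.T
        d = np.sqrt(np.diag(m))
        m = m / np.outer(d, d)
        m = (m + m.T) / 2.0
        np.fill_diagonal(m, 1.0)
        return LdMatrix(list(self.ids), m)

    # ---------------------------------------------------------------- I/O

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.ids, columns=self.ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LdMatrix":
        if list(frame.index) != list(frame.columns):
            raise ValueError("LD matrix row and column ids differ")
        return cls(list(frame.columns), frame.to_numpy(dtype=float))

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="ID")

    @classmethod
    def read(cls, path) -> "LdMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        return cls.from_frame(frame)
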