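"""Shared containers: symmetric pairwise matrices keyed by sample ids."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PairwiseMatrix"]


@dataclass
class PairwiseMatrix:
    """A symmetric samples x samples matrix with a units tag.

    Used for genetic distances (substitutions), geographic distances (km),
    travel times (hours), F_ST-derived matrices (diagonal NaN) and IBD
    sharing (mean segment counts).

    Parameters
    ----------
    values : (n, n) float array, symmetric.  NaN entries are allowed and
        mean "undefined for this pair" (e.g. no shared non-missing loci).
    ids : sequence of n unique sample identifiers.
    units : free-text tag, e.g. ``"km"``, ``"hours"``, ``"substitutions"``.
    """

    values: np.ndarray
    ids: list[str]
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = [str(i) for i in self.ids]
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if len(set(self.ids)) != n:
            raise ValueError("sample ids must be unique")
        finite = np.isfinite(self.values)
        both = finite & finite.T
        if not np.allclose(
            self.values[both], self.values.T[both], rtol=1e-8, atol=1e-10
        ):
            raise ValueError("matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i < j) values in row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def align_to(self, ids: list[str]) -> "PairwiseMatrix":
        """Reorder (or subset) rows/columns to a given id order."""
        pos = {s: k for k, s in enumerate(self.ids)}
        try:
            idx = np.array([pos[str(s)] for s in ids])
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"sample {exc} not present in matrix") from exc
        return PairwiseMatrix(
            self.values[np.ix_(idx, idx)], list(ids), self.units, dict(self.meta)
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path, units: str = "") -> "PairwiseMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns], units)


def condensed_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strict upper triangle of an n x n matrix."""
    return np.triu_indices(n, k=1)
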