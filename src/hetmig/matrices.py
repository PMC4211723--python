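"""Square symmetric pairwise matrices and their shared CSV format.

The matrix CSV has ids as the first row and first column; the diagonal
is written as ``NA``.  Off-diagonal ``NA`` entries mark dyads excluded
pairwise from downstream tests (e.g. no shared typed loci).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PairwiseMatrix", "read_matrix_csv", "write_matrix_csv"]


@dataclass
class PairwiseMatrix:
    """Symmetric pairwise values (similarity or distance) over ids."""

    ids: list[str]
    values: np.ndarray
    kind: str = "distance"  # {"similarity", "distance"}
    units: str = "unitless"

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n},{n})")
        off = ~np.eye(n, dtype=bool)
        a, b = self.values, self.values.T
        both = off & np.isfinite(a) & np.isfinite(b)
        if not np.allclose(a[both], b[both], rtol=0, atol=0):
            raise ValueError("matrix is not symmetric")
        if not np.array_equal(np.isnan(a) & off, np.isnan(b) & off):
            raise ValueError("asymmetric missingness pattern")
        if self.kind not in ("similarity", "distance"):
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def n(self) -> int:
        return len(self.ids)

    def align(self, ids: list[str]) -> "PairwiseMatrix":
        """Return a copy restricted/reordered to ``ids``."""
        idx = [self.ids.index(str(i)) for i in ids]
        return PairwiseMatrix(
            [self.ids[i] for i in idx],
            self.values[np.ix_(idx, idx)].copy(),
            self.kind,
            self.units,
        )

    def upper_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the upper triangle (i < j)."""
        return np.triu_indices(self.n, k=1)


def write_matrix_csv(m: PairwiseMatrix, path) -> None:
    vals = m.values.copy().astype(object)
    np.fill_diagonal(vals, np.nan)
    df = pd.DataFrame(m.values, index=m.ids, columns=m.ids)
    np.fill_diagonal(df.values, np.nan)
    df.to_csv(path, na_rep="NA", float_format="%.12g")


def read_matrix_csv(path, kind: str = "distance", units: str = "unitless") -> PairwiseMatrix:
    df = pd.read_csv(path, index_col=0, na_values=["NA"], comment="#")
    ids = [str(i) for i in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ValueError(f"{path}: row and column ids differ")
    return PairwiseMatrix(ids, df.to_numpy(dtype=float), kind, units)
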