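"""Labeled symmetric pairwise matrices (relatedness, acoustic distance)."""

from __future__ import annotations

import numpy as np
import pandas as pd


class PairwiseMatrix:
    """Symmetric individual x individual matrix with row/column labels.

    The diagonal is not meaningful for dyadic statistics and defaults to 0;
    entries may be NaN (e.g. a dyad with no co-typed loci).
    """

    def __init__(self, labels: list[str], values: np.ndarray, check_symmetry: bool = True):
        values = np.asarray(values, dtype=float)
        n = len(labels)
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} does not match {n} labels")
        if len(set(labels)) != n:
            raise ValueError("labels must be unique")
        if check_symmetry:
            finite = np.isfinite(values)
            if not (finite == finite.T).all() or not np.allclose(
                values[finite & finite.T], values.T[finite & finite.T], atol=1e-9
            ):
                raise ValueError("matrix is not symmetric within 1e-9")
        self.labels = list(labels)
        self.values = values

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i < j) entries as a flat dyad vector."""
        iu = np.triu_indices(self.n, 1)
        return self.values[iu]

    def dyads(self) -> list[tuple[str, str]]:
        iu = np.triu_indices(self.n, 1)
        return [(self.labels[i], self.labels[j]) for i, j in zip(*iu)]

    def reorder(self, labels: list[str]) -> "PairwiseMatrix":
        idx = [self.labels.index(l) for l in labels]
        return PairwiseMatrix(list(labels), self.values[np.ix_(idx, idx)],
                              check_symmetry=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path, check_symmetry: bool = True) -> "PairwiseMatrix":
        df = pd.read_csv(path, index_col=0, comment="#")
        return cls([str(c) for c in df.columns], df.to_numpy(float),
                   check_symmetry=check_symmetry)
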