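"""Mantel matrix-permutation test and acoustic distance matrices.

The test statistic Z is the cross-product sum of two symmetric matrices
over dyads; r is the Pearson correlation of the dyad vectors; g is Z
standardized by its exact permutational moments, (Z - E[Z]) / sqrt(Var[Z]).
Significance comes from jointly permuting the rows and columns of one
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrices import PairwiseMatrix

__all__ = ["MantelResult", "MantelTest", "mantel_test", "acoustic_distance_matrix"]


def acoustic_distance_matrix(mean_scores: pd.Series | dict) -> PairwiseMatrix:
    """Pairwise acoustic distances from per-individual mean PC scores.

    With a single component the Euclidean distance is simply
    ``|mean_i - mean_j|``.  Input maps individual id -> mean score (e.g.
    ``PCAResult.mean_scores()``).
    """
    s = pd.Series(mean_scores)
    if s.isna().any():
        bad = s[s.isna()].index.tolist()
        raise ValueError(f"individuals without scored calls: {bad}")
    labels = [str(i) for i in s.index]
    v = s.to_numpy(float)
    return PairwiseMatrix(labels, np.abs(v[:, None] - v[None, :]))


def _moment_sums(M: np.ndarray) -> tuple[float, float, float]:
    """(G, H, K): dyad sum, dyad square sum, sum of squared row sums."""
    n = M.shape[0]
    iu = np.triu_indices(n, 1)
    G = float(M[iu].sum())
    H = float((M[iu] ** 2).sum())
    K = float((M.sum(axis=1) ** 2).sum())
    return G, H, K


def _permutation_moments(X: np.ndarray, Y: np.ndarray) -> tuple[float, float]:
    """Exact mean and variance of the upper-triangle Z under uniform random
    relabeling of one matrix.

    Derived by splitting the double sum over dyad pairs into identical,
    one-shared-index and disjoint configurations; each class is uniform
    over the corresponding configurations of the permuted matrix.
    """
    n = X.shape[0]
    d = n * (n - 1) / 2.0
    Gx, Hx, Kx = _moment_sums(X)
    Gy, Hy, Ky = _moment_sums(Y)
    EZ = Gx * Gy / d
    Tx, Ty = Kx - 2.0 * Hx, Ky - 2.0 * Hy
    Dx = Gx**2 + Hx - Kx
    Dy = Gy**2 + Hy - Ky
    EZ2 = (
        Hx * Hy / d
        + Tx * Ty / (n * (n - 1) * (n - 2))
        + Dx * Dy / (d * (d - 1 - 2 * (n - 2)))
    )
    return EZ, EZ2 - EZ**2


@dataclass
class MantelResult:
    """Observed statistics, permutational moments and permutation p-value."""

    z: float
    r: float
    g: float
    expected_z: float
    var_z: float
    p_value: float
    n_permutations: int
    tail: str
    sum_convention: str  # "full" (double sum) or "upper" (i < j only)
    moments: str  # "closed" or "permutation"
    seed: int | None

    def summary(self) -> str:
        return (
            "Mantel matrix-permutation test\n"
            f"  Z = {self.z:.4g} ({self.sum_convention} sum; "
            f"E[Z] = {self.expected_z:.4g}, SD = {np.sqrt(self.var_z):.4g})\n"
            f"  r = {self.r:.4f}\n"
            f"  g = {self.g:.4f} ({self.moments} moments)\n"
            f"  p = {self.p_value:.4g} ({self.tail}-tailed, "
            f"{self.n_permutations} permutations)"
        )


class MantelTest:
    """Association between two labeled symmetric matrices.

    ``sum_convention`` controls whether Z sums every ordered cell (``full``,
    the double sum, the default) or the upper triangle only (``upper``);
    r, g and the p-value are identical under both, only the printed Z
    scales by two.
    """

    def __init__(
        self,
        X: PairwiseMatrix,
        Y: PairwiseMatrix,
        sum_convention: str = "full",
    ):
        if sorted(X.labels) != sorted(Y.labels):
            raise ValueError("matrices must carry the same labels")
        if X.n < 4:
            raise ValueError("Mantel test needs at least 4 individuals")
        if sum_convention not in ("full", "upper"):
            raise ValueError("sum_convention must be 'full' or 'upper'")
        Y = Y.reorder(X.labels)
        for M, name in ((X, "X"), (Y, "Y")):
            vals = M.values[np.triu_indices(M.n, 1)]
            if np.isnan(vals).any():
                raise ValueError(f"matrix {name} contains NaN dyads")
        self.X = X
        self.Y = Y
        self.sum_convention = sum_convention

    def fit(
        self,
        n_permutations: int = 1000,
        tail: str = "auto",
        seed: int | None = None,
        moments: str = "closed",
    ) -> MantelResult:
        """Run the permutation test.

        ``tail='auto'`` tests in the direction of the observed deviation of
        Z from its permutational expectation (the directional hypothesis);
        ``'lower'``, ``'upper'`` and ``'two'`` are available.  ``moments``
        selects closed-form permutational moments for g (deterministic,
        default) or the Monte-Carlo mean/SD of the permutation sample.
        """
        if tail not in ("auto", "lower", "upper", "two"):
            raise ValueError(f"unknown tail {tail!r}")
        rng = np.random.default_rng(seed)
        Xv, Yv = self.X.values, self.Y.values
        n = self.X.n
        iu = np.triu_indices(n, 1)
        x, y = Xv[iu], Yv[iu]

        z_upper = float(np.sum(x * y))
        r = float(np.corrcoef(x, y)[0, 1])
        EZ, VZ = _permutation_moments(Xv, Yv)

        perm_z = np.empty(n_permutations)
        for k in range(n_permutations):
            p = rng.permutation(n)
            perm_z[k] = np.sum(Xv[np.ix_(p, p)][iu] * y)

        if moments == "closed":
            ez, vz = EZ, VZ
        elif moments == "permutation":
            ez, vz = float(perm_z.mean()), float(perm_z.var(ddof=0))
        else:
            raise ValueError("moments must be 'closed' or 'permutation'")
        g = (z_upper - ez) / np.sqrt(vz)

        if tail == "auto":
            tail = "lower" if z_upper <= EZ else "upper"
        if tail == "lower":
            extreme = perm_z <= z_upper
        elif tail == "upper":
            extreme = perm_z >= z_upper
        else:
            extreme = np.abs(perm_z - EZ) >= abs(z_upper - EZ)
        p_value = (extreme.sum() + 1.0) / (n_permutations + 1.0)

        scale = 2.0 if self.sum_convention == "full" else 1.0
        return MantelResult(
            z=scale * z_upper,
            r=r,
            g=float(g),
            expected_z=scale * ez,
            var_z=scale**2 * vz,
            p_value=float(p_value),
            n_permutations=n_permutations,
            tail=tail,
            sum_convention=self.sum_convention,
            moments=moments,
            seed=seed,
        )


def mantel_test(
    X: PairwiseMatrix,
    Y: PairwiseMatrix,
    n_permutations: int = 1000,
    tail: str = "auto",
    seed: int | None = None,
    **kwargs,
) -> MantelResult:
    """Functional shorthand for ``MantelTest(X, Y).fit(...)``."""
    conv = kwargs.pop("sum_convention", "full")
    return MantelTest(X, Y, sum_convention=conv).fit(
        n_permutations=n_permutations, tail=tail, seed=seed, **kwargs
    )
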