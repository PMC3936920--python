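"""Nested permuted discriminant function analysis (pDFA).

Classifies calls by kin group with a linear discriminant on the chosen
predictors and leave-one-out cross-validation, and assesses significance by
permuting *individuals* (the control factor) between kin groups — all of an
individual's calls move together, which respects the non-independence of
repeated calls from the same animal.  The chance level is the mean
correct-classification rate over permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NestedPDFA", "PDFAResult", "lda_loo_correct"]


def _loo_correct_1d(x: np.ndarray, labels: np.ndarray, n_groups: int) -> np.ndarray:
    """Leave-one-call-out nearest-group-mean classification for a single
    predictor.

    With one predictor, a pooled-covariance LDA under equal priors reduces
    to classifying each call to the group with the nearest mean (the common
    within-group variance cancels), so the leave-one-out fit only requires
    removing the held-out call from its own group mean.  Ties break toward
    the lower group index (label order).

    Returns a boolean array: call correctly classified.
    """
    sums = np.bincount(labels, weights=x, minlength=n_groups)
    counts = np.bincount(labels, minlength=n_groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    M = np.broadcast_to(means, (len(x), n_groups)).copy()
    own_count = counts[labels]
    denom = np.maximum(own_count - 1, 1)
    own_mean_loo = np.where(own_count > 1, (sums[labels] - x) / denom, np.inf)
    M[np.arange(len(x)), labels] = own_mean_loo
    dist = np.abs(x[:, None] - M)
    pred = np.argmin(dist, axis=1)  # first minimum = lowest label order
    return pred == labels


def _loo_correct_nd(X: np.ndarray, labels: np.ndarray, n_groups: int) -> np.ndarray:
    """Generic leave-one-call-out LDA (pooled within-group covariance,
    equal priors): each call is classified by a discriminant refitted on
    all other calls."""
    n = len(X)
    correct = np.zeros(n, dtype=bool)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xi, yi = X[mask], labels[mask]
        means = np.vstack([
            Xi[yi == g].mean(axis=0) if (yi == g).any() else np.full(X.shape[1], np.inf)
            for g in range(n_groups)
        ])
        resid = Xi - means[yi]
        cov = (resid.T @ resid) / max(len(Xi) - n_groups, 1)
        try:
            cov_inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular pooled within-group covariance") from exc
        d = X[i] - means
        maha = np.einsum("gj,jk,gk->g", d, cov_inv, d)
        correct[i] = int(np.argmin(maha)) == labels[i]
    return correct


def lda_loo_correct(
    X: np.ndarray,
    groups: np.ndarray | list,
    return_table: bool = False,
):
    """Leave-one-out correct-classification rate of a pooled-covariance LDA.

    ``X`` is (n_calls, n_predictors) (a 1-D array is treated as a single
    predictor); ``groups`` the per-call class labels.  Returns the percent
    correct, optionally with a per-call table of true label and hit/miss.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    group_labels, y = np.unique(np.asarray(groups), return_inverse=True)
    if len(group_labels) < 2:
        raise ValueError("need at least two groups")
    if X.shape[1] == 1:
        correct = _loo_correct_1d(X[:, 0], y, len(group_labels))
    else:
        correct = _loo_correct_nd(X, y, len(group_labels))
    pct = 100.0 * correct.mean()
    if return_table:
        table = pd.DataFrame({"group": group_labels[y], "correct": correct})
        return pct, table
    return pct


@dataclass
class PDFAResult:
    """Outcome of a nested pDFA run."""

    observed_correct: float  # % of calls correctly cross-classified
    chance_level: float  # mean permuted correct %
    p_value: float  # add-one permutation p
    n_permutations: int
    seed: int | None
    classification: pd.DataFrame  # per-call: id, group, correct
    permuted_correct: np.ndarray  # permutation distribution (percent)

    def summary(self) -> str:
        return (
            "Nested permuted discriminant function analysis\n"
            f"  calls: {len(self.classification)}, "
            f"groups: {self.classification['group'].nunique()}\n"
            f"  correctly cross-classified: {self.observed_correct:.1f}%\n"
            f"  chance level (mean of {self.n_permutations} permutations): "
            f"{self.chance_level:.1f}%\n"
            f"  p = {self.p_value:.4g}"
        )

    def by_individual(self) -> pd.DataFrame:
        """Percent of each individual's calls classified correctly."""
        return (
            self.classification.groupby(["group", "id"])["correct"]
            .mean()
            .mul(100.0)
            .rename("correct_pct")
            .reset_index()
        )


class NestedPDFA:
    """Discriminant analysis of calls by kin group with individual as the
    nested control factor.

    Parameters
    ----------
    data : call-level DataFrame with predictor column(s), an individual id
        column and a kin-group column.  Every individual must belong to
        exactly one kin group.
    predictors : predictor column names; the count may not exceed the
        smallest group size in individuals minus one (the discriminant-
        analysis identifiability constraint), which in the target design
        means a single principal component.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        predictors: list[str] | str = "PC1",
        group_col: str = "group",
        id_col: str = "id",
    ):
        if isinstance(predictors, str):
            predictors = [predictors]
        self.predictors = list(predictors)
        for c in [*self.predictors, group_col, id_col]:
            if c not in data.columns:
                raise ValueError(f"column {c!r} missing from call table")
        data = data.reset_index(drop=True)
        per_ind = data.groupby(id_col)[group_col].nunique()
        if (per_ind > 1).any():
            bad = per_ind[per_ind > 1].index.tolist()
            raise ValueError(f"individuals with calls in several groups: {bad}")

        self.data = data
        self.group_col = group_col
        self.id_col = id_col
        ind_group = data.drop_duplicates(id_col).set_index(id_col)[group_col]
        self.individuals = ind_group.index.to_numpy()
        self.ind_groups = ind_group.to_numpy()
        groups, sizes = np.unique(self.ind_groups, return_counts=True)
        if len(groups) < 2:
            raise ValueError("need at least two kin groups")
        if len(self.individuals) < len(groups):
            raise ValueError("fewer individuals than groups")
        if len(self.predictors) > sizes.min() - 1:
            raise ValueError(
                f"{len(self.predictors)} predictors exceed the limit of "
                f"{sizes.min() - 1} (smallest group has {sizes.min()} individuals)"
            )

    def _correct_pct(self, ind_to_group: dict) -> float:
        y = self.data[self.id_col].map(ind_to_group)
        X = self.data[self.predictors].to_numpy(float)
        return lda_loo_correct(X, y.to_numpy())

    def fit(self, n_permutations: int = 10_000, seed: int | None = None) -> PDFAResult:
        """Observed cross-validated classification rate, permutation-based
        chance level and p-value.

        Each permutation reassigns whole individuals to kin groups,
        preserving the observed distribution of group sizes (in
        individuals); p uses the add-one convention
        ``(#{permuted >= observed} + 1) / (n + 1)``.
        """
        if n_permutations < 100:
            raise ValueError("n_permutations must be at least 100")
        rng = np.random.default_rng(seed)

        X = self.data[self.predictors].to_numpy(float)
        if X.shape[1] == 1:
            x = X[:, 0]
        group_labels, y_ind = np.unique(self.ind_groups, return_inverse=True)
        n_groups = len(group_labels)
        # per-call individual index
        ind_index = {ind: k for k, ind in enumerate(self.individuals)}
        call_ind = self.data[self.id_col].map(ind_index).to_numpy()

        def correct_pct(y_ind_perm: np.ndarray) -> tuple[float, np.ndarray]:
            call_labels = y_ind_perm[call_ind]
            if X.shape[1] == 1:
                correct = _loo_correct_1d(x, call_labels, n_groups)
            else:
                correct = _loo_correct_nd(X, call_labels, n_groups)
            return 100.0 * correct.mean(), correct

        observed, correct = correct_pct(y_ind)
        permuted = np.empty(n_permutations)
        for k in range(n_permutations):
            permuted[k], _ = correct_pct(rng.permutation(y_ind))
        chance = float(permuted.mean())
        p = (np.sum(permuted >= observed) + 1.0) / (n_permutations + 1.0)

        classification = pd.DataFrame(
            {
                "id": self.data[self.id_col],
                "group": group_labels[y_ind[call_ind]],
                "correct": correct,
            }
        )
        return PDFAResult(
            observed_correct=float(observed),
            chance_level=chance,
            p_value=float(p),
            n_permutations=n_permutations,
            seed=seed,
            classification=classification,
            permuted_correct=permuted,
        )
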