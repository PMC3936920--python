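"""Agonistic-call acoustic parameters and correlation-matrix PCA.

Calls are rows of a DataFrame ("call table") carrying an individual id, a
series id and seven analysis parameters: three fundamental-frequency
measurements (F0S, F0Peak, F0E, in Hz), the start bandwidth (Hz), and three
temporal parameters (CallDuration, TimeToPeak, InterCallInterval, in ms).
The temporal parameters derive from raw time marks: S (call start), P
(fundamental-frequency peak), E (call end) and N (start of the next call in
the series).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: the seven parameters entering the PCA, in canonical order
ACOUSTIC_PARAMETERS = [
    "F0S",
    "F0Peak",
    "F0E",
    "StartBandwidth",
    "CallDuration",
    "TimeToPeak",
    "InterCallInterval",
]

FREQUENCY_PARAMETERS = ["F0S", "F0Peak", "F0E", "StartBandwidth"]
TEMPORAL_PARAMETERS = ["CallDuration", "TimeToPeak", "InterCallInterval"]


def derive_parameters(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute the four calculated parameters from raw measurements.

    ``raw`` needs columns F0S, F0Peak, F0E, SB_Max, SB_Min, S, P, E and
    optionally N (missing for the last call of a series).  Returns
    ``(calls, rejected)``: rows with E < S or N < E are moved to
    ``rejected`` with a ``reason`` column; a missing N leaves
    InterCallInterval missing but keeps the call.
    """
    required = ["F0S", "F0Peak", "F0E", "SB_Max", "SB_Min", "S", "P", "E"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"missing measured columns: {missing}")
    df = raw.copy()
    if "N" not in df.columns:
        df["N"] = np.nan

    bad_duration = df["E"] < df["S"]
    bad_interval = df["N"].notna() & (df["N"] < df["E"])
    reasons = np.select(
        [bad_duration, bad_interval],
        ["end before start (E < S)", "next call before end (N < E)"],
        default="",
    )
    rejected = df[bad_duration | bad_interval].copy()
    rejected["reason"] = reasons[(bad_duration | bad_interval).to_numpy()]
    df = df[~(bad_duration | bad_interval)].copy()

    df["StartBandwidth"] = df["SB_Max"] - df["SB_Min"]
    df["CallDuration"] = df["E"] - df["S"]
    df["TimeToPeak"] = df["P"] - df["S"]
    df["InterCallInterval"] = df["N"] - df["E"]
    return df, rejected


def impute_intercall_interval(calls: pd.DataFrame, id_col: str = "id") -> pd.DataFrame:
    """Fill missing InterCallInterval with the individual's median ICI.

    Series-final calls have no following call and hence no interval; the
    individual-median imputation keeps them in the PCA.  Imputed rows are
    flagged in a boolean ``ici_imputed`` column.
    """
    out = calls.copy()
    missing = out["InterCallInterval"].isna()
    out["ici_imputed"] = missing
    if missing.any():
        medians = out.groupby(id_col)["InterCallInterval"].transform("median")
        if medians[missing].isna().any():
            bad = out.loc[missing & medians.isna(), id_col].unique()
            raise ValueError(f"individuals with no observed intervals at all: {list(bad)}")
        out.loc[missing, "InterCallInterval"] = medians[missing]
    return out


def quartile_summary(
    calls: pd.DataFrame,
    by: str | list[str] | None = None,
    parameters: list[str] | None = None,
    interpolation: str = "linear",
) -> pd.DataFrame:
    """25%, 50% and 75% quantiles per parameter, pooled or per group.

    The quantile rule defaults to linear interpolation (numpy/R type 7);
    statistical packages differ here, so it is configurable.
    """
    parameters = parameters or [p for p in ACOUSTIC_PARAMETERS if p in calls.columns]
    quantiles = [0.25, 0.50, 0.75]

    def q(df: pd.DataFrame) -> pd.DataFrame:
        out = pd.DataFrame(
            {p: df[p].quantile(quantiles, interpolation=interpolation) for p in parameters}
        )
        out.index = pd.Index(["q25", "median", "q75"])
        return out.T

    if by is None:
        return q(calls)
    return calls.groupby(by, group_keys=True).apply(q, include_groups=False)


# --------------------------------------------------------------------------
# PCA on the correlation matrix
# --------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Fitted correlation-matrix PCA.

    ``loadings`` are parameter-component correlations (eigenvector scaled by
    the square root of its eigenvalue); ``scores`` are standardized to unit
    variance per retained component.  Component signs are fixed so that the
    parameter with the largest |loading| loads positive.
    """

    parameters: list[str]
    means: pd.Series
    sds: pd.Series
    eigenvalues: np.ndarray  # all p eigenvalues, descending
    loadings: pd.DataFrame  # parameters x retained components
    full_loadings: pd.DataFrame  # parameters x all components
    scores: pd.DataFrame  # calls x retained components (+ id/series columns)
    n_retained: int

    @property
    def variance_fractions(self) -> np.ndarray:
        return self.eigenvalues / len(self.parameters)

    def mean_scores(self, component: str = "PC1", id_col: str = "id") -> pd.Series:
        """Per-individual mean component score."""
        return self.scores.groupby(id_col)[component].mean()

    def summary(self) -> str:
        lines = ["Principal component analysis (correlation matrix)", ""]
        frac = self.variance_fractions
        for k in range(self.n_retained):
            lines.append(
                f"PC{k + 1}: eigenvalue {self.eigenvalues[k]:.3f}, "
                f"{100 * frac[k]:.1f}% of variance"
            )
        lines.append(
            f"retained {self.n_retained} components explaining "
            f"{100 * frac[: self.n_retained].sum():.1f}% of variance"
        )
        lines.append("")
        lines.append("Component loadings:")
        lines.append(self.loadings.round(3).to_string())
        return "\n".join(lines)

    def plot_scores(self, labels=None, ax=None):
        """Scatter of the first two retained components (or PC1 vs call index)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.scores["PC1"]
        y = self.scores["PC2"] if "PC2" in self.scores else np.arange(len(x))
        if labels is not None:
            for lab in pd.unique(labels):
                m = np.asarray(labels) == lab
                ax.scatter(x[m], y[m], label=str(lab), s=18)
            ax.legend(fontsize="small")
        else:
            ax.scatter(x, y, s=18)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2" if "PC2" in self.scores else "call index")
        return ax


class CallPCA:
    """Principal component analysis of the seven call parameters on the
    correlation matrix, with Kaiser (eigenvalue > 1) retention by default.

    Parameters
    ----------
    calls : DataFrame with the seven analysis parameters plus id/series.
    parameters : which columns enter the PCA (default the canonical seven).
    impute_ici : impute missing InterCallInterval by individual medians
        before fitting (series-final calls).
    """

    def __init__(
        self,
        calls: pd.DataFrame,
        parameters: list[str] | None = None,
        impute_ici: bool = True,
        id_col: str = "id",
    ):
        self.parameters = list(parameters or ACOUSTIC_PARAMETERS)
        missing = [p for p in self.parameters if p not in calls.columns]
        if missing:
            raise ValueError(f"call table lacks parameters: {missing}")
        if impute_ici and "InterCallInterval" in self.parameters:
            calls = impute_intercall_interval(calls, id_col=id_col)
        if calls[self.parameters].isna().any().any():
            bad = [p for p in self.parameters if calls[p].isna().any()]
            raise ValueError(f"missing values among PCA parameters: {bad}")
        if len(calls) < 2:
            raise ValueError("PCA needs at least 2 calls")
        self.calls = calls.reset_index(drop=True)
        self.id_col = id_col

    def fit(self, n_components: int | None = None) -> PCAResult:
        """Eigendecompose the correlation matrix.

        ``n_components=None`` applies the Kaiser criterion (eigenvalue > 1);
        an explicit count overrides it.
        """
        X = self.calls[self.parameters].to_numpy(float)
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        constant = [p for p, s in zip(self.parameters, sds) if s == 0]
        if constant:
            raise ValueError(
                f"constant parameter(s) {constant}: correlation undefined"
            )
        Z = (X - means) / sds
        R = np.corrcoef(Z, rowvar=False)
        eigval, eigvec = np.linalg.eigh(R)
        order = np.argsort(eigval)[::-1]
        eigval = np.clip(eigval[order], 0.0, None)
        eigvec = eigvec[:, order]

        p = len(self.parameters)
        load_all = eigvec * np.sqrt(eigval)
        # sign convention: largest-|loading| parameter loads positive
        for k in range(p):
            imax = int(np.argmax(np.abs(load_all[:, k])))
            if load_all[imax, k] < 0:
                load_all[:, k] *= -1
                eigvec[:, k] *= -1

        if n_components is None:
            n_retained = max(int(np.sum(eigval > 1.0)), 1)
        else:
            n_retained = int(n_components)

        comp_names = [f"PC{k + 1}" for k in range(p)]
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = np.where(eigval > 0, (Z @ eigvec) / np.sqrt(eigval), 0.0)
        score_df = pd.DataFrame(
            scores[:, :n_retained], columns=comp_names[:n_retained]
        )
        for c in (self.id_col, "series"):
            if c in self.calls.columns:
                score_df.insert(0, c, self.calls[c].to_numpy())

        return PCAResult(
            parameters=self.parameters,
            means=pd.Series(means, index=self.parameters),
            sds=pd.Series(sds, index=self.parameters),
            eigenvalues=eigval,
            loadings=pd.DataFrame(
                load_all[:, :n_retained],
                index=self.parameters,
                columns=comp_names[:n_retained],
            ),
            full_loadings=pd.DataFrame(
                load_all, index=self.parameters, columns=comp_names
            ),
            scores=score_df,
            n_retained=n_retained,
        )


def pca_correlation(calls: pd.DataFrame, **kwargs) -> PCAResult:
    """Functional shorthand for ``CallPCA(calls).fit()``."""
    n_components = kwargs.pop("n_components", None)
    return CallPCA(calls, **kwargs).fit(n_components=n_components)
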